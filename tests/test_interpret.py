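"""Occlusion sensitivity and architectural parameter oracles."""

import math
import warnings

import numpy as np
import pytest

from histoprog import interpret_architecture as ia
from histoprog import segmap as sm
from histoprog import survival_stats as ss
from histoprog import synthetic_data as sd
from histoprog.segmap import TissueClass

from conftest import random_label_map, small_slide_spec


class _LinearCountModel:
    """Surrogate: risk = sum_c w_c * count_c over GSM cells."""

    def __init__(self, weights):
        self.w = np.asarray(weights, dtype=float)

    def score_gsm(self, label_map):
        counts = np.bincount(label_map.grid.ravel(), minlength=6)
        return float(self.w @ counts)


class _ConstantModel:
    def score_gsm(self, label_map):
        return 3.14


class TestOcclusion:
    def test_constant_model_all_zero(self):
        rng = np.random.default_rng(0)
        lm = random_label_map(rng, shape=(12, 12))
        osm = ia.occlusion_map(_ConstantModel(), lm)
        assert np.allclose(osm.grid, 0.0)

    def test_linear_surrogate_matches_analytic_delta(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=6)
        model = _LinearCountModel(w)
        lm = random_label_map(rng, shape=(10, 10))
        cfg = ia.OcclusionConfig(window_cells=3, stride_cells=3)
        osm = ia.occlusion_map(model, lm, cfg)
        # analytic: delta(window) = sum_c w_c*(count_c^win) - w_BG*win_area
        expect = np.zeros(lm.shape)
        win = 3
        for r0 in (0, 3, 6, 7):
            for c0 in (0, 3, 6, 7):
                counts = np.bincount(
                    lm.grid[r0:r0 + win, c0:c0 + win].ravel(), minlength=6)
                delta = float(w @ counts) - w[0] * win * win
                expect[r0:r0 + win, c0:c0 + win] = 0  # filled below
        acc = np.zeros(lm.shape)
        cnt = np.zeros(lm.shape)
        for r0 in (0, 3, 6, 7):
            for c0 in (0, 3, 6, 7):
                counts = np.bincount(
                    lm.grid[r0:r0 + win, c0:c0 + win].ravel(), minlength=6)
                delta = float(w @ counts) - w[0] * win * win
                acc[r0:r0 + win, c0:c0 + win] += delta
                cnt[r0:r0 + win, c0:c0 + win] += 1
        assert np.abs(osm.grid - acc / cnt).max() < 1e-9

    def test_stride_equals_window_matches_brute_force(self):
        rng = np.random.default_rng(2)
        lm = random_label_map(rng, shape=(8, 8))

        class Quirky:
            def score_gsm(self, m):
                return float(np.sin(m.grid.astype(float)).sum()
                             + (m.grid == 5).sum() ** 2)

        model = Quirky()
        cfg = ia.OcclusionConfig(window_cells=4, stride_cells=4)
        osm = ia.occlusion_map(model, lm, cfg)
        base = model.score_gsm(lm)
        for r0 in (0, 4):
            for c0 in (0, 4):
                occ = lm.grid.copy()
                occ[r0:r0 + 4, c0:c0 + 4] = 0
                want = base - model.score_gsm(sm.LabelMap(occ))
                got = osm.grid[r0:r0 + 4, c0:c0 + 4]
                assert np.allclose(got, want)

    def test_window_larger_than_grid_rejected(self):
        rng = np.random.default_rng(3)
        lm = random_label_map(rng, shape=(4, 4))
        with pytest.raises(ValueError, match="window"):
            ia.occlusion_map(_ConstantModel(), lm,
                             ia.OcclusionConfig(window_cells=5, stride_cells=1))

    def test_stride_exceeding_window_rejected(self):
        with pytest.raises(ValueError):
            ia.OcclusionConfig(window_cells=2, stride_cells=3)


class TestSplitTLS:
    def _map_with_tls(self, tls_center):
        grid = np.full((40, 40), int(TissueClass.LT), np.uint8)
        grid[10:30, 10:30] = int(TissueClass.TT_P)
        y, x = tls_center
        grid[y - 2:y + 3, x - 2:x + 3] = int(TissueClass.TLS)
        return sm.LabelMap(grid)

    def test_central_tls_is_intra(self):
        intra, peri = ia.split_tls(self._map_with_tls((20, 20)))
        assert len(intra) == 1 and len(peri) == 0

    def test_distant_tls_is_peri(self):
        intra, peri = ia.split_tls(self._map_with_tls((35, 5)))
        assert len(intra) == 0 and len(peri) == 1

    def test_matches_generator_truth(self):
        hits = total = 0
        for seed in range(25):
            spec = small_slide_spec(n_tls_intra=2, n_tls_peri=2, seed=seed)
            lm, gt = sd.generate_label_map(spec)
            intra, peri = ia.split_tls(lm)
            want_intra = {tuple(np.round(c, 0)) for c in gt["tls_centroids_intra"]}
            got_intra = {tuple(np.round(c.centroid, 0)) for c in intra}
            total += 1
            hits += (len(intra) == 2 and len(peri) == 2)
        assert hits == total


class TestAreaRatio:
    def test_simple_ratio(self):
        grid = np.full((10, 1), int(TissueClass.TT_P), np.uint8)
        grid[:2, 0] = int(TissueClass.TLS)
        lm = sm.LabelMap(grid)
        assert ia.area_ratio(lm, TissueClass.TLS, TissueClass.TT_P) == pytest.approx(
            2 / 8)

    def test_absent_numerator_zero(self):
        grid = np.full((5, 5), int(TissueClass.TT_P), np.uint8)
        assert ia.area_ratio(sm.LabelMap(grid), TissueClass.HN,
                             TissueClass.TT_P) == 0.0

    def test_zero_denominator_missing(self):
        grid = np.full((5, 5), int(TissueClass.LT), np.uint8)
        assert math.isnan(ia.area_ratio(sm.LabelMap(grid), TissueClass.HN,
                                        TissueClass.TT_P))

    def test_matches_pixel_count_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            lm = random_label_map(rng, shape=(15, 15))
            got = ia.area_ratio(lm, TissueClass.HN,
                                [TissueClass.TT_P, TissueClass.TT_S])
            num = sum(1 for v in lm.grid.ravel() if v == 4)
            den = sum(1 for v in lm.grid.ravel() if v in (2, 3))
            if den == 0:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(num / den, abs=1e-12)


class TestDistributionVariance:
    def test_single_component_zero(self):
        comp = sm.Component(TissueClass.TLS, np.array([[1, 1]]), (1.0, 1.0), 1)
        assert ia.distribution_variance([comp], 100) == 0.0

    def test_two_centroids_closed_form(self):
        c1 = sm.Component(TissueClass.TLS, np.array([[0, 0]]), (0.0, 0.0), 1)
        c2 = sm.Component(TissueClass.TLS, np.array([[0, 6]]), (0.0, 6.0), 1)
        # distance d=6: expect d^2/(4*area)
        assert ia.distribution_variance([c1, c2], 144) == pytest.approx(
            36 / (4 * 144))

    def test_no_components_missing(self):
        assert math.isnan(ia.distribution_variance([], 100))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(1, 6))
            cents = rng.uniform(0, 20, size=(k, 2))
            comps = [sm.Component(TissueClass.HN, np.zeros((1, 2), int),
                                  tuple(c), 1) for c in cents]
            got = ia.distribution_variance(comps, 400)
            bary = cents.mean(axis=0)
            want = np.mean(((cents - bary) ** 2).sum(axis=1)) / 400
            assert got == pytest.approx(want, abs=1e-12)


class TestMarginSmoothness:
    def test_square_is_smooth(self):
        grid = np.full((60, 60), int(TissueClass.LT), np.uint8)
        grid[15:45, 15:45] = int(TissueClass.TT_P)
        assert ia.margin_smoothness(sm.LabelMap(grid)) >= 0.95

    def test_disc_smoother_than_star(self):
        def make(shape_fn):
            grid = np.full((120, 120), int(TissueClass.LT), np.uint8)
            rr, cc = np.mgrid[0:120, 0:120]
            grid[shape_fn(rr - 60.0, cc - 60.0)] = int(TissueClass.TT_P)
            return sm.LabelMap(grid)

        disc = make(lambda y, x: np.hypot(y, x) <= 40)
        star = make(lambda y, x: np.hypot(y, x)
                    <= 40 * (1 + 0.45 * np.sin(8 * np.arctan2(y, x))) * 0.82)
        assert (ia.margin_smoothness(disc) > ia.margin_smoothness(star))

    def test_tracks_planted_irregularity(self):
        from scipy import stats as sps

        amps, scores = [], []
        for i, amp in enumerate(np.linspace(0.0, 0.22, 25)):
            lm, _ = sd.generate_label_map(
                small_slide_spec(boundary_irregularity=float(amp),
                                 n_tls_intra=0, n_tls_peri=0, seed=100 + i))
            amps.append(amp)
            scores.append(1 - ia.margin_smoothness(lm))
        rho, _ = sps.spearmanr(amps, scores)
        assert rho >= 0.8


class TestTLSMarginDistances:
    def test_straight_margin_distance(self):
        grid = np.full((20, 30), int(TissueClass.LT), np.uint8)
        grid[:, 15:] = int(TissueClass.TT_P)  # margin at column 15
        grid[10, 5] = int(TissueClass.TLS)
        d = ia.tls_margin_distances(sm.LabelMap(grid))
        assert d == [10.0]  # centroid (10,5) to boundary column 15

    def test_centroid_on_boundary_zero(self):
        grid = np.full((20, 20), int(TissueClass.LT), np.uint8)
        grid[5:15, 5:15] = int(TissueClass.TT_P)
        grid[5, 5] = int(TissueClass.TLS)
        # TLS replaces a boundary pixel; its centroid is adjacent to margin
        d = ia.tls_margin_distances(sm.LabelMap(grid))
        assert min(d) <= 1.0

    def test_no_tls_empty(self):
        grid = np.full((10, 10), int(TissueClass.TT_P), np.uint8)
        assert ia.tls_margin_distances(sm.LabelMap(grid)) == []

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(40):
            lm = random_label_map(rng, shape=(14, 14), classes=(1, 2, 5))
            if not (lm.grid == 2).any() or not (lm.grid == 5).any():
                continue
            got = ia.tls_margin_distances(lm)
            tumor = ia.filled_tumor_mask(lm)
            boundary = sm.boundary_of_mask(tumor)
            bp = np.column_stack(np.nonzero(boundary))
            if bp.size == 0:
                continue
            comps = sm.connected_components(lm, TissueClass.TLS)
            for comp, d in zip(comps, got):
                want = min(np.hypot(comp.centroid[0] - r, comp.centroid[1] - c)
                           for r, c in bp)
                assert d == pytest.approx(want, abs=1e-9)
            checked += 1
        assert checked >= 10


class TestInvariances:
    def test_translation_invariance_of_parameters(self):
        lm, _ = sd.generate_label_map(small_slide_spec(seed=8))
        # embed in a larger canvas at two offsets
        def embed(offset):
            big = np.zeros((lm.shape[0] + 40, lm.shape[1] + 40), np.uint8)
            big[offset:offset + lm.shape[0],
                offset:offset + lm.shape[1]] = lm.grid
            return sm.LabelMap(big)

        fv1 = ia.architectural_features(embed(5)).as_dict()
        fv2 = ia.architectural_features(embed(25)).as_dict()
        for k in fv1:
            if math.isnan(fv1[k]):
                assert math.isnan(fv2[k])
            else:
                assert fv1[k] == pytest.approx(fv2[k], abs=1e-9), k

    def test_ratio_invariance_under_integer_upscaling(self):
        rng = np.random.default_rng(7)
        lm = random_label_map(rng, shape=(12, 12))
        up = sm.LabelMap(np.kron(lm.grid, np.ones((3, 3), np.uint8)))
        for num, den in [(TissueClass.HN, [TissueClass.TT_P, TissueClass.TT_S]),
                         (TissueClass.TLS, TissueClass.LT)]:
            a = ia.area_ratio(lm, num, den)
            b = ia.area_ratio(up, num, den)
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-12)


@pytest.fixture(scope="module")
def planted_table():
    cohort = sd.CohortSpec(
        n_patients=100, baseline_hazard=0.02,
        beta={"necrosis_ratio": 0.9, "intra_tls_ratio": -0.9}, seed=31)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        patients, slides, gt = sd.generate_cohort(
            cohort, small_slide_spec(), sd.RenderSpec())
    import pandas as pd

    rows = [ia.architectural_features(s.label_map).as_dict()
            for s in slides]
    feats = pd.DataFrame(rows)
    surv = ss.SurvivalData(gt["time_months"], gt["event"])
    return ia.feature_cox_table(feats, surv)


class TestFeatureCoxTable:
    def test_necrosis_harmful(self, planted_table):
        row = planted_table.set_index("feature").loc["ratio_hn_TT"]
        assert row["hr"] > 1 and row["p"] < 0.05

    def test_intra_tls_protective(self, planted_table):
        row = planted_table.set_index("feature").loc["ratio_tls_intra_TT"]
        assert row["hr"] < 1 and row["p"] < 0.05

    def test_table_columns(self, planted_table):
        assert {"feature", "hr", "ci_low", "ci_high", "p"} <= set(
            planted_table.columns)
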