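"""Tile grid, GSM assembly, geometry and I/O round trips."""

import numpy as np
import pytest

from histoprog import segmap as sm
from histoprog import synthetic_data as sd
from histoprog.segmap import TissueClass

from conftest import random_label_map


class TestTissueMask:
    def test_pure_white_all_background(self):
        img = np.full((32, 32, 3), 255, np.uint8)
        with pytest.warns(UserWarning):
            mask = sm.tissue_mask(img)
        assert mask.sum() == 0

    def test_bimodal_image_splits_exactly(self):
        img = np.full((20, 40, 3), 255, np.uint8)
        img[:, :20] = (80, 40, 120)
        mask = sm.tissue_mask(img)
        assert mask[:, :20].all() and not mask[:, 20:].any()

    def test_otsu_threshold_matches_exhaustive_oracle(self):
        # 8 saturation levels; compare skimage's cut with brute force
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(0)
        vals = rng.choice(np.linspace(0.05, 0.95, 8), size=500)
        thr = threshold_otsu(vals, nbins=8)
        # brute force: maximize between-class variance over candidate cuts
        best, best_var = None, -1
        for cut in np.unique(vals)[:-1]:
            lo, hi = vals[vals <= cut], vals[vals > cut]
            w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best, best_var = cut, var
        lo_count = (vals <= thr).sum()
        assert lo_count == (vals <= best).sum()


class TestTileGrid:
    @pytest.mark.parametrize("h,w,size,expected", [
        (512, 512, 256, 4),
        (600, 600, 256, 4),
        (1024, 768, 256, 12),
    ])
    def test_counts(self, h, w, size, expected):
        assert len(sm.tile_grid(h, w, size)) == expected

    def test_row_major_order_and_corners(self):
        refs = sm.tile_grid(1024, 768, 256)
        assert (refs[0].row0, refs[0].col0) == (0, 0)
        assert (refs[-1].row0, refs[-1].col0) == (768, 512)

    def test_too_small_slide_warns_empty(self):
        with pytest.warns(UserWarning):
            assert sm.tile_grid(100, 100, 256) == []


class TestAssembleGSM:
    def test_uniform_probabilities(self):
        refs = sm.tile_grid(512, 512, 256, slide_id="s")
        probs = np.tile([0, 1.0, 0, 0, 0, 0], (4, 1))
        gsm = sm.assemble_gsm(refs, probs)
        assert (gsm.grid == int(TissueClass.LT)).all()
        assert gsm.cell_size_px == 256

    def test_tie_breaks_to_lowest_code(self):
        refs = sm.tile_grid(256, 256, 256, slide_id="s")
        probs = np.array([[0, 0.5, 0, 0, 0, 0.5]])
        gsm = sm.assemble_gsm(refs, probs)
        assert gsm.grid[0, 0] == int(TissueClass.LT)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        refs = sm.tile_grid(1024, 768, 256, slide_id="s")
        probs = rng.dirichlet(np.ones(6), size=len(refs))
        gsm = sm.assemble_gsm(refs, probs)
        perm = rng.permutation(len(refs))
        gsm2 = sm.assemble_gsm([refs[i] for i in perm], probs[perm])
        assert np.array_equal(gsm.grid, gsm2.grid)

    def test_majority_oracle_on_synthetic_truth(self, small_map):
        lm, _ = small_map
        gsm = sd.oracle_gsm(lm, 8)
        # direct tile-majority downsample oracle
        h, w = lm.shape
        expect = np.zeros((h // 8, w // 8), np.uint8)
        for r in range(h // 8):
            for c in range(w // 8):
                win = lm.grid[r * 8:(r + 1) * 8, c * 8:(c + 1) * 8]
                counts = np.bincount(win.ravel(), minlength=6)
                expect[r, c] = counts.argmax()
        assert np.array_equal(gsm.grid, expect)

    def test_mixed_slides_rejected(self):
        r1 = sm.TileRef("a", 0, 0, 256)
        r2 = sm.TileRef("b", 0, 256, 256)
        with pytest.raises(ValueError, match="mixed"):
            sm.assemble_gsm([r1, r2], np.tile([1.0, 0, 0, 0, 0, 0], (2, 1)))


def _flood_fill_components(mask):
    """8-connectivity flood-fill oracle; returns list of pixel sets."""
    seen = np.zeros_like(mask, bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < h and 0 <= xx < w
                                    and mask[yy, xx] and not seen[yy, xx]):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(comp)
    return comps


class TestConnectedComponents:
    def test_single_block(self):
        grid = np.zeros((8, 10), np.uint8)
        grid[2:5, 5:8] = int(TissueClass.TLS)
        comps = sm.connected_components(sm.LabelMap(grid), TissueClass.TLS)
        assert len(comps) == 1
        assert comps[0].centroid == (3.0, 6.0)
        assert comps[0].area_px == 9

    def test_diagonal_touching_is_one_component(self):
        grid = np.zeros((4, 4), np.uint8)
        grid[1, 1] = grid[2, 2] = int(TissueClass.TLS)
        comps = sm.connected_components(sm.LabelMap(grid), TissueClass.TLS)
        assert len(comps) == 1

    def test_absent_class_empty(self):
        comps = sm.connected_components(
            sm.LabelMap(np.zeros((4, 4), np.uint8)), TissueClass.HN)
        assert comps == []

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            lm = random_label_map(rng, shape=(16, 16), classes=(0, 5))
            comps = sm.connected_components(lm, TissueClass.TLS)
            oracle = _flood_fill_components(lm.grid == 5)
            got = sorted(
                [frozenset(map(tuple, c.pixels.tolist())) for c in comps],
                key=lambda s: min(s))
            want = sorted([frozenset(c) for c in oracle], key=lambda s: min(s))
            assert got == want


class TestBoundaryPixels:
    def test_full_map_has_no_boundary(self):
        grid = np.full((10, 10), int(TissueClass.TT_P), np.uint8)
        b = sm.boundary_pixels(sm.LabelMap(grid), TissueClass.TT_P)
        assert b.sum() == 0

    def test_square_perimeter(self):
        grid = np.full((10, 10), int(TissueClass.LT), np.uint8)
        grid[3:7, 3:7] = int(TissueClass.TT_P)
        b = sm.boundary_pixels(sm.LabelMap(grid), TissueClass.TT_P)
        assert b.sum() == 12  # 4x4 square: all but the 2x2 interior

    def test_matches_neighbor_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            lm = random_label_map(rng, shape=(12, 12), classes=(0, 1, 2))
            region = lm.grid == 2
            if not region.any():
                continue
            b = sm.boundary_pixels(lm, TissueClass.TT_P)
            h, w = region.shape
            oracle = np.zeros_like(region)
            for r in range(h):
                for c in range(w):
                    if not region[r, c]:
                        continue
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = r + dy, c + dx
                            if (0 <= yy < h and 0 <= xx < w
                                    and not region[yy, xx]):
                                oracle[r, c] = True
            assert np.array_equal(b, oracle)

    def test_absent_region_warns_empty(self):
        grid = np.zeros((5, 5), np.uint8)
        with pytest.warns(UserWarning):
            b = sm.boundary_pixels(sm.LabelMap(grid), TissueClass.TLS)
        assert b.sum() == 0


class TestSampleTiles:
    def _map(self):
        rng = np.random.default_rng(4)
        return random_label_map(rng, shape=(20, 20))

    def test_parenchyma_only_postcondition(self):
        refs = sm.sample_tiles(self._map(), "parenchyma_only", 10, seed=0)
        assert all(r.label == TissueClass.TT_P for r in refs)

    def test_exhaustive_when_exact_count(self):
        grid = np.zeros((8, 8), np.uint8)
        coords = [(r, c) for r in range(4) for c in range(8)]
        for r, c in coords:
            grid[r, c] = int(TissueClass.TT_P)
        lm = sm.LabelMap(grid)
        refs = sm.sample_tiles(lm, "parenchyma_only", 32, seed=1)
        assert len({(r.row0, r.col0) for r in refs}) == 32

    def test_replacement_fallback_warns(self):
        grid = np.zeros((4, 4), np.uint8)
        grid[0, 0] = int(TissueClass.TT_P)
        with pytest.warns(UserWarning, match="replacement"):
            refs = sm.sample_tiles(sm.LabelMap(grid), "parenchyma_only", 5,
                                   seed=0)
        assert len(refs) == 5

    def test_zero_eligible_raises(self):
        grid = np.zeros((4, 4), np.uint8)
        with pytest.raises(sm.SamplingError, match="parenchyma_only"):
            sm.sample_tiles(sm.LabelMap(grid), "parenchyma_only", 1, seed=0)

    def test_seed_reproducibility(self):
        lm = self._map()
        a = sm.sample_tiles(lm, "global_random", 20, seed=9)
        b = sm.sample_tiles(lm, "global_random", 20, seed=9)
        assert a == b

    def test_selection_frequencies_uniform(self):
        lm = self._map()
        eligible = int(np.isin(lm.grid, [1, 2, 3, 4, 5]).sum())
        counts = {}
        n_draw, per = 2000, 5
        for s in range(n_draw):
            for r in sm.sample_tiles(lm, "global_random", per, seed=s):
                counts[(r.row0, r.col0)] = counts.get((r.row0, r.col0), 0) + 1
        total = n_draw * per
        p = 1 / eligible
        sd3 = 3 * np.sqrt(total * p * (1 - p))
        observed = np.array(list(counts.values()))
        assert len(counts) == eligible
        assert np.all(np.abs(observed - total * p) < sd3 + 3)


class TestLabelMapIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(5)
        lm = random_label_map(rng, shape=(30, 17))
        lm.cell_size_px = 8
        lm.scale = 4.0
        path = tmp_path / "map.png"
        sm.write_label_map(lm, path)
        back = sm.read_label_map(path)
        assert np.array_equal(back.grid, lm.grid)
        assert back.cell_size_px == 8 and back.scale == 4.0

    def test_missing_sidecar_raises(self, tmp_path):
        rng = np.random.default_rng(6)
        lm = random_label_map(rng)
        sm.write_label_map(lm, tmp_path / "m.png")
        (tmp_path / "m.png.json").unlink()
        with pytest.raises(sm.LabelMapFormatError, match="sidecar"):
            sm.read_label_map(tmp_path / "m.png")

    def test_permuted_legend_remapped(self, tmp_path):
        import json

        rng = np.random.default_rng(7)
        lm = random_label_map(rng, shape=(10, 10))
        path = tmp_path / "m.png"
        sm.write_label_map(lm, path)
        # permute the legend: swap LT and TLS codes in the sidecar
        sidecar = json.loads((tmp_path / "m.png.json").read_text())
        sidecar["legend"]["LT"], sidecar["legend"]["TLS"] = (
            sidecar["legend"]["TLS"], sidecar["legend"]["LT"])
        (tmp_path / "m.png.json").write_text(json.dumps(sidecar))
        back = sm.read_label_map(path)
        manual = lm.grid.copy()
        manual[lm.grid == 1] = 255  # temp
        manual[lm.grid == 5] = 5    # file code 5 is named LT -> 1
        manual = np.where(lm.grid == 1, 5, np.where(lm.grid == 5, 1, lm.grid))
        assert np.array_equal(back.grid, manual)

    def test_invalid_code_rejected(self):
        with pytest.raises(sm.LabelMapFormatError):
            sm.LabelMap(np.full((3, 3), 9, np.uint8))


class TestCohortCSV:
    def test_round_trip(self, tmp_path):
        patients = [
            sm.PatientRecord("P1", 12.5, 1, ["P1-S0", "P1-S1"], {"age": 61.0}),
            sm.PatientRecord("P2", 30.0, 0, ["P2-S0"], {"age": 47.0}),
        ]
        path = tmp_path / "cohort.csv"
        sm.write_cohort_csv(patients, path)
        back = sm.read_cohort_csv(path)
        assert [p.patient_id for p in back] == ["P1", "P2"]
        assert back[0].slide_ids == ["P1-S0", "P1-S1"]
        assert back[0].covariates["age"] == 61.0
        assert back[1].event == 0
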