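"""Shared fixtures: small synthetic slides, cohorts and helpers.

Everything is generated programmatically at test time from fixed
seeds; image sizes are kept small so the suite runs quickly on one
CPU.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from histoprog import risk_models as rm
from histoprog import segmap as sm
from histoprog import survival_stats as ss
from histoprog import synthetic_data as sd


def small_slide_spec(seed=0, **overrides) -> sd.SlideSpec:
    base = dict(height_px=192, width_px=192, tumor_axes=(60.0, 52.0),
                boundary_irregularity=0.10, n_tls_intra=2, n_tls_peri=2,
                tls_radius_px=8.0, necrosis_fraction=0.15,
                stroma_fraction=0.40, seed=seed)
    base.update(overrides)
    return sd.SlideSpec(**base)


def random_label_map(rng: np.random.Generator, shape=(24, 24),
                     classes=(0, 1, 2, 3, 4, 5)) -> sm.LabelMap:
    """Unstructured random map for oracle-equivalence tests."""
    grid = rng.choice(classes, size=shape).astype(np.uint8)
    return sm.LabelMap(grid=grid, cell_size_px=1, slide_id="rand")


@pytest.fixture(scope="session")
def small_map():
    lm, gt = sd.generate_label_map(small_slide_spec(seed=3))
    return lm, gt


@pytest.fixture(scope="session")
def render_spec():
    return sd.RenderSpec()


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient cohort with planted necrosis/TLS/nucleus-size hazard."""
    slide = small_slide_spec()
    render = sd.RenderSpec()
    cohort = sd.CohortSpec(
        n_patients=120, baseline_hazard=0.02,
        beta={"necrosis_ratio": 0.8, "intra_tls_ratio": -0.8,
              "nucleus_mean_area": 0.8},
        censor_rate_target=0.3, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        patients, slides, gt = sd.generate_cohort(cohort, slide, render)
    gsms = {s.slide_id: sd.oracle_gsm(s.label_map, 8) for s in slides}
    source = sd.CohortTileSource(slides, gt, render, seed=7)
    return {"patients": patients, "slides": slides, "gt": gt,
            "gsms": gsms, "source": source}


def survival_of(patients) -> ss.SurvivalData:
    return ss.SurvivalData([p.time_months for p in patients],
                           [p.event for p in patients])


def patient_scores(model, patients, gsms, source=None):
    out = []
    for p in patients:
        if source is None:
            vals = [model.score_slide(gsms[sid]) for sid in p.slide_ids]
        else:
            vals = [model.score_slide(gsms[sid], source) for sid in p.slide_ids]
        out.append(float(np.mean(vals)))
    return np.array(out)
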