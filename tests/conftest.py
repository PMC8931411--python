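import warnings

import numpy as np
import pytest

from cropxfer.synthetic_scene import (
    SceneConfig,
    draw_field_samples,
    generate_scene_series,
)

FEATURE_MODELS = {"nir": "cubic", "ndvi": "harmonic5", "ndwi": "gaussian"}


@pytest.fixture(scope="session")
def feature_models():
    return dict(FEATURE_MODELS)


def make_scene_pair(
    seed=1,
    grid=48,
    n_fields=64,
    rotation_rate=0.0,
    noise_sd=0.02,
    phase_shift_sd_days=10.0,
    missing_rate=0.1,
):
    cfg = SceneConfig(
        grid_rows=grid,
        grid_cols=grid,
        n_fields=n_fields,
        years=(2017, 2018),
        rotation_rate=rotation_rate,
        noise_sd=noise_sd,
        phase_shift_sd_days=phase_shift_sd_days,
        missing_rate=missing_rate,
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stacks, truth = generate_scene_series(cfg)
    return cfg, stacks, truth


@pytest.fixture(scope="session")
def small_scene():
    """48x48 two-year no-rotation scene with mild noise and gaps."""
    cfg, stacks, truth = make_scene_pair(seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = draw_field_samples(truth, 2017, 12, min_spacing_px=6, seed=3)
    return {"config": cfg, "stacks": stacks, "truth": truth, "samples": samples}


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, gap-free, shift-free scene pair for exact checks."""
    cfg, stacks, truth = make_scene_pair(
        seed=5, noise_sd=0.0, phase_shift_sd_days=0.0, missing_rate=0.0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = draw_field_samples(truth, 2017, 10, min_spacing_px=6, seed=4)
    return {"config": cfg, "stacks": stacks, "truth": truth, "samples": samples}


def purity(samples, truth, year):
    """Fraction of samples whose class matches the truth raster."""
    labels = truth.labels(year)
    hits = [
        truth.classes[labels[rec["row"], rec["col"]]] == rec["class"]
        for rec in samples.to_dict("records")
    ]
    return float(np.mean(hits)) if hits else np.nan
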