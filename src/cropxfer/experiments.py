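"""Reference end-to-end recovery experiments on synthetic scenes.

These drive the full transfer chain (simulate -> potential samples ->
screening -> classification) at a fixed benchmark geometry and report
recovery metrics: how often the selected neighbour is the same crop,
label purity before and after screening, class-proportion preservation,
the silhouette-optimal cluster count, and the accuracy gap between a
forest trained on generated samples and one trained on real target-year
samples.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classification, evaluation
from .sample_screening import screen_samples
from .similarity_transfer import select_potential_samples
from .synthetic_scene import SceneConfig, draw_field_samples, generate_scene_series

#: model winners used throughout the benchmark (one per similarity feature)
BENCH_FEATURE_MODELS = {"nir": "cubic", "ndvi": "harmonic5", "ndwi": "gaussian"}


@dataclass
class BenchConfig:
    grid: int = 128
    n_fields: int = 400
    n_per_class: int = 60
    min_spacing_px: int = 6
    rotation_rate: float = 0.0
    phase_shift_sd_days: float = 10.0
    noise_sd: float = 0.02
    missing_rate: float = 0.1
    k_max: int = 20
    window: int = 5


def _purity(samples: pd.DataFrame, truth, year: int) -> float:
    labels = truth.labels(year)
    hits = [
        truth.classes[labels[rec["row"], rec["col"]]] == rec["class"]
        for rec in samples.to_dict("records")
    ]
    return float(np.mean(hits)) if hits else float("nan")


def _proportions(samples: pd.DataFrame, classes) -> dict:
    total = len(samples)
    counts = samples.groupby("class").size()
    return {c: float(counts.get(c, 0)) / total if total else 0.0 for c in classes}


def transfer_trial(seed: int, bench: BenchConfig | None = None) -> dict:
    """One seeded transfer+screen run; returns per-seed recovery metrics."""
    bench = bench or BenchConfig()
    cfg = SceneConfig(
        grid_rows=bench.grid,
        grid_cols=bench.grid,
        n_fields=bench.n_fields,
        years=(2017, 2018),
        rotation_rate=bench.rotation_rate,
        phase_shift_sd_days=bench.phase_shift_sd_days,
        noise_sd=bench.noise_sd,
        missing_rate=bench.missing_rate,
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stacks, truth = generate_scene_series(cfg)
        hist = draw_field_samples(
            truth, 2017, bench.n_per_class, bench.min_spacing_px, seed=seed + 500
        )
        potential, skips = select_potential_samples(
            hist, stacks[2017], stacks[2018], BENCH_FEATURE_MODELS, window=bench.window
        )
        generated, report = screen_samples(
            potential, k_max=bench.k_max, seed=seed + 700
        )
    labels_2018 = truth.labels(2018)
    same_crop = [
        truth.classes[labels_2018[rec["row"], rec["col"]]] == rec["class"]
        for rec in potential.to_dict("records")
    ]
    centered = (potential["offset_row"] == 0) & (potential["offset_col"] == 0)
    k_stars = {
        crop: rep.get("k_star") for crop, rep in report["per_crop"].items()
    }
    k_values = [k for k in k_stars.values() if k is not None]
    modal_k = min(Counter(k_values).most_common(), key=lambda kv: (-kv[1], kv[0]))[0] if k_values else None
    return {
        "seed": seed,
        "n_hist": len(hist),
        "n_potential": len(potential),
        "n_generated": len(generated),
        "n_skipped": len(skips),
        "same_crop_fraction": float(np.mean(same_crop)) if same_crop else float("nan"),
        "center_fraction": float(centered.mean()) if len(potential) else float("nan"),
        "purity_potential": _purity(potential, truth, 2018),
        "purity_generated": _purity(generated, truth, 2018),
        "hist_proportions": _proportions(hist, truth.classes),
        "generated_proportions": _proportions(generated, truth.classes),
        "k_stars": k_stars,
        "modal_k_star": modal_k,
        "_frames": {
            "stacks": stacks,
            "truth": truth,
            "hist": hist,
            "potential": potential,
            "generated": generated,
        },
    }


def classification_comparison(trial: dict, seed: int, n_trees: int = 150) -> dict:
    """OA of a generated-sample forest vs a real target-sample baseline.

    Both models are evaluated on the held-out 30% of independent
    target-year truth samples.
    """
    frames = trial["_frames"]
    stacks, truth = frames["stacks"], frames["truth"]
    bench_seed = trial["seed"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        target_samples = draw_field_samples(
            truth, 2018, len(frames["hist"]) // len(truth.classes) or 1,
            min_spacing_px=6, seed=bench_seed + 900,
        )
    train, test = evaluation.split_validation(target_samples, 0.7, seed=seed)
    classes = list(truth.classes)

    def fit_and_score(samples: pd.DataFrame) -> float:
        matrix = classification.build_feature_matrix(
            samples, stacks[2018], BENCH_FEATURE_MODELS
        )
        model = classification.train_forest(
            matrix, classification.ForestConfig(n_trees=n_trees, seed=seed)
        )
        test_matrix = classification.build_feature_matrix(
            test, stacks[2018], BENCH_FEATURE_MODELS
        )
        preds = model.predict(test_matrix)
        ok = test_matrix.valid
        cm = evaluation.confusion_matrix(
            np.asarray(test_matrix.labels)[ok], preds[ok], classes
        )
        return evaluation.accuracy_metrics(cm).oa

    return {
        "oa_generated": fit_and_score(frames["generated"]),
        "oa_baseline": fit_and_score(train),
        "n_test": len(test),
    }


def run_transfer_suite(
    n_seeds: int = 20, base_seed: int = 1, bench: BenchConfig | None = None,
    with_classification: bool = True,
) -> dict:
    """The multi-seed recovery benchmark; heavy (~10-20 s per seed)."""
    trials = []
    for i in range(n_seeds):
        trial = transfer_trial(base_seed + i, bench)
        if i == 0 and with_classification:
            trial["classification"] = classification_comparison(trial, seed=base_seed)
        trial.pop("_frames")
        trials.append(trial)
    return {"trials": trials, "n_seeds": n_seeds, "base_seed": base_seed}
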