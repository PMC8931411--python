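"""End-to-end experiment runner: simulate -> transfer -> screen -> train
-> classify -> evaluate, with per-stage seeds and a run manifest.

A single YAML/dict config drives one or more *schemes*: each scheme is a
subset of historical years whose generated samples are pooled to train
the target-year classifier; an optional baseline scheme trains on real
target-year samples instead (the ablation the reference design uses).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification, evaluation, raster_io, sample_screening, similarity_transfer
from .errors import ContractError
from .feature_curves import select_feature_models
from .synthetic_scene import SceneConfig, draw_field_samples, generate_scene_series

STAGE_SEED_OFFSETS = {
    "scene": 0,
    "samples": 1,
    "model_select": 2,
    "screen": 3,
    "forest": 4,
    "split": 5,
}


def derive_stage_seeds(seed: int) -> dict:
    return {k: int(seed) + off for k, off in STAGE_SEED_OFFSETS.items()}


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _truth_samples(truth, year, n_per_class, min_spacing, seed):
    return draw_field_samples(truth, year, n_per_class, min_spacing_px=min_spacing, seed=seed)


def run_experiment(config: dict, out_dir) -> Path:
    """Run every configured scheme; return the run directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(int(config.get("seed", 0)))
    chash = config_hash(config)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"{time.strftime('%H:%M:%S')} [{stage}] {msg}")

    scene_cfg_raw = dict(config.get("scene", {}))
    scene_cfg_raw.setdefault("seed", seeds["scene"])
    for key in ("years", "doy_grid", "crop_classes", "crop_proportions"):
        if key in scene_cfg_raw:
            scene_cfg_raw[key] = tuple(scene_cfg_raw[key])
    scene_cfg = SceneConfig(**scene_cfg_raw)
    target_year = int(config["target_year"])
    if target_year not in scene_cfg.years:
        raise ContractError("target_year must be among scene years")
    schemes = [list(map(int, s)) for s in config.get("schemes", [[y for y in scene_cfg.years if y != target_year]])]
    for scheme in schemes:
        if target_year in scheme:
            raise ContractError("target_year must not appear in a historical scheme")

    log("simulate", f"generating scenes for years {scene_cfg.years}")
    stacks, truth = generate_scene_series(scene_cfg)
    classes = list(truth.classes)

    n_per_class = int(config.get("n_samples_per_class", 20))
    min_spacing = int(config.get("min_spacing_px", 6))
    samples_by_year = {
        year: _truth_samples(truth, year, n_per_class, min_spacing, seeds["samples"] + i)
        for i, year in enumerate(scene_cfg.years)
    }
    target_train, target_test = evaluation.split_validation(
        samples_by_year[target_year], float(config.get("train_fraction", 0.7)), seeds["split"]
    )
    log("samples", f"target year {target_year}: {len(target_train)} train / {len(target_test)} test")

    hist_years = sorted({y for s in schemes for y in s})
    if "feature_models" in config:
        feature_models = dict(config["feature_models"])
    else:
        ref_year = hist_years[0] if hist_years else target_year
        feature_models = select_feature_models(
            stacks[ref_year], samples_by_year[ref_year], split_seed=seeds["model_select"]
        )
    log("model_select", f"winning models: {feature_models}")

    window = int(config.get("window", 5))
    n_points = int(config.get("n_points", 100))
    k_min, k_max = config.get("k_range", [2, 20])
    doy_grid = config.get("doy_grid_classify", list(classification.DEFAULT_DOY_GRID))
    forest_cfg = classification.ForestConfig(
        n_trees=int(config.get("forest", {}).get("n_trees", 150)), seed=seeds["forest"]
    )

    # generate + screen once per historical year, reused across schemes
    generated_by_year: dict[int, pd.DataFrame] = {}
    screening_by_year: dict[int, dict] = {}
    for year in hist_years:
        potential, skips = similarity_transfer.select_potential_samples(
            samples_by_year[year], stacks[year], stacks[target_year],
            feature_models, window=window, n_points=n_points,
        )
        generated, report = sample_screening.screen_samples(
            potential, k_min=int(k_min), k_max=int(k_max), seed=seeds["screen"]
        )
        generated_by_year[year] = generated
        screening_by_year[year] = report
        log("transfer", f"year {year}: {len(potential)} potential -> {len(generated)} generated"
            f" ({len(skips)} skipped)")
        potential.to_csv(out_dir / f"potential_{year}.csv", index=False)
        skips.to_csv(out_dir / f"skips_{year}.csv", index=False)
        generated.to_csv(out_dir / f"generated_{year}.csv", index=False)
        (out_dir / f"screening_{year}.json").write_text(json.dumps(report, indent=2))

    def evaluate_model(model) -> dict:
        matrix = classification.build_feature_matrix(
            target_test, stacks[target_year], feature_models, doy_grid
        )
        preds = model.predict(matrix)
        ok = matrix.valid
        cm = evaluation.confusion_matrix(
            np.asarray(matrix.labels)[ok], preds[ok], classes
        )
        rep = evaluation.accuracy_metrics(cm)
        return {
            "oa": rep.oa,
            "per_class": rep.per_class,
            "n_test": int(ok.sum()),
            "confusion": cm.counts.tolist(),
            "class_order": classes,
        }

    results = {}
    manifest = {"config_hash": chash, "schemes": {}, "artifacts": []}
    classify_map = bool(config.get("classify_map", True))
    for scheme in schemes:
        name = "+".join(map(str, scheme))
        pooled = pd.concat([generated_by_year[y] for y in scheme], ignore_index=True)
        log("train", f"scheme {name}: {len(pooled)} pooled generated samples")
        matrix = classification.build_feature_matrix(
            pooled, stacks[target_year], feature_models, doy_grid
        )
        model = classification.train_forest(matrix, forest_cfg)
        scheme_result = {"scheme": name, "baseline": False, "n_train": int(matrix.valid.sum())}
        scheme_result.update(evaluate_model(model))
        if classify_map:
            labels, bad, order = classification.classify_scene(
                model, stacks[target_year], feature_models, doy_grid
            )
            map_path = out_dir / f"map_{name}.tif"
            raster_io.write_labels(np.where(bad, -1, labels), order, map_path)
            manifest["artifacts"].append(map_path.name)
        results[name] = scheme_result
        pooled.to_csv(out_dir / f"generated_pooled_{name}.csv", index=False)

    if config.get("baseline", True):
        matrix = classification.build_feature_matrix(
            target_train, stacks[target_year], feature_models, doy_grid
        )
        model = classification.train_forest(matrix, forest_cfg)
        res = {"scheme": "baseline", "baseline": True, "n_train": int(matrix.valid.sum())}
        res.update(evaluate_model(model))
        results["baseline"] = res
        log("train", f"baseline: {len(target_train)} real target-year samples")

    report = {
        "config_hash": chash,
        "target_year": target_year,
        "feature_models": feature_models,
        "results": results,
        "screening": screening_by_year,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    manifest["schemes"] = {k: f"report.json#results.{k}" for k in results}
    manifest["artifacts"] += sorted(
        p.name for p in out_dir.iterdir() if p.suffix in (".csv", ".json", ".tif")
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return out_dir


def summarize_runs(run_dirs) -> pd.DataFrame:
    """One row per scheme across run directories, sorted by OA (best first)."""
    rows = []
    for d in run_dirs:
        d = Path(d)
        report_path = d / "report.json"
        if not report_path.exists():
            rows.append({"run": d.name, "scheme": None, "oa": np.nan, "incomplete": True})
            continue
        report = json.loads(report_path.read_text())
        for name, res in report["results"].items():
            f1s = [v["f1"] for v in res["per_class"].values()]
            rows.append(
                {
                    "run": d.name,
                    "scheme": name,
                    "baseline": bool(res.get("baseline", False)),
                    "oa": res["oa"],
                    "macro_f1": float(np.mean(f1s)) if f1s else np.nan,
                    "n_train": res.get("n_train"),
                    "incomplete": False,
                }
            )
    df = pd.DataFrame(rows).sort_values("oa", ascending=False, na_position="last")
    df = df.reset_index(drop=True)
    if len(df):
        df["best"] = False
        complete = df.index[~df["incomplete"]]
        if len(complete):
            df.loc[complete[0], "best"] = True
    return df
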