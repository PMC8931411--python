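"""DTW similarity between feature-curve sets and potential-sample selection.

For every historical sample, each pixel in its centered window in the
target year is compared feature-by-feature: both fitted curves are
resampled to 100 equally spaced points, aligned with classic dynamic
time warping (local cost |a_i - b_j|, symmetric steps, no window), and
the distance mapped to a similarity S = exp(-D / max(m, n)).  The
single most similar eligible neighbour inherits the historical label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, IncomparablePixelError
from .feature_curves import (
    MIN_FIT_POINTS,
    SIMILARITY_FEATURES,
    feature_cube,
    fit_pixel_curves,
    sample_curve,
)
from .raster_io import SceneStack


def _dtw_impl(a, b):  # pragma: no cover - exercised via dtw_distance
    m = a.shape[0]
    n = b.shape[0]
    prev = np.empty(n)
    cur = np.empty(n)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, n):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, m):
        cur[0] = prev[0] + abs(a[i] - b[0])
        for j in range(1, n):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = best + abs(a[i] - b[j])
        prev, cur = cur, prev
    return prev[n - 1]


try:  # optional JIT; pure-python fallback is exact but slower
    from numba import njit

    _dtw_core = njit(cache=False, fastmath=False)(_dtw_impl)
except ImportError:  # pragma: no cover
    _dtw_core = _dtw_impl


def dtw_distance(a, b) -> float:
    """Classic DTW distance with |a_i - b_j| local cost, unconstrained."""
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) == 0 or len(b) == 0:
        raise ContractError("dtw_distance needs two non-empty 1-D sequences")
    return float(_dtw_core(a, b))


def similarity_from_distance(d: float, m: int, n: int) -> float:
    """S = exp(-D / max(m, n)); 1 at D = 0, strictly decreasing in D."""
    if d < 0:
        raise ContractError("distance must be >= 0")
    if m < 1 or n < 1:
        raise ContractError("sequence lengths must be >= 1")
    return float(np.exp(-d / max(m, n)))


@dataclass
class SimilarityScore:
    dtw_distance: float  # mean per-feature DTW distance
    len_a: int
    len_b: int
    similarity: float  # aggregate: unweighted mean of per-feature S
    per_feature: dict

    def __post_init__(self) -> None:
        assert 0.0 < self.similarity <= 1.0


def pixel_similarity(hist_curves: dict, target_curves: dict, n_points: int = 100) -> SimilarityScore:
    """Aggregate curve similarity of two pixels over their shared features."""
    shared = [f for f in SIMILARITY_FEATURES if f in hist_curves and f in target_curves]
    if not shared:
        raise IncomparablePixelError("no shared usable feature between pixels")
    per_feature = {}
    dists = []
    for f in shared:
        a = sample_curve(hist_curves[f], n_points)
        b = sample_curve(target_curves[f], n_points)
        d = dtw_distance(a, b)
        per_feature[f] = similarity_from_distance(d, n_points, n_points)
        dists.append(d)
    return SimilarityScore(
        dtw_distance=float(np.mean(dists)),
        len_a=n_points,
        len_b=n_points,
        similarity=float(np.mean(list(per_feature.values()))),
        per_feature=per_feature,
    )


def _window_offsets(window: int) -> list[tuple[int, int]]:
    """Window offsets ordered centre-out (ties among equidistant offsets
    broken row-major), so that an argmax with a strict comparison prefers
    the pixel nearest the historical sample."""
    h = window // 2
    offs = [(dr, dc) for dr in range(-h, h + 1) for dc in range(-h, h + 1)]
    offs.sort(key=lambda o: (max(abs(o[0]), abs(o[1])), o[0], o[1]))
    return offs


def select_potential_samples(
    hist_samples: pd.DataFrame,
    hist_stack: SceneStack,
    target_stack: SceneStack,
    feature_models: dict,
    window: int = 5,
    n_points: int = 100,
    min_valid: int = MIN_FIT_POINTS,
    with_cluster_features: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select at most one target-year potential sample per historical sample.

    Returns ``(potential, skip_log)`` data frames.  ``potential`` rows
    carry the source id, the chosen pixel, its window offset, the
    inherited class, per-feature and aggregate similarity and (by
    default) the clustering summary features of the chosen pixel's
    curves.
    """
    if window % 2 != 1 or window < 1:
        raise ContractError("window must be odd and positive")
    features = tuple(feature_models)
    hist_cube = feature_cube(hist_stack, features)
    tgt_cube = feature_cube(target_stack, features)
    rows, cols = target_stack.shape
    offsets = _window_offsets(window)

    from .sample_screening import curve_summary_features  # cycle-free at call time

    records, skips = [], []
    cache: dict[tuple[int, int], dict | None] = {}
    for rec in hist_samples.to_dict("records"):
        hist_curves = fit_pixel_curves(
            hist_cube, hist_stack.dates, rec["row"], rec["col"], feature_models, min_valid
        )
        if hist_curves is None:
            skips.append({"id": rec["id"], "reason": "historical pixel ineligible"})
            continue
        best = None  # (similarity, offset, row, col, score, curves)
        for dr, dc in offsets:
            rr, cc = rec["row"] + dr, rec["col"] + dc
            if not (0 <= rr < rows and 0 <= cc < cols):
                continue
            if (rr, cc) in cache:
                curves = cache[(rr, cc)]
            else:
                curves = fit_pixel_curves(
                    tgt_cube, target_stack.dates, rr, cc, feature_models, min_valid
                )
                if (
                    curves is not None
                    and with_cluster_features
                    and set(curves) != set(features)
                ):
                    # partial fits would break the fixed-length cluster vector
                    curves = None
                cache[(rr, cc)] = curves
            if curves is None:
                continue
            try:
                score = pixel_similarity(hist_curves, curves, n_points)
            except IncomparablePixelError:
                continue
            if best is None or score.similarity > best[0]:
                best = (score.similarity, (dr, dc), rr, cc, score, curves)
        if best is None:
            skips.append({"id": rec["id"], "reason": "no eligible neighbor"})
            continue
        sim, (dr, dc), rr, cc, score, curves = best
        row = {
            "id": f"p_{rec['id']}",
            "source_id": rec["id"],
            "year": int(target_stack.year),
            "row": int(rr),
            "col": int(cc),
            "offset_row": int(dr),
            "offset_col": int(dc),
            "class": rec["class"],
            "provenance": "potential",
            "similarity": float(sim),
        }
        for f, s in score.per_feature.items():
            row[f"sim_{f}"] = float(s)
        if with_cluster_features:
            vec = curve_summary_features(curves, features=features, n_points=n_points)
            for i, v in enumerate(vec):
                row[f"cf_{i:02d}"] = float(v)
        records.append(row)
    potential = pd.DataFrame(records)
    skip_log = pd.DataFrame(skips, columns=["id", "reason"])
    return potential, skip_log
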