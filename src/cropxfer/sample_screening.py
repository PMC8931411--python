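"""Cluster-and-silhouette screening of potential samples.

Potential samples of one crop are summarised by seven order statistics
of each resampled feature curve (mean, SD, min, max, 25/50/75th
percentile, concatenated over features), clustered with k-means on
z-scored vectors for k in a configured range, and scored with the
silhouette coefficient; the best k's largest cluster survives as the
"generated" sample set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .errors import ContractError, DegenerateDataError
from .feature_curves import SIMILARITY_FEATURES, sample_curve

STAT_NAMES = ("mean", "sd", "min", "max", "p25", "p50", "p75")


def curve_summary_features(
    curves: dict, features: Sequence[str] = SIMILARITY_FEATURES, n_points: int = 100
) -> np.ndarray:
    """Concatenated order statistics of the resampled curves.

    Order is fixed: features in the given order, each contributing
    (mean, sd, min, max, p25, p50, p75) of its 100-point resampling.
    """
    parts = []
    for f in features:
        if f not in curves or curves[f] is None:
            raise ContractError(f"unusable curve for feature {f!r}")
        v = sample_curve(curves[f], n_points)
        parts.append(
            [
                float(np.mean(v)),
                float(np.std(v)),
                float(np.min(v)),
                float(np.max(v)),
                float(np.percentile(v, 25)),
                float(np.percentile(v, 50)),
                float(np.percentile(v, 75)),
            ]
        )
    return np.concatenate(parts)


def zscore(X: np.ndarray) -> np.ndarray:
    """Per-dimension standardisation; zero-variance dimensions map to 0."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def cluster_points(features: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels on z-scored features, 10 restarts, deterministic."""
    X = np.asarray(features, dtype=float)
    n = len(X)
    if not 2 <= k <= n - 1:
        raise ContractError(f"need 2 <= k <= n-1, got k={k}, n={n}")
    if np.allclose(X, X[0]):
        raise DegenerateDataError("all points identical; clustering undefined")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(zscore(X))


@dataclass
class SilhouetteResult:
    k: int
    per_point_a: np.ndarray
    per_point_b: np.ndarray
    per_point_s: np.ndarray
    sc: float
    n: int


def silhouette_coefficient(features: np.ndarray, labels: np.ndarray) -> SilhouetteResult:
    """Mean silhouette of a labelled point set (Euclidean dissimilarity).

    a(i) is the mean distance to the other members of i's cluster, b(i)
    the smallest mean distance to any other cluster, and
    S(i) = (b - a) / max(a, b); singleton-cluster points score 0.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ContractError("silhouette needs at least 2 clusters")
    D = cdist(X, X)
    n = len(X)
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    members = {u: np.flatnonzero(labels == u) for u in uniq}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            a[i] = 0.0
            b[i] = float(min(D[i, members[u]].mean() for u in uniq if u != labels[i]))
            continue
        a[i] = float(D[i, own[own != i]].mean())
        b[i] = float(min(D[i, members[u]].mean() for u in uniq if u != labels[i]))
        denom = max(a[i], b[i])
        s[i] = (b[i] - a[i]) / denom if denom > 0 else 0.0
    return SilhouetteResult(
        k=len(uniq), per_point_a=a, per_point_b=b, per_point_s=s, sc=float(s.mean()), n=n
    )


def screen_samples(
    potential: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-crop cluster/silhouette screening of potential samples.

    ``potential`` must carry the cluster feature columns ``cf_*`` (as
    written by potential-sample selection).  Per crop, k sweeps
    [k_min, min(k_max, n-1)], the k with the highest silhouette wins
    (ties: smaller k) and only the largest cluster (ties: higher mean
    similarity) is retained, relabelled provenance='generated'.  Crops
    with fewer than 4 candidates pass through unscreened.
    """
    report: dict = {"per_crop": {}, "k_min": k_min, "k_max": k_max, "seed": seed}
    if len(potential) == 0:
        warnings.warn("no potential samples to screen")
        return potential.copy(), report
    cf_cols = sorted(c for c in potential.columns if c.startswith("cf_"))
    if not cf_cols:
        raise ContractError("potential samples lack cf_* cluster feature columns")
    kept_parts = []
    for crop, grp in potential.groupby("class", sort=True):
        n = len(grp)
        crop_report: dict = {"n_in": int(n)}
        if n < 4:
            warnings.warn(f"crop {crop!r}: only {n} potential samples; screening skipped")
            crop_report.update({"k_star": None, "sc_by_k": {}, "n_out": int(n), "screened": False})
            report["per_crop"][crop] = crop_report
            kept_parts.append(grp)
            continue
        X = grp[cf_cols].to_numpy(dtype=float)
        sc_by_k = {}
        labels_by_k = {}
        degenerate = False
        for k in range(k_min, min(k_max, n - 1) + 1):
            try:
                labels = cluster_points(X, k, seed=seed)
            except DegenerateDataError:
                degenerate = True
                break
            if len(np.unique(labels)) < 2:
                continue
            Xz = zscore(X)
            sc_by_k[k] = silhouette_coefficient(Xz, labels).sc
            labels_by_k[k] = labels
        if degenerate or not sc_by_k:
            warnings.warn(f"crop {crop!r}: degenerate feature vectors; screening skipped")
            crop_report.update({"k_star": None, "sc_by_k": {}, "n_out": int(n), "screened": False})
            report["per_crop"][crop] = crop_report
            kept_parts.append(grp)
            continue
        k_star = min(sc_by_k, key=lambda k: (-sc_by_k[k], k))
        labels = labels_by_k[k_star]
        sizes = pd.Series(labels).value_counts()
        top = sizes[sizes == sizes.max()].index.tolist()
        if len(top) > 1:  # tie: prefer the cluster with higher mean similarity
            sims = {c: grp.loc[labels == c, "similarity"].mean() for c in top}
            top = [max(sims, key=sims.get)]
        keep = grp.loc[labels == top[0]]
        crop_report.update(
            {
                "k_star": int(k_star),
                "sc_by_k": {int(k): float(v) for k, v in sc_by_k.items()},
                "n_out": int(len(keep)),
                "retained_fraction": float(len(keep) / n),
                "screened": True,
            }
        )
        report["per_crop"][crop] = crop_report
        kept_parts.append(keep)
    generated = pd.concat(kept_parts, ignore_index=True) if kept_parts else potential.iloc[:0]
    generated = generated.copy()
    generated["provenance"] = "generated"
    generated["id"] = ["g_" + str(s)[2:] if str(s).startswith("p_") else f"g_{s}" for s in generated["id"]]
    return generated, report
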