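"""Spectral indices and per-pixel feature-curve fitting.

Each pixel's irregular seasonal time series of one feature (a band or a
vegetation index) is condensed into a continuous "feature curve": a
cubic polynomial, a 3-parameter Gaussian, or a 5-parameter annual
harmonic, whichever wins a 2/3-1/3 chronologically stratified
train/test comparison on R2 (ties: lower RMSE, then fixed model order).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ContractError, CurveFitError, InsufficientDataError
from .raster_io import SceneStack

FEATURES = ("blue", "green", "red", "nir", "ndvi", "ndwi")
SIMILARITY_FEATURES = ("nir", "ndvi", "ndwi")
MODELS = ("cubic", "harmonic5", "gaussian")

HARMONIC_OMEGA = 2.0 * np.pi / 365.0  # fixed annual period

MIN_FIT_POINTS = 6  # harmonic5 has 5 unknowns; require one extra
MIN_SELECT_POINTS = 9  # so the 1/3 test split keeps >= 3 points


@dataclass
class FitStatistics:
    sse: float
    sst: float
    ssr: float
    r2: float
    rmse: float
    m: int


@dataclass
class FeatureSeries:
    feature: str
    doys: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.doys = np.asarray(self.doys, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not len(self.doys) == len(self.values) == len(self.valid):
            raise ContractError("doys/values/valid lengths differ")

    def clean(self) -> tuple[np.ndarray, np.ndarray]:
        """Valid, finite observations sorted by DOY."""
        ok = self.valid & np.isfinite(self.values)
        t, y = self.doys[ok], self.values[ok]
        order = np.argsort(t, kind="stable")
        return t[order], y[order]


@dataclass
class FeatureCurve:
    feature: str
    model: str
    coefficients: np.ndarray
    doy_domain: tuple
    fit_stats: FitStatistics | None = None
    test_stats: FitStatistics | None = None

    def __call__(self, t) -> np.ndarray:
        return evaluate_model(self.model, self.coefficients, t)


def fit_statistics(y: Sequence[float], f: Sequence[float]) -> FitStatistics:
    """SSE/SST/SSR, R2 and RMSE of predictions ``f`` against truth ``y``.

    RMSE is the root mean squared residual against the predictions; with
    zero total variance R2 is 1 for a perfect fit and 0 otherwise.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.ndim != 1 or len(y) == 0:
        raise ContractError("y and f must be equal-length non-empty 1-D arrays")
    m = len(y)
    sse = float(np.sum((y - f) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = sst - sse
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        r2 = 1.0 if sse == 0 else 0.0
    rmse = float(np.sqrt(sse / m))
    return FitStatistics(sse=sse, sst=sst, ssr=ssr, r2=r2, rmse=rmse, m=m)


# ---------------------------------------------------------------------------
# model primitives


def _harmonic_design(t: np.ndarray) -> np.ndarray:
    w = HARMONIC_OMEGA
    return np.column_stack(
        [np.ones_like(t), np.cos(w * t), np.sin(w * t), np.cos(2 * w * t), np.sin(2 * w * t)]
    )


def _gaussian(t, a, b, c):
    return a * np.exp(-(((t - b) / c) ** 2))


def evaluate_model(model: str, coef: np.ndarray, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if model == "cubic":
        return np.polynomial.polynomial.polyval(t, coef)
    if model == "harmonic5":
        out = _harmonic_design(np.atleast_1d(t)) @ np.asarray(coef)
        return out if t.ndim else float(out[0])
    if model == "gaussian":
        return _gaussian(t, *coef)
    raise ContractError(f"unknown model {model!r}")


_CUBIC_T0, _CUBIC_SCALE = 215.0, 100.0  # season midpoint / half-range


def _fit_cubic(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    # fit in a scaled domain for conditioning, then expand to raw DOY
    tau = (t - _CUBIC_T0) / _CUBIC_SCALE
    X = np.column_stack([np.ones_like(tau), tau, tau**2, tau**3])
    coef_tau, *_ = np.linalg.lstsq(X, y, rcond=None)
    base = np.array([-_CUBIC_T0 / _CUBIC_SCALE, 1.0 / _CUBIC_SCALE])  # tau as poly in t
    out = np.zeros(4)
    power = np.array([1.0])
    for k in range(4):
        out[: len(power)] += coef_tau[k] * power
        power = np.polynomial.polynomial.polymul(power, base)
    return out


def _fit_harmonic5(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    X = _harmonic_design(t)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def _fit_gaussian(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    med = float(np.median(y))
    ihi, ilo = int(np.argmax(y)), int(np.argmin(y))
    if y[ihi] - med >= med - y[ilo]:
        a0, b0 = y[ihi], t[ihi]
    else:
        a0, b0 = y[ilo], t[ilo]
    if a0 == 0:
        a0 = med if med != 0 else 1e-3
    c0 = max((t.max() - t.min()) / 4.0, 1.0)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # covariance warnings are irrelevant here
            coef, _ = curve_fit(_gaussian, t, y, p0=[a0, b0, c0], maxfev=2000)
    except (RuntimeError, ValueError) as exc:
        raise CurveFitError(f"gaussian fit failed: {exc}") from exc
    if not np.all(np.isfinite(coef)):
        raise CurveFitError("gaussian fit produced non-finite parameters")
    coef[2] = abs(coef[2])
    return np.asarray(coef, dtype=float)


_FITTERS = {"cubic": _fit_cubic, "harmonic5": _fit_harmonic5, "gaussian": _fit_gaussian}


def fit_curve(series: FeatureSeries, model: str) -> FeatureCurve:
    """Fit one model to the valid observations of one feature series."""
    if model not in _FITTERS:
        raise ContractError(f"unknown model {model!r}")
    t, y = series.clean()
    if len(t) < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"{series.feature}: {len(t)} valid points < {MIN_FIT_POINTS}"
        )
    coef = _FITTERS[model](t, y)
    curve = FeatureCurve(
        feature=series.feature,
        model=model,
        coefficients=coef,
        doy_domain=(float(t[0]), float(t[-1])),
    )
    curve.fit_stats = fit_statistics(y, curve(t))
    return curve


def select_best_model(
    series: FeatureSeries, split_seed: int = 0, models: Sequence[str] = MODELS
) -> tuple[str, FeatureCurve]:
    """Pick the best-fitting model by held-out R2 and refit on all points.

    The valid observations are sorted by DOY and every third one (a
    chronologically stratified 1/3) is held out for scoring; the winner
    is refit on the full series.  ``split_seed`` only rotates which
    residue class is held out.
    """
    t, y = series.clean()
    if len(t) < MIN_SELECT_POINTS:
        raise InsufficientDataError(
            f"{series.feature}: {len(t)} valid points < {MIN_SELECT_POINTS}"
        )
    idx = np.arange(len(t))
    test = idx % 3 == (split_seed % 3)
    train = ~test
    scored = []
    for model in models:
        try:
            fitter = _FITTERS[model]
            coef = fitter(t[train], y[train])
            stats = fit_statistics(y[test], evaluate_model(model, coef, t[test]))
        except (CurveFitError, InsufficientDataError):
            continue
        except KeyError:
            raise ContractError(f"unknown model {model!r}") from None
        scored.append((model, stats))
    if not scored:
        raise InsufficientDataError(f"{series.feature}: every candidate model failed")
    model_rank = {m: i for i, m in enumerate(MODELS)}
    best_model, best_stats = min(
        scored, key=lambda ms: (-ms[1].r2, ms[1].rmse, model_rank[ms[0]])
    )
    curve = fit_curve(series, best_model)
    curve.test_stats = best_stats
    return best_model, curve


def sample_curve(curve: FeatureCurve, n: int = 100) -> np.ndarray:
    """Evaluate the curve at ``n`` equally spaced DOYs spanning its domain."""
    if n < 2:
        raise ContractError("n must be >= 2")
    t = np.linspace(curve.doy_domain[0], curve.doy_domain[1], n)
    return np.asarray(curve(t), dtype=float)


# ---------------------------------------------------------------------------
# stack-level feature extraction


def compute_index(stack: SceneStack, which: str) -> tuple[np.ndarray, np.ndarray]:
    """NDVI or NDWI cube plus its validity mask (zero denominators masked)."""
    which = which.lower()
    if which == "ndvi":
        num = stack.band("nir") - stack.band("red")
        den = stack.band("nir") + stack.band("red")
    elif which == "ndwi":
        num = stack.band("green") - stack.band("nir")
        den = stack.band("green") + stack.band("nir")
    else:
        raise ContractError(f"unknown index {which!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = num / den
    valid = stack.valid_mask & (den != 0) & np.isfinite(values)
    values = np.where(valid, values, np.nan)
    return values, valid


def feature_cube(stack: SceneStack, features: Sequence[str]) -> dict:
    """Map feature name -> (values, valid) cubes for the given stack."""
    cube = {}
    for f in features:
        f = f.lower()
        if f in ("ndvi", "ndwi"):
            cube[f] = compute_index(stack, f)
        else:
            vals = stack.band(f)
            valid = stack.valid_mask & np.isfinite(vals)
            cube[f] = (np.where(valid, vals, np.nan), valid)
    return cube


def pixel_series(cube: dict, dates: np.ndarray, feature: str, row: int, col: int) -> FeatureSeries:
    values, valid = cube[feature]
    return FeatureSeries(
        feature=feature,
        doys=dates,
        values=values[:, row, col],
        valid=valid[:, row, col],
    )


def fit_pixel_curves(
    cube: dict,
    dates: np.ndarray,
    row: int,
    col: int,
    feature_models: dict,
    min_valid: int = MIN_FIT_POINTS,
) -> dict | None:
    """Fit the per-feature winner models at one pixel.

    Returns None when any required feature has fewer than ``min_valid``
    valid dates (the pixel is ineligible); features whose nonlinear fit
    fails are dropped, and None is returned if none survive.
    """
    for feature in feature_models:
        valid = cube[feature][1][:, row, col]
        if int(valid.sum()) < min_valid:
            return None
    curves = {}
    for feature, model in feature_models.items():
        series = pixel_series(cube, dates, feature, row, col)
        try:
            curves[feature] = fit_curve(series, model)
        except (CurveFitError, InsufficientDataError):
            continue
    return curves or None


def select_feature_models(
    stack: SceneStack,
    samples,
    features: Sequence[str] = SIMILARITY_FEATURES,
    split_seed: int = 0,
) -> dict:
    """Choose one winning model per feature by majority vote over samples.

    Each sample pixel runs the train/test model selection; the most
    frequent winner per feature is kept (ties resolved by fixed model
    order).
    """
    cube = feature_cube(stack, features)
    votes: dict[str, Counter] = {f: Counter() for f in features}
    for rec in samples.itertuples():
        for feature in features:
            series = pixel_series(cube, stack.dates, feature, rec.row, rec.col)
            try:
                winner, _ = select_best_model(series, split_seed=split_seed)
            except (CurveFitError, InsufficientDataError):
                continue
            votes[feature][winner] += 1
    out = {}
    model_rank = {m: i for i, m in enumerate(MODELS)}
    for feature in features:
        if not votes[feature]:
            raise InsufficientDataError(f"no sample supported model selection for {feature}")
        out[feature] = min(
            votes[feature].items(), key=lambda kv: (-kv[1], model_rank[kv[0]])
        )[0]
    return out
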