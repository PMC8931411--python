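"""Synthetic multi-year crop scenes with known ground truth.

The generator tiles a pixel grid into rectangular fields, assigns each
field a crop per year (with a configurable rotation rate between
consecutive years), synthesises a double-logistic NDVI trajectory per
crop, converts NDVI to four reflectance bands through fixed linear
endmember mixing, adds Gaussian noise and knocks out observations with
per-date, per-field validity masks.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import SizingError, ValidationError
from .raster_io import BAND_NAMES, DEFAULT_TRANSFORM, SceneStack, make_sample_frame

DEFAULT_CLASSES = ("maize", "rice", "soybean", "other")
DEFAULT_DOY_GRID = tuple(range(139, 295, 8))  # every 8 days over the season


@dataclass
class PhenologyTemplate:
    """Seasonal NDVI shape for one crop."""

    crop: str
    peak_doy: float
    amplitude: float
    base_ndvi: float
    width_days: float
    early_water_signal: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.amplitude <= 1:
            raise ValidationError("amplitude must be in (0, 1]")
        if self.base_ndvi + self.amplitude > 1:
            raise ValidationError("base_ndvi + amplitude must be <= 1")


#: Plausible default templates; peaks sit inside DOY 192-212.
DEFAULT_TEMPLATES = {
    "maize": PhenologyTemplate("maize", peak_doy=205, amplitude=0.65, base_ndvi=0.15, width_days=46),
    "rice": PhenologyTemplate(
        "rice", peak_doy=210, amplitude=0.60, base_ndvi=0.12, width_days=40, early_water_signal=True
    ),
    "soybean": PhenologyTemplate("soybean", peak_doy=198, amplitude=0.55, base_ndvi=0.15, width_days=36),
    "other": PhenologyTemplate("other", peak_doy=185, amplitude=0.38, base_ndvi=0.22, width_days=58),
}


@dataclass
class SceneConfig:
    grid_rows: int = 64
    grid_cols: int = 64
    pixel_size_m: float = 16.0
    n_fields: int = 64
    crop_classes: tuple = DEFAULT_CLASSES
    crop_proportions: tuple = (0.45, 0.15, 0.25, 0.15)
    rotation_rate: float = 0.0
    years: tuple = (2017, 2018)
    doy_grid: tuple = DEFAULT_DOY_GRID
    missing_rate: float = 0.0
    phase_shift_sd_days: float = 0.0
    noise_sd: float = 0.0
    # per-field agronomic variability, constant across years (sowing habit,
    # soil fertility); gives each crop a realistic within-class continuum
    field_phase_jitter_sd_days: float = 3.0
    field_amplitude_jitter_sd: float = 0.04
    seed: int = 0
    templates: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))

    def __post_init__(self) -> None:
        if abs(sum(self.crop_proportions) - 1.0) > 1e-9:
            raise ValidationError("crop_proportions must sum to 1")
        if len(self.crop_proportions) != len(self.crop_classes):
            raise ValidationError("crop_proportions/crop_classes length mismatch")
        if not 0 <= self.rotation_rate <= 1:
            raise ValidationError("rotation_rate must be in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValidationError("missing_rate must be in [0, 1]")
        if np.any(np.diff(self.doy_grid) <= 0):
            raise ValidationError("doy_grid must be strictly increasing")


@dataclass
class GroundTruth:
    """Per-year class-id rasters plus the static field index raster."""

    label_rasters: dict  # year -> (rows, cols) int array of class ids
    field_id_raster: np.ndarray
    classes: tuple

    def labels(self, year: int) -> np.ndarray:
        return self.label_rasters[year]


def phenology_value(
    template: PhenologyTemplate, doy, phase_shift: float = 0.0
):
    """Double-logistic seasonal NDVI value at ``doy`` (scalar or array).

    The curve is ``base + amplitude * rise * fall`` with inflection
    points ``width_days`` before and after the (possibly shifted) peak;
    slopes are chosen so the value at the peak is within 1% of
    ``base + amplitude``.
    """
    t = np.asarray(doy, dtype=float) - phase_shift
    k = template.width_days / 6.0
    rise = 1.0 / (1.0 + np.exp(-(t - (template.peak_doy - template.width_days)) / k))
    fall = 1.0 / (1.0 + np.exp((t - (template.peak_doy + template.width_days)) / k))
    v = template.base_ndvi + template.amplitude * rise * fall
    if template.early_water_signal:
        # paddy flooding: depressed NDVI well before the peak
        flood_doy = template.peak_doy - 1.5 * template.width_days
        v = v - 0.10 * np.exp(-(((t - flood_doy) / 14.0) ** 2))
    return np.clip(v, -1.0, 1.0)


# Fixed soil/vegetation endmembers per band: reflectance = soil*(1-v) + veg*v.
_ENDMEMBERS = {
    "blue": (0.20, 0.04),
    "green": (0.24, 0.08),
    "red": (0.26, 0.03),
    "nir": (0.28, 0.52),
}


def ndvi_to_bands(ndvi: np.ndarray, water: np.ndarray | None = None) -> dict:
    """Invert NDVI to four bands via linear endmember mixing.

    ``water`` is an optional 0-1 weight adding a paddy-water signature
    (lower NIR, slightly higher green) so NDWI rises early season.
    """
    v = np.clip(np.asarray(ndvi, dtype=float), 0.0, 1.0)
    bands = {}
    for name, (soil, veg) in _ENDMEMBERS.items():
        bands[name] = soil * (1.0 - v) + veg * v
    if water is not None:
        w = np.clip(np.asarray(water, dtype=float), 0.0, 1.0)
        bands["nir"] = bands["nir"] - 0.12 * w
        bands["green"] = bands["green"] + 0.04 * w
    for name in bands:
        bands[name] = np.clip(bands[name], 0.01, 1.0)
    return bands


def _field_grid(config: SceneConfig) -> tuple[np.ndarray, int]:
    """Tile the grid into ~n_fields rectangles; return field-id raster."""
    n = config.n_fields
    if n < 1 or n > config.grid_rows * config.grid_cols:
        raise SizingError(
            f"cannot place {n} fields on a {config.grid_rows}x{config.grid_cols} grid"
        )
    fr = max(1, int(round(math.sqrt(n * config.grid_rows / max(config.grid_cols, 1)))))
    fr = min(fr, config.grid_rows, n)
    fc = math.ceil(n / fr)
    if fc > config.grid_cols:
        raise SizingError(
            f"cannot place {n} fields on a {config.grid_rows}x{config.grid_cols} grid"
        )
    row_edges = np.linspace(0, config.grid_rows, fr + 1).astype(int)
    col_edges = np.linspace(0, config.grid_cols, fc + 1).astype(int)
    fid = np.empty((config.grid_rows, config.grid_cols), dtype=int)
    k = 0
    for i in range(fr):
        for j in range(fc):
            fid[row_edges[i]: row_edges[i + 1], col_edges[j]: col_edges[j + 1]] = k
            k += 1
    return fid, fr * fc


def generate_scene_series(config: SceneConfig) -> tuple[dict, GroundTruth]:
    """Generate one SceneStack per configured year plus the ground truth."""
    rng = np.random.default_rng(config.seed)
    fid, n_fields = _field_grid(config)
    rows, cols = config.grid_rows, config.grid_cols
    classes = tuple(config.crop_classes)
    n_classes = len(classes)

    # crops per field per year
    crop_by_year: dict[int, np.ndarray] = {}
    first = rng.choice(n_classes, size=n_fields, p=np.asarray(config.crop_proportions))
    crop_by_year[config.years[0]] = first
    for prev, year in zip(config.years, config.years[1:]):
        prior = crop_by_year[prev]
        rotate = rng.random(n_fields) < config.rotation_rate
        new = prior.copy()
        if rotate.any():
            # draw a different crop uniformly for rotated fields
            shift = rng.integers(1, n_classes, size=int(rotate.sum()))
            new[rotate] = (prior[rotate] + shift) % n_classes
        crop_by_year[year] = new

    doys = np.asarray(config.doy_grid, dtype=int)
    field_phase = (
        rng.normal(0.0, config.field_phase_jitter_sd_days, n_fields)
        if config.field_phase_jitter_sd_days
        else np.zeros(n_fields)
    )
    field_amp_scale = (
        1.0 + rng.normal(0.0, config.field_amplitude_jitter_sd, n_fields)
        if config.field_amplitude_jitter_sd
        else np.ones(n_fields)
    )
    # paddy flooding depth/duration varies per field
    field_water_scale = np.clip(1.0 + rng.normal(0.0, 0.3, n_fields), 0.2, 1.8)
    label_rasters = {}
    stacks = {}
    for year in config.years:
        crops = crop_by_year[year]
        label_rasters[year] = crops[fid]
        shift = rng.normal(0.0, config.phase_shift_sd_days) if config.phase_shift_sd_days else 0.0

        # per-field NDVI/water trajectories on this year's dates
        ndvi_by_field = np.empty((n_fields, len(doys)))
        water_by_field = np.zeros((n_fields, len(doys)))
        for k in range(n_fields):
            tmpl = config.templates[classes[crops[k]]]
            amp = float(np.clip(tmpl.amplitude * field_amp_scale[k], 0.05, 1.0 - tmpl.base_ndvi))
            tmpl_k = replace(tmpl, amplitude=amp)
            ndvi_by_field[k] = phenology_value(tmpl_k, doys, shift + field_phase[k])
            if tmpl.early_water_signal:
                flood_doy = tmpl.peak_doy - 1.5 * tmpl.width_days
                water_by_field[k] = field_water_scale[k] * np.exp(
                    -(((doys - shift - field_phase[k] - flood_doy) / 14.0) ** 2)
                )

        bands = np.empty((len(doys), len(BAND_NAMES), rows, cols))
        for d in range(len(doys)):
            ndvi = ndvi_by_field[:, d][fid]
            water = water_by_field[:, d][fid]
            bd = ndvi_to_bands(ndvi, water)
            for bi, bname in enumerate(BAND_NAMES):
                layer = bd[bname]
                if config.noise_sd > 0:
                    layer = layer + rng.normal(0.0, config.noise_sd, size=layer.shape)
                bands[d, bi] = np.clip(layer, 0.0, 1.0)

        # per-date, per-field validity (cloud) mask
        valid = np.ones((len(doys), rows, cols), dtype=bool)
        if config.missing_rate > 0:
            knockout = rng.random((len(doys), n_fields)) < config.missing_rate
            for d in range(len(doys)):
                if knockout[d].any():
                    valid[d] = ~knockout[d][fid]
        bands[~np.repeat(valid[:, None], len(BAND_NAMES), axis=1)] = np.nan

        stacks[year] = SceneStack(
            year=year,
            dates=doys.copy(),
            bands=bands,
            valid_mask=valid,
            transform=(0.0, config.pixel_size_m, 0.0, 0.0, 0.0, -config.pixel_size_m),
        )

    truth = GroundTruth(
        label_rasters=label_rasters, field_id_raster=fid, classes=classes
    )
    return stacks, truth


def draw_field_samples(
    truth: GroundTruth,
    year: int,
    n_per_class: int,
    min_spacing_px: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw labeled sample points from the ground truth of one year.

    Pairwise Chebyshev spacing between accepted samples is at least
    ``min_spacing_px``.  When a class runs out of eligible pixels the
    count is reduced with a warning.
    """
    rng = np.random.default_rng(seed)
    labels = truth.labels(year)
    records = []
    accepted: list[tuple[int, int]] = []
    next_id = 0
    for ci, cname in enumerate(truth.classes):
        pos = np.argwhere(labels == ci)
        if len(pos) == 0:
            warnings.warn(f"class {cname!r} absent from year {year}; 0 samples drawn")
            continue
        pos = pos[rng.permutation(len(pos))]
        taken = 0
        for r, c in pos:
            if taken >= n_per_class:
                break
            if min_spacing_px > 0 and any(
                max(abs(r - ar), abs(c - ac)) < min_spacing_px for ar, ac in accepted
            ):
                continue
            accepted.append((int(r), int(c)))
            records.append(
                {
                    "id": f"s{next_id:05d}",
                    "year": int(year),
                    "row": int(r),
                    "col": int(c),
                    "class": cname,
                    "provenance": "field",
                    "similarity": np.nan,
                }
            )
            next_id += 1
            taken += 1
        if taken < n_per_class:
            warnings.warn(
                f"class {cname!r}: only {taken}/{n_per_class} samples satisfy spacing"
            )
    return make_sample_frame(records)
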