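"""Scene / sample I/O and radiometric conversion.

A *scene* is one year's stack of multi-date, four-band reflectance grids.
On disk it is a directory of per-date TIFFs (band-major, float32, NaN =
nodata) plus a ``scene.json`` sidecar carrying the year, the day-of-year
of every date, the band order and the affine geotransform.  Samples travel
as CSV or GeoJSON point files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

BAND_NAMES = ("blue", "green", "red", "nir")

#: GDAL-style geotransform (x0, dx, rot, y0, rot, dy) for a 16 m grid.
DEFAULT_TRANSFORM = (0.0, 16.0, 0.0, 0.0, 0.0, -16.0)

SAMPLE_COLUMNS = ["id", "year", "row", "col", "class", "provenance", "similarity"]


@dataclass
class SceneStack:
    """One year's multi-date, multi-band pixel grid.

    ``bands`` has shape ``(n_dates, n_bands, rows, cols)``; invalid
    observations are NaN and additionally flagged in ``valid_mask`` of
    shape ``(n_dates, rows, cols)``.  ``dates`` are strictly increasing
    days of year.
    """

    year: int
    dates: np.ndarray
    bands: np.ndarray
    valid_mask: np.ndarray
    band_names: tuple = BAND_NAMES
    transform: tuple = DEFAULT_TRANSFORM

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=int)
        self.bands = np.asarray(self.bands, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.bands.ndim != 4:
            raise FormatError("bands must be (n_dates, n_bands, rows, cols)")
        if self.valid_mask.shape != (
            self.bands.shape[0],
            self.bands.shape[2],
            self.bands.shape[3],
        ):
            raise FormatError("valid_mask shape does not match bands")
        if len(self.dates) != self.bands.shape[0]:
            raise FormatError("dates length does not match bands")
        if np.any(np.diff(self.dates) <= 0):
            order = np.argsort(self.dates, kind="stable")
            self.dates = self.dates[order]
            self.bands = self.bands[order]
            self.valid_mask = self.valid_mask[order]

    @property
    def shape(self) -> tuple:
        return self.bands.shape[2], self.bands.shape[3]

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    def band(self, name: str) -> np.ndarray:
        """Return the (n_dates, rows, cols) cube for one named band."""
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise FormatError(f"unknown band {name!r}") from None
        return self.bands[:, i]


@dataclass
class CalibrationCoefficients:
    """Per-band absolute calibration: radiance = gain * DN + offset."""

    gain: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValidationError("gain must be positive")


def dn_to_radiance(
    dn: np.ndarray, coeffs: CalibrationCoefficients, mask: np.ndarray | None = None
) -> np.ndarray:
    """Convert digital numbers to radiance, elementwise.

    NaNs (and any ``mask == False`` cells) are preserved as NaN.
    """
    out = coeffs.gain * np.asarray(dn, dtype=float) + coeffs.offset
    if mask is not None:
        out = np.where(np.asarray(mask, dtype=bool), out, np.nan)
    return out


# ---------------------------------------------------------------------------
# scene read/write


def write_scene(stack: SceneStack, dir_path: str | Path) -> Path:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    files = []
    for d, doy in enumerate(stack.dates):
        data = stack.bands[d].astype(np.float32).copy()
        data[:, ~stack.valid_mask[d]] = np.nan
        name = f"{stack.year}_doy{int(doy):03d}.tif"
        tifffile.imwrite(dir_path / name, data)
        files.append(name)
    sidecar = {
        "year": int(stack.year),
        "doys": [int(d) for d in stack.dates],
        "band_names": list(stack.band_names),
        "transform": list(stack.transform),
        "files": files,
    }
    (dir_path / "scene.json").write_text(json.dumps(sidecar, indent=2))
    return dir_path


def read_scene(dir_path: str | Path) -> SceneStack:
    dir_path = Path(dir_path)
    sidecar_path = dir_path / "scene.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing scene sidecar: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    doys = meta["doys"]
    files = meta.get("files")
    if files is None or len(files) != len(doys):
        raise FormatError("sidecar files/doys mismatch")
    cubes = []
    for name in files:
        arr = tifffile.imread(dir_path / name).astype(float)
        if arr.ndim == 2:
            arr = arr[None]
        cubes.append(arr)
    shapes = {c.shape for c in cubes}
    if len(shapes) > 1:
        raise FormatError(f"per-date rasters disagree in shape: {sorted(shapes)}")
    bands = np.stack(cubes)
    valid = np.all(np.isfinite(bands), axis=1)
    stack = SceneStack(
        year=int(meta["year"]),
        dates=np.asarray(doys, dtype=int),
        bands=bands,
        valid_mask=valid,
        band_names=tuple(meta.get("band_names", BAND_NAMES)),
        transform=tuple(meta.get("transform", DEFAULT_TRANSFORM)),
    )
    return stack


def write_labels(
    labels: np.ndarray, classes: Sequence[str], path: str | Path
) -> Path:
    """Write a class-id raster plus a JSON class map next to it."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int16))
    path.with_suffix(".json").write_text(json.dumps({"classes": list(classes)}))
    return path


def read_labels(path: str | Path) -> tuple[np.ndarray, list]:
    path = Path(path)
    labels = tifffile.imread(path).astype(int)
    classes = json.loads(path.with_suffix(".json").read_text())["classes"]
    return labels, classes


# ---------------------------------------------------------------------------
# samples


def _validate_samples(
    df: pd.DataFrame,
    classes: Sequence[str] | None = None,
    grid_shape: tuple | None = None,
) -> pd.DataFrame:
    required = {"id", "year", "row", "col", "class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample table missing columns: {sorted(missing)}")
    df = df.copy()
    if "provenance" not in df.columns:
        df["provenance"] = "field"
    if "similarity" not in df.columns:
        df["similarity"] = np.nan
    if classes is not None:
        bad = sorted(set(df["class"]) - set(classes))
        if bad:
            raise ValidationError(f"unknown class labels: {bad}")
    if grid_shape is not None:
        rows, cols = grid_shape
        out = df[
            (df["row"] < 0) | (df["row"] >= rows) | (df["col"] < 0) | (df["col"] >= cols)
        ]
        if len(out):
            raise ValidationError(
                f"sample rows out of grid bounds: ids {sorted(out['id'].tolist())}"
            )
    return df[SAMPLE_COLUMNS]


def write_samples(df: pd.DataFrame, path: str | Path, transform=DEFAULT_TRANSFORM) -> Path:
    """Write a sample table as CSV or GeoJSON (decided by extension)."""
    path = Path(path)
    df = _validate_samples(df)
    if path.suffix.lower() == ".csv":
        df.to_csv(path, index=False)
    elif path.suffix.lower() in (".geojson", ".json"):
        x0, dx, _, y0, _, dy = transform
        features = []
        for rec in df.to_dict("records"):
            sim = rec["similarity"]
            props = {
                "id": rec["id"],
                "year": int(rec["year"]),
                "row": int(rec["row"]),
                "col": int(rec["col"]),
                "class": rec["class"],
                "provenance": rec["provenance"],
                "similarity": None if pd.isna(sim) else float(sim),
            }
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [
                            x0 + (rec["col"] + 0.5) * dx,
                            y0 + (rec["row"] + 0.5) * dy,
                        ],
                    },
                    "properties": props,
                }
            )
        path.write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=2)
        )
    else:
        raise FormatError(f"unsupported sample format: {path.suffix}")
    return path


def read_samples(
    path: str | Path,
    classes: Sequence[str] | None = None,
    grid_shape: tuple | None = None,
) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
    elif path.suffix.lower() in (".geojson", ".json"):
        fc = json.loads(path.read_text())
        df = pd.DataFrame([f["properties"] for f in fc.get("features", [])])
    else:
        raise FormatError(f"unsupported sample format: {path.suffix}")
    return _validate_samples(df, classes=classes, grid_shape=grid_shape)


def make_sample_frame(records: list[dict]) -> pd.DataFrame:
    """Normalize a list of sample dicts to the canonical column set."""
    return _validate_samples(pd.DataFrame(records))
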