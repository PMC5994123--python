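"""Dense-tissue-height maps and thresholded percent-density measures.

A *density map* is a per-pixel estimate of the height (mm) of radiodense
fibroglandular tissue at each point of a mammogram, together with a breast
mask.  Thresholding the heights at ``t`` mm and discarding everything at or
below the threshold yields two families of percent-density (PD) measures:

* volumetric PD, ``VPD(t)`` — the dense volume above the threshold as a
  percentage of total breast volume;
* areal PD, ``APD(t)`` — the count of above-threshold pixels as a
  percentage of in-breast pixels.

``VPD(0)`` is the conventional un-thresholded volumetric PD.  Both families
are nonincreasing in ``t`` and live on a 0–100 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DensityMap",
    "DensityMeasure",
    "ThresholdGrid",
    "dense_volume",
    "breast_volume",
    "vpd",
    "apd",
    "threshold_mask",
    "sweep_measures",
    "measures_to_frame",
    "load_density_map",
    "save_density_map",
]

#: quantization used by the raster format, mm per integer unit
DEFAULT_HEIGHT_SCALE = 0.01


class DensityMapError(ValueError):
    """Raised when a density map violates its invariants."""


@dataclass(frozen=True)
class DensityMap:
    """Per-pixel dense-tissue heights with a breast mask.

    Parameters
    ----------
    heights:
        2-D float array of dense-tissue heights in mm.  Finite, ``>= 0``,
        zero outside the mask and bounded by ``breast_thickness`` inside it.
    breast_mask:
        Boolean array of the same shape; at least one pixel must be True.
    pixel_area:
        Area of one pixel in mm².
    breast_thickness:
        Recorded compressed-breast thickness in mm.
    subject_id:
        Opaque identifier carried through to error messages and output rows.
    """

    heights: np.ndarray
    breast_mask: np.ndarray
    pixel_area: float
    breast_thickness: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        heights = np.asarray(self.heights, dtype=float)
        mask = np.asarray(self.breast_mask, dtype=bool)
        object.__setattr__(self, "heights", heights)
        object.__setattr__(self, "breast_mask", mask)
        self.validate()

    def validate(self) -> None:
        sid = f" (subject {self.subject_id!r})" if self.subject_id else ""
        if self.heights.ndim != 2:
            raise DensityMapError(f"heights must be 2-D{sid}")
        if self.breast_mask.shape != self.heights.shape:
            raise DensityMapError(
                f"mask shape {self.breast_mask.shape} != heights shape "
                f"{self.heights.shape}{sid}"
            )
        if not self.pixel_area > 0:
            raise DensityMapError(f"pixel_area must be > 0{sid}")
        if not self.breast_thickness > 0:
            raise DensityMapError(f"breast_thickness must be > 0{sid}")
        if not np.all(np.isfinite(self.heights)):
            raise DensityMapError(f"heights must be finite{sid}")
        if np.any(self.heights < 0):
            raise DensityMapError(f"heights must be >= 0{sid}")
        if np.any(self.heights[~self.breast_mask] != 0):
            raise DensityMapError(f"out-of-mask heights must be 0{sid}")
        if not self.breast_mask.any():
            raise DensityMapError(f"breast mask is empty{sid}")
        if np.any(self.heights[self.breast_mask] > self.breast_thickness + 1e-9):
            raise DensityMapError(
                f"in-mask height exceeds breast thickness "
                f"{self.breast_thickness} mm{sid}"
            )

    @property
    def n_mask(self) -> int:
        return int(self.breast_mask.sum())


@dataclass(frozen=True)
class DensityMeasure:
    """Percent-density record for one subject at one threshold."""

    subject_id: str
    threshold: float  # mm
    vpd: float  # percent, [0, 100]
    apd: float  # percent, [0, 100]
    dense_volume: float  # cm³
    breast_volume: float  # cm³
    dense_area: float  # cm²
    breast_area: float  # cm²


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing thresholds in mm, within [0, 25]."""

    values: tuple = field(default_factory=lambda: tuple(range(26)))

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) == 0:
            raise ValueError("threshold grid must be non-empty")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if vals[0] < 0 or vals[-1] > 25:
            raise ValueError("thresholds must lie within [0, 25] mm")
        object.__setattr__(self, "values", vals)

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def dense_volume(dmap: DensityMap, t: float) -> float:
    """Dense-tissue volume above threshold ``t`` mm, in cm³.

    Sums heights strictly greater than ``t`` over in-mask pixels and scales
    by the pixel area (mm³ → cm³).
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    h = dmap.heights[dmap.breast_mask]
    return float(dmap.pixel_area * h[h > t].sum() / 1000.0)


def breast_volume(dmap: DensityMap) -> float:
    """Total breast volume as a uniform-thickness slab, in cm³.

    ``pixel_area × breast_thickness × (# in-mask pixels)``.  The recorded
    compressed-breast thickness is treated as uniform across the breast.
    """
    return float(dmap.pixel_area * dmap.breast_thickness * dmap.n_mask / 1000.0)


def vpd(dmap: DensityMap, t: float) -> float:
    """Volumetric percent density at threshold ``t`` mm (0–100)."""
    return 100.0 * dense_volume(dmap, t) / breast_volume(dmap)


def apd(dmap: DensityMap, t: float) -> float:
    """Areal percent density at threshold ``t`` mm (0–100).

    Percentage of in-mask pixels whose dense-tissue height strictly exceeds
    ``t``; at ``t = 0`` zero-height in-mask pixels are not counted dense.
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    h = dmap.heights[dmap.breast_mask]
    return float(100.0 * (h > t).sum() / h.size)


def threshold_mask(dmap: DensityMap, t: float) -> np.ndarray:
    """Boolean grid: in-mask pixels with height strictly above ``t``."""
    return dmap.breast_mask & (dmap.heights > t)


def sweep_measures(dmap: DensityMap, grid: ThresholdGrid) -> list[DensityMeasure]:
    """One :class:`DensityMeasure` per grid threshold, in grid order."""
    bvol = breast_volume(dmap)
    barea = dmap.pixel_area * dmap.n_mask / 100.0  # mm² → cm²
    h = dmap.heights[dmap.breast_mask]
    out = []
    for t in grid:
        above = h > t
        dvol = float(dmap.pixel_area * h[above].sum() / 1000.0)
        darea = float(dmap.pixel_area * above.sum() / 100.0)
        out.append(
            DensityMeasure(
                subject_id=dmap.subject_id,
                threshold=float(t),
                vpd=100.0 * dvol / bvol,
                apd=100.0 * above.sum() / h.size,
                dense_volume=dvol,
                breast_volume=bvol,
                dense_area=darea,
                breast_area=barea,
            )
        )
    return out


def measures_to_frame(measures: Sequence[DensityMeasure]):
    """Measures as a pandas DataFrame with the documented CSV columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in measures],
            "threshold_mm": [m.threshold for m in measures],
            "vpd_pct": [m.vpd for m in measures],
            "apd_pct": [m.apd for m in measures],
            "dense_volume_cm3": [m.dense_volume for m in measures],
            "breast_volume_cm3": [m.breast_volume for m in measures],
        }
    )


# ---------------------------------------------------------------------------
# Raster I/O: 16-bit TIFF (or PGM) heights in 0.01 mm units, 8-bit mask,
# JSON sidecar with the physical metadata.
# ---------------------------------------------------------------------------


def _read_raster(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    from PIL import Image

    return np.asarray(Image.open(path))


def _write_raster(path: Path, arr: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)


def _mask_path(raster_path: Path) -> Path:
    raster_path = Path(raster_path)
    return raster_path.with_name(raster_path.stem + ".mask" + raster_path.suffix)


def save_density_map(
    dmap: DensityMap,
    raster_path: str | Path,
    metadata_path: str | Path,
    height_scale: float = DEFAULT_HEIGHT_SCALE,
) -> None:
    """Write heights as a 16-bit raster plus mask raster and JSON sidecar.

    Heights are stored as ``round(h / height_scale)`` unsigned 16-bit
    integers, so a save→load round trip is exact at the stored quantization.
    """
    quant = np.round(dmap.heights / height_scale)
    if quant.max() > np.iinfo(np.uint16).max:
        raise ValueError(
            f"height {dmap.heights.max():.2f} mm does not fit a 16-bit raster "
            f"at scale {height_scale} mm/unit"
        )
    _write_raster(Path(raster_path), quant.astype(np.uint16))
    _write_raster(
        _mask_path(raster_path), np.where(dmap.breast_mask, 255, 0).astype(np.uint8)
    )
    meta = {
        "subject_id": dmap.subject_id,
        "pixel_area_mm2": dmap.pixel_area,
        "breast_thickness_mm": dmap.breast_thickness,
        "height_scale_mm_per_unit": height_scale,
    }
    Path(metadata_path).write_text(json.dumps(meta, indent=2))


def load_density_map(raster_path: str | Path, metadata_path: str | Path) -> DensityMap:
    """Load a density map written by :func:`save_density_map`."""
    meta = json.loads(Path(metadata_path).read_text())
    for key in ("pixel_area_mm2", "breast_thickness_mm", "height_scale_mm_per_unit"):
        if key not in meta:
            raise DensityMapError(f"metadata {metadata_path} missing key {key!r}")
    raw = _read_raster(Path(raster_path)).astype(np.int64)
    mask = _read_raster(_mask_path(raster_path)) > 0
    if mask.shape != raw.shape:
        raise DensityMapError(
            f"mask raster shape {mask.shape} != height raster shape {raw.shape}"
        )
    heights = raw * float(meta["height_scale_mm_per_unit"])
    heights[~mask] = 0.0
    return DensityMap(
        heights=heights,
        breast_mask=mask,
        pixel_area=float(meta["pixel_area_mm2"]),
        breast_thickness=float(meta["breast_thickness_mm"]),
        subject_id=str(meta.get("subject_id", "")),
    )
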