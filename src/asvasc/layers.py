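"""Depth-slab projection and quadrant ROI construction for AS-OCTA scans.

The anterior-segment scans are 3 x 3 mm fields sampled at 304 x 304 A-scans.
Vascular metrics are read off two depth slabs of the volume: a *superficial*
slab from the conjunctival epithelium down to 200 um, and a *deep*
(intrascleral) slab from 200 um to 1000 um.  Each en-face image is further
split into nasal and temporal quadrants; the quadrant-to-image-side mapping
depends on eye laterality (OD/OS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "DEFAULT_LATERAL_SPACING",
    "SUPERFICIAL",
    "DEEP",
    "DepthLayer",
    "OCTAVolume",
    "EnFaceImage",
    "ROIMask",
    "load_enface",
    "load_volume",
    "project_slab",
    "quadrant_roi",
]

#: Lateral sampling of a 3 x 3 mm scan acquired as 304 x 304 A-scans (um/px).
DEFAULT_LATERAL_SPACING = 3000.0 / 304.0


@dataclass(frozen=True)
class DepthLayer:
    """Half-open axial interval [z_min, z_max) in micrometres."""

    name: str
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.z_min < self.z_max):
            raise ValueError(
                f"invalid depth layer {self.name!r}: need 0 <= z_min < z_max, "
                f"got [{self.z_min}, {self.z_max})"
            )


#: Conjunctival epithelium to 200 um.
SUPERFICIAL = DepthLayer("superficial", 0.0, 200.0)
#: 200 um to 1000 um — the intrascleral layer.
DEEP = DepthLayer("deep", 200.0, 1000.0)


@dataclass
class OCTAVolume:
    """A 3-D OCTA scan: (depth, rows, cols) with physical voxel spacing."""

    voxels: np.ndarray
    axial_spacing: float  # um per depth sample
    lateral_spacing: float = DEFAULT_LATERAL_SPACING  # um per pixel
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3-D (depth, rows, cols)")
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def depth_extent(self) -> float:
        """Total axial extent in um."""
        return self.voxels.shape[0] * self.axial_spacing


@dataclass
class EnFaceImage:
    """A 2-D en-face projection (or directly loaded en-face frame)."""

    pixels: np.ndarray
    lateral_spacing: float = DEFAULT_LATERAL_SPACING
    layer: str | None = None  # "superficial" | "deep"
    region: str | None = None  # "nasal" | "temporal"
    eye: str | None = None  # "OD" | "OS"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("en-face image must be a non-empty 2-D array")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("en-face image contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """Binary analysis region paired with an image of the same shape."""

    pixels: np.ndarray
    quadrant: str = "whole"  # "nasal" | "temporal" | "whole"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.pixels.any():
            raise ValueError("ROI mask is empty")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


def load_enface(path: str | Path, meta: dict[str, Any] | None = None) -> EnFaceImage:
    """Load a single-channel 8/16-bit PNG or TIFF as an en-face image.

    Intensities are preserved bit-exactly.  ``meta`` may carry
    ``lateral_spacing`` (um/px, default 3000/304) and the usual labels
    (``layer``, ``region``, ``eye``).
    """
    meta = dict(meta or {})
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - message path
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        channel = meta.pop("channel", None)
        if channel is None:
            raise ValueError(
                f"{path} is multi-channel; declare meta['channel'] to select one"
            )
        arr = arr[..., int(channel)]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    return EnFaceImage(
        pixels=arr,
        lateral_spacing=float(meta.pop("lateral_spacing", DEFAULT_LATERAL_SPACING)),
        layer=meta.pop("layer", None),
        region=meta.pop("region", None),
        eye=meta.pop("eye", None),
        metadata=meta,
    )


def load_volume(
    path: str | Path,
    axial_spacing: float,
    lateral_spacing: float = DEFAULT_LATERAL_SPACING,
    meta: dict[str, Any] | None = None,
) -> OCTAVolume:
    """Load a multi-page TIFF stack (page = depth sample) as an OCTA volume."""
    voxels = tifffile.imread(Path(path))
    if voxels.ndim == 2:
        voxels = voxels[None]
    return OCTAVolume(
        voxels=voxels,
        axial_spacing=float(axial_spacing),
        lateral_spacing=float(lateral_spacing),
        metadata=dict(meta or {}),
    )


def _slab_indices(vol: OCTAVolume, layer: DepthLayer) -> tuple[int, int]:
    """Map [z_min, z_max) in um to voxel index range [i0, i1).

    Depth sample i spans physical depths [i*dz, (i+1)*dz), so the half-open
    interval maps to indices floor(z_min/dz) .. floor(z_max/dz): the two
    standard slabs partition the depth samples with no double-counted row.
    """
    dz = vol.axial_spacing
    i0 = int(np.floor(layer.z_min / dz))
    i1 = int(np.floor(layer.z_max / dz))
    i0 = max(i0, 0)
    i1 = min(i1, vol.voxels.shape[0])
    return i0, i1


def project_slab(
    vol: OCTAVolume,
    layer: DepthLayer,
    mode: Literal["max", "mean"] = "max",
) -> EnFaceImage:
    """Project a depth slab of the volume onto an en-face image.

    ``mode="max"`` is the maximum-intensity projection conventional for OCTA
    flow signal; ``mode="mean"`` averages the slab.
    """
    i0, i1 = _slab_indices(vol, layer)
    if i1 <= i0:
        raise ValueError(
            f"layer {layer.name!r} [{layer.z_min}, {layer.z_max}) um does not "
            f"intersect the volume depth extent ({vol.depth_extent:g} um)"
        )
    slab = vol.voxels[i0:i1]
    if mode == "max":
        pixels = slab.max(axis=0)
    elif mode == "mean":
        pixels = slab.mean(axis=0)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return EnFaceImage(
        pixels=pixels,
        lateral_spacing=vol.lateral_spacing,
        layer=layer.name,
        metadata=dict(vol.metadata),
    )


def _limbus_column(limbus: Sequence[Sequence[float]], n_rows: int) -> np.ndarray:
    """Interpolate a (x, y) polyline to one boundary column per image row."""
    pts = np.asarray(limbus, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("limbus must be a polyline of >= 2 (x, y) vertices")
    x, y = pts[:, 0], pts[:, 1]
    order = np.argsort(y)
    rows = np.arange(n_rows, dtype=float)
    return np.interp(rows, y[order], x[order])


def quadrant_roi(
    img: EnFaceImage,
    quadrant: Literal["nasal", "temporal"],
    limbus: Sequence[Sequence[float]] | None = None,
    eye: str | None = None,
    nasal_side_od: Literal["left", "right"] = "right",
) -> ROIMask:
    """Build the nasal or temporal half-frame ROI, optionally limbus-clipped.

    The frame is split down the middle column.  For a right eye (OD) in the
    standard en-face view the nasal conjunctiva is on the ``nasal_side_od``
    side of the image (default right); OS mirrors it.  When a limbus polyline
    (list of (x, y) = (col, row) vertices) is supplied, pixels on the corneal
    side of the boundary — the side away from the selected quadrant — are
    excluded.
    """
    if quadrant not in ("nasal", "temporal"):
        raise ValueError(f"unknown quadrant {quadrant!r}")
    eye = (eye or img.eye or "OD").upper()
    if eye not in ("OD", "OS"):
        raise ValueError(f"unknown eye laterality {eye!r}")

    n_rows, n_cols = img.shape
    nasal_right = (nasal_side_od == "right") == (eye == "OD")
    want_right = nasal_right if quadrant == "nasal" else not nasal_right

    cols = np.arange(n_cols)
    half = n_cols // 2
    mask = np.broadcast_to(cols >= half if want_right else cols < half,
                           (n_rows, n_cols)).copy()

    if limbus is not None:
        # The cornea lies on the far side of the limbus from the quadrant:
        # keep only pixels strictly beyond the boundary column, row by row.
        bound = _limbus_column(limbus, n_rows)[:, None]
        keep = cols[None, :] > bound if want_right else cols[None, :] < bound
        mask &= keep

    if not mask.any():
        raise ValueError(f"{quadrant} ROI is empty after limbus exclusion")
    return ROIMask(pixels=mask, quadrant=quadrant)
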