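"""Calibrated cross-sectional area measurement.

Reproduces the manual ImageJ workflow on synthetic inputs: a planar contour
(or binary mask) in pixel coordinates is converted to an area in mm^2 via a
pixel-calibration scale.  Two entry points are provided because manual ROIs
may be polygonal or freehand-rasterized: :func:`polygon_area` for vertex
lists and :func:`mask_area` for binary rasters.

Coordinate convention (shared with :mod:`ccar.synthetic`): pixel centers sit
at integer coordinates, origin at the top-left, y increasing downward.  A
pixel is counted entirely in or out of a mask; no partial-pixel coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Calibration",
    "Contour",
    "AreaMeasurement",
    "MEASUREMENT_SITES",
    "polygon_area",
    "mask_area",
    "average_repeats",
    "reference_dural_sac_area",
    "write_mask_png",
    "read_mask_png",
]

#: The five structures measured per patient (CT: bony canal and ossified
#: mass; MRI: dural sac one level above/below, and spinal cord).
MEASUREMENT_SITES = (
    "canal_ct",
    "mass_ct",
    "dural_sac_upper_mri",
    "dural_sac_lower_mri",
    "cord_mri",
)


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel size, in mm per pixel."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if not (self.mm_per_pixel > 0):
            raise ValueError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")

    @property
    def mm2_per_pixel(self) -> float:
        """Area of one pixel in mm^2."""
        return self.mm_per_pixel**2


@dataclass(frozen=True)
class Contour:
    """A closed planar contour as an ordered vertex list in pixel coordinates.

    Vertices are (x, y) pairs; the closing edge back to the first vertex is
    implicit.  At least 3 distinct vertices are required.  Self-intersection
    is not detected (anatomical ROIs are near-convex); a self-intersecting
    contour yields the signed-area magnitude, which may not be meaningful.
    """

    vertices: tuple[tuple[float, float], ...]
    calibration: Calibration

    def __init__(self, vertices: Iterable[Sequence[float]], calibration: Calibration):
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(set(verts)) < 3:
            raise ValueError("contour needs at least 3 distinct vertices")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "calibration", calibration)


@dataclass(frozen=True)
class AreaMeasurement:
    """One raw area reading: a site, an observer, and a repeat index."""

    value: float  # mm^2
    site: str
    observer: str
    repeat: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"area must be >= 0, got {self.value}")
        if self.site not in MEASUREMENT_SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {MEASUREMENT_SITES}")
        if self.repeat not in (1, 2):
            raise ValueError(f"repeat must be 1 or 2, got {self.repeat}")


def polygon_area(contour: Contour) -> float:
    """Area enclosed by a polygonal contour, in mm^2.

    Shoelace formula on the vertex list, absolute value taken so winding
    direction never matters, then scaled by the squared pixel size.
    """
    xy = np.asarray(contour.vertices, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    signed_px2 = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return abs(signed_px2) * contour.calibration.mm2_per_pixel


def mask_area(mask: np.ndarray, calibration: Calibration) -> float:
    """Area of a binary mask, in mm^2: set-pixel count times pixel area."""
    arr = np.asarray(mask)
    if arr.size == 0:
        raise ValueError("empty mask")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must contain only {0, 1}")
    return float(arr.sum()) * calibration.mm2_per_pixel


def average_repeats(measurements: Sequence[AreaMeasurement]) -> float:
    """Mean area across observers and repeats for one site.

    Each image was read twice by each of two observers and the mean of the
    readings enters all downstream ratios; any non-empty subset of readings
    is accepted so partially measured sites still average.
    """
    if len(measurements) == 0:
        raise ValueError("need at least one measurement")
    sites = {m.site for m in measurements}
    if len(sites) > 1:
        raise ValueError(f"measurements mix sites: {sorted(sites)}")
    return float(np.mean([m.value for m in measurements]))


def reference_dural_sac_area(upper: float, lower: float) -> float:
    """Reference dural-sac area: mean of the adjacent upper and lower levels.

    At the compressed level itself the sac is deformed, so the mean sac area
    of the adjacent segments stands in for the normal (uncompressed) value.
    """
    if upper < 0 or lower < 0:
        raise ValueError(f"areas must be >= 0, got ({upper}, {lower})")
    return (upper + lower) / 2.0


# -- phantom mask I/O: single-channel PNG (0/255) + JSON sidecar -------------


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit single-channel PNG with values {0,255}."""
    from PIL import Image

    arr = np.asarray(mask, dtype=np.uint8)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must contain only {0, 1}")
    Image.fromarray(arr * 255, mode="L").save(Path(path), format="PNG")


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG back to a {0,1} uint8 mask."""
    from PIL import Image

    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return (arr > 127).astype(np.uint8)


def write_sidecar(path: str | Path, calibration: Calibration, truth_mm2: dict[str, float]) -> None:
    """JSON sidecar holding the calibration and analytic ground-truth areas."""
    payload = {
        "mm_per_pixel": calibration.mm_per_pixel,
        "ground_truth_mm2": {k: float(v) for k, v in truth_mm2.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar(path: str | Path) -> tuple[Calibration, dict[str, float]]:
    payload = json.loads(Path(path).read_text())
    return Calibration(payload["mm_per_pixel"]), payload["ground_truth_mm2"]
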