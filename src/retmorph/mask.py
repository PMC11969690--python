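"""Labeled artery/vein segmentation masks and the optic-disc measurement frame.

A fundus segmentation is represented as a 2-D label image (0 = background,
1 = artery, 2 = vein) together with a disc specification giving the optic
disc center and diameter in pixels.  All downstream morphometry is organised
around three concentric annuli (zones A, B, C) whose radii are expressed in
multiples of the disc diameter measured from the disc *center*:

    disc interior : r/dd <= 0.5          (never measured)
    zone A        : 0.5 < r/dd <= 1.0
    zone B        : 1.0 < r/dd <= 1.5    (vessel calibers)
    zone C        : 1.5 < r/dd <= 2.5    (density, bifurcation geometry,
                                          tortuosity, fractal dimension)

Boundaries are closed on the outer edge, so a point exactly on r = 1.0 dd
belongs to zone A.

Coordinates are (row, col), 0-based, with pixel centers at integer positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

BACKGROUND = 0
ARTERY = 1
VEIN = 2

VALID_LABELS = frozenset({BACKGROUND, ARTERY, VEIN})

#: (zone name, inner radius, outer radius) in units of disc diameter,
#: measured from the disc center; half-open (inner, outer].
ZONE_BOUNDS = (
    ("A", 0.5, 1.0),
    ("B", 1.0, 1.5),
    ("C", 1.5, 2.5),
)


class MaskError(ValueError):
    """Raised for invalid segmentation masks or disc specifications."""


@dataclass(frozen=True)
class DiscSpec:
    """Optic disc location and size in pixel coordinates.

    Parameters
    ----------
    center : (float, float)
        Disc center as (row, col).
    dd_px : float
        Disc diameter in pixels; must be positive.
    scale_um_per_px : float or None
        Physical scale if known; calibers are reported in µm when set.
    """

    center: tuple[float, float]
    dd_px: float
    scale_um_per_px: float | None = None

    def __post_init__(self) -> None:
        if not self.dd_px > 0:
            raise MaskError(f"dd_px must be positive, got {self.dd_px}")
        if self.scale_um_per_px is not None and not self.scale_um_per_px > 0:
            raise MaskError("scale_um_per_px must be positive when given")

    def radii(self, shape: tuple[int, int]) -> np.ndarray:
        """Radial distance (px) from the disc center for every pixel."""
        rr, cc = np.indices(shape)
        return np.hypot(rr - self.center[0], cc - self.center[1])

    def to_json(self) -> dict:
        return {
            "center": [float(self.center[0]), float(self.center[1])],
            "dd_px": float(self.dd_px),
            "scale_um_per_px": self.scale_um_per_px,
        }


@dataclass(frozen=True)
class SegmentationMask:
    """Validated artery/vein label image."""

    pixels: np.ndarray  # 2-D uint8, labels in {0, 1, 2}

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.size == 0:
            raise MaskError("mask must be a non-empty 2-D array")
        bad = set(np.unique(px)) - VALID_LABELS
        if bad:
            raise MaskError(f"unknown label(s) {sorted(bad)}; expected 0/1/2")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def class_mask(self, vessel_class: int) -> np.ndarray:
        """Boolean foreground of one vessel class (ARTERY or VEIN)."""
        if vessel_class not in (ARTERY, VEIN):
            raise MaskError(f"vessel_class must be 1 or 2, got {vessel_class}")
        return self.pixels == vessel_class

    @property
    def vessel_mask(self) -> np.ndarray:
        """Boolean union of artery and vein pixels."""
        return self.pixels != BACKGROUND


def zone_of_radius(r: np.ndarray | float, dd_px: float, bounds=ZONE_BOUNDS) -> np.ndarray:
    """Map radial distances (px) to zone labels 'A'/'B'/'C'/'outside'.

    Intervals are half-open (inner, outer] in units of disc diameter, so the
    shared boundary belongs to the inner zone (e.g. r = 1.0 dd is zone A).
    """
    rel = np.asarray(r, dtype=float) / dd_px
    out = np.full(rel.shape, "outside", dtype=object)
    for name, lo, hi in bounds:
        out[(rel > lo) & (rel <= hi)] = name
    return out


def zone_annulus(shape: tuple[int, int], disc: DiscSpec, zone: str, bounds=ZONE_BOUNDS) -> np.ndarray:
    """Boolean pixel mask of one zone annulus clipped to the image."""
    bounds = {name: (lo, hi) for name, lo, hi in bounds}
    if zone not in bounds:
        raise MaskError(f"unknown zone {zone!r}")
    lo, hi = bounds[zone]
    rel = disc.radii(shape) / disc.dd_px
    return (rel > lo) & (rel <= hi)


def read_mask(path: str | Path, disc_path: str | Path) -> tuple[SegmentationMask, DiscSpec]:
    """Load a PNG/TIFF label image and its JSON disc specification.

    The image must contain only labels {0, 1, 2}.  The disc JSON has keys
    ``center`` ([row, col]), ``dd_px`` and optionally ``scale_um_per_px``.
    """
    path, disc_path = Path(path), Path(disc_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not disc_path.exists():
        raise FileNotFoundError(disc_path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # paletted/rgb export of a label image
        raise MaskError(f"{path} is not a single-channel label image")
    mask = SegmentationMask(arr.astype(np.uint8))
    spec = json.loads(disc_path.read_text())
    disc = DiscSpec(
        center=(float(spec["center"][0]), float(spec["center"][1])),
        dd_px=float(spec["dd_px"]),
        scale_um_per_px=spec.get("scale_um_per_px"),
    )
    h, w = mask.shape
    r0, c0 = disc.center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise MaskError(f"disc center {disc.center} outside image bounds {mask.shape}")
    return mask, disc


def write_mask(mask: SegmentationMask, disc: DiscSpec, path: str | Path, disc_path: str | Path) -> None:
    """Write the label image (PNG/TIFF, 8-bit) and disc JSON; round-trips through read_mask."""
    Image.fromarray(mask.pixels.astype(np.uint8)).save(Path(path))
    Path(disc_path).write_text(json.dumps(disc.to_json(), indent=2))
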