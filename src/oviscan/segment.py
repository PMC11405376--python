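"""2D/3D processing chain: ROI crop, point-wise contrast, value-band masks,
and separation of the organ solid (external) from its lumen (internal).

The chain mirrors an interactive tomography workflow: a rectangular volume
of interest is cropped in all three views, a narrow band of gray values is
stretched over the full range for visibility, masks are defined by a
minimum and maximum value (closed interval on both ends), and the tissue
mask is split into the whole-organ solid and the enclosed cavity.

Value bands are explicit user inputs, never inferred: the source protocol
was interactive and its thresholds are unrecoverable.  An Otsu-based
convenience (:func:`suggest_band`) is provided and labeled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imgio import BinaryMask, ImageStack

__all__ = [
    "RoiBox",
    "ValueBand",
    "crop_roi",
    "enhance_contrast",
    "band_mask",
    "split_structures",
    "suggest_band",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoiBox:
    """Half-open box ``[z0,z1) × [y0,y1) × [x0,x1)`` in voxel indices."""

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def validate(self, shape: tuple[int, int, int]) -> None:
        for lo, hi, ext, ax in (
            (self.z0, self.z1, shape[0], "z"),
            (self.y0, self.y1, shape[1], "y"),
            (self.x0, self.x1, shape[2], "x"),
        ):
            if not (0 <= lo < hi <= ext):
                raise ValueError(f"ROI {ax}-range [{lo}, {hi}) invalid for extent {ext}")

    def intersect(self, other: "RoiBox") -> "RoiBox":
        return RoiBox(
            max(self.z0, other.z0), min(self.z1, other.z1),
            max(self.y0, other.y0), min(self.y1, other.y1),
            max(self.x0, other.x0), min(self.x1, other.x1),
        )


@dataclass(frozen=True)
class ValueBand:
    """Closed gray-value interval ``[min_value, max_value]``."""

    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if self.min_value > self.max_value:
            raise ValueError("min_value must be ≤ max_value")


def crop_roi(stack: ImageStack, box: RoiBox) -> ImageStack:
    """Copy the boxed sub-volume; spacing is unchanged (no resampling)."""
    box.validate(stack.shape)
    sub = stack.voxels[box.z0 : box.z1, box.y0 : box.y1, box.x0 : box.x1].copy()
    return ImageStack(voxels=sub, spacing_um=stack.spacing_um, origin=stack.origin)


def enhance_contrast(stack: ImageStack, band: ValueBand) -> ImageStack:
    """Map the band linearly onto the stack's full value domain.

    Values at or below the band minimum map to the domain minimum, values
    at or above the band maximum to the domain maximum, affine in between.
    Integer outputs are rounded half-up; the dtype is preserved.
    """
    lo, hi = stack.value_domain()
    if band.min_value == band.max_value:
        raise ValueError("degenerate band (min == max) cannot be stretched")
    if band.min_value < lo or band.max_value > hi:
        raise ValueError(f"band {band} outside value domain [{lo}, {hi}]")
    x = stack.voxels.astype(np.float64)
    y = lo + (x - band.min_value) * (hi - lo) / (band.max_value - band.min_value)
    y = np.clip(y, lo, hi)
    if np.issubdtype(stack.voxels.dtype, np.integer):
        y = np.floor(y + 0.5)  # round half-up
    return ImageStack(voxels=y.astype(stack.voxels.dtype), spacing_um=stack.spacing_um,
                      origin=stack.origin)


def band_mask(stack: ImageStack, band: ValueBand) -> BinaryMask:
    """Select voxels with ``min_value ≤ value ≤ max_value`` (closed band)."""
    grid = (stack.voxels >= band.min_value) & (stack.voxels <= band.max_value)
    return BinaryMask(grid=grid, spacing_um=stack.spacing_um)


def suggest_band(stack: ImageStack) -> ValueBand:
    """Convenience only: an automatic band from Otsu's threshold to the
    domain maximum.  The core path treats bands as explicit inputs."""
    from skimage.filters import threshold_otsu

    _, hi = stack.value_domain()
    return ValueBand(float(threshold_otsu(stack.voxels)), hi)


def _full_structure(ndim: int) -> np.ndarray:
    # 8-connectivity in 2D, 26 in 3D for tissue
    return np.ones((3,) * ndim, dtype=bool)


def split_structures(tissue_mask: BinaryMask) -> tuple[BinaryMask, BinaryMask]:
    """Split a tissue mask into the organ solid and its lumen.

    ``external`` is the largest connected component of tissue
    (8/26-connectivity) with every enclosed cavity filled — the whole-organ
    solid.  ``internal`` is ``external`` minus that tissue component: the
    lumen, including inter-fold clefts and blind crypts.  Cavities are
    filled under the complementary (4/6) connectivity, the standard duality
    that avoids topological leaks.
    """
    grid = tissue_mask.grid
    if not grid.any():
        raise ValueError("empty tissue mask")
    labels, n = ndi.label(grid, structure=_full_structure(grid.ndim))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
    else:
        keep = 1
    component = labels == keep
    # default binary_fill_holes structure is the 4/6-connected cross
    external = ndi.binary_fill_holes(component)
    internal = external & ~component
    if not internal.any():
        log.info("split_structures: no enclosed cavity; internal mask is empty")
    sp = tissue_mask.spacing_um
    return BinaryMask(external, sp), BinaryMask(internal, sp)
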