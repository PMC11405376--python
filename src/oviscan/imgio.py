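"""Image-stack, mask and mesh containers plus file I/O.

Conventions used throughout the package:

* voxel arrays are ordered ``(z, y, x)``; a single slice is a stack of
  depth 1;
* physical spacing travels with every object as an ``(x, y, z)`` triple in
  micrometres and is never resampled by any operation;
* pixel coordinates are 0-based and boxes are half-open;
* meshes live in millimetre coordinates.

Interchange formats are multi-page TIFF (uint8/uint16) or directories of
per-slice PNG/TIFF files for stacks, and STL/PLY/OBJ for meshes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import trimesh

__all__ = [
    "ImageStack",
    "BinaryMask",
    "Mesh",
    "read_stack",
    "write_stack",
    "write_mask_stack",
    "read_mask_stack",
    "export_mesh",
    "load_mesh",
]

_SLICE_SUFFIXES = {".tif", ".tiff", ".png"}


def _check_spacing(spacing_um: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing_um)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValueError(f"spacing_um must be three positive reals, got {spacing_um!r}")
    return sp  # type: ignore[return-value]


@dataclass
class ImageStack:
    """A 3D grid of gray values with anisotropy-aware spacing.

    ``voxels`` is ordered ``(z, y, x)``; ``spacing_um`` is ``(x, y, z)`` in
    micrometres; ``origin`` is the physical position of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:  # tolerate a bare slice
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a 3D (z, y, x) array with ≥ 1 slice")
        self.spacing_um = _check_spacing(self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def value_domain(self) -> tuple[float, float]:
        """Representable value range for the stack's dtype.

        Integer stacks use the full dtype range; float stacks use [0, 1].
        """
        dt = self.voxels.dtype
        if np.issubdtype(dt, np.integer):
            info = np.iinfo(dt)
            return float(info.min), float(info.max)
        return 0.0, 1.0


@dataclass
class BinaryMask:
    """A boolean 2D or 3D grid sharing spacing with its source stack."""

    grid: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.dtype != bool:
            if not np.isin(self.grid, (0, 1)).all():
                raise ValueError("mask values must be strictly boolean (0/1)")
            self.grid = self.grid.astype(bool)
        if self.grid.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        self.spacing_um = _check_spacing(self.spacing_um)

    @property
    def ndim(self) -> int:
        return self.grid.ndim

    def count(self) -> int:
        return int(self.grid.sum())

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = (s / 1000.0 for s in self.spacing_um)
        return sx * sy * sz

    def pixel_area_mm2(self) -> float:
        sx, sy, _ = (s / 1000.0 for s in self.spacing_um)
        return sx * sy


@dataclass
class Mesh:
    """Triangle mesh in millimetre coordinates."""

    vertices: np.ndarray
    faces: np.ndarray
    closed: bool = False
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of triangles")
        if len(self.faces) == 0 or len(self.vertices) == 0:
            raise ValueError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# stack I/O


def _spacing_from_tiff(path: Path) -> tuple[float, float, float] | None:
    """Best-effort spacing from TIFF resolution tags (x, y) and ImageJ z metadata."""
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None or yres is None:
                return None
            unit_um = {2: 25400.0, 3: 10000.0}.get(
                getattr(unit, "value", 3) if unit is not None else 3
            )
            if unit_um is None:
                return None

            def _per_px(tag) -> float | None:
                num, den = tag.value
                if num == 0:
                    return None
                return unit_um * den / num

            sx, sy = _per_px(xres), _per_px(yres)
            if sx is None or sy is None:
                return None
            sz = sx
            ij = tf.imagej_metadata
            if ij and "spacing" in ij:
                sz = float(ij["spacing"])
                if ij.get("unit") in ("micron", "um", "µm", None):
                    pass  # already micrometres under our writing convention
            return (sx, sy, sz)
    except Exception:
        return None


def read_stack(path: str | os.PathLike, spacing_um: Sequence[float] | None = None) -> ImageStack:
    """Read a multi-page TIFF or a directory of equally sized slices.

    Directory slices are taken in lexicographic order. ``spacing_um``
    overrides any resolution metadata found in the file; with neither,
    spacing defaults to 1 µm isotropic.
    """
    p = Path(path)
    tag_spacing: tuple[float, float, float] | None = None
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _SLICE_SUFFIXES)
        if not files:
            raise OSError(f"no slice files (*.tif/*.tiff/*.png) in {p}")
        slices = []
        for f in files:
            if f.suffix.lower() == ".png":
                import imageio.v3 as iio

                arr = np.asarray(iio.imread(f))
            else:
                arr = tifffile.imread(f)
            if arr.ndim == 3:  # drop trivial color axis from grayscale PNGs
                arr = arr[..., 0]
            slices.append(arr)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {p}: {sorted(shapes)}")
        voxels = np.stack(slices, axis=0)
    else:
        if not p.exists():
            raise OSError(f"no such file: {p}")
        voxels = tifffile.imread(p)
        if voxels.ndim == 2:
            voxels = voxels[np.newaxis]
        tag_spacing = _spacing_from_tiff(p)
    if spacing_um is not None:
        sp = _check_spacing(spacing_um)
    elif tag_spacing is not None:
        sp = tag_spacing
    else:
        sp = (1.0, 1.0, 1.0)
    return ImageStack(voxels=voxels, spacing_um=sp)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as multi-page TIFF, embedding spacing in resolution tags."""
    sx, sy, sz = stack.spacing_um
    tifffile.imwrite(
        Path(path),
        stack.voxels,
        resolution=(10000.0 / sx, 10000.0 / sy),
        resolutionunit="CENTIMETER",
        imagej=stack.voxels.dtype in (np.dtype(np.uint8), np.dtype(np.uint16)),
        metadata={"spacing": sz, "unit": "um"},
    )


def write_mask_stack(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as a 0/255 uint8 multi-page TIFF."""
    grid = mask.grid if mask.ndim == 3 else mask.grid[np.newaxis]
    stack = ImageStack(voxels=(grid.astype(np.uint8) * 255), spacing_um=mask.spacing_um)
    write_stack(stack, path)


def read_mask_stack(
    path: str | os.PathLike, spacing_um: Sequence[float] | None = None, squeeze: bool = True
) -> BinaryMask:
    """Read a mask written by :func:`write_mask_stack` (threshold at 128)."""
    stack = read_stack(path, spacing_um=spacing_um)
    grid = stack.voxels >= 128
    if squeeze and grid.shape[0] == 1:
        grid = grid[0]
    return BinaryMask(grid=grid, spacing_um=stack.spacing_um)


# ---------------------------------------------------------------------------
# mesh I/O

_MESH_FORMATS = {"stl", "ply", "obj"}


def export_mesh(mesh: Mesh, path: str | os.PathLike, format: str | None = None) -> None:
    """Export a triangle mesh as STL/PLY/OBJ (format inferred from suffix)."""
    p = Path(path)
    fmt = (format or p.suffix.lstrip(".")).lower()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; choose one of {sorted(_MESH_FORMATS)}")
    mesh.as_trimesh().export(p, file_type=fmt)


def load_mesh(path: str | os.PathLike) -> Mesh:
    tm = trimesh.load_mesh(Path(path), process=False)
    return Mesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces),
                closed=bool(tm.is_watertight))
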