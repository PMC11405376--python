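"""Synthetic phantoms with known ground truth.

Three families of phantoms stand in for microCT acquisitions of a tubular
organ, at desk scale and with exact ground truth:

* **fold cross-sections** — an annular tissue wall whose mucosa carries N
  radially oriented folds (rounded-tip rectangles) protruding into the
  lumen, optionally with blind crypts in the wall.  Default sizes emulate
  mucosal folds of a swine oviduct imaged at 7.4 µm/px: fold lengths of a
  few hundred µm and widths of some tens to a few hundred µm.
* **fractal rasters** — binary sets of known box-counting dimension (line,
  filled square, Koch curve, Sierpinski triangle) plus Bernoulli "dust"
  for lacunarity-ordering experiments.
* **voxel tubes** — straight, helical and fold-bearing tubes with analytic
  volume/surface where a closed form exists.

Every generator is a pure function of its spec (including the seed):
regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import line as _draw_line

from .imgio import BinaryMask

__all__ = [
    "FoldPhantomSpec",
    "TubePhantomSpec",
    "PhantomGroundTruth",
    "make_fold_cross_section",
    "make_fractal_raster",
    "make_tube_volume",
]

#: Acquisition pixel size of the emulated microCT protocol (µm per pixel).
DEFAULT_PX_SIZE_UM = 7.4


@dataclass
class PhantomGroundTruth:
    """Ground-truth ledger attached to every phantom.

    Analytic values are present only when a closed form exists for the
    generating spec; otherwise they are ``None``.
    """

    true_fold_lengths_um: list[float] = field(default_factory=list)
    true_fold_widths_um: list[float] = field(default_factory=list)
    analytic_fd: float | None = None
    analytic_volume_mm3: float | None = None
    analytic_surface_mm2: float | None = None
    height_mm: float | None = None
    #: angular position of each fold (radians, same order as lengths/widths)
    fold_angles_rad: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.true_fold_lengths_um):
            raise ValueError("fold lengths must be strictly positive")
        if any(v <= 0 for v in self.true_fold_widths_um):
            raise ValueError("fold widths must be strictly positive")



def _resolve(value, n: int, rng: np.random.Generator) -> np.ndarray:
    """A per-fold array from a scalar or a (lo, hi) uniform range."""
    if np.isscalar(value):
        return np.full(n, float(value))
    lo, hi = value
    if not (0 < lo <= hi):
        raise ValueError(f"invalid range {value!r}")
    return rng.uniform(lo, hi, size=n)


@dataclass
class FoldPhantomSpec:
    """Geometry of one synthetic cross-section.

    Lengths/widths may be scalars (all folds equal) or ``(lo, hi)`` ranges
    sampled uniformly per fold with ``seed``.  Defaults place fold sizes in
    the mid range reported for oviduct mucosa at 7.4 µm/px (lengths
    ≈150–800 µm, widths ≈60–270 µm).
    """

    image_size_px: tuple[int, int] = (576, 576)
    px_size_um: float = DEFAULT_PX_SIZE_UM
    lumen_radius_px: float = 180.0
    wall_thickness_px: float = 64.0
    n_folds: int = 6
    fold_length_px: "float | tuple[float, float]" = (20.0, 110.0)
    fold_width_px: "float | tuple[float, float]" = (8.0, 36.0)
    n_crypts: int = 0
    crypt_depth_px: float = 32.0
    crypt_width_px: float = 8.0
    angle_jitter_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 8 or w < 8:
            raise ValueError("image_size_px too small")
        if self.px_size_um <= 0:
            raise ValueError("px_size_um must be > 0")
        if self.lumen_radius_px <= 0 or self.wall_thickness_px <= 0:
            raise ValueError("radii must be > 0")
        if self.n_folds < 0 or self.n_crypts < 0:
            raise ValueError("counts must be ≥ 0")
        max_len = self.fold_length_px if np.isscalar(self.fold_length_px) else self.fold_length_px[1]
        if self.n_folds and max_len >= self.lumen_radius_px:
            raise ValueError("folds must protrude into, never across, the lumen "
                             "(fold_length_px < lumen_radius_px)")
        outer = self.lumen_radius_px + self.wall_thickness_px
        if outer + 2 > min(h, w) / 2:
            raise ValueError("outer wall exceeds image extent")
        if self.n_crypts and self.crypt_depth_px >= self.wall_thickness_px:
            raise ValueError("crypts must be blind (crypt_depth_px < wall_thickness_px)")


def _fold_geometry(spec: FoldPhantomSpec, rng: np.random.Generator):
    """Per-fold (angle, length, width), validated against merging."""
    n = spec.n_folds
    lengths = _resolve(spec.fold_length_px, n, rng)
    widths = _resolve(spec.fold_width_px, n, rng)
    base = np.arange(n) * (2 * math.pi / n)
    jitter = rng.uniform(-1, 1, size=n) * spec.angle_jitter_frac * (2 * math.pi / n) / 2
    angles = base + jitter + rng.uniform(0, 2 * math.pi)  # global rotation
    # adjacent folds must stay separated down to the tip radius of the
    # longer one, else the phantom is unmeasurable
    for i in range(n):
        j = (i + 1) % n
        if n == 1:
            break
        gap = (angles[j] - angles[i]) % (2 * math.pi)
        r_min = spec.lumen_radius_px - max(lengths[i], lengths[j])
        chord = 2 * r_min * math.sin(min(gap, math.pi) / 2)
        if chord <= (widths[i] + widths[j]) / 2 + 2:
            raise ValueError(
                f"folds {i} and {j} would merge (clearance {chord:.1f} px); "
                "reduce n_folds, widths or lengths, or enlarge lumen_radius_px"
            )
        if min(lengths[i], widths[i]) <= 0:
            raise ValueError("fold sizes must be positive")
    for i in range(n):
        if lengths[i] <= widths[i] / 2:
            raise ValueError("fold length must exceed half its width (rounded tip)")
    return angles, lengths, widths


def make_fold_cross_section(
    spec: FoldPhantomSpec,
) -> tuple[BinaryMask, BinaryMask, PhantomGroundTruth]:
    """Rasterize one cross-section phantom.

    Returns ``(tissue_mask, lumen_mask, truth)`` where tissue is the
    annular wall plus folds (minus crypts), lumen is the cavity enclosed by
    the wall minus tissue (clefts and crypts included), and truth records
    each fold's constructed length/width in µm.

    A fold of constructed length L extends from the inner wall circle to a
    rounded tip at radius ``lumen_radius − L``; its width W is the width of
    the rectangular shaft and the diameter of the tip cap.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    r0 = spec.lumen_radius_px
    r1 = r0 + spec.wall_thickness_px

    tissue = (rr >= r0) & (rr <= r1)

    angles, lengths, widths = ([], [], [])
    if spec.n_folds:
        angles, lengths, widths = _fold_geometry(spec, rng)
        for theta, L, W in zip(angles, lengths, widths):
            uy, ux = math.sin(theta), math.cos(theta)  # outward unit vector
            by, bx = cy + r0 * uy, cx + r0 * ux  # base point on inner wall
            ay, ax = -uy, -ux  # fold axis, pointing into the lumen
            t = (yy - by) * ay + (xx - bx) * ax  # along-axis coordinate
            q = -(yy - by) * ax + (xx - bx) * ay  # transverse coordinate
            shaft = (t >= -2.0) & (t <= L - W / 2) & (np.abs(q) <= W / 2)
            ty, tx = by + (L - W / 2) * ay, bx + (L - W / 2) * ax  # cap centre
            cap = (yy - ty) ** 2 + (xx - tx) ** 2 <= (W / 2) ** 2
            tissue |= shaft | cap

    if spec.n_crypts:
        # blind radial slots carved into the wall, opening into the lumen,
        # placed between fold positions
        crypt_angles = rng.uniform(0, 2 * math.pi, size=spec.n_crypts)
        for theta in crypt_angles:
            uy, ux = math.sin(theta), math.cos(theta)
            by, bx = cy + r0 * uy, cx + r0 * ux
            t = (yy - by) * uy + (xx - bx) * ux  # outward into the wall
            q = -(yy - by) * ux + (xx - bx) * uy
            slot = (t >= -1.0) & (t <= spec.crypt_depth_px) & (np.abs(q) <= spec.crypt_width_px / 2)
            tissue &= ~slot

    lumen = (rr < r1) & ~tissue

    truth = PhantomGroundTruth(
        true_fold_lengths_um=[float(L * spec.px_size_um) for L in lengths],
        true_fold_widths_um=[float(W * spec.px_size_um) for W in widths],
        fold_angles_rad=[float(a % (2 * math.pi)) for a in angles],
    )
    sp = (spec.px_size_um, spec.px_size_um, spec.px_size_um)
    return BinaryMask(tissue, sp), BinaryMask(lumen, sp), truth


# ---------------------------------------------------------------------------
# fractal rasters

FractalKind = Literal["line", "filled_square", "koch_curve", "sierpinski_triangle", "random_dust"]


def _koch_segments(order: int):
    """Unit Koch-curve segment list via L-system turtle, in the unit square."""
    angle = 0.0
    pos = np.array([0.0, 0.0])
    pts = [pos.copy()]
    turns = {"F": None, "+": -math.pi / 3, "-": 2 * math.pi / 3}
    seq = "F"
    for _ in range(order):
        seq = seq.replace("F", "F+F-F+F")
    step = 1.0 / 3**order
    for ch in seq:
        if ch == "F":
            pos = pos + step * np.array([math.cos(angle), math.sin(angle)])
            pts.append(pos.copy())
        elif ch == "+":
            angle += math.pi / 3
        elif ch == "-":
            angle -= 2 * math.pi / 3
    return np.array(pts)


def make_fractal_raster(
    kind: FractalKind,
    order_or_p: int | float = 0,
    size_px: int = 256,
    seed: int = 0,
) -> tuple[BinaryMask, PhantomGroundTruth]:
    """Binary raster of known (or deliberately unrecorded) fractal dimension.

    ``order_or_p`` is the recursion order for ``koch_curve`` /
    ``sierpinski_triangle`` and the fill probability for ``random_dust``
    (which records no analytic dimension — it exists for lacunarity
    ordering experiments).
    """
    if size_px < 2:
        raise ValueError("size_px must be ≥ 2")
    rng = np.random.default_rng(seed)
    grid = np.zeros((size_px, size_px), dtype=bool)
    fd: float | None

    if kind == "line":
        grid[size_px // 2, :] = True
        fd = 1.0
    elif kind == "filled_square":
        grid[:, :] = True
        fd = 2.0
    elif kind == "koch_curve":
        # drawn at the curve's natural pixel scale (unit segment = 1 px,
        # base = 3^order px) so the scaling band starts at the pixel level
        order = int(order_or_p)
        base_px = 3**order
        if base_px > size_px:
            raise ValueError(f"size_px={size_px} cannot resolve Koch order {order} (needs ≥ {base_px})")
        pts = _koch_segments(order) * base_px
        col0 = (size_px - base_px) // 2
        row0 = size_px - 2
        rows = np.clip(np.round(row0 - pts[:, 1]).astype(int), 0, size_px - 1)
        cols = np.clip(np.round(col0 + pts[:, 0]).astype(int), 0, size_px - 1)
        for k in range(len(pts) - 1):
            rr_, cc_ = _draw_line(rows[k], cols[k], rows[k + 1], cols[k + 1])
            grid[rr_, cc_] = True
        fd = math.log(4) / math.log(3)
    elif kind == "sierpinski_triangle":
        # rasterized at cell = 1 px (side 2^order px), centred on the canvas
        order = int(order_or_p)
        n = 2**order
        if n > size_px:
            raise ValueError(f"size_px={size_px} cannot resolve Sierpinski order {order} (needs ≥ {n})")
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        base = (i & j) == 0
        o = (size_px - n) // 2
        grid[o : o + n, o : o + n] = base
        fd = math.log(3) / math.log(2)
    elif kind == "random_dust":
        p = float(order_or_p)
        if not 0 < p < 1:
            raise ValueError("random_dust needs a fill probability in (0, 1)")
        grid = rng.random((size_px, size_px)) < p
        fd = None
    else:
        raise ValueError(f"unknown raster kind {kind!r}")

    return BinaryMask(grid), PhantomGroundTruth(analytic_fd=fd)


# ---------------------------------------------------------------------------
# voxel tubes

TubeKind = Literal["straight_cylinder", "helical_tube", "folded_tube"]


@dataclass
class TubePhantomSpec:
    """A 3D tube phantom in millimetres.

    ``straight_cylinder`` is a solid cylinder of radius ``outer_radius_mm``
    (analytic V, S and h recorded).  ``helical_tube`` sweeps a solid tube of
    radius ``outer_radius_mm`` along a helix of radius ``helix_radius_mm``
    and pitch ``helix_pitch_mm``.  ``folded_tube`` extrudes an annular
    cross-section (with optional longitudinal folds) along z; with 0 folds
    it is a straight annular tube.
    """

    kind: TubeKind = "straight_cylinder"
    outer_radius_mm: float = 1.0
    inner_radius_mm: float = 0.5
    height_mm: float = 4.46
    voxel_mm: float = 0.05
    helix_pitch_mm: float | None = None
    helix_radius_mm: float | None = None
    n_folds: int = 0
    fold_length_mm: float = 0.0
    fold_width_mm: float = 0.0
    seed: int = 0
    voxel_cap: int = int(2e8)

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("need 0 < inner_radius_mm < outer_radius_mm")
        if self.voxel_mm <= 0 or self.height_mm <= 0:
            raise ValueError("voxel_mm and height_mm must be > 0")
        if self.voxel_mm > self.inner_radius_mm / 4:
            raise ValueError("voxel_mm must be ≤ inner_radius_mm / 4 (resolvable lumen)")
        if self.kind == "helical_tube" and (self.helix_pitch_mm is None or self.helix_radius_mm is None):
            raise ValueError("helical_tube needs helix_pitch_mm and helix_radius_mm")


def _grid_1d(lo: float, hi: float, v: float) -> np.ndarray:
    n = int(math.ceil((hi - lo) / v))
    return lo + (np.arange(n) + 0.5) * v


def make_tube_volume(spec: TubePhantomSpec) -> tuple[BinaryMask, PhantomGroundTruth]:
    """Voxelize a tube phantom; voxel centres inside the solid are set."""
    v = spec.voxel_mm
    r, ri, h = spec.outer_radius_mm, spec.inner_radius_mm, spec.height_mm

    if spec.kind == "helical_tube":
        R = float(spec.helix_radius_mm)
        half = R + r + v
    else:
        half = r + max(spec.fold_length_mm, 0.0) * 0.0 + v  # folds protrude inward
    xs = _grid_1d(-half, half, v)
    zs = _grid_1d(0.0, h, v)
    zs = zs[zs <= h]  # voxel-centre-inside rule along the tube axis too
    n_vox = len(zs) * len(xs) * len(xs)
    if n_vox > spec.voxel_cap:
        raise ValueError(f"voxel budget {n_vox} exceeds cap {spec.voxel_cap}; coarsen voxel_mm")

    X, Y = np.meshgrid(xs, xs, indexing="xy")
    rr2 = X**2 + Y**2

    if spec.kind == "straight_cylinder":
        disc = rr2 <= r**2
        grid = np.broadcast_to(disc, (len(zs),) + disc.shape).copy()
        truth = PhantomGroundTruth(
            analytic_volume_mm3=math.pi * r**2 * h,
            analytic_surface_mm2=2 * math.pi * r * h + 2 * math.pi * r**2,
            height_mm=h,
        )
    elif spec.kind == "folded_tube":
        section = (rr2 >= ri**2) & (rr2 <= r**2)
        if spec.n_folds:
            rng = np.random.default_rng(spec.seed)
            L, W = spec.fold_length_mm, spec.fold_width_mm
            if not 0 < L < ri or not 0 < W:
                raise ValueError("folded_tube needs 0 < fold_length_mm < inner_radius_mm and fold_width_mm > 0")
            angles = np.arange(spec.n_folds) * 2 * math.pi / spec.n_folds + rng.uniform(0, 2 * math.pi)
            for theta in angles:
                ux, uy = math.cos(theta), math.sin(theta)
                bx, by = ri * ux, ri * uy
                t = -((X - bx) * ux + (Y - by) * uy)
                q = -(X - bx) * uy + (Y - by) * ux
                shaft = (t >= -2 * v) & (t <= L - W / 2) & (np.abs(q) <= W / 2)
                tx, ty = bx - (L - W / 2) * ux, by - (L - W / 2) * uy
                cap = (X - tx) ** 2 + (Y - ty) ** 2 <= (W / 2) ** 2
                section |= shaft | cap
        grid = np.broadcast_to(section, (len(zs),) + section.shape).copy()
        truth = PhantomGroundTruth(
            analytic_volume_mm3=(math.pi * (r**2 - ri**2) * h) if spec.n_folds == 0 else None,
            height_mm=h,
        )
    elif spec.kind == "helical_tube":
        R = float(spec.helix_radius_mm)
        pitch = float(spec.helix_pitch_mm)
        # polyline sampling of the centre line, fine relative to the voxel
        n_samp = max(64, int(20 * h / v))
        z_line = np.linspace(0.0, h, n_samp)
        phi = 2 * math.pi * z_line / pitch
        line = np.column_stack([R * np.cos(phi), R * np.sin(phi), z_line])
        tree = cKDTree(line)
        Z = zs[:, None, None]
        pts = np.stack(
            [
                np.broadcast_to(X, (len(zs),) + X.shape),
                np.broadcast_to(Y, (len(zs),) + Y.shape),
                np.broadcast_to(Z, (len(zs),) + X.shape),
            ],
            axis=-1,
        ).reshape(-1, 3)
        d, _ = tree.query(pts, workers=-1)
        grid = (d.reshape(len(zs), len(xs), len(xs)) <= r)
        truth = PhantomGroundTruth(height_mm=h)
    else:
        raise ValueError(f"unknown tube kind {spec.kind!r}")

    sp_um = (v * 1000.0,) * 3
    return BinaryMask(grid, sp_um), truth
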