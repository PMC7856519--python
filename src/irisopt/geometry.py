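"""Voxel grids, target structure masks, margin expansion and axis lengths.

All world coordinates are in millimetres. A regular axis-aligned grid uses the
voxel-center convention: the world coordinate of voxel index ``i`` is
``origin + (i + 0.5) * spacing``. Structure masks are binary indicator volumes
on such a grid and carry a clinical label (GTV, CTV, PTV or other).

The target-volume chain follows standard lung SBRT practice: the gross tumor
volume (GTV) is expanded isotropically by 2 mm to the clinical target volume
(CTV) to cover microscopic extension, and the CTV by a further 4 mm to the
planning target volume (PTV) to absorb residual treatment uncertainties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "AxisLengths",
    "make_sphere_phantom",
    "make_ellipsoid_phantom",
    "expand_margin",
    "axis_lengths",
    "load_mask",
    "save_mask",
]

STRUCTURE_LABELS = ("GTV", "CTV", "PTV", "other")

# standard isotropic margins of the GTV -> CTV -> PTV chain, mm
GTV_TO_CTV_MM = 2.0
CTV_TO_PTV_MM = 4.0

_LABEL_PROMOTION = {"GTV": "CTV", "CTV": "PTV"}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned 3D voxel grid (spacing/origin in mm)."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        sp = np.asarray(self.spacing, dtype=float)
        dm = np.asarray(self.dims, dtype=int)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if dm.shape != (3,) or np.any(dm < 1):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        object.__setattr__(self, "spacing", tuple(float(s) for s in sp))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in dm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.spacing[axis]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis center coordinate arrays, broadcastable to the grid shape."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def same_lattice(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        """True if the grids share spacing and their origins differ by whole voxels."""
        if not np.allclose(self.spacing, other.spacing, atol=atol):
            return False
        shift = (np.asarray(other.origin) - np.asarray(self.origin)) / np.asarray(self.spacing)
        return bool(np.allclose(shift, np.round(shift), atol=1e-4))

    @classmethod
    def for_extent(
        cls,
        lo: np.ndarray,
        hi: np.ndarray,
        spacing: float | tuple[float, float, float] = 1.0,
    ) -> "VoxelGrid":
        """Smallest grid whose voxel centers cover the world box [lo, hi]."""
        sp = np.broadcast_to(np.atleast_1d(np.asarray(spacing, dtype=float)), (3,)).astype(float)
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        dims = np.maximum(np.ceil((hi - lo) / sp).astype(int), 1)
        return cls(spacing=tuple(sp), origin=tuple(lo), dims=tuple(int(d) for d in dims))


@dataclass
class StructureMask:
    """Binary structure on a voxel grid with a clinical label."""

    grid: VoxelGrid
    mask: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.dims):
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid dims {self.grid.dims}"
            )
        if self.label not in STRUCTURE_LABELS:
            raise ValueError(f"label must be one of {STRUCTURE_LABELS}, got {self.label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def centroid_mm(self) -> np.ndarray:
        """Center of mass of the set voxels in world coordinates."""
        if self.n_voxels == 0:
            raise ValueError("empty mask has no centroid")
        idx = np.argwhere(self.mask)
        return np.asarray(self.grid.origin) + (idx.mean(axis=0) + 0.5) * np.asarray(
            self.grid.spacing
        )

    def voxel_coords_mm(self) -> np.ndarray:
        """(n, 3) world coordinates of the set voxel centers."""
        idx = np.argwhere(self.mask)
        return np.asarray(self.grid.origin) + (idx + 0.5) * np.asarray(self.grid.spacing)


@dataclass(frozen=True)
class AxisLengths:
    """Long/short axis lengths of a structure, mm (a_max >= a_min > 0)."""

    a_max: float
    a_min: float

    def __post_init__(self) -> None:
        if not (self.a_max >= self.a_min > 0):
            raise ValueError(f"need a_max >= a_min > 0, got {self.a_max}, {self.a_min}")


def make_sphere_phantom(
    grid: VoxelGrid,
    center: tuple[float, float, float],
    radius: float,
    label: str = "other",
) -> StructureMask:
    """Ball phantom: a voxel is set iff its center lies within ``radius`` of ``center``."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    x, y, z = grid.voxel_centers()
    c = np.asarray(center, dtype=float)
    mask = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= radius**2
    if not mask.any():
        raise ValueError("sphere does not intersect the grid (empty mask)")
    return StructureMask(grid=grid, mask=mask, label=label)


def make_ellipsoid_phantom(
    grid: VoxelGrid,
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    label: str = "other",
) -> StructureMask:
    """Axis-aligned ellipsoid phantom (voxel-center membership)."""
    sa = np.asarray(semi_axes, dtype=float)
    if np.any(sa <= 0):
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    x, y, z = grid.voxel_centers()
    c = np.asarray(center, dtype=float)
    q = ((x - c[0]) / sa[0]) ** 2 + ((y - c[1]) / sa[1]) ** 2 + ((z - c[2]) / sa[2]) ** 2
    mask = q <= 1.0
    if not mask.any():
        raise ValueError("ellipsoid does not intersect the grid (empty mask)")
    return StructureMask(grid=grid, mask=mask, label=label)


def _pad_grid(
    s: StructureMask, pad_voxels: np.ndarray, pad_hi_voxels: np.ndarray | None = None
) -> StructureMask:
    """Embed the mask in a grid enlarged by the given voxel counts per face.

    ``pad_voxels`` applies to the low faces (and to the high faces too unless
    ``pad_hi_voxels`` is given).
    """
    lo = np.asarray(pad_voxels, dtype=int)
    hi = lo if pad_hi_voxels is None else np.asarray(pad_hi_voxels, dtype=int)
    if np.all(lo == 0) and np.all(hi == 0):
        return s
    g = s.grid
    new_dims = tuple(int(d + a + b) for d, a, b in zip(g.dims, lo, hi))
    new_origin = tuple(float(o - a * sp) for o, a, sp in zip(g.origin, lo, g.spacing))
    new_mask = np.zeros(new_dims, dtype=bool)
    sl = tuple(slice(a, a + d) for a, d in zip(lo, g.dims))
    new_mask[sl] = s.mask
    return StructureMask(
        grid=VoxelGrid(spacing=g.spacing, origin=new_origin, dims=new_dims),
        mask=new_mask,
        label=s.label,
    )


def embed_covering(s: StructureMask, other: VoxelGrid) -> StructureMask:
    """Pad a structure's grid (same lattice) until it covers ``other``'s extent."""
    if not s.grid.same_lattice(other):
        raise ValueError("grids are not on the same lattice")
    sp = np.asarray(s.grid.spacing)
    lo_gap = np.asarray(s.grid.origin) - np.asarray(other.origin)
    hi_gap = (np.asarray(other.origin) + np.asarray(other.dims) * sp) - (
        np.asarray(s.grid.origin) + np.asarray(s.grid.dims) * sp
    )
    pad_lo = np.maximum(np.round(lo_gap / sp).astype(int), 0)
    pad_hi = np.maximum(np.round(hi_gap / sp).astype(int), 0)
    return _pad_grid(s, pad_lo, pad_hi)


def expand_margin(
    s: StructureMask,
    margin: float,
    label: str | None = None,
) -> StructureMask:
    """Isotropic Euclidean-distance dilation of a structure by ``margin`` mm.

    A voxel of the output is set iff its center lies within ``margin`` of the
    center of any set input voxel. The grid is enlarged automatically when the
    expanded structure would not fit (``ceil(margin/spacing)+1`` voxels per
    face). When ``label`` is None, GTV promotes to CTV and CTV to PTV
    (the standard margin chain); other labels are kept.
    """
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    if s.n_voxels == 0:
        raise ValueError("cannot expand an empty mask")
    new_label = label if label is not None else _LABEL_PROMOTION.get(s.label, s.label)
    if margin == 0:
        return StructureMask(grid=s.grid, mask=s.mask.copy(), label=new_label)

    # pad only on faces the structure touches within the margin reach
    sp = np.asarray(s.grid.spacing)
    pad = np.ceil(margin / sp).astype(int) + 1
    idx = np.argwhere(s.mask)
    lo_touch = idx.min(axis=0) <= pad
    hi_touch = idx.max(axis=0) >= np.asarray(s.grid.dims) - 1 - pad
    pad = np.where(lo_touch | hi_touch, pad, 0)
    padded = _pad_grid(s, pad)

    # Euclidean distance from every voxel center to the nearest set voxel center
    dist = ndimage.distance_transform_edt(~padded.mask, sampling=padded.grid.spacing)
    return StructureMask(grid=padded.grid, mask=dist <= margin, label=new_label)


def _surface_coords(s: StructureMask) -> np.ndarray:
    """World coordinates of surface voxel centers (mask minus its erosion)."""
    eroded = ndimage.binary_erosion(s.mask)
    surface = s.mask & ~eroded
    idx = np.argwhere(surface)
    return np.asarray(s.grid.origin) + (idx + 0.5) * np.asarray(s.grid.spacing)


def _hull_points(pts: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of a point cloud; falls back to the cloud if degenerate."""
    if len(pts) < 5:
        return pts
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return pts
    return pts[hull.vertices]


def _min_width_2d(pts2d: np.ndarray) -> float:
    """Minimum width of a planar point set (rotating-calipers over hull edges)."""
    uniq = np.unique(np.round(pts2d, 9), axis=0)
    if len(uniq) < 3:
        if len(uniq) < 2:
            return 0.0
        # collinear or two points: width orthogonal to the segment is 0
        d = uniq - uniq.mean(axis=0)
        if np.allclose(np.cross(d[:1], d), 0, atol=1e-9):
            return 0.0
    try:
        hull = ConvexHull(uniq)
    except QhullError:
        return 0.0
    hp = uniq[hull.vertices]
    widths = []
    for i in range(len(hp)):
        edge = hp[(i + 1) % len(hp)] - hp[i]
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        n = np.array([-edge[1], edge[0]]) / norm
        proj = hp @ n
        widths.append(proj.max() - proj.min())
    return float(min(widths)) if widths else 0.0


def axis_lengths(s: StructureMask) -> AxisLengths:
    """Long (a_max) and short (a_min) axis lengths of a structure, mm.

    a_max is the maximum Feret diameter: the largest pairwise distance between
    surface voxel centers, plus one voxel spacing so that a digitized ball of
    diameter d measures d rather than d - spacing. a_min is the minimum width
    of the structure's projection onto the plane orthogonal to the a_max
    direction, padded the same way. A single-voxel structure reports both
    lengths equal to the voxel spacing.
    """
    if s.n_voxels == 0:
        raise ValueError("axis lengths of an empty mask are undefined")
    pad = float(np.mean(s.grid.spacing))
    if s.n_voxels == 1:
        return AxisLengths(a_max=pad, a_min=pad)

    pts = _hull_points(_surface_coords(s))
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    feret = math.sqrt(d2[i, j])
    a_max = feret + pad

    u = pts[j] - pts[i]
    u = u / np.linalg.norm(u)
    # orthonormal basis of the plane orthogonal to the long axis
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    pts2d = np.column_stack([pts @ v, pts @ w])
    a_min = _min_width_2d(pts2d) + pad
    a_min = min(a_min, a_max)
    return AxisLengths(a_max=a_max, a_min=a_min)


def save_mask(s: StructureMask, path: str) -> None:
    """Write a structure mask as NIfTI (.nii/.nii.gz), voxel-center convention."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(s.grid.spacing)
    affine[:3, 3] = np.asarray(s.grid.origin) + 0.5 * np.asarray(s.grid.spacing)
    img = nib.Nifti1Image(s.mask.astype(np.uint8), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, path)


def load_mask(path: str, label: str = "other") -> StructureMask:
    """Read a NIfTI volume as a binary structure mask (nonzero = inside)."""
    img = nib.load(path)
    affine = img.affine
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-5):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = np.abs(np.diag(lin))
    if np.any(spacing <= 0):
        raise ValueError("volume header has non-positive spacing")
    origin = affine[:3, 3] - 0.5 * spacing
    data = np.asanyarray(img.dataobj)
    grid = VoxelGrid(spacing=tuple(spacing), origin=tuple(origin), dims=data.shape)
    return StructureMask(grid=grid, mask=data != 0, label=label)
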