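"""Coverage/leakage accumulation of a tracked collimator aperture over a target.

At each imaging time point the collimator aperture — modeled as a ball of the
nominal field diameter — is centered on the predicted target position while
the CTV sits at the imaged (true) position. Only the relative displacement
matters for their intersection, so accumulation works in the target frame:
the CTV stays fixed and the aperture center is offset by the per-point
tracking error e = pred - true from the tracked reference point (the CTV
centroid by default).

Each voxel accumulates the fraction of imaging time points (pooled over all
fractions, equal weight) for which its center lies inside the aperture ball.
On CTV voxels that fraction is the coverage possibility; on non-CTV voxels
that ever enter the aperture it is the leakage possibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import StructureMask, VoxelGrid, _pad_grid
from .motion import MotionTrace

__all__ = [
    "IRIS_DIAMETERS_MM",
    "CollimatorModel",
    "CoverageMap",
    "LeakageMap",
    "accumulate",
    "coverage_on_structure",
]

# the 12 Iris variable-aperture field diameters, mm, defined 800 mm from the focal spot
IRIS_DIAMETERS_MM = (5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0, 60.0)


@dataclass(frozen=True)
class CollimatorModel:
    """Discrete set of selectable field diameters (mm)."""

    diameters: tuple[float, ...] = IRIS_DIAMETERS_MM
    reference_distance_mm: float = 800.0

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if len(d) == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be positive and strictly increasing")
        object.__setattr__(self, "diameters", tuple(float(x) for x in d))

    @classmethod
    def iris(cls) -> "CollimatorModel":
        return cls()


@dataclass
class _FractionMap:
    """Per-voxel time-point inclusion fraction with a domain mask."""

    grid: VoxelGrid
    values: np.ndarray  # inclusion fraction in [0,1], full grid
    mask: np.ndarray  # domain of the map (bool, full grid)
    n_points: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != tuple(self.grid.dims) or self.mask.shape != self.values.shape:
            raise ValueError("map arrays do not match the grid dims")
        dom = self.values[self.mask]
        if dom.size and (dom.min() < -1e-12 or dom.max() > 1 + 1e-12):
            raise ValueError("inclusion fractions must lie in [0, 1]")

    @property
    def domain_values(self) -> np.ndarray:
        """Raw per-voxel fractions restricted to the domain mask."""
        return self.values[self.mask]

    @property
    def domain_volume_cm3(self) -> float:
        return float(self.mask.sum()) * self.grid.voxel_volume_cm3


class CoverageMap(_FractionMap):
    """Coverage possibility per target voxel (domain = evaluation structure)."""


class LeakageMap(_FractionMap):
    """Leakage possibility per non-target voxel that ever entered the aperture."""


def _aperture_counts(
    grid: VoxelGrid, centers: np.ndarray, radius: float
) -> np.ndarray:
    """Count, per voxel, the time points whose aperture ball contains its center.

    Only voxels inside the bounding box of all aperture balls are touched;
    everything outside has count zero by construction.
    """
    counts = np.zeros(grid.dims, dtype=np.int32)
    lo_w = centers.min(axis=0) - radius
    hi_w = centers.max(axis=0) + radius
    origin = np.asarray(grid.origin)
    sp = np.asarray(grid.spacing)
    lo = np.maximum(np.floor((lo_w - origin) / sp - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - origin) / sp - 0.5).astype(int) + 1, grid.dims)
    if np.any(lo >= hi):
        return counts
    ax = [grid.axis_centers(k)[lo[k] : hi[k]] for k in range(3)]
    sub = np.zeros(tuple(h - l for l, h in zip(lo, hi)), dtype=np.int32)
    r2 = radius**2
    for c in centers:
        d2 = (
            ((ax[0] - c[0]) ** 2)[:, None, None]
            + ((ax[1] - c[1]) ** 2)[None, :, None]
            + ((ax[2] - c[2]) ** 2)[None, None, :]
        )
        sub += d2 <= r2
    counts[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return counts


def accumulate(
    ctv: StructureMask,
    trace: MotionTrace,
    diameter: float,
    center: np.ndarray | None = None,
) -> tuple[CoverageMap, LeakageMap]:
    """Accumulate per-voxel aperture-inclusion fractions over a trace.

    Parameters
    ----------
    ctv
        Target structure; stays fixed in the target frame.
    trace
        Imaging time points; only the error vectors e = pred - true enter.
    diameter
        Nominal aperture diameter, mm.
    center
        Tracked reference point (mm world). Defaults to the CTV centroid.

    Returns
    -------
    (CoverageMap, LeakageMap)
        Both live on a common grid (the CTV grid, auto-padded so every
        aperture position fits). The coverage map's domain is the CTV; the
        leakage map's domain is every non-CTV voxel with nonzero inclusion.
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    if ctv.n_voxels == 0:
        raise ValueError("CTV mask is empty")
    errors = trace.errors
    n = len(trace)
    if center is None:
        center = ctv.centroid_mm()
    center = np.asarray(center, dtype=float)

    # pad the grid so the aperture ball fits at its most displaced position
    radius = diameter / 2.0
    reach = radius + np.abs(errors).max(axis=0)  # per-axis, mm
    sp = np.asarray(ctv.grid.spacing)
    origin = np.asarray(ctv.grid.origin)
    extent_hi = origin + np.asarray(ctv.grid.dims) * sp
    need_lo = np.maximum(origin - (center - reach), 0.0)
    need_hi = np.maximum((center + reach) - extent_hi, 0.0)
    pad_lo = np.where(need_lo > 0, np.ceil(need_lo / sp).astype(int) + 1, 0)
    pad_hi = np.where(need_hi > 0, np.ceil(need_hi / sp).astype(int) + 1, 0)
    padded = _pad_grid(ctv, pad_lo, pad_hi)

    counts = _aperture_counts(padded.grid, center[None, :] + errors, radius)
    frac = counts / float(n)
    cov = CoverageMap(grid=padded.grid, values=frac, mask=padded.mask.copy(), n_points=n)
    leak_mask = (~padded.mask) & (counts > 0)
    leak = LeakageMap(grid=padded.grid, values=frac, mask=leak_mask, n_points=n)
    return cov, leak


def _align_mask(structure: StructureMask, grid: VoxelGrid) -> np.ndarray:
    """Embed a structure mask into another grid on the same lattice."""
    if not structure.grid.same_lattice(grid):
        raise ValueError(
            "structure grid is not on the same lattice as the map grid "
            "(spacing mismatch or fractional origin offset)"
        )
    shift = np.round(
        (np.asarray(structure.grid.origin) - np.asarray(grid.origin))
        / np.asarray(grid.spacing)
    ).astype(int)
    out = np.zeros(grid.dims, dtype=bool)
    src_lo = np.maximum(-shift, 0)
    dst_lo = np.maximum(shift, 0)
    span = np.minimum(np.asarray(structure.grid.dims) - src_lo, np.asarray(grid.dims) - dst_lo)
    if np.any(span <= 0):
        raise ValueError("structure does not overlap the map grid")
    src = tuple(slice(a, a + s) for a, s in zip(src_lo, span))
    dst = tuple(slice(a, a + s) for a, s in zip(dst_lo, span))
    out[dst] = structure.mask[src]
    if structure.mask.sum() != out.sum():
        raise ValueError("structure extends outside the map grid")
    return out


def _extend_map(cov: CoverageMap, other: VoxelGrid) -> CoverageMap:
    """Zero-extend a map so its grid also covers ``other``'s extent.

    Valid because the accumulation grid already contains every aperture
    position: the inclusion fraction outside it is exactly zero.
    """
    carrier = StructureMask(grid=cov.grid, mask=cov.mask)
    from .geometry import embed_covering

    grown = embed_covering(carrier, other)
    if grown.grid.dims == cov.grid.dims:
        return cov
    values = np.zeros(grown.grid.dims, dtype=float)
    shift = np.round(
        (np.asarray(cov.grid.origin) - np.asarray(grown.grid.origin))
        / np.asarray(grown.grid.spacing)
    ).astype(int)
    sl = tuple(slice(a, a + d) for a, d in zip(shift, cov.grid.dims))
    values[sl] = cov.values
    return CoverageMap(grid=grown.grid, values=values, mask=grown.mask, n_points=cov.n_points)


def coverage_on_structure(cov: CoverageMap, eval_structure: StructureMask) -> CoverageMap:
    """Restrict a coverage map to another evaluation structure (e.g. the PTV).

    Voxels of the evaluation structure outside the original target score their
    plain aperture-inclusion fraction, so PTV-level coverage statistics can be
    read off the same accumulation that produced the CTV coverage. The map is
    zero-extended when the structure's grid reaches beyond it (such voxels
    were never inside any aperture position).
    """
    cov = _extend_map(cov, eval_structure.grid)
    mask = _align_mask(eval_structure, cov.grid)
    if not mask.any():
        raise ValueError("evaluation structure is empty on the map grid")
    return CoverageMap(grid=cov.grid, values=cov.values, mask=mask, n_points=cov.n_points)
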