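"""Cumulative coverage/leakage-volume histograms and scalar plan metrics.

The CVH is the coverage analog of a cumulative DVH: for each coverage level
c in [0, 1] it gives the percent of the evaluation structure's volume whose
voxels achieve coverage possibility >= c. The LVH gives, for each leakage
level, the absolute volume (cm^3) of non-target voxels whose leakage
possibility is at least that level.

Scalar metrics (C95/C90 quantiles, areas under the curves, absolute mean
leakage, leakage/coverage ratio) are computed from the raw voxel values, not
from the discretized curves, so they do not depend on the level grid. Both
areas are on absolute volume scales (cm^3 x possibility), which makes the
leakage/coverage ratio dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import CoverageMap, LeakageMap, _FractionMap
from .geometry import AxisLengths

__all__ = [
    "CumulativeHistogram",
    "MetricsSet",
    "build_cvh",
    "build_lvh",
    "coverage_at_volume",
    "auc",
    "summarize",
]

DEFAULT_N_LEVELS = 1001


@dataclass
class CumulativeHistogram:
    """Cumulative histogram: volume vs possibility level.

    ``volume`` is percent of structure volume for kind "CVH" and absolute
    cm^3 for kind "LVH"; it is non-increasing in the level.
    """

    levels: np.ndarray
    volume: np.ndarray
    kind: str  # "CVH" | "LVH"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.kind not in ("CVH", "LVH"):
            raise ValueError(f"kind must be CVH or LVH, got {self.kind!r}")
        if self.levels.shape != self.volume.shape:
            raise ValueError("levels and volume must have the same shape")
        if np.any(np.diff(self.volume) > 1e-9):
            raise ValueError("cumulative volume must be non-increasing in level")

    def level_at_volume(self, vol: float) -> float:
        """Largest level whose cumulative volume is still >= ``vol``."""
        ok = np.flatnonzero(self.volume >= vol - 1e-12)
        return float(self.levels[ok[-1]]) if ok.size else float(self.levels[0])


def _cumulative_counts(values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """For each level, the number of values >= level."""
    s = np.sort(values)
    return len(s) - np.searchsorted(s, levels - 1e-12, side="left")


def build_cvh(cov: CoverageMap, n_levels: int = DEFAULT_N_LEVELS) -> CumulativeHistogram:
    """Relative CVH of a (possibly restricted) coverage map."""
    vals = cov.domain_values
    if vals.size == 0:
        raise ValueError("cannot build a CVH for an empty structure")
    levels = np.linspace(0.0, 1.0, n_levels)
    volume = 100.0 * _cumulative_counts(vals, levels) / vals.size
    return CumulativeHistogram(levels=levels, volume=volume, kind="CVH")


def build_lvh(leak: LeakageMap, n_levels: int = DEFAULT_N_LEVELS) -> CumulativeHistogram:
    """Absolute LVH (cm^3) of a leakage map; identically zero for empty support."""
    vals = leak.domain_values
    levels = np.linspace(0.0, 1.0, n_levels)
    if vals.size == 0:
        return CumulativeHistogram(levels=levels, volume=np.zeros(n_levels), kind="LVH")
    volume = leak.grid.voxel_volume_cm3 * _cumulative_counts(vals, levels)
    return CumulativeHistogram(levels=levels, volume=volume, kind="LVH")


def coverage_at_volume(
    source: CoverageMap | CumulativeHistogram | np.ndarray, vol_pct: float
) -> float:
    """Coverage level (percent) achieved by at least ``vol_pct``% of the volume.

    This is the DVH D95/D90 analog: C95 for vol_pct=95, C90 for vol_pct=90.
    Given raw voxel values (or a coverage map) the answer is the exact order
    statistic — the value of the ceil(vol_pct% * n)-th best-covered voxel; a
    pre-built curve is interrogated directly.
    """
    if not 0 < vol_pct <= 100:
        raise ValueError(f"vol_pct must be in (0, 100], got {vol_pct}")
    if isinstance(source, CumulativeHistogram):
        return 100.0 * source.level_at_volume(vol_pct)
    vals = source.domain_values if isinstance(source, _FractionMap) else np.asarray(source)
    vals = np.sort(vals.ravel())[::-1]
    if vals.size == 0:
        raise ValueError("no voxel values to compute a coverage quantile from")
    m = int(np.ceil(vol_pct / 100.0 * vals.size))
    return 100.0 * float(vals[m - 1])


def auc(source: _FractionMap | CumulativeHistogram) -> float:
    """Possibility-weighted volume: the area under a cumulative curve.

    For a map this is computed exactly as voxel_volume * sum(values) over the
    domain (cm^3 x possibility) — the layer-cake identity makes it equal the
    integral of the absolute cumulative curve over levels [0, 1]. For a
    pre-built curve, trapezoidal integration is used (in the curve's own
    volume units).
    """
    if isinstance(source, CumulativeHistogram):
        return float(np.trapezoid(source.volume, source.levels))
    return float(source.domain_values.sum()) * source.grid.voxel_volume_cm3


@dataclass(frozen=True)
class MetricsSet:
    """Scalar CVH/LVH evaluation metrics for one (plan, diameter) pair."""

    diameter: float  # aperture diameter, mm
    c95_ctv: float  # coverage of 95% of CTV volume, percent
    c90_ctv: float
    c95_ptv: float  # coverage of 95% of PTV volume, percent
    c90_ptv: float
    auc_cov_ptv: float  # area under the absolute PTV coverage curve, cm^3 x possibility
    auc_leak: float  # area under the leakage curve, cm^3 x possibility
    leakage_volume_cm3: float  # absolute leakage support volume
    mean_leakage: float  # auc_leak / leakage volume, dimensionless in [0,1]
    leak_cov_ratio: float  # auc_leak / auc_cov_ptv (NaN if coverage AUC is 0)
    phi_over_amin: float
    phi_over_amax: float

    def __post_init__(self) -> None:
        if not (0 - 1e-9 <= self.c95_ptv <= self.c90_ptv + 1e-9 <= 100 + 1e-9):
            raise ValueError("need 0 <= C95 <= C90 <= 100 on the PTV")
        if not (0 - 1e-9 <= self.c95_ctv <= self.c90_ctv + 1e-9 <= 100 + 1e-9):
            raise ValueError("need 0 <= C95 <= C90 <= 100 on the CTV")
        if self.leakage_volume_cm3 > 0 and not (0 <= self.mean_leakage <= 1 + 1e-9):
            raise ValueError("mean leakage must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize(
    cov_ctv: CoverageMap,
    cov_ptv: CoverageMap,
    leak: LeakageMap,
    diameter: float,
    axes: AxisLengths,
) -> MetricsSet:
    """All scalar metrics for one accumulated diameter.

    mean_leakage is the leakage AUC divided by the leakage support volume —
    equivalently the mean leakage possibility over irradiated normal-tissue
    voxels. leak_cov_ratio divides the leakage AUC by the absolute PTV
    coverage AUC; it is flagged NaN when the coverage AUC is zero.
    """
    auc_cov_ptv = auc(cov_ptv)
    auc_leak = auc(leak)
    leak_vol = leak.domain_volume_cm3
    mean_leakage = auc_leak / leak_vol if leak_vol > 0 else 0.0
    ratio = auc_leak / auc_cov_ptv if auc_cov_ptv > 0 else float("nan")
    return MetricsSet(
        diameter=float(diameter),
        c95_ctv=coverage_at_volume(cov_ctv, 95.0),
        c90_ctv=coverage_at_volume(cov_ctv, 90.0),
        c95_ptv=coverage_at_volume(cov_ptv, 95.0),
        c90_ptv=coverage_at_volume(cov_ptv, 90.0),
        auc_cov_ptv=auc_cov_ptv,
        auc_leak=auc_leak,
        leakage_volume_cm3=leak_vol,
        mean_leakage=mean_leakage,
        leak_cov_ratio=ratio,
        phi_over_amin=float(diameter) / axes.a_min,
        phi_over_amax=float(diameter) / axes.a_max,
    )
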