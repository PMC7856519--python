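"""Synthetic patient cohorts and cohort-level statistics.

No patient tracking logs are distributable, so cohort-level behavior is
studied on synthetic patients whose geometry and delivery-error statistics
emulate a typical lung-SBRT tracking cohort: PTV volume ~ 41 +/- 30 cm^3,
PTV long/short axes ~ 57 +/- 17 / 36 +/- 10 mm, per-axis delivery-error SDs
around LR 1.21, AP 0.58, SI 0.86 mm, and 3-7 fractions. Each patient is an
ellipsoidal PTV (eroded 4 mm to its CTV), a Gaussian error model, and an
affected-lung volume.

Cohort analyses mirror the clinical evaluation: per-patient optimization
under the strict (C95) and relaxed (C90) coverage-threshold groups, paired
two-tailed Wilcoxon signed-rank comparison of the metric columns, Spearman
rank correlations of the normalized aperture (Phi/a_min, Phi/a_max) against
the leakage metrics, and the contingency table of selected diameters by
short-axis range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import CollimatorModel
from .geometry import (
    CTV_TO_PTV_MM,
    AxisLengths,
    StructureMask,
    VoxelGrid,
    axis_lengths,
    expand_margin,
    make_ellipsoid_phantom,
)
from .metrics import MetricsSet
from .motion import ErrorModel, simulate_trace
from .optimizer import OptimizationResult, OptimizerConfig, optimize_collimator

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "CohortResult",
    "sample_cohort",
    "build_patient_structures",
    "run_cohort_study",
    "paired_threshold_comparison",
    "correlation_analysis",
    "diameter_distribution_table",
]

# a_min bin edges for the diameter-distribution table, mm (half-open [lo, hi))
AMIN_BIN_EDGES = (0.0, 25.0, 30.0, 35.0, 40.0, 50.0, 60.0, math.inf)
AMIN_BIN_LABELS = ("<25", "25-30", "30-35", "35-40", "40-50", "50-60", ">=60")

METRIC_COLUMNS = (
    "c90_ptv",
    "c95_ptv",
    "mean_leakage",
    "leak_cov_ratio",
    "selected_diameter",
    "phi_over_amin",
    "phi_over_amax",
)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions for a synthetic cohort.

    PTV volume is lognormal with the given arithmetic mean/SD; axis lengths
    and per-axis error SDs are truncated normals; fraction counts are rounded
    normals clipped to the clinical 3-7 range; the affected-lung volume is
    lognormal around a 1500 cm^3 median. Patients with a_min > a_max are
    resampled (retry cap 1000 per patient).
    """

    n_patients: int = 37
    ptv_volume_mean_cm3: float = 41.15
    ptv_volume_sd_cm3: float = 30.17
    a_max_mean_mm: float = 56.80
    a_max_sd_mm: float = 17.26
    a_min_mean_mm: float = 36.36
    a_min_sd_mm: float = 10.44
    error_sd_mean_mm: tuple[float, float, float] = (1.21, 0.58, 0.86)  # (LR, AP, SI)
    error_sd_sd_mm: tuple[float, float, float] = (0.81, 0.31, 0.52)
    fractions_mean: float = 5.11
    fractions_sd: float = 1.73
    fractions_range: tuple[int, int] = (3, 7)
    v_lung_median_cm3: float = 1500.0
    v_lung_sigma: float = 0.25
    n_points_per_fraction: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")


@dataclass(frozen=True)
class SyntheticPatient:
    """One sampled patient: PTV geometry, error model, lung volume."""

    patient_id: int
    a_max_mm: float  # PTV long axis
    a_min_mm: float  # PTV short axis
    ptv_volume_cm3: float  # sampled target volume (middle axis is fit to it)
    error_sd_mm: tuple[float, float, float]  # (LR, AP, SI)
    n_fractions: int
    v_lung_cm3: float
    trace_seed: int

    def error_model(self, n_points_per_fraction: int = 40) -> ErrorModel:
        return ErrorModel(
            sd_lr=self.error_sd_mm[0],
            sd_ap=self.error_sd_mm[1],
            sd_si=self.error_sd_mm[2],
            n_points_per_fraction=n_points_per_fraction,
            n_fractions=self.n_fractions,
            seed=self.trace_seed,
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    raise RuntimeError("truncated-normal sampling failed (retry cap hit)")


def sample_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Draw a reproducible synthetic cohort from the spec's distributions."""
    rng = np.random.default_rng(spec.seed)
    mu_v, sig_v = _lognormal_params(spec.ptv_volume_mean_cm3, spec.ptv_volume_sd_cm3)
    mu_l, sig_l = math.log(spec.v_lung_median_cm3), spec.v_lung_sigma
    patients = []
    for pid in range(spec.n_patients):
        # joint axis draw with rejection so a_max >= a_min > 0
        for _ in range(1000):
            a_min = rng.normal(spec.a_min_mean_mm, spec.a_min_sd_mm)
            a_max = rng.normal(spec.a_max_mean_mm, spec.a_max_sd_mm)
            if 0 < a_min <= a_max:
                break
        else:
            raise RuntimeError("axis sampling failed (retry cap hit)")
        # the short axis must leave room for the CTV after the 4 mm erosion
        a_min = max(a_min, 2.0 * (CTV_TO_PTV_MM + 2.0))
        a_max = max(a_max, a_min)
        sds = tuple(
            _trunc_normal(rng, m, s, 0.0)
            for m, s in zip(spec.error_sd_mean_mm, spec.error_sd_sd_mm)
        )
        n_frac = int(np.clip(round(rng.normal(spec.fractions_mean, spec.fractions_sd)),
                             *spec.fractions_range))
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                a_max_mm=float(a_max),
                a_min_mm=float(a_min),
                ptv_volume_cm3=float(rng.lognormal(mu_v, sig_v)),
                error_sd_mm=sds,
                n_fractions=n_frac,
                v_lung_cm3=float(rng.lognormal(mu_l, sig_l)),
                trace_seed=int(rng.integers(2**31)),
            )
        )
    return patients


def build_patient_structures(
    patient: SyntheticPatient, spacing_mm: float = 1.0
) -> tuple[StructureMask, StructureMask]:
    """Voxelize a patient's (CTV, PTV) pair on an isotropic grid.

    The PTV is an axis-aligned ellipsoid whose extreme semi-axes match the
    sampled long/short axes; the middle semi-axis is fit to the sampled PTV
    volume (clipped between the other two). The CTV ellipsoid has every
    semi-axis 4 mm smaller, so expanding it by the standard CTV->PTV margin
    reproduces the sampled axes within a voxel.
    """
    A = patient.a_max_mm / 2.0
    C = patient.a_min_mm / 2.0
    v_mm3 = patient.ptv_volume_cm3 * 1000.0
    B = float(np.clip(3.0 * v_mm3 / (4.0 * math.pi * A * C), C, A))
    semi_ptv = (A, B, C)
    semi_ctv = tuple(s - CTV_TO_PTV_MM for s in semi_ptv)
    pad = 2.0 * spacing_mm
    lo = -np.asarray(semi_ctv) - pad
    hi = np.asarray(semi_ctv) + pad
    grid = VoxelGrid.for_extent(lo, hi, spacing_mm)
    ctv = make_ellipsoid_phantom(grid, (0.0, 0.0, 0.0), semi_ctv, label="CTV")
    ptv = expand_margin(ctv, CTV_TO_PTV_MM)
    return ctv, ptv


@dataclass
class CohortResult:
    """Per-patient records plus the cohort-level statistical summaries."""

    patients: list[SyntheticPatient]
    records: pd.DataFrame  # one row per (patient, tier)
    results: dict[tuple[int, str], OptimizationResult] = field(default_factory=dict)

    def tier_frame(self, tier: str) -> pd.DataFrame:
        return self.records[self.records["tier_group"] == tier].set_index("patient_id")


def _record(patient: SyntheticPatient, tier_group: str, res: OptimizationResult) -> dict:
    m: MetricsSet | None = (
        res.metrics[res.selected_diameter] if res.selected_diameter is not None else None
    )
    rec = {
        "patient_id": patient.patient_id,
        "tier_group": tier_group,
        "tier_used": res.tier,
        "a_max_mm": res.axes.a_max if res.axes else float("nan"),
        "a_min_mm": res.axes.a_min if res.axes else float("nan"),
        "n_fractions": patient.n_fractions,
        "v_lung_cm3": patient.v_lung_cm3,
        "selected_diameter": res.selected_diameter if res.selected_diameter else float("nan"),
    }
    for col in METRIC_COLUMNS:
        if col == "selected_diameter":
            continue
        rec[col] = getattr(m, col) if m is not None else float("nan")
    return rec


def run_cohort_study(
    spec: CohortSpec,
    spacing_mm: float = 2.0,
    model: CollimatorModel | None = None,
    config: OptimizerConfig | None = None,
) -> CohortResult:
    """Optimize every patient under both coverage-threshold groups.

    The "C95" group runs the full feasibility cascade (C95 first, C90 as
    fallback); the "C90" group applies only the C90 threshold. Metrics are
    accumulated once per candidate diameter and reused by both groups.
    """
    model = model or CollimatorModel.iris()
    patients = sample_cohort(spec)
    rows: list[dict] = []
    results: dict[tuple[int, str], OptimizationResult] = {}
    for p in patients:
        ctv, ptv = build_patient_structures(p, spacing_mm)
        em = p.error_model(spec.n_points_per_fraction)
        trace = simulate_trace(em)
        axes = axis_lengths(ptv)
        cfg = config or OptimizerConfig(v_lung_cm3=p.v_lung_cm3)
        for tier_group in ("C95", "C90"):
            res = optimize_collimator(
                ctv, ptv, trace, model=model, config=cfg, axes=axes, start_tier=tier_group
            )
            results[(p.patient_id, tier_group)] = res
            rows.append(_record(p, tier_group, res))
    return CohortResult(patients=patients, records=pd.DataFrame(rows), results=results)


def paired_threshold_comparison(result: CohortResult) -> pd.DataFrame:
    """Paired two-tailed Wilcoxon signed-rank tests, C95 group vs C90 group.

    One row per metric column with the group means, the signed-rank statistic
    and the two-tailed p-value. Zero differences are dropped (Wilcoxon's
    convention, ``zero_method="wilcox"``); with fewer than two non-zero
    differences the test is flagged undefined (NaN statistic/p).
    """
    a = result.tier_frame("C95")
    b = result.tier_frame("C90").loc[a.index]
    rows = []
    for col in METRIC_COLUMNS:
        x = a[col].to_numpy(dtype=float)
        y = b[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        diff = x[ok] - y[ok]
        nz = np.count_nonzero(diff)
        if nz < 2:
            stat, p = float("nan"), float("nan")
        else:
            stat, p = stats.wilcoxon(
                x[ok], y[ok], zero_method="wilcox", alternative="two-sided"
            )
        rows.append(
            {
                "metric": col,
                "mean_c95_group": float(np.mean(x[ok])) if ok.any() else float("nan"),
                "mean_c90_group": float(np.mean(y[ok])) if ok.any() else float("nan"),
                "n_nonzero_diff": int(nz),
                "wilcoxon_stat": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def correlation_analysis(result: CohortResult, tier_group: str = "C95") -> pd.DataFrame:
    """Two-tailed Spearman correlations of Phi/a_min and Phi/a_max vs leakage.

    Rho uses midranks for ties; p-values come from the t approximation. A
    constant column yields an undefined (NaN) rho, flagged as such.
    """
    df = result.tier_frame(tier_group)
    rows = []
    for xcol in ("phi_over_amin", "phi_over_amax"):
        for ycol in ("leak_cov_ratio", "mean_leakage"):
            x = df[xcol].to_numpy(dtype=float)
            y = df[ycol].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(x[ok], y[ok])
            rows.append({"x": xcol, "y": ycol, "rho": float(rho), "p_value": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows).set_index(["x", "y"])


def diameter_distribution_table(
    result: CohortResult, tier_group: str = "C95"
) -> pd.DataFrame:
    """Selected-diameter counts per a_min range (half-open bins, with totals)."""
    df = result.tier_frame(tier_group)
    sel = df.dropna(subset=["selected_diameter"])
    bins = pd.cut(
        sel["a_min_mm"],
        bins=list(AMIN_BIN_EDGES),
        labels=list(AMIN_BIN_LABELS),
        right=False,
    )
    table = pd.crosstab(bins, sel["selected_diameter"], margins=True, margins_name="Total",
                        dropna=False)
    table.index.name = "a_min_range"
    table.columns.name = "diameter_mm"
    return table
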