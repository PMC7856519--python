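"""Patient-specific collimator diameter selection.

Three steps:

1. Candidate enumeration — field diameters d with
   0.5 * a_min <= d <= a_max + 5 mm, where a_max/a_min are the PTV's long and
   short axis lengths. Smaller apertures cannot cover the target; larger ones
   irradiate too much surrounding tissue.
2. Coverage feasibility cascade — keep candidates whose CTV coverage
   satisfies C95 >= 90%; if none do, fall back to C90 >= 90%; if still none,
   report the whole candidate list as infeasible.
3. Cost selection — F(d) = w * C95_PTV(d) - mean_leakage(d) / v_lung, with
   C95_PTV as a fraction in [0, 1], mean_leakage dimensionless and v_lung the
   affected-lung volume in cm^3. The selected diameter maximizes F over the
   feasible set (with the default w = 0 this minimizes mean leakage); ties go
   to the smaller aperture. A literal minimize-F mode exists for fidelity
   experiments with the printed selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CollimatorModel, accumulate, coverage_on_structure
from .geometry import AxisLengths, StructureMask, axis_lengths, embed_covering
from .metrics import MetricsSet, summarize
from .motion import MotionTrace

__all__ = [
    "NoAdmissibleDiameterError",
    "OptimizerConfig",
    "OptimizationResult",
    "candidate_diameters",
    "feasibility_cascade",
    "cost",
    "select",
    "optimize_collimator",
]

CANDIDATE_MARGIN_MM = 5.0  # upper candidate bound is a_max + 5 mm
COVERAGE_REQUIRED_PCT = 90.0  # CTV C95 (or C90) must reach 90%


class NoAdmissibleDiameterError(ValueError):
    """No field diameter falls inside [0.5 * a_min, a_max + 5 mm]."""


@dataclass(frozen=True)
class OptimizerConfig:
    """Selection-cost configuration.

    w
        Weight of the PTV C95 coverage term (dimensionless; the default 0
        drops target coverage from the cost, leaving pure leakage
        minimization — CTV coverage is already guaranteed by the cascade).
    v_lung_cm3
        Affected (ipsilateral) lung volume used to normalize the leakage term.
    coverage_required_pct
        Coverage threshold on the CTV quantiles (percent).
    literal_minimize
        If True, pick the candidate with the lowest F instead of the highest.
    """

    w: float = 0.0
    v_lung_cm3: float = 1500.0
    coverage_required_pct: float = COVERAGE_REQUIRED_PCT
    literal_minimize: bool = False

    def __post_init__(self) -> None:
        if self.v_lung_cm3 <= 0:
            raise ValueError("affected-lung volume must be positive")
        if self.w < 0:
            raise ValueError("coverage weight w must be non-negative")


@dataclass
class OptimizationResult:
    """Outcome of the three-step selection for one plan."""

    selected_diameter: float | None  # Phi, mm; None when no tier is feasible
    tier: str  # "C95" | "C90" | "none-feasible"
    candidates: list[float]
    feasible: list[float]
    costs: dict[float, float]  # per-candidate F(d)
    metrics: dict[float, MetricsSet]  # per-candidate scalar metrics
    axes: AxisLengths | None = None

    def __post_init__(self) -> None:
        if self.tier != "none-feasible" and self.selected_diameter not in self.feasible:
            raise ValueError("selected diameter must belong to the feasible set")
        if any(not np.isfinite(v) for v in self.costs.values()):
            raise ValueError("candidate costs must be finite")


def candidate_diameters(model: CollimatorModel, axes: AxisLengths) -> list[float]:
    """Field diameters admissible for this target geometry, increasing order."""
    lo = 0.5 * axes.a_min
    hi = axes.a_max + CANDIDATE_MARGIN_MM
    cands = [d for d in model.diameters if lo <= d <= hi]
    if not cands:
        raise NoAdmissibleDiameterError(
            f"no admissible field diameter in [{lo:.2f}, {hi:.2f}] mm "
            f"for a_min={axes.a_min:.2f}, a_max={axes.a_max:.2f}"
        )
    return cands


def feasibility_cascade(
    candidates: list[float],
    c95_ctv: dict[float, float],
    c90_ctv: dict[float, float],
    required_pct: float = COVERAGE_REQUIRED_PCT,
    start_tier: str = "C95",
) -> tuple[list[float], str]:
    """Coverage-threshold cascade over the candidate diameters.

    Tier "C95" keeps candidates with C95_CTV >= required; when empty, it
    degrades to tier "C90" (C90_CTV >= required); when that is empty too, the
    tier is "none-feasible" and the full candidate list is passed through so
    the caller can still inspect the cost table. ``start_tier="C90"`` skips
    the C95 stage (the comparison group that only demands C90 coverage).
    """
    if start_tier not in ("C95", "C90"):
        raise ValueError(f"start_tier must be C95 or C90, got {start_tier!r}")
    if start_tier == "C95":
        feas = [d for d in candidates if c95_ctv[d] >= required_pct]
        if feas:
            return feas, "C95"
    feas = [d for d in candidates if c90_ctv[d] >= required_pct]
    if feas:
        return feas, "C90"
    return list(candidates), "none-feasible"


def cost(m: MetricsSet, config: OptimizerConfig) -> float:
    """Selection cost F(d) = w * C95_PTV(d) - mean_leakage(d) / v_lung."""
    return config.w * (m.c95_ptv / 100.0) - m.mean_leakage / config.v_lung_cm3


def select(
    feasible: list[float],
    costs: dict[float, float],
    tier: str,
    metrics: dict[float, MetricsSet],
    config: OptimizerConfig | None = None,
    axes: AxisLengths | None = None,
) -> OptimizationResult:
    """Pick the best feasible diameter by cost; ties go to the smaller aperture."""
    config = config or OptimizerConfig()
    all_candidates = sorted(costs)
    if tier == "none-feasible" or not feasible:
        return OptimizationResult(
            selected_diameter=None,
            tier="none-feasible",
            candidates=all_candidates,
            feasible=[],
            costs=dict(costs),
            metrics=dict(metrics),
            axes=axes,
        )
    sign = -1.0 if config.literal_minimize else 1.0
    # on (sign*F, -d): cost ties resolve toward the smaller diameter
    best = max(feasible, key=lambda d: (sign * costs[d], -d))
    return OptimizationResult(
        selected_diameter=best,
        tier=tier,
        candidates=all_candidates,
        feasible=sorted(feasible),
        costs=dict(costs),
        metrics=dict(metrics),
        axes=axes,
    )


def optimize_collimator(
    ctv: StructureMask,
    ptv: StructureMask,
    trace: MotionTrace,
    model: CollimatorModel | None = None,
    config: OptimizerConfig | None = None,
    axes: AxisLengths | None = None,
    start_tier: str = "C95",
    center: np.ndarray | None = None,
) -> OptimizationResult:
    """Run the full three-step selection for one plan.

    ``axes`` (PTV long/short axis lengths) are measured from the PTV mask
    when not supplied. ``start_tier`` selects the coverage-threshold group:
    "C95" runs the full cascade, "C90" applies only the C90 threshold.
    """
    model = model or CollimatorModel.iris()
    config = config or OptimizerConfig()
    if axes is None:
        axes = axis_lengths(ptv)
    cands = candidate_diameters(model, axes)

    # the accumulation grid must also cover the PTV for its restriction
    ctv = embed_covering(ctv, ptv.grid)

    per_metric: dict[float, MetricsSet] = {}
    for d in cands:
        cov_ctv, leak = accumulate(ctv, trace, d, center=center)
        cov_ptv = coverage_on_structure(cov_ctv, ptv)
        per_metric[d] = summarize(cov_ctv, cov_ptv, leak, d, axes)

    feas, tier = feasibility_cascade(
        cands,
        {d: m.c95_ctv for d, m in per_metric.items()},
        {d: m.c90_ctv for d, m in per_metric.items()},
        required_pct=config.coverage_required_pct,
        start_tier=start_tier,
    )
    costs = {d: cost(per_metric[d], config) for d in cands}
    return select(feas, costs, tier, per_metric, config, axes=axes)
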