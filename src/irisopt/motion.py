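"""Motion traces: true vs predicted target positions per imaging time point.

A trace records, for every x-ray imaging time point of every treatment
fraction, the imaged ("true") 3D target position and the position the
tracking system predicted for the beam. Their difference is the treatment
delivery error — the combination of correlation error (tracking model vs
imaged position) and prediction error (look-ahead model vs tracking model).
Axes are ordered (LR, AP, SI), units mm.

Traces are exchanged as plain CSV with header
``fraction,time_s,true_lr,true_ap,true_si,pred_lr,pred_ap,pred_si``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TracePoint",
    "MotionTrace",
    "ErrorModel",
    "ErrorSummary",
    "read_trace",
    "write_trace",
    "simulate_trace",
    "error_summary",
]

AXES = ("lr", "ap", "si")
TRACE_COLUMNS = (
    "fraction",
    "time_s",
    "true_lr",
    "true_ap",
    "true_si",
    "pred_lr",
    "pred_ap",
    "pred_si",
)


@dataclass(frozen=True)
class TracePoint:
    fraction_index: int
    time_s: float
    true_pos: tuple[float, float, float]
    pred_pos: tuple[float, float, float]

    @property
    def error(self) -> np.ndarray:
        return np.asarray(self.pred_pos) - np.asarray(self.true_pos)


@dataclass
class MotionTrace:
    """Time-ordered imaging points over one or more fractions.

    Stored columnar for efficiency: ``fraction`` (int, 1-based), ``time_s``,
    and (n, 3) position arrays in (LR, AP, SI) order.
    """

    fraction: np.ndarray
    time_s: np.ndarray
    true_pos: np.ndarray
    pred_pos: np.ndarray

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.true_pos = np.asarray(self.true_pos, dtype=float).reshape(-1, 3)
        self.pred_pos = np.asarray(self.pred_pos, dtype=float).reshape(-1, 3)
        n = len(self.fraction)
        if n == 0:
            raise ValueError("a motion trace must contain at least one point")
        if not (len(self.time_s) == len(self.true_pos) == len(self.pred_pos) == n):
            raise ValueError("trace columns have inconsistent lengths")
        if not np.all(np.isfinite(self.true_pos)) or not np.all(np.isfinite(self.pred_pos)):
            raise ValueError("trace contains non-finite coordinates")
        for f in np.unique(self.fraction):
            t = self.time_s[self.fraction == f]
            if np.any(np.diff(t) < 0):
                raise ValueError(f"time must be non-decreasing within fraction {f}")

    def __len__(self) -> int:
        return len(self.fraction)

    @property
    def n_fractions(self) -> int:
        return len(np.unique(self.fraction))

    @property
    def errors(self) -> np.ndarray:
        """(n, 3) per-point tracking error e = pred - true, mm."""
        return self.pred_pos - self.true_pos

    @property
    def points(self) -> list[TracePoint]:
        return [
            TracePoint(
                fraction_index=int(self.fraction[i]),
                time_s=float(self.time_s[i]),
                true_pos=tuple(self.true_pos[i]),
                pred_pos=tuple(self.pred_pos[i]),
            )
            for i in range(len(self))
        ]


@dataclass(frozen=True)
class ErrorModel:
    """Per-axis Gaussian treatment delivery error model, mm.

    Defaults are the study-cohort per-axis error magnitudes of lung tracking
    delivery: LR 1.21, AP 0.58, SI 0.86 mm SD around zero mean.
    """

    sd_lr: float = 1.21
    sd_ap: float = 0.58
    sd_si: float = 0.86
    mean_lr: float = 0.0
    mean_ap: float = 0.0
    mean_si: float = 0.0
    n_points_per_fraction: int = 40
    n_fractions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_lr, self.sd_ap, self.sd_si) < 0:
            raise ValueError("error SDs must be non-negative")
        if self.n_points_per_fraction < 1 or self.n_fractions < 1:
            raise ValueError("need at least one point per fraction and one fraction")

    @property
    def sd(self) -> np.ndarray:
        return np.array([self.sd_lr, self.sd_ap, self.sd_si])

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mean_lr, self.mean_ap, self.mean_si])


@dataclass(frozen=True)
class ErrorSummary:
    """Per-axis moments of the error components and moments of |e|."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    total_mean: float
    total_sd: float

    def as_dict(self) -> dict[str, float]:
        out = {}
        for i, ax in enumerate(AXES):
            out[f"mean_{ax}"] = self.mean[i]
            out[f"sd_{ax}"] = self.sd[i]
        out["total_mean"] = self.total_mean
        out["total_sd"] = self.total_sd
        return out


def read_trace(path: str) -> MotionTrace:
    """Read a motion trace CSV (documented dialect; units mm)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing column(s): {', '.join(missing)}")
    coords = df[list(TRACE_COLUMNS[1:])].to_numpy(dtype=float)
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in np.flatnonzero(bad)[:5])
        raise ValueError(f"non-finite coordinate(s) in {path} at line(s) {lines}")
    return MotionTrace(
        fraction=df["fraction"].to_numpy(),
        time_s=df["time_s"].to_numpy(dtype=float),
        true_pos=df[["true_lr", "true_ap", "true_si"]].to_numpy(dtype=float),
        pred_pos=df[["pred_lr", "pred_ap", "pred_si"]].to_numpy(dtype=float),
    )


def write_trace(trace: MotionTrace, path: str) -> None:
    """Write a motion trace in the CSV dialect (lossless float round-trip)."""
    df = pd.DataFrame(
        {
            "fraction": trace.fraction,
            "time_s": trace.time_s,
            "true_lr": trace.true_pos[:, 0],
            "true_ap": trace.true_pos[:, 1],
            "true_si": trace.true_pos[:, 2],
            "pred_lr": trace.pred_pos[:, 0],
            "pred_ap": trace.pred_pos[:, 1],
            "pred_si": trace.pred_pos[:, 2],
        }
    )
    df.to_csv(path, index=False)


def simulate_trace(
    model: ErrorModel,
    path_amplitude: tuple[float, float, float] = (1.0, 1.0, 5.0),
    period_s: float = 4.0,
    dt_s: float = 15.0,
) -> MotionTrace:
    """Simulate a trace: periodic breathing-like true path plus Gaussian error.

    True positions follow a cosine path per axis with the given amplitude
    (default dominated by SI excursion, as in free-breathing lung motion) and
    period (default 4 s); imaging points are ``dt_s`` apart (default one x-ray
    image per 15 s). The predicted position is the true position plus an
    independent per-axis Gaussian draw from ``model``. Reproducible for a
    fixed ``model.seed``. Only the error (pred - true) matters for the
    coverage accumulation, which works in the target frame; the breathing path
    is kept for realism and frame experiments.
    """
    rng = np.random.default_rng(model.seed)
    amp = np.asarray(path_amplitude, dtype=float)
    n = model.n_points_per_fraction
    fraction = np.repeat(np.arange(1, model.n_fractions + 1), n)
    t = np.tile(np.arange(n) * dt_s, model.n_fractions)
    phase = 2.0 * np.pi * t / period_s
    true_pos = amp[None, :] * np.cos(phase)[:, None]
    err = rng.normal(loc=model.mean, scale=model.sd, size=(len(t), 3))
    return MotionTrace(fraction=fraction, time_s=t, true_pos=true_pos, pred_pos=true_pos + err)


def error_summary(trace: MotionTrace) -> ErrorSummary:
    """Per-axis mean/SD of the error components and mean/SD of the error norm.

    Sample SDs (ddof=1); a single-point trace reports zero SDs.
    """
    e = trace.errors
    ddof = 1 if len(trace) > 1 else 0
    norms = np.linalg.norm(e, axis=1)
    return ErrorSummary(
        mean=tuple(float(m) for m in e.mean(axis=0)),
        sd=tuple(float(s) for s in e.std(axis=0, ddof=ddof)),
        total_mean=float(norms.mean()),
        total_sd=float(norms.std(ddof=ddof)),
    )
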