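"""Time-resolved bootstrap reaction-time estimation from beam-break traces.

At each time point the observed statistic is the fraction of S+ trials with
the beam interrupted minus the fraction of S- trials interrupted.  Trials
are resampled with replacement within class (B bootstrap draws) and the
significance value p(t) is the bootstrap probability that the resampled
difference is <= 0, floored at 1/(B+1).  The reaction time is the last
downward crossing of the p = alpha line after which p stays below alpha to
the end of the window; the point of largest curvature of log10 p versus t
is available as a fallback estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import SMINUS, SPLUS, Session

__all__ = [
    "BeamBreakMatrix",
    "PValueCurve",
    "ReactionTime",
    "pvalue_curve",
    "reaction_time_last_crossing",
    "reaction_time_curvature",
]


@dataclass
class BeamBreakMatrix:
    """S+ and S- beam-break traces on a common time grid (ms, post-onset)."""

    times_ms: np.ndarray
    sp_traces: np.ndarray  # (n S+ trials, n times) bool
    sm_traces: np.ndarray  # (n S- trials, n times) bool

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.sp_traces = np.asarray(self.sp_traces, dtype=bool)
        self.sm_traces = np.asarray(self.sm_traces, dtype=bool)
        if self.sp_traces.size == 0 or self.sm_traces.size == 0:
            raise ValueError("both trial classes must be non-empty")
        if self.sp_traces.shape[1] != self.times_ms.size or (
            self.sm_traces.shape[1] != self.times_ms.size
        ):
            raise ValueError("trace width must match the time grid")

    @classmethod
    def from_session(cls, s: Session) -> "BeamBreakMatrix":
        sp = [t.beam_break for t in s.trials if t.valence == SPLUS and t.beam_break is not None]
        sm = [t.beam_break for t in s.trials if t.valence == SMINUS and t.beam_break is not None]
        if not sp or not sm:
            raise ValueError("session lacks beam-break traces for one of the classes")
        times = next(t.beam_times_ms for t in s.trials if t.beam_times_ms is not None)
        return cls(times_ms=times, sp_traces=np.array(sp), sm_traces=np.array(sm))


@dataclass
class PValueCurve:
    times_ms: np.ndarray
    p: np.ndarray
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != self.times_ms.size:
            raise ValueError("p and time grid length mismatch")
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValueError("p values must lie in (0, 1]")


@dataclass
class ReactionTime:
    rt_ms: float | None
    method: str  # last_crossing | curvature
    curve: PValueCurve
    boundary: bool = False  # p already below alpha at the first grid point


def pvalue_curve(
    m: BeamBreakMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    min_trials: int = 10,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> PValueCurve:
    """Bootstrap significance of the S+/S- break-fraction difference over time.

    One-sided by default (S+ fraction greater than S-); ``alternative="two-sided"``
    doubles the one-sided p (capped at 1).
    """
    n_sp = m.sp_traces.shape[0]
    n_sm = m.sm_traces.shape[0]
    if min(n_sp, n_sm) < min_trials:
        raise ValueError(
            f"need at least {min_trials} trials per class, got {n_sp} S+ / {n_sm} S-"
        )
    rng = np.random.default_rng(seed)
    # resample with replacement within class, expressed as multinomial counts;
    # the d* <= 0 comparison is done in exact integer arithmetic so that
    # identical trace classes give d* == 0, not floating-point dust
    c_sp = rng.multinomial(n_sp, np.full(n_sp, 1.0 / n_sp), size=n_boot)
    c_sm = rng.multinomial(n_sm, np.full(n_sm, 1.0 / n_sm), size=n_boot)
    a = c_sp @ m.sp_traces.astype(np.int64)  # (n_boot, n_times), sums of n_sp draws
    b = c_sm @ m.sm_traces.astype(np.int64)
    le = a * n_sm <= b * n_sp  # d* = a/n_sp - b/n_sm <= 0
    p = le.mean(axis=0)
    if alternative == "two-sided":
        ge = a * n_sm >= b * n_sp
        p = np.minimum(1.0, 2.0 * np.minimum(p, ge.mean(axis=0)))
    elif alternative != "greater":
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.maximum(p, 1.0 / (n_boot + 1))
    return PValueCurve(times_ms=m.times_ms, p=p, alpha=alpha, n_boot=n_boot, seed=seed)


def reaction_time_last_crossing(c: PValueCurve) -> ReactionTime:
    """Latest time from which p stays below alpha through the window end.

    Undefined (``rt_ms`` is None) when p never settles below alpha; flagged
    ``boundary`` when p is already below alpha at the first grid point.
    """
    below = c.p < c.alpha
    if not below[-1]:
        return ReactionTime(rt_ms=None, method="last_crossing", curve=c)
    # first index of the trailing run of sub-alpha points
    idx = int(np.flatnonzero(~below)[-1]) + 1 if not below.all() else 0
    return ReactionTime(
        rt_ms=float(c.times_ms[idx]),
        method="last_crossing",
        curve=c,
        boundary=idx == 0,
    )


def reaction_time_curvature(c: PValueCurve, flat_tol: float = 1e-9) -> ReactionTime:
    """Point of largest discrete curvature of the smoothed log10 p(t) curve.

    The curve is smoothed with a 3-point moving average; curvature is the
    absolute second difference normalised by (1 + slope^2)^(3/2), with t in
    grid-step units.  Near-tied maxima (within 1e-12) are resolved to their
    median index so a clean piecewise-linear corner maps to the corner
    itself.  A flat or purely linear curve yields an undefined estimate.
    """
    if c.p.size < 5:
        raise ValueError("need at least 5 points for the curvature estimate")
    y = np.log10(c.p)
    y = np.convolve(y, np.ones(3) / 3.0, mode="valid")  # centres 1..n-2
    d1 = 0.5 * (y[2:] - y[:-2])
    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]
    kappa = np.abs(d2) / (1.0 + d1**2) ** 1.5  # centres 2..n-3 of original grid
    if kappa.size == 0 or kappa.max() < flat_tol:
        return ReactionTime(rt_ms=None, method="curvature", curve=c)
    near = np.flatnonzero(kappa >= kappa.max() - 1e-12)
    idx = int(np.median(near)) + 2
    return ReactionTime(rt_ms=float(c.times_ms[idx]), method="curvature", curve=c)
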