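"""Trial scoring and discrimination-performance analysis for go/no-go sessions.

A trial is scored from lick occupancy of the four 500 ms bins that tile the
2 s stimulus: an S+ trial is a hit when at least three of the four bins
contain a lick, and an S- trial is a correct rejection when at most one bin
does.  Session-level performance is the percentage of correct trials over a
trailing window (default 300 trials), and the discrimination threshold is
the dilution interval where accuracy first crosses a criterion scanning
from the most dilute condition upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SPLUS",
    "SMINUS",
    "Trial",
    "Session",
    "PerformanceCurve",
    "TrialScore",
    "SequenceReport",
    "score_trial",
    "performance",
    "block_performance",
    "discrimination_threshold",
    "validate_sequence",
    "bins_from_lick_times",
]

SPLUS = "S+"
SMINUS = "S-"

#: duration of one lick bin in ms; four bins tile the 2 s stimulus
LICK_BIN_MS = 500.0
N_LICK_BINS = 4
STIMULUS_MS = 2000.0
MIN_ITI_S = 5.0


@dataclass(frozen=True)
class Trial:
    """One behavioral trial.

    ``bin_licks`` holds lick occupancy of the four 500 ms bins covering the
    2 s stimulus.  ``beam_break`` (optional) is a boolean time series on
    ``beam_times_ms`` (ms relative to odor onset), True while the head-port
    light beam is interrupted.
    """

    index: int
    odor: str
    valence: str
    bin_licks: tuple[bool, bool, bool, bool]
    iti_s: float = 10.0
    beam_break: np.ndarray | None = None
    beam_times_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valence not in (SPLUS, SMINUS):
            raise ValueError(f"valence must be {SPLUS!r} or {SMINUS!r}, got {self.valence!r}")
        if len(self.bin_licks) != N_LICK_BINS:
            raise ValueError(f"expected {N_LICK_BINS} lick bins, got {len(self.bin_licks)}")
        if self.iti_s < MIN_ITI_S:
            raise ValueError(f"inter-trial interval must be >= {MIN_ITI_S} s, got {self.iti_s}")


@dataclass
class Session:
    """Ordered trials for one mouse / odor pair / dilution."""

    mouse_id: str
    odor_pair: tuple[str, str]
    dilution_exponent: int
    trials: list[Trial]
    group: str = "trained"
    #: generator-side correctness labels, when the session is synthetic
    gt_correct: list[bool] | None = None

    def __post_init__(self) -> None:
        if self.group not in ("trained", "exposed", "naive"):
            raise ValueError(f"unknown group {self.group!r}")
        idx = [t.index for t in self.trials]
        if idx != sorted(idx):
            raise ValueError("trials must be ordered by index")

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class PerformanceCurve:
    """Accuracy (percent correct over the last ``window`` trials) per dilution."""

    dilution_exponents: list[int]
    accuracy_pct: list[float]
    block_accuracy: dict[int, list[float]] = field(default_factory=dict)
    threshold_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.dilution_exponents) != len(self.accuracy_pct):
            raise ValueError("dilution_exponents and accuracy_pct length mismatch")
        for a in self.accuracy_pct:
            if not 0.0 <= a <= 100.0:
                raise ValueError(f"accuracy out of [0, 100]: {a}")


@dataclass(frozen=True)
class TrialScore:
    correct: bool
    outcome: str  # hit | miss | correct_rejection | false_alarm


def bins_from_lick_times(lick_times_ms: Sequence[float]) -> tuple[bool, bool, bool, bool]:
    """Derive bin occupancy from lick event timestamps (ms after odor onset).

    Bin ``b`` is occupied iff at least one lick falls in the half-open
    interval ``[500 b, 500 (b + 1))``.
    """
    bins = [False] * N_LICK_BINS
    for t in lick_times_ms:
        b = int(math.floor(t / LICK_BIN_MS))
        if 0 <= b < N_LICK_BINS:
            bins[b] = True
    return tuple(bins)  # type: ignore[return-value]


def score_trial(t: Trial) -> TrialScore:
    """Score one trial.

    S+ is correct (hit) iff licking occurred in at least 3 of the 4 bins;
    S- is correct (correct rejection) iff licking occurred in at most 1 bin.
    """
    n_licked = sum(bool(b) for b in t.bin_licks)
    if t.valence == SPLUS:
        if n_licked >= 3:
            return TrialScore(True, "hit")
        return TrialScore(False, "miss")
    if n_licked <= 1:
        return TrialScore(True, "correct_rejection")
    return TrialScore(False, "false_alarm")


def performance(s: Session, window: int = 300) -> float:
    """Percent correct over the last ``window`` trials of the session."""
    if len(s.trials) == 0:
        raise ValueError("empty session")
    if window <= 0:
        raise ValueError("window must be positive")
    if window > len(s.trials):
        raise ValueError(f"window {window} exceeds session length {len(s.trials)}")
    tail = s.trials[-window:]
    n_correct = sum(score_trial(t).correct for t in tail)
    return 100.0 * n_correct / window


def block_performance(s: Session, block: int = 100) -> list[float]:
    """Percent correct per non-overlapping consecutive block; the trailing
    partial block is dropped."""
    if block <= 0:
        raise ValueError("block size must be positive")
    n_blocks = len(s.trials) // block
    out = []
    for i in range(n_blocks):
        chunk = s.trials[i * block : (i + 1) * block]
        out.append(100.0 * sum(score_trial(t).correct for t in chunk) / block)
    return out


def discrimination_threshold(
    curve: PerformanceCurve | dict[int, float], criterion_pct: float = 70.0
) -> tuple[float, float]:
    """Bracketing dilution interval around the discrimination threshold.

    Scanning dilutions from most to least dilute (ascending exponent), the
    threshold interval is (highest exponent still below criterion, lowest
    exponent at or above criterion).  Ties at the criterion count as
    discriminating.  If even the most dilute condition is at criterion the
    lower bound is ``-inf``; if the criterion is never reached the result is
    ``(nan, nan)``.
    """
    if isinstance(curve, PerformanceCurve):
        acc = dict(zip(curve.dilution_exponents, curve.accuracy_pct))
    else:
        acc = dict(curve)
    if len(acc) < 2:
        raise ValueError("need accuracies for at least two dilutions")
    exps = sorted(acc)  # most dilute (most negative) first
    for i, e in enumerate(exps):
        if acc[e] >= criterion_pct:
            lower = exps[i - 1] if i > 0 else -math.inf
            return (lower, float(e))
    return (math.nan, math.nan)


@dataclass
class SequenceReport:
    """Validity report for a session's trial sequence (report-only)."""

    run_violations: list[int]  # index of the 3rd trial of each same-odor run
    iti_violations: list[int]
    day_imbalance: dict[int, tuple[int, int]]  # day -> (n S+, n S-) when unequal
    trials_per_day: int = 300

    @property
    def ok(self) -> bool:
        return not (self.run_violations or self.iti_violations or self.day_imbalance)


def validate_sequence(s: Session, trials_per_day: int = 300) -> SequenceReport:
    """Flag same-odor runs of length >= 3, ITI < 5 s, and per-day S+/S-
    imbalance (complete days only)."""
    runs: list[int] = []
    odors = [t.odor for t in s.trials]
    for i in range(2, len(odors)):
        if odors[i] == odors[i - 1] == odors[i - 2]:
            runs.append(i)
    itis = [t.index for t in s.trials if t.iti_s < MIN_ITI_S]
    imbalance: dict[int, tuple[int, int]] = {}
    n_days = len(s.trials) // trials_per_day
    for d in range(n_days):
        day = s.trials[d * trials_per_day : (d + 1) * trials_per_day]
        n_plus = sum(t.valence == SPLUS for t in day)
        n_minus = len(day) - n_plus
        if n_plus != n_minus:
            imbalance[d] = (n_plus, n_minus)
    return SequenceReport(runs, itis, imbalance, trials_per_day)
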