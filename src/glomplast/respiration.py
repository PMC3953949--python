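"""Breathing-frequency estimation from airflow traces and the
amplitude-versus-frequency independence analysis.

Cycles are detected as successive negative-to-positive zero crossings of
the mean-subtracted, low-pass-filtered airflow signal inside the analysis
window; crossing times are refined on a cubic spline so the estimate is
grid-independent for smooth signals.  Frequency is the number of complete
cycles divided by the time between the first and last crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal
from scipy.interpolate import CubicSpline
from scipy.stats import mannwhitneyu, wilcoxon

__all__ = [
    "AirflowTrace",
    "BreathingEstimate",
    "AmplitudeFrequencyResult",
    "breathing_frequency",
    "amplitude_vs_frequency",
]

DEFAULT_BINS_HZ = (1.8, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0)


@dataclass
class AirflowTrace:
    """Uniformly sampled airflow signal with an analysis window (seconds)."""

    times_s: np.ndarray
    signal: np.ndarray
    window_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times_s.size != self.signal.size:
            raise ValueError("times and signal length mismatch")
        dt = np.diff(self.times_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")
        if self.window_s is not None:
            lo, hi = self.window_s
            if lo < self.times_s[0] - 1e-9 or hi > self.times_s[-1] + 1e-9:
                raise ValueError("analysis window lies outside the trace")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(self.times_s[1] - self.times_s[0])


@dataclass
class BreathingEstimate:
    frequency_hz: float
    n_cycles: int
    window_s: tuple[float, float]
    crossing_times_s: np.ndarray | None = None


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq * 0.95:
        return x
    b, a = signal.butter(4, cutoff_hz / nyq)
    return signal.filtfilt(b, a, x)


def breathing_frequency(t: AirflowTrace, cutoff_hz: float = 15.0) -> BreathingEstimate | None:
    """Breathing frequency inside the trace's analysis window.

    Returns None (with a warning) when fewer than two upward zero crossings
    are found, i.e. no complete cycle.
    """
    lo, hi = t.window_s if t.window_s is not None else (t.times_s[0], t.times_s[-1])
    sel = (t.times_s >= lo - 1e-12) & (t.times_s <= hi + 1e-12)
    times = t.times_s[sel]
    x = t.signal[sel].astype(float)
    if x.size < 4:
        warnings.warn("window too short for cycle detection")
        return None
    x = _lowpass(x - x.mean(), t.sample_rate_hz, cutoff_hz)
    up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    if up.size < 2:
        warnings.warn("fewer than two zero crossings: frequency undefined")
        return None
    spline = CubicSpline(times, x)
    crossings = []
    for i in up:
        try:
            crossings.append(optimize.brentq(spline, times[i], times[i + 1], xtol=1e-12))
        except ValueError:  # no sign change on the spline (grazing crossing)
            crossings.append(float(times[i]))
    crossings = np.asarray(crossings)
    n_cycles = crossings.size - 1
    freq = n_cycles / (crossings[-1] - crossings[0])
    return BreathingEstimate(
        frequency_hz=float(freq),
        n_cycles=int(n_cycles),
        window_s=(float(lo), float(hi)),
        crossing_times_s=crossings,
    )


@dataclass
class AmplitudeFrequencyResult:
    bins_hz: list[float]
    bin_means: dict[float, float]
    normalized_means: dict[float, float]
    n_per_bin: dict[float, int]
    ref_freq_hz: float
    test_name: str | None = None
    statistic: float | None = None
    p_value: float | None = None


def amplitude_vs_frequency(
    amplitudes: np.ndarray,
    freqs: np.ndarray,
    ref_freq_hz: float = 1.8,
    bins_hz: tuple[float, ...] = DEFAULT_BINS_HZ,
    bin_tol_hz: float = 0.1,
    roi_ids: np.ndarray | None = None,
    compare_freq_hz: float = 3.0,
) -> AmplitudeFrequencyResult:
    """Bin per-trial response amplitudes by breathing frequency, normalize to
    the reference bin, and compare the reference against ``compare_freq_hz``.

    When ``roi_ids`` is given the comparison is a paired Wilcoxon signed-rank
    test on per-ROI means in the two bins; otherwise an unpaired
    Mann-Whitney U test on the pooled amplitudes.  Bins with no trials are
    omitted with a warning.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if amplitudes.size != freqs.size:
        raise ValueError("amplitudes and freqs must be matched per trial")
    if ref_freq_hz not in bins_hz:
        raise ValueError("reference frequency must be one of the bins")
    assign = {}
    for b in bins_hz:
        assign[b] = np.abs(freqs - b) <= bin_tol_hz
    bin_means: dict[float, float] = {}
    n_per_bin: dict[float, int] = {}
    for b in bins_hz:
        n = int(assign[b].sum())
        if n == 0:
            warnings.warn(f"no trials in the {b} Hz bin; omitted")
            continue
        bin_means[b] = float(amplitudes[assign[b]].mean())
        n_per_bin[b] = n
    if ref_freq_hz not in bin_means:
        raise ValueError("reference bin is empty")
    ref = bin_means[ref_freq_hz]
    if ref == 0:
        raise ValueError("reference bin mean is zero; cannot normalize")
    normalized = {b: m / ref for b, m in bin_means.items()}

    test_name = statistic = p_value = None
    if compare_freq_hz in bin_means:
        a_sel = assign[ref_freq_hz]
        b_sel = assign[compare_freq_hz]
        if roi_ids is not None:
            roi_ids = np.asarray(roi_ids)
            pairs_a, pairs_b = [], []
            for roi in np.unique(roi_ids):
                ra = amplitudes[a_sel & (roi_ids == roi)]
                rb = amplitudes[b_sel & (roi_ids == roi)]
                if ra.size and rb.size:
                    pairs_a.append(ra.mean())
                    pairs_b.append(rb.mean())
            if len(pairs_a) >= 5:
                res = wilcoxon(pairs_a, pairs_b)
                test_name, statistic, p_value = "wilcoxon", float(res.statistic), float(res.pvalue)
        if test_name is None:
            res = mannwhitneyu(amplitudes[a_sel], amplitudes[b_sel])
            test_name, statistic, p_value = "mannwhitneyu", float(res.statistic), float(res.pvalue)
    return AmplitudeFrequencyResult(
        bins_hz=[b for b in bins_hz if b in bin_means],
        bin_means=bin_means,
        normalized_means=normalized,
        n_per_bin=n_per_bin,
        ref_freq_hz=ref_freq_hz,
        test_name=test_name,
        statistic=statistic,
        p_value=p_value,
    )
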