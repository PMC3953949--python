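"""Group-level statistics and the psychometric linkage between glomerular
input strength and discrimination accuracy.

Amplitude tables are flat records (mouse, group, odorant, dilution_exponent,
roi_id, rep, amplitude_permil) as produced by
:func:`glomplast.imaging.run_mouse_pipeline`; ``rep == 0`` rows hold the
repetition-averaged amplitude used for all summaries.  The mouse is the unit
of replication for means and SEMs; ROI-level pooling is used only for the
cumulative-distribution comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupSummary",
    "PsychometricFit",
    "CdfComparison",
    "RewardSplit",
    "ThresholdContrast",
    "group_summary",
    "fold_change_counts",
    "amplitude_cdf_compare",
    "reward_value_split",
    "boltzmann_fit",
    "boltzmann",
    "plot_cdf_and_fit",
    "threshold_accuracy_contrast",
]

GROUPS = ("trained", "exposed", "naive")

#: high/low dilution-exponent pooling per odor pair (high = near threshold)
DEFAULT_DILUTION_CLASSES = {
    "Cin": {"high": (-3, -2), "low": (-1, 0)},
    "Eu": {"high": (-3, -2), "low": (-1, 0)},
    "IAA": {"high": (-6, -4), "low": (-2, 0)},
    "EB": {"high": (-6, -4), "low": (-2, 0)},
}


@dataclass
class GroupSummary:
    group: str
    n_mice: int
    amplitude_mean: dict[tuple[str, int], tuple[float, float]]  # (odorant, dil) -> (mean, sem)
    count_mean: dict[tuple[str, int], tuple[float, float]]
    class_count_mean: dict[str, float] = field(default_factory=dict)  # high/low
    overall_amplitude: float = math.nan  # hierarchical ROIs -> mouse -> group
    normalized_amplitude: float = math.nan  # overall / naive overall
    pooled_roi_amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def group_summary(
    amplitude_df: pd.DataFrame,
    count_df: pd.DataFrame,
    dilution_classes: dict | None = None,
    pool_class: str | None = None,
) -> dict[str, GroupSummary]:
    """Per-group hierarchical summaries (ROIs -> mouse -> group, SEM over mice).

    ``pool_class`` restricts the pooled ROI amplitude list (for CDF
    comparisons) to the given dilution class ('high' or 'low'); by default
    all dilutions present in the table are pooled.  Normalized amplitudes
    divide each group's overall mean by the naive group's, so the naive
    normalized value is exactly 1.
    """
    classes = dilution_classes or DEFAULT_DILUTION_CLASSES
    amp = amplitude_df[amplitude_df["rep"] == 0] if "rep" in amplitude_df else amplitude_df
    for g in amp["group"].unique():
        if g not in GROUPS:
            raise ValueError(f"unknown group label {g!r}")
    out: dict[str, GroupSummary] = {}
    for g in GROUPS:
        ga = amp[amp["group"] == g]
        gc = count_df[count_df["group"] == g]
        if ga.empty and gc.empty:
            continue
        amp_mean: dict[tuple[str, int], tuple[float, float]] = {}
        for (od, dil), sub in ga.groupby(["odorant", "dilution_exponent"]):
            per_mouse = sub.groupby("mouse")["amplitude_permil"].mean().to_numpy()
            amp_mean[(od, int(dil))] = (float(per_mouse.mean()), _sem(per_mouse))
        cnt_mean: dict[tuple[str, int], tuple[float, float]] = {}
        for (od, dil), sub in gc.groupby(["odorant", "dilution_exponent"]):
            per_mouse = sub.groupby("mouse")["count"].mean().to_numpy()
            cnt_mean[(od, int(dil))] = (float(per_mouse.mean()), _sem(per_mouse))
        class_counts: dict[str, float] = {}
        for cls in ("high", "low"):
            sel = gc[
                gc.apply(
                    lambda r, c=cls: int(r["dilution_exponent"])
                    in classes.get(r["odorant"], {}).get(c, ()),
                    axis=1,
                )
            ] if not gc.empty else gc
            if not sel.empty:
                per_mouse = sel.groupby("mouse")["count"].mean().to_numpy()
                class_counts[cls] = float(per_mouse.mean())
        # pooled ROI list: one entry per (mouse, roi) -- the driving odorant's
        # mean amplitude over the pooled dilutions
        pool = ga
        if pool_class is not None and not ga.empty:
            pool = ga[
                ga.apply(
                    lambda r: int(r["dilution_exponent"])
                    in classes.get(r["odorant"], {}).get(pool_class, ()),
                    axis=1,
                )
            ]
        pooled = np.array([])
        overall = math.nan
        if not pool.empty:
            per_roi = (
                pool.groupby(["mouse", "roi_id", "odorant"])["amplitude_permil"]
                .mean()
                .reset_index()
            )
            idx = (
                per_roi.assign(mag=per_roi["amplitude_permil"].abs())
                .groupby(["mouse", "roi_id"])["mag"]
                .idxmax()
            )
            driving = per_roi.loc[idx]
            pooled = driving["amplitude_permil"].to_numpy()
            per_mouse = driving.groupby("mouse")["amplitude_permil"].mean().to_numpy()
            overall = float(per_mouse.mean())
        out[g] = GroupSummary(
            group=g,
            n_mice=int(max(ga["mouse"].nunique() if not ga.empty else 0,
                           gc["mouse"].nunique() if not gc.empty else 0)),
            amplitude_mean=amp_mean,
            count_mean=cnt_mean,
            class_count_mean=class_counts,
            overall_amplitude=overall,
            pooled_roi_amplitudes=pooled,
        )
    if "naive" in out and np.isfinite(out["naive"].overall_amplitude):
        naive = out["naive"].overall_amplitude
        for g in out.values():
            g.normalized_amplitude = g.overall_amplitude / naive
    return out


def fold_change_counts(
    summary_a: GroupSummary, summary_b: GroupSummary, dilution_class: str = "high"
) -> float:
    """Ratio of mean activated-glomerulus counts (a over b) in a dilution class."""
    if dilution_class not in summary_a.class_count_mean or (
        dilution_class not in summary_b.class_count_mean
    ):
        raise ValueError(f"both summaries must cover the {dilution_class!r} dilution class")
    denom = summary_b.class_count_mean[dilution_class]
    if denom == 0:
        warnings.warn("zero denominator count: fold change undefined")
        return math.nan
    return summary_a.class_count_mean[dilution_class] / denom


@dataclass
class CdfComparison:
    ks_statistic: float
    p_value: float
    n_a: int
    n_b: int
    shift_direction: str  # 'a_larger' | 'b_larger' | 'none' (by median |amplitude|)
    ecdf_a: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    ecdf_b: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x)
    return xs, np.arange(1, xs.size + 1) / xs.size


def amplitude_cdf_compare(pooled_a: np.ndarray, pooled_b: np.ndarray) -> CdfComparison:
    """Two-sample Kolmogorov-Smirnov comparison of pooled ROI amplitudes."""
    a = np.asarray(pooled_a, dtype=float)
    b = np.asarray(pooled_b, dtype=float)
    if min(a.size, b.size) == 0:
        raise ValueError("both pools must be non-empty")
    if min(a.size, b.size) < 20:
        warnings.warn("fewer than 20 ROIs in a pool: KS comparison is unreliable")
    res = stats.ks_2samp(a, b)
    med_a, med_b = np.median(np.abs(a)), np.median(np.abs(b))
    if med_a > med_b:
        direction = "a_larger"
    elif med_b > med_a:
        direction = "b_larger"
    else:
        direction = "none"
    return CdfComparison(
        ks_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        shift_direction=direction,
        ecdf_a=_ecdf(a),
        ecdf_b=_ecdf(b),
    )


@dataclass
class RewardSplit:
    rewarded: np.ndarray
    non_rewarded: np.ndarray
    pooled_p: float
    paired_p: float | None
    n_pairs: int


def reward_value_split(
    amplitude_df: pd.DataFrame, valences: dict[tuple[str, str], str]
) -> RewardSplit:
    """Compare amplitudes of glomeruli driven by rewarded (S+) vs
    non-rewarded (S-) odorants, supporting counterbalanced valence.

    ``valences`` maps (mouse, odorant) -> 'S+' or 'S-'.  Pooled comparison is
    Mann-Whitney on ROI amplitudes; the paired comparison uses per-mouse
    means (paired t-test) when every mouse has both valences.
    """
    amp = amplitude_df[amplitude_df["rep"] == 0] if "rep" in amplitude_df else amplitude_df
    keys = set(zip(amp["mouse"], amp["odorant"]))
    missing = [k for k in keys if k not in valences]
    if missing:
        raise ValueError(f"missing valence assignment for {sorted(missing)[:3]}")
    if len({valences[k] for k in keys}) < 2:
        raise ValueError("need both rewarded and non-rewarded odorants")
    val = amp.apply(lambda r: valences[(r["mouse"], r["odorant"])], axis=1)
    rewarded = amp[val == "S+"]["amplitude_permil"].to_numpy()
    non_rewarded = amp[val == "S-"]["amplitude_permil"].to_numpy()
    pooled_p = float(stats.mannwhitneyu(rewarded, non_rewarded).pvalue)
    paired_p = None
    pairs_r, pairs_n = [], []
    for mouse, sub in amp.assign(valence=val.values).groupby("mouse"):
        r = sub[sub["valence"] == "S+"]["amplitude_permil"]
        n = sub[sub["valence"] == "S-"]["amplitude_permil"]
        if len(r) and len(n):
            pairs_r.append(r.mean())
            pairs_n.append(n.mean())
    if len(pairs_r) >= 3:
        paired_p = float(stats.ttest_rel(pairs_r, pairs_n).pvalue)
    return RewardSplit(rewarded, non_rewarded, pooled_p, paired_p, len(pairs_r))


@dataclass
class PsychometricFit:
    """Four-parameter Boltzmann sigmoid y = a2 + (a1 - a2)/(1 + exp((x - x0)/dx))."""

    a1: float  # lower asymptote (%)
    a2: float  # upper asymptote (%)
    x0: float  # midpoint on the input-strength axis (permil)
    dx: float  # slope scale (permil)
    r_squared: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not self.a1 < self.a2:
                raise ValueError("lower asymptote must be below the upper asymptote")
            if self.dx <= 0:
                raise ValueError("slope scale must be positive")
            if not -1e-9 <= self.r_squared <= 1 + 1e-9:
                raise ValueError("r_squared out of [0, 1]")
            self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))

    def __call__(self, x) -> np.ndarray:
        return boltzmann(np.asarray(x, dtype=float), self.a1, self.a2, self.x0, self.dx)


def boltzmann(x: np.ndarray, a1: float, a2: float, x0: float, dx: float) -> np.ndarray:
    u = np.clip((x - x0) / dx, -700.0, 700.0)  # avoid exp overflow during search
    return a2 + (a1 - a2) / (1.0 + np.exp(u))


def boltzmann_fit(x, y, degenerate_dx_factor: float = 100.0) -> PsychometricFit:
    """Multi-start least-squares Boltzmann fit of accuracy (%) versus input
    strength (permil).

    Raises on non-convergence of every start; a flat response or an
    effectively unbounded slope scale returns a fit flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y length mismatch")
    if x.size < 4:
        raise ValueError("need at least 4 points for a 4-parameter fit")
    span = float(x.max() - x.min())
    y_span = float(y.max() - y.min())
    if span <= 0:
        raise ValueError("degenerate x axis")
    if y_span < 1e-9:
        return PsychometricFit(
            a1=float(y.mean()), a2=float(y.mean()), x0=float(x.mean()),
            dx=math.inf, r_squared=0.0, degenerate=True,
        )

    def resid(p):
        return boltzmann(x, *p) - y

    lo = [-np.inf, -np.inf, x.min() - span, 1e-9 * span]
    hi = [np.inf, np.inf, x.max() + span, 1e4 * span]
    best = None
    for x0_0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for dx_0 in (0.05 * span, 0.15 * span, 0.5 * span):
            try:
                res = optimize.least_squares(
                    resid,
                    [float(y.min()), float(y.max()), float(x0_0), float(dx_0)],
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise RuntimeError("Boltzmann fit failed to converge from every start")
    a1, a2, x0, dx = (float(v) for v in best.x)
    if a1 > a2:  # same curve re-parameterised; keep a1 < a2 with dx sign flip
        a1, a2, dx = a2, a1, -dx
    ss_res = float(np.sum(best.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    degenerate = dx <= 0 or dx > degenerate_dx_factor * span
    return PsychometricFit(a1=a1, a2=a2, x0=x0, dx=dx,
                           r_squared=r2 if not degenerate else max(r2, 0.0),
                           degenerate=degenerate)


def plot_cdf_and_fit(
    cdf: CdfComparison | None,
    fit: PsychometricFit | None,
    path,
    labels: tuple[str, str] = ("trained", "naive"),
    xy: tuple[np.ndarray, np.ndarray] | None = None,
) -> None:
    """Summary figure: pooled-amplitude ECDFs and/or the psychometric fit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = int(cdf is not None) + int(fit is not None)
    fig, axes = plt.subplots(1, max(n_panels, 1), figsize=(4.5 * max(n_panels, 1), 3.5))
    axes = np.atleast_1d(axes)
    i = 0
    if cdf is not None:
        ax = axes[i]
        ax.step(*cdf.ecdf_a, where="post", label=f"{labels[0]} (n={cdf.n_a})")
        ax.step(*cdf.ecdf_b, where="post", label=f"{labels[1]} (n={cdf.n_b})")
        ax.set_xlabel("amplitude (permil)")
        ax.set_ylabel("cumulative fraction")
        ax.set_title(f"KS D={cdf.ks_statistic:.2f}, p={cdf.p_value:.2g}")
        ax.legend(frameon=False, fontsize=8)
        i += 1
    if fit is not None:
        ax = axes[i]
        if xy is not None:
            ax.plot(xy[0], xy[1], "o", ms=5)
            grid = np.linspace(min(xy[0]), max(xy[0]), 200)
        else:
            grid = np.linspace(fit.x0 - 4 * fit.dx, fit.x0 + 4 * fit.dx, 200)
        ax.plot(grid, fit(grid), "k--")
        ax.set_xlabel("input strength (permil)")
        ax.set_ylabel("accuracy (%)")
        ax.set_title(f"Boltzmann fit, R$^2$={fit.r_squared:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class ThresholdContrast:
    """Paired per-mouse contrasts between the two dilutions bracketing the
    discrimination threshold."""

    bracket: tuple[int, int]
    deltas: dict[str, float]  # measure -> mean paired change (more dilute -> less dilute)
    p_values: dict[str, float]
    attribution: list[str]  # measures changing significantly alongside accuracy


def _paired(df: pd.DataFrame, value: str, bracket: tuple[int, int]) -> tuple[float, float] | None:
    lo, hi = bracket
    a = df[df["dilution_exponent"] == lo].groupby("mouse")[value].mean()
    b = df[df["dilution_exponent"] == hi].groupby("mouse")[value].mean()
    common = a.index.intersection(b.index)
    if len(common) < 3:
        return None
    d = b[common].to_numpy() - a[common].to_numpy()
    t = stats.ttest_rel(b[common], a[common])
    return float(d.mean()), float(t.pvalue)


def threshold_accuracy_contrast(
    accuracy_df: pd.DataFrame,
    count_df: pd.DataFrame,
    amplitude_df: pd.DataFrame,
    bracket: tuple[int, int],
    alpha: float = 0.05,
) -> ThresholdContrast | None:
    """Paired near-threshold contrasts of accuracy, activated-glomerulus
    count and response-amplitude magnitude between two adjacent dilutions.

    ``accuracy_df`` needs (mouse, dilution_exponent, accuracy_pct);
    ``count_df`` (mouse, dilution_exponent, count); ``amplitude_df``
    (mouse, dilution_exponent, amplitude_permil).  Amplitude changes are
    assessed on magnitudes so that stronger (more negative) responses count
    as increases.  Returns None with a warning when a bracket dilution is
    missing.
    """
    amp = amplitude_df.copy()
    amp["amplitude_mag"] = amp["amplitude_permil"].abs()
    deltas: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for name, df, col in (
        ("accuracy", accuracy_df, "accuracy_pct"),
        ("count", count_df, "count"),
        ("amplitude", amp, "amplitude_mag"),
    ):
        res = _paired(df, col, bracket)
        if res is None:
            warnings.warn(f"missing bracketing dilutions for {name}; contrast skipped")
            return None
        deltas[name], pvals[name] = res
    attribution = [
        m for m in ("count", "amplitude")
        if pvals[m] < alpha and deltas[m] > 0
    ]
    return ThresholdContrast(bracket=bracket, deltas=deltas, p_values=pvals,
                             attribution=attribution)
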