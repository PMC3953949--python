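"""Ground-truth synthetic data: behavioral sessions, IOS trial stacks, and
respiration traces.

Every generator draws from a single seeded :class:`numpy.random.Generator`
derived deterministically from the ground-truth seed plus the stimulus
identifiers, so identical inputs give bit-identical outputs and different
repetitions/stimuli give independent streams.

Behavioral model
----------------
Odors are sequenced pseudo-randomly per 300-trial day with exact 150/150
S+/S- balance and never more than two successive presentations of the same
odor.  Each trial is drawn correct with the programmed per-dilution
probability; lick-bin patterns are then sampled consistent with the scoring
rule (>=3 of 4 bins for a hit, <=1 bin for a correct rejection).  Beam-break
traces stay interrupted through the 2 s stimulus on S+ trials, while correct
S- trials release the beam at the programmed divergence latency plus a
folded-Gaussian delay, so the two classes are identical before the latency
and diverge exactly at it.

Imaging model
-------------
Glomerular responses are flat-topped disks of negative permil reflectance
change, switched on for the frames fully inside the odor window, attenuated
with dilution by a saturating logistic ramp (zero below a floor exponent),
and optionally gated per glomerulus at the configured high-dilution
exponents so that group count differences can be programmed.  Blood-vessel
artifacts are elongated ridges; single-frame transients exercise the
one-frame exclusion rule.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .behavior import SMINUS, SPLUS, Session, Trial

__all__ = [
    "BehaviorGroundTruth",
    "Glomerulus",
    "Vessel",
    "Transient",
    "ImagingGroundTruth",
    "RespirationGroundTruth",
    "RespirationTrace",
    "GenerationError",
    "generate_session",
    "generate_trial_stack",
    "generate_respiration",
    "dilution_attenuation",
    "injected_amplitude",
    "response_image",
    "noiseless_response_stack",
    "sample_imaging_ground_truth",
]


class GenerationError(RuntimeError):
    """Raised when a constrained random sequence cannot be generated."""


def _subseed(seed: int, *parts) -> np.random.Generator:
    """Deterministic child generator keyed on hashable stimulus identifiers."""
    words = [seed & 0xFFFFFFFF]
    for p in parts:
        if isinstance(p, str):
            words.append(zlib.crc32(p.encode()))
        else:
            words.append(int(p) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass
class BehaviorGroundTruth:
    """Programmed structure of a synthetic behavioral experiment."""

    dilution_exponents: list[int]
    p_correct_by_dilution: dict[int, float]
    divergence_time_ms: float = 400.0
    divergence_jitter_ms: float = 50.0
    lick_bin_ms: float = 500.0
    n_trials: int = 300
    trials_per_day: int = 300
    beam_step_ms: float = 10.0
    beam_window_ms: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for e in self.dilution_exponents:
            if e not in self.p_correct_by_dilution:
                raise ValueError(f"no p_correct for dilution exponent {e}")
        for e, p in self.p_correct_by_dilution.items():
            if not 0.5 <= p <= 1.0:
                raise ValueError(f"p_correct must be in [0.5, 1], got {p} at {e}")
        if self.divergence_time_ms <= 0:
            raise ValueError("divergence_time_ms must be positive")
        if self.n_trials <= 0 or self.n_trials % 2:
            raise ValueError("n_trials must be a positive even integer")
        if self.trials_per_day % 2:
            raise ValueError("trials_per_day must be even")


def _day_sequence(rng: np.random.Generator, odors: tuple[str, str], n: int,
                  prev_tail: list[str], max_attempts: int = 1000) -> list[str]:
    """Balanced (n/2 each) odor sequence with no 3-run, continuing prev_tail."""
    a, b = odors
    for _ in range(max_attempts):
        counts = {a: n // 2, b: n // 2}
        seq: list[str] = []
        tail = list(prev_tail[-2:])
        ok = True
        for _i in range(n):
            allowed = [o for o in (a, b) if counts[o] > 0]
            if len(tail) >= 2 and tail[-1] == tail[-2] and tail[-1] in allowed:
                allowed.remove(tail[-1])
            if not allowed:
                ok = False
                break
            w = np.array([counts[o] for o in allowed], dtype=float)
            o = allowed[int(rng.choice(len(allowed), p=w / w.sum()))]
            seq.append(o)
            counts[o] -= 1
            tail.append(o)
        if ok:
            return seq
    raise GenerationError("could not satisfy the sequence constraints")


def _bin_pattern(rng: np.random.Generator, n_licked: int) -> tuple[bool, ...]:
    bins = np.zeros(4, dtype=bool)
    if n_licked:
        bins[rng.choice(4, size=n_licked, replace=False)] = True
    return tuple(bool(x) for x in bins)


def generate_session(
    gt: BehaviorGroundTruth,
    odor_pair: tuple[str, str],
    dilution_exponent: int | None = None,
    mouse_id: str = "m0",
    group: str = "trained",
    p_correct_override: Sequence[float] | None = None,
) -> Session:
    """Generate one session at a single dilution.

    The first odor of ``odor_pair`` is S+.  ``p_correct_override`` supplies a
    per-trial correctness probability (e.g. a learning curve) instead of the
    per-dilution constant.
    """
    if dilution_exponent is None:
        dilution_exponent = gt.dilution_exponents[0]
    if dilution_exponent not in gt.p_correct_by_dilution:
        raise ValueError(f"dilution exponent {dilution_exponent} not configured")
    if p_correct_override is not None and len(p_correct_override) != gt.n_trials:
        raise ValueError("p_correct_override must have one entry per trial")
    rng = _subseed(gt.seed, mouse_id, dilution_exponent, "session")
    sp_odor, sm_odor = odor_pair

    # odor sequence, balanced per complete day (and per trailing partial day)
    seq: list[str] = []
    remaining = gt.n_trials
    while remaining > 0:
        n_day = min(gt.trials_per_day, remaining)
        seq.extend(_day_sequence(rng, odor_pair, n_day, seq))
        remaining -= n_day

    p_const = gt.p_correct_by_dilution[dilution_exponent]
    times = np.arange(0.0, gt.beam_window_ms, gt.beam_step_ms)
    trials: list[Trial] = []
    gt_correct: list[bool] = []
    for i, odor in enumerate(seq):
        p = p_const if p_correct_override is None else float(p_correct_override[i])
        correct = bool(rng.random() < p)
        valence = SPLUS if odor == sp_odor else SMINUS
        if valence == SPLUS:
            n_licked = int(rng.choice([3, 4])) if correct else int(rng.choice([0, 1, 2]))
        else:
            n_licked = int(rng.choice([0, 1])) if correct else int(rng.choice([2, 3, 4]))
        beam = np.ones(times.size, dtype=bool)
        if valence == SMINUS and correct:
            # release at divergence latency + folded-Gaussian delay: the two
            # trace classes are identical before the latency, diverge at it
            release = gt.divergence_time_ms + abs(rng.normal(0.0, gt.divergence_jitter_ms))
            beam[times >= release] = False
        trials.append(
            Trial(
                index=i,
                odor=odor,
                valence=valence,
                bin_licks=_bin_pattern(rng, n_licked),
                iti_s=float(rng.uniform(10.0, 20.0)),
                beam_break=beam,
                beam_times_ms=times,
            )
        )
        gt_correct.append(correct)
    return Session(
        mouse_id=mouse_id,
        odor_pair=odor_pair,
        dilution_exponent=dilution_exponent,
        trials=trials,
        group=group,
        gt_correct=gt_correct,
    )


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

@dataclass
class Glomerulus:
    """Flat-topped disk response source.

    ``base_amplitude`` maps odorant -> permil amplitude at full strength
    (negative for odor-evoked IOS darkening).  ``responder`` maps odorant ->
    whether this glomerulus stays responsive at the gated high-dilution
    exponents.
    """

    center: tuple[float, float]  # (row, col)
    radius: float
    base_amplitude: dict[str, float]
    responder: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("glomerulus radius must be positive")


@dataclass
class Vessel:
    """Elongated ridge artifact (dark during the odor window)."""

    start: tuple[float, float]
    end: tuple[float, float]
    width: float
    amplitude_permil: float = -1.5


@dataclass
class Transient:
    """Blob present in exactly one frame (exercises the one-frame rule)."""

    center: tuple[float, float]
    radius: float
    amplitude_permil: float
    frame_index: int


@dataclass
class ImagingGroundTruth:
    field_shape: tuple[int, int] = (64, 64)
    glomeruli: list[Glomerulus] = field(default_factory=list)
    vessels: list[Vessel] = field(default_factory=list)
    transients: list[Transient] = field(default_factory=list)
    noise_sd_permil: float = 0.0
    frame_rate_hz: float = 2.0
    duration_s: float = 8.0
    odor_window_s: tuple[float, float] = (2.0, 7.0)
    baseline_level: float = 4000.0
    attenuation_floor: int = -7
    attenuation_full: int = -1
    attenuation_width: float = 1.0
    high_dilution_exponents: tuple[int, ...] = ()
    group: str = "naive"
    group_amplitude_scale: float = 1.0
    group_count_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_shape
        for g in self.glomeruli:
            r, c = g.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"glomerulus center {g.center} outside field {self.field_shape}")
        if self.odor_window_s[0] >= self.odor_window_s[1]:
            raise ValueError("odor window must have onset < offset")
        if self.odor_window_s[1] > self.duration_s:
            raise ValueError("odor window exceeds stack duration")
        if self.odor_window_s[0] <= 0:
            raise ValueError("need at least one pre-odor baseline frame")
        if self.group_amplitude_scale <= 0 or self.group_count_scale <= 0:
            raise ValueError("group scales must be positive")


def dilution_attenuation(gt: ImagingGroundTruth, exponent: int) -> float:
    """Saturating attenuation of response amplitude with dilution.

    1 at or above ``attenuation_full``, 0 below ``attenuation_floor``, and a
    logistic ramp centred between the two in the intermediate range.
    """
    if exponent < gt.attenuation_floor:
        return 0.0
    if exponent >= gt.attenuation_full:
        return 1.0
    mid = 0.5 * (gt.attenuation_floor + gt.attenuation_full)
    return float(1.0 / (1.0 + np.exp(-(exponent - mid) / gt.attenuation_width)))


def injected_amplitude(
    gt: ImagingGroundTruth, glom: Glomerulus, odorant: str, dilution_exponent: int
) -> float:
    """Ground-truth permil amplitude of one glomerulus for one stimulus."""
    if odorant not in glom.base_amplitude:
        return 0.0
    att = dilution_attenuation(gt, dilution_exponent)
    if dilution_exponent in gt.high_dilution_exponents and not glom.responder.get(odorant, True):
        return 0.0
    return glom.base_amplitude[odorant] * att * gt.group_amplitude_scale


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ridge_mask(shape: tuple[int, int], start, end, width: float) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    p = np.stack([rr, cc], axis=-1).astype(float)
    a = np.asarray(start, dtype=float)
    b = np.asarray(end, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(shape)
    closest = a + t[..., None] * ab
    d2 = ((p - closest) ** 2).sum(axis=-1)
    return d2 <= (width / 2.0) ** 2


def response_image(gt: ImagingGroundTruth, odorant: str, dilution_exponent: int,
                   include_vessels: bool = True) -> np.ndarray:
    """Noiseless permil response image active during the odor window."""
    img = np.zeros(gt.field_shape, dtype=float)
    for g in gt.glomeruli:
        amp = injected_amplitude(gt, g, odorant, dilution_exponent)
        if amp != 0.0:
            img[_disk_mask(gt.field_shape, g.center, g.radius)] += amp
    if include_vessels:
        for v in gt.vessels:
            img[_ridge_mask(gt.field_shape, v.start, v.end, v.width)] += v.amplitude_permil
    return img


def _frame_windows(gt: ImagingGroundTruth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_frames = int(round(gt.duration_s * gt.frame_rate_hz))
    starts = np.arange(n_frames) / gt.frame_rate_hz
    ends = starts + 1.0 / gt.frame_rate_hz
    onset, offset = gt.odor_window_s
    baseline = ends <= onset + 1e-9
    response = (starts >= onset - 1e-9) & (ends <= offset + 1e-9)
    return starts, baseline, response


def noiseless_response_stack(gt: ImagingGroundTruth, odorant: str,
                             dilution_exponent: int) -> np.ndarray:
    """Permil response per frame (glomeruli + vessels + transients, no noise)."""
    starts, _, response = _frame_windows(gt)
    stack = np.zeros((starts.size,) + gt.field_shape, dtype=float)
    img = response_image(gt, odorant, dilution_exponent)
    stack[response] = img
    for tr in gt.transients:
        if 0 <= tr.frame_index < starts.size:
            stack[tr.frame_index][_disk_mask(gt.field_shape, tr.center, tr.radius)] += (
                tr.amplitude_permil
            )
    return stack


def generate_trial_stack(
    gt: ImagingGroundTruth,
    odorant: str,
    dilution_exponent: int,
    repetition: int,
    mouse_id: str = "m0",
):
    """Generate one imaging acquisition (returns :class:`imaging.TrialStack`).

    Reflectance is ``baseline_level * (1 + response_permil/1000)`` plus
    Gaussian noise of ``noise_sd_permil`` (in permil of the baseline level)
    per pixel per frame.  Ground-truth per-glomerulus amplitudes are recorded
    in the stack's ``truth`` mapping.
    """
    from .imaging import TrialStack  # local import to avoid a cycle

    if not 1 <= repetition <= 4:
        raise ValueError("repetition must be in 1..4")
    rng = _subseed(gt.seed, mouse_id, odorant, dilution_exponent, repetition)
    permil = noiseless_response_stack(gt, odorant, dilution_exponent)
    frames = gt.baseline_level * (1.0 + permil / 1000.0)
    if gt.noise_sd_permil > 0:
        frames = frames + rng.normal(
            0.0, gt.noise_sd_permil / 1000.0 * gt.baseline_level, size=frames.shape
        )
    truth = {
        "glomerulus_amplitudes": [
            injected_amplitude(gt, g, odorant, dilution_exponent) for g in gt.glomeruli
        ],
        "glomerulus_centers": [list(g.center) for g in gt.glomeruli],
        "glomerulus_radii": [g.radius for g in gt.glomeruli],
    }
    return TrialStack(
        frames=frames.astype(np.float32),
        frame_rate_hz=gt.frame_rate_hz,
        odor_window_s=gt.odor_window_s,
        odorant=odorant,
        dilution_exponent=dilution_exponent,
        repetition=repetition,
        group=gt.group,
        mouse_id=mouse_id,
        truth=truth,
    )


def sample_imaging_ground_truth(
    n_glomeruli: int,
    odorants: Sequence[str],
    seed: int,
    group: str = "naive",
    field_shape: tuple[int, int] = (64, 64),
    radius_range: tuple[float, float] = (2.0, 3.5),
    amplitude_range: tuple[float, float] = (-2.5, -1.5),
    responder_fraction: float = 1.0,
    group_amplitude_scale: float = 1.0,
    group_count_scale: float = 1.0,
    high_dilution_exponents: tuple[int, ...] = (),
    n_vessels: int = 0,
    noise_sd_permil: float = 0.0,
    margin: float = 6.0,
    min_separation: float = 4.0,
    **kwargs,
) -> ImagingGroundTruth:
    """Randomly place non-overlapping glomeruli (one driving odorant each)
    and optional vessels, with per-glomerulus high-dilution responder gates.

    Each glomerulus responds to exactly one odorant (round-robin over
    ``odorants``); its gate is drawn Bernoulli with probability
    ``min(1, responder_fraction * group_count_scale)``.
    """
    rng = np.random.default_rng(seed)
    h, w = field_shape
    vessels = []
    for _ in range(n_vessels):
        r0 = float(rng.uniform(2, h - 2))
        vessels.append(
            Vessel(start=(r0, float(rng.uniform(2, 6))),
                   end=(min(h - 2.0, max(2.0, r0 + rng.uniform(-6, 6))), w - 4.0),
                   width=2.5)
        )

    def _vessel_dist(c: tuple[float, float]) -> float:
        d = np.inf
        for v in vessels:
            a = np.asarray(v.start)
            b = np.asarray(v.end)
            ab = b - a
            t = np.clip(np.dot(np.asarray(c) - a, ab) / (ab @ ab), 0.0, 1.0)
            d = min(d, float(np.hypot(*(np.asarray(c) - (a + t * ab)))))
        return d

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < n_glomeruli:
        attempts += 1
        if attempts > 20000:
            raise GenerationError("could not place glomeruli without overlap")
        r = float(rng.uniform(*radius_range))
        c = (float(rng.uniform(margin, h - margin)), float(rng.uniform(margin, w - margin)))
        if _vessel_dist(c) < r + 2.5 + min_separation:
            continue
        if all(
            np.hypot(c[0] - c2[0], c[1] - c2[1]) >= r + r2 + min_separation
            for c2, r2 in zip(centers, radii)
        ):
            centers.append(c)
            radii.append(r)
    p_resp = min(1.0, responder_fraction * group_count_scale)
    gloms = []
    for i, (c, r) in enumerate(zip(centers, radii)):
        od = odorants[i % len(odorants)]
        gloms.append(
            Glomerulus(
                center=c,
                radius=r,
                base_amplitude={od: float(rng.uniform(*amplitude_range))},
                responder={od: True},
            )
        )
    # exactly round(p_resp * n) responders over the whole field, so the
    # programmed supra-threshold fraction is a fraction, not a Bernoulli
    # rate, and its granularity is 1/n rather than odorants/n
    if gloms:
        n_resp = int(round(p_resp * len(gloms)))
        chosen = set(rng.choice(len(gloms), size=n_resp, replace=False).tolist())
        for j, g in enumerate(gloms):
            for od in g.base_amplitude:
                g.responder[od] = j in chosen
    return ImagingGroundTruth(
        field_shape=field_shape,
        glomeruli=gloms,
        vessels=vessels,
        noise_sd_permil=noise_sd_permil,
        group=group,
        group_amplitude_scale=group_amplitude_scale,
        group_count_scale=group_count_scale,
        high_dilution_exponents=tuple(high_dilution_exponents),
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

@dataclass
class RespirationGroundTruth:
    base_frequency_hz: float = 3.1
    jitter_cv: float = 0.0
    duration_s: float = 10.0
    sample_rate_hz: float = 1000.0
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 <= self.base_frequency_hz <= 12.0:
            raise ValueError("base frequency must be in the 1-12 Hz physiological band")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration and sample rate must be positive")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be non-negative")


@dataclass
class RespirationTrace:
    """Quasi-sinusoidal airflow trace with ground-truth cycle onset times."""

    times_s: np.ndarray
    signal: np.ndarray
    cycle_times_s: np.ndarray


def generate_respiration(gt: RespirationGroundTruth) -> RespirationTrace:
    """Airflow trace whose cycle periods are jittered by ``jitter_cv``.

    The phase starts a quarter-cycle before the first upward zero crossing
    so crossings fall strictly inside the trace.
    """
    rng = np.random.default_rng(gt.seed)
    mean_period = 1.0 / gt.base_frequency_hz
    n_cycles = int(np.ceil(gt.duration_s / mean_period)) + 3
    if gt.jitter_cv > 0:
        periods = mean_period * np.maximum(
            0.2, 1.0 + gt.jitter_cv * rng.standard_normal(n_cycles)
        )
    else:
        periods = np.full(n_cycles, mean_period)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    times = np.arange(0.0, gt.duration_s, 1.0 / gt.sample_rate_hz)
    # piecewise-linear phase: one unit per cycle
    phase = np.interp(times, boundaries, np.arange(boundaries.size, dtype=float))
    signal = gt.amplitude * np.sin(2.0 * np.pi * (phase - 0.25))
    # upward zero crossings sit at phase = integer + 0.25
    cycle_phase = np.arange(n_cycles) + 0.25
    cycle_times = np.interp(cycle_phase, np.arange(boundaries.size, dtype=float), boundaries)
    cycle_times = cycle_times[cycle_times < gt.duration_s]
    return RespirationTrace(times_s=times, signal=signal, cycle_times_s=cycle_times)
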