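"""Fractional-reflectance (dR/R) mapping, reference glomerular-map building,
per-ROI amplitude quantification, and activated-glomerulus counting.

dR/R is computed per pixel as (mean response-window reflectance - mean
baseline reflectance) / mean baseline reflectance, expressed in permil.
Odor-evoked responses are reflectance decreases, so signal amplitudes are
negative; detection and counting threshold on absolute amplitude but the
sign is preserved everywhere.

The reference map is built from the strongest (lowest-dilution) stimuli of
each odorant: supra-threshold connected components are kept unless they are
present in only a single time frame or are vessel-like (elongation above a
configured ratio), and overlapping components across odorants are merged.
The same reference ROIs are then used to quantify every other dilution.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "TrialStack",
    "DeltaMap",
    "GlomerulusROI",
    "GlomerularMap",
    "RoiParams",
    "delta_map",
    "frame_delta_maps",
    "average_repetitions",
    "detect_rois",
    "build_reference_map",
    "quantify",
    "count_activated",
    "run_mouse_pipeline",
]

GROUPS = ("trained", "exposed", "naive")


@dataclass
class TrialStack:
    """One imaging acquisition: frames (time x rows x cols) plus stimulus
    metadata.  Frame ``i`` spans ``[i/rate, (i+1)/rate)`` seconds."""

    frames: np.ndarray
    frame_rate_hz: float
    odor_window_s: tuple[float, float] = (2.0, 7.0)
    odorant: str = "odor"
    dilution_exponent: int = 0
    repetition: int = 1
    group: str = "naive"
    mouse_id: str = "m0"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, rows, cols) array")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        onset, offset = self.odor_window_s
        duration = self.frames.shape[0] / self.frame_rate_hz
        if not (0 < onset < offset <= duration + 1e-9):
            raise ValueError("odor window must lie inside the stack duration")
        if not self.baseline_indices.size:
            raise ValueError("need at least one full pre-odor baseline frame")

    @property
    def frame_starts_s(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.frame_rate_hz

    @property
    def baseline_indices(self) -> np.ndarray:
        ends = self.frame_starts_s + 1.0 / self.frame_rate_hz
        return np.flatnonzero(ends <= self.odor_window_s[0] + 1e-9)

    @property
    def response_indices(self) -> np.ndarray:
        starts = self.frame_starts_s
        ends = starts + 1.0 / self.frame_rate_hz
        return np.flatnonzero(
            (starts >= self.odor_window_s[0] - 1e-9) & (ends <= self.odor_window_s[1] + 1e-9)
        )

    def stimulus_key(self) -> tuple:
        return (self.mouse_id, self.group, self.odorant, self.dilution_exponent)


@dataclass
class DeltaMap:
    """dR/R image in permil with noise bookkeeping.

    ``noise_sd_frame_permil`` is the robust per-pixel, per-frame noise SD
    estimated from pre-odor frame-to-frame residuals; ``noise_se_permil`` is
    the implied SD of a single map pixel.
    """

    values: np.ndarray
    baseline_frames: tuple[int, int]
    response_frames: tuple[int, int]
    noise_sd_frame_permil: float = float("nan")
    noise_se_permil: float = float("nan")

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("delta map contains non-finite values")


def _baseline_noise_sd(stack: TrialStack, baseline_mean: np.ndarray) -> float:
    """Robust per-frame permil noise SD from consecutive baseline residuals."""
    idx = stack.baseline_indices
    if idx.size < 2:
        return float("nan")
    frames = stack.frames[idx].astype(float)
    safe = np.where(baseline_mean > 0, baseline_mean, 1.0)
    permil = (frames - baseline_mean) / safe * 1000.0
    resid = np.diff(permil, axis=0) / np.sqrt(2.0)
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def delta_map(s: TrialStack, response_window_s: tuple[float, float] | None = None) -> DeltaMap:
    """Per-pixel dR/R in permil over the response window (default: the full
    odor period).  Pixels with non-positive baseline are masked to 0 with a
    warning."""
    base_idx = s.baseline_indices
    if response_window_s is None:
        resp_idx = s.response_indices
    else:
        starts = s.frame_starts_s
        ends = starts + 1.0 / s.frame_rate_hz
        resp_idx = np.flatnonzero(
            (starts >= response_window_s[0] - 1e-9) & (ends <= response_window_s[1] + 1e-9)
        )
    if resp_idx.size == 0:
        raise ValueError("response window contains no full frames")
    baseline = s.frames[base_idx].astype(float).mean(axis=0)
    response = s.frames[resp_idx].astype(float).mean(axis=0)
    bad = baseline <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pixels with non-positive baseline masked to 0")
    safe = np.where(bad, 1.0, baseline)
    values = np.where(bad, 0.0, (response - baseline) / safe * 1000.0)
    sd_frame = _baseline_noise_sd(s, baseline)
    se = sd_frame * np.sqrt(1.0 / resp_idx.size + 1.0 / base_idx.size)
    return DeltaMap(
        values=values,
        baseline_frames=(int(base_idx[0]), int(base_idx[-1]) + 1),
        response_frames=(int(resp_idx[0]), int(resp_idx[-1]) + 1),
        noise_sd_frame_permil=sd_frame,
        noise_se_permil=float(se),
    )


def frame_delta_maps(s: TrialStack) -> np.ndarray:
    """dR/R of each individual response frame versus the baseline mean
    (permil), for the single-frame exclusion rule."""
    base_idx = s.baseline_indices
    baseline = s.frames[base_idx].astype(float).mean(axis=0)
    safe = np.where(baseline > 0, baseline, 1.0)
    resp = s.frames[s.response_indices].astype(float)
    return (resp - baseline) / safe * 1000.0


def average_repetitions(stacks: Sequence[TrialStack]) -> DeltaMap:
    """Pixel-wise mean of per-repetition dR/R maps for one stimulus."""
    if not stacks:
        raise ValueError("no stacks given")
    key = stacks[0].stimulus_key()
    if any(s.stimulus_key() != key for s in stacks[1:]):
        raise ValueError("stacks do not share stimulus metadata")
    maps = [delta_map(s) for s in stacks]
    values = np.mean([m.values for m in maps], axis=0)
    sd_frame = float(np.nanmean([m.noise_sd_frame_permil for m in maps]))
    se = float(np.nanmean([m.noise_se_permil for m in maps])) / np.sqrt(len(maps))
    return DeltaMap(
        values=values,
        baseline_frames=maps[0].baseline_frames,
        response_frames=maps[0].response_frames,
        noise_sd_frame_permil=sd_frame,
        noise_se_permil=se,
    )


@dataclass
class GlomerulusROI:
    id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    centroid: tuple[float, float]
    area: int
    elongation: float
    n_frames_present: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class RoiParams:
    detection_k: float = 3.0  # averaged-map threshold in robust noise SDs
    presence_k: float = 2.0  # per-frame threshold for the single-frame rule
    min_area: int = 5
    max_area: int = 500
    vessel_elongation: float = 4.0
    min_frames_present: int = 2
    frame_overlap_frac: float = 0.5


@dataclass
class GlomerularMap:
    """Reference ROI set for one mouse plus quantified amplitudes.

    ``amplitudes`` and ``amplitude_se`` are keyed by
    ``(roi_id, odorant, dilution_exponent, repetition)`` where repetition
    ``None`` denotes the repetition-averaged map."""

    mouse_id: str
    group: str
    rois: list[GlomerulusROI]
    source: dict = field(default_factory=dict)
    amplitudes: dict[tuple, float] = field(default_factory=dict)
    amplitude_se: dict[tuple, float] = field(default_factory=dict)


def _regionprops(mask: np.ndarray) -> list:
    labels = measure.label(mask, connectivity=2)
    return measure.regionprops(labels)


def _elongation(prop) -> float:
    minor = prop.axis_minor_length
    major = prop.axis_major_length
    if minor <= 1e-9:
        return float("inf")
    return float(major / minor)


def detect_rois(
    stacks: Iterable[TrialStack],
    params: RoiParams | None = None,
) -> list[GlomerulusROI]:
    """Detect glomerular ROIs on lowest-dilution stacks and merge across
    odorants into one reference set.

    Stacks are grouped by odorant and averaged over repetitions.  Components
    of the thresholded averaged map are discarded when out of area bounds,
    vessel-like (elongation above ``vessel_elongation``), or present in
    fewer than ``min_frames_present`` individual time frames (presence =
    supra-threshold overlap of at least ``frame_overlap_frac`` of the
    component in that frame).
    """
    params = params or RoiParams()
    by_odorant: dict[str, list[TrialStack]] = defaultdict(list)
    for s in stacks:
        by_odorant[s.odorant].append(s)
    if not by_odorant:
        raise ValueError("no stacks given")

    kept_masks: list[tuple[np.ndarray, int]] = []  # (mask, n_frames_present)
    shape = None
    for odorant, reps in by_odorant.items():
        avg = average_repetitions(reps)
        shape = avg.values.shape
        thr = params.detection_k * avg.noise_se_permil
        if not np.isfinite(thr) or thr <= 0:
            # noiseless stack: any non-zero response is signal
            thr = 1e-9
        mask = np.abs(avg.values) > thr
        # per-frame supra-threshold masks, averaged across repetitions
        fmaps = np.mean([frame_delta_maps(s) for s in reps], axis=0)
        sd_frame = avg.noise_sd_frame_permil
        n_base = avg.baseline_frames[1] - avg.baseline_frames[0]
        fthr = params.presence_k * sd_frame * np.sqrt(1.0 + 1.0 / n_base) / np.sqrt(len(reps))
        if not np.isfinite(fthr) or fthr <= 0:
            fthr = 1e-9
        fmasks = np.abs(fmaps) > fthr
        for prop in _regionprops(mask):
            if not params.min_area <= prop.area <= params.max_area:
                continue
            if _elongation(prop) > params.vessel_elongation:
                continue
            comp = np.zeros(shape, dtype=bool)
            comp[tuple(prop.coords.T)] = True
            present = int(
                sum(
                    (fm & comp).sum() >= params.frame_overlap_frac * prop.area
                    for fm in fmasks
                )
            )
            if present < params.min_frames_present:
                continue
            kept_masks.append((comp, present))

    if not kept_masks:
        warnings.warn("no ROIs detected")
        return []
    union = np.zeros(shape, dtype=bool)
    for m, _ in kept_masks:
        union |= m
    rois: list[GlomerulusROI] = []
    for i, prop in enumerate(_regionprops(union)):
        comp = np.zeros(shape, dtype=bool)
        comp[tuple(prop.coords.T)] = True
        present = max(n for m, n in kept_masks if (m & comp).any())
        rois.append(
            GlomerulusROI(
                id=i,
                pixels=prop.coords.astype(int),
                centroid=tuple(float(c) for c in prop.centroid),
                area=int(prop.area),
                elongation=_elongation(prop),
                n_frames_present=present,
            )
        )
    return rois


def build_reference_map(
    mouse_id: str,
    group: str,
    stacks: Iterable[TrialStack],
    params: RoiParams | None = None,
) -> GlomerularMap:
    """Reference map from the lowest-dilution stacks of each odorant."""
    stacks = list(stacks)
    rois = detect_rois(stacks, params)
    source = {
        "odorants": sorted({s.odorant for s in stacks}),
        "dilution_exponents": sorted({s.dilution_exponent for s in stacks}),
    }
    return GlomerularMap(mouse_id=mouse_id, group=group, rois=rois, source=source)


def quantify(
    gmap: GlomerularMap,
    dm: DeltaMap,
    odorant: str,
    dilution_exponent: int,
    repetition: int | None = None,
) -> dict[int, float]:
    """Mean dR/R over each reference ROI; stored on the map and returned."""
    out: dict[int, float] = {}
    shape = dm.values.shape
    for roi in gmap.rois:
        if (roi.pixels[:, 0].max() >= shape[0]) or (roi.pixels[:, 1].max() >= shape[1]):
            raise ValueError(f"ROI {roi.id} lies outside the image")
        amp = float(dm.values[roi.pixels[:, 0], roi.pixels[:, 1]].mean())
        se = float(dm.noise_se_permil / np.sqrt(roi.area))
        key = (roi.id, odorant, dilution_exponent, repetition)
        gmap.amplitudes[key] = amp
        gmap.amplitude_se[key] = se
        out[roi.id] = amp
    return out


def count_activated(
    gmap: GlomerularMap,
    odorant: str,
    dilution_exponent: int,
    activation_k: float = 3.0,
    repetition: int | None = None,
) -> int:
    """Number of reference ROIs whose absolute amplitude for the stimulus
    exceeds ``activation_k`` times the per-ROI noise SE."""
    n = 0
    for roi in gmap.rois:
        key = (roi.id, odorant, dilution_exponent, repetition)
        if key not in gmap.amplitudes:
            continue
        se = gmap.amplitude_se[key]
        thr = activation_k * se if np.isfinite(se) and se > 0 else 1e-9
        if abs(gmap.amplitudes[key]) > thr:
            n += 1
    return n


def run_mouse_pipeline(
    stacks: Sequence[TrialStack],
    reference_exponent: int | None = None,
    params: RoiParams | None = None,
    activation_k: float = 3.0,
):
    """End-to-end per-mouse analysis of a set of trial stacks.

    Builds the reference map from the lowest-dilution (or given
    ``reference_exponent``) stacks of every odorant, quantifies each
    (odorant, dilution) from its repetition-averaged map, and counts
    activated ROIs.  Returns ``(gmap, amplitude_rows, count_rows)`` where the
    rows are flat dicts ready for a DataFrame.
    """
    stacks = list(stacks)
    if not stacks:
        raise ValueError("no stacks given")
    mouse_id = stacks[0].mouse_id
    group = stacks[0].group
    if reference_exponent is None:
        reference_exponent = max(s.dilution_exponent for s in stacks)
    ref = [s for s in stacks if s.dilution_exponent == reference_exponent]
    gmap = build_reference_map(mouse_id, group, ref, params)

    by_stim: dict[tuple[str, int], list[TrialStack]] = defaultdict(list)
    for s in stacks:
        by_stim[(s.odorant, s.dilution_exponent)].append(s)

    amp_rows: list[dict] = []
    count_rows: list[dict] = []
    for (odorant, exponent), reps in sorted(by_stim.items()):
        for s in reps:
            dm = delta_map(s)
            amps = quantify(gmap, dm, odorant, exponent, repetition=s.repetition)
            for roi_id, amp in amps.items():
                amp_rows.append(
                    dict(
                        mouse=mouse_id,
                        group=group,
                        odorant=odorant,
                        dilution_exponent=exponent,
                        roi_id=roi_id,
                        rep=s.repetition,
                        amplitude_permil=amp,
                        amplitude_se=gmap.amplitude_se[(roi_id, odorant, exponent, s.repetition)],
                    )
                )
        avg = average_repetitions(reps)
        amps = quantify(gmap, avg, odorant, exponent, repetition=None)
        for roi_id, amp in amps.items():
            amp_rows.append(
                dict(
                    mouse=mouse_id,
                    group=group,
                    odorant=odorant,
                    dilution_exponent=exponent,
                    roi_id=roi_id,
                    rep=0,  # 0 marks the repetition average
                    amplitude_permil=amp,
                    amplitude_se=gmap.amplitude_se[(roi_id, odorant, exponent, None)],
                )
            )
        count_rows.append(
            dict(
                mouse=mouse_id,
                group=group,
                odorant=odorant,
                dilution_exponent=exponent,
                count=count_activated(gmap, odorant, exponent, activation_k),
            )
        )
    return gmap, amp_rows, count_rows
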