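"""Readers and writers for the on-disk formats used by the pipeline.

Sessions are CSV (one row per trial); beam-break matrices are HDF5; trial
stacks are multi-page float32 TIFF with a JSON sidecar holding the stimulus
metadata and generator ground truth; respiration traces and amplitude/count
tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .behavior import PerformanceCurve, Session, Trial, score_trial
from .imaging import TrialStack
from .reaction_time import BeamBreakMatrix
from .respiration import AirflowTrace
from .synthetic_data import RespirationTrace

__all__ = [
    "save_session_csv",
    "load_session_csv",
    "save_beam_h5",
    "load_beam_h5",
    "save_trial_stack",
    "load_trial_stack",
    "save_respiration_csv",
    "load_respiration_csv",
    "save_performance_curve",
]


def save_session_csv(session: Session, path: str | Path) -> None:
    rows = []
    for t in session.trials:
        s = score_trial(t)
        rows.append(
            dict(
                trial_index=t.index,
                odor=t.odor,
                valence=t.valence,
                bin0=int(t.bin_licks[0]),
                bin1=int(t.bin_licks[1]),
                bin2=int(t.bin_licks[2]),
                bin3=int(t.bin_licks[3]),
                response=s.outcome,
                iti_s=t.iti_s,
                mouse_id=session.mouse_id,
                odor_sp=session.odor_pair[0],
                odor_sm=session.odor_pair[1],
                dilution_exponent=session.dilution_exponent,
                group=session.group,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_session_csv(path: str | Path) -> Session:
    df = pd.read_csv(path)
    trials = [
        Trial(
            index=int(r.trial_index),
            odor=str(r.odor),
            valence=str(r.valence),
            bin_licks=(bool(r.bin0), bool(r.bin1), bool(r.bin2), bool(r.bin3)),
            iti_s=float(r.iti_s),
        )
        for r in df.itertuples()
    ]
    first = df.iloc[0]
    return Session(
        mouse_id=str(first.mouse_id),
        odor_pair=(str(first.odor_sp), str(first.odor_sm)),
        dilution_exponent=int(first.dilution_exponent),
        trials=trials,
        group=str(first.group),
    )


def save_beam_h5(m: BeamBreakMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times_ms", data=m.times_ms)
        f.create_dataset("sp_traces", data=m.sp_traces)
        f.create_dataset("sm_traces", data=m.sm_traces)


def load_beam_h5(path: str | Path) -> BeamBreakMatrix:
    with h5py.File(path, "r") as f:
        return BeamBreakMatrix(
            times_ms=f["times_ms"][...],
            sp_traces=f["sp_traces"][...],
            sm_traces=f["sm_traces"][...],
        )


def save_trial_stack(stack: TrialStack, tiff_path: str | Path) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32))
    meta = dict(
        frame_rate_hz=stack.frame_rate_hz,
        odor_window_s=list(stack.odor_window_s),
        odorant=stack.odorant,
        dilution_exponent=stack.dilution_exponent,
        repetition=stack.repetition,
        group=stack.group,
        mouse_id=stack.mouse_id,
        truth=stack.truth,
    )
    tiff_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_trial_stack(tiff_path: str | Path) -> TrialStack:
    tiff_path = Path(tiff_path)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    return TrialStack(
        frames=tifffile.imread(tiff_path),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        odor_window_s=tuple(meta["odor_window_s"]),
        odorant=meta["odorant"],
        dilution_exponent=int(meta["dilution_exponent"]),
        repetition=int(meta["repetition"]),
        group=meta["group"],
        mouse_id=meta["mouse_id"],
        truth=meta.get("truth"),
    )


def save_respiration_csv(trace: RespirationTrace | AirflowTrace, path: str | Path) -> None:
    times = trace.times_s
    signal = trace.signal
    pd.DataFrame({"time_s": times, "signal": signal}).to_csv(path, index=False)


def load_respiration_csv(path: str | Path, window_s: tuple[float, float] | None = None) -> AirflowTrace:
    df = pd.read_csv(path)
    return AirflowTrace(
        times_s=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        window_s=window_s,
    )


def save_performance_curve(curve: PerformanceCurve, path: str | Path) -> None:
    payload = dict(
        dilution_exponents=curve.dilution_exponents,
        accuracy_pct=curve.accuracy_pct,
        block_accuracy={str(k): v for k, v in curve.block_accuracy.items()},
        threshold_interval=list(curve.threshold_interval)
        if curve.threshold_interval is not None
        else None,
    )
    Path(path).write_text(json.dumps(payload, indent=1))
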