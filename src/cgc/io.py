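"""File formats: WAV audio, HDF5 trace/sweep/STRF schemas, CSV spike tables.

HDF5 schemas
------------
stimulus sidecar : /levels (n_freqs x n_chords, dB SPL), /freqs_hz,
                   /chord_dur_s, /seed, /condition (name, mean, range attrs)
trace file       : /raw or /values (channels x samples), /fs_hz, /labels attrs
sweep file       : /sweeps (trial x time, mV), /I_inj_pA, /fs_hz, /current_pA,
                   /epochs (names + bounds as attrs)
STRF file        : /k_f, /k_h, /bias, /freq_axis_hz, /lag_axis_s, fit_meta attrs
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .exsignal import ResponseTrace
from .patch import VoltageSweepSet
from .stimgen import ContrastCondition, DRCStimulus
from .strf import SeparableSTRF

__all__ = [
    "write_stimulus",
    "read_stimulus",
    "write_trace",
    "read_trace",
    "write_sweeps",
    "read_sweeps",
    "write_strf",
    "read_strf",
    "read_spike_csv",
]


def write_stimulus(stem: str, drc: DRCStimulus) -> None:
    """Write a DRC as ``stem.wav`` (if audio present) plus ``stem.h5`` sidecar."""
    if drc.audio is not None:
        wavfile.write(f"{stem}.wav", int(drc.sample_rate), drc.audio.astype(np.float32))
    with h5py.File(f"{stem}.h5", "w") as f:
        f.create_dataset("levels", data=drc.levels)
        f.create_dataset("freqs_hz", data=drc.freqs_hz)
        f.attrs["chord_dur_s"] = drc.chord_dur
        f.attrs["ramp_dur_s"] = drc.ramp_dur
        if drc.seed is not None:
            f.attrs["seed"] = drc.seed
        if drc.condition is not None:
            f.attrs["condition_name"] = drc.condition.name
            f.attrs["condition_mean_db"] = drc.condition.mean_level
            f.attrs["condition_range_db"] = drc.condition.level_range
        if drc.noise_bursts:
            f.attrs["noise_bursts"] = json.dumps(
                [
                    {"onset": b.onset, "duration": b.duration, "seed": b.seed,
                     "chord_indices": list(b.chord_indices)}
                    for b in drc.noise_bursts
                ]
            )


def read_stimulus(stem: str) -> DRCStimulus:
    from .stimgen import NoiseBurst

    with h5py.File(f"{stem}.h5", "r") as f:
        cond = None
        if "condition_name" in f.attrs:
            cond = ContrastCondition(
                str(f.attrs["condition_name"]),
                float(f.attrs["condition_mean_db"]),
                float(f.attrs["condition_range_db"]),
            )
        bursts = []
        if "noise_bursts" in f.attrs:
            for b in json.loads(f.attrs["noise_bursts"]):
                bursts.append(NoiseBurst(b["onset"], b["duration"], b["seed"],
                                         tuple(b["chord_indices"])))
        return DRCStimulus(
            freqs_hz=f["freqs_hz"][()],
            levels=f["levels"][()],
            chord_dur=float(f.attrs["chord_dur_s"]),
            ramp_dur=float(f.attrs.get("ramp_dur_s", 0.005)),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            condition=cond,
            noise_bursts=bursts,
        )


def write_trace(path: str, trace: ResponseTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=trace.values)
        f.attrs["fs_hz"] = trace.fs
        f.attrs["t0_s"] = trace.t0
        f.attrs["labels"] = json.dumps(trace.labels, default=str)


def read_trace(path: str) -> ResponseTrace:
    with h5py.File(path, "r") as f:
        return ResponseTrace(
            values=f["values"][()],
            fs=float(f.attrs["fs_hz"]),
            t0=float(f.attrs.get("t0_s", 0.0)),
            labels=json.loads(f.attrs.get("labels", "{}")),
        )


def read_raw(path: str) -> tuple[np.ndarray, float]:
    """Raw voltage traces: /raw (channels x samples) + /fs_hz."""
    with h5py.File(path, "r") as f:
        return f["raw"][()], float(f.attrs["fs_hz"])


def write_sweeps(path: str, sweeps: VoltageSweepSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sweeps", data=sweeps.sweeps)
        f.create_dataset("I_inj_pA", data=sweeps.I_inj)
        f.attrs["fs_hz"] = sweeps.fs
        if sweeps.current is not None:
            f.create_dataset("current_pA", data=sweeps.current)
        if sweeps.condition is not None:
            f.create_dataset(
                "condition", data=np.asarray(sweeps.condition, dtype="S")
            )
        f.attrs["epochs"] = json.dumps(sweeps.epochs)


def read_sweeps(path: str) -> VoltageSweepSet:
    with h5py.File(path, "r") as f:
        return VoltageSweepSet(
            sweeps=f["sweeps"][()],
            I_inj=f["I_inj_pA"][()],
            fs=float(f.attrs["fs_hz"]),
            current=f["current_pA"][()] if "current_pA" in f else None,
            condition=(
                f["condition"][()].astype(str) if "condition" in f else None
            ),
            epochs={k: tuple(v) for k, v in json.loads(f.attrs["epochs"]).items()},
        )


def write_strf(path: str, strf: SeparableSTRF) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("k_f", data=strf.k_f)
        f.create_dataset("k_h", data=strf.k_h)
        f.attrs["bias"] = strf.bias
        if strf.freq_axis is not None:
            f.create_dataset("freq_axis_hz", data=strf.freq_axis)
        if strf.lag_axis is not None:
            f.create_dataset("lag_axis_s", data=strf.lag_axis)
        meta = {k: v for k, v in strf.fit_meta.items() if k != "loss_history"}
        f.attrs["fit_meta"] = json.dumps(meta, default=float)


def read_strf(path: str) -> SeparableSTRF:
    with h5py.File(path, "r") as f:
        return SeparableSTRF(
            k_f=f["k_f"][()],
            k_h=f["k_h"][()],
            bias=float(f.attrs["bias"]),
            freq_axis=f["freq_axis_hz"][()] if "freq_axis_hz" in f else None,
            lag_axis=f["lag_axis_s"][()] if "lag_axis_s" in f else None,
            fit_meta=json.loads(f.attrs.get("fit_meta", "{}")),
        )


def read_spike_csv(path: str) -> pd.DataFrame:
    """Spike-time table with columns unit_id, t_s and optionally width_ms."""
    df = pd.read_csv(path)
    missing = {"unit_id", "t_s"} - set(df.columns)
    if missing:
        raise ValueError(f"spike CSV missing columns: {sorted(missing)}")
    return df
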