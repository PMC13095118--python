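"""Serialisation of the package's containers.

Epoched wake data and generalization matrices round-trip through HDF5;
sleep-stage labels and event lists are plain CSV. Sleep signals are stored
in HDF5 as well; EDF files from real recordings can be read through MNE when
it is installed (EDF writing needs an external exporter and is not provided).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import GeneralizationMatrix
from .preprocess import EpochSet
from .sleepev import SleepRecord, SlowOscillation, Spindle

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_sleep_record",
    "load_sleep_record",
    "stages_to_csv",
    "stages_from_csv",
    "events_to_csv",
    "save_generalization",
    "load_generalization",
    "read_edf",
]


def _write_trials(g: h5py.Group, trials: pd.DataFrame) -> None:
    tg = g.create_group("trials")
    tg.attrs["columns"] = json.dumps(list(trials.columns))
    for col in trials.columns:
        vals = trials[col].to_numpy()
        if vals.dtype == object or str(vals.dtype).startswith("str"):
            vals = np.asarray([str(v) for v in vals], dtype="S")
        tg.create_dataset(col, data=vals)


def _read_trials(g: h5py.Group) -> pd.DataFrame:
    tg = g["trials"]
    cols = json.loads(tg.attrs["columns"])
    out = {}
    for col in cols:
        vals = tg[col][()]
        if vals.dtype.kind == "S":
            vals = np.asarray([v.decode() for v in vals])
        out[col] = vals
    return pd.DataFrame(out)


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sample_rate"] = epochs.sample_rate
        f.attrs["ch_names"] = json.dumps(list(epochs.ch_names))
        _write_trials(f, epochs.trials)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            trials=_read_trials(f),
            ch_names=tuple(json.loads(f.attrs["ch_names"])),
        )


def save_sleep_record(record: SleepRecord, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=record.signal)
        f.attrs["sample_rate"] = record.sample_rate
        f.attrs["ch_names"] = json.dumps(list(record.ch_names))
        f.attrs["stages"] = json.dumps(list(record.stages))


def load_sleep_record(path) -> SleepRecord:
    with h5py.File(path, "r") as f:
        return SleepRecord(
            signal=f["signal"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            stages=tuple(json.loads(f.attrs["stages"])),
            ch_names=tuple(json.loads(f.attrs["ch_names"])),
        )


def stages_to_csv(stages, path) -> None:
    pd.DataFrame({"epoch": np.arange(len(stages)), "stage": list(stages)}).to_csv(
        path, index=False
    )


def stages_from_csv(path) -> tuple[str, ...]:
    df = pd.read_csv(path)
    return tuple(df.sort_values("epoch")["stage"].astype(str))


def events_to_csv(events, path) -> None:
    """Write detected SO/spindle events as one tidy CSV."""
    rows = []
    for ev in events:
        if isinstance(ev, SlowOscillation):
            rows.append(
                dict(kind="SO", onset_s=ev.onset, offset_s=ev.offset,
                     center_s=np.nan, trough_amp=ev.trough_amp,
                     p2p_amp=ev.p2p_amp, n_cycles=np.nan, channel=ev.channel)
            )
        elif isinstance(ev, Spindle):
            rows.append(
                dict(kind="spindle", onset_s=ev.onset, offset_s=ev.offset,
                     center_s=ev.center, trough_amp=np.nan, p2p_amp=np.nan,
                     n_cycles=ev.n_cycles, channel=ev.channel)
            )
        else:
            raise TypeError(f"unsupported event type {type(ev)}")
    pd.DataFrame(rows).to_csv(path, index=False)


def save_generalization(matrix: GeneralizationMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values)
        f.create_dataset("train_times", data=matrix.train_times)
        f.create_dataset("test_times", data=matrix.test_times)
        f.attrs["offset"] = matrix.offset
        f.attrs["train_session"] = matrix.train_session
        f.attrs["test_session"] = matrix.test_session
        f.attrs["chance"] = matrix.chance


def load_generalization(path) -> GeneralizationMatrix:
    with h5py.File(path, "r") as f:
        return GeneralizationMatrix(
            values=f["values"][()],
            train_times=f["train_times"][()],
            test_times=f["test_times"][()],
            offset=int(f.attrs["offset"]),
            train_session=str(f.attrs["train_session"]),
            test_session=str(f.attrs["test_session"]),
            chance=float(f.attrs["chance"]),
        )


def read_edf(path, stages_csv=None) -> SleepRecord:
    """Load a polysomnography EDF (via MNE) plus a stage-label CSV."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading EDF files requires mne") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    stages = stages_from_csv(stages_csv) if stages_csv else ()
    return SleepRecord(
        signal=raw.get_data(),
        sample_rate=float(raw.info["sfreq"]),
        stages=stages,
        ch_names=tuple(raw.ch_names),
    )
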