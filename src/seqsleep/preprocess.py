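"""Epoch-level conditioning of wake-task EEG.

The fixed order of the pipeline is: moving-mean smoothing, baseline
correction against the pre-stimulus interval, z-scoring across trials, and
sliding-window averaging that defines the analysis time grid (20 ms windows,
12 ms steps at 250 Hz). None of these operations changes the trial count or
metadata. Sample indexing is 0-based and half-open throughout; window times
refer to window centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "WindowedEpochSet",
    "smooth_moving_mean",
    "baseline_correct",
    "zscore_across_trials",
    "sliding_window_average",
    "preprocess_pipeline",
]


@dataclass
class EpochSet:
    """Epoched multichannel EEG: ``data`` is trials x channels x time."""

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    trials: pd.DataFrame
    ch_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("metadata rows must equal trial count")
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("time axis must be uniform")
        if not self.ch_names:
            self.ch_names = tuple(f"EEG{c:03d}" for c in range(self.data.shape[1]))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def _with_data(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=data,
            times=self.times.copy(),
            sample_rate=self.sample_rate,
            trials=self.trials.copy(),
            ch_names=self.ch_names,
        )


@dataclass
class WindowedEpochSet:
    """Trials x channels x analysis-windows, after sliding-window averaging."""

    data: np.ndarray
    window_centers: np.ndarray
    window_len: float
    step: float
    trials: pd.DataFrame
    ch_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        if self.data.shape[2] != self.window_centers.size:
            raise ValueError("window axis length mismatch")
        if np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window centers must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_windows(self) -> int:
        return self.data.shape[2]


def _window_samples(window_s: float, sample_rate: float, what: str) -> int:
    n = window_s * sample_rate
    if abs(n - round(n)) > 1e-6:
        raise ValueError(
            f"{what} of {window_s} s is not an integral number of samples at "
            f"{sample_rate} Hz; pass explicit sample counts instead"
        )
    return int(round(n))


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving mean along the last axis with shrinking edge windows.

    Window at index i covers [i - w//2, i + (w - 1 - w//2)] clipped to the
    valid range, i.e. edge values are means of whatever samples exist.
    """
    from scipy.ndimage import uniform_filter1d

    n = x.shape[-1]
    sums = uniform_filter1d(x, w, axis=-1, mode="constant", cval=0.0) * w
    counts = uniform_filter1d(np.ones(n), w, mode="constant", cval=0.0) * w
    return sums / np.round(counts)


def smooth_moving_mean(epochs: EpochSet, window_s: float = 0.2) -> EpochSet:
    """Centered moving-mean smoothing (200 ms default) per trial and channel.

    At the epoch edges the window shrinks to the available samples rather
    than padding, so constant traces are left exactly unchanged.
    """
    w = max(int(round(window_s * epochs.sample_rate)), 0)
    if w < 1:
        raise ValueError("smoothing window must cover at least one sample")
    if w > epochs.n_times:
        raise ValueError("smoothing window longer than epoch")
    if w == 1:
        return epochs._with_data(epochs.data.copy())
    return epochs._with_data(_moving_mean(epochs.data, w))


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-0.2, 0.0)
) -> EpochSet:
    """Subtract the mean over the pre-stimulus ``window`` ([t0, t1) in s)
    per trial and channel."""
    lo, hi = window
    sel = (epochs.times >= lo) & (epochs.times < hi)
    if not sel.any():
        raise ValueError(f"baseline window {window} contains no samples")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return epochs._with_data(epochs.data - base)


def zscore_across_trials(epochs: EpochSet, ddof: int = 1) -> EpochSet:
    """Z-score every (channel, time) cell across trials (sample s.d., n-1).

    Cells with zero across-trial variance are set to 0 with a warning.
    """
    if epochs.n_trials < 2:
        raise ValueError("z-scoring requires at least 2 trials")
    mean = epochs.data.mean(axis=0, keepdims=True)
    sd = epochs.data.std(axis=0, ddof=ddof, keepdims=True)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} (channel, time) cells have zero across-trial "
            "variance; set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    sd_safe = np.where(zero, 1.0, sd)
    z = (epochs.data - mean) / sd_safe
    z = np.where(zero, 0.0, z)
    return epochs._with_data(z)


def sliding_window_average(
    epochs: EpochSet,
    window_s: float = 0.02,
    step_s: float = 0.012,
    window_samples: int | None = None,
    step_samples: int | None = None,
) -> WindowedEpochSet:
    """Average within sliding windows (20 ms / 12 ms step: 5 and 3 samples
    at 250 Hz). Window k covers samples [k*step, k*step + w), 0-based and
    half-open; its time stamp is the center of the covered samples."""
    w = window_samples if window_samples is not None else _window_samples(
        window_s, epochs.sample_rate, "window"
    )
    s = step_samples if step_samples is not None else _window_samples(
        step_s, epochs.sample_rate, "step"
    )
    if w < 1 or s < 1:
        raise ValueError("window and step must cover at least one sample")
    if w > epochs.n_times:
        raise ValueError("window longer than epoch")
    n_win = (epochs.n_times - w) // s + 1
    starts = np.arange(n_win) * s
    idx = starts[:, None] + np.arange(w)[None, :]
    data = epochs.data[:, :, idx].mean(axis=3)
    centers = epochs.times[idx].mean(axis=1)
    return WindowedEpochSet(
        data=data,
        window_centers=centers,
        window_len=w / epochs.sample_rate,
        step=s / epochs.sample_rate,
        trials=epochs.trials.copy(),
        ch_names=epochs.ch_names,
    )


def preprocess_pipeline(
    epochs: EpochSet,
    smooth_s: float = 0.2,
    baseline: tuple[float, float] = (-0.2, 0.0),
    window_s: float = 0.02,
    step_s: float = 0.012,
) -> WindowedEpochSet:
    """The full conditioning chain in its fixed order:
    smoothing -> baseline correction -> across-trial z-scoring -> windows."""
    out = smooth_moving_mean(epochs, smooth_s)
    out = baseline_correct(out, baseline)
    out = zscore_across_trials(out)
    return sliding_window_average(out, window_s, step_s)
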