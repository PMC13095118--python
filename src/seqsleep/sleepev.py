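"""Slow-oscillation and spindle detection, coupling, and circular statistics.

Detection follows the standard amplitude-threshold protocol: slow
oscillations (SOs) are candidate segments between consecutive positive-to-
negative zero crossings of the 0.3-1.25 Hz zero-phase filtered signal,
retained when 0.8-2 s long and when both trough and trough-to-peak amplitude
exceed the mean + 1 s.d. of the duration-valid candidate pool; spindles are
intervals where the smoothed 200 ms RMS of the 12-16 Hz filtered signal
exceeds the mean + 1 s.d. for 0.4-3 s, contain no sample above mean + 9 s.d.
(artifact rule), and hold at least six oscillatory cycles. A spindle is
coupled to an SO when its envelope maximum falls inside the SO interval; the
SO phase at that maximum (Hilbert transform; phase 0 = up-state peak,
+/- pi = down-state) feeds pairwise phase consistency (PPC),

    PPC = 1 / (N (N - 1)) * sum_{i != j} cos(phi_i - phi_j),

an unbiased estimate of the squared population resultant length, insensitive
to the number of detected events.

Events are detected during NREM sleep only (stages N2 and SWS by default;
N1 excluded). Filters are zero-phase Butterworth (second-order sections,
forward-backward), order 3 for the SO band and 4 for the sigma band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt
from scipy.stats import norm

__all__ = [
    "SleepRecord",
    "SlowOscillation",
    "Spindle",
    "PhaseSet",
    "detect_sos",
    "detect_spindles",
    "couple_events",
    "so_phases_at_spindles",
    "ppc",
    "rayleigh_test",
    "stage_proportions",
]

STAGE_LABELS = ("W", "N1", "N2", "SWS", "REM")
NREM_STAGES = ("N2", "SWS")
SO_BAND = (0.3, 1.25)
SIGMA_BAND = (12.0, 16.0)
EPOCH_SECONDS = 30.0


from dataclasses import dataclass


@dataclass
class SleepRecord:
    """Continuous sleep EEG with per-30-s sleep-stage labels."""

    signal: np.ndarray  # channels x samples
    sample_rate: float
    stages: tuple[str, ...]
    ch_names: tuple[str, ...]

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        bad = set(self.stages) - set(STAGE_LABELS)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        needed = int(np.ceil(self.duration / EPOCH_SECONDS))
        if self.stages and len(self.stages) != needed:
            raise ValueError(
                f"expected {needed} stage labels for {self.duration:.0f} s, "
                f"got {len(self.stages)}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in self.ch_names:
            raise KeyError(f"channel {name!r} not in record")
        return self.signal[self.ch_names.index(name)]

    def nrem_mask(self, stages=NREM_STAGES) -> np.ndarray:
        """Boolean per-sample mask of the requested stages (default N2+SWS)."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for i, st in enumerate(self.stages):
            if st in stages:
                lo = int(i * EPOCH_SECONDS * self.sample_rate)
                hi = min(int((i + 1) * EPOCH_SECONDS * self.sample_rate), self.n_samples)
                mask[lo:hi] = True
        return mask


@dataclass(frozen=True)
class SlowOscillation:
    onset: float
    offset: float
    trough_amp: float  # |minimum|, uV
    p2p_amp: float  # trough-to-peak, uV
    channel: str

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Spindle:
    onset: float
    offset: float
    center: float  # envelope maximum
    n_cycles: int
    channel: str

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class PhaseSet:
    """SO phases at coupled spindle envelope maxima, radians in (-pi, pi]."""

    phases: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=float))
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases must be finite")

    @property
    def n(self) -> int:
        return self.phases.size


def bandpass(x: np.ndarray, band: tuple[float, float], fs: float, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (SOS, forward-backward)."""
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _moving_mean_1d(x: np.ndarray, w: int) -> np.ndarray:
    from .preprocess import _moving_mean

    return _moving_mean(x[None, :], w)[0]


def detect_sos(
    record: SleepRecord,
    channel: str = "Cz",
    nrem_mask: np.ndarray | None = None,
    band: tuple[float, float] = SO_BAND,
    duration_range: tuple[float, float] = (0.8, 2.0),
    threshold_sd: float = 1.0,
) -> list[SlowOscillation]:
    """Detect slow oscillations on one channel during NREM sleep.

    Candidates are segments between consecutive positive-to-negative zero
    crossings of the band-filtered signal lying wholly inside NREM; those of
    valid duration whose trough amplitude AND trough-to-peak amplitude both
    strictly exceed mean + ``threshold_sd`` s.d. of the candidate pool are
    returned. An empty candidate pool yields an empty list.
    """
    x = record.channel(channel)
    fs = record.sample_rate
    if nrem_mask is None:
        nrem_mask = record.nrem_mask()
    if not nrem_mask.any():
        raise ValueError("NREM mask is empty")
    filt = bandpass(x, band, fs, order=3)

    pos2neg = np.flatnonzero((filt[:-1] > 0) & (filt[1:] <= 0)) + 1
    cands = []
    for a, b in zip(pos2neg[:-1], pos2neg[1:]):
        dur = (b - a) / fs
        if not duration_range[0] <= dur <= duration_range[1]:
            continue
        if not nrem_mask[a:b].all():
            continue
        seg = filt[a:b]
        trough = float(-seg.min())
        p2p = float(seg.max() - seg.min())
        cands.append((a / fs, b / fs, trough, p2p))
    if not cands:
        return []
    troughs = np.array([c[2] for c in cands])
    p2ps = np.array([c[3] for c in cands])
    thr_t = troughs.mean() + threshold_sd * troughs.std(ddof=0)
    thr_p = p2ps.mean() + threshold_sd * p2ps.std(ddof=0)
    return [
        SlowOscillation(onset=a, offset=b, trough_amp=tr, p2p_amp=pp, channel=channel)
        for (a, b, tr, pp) in cands
        if tr > thr_t and pp > thr_p
    ]


def detect_spindles(
    record: SleepRecord,
    channel: str = "Cz",
    nrem_mask: np.ndarray | None = None,
    band: tuple[float, float] = SIGMA_BAND,
    rms_window_s: float = 0.2,
    duration_range: tuple[float, float] = (0.4, 3.0),
    threshold_sd: float = 1.0,
    artifact_sd: float = 9.0,
    min_cycles: int = 6,
) -> list[Spindle]:
    """Detect sleep spindles on one channel during NREM sleep.

    The RMS of the sigma-filtered signal is computed in a 200 ms moving
    window and smoothed with the same kernel; events are contiguous NREM
    intervals where the smoothed RMS exceeds mean + 1 s.d. for 0.4-3 s,
    contain no sample above mean + 9 s.d. (artifact exclusion), and hold at
    least ``min_cycles`` positive peaks of the filtered signal. The center is
    the envelope (smoothed RMS) maximum.
    """
    x = record.channel(channel)
    fs = record.sample_rate
    if nrem_mask is None:
        nrem_mask = record.nrem_mask()
    if not nrem_mask.any():
        raise ValueError("NREM mask is empty")
    filt = bandpass(x, band, fs, order=4)
    w = max(int(round(rms_window_s * fs)), 1)
    rms = np.sqrt(np.maximum(_moving_mean_1d(filt**2, w), 0.0))
    env = _moving_mean_1d(rms, w)

    mu = env[nrem_mask].mean()
    sd = env[nrem_mask].std(ddof=0)
    thr = mu + threshold_sd * sd
    art = mu + artifact_sd * sd

    above = (env > thr) & nrem_mask
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]

    out = []
    for a, b in zip(starts, stops):
        dur = (b - a) / fs
        if not duration_range[0] <= dur <= duration_range[1]:
            continue
        if np.any(env[a:b] > art):
            continue
        # Oscillatory cycles: positive peaks of the band-passed signal within
        # the event. Note the rule binds only for the shortest events — any
        # suprathreshold sigma-band interval oscillates at 12-16 Hz
        # throughout, so events beyond ~0.5 s carry 6+ peaks by construction.
        peaks, _ = find_peaks(filt[a:b])
        n_cycles = int((filt[a:b][peaks] > 0).sum())
        if n_cycles < min_cycles:
            continue
        center = (a + int(np.argmax(env[a:b]))) / fs
        out.append(
            Spindle(onset=a / fs, offset=b / fs, center=center, n_cycles=n_cycles,
                    channel=channel)
        )
    return out


def couple_events(
    sos: list[SlowOscillation], spindles: list[Spindle]
) -> list[tuple[SlowOscillation, Spindle]]:
    """Pair each spindle with the SO containing its envelope maximum.

    A pair (s, p) is formed iff ``s.onset <= p.center <= s.offset``. SOs do
    not overlap by construction, so each spindle matches at most one SO; one
    SO may host several spindles.
    """
    channels = {e.channel for e in sos} | {e.channel for e in spindles}
    if len(channels) > 1:
        raise ValueError("events must come from a single channel")
    pairs = []
    for p in spindles:
        for s in sos:
            if s.onset <= p.center <= s.offset:
                pairs.append((s, p))
                break
    return pairs


def so_phases_at_spindles(
    record: SleepRecord,
    channel: str,
    pairs: list[tuple[SlowOscillation, Spindle]],
    band: tuple[float, float] = SO_BAND,
) -> PhaseSet:
    """SO-band instantaneous phase at each coupled spindle's envelope maximum.

    Phase is the angle of the analytic (Hilbert) signal of the SO-filtered
    trace: 0 at the up-state peak, +/- pi at the down-state trough. Phase
    increases through time within a cycle.
    """
    if not pairs:
        raise ValueError("no coupled SO-spindle pairs")
    filt = bandpass(record.channel(channel), band, record.sample_rate, order=3)
    phase = np.angle(hilbert(filt))
    out = []
    for _, p in pairs:
        i = int(round(p.center * record.sample_rate))
        if not 0 <= i < record.n_samples:
            raise ValueError(f"spindle center {p.center} s outside record")
        out.append(phase[i])
    return PhaseSet(phases=np.asarray(out))


def ppc(phases: PhaseSet | np.ndarray) -> float:
    """Pairwise phase consistency: mean cosine of all pairwise differences.

    Evaluates 1/(N(N-1)) * sum_{i != j} cos(phi_i - phi_j) exactly via the
    resultant identity |sum_k e^{i phi_k}|^2 = N + sum_{i != j} cos(...).
    Unbiased for the squared population resultant length; 1 for identical
    phases, about 0 for uniform phases, slightly negative values possible.
    """
    phi = phases.phases if isinstance(phases, PhaseSet) else np.asarray(phases, float)
    n = phi.size
    if n < 2:
        raise ValueError("PPC requires at least 2 phases")
    resultant_sq = np.abs(np.exp(1j * phi).sum()) ** 2
    return float((resultant_sq - n) / (n * (n - 1)))


def rayleigh_test(phases: PhaseSet | np.ndarray) -> tuple[float, float]:
    """Rayleigh test for non-uniformity of circular data.

    Returns ``(R, p)`` where R is the mean resultant length and p the
    standard approximation p = exp(sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n))
    with finite-sample correction.
    """
    phi = phases.phases if isinstance(phases, PhaseSet) else np.asarray(phases, float)
    n = phi.size
    if n < 2:
        raise ValueError("Rayleigh test requires at least 2 phases")
    R = float(np.abs(np.exp(1j * phi).mean()))
    Rn = n * R
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n))
    return R, float(min(max(p, 0.0), 1.0))


def stage_proportions(
    stages, include_wake: bool = True
) -> dict[str, float]:
    """Fraction of scored 30-s epochs spent in each stage.

    By default proportions are over all scored epochs (wake included in the
    denominator); ``include_wake=False`` restricts the denominator to sleep
    epochs and reports W as 0. Fractions sum to 1.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("empty stage vector")
    bad = set(stages) - set(STAGE_LABELS)
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    if include_wake:
        denom = len(stages)
        counts = {st: stages.count(st) for st in STAGE_LABELS}
    else:
        sleep = [s for s in stages if s != "W"]
        if not sleep:
            raise ValueError("no sleep epochs in record")
        denom = len(sleep)
        counts = {st: (sleep.count(st) if st != "W" else 0) for st in STAGE_LABELS}
    return {st: counts[st] / denom for st in STAGE_LABELS}
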