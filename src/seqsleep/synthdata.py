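"""Ground-truth synthetic data generators.

Every downstream stage of the package (preprocessing, decoding, RSA, sleep
event detection) is validated against data produced here, where the embedded
structure — category-tuned evoked patterns, a successor "leak" of adjustable
strength/latency/layer format, hierarchical feature spaces, and slow
oscillation/spindle events with a controllable coupling phase distribution —
is known exactly.

Data are generated at the post-preprocessing stage: clean, epoched, 250 Hz
wake EEG and clean continuous sleep EEG. Filtering artefacts, ocular
components and bad channels are deliberately not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .sleepev import SleepRecord

__all__ = [
    "CATEGORIES",
    "ORDER_VARIANTS",
    "SUBCATEGORIES",
    "SequenceDesign",
    "LayerFeatureSet",
    "WakeGenParams",
    "SleepGenParams",
    "SleepTruth",
    "make_sequence_design",
    "make_layer_features",
    "simulate_wake_session",
    "simulate_sleep_record",
]

#: Canonical category ordering. Used wherever a deterministic ordering of
#: category labels is needed (classifier tie-breaks, arena slices).
CATEGORIES = ("letter", "scene", "object", "face", "body")

#: The two fixed category orders a subsequence can follow. Body-part images
#: are inserted into these primary orders at random slots.
ORDER_VARIANTS = {
    "letter-scene-object-face": ("letter", "scene", "object", "face"),
    "object-scene-letter-face": ("object", "scene", "letter", "face"),
}

SUBCATEGORIES = {
    "letter": ("caps", "lower"),
    "scene": ("natural", "manmade"),
    "object": ("animate", "inanimate"),
    "face": ("young", "old"),
    "body": ("upper", "lower"),
}

ARENA_RADIUS = 300.0  # pixels


@dataclass(frozen=True)
class SequenceDesign:
    """A learned image sequence: ordering, categories and arena positions.

    ``images`` is the full learned order. Each subsequence contains the four
    primary categories in the variant's fixed order, with one body-part image
    inserted at a recorded slot to obscure the category regularity.
    """

    images: tuple[str, ...]
    category: dict[str, str]
    subcategory: dict[str, str]
    subsequences: tuple[tuple[str, ...], ...]
    order_variant: str
    positions: dict[str, tuple[float, float]]
    body_insertions: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.images)) != len(self.images):
            raise ValueError("every image must appear exactly once")
        if self.order_variant not in ORDER_VARIANTS:
            raise ValueError(f"unknown order variant {self.order_variant!r}")

    @property
    def index(self) -> dict[str, int]:
        return {img: i for i, img in enumerate(self.images)}

    def neighbor(self, image: str, offset: int, mode: str = "primary"):
        """Image at a signed ``offset`` along the learned order, or ``None``.

        In ``"primary"`` mode (default) body-part images are transparent:
        stepping skips over them, so the successor of an object image is the
        next face image even if a body part sits in between. ``"literal"``
        steps through the sequence as presented. Returns ``None`` past either
        end of the sequence.
        """
        if image not in self.category:
            raise KeyError(f"unknown image {image!r}")
        if offset == 0:
            return image
        if mode not in ("primary", "literal"):
            raise ValueError(f"unknown neighbor mode {mode!r}")
        idx = self.index
        i = idx[image]
        step = 1 if offset > 0 else -1
        for _ in range(abs(offset)):
            j = i + step
            if mode == "primary":
                while 0 <= j < len(self.images) and self.category[self.images[j]] == "body":
                    j += step
            if not (0 <= j < len(self.images)):
                return None
            i = j
        return self.images[i]

    def neighbor_category(self, image: str, offset: int, mode: str = "primary"):
        nb = self.neighbor(image, offset, mode=mode)
        return None if nb is None else self.category[nb]

    def to_dict(self) -> dict:
        return {
            "images": list(self.images),
            "category": dict(self.category),
            "subcategory": dict(self.subcategory),
            "subsequences": [list(s) for s in self.subsequences],
            "order_variant": self.order_variant,
            "positions": {k: list(v) for k, v in self.positions.items()},
            "body_insertions": list(self.body_insertions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceDesign":
        return cls(
            images=tuple(d["images"]),
            category=dict(d["category"]),
            subcategory=dict(d["subcategory"]),
            subsequences=tuple(tuple(s) for s in d["subsequences"]),
            order_variant=d["order_variant"],
            positions={k: (float(v[0]), float(v[1])) for k, v in d["positions"].items()},
            body_insertions=tuple(int(i) for i in d["body_insertions"]),
        )


def make_sequence_design(
    order_variant: str = "letter-scene-object-face",
    n_subsequences: int = 10,
    seed: int = 0,
    include_body: bool = True,
) -> SequenceDesign:
    """Build a learned sequence of ``5 * n_subsequences`` images.

    Each subsequence holds one image from each of the four primary categories
    in the variant's fixed order, plus (if ``include_body``) one body-part
    image inserted at a seeded random slot. Image-to-subsequence assignment
    and arena positions are randomised by ``seed``.
    """
    if order_variant not in ORDER_VARIANTS:
        raise ValueError(
            f"unknown order variant {order_variant!r}; choose from {sorted(ORDER_VARIANTS)}"
        )
    if n_subsequences < 1:
        raise ValueError("n_subsequences must be >= 1")
    rng = np.random.default_rng(seed)
    primary = ORDER_VARIANTS[order_variant]
    cats = primary + (("body",) if include_body else ())

    # One image per category per subsequence; subcategories split half/half.
    pools: dict[str, list[str]] = {}
    category: dict[str, str] = {}
    subcategory: dict[str, str] = {}
    for cat in cats:
        ids = [f"{cat}{k:02d}" for k in range(1, n_subsequences + 1)]
        rng.shuffle(ids)
        pools[cat] = ids
        subs = SUBCATEGORIES[cat]
        for k, img in enumerate(sorted(ids)):
            category[img] = cat
            subcategory[img] = subs[0] if k < (n_subsequences + 1) // 2 else subs[1]

    subsequences = []
    body_insertions = []
    for b in range(n_subsequences):
        block = [pools[cat][b] for cat in primary]
        if include_body:
            slot = int(rng.integers(0, len(block) + 1))
            block.insert(slot, pools["body"][b])
            body_insertions.append(slot)
        subsequences.append(tuple(block))

    images = tuple(img for block in subsequences for img in block)

    # Arena positions: one 72-degree slice per category (canonical order).
    positions = {}
    for img in images:
        s = CATEGORIES.index(category[img])
        theta = np.deg2rad(72.0 * s + rng.uniform(5.0, 67.0))
        r = rng.uniform(0.2, 0.95) * ARENA_RADIUS
        positions[img] = (float(r * np.cos(theta)), float(r * np.sin(theta)))

    return SequenceDesign(
        images=images,
        category=category,
        subcategory=subcategory,
        subsequences=tuple(subsequences),
        order_variant=order_variant,
        positions=positions,
        body_insertions=tuple(body_insertions),
    )


@dataclass(frozen=True)
class LayerFeatureSet:
    """Per-layer, per-image feature vectors with graded category structure.

    Stands in for the activations of a feed-forward visual hierarchy: layer
    rank runs 1..n_layers from shallow to deep, and ``profile[rank-1]``
    controls how strongly features cluster by category at that layer.
    """

    images: tuple[str, ...]
    features: dict[int, np.ndarray]  # rank -> (n_images, dim)
    profile: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.features)

    @property
    def ranks(self) -> tuple[int, ...]:
        return tuple(sorted(self.features))

    def matrix(self, rank: int) -> np.ndarray:
        return self.features[rank]

    def vector(self, rank: int, image: str) -> np.ndarray:
        return self.features[rank][self.images.index(image)]

    def category_gap(self, rank: int, category: dict[str, str]) -> float:
        """Within-category minus between-category mean feature correlation."""
        X = self.features[rank]
        C = np.corrcoef(X)
        labels = np.asarray([category[img] for img in self.images])
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(labels), k=1)
        same_u = same[iu]
        return float(C[iu][same_u].mean() - C[iu][~same_u].mean())


def make_layer_features(
    design: SequenceDesign,
    n_layers: int = 7,
    dims: int | list[int] = 50,
    category_depth_profile=None,
    seed: int = 0,
) -> LayerFeatureSet:
    """Generate hierarchical feature vectors for every image in ``design``.

    Features at layer rank r are isotropic Gaussian noise plus category (and
    weaker subcategory) centroids scaled by ``category_depth_profile[r-1]``;
    a monotonically increasing profile therefore yields category clustering
    that deepens with layer rank, the hallmark of trained visual hierarchies.
    """
    if category_depth_profile is None:
        category_depth_profile = np.linspace(0.25, 1.5, n_layers)
    profile = np.asarray(category_depth_profile, dtype=float)
    if profile.shape != (n_layers,):
        raise ValueError("category_depth_profile length must equal n_layers")
    if not np.all(np.isfinite(profile)):
        raise ValueError("category_depth_profile must be finite")
    if np.isscalar(dims):
        dims = [int(dims)] * n_layers
    if len(dims) != n_layers or any(d < 1 for d in dims):
        raise ValueError("dims must be positive, one per layer")

    rng = np.random.default_rng(seed)
    cats = sorted(set(design.category.values()))
    features: dict[int, np.ndarray] = {}
    for r in range(1, n_layers + 1):
        dim = dims[r - 1]
        c = profile[r - 1]
        cent = rng.normal(size=(len(cats), dim))
        cent *= np.sqrt(dim) / np.linalg.norm(cent, axis=1, keepdims=True)
        subcent = {}
        for cat in cats:
            for sub in SUBCATEGORIES[cat]:
                v = rng.normal(size=dim)
                subcent[(cat, sub)] = v * np.sqrt(dim) / np.linalg.norm(v)
        X = rng.normal(size=(len(design.images), dim))
        for i, img in enumerate(design.images):
            cat = design.category[img]
            X[i] += c * cent[cats.index(cat)]
            X[i] += 0.5 * c * subcent[(cat, design.subcategory[img])]
        features[r] = X
    return LayerFeatureSet(images=design.images, features=features, profile=profile)


@dataclass
class WakeGenParams:
    """Generator settings for one participant's wake-task sessions.

    ``successor_amp`` is the strength of the learned "leak": during post-
    learning trials the evoked response additionally carries the channel
    pattern of the *successor* image, time-localised around
    ``successor_latency`` and mixed across layers by
    ``successor_layer_weighting``. Setting it to zero yields sessions
    identical in distribution to pre-learning.
    """

    n_trials_per_image: int = 4
    n_channels: int = 58
    sample_rate: float = 250.0
    epoch_window: tuple[float, float] = (-0.5, 1.5)
    current_amp: float = 1.0
    successor_amp: float = 0.0
    successor_latency: float = 0.5
    successor_layer_weighting: np.ndarray | None = None
    current_layer_weighting: np.ndarray | None = None
    noise_sd: float = 2.0
    neighbor_mode: str = "primary"
    seed: int = 0

    def __post_init__(self):
        for name in ("current_amp", "successor_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _envelope_current(t: np.ndarray) -> np.ndarray:
    """Stimulus-locked evoked envelope: ramps up after onset, sustained over
    the 1 s presentation, ramps down by 1.1 s."""
    env = np.zeros_like(t)
    ramp = (t >= 0) & (t < 0.1)
    env[ramp] = 0.5 - 0.5 * np.cos(np.pi * t[ramp] / 0.1)
    env[(t >= 0.1) & (t < 0.9)] = 1.0
    down = (t >= 0.9) & (t < 1.1)
    env[down] = 0.5 + 0.5 * np.cos(np.pi * (t[down] - 0.9) / 0.2)
    return env


def _envelope_successor(t: np.ndarray, latency: float, width: float = 0.15) -> np.ndarray:
    env = np.exp(-0.5 * ((t - latency) / width) ** 2)
    env[t < 0] = 0.0
    return env


def _layer_templates(features: LayerFeatureSet, weights, mixing) -> np.ndarray:
    """Per-image channel patterns: weighted sum of layer features projected
    through the participant's fixed channel mixing; globally scaled to unit
    pattern s.d. so amplitudes in WakeGenParams are in noise-comparable
    units."""
    ranks = features.ranks
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    T = sum(w[i] * features.matrix(r) @ mixing[r].T for i, r in enumerate(ranks))
    return T / T.std()


def simulate_wake_session(
    design: SequenceDesign,
    features: LayerFeatureSet,
    params: WakeGenParams,
    session: str,
) -> EpochSet:
    """Simulate one epoched perceptual-task session for one participant.

    Every trial carries the channel pattern of the current image under a
    sustained stimulus envelope. In post-learning sessions with
    ``successor_amp > 0``, the pattern of the learned successor image is added
    under a Gaussian envelope centred on ``successor_latency``. Channel
    mixing is fixed per participant (seeded), so patterns generalise across
    the pre/post sessions as required by cross-session decoding.
    """
    if session not in ("pre", "post"):
        raise ValueError(f"session must be 'pre' or 'post', got {session!r}")
    if session == "pre" and params.successor_amp > 0:
        raise ValueError("pre-learning sessions must be leak-free (successor_amp == 0)")
    missing = [img for img in design.images if img not in features.images]
    if missing:
        raise ValueError(f"features missing for images: {missing[:5]}")

    L = features.n_layers
    ss = np.random.SeedSequence([int(params.seed), 0])
    rng_mix = np.random.default_rng(ss)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), 1 if session == "pre" else 2])
    )

    # Fixed per-participant channel loadings, one projection per layer.
    mixing = {
        r: rng_mix.normal(size=(params.n_channels, features.matrix(r).shape[1]))
        / np.sqrt(features.matrix(r).shape[1])
        for r in features.ranks
    }
    w_cur = (
        np.linspace(2.0, 0.5, L)
        if params.current_layer_weighting is None
        else np.asarray(params.current_layer_weighting, float)
    )
    w_suc = (
        np.ones(L)
        if params.successor_layer_weighting is None
        else np.asarray(params.successor_layer_weighting, float)
    )
    T_cur = _layer_templates(features, w_cur, mixing)  # (n_images, n_channels)
    T_suc = _layer_templates(features, w_suc, mixing)

    t0, t1 = params.epoch_window
    n_t = int(round((t1 - t0) * params.sample_rate))
    times = t0 + np.arange(n_t) / params.sample_rate
    env_c = _envelope_current(times)
    env_s = _envelope_successor(times, params.successor_latency)

    img_index = {img: i for i, img in enumerate(features.images)}
    order = np.repeat(np.arange(len(design.images)), params.n_trials_per_image)
    rng.shuffle(order)

    data = np.empty((len(order), params.n_channels, n_t))
    rows = []
    for k, di in enumerate(order):
        img = design.images[di]
        tpl = params.current_amp * np.outer(T_cur[img_index[img]], env_c)
        if session == "post" and params.successor_amp > 0:
            succ = design.neighbor(img, +1, mode=params.neighbor_mode)
            if succ is not None:
                tpl = tpl + params.successor_amp * np.outer(T_suc[img_index[succ]], env_s)
        data[k] = tpl + rng.normal(0.0, params.noise_sd, size=(params.n_channels, n_t))
        rows.append(
            {
                "image": img,
                "category": design.category[img],
                "subcategory": design.subcategory[img],
                "session": session,
                "correct": True,
                "is_target": False,
                "seq_position": int(design.index[img]),
            }
        )
    trials = pd.DataFrame(rows)
    ch_names = tuple(f"EEG{c:03d}" for c in range(params.n_channels))
    return EpochSet(
        data=data, times=times, sample_rate=params.sample_rate, trials=trials, ch_names=ch_names
    )


@dataclass
class SleepGenParams:
    """Generator settings for a continuous sleep EEG record.

    Rates are per minute of NREM sleep. ``p_coupled`` is the fraction of
    spindles whose envelope maximum is nested inside a slow oscillation, at
    an SO phase drawn from von Mises(``coupling_mu``, ``coupling_kappa``)
    (phase 0 = SO up-state peak, +/-pi = down-state).
    """

    duration: float = 600.0
    sample_rate: float = 100.0
    so_rate: float = 3.0
    spindle_rate: float = 4.0
    p_coupled: float = 0.6
    coupling_mu: float = 0.0
    coupling_kappa: float = 5.0
    so_amp: float = 75.0
    spindle_amp: float = 20.0
    noise_amp: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_coupled <= 1.0:
            raise ValueError("p_coupled must lie in [0, 1]")
        if self.duration <= 60.0:
            raise ValueError("duration must exceed 60 s")


@dataclass
class SleepTruth:
    """Ground-truth event lists returned alongside a simulated record."""

    sos: pd.DataFrame  # onset, offset, duration (s)
    spindles: pd.DataFrame  # onset, offset, center, coupled, so_index, phase
    phases: np.ndarray  # coupling phases of the coupled spindles (rad)


def _hypnogram(n_epochs: int, rng: np.random.Generator | None = None) -> list[str]:
    """Nap-like stage sequence: brief wake and N1, then alternating N2/SWS
    blocks of seeded-random length (so stage proportions vary across
    records), ending in REM when long enough."""
    if rng is None:
        rng = np.random.default_rng(0)
    stages = ["W", "N1"]
    while len(stages) < n_epochs:
        stages.extend(["N2"] * int(rng.integers(2, 7)))
        stages.extend(["SWS"] * int(rng.integers(1, 7)))
    stages = stages[:n_epochs]
    if n_epochs >= 20:
        stages[-1] = "REM"
    return stages


def _one_over_f_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5  # 1/f power spectrum
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def _place_events(rng, runs, n, dur_range, occupied, gap, max_tries=2000):
    """Uniformly place n non-overlapping intervals inside the allowed runs,
    respecting a minimum gap from previously occupied intervals."""
    placed = []
    weights = np.array([hi - lo for lo, hi in runs], float)
    if weights.sum() <= 0 and n > 0:
        raise ValueError("no NREM time available for event placement")
    for _ in range(n):
        for attempt in range(max_tries):
            dur = rng.uniform(*dur_range)
            ri = rng.choice(len(runs), p=weights / weights.sum())
            lo, hi = runs[ri]
            if hi - lo <= dur:
                continue
            start = rng.uniform(lo, hi - dur)
            iv = (start, start + dur)
            if all(iv[1] + gap < a or iv[0] - gap > b for a, b in occupied + placed):
                placed.append(iv)
                break
        else:
            raise ValueError(
                "event rates imply overlapping events beyond record capacity"
            )
    return placed


def simulate_sleep_record(params: SleepGenParams):
    """Simulate a single-channel sleep record plus ground-truth event lists.

    Slow oscillations are single full cycles of a 0.9-1.6 s sine (duration
    within the 0.8-2 s detection band) starting at a positive-to-negative
    zero crossing; spindles are Hann-tapered 13.5 Hz bursts of 0.6-1.2 s
    (>= 6 cycles). Background is 1/f-like noise. Coupled spindles are placed
    so their envelope maximum falls at the sampled SO phase.

    Returns ``(SleepRecord, SleepTruth)``.
    """
    fs = params.sample_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(params.seed)

    stages = _hypnogram(int(np.ceil(params.duration / 30.0)), rng)
    nrem_epochs = [i for i, s in enumerate(stages) if s in ("N2", "SWS")]
    # Contiguous NREM runs in seconds, with margins for event tails.
    runs = []
    start = None
    for i in range(len(stages) + 1):
        is_nrem = i < len(stages) and stages[i] in ("N2", "SWS")
        if is_nrem and start is None:
            start = i
        elif not is_nrem and start is not None:
            lo = start * 30.0 + 2.0
            hi = min(i * 30.0, params.duration) - 2.0
            if hi > lo:
                runs.append((lo, hi))
            start = None
    nrem_seconds = sum(hi - lo for lo, hi in runs)

    n_so = int(round(params.so_rate * nrem_seconds / 60.0))
    n_sp = int(round(params.spindle_rate * nrem_seconds / 60.0))
    n_coupled = int(round(params.p_coupled * n_sp))
    if n_coupled > n_so:
        raise ValueError(
            f"p_coupled requires {n_coupled} coupled spindles but only {n_so} SOs"
        )

    so_iv = _place_events(rng, runs, n_so, (0.9, 1.6), [], gap=2.0)
    so_iv.sort()
    so_df = pd.DataFrame(
        {
            "onset": [a for a, b in so_iv],
            "offset": [b for a, b in so_iv],
            "duration": [b - a for a, b in so_iv],
        }
    )

    signal = params.noise_amp * _one_over_f_noise(n, fs, rng)
    for a, b in so_iv:
        sel = (t >= a) & (t < b)
        signal[sel] += -params.so_amp * np.sin(2 * np.pi * (t[sel] - a) / (b - a))

    # Coupled spindles: envelope max at the sampled SO phase. Inside one SO
    # cycle of length T with up-state peak at 3T/4, instantaneous phase is
    # 2*pi*(tau/T) - 3*pi/2, covering the full circle once.
    coupled_idx = rng.choice(n_so, size=n_coupled, replace=False) if n_coupled else []
    if params.coupling_kappa >= 1e8 or np.isinf(params.coupling_kappa):
        phases = np.full(n_coupled, params.coupling_mu, float)
    elif params.coupling_kappa <= 0:
        phases = rng.uniform(-np.pi, np.pi, size=n_coupled)
    else:
        phases = rng.vonmises(params.coupling_mu, params.coupling_kappa, size=n_coupled)

    sp_rows = []
    occupied = list(so_iv)
    for so_i, phi in zip(coupled_idx, phases):
        a, b = so_iv[so_i]
        T = b - a
        phi_b = phi if phi <= np.pi / 2 else phi - 2 * np.pi  # branch (-3pi/2, pi/2]
        center = a + (phi_b + 1.5 * np.pi) * T / (2 * np.pi)
        dur = rng.uniform(0.6, 1.2)
        sp_rows.append(
            {
                "onset": center - dur / 2,
                "offset": center + dur / 2,
                "center": center,
                "coupled": True,
                "so_index": int(so_i),
                "phase": float((phi + np.pi) % (2 * np.pi) - np.pi),
            }
        )
        occupied.append((center - dur / 2, center + dur / 2))

    free_iv = _place_events(
        rng, runs, n_sp - n_coupled, (0.6, 1.2), occupied, gap=1.0
    )
    for a, b in free_iv:
        sp_rows.append(
            {
                "onset": a,
                "offset": b,
                "center": (a + b) / 2,
                "coupled": False,
                "so_index": -1,
                "phase": np.nan,
            }
        )
    sp_df = pd.DataFrame(
        sp_rows,
        columns=["onset", "offset", "center", "coupled", "so_index", "phase"],
    ).sort_values("onset", ignore_index=True)

    for row in sp_df.itertuples():
        sel = (t >= row.onset) & (t < row.offset)
        m = sel.sum()
        if m == 0:
            continue
        # Sine taper: unique envelope maximum at the burst center (needed for
        # well-defined coupling phases) with a rise steep enough that the
        # nominal onset marks actual oscillatory energy.
        taper = np.sqrt(np.hanning(m))
        carrier = np.sin(2 * np.pi * 13.5 * (t[sel] - row.center) + rng.uniform(0, 2 * np.pi))
        signal[sel] += params.spindle_amp * taper * carrier

    record = SleepRecord(
        signal=signal[None, :],
        sample_rate=fs,
        stages=tuple(stages),
        ch_names=("Cz",),
    )
    truth = SleepTruth(sos=so_df, spindles=sp_df, phases=np.asarray(phases, float))
    return record, truth
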