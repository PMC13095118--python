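"""Cohort-level orchestration.

``run_group`` drives the full analysis for a synthetic cohort: per
participant it simulates the learned sequence, layer features, pre/post
wake sessions, behaviour reports and a nap record; runs preprocessing,
cross-session successor decoding, layer-hierarchy RSA and sleep event
detection; then at the group level runs the cluster permutation test
against chance, extracts each participant's mean decoding accuracy inside
the group cluster ("successor strength"), and assembles the cross-
participant correlation table (strength/shift vs behaviour, SWS proportion
and SO-spindle PPC).

The group cluster mask is estimated once on the cohort and then applied to
every individual — the procedure inherits the circularity of defining the
window on the same data used for the correlations, which is documented
rather than corrected. Participant exclusion applies two rules: behavioural
outliers (beyond 3 scaled MADs on either metric in BOTH the final learning
block and the pre-sleep test) and absence of any sleep beyond N1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from . import __version__
from .decoding import GeneralizationMatrix, cross_session_neighbor_accuracy, group_decoding_test
from .preprocess import preprocess_pipeline
from .rsa import eeg_successor_similarity, representational_shift
from .sleepev import (
    couple_events,
    detect_sos,
    detect_spindles,
    ppc,
    so_phases_at_spindles,
    stage_proportions,
)
from .stats import ClusterResult, mad_outliers, sequence_accuracy, spearman
from .synthdata import (
    ORDER_VARIANTS,
    SleepGenParams,
    WakeGenParams,
    make_layer_features,
    make_sequence_design,
    simulate_sleep_record,
    simulate_wake_session,
)

__all__ = [
    "CohortConfig",
    "ParticipantResult",
    "GroupResult",
    "extract_strength",
    "run_participant",
    "run_group",
]

# Geometric profiles concentrate the leak on one end of the hierarchy.
# Because deep-layer models carry strong category structure, a broad linear
# "shallow" mixture would still correlate with deep-layer models through its
# shared category content; concentrated profiles keep the two conditions
# genuinely shallow vs deep.
LAYER_WEIGHTINGS = {
    "deep": np.geomspace(0.05, 2.0, 7),
    "shallow": np.geomspace(2.0, 0.05, 7),
    "uniform": np.ones(7),
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the wake-task design (58 channels, 250 Hz, epochs from
    -0.5 to 1.5 s, 20 ms/12 ms analysis windows) at desk scale (4 trials per
    image = 40 per category). ``successor_amp`` is the cohort-wide leak
    strength; ``link_strength_to_coupling`` instead draws per-participant
    coupling concentration and ties the leak to the resulting expected PPC,
    for brain-sleep correlation recovery runs.
    """

    n_participants: int = 12
    seed: int = 0
    n_trials_per_image: int = 4
    n_channels: int = 58
    successor_amp: float = 0.8
    successor_latency: float = 0.5
    successor_layer_weighting: str = "uniform"  # deep | shallow | uniform
    noise_sd: float = 2.0
    offset: int = 1
    sleep: SleepGenParams = field(default_factory=SleepGenParams)
    link_strength_to_coupling: bool = False
    link_slope: float = 1.2
    kappa_range: tuple[float, float] = (0.3, 8.0)
    n_perm: int = 500
    alpha: float = 0.05
    run_rsa: bool = True
    run_sleep: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sleep"] = asdict(self.sleep)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ParticipantResult:
    """Everything one simulated participant contributes to the group stage."""

    participant: int
    seed: int
    matrix: GeneralizationMatrix
    layer_similarity: dict | None  # session -> layers x windows
    shift: float
    behavior: dict  # sequence accuracies (%), placement errors (px)
    sleep: dict  # stage proportions, ppc, n_coupled, counts
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class GroupResult:
    cluster: ClusterResult
    cluster_mask: np.ndarray
    mask_is_fallback: bool
    strengths: np.ndarray
    shifts: np.ndarray
    correlations: pd.DataFrame
    participants: list
    included: list
    provenance: dict


def _participant_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))


def _expected_ppc(kappa: float) -> float:
    """Population squared resultant length of a von Mises distribution,
    (I1(kappa)/I0(kappa))^2 — the quantity PPC estimates without bias."""
    if kappa <= 0:
        return 0.0
    return float((i1(kappa) / i0(kappa)) ** 2)


def _corrupt_order(truth, target_pct: float, rng) -> list:
    """Degrade a reported order by random adjacent transpositions until its
    pairwise sequential accuracy drops to about ``target_pct``."""
    order = list(truth)
    for _ in range(20 * len(order)):
        if sequence_accuracy(order, truth) <= target_pct:
            break
        i = int(rng.integers(0, len(order) - 1))
        order[i], order[i + 1] = order[i + 1], order[i]
    return order


def _remembered_images(design, reports: dict, mode: str = "primary") -> list:
    """Images whose successor was correctly recalled in both memory tests:
    the (image, successor) pair appears adjacent and in order in both the
    pre- and post-sleep reports."""
    out = []
    for img in design.images:
        succ = design.neighbor(img, +1, mode="literal")
        if succ is None:
            continue
        ok = True
        for key in ("pre_test", "post_test"):
            rep = reports[key]
            pos = {im: i for i, im in enumerate(rep)}
            if pos[succ] != pos[img] + 1:
                ok = False
                break
        if ok:
            out.append(img)
    return out


def run_participant(i: int, cfg: CohortConfig) -> ParticipantResult:
    """Simulate and analyse one participant."""
    pseed = _participant_seed(cfg.seed, i)
    rng = np.random.default_rng(pseed)
    variant = list(ORDER_VARIANTS)[i % 2]  # counterbalanced across cohort
    design = make_sequence_design(order_variant=variant, seed=pseed)
    features = make_layer_features(design, seed=pseed + 1)

    if isinstance(cfg.successor_layer_weighting, str):
        w_succ = LAYER_WEIGHTINGS[cfg.successor_layer_weighting]
    else:
        w_succ = np.asarray(cfg.successor_layer_weighting, float)

    # Sleep first when the leak is tied to coupling strength.
    kappa = cfg.sleep.coupling_kappa
    succ_amp = cfg.successor_amp
    if cfg.link_strength_to_coupling:
        kappa = float(rng.uniform(*cfg.kappa_range))
        succ_amp = max(
            0.0,
            cfg.successor_amp
            + cfg.link_slope * _expected_ppc(kappa)
            + rng.normal(0.0, 0.05),
        )

    params = WakeGenParams(
        n_trials_per_image=cfg.n_trials_per_image,
        n_channels=cfg.n_channels,
        successor_amp=succ_amp,
        successor_latency=cfg.successor_latency,
        successor_layer_weighting=w_succ,
        noise_sd=cfg.noise_sd,
        seed=pseed,
    )
    pre = simulate_wake_session(design, features, replace(params, successor_amp=0.0), "pre")
    post = simulate_wake_session(design, features, params, "post")
    wpre = preprocess_pipeline(pre)
    wpost = preprocess_pipeline(post)

    matrix = cross_session_neighbor_accuracy(wpre, wpost, design, offset=cfg.offset)

    # Behaviour: ability drives report fidelity in learning and both tests.
    ability = float(rng.uniform(68.0, 96.0))
    reports = {
        "final_block": _corrupt_order(design.images, ability, rng),
        "pre_test": _corrupt_order(design.images, ability + rng.normal(0, 4), rng),
        "post_test": _corrupt_order(design.images, ability - 8 + rng.normal(0, 5), rng),
    }
    interference = list(design.images)
    rng.shuffle(interference)
    behavior = {
        key: sequence_accuracy(rep, design.images) for key, rep in reports.items()
    }
    behavior["interference"] = sequence_accuracy(
        _corrupt_order(interference, 16.0, rng), interference
    )
    behavior["placement_error_final"] = float(rng.gamma(4.0, 8.0))
    behavior["placement_error_pre"] = float(rng.gamma(4.0, 8.0))

    layer_sim = None
    shift = np.nan
    if cfg.run_rsa:
        remembered = _remembered_images(design, reports)
        if len(remembered) < 3:
            remembered = None  # fall back to the full image set
        sims, centers, _ = eeg_successor_similarity(
            {"pre": wpre, "post": wpost}, features, design, remembered_images=remembered
        )
        layer_sim = sims
        in_window = (centers >= 0.0) & (centers <= 1.0)
        delta = (sims["post"] - sims["pre"])[:, in_window].mean(axis=1)
        shift = representational_shift(delta)

    sleep_metrics = {}
    if cfg.run_sleep:
        sp = replace(cfg.sleep, coupling_kappa=kappa, seed=pseed + 7)
        record, _ = simulate_sleep_record(sp)
        sos = detect_sos(record)
        spindles = detect_spindles(record)
        pairs = couple_events(sos, spindles)
        ppc_val = np.nan
        if len(pairs) >= 2:
            ppc_val = ppc(so_phases_at_spindles(record, "Cz", pairs))
        props = stage_proportions(record.stages)
        sleep_metrics = {
            "proportions": props,
            "ppc": ppc_val,
            "n_coupled": len(pairs),
            "n_sos": len(sos),
            "n_spindles": len(spindles),
        }

    return ParticipantResult(
        participant=i,
        seed=pseed,
        matrix=matrix,
        layer_similarity=layer_sim,
        shift=shift,
        behavior=behavior,
        sleep=sleep_metrics,
    )


def extract_strength(matrix, cluster_mask: np.ndarray) -> float:
    """Mean accuracy of one participant's matrix over the group cluster."""
    values = matrix.values if isinstance(matrix, GeneralizationMatrix) else np.asarray(matrix)
    mask = np.asarray(cluster_mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape must match the matrix")
    if not mask.any():
        raise ValueError("cluster mask is empty")
    return float(values[mask].mean())


def _apply_exclusions(results: list[ParticipantResult]) -> None:
    accs = np.array([r.behavior["final_block"] for r in results])
    errs = np.array([r.behavior["placement_error_final"] for r in results])
    accs_pre = np.array([r.behavior["pre_test"] for r in results])
    errs_pre = np.array([r.behavior["placement_error_pre"] for r in results])
    flag_final = mad_outliers(accs) | mad_outliers(errs)
    flag_pre = mad_outliers(accs_pre) | mad_outliers(errs_pre)
    for r, bad in zip(results, flag_final & flag_pre):
        if bad:
            r.excluded = True
            r.exclusion_reason = "behavioral outlier (final block and pre-sleep test)"
    for r in results:
        props = r.sleep.get("proportions")
        if props is not None:
            beyond_n1 = props["N2"] + props["SWS"] + props["REM"]
            if beyond_n1 == 0:
                r.excluded = True
                r.exclusion_reason = "no sleep beyond N1"


def run_group(cfg: CohortConfig) -> GroupResult:
    """Run the full cohort analysis and the cross-participant correlations."""
    results = [run_participant(i, cfg) for i in range(cfg.n_participants)]
    _apply_exclusions(results)
    included = [r for r in results if not r.excluded]
    if len(included) < 3:
        raise ValueError("fewer than 3 participants remain after exclusions")

    matrices = [r.matrix for r in included]
    cluster = group_decoding_test(
        matrices, n_perm=cfg.n_perm, seed=_participant_seed(cfg.seed, 10_000)
    )
    mask = cluster.significant_mask(cfg.alpha)
    fallback = not mask.any()
    if fallback:
        # No significant cluster (e.g. a null cohort): report grand means.
        mask = np.ones_like(mask, dtype=bool)

    strengths = np.array([extract_strength(r.matrix, mask) for r in included])
    shifts = np.array([r.shift for r in included])

    rows = []

    def _corr(name_x, x, name_y, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < 3:
            rows.append(dict(x=name_x, y=name_y, rho=np.nan, p=np.nan, n=int(keep.sum())))
            return
        try:
            rho, p = spearman(x[keep], y[keep])
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append(dict(x=name_x, y=name_y, rho=rho, p=p, n=int(keep.sum())))

    beh = {k: np.array([r.behavior[k] for r in included]) for k in
           ("pre_test", "post_test", "interference")}
    _corr("strength", strengths, "pre_sleep_accuracy", beh["pre_test"])
    _corr("strength", strengths, "post_sleep_accuracy", beh["post_test"])
    _corr("strength", strengths, "interference_accuracy", beh["interference"])
    if cfg.run_sleep:
        sws = np.array([r.sleep["proportions"]["SWS"] for r in included])
        ppcs = np.array([r.sleep["ppc"] for r in included])
        _corr("strength", strengths, "sws_proportion", sws)
        _corr("shift", shifts, "sws_proportion", sws)
        _corr("strength", strengths, "ppc", ppcs)
        _corr("shift", shifts, "ppc", ppcs)
    _corr("strength", strengths, "shift", shifts)
    correlations = pd.DataFrame(rows, columns=["x", "y", "rho", "p", "n"])

    provenance = {
        "package": "seqsleep",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_included": len(included),
        "excluded": [
            {"participant": r.participant, "reason": r.exclusion_reason}
            for r in results
            if r.excluded
        ],
    }
    return GroupResult(
        cluster=cluster,
        cluster_mask=mask,
        mask_is_fallback=fallback,
        strengths=strengths,
        shifts=shifts,
        correlations=correlations,
        participants=results,
        included=[r.participant for r in included],
        provenance=provenance,
    )
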