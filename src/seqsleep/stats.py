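"""Group-level inference machinery.

Cluster-based permutation tests correct for multiple comparisons over time
(1-D) or train-time x test-time (2-D) grids: per-point parametric statistics
above a cluster-forming threshold (p < alpha at the stated tail) are grouped
by adjacency (4-neighbourhood on 2-D grids) and each cluster's mass — the
sum of its statistic values — is compared against the distribution of
maximum cluster masses over random permutations (subject-level sign flips
for the one-sample test; within-subject session-label flips for the
session x layer interaction test). Permutation p-values carry the +1
correction and are never smaller than 1/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "ClusterResult",
    "cluster_permutation_1samp",
    "cluster_permutation_interaction",
    "within_subject_contrast",
    "linear_weights",
    "cosine_weights",
    "spearman",
    "mad_outliers",
    "sequence_accuracy",
]


@dataclass
class ClusterResult:
    """Per-point statistic map plus permutation-calibrated clusters."""

    stat_map: np.ndarray
    clusters: list[np.ndarray]  # boolean masks, disjoint
    cluster_stats: np.ndarray  # signed cluster mass (sum of statistic)
    cluster_p: np.ndarray
    n_permutations: int
    tail: str
    threshold: float

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        """Union of clusters with permutation p <= alpha."""
        mask = np.zeros(self.stat_map.shape, dtype=bool)
        for m, p in zip(self.clusters, self.cluster_p):
            if p <= alpha:
                mask |= m
        return mask

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _t_maps(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t maps for a batch of sign-flip assignments.

    ``d`` is subjects x points (already mu-centred); ``signs`` is
    batch x subjects of +/-1. Uses the identity sum((s*d)^2) = sum(d^2) to
    avoid materialising flipped data.
    """
    n = d.shape[0]
    ssq = (d**2).sum(axis=0)  # invariant under sign flips
    means = signs @ d / n
    var = (ssq - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _clusters_and_masses(stat: np.ndarray, thr: float, tail: str):
    """Label supra-threshold clusters (adjacency: 4-connectivity in 2-D) and
    return (masks, signed masses)."""
    masks, masses = [], []
    directions = []
    if tail in ("greater", "two-sided"):
        directions.append(1)
    if tail in ("less", "two-sided"):
        directions.append(-1)
    for sign in directions:
        supra = sign * stat > thr
        labels, n = ndimage.label(supra)
        for k in range(1, n + 1):
            m = labels == k
            masks.append(m)
            masses.append(float(stat[m].sum()))
    return masks, np.asarray(masses)


def _max_null_mass(stat: np.ndarray, thr: float, tail: str) -> float:
    _, masses = _clusters_and_masses(stat, thr, tail)
    if masses.size == 0:
        return 0.0
    return float(np.abs(masses).max())


def cluster_permutation_1samp(
    data: np.ndarray,
    mu: float = 0.0,
    tail: str = "greater",
    alpha_cluster: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = None,
) -> ClusterResult:
    """One-sample cluster permutation test of ``data`` (subjects x grid)
    against ``mu``.

    The cluster-forming threshold is the parametric t critical value for
    p < ``alpha_cluster`` at the stated tail; the null distribution is built
    from random sign flips of the subject-level deviations from ``mu``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim < 2 or data.ndim > 3:
        raise ValueError("data must be subjects x grid (1-D or 2-D grid)")
    n_sub = data.shape[0]
    if n_sub < 2:
        raise ValueError("at least 2 subjects required")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    grid_shape = data.shape[1:]
    d = data.reshape(n_sub, -1) - mu
    if np.all(d.std(axis=0) == 0):
        if np.all(d == 0):
            # Data identically at mu: t = 0 everywhere, nothing supra-threshold.
            df = n_sub - 1
            thr = float(
                sps.t.ppf(1 - alpha_cluster / (2 if tail == "two-sided" else 1), df)
            )
            return ClusterResult(
                stat_map=np.zeros(grid_shape),
                clusters=[],
                cluster_stats=np.empty(0),
                cluster_p=np.empty(0),
                n_permutations=n_perm,
                tail=tail,
                threshold=thr,
            )
        raise ValueError("zero variance at every grid point")

    df = n_sub - 1
    if tail == "two-sided":
        thr = float(sps.t.ppf(1 - alpha_cluster / 2, df))
    else:
        thr = float(sps.t.ppf(1 - alpha_cluster, df))

    t_obs = _t_maps(d, np.ones((1, n_sub)))[0].reshape(grid_shape)
    masks, masses = _clusters_and_masses(t_obs, thr, tail)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(d.size, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(b, n_sub))
        t_perm = _t_maps(d, signs)
        for i in range(b):
            null_max[done + i] = _max_null_mass(t_perm[i].reshape(grid_shape), thr, tail)
        done += b

    cluster_p = np.array(
        [(1 + np.sum(null_max >= abs(m))) / (n_perm + 1) for m in masses]
    )
    return ClusterResult(
        stat_map=t_obs,
        clusters=masks,
        cluster_stats=masses,
        cluster_p=cluster_p,
        n_permutations=n_perm,
        tail=tail,
        threshold=thr,
    )


def _interaction_f(diff: np.ndarray) -> np.ndarray:
    """Session x layer interaction F over time from per-subject session
    differences ``diff`` (subjects x layers x time).

    For a two-level session factor the interaction is equivalent to the
    repeated-measures layer effect on the session difference: F with
    (L-1, (S-1)(L-1)) degrees of freedom.
    """
    S, L, T = diff.shape
    grand = diff.mean(axis=(0, 1), keepdims=True)
    m_layer = diff.mean(axis=0, keepdims=True)
    m_subj = diff.mean(axis=1, keepdims=True)
    ss_layer = S * ((m_layer - grand) ** 2).sum(axis=(0, 1))
    resid = diff - m_subj - m_layer + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1, df2 = L - 1, (S - 1) * (L - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_layer / df1) / (ss_err / df2)
    return np.nan_to_num(F, nan=0.0, posinf=0.0, neginf=0.0)


def cluster_permutation_interaction(
    data: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster permutation test of the session x layer interaction over time.

    ``data`` is subjects x session(2) x layer x time (balanced within-subject
    design). Per time point a repeated-measures interaction F is computed;
    clusters of consecutive supra-threshold time points are calibrated by
    independently flipping the session labels within each subject — an
    approximate permutation scheme that is exchangeable when the session has
    no effect.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError("data must be subjects x session(2) x layer x time")
    if not np.all(np.isfinite(data)):
        raise ValueError("design must be balanced and finite")
    S, _, L, T = data.shape
    if S < 2 or L < 2:
        raise ValueError("need >= 2 subjects and >= 2 layers")

    diff = data[:, 1] - data[:, 0]  # subjects x layer x time
    df1, df2 = L - 1, (S - 1) * (L - 1)
    thr = float(sps.f.ppf(1 - alpha_cluster, df1, df2))

    f_obs = _interaction_f(diff)
    masks, masses = _clusters_and_masses(f_obs, thr, "greater")

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=(S, 1, 1))
        null_max[p] = _max_null_mass(_interaction_f(signs * diff), thr, "greater")
    cluster_p = np.array(
        [(1 + np.sum(null_max >= m)) / (n_perm + 1) for m in masses]
    )
    return ClusterResult(
        stat_map=f_obs,
        clusters=masks,
        cluster_stats=masses,
        cluster_p=cluster_p,
        n_permutations=n_perm,
        tail="greater",
        threshold=thr,
    )


def linear_weights(n_layers: int = 7) -> np.ndarray:
    """Centered layer ranks: the linear trend contrast."""
    k = np.arange(1, n_layers + 1, dtype=float)
    return k - k.mean()


def cosine_weights(n_layers: int = 7) -> np.ndarray:
    """Half-cosine contrast cos(pi * (k - 1) / (n - 1)), centered."""
    k = np.arange(1, n_layers + 1, dtype=float)
    w = np.cos(np.pi * (k - 1) / (n_layers - 1))
    return w - w.mean()


def within_subject_contrast(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """One-sample two-tailed t-test of per-subject contrast scores vs 0.

    ``values`` is subjects x layers; ``weights`` must sum to zero.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.ndim != 2 or values.shape[1] != weights.size:
        raise ValueError("values must be subjects x layers matching weights")
    if abs(weights.sum()) > 1e-9 * max(np.abs(weights).max(), 1.0):
        raise ValueError("contrast weights must sum to zero")
    scores = values @ weights
    if np.allclose(scores.std(ddof=1), 0):
        if np.allclose(scores, 0):
            return 0.0, 1.0
        raise ValueError("contrast scores have zero variance but non-zero mean")
    t, p = sps.ttest_1samp(scores, 0.0)
    return float(t), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Average-rank Spearman correlation with two-tailed t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def mad_outliers(values) -> np.ndarray:
    """Flag values more than 3 scaled MADs from the median (strict >).

    The scaled MAD is 1.4826 * median(|v - median|), the consistency-
    corrected robust spread. A zero MAD flags every deviating value, with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(v)
    mad = 1.4826 * np.median(np.abs(v - med))
    if mad == 0:
        warnings.warn(
            "scaled MAD is zero; flagging every deviation from the median",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.abs(v - med) > 0
    return np.abs(v - med) > 3.0 * mad


def sequence_accuracy(reported, truth) -> float:
    """Pairwise sequential accuracy, in percent.

    The fraction of adjacent ordered pairs (truth[i], truth[i+1]) that appear
    adjacent and in the same order in the report, x 100.
    """
    reported = list(reported)
    truth = list(truth)
    if sorted(reported) != sorted(truth) or len(set(truth)) != len(truth):
        raise ValueError("report and truth must contain the same items, once each")
    if len(truth) < 2:
        raise ValueError("need at least 2 items")
    pos = {item: i for i, item in enumerate(reported)}
    hits = sum(pos[b] == pos[a] + 1 for a, b in zip(truth[:-1], truth[1:]))
    return 100.0 * hits / (len(truth) - 1)
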