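"""Time-resolved representational similarity analysis against a layered
feature hierarchy.

EEG representational similarity matrices (RSMs) are pairwise Spearman
correlations of trial-averaged channel patterns between images, computed per
analysis window. Model RSMs come from per-layer feature vectors of either
the current image or its learned successor. Because successor-model and
current-model RSMs are collinear, the current-image structure is regressed
out of the EEG similarities (OLS with intercept on the vectorised upper
triangle) before correlating the residuals with the successor model.

The representational-shift statistic summarises where, along the layer
hierarchy (ranks 1..7, shallow to deep), the learning-related change in
EEG-successor similarity concentrates: Spearman correlation of the per-layer
post-minus-pre change with layer rank, winsorised to +/-0.99 and Fisher
z-transformed. Positive shift = change concentrated in deep (abstract)
layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr

__all__ = [
    "SimilarityMatrix",
    "RSMTimecourse",
    "LayerSimilarityProfile",
    "upper_tri",
    "compute_rsm_timecourse",
    "model_rsm",
    "category_specificity",
    "residualize",
    "eeg_successor_similarity",
    "winsorized_fisher_z",
    "representational_shift",
]

WINSOR_LIMIT = 0.99


@dataclass
class SimilarityMatrix:
    """Symmetric image x image Spearman-rho matrix; diagonal ignored."""

    values: np.ndarray
    images: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.images)
        if self.values.shape != (m, m):
            raise ValueError("matrix shape must match image list")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")

    def pair_values(self) -> np.ndarray:
        return upper_tri(self.values)


@dataclass
class RSMTimecourse:
    """Per-window EEG similarity matrices: values is windows x m x m."""

    values: np.ndarray
    images: tuple[str, ...]
    window_centers: np.ndarray

    def at(self, k: int) -> SimilarityMatrix:
        return SimilarityMatrix(values=self.values[k], images=self.images)


@dataclass
class LayerSimilarityProfile:
    """One scalar similarity (or similarity change) per layer rank."""

    values: np.ndarray  # aligned with ranks 1..n
    session: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile must be one value per layer")


def upper_tri(mat: np.ndarray) -> np.ndarray:
    """Vectorise the strict upper triangle (pairs i < j, canonical order)."""
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _spearman_rsm(patterns: np.ndarray) -> np.ndarray:
    """All pairwise Spearman correlations between the rows of ``patterns``
    (items x features), with average ranks for ties."""
    ranks = rankdata(patterns, axis=1)
    return np.corrcoef(ranks)


def compute_rsm_timecourse(
    windowed,
    image_subset=None,
) -> RSMTimecourse:
    """EEG RSMs per analysis window from trial-averaged channel patterns.

    Only correct, non-target trials enter the image averages. ``image_subset``
    restricts the matrix to those images (at least 3 required). Images in the
    subset without any valid trial are dropped.
    """
    trials = windowed.trials
    ok = trials["correct"].to_numpy() & ~trials["is_target"].to_numpy()
    imgs_all = trials["image"].to_numpy()
    candidates = (
        sorted(set(imgs_all[ok]))
        if image_subset is None
        else [i for i in image_subset if (ok & (imgs_all == i)).any()]
    )
    if len(candidates) < 3:
        raise ValueError("need at least 3 images with valid trials for an RSM")
    patterns = np.stack(
        [windowed.data[ok & (imgs_all == img)].mean(axis=0) for img in candidates]
    )  # images x channels x windows
    K = windowed.n_windows
    values = np.empty((K, len(candidates), len(candidates)))
    for k in range(K):
        values[k] = _spearman_rsm(patterns[:, :, k])
    return RSMTimecourse(
        values=values,
        images=tuple(candidates),
        window_centers=windowed.window_centers.copy(),
    )


def model_rsm(
    features,
    rank: int,
    mapping: str = "current",
    design=None,
    images=None,
    mode: str = "primary",
) -> SimilarityMatrix:
    """Model RSM from layer-``rank`` feature vectors.

    ``mapping="current"`` correlates each image's own features;
    ``mapping="successor"`` correlates the features of each image's learned
    successor (requires ``design``). Images lacking a successor are dropped
    with a warning.
    """
    if mapping not in ("current", "successor"):
        raise ValueError(f"unknown mapping {mapping!r}")
    imgs = list(images) if images is not None else list(features.images)
    if mapping == "successor":
        if design is None:
            raise ValueError("successor mapping requires a sequence design")
        mapped, kept = [], []
        for img in imgs:
            succ = design.neighbor(img, +1, mode=mode)
            if succ is None:
                warnings.warn(
                    f"image {img!r} has no successor; dropped from successor RSM",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            mapped.append(succ)
            kept.append(img)
        imgs = kept
    else:
        mapped = imgs
    if len(imgs) < 3:
        raise ValueError("need at least 3 images for a model RSM")
    X = np.stack([features.vector(rank, m) for m in mapped])
    return SimilarityMatrix(values=_spearman_rsm(X), images=tuple(imgs))


def category_specificity(rsm, categories) -> float:
    """Mean within-category minus mean between-category similarity
    (off-diagonal pairs only).

    ``categories`` maps image -> category (or is a list aligned with the
    matrix rows).
    """
    if isinstance(rsm, SimilarityMatrix):
        labels = [categories[i] for i in rsm.images] if isinstance(categories, dict) else list(categories)
        mat = rsm.values
    else:
        mat = np.asarray(rsm, dtype=float)
        labels = list(categories)
    if len(labels) != mat.shape[0]:
        raise ValueError("category labels must align with matrix rows")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 categories")
    labels = np.asarray(labels)
    iu = np.triu_indices(mat.shape[0], k=1)
    same = (labels[:, None] == labels[None, :])[iu]
    if not same.any():
        raise ValueError("no within-category pairs")
    vals = mat[iu]
    return float(vals[same].mean() - vals[~same].mean())


def residualize(eeg_values: np.ndarray, model_values: np.ndarray) -> np.ndarray:
    """OLS residuals of EEG pair-values on model pair-values (with intercept).

    ``model_values`` may be one regressor (n_pairs,) or several
    (n_pairs x k). The residuals have exactly zero sample correlation with
    each regressor. A zero-variance regressor contributes nothing beyond the
    intercept; with a single such regressor the result is the centered EEG
    values, with a warning.
    """
    y = np.asarray(eeg_values, dtype=float)
    X = np.asarray(model_values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise ValueError("EEG and model pair vectors must align")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            "zero-variance model regressor; residual is the centered EEG vector",
            RuntimeWarning,
            stacklevel=2,
        )
        X = X[:, keep]
    design = np.column_stack([np.ones(y.size), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def eeg_successor_similarity(
    windowed_by_session: dict,
    features,
    design,
    remembered_images=None,
    residualize_mode: str = "same-layer",
    mode: str = "primary",
):
    """EEG-successor similarity per session, layer and window.

    For every session: compute the EEG RSM timecourse over the remembered
    images (those whose successors were correctly recalled in both memory
    tests; default all), regress the current-image model structure out of the
    EEG pair-values (``"same-layer"``: that layer's current RSM;
    ``"all-layers"``: all current RSMs jointly; ``"none"``), and Spearman-
    correlate the residuals with the successor-model pair-values.

    Returns ``(similarity, window_centers, images_used)`` where
    ``similarity[session]`` is layers x windows.
    """
    if residualize_mode not in ("same-layer", "all-layers", "none"):
        raise ValueError(f"unknown residualize mode {residualize_mode!r}")
    imgs = list(remembered_images) if remembered_images is not None else list(features.images)
    # The successor model needs a successor for every included image.
    imgs = [i for i in imgs if design.neighbor(i, +1, mode=mode) is not None]
    if len(imgs) < 3:
        raise ValueError("fewer than 3 remembered images; participant excluded")

    ranks = features.ranks
    succ_vecs = {}
    cur_vecs = {}
    for r in ranks:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            succ_vecs[r] = model_rsm(
                features, r, "successor", design, images=imgs, mode=mode
            ).pair_values()
        cur_vecs[r] = model_rsm(features, r, "current", images=imgs).pair_values()
    all_cur = np.column_stack([cur_vecs[r] for r in ranks])

    out = {}
    centers = None
    images_used = None
    for session, ws in windowed_by_session.items():
        tc = compute_rsm_timecourse(ws, image_subset=imgs)
        if list(tc.images) != imgs:
            raise ValueError("sessions must cover all remembered images")
        centers = tc.window_centers
        images_used = tc.images
        K = tc.values.shape[0]
        sims = np.empty((len(ranks), K))
        for li, r in enumerate(ranks):
            for k in range(K):
                eeg_vec = upper_tri(tc.values[k])
                if residualize_mode == "same-layer":
                    resid = residualize(eeg_vec, cur_vecs[r])
                elif residualize_mode == "all-layers":
                    resid = residualize(eeg_vec, all_cur)
                else:
                    resid = eeg_vec
                sims[li, k] = spearmanr(resid, succ_vecs[r]).statistic
        out[session] = sims
    return out, centers, images_used


def winsorized_fisher_z(rho: float, limit: float = WINSOR_LIMIT) -> float:
    """Fisher z = atanh(rho) after winsorising rho to +/-``limit``.

    Winsorisation avoids infinite z at |rho| = 1 and applies to every
    Fisher-transformed correlation in this module.
    """
    return float(np.arctanh(np.clip(rho, -limit, limit)))


def representational_shift(delta) -> float:
    """Fisher-z of the Spearman correlation between per-layer similarity
    change and layer rank (1..n).

    Positive values mean the post-minus-pre change in EEG-successor
    similarity grows with layer depth. A constant profile (all ties) has an
    undefined correlation and returns 0 with a warning.
    """
    values = delta.values if isinstance(delta, LayerSimilarityProfile) else np.asarray(delta, float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need one change value per layer")
    if np.all(values == values[0]):
        warnings.warn(
            "constant layer profile; shift correlation undefined, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    ranks = np.arange(1, values.size + 1)
    rho = spearmanr(values, ranks).statistic
    return winsorized_fisher_z(rho)
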