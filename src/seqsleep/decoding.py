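"""Cross-session successor/predecessor category decoding.

For each held-out image category, a multiclass shrinkage LDA is trained on
the other four categories' trials from the pre-learning session at each
training time window, and applied to the held-out category's trials in a
target session at every test time window. Predictions are scored against the
category of the sequence neighbour at a signed offset (+1 = successor,
-1 = predecessor, +/-2 = second neighbours), yielding a train-time x
test-time generalization matrix of neighbour-category accuracy whose chance
level is 25% (four trained classes).

Trials whose image has no neighbour at the requested offset (sequence
boundaries) are excluded; sequences do not wrap. Accuracies are averaged
across trials within each image (= sequence position), then across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .preprocess import WindowedEpochSet
from .stats import ClusterResult, cluster_permutation_1samp

__all__ = [
    "GeneralizationMatrix",
    "train_classifier",
    "neighbor_of",
    "cross_session_neighbor_accuracy",
    "group_decoding_test",
]

CHANCE = 0.25

#: Canonical label ordering used to encode classes; argmax ties break toward
#: the lowest index, making predictions deterministic.
CANONICAL_ORDER = ("letter", "scene", "object", "face", "body")


def _encode(labels, order=CANONICAL_ORDER) -> np.ndarray:
    lut = {c: i for i, c in enumerate(order)}
    try:
        return np.asarray([lut[l] for l in labels], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown category label {e.args[0]!r}") from None


def train_classifier(patterns: np.ndarray, labels) -> LinearDiscriminantAnalysis:
    """Fit a multiclass LDA with analytic (Ledoit-Wolf) covariance shrinkage.

    ``patterns`` is trials x channels. Shrinkage keeps the pooled covariance
    invertible even with more channels than trials. Deterministic given the
    data; ties in the discriminant scores resolve to the lowest canonical
    category index.
    """
    patterns = np.asarray(patterns, dtype=float)
    y = _encode(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        short = [CANONICAL_ORDER[c] for c, n in zip(classes, counts) if n < 2]
        raise ValueError(f"need >= 2 trials per class; too few for {short}")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    clf.fit(patterns, y)
    return clf


def neighbor_of(design, image: str, offset: int, mode: str = "primary"):
    """Category of the sequence neighbour at ``offset``, or ``None`` at a
    boundary.

    In the default ``"primary"`` mode body-part insertions are transparent:
    neighbours follow the primary category order of the learned sequence.
    """
    if offset not in (-2, -1, 1, 2):
        raise ValueError("offset must be one of -2, -1, +1, +2")
    return design.neighbor_category(image, offset, mode=mode)


@dataclass
class GeneralizationMatrix:
    """Train-window x test-window neighbour-category accuracy, one
    participant."""

    values: np.ndarray  # train_windows x test_windows, in [0, 1]
    train_times: np.ndarray
    test_times: np.ndarray
    offset: int
    train_session: str
    test_session: str
    chance: float = CHANCE
    per_image: dict | None = None  # image -> matrix, retained for audit

    def __post_init__(self):
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        if self.values.shape != (self.train_times.size, self.test_times.size):
            raise ValueError("matrix dimensions must match the window grids")


def _select(ws: WindowedEpochSet, mask: np.ndarray) -> np.ndarray:
    return ws.data[np.asarray(mask, dtype=bool)]


def cross_session_neighbor_accuracy(
    train: WindowedEpochSet,
    test: WindowedEpochSet,
    design,
    offset: int = 1,
    mode: str = "primary",
    train_session: str = "pre",
    test_session: str = "post",
) -> GeneralizationMatrix:
    """Temporal-generalization neighbour decoding for one participant.

    For each of the five categories in turn: train on the other four
    categories' (correct, non-target) trials in ``train`` at each training
    window, predict every test window of the held-out category's trials in
    ``test``, and score a hit when the predicted category equals the
    neighbour category of the trial's image at ``offset``. Hits are averaged
    within image, then across images, over all held-out categories.
    """
    if train.data.shape[1] != test.data.shape[1]:
        raise ValueError("train and test sessions must share the channel set")
    categories = sorted(set(design.category.values()), key=CANONICAL_ORDER.index)
    Kt, Ks = train.n_windows, test.n_windows
    tr_ok = train.trials["correct"].to_numpy() & ~train.trials["is_target"].to_numpy()
    te_ok = test.trials["correct"].to_numpy() & ~test.trials["is_target"].to_numpy()
    tr_cat = train.trials["category"].to_numpy()
    te_img = test.trials["image"].to_numpy()
    te_cat = test.trials["category"].to_numpy()

    per_image: dict[str, np.ndarray] = {}
    for held_out in categories:
        tr_mask = tr_ok & (tr_cat != held_out)
        y_train = _encode(tr_cat[tr_mask])
        X_train = _select(train, tr_mask)  # trials x channels x windows

        te_mask = te_ok & (te_cat == held_out)
        imgs = te_img[te_mask]
        targets = np.array(
            [
                -1
                if (c := neighbor_of(design, img, offset, mode)) is None
                else CANONICAL_ORDER.index(c)
                for img in imgs
            ]
        )
        valid = targets >= 0
        if not valid.any():
            continue
        X_test = _select(test, te_mask)[valid]
        imgs = imgs[valid]
        targets = targets[valid]
        n_te = X_test.shape[0]
        # Flatten test trials x windows once; each fitted window predicts all.
        X_test_flat = X_test.transpose(0, 2, 1).reshape(n_te * Ks, -1)

        hits = np.empty((n_te, Kt, Ks))
        for w in range(Kt):
            clf = train_classifier(
                X_train[:, :, w], [CANONICAL_ORDER[i] for i in y_train]
            )
            scores = X_test_flat @ clf.coef_.T + clf.intercept_
            pred = clf.classes_[np.argmax(scores, axis=1)].reshape(n_te, Ks)
            hits[:, w, :] = pred == targets[:, None]
        for img in np.unique(imgs):
            per_image[img] = hits[imgs == img].mean(axis=0)

    if not per_image:
        raise ValueError(f"no valid trials for offset {offset:+d}")
    values = np.mean(list(per_image.values()), axis=0)
    return GeneralizationMatrix(
        values=values,
        train_times=train.window_centers.copy(),
        test_times=test.window_centers.copy(),
        offset=offset,
        train_session=train_session,
        test_session=test_session,
        per_image=per_image,
    )


def group_decoding_test(
    matrices: list[GeneralizationMatrix] | np.ndarray,
    mu: float = CHANCE,
    tail: str = "greater",
    alpha_cluster: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster permutation test of participant matrices against chance.

    One-tailed by default: only above-chance neighbour decoding is
    meaningful. Delegates to the one-sample cluster test over the 2-D
    train x test grid.
    """
    if isinstance(matrices, np.ndarray):
        data = matrices
    else:
        data = np.stack([m.values for m in matrices])
    if data.shape[0] < 2:
        raise ValueError("at least 2 participants required")
    return cluster_permutation_1samp(
        data, mu=mu, tail=tail, alpha_cluster=alpha_cluster, n_perm=n_perm, seed=seed
    )
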