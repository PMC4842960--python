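"""Quantifying how faithfully one map preserves another's local structure.

The central statistic is a rank-based local-similarity score between two
maps X and Y of the same samples. With r^x_ij the rank of sample j's
distance to sample i in map X (nearest neighbor has rank 1), the score is

    s_{x,y}(kx, ky) = (1 / (n * min(kx, ky)))
                      * sum_i sum_{j != i} 1[r^x_ij <= kx and r^y_ij <= ky]

It lies in [0, 1] and equals 1 exactly when, for every sample, all kx
nearest neighbors in X are among the ky nearest in Y or vice versa; it is
symmetric under exchanging (X, kx) with (Y, ky).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

from .integrate import EmbeddingMap, IntegratedMatrix


@dataclass(frozen=True)
class NeighborRanks:
    """Per-row distance ranks of a map; entry (i, j) is r_ij, diagonal 0.

    Every off-diagonal row is a permutation of 1..n-1; distance ties are
    broken by ascending sample index so ranks are deterministic.
    """

    ranks: np.ndarray
    sample_ids: Optional[list] = None

    @property
    def n_samples(self) -> int:
        return self.ranks.shape[0]


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    kx: int
    ky: int
    n: int


@dataclass(frozen=True)
class NNLabelAUC:
    """Macro one-vs-rest AUC of the leave-one-out 1-NN label predictor."""

    value: float
    per_class: pd.Series
    construction: str


def _as_coords(x) -> tuple[np.ndarray, Optional[list]]:
    if isinstance(x, EmbeddingMap):
        return x.coordinates.to_numpy(dtype=float), list(x.coordinates.index)
    if isinstance(x, IntegratedMatrix):
        return x.values.to_numpy(dtype=float), list(x.values.index)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index)
    return np.asarray(x, dtype=float), None


def neighbor_ranks(coords) -> NeighborRanks:
    """Rank Euclidean distances per row; ties go to the lower sample index."""
    if isinstance(coords, NeighborRanks):
        return coords
    x, ids = _as_coords(coords)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to rank neighbors")
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    ranks = np.zeros((n, n), dtype=np.int64)
    np.put_along_axis(
        ranks,
        order[:, : n - 1],
        np.broadcast_to(np.arange(1, n), (n, n - 1)),
        axis=1,
    )
    return NeighborRanks(ranks=ranks, sample_ids=ids)


def local_similarity(
    x: Union[NeighborRanks, EmbeddingMap, pd.DataFrame, np.ndarray],
    y: Union[NeighborRanks, EmbeddingMap, pd.DataFrame, np.ndarray],
    kx: int,
    ky: int,
) -> SimilarityScore:
    """Min-normalized joint-neighborhood count between two maps (see module docs)."""
    rx = neighbor_ranks(x)
    ry = neighbor_ranks(y)
    n = rx.n_samples
    if ry.n_samples != n:
        raise ValueError("maps have different sample counts")
    if rx.sample_ids is not None and ry.sample_ids is not None:
        if rx.sample_ids != ry.sample_ids:
            raise ValueError("maps have mismatched sample sets/orders")
    if not (1 <= kx <= n - 1 and 1 <= ky <= n - 1):
        raise ValueError(f"kx and ky must lie in [1, n-1] = [1, {n - 1}]")
    joint = (rx.ranks >= 1) & (rx.ranks <= kx) & (ry.ranks >= 1) & (ry.ranks <= ky)
    value = joint.sum() / (n * min(kx, ky))
    return SimilarityScore(value=float(value), kx=kx, ky=ky, n=n)


def per_label_within_distance(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)]
    m = len(idx)
    return float(sub.sum() / (m * (m - 1)))


def tissue_cohesion_test(
    coords,
    labels: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.Series:
    """Permutation test: are within-label map distances smaller than random?

    Per label, the statistic is the mean pairwise distance among its
    samples; the null draws ``n_perm`` random same-size sample subsets.
    p = (1 + #{null <= observed}) / (1 + n_perm), so the minimal
    attainable p is 1/(1+n_perm). Labels with fewer than two samples are
    skipped with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x, ids = _as_coords(coords)
    labels = pd.Series(np.asarray(labels), index=ids if ids is not None else None)
    n = x.shape[0]
    if len(labels) != n:
        raise ValueError("labels length differs from sample count")
    d = cdist(x, x)
    rng = np.random.default_rng(seed)
    out = {}
    values = labels.to_numpy()
    for label in pd.unique(values):
        idx = np.flatnonzero(values == label)
        if len(idx) < 2:
            warnings.warn(f"label {label!r} has fewer than two samples; skipped")
            continue
        observed = per_label_within_distance(d, idx)
        m = len(idx)
        hits = 0
        for _ in range(n_perm):
            sub = rng.choice(n, size=m, replace=False)
            if per_label_within_distance(d, sub) <= observed:
                hits += 1
        out[label] = (1 + hits) / (1 + n_perm)
    return pd.Series(out, name="p_cohesion")


_AUC_CONSTRUCTION = (
    "macro one-vs-rest AUC; per class c the membership score of sample j is "
    "d(j, nearest non-c sample) - d(j, nearest c sample excluding j); "
    "positives are the samples labelled c; classes with a single sample "
    "contribute no positives and are skipped"
)


def nn_label_auc(coords, labels: Sequence) -> NNLabelAUC:
    """How well map neighborhoods predict sample labels (1-NN margin AUC).

    For each class, every sample gets a margin score: distance to its
    nearest neighbor outside the class minus distance to its nearest
    neighbor inside it (leave-one-out). The class AUC is the one-vs-rest
    ROC area of that score; the reported value is the macro average.
    """
    x, ids = _as_coords(coords)
    n = x.shape[0]
    values = np.asarray(labels)
    if len(values) != n:
        raise ValueError("labels length differs from sample count")
    classes = pd.unique(values)
    if len(classes) < 2:
        raise ValueError("need at least two distinct labels")
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    per_class = {}
    for c in classes:
        mask = values == c
        if mask.sum() == 0:
            continue
        d_in = d[:, mask].min(axis=1)
        d_out = d[:, ~mask].min(axis=1)
        score = d_out - d_in
        keep = np.isfinite(score)
        y = mask[keep].astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            continue
        per_class[c] = float(roc_auc_score(y, score[keep]))
    if not per_class:
        raise ValueError("no class admits a one-vs-rest curve")
    per_class = pd.Series(per_class, name="auc")
    return NNLabelAUC(
        value=float(per_class.mean()),
        per_class=per_class,
        construction=_AUC_CONSTRUCTION,
    )


def cophenetic_comparison(space, embedding, method: str = "ward") -> float:
    """Pearson correlation of cophenetic distances of two hierarchical trees.

    One tree is built on the high-dimensional representation, the other on
    the map; agreement of the dendrograms is the correlation of their
    cophenetic-distance vectors.
    """
    a, ids_a = _as_coords(space)
    b, ids_b = _as_coords(embedding)
    if a.shape[0] != b.shape[0]:
        raise ValueError("representations have different sample counts")
    if ids_a is not None and ids_b is not None and ids_a != ids_b:
        raise ValueError("representations have mismatched sample sets")
    if a.shape[0] < 3:
        raise ValueError("need at least three samples for a dendrogram")
    coph_a = cophenet(linkage(a, method=method))
    coph_b = cophenet(linkage(b, method=method))
    return float(pearsonr(coph_a, coph_b)[0])
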