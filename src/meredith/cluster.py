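"""Density clustering of a map, cluster-label enrichment, and COP detection.

Clusters are found with DBSCAN. The density radius eps is selected by
maximizing the silhouette score over a grid, under the constraint that at
most a configured fraction of samples (default 10%) is left non-clustering
(noise). A Davies-Bouldin score is reported alongside as a diagnostic.

Cluster-label association uses the upper-tail hypergeometric test. A
sample whose own tissue-of-origin is not among its cluster's significantly
enriched labels is a COP (cancer outside primary): COP-I when the cluster
is enriched for some other tissue, COP-II candidate when the cluster has
no enriched tissue at all. Noise samples are COPs by definition and are
attached to the nearest cluster centroid for the type-I/II decision.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import hypergeom
from sklearn.cluster import DBSCAN
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .integrate import MeredithConfig, run_meredith
from .mapeval import _as_coords
from .omics_io import MultiOmicsCohort

#: Label assigned to non-clustering samples.
NOISE = -1


class COPType(str, enum.Enum):
    NONE = "NONE"
    COP_I = "COP_I"
    COP_II = "COP_II"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClusterAssignment:
    """DBSCAN labels (noise = -1) plus the quality statistics of the fit.

    ``silhouette`` and ``davies_bouldin`` are computed on the clustered
    (non-noise) samples only and are NaN when fewer than two clusters exist.
    """

    labels: pd.Series
    eps: float
    min_samples: int
    silhouette: float
    davies_bouldin: float
    noise_fraction: float

    @property
    def n_clusters(self) -> int:
        return int((pd.unique(self.labels) != NOISE).sum())

    def cluster_ids(self) -> list[int]:
        return sorted(c for c in pd.unique(self.labels) if c != NOISE)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric cluster-vs-label over-representation table."""

    table: pd.DataFrame
    alpha: float

    def enriched_labels(self, cluster) -> set:
        t = self.table
        rows = t[(t["cluster"] == cluster) & t["significant"]]
        return set(rows["label"])


@dataclass(frozen=True)
class COP2Dissection:
    assignment: "ClusterAssignment"
    enrichment: "EnrichmentResult"
    confirmed_cop2: list


def dbscan_cluster(coords, eps: float, min_samples: int = 5) -> ClusterAssignment:
    """Density-reachability clustering; records silhouette, DB and noise stats."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    x, ids = _as_coords(coords)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(x)
    mask = labels != NOISE
    n_clusters = len(set(labels[mask]))
    sil = db = float("nan")
    if n_clusters >= 2 and mask.sum() > n_clusters:
        sil = float(silhouette_score(x[mask], labels[mask]))
        db = float(davies_bouldin_score(x[mask], labels[mask]))
    return ClusterAssignment(
        labels=pd.Series(labels, index=ids, name="cluster"),
        eps=float(eps),
        min_samples=min_samples,
        silhouette=sil,
        davies_bouldin=db,
        noise_fraction=float(1.0 - mask.mean()),
    )


def default_eps_grid(coords, size: int = 50) -> np.ndarray:
    """Log-spaced grid between the 1st and 50th percentile of pairwise distances."""
    x, _ = _as_coords(coords)
    d = pdist(x)
    lo, hi = np.percentile(d[d > 0], [1, 50])
    if lo <= 0:
        lo = hi / 1e3
    return np.geomspace(lo, hi, size)


def select_eps(
    coords,
    eps_grid: Optional[Sequence[float]] = None,
    min_samples: int = 5,
    max_noise: float = 0.10,
) -> float:
    """Silhouette-maximizing eps under the non-clustering cap.

    Admissible grid values must yield at least two clusters and a noise
    fraction no larger than ``max_noise``; among them the one with the
    highest silhouette (on clustered samples) wins, ties going to the
    smaller eps. When no value is admissible the best diagnostic triple
    is reported in the error.
    """
    if eps_grid is None:
        eps_grid = default_eps_grid(coords)
    eps_grid = sorted(float(e) for e in eps_grid)
    if not eps_grid:
        raise ValueError("eps grid is empty")
    best: Optional[tuple[float, float]] = None  # (silhouette, eps)
    diagnostic: Optional[tuple[float, float, float]] = None
    for eps in eps_grid:
        a = dbscan_cluster(coords, eps=eps, min_samples=min_samples)
        if diagnostic is None or (
            np.nan_to_num(a.silhouette, nan=-2.0)
            > np.nan_to_num(diagnostic[2], nan=-2.0)
        ):
            diagnostic = (eps, a.noise_fraction, a.silhouette)
        if a.n_clusters < 2 or a.noise_fraction > max_noise or np.isnan(a.silhouette):
            continue
        if best is None or a.silhouette > best[0]:
            best = (a.silhouette, eps)
    if best is None:
        raise ValueError(
            "no admissible eps: every grid value violates the >=2-cluster or "
            f"noise<= {max_noise:.0%} constraint; best diagnostic "
            f"(eps, noise, silhouette) = {diagnostic}"
        )
    return best[1]


def hypergeom_upper_tail(overlap: int, cohort: int, label_total: int, cluster: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(cohort, label_total, cluster)."""
    return float(hypergeom.sf(overlap - 1, cohort, label_total, cluster))


def enrich_clusters(
    assignment,
    labels: Sequence,
    alpha: float = 0.001,
) -> EnrichmentResult:
    """Hypergeometric over-representation of every label in every cluster.

    ``assignment`` may be a :class:`ClusterAssignment` or a per-sample
    series of group labels (noise = -1 is never treated as a cluster).
    """
    cluster_labels = assignment.labels if isinstance(assignment, ClusterAssignment) else pd.Series(assignment)
    labels = pd.Series(np.asarray(labels), index=cluster_labels.index)
    n = len(cluster_labels)
    rows = []
    label_totals = labels.value_counts()
    for c in sorted(x for x in pd.unique(cluster_labels) if x != NOISE):
        members = labels[cluster_labels == c]
        size = len(members)
        counts = members.value_counts()
        for lab, total in label_totals.items():
            overlap = int(counts.get(lab, 0))
            p = hypergeom_upper_tail(overlap, n, int(total), size)
            rows.append(
                {
                    "cluster": c,
                    "label": lab,
                    "overlap": overlap,
                    "cluster_size": size,
                    "label_total": int(total),
                    "cohort_size": n,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return EnrichmentResult(table=pd.DataFrame(rows), alpha=alpha)


def detect_cops(
    assignment: ClusterAssignment,
    enrichment: EnrichmentResult,
    labels: Sequence,
    coords=None,
) -> pd.DataFrame:
    """Call out-of-tissue samples (COPs) from cluster enrichment.

    A clustered sample is a COP iff its own tissue label is not among its
    cluster's significantly enriched labels. Noise samples are COPs by
    definition; they are assigned to the nearest cluster centroid to
    decide the subtype. COP-I: the assigned cluster is enriched for some
    tissue (necessarily a different one for clustered samples); COP-II
    candidate: the assigned cluster has no enriched tissue.
    """
    labels = pd.Series(np.asarray(labels), index=assignment.labels.index)
    clusters = assignment.cluster_ids()
    enriched = {c: enrichment.enriched_labels(c) for c in clusters}
    centroids = None
    has_noise = (assignment.labels == NOISE).any()
    if has_noise:
        if coords is None:
            raise ValueError("coords required to attach noise samples to clusters")
        x, ids = _as_coords(coords)
        pos = pd.DataFrame(x, index=ids if ids is not None else assignment.labels.index)
        if not clusters:
            raise ValueError("no clusters to attach noise samples to")
        centroids = np.vstack(
            [pos[(assignment.labels == c).to_numpy()].mean(axis=0) for c in clusters]
        )
    rows = []
    for sample, c in assignment.labels.items():
        own = labels.loc[sample]
        if c == NOISE:
            xi = pos.loc[[sample]].to_numpy()
            assigned = clusters[int(np.argmin(cdist(xi, centroids)))]
            cop = COPType.COP_I if enriched[assigned] else COPType.COP_II
        else:
            assigned = c
            if own in enriched[c]:
                cop = COPType.NONE
            elif enriched[c]:
                cop = COPType.COP_I
            else:
                cop = COPType.COP_II
        rows.append(
            {
                "sample_id": sample,
                "tissue": own,
                "cluster": c,
                "assigned_cluster": assigned,
                "enriched_labels": ";".join(sorted(map(str, enriched[assigned]))),
                "cop_type": str(cop),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def dissect_cop2(
    cohort: MultiOmicsCohort,
    cop_sample_ids: Sequence,
    config: Optional[MeredithConfig] = None,
    min_samples: int = 5,
    max_noise: float = 0.10,
    alpha: float = 0.001,
    min_cops: int = 10,
    tissue_column: str = "tissue",
) -> Optional[COP2Dissection]:
    """Re-run the full pipeline on the COP samples in isolation.

    COP clusters with no single enriched tissue are confirmed COP-II
    groups. Skipped (returns None, with a warning) when fewer than
    ``min_cops`` COPs exist. The retained-component count is clamped to
    the rank bound of the COP subset.
    """
    cop_sample_ids = list(cop_sample_ids)
    if len(cop_sample_ids) < min_cops:
        warnings.warn(
            f"only {len(cop_sample_ids)} COP samples (< {min_cops}); "
            "dissection skipped, calls left unchanged"
        )
        return None
    sub = cohort.subset(cop_sample_ids)
    config = config or MeredithConfig()
    bound = min(
        sub.n_samples - 1,
        min(ds.n_features for ds in sub.datasets.values()),
    )
    if config.n_pcs > bound:
        config = MeredithConfig(
            n_pcs=bound,
            retain_variance=config.retain_variance,
            dims=config.dims,
            n_restarts=config.n_restarts,
            perplexity=config.perplexity,
            seed=config.seed,
            max_iter=config.max_iter,
        )
    emap = run_meredith(sub, config=config)
    try:
        eps = select_eps(emap, min_samples=min_samples, max_noise=max_noise)
    except ValueError:
        # the COPs may share one signature and form a single cluster; fall
        # back to an eps spanning the whole map so enrichment can still run
        x, _ = _as_coords(emap)
        eps = float(pdist(x).max()) * 1.01
    assignment = dbscan_cluster(emap, eps=eps, min_samples=min_samples)
    tissues = sub.clinical[tissue_column]
    enrichment = enrich_clusters(assignment, tissues, alpha=alpha)
    confirmed = []
    for c in assignment.cluster_ids():
        if not enrichment.enriched_labels(c):
            confirmed.extend(assignment.labels.index[assignment.labels == c])
    return COP2Dissection(
        assignment=assignment, enrichment=enrichment, confirmed_cop2=confirmed
    )
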