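"""Per-sample contribution of data-type combinations to local map structure.

For four data types there are 14 proper non-empty combinations. Each is
embedded into its own map and, per sample, the percentage overlap of its
k(=20)-nearest neighborhoods with those of the full-combination map is
recorded. Ward-clustering the resulting samples x combinations overlap
matrix groups samples into "genomic profiles" - sets of samples whose
local neighborhoods are driven by the same (combinations of) data types.
A companion stability analysis re-embeds the full combination from many
random restarts and flags samples whose neighborhoods are not reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .cluster import EnrichmentResult, enrich_clusters
from .integrate import EmbeddingMap, MeredithConfig, run_meredith
from .mapeval import neighbor_ranks
from .omics_io import CANONICAL_ORDER, DataType, MultiOmicsCohort


def combination_name(combo: Sequence[DataType]) -> str:
    return "+".join(dt.value.lower() for dt in combo)


def enumerate_combinations(
    types: Sequence[DataType] = CANONICAL_ORDER,
) -> list[tuple[DataType, ...]]:
    """All proper non-empty subsets of the data types, canonically ordered.

    Singletons first, then pairs, then triples (and so on), ordered within
    each size by the canonical data-type order GE, ME, CN, MIR.
    """
    types = [DataType(t) for t in types]
    if len(set(types)) != len(types):
        raise ValueError("duplicate data types")
    if len(types) < 2:
        raise ValueError("need at least two data types")
    ordered = [dt for dt in CANONICAL_ORDER if dt in types]
    out: list[tuple[DataType, ...]] = []
    for size in range(1, len(ordered)):
        out.extend(itertools.combinations(ordered, size))
    return out


@dataclass(frozen=True)
class OverlapProfile:
    """Samples x combinations k-NN overlap percentages, plus profile labels.

    ``matrix`` holds, per sample and combination map, the percentage of
    that sample's k nearest neighbors shared with the full-combination
    reference map (values in [0, 100]).
    """

    matrix: pd.DataFrame
    combinations: tuple[tuple[DataType, ...], ...]
    k: int
    profile_labels: Optional[pd.Series] = None
    maps: Optional[dict] = None
    reference: Optional[EmbeddingMap] = None


@dataclass(frozen=True)
class StabilityReport:
    """Per-sample mean k-NN overlap with the reference map across reruns."""

    mean_overlap: pd.Series
    consistent: pd.Series
    n_runs: int
    k: int
    threshold: float

    @property
    def average_overlap(self) -> float:
        return float(self.mean_overlap.mean())


def per_sample_overlap(map_a, map_b, k: int = 20) -> pd.Series:
    """Percentage of shared k-nearest neighbors per sample between two maps."""
    ra = neighbor_ranks(map_a)
    rb = neighbor_ranks(map_b)
    n = ra.n_samples
    if rb.n_samples != n:
        raise ValueError("maps have different sample counts")
    if ra.sample_ids is not None and rb.sample_ids is not None:
        if ra.sample_ids != rb.sample_ids:
            raise ValueError("maps have mismatched sample sets/orders")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, n-1] = [1, {n - 1}]")
    in_a = (ra.ranks >= 1) & (ra.ranks <= k)
    in_b = (rb.ranks >= 1) & (rb.ranks <= k)
    overlap = 100.0 * (in_a & in_b).sum(axis=1) / k
    index = ra.sample_ids if ra.sample_ids is not None else pd.RangeIndex(n)
    return pd.Series(overlap, index=index, name=f"overlap_k{k}")


def combination_overlaps(
    cohort: MultiOmicsCohort,
    config: Optional[MeredithConfig] = None,
    k: int = 20,
    reference: Optional[EmbeddingMap] = None,
    keep_maps: bool = True,
) -> OverlapProfile:
    """Embed every proper combination and score its overlap with the full map.

    Every combination map uses the same restart budget and perplexity as
    the full map, with its own deterministic seed fan-out, so the
    comparison is like-for-like.
    """
    config = config or MeredithConfig()
    types = [dt for dt in CANONICAL_ORDER if dt in cohort.datasets]
    combos = tuple(enumerate_combinations(types))
    if reference is None:
        reference = run_meredith(cohort, None, config)
    columns = {}
    maps = {}
    for i, combo in enumerate(combos):
        combo_config = replace(config, seed=config.seed + config.n_restarts * (i + 1))
        emap = run_meredith(cohort, combo, combo_config)
        columns[combination_name(combo)] = per_sample_overlap(emap, reference, k=k)
        if keep_maps:
            maps[combination_name(combo)] = emap
    matrix = pd.DataFrame(columns)
    return OverlapProfile(
        matrix=matrix,
        combinations=combos,
        k=k,
        maps=maps if keep_maps else None,
        reference=reference,
    )


def profile_clusters(op: OverlapProfile, n_profiles: int | str = 5) -> OverlapProfile:
    """Ward-cluster the overlap matrix into flat genomic profiles.

    ``n_profiles`` may be an integer cut or ``"silhouette"`` to pick the
    cut (2..10) with the best silhouette on the overlap matrix.
    """
    x = op.matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("overlap matrix must be complete")
    n = x.shape[0]
    z = linkage(x, method="ward", metric="euclidean")
    if n_profiles == "silhouette":
        best = None
        for m in range(2, min(10, n - 1) + 1):
            lab = fcluster(z, t=m, criterion="maxclust")
            if len(set(lab)) < 2:
                continue
            s = silhouette_score(x, lab)
            if best is None or s > best[0]:
                best = (s, lab)
        if best is None:
            raise ValueError("no admissible silhouette cut")
        labels = best[1]
    else:
        if not 1 <= int(n_profiles) <= n:
            raise ValueError(f"n_profiles must lie in [1, {n}]")
        labels = fcluster(z, t=int(n_profiles), criterion="maxclust")
    return replace(
        op, profile_labels=pd.Series(labels, index=op.matrix.index, name="profile")
    )


def stability(
    cohort: MultiOmicsCohort,
    config: Optional[MeredithConfig] = None,
    n_runs: int = 100,
    k: int = 20,
    threshold: float = 20.0,
    reference: Optional[EmbeddingMap] = None,
    seeds: Optional[Sequence[int]] = None,
) -> StabilityReport:
    """Neighborhood reproducibility across random single-restart re-embeddings.

    Each rerun embeds the full combination once from seed ``config.seed +
    run`` (or explicit ``seeds``); the report records each sample's mean
    k-NN overlap with the reference map and flags samples below
    ``threshold`` percent as inconsistent.
    """
    if n_runs < 2 and seeds is None:
        raise ValueError("n_runs must be >= 2")
    config = config or MeredithConfig()
    if reference is None:
        reference = run_meredith(cohort, None, config)
    if seeds is None:
        seeds = [config.seed + i + 1 for i in range(n_runs)]
    overlaps = []
    for s in seeds:
        rerun_config = replace(config, seed=int(s), n_restarts=1)
        emap = run_meredith(cohort, None, rerun_config)
        overlaps.append(per_sample_overlap(emap, reference, k=k))
    mean_overlap = pd.concat(overlaps, axis=1).mean(axis=1)
    mean_overlap.name = f"mean_overlap_k{k}"
    consistent = mean_overlap >= threshold
    consistent.name = "consistent"
    return StabilityReport(
        mean_overlap=mean_overlap,
        consistent=consistent,
        n_runs=len(list(seeds)),
        k=k,
        threshold=threshold,
    )


def profile_enrichment(
    op: OverlapProfile,
    labels: Sequence,
    alpha: float = 0.001,
) -> EnrichmentResult:
    """Hypergeometric enrichment of each label within each genomic profile."""
    if op.profile_labels is None:
        raise ValueError("profiles not assigned; run profile_clusters first")
    return enrich_clusters(op.profile_labels, labels, alpha=alpha)
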