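"""The integration core: per-type PCA, variance balancing, concatenation, t-SNE.

Each normalized data type is reduced to its top principal components
(default 50), every block is rescaled so its retained components carry a
total variance of exactly 1 (no single data type can dominate), the
blocks are concatenated in canonical order (GE, ME, CN, MIR), and the
concatenated space is embedded into 2D with Barnes-Hut t-SNE. Because
the embedding is stochastic, it is run from several random restarts and
the solution with the lowest final Kullback-Leibler divergence is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .omics_io import CANONICAL_ORDER, DataType, MultiOmicsCohort, OmicsDataset


@dataclass(frozen=True)
class ReducedBlock:
    """Principal-component scores of one data type.

    ``eigenvalues`` are the component variances (sample variance of each
    score column, ddof=1), in decreasing order. ``scale_factor`` is the
    positive factor already applied to the scores; ``None`` until
    :func:`scale_block` has run.
    """

    data_type: DataType
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    scale_factor: Optional[float] = None

    @property
    def scaled(self) -> bool:
        return self.scale_factor is not None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class IntegratedMatrix:
    """Concatenated, variance-balanced PC scores of several data types."""

    values: pd.DataFrame
    block_spans: dict[DataType, tuple[int, int]]
    combination: tuple[DataType, ...]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_dimensions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EmbeddingMap:
    """Low-dimensional sample coordinates for one data-type combination.

    ``kl_divergence`` is the final t-SNE objective of the restart that was
    kept (the minimum across all restarts run); ``seed`` is that restart's
    seed. Coordinate axes carry no meaning: only neighborhoods do.
    """

    combination: tuple[DataType, ...]
    coordinates: pd.DataFrame
    kl_divergence: float
    seed: int
    perplexity: float
    n_restarts: int = 1

    @property
    def sample_ids(self) -> list:
        return list(self.coordinates.index)

    @property
    def n_samples(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class MeredithConfig:
    """Tunable parameters of the integration pipeline.

    n_pcs: components retained per data type (ignored when
        ``retain_variance`` is set).
    retain_variance: alternative retention rule - keep the smallest number
        of components whose cumulative explained-variance fraction reaches
        this value (e.g. 0.95).
    n_restarts: t-SNE restarts; the lowest-KL solution is kept. Large
        pan-cancer maps are worth a budget of ~1000 restarts; the default
        here is a practical 10.
    perplexity: t-SNE perplexity; ``None`` means 30, or n/10 for cohorts
        under 100 samples.
    """

    n_pcs: int = 50
    retain_variance: Optional[float] = None
    dims: int = 2
    n_restarts: int = 10
    perplexity: Optional[float] = None
    seed: int = 0
    max_iter: int = 1000


def reduce_block(
    ds: OmicsDataset,
    n_components: int = 50,
    retain_variance: Optional[float] = None,
) -> ReducedBlock:
    """Project one normalized dataset onto its top principal axes.

    ``retain_variance``, when given, overrides ``n_components`` with the
    smallest count whose cumulative explained-variance fraction reaches it.
    """
    x = ds.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"{ds.data_type}: matrix contains missing values; impute first")
    n, p = x.shape
    max_rank = min(n - 1, p)
    if retain_variance is not None:
        if not 0.0 < retain_variance <= 1.0:
            raise ValueError("retain_variance must be in (0, 1]")
        full = PCA(n_components=max_rank, svd_solver="full").fit(x)
        frac = np.cumsum(full.explained_variance_ratio_)
        n_components = int(np.searchsorted(frac, retain_variance - 1e-12) + 1)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"{ds.data_type}: n_components={n_components} exceeds the rank bound; "
            f"admissible maximum is min(samples-1, features) = {max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(x)
    cols = [f"{ds.data_type}_PC{i + 1}" for i in range(n_components)]
    return ReducedBlock(
        data_type=ds.data_type,
        scores=pd.DataFrame(scores, index=ds.values.index, columns=cols),
        eigenvalues=pca.explained_variance_.copy(),
    )


def scale_block(block: ReducedBlock) -> ReducedBlock:
    """Divide scores by sqrt(total retained variance); block variance becomes 1."""
    total = float(block.eigenvalues.sum())
    if total <= 0.0:
        raise ValueError(f"{block.data_type}: zero total variance; cannot scale")
    factor = 1.0 / np.sqrt(total)
    return replace(
        block,
        scores=block.scores * factor,
        eigenvalues=block.eigenvalues * factor**2,
        scale_factor=factor,
    )


def concatenate(blocks: Sequence[ReducedBlock]) -> IntegratedMatrix:
    """Append scaled blocks column-wise in canonical data-type order."""
    if not blocks:
        raise ValueError("no blocks to concatenate")
    seen: dict[DataType, ReducedBlock] = {}
    for b in blocks:
        if not b.scaled:
            raise ValueError(f"{b.data_type}: block must be scaled before concatenation")
        if b.data_type in seen:
            raise ValueError(f"two blocks share the data type {b.data_type}")
        seen[b.data_type] = b
    ordered = [seen[dt] for dt in CANONICAL_ORDER if dt in seen]
    index = ordered[0].scores.index
    for b in ordered[1:]:
        if not b.scores.index.equals(index):
            raise ValueError(
                f"{b.data_type}: sample set/order differs from {ordered[0].data_type}"
            )
    spans: dict[DataType, tuple[int, int]] = {}
    start = 0
    for b in ordered:
        spans[b.data_type] = (start, start + b.n_components)
        start += b.n_components
    values = pd.concat([b.scores for b in ordered], axis=1)
    return IntegratedMatrix(
        values=values,
        block_spans=spans,
        combination=tuple(b.data_type for b in ordered),
    )


def default_perplexity(n_samples: int) -> float:
    return 30.0 if n_samples >= 100 else n_samples / 10.0


def embed(
    matrix,
    dims: int = 2,
    n_restarts: int = 1,
    perplexity: Optional[float] = None,
    seed: int = 0,
    max_iter: int = 1000,
) -> EmbeddingMap:
    """Barnes-Hut t-SNE with deterministic restart fan-out.

    Runs ``n_restarts`` embeddings seeded ``seed, seed+1, ...`` and keeps
    the one with the lowest final KL divergence. ``matrix`` may be an
    :class:`IntegratedMatrix`, a DataFrame, or an array.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    combination: tuple[DataType, ...] = ()
    if isinstance(matrix, IntegratedMatrix):
        combination = matrix.combination
        values = matrix.values
    elif isinstance(matrix, pd.DataFrame):
        values = matrix
    else:
        arr = np.asarray(matrix, dtype=float)
        values = pd.DataFrame(arr, index=pd.RangeIndex(arr.shape[0]))
    n = values.shape[0]
    if perplexity is None:
        perplexity = default_perplexity(n)
    if not 0 < perplexity < n / 3:
        raise ValueError(
            f"perplexity={perplexity} too large for {n} samples (must be < n/3)"
        )
    x = values.to_numpy(dtype=float)
    method = "barnes_hut" if dims <= 3 else "exact"
    best: Optional[tuple[float, int, np.ndarray]] = None
    for i in range(n_restarts):
        tsne = TSNE(
            n_components=dims,
            perplexity=perplexity,
            init="random",
            random_state=seed + i,
            method=method,
            max_iter=max_iter,
        )
        coords = tsne.fit_transform(x)
        kl = float(tsne.kl_divergence_)
        if best is None or kl < best[0]:
            best = (kl, seed + i, coords)
    kl, best_seed, coords = best
    cols = [f"t{i + 1}" for i in range(dims)]
    return EmbeddingMap(
        combination=combination,
        coordinates=pd.DataFrame(coords, index=values.index, columns=cols),
        kl_divergence=kl,
        seed=best_seed,
        perplexity=float(perplexity),
        n_restarts=n_restarts,
    )


def integrate_cohort(
    cohort: MultiOmicsCohort,
    combination: Optional[Sequence[DataType]] = None,
    n_pcs: int = 50,
    retain_variance: Optional[float] = None,
) -> IntegratedMatrix:
    """Reduce, scale and concatenate the requested data types of a cohort."""
    if combination is None:
        combination = [dt for dt in CANONICAL_ORDER if dt in cohort.datasets]
    combination = [DataType(dt) for dt in combination]
    if not combination:
        raise ValueError("combination must name at least one data type")
    missing = [dt for dt in combination if dt not in cohort.datasets]
    if missing:
        raise ValueError(f"data types not present in cohort: {missing}")
    blocks = []
    for dt in combination:
        try:
            block = reduce_block(cohort.datasets[dt], n_pcs, retain_variance)
            blocks.append(scale_block(block))
        except ValueError as exc:
            raise ValueError(f"[reduce/scale {dt}] {exc}") from exc
    try:
        return concatenate(blocks)
    except ValueError as exc:
        raise ValueError(f"[concatenate] {exc}") from exc


def run_meredith(
    cohort: MultiOmicsCohort,
    combination: Optional[Sequence[DataType]] = None,
    config: Optional[MeredithConfig] = None,
) -> EmbeddingMap:
    """Full integration pipeline for one data-type combination.

    Composes per-type PCA reduction, variance-balancing scaling,
    concatenation and lowest-KL multi-restart t-SNE. The requested
    combination is recorded on the returned map.
    """
    config = config or MeredithConfig()
    matrix = integrate_cohort(
        cohort,
        combination,
        n_pcs=config.n_pcs,
        retain_variance=config.retain_variance,
    )
    try:
        return embed(
            matrix,
            dims=config.dims,
            n_restarts=config.n_restarts,
            perplexity=config.perplexity,
            seed=config.seed,
            max_iter=config.max_iter,
        )
    except ValueError as exc:
        raise ValueError(f"[embed] {exc}") from exc
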