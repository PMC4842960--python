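"""Loading, normalization, filtering and alignment of the four molecular data types.

Supported data types and their normalization protocols:

GE   gene expression (RSEM): log2(x + 1), then zero-mean per gene.
ME   DNA methylation (beta values in [0, 1]): optional probe-to-gene
     collapsing (mean beta within a window around the TSS), per-sample
     quantile normalization, zero-mean per gene, and removal of the top
     principal components of the centered matrix (technical variation).
CN   per-gene copy number: log2(x / 2) (diploid maps to 0), then
     zero-mean per gene.
MIR  microRNA expression (RPM): log2(x + 1), then zero-mean per gene.

All types additionally go through sex-chromosome removal (to avoid
sex-driven grouping) and K-nearest-neighbor imputation of scattered
missing values; features missing in every sample are dropped.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.impute import KNNImputer


class DataType(str, enum.Enum):
    """The four molecular data types handled by the pipeline."""

    GE = "GE"
    ME = "ME"
    CN = "CN"
    MIR = "MIR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical data-type order used everywhere a deterministic order is needed
#: (block concatenation, combination enumeration, file conventions).
CANONICAL_ORDER: tuple[DataType, ...] = (
    DataType.GE,
    DataType.ME,
    DataType.CN,
    DataType.MIR,
)

_SEX_CHROMOSOMES = {"X", "Y"}

#: Header token that marks a matrix file as sample-per-row. Any other
#: first-column header (e.g. ``gene_id``) means feature-per-row and the
#: table is transposed on load.
SAMPLE_ROW_HEADER = "sample_id"


def _check_unique(ids: Sequence, kind: str) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} ID: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class OmicsDataset:
    """One data type's samples x genes matrix plus its normalization state.

    ``values`` is indexed by sample ID (rows) and gene symbol (columns).
    ``stages`` records the normalization stages already applied, in order.
    """

    data_type: DataType
    values: pd.DataFrame
    chromosomes: Optional[Mapping[str, str]] = None
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "sample")
        _check_unique(list(self.values.columns), "feature")
        if self.data_type is DataType.ME and not self.stages:
            arr = self.values.to_numpy(dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError(
                    "un-normalized ME values must be beta fractions in [0, 1]"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, stage: Optional[str] = None) -> "OmicsDataset":
        stages = self.stages + (stage,) if stage else self.stages
        chrom = self.chromosomes
        if chrom is not None:
            chrom = {g: chrom[g] for g in values.columns if g in chrom}
        return replace(self, values=values, chromosomes=chrom, stages=stages)


@dataclass(frozen=True)
class MultiOmicsCohort:
    """Same-sample collection of datasets plus the clinical table.

    Every dataset shares one identically ordered sample set, and every
    sample has a clinical row (tissue label, sex, age, survival).
    """

    datasets: Mapping[DataType, OmicsDataset]
    clinical: pd.DataFrame
    dropped: Mapping[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = None
        for dt, ds in self.datasets.items():
            if ids is None:
                ids = ds.sample_ids
            elif ds.sample_ids != ids:
                raise ValueError(f"dataset {dt} sample order differs from the cohort")
        if ids is not None and list(self.clinical.index) != ids:
            raise ValueError("clinical table sample order differs from the datasets")

    @property
    def sample_ids(self) -> list:
        return list(self.clinical.index)

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    def subset(self, sample_ids: Sequence) -> "MultiOmicsCohort":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.clinical.index]
        if missing:
            raise ValueError(f"samples not in cohort: {missing[:5]}")
        datasets = {
            dt: replace(ds, values=ds.values.loc[ids])
            for dt, ds in self.datasets.items()
        }
        return MultiOmicsCohort(datasets=datasets, clinical=self.clinical.loc[ids])


def load_matrix(path, data_type: DataType, sep: str = "\t") -> OmicsDataset:
    """Read a delimited samples-x-genes (or genes-x-samples) matrix.

    Orientation is auto-detected from the header: a first column named
    ``sample_id`` means one row per sample; any other header (for example
    ``gene_id``) means one row per feature and the table is transposed.
    Empty cells and ``NA`` become missing values.  Non-rectangular tables
    and duplicated IDs are rejected with the offending row/ID named.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows) < 2:
        raise ValueError(f"{path}: empty or header-only table")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: non-rectangular table; row {i + 1} has {len(row)} "
                f"fields, expected {width}"
            )
    header, body = rows[0], rows[1:]
    index = [r[0] for r in body]
    columns = header[1:]
    _check_unique(index, "row")
    _check_unique(columns, "column")
    data = [[_parse_cell(x) for x in r[1:]] for r in body]
    df = pd.DataFrame(data, index=index, columns=columns, dtype=float)
    if header[0].strip().lower() != SAMPLE_ROW_HEADER:
        df = df.T
    df.index.name = SAMPLE_ROW_HEADER
    _check_unique(list(df.index), "sample")
    _check_unique(list(df.columns), "feature")
    return OmicsDataset(data_type=DataType(data_type), values=df)


def _parse_cell(x: str) -> float:
    x = x.strip()
    if x == "" or x.upper() == "NA":
        return np.nan
    return float(x)


def _center_genes(values: pd.DataFrame) -> pd.DataFrame:
    return values - values.mean(axis=0)


def _require_nonnegative(values: pd.DataFrame, what: str) -> None:
    arr = values.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError(f"{what} values must be non-negative")


def normalize_ge(ds: OmicsDataset) -> OmicsDataset:
    """log2(x + 1) then zero-mean per gene (gene-expression protocol)."""
    if ds.data_type is not DataType.GE:
        raise ValueError(f"expected GE dataset, got {ds.data_type}")
    _require_nonnegative(ds.values, "GE")
    out = _center_genes(np.log2(ds.values + 1.0))
    return ds.with_values(out, stage="log2+center")


def normalize_mir(ds: OmicsDataset) -> OmicsDataset:
    """log2(x + 1) then zero-mean per gene (microRNA RPM protocol)."""
    if ds.data_type is not DataType.MIR:
        raise ValueError(f"expected MIR dataset, got {ds.data_type}")
    _require_nonnegative(ds.values, "MIR")
    out = _center_genes(np.log2(ds.values + 1.0))
    return ds.with_values(out, stage="log2+center")


def normalize_cn(ds: OmicsDataset) -> OmicsDataset:
    """log2(x / 2) then zero-mean per gene; diploid (2) maps to 0."""
    if ds.data_type is not DataType.CN:
        raise ValueError(f"expected CN dataset, got {ds.data_type}")
    arr = ds.values.to_numpy(dtype=float)
    if np.nanmin(arr) <= 0:
        raise ValueError("CN values must be strictly positive copy numbers")
    out = _center_genes(np.log2(ds.values / 2.0))
    return ds.with_values(out, stage="log2ratio+center")


def collapse_methylation(
    probe_values: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 1500,
) -> OmicsDataset:
    """Collapse probe-level beta values to gene level.

    Per gene, the value is the mean beta over probes whose TSS distance
    satisfies ``|distance| <= window`` (default 1,500 bp). Genes with no
    qualifying probe are absent from the result.

    ``annotation`` needs columns ``probe_id``, ``gene``, ``tss_distance``
    (signed base pairs); every probe in ``probe_values`` must be annotated.
    """
    ann = annotation[["probe_id", "gene", "tss_distance"]].copy()
    known = set(ann["probe_id"])
    unknown = [p for p in probe_values.columns if p not in known]
    if unknown:
        raise ValueError(f"probes without annotation: {unknown[:5]}")
    ann = ann[ann["probe_id"].isin(probe_values.columns)]
    ann = ann[ann["tss_distance"].abs() <= window]
    if ann.empty:
        raise ValueError(f"no probe within {window} bp of any TSS")
    cols = {}
    for gene, grp in ann.groupby("gene", sort=False):
        cols[gene] = probe_values[grp["probe_id"]].mean(axis=1)
    out = pd.DataFrame(cols, index=probe_values.index)
    return OmicsDataset(data_type=DataType.ME, values=out)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Map every sample (row) onto the mean-of-sorted-rows reference.

    Ties within a sample receive the average of the reference values at
    their tied rank positions (average ranks + linear interpolation).
    """
    arr = values.to_numpy(dtype=float)
    n, m = arr.shape
    reference = np.sort(arr, axis=1).mean(axis=0)
    ranks = np.apply_along_axis(rankdata, 1, arr)
    out = np.interp(ranks, np.arange(1, m + 1), reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_me(ds: OmicsDataset, remove_pcs: int = 1) -> OmicsDataset:
    """Quantile-normalize samples, center genes, strip top principal components.

    The removed-component step targets technical variation shared across
    many genes (e.g. array batch structure): the reconstruction from the
    top ``remove_pcs`` principal components of the centered matrix is
    subtracted. ``remove_pcs=0`` disables it. The matrix must be complete
    (run :func:`filter_and_impute` first).
    """
    if ds.data_type is not DataType.ME:
        raise ValueError(f"expected ME dataset, got {ds.data_type}")
    if remove_pcs < 0:
        raise ValueError("remove_pcs must be >= 0")
    if ds.n_samples < remove_pcs + 1:
        raise ValueError(
            f"need at least remove_pcs+1={remove_pcs + 1} samples, have {ds.n_samples}"
        )
    arr = ds.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("ME normalization requires a complete matrix; impute first")
    qn = quantile_normalize(ds.values)
    centered = _center_genes(qn)
    if remove_pcs == 0:
        return ds.with_values(centered, stage="quantile+center")
    x = centered.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    r = min(remove_pcs, s.size)
    residual = x - (u[:, :r] * s[:r]) @ vt[:r]
    out = pd.DataFrame(residual, index=ds.values.index, columns=ds.values.columns)
    return ds.with_values(out, stage=f"quantile+center+pc-{r}-removed")


def drop_sex_chromosomes(ds: OmicsDataset) -> OmicsDataset:
    """Remove features on chromosomes X and Y (avoids sex-driven grouping).

    Features without a chromosome annotation are kept with a warning.
    """
    if ds.chromosomes is None:
        raise ValueError("chromosome annotation required to drop sex chromosomes")

    def _norm(c) -> Optional[str]:
        if c is None:
            return None
        c = str(c).strip()
        if c.lower().startswith("chr"):
            c = c[3:]
        return c.upper()

    keep, unannotated = [], []
    for g in ds.values.columns:
        chrom = _norm(ds.chromosomes.get(g))
        if chrom is None:
            unannotated.append(g)
            keep.append(g)
        elif chrom not in _SEX_CHROMOSOMES:
            keep.append(g)
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} features have no chromosome annotation and "
            f"were kept (first: {unannotated[0]!r})"
        )
    if not keep:
        raise ValueError("all features lie on chromosome X or Y; nothing remains")
    if len(keep) == ds.n_features:
        return ds.with_values(ds.values, stage="sex-chrom-filtered")
    return ds.with_values(ds.values[keep], stage="sex-chrom-filtered")


def filter_and_impute(ds: OmicsDataset, k: int = 3) -> OmicsDataset:
    """Drop features missing in every sample; KNN-impute the rest.

    Each remaining missing cell becomes the mean of that feature over the
    ``k`` nearest samples, with nearness measured by Euclidean distance on
    the features observed in both samples, scaled by the fraction observed
    (nan-Euclidean, as in scikit-learn's KNNImputer).
    """
    arr = ds.values.to_numpy(dtype=float)
    all_missing_samples = ds.values.index[np.isnan(arr).all(axis=1)]
    if len(all_missing_samples):
        raise ValueError(f"sample with all values missing: {all_missing_samples[0]!r}")
    keep = ds.values.columns[~np.isnan(arr).all(axis=0)]
    values = ds.values[keep] if len(keep) < ds.n_features else ds.values
    if not np.isnan(values.to_numpy(dtype=float)).any():
        return ds.with_values(values, stage="filtered+imputed")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(values.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=values.index, columns=values.columns)
    return ds.with_values(out, stage="filtered+imputed")


def align_samples(
    datasets: Sequence[OmicsDataset],
    clinical: pd.DataFrame,
) -> MultiOmicsCohort:
    """Intersect sample sets across datasets and the clinical table.

    The shared samples keep the order they have in the first dataset; the
    same order is imposed everywhere. Dropped samples are reported on the
    returned cohort's ``dropped`` mapping.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to align")
    clin = clinical.copy()
    if "sample_id" in clin.columns:
        clin = clin.set_index("sample_id")
    _check_unique(list(clin.index), "clinical sample")
    shared = set(datasets[0].sample_ids)
    for ds in datasets[1:]:
        shared &= set(ds.sample_ids)
    shared &= set(clin.index)
    order = [s for s in datasets[0].sample_ids if s in shared]
    if not order:
        raise ValueError("no sample is shared by all datasets and the clinical table")
    dropped = {}
    for ds in datasets:
        gone = [s for s in ds.sample_ids if s not in shared]
        if gone:
            dropped[str(ds.data_type)] = gone
    gone = [s for s in clin.index if s not in shared]
    if gone:
        dropped["clinical"] = gone
    by_type: dict[DataType, OmicsDataset] = {}
    for ds in datasets:
        if ds.data_type in by_type:
            raise ValueError(f"two datasets share the data type {ds.data_type}")
        by_type[ds.data_type] = replace(ds, values=ds.values.loc[order])
    return MultiOmicsCohort(datasets=by_type, clinical=clin.loc[order], dropped=dropped)


def preprocess_dataset(
    ds: OmicsDataset,
    k: int = 3,
    remove_pcs: int = 1,
    drop_sex: bool = True,
) -> OmicsDataset:
    """Standard per-type preprocessing chain.

    Sex-chromosome filtering (when annotation is available), missing-value
    filtering + K=3 imputation, then the type-appropriate normalization.
    """
    if drop_sex and ds.chromosomes is not None:
        ds = drop_sex_chromosomes(ds)
    ds = filter_and_impute(ds, k=k)
    if ds.data_type is DataType.GE:
        return normalize_ge(ds)
    if ds.data_type is DataType.MIR:
        return normalize_mir(ds)
    if ds.data_type is DataType.CN:
        return normalize_cn(ds)
    return normalize_me(ds, remove_pcs=remove_pcs)


def preprocess_cohort(
    cohort: MultiOmicsCohort,
    k: int = 3,
    remove_pcs: int = 1,
    drop_sex: bool = True,
) -> MultiOmicsCohort:
    """Apply :func:`preprocess_dataset` to every dataset of a raw cohort."""
    datasets = {
        dt: preprocess_dataset(ds, k=k, remove_pcs=remove_pcs, drop_sex=drop_sex)
        for dt, ds in cohort.datasets.items()
    }
    return MultiOmicsCohort(datasets=datasets, clinical=cohort.clinical)
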