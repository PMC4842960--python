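"""Synthetic multi-omic cohorts with known ground truth.

The generator plants latent sample clusters whose between-cluster
separation lives only in a configurable subset of the four data types
(the cluster's "drivers"); non-driver types share a common center, so a
cluster is invisible to combinations made only of its non-driver types.
Values are emitted on each type's natural scale: gene and microRNA
expression as exponentiated Gaussians (non-negative, log2(x+1) recovers
the latent scale), methylation as logistic-squashed Gaussians in [0, 1],
and copy number as 2 * 2^(sigma * z) (positive, centered near diploid).
A fraction of features sits on the sex chromosomes with a sex-linked
shift, scattered cells are missing, optional out-of-tissue samples (COPs)
copy another cluster's latent signal in every data type while keeping
their source tissue label, and survival times are exponential per true
cluster with uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .omics_io import CANONICAL_ORDER, DataType, MultiOmicsCohort, OmicsDataset

#: Target index meaning "a novel latent signature shared by the planted
#: COPs but carried by no ordinary cluster" (yields COP-II candidates).
NOVEL_SIGNATURE = -1


@dataclass(frozen=True)
class SynthSpec:
    """Generative recipe for a cohort; defaults give three well-separated
    clusters of 50 samples driven by GE only, ME only, and all four types.

    effect_size is the between-cluster center spread in within-cluster
    standard-deviation units on the latent (log-like) scale; 0 plants no
    structure at all (null cohorts for calibration).
    """

    n_clusters: int = 3
    samples_per_cluster: int = 50
    n_features: Mapping[DataType, int] = field(
        default_factory=lambda: {
            DataType.GE: 400,
            DataType.ME: 300,
            DataType.CN: 300,
            DataType.MIR: 100,
        }
    )
    drivers: tuple[frozenset, ...] = (
        frozenset({DataType.GE}),
        frozenset({DataType.ME}),
        frozenset({DataType.GE, DataType.ME, DataType.CN, DataType.MIR}),
    )
    effect_size: float = 4.0
    missing_rate: float = 0.01
    sex_feature_fraction: float = 0.05
    sex_effect: float = 2.0
    cop_plan: tuple[tuple[int, int], ...] = ()
    event_rates: tuple[float, ...] = (0.0005, 0.001, 0.002)
    censor_window: float = 2000.0
    cn_sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1 or self.samples_per_cluster < 1:
            raise ValueError("need at least one cluster and one sample per cluster")
        if len(self.drivers) != self.n_clusters:
            raise ValueError("drivers must name one type subset per cluster")
        for d in self.drivers:
            if not d:
                raise ValueError("every cluster's driver subset must be non-empty")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.event_rates) != self.n_clusters:
            raise ValueError("event_rates must give one rate per cluster")
        if any(r <= 0 for r in self.event_rates):
            raise ValueError("event rates must be positive")
        n = self.n_clusters * self.samples_per_cluster
        if len(self.cop_plan) > n:
            raise ValueError("more planted COPs than samples")
        for src, tgt in self.cop_plan:
            if not 0 <= src < self.n_clusters:
                raise ValueError(f"COP source cluster {src} out of range")
            if tgt != NOVEL_SIGNATURE and not 0 <= tgt < self.n_clusters:
                raise ValueError(f"COP target cluster {tgt} out of range")
            if tgt == src:
                raise ValueError("COP target must differ from its source cluster")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, keyed by sample ID.

    ``cluster`` is the molecular cluster a sample actually carries (for a
    planted COP this is the target signature, NOVEL_SIGNATURE for the
    shared novel one); ``tissue`` labels follow the source cluster.
    """

    cluster: pd.Series
    is_cop: pd.Series
    cop_source: pd.Series
    drivers: tuple[frozenset, ...]


def generate_cohort(spec: SynthSpec) -> tuple[MultiOmicsCohort, GroundTruth]:
    """Draw a raw (un-normalized) cohort plus its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_clusters * spec.samples_per_cluster
    source_cluster = np.repeat(np.arange(spec.n_clusters), spec.samples_per_cluster)
    samples = [f"S{i:04d}" for i in range(n)]
    sex = rng.choice(["M", "F"], size=n)

    # choose COP samples: spread over the requested source clusters
    true_cluster = source_cluster.copy()
    is_cop = np.zeros(n, dtype=bool)
    cop_source = np.full(n, -9, dtype=int)
    used: set[int] = set()
    for src, tgt in spec.cop_plan:
        candidates = [i for i in np.flatnonzero(source_cluster == src) if i not in used]
        if not candidates:
            raise ValueError(f"cluster {src} has no free sample left to turn into a COP")
        i = int(rng.choice(candidates))
        used.add(i)
        is_cop[i] = True
        cop_source[i] = src
        true_cluster[i] = tgt

    datasets: dict[DataType, OmicsDataset] = {}
    for dt in CANONICAL_ORDER:
        f = int(spec.n_features[dt])
        centers = np.zeros((spec.n_clusters + 1, f))
        for c, drv in enumerate(spec.drivers):
            if dt in drv:
                centers[c] = spec.effect_size * rng.standard_normal(f)
        # the novel signature (row index -1) spans every data type
        centers[-1] = spec.effect_size * rng.standard_normal(f)
        z = centers[true_cluster] + rng.standard_normal((n, f))

        n_sex = int(round(spec.sex_feature_fraction * f))
        chroms: dict[str, str] = {}
        features = [f"{dt.value}_G{j:04d}" for j in range(f)]
        autosome = 1
        for j, name in enumerate(features):
            if j < n_sex:
                chroms[name] = "X" if j % 2 == 0 else "Y"
            else:
                chroms[name] = str(autosome)
                autosome = autosome % 22 + 1
        if n_sex:
            female = (sex == "F").astype(float)[:, None]
            x_cols = [j for j in range(n_sex) if j % 2 == 0]
            y_cols = [j for j in range(n_sex) if j % 2 == 1]
            if x_cols:
                z[:, x_cols] += spec.sex_effect * female
            if y_cols:
                z[:, y_cols] += spec.sex_effect * (1.0 - female)

        if dt in (DataType.GE, DataType.MIR):
            base = rng.normal(6.0 if dt is DataType.GE else 4.0, 2.0, size=f)
            values = np.exp2(z + base)
        elif dt is DataType.ME:
            base = rng.normal(0.0, 1.5, size=f)
            values = 1.0 / (1.0 + np.exp(-(z + base)))
        else:
            values = 2.0 * np.exp2(spec.cn_sigma * z)

        if spec.missing_rate > 0:
            mask = rng.random((n, f)) < spec.missing_rate
            values = values.astype(float)
            values[mask] = np.nan

        datasets[dt] = OmicsDataset(
            data_type=dt,
            values=pd.DataFrame(values, index=samples, columns=features),
            chromosomes=chroms,
        )

    rates = np.asarray(spec.event_rates, dtype=float)
    rate_of = rates[np.where(true_cluster == NOVEL_SIGNATURE, source_cluster, true_cluster)]
    latent_time = rng.exponential(1.0 / rate_of)
    censor = rng.uniform(0.0, spec.censor_window, size=n)
    os_days = np.minimum(latent_time, censor)
    os_event = (latent_time <= censor).astype(int)
    clinical = pd.DataFrame(
        {
            "tissue": [f"C{c + 1}" for c in source_cluster],
            "sex": sex,
            "age": np.clip(rng.normal(60.0, 10.0, size=n), 30.0, 90.0),
            "os_days": os_days,
            "os_event": os_event,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    cohort = MultiOmicsCohort(datasets=datasets, clinical=clinical)
    truth = GroundTruth(
        cluster=pd.Series(true_cluster, index=samples, name="cluster"),
        is_cop=pd.Series(is_cop, index=samples, name="is_cop"),
        cop_source=pd.Series(
            np.where(is_cop, cop_source, -9), index=samples, name="cop_source"
        ),
        drivers=spec.drivers,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# worked example: a deterministic toy used throughout the documentation


@dataclass(frozen=True)
class WorkedExample:
    map_x: pd.DataFrame
    map_y: pd.DataFrame
    labels: pd.Series
    similarity: float
    ranks_x: np.ndarray
    hypergeom_p: float
    survival: pd.DataFrame
    logrank_statistic: float
    logrank_p: float


def worked_example() -> WorkedExample:
    """An 8-sample, 2-map toy exercising every headline statistic.

    Two tight blobs of four samples; map Y swaps two samples between the
    blobs, so neighborhoods only partially agree. A 4-sample cluster
    containing all four label-A samples gives the minimal hypergeometric
    p of 1/C(8,4) = 1/70, and a 6-subject survival table illustrates the
    log-rank statistic. Pure function of constants: regenerates
    identically on every call.
    """
    from .cluster import hypergeom_upper_tail
    from .mapeval import local_similarity, neighbor_ranks

    samples = [f"P{i + 1}" for i in range(8)]
    map_x = pd.DataFrame(
        [
            [0.0, 0.0],
            [0.0, 1.0],
            [1.0, 0.0],
            [1.0, 1.0],
            [10.0, 10.0],
            [10.0, 11.0],
            [11.0, 10.0],
            [11.0, 11.0],
        ],
        index=samples,
        columns=["t1", "t2"],
    )
    map_y = map_x.copy()
    # swap P4 and P5 across the blobs in map Y
    map_y.loc["P4"], map_y.loc["P5"] = (
        map_x.loc["P5"].to_numpy().copy(),
        map_x.loc["P4"].to_numpy().copy(),
    )
    labels = pd.Series(["A"] * 4 + ["B"] * 4, index=samples, name="tissue")
    sim = local_similarity(map_x, map_y, kx=2, ky=2).value
    ranks_x = neighbor_ranks(map_x).ranks
    p_hyper = hypergeom_upper_tail(overlap=4, cohort=8, label_total=4, cluster=4)
    survival = pd.DataFrame(
        {
            "group": ["g1", "g1", "g1", "g2", "g2", "g2"],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 0],
        },
        index=[f"P{i + 1}" for i in range(6)],
    )
    from .outcomes import km_logrank

    lr = km_logrank(survival)
    return WorkedExample(
        map_x=map_x,
        map_y=map_y,
        labels=labels,
        similarity=sim,
        ranks_x=ranks_x,
        hypergeom_p=p_hyper,
        survival=survival,
        logrank_statistic=lr.statistic,
        logrank_p=lr.p_value,
    )
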