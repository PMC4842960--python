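"""Downstream statistics on clusters and profiles.

Survival: Kaplan-Meier curves with the log-rank test for group
comparisons, and Cox proportional hazards (Breslow tie handling) with
age/sex/tissue covariate adjustment. Annotation comparisons use the
Mann-Whitney U test (continuous) and the one-sided Fisher exact test
(categorical). Gene-set enrichment is the upper-tail hypergeometric test
with Benjamini-Yekutieli correction; differential expression is Welch's
two-sample t-test with Holm correction (a documented substitution for a
moderated-variance model); co-expression networks threshold pairwise
Pearson correlations and keep genes with at least two partners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.stats import hypergeom
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene-symbol sets (e.g. canonical pathways read from GMT)."""

    sets: Mapping[str, frozenset]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, source: Optional[str] = None) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                warnings.warn(f"gene set {name!r} is empty; skipped")
                continue
            if name in sets:
                raise ValueError(f"duplicate gene set name: {name!r}")
            sets[name] = frozenset(genes)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, source=source or str(path))


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    degrees_of_freedom: int
    curves: Mapping[str, pd.Series]


@dataclass(frozen=True)
class CoxResult:
    """Cox proportional-hazards fit (Breslow ties).

    ``table`` has one row per model term: coefficient, hazard ratio, 95%
    Wald confidence bounds and p-value. The convenience attributes refer
    to the first group-contrast term.
    """

    table: pd.DataFrame
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    ties: str = "breslow"


def km_logrank(
    records: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "time",
    event_col: str = "event",
) -> LogRankResult:
    """Kaplan-Meier curves per group and the standard log-rank test.

    Needs at least two groups and one observed event overall; the test
    statistic is chi-square with (groups - 1) degrees of freedom.
    """
    df = records[[group_col, time_col, event_col]].dropna()
    groups = pd.unique(df[group_col])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (df[time_col] < 0).any():
        raise ValueError("survival times must be non-negative")
    if int(df[event_col].sum()) == 0:
        raise ValueError("no events observed; log-rank test undefined")
    curves = {}
    for g in groups:
        sub = df[df[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], event_observed=sub[event_col], label=str(g))
        curves[g] = kmf.survival_function_.iloc[:, 0]
    res = multivariate_logrank_test(df[time_col], df[group_col], df[event_col])
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        degrees_of_freedom=len(groups) - 1,
        curves=curves,
    )


def cox_ph(
    records: pd.DataFrame,
    group_col: str = "group",
    covariates: Sequence[str] = (),
    time_col: str = "time",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional hazards with Breslow tie handling.

    The group variable and any categorical covariates (e.g. sex, tissue)
    are reference-coded; numeric covariates (e.g. age) enter as-is.
    Hazard ratios and 95% Wald intervals come from the partial-likelihood
    fit. Non-convergence and separation are rejected with a diagnostic.
    """
    cols = [group_col, *covariates, time_col, event_col]
    df = records[cols].dropna().copy()
    levels = pd.unique(df[group_col])
    if len(levels) < 2:
        raise ValueError("group variable needs at least two levels")
    pieces = [pd.get_dummies(df[group_col].astype("category"), prefix=group_col, drop_first=True, dtype=float)]
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(df[cov]):
            pieces.append(df[[cov]].astype(float))
        else:
            pieces.append(pd.get_dummies(df[cov].astype("category"), prefix=cov, drop_first=True, dtype=float))
    exog = pd.concat(pieces, axis=1)
    n_events = int(df[event_col].sum())
    if n_events < exog.shape[1] + 1:
        raise ValueError(
            f"{n_events} events for {exog.shape[1]} parameters; model under-determined"
        )
    model = PHReg(
        df[time_col].to_numpy(dtype=float),
        exog.to_numpy(dtype=float),
        status=df[event_col].to_numpy(dtype=int),
        ties="breslow",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit()
        except Exception as exc:  # pragma: no cover - backend specific
            raise ValueError(f"Cox fit failed: {exc}") from exc
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        raise ValueError("Cox fit did not converge (non-finite estimates)")
    if np.any(np.abs(params) > 50):
        raise ValueError("Cox fit suggests complete separation (runaway coefficient)")
    z = params / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    crit = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "coef": params,
            "hazard_ratio": np.exp(params),
            "ci_low": np.exp(params - crit * bse),
            "ci_high": np.exp(params + crit * bse),
            "p": pvals,
        },
        index=exog.columns,
    )
    return CoxResult(
        table=table,
        hazard_ratio=float(table["hazard_ratio"].iloc[0]),
        ci_low=float(table["ci_low"].iloc[0]),
        ci_high=float(table["ci_high"].iloc[0]),
        p_value=float(table["p"].iloc[0]),
    )


def fisher_exact_one_sided(table) -> float:
    """One-sided (greater) Fisher exact p for a 2x2 contingency table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("Fisher exact test needs a 2x2 table")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def annotation_test(group_a, group_b) -> float:
    """Two-group annotation comparison.

    Numeric inputs: two-sided Mann-Whitney U p-value. Categorical inputs:
    one-sided (greater) Fisher exact p on the 2x2 table groups x
    categories, with the category observed first in group A as the
    reference column (the tested direction is its over-representation in
    group A). A single shared category is a zero-margin table with p = 1.
    """
    a = pd.Series(group_a)
    b = pd.Series(group_b)
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if pd.api.types.is_numeric_dtype(a) and pd.api.types.is_numeric_dtype(b):
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    cats = list(pd.unique(pd.concat([a, b], ignore_index=True)))
    if len(cats) == 1:
        return 1.0
    if len(cats) != 2:
        raise ValueError(f"categorical test needs at most two categories, got {cats}")
    table = [
        [int((a == cats[0]).sum()), int((a == cats[1]).sum())],
        [int((b == cats[0]).sum()), int((b == cats[1]).sum())],
    ]
    return fisher_exact_one_sided(table)


def pathway_enrichment(
    hit_genes: Sequence[str],
    background_genes: Sequence[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of hits in each gene set, BY-corrected.

    Each set is intersected with the background universe first. Sets are
    selected when the Benjamini-Yekutieli adjusted p is below ``alpha``.
    """
    background = frozenset(background_genes)
    if not background:
        raise ValueError("background gene universe is empty")
    hits = frozenset(hit_genes)
    stray = hits - background
    if stray:
        raise ValueError(f"hit genes outside the background: {sorted(stray)[:5]}")
    rows = []
    for name, genes in collection.sets.items():
        in_bg = genes & background
        overlap = len(hits & in_bg)
        p = float(hypergeom.sf(overlap - 1, len(background), len(in_bg), len(hits)))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(in_bg),
                "n_hits": len(hits),
                "n_background": len(background),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_by"] = multipletests(out["p"], method="fdr_by")[1]
    out["selected"] = out["p_by"] < alpha
    return out


def differential_expression(
    expr: pd.DataFrame,
    group_a: Sequence,
    group_b: Sequence,
    center_within: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-gene Welch t-test between two sample groups, Holm-corrected.

    ``center_within`` optionally names a per-sample category (e.g. the
    cancer tissue); expression is mean-centered within each category
    first, so category-specific baselines cannot drive the comparison.
    Genes with zero variance in both groups get statistic NaN and p = 1.
    The test is a documented substitution for a moderated-variance model:
    the output carries ``method = "welch-t + holm"``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least two samples")
    data = expr.copy()
    if center_within is not None:
        cats = pd.Series(center_within).loc[data.index]
        data = data - data.groupby(cats.to_numpy()).transform("mean")
    a = data.loc[group_a].to_numpy(dtype=float)
    b = data.loc[group_b].to_numpy(dtype=float)
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, equal_var=False, axis=0)
    statistic = np.where(degenerate, np.nan, res.statistic)
    p = np.where(degenerate, 1.0, res.pvalue)
    p = np.nan_to_num(p, nan=1.0)
    out = pd.DataFrame(
        {
            "statistic": statistic,
            "p": p,
            "p_holm": multipletests(p, method="holm")[1],
        },
        index=expr.columns,
    )
    out.attrs["method"] = "welch-t + holm"
    return out


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Thresholded Pearson co-expression graph with module labels.

    Every surviving node has at least ``min_partners`` incident edges
    whose |r| exceeds the threshold; modules are connected components
    (largest first).
    """

    graph: nx.Graph
    edges: pd.DataFrame
    modules: pd.Series
    r_threshold: float
    min_partners: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_modules(self) -> int:
        return int(self.modules.nunique()) if len(self.modules) else 0


def coexpression_network(
    expr: pd.DataFrame,
    genes: Optional[Sequence[str]] = None,
    r_threshold: float = 0.6,
    min_partners: int = 2,
    de_stats: Optional[pd.DataFrame] = None,
    refine: Optional[str] = None,
) -> CoexpressionNetwork:
    """Build a co-expression network from pairwise Pearson correlations.

    Edges require |r| > ``r_threshold`` (positive and negative edges are
    both kept, with the sign recorded); nodes with fewer than
    ``min_partners`` edges are dropped iteratively until a fixed point.
    ``refine="modularity"`` replaces connected-component modules with a
    greedy-modularity community partition.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least three samples for correlations")
    if genes is None:
        genes = list(expr.columns)
    else:
        genes = list(genes)
        missing = [g for g in genes if g not in expr.columns]
        if missing:
            raise ValueError(f"genes not in expression matrix: {missing[:5]}")
    x = expr[genes].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x.T)
    g = nx.Graph()
    m = len(genes)
    for i in range(m):
        for j in range(i + 1, m):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > r_threshold:
                g.add_edge(genes[i], genes[j], r=float(r))
    # prune to the maximal subgraph in which every node keeps >= min_partners edges
    while True:
        weak = [v for v, deg in g.degree() if deg < min_partners]
        if not weak:
            break
        g.remove_nodes_from(weak)
    edges = pd.DataFrame(
        [(u, v, d["r"]) for u, v, d in g.edges(data=True)],
        columns=["gene_a", "gene_b", "r"],
    )
    if refine == "modularity" and g.number_of_nodes():
        communities = nx.community.greedy_modularity_communities(g)
    else:
        communities = sorted(nx.connected_components(g), key=len, reverse=True)
    modules = {}
    for i, comp in enumerate(communities, start=1):
        for node in comp:
            modules[node] = i
    modules = pd.Series(modules, dtype="int64", name="module").sort_index()
    if de_stats is not None:
        for node in g.nodes:
            if node in de_stats.index:
                stat = float(de_stats.loc[node, "statistic"])
                g.nodes[node]["statistic"] = stat
                g.nodes[node]["direction"] = "up" if stat > 0 else "down"
    return CoexpressionNetwork(
        graph=g,
        edges=edges,
        modules=modules,
        r_threshold=r_threshold,
        min_partners=min_partners,
    )
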