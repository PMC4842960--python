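"""Shared fixtures: one default synthetic cohort, preprocessed and embedded once."""

import numpy as np
import pytest

import meredith as m


@pytest.fixture(scope="session")
def default_cohort():
    """The default three-cluster cohort (drivers GE / ME / all-four, 4 SD)."""
    return m.generate_cohort(m.SynthSpec(seed=0))


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    cohort, truth = default_cohort
    return m.preprocess_cohort(cohort), truth


@pytest.fixture(scope="session")
def pipeline_config():
    return m.MeredithConfig(n_restarts=2, seed=0)


@pytest.fixture(scope="session")
def default_map(preprocessed, pipeline_config):
    pre, _ = preprocessed
    return m.run_meredith(pre, config=pipeline_config)


@pytest.fixture(scope="session")
def default_overlaps(preprocessed, pipeline_config, default_map):
    """k=20 neighborhood overlaps of all 14 combination maps vs the full map."""
    pre, _ = preprocessed
    return m.combination_overlaps(pre, pipeline_config, k=20, reference=default_map)


def brute_force_similarity(x, y, kx, ky):
    """Independent double-loop oracle for the local-similarity score."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]

    def rank_of(coords, i):
        dist = {j: float(np.linalg.norm(coords[i] - coords[j])) for j in range(n) if j != i}
        order = sorted(dist, key=lambda j: (dist[j], j))
        return {j: r + 1 for r, j in enumerate(order)}

    count = 0
    for i in range(n):
        rx = rank_of(x, i)
        ry = rank_of(y, i)
        for j in range(n):
            if j != i and rx[j] <= kx and ry[j] <= ky:
                count += 1
    return count / (n * min(kx, ky))


def hypergeom_tail_by_enumeration(overlap, cohort, label_total, cluster):
    """P(X >= overlap) by summing the hypergeometric pmf with exact binomials."""
    from math import comb

    total = comb(cohort, cluster)
    acc = 0
    for j in range(overlap, min(label_total, cluster) + 1):
        if cluster - j <= cohort - label_total:
            acc += comb(label_total, j) * comb(cohort - label_total, cluster - j)
    return acc / total
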