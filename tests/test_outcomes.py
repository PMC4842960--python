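"""Survival statistics, enrichment corrections, DE and co-expression networks."""

import numpy as np
import pandas as pd
import pytest

import meredith as m
from meredith.outcomes import GeneSetCollection, read_gmt


def logrank_by_hand(times, events, groups):
    """Two-group log-rank chi-square via the observed-minus-expected table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    g1 = pd.unique(groups)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g1)).sum()
        expected = d * n1 / n
        o_minus_e += d1 - expected
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def breslow_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestKMLogrank:
    def toy(self):
        return pd.DataFrame(
            {
                "group": ["g1"] * 3 + ["g2"] * 3,
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 1, 1, 0],
            }
        )

    def test_identical_groups_give_zero_statistic(self):
        df = pd.DataFrame(
            {
                "group": ["a", "b"] * 4,
                "time": np.repeat([1.0, 2.0, 3.0, 4.0], 2),
                "event": [1, 1, 0, 0, 1, 1, 1, 1],
            }
        )
        res = m.km_logrank(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_toy_matches_hand_computation(self):
        df = self.toy()
        res = m.km_logrank(df)
        expected = logrank_by_hand(df.time, df.event, df.group)
        assert res.statistic == pytest.approx(expected, abs=1e-6)
        assert res.degrees_of_freedom == 1

    def test_km_curve_is_nonincreasing_step_from_one(self):
        res = m.km_logrank(self.toy())
        for curve in res.curves.values():
            values = curve.to_numpy()
            assert values[0] == pytest.approx(1.0)
            assert np.all(np.diff(values) <= 1e-12)

    def test_event_only_in_one_group_steps_once(self):
        df = pd.DataFrame(
            {"group": ["a", "a", "b", "b"], "time": [1.0, 1.0, 2.0, 2.0], "event": [1, 1, 0, 0]}
        )
        res = m.km_logrank(df)
        assert res.curves["a"].iloc[-1] == pytest.approx(0.0)
        assert (res.curves["b"] == 1.0).all()

    def test_label_swap_invariance(self):
        df = self.toy()
        swapped = df.assign(group=df.group.map({"g1": "g2", "g2": "g1"}))
        assert m.km_logrank(df).p_value == pytest.approx(m.km_logrank(swapped).p_value)

    def test_zero_events_rejected(self):
        df = self.toy().assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            m.km_logrank(df)


class TestCoxPH:
    def test_six_subject_coefficient_matches_grid_search(self):
        df = pd.DataFrame(
            {
                "group": [1, 1, 0, 0, 1, 0],
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 0, 1, 1, 0, 1],
            }
        )
        res = m.cox_ph(df, group_col="group")
        coarse = np.linspace(-4, 4, 801)
        ll = [breslow_loglik(b, df.time.to_numpy(), df.event.to_numpy(), df.group.to_numpy())
              for b in coarse]
        b0 = coarse[int(np.argmax(ll))]
        fine = np.linspace(b0 - 0.02, b0 + 0.02, 401)
        ll = [breslow_loglik(b, df.time.to_numpy(), df.event.to_numpy(), df.group.to_numpy())
              for b in fine]
        best = fine[int(np.argmax(ll))]
        assert np.log(res.hazard_ratio) == pytest.approx(best, abs=1e-3)

    def test_null_simulation_ci_covers_one(self):
        rng = np.random.default_rng(0)
        covered = 0
        for _ in range(50):
            x = rng.integers(0, 2, 200)
            t = rng.exponential(100.0, 200)
            c = rng.uniform(0, 200.0, 200)
            df = pd.DataFrame(
                {"group": x, "time": np.minimum(t, c), "event": (t <= c).astype(int)}
            )
            res = m.cox_ph(df, group_col="group")
            if res.ci_low <= 1.0 <= res.ci_high:
                covered += 1
        assert covered >= 45  # 90% of 50 replicates

    def test_hazard_ratio_two_recovered(self):
        rng = np.random.default_rng(1)
        n = 500
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.01 * 2.0**x))
        c = rng.uniform(0, 200.0, n)
        df = pd.DataFrame({"group": x, "time": np.minimum(t, c), "event": (t <= c).astype(int)})
        res = m.cox_ph(df, group_col="group")
        assert 1.6 <= res.hazard_ratio <= 2.5

    def test_covariate_adjustment_runs(self):
        rng = np.random.default_rng(2)
        n = 120
        df = pd.DataFrame(
            {
                "group": rng.integers(0, 2, n),
                "age": rng.normal(60, 10, n),
                "sex": rng.choice(["M", "F"], n),
                "time": rng.exponential(50.0, n),
                "event": rng.integers(0, 2, n),
            }
        )
        res = m.cox_ph(df, group_col="group", covariates=["age", "sex"])
        assert set(res.table.index) == {"group_1", "age", "sex_M"}

    def test_underdetermined_rejected(self):
        df = pd.DataFrame({"group": [0, 1, 0, 1], "time": [1.0, 2, 3, 4], "event": [1, 0, 0, 0]})
        with pytest.raises(ValueError, match="under-determined"):
            m.cox_ph(df, group_col="group")


class TestAnnotationTests:
    def test_identical_continuous_samples_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert m.annotation_test(x, list(x)) > 0.5

    def test_fisher_one_sided_matches_exhaustive_tables(self):
        # table (3,0 / 0,3): only one more-extreme table exists;
        # p = C(3,3)C(3,0)/C(6,3) = 1/20
        from math import comb

        p = m.annotation_test(["yes"] * 3, ["no"] * 3)
        tables = sum(comb(3, a) * comb(3, 3 - a) for a in range(3, 4))
        assert p == pytest.approx(tables / comb(6, 3))
        assert p == pytest.approx(0.05)

    def test_zero_margin_gives_p_one(self):
        assert m.annotation_test(["yes", "yes"], ["yes", "yes", "yes"]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            m.annotation_test([], [1.0])


class TestPathwayEnrichment:
    def collection(self, sets):
        return GeneSetCollection(sets={k: frozenset(v) for k, v in sets.items()})

    def test_background_equals_set_degenerate_p_one(self):
        gsc = self.collection({"all": ["a", "b", "c"]})
        out = m.pathway_enrichment(["a", "b"], ["a", "b", "c"], gsc)
        assert out.p.iloc[0] == pytest.approx(1.0)

    def test_by_adjustment_matches_hand_step_up(self):
        rng = np.random.default_rng(0)
        background = [f"g{i}" for i in range(40)]
        hits = background[:8]
        gsc = self.collection(
            {
                "hot": background[:6],  # strongly enriched
                "warm": background[4:14],
                "cold": background[25:35],
            }
        )
        out = m.pathway_enrichment(hits, background, gsc)
        p = out.p.to_numpy()
        m_tests = len(p)
        c_m = sum(1.0 / i for i in range(1, m_tests + 1))
        order = np.argsort(p)
        adj = np.empty(m_tests)
        running = 1.0
        for rank_pos in range(m_tests - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, p[idx] * m_tests * c_m / (rank_pos + 1))
            adj[idx] = running
        assert np.allclose(out.p_by.to_numpy(), adj, atol=1e-6)
        # monotone: adjusted ordering preserves raw ordering, adjusted >= raw
        assert np.all(out.p_by.to_numpy() >= p - 1e-12)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_disjoint_hit_set_p_one(self):
        background = [f"g{i}" for i in range(20)]
        gsc = self.collection({"far": background[10:]})
        out = m.pathway_enrichment(background[:5], background, gsc)
        assert out.p.iloc[0] == pytest.approx(1.0)

    def test_hits_outside_background_rejected(self):
        gsc = self.collection({"s": ["a"]})
        with pytest.raises(ValueError, match="outside the background"):
            m.pathway_enrichment(["zz"], ["a", "b"], gsc)

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc\ta\tb\tc\ns2\tdesc\td\te\n")
        gsc = read_gmt(path)
        assert gsc.sets["s1"] == frozenset({"a", "b", "c"})
        assert len(gsc) == 2


def holm_by_hand(p):
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 0.0
    for rank_pos, idx in enumerate(order):
        running = max(running, (n - rank_pos) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestDifferentialExpression:
    def test_identical_groups_all_p_one(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(4, 6))
        expr = pd.DataFrame(np.vstack([block, block]), index=[f"s{i}" for i in range(8)])
        out = m.differential_expression(expr, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert np.allclose(out.p_holm, 1.0)

    def test_shifted_gene_survives_holm(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(40, 30)), index=[f"s{i}" for i in range(40)])
        a = [f"s{i}" for i in range(20)]
        b = [f"s{i}" for i in range(20, 40)]
        expr.loc[b, 5] += 5.0  # 5 SD shift on gene 5
        out = m.differential_expression(expr, a, b)
        assert out.p_holm.iloc[5] < 0.05
        assert out.p_holm.drop(out.index[5]).min() > 0.05

    def test_holm_matches_hand_step_down(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(12, 9)), index=[f"s{i}" for i in range(12)])
        out = m.differential_expression(expr, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)])
        assert np.allclose(out.p_holm.to_numpy(), holm_by_hand(out.p.to_numpy()), atol=1e-6)

    def test_holm_between_bonferroni_and_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        adj = holm_by_hand(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= np.minimum(1.0, p * len(p)) + 1e-12)

    def test_zero_variance_gene_records_p_one(self):
        expr = pd.DataFrame(
            {"flat": [1.0] * 6, "varying": [1.0, 2, 3, 4, 5, 6]},
            index=[f"s{i}" for i in range(6)],
        )
        out = m.differential_expression(expr, [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)])
        assert out.loc["flat", "p"] == pytest.approx(1.0)
        assert np.isnan(out.loc["flat", "statistic"])

    def test_within_category_centering_removes_tissue_shift(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(20, 5)), index=[f"s{i}" for i in range(20)])
        tissue = pd.Series(["t1"] * 10 + ["t2"] * 10, index=expr.index)
        expr.loc[tissue == "t2"] += 100.0  # pure tissue offset
        a = [f"s{i}" for i in range(0, 20, 2)]   # mixes both tissues
        b = [f"s{i}" for i in range(1, 20, 2)]
        out = m.differential_expression(expr, a, b, center_within=tissue)
        assert out.p_holm.min() > 0.05

    def test_method_recorded(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"s{i}" for i in range(6)])
        out = m.differential_expression(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert out.attrs["method"] == "welch-t + holm"


class TestCoexpressionNetwork:
    def test_duplicated_columns_form_triangle(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        expr = pd.DataFrame({"a": base, "b": base * 2, "c": -base})
        net = m.coexpression_network(expr, r_threshold=0.6)
        assert net.graph.number_of_edges() == 3
        assert net.n_modules == 1
        signs = {tuple(sorted((r.gene_a, r.gene_b))): np.sign(r.r) for r in net.edges.itertuples()}
        assert signs[("a", "c")] == -1  # negative edges retained with sign

    def test_unattainable_threshold_gives_empty_network(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(10, 4)))
        net = m.coexpression_network(expr, r_threshold=1.01)
        assert net.n_nodes == 0 and net.edges.empty

    def test_two_planted_triples_give_two_modules(self):
        rng = np.random.default_rng(2)
        f1, f2 = rng.normal(size=50), rng.normal(size=50)
        noise = lambda: rng.normal(scale=0.1, size=50)
        expr = pd.DataFrame(
            {
                "a1": f1 + noise(), "a2": f1 + noise(), "a3": f1 + noise(),
                "b1": f2 + noise(), "b2": f2 + noise(), "b3": f2 + noise(),
            }
        )
        net = m.coexpression_network(expr, r_threshold=0.6, min_partners=2)
        assert net.n_modules == 2
        assert set(net.modules[net.modules == net.modules["a1"]].index) == {"a1", "a2", "a3"}

    def test_pruning_reaches_fixed_point(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=30)
        expr = pd.DataFrame(
            {
                "a": f + rng.normal(scale=0.1, size=30),
                "b": f + rng.normal(scale=0.1, size=30),
                "c": f + rng.normal(scale=0.1, size=30),
                "lonely": f + rng.normal(scale=1.2, size=30),
            }
        )
        net = m.coexpression_network(expr, r_threshold=0.6, min_partners=2)
        degrees = dict(net.graph.degree())
        assert all(d >= 2 for d in degrees.values())
        rebuilt = m.coexpression_network(
            expr[list(net.graph.nodes)], r_threshold=0.6, min_partners=2
        )
        assert set(rebuilt.graph.nodes) == set(net.graph.nodes)
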