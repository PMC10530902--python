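"""Evaluation battery: subset AUC, hypergeometric enrichment, survival
screen, t-test contrast, and network adjacency, each against an
independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from math import comb

import metascore as ms
from metascore.evaluation import _logrank


# ---------------------------------------------------------------------------
# independent oracles

def enum_hypergeom_tail(N, K, n, k):
    """Exhaustive upper-tail hypergeometric probability."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def naive_logrank(times_a, events_a, times_b, events_b):
    """Observed/expected log-rank chi-square from first principles."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_a = e_a = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return (o_a - e_a) ** 2 / var


def naive_adjacency(markers, edges):
    """Neighbor-scan oracle for adjacent-marker counts."""
    markers = set(markers)
    counts = {m: 0 for m in markers}
    for a, b in edges.itertuples(index=False):
        if a in markers and b in markers and a != b:
            counts[a] += 1
            counts[b] += 1
    return counts


# ---------------------------------------------------------------------------

class TestHypergeomTest:
    def test_worked_example(self):
        # N=10, K=4, n=5, k=4: C(4,4)*C(6,1)/C(10,5) = 6/252
        universe = set(range(10))
        reference = set(range(4))
        markers = {0, 1, 2, 3, 9}
        k, p = ms.hypergeom_test(markers, reference, universe)
        assert k == 4
        assert p == pytest.approx(6 / 252)

    def test_zero_overlap_tail_is_one(self):
        universe = set(range(10))
        k, p = ms.hypergeom_test({8, 9}, {0, 1}, universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            N = int(rng.integers(2, 21))
            universe = set(range(N))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            reference = set(rng.choice(N, K, replace=False).tolist())
            markers = set(rng.choice(N, n, replace=False).tolist())
            k, p = ms.hypergeom_test(markers, reference, universe)
            assert p == pytest.approx(enum_hypergeom_tail(N, K, n, k))

    def test_reference_intersected_with_universe(self):
        universe = set(range(10))
        k, p = ms.hypergeom_test({0, 1}, {0, 1, "outside"}, universe)
        assert k == 2
        assert p == pytest.approx(enum_hypergeom_tail(10, 2, 2, 2))

    def test_markers_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ms.hypergeom_test({"x"}, {"a"}, {"a", "b"})


class TestLogrank:
    def test_hand_computed_six_subjects(self):
        # groups {1,2,3} vs {4,5,6}, all events: O_A=3, E_A=1.15, V=0.6775
        ta, tb = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        ea = eb = np.ones(3, dtype=int)
        expected = (3 - 1.15) ** 2 / 0.6775
        stat, p = _logrank(ta, ea, tb, eb)
        assert stat == pytest.approx(expected, rel=1e-6)
        assert naive_logrank(ta, ea, tb, eb) == pytest.approx(expected, rel=1e-12)

    def test_identical_groups_statistic_zero(self):
        t = np.array([2.0, 4.0, 6.0])
        e = np.array([1, 0, 1])
        stat, p = _logrank(t, e, t.copy(), e.copy())
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_all_censored_degenerate(self):
        t = np.full(4, 100.0)
        e = np.zeros(4, dtype=int)
        stat, p = _logrank(t, e, t, e)
        assert stat == 0.0 and p == 1.0

    def test_label_swap_invariance_and_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            na, nb = rng.integers(3, 15), rng.integers(3, 15)
            ta = rng.exponential(10, na).round(1) + 0.1
            tb = rng.exponential(15, nb).round(1) + 0.1
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            s1, _ = _logrank(ta, ea, tb, eb)
            s2, _ = _logrank(tb, eb, ta, ea)
            assert s1 == pytest.approx(s2, rel=1e-9, abs=1e-9)
            assert s1 == pytest.approx(naive_logrank(ta, ea, tb, eb),
                                       rel=1e-6, abs=1e-9)


class TestKMLogrankScreen:
    def _cohort(self):
        expr, labels, truth = ms.generate_cohort(20, 1, 0.0, (30, 30), 1.0, seed=8)
        surv = ms.generate_survival(labels, expr, ["G000001"], 1.5, seed=9)
        return expr, labels, surv

    def test_split_sizes_and_schema(self):
        expr, labels, surv = self._cohort()
        res = ms.km_logrank_screen(expr, surv, ["G000001", "G000002"])
        assert set(res.columns) == {"n_low", "n_high", "statistic", "p"}
        assert (res["n_low"] + res["n_high"] == 60).all()
        # strictly-below-median rule: low group is just under half
        assert (res["n_low"] == 30).all()

    def test_hazard_gene_detected(self):
        expr, labels, surv = self._cohort()
        res = ms.km_logrank_screen(expr, surv, ["G000001"])
        assert res.loc["G000001", "p"] < 0.05

    def test_constant_gene_skipped(self):
        expr, labels, surv = self._cohort()
        expr = expr.copy()
        expr.loc["G000002"] = 1.0
        res = ms.km_logrank_screen(expr, surv, ["G000001", "G000002"])
        assert "G000002" not in res.index

    def test_cohort_filter_restricts_samples(self):
        expr, labels, surv = self._cohort()
        res = ms.km_logrank_screen(expr, surv, ["G000001"], labels=labels,
                                   cohort_filter="M1")
        assert (res["n_low"] + res["n_high"] == 30).all()

    def test_km_curves_step_down_from_one(self):
        expr, labels, surv = self._cohort()
        res, curves = ms.km_logrank_screen(expr, surv, ["G000001"],
                                           return_curves=True)
        curve = curves["G000001"]
        for _, grp in curve.groupby("group"):
            s = grp.sort_values("time")["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()


class TestTTestFlagging:
    def test_zero_variance_gene_flagged_with_p_one(self):
        expr, labels, _ = ms.generate_cohort(5, 0, 0.0, (10, 10), 1.0, seed=1)
        expr.loc["G000001"] = 3.14
        flagged = ms.flag_nonsignificant_ttest(expr, labels, ["G000001"])
        assert flagged.loc["G000001", "p"] == 1.0

    def test_strong_signal_not_flagged(self):
        expr, labels, truth = ms.generate_cohort(20, 5, 5.0, (100, 100), 1.0, seed=2)
        flagged = ms.flag_nonsignificant_ttest(
            expr, labels, sorted(truth.informative_genes), alpha=0.1
        )
        assert len(flagged) == 0

    def test_null_genes_mostly_flagged(self):
        expr, labels, _ = ms.generate_cohort(50, 0, 0.0, (40, 40), 1.0, seed=3)
        flagged = ms.flag_nonsignificant_ttest(expr, labels, list(expr.index))
        assert len(flagged) > 35  # ~90% of null genes have p > 0.1

    def test_small_class_rejected(self):
        expr, labels, _ = ms.generate_cohort(5, 0, 0.0, (2, 5), 1.0, seed=4)
        tiny = labels[labels.index[1:]]  # leaves one M0 sample
        with pytest.raises(ValueError):
            ms.flag_nonsignificant_ttest(expr[tiny.index], tiny, ["G000001"])


class TestPPIAdjacency:
    def test_clique_counts(self):
        markers = [f"m{i}" for i in range(5)]
        edges = pd.DataFrame(
            [(a, b) for i, a in enumerate(markers) for b in markers[i + 1:]],
            columns=["gene_a", "gene_b"],
        )
        counts, mean = ms.ppi_adjacency(markers, edges)
        assert (counts == 4).all()
        assert mean == pytest.approx(4.0)

    def test_empty_network(self):
        counts, mean = ms.ppi_adjacency(["a", "b"],
                                        pd.DataFrame(columns=["gene_a", "gene_b"]))
        assert (counts == 0).all() and mean == 0.0

    def test_matches_neighbor_scan_oracle(self):
        rng = np.random.default_rng(6)
        nodes = [f"n{i}" for i in range(40)]
        for _ in range(100):
            k = int(rng.integers(2, 15))
            markers = list(rng.choice(nodes, k, replace=False))
            pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
            idx = rng.choice(len(pairs), 60, replace=False)
            edges = pd.DataFrame([pairs[i] for i in idx],
                                 columns=["gene_a", "gene_b"])
            counts, _ = ms.ppi_adjacency(markers, edges)
            assert counts.to_dict() == naive_adjacency(markers, edges)

    def test_mean_equals_twice_internal_edges_over_set_size(self):
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(30)]
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        idx = rng.choice(len(pairs), 80, replace=False)
        edges = pd.DataFrame([pairs[i] for i in idx], columns=["gene_a", "gene_b"])
        markers = set(rng.choice(nodes, 12, replace=False))
        counts, mean = ms.ppi_adjacency(markers, edges)
        internal = sum(1 for a, b in edges.itertuples(index=False)
                       if a in markers and b in markers)
        assert mean == pytest.approx(2 * internal / len(markers))


class TestSubsetAUC:
    def test_planted_beats_all_beats_random(self, light_params):
        expr, labels, truth = ms.generate_cohort(
            200, 5, 1.5, (60, 60), 1.0, seed=12
        )
        planted = sorted(truth.informative_genes)
        null_genes = [g for g in expr.index if g not in truth.informative_genes][:5]
        auc_planted = ms.evaluate_subset_auc(expr, labels, planted, 6, seed=0,
                                             backend_params=light_params).mean
        auc_all = ms.evaluate_subset_auc(expr, labels, list(expr.index), 6, seed=0,
                                         backend_params=light_params).mean
        auc_null = ms.evaluate_subset_auc(expr, labels, null_genes, 6, seed=0,
                                          backend_params=light_params).mean
        assert auc_planted > auc_all > auc_null

    def test_empty_subset_rejected(self, null_cohort):
        expr, labels, _ = null_cohort
        with pytest.raises(ValueError):
            ms.evaluate_subset_auc(expr, labels, [], 2, seed=0)

    def test_random_null_percentile_of_median(self, null_cohort, light_params):
        expr, labels, _ = null_cohort
        null_aucs, _ = ms.random_subset_null(
            expr, labels, subset_size=5, n_draws=9, models_per_draw=2,
            seed=1, backend_params=light_params,
        )
        ref = float(np.median(null_aucs))
        _, pct = ms.random_subset_null(
            expr, labels, subset_size=5, n_draws=9, models_per_draw=2,
            seed=1, reference_auc=ref, backend_params=light_params,
        )
        assert 0.3 <= pct <= 0.8

    def test_oversized_subset_rejected(self, null_cohort):
        expr, labels, _ = null_cohort
        with pytest.raises(ValueError):
            ms.random_subset_null(expr, labels, subset_size=1000, n_draws=1,
                                  models_per_draw=1, seed=0)


class TestCombinatorialMarkers:
    def test_xor_pair_scored_but_invisible_to_ttest(self, light_params):
        """A pair of genes informative only jointly can enter the marker
        set while each is flagged nonsignificant by the univariate test."""
        rng = np.random.default_rng(13)
        n = 240
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        noise = rng.normal(size=(48, n))
        samples = [f"S{i:04d}" for i in range(n)]
        expr = pd.DataFrame(
            np.vstack([x1, x2, noise]),
            index=pd.Index([f"G{i + 1:06d}" for i in range(50)], name="gene"),
            columns=samples,
        )
        labels = pd.Series(np.where(x1 * x2 > 0, "M1", "M0"), index=samples)

        records = ms.train_eval_models(expr, labels, 8, seed=0,
                                       backend_params=light_params)
        score = ms.compute_ms(records)
        pool = ms.build_background(expr, labels, 3, 8, seed=1,
                                   backend_params=light_params)
        ep = ms.empirical_pvalues(score, pool)
        table = ms.score_table(expr.index, score, ep)

        flagged = ms.flag_nonsignificant_ttest(expr, labels,
                                               ["G000001", "G000002"], alpha=0.1)
        assert {"G000001", "G000002"} <= set(flagged.index)
        assert (table.loc[["G000001", "G000002"], "ep"] <= 0.01).all()
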