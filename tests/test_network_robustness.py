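from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from microstage.cooc_network import (
    build_network,
    network_summary,
    shared_asv_counts,
)
from microstage.robustness import (
    compare_curves,
    natural_connectivity,
    removal_curve,
)
from microstage.sparcc import CorrelationResult
from microstage.tables_io import AsvTable


def _corr(ids, rho_pairs, p_pairs):
    n = len(ids)
    rho = np.eye(n)
    pv = np.ones((n, n))
    for (i, j), r in rho_pairs.items():
        rho[i, j] = rho[j, i] = r
    for (i, j), p in p_pairs.items():
        pv[i, j] = pv[j, i] = p
    return CorrelationResult(ids, rho, pv, n_bootstrap=99, pseudocount=1.0)


class TestBuildNetwork:
    def test_edge_filters(self):
        corr = _corr(list("abcd"),
                     {(0, 1): 0.5, (0, 2): 0.25, (1, 2): -0.4},
                     {(0, 1): 0.01, (0, 2): 0.001, (1, 2): 0.2})
        net = build_network(corr)
        assert net.has_edge("a", "b")        # strong and significant
        assert not net.has_edge("a", "c")    # significant but weak (|rho| < 0.3)
        assert not net.has_edge("b", "c")    # strong but not significant
        assert set(net.nodes) == set("abcd")  # isolated nodes retained

    def test_all_insignificant_gives_edgeless_full_node_set(self):
        corr = _corr(list("abcd"), {(0, 1): 0.9}, {(0, 1): 0.05})
        net = build_network(corr)  # p < alpha is strict
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 4

    def test_threshold_monotonicity(self, rng):
        ids = [f"t{k}" for k in range(12)]
        rho_pairs = {(i, j): rng.uniform(-1, 1) for i, j in combinations(range(12), 2)}
        p_pairs = {(i, j): rng.uniform(0, 1) for i, j in combinations(range(12), 2)}
        corr = _corr(ids, rho_pairs, p_pairs)
        base = set(build_network(corr, r_min=0.3, alpha=0.05).edges)
        stricter_r = set(build_network(corr, r_min=0.5, alpha=0.05).edges)
        stricter_a = set(build_network(corr, r_min=0.3, alpha=0.01).edges)
        assert stricter_r <= base
        assert stricter_a <= base

    def test_edge_set_invariant_to_node_order(self, rng):
        ids = [f"t{k}" for k in range(8)]
        rho_pairs = {(i, j): rng.uniform(-1, 1) for i, j in combinations(range(8), 2)}
        p_pairs = {(i, j): rng.uniform(0, 0.1) for i, j in combinations(range(8), 2)}
        corr = _corr(ids, rho_pairs, p_pairs)
        perm = rng.permutation(8)
        corr_perm = CorrelationResult(
            [ids[k] for k in perm],
            corr.rho[np.ix_(perm, perm)], corr.pvalues[np.ix_(perm, perm)],
            99, 1.0)
        e1 = {frozenset(e) for e in build_network(corr).edges}
        e2 = {frozenset(e) for e in build_network(corr_perm).edges}
        assert e1 == e2


class TestNetworkSummary:
    def test_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        nx.set_edge_attributes(g, 1, "sign")
        s = network_summary(g)
        assert s["density"] == pytest.approx(1.0)
        assert s["mean_degree"] == pytest.approx(2.0)

    def test_edgeless_and_tiny(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert network_summary(g)["density"] == 0.0
        g1 = nx.Graph()
        g1.add_node("a")
        assert network_summary(g1)["density"] == 0.0

    def test_density_matches_brute_force(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=4)
        nx.set_edge_attributes(g, 1, "sign")
        n_edges = sum(1 for i, j in combinations(g.nodes, 2) if g.has_edge(i, j))
        s = network_summary(g)
        assert s["n_edges"] == n_edges
        assert s["density"] == pytest.approx(2 * n_edges / (15 * 14))


class TestSharedAsvCounts:
    @staticmethod
    def _tab(presence, site):
        counts = pd.DataFrame(
            presence, index=[f"s{i}" for i in range(len(presence))],
            columns=[f"a{j}" for j in range(len(presence[0]))])
        return AsvTable(counts, site=site, require_positive_totals=False)

    def test_identical_and_disjoint_sets(self):
        tables = {
            ("NC", "feces"): self._tab([[1, 1, 0]], "feces"),
            ("NC", "saliva"): self._tab([[1, 1, 0]], "saliva"),
            ("NM", "feces"): self._tab([[1, 0, 0]], "feces"),
            ("NM", "saliva"): self._tab([[0, 0, 1]], "saliva"),
        }
        out = shared_asv_counts(tables)
        assert out.loc["NC", "n_shared"] == 2
        assert out.loc["NM", "n_shared"] == 0

    def test_matches_brute_force_sets(self, rng):
        pres_f = rng.integers(0, 2, size=(4, 20))
        pres_s = rng.integers(0, 2, size=(4, 20))
        tables = {("M", "feces"): self._tab(pres_f, "feces"),
                  ("M", "saliva"): self._tab(pres_s, "saliva")}
        out = shared_asv_counts(tables)
        set_f = {j for j in range(20) if pres_f[:, j].any()}
        set_s = {j for j in range(20) if pres_s[:, j].any()}
        assert out.loc["M", "n_shared"] == len(set_f & set_s)
        assert out.loc["M", "n_fecal_asvs"] == len(set_f)


def _kn_nat_conn(n):
    # K_n eigenvalues: (n-1) once, -1 with multiplicity n-1
    return np.log((np.exp(n - 1.0) + (n - 1) * np.exp(-1.0)) / n)


class TestNaturalConnectivity:
    def test_edgeless_graph_exactly_zero(self):
        g = nx.Graph()
        g.add_nodes_from(range(7))
        assert natural_connectivity(g) == 0.0

    def test_single_node_zero(self):
        g = nx.Graph()
        g.add_node("x")
        assert natural_connectivity(g) == 0.0

    def test_complete_graph_closed_form(self):
        # K3 eigenvalues (2, -1, -1): ln((e^2 + 2 e^-1) / 3) = 0.996311
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            _kn_nat_conn(3), abs=1e-12)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            0.996311, abs=1e-6)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            natural_connectivity(nx.Graph())

    def test_adding_isolated_vertex_follows_formula(self, rng):
        g = nx.gnp_random_graph(9, 0.4, seed=2)
        lam = np.linalg.eigvalsh(nx.to_numpy_array(g))
        n = g.number_of_nodes()
        g2 = g.copy()
        g2.add_node("iso")
        expected = np.log((np.exp(lam).sum() + 1.0) / (n + 1))
        assert natural_connectivity(g2) == pytest.approx(expected, abs=1e-12)

    def test_complete_graph_value_increases_with_n(self):
        vals = [natural_connectivity(nx.complete_graph(n)) for n in range(2, 11)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_matches_characteristic_polynomial_oracle(self, rng):
        """Eigenvalues via np.roots of the characteristic polynomial on random
        small graphs (exhaustive <=6-node enumeration runs in the acceptance
        suite)."""
        for seed in range(10):
            g = nx.gnp_random_graph(6, 0.5, seed=seed)
            a = nx.to_numpy_array(g)
            roots = np.sort(np.real(np.roots(np.poly(a))))
            expected = np.log(np.exp(roots).mean())
            assert natural_connectivity(g) == pytest.approx(expected, abs=1e-9)


class TestRemovalCurve:
    def test_step_zero_equals_natural_connectivity(self):
        g = nx.gnp_random_graph(10, 0.4, seed=1)
        curve = removal_curve(g, repeats=3, seed=0)
        assert curve.points["mean"].iloc[0] == pytest.approx(natural_connectivity(g))
        assert len(curve.points) == 10

    def test_k4_first_removal_gives_k3_value(self):
        curve = removal_curve(nx.complete_graph(4), strategy="random",
                              repeats=5, seed=0)
        assert curve.points["mean"].iloc[1] == pytest.approx(_kn_nat_conn(3), abs=1e-12)
        assert curve.points["sd"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        a = removal_curve(g, repeats=4, seed=9).points
        b = removal_curve(g, repeats=4, seed=9).points
        pd.testing.assert_frame_equal(a, b)

    def test_degree_descending_is_deterministic(self):
        g = nx.barbell_graph(4, 1)
        curve = removal_curve(g, strategy="degree_descending", repeats=50, seed=0)
        assert curve.repeats == 1
        assert (curve.points["sd"] == 0).all()


class TestCompareCurves:
    def test_zero_curve_auc_zero(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        curve = removal_curve(g, repeats=1, seed=0)
        assert curve.auc() == pytest.approx(0.0)

    def test_larger_complete_graph_more_robust(self):
        c10 = removal_curve(nx.complete_graph(10), repeats=1, seed=0)
        c5 = removal_curve(nx.complete_graph(5), repeats=1, seed=0)
        ranking = compare_curves([c10, c5])
        assert c10.auc() > c5.auc()
        assert ranking.loc[0, "n_nodes"] == 10

    def test_mismatched_strategies_rejected(self):
        a = removal_curve(nx.complete_graph(5), strategy="random", repeats=1, seed=0)
        b = removal_curve(nx.complete_graph(5), strategy="degree_descending", seed=0)
        with pytest.raises(ValueError, match="strategies"):
            compare_curves([a, b])
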