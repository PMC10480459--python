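"""Spanning-tree splits, AUC counting, and the benchmark protocols."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from linkdiffuse.netio import Network
from linkdiffuse.indices import ScoreMatrix
from linkdiffuse.evaluation import (
    auc,
    beta_sweep,
    fraction_sweep,
    preweight_comparison,
    ra_threshold_counts,
    random_spanning_tree,
    run_benchmark,
    split_train_probe,
)
from linkdiffuse.fixtures import worked_example_network, two_community_network
from conftest import seeded_graphs


def cycle(n: int) -> Network:
    return Network([f"c{i}" for i in range(n)],
                   {(i, (i + 1) % n) if i + 1 < n else (0, n - 1): 1.0 for i in range(n)})


class TestRandomSpanningTree:
    def test_tree_input_returns_itself(self, path4):
        for seed in (0, 1, 2):
            assert random_spanning_tree(path4, seed) == frozenset(path4.edges)

    def test_triangle_all_trees_occur(self, triangle):
        seen = {random_spanning_tree(triangle, seed) for seed in range(300)}
        # enumeration: a triangle has exactly 3 spanning trees
        assert len(seen) == 3

    def test_cycle_drops_exactly_one_edge(self):
        net = cycle(8)
        tree = random_spanning_tree(net, 5)
        assert len(tree) == 7
        assert len(set(net.edges) - tree) == 1

    def test_result_is_spanning_tree(self):
        import networkx as nx

        for g in seeded_graphs(5, n=15, m=30):
            tree = random_spanning_tree(g, 11)
            tg = nx.Graph(list(tree))
            tg.add_nodes_from(range(g.n))
            assert nx.is_tree(tg)

    def test_disconnected_errors(self):
        net = Network(list("abcd"), {(0, 1): 1.0, (2, 3): 1.0})
        with pytest.raises(ValueError, match="connected"):
            random_spanning_tree(net, 0)

    def test_deterministic_given_seed(self, triangle):
        assert random_spanning_tree(triangle, 7) == random_spanning_tree(triangle, 7)


class TestSplitTrainProbe:
    def test_triangle_third(self, triangle):
        split = split_train_probe(triangle, 1 / 3, 0)
        assert len(split.probe) == 1
        assert split.training.is_connected()
        assert next(iter(split.probe)) not in split.tree_edges

    def test_fraction_zero(self, triangle):
        split = split_train_probe(triangle, 0.0, 0)
        assert split.probe == frozenset()
        assert split.training.edge_set() == triangle.edge_set()

    def test_partition_and_connectivity_sweep(self):
        for seed, g in enumerate(seeded_graphs(10, n=20, m=50)):
            split = split_train_probe(g, 0.5, seed)
            assert split.training.is_connected()
            assert split.probe | split.training.edge_set() == g.edge_set()
            assert not (split.probe & split.training.edge_set())
            assert len(split.probe) == round(0.5 * g.m)
            assert split.tree_edges <= split.training.edge_set()

    def test_infeasible_fraction_reports_maximum(self, path4):
        with pytest.raises(ValueError, match="max feasible"):
            split_train_probe(path4, 0.5, 0)

    def test_deterministic(self):
        g = seeded_graphs(1, n=15, m=30)[0]
        a = split_train_probe(g, 0.2, 42)
        b = split_train_probe(g, 0.2, 42)
        assert a.probe == b.probe and a.tree_edges == b.tree_edges


def _score_matrix_from(pairs_scores: dict, n: int) -> ScoreMatrix:
    vals = np.zeros((n, n))
    for (i, j), s in pairs_scores.items():
        vals[i, j] = vals[j, i] = s
    return ScoreMatrix(vals, "toy")


class TestAUC:
    def test_perfect_scorer(self):
        sm = _score_matrix_from({(0, 1): 0.9, (0, 2): 0.1, (1, 2): 0.2}, 3)
        est = auc(sm, [(0, 1)], [(0, 2), (1, 2)])
        assert est.auc == 1.0 and est.sigma == 2 and est.sigma1 == 2

    def test_all_ties_gives_half(self):
        sm = _score_matrix_from({(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5}, 3)
        est = auc(sm, [(0, 1)], [(0, 2), (1, 2)])
        assert est.auc == 0.5 and est.sigma2 == est.sigma

    def test_hand_enumerated_mixture(self):
        # probe {0.9} vs nonexistent {0.5, 0.9}: one win, one tie
        sm = _score_matrix_from({(0, 1): 0.9, (0, 2): 0.5, (1, 2): 0.9}, 3)
        est = auc(sm, [(0, 1)], [(0, 2), (1, 2)])
        assert (est.sigma, est.sigma1, est.sigma2) == (2, 1, 1)
        assert est.auc == 0.75

    def test_exhaustive_matches_rank_oracle(self):
        """(sigma1 + 0.5 sigma2)/sigma equals the Mann-Whitney statistic
        computed from midranks, over random score configurations."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_p = int(rng.integers(1, 8))
            n_q = int(rng.integers(1, 30))
            # draw from a small value set to force ties
            p = rng.choice([0.0, 0.1, 0.2, 0.5, 0.9], size=n_p)
            q = rng.choice([0.0, 0.1, 0.2, 0.5, 0.9], size=n_q)
            pairs_p = [(0, k + 1) for k in range(n_p)]
            pairs_q = [(1, k + 2) for k in range(n_q)]
            n = n_p + n_q + 3
            vals = np.zeros((n, n))
            for (i, j), s in zip(pairs_p, p):
                vals[i, j] = vals[j, i] = s
            for (i, j), s in zip(pairs_q, q):
                vals[i, j] = vals[j, i] = s
            est = auc(ScoreMatrix(vals, "rand"), pairs_p, pairs_q)
            ranks = rankdata(np.concatenate([p, q]))
            u = ranks[:n_p].sum() - n_p * (n_p + 1) / 2
            assert est.auc == pytest.approx(u / (n_p * n_q), abs=1e-12)

    def test_sampled_converges_to_exhaustive(self):
        g = seeded_graphs(1, n=25, m=60)[0]
        from linkdiffuse.indices import resource_allocation_scores

        split = split_train_probe(g, 0.3, 3)
        sm = resource_allocation_scores(split.training)
        ex = auc(sm, split.probe, g.non_edges())
        sa = auc(sm, split.probe, g.non_edges(), mode="sampled",
                 n_samples=100_000, rng_seed=5)
        assert abs(sa.auc - ex.auc) < 0.01

    def test_empty_sets_error(self):
        sm = _score_matrix_from({(0, 1): 1.0}, 3)
        with pytest.raises(ValueError):
            auc(sm, [], [(0, 2)])
        with pytest.raises(ValueError):
            auc(sm, [(0, 1)], [])

    def test_overlap_errors(self):
        sm = _score_matrix_from({(0, 1): 1.0}, 3)
        with pytest.raises(ValueError, match="overlap"):
            auc(sm, [(0, 1)], [(0, 1), (0, 2)])


class TestRunBenchmark:
    def test_single_repeat_std_zero(self):
        g = seeded_graphs(1, n=15, m=35)[0]
        res = run_benchmark(g, ["ra"], 0.2, repeats=1, master_seed=0)
        assert len(res.raw) == 1
        assert res.summary["std"].iloc[0] == 0.0

    def test_deterministic_rerun(self):
        g = seeded_graphs(1, n=15, m=35)[0]
        a = run_benchmark(g, ["cn", "ra"], 0.2, repeats=5, master_seed=9)
        b = run_benchmark(g, ["cn", "ra"], 0.2, repeats=5, master_seed=9)
        pd.testing.assert_frame_equal(a.raw, b.raw)

    def test_random_scores_near_half(self):
        """An index assigning i.i.d. uniform scores must sit at AUC ~ 0.5."""
        g = seeded_graphs(1, n=30, m=90)[0]

        state = {"seed": 0}

        def random_scorer(net):
            state["seed"] += 1
            rng = np.random.default_rng(state["seed"])
            v = rng.random((net.n, net.n))
            return ScoreMatrix((v + v.T) / 2, "random")

        res = run_benchmark(g, ["random"], 0.2, repeats=20, master_seed=1,
                            scorers={"random": random_scorer})
        assert 0.45 < res.mean_auc("random") < 0.55

    def test_shared_splits_across_indices(self):
        """Every index must be scored on the identical training network."""
        g = seeded_graphs(1, n=15, m=35)[0]
        calls: list[tuple[str, frozenset]] = []

        def recorder(name):
            def fn(net):
                calls.append((name, frozenset(net.edge_set())))
                from linkdiffuse.indices import common_neighbour_scores

                return common_neighbour_scores(net)
            return fn

        run_benchmark(g, ["a", "b"], 0.2, repeats=3, master_seed=0,
                      scorers={"a": recorder("a"), "b": recorder("b")})
        assert [name for name, _ in calls] == ["a", "b"] * 3
        for k in range(0, 6, 2):
            assert calls[k][1] == calls[k + 1][1]  # identical training set


class TestSweeps:
    def test_fraction_sweep_shape_and_reduction(self):
        g = seeded_graphs(1, n=20, m=60)[0]
        out = fraction_sweep(g, ["cn", "ra"], fractions=(0.1,), repeats=2,
                             master_seed=4)
        assert set(out) == {0.1}
        assert len(out[0.1].summary) == 2

    def test_fraction_sweep_skips_infeasible(self, path4):
        with pytest.warns(UserWarning, match="skipped"):
            out = fraction_sweep(path4, ["cn"], fractions=(0.9,), repeats=1)
        assert out == {}

    def test_beta_sweep_indexed_by_beta(self):
        g, _ = two_community_network(size_per_community=12, seed=5)
        betas = (0.0001, 0.05, 1.0)
        tab = beta_sweep(g, betas=betas, repeats=2, master_seed=3)
        assert list(tab["beta"]) == list(betas)
        assert {"mean", "std"} <= set(tab.columns)

    def test_preweight_comparison_rows_and_none_baseline(self):
        g, _ = two_community_network(size_per_community=12, seed=6)
        res = preweight_comparison(g, repeats=2, master_seed=2)
        assert list(res.summary["index"]) == ["none", "cn", "aa", "ra"]

    def test_preweight_variants_agree_without_common_neighbours(self):
        # a single edge has no common neighbours: transform is the identity
        k2 = Network(["x", "y"], {(0, 1): 1.0})
        from linkdiffuse.wpmfi import pmfi_scores, wpmfi_scores

        for w in ("cn", "aa", "ra"):
            assert np.allclose(wpmfi_scores(k2, 0.05, w).values,
                               pmfi_scores(k2, 0.05).values, atol=1e-12)


class TestRAThresholdCounts:
    def test_worked_example_counts(self):
        net = worked_example_network()
        tab = ra_threshold_counts(net, thresholds=(0.5, 1 / 3))
        ra_vals = sorted(
            tab["cumulative"]
        )
        # worked example: two-hop pairs have RA in {1/2, 1/3}; cumulative counts grow
        assert tab["cumulative"].is_monotonic_increasing
        assert tab["band"].sum() == tab["cumulative"].iloc[-1]

    def test_requires_descending_thresholds(self, triangle):
        with pytest.raises(ValueError, match="descending"):
            ra_threshold_counts(triangle, thresholds=(0.1, 0.2))
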