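"""TOM against a brute-force oracle, module detection/preservation,
edge filtering, DEG overlap and hypergeometric enrichment."""

import math

import numpy as np
import pytest
from scipy.special import comb

from lumastrat import (
    SimulationConfig,
    detect_modules,
    filter_by_read_count,
    filter_top_edges,
    generate_normal_tissue,
    module_deg_overlap,
    module_enrichment,
    module_preservation,
    pick_soft_threshold,
    split_train_test,
    tom_from_expression,
)
from lumastrat.coexpression import CoexpressionNetwork, _tom_from_adjacency
from lumastrat.types import ExpressionMatrix

from conftest import make_expression


def brute_force_tom(a):
    """Triple-loop TOM implementation straight from the formula."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTom:
    def test_all_ones_triangle_gives_unit_overlap(self):
        a = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        tom = _tom_from_adjacency(a)
        assert tom[0, 1] == pytest.approx(1.0)  # (1+1)/(2+1-1)

    def test_empty_network_zero_overlap(self):
        tom = _tom_from_adjacency(np.zeros((4, 4)))
        off = tom[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0)

    @pytest.mark.parametrize("n_genes", [8, 10, 12])
    def test_matches_brute_force_oracle(self, n_genes, rng):
        c = rng.uniform(0, 1, size=(n_genes, n_genes))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 0.0)
        np.testing.assert_allclose(
            _tom_from_adjacency(a), brute_force_tom(a), atol=1e-12
        )

    def test_from_expression_validates(self, rng):
        tiny = make_expression(rng.standard_normal((2, 10)))
        with pytest.raises(ValueError):
            tom_from_expression(tiny, 6.0)
        const = make_expression(np.vstack([np.ones(10),
                                           rng.standard_normal((3, 10))]),
                                gene_ids=["flat", "a", "b", "c"])
        with pytest.raises(ValueError, match="flat"):
            tom_from_expression(const, 6.0)

    def test_higher_beta_sparsifies(self, rng):
        expr = make_expression(rng.standard_normal((20, 30)))
        means = [
            tom_from_expression(expr, beta).adjacency.mean()
            for beta in (1.0, 3.0, 6.0, 9.0)
        ]
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestReadCountFilter:
    def test_strict_boundary(self):
        counts = make_expression(
            [[10, 10, 10], [11, 11, 11], [9, 30, 50]],
            gene_ids=["at", "above", "mixed"],
        )
        keep = filter_by_read_count(counts, counts, min_median=10)
        assert keep == ["above", "mixed"]

    def test_no_survivors_raises(self):
        counts = make_expression([[1.0, 2.0]], gene_ids=["low"])
        with pytest.raises(ValueError):
            filter_by_read_count(counts, counts, min_median=10)


class TestSplit:
    @pytest.mark.parametrize(
        "n, fraction, expected", [(459, 0.8, (367, 92)), (10, 0.8, (8, 2))]
    )
    def test_split_sizes(self, n, fraction, expected):
        train, test = split_train_test([f"s{i}" for i in range(n)], fraction, 0)
        assert (len(train), len(test)) == expected

    def test_partition_properties(self):
        ids = [f"s{i}" for i in range(37)]
        train, test = split_train_test(ids, 0.8, seed=3)
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()
        assert split_train_test(ids, 0.8, seed=3) == (train, test)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(["a", "b"], 1.0, 0)


class TestSoftThreshold:
    def test_deterministic(self):
        cfg = SimulationConfig(n_genes=200, n_samples=120, module_count=4,
                               module_size=40, intra_module_correlation=0.8,
                               seed=2)
        expr, _ = generate_normal_tissue(cfg)
        log = ExpressionMatrix(np.log2(expr.data + 1.0))
        assert pick_soft_threshold(log) == pick_soft_threshold(log)

    def test_unstructured_data_falls_back_to_max_r2(self, rng, caplog):
        expr = make_expression(rng.standard_normal((60, 40)))
        with caplog.at_level("WARNING"):
            beta = pick_soft_threshold(expr, candidate_powers=[1, 2, 3])
        assert beta in (1.0, 2.0, 3.0)

    def test_needs_two_candidates(self, rng):
        expr = make_expression(rng.standard_normal((10, 10)))
        with pytest.raises(ValueError):
            pick_soft_threshold(expr, candidate_powers=[6])


def planted_network(seed=0, rho=0.8, module_count=5, module_size=40,
                    n_genes=320, n_samples=200):
    cfg = SimulationConfig(
        n_genes=n_genes, n_samples=n_samples, module_count=module_count,
        module_size=module_size, intra_module_correlation=rho, seed=seed,
    )
    expr, truth = generate_normal_tissue(cfg)
    log = ExpressionMatrix(np.log2(expr.data + 1.0))
    truth_modules = np.array([truth.module_assignment[g] for g in expr.gene_ids])
    return log, truth_modules


class TestModuleDetection:
    @pytest.mark.parametrize("seed", range(3))
    def test_planted_modules_recovered(self, seed):
        log, truth_modules = planted_network(seed=seed)
        net = tom_from_expression(log, 6.0)
        detected = detect_modules(net, min_module_size=20, cut_height=0.97)
        recovered = 0
        for m in range(1, 6):
            planted = set(np.flatnonzero(truth_modules == m))
            best = max(
                (
                    len(planted & set(np.flatnonzero(detected == d)))
                    / len(planted | set(np.flatnonzero(detected == d)))
                    for d in set(detected) - {0}
                ),
                default=0.0,
            )
            recovered += best >= 0.7
        assert recovered >= 4

    def test_twenty_three_modules_recoverable(self):
        """A 23-module network (the realistic module count for breast
        tissue) is recovered at high within-module correlation."""
        log, truth_modules = planted_network(
            seed=1, rho=0.85, module_count=23, module_size=20, n_genes=600,
            n_samples=250,
        )
        net = tom_from_expression(log, 6.0)
        detected = detect_modules(net, min_module_size=10, cut_height=0.97)
        n_detected = len(set(detected) - {0})
        assert n_detected >= 20

    def test_degenerate_cut_unassigns_everything(self):
        log, _ = planted_network(seed=0, n_genes=100, module_count=2,
                                 module_size=20, n_samples=60)
        net = tom_from_expression(log, 6.0)
        detected = detect_modules(net, min_module_size=5, cut_height=1e-9)
        assert np.all(detected == 0)

    def test_labels_ordered_by_size(self):
        log, _ = planted_network(seed=0)
        net = tom_from_expression(log, 6.0)
        detected = detect_modules(net, min_module_size=20, cut_height=0.97)
        sizes = [np.sum(detected == m) for m in sorted(set(detected) - {0})]
        assert sizes == sorted(sizes, reverse=True)


class TestPreservation:
    def test_planted_module_extreme_rank(self):
        log, truth_modules = planted_network(seed=3, module_count=3,
                                             module_size=30, n_genes=200,
                                             n_samples=240)
        ids = log.sample_ids
        train, test = split_train_test(ids, 0.5, seed=0)
        train_x = ExpressionMatrix(log.data[train])
        test_x = ExpressionMatrix(log.data[test])
        res = module_preservation(train_x, test_x, truth_modules, n_perm=99,
                                  beta=6.0, seed=0)
        np.testing.assert_allclose(res["p"].to_numpy(), 1 / 100)
        assert res["preserved"].all()

    def test_random_module_not_preserved(self, rng):
        x = make_expression(rng.standard_normal((80, 120)))
        train_x = ExpressionMatrix(x.data.iloc[:, :60])
        test_x = ExpressionMatrix(x.data.iloc[:, 60:])
        modules = np.zeros(80, dtype=int)
        modules[rng.choice(80, 15, replace=False)] = 1
        res = module_preservation(train_x, test_x, modules, n_perm=99,
                                  beta=6.0, seed=1)
        assert res["p"].iloc[0] > 0.05

    def test_zero_permutations_rejected(self, rng):
        x = make_expression(rng.standard_normal((10, 12)))
        with pytest.raises(ValueError):
            module_preservation(x, x, np.ones(10, dtype=int), n_perm=0)


class TestEdgeFilter:
    def _net_with_modules(self, rng, n=12):
        c = rng.uniform(0.1, 0.9, size=(n, n))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 0.0)
        net = CoexpressionNetwork(
            gene_ids=[f"g{i}" for i in range(n)], beta=1.0, adjacency=a,
            tom=_tom_from_adjacency(a),
        )
        net.modules = np.array([1] * 5 + [2] * 5 + [0, 0])
        return net

    def test_counts_and_ceiling(self, rng):
        net = self._net_with_modules(rng)
        edges = filter_top_edges(net, fraction=0.10)
        # 5-gene module has C(5,2)=10 edges -> ceil(1.0)=1 edge kept
        assert len(edges[1]) == 1 and len(edges[2]) == 1
        all_weights = [
            net.adjacency[i, j]
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        assert edges[1][0][2] == pytest.approx(max(all_weights))

    def test_fraction_one_keeps_everything(self, rng):
        net = self._net_with_modules(rng)
        edges = filter_top_edges(net, fraction=1.0)
        assert len(edges[1]) == 10

    def test_requires_modules(self, rng):
        net = self._net_with_modules(rng)
        net.modules = None
        with pytest.raises(ValueError):
            filter_top_edges(net)


class TestOverlapAndEnrichment:
    def test_overlap_percentages(self):
        modules = {1: [f"g{i}" for i in range(10)], 2: ["x", "y"], 3: []}
        degs = [f"g{i}" for i in range(5)]
        pct = module_deg_overlap(modules, degs)
        assert pct[1] == pytest.approx(50.0)
        assert pct[2] == 0.0
        assert pct[3] == 0.0

    def test_lightcyan_style_proportion(self):
        """95-gene module with 11 DEG members -> 11.58%, printed as 11.6%."""
        module = [f"g{i}" for i in range(95)]
        degs = module[:11]
        pct = module_deg_overlap({1: module}, degs)[1]
        assert pct == pytest.approx(100 * 11 / 95)
        assert f"{pct:.1f}" == "11.6"

    def test_full_overlap_closed_form(self):
        """Universe 100, term 10, module 10, overlap 10: p = 1/C(100,10)."""
        universe = [f"g{i}" for i in range(100)]
        term = universe[:10]
        res = module_enrichment(term, {"T": term}, universe)
        assert res["p"].iloc[0] == pytest.approx(
            1.0 / comb(100, 10, exact=True), rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_random_module_rarely_enriched(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(400)]
        sets = {
            f"T{k}": list(rng.choice(universe, 25, replace=False))
            for k in range(30)
        }
        module = list(rng.choice(universe, 30, replace=False))
        res = module_enrichment(module, sets, universe, adj_threshold=1e-4)
        assert not res["significant"].any()

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            module_enrichment(["z"], {"T": ["a"]}, ["a", "b"])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            module_enrichment(["a"], {}, ["a"])
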