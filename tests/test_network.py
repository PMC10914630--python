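"""Adjacency, TOM modules, MDC permutation test, NHNN hubs, set enrichment."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from circasyn import SimulationConfig, simulate_cohort
from circasyn.network import (AdjacencyMatrix, ModuleConnectivityModel,
                              build_adjacency, detect_modules,
                              disease_specific_hubs, identify_hubs, mdc_test,
                              module_flag_enrichment, pick_soft_power,
                              tom_similarity)

from conftest import hypergeom_tail_oracle


def _block_data(rng, sizes, rs, n_samples):
    blocks = []
    for m, r in zip(sizes, rs):
        f = rng.standard_normal(n_samples)
        lam = np.sqrt(r)
        blocks.append(lam * f[None, :] + np.sqrt(1 - r) * rng.standard_normal((m, n_samples)))
    return np.vstack(blocks)


class TestAdjacency:
    def test_perfect_correlation_gives_unit_adjacency(self):
        x = np.arange(10.0)
        vals = np.vstack([x, 2 * x + 3, -x])
        for beta in (1, 6, 12):
            adj = build_adjacency(vals, beta=beta)
            assert adj.values[0, 1] == pytest.approx(1.0)
            assert adj.values[0, 2] == pytest.approx(1.0)   # unsigned

    def test_soft_threshold_suppresses_weak_correlations(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((20, 200))
        a1 = build_adjacency(vals, beta=1).values
        a12 = build_adjacency(vals, beta=12).values
        off = ~np.eye(20, dtype=bool)
        assert a12[off].mean() < a1[off].mean() / 10

    def test_matches_direct_correlation_formula(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 6))
        adj = build_adjacency(vals, beta=3)
        for i in range(5):
            for j in range(5):
                r = np.corrcoef(vals[i], vals[j])[0, 1]
                assert adj.values[i, j] == pytest.approx(abs(r) ** 3 if i != j else 1.0,
                                                         abs=1e-12)

    def test_constant_row_dropped(self):
        vals = np.vstack([np.ones(8), np.random.default_rng(2).normal(size=(3, 8))])
        adj = build_adjacency(vals, beta=2, protein_ids=["C", "A", "B", "D"])
        assert adj.protein_ids == ["A", "B", "D"]

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 30))
        scaled = vals * rng.uniform(0.5, 4, size=(6, 1)) + rng.normal(size=(6, 1))
        np.testing.assert_allclose(build_adjacency(vals, beta=6).values,
                                   build_adjacency(scaled, beta=6).values, atol=1e-12)


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(4)
        X = np.vstack([_block_data(rng, [40, 40], [0.8, 0.8], 120),
                       rng.standard_normal((40, 120))])
        adj = build_adjacency(X, beta=6)
        mods = detect_modules(adj, min_size=20, expr=X)
        truth = np.array([0] * 40 + [1] * 40 + [2] * 40)
        labels = pd.factorize(mods.to_numpy())[0]
        # adjusted agreement: planted blocks must map to two clean modules
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels) >= 0.95
        assert (mods.to_numpy()[:80] != "grey").all()

    def test_pure_noise_gives_no_modules(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 120))
        mods = detect_modules(build_adjacency(X, beta=6), min_size=20, expr=X)
        assert (mods == "grey").all()

    def test_order_invariance_up_to_labels(self):
        rng = np.random.default_rng(6)
        X = np.vstack([_block_data(rng, [30, 30], [0.8, 0.8], 100),
                       rng.standard_normal((20, 100))])
        ids = [f"P{i}" for i in range(80)]
        adj = build_adjacency(X, beta=6, protein_ids=ids)
        mods = detect_modules(adj, min_size=15, expr=X)
        perm = rng.permutation(80)
        adj_p = build_adjacency(X[perm], beta=6, protein_ids=[ids[i] for i in perm])
        mods_p = detect_modules(adj_p, min_size=15, expr=X[perm])
        joined = pd.concat([mods.rename("a"), mods_p.rename("b")], axis=1)
        # identical partition: each label in one maps to exactly one in the other
        assert joined.groupby("a")["b"].nunique().max() == 1

    def test_fewer_proteins_than_min_size_all_grey(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 40))
        mods = detect_modules(build_adjacency(X, beta=6), min_size=30)
        assert (mods == "grey").all()

    def test_tom_has_unit_diagonal_and_is_bounded(self):
        rng = np.random.default_rng(8)
        adj = build_adjacency(rng.normal(size=(15, 40)), beta=6)
        tom = tom_similarity(adj)
        np.testing.assert_allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0 and tom.max() <= 1
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)


def _group_pair(seed, r_u=0.6, r_o=0.6, n_per_group=20, n_proteins=200,
                n_modules=10, module_size=20):
    cfg = SimulationConfig(n_per_group=n_per_group, n_proteins=n_proteins,
                           n_modules=n_modules, module_size=module_size,
                           module_cor_by_group={"unaffected": r_u, "OUD": r_o},
                           frac_rhythmic=0, frac_de=0, seed=seed)
    ds, truth = simulate_cohort(cfg)
    members = list(truth.proteins.loc[truth.proteins["module"] == "M1", "protein_id"])
    return ds.select_group("unaffected"), ds.select_group("OUD"), members


class TestMDC:
    def test_identical_data_gives_mdc_exactly_one(self):
        u, o, members = _group_pair(seed=9)
        res = mdc_test(u, u, members, beta=6, n_perm=200, seed=1)
        assert res.mdc == 1.0
        assert res.direction == "unchanged"

    def test_attenuated_oud_correlation_called_loss(self):
        u, o, members = _group_pair(seed=10, r_u=0.7, r_o=0.175)
        res = mdc_test(u, o, members, beta=6, n_perm=1000, seed=2)
        assert res.mdc < 1.0
        assert res.direction == "loss"

    def test_swapped_groups_give_reciprocal_mdc(self):
        u, o, members = _group_pair(seed=11, r_u=0.8, r_o=0.2)
        fwd = mdc_test(u, o, members, beta=6, n_perm=500, seed=3)
        rev = mdc_test(o, u, members, beta=6, n_perm=500, seed=3)
        assert fwd.mdc * rev.mdc == pytest.approx(1.0, abs=1e-12)
        assert {fwd.direction, rev.direction} == {"loss", "gain"}

    def test_small_module_rejected(self):
        u, o, members = _group_pair(seed=12)
        with pytest.raises(ValueError):
            mdc_test(u, o, members[:2], beta=6)


class TestHubs:
    def test_equal_adjacency_yields_no_hubs(self):
        n = 6
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, 1.0)
        adj = AdjacencyMatrix([f"P{i}" for i in range(n)], vals, beta=1)
        hubs, nhnn = identify_hubs(adj, adj.protein_ids)
        assert hubs == set()
        assert (nhnn == 0).all()

    def test_star_center_is_unique_hub(self):
        n = 12
        vals = np.full((n, n), 0.1)
        strong = np.linspace(0.5, 0.9, n - 1)   # distinct spoke weights
        vals[0, 1:] = vals[1:, 0] = strong
        np.fill_diagonal(vals, 1.0)
        adj = AdjacencyMatrix([f"P{i}" for i in range(n)], vals, beta=1)
        hubs, nhnn = identify_hubs(adj, adj.protein_ids, quantile=0.90, n_hops=1)
        assert hubs == {"P0"}

    def test_matches_bfs_oracle_on_random_adjacency(self):
        rng = np.random.default_rng(13)
        for n_hops in (1, 2):
            for rep in range(5):
                n = 10
                w = rng.random((n, n))
                vals = (w + w.T) / 2
                np.fill_diagonal(vals, 1.0)
                ids = [f"P{i}" for i in range(n)]
                adj = AdjacencyMatrix(ids, vals, beta=1)
                hubs, nhnn = identify_hubs(adj, ids, quantile=0.90, n_hops=n_hops)
                # oracle: threshold, then BFS-count n-hop neighborhoods
                off = vals[~np.eye(n, dtype=bool)]
                thr = np.quantile(off, 0.90)
                g = nx.Graph()
                g.add_nodes_from(range(n))
                for i in range(n):
                    for j in range(i + 1, n):
                        if vals[i, j] > thr:
                            g.add_edge(i, j)
                counts = []
                for i in range(n):
                    seen, frontier = {i}, {i}
                    for _ in range(n_hops):
                        frontier = {v for u in frontier for v in g.neighbors(u)} - seen
                        seen |= frontier
                    counts.append(len(seen) - 1)
                counts = np.array(counts, dtype=float)
                expected = {ids[i] for i in range(n) if counts[i] > counts.mean()}
                assert hubs == expected
                np.testing.assert_array_equal(nhnn.to_numpy(), counts)

    def test_disease_specific_hubs_set_algebra(self):
        assert disease_specific_hubs({"A", "B"}, {"B", "C"}) == ({"A"}, {"C"}, {"B"})
        assert disease_specific_hubs({"A"}, {"A"}) == (set(), set(), {"A"})
        assert disease_specific_hubs({"A"}, {"B"}) == ({"A"}, {"B"}, set())


class TestModuleFlagEnrichment:
    def test_worked_example(self):
        bg = [f"P{i}" for i in range(10)]
        p, fold = module_flag_enrichment(bg[:4], bg[:4], bg)
        assert p == pytest.approx(1 / 210, abs=1e-12)
        assert fold == pytest.approx(4 / (4 * 4 / 10))

    def test_flagged_equals_background(self):
        bg = [f"P{i}" for i in range(12)]
        p, fold = module_flag_enrichment(bg[:5], bg, bg)
        assert p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            N = int(rng.integers(8, 30))
            bg = [f"P{i}" for i in range(N)]
            members = list(rng.choice(bg, size=int(rng.integers(2, N // 2 + 2)), replace=False))
            flagged = list(rng.choice(bg, size=int(rng.integers(1, N // 2 + 2)), replace=False))
            p, _ = module_flag_enrichment(members, flagged, bg)
            k = len(set(members) & set(flagged))
            assert p == pytest.approx(
                hypergeom_tail_oracle(k, N, len(flagged), len(members)), abs=1e-12)


def test_model_results_workflow():
    cfg = SimulationConfig(n_per_group=20, n_proteins=150, n_modules=2, module_size=40,
                           module_cor_by_group={"unaffected": 0.7, "OUD": 0.2},
                           frac_rhythmic=0, frac_de=0, seed=15)
    ds, truth = simulate_cohort(cfg)
    model = ModuleConnectivityModel(ds, beta=6.0, min_size=20)
    res = model.fit(n_perm=300, seed=1)
    table = res.summary_table()
    assert len(res.modules) >= 1
    assert (table["direction"] == "loss").all()
    assert "loss" in res.summary()


def test_pick_soft_power_returns_integer_in_range():
    rng = np.random.default_rng(16)
    X = np.vstack([_block_data(rng, [30, 30, 30], [0.7, 0.5, 0.6], 60),
                   rng.standard_normal((60, 60))])
    beta = pick_soft_power(X)
    assert 1 <= beta <= 20
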