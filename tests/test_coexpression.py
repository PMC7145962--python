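"""Weighted co-expression core: adjacency, TOM, module detection,
eigengenes and trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from bridgefinder import coexpression as cx
from tests.conftest import gene_level_matrix, three_module_config


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Naive O(n^3) topological overlap oracle."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            tom[i, j] = (shared + a[i, j]) / denom if denom > 0 else 0.0
    return tom


class TestAdjacency:
    def test_power_arithmetic(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        noise = rng.normal(size=20)
        x1 = base
        # construct a pair with known correlation then check a = |r|^beta
        x2 = 0.5 * base + np.sqrt(1 - 0.25) * noise
        m = pd.DataFrame([x1, x2], index=["g1", "g2"])
        r = abs(np.corrcoef(x1, x2)[0, 1])
        a = cx.adjacency(m, 2)
        assert a.loc["g1", "g2"] == pytest.approx(r**2, abs=1e-12)

    def test_anticorrelation_is_unsigned(self):
        x = np.arange(10, dtype=float)
        m = pd.DataFrame([x, -0.9 * x + np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])],
                         index=["g1", "g2"])
        r = np.corrcoef(m.to_numpy())[0, 1]
        assert r < 0
        a = cx.adjacency(m, 1)
        assert a.loc["g1", "g2"] == pytest.approx(abs(r))

    def test_perfect_pair_any_power(self):
        x = np.arange(8, dtype=float)
        m = pd.DataFrame([x, 2 * x + 3], index=["g1", "g2"])
        for beta in (1, 3, 7):
            assert cx.adjacency(m, beta).loc["g1", "g2"] == pytest.approx(1.0)


class TestTOM:
    def test_two_gene_closed_form(self):
        for a12 in (0.0, 0.3, 0.8, 1.0):
            adj = np.array([[1.0, a12], [a12, 1.0]])
            tom = cx.tom_similarity(adj)
            assert tom[0, 1] == pytest.approx(a12, abs=1e-15)

    def test_complete_graph_gives_one(self):
        adj = np.ones((6, 6))
        tom = cx.tom_similarity(adj)
        assert np.allclose(tom, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.tom_similarity(a)
        assert np.max(np.abs(tom - brute_force_tom(a))) < 1e-12

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, size=(15, 15))
        a = (a + a.T) / 2
        tom = cx.tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(np.diag(tom), 1.0)


class TestSoftThreshold:
    def test_mean_connectivity_non_increasing(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(40, 30)), index=[f"g{i}" for i in range(40)]
        )
        report = cx.pick_soft_threshold(m)
        k = report.table["mean_connectivity"].to_numpy()
        assert (np.diff(k) <= 1e-12).all()

    def test_degenerate_equal_connectivity_handled(self):
        # two noiseless modules: every beta gives identical k within module
        x = np.arange(12, dtype=float)
        rows = [x, 2 * x, 3 * x + 1, -x + 5, -2 * x, -x * 3 + 2]
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(6)])
        report = cx.pick_soft_threshold(m)
        assert report.chosen in range(1, 21)

    def test_scale_free_input_reaches_target(self, rng):
        # hub-and-spoke style data: a few latent factors with power-law
        # loadings give a heavy-tailed connectivity distribution
        n, g = 120, 300
        exponents = rng.pareto(2.0, size=g) + 0.1
        factor = rng.normal(size=n)
        rows = [
            e / (1 + e) * factor + (1 / (1 + e)) * rng.normal(size=n)
            for e in exponents
        ]
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(g)])
        report = cx.pick_soft_threshold(m)
        assert report.table["r2_signed"].max() >= 0.8

    def test_too_few_genes_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(2, 10)))
        with pytest.raises(ValueError):
            cx.pick_soft_threshold(m)


class TestEigengene:
    def test_two_identical_genes(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        m = pd.DataFrame([x, x], index=["g1", "g2"], columns=list("abcdef"))
        e = cx.module_eigengene(m, ["g1", "g2"])
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(e.to_numpy(), z, atol=1e-12)

    def test_unit_variance_and_orientation(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(10, 50)), index=[f"g{i}" for i in range(10)]
        )
        e = cx.module_eigengene(m, list(m.index))
        assert e.std(ddof=1) == pytest.approx(1.0)
        cors = [np.corrcoef(e, m.loc[g])[0, 1] for g in m.index]
        assert np.mean(cors) >= 0

    def test_sign_flip_of_members_flips_eigengene(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(8, 40)), index=[f"g{i}" for i in range(8)]
        )
        e1 = cx.module_eigengene(m, list(m.index))
        e2 = cx.module_eigengene(-m, list(m.index))
        assert np.allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-10)

    def test_recovers_latent_factor(self):
        config = three_module_config(seed=8, n_per_group=100, within_cor=0.7,
                                     module_size=100)
        config.trait_effect = {0: {}, 1: {}, 2: {}}
        matrix, _, truth = gene_level_matrix(config)
        genes = truth.module_genes(0)
        e = cx.module_eigengene(matrix, genes)
        # the mean standardized member profile is a proxy for the factor
        sub = matrix.loc[genes].to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        factor_proxy = z.mean(axis=0)
        assert abs(np.corrcoef(e, factor_proxy)[0, 1]) >= 0.95


class TestModuleDetection:
    def test_three_planted_modules_recovered(self):
        config = three_module_config(seed=1)
        matrix, _, truth = gene_level_matrix(config)
        adj = cx.adjacency(matrix, 6)
        tom = cx.tom_similarity(adj)
        modules = cx.detect_modules(tom, matrix)
        truth_labels = [truth.gene_module[g] for g in matrix.index]
        ari = adjusted_rand_score(truth_labels, modules.labels[matrix.index])
        assert ari >= 0.95
        assert modules.eigengenes.shape[1] == 3

    def test_single_block_of_identical_genes(self):
        x = np.arange(40, dtype=float)
        rng = np.random.default_rng(0)
        rows = [x * (i + 1) + i for i in range(35)]
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(35)])
        tom = cx.tom_similarity(cx.adjacency(m, 6))
        modules = cx.detect_modules(tom, m, min_size=30)
        assert set(modules.labels) == {"turquoise"}

    def test_independent_genes_all_grey(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(
            rng.normal(size=(100, 60)), index=[f"g{i}" for i in range(100)]
        )
        tom = cx.tom_similarity(cx.adjacency(m, 6))
        modules = cx.detect_modules(tom, m, min_size=30)
        assert set(modules.labels) == {"grey"}

    def test_gene_order_invariance(self):
        config = three_module_config(seed=2, n_per_group=60, module_size=40)
        matrix, _, _ = gene_level_matrix(config)
        shuffled = matrix.sample(frac=1.0, random_state=99)
        out1 = cx.detect_modules(cx.tom_similarity(cx.adjacency(matrix, 6)), matrix)
        out2 = cx.detect_modules(
            cx.tom_similarity(cx.adjacency(shuffled, 6)), shuffled
        )
        joined = pd.concat(
            [out1.labels.rename("a"), out2.labels.rename("b")], axis=1
        )
        ari = adjusted_rand_score(joined["a"], joined["b"])
        assert ari == pytest.approx(1.0)


class TestTraitCorrelation:
    def test_perfect_indicator(self):
        trait = np.array([0.0] * 10 + [1.0] * 10)
        r, p = cx.module_trait_correlation(pd.Series(trait), trait)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_null_correlation_is_small(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            e = rng.normal(size=500)
            trait = (np.arange(500) < 250).astype(float)
            r, p = cx.module_trait_correlation(pd.Series(e), trait)
            if abs(r) < 0.12 and p > 0.01:
                hits += 1
        assert hits >= 95

    def test_planted_negative_effect_recovered(self):
        config = three_module_config(seed=4)
        matrix, meta, truth = gene_level_matrix(config)
        e = cx.module_eigengene(matrix, truth.module_genes(0))
        trait = (meta.set_index("sample_id").loc[e.index, "diagnosis"] == "MCI").astype(float)
        r, p = cx.module_trait_correlation(e, trait)
        assert r < 0 and p < 0.05

    def test_single_class_trait_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cx.module_trait_correlation(pd.Series([1.0, 2.0]), np.array([1.0, 1.0]))


class TestEdgeExport:
    def _toy_modules(self):
        genes = ["g1", "g2", "g3", "g4"]
        tom = pd.DataFrame(
            [
                [1.0, 0.9, 0.5, 0.1],
                [0.9, 1.0, 0.4, 0.2],
                [0.5, 0.4, 1.0, 0.05],
                [0.1, 0.2, 0.05, 1.0],
            ],
            index=genes,
            columns=genes,
        )
        labels = pd.Series("turquoise", index=genes)
        eg = pd.DataFrame({"turquoise": np.zeros(3)}, index=["s1", "s2", "s3"])
        return tom, cx.ModuleSet(labels=labels, eigengenes=eg)

    def test_threshold_zero_keeps_all_positive_edges(self):
        tom, modules = self._toy_modules()
        out = cx.export_module_network(tom, modules, 0.0)
        assert len(out.edges) == 6  # all pairs have weight > 0

    def test_threshold_near_one_empties(self):
        tom, modules = self._toy_modules()
        out = cx.export_module_network(tom, modules, 0.99)
        assert out.edges.empty
        assert (out.degrees["degree"] == 0).all()

    def test_hand_computed_degrees(self):
        tom, modules = self._toy_modules()
        out = cx.export_module_network(tom, modules, 0.3)
        # edges > 0.3: (g1,g2)=.9, (g1,g3)=.5, (g2,g3)=.4
        deg = out.degrees.set_index("gene")["degree"]
        assert deg["g1"] == 2 and deg["g2"] == 2 and deg["g3"] == 2 and deg["g4"] == 0
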