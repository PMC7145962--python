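"""Probe collapse, platform merge, sample filtering and batch adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from bridgefinder import preprocess as pp
from bridgefinder import simulate


def _matrix(values, index, columns):
    return pd.DataFrame(values, index=index, columns=columns)


class TestCollapseProbes:
    @pytest.mark.parametrize(
        "probe_values,expected",
        [([1.0, 3.0], 2.0), ([5.0], 5.0), ([0.0, 1.0, 5.0], 2.0)],
    )
    def test_mean_over_probes(self, probe_values, expected):
        m = _matrix(
            [[v] for v in probe_values],
            [f"p{i}" for i in range(len(probe_values))],
            ["s1"],
        )
        mapping = {f"p{i}": "G1" for i in range(len(probe_values))}
        out = pp.collapse_probes(m, mapping)
        assert out.loc["G1", "s1"] == pytest.approx(expected)

    def test_unmapped_probes_dropped(self):
        m = _matrix([[1.0], [9.0]], ["p1", "px"], ["s1"])
        out = pp.collapse_probes(m, {"p1": "G1"})
        assert list(out.index) == ["G1"]

    def test_empty_mapping_rejected(self):
        m = _matrix([[1.0]], ["p1"], ["s1"])
        with pytest.raises(ValueError, match="empty"):
            pp.collapse_probes(m, {})

    def test_probe_with_two_genes_rejected(self):
        m = _matrix([[1.0]], ["p1"], ["s1"])
        mapping = pd.DataFrame({"probe": ["p1", "p1"], "gene": ["G1", "G2"]})
        with pytest.raises(ValueError, match="p1"):
            pp.collapse_probes(m, mapping)


class TestMergePlatforms:
    def test_intersection_of_gene_sets(self):
        a = _matrix(np.ones((3, 2)), ["A", "B", "C"], ["s1", "s2"])
        b = _matrix(np.ones((3, 2)), ["B", "C", "D"], ["t1", "t2"])
        merged = pp.merge_platforms(a, b)
        assert list(merged.index) == ["B", "C"]
        assert list(merged.columns) == ["s1", "s2", "t1", "t2"]

    def test_identical_gene_sets_keep_all_rows(self):
        genes = [f"G{i}" for i in range(100)]
        a = _matrix(np.zeros((100, 2)), genes, ["s1", "s2"])
        b = _matrix(np.zeros((100, 2)), genes, ["t1", "t2"])
        assert pp.merge_platforms(a, b).shape[0] == 100

    def test_partial_overlap_counted(self, rng):
        genes_a = [f"G{i}" for i in range(25)]
        genes_b = [f"G{i}" for i in range(6, 31)]  # shares G6..G24 -> 19
        a = _matrix(rng.normal(size=(25, 3)), genes_a, ["a1", "a2", "a3"])
        b = _matrix(rng.normal(size=(25, 3)), genes_b, ["b1", "b2", "b3"])
        assert pp.merge_platforms(a, b).shape[0] == 19

    def test_empty_intersection_rejected(self):
        a = _matrix([[1.0]], ["A"], ["s1"])
        b = _matrix([[1.0]], ["B"], ["t1"])
        with pytest.raises(ValueError, match="shared"):
            pp.merge_platforms(a, b)

    def test_duplicate_sample_ids_rejected(self):
        a = _matrix([[1.0]], ["A"], ["s1"])
        b = _matrix([[1.0]], ["A"], ["s1"])
        with pytest.raises(ValueError, match="duplicate"):
            pp.merge_platforms(a, b)


class TestFilterSamples:
    def test_study_composition_yields_711(self, small_sim, paper_composition_config):
        meta = small_sim.metadata
        matrix = _matrix(
            np.zeros((2, len(meta))), ["G1", "G2"], meta["sample_id"].to_numpy()
        )
        out, out_meta, counts = pp.filter_samples(matrix, meta)
        assert out.shape[1] == 711
        assert counts == {"MCI": 189, "AD": 284, "CTL": 238}

    def test_keep_all_labels_is_identity(self, small_sim):
        meta = small_sim.metadata
        matrix = _matrix(
            np.zeros((1, len(meta))), ["G1"], meta["sample_id"].to_numpy()
        )
        out, _, _ = pp.filter_samples(
            matrix, meta, keep=set(meta["diagnosis"].unique())
        )
        assert list(out.columns) == list(matrix.columns)

    def test_empty_keep_empties_samples_not_genes(self, small_sim):
        meta = small_sim.metadata
        matrix = _matrix(
            np.zeros((3, len(meta))), ["G1", "G2", "G3"], meta["sample_id"].to_numpy()
        )
        out, out_meta, counts = pp.filter_samples(matrix, meta, keep=set())
        assert out.shape == (3, 0)
        assert counts == {}

    def test_sample_missing_from_metadata_rejected(self, small_sim):
        meta = small_sim.metadata
        matrix = _matrix(np.zeros((1, 2)), ["G1"], ["ghost1", "ghost2"])
        with pytest.raises(ValueError, match="missing"):
            pp.filter_samples(matrix, meta)


class TestAdjustBatch:
    def _shifted_batches(self, rng, n_genes=50, n=40, shift=2.0):
        a = rng.normal(5.0, 1.0, size=(n_genes, n))
        b = rng.normal(5.0, 1.0, size=(n_genes, n)) + shift
        m = _matrix(
            np.hstack([a, b]),
            [f"G{i}" for i in range(n_genes)],
            [f"s{i}" for i in range(2 * n)],
        )
        batch = ["A"] * n + ["B"] * n
        return m, batch

    def test_constant_shift_removed_exactly(self, rng):
        m, batch = self._shifted_batches(rng)
        out = pp.adjust_batch(m, batch, shrink=False)
        means_a = out.iloc[:, :40].mean(axis=1)
        means_b = out.iloc[:, 40:].mean(axis=1)
        assert np.max(np.abs(means_a - means_b)) < 1e-9

    def test_scale_difference_equalized(self):
        rng = np.random.default_rng(77)
        a = rng.normal(0.0, 1.0, size=(1, 500))
        b = rng.normal(3.0, 2.0, size=(1, 500))
        m = _matrix(np.hstack([a, b]), ["G0"], [f"s{i}" for i in range(1000)])
        out = pp.adjust_batch(m, ["A"] * 500 + ["B"] * 500, shrink=False)
        va = out.iloc[0, :500].var()
        vb = out.iloc[0, 500:].var()
        assert abs(va - vb) / max(va, vb) < 0.05

    def test_single_gene_shrink_degenerates_gracefully(self):
        rng = np.random.default_rng(5)
        m = _matrix(
            rng.normal(size=(1, 40)), ["G0"], [f"s{i}" for i in range(40)]
        )
        batch = ["A"] * 20 + ["B"] * 20
        shrunk = pp.adjust_batch(m, batch, shrink=True)
        plain = pp.adjust_batch(m, batch, shrink=False)
        pd.testing.assert_frame_equal(shrunk, plain)

    def test_identical_batches_nearly_unchanged(self):
        rng = np.random.default_rng(9)
        n = 200
        m = _matrix(
            rng.normal(7.0, 1.0, size=(30, 2 * n)),
            [f"G{i}" for i in range(30)],
            [f"s{i}" for i in range(2 * n)],
        )
        out = pp.adjust_batch(m, ["A"] * n + ["B"] * n, shrink=True)
        se = 1.0 / np.sqrt(n)
        assert np.max(np.abs(out.to_numpy() - m.to_numpy())) < 3 * se

    def test_dimensions_preserved(self, rng):
        m, batch = self._shifted_batches(rng)
        out = pp.adjust_batch(m, batch)
        assert out.shape == m.shape
        assert list(out.index) == list(m.index)
        assert list(out.columns) == list(m.columns)

    def test_small_batch_rejected(self):
        m = _matrix(np.zeros((2, 3)), ["G1", "G2"], ["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="fewer than 2"):
            pp.adjust_batch(m, ["A", "A", "B"])

    def test_silhouette_drops_after_adjustment(self, small_sim):
        gene_a = pp.collapse_probes(small_sim.platform_a, small_sim.probe_to_gene_a)
        gene_b = pp.collapse_probes(small_sim.platform_b, small_sim.probe_to_gene_b)
        merged = pp.merge_platforms(gene_a, gene_b)
        merged, meta, _ = pp.filter_samples(merged, small_sim.metadata)
        mi = meta.set_index("sample_id")
        labels = mi.loc[merged.columns, "platform"]
        adjusted = pp.adjust_batch(
            merged, labels, covariates=mi.loc[merged.columns, "diagnosis"]
        )
        pcs = PCA(n_components=2).fit_transform(adjusted.to_numpy().T)
        assert silhouette_score(pcs, labels) < 0.1

    def test_batch_f_statistics_null_before_vs_suppressed_after(self):
        # on null data the per-gene batch F statistic follows F(1, n-2)
        # before adjustment; after adjustment observed batch differences
        # are removed, so the statistics collapse toward zero
        rng = np.random.default_rng(21)
        n = 100
        m = _matrix(
            rng.normal(size=(400, 2 * n)),
            [f"G{i}" for i in range(400)],
            [f"s{i}" for i in range(2 * n)],
        )
        batch = np.array(["A"] * n + ["B"] * n)

        def f_stats(frame):
            x = frame.to_numpy()
            a, b = x[:, :n], x[:, n:]
            num = n * ((a.mean(1) - x.mean(1)) ** 2 + (b.mean(1) - x.mean(1)) ** 2)
            resid = np.hstack([a - a.mean(1, keepdims=True), b - b.mean(1, keepdims=True)])
            den = (resid**2).sum(1) / (2 * n - 2)
            return num / den

        before = f_stats(m)
        ks_p = stats.kstest(before, stats.f(1, 2 * n - 2).cdf).pvalue
        assert ks_p > 0.01
        after = f_stats(pp.adjust_batch(m, batch, shrink=False))
        assert after.mean() < before.mean()


class TestCommutation:
    def test_collapse_then_merge_commutes_with_column_subset(self, small_sim):
        gene_a = pp.collapse_probes(small_sim.platform_a, small_sim.probe_to_gene_a)
        gene_b = pp.collapse_probes(small_sim.platform_b, small_sim.probe_to_gene_b)
        merged = pp.merge_platforms(gene_a, gene_b)
        cols = list(merged.columns[::7])
        direct = merged[cols]
        a_cols = [c for c in cols if c in gene_a.columns]
        b_cols = [c for c in cols if c in gene_b.columns]
        sub = pp.merge_platforms(
            pp.collapse_probes(small_sim.platform_a[a_cols], small_sim.probe_to_gene_a),
            pp.collapse_probes(small_sim.platform_b[b_cols], small_sim.probe_to_gene_b),
        )
        pd.testing.assert_frame_equal(direct, sub)
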