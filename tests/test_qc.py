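"""QC filters and the pseudobulk normalization chain."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ddgnet.datatypes import CellCounts, PseudobulkSet, SchemaError, StageError
from ddgnet.qc import (
    filter_cells,
    filter_genes_min_cells,
    filter_low_expressed,
    mean_expression,
    normalize_cpm,
    quantile_normalize,
    quantile_normalize_frame,
    vst,
    vst_transform_values,
)


def _toy_counts(matrix, gene_flags=None, samples=None, clusters=None):
    matrix = np.asarray(matrix)
    n_genes, n_cells = matrix.shape
    gene_meta = pd.DataFrame({
        "symbol": [f"g{i}" for i in range(n_genes)],
        "chrom": ["1"] * n_genes,
        "tss_pos": np.arange(1, n_genes + 1),
        "mito": [False] * n_genes,
        "rpl": [False] * n_genes,
        "rps": [False] * n_genes,
    })
    if gene_flags:
        for col, flags in gene_flags.items():
            gene_meta[col] = flags
    cell_meta = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n_cells)],
        "sample_id": samples or ["s1"] * n_cells,
        "cluster_label": clusters or ["A"] * n_cells,
    })
    return CellCounts(sp.csr_matrix(matrix), gene_meta, cell_meta)


class TestFilterCells:
    def test_read_bounds_are_inclusive(self):
        # totals 100, 400, 3000, 6200, 7000 across one high-count gene
        counts = _toy_counts(np.array([[100, 400, 3000, 6200, 7000]]))
        kept = filter_cells(counts, min_features=1)
        assert kept.n_cells == 3
        assert list(np.asarray(kept.matrix.sum(axis=0)).ravel()) == [400, 3000, 6200]

    def test_all_zero_cell_removed(self):
        counts = _toy_counts(np.array([[0, 500], [0, 500]]))
        kept = filter_cells(counts, min_features=1)
        assert kept.n_cells == 1

    def test_mito_fraction_filter(self):
        m = np.array([[50, 200], [450, 1800]])  # mito fractions 0.10, 0.10
        counts = _toy_counts(m, gene_flags={"mito": [True, False]})
        assert filter_cells(counts, min_features=1).n_cells == 2
        m2 = np.array([[51, 200], [449, 1800]])  # first cell now > 10%
        counts2 = _toy_counts(m2, gene_flags={"mito": [True, False]})
        assert filter_cells(counts2, min_features=1).n_cells == 1

    def test_missing_flags_raise_schema_error(self):
        counts = _toy_counts(np.array([[500]]))
        counts.gene_meta = counts.gene_meta.drop(columns=["mito"])
        with pytest.raises(SchemaError):
            filter_cells(counts)

    def test_idempotent(self, default_population):
        counts, *_ = default_population
        once = filter_cells(counts)
        twice = filter_cells(once)
        assert once.n_cells == twice.n_cells


def test_filter_genes_min_cells_counting():
    m = np.zeros((5, 4))
    for g in range(5):
        m[g, :g] = 1  # gene g detected in g cells
    counts = _toy_counts(m)
    assert filter_genes_min_cells(counts, 3).n_genes == 2
    assert filter_genes_min_cells(counts, 0).n_genes == 5


class TestMeanExpression:
    def test_mean_rounded_to_two_decimals(self):
        m = np.array([[1, 2, 7, 7, 7, 7, 7]])
        samples = ["a"] * 2 + ["b"] * 5
        counts = _toy_counts(m, samples=samples)
        pb = mean_expression(counts, min_cells=2)
        assert pb.matrices["A"].loc["g0", "a"] == 1.50
        assert pb.matrices["A"].loc["g0", "b"] == 7.00

    def test_min_cells_column_omitted(self):
        samples = ["a"] * 4 + ["b"] * 5
        counts = _toy_counts(np.ones((1, 9)), samples=samples)
        pb = mean_expression(counts, min_cells=5)
        assert list(pb.matrices["A"].columns) == ["b"]

    def test_commutes_with_cell_permutation(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 10, size=(6, 30))
        samples = list(rng.choice(["a", "b", "c"], size=30))
        counts = _toy_counts(m, samples=samples)
        perm = rng.permutation(30)
        shuffled = _toy_counts(m[:, perm], samples=[samples[i] for i in perm])
        pd.testing.assert_frame_equal(
            mean_expression(counts).matrices["A"],
            mean_expression(shuffled).matrices["A"],
        )


def test_filter_low_expressed_threshold():
    mat = pd.DataFrame(np.zeros((3, 20)), index=list("abc"))
    mat.iloc[0, :10] = 1.0
    mat.iloc[1, :14] = 1.0
    mat.iloc[2, :15] = 1.0
    pb = PseudobulkSet({"A": mat}, "raw_mean")
    out = filter_low_expressed(pb, 15)
    assert list(out.matrices["A"].index) == ["c"]
    assert filter_low_expressed(pb, 0).matrices["A"].shape[0] == 3


class TestCPM:
    def test_uniform_column(self):
        mat = pd.DataFrame({"s": [1.0, 1.0, 1.0, 1.0]})
        out = normalize_cpm(PseudobulkSet({"A": mat}, "raw_mean"))
        assert np.allclose(out.matrices["A"]["s"], 250_000)

    def test_proportional_scaling_and_sum(self):
        mat = pd.DataFrame({"s": [1.0, 3.0]})
        out = normalize_cpm(PseudobulkSet({"A": mat}, "raw_mean"))
        assert np.allclose(out.matrices["A"]["s"], [250_000, 750_000])
        assert np.isclose(out.matrices["A"].sum().iloc[0], 1e6, rtol=1e-6)

    def test_zero_column_raises(self):
        mat = pd.DataFrame({"s": [0.0, 0.0]})
        with pytest.raises(ValueError, match="s"):
            normalize_cpm(PseudobulkSet({"A": mat}, "raw_mean"))


class TestVST:
    def test_closed_form_at_zero(self):
        assert np.isclose(vst_transform_values(np.array([0.0]), 0.5, 1.0)[0], 0.0)

    def test_strictly_increasing(self):
        q = np.linspace(0, 1000, 500)
        for a0, a1 in [(0.05, 2.0), (0.5, 1.0), (1.0, 0.0)]:
            f = vst_transform_values(q, a0, a1)
            assert np.all(np.diff(f) > 0)

    def test_variance_flattening_on_nb_simulation(self):
        """On NB data with a known trend the transform flattens the
        mean-variance relationship (max/min binned variance < 3 vs > 10)."""
        rng = np.random.default_rng(0)
        a0, a1 = 0.05, 2.0
        mus = np.geomspace(1, 1000, 60)
        n = 50
        raw = np.empty((60, n))
        for i, mu in enumerate(mus):
            alpha = a1 / mu + a0
            r = 1 / alpha
            raw[i] = rng.negative_binomial(r, r / (r + mu), size=n)
        pre_var = raw.var(axis=1, ddof=1)
        bins = np.array_split(np.arange(60), 6)
        pre = [pre_var[b].mean() for b in bins]
        assert max(pre) / max(min(pre), 1e-9) > 10
        f = vst_transform_values(raw, a0, a1)
        post_var = f.var(axis=1, ddof=1)
        post = [post_var[b].mean() for b in bins[1:]]  # lowest-mean bin is
        # quantization-dominated at mu ~ 1
        assert max(post) / max(min(post), 1e-9) < 3

    def test_vst_requires_cpm_stage(self):
        mat = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        with pytest.raises(StageError):
            vst(PseudobulkSet({"A": mat}, "raw_mean"))


class TestQuantileNormalize:
    def test_two_by_two_worked_example(self):
        mat = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize_frame(mat)
        assert np.allclose(out["a"], [1.5, 3.5])
        assert np.allclose(out["b"], [1.5, 3.5])

    def test_identical_columns_unchanged(self):
        mat = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize_frame(mat), mat)

    def test_columns_share_sorted_values_without_ties(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(100, 8)))
        X = quantile_normalize_frame(mat).to_numpy()
        ref = np.sort(X[:, 0])
        for j in range(1, X.shape[1]):
            assert np.allclose(np.sort(X[:, j]), ref, atol=1e-9)

    def test_column_distributions_match_on_pseudobulk(self, default_pseudobulk):
        """With ties (zeros) the tie rule perturbs individual order
        statistics, but the column empirical distributions still coincide
        (Kolmogorov distance ~ 0)."""
        from scipy.stats import ks_2samp

        for mat in default_pseudobulk.matrices.values():
            X = mat.to_numpy()
            for j in range(1, X.shape[1]):
                assert ks_2samp(X[:, 0], X[:, j]).statistic <= 0.02

    def test_ties_get_mean_of_spanned_reference(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 10.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize_frame(mat)
        ref = np.sort(mat.to_numpy(), axis=0).mean(axis=1)
        assert np.allclose(out["a"], [(ref[0] + ref[1]) / 2] * 2 + [ref[2]])


def test_stage_order_enforced():
    mat = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]})
    pb = PseudobulkSet({"A": mat}, "raw_mean")
    with pytest.raises(StageError):
        quantile_normalize(pb)
    with pytest.raises(StageError):
        PseudobulkSet({"A": mat}, "nope")
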