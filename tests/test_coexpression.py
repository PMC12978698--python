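"""Signed adjacency, TOM, module detection and iterative kME refinement."""

import numpy as np
import pandas as pd
import pytest

from ddgnet.coexpression import (
    detect_cluster_modules,
    detect_modules,
    iterative_refine,
    module_eigengene,
    pick_soft_threshold,
    signed_adjacency,
    tom_similarity,
)


def _expr_from_corr(blocks, n_samples=60, noise=0.5, seed=0):
    """Block-structured genes x samples frame: genes within a block share a
    latent factor."""
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for b, size in enumerate(blocks):
        z = rng.normal(size=n_samples)
        for g in range(size):
            rows.append(z + rng.normal(0, noise, size=n_samples))
            names.append(f"b{b}g{g}")
    return pd.DataFrame(rows, index=names)


class TestSignedAdjacency:
    def test_range_endpoints(self):
        x = np.arange(10, dtype=float)
        expr = pd.DataFrame([x, 2 * x + 1, -x], index=["a", "b", "c"])
        a = signed_adjacency(expr, beta=14)
        assert np.isclose(a.loc["a", "b"], 1.0)
        assert np.isclose(a.loc["a", "c"], 0.0)

    def test_zero_correlation_value(self):
        assert np.isclose(((1 + 0) / 2) ** 14, 1 / 16384)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(2, 100000)), index=["a", "b"])
        a = signed_adjacency(expr, beta=14)
        assert a.loc["a", "b"] < 1e-3  # ~0.5^14

    def test_symmetric_unit_interval(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(8, 30)))
        a = signed_adjacency(expr, beta=6).to_numpy()
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1

    def test_zero_variance_gene_raises(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "x"])
        with pytest.raises(ValueError, match="flat"):
            signed_adjacency(expr)


class TestTOM:
    def test_hand_computed_triangle(self):
        a = pd.DataFrame(0.5 * (1 - np.eye(3)) + np.eye(3),
                         index=list("abc"), columns=list("abc"))
        w = tom_similarity(a)
        assert np.allclose(w.to_numpy()[~np.eye(3, dtype=bool)], 0.5)

    def test_empty_adjacency(self):
        a = pd.DataFrame(np.eye(4))
        w = tom_similarity(a).to_numpy()
        off = w[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(20, 30)))
        A = signed_adjacency(expr, beta=6)
        W = tom_similarity(A).to_numpy()
        a = A.to_numpy()
        k = a.sum(axis=1) - 1
        n = len(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                w = (num + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert np.isclose(W[i, j], w, atol=1e-12)


class TestSoftThreshold:
    def test_default_when_no_power_reaches_target(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(30, 10)))
        # pure noise at few samples rarely reaches scale-free fit 0.999
        assert pick_soft_threshold(expr, powers=(1, 2), r2_target=0.9999) == 14.0

    def test_degenerate_identical_genes_returns_default(self):
        x = np.arange(8, dtype=float)
        expr = pd.DataFrame([x + 0.001 * i for i in range(10)])
        assert pick_soft_threshold(expr) == 14.0

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(pd.DataFrame(np.ones((5, 2))))


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        expr = _expr_from_corr([30, 30], noise=0.5, seed=4)
        part = detect_cluster_modules(expr, beta=6, refine=False)
        mods = part.modules()
        assert len(mods) == 2
        for m in mods:
            prefixes = {g[:2] for g in part.members(m)}
            assert len(prefixes) == 1  # block-pure

    def test_all_noise_gives_no_modules(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(40, 40)),
                            index=[f"g{i}" for i in range(40)])
        part = detect_cluster_modules(expr, beta=6, refine=True)
        # nothing should survive refinement against a 0.7 core-kME floor
        for m in part.modules():
            assert part.kme.loc[part.members(m)].mean() >= 0.7

    def test_min_module_size_honored(self, default_pseudobulk):
        expr = default_pseudobulk.matrices["LMP"]
        part = detect_cluster_modules(expr)
        for m in part.modules():
            assert len(part.members(m)) >= 20

    def test_fewer_genes_than_floor_all_unassigned(self):
        expr = _expr_from_corr([10], seed=6)
        adj = signed_adjacency(expr, beta=6)
        part = detect_modules(tom_similarity(adj), expr, min_module_size=20)
        assert part.modules() == []


class TestEigengeneAndRefine:
    def test_eigengene_sign_convention_and_unit_variance(self):
        expr = _expr_from_corr([20], seed=7)
        eig = module_eigengene(expr, list(expr.index))
        kme = [np.corrcoef(expr.loc[g], eig)[0, 1] for g in expr.index]
        assert np.mean(kme) > 0
        assert np.isclose(eig.to_numpy().std(), 1.0)

    def test_anticorrelated_gene_ejected_first_pass(self):
        expr = _expr_from_corr([25], noise=0.3, seed=8)
        expr.loc["anti"] = -expr.iloc[0] + np.random.default_rng(8).normal(
            0, 0.3, expr.shape[1]
        )
        from ddgnet.datatypes import ModulePartition

        assignments = pd.Series("M1", index=expr.index, dtype=object)
        part = iterative_refine(ModulePartition("c", assignments), expr, max_iter=1)
        assert part.assignments["anti"] == "unassigned"

    def test_strong_module_is_fixed_point(self):
        expr = _expr_from_corr([30], noise=0.15, seed=9)
        from ddgnet.datatypes import ModulePartition

        assignments = pd.Series("M1", index=expr.index, dtype=object)
        part = iterative_refine(ModulePartition("c", assignments), expr)
        assert (part.assignments == "M1").all()

    def test_noise_genes_ejected_from_strong_module(self):
        expr = _expr_from_corr([30], noise=0.3, seed=10)
        rng = np.random.default_rng(10)
        for i in range(10):
            expr.loc[f"noise{i}"] = rng.normal(size=expr.shape[1])
        from ddgnet.datatypes import ModulePartition

        assignments = pd.Series("M1", index=expr.index, dtype=object)
        part = iterative_refine(ModulePartition("c", assignments), expr)
        ejected = sum(part.assignments[f"noise{i}"] != "M1" for i in range(10))
        assert ejected >= 8


def test_planted_module_recovery_ari(default_population, default_pseudobulk):
    from sklearn.metrics import adjusted_rand_score

    _, _, _, truth = default_population
    part = detect_cluster_modules(default_pseudobulk.matrices["LMP"],
                                  cluster_label="LMP")
    genes = list(truth.module_membership)
    pred = part.assignments.reindex(genes).fillna("unassigned")
    ari = adjusted_rand_score([truth.module_membership[g] for g in genes], list(pred))
    assert ari >= 0.8
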