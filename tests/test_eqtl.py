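"""Haplotype eQTL scans, permutation thresholds, carrier and composition tests."""

import numpy as np
import pandas as pd
import pytest

from ddgnet.composition import (
    asin_sqrt_transform,
    cluster_proportions,
    composition_test,
    trait_correlation,
)
from ddgnet.datatypes import FounderGenotypes
from ddgnet.eqtl import (
    GenotypeScanner,
    call_cis_eqtl,
    carrier_groups,
    founder_effects,
    permutation_threshold,
    scan_gene,
)
from ddgnet.sim import SimConfig, simulate_genotypes


@pytest.fixture(scope="module")
def geno80():
    return simulate_genotypes(SimConfig(n_mice=80, seed=11))


@pytest.fixture(scope="module")
def covariates(geno80):
    rng = np.random.default_rng(0)
    n = len(geno80.sample_ids)
    return pd.DataFrame({
        "sex": rng.choice(["M", "F"], n),
        "age_days": rng.normal(70, 8, n),
    }, index=geno80.sample_ids)


def test_lod_closed_form_bookkeeping(geno80, covariates):
    """LOD equals (n/2) log10(RSS0/RSS1) recomputed from two explicit fits."""
    rng = np.random.default_rng(1)
    y = rng.normal(size=80)
    curve = scan_gene(y, geno80, covariates)
    mi = 7
    # explicit regressions
    X0 = np.column_stack([
        np.ones(80),
        covariates["age_days"].to_numpy(),
        (covariates["sex"] == covariates["sex"].unique()[1]).astype(float),
    ])
    D = geno80.dosage[:, mi, :7]
    X1 = np.column_stack([X0, D])
    r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
    r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
    lod = 40 * np.log10((r0 @ r0) / (r1 @ r1))
    assert np.isclose(curve["lod"].iloc[mi], lod, atol=1e-6)


def test_null_genotype_column_gives_zero_lod(geno80):
    """When the 'genotype' carries no information beyond the intercept the
    LOD is zero."""
    flat = FounderGenotypes(
        np.tile(np.full(8, 0.25), (80, 2, 1)),
        pd.DataFrame({"marker": ["m1", "m2"], "chrom": ["1", "1"],
                      "pos": [1, 2]}),
        geno80.sample_ids,
    )
    y = np.random.default_rng(2).normal(size=80)
    curve = scan_gene(y, flat, None)
    assert np.allclose(curve["lod"], 0.0, atol=1e-8)


def test_founder_effects_sum_to_zero(geno80, covariates):
    rng = np.random.default_rng(3)
    y = rng.normal(size=80)
    eff = founder_effects(y, geno80, 5, covariates)
    assert len(eff) == 8
    assert np.isclose(eff.sum(), 0.0, atol=1e-9)


def test_planted_effect_peaks_at_causal_marker(geno80, covariates):
    rng = np.random.default_rng(4)
    mi, founder = 13, 6
    beta = np.zeros(8)
    beta[founder] = 1.5
    beta -= beta.mean()
    y = geno80.dosage[:, mi, :] @ beta + rng.normal(size=80) * 0.5
    curve = scan_gene(y, geno80, covariates)
    peak = int(curve["lod"].idxmax())
    assert abs(peak - mi) <= 2  # linkage can shift the peak slightly
    eff = founder_effects(y, geno80, peak, covariates)
    assert np.argmax(np.abs(eff)) == founder


def test_threshold_monotone_in_quantile(geno80, covariates):
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(rng.normal(size=(8, 80)), columns=geno80.sample_ids,
                        index=[f"g{i}" for i in range(8)])
    lo = permutation_threshold({"C": expr}, geno80, covariates,
                               n_genes=5, n_perm=50, quantile=0.80, seed=1)
    hi = permutation_threshold({"C": expr}, geno80, covariates,
                               n_genes=5, n_perm=50, quantile=0.95, seed=1)
    assert hi["A"] > lo["A"]
    again = permutation_threshold({"C": expr}, geno80, covariates,
                                  n_genes=5, n_perm=50, quantile=0.95, seed=1)
    assert again["A"] == hi["A"]


class TestCisCalls:
    def _peaks(self, lod, pos, chrom="1"):
        return pd.DataFrame([{
            "gene": "g", "cluster_label": "c", "peak_marker": "m",
            "peak_chrom": chrom, "peak_pos": pos, "lod": lod,
            "founder_effects": np.zeros(8),
        }])

    ANn = pd.DataFrame({"symbol": ["g"], "chrom": ["1"], "tss_pos": [5_000_000]})

    def test_exactly_one_mbp_retained(self):
        out = call_cis_eqtl(self._peaks(10.0, 6_000_000), 5.0, self.ANn)
        assert len(out) == 1 and bool(out["cis"].iloc[0])

    def test_beyond_window_rejected(self):
        out = call_cis_eqtl(self._peaks(10.0, 6_000_001), 5.0, self.ANn)
        assert len(out) == 0

    def test_wrong_chromosome_rejected(self):
        out = call_cis_eqtl(self._peaks(99.0, 5_000_000, chrom="2"), 5.0, self.ANn)
        assert len(out) == 0

    def test_lod_below_threshold_rejected(self):
        out = call_cis_eqtl(self._peaks(4.99, 5_000_000), 5.0, self.ANn)
        assert len(out) == 0


class TestCarriers:
    def test_boundary_dosage_is_carrier(self):
        dosage = np.zeros((2, 2, 8))
        dosage[:, :, 0] = 1.5
        dosage[0, :, 1] = 0.5
        dosage[1, :, 2] = 0.5
        geno = FounderGenotypes(
            dosage, pd.DataFrame({"marker": ["m1", "m2"], "chrom": ["1", "1"],
                                  "pos": [1, 2]}), ["s1", "s2"],
        )
        carriers = carrier_groups(geno, "m1", 1)
        assert carriers.tolist() == [True, False]

    def test_absent_founder_empty(self, geno80):
        calls = carrier_groups(geno80, geno80.marker_map["marker"].iloc[0], 0,
                               dosage_min=2.5)
        assert not calls.any()

    def test_matches_true_haplotype_content(self, geno80):
        marker = geno80.marker_map["marker"].iloc[3]
        for founder in range(8):
            carriers = carrier_groups(geno80, marker, founder)
            truth = geno80.dosage[:, 3, founder] >= 0.5
            assert (carriers.to_numpy() == truth).all()


class TestAsinSqrt:
    def test_endpoints_and_quarter(self):
        assert asin_sqrt_transform(np.array([0.0]))[0] == 0.0
        assert np.isclose(asin_sqrt_transform(np.array([1.0]))[0], np.pi / 2)
        assert np.isclose(asin_sqrt_transform(np.array([0.25]))[0], np.pi / 6)

    def test_monotone(self):
        p = np.linspace(0, 1, 100)
        y = asin_sqrt_transform(p)
        assert np.all(np.diff(y) > 0)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            asin_sqrt_transform(np.array([1.1]))


class TestCompositionTest:
    def _data(self, shift=0.0, n=24, seed=0, base=0.25):
        rng = np.random.default_rng(seed)
        group = pd.Series(["carrier"] * 6 + ["rest"] * (n - 6),
                          index=[f"s{i}" for i in range(n)])
        p = np.clip(rng.normal(base, 0.04, n), 0.01, 0.99)
        p[:6] = np.clip(p[:6] - shift, 0.01, 0.99)
        y = pd.Series(np.arcsin(np.sqrt(p)), index=group.index)
        cov = pd.DataFrame({"sex": rng.choice(["M", "F"], n)}, index=group.index)
        return y, group, cov

    def test_no_group_difference_gives_uniform_p(self):
        """Groups drawn from the same distribution: expected |t| near 0."""
        ps = [composition_test(*self._data(shift=0.0, seed=s))["p"]
              for s in range(40)]
        assert np.mean(ps) > 0.3  # roughly uniform, not concentrated at 0

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(20):
            y, group, cov = self._data(shift=0.15, seed=seed)
            if composition_test(y, group, cov)["p"] < 0.05:
                hits += 1
        assert hits >= 16  # >= 80% power

    def test_type_one_error_calibrated(self):
        hits = 0
        n_sim = 400
        for seed in range(n_sim):
            y, group, cov = self._data(shift=0.0, seed=seed)
            if composition_test(y, group, cov)["p"] < 0.05:
                hits += 1
        assert 0.02 <= hits / n_sim <= 0.08

    def test_three_groups_use_f_test(self):
        y, group, cov = self._data(seed=2)
        group[:] = ["a", "b", "c"] * 8
        res = composition_test(y, pd.Series(group, index=y.index), cov)
        assert res["test"] == "F"

    def test_confounded_design_raises(self):
        y, group, cov = self._data(seed=3)
        cov["dup"] = (group == "carrier").astype(float)
        with pytest.raises(ValueError):
            composition_test(y, group, cov)


class TestTraitCorrelation:
    def test_exact_copy_gives_r_one(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"A": rng.normal(size=20)}, index=[f"s{i}" for i in range(20)])
        traits = pd.DataFrame({"trait": t["A"]}, index=t.index)
        out = trait_correlation(t, traits)
        assert np.isclose(out["r"].iloc[0], 1.0)

    def test_independent_trait_small_r(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(200)]
        t = pd.DataFrame({"A": rng.normal(size=200)}, index=idx)
        traits = pd.DataFrame({"trait": rng.normal(size=200)}, index=idx)
        out = trait_correlation(t, traits)
        assert abs(out["r"].iloc[0]) < 0.2

    def test_degenerate_inputs_skipped(self):
        idx = ["s1", "s2"]
        t = pd.DataFrame({"A": [0.1, 0.2]}, index=idx)
        traits = pd.DataFrame({"flat": [1.0, 1.0], "ok": [1.0, 2.0]}, index=idx)
        out = trait_correlation(t, traits)
        assert len(out) == 0  # constant trait skipped; n=2 below minimum


def test_cluster_proportions_sum_to_one(default_population):
    counts, *_ = default_population
    props = cluster_proportions(counts.cell_meta)
    assert np.allclose(props.sum(axis=1), 1.0)
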