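"""Weir-Cockerham FST and the LD / FST conservation resampling tests."""

import numpy as np
import pytest

from prspop.conservation_tests import (fst_conservation_test,
                                       ld_conservation_test, mean_pairwise_fst,
                                       multi_snp_theta, region_ld_vectors,
                                       weir_cockerham_fst,
                                       weir_cockerham_fst_vector)
from tests.conftest import make_dataset


def wc_oracle(c1, c2):
    """Independent scalar coding of the 1984 a, b, c variance components."""
    n1, n2 = sum(c1), sum(c2)
    r = 2
    p1 = (2 * c1[0] + c1[1]) / (2 * n1)
    p2 = (2 * c2[0] + c2[1]) / (2 * n2)
    h1, h2 = c1[1] / n1, c2[1] / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


class TestWeirCockerham:
    def test_fixture_value(self):
        # frozen from the independently coded variance-components oracle
        assert weir_cockerham_fst((7, 2, 1), (3, 4, 3)) == pytest.approx(
            0.12222222222222229, rel=1e-12)

    def test_identical_tables_nonpositive(self):
        assert weir_cockerham_fst((25, 50, 25), (25, 50, 25)) <= 0.0

    def test_fixation_limit(self):
        theta = weir_cockerham_fst((1000, 0, 0), (0, 0, 1000))
        assert theta == pytest.approx(1.0, abs=0.01)

    def test_monomorphic_undefined(self):
        assert np.isnan(weir_cockerham_fst((10, 0, 0), (12, 0, 0)))

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            c1 = tuple(rng.integers(0, 20, 3) + np.array([1, 1, 0]))
            c2 = tuple(rng.integers(0, 20, 3) + np.array([0, 1, 1]))
            a = weir_cockerham_fst(c1, c2)
            b = weir_cockerham_fst(c1[::-1], c2[::-1])
            assert a == pytest.approx(b, rel=1e-10)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(15)
        for _ in range(30):
            c1 = tuple(int(v) for v in rng.integers(0, 30, 3) + 1)
            c2 = tuple(int(v) for v in rng.integers(0, 30, 3) + 1)
            got = weir_cockerham_fst(c1, c2)
            want = wc_oracle(c1, c2)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-10)

    def test_vector_form_matches_scalar(self):
        rng = np.random.default_rng(16)
        C1 = rng.integers(1, 30, (10, 3))
        C2 = rng.integers(1, 30, (10, 3))
        vec = weir_cockerham_fst_vector(C1, C2)
        for i in range(10):
            want = wc_oracle(tuple(C1[i]), tuple(C2[i]))
            assert vec[i] == pytest.approx(want, rel=1e-10)


class TestRegionLd:
    def test_three_variant_region_gives_three_pairs(self):
        rng = np.random.default_rng(17)
        D = rng.integers(0, 3, (60, 3)).astype(np.int8)
        countries = ["A"] * 30 + ["B"] * 30
        ds = make_dataset(D, positions=[1000, 2000, 3000], countries=countries)
        keys, vecs = region_ld_vectors(ds, ["v0"], flank_kb=100)
        assert len(keys) == 3
        assert set(vecs) == {"A", "B"}

    def test_overlapping_regions_deduplicate_pairs(self):
        rng = np.random.default_rng(18)
        D = rng.integers(0, 3, (40, 3)).astype(np.int8)
        ds = make_dataset(D, positions=[1000, 2000, 3000],
                          countries=["A"] * 20 + ["B"] * 20)
        keys1, _ = region_ld_vectors(ds, ["v0"], flank_kb=100)
        keys2, _ = region_ld_vectors(ds, ["v0", "v1", "v2"], flank_kb=100)
        assert sorted(keys1) == sorted(keys2)

    def test_identical_population_samples_correlation_one(self):
        rng = np.random.default_rng(19)
        D = rng.integers(0, 3, (50, 4)).astype(np.int8)
        ds = make_dataset(np.vstack([D, D]), positions=[1000, 2000, 3000, 4000],
                          countries=["A"] * 50 + ["B"] * 50)
        _, vecs = region_ld_vectors(ds, ["v0"], flank_kb=100)
        np.testing.assert_allclose(vecs["A"], vecs["B"], rtol=1e-10)

    def test_random_split_of_one_panel_highly_correlated(self, small_world):
        """Two 'populations' split at random from one pooled panel share the
        haplotype structure, so their paired r2 vectors agree closely."""
        from prspop.io_formats import GenotypeDataset
        from prspop.prevalence_association import pearson_r
        from prspop.synthetic_data import SyntheticConfig, simulate_genotypes

        cfg = SyntheticConfig(seed=23, n_pops=1, fst=(0.0,), samples_per_pop=1000,
                              n_snps=300, missing_rate=0.0, n_causal=5)
        ds, _ = simulate_genotypes(cfg)
        half = np.array(["A"] * 500 + ["B"] * 500)
        samples = ds.samples.copy()
        samples["country"] = half
        samples["superpop"] = half
        split = GenotypeDataset(ds.variants, samples, ds.dosages)
        snps = ds.variants["id"].iloc[[5, 105, 205]].tolist()
        _, vecs = region_ld_vectors(split, snps, flank_kb=100)
        assert pearson_r(vecs["A"], vecs["B"]) > 0.95


class TestConservationTests:
    def test_ld_extreme_significance(self, harmonized_world):
        """PRS SNPs engineered to sit in the most conserved regions rank above
        every null draw only when observed > all nulls; check the p formula
        via the extreme case of a tiny null."""
        _, qc_ds, truth, pair, _ = harmonized_world
        snps = [s for s in truth.causal_ids
                if s in set(qc_ds.variants["id"])][:8]
        res = ld_conservation_test(qc_ds, snps, ref_pop="POP1", n_sets=10,
                                   set_size=20, seed=4)
        for r in res:
            assert 0 < r.empirical_p <= 1
            assert len(r.null_corrs) == 10
            assert abs(r.observed_corr) <= 1
            if np.all(r.null_corrs < r.observed_corr):
                assert r.empirical_p == pytest.approx(1 / 11)

    def test_fst_extreme_and_structure(self, harmonized_world):
        _, qc_ds, truth, pair, _ = harmonized_world
        snps = [s for s in truth.causal_ids if s in set(qc_ds.variants["id"])][:8]
        res = fst_conservation_test(qc_ds, snps, ref_pop="POP1", n_sets=10,
                                    set_size=20, seed=5)
        for r in res:
            assert len(r.null_means) == 10
            assert r.per_snp_fst.shape == (len(snps),)
            if np.all(r.null_means > r.mean_fst):
                assert r.empirical_p == pytest.approx(1 / 11)

    def test_pool_smaller_than_set_size_is_error(self, harmonized_world):
        _, qc_ds, _, _, _ = harmonized_world
        with pytest.raises(ValueError):
            fst_conservation_test(qc_ds, ["rs1"], ref_pop="POP1",
                                  set_size=qc_ds.n_variants + 1)


class TestGeneratorRecovery:
    def test_two_pop_balding_nichols_theta_recovery(self):
        """Combined W-C theta recovers the Balding-Nichols F parameter."""
        from prspop.conservation_tests import _genotype_counts
        from prspop.synthetic_data import SyntheticConfig, simulate_genotypes

        F = 0.05
        cfg = SyntheticConfig(seed=31, n_pops=2, fst=(F, F), samples_per_pop=500,
                              n_snps=10_000, block_size=1, block_r=0.0,
                              missing_rate=0.0, n_causal=0)
        ds, _ = simulate_genotypes(cfg)
        groups = ds.country_groups()
        rows1, rows2 = list(groups.values())
        C1 = _genotype_counts(ds.dosages[rows1])
        C2 = _genotype_counts(ds.dosages[rows2])
        assert multi_snp_theta(C1, C2) == pytest.approx(F, abs=0.01)

    def test_mean_fst_of_random_subsets_converges_to_pool_mean(self, harmonized_world):
        _, qc_ds, _, _, _ = harmonized_world
        groups = qc_ds.country_groups()
        rows1, rows2 = groups["POP1"], groups["POP5"]
        all_ids = qc_ds.variants["id"].tolist()
        pool_mean, _ = mean_pairwise_fst(qc_ds, all_ids, rows1, rows2)
        rng = np.random.default_rng(6)
        sub_means = []
        for _ in range(30):
            snps = list(np.array(all_ids)[rng.choice(len(all_ids), 400,
                                                     replace=False)])
            sub_means.append(mean_pairwise_fst(qc_ds, snps, rows1, rows2)[0])
        assert np.mean(sub_means) == pytest.approx(pool_mean, abs=0.01)
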