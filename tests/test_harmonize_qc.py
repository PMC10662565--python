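"""QC filters, the Hardy-Weinberg exact test, and allele harmonization."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from prspop.harmonize_qc import (QcError, harmonize, hwe_exact_pvalue, qc_filter)
from prspop.io_formats import SummaryStats
from tests.conftest import make_dataset


def hwe_bruteforce(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration over all heterozygote configurations."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    if min(n_a, 2 * n - n_a) == 0:
        return 1.0

    def prob(h):
        hom_rare = (n_a - h) // 2
        hom_com = n - h - hom_rare
        if hom_rare < 0 or hom_com < 0:
            return Fraction(0)
        num = Fraction(factorial(n) * 2 ** h,
                       factorial(hom_rare) * factorial(h) * factorial(hom_com))
        den = Fraction(factorial(2 * n), factorial(n_a) * factorial(2 * n - n_a))
        return num / den

    hs = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    obs = prob(n_Aa)
    return float(sum(prob(h) for h in hs if prob(h) <= obs))


class TestHweExact:
    def test_single_het_pair_is_modal(self):
        # het in {0, 2} with probabilities 1/3 and 2/3; observed is modal
        assert hwe_exact_pvalue(0, 2, 0) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_exact_pvalue(10, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 7) == 1.0

    def test_extreme_het_deficit_frozen_value(self):
        # full-enumeration oracle value, frozen
        assert hwe_exact_pvalue(50, 0, 50) == pytest.approx(1.114224180581451e-30,
                                                            rel=1e-9)

    def test_matches_bruteforce_up_to_30_alleles(self):
        for n_AA in range(0, 8):
            for n_Aa in range(0, 8):
                for n_aa in range(0, 8):
                    if n_AA + n_Aa + n_aa == 0:
                        continue
                    got = hwe_exact_pvalue(n_AA, n_Aa, n_aa)
                    want = hwe_bruteforce(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, rel=1e-10), (n_AA, n_Aa, n_aa)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)


class TestQcFilter:
    def test_missingness_threshold(self):
        # variant 0: 3/100 missing (3% > 2%) -> removed; variant 1 clean
        hwe_col = np.array([2] * 25 + [1] * 50 + [0] * 25, dtype=np.int8)
        D = np.stack([hwe_col, hwe_col], axis=1)
        D[:3, 0] = -1
        ds = make_dataset(D)
        kept, report = qc_filter(ds)
        assert kept.variants["id"].tolist() == ["v1"]
        assert report.n_missingness == 1
        assert report.n_input == report.n_retained + report.n_missingness \
            + report.n_maf + report.n_hwe

    def test_hwe_extremes(self):
        # col 0: AA=50, aa=50 (no hets) -> HWE p << 1e-6, removed
        # col 1: perfect HWE proportions AA=25, Aa=50, aa=25 -> retained
        col0 = np.array([2] * 50 + [0] * 50, dtype=np.int8)
        col1 = np.array([2] * 25 + [1] * 50 + [0] * 25, dtype=np.int8)
        ds = make_dataset(np.stack([col0, col1], axis=1))
        kept, report = qc_filter(ds)
        assert kept.variants["id"].tolist() == ["v1"]
        assert report.n_hwe == 1

    def test_maf_filter(self):
        col0 = np.zeros(200, dtype=np.int8)
        col0[0] = 1  # MAF 1/400 = 0.0025 < 0.01
        col1 = np.array([2] * 50 + [1] * 100 + [0] * 50, dtype=np.int8)
        ds = make_dataset(np.stack([col0, col1], axis=1))
        kept, report = qc_filter(ds)
        assert kept.variants["id"].tolist() == ["v1"]
        assert report.n_maf == 1

    def test_idempotent(self, small_world):
        _, dataset, _, _, _ = small_world
        once, _ = qc_filter(dataset)
        twice, report = qc_filter(once)
        assert twice.variants["id"].tolist() == once.variants["id"].tolist()
        assert report.n_retained == report.n_input

    def test_all_removed_is_hard_error(self):
        col = np.zeros((50, 1), dtype=np.int8)  # monomorphic -> MAF failure
        with pytest.raises(QcError):
            qc_filter(make_dataset(col))


def stats_table(rows):
    df = pd.DataFrame(rows, columns=["id", "effect_allele", "other_allele",
                                     "effect", "pvalue"])
    df["chrom"] = "1"
    df["pos"] = 0
    return SummaryStats(df)


class TestHarmonize:
    # the 8 allele-orientation cases for genotype (a1=A, a2=G):
    # (effect, other) -> expected sign multiplier or None for removed
    CASES = [
        (("A", "G"), +1),      # direct match
        (("G", "A"), -1),      # swap -> sign flip
        (("T", "C"), +1),      # strand flip of (A, G)
        (("C", "T"), -1),      # strand flip of (G, A)
        (("A", "C"), None),    # irreconcilable -> mismatch
        (("C", "A"), None),
        (("G", "T"), None),
        (("T", "G"), None),
    ]

    @pytest.mark.parametrize("alleles,expected_sign", CASES)
    def test_orientation_table(self, alleles, expected_sign):
        ds = make_dataset(np.array([[0], [1], [2]], dtype=np.int8), a1="A", a2="G")
        ds.variants.loc[0, "id"] = "v0"
        stats = stats_table([("v0", alleles[0], alleles[1], 0.3, 1e-9)])
        if expected_sign is None:
            from prspop.harmonize_qc import QcError
            with pytest.raises(QcError):
                harmonize(ds, stats)
        else:
            pair, report = harmonize(ds, stats)
            assert pair.effects[0] == pytest.approx(expected_sign * 0.3)
            assert report.n_retained == 1

    def test_ambiguous_policy(self):
        ds = make_dataset(np.array([[0], [1], [2]], dtype=np.int8), a1="A", a2="T")
        stats = stats_table([("v0", "A", "T", 0.3, 1e-9)])
        with pytest.raises(QcError):  # only variant dropped as ambiguous
            harmonize(ds, stats, ambiguous_policy="drop")
        pair, _ = harmonize(ds, stats, ambiguous_policy="keep")
        assert pair.effects[0] == pytest.approx(0.3)

    def test_orientation_invariance_of_downstream_prs(self, harmonized_world):
        """Flipping a1/a2 and d -> 2-d yields identical PRS after re-harmonization."""
        from prspop.io_formats import GenotypeDataset
        from prspop.ld_core import clump
        from prspop.prs_scoring import compute_unweighted_prs
        from prspop.harmonize_qc import harmonize as _harmonize

        cfg, qc_ds, truth, pair, _ = harmonized_world
        stats_df = pd.DataFrame({
            "id": pair.dataset.variants["id"],
            "chrom": pair.dataset.variants["chrom"],
            "pos": pair.dataset.variants["pos"],
            "effect_allele": pair.dataset.variants["a1"],
            "other_allele": pair.dataset.variants["a2"],
            "effect": pair.effects,
            "pvalue": pair.pvalues,
        })
        stats = SummaryStats(stats_df)

        flipped_variants = pair.dataset.variants.rename(
            columns={"a1": "a2", "a2": "a1"})[["id", "chrom", "pos", "a1", "a2"]]
        D = pair.dataset.dosages
        flipped_D = np.where(D == -1, -1, 2 - D).astype(np.int8)
        flipped = GenotypeDataset(flipped_variants, pair.dataset.samples, flipped_D)

        pair_f, _ = _harmonize(flipped, stats)
        cs = clump(pair.pvalues, pair.dataset, 5e-8)
        cs_f = clump(pair_f.pvalues, pair_f.dataset, 5e-8)
        assert cs.variant_ids == cs_f.variant_ids
        s1 = compute_unweighted_prs(pair, cs).sample_scores
        s2 = compute_unweighted_prs(pair_f, cs_f).sample_scores
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)
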