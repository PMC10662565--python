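"""Variant QC and allele harmonization between genotypes and summary stats.

QC applies the standard pre-PRS filters to the pooled target dataset:
missingness > 2%, minor allele frequency < 1%, and Hardy-Weinberg exact
p-value < 1e-6 (computed on all samples pooled).  Harmonization aligns
summary-statistic alleles to the genotype ``a1`` encoding by allele swap
(with effect sign negation) and strand flip; strand-ambiguous A/T and C/G
variants are dropped by default, and irreconcilable allele pairs are removed
as mismatched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset, SummaryStats

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class QcError(ValueError):
    """Raised when QC or harmonization leaves nothing to analyze."""


@dataclass
class QcReport:
    """Counts of variants removed per filter; removed + retained = input."""

    n_input: int = 0
    n_missingness: int = 0
    n_maf: int = 0
    n_hwe: int = 0
    n_mismatch: int = 0
    n_ambiguous: int = 0
    n_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": ["input", "missingness", "maf", "hwe", "mismatch",
                           "ambiguous", "retained"],
                "count": [self.n_input, self.n_missingness, self.n_maf, self.n_hwe,
                          self.n_mismatch, self.n_ambiguous, self.n_retained],
            }
        )


@dataclass
class HarmonizedPair:
    """Genotypes and summary stats restricted to shared variants.

    ``effects`` and ``pvalues`` are aligned to the dataset's variant order,
    with effect signs expressed relative to the genotype ``a1`` allele.
    """

    dataset: GenotypeDataset
    effects: np.ndarray
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        n = self.dataset.n_variants
        if len(self.effects) != n or len(self.pvalues) != n:
            raise ValueError("effects/pvalues length must match variant count")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration (same parity) whose probability is at
    most that of the observed one.  Monomorphic variants return 1 by
    convention.  This is the exact test of Wigginton, Cutler & Abecasis
    (2005), the default in genotype-QC tooling.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-side allele count (either side works; symmetric)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # P(het = h | allele counts) ∝ n! / (nAA! nAa! naa!) * 2^h; compute the
    # whole conditional distribution by the standard recurrence, then sum
    # probabilities <= the observed one.
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(len(hets), dtype=float)
    probs[0] = 1.0
    for i in range(len(hets) - 1):
        h = hets[i]
        n_hom_rare = (rare - h) // 2
        n_hom_com = (2 * n - rare - h) // 2
        # ratio P(h+2)/P(h)
        probs[i + 1] = probs[i] * 4.0 * n_hom_rare * n_hom_com / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    observed = probs[hets == n_Aa]
    if observed.size == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("inconsistent genotype counts")
    # 1e-12 relative slack guards against float noise in the <= comparison
    p = probs[probs <= observed[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_filter(dataset: GenotypeDataset, missingness_max: float = 0.02,
              maf_min: float = 0.01, hwe_min: float = 1e-6
              ) -> tuple[GenotypeDataset, QcReport]:
    """Remove variants failing missingness, MAF, or HWE thresholds.

    A variant is removed when its missingness exceeds ``missingness_max``,
    its minor allele frequency (from non-missing dosages) is below
    ``maf_min``, or its pooled-sample HWE exact p-value is below ``hwe_min``.
    Filters are attributed in that order for reporting.
    """
    if dataset.n_variants == 0:
        raise QcError("empty dataset")
    d = dataset.dosages
    n = dataset.n_samples
    miss = d == MISSING
    n_miss = miss.sum(axis=0)
    n_obs = n - n_miss
    miss_fail = n_miss > missingness_max * n

    with np.errstate(invalid="ignore", divide="ignore"):
        alt_count = np.where(miss, 0, d).sum(axis=0)
        p = np.where(n_obs > 0, alt_count / (2.0 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(p, 1 - p)
    maf_fail = (maf < maf_min) | (n_obs == 0)

    n_het = ((d == 1) & ~miss).sum(axis=0)
    n_hom_alt = (d == 2).sum(axis=0)
    n_hom_ref = (d == 0).sum(axis=0)
    hwe_fail = np.zeros(dataset.n_variants, dtype=bool)
    need_hwe = ~(miss_fail | maf_fail)
    for j in np.flatnonzero(need_hwe):
        if hwe_exact_pvalue(int(n_hom_alt[j]), int(n_het[j]), int(n_hom_ref[j])) < hwe_min:
            hwe_fail[j] = True

    keep = ~(miss_fail | maf_fail | hwe_fail)
    report = QcReport(
        n_input=dataset.n_variants,
        n_missingness=int(miss_fail.sum()),
        n_maf=int((maf_fail & ~miss_fail).sum()),
        n_hwe=int(hwe_fail.sum()),
        n_retained=int(keep.sum()),
    )
    if not keep.any():
        raise QcError("all variants removed by QC")
    logger.info("QC retained %d / %d variants", report.n_retained, report.n_input)
    return dataset.subset_variants(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_ambiguous(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b


def harmonize(dataset: GenotypeDataset, stats: SummaryStats,
              ambiguous_policy: str = "drop") -> tuple[HarmonizedPair, QcReport]:
    """Match variants by id and orient effect signs to the genotype ``a1``.

    Orientation cases per shared variant, with genotype alleles (a1, a2) and
    summary alleles (E, O):

    * (E, O) == (a1, a2): effect kept as-is.
    * (E, O) == (a2, a1): effect negated (the effect now refers to a1).
    * complement(E, O) matches either orientation: strand flip, then as above.
    * anything else: removed as mismatched.

    A/T and C/G pairs cannot be strand-resolved; policy ``"drop"`` (default)
    removes them, ``"keep"`` treats them as already on the genotype strand.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    st = stats.table.set_index("id")
    shared_mask = dataset.variants["id"].isin(st.index).to_numpy()
    idx = np.flatnonzero(shared_mask)
    report = QcReport(n_input=dataset.n_variants)
    if idx.size == 0:
        raise QcError("no shared variant ids between genotypes and summary stats")

    var = dataset.variants.iloc[idx]
    sub = st.loc[var["id"]]
    a1 = var["a1"].to_numpy()
    a2 = var["a2"].to_numpy()
    ea = sub["effect_allele"].to_numpy()
    oa = sub["other_allele"].to_numpy()
    eff = sub["effect"].to_numpy(float)
    pval = sub["pvalue"].to_numpy(float)

    keep = np.zeros(idx.size, dtype=bool)
    sign = np.ones(idx.size, dtype=float)
    n_ambiguous = n_mismatch = 0
    for i in range(idx.size):
        if _is_ambiguous(ea[i], oa[i]):
            if ambiguous_policy == "drop":
                n_ambiguous += 1
                continue
        e, o = ea[i], oa[i]
        if (e, o) == (a1[i], a2[i]):
            keep[i] = True
        elif (e, o) == (a2[i], a1[i]):
            keep[i], sign[i] = True, -1.0
        else:
            ec, oc = _COMPLEMENT.get(e), _COMPLEMENT.get(o)
            if (ec, oc) == (a1[i], a2[i]):
                keep[i] = True
            elif (ec, oc) == (a2[i], a1[i]):
                keep[i], sign[i] = True, -1.0
            else:
                n_mismatch += 1

    report.n_ambiguous = n_ambiguous
    # unmatched ids count as mismatches so removed + retained = input
    report.n_mismatch = n_mismatch + (dataset.n_variants - idx.size)
    kept_local = np.flatnonzero(keep)
    report.n_retained = kept_local.size
    if kept_local.size == 0:
        raise QcError("no variants left after harmonization")
    ds = dataset.subset_variants(idx[kept_local])
    pair = HarmonizedPair(dataset=ds, effects=eff[kept_local] * sign[kept_local],
                          pvalues=pval[kept_local])
    logger.info("harmonized %d variants (%d ambiguous dropped, %d mismatched)",
                report.n_retained, n_ambiguous, n_mismatch)
    return pair, report
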