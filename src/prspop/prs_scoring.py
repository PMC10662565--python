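"""Unweighted (direction-of-effect) polygenic risk scores.

The score of an individual is the count of risk alleles over the clumped SNP
set: for each SNP the risk allele is the effect allele when the harmonized
effect is positive, otherwise the other allele.  Only the direction of each
GWAS association enters the score — effect magnitudes are deliberately
ignored so the score transfers across populations as a pure function of
allele frequency.  Per-country means are standardized as z-scores across
countries (population-variance convention) for heatmap-style comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize_qc import HarmonizedPair
from .io_formats import MISSING, GenotypeDataset
from .ld_core import ClumpSet, clump

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (5e-8, 1e-5, 1e-3, 0.05, 1.0)


@dataclass
class PrsResult:
    """Per-sample scores and per-country summaries at one p-value threshold."""

    disorder: str
    p_threshold: float
    n_snps: int
    sample_scores: pd.Series          # index = sample id
    country_means: pd.Series          # index = country
    country_z: pd.Series              # standardized across countries
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "disorder": self.disorder,
            "threshold": self.p_threshold,
            "n_snps": self.n_snps,
            "country": self.country_means.index,
            "mean_score": self.country_means.to_numpy(),
            "z_score": self.country_z.to_numpy(),
        })


def standardize_scores(country_means: pd.Series) -> pd.Series:
    """z-scores of country means across countries (population variance).

    All-equal means give all-zero z with a warning rather than an error.
    """
    vals = country_means.to_numpy(float)
    if len(vals) < 2:
        raise ValueError("need at least 2 countries to standardize")
    sd = vals.std()  # ddof=0: population-of-countries convention
    if sd == 0:
        warnings.warn("zero variance across country means; z-scores set to 0")
        return pd.Series(np.zeros(len(vals)), index=country_means.index)
    return pd.Series((vals - vals.mean()) / sd, index=country_means.index)


def compute_unweighted_prs(pair: HarmonizedPair, clump_set: ClumpSet,
                           missing_policy: str = "mean_impute") -> PrsResult:
    """Risk-allele count per individual over the clumped SNP set.

    Per SNP the counted dosage is the a1 dosage when the harmonized effect is
    positive and ``2 - dosage`` when negative (the risk allele is then a2).
    SNPs with effect exactly 0 carry no direction and are excluded with a
    warning.  Missing dosages are replaced by the per-SNP mean of observed
    risk-allele dosages (``mean_impute``, default) or the SNP is skipped for
    that sample with the final score rescaled to the full SNP count
    (``omit_rescale``).
    """
    if missing_policy not in ("mean_impute", "omit_rescale"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    ds = pair.dataset
    indexer = ds.variant_indexer()
    absent = [v for v in clump_set.variant_ids if v not in indexer.index]
    if absent:
        raise KeyError(f"clumped variants absent from harmonized pair: {absent[:5]}")
    cols = indexer[clump_set.variant_ids].to_numpy() if clump_set.variant_ids else np.array([], int)
    eff = pair.effects[cols]
    zero = eff == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} clumped SNPs have zero effect (no direction); excluded")
        cols, eff = cols[~zero], eff[~zero]

    n_snps = len(cols)
    if n_snps == 0:
        scores = pd.Series(np.zeros(ds.n_samples), index=ds.samples["sample"])
        means = scores.groupby(ds.samples["country"].to_numpy(), sort=False).mean()
        z = pd.Series(np.zeros(len(means)), index=means.index)
        return PrsResult(clump_set.disorder, clump_set.p_threshold, 0, scores, means, z, empty=True)

    D = ds.dosages[:, cols].astype(float)
    miss = D == MISSING
    # risk-allele dosage: a1 dosage for positive effects, reflected for negative
    R = np.where(eff > 0, D, 2.0 - D)
    R[miss] = np.nan
    if missing_policy == "mean_impute":
        col_mean = np.nanmean(R, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        R = np.where(np.isnan(R), col_mean, R)
        scores_arr = R.sum(axis=1)
    else:  # omit_rescale
        observed = (~np.isnan(R)).sum(axis=1)
        scores_arr = np.nansum(R, axis=1) * (n_snps / np.maximum(observed, 1))

    scores = pd.Series(scores_arr, index=ds.samples["sample"].to_numpy())
    means = scores.groupby(ds.samples["country"].to_numpy(), sort=False).mean()
    z = standardize_scores(means) if len(means) >= 2 else pd.Series(
        np.zeros(len(means)), index=means.index)
    return PrsResult(clump_set.disorder, clump_set.p_threshold, n_snps, scores, means, z)


def threshold_sweep(pair: HarmonizedPair, thresholds=DEFAULT_THRESHOLDS,
                    r2_threshold: float = 0.1, window_kb: float = 250.0,
                    disorder: str = "", missing_policy: str = "mean_impute"
                    ) -> list[PrsResult]:
    """Clump and score at each p-value threshold (sensitivity sweep).

    An empty threshold yields a flagged-empty result, never an error; SNP
    counts are non-decreasing as the threshold relaxes.
    """
    results = []
    for thr in sorted(thresholds):
        cs = clump(pair.pvalues, pair.dataset, thr, r2_threshold, window_kb, disorder)
        res = compute_unweighted_prs(pair, cs, missing_policy)
        logger.info("threshold %g: %d SNPs", thr, res.n_snps)
        results.append(res)
    return results
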