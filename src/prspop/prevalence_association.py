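"""Country-level association between mean PRS and disease prevalence.

Two resampling p-values accompany each Pearson correlation:

* a two-sided label-permutation p-value (prevalence shuffled across
  countries, 1000 permutations by default);
* a one-sided empirical p-value from random SNP sets — each null set has as
  many SNPs as the observed clumped set, drawn uniformly from the post-QC
  pool with a coin-flip risk direction per SNP, scored exactly like the real
  PRS, and correlated with prevalence.  The empirical p is the fraction of
  null correlations at least as large as the observed one, with the
  +1/(N+1) correction so p = 0 is never reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset

ALPHA = 0.05


@dataclass
class AssociationResult:
    disorder: str
    threshold: float
    pearson_r: float
    permutation_p: float
    empirical_p: float
    n_countries: int
    null_r_values: np.ndarray

    @property
    def significant(self) -> bool:
        return self.empirical_p <= ALPHA

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "disorder": self.disorder,
            "threshold": self.threshold,
            "pearson_r": self.pearson_r,
            "permutation_p": self.permutation_p,
            "empirical_p": self.empirical_p,
            "n_countries": self.n_countries,
            "n_sets": len(self.null_r_values),
            "significant": self.significant,
        }])


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; constant input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def permutation_pvalue(x, y, n_perm: int = 1000, seed: int | np.random.Generator = 0) -> float:
    """Two-sided permutation p-value for the Pearson correlation of x and y.

    p = (1 + #{permutations with |r| >= |observed|}) / (n_perm + 1),
    deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        warnings.warn("permutation space is tiny for n < 4; p-value is coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = abs(pearson_r(x, y))
    count = 0
    for _ in range(n_perm):
        r = pearson_r(x, rng.permutation(y))
        if abs(r) >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def empirical_pvalue(observed: float, null_values: np.ndarray, tail: str = "greater") -> float:
    """Percentile p with the +1/(N+1) correction; ``tail`` in {greater, less}."""
    null_values = np.asarray(null_values, dtype=float)
    if tail == "greater":
        count = int(np.sum(null_values >= observed - 1e-12))
    elif tail == "less":
        count = int(np.sum(null_values <= observed + 1e-12))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + count) / (len(null_values) + 1)


def random_set_scores(dataset: GenotypeDataset, n_snps: int, rng: np.random.Generator,
                      direction_scheme: str = "coin") -> np.ndarray:
    """Per-sample unweighted PRS over one random SNP set from the pool.

    Directions: ``"coin"`` flips an independent fair coin per SNP (default);
    ``"minor"`` takes the minor allele as the risk allele.
    """
    pool = dataset.n_variants
    if pool < n_snps:
        raise ValueError(f"variant pool ({pool}) smaller than requested set ({n_snps})")
    cols = rng.choice(pool, size=n_snps, replace=False)
    D = dataset.dosages[:, cols].astype(float)
    miss = D == MISSING
    D[miss] = np.nan
    if direction_scheme == "coin":
        risk_is_a1 = rng.random(n_snps) < 0.5
    elif direction_scheme == "minor":
        freq = np.nanmean(D, axis=0) / 2.0
        risk_is_a1 = freq <= 0.5
    else:
        raise ValueError(f"unknown direction_scheme {direction_scheme!r}")
    R = np.where(risk_is_a1, D, 2.0 - D)
    col_mean = np.nanmean(R, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    R = np.where(np.isnan(R), col_mean, R)
    return R.sum(axis=1)


def random_set_empirical_pvalue(dataset: GenotypeDataset, prevalence_vec: np.ndarray,
                                observed_r: float, n_snps: int, n_sets: int = 100,
                                seed: int | np.random.Generator = 0,
                                direction_scheme: str = "coin",
                                ) -> tuple[float, np.ndarray]:
    """Empirical p of the observed PRS-prevalence correlation vs random sets.

    ``prevalence_vec`` must be ordered like the dataset's countries
    (first-appearance order).  One-sided: null correlations >= observed count
    against the observed association.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = dataset.country_groups()
    if len(groups) != len(prevalence_vec):
        raise ValueError("prevalence vector length must equal number of countries")
    null_r = np.empty(n_sets)
    for s in range(n_sets):
        scores = random_set_scores(dataset, n_snps, rng, direction_scheme)
        means = np.array([scores[idx].mean() for idx in groups.values()])
        null_r[s] = pearson_r(means, prevalence_vec)
    return empirical_pvalue(observed_r, null_r, tail="greater"), null_r


def associate(pool_dataset: GenotypeDataset, prs_result, prevalence_vec: np.ndarray,
              n_perm: int = 1000, n_sets: int = 100,
              seed: int | np.random.Generator = 0,
              direction_scheme: str = "coin") -> AssociationResult:
    """Full association for one disorder/threshold: r + both p-values.

    ``pool_dataset`` is the post-QC dataset the random null sets are drawn
    from (all QC-passing variants, not just those shared with the summary
    statistics).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = prs_result.country_means.to_numpy(float)
    r = pearson_r(means, prevalence_vec)
    perm_p = permutation_pvalue(means, prevalence_vec, n_perm=n_perm, seed=rng)
    emp_p, null_r = random_set_empirical_pvalue(
        pool_dataset, prevalence_vec, r, max(prs_result.n_snps, 1),
        n_sets=n_sets, seed=rng, direction_scheme=direction_scheme)
    return AssociationResult(
        disorder=prs_result.disorder, threshold=prs_result.p_threshold,
        pearson_r=r, permutation_p=perm_p, empirical_p=emp_p,
        n_countries=len(means), null_r_values=null_r)
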