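"""Cross-population conservation of the genomic regions behind a PRS.

Two analyses, both compared against a null of random SNP sets:

* **LD-structure conservation** — all variants within ±100 kb of each PRS
  SNP are collected, r² is computed for every within-region pair separately
  in a reference population (Europeans in the original design) and in each
  comparison population, and the paired r² vectors are correlated.  High
  correlation means the local LD structure is similar in both populations.
* **FST conservation** — the mean Weir–Cockerham (1984) theta of the PRS
  SNPs between the reference population and each comparison population.
  Low mean FST means the risk loci are less frequency-differentiated than
  random SNPs.

Each observed statistic gets an empirical p-value from repeating the
identical procedure on random SNP sets (100 sets of 1000 SNPs in the
original design); LD conservation is significant when the observed
correlation is in the null's top 5%, FST conservation when the observed
mean is in the bottom 5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset
from .ld_core import r2_one_vs_many
from .prevalence_association import ALPHA, empirical_pvalue

logger = logging.getLogger(__name__)


@dataclass
class LdConservationResult:
    disorder: str
    pop_pair: tuple[str, str]
    observed_corr: float
    null_corrs: np.ndarray
    empirical_p: float
    n_pairs: int

    @property
    def significant(self) -> bool:
        return self.empirical_p <= ALPHA


@dataclass
class FstConservationResult:
    disorder: str
    pop_pair: tuple[str, str]
    mean_fst: float
    per_snp_fst: np.ndarray
    null_means: np.ndarray
    empirical_p: float

    @property
    def significant(self) -> bool:
        return self.empirical_p <= ALPHA


# ---------------------------------------------------------------------------
# LD-structure conservation
# ---------------------------------------------------------------------------

def region_ld_vectors(dataset: GenotypeDataset, prs_snps: list[str],
                      flank_kb: float = 100.0,
                      populations: dict[str, np.ndarray] | None = None
                      ) -> tuple[list[tuple[str, str]], dict[str, np.ndarray]]:
    """Aligned per-population r² vectors over all within-region SNP pairs.

    For every PRS SNP, variants within ±``flank_kb`` form a region; every
    within-region pair is enumerated (deduplicated across overlapping
    regions) and its r² computed per population on that population's
    samples.  Pairs with undefined r² in any requested population are
    dropped listwise.  Returns the pair keys and an id-pair-aligned vector
    per population.
    """
    if populations is None:
        populations = dataset.superpop_groups()
    for name, idx in populations.items():
        if len(idx) < 2:
            raise ValueError(f"population {name!r} has fewer than 2 samples")
    indexer = dataset.variant_indexer()
    absent = [v for v in prs_snps if v not in indexer.index]
    if absent:
        raise KeyError(f"PRS SNPs absent from dataset: {absent[:5]}")
    chrom = dataset.variants["chrom"].to_numpy()
    pos = dataset.variants["pos"].to_numpy()
    ids = dataset.variants["id"].to_numpy()
    flank = flank_kb * 1000.0

    pair_keys: dict[tuple[int, int], None] = {}
    for snp in prs_snps:
        j = int(indexer[snp])
        region = np.flatnonzero((chrom == chrom[j]) & (np.abs(pos - pos[j]) <= flank))
        if region.size < 2:
            logger.info("PRS SNP %s has <2 flanking variants; contributes no pairs", snp)
            continue
        for a_i in range(len(region)):
            for b_i in range(a_i + 1, len(region)):
                a, b = int(region[a_i]), int(region[b_i])
                pair_keys.setdefault((a, b) if a < b else (b, a))
    if not pair_keys:
        return [], {name: np.array([]) for name in populations}

    pairs = np.array(list(pair_keys))
    vectors = {}
    for name, rows in populations.items():
        D = dataset.dosages[rows]
        vals = np.empty(len(pairs))
        # group pairs by left member for vectorized one-vs-many r2
        left_ids = pairs[:, 0]
        for a in np.unique(left_ids):
            sel = np.flatnonzero(left_ids == a)
            vals[sel] = r2_one_vs_many(D[:, a], D[:, pairs[sel, 1]])
        vectors[name] = vals

    ok = np.ones(len(pairs), dtype=bool)
    for vals in vectors.values():
        ok &= np.isfinite(vals)
    keys = [(ids[a], ids[b]) for a, b in pairs[ok]]
    return keys, {name: vals[ok] for name, vals in vectors.items()}


def _paired_corr(x: np.ndarray, y: np.ndarray) -> float:
    from .prevalence_association import pearson_r
    return pearson_r(x, y)


def ld_conservation_test(dataset: GenotypeDataset, prs_snps: list[str],
                         ref_pop: str = "EUR", flank_kb: float = 100.0,
                         n_sets: int = 100, set_size: int = 1000,
                         seed: int | np.random.Generator = 0,
                         populations: dict[str, np.ndarray] | None = None,
                         ) -> list[LdConservationResult]:
    """LD-structure conservation of PRS regions, per population pair.

    Observed statistic: Pearson correlation between the reference
    population's region r² vector and each other population's, pooled over
    regions.  Null: the same procedure on ``n_sets`` random sets of
    ``set_size`` SNPs; empirical p one-sided (null >= observed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if populations is None:
        populations = dataset.superpop_groups()
    if ref_pop not in populations:
        raise ValueError(f"reference population {ref_pop!r} not present")
    if dataset.n_variants < set_size:
        raise ValueError(f"variant pool ({dataset.n_variants}) smaller than set_size ({set_size})")
    others = [p for p in populations if p != ref_pop]

    def observed_corrs(snps: list[str]) -> tuple[dict[str, float], int]:
        _, vecs = region_ld_vectors(dataset, snps, flank_kb, populations)
        n_pairs = len(vecs[ref_pop])
        out = {}
        for p in others:
            out[p] = _paired_corr(vecs[ref_pop], vecs[p]) if n_pairs >= 3 else np.nan
        return out, n_pairs

    obs, n_pairs = observed_corrs(prs_snps)
    all_ids = dataset.variants["id"].to_numpy()
    null = {p: np.empty(n_sets) for p in others}
    for s in range(n_sets):
        snps = all_ids[rng.choice(dataset.n_variants, size=set_size, replace=False)]
        vals, _ = observed_corrs(list(snps))
        for p in others:
            null[p][s] = vals[p]

    results = []
    for p in others:
        nv = null[p][np.isfinite(null[p])]
        emp = empirical_pvalue(obs[p], nv, tail="greater") if np.isfinite(obs[p]) else np.nan
        results.append(LdConservationResult(
            disorder="", pop_pair=(ref_pop, p), observed_corr=obs[p],
            null_corrs=null[p], empirical_p=emp, n_pairs=n_pairs))
    return results


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(counts1, counts2) -> float:
    """Two-population Weir & Cockerham (1984) theta for one biallelic SNP.

    ``counts1``/``counts2`` are (n_AA, n_Aa, n_aa) genotype counts; the
    estimate uses the a/(a+b+c) ratio of variance components with observed
    heterozygote frequencies and may be slightly negative.  NaN when the
    variant is monomorphic in both populations combined.
    """
    theta = weir_cockerham_fst_vector(np.array([counts1]), np.array([counts2]))
    return float(theta[0])


def multi_snp_theta(C1: np.ndarray, C2: np.ndarray) -> float:
    """Weir & Cockerham's combined multi-locus theta (ratio of summed
    variance components), the estimator they recommend for aggregating over
    loci.  Unlike the per-SNP average it is nearly unbiased for the
    Balding-Nichols differentiation parameter even at high F.
    """
    a, b, c = _wc_components(np.asarray(C1, float), np.asarray(C2, float))
    ok = np.isfinite(a + b + c)
    return float(a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum())


def weir_cockerham_fst_vector(C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    """Vectorized per-SNP theta; rows are (n_AA, n_Aa, n_aa) counts."""
    a, b, c = _wc_components(np.asarray(C1, float), np.asarray(C2, float))
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    theta[denom == 0] = np.nan  # monomorphic in both populations
    return theta


def _wc_components(C1: np.ndarray, C2: np.ndarray):
    """Per-SNP Weir-Cockerham variance components (a, b, c) for two pops."""
    n1 = C1.sum(axis=1)
    n2 = C2.sum(axis=1)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each population needs at least 2 genotyped samples per SNP")
    r = 2.0
    p1 = (2 * C1[:, 0] + C1[:, 1]) / (2 * n1)
    p2 = (2 * C2[:, 0] + C2[:, 1]) / (2 * n2)
    h1 = C1[:, 1] / n1
    h2 = C2[:, 1] / n2

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _genotype_counts(D: np.ndarray) -> np.ndarray:
    """(n_AA, n_Aa, n_aa) counts per column; AA = two copies of a1."""
    return np.stack([(D == 2).sum(axis=0), (D == 1).sum(axis=0), (D == 0).sum(axis=0)],
                    axis=1).astype(float)


def mean_pairwise_fst(dataset: GenotypeDataset, snp_ids: list[str],
                      rows1: np.ndarray, rows2: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    """Mean per-SNP theta (average of ratios) between two sample groups."""
    indexer = dataset.variant_indexer()
    cols = indexer[list(snp_ids)].to_numpy()
    D1 = dataset.dosages[np.ix_(rows1, cols)]
    D2 = dataset.dosages[np.ix_(rows2, cols)]
    theta = weir_cockerham_fst_vector(_genotype_counts(D1), _genotype_counts(D2))
    ok = np.isfinite(theta)
    if not ok.any():
        return float("nan"), theta
    return float(theta[ok].mean()), theta


def fst_conservation_test(dataset: GenotypeDataset, prs_snps: list[str],
                          ref_pop: str = "EUR", n_sets: int = 100,
                          set_size: int = 1000,
                          seed: int | np.random.Generator = 0,
                          populations: dict[str, np.ndarray] | None = None,
                          ) -> list[FstConservationResult]:
    """Mean-FST conservation of PRS SNPs, per population pair.

    Observed statistic: mean Weir-Cockerham theta of the PRS SNPs between
    the reference population and each other population.  Null: mean theta of
    random SNP sets; empirical p one-sided (null <= observed, i.e. the PRS
    SNPs are called conserved when their differentiation is unusually low).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if populations is None:
        populations = dataset.superpop_groups()
    if ref_pop not in populations:
        raise ValueError(f"reference population {ref_pop!r} not present")
    if dataset.n_variants < set_size:
        raise ValueError(f"variant pool ({dataset.n_variants}) smaller than set_size ({set_size})")
    others = [p for p in populations if p != ref_pop]
    all_ids = dataset.variants["id"].to_numpy()

    obs = {}
    per_snp = {}
    for p in others:
        obs[p], per_snp[p] = mean_pairwise_fst(dataset, prs_snps,
                                               populations[ref_pop], populations[p])
    null = {p: np.empty(n_sets) for p in others}
    for s in range(n_sets):
        snps = list(all_ids[rng.choice(dataset.n_variants, size=set_size, replace=False)])
        for p in others:
            null[p][s], _ = mean_pairwise_fst(dataset, snps,
                                              populations[ref_pop], populations[p])

    results = []
    for p in others:
        nv = null[p][np.isfinite(null[p])]
        emp = empirical_pvalue(obs[p], nv, tail="less") if np.isfinite(obs[p]) else np.nan
        results.append(FstConservationResult(
            disorder="", pop_pair=(ref_pop, p), mean_fst=obs[p],
            per_snp_fst=per_snp[p], null_means=null[p], empirical_p=emp))
    return results
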