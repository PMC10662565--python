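"""Eigenstrat-style PCA of the genotype matrix, with exclusion regions.

Variants inside configured exclusion intervals (by default the GRCh37 MHC,
chr6:25-34 Mb, and the chromosome 8 inversion, chr8:8-12 Mb — conventional
intervals for these structure-distorting regions) are dropped, the remainder
is LD-pruned (100 kb window, r² 0.1), each variant is normalized by its
estimated allele frequency, and the top components of the sample covariance
are returned.  Eigenvector signs are fixed by forcing the largest-magnitude
variant loading positive so coordinates are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset
from .ld_core import prune
from .prevalence_association import pearson_r

DEFAULT_EXCLUDE_REGIONS = (
    ("6", 25_000_000, 34_000_000),   # MHC
    ("8", 8_000_000, 12_000_000),    # chr8 inversion
)


@dataclass
class PcaResult:
    coords: pd.DataFrame        # sample, country, PC1..PCk
    eigenvalues: np.ndarray     # non-increasing
    variant_ids: list[str]      # variants used after exclusion + pruning
    country_mean_pcs: pd.DataFrame  # index country, columns PC1..PCk

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


def _drop_excluded(dataset: GenotypeDataset, regions) -> GenotypeDataset:
    if not regions:
        return dataset
    chrom = dataset.variants["chrom"].to_numpy()
    pos = dataset.variants["pos"].to_numpy()
    drop = np.zeros(dataset.n_variants, dtype=bool)
    for c, start, end in regions:
        drop |= (chrom == str(c)) & (pos >= start) & (pos <= end)
    return dataset.subset_variants(np.flatnonzero(~drop))


def run_pca(dataset: GenotypeDataset, exclude_regions=DEFAULT_EXCLUDE_REGIONS,
            window_kb: float = 100.0, r2: float = 0.1, k: int = 10,
            do_prune: bool = True) -> PcaResult:
    """Principal components of frequency-normalized genotypes.

    Each variant column is normalized as (d - 2*p) / sqrt(p*(1-p)) with
    p = (1 + sum d) / (2 + 2n), the posterior-smoothed sample allele
    frequency (smoothing keeps the denominator away from zero).  Missing
    dosages contribute zero after centering.
    """
    ds = _drop_excluded(dataset, exclude_regions)
    if do_prune:
        kept = prune(ds, window_kb=window_kb, r2_threshold=r2)
        ds = ds.subset_variants(ds.variant_indexer()[kept].to_numpy())
    n, m = ds.n_samples, ds.n_variants
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(samples, variants)={min(n, m)}")

    D = ds.dosages.astype(float)
    miss = D == MISSING
    D[miss] = np.nan
    n_obs = (~miss).sum(axis=0)
    p_hat = (1.0 + np.nansum(D, axis=0)) / (2.0 + 2.0 * n_obs)
    X = (D - 2.0 * p_hat) / np.sqrt(p_hat * (1.0 - p_hat))
    X[miss] = 0.0

    # sample covariance eigendecomposition via SVD of the normalized matrix
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = (S ** 2) / m
    # sign convention: largest-magnitude variant loading positive
    for comp in range(min(k, len(S))):
        load = Vt[comp]
        j = np.argmax(np.abs(load))
        if load[j] < 0:
            Vt[comp] = -load
            U[:, comp] = -U[:, comp]
    coords_arr = U[:, :k] * S[:k]

    cols = [f"PC{i + 1}" for i in range(k)]
    coords = pd.DataFrame(coords_arr, columns=cols)
    coords.insert(0, "country", ds.samples["country"].to_numpy())
    coords.insert(0, "sample", ds.samples["sample"].to_numpy())
    country_means = coords.groupby("country", sort=False)[cols].mean()
    return PcaResult(coords=coords, eigenvalues=eigvals[:k],
                     variant_ids=ds.variants["id"].tolist(),
                     country_mean_pcs=country_means)


def pc_prs_correlation(pca: PcaResult, prs_result) -> pd.DataFrame:
    """Pearson r (and t-distribution p) of country-mean PRS vs mean PC1/PC2."""
    from scipy import stats as sps

    shared = [c for c in prs_result.country_means.index if c in pca.country_mean_pcs.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared countries")
    prs_means = prs_result.country_means.loc[shared].to_numpy(float)
    rows = []
    for pc in ("PC1", "PC2"):
        pcs = pca.country_mean_pcs.loc[shared, pc].to_numpy(float)
        r = pearson_r(prs_means, pcs)
        n = len(shared)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = 2 * sps.t.sf(abs(t), df=n - 2)
        rows.append({"disorder": prs_result.disorder, "threshold": prs_result.p_threshold,
                     "component": pc, "pearson_r": r, "pvalue": p, "n_countries": n})
    return pd.DataFrame(rows)
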