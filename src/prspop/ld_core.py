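"""Pairwise LD r-squared, greedy clumping, and window-based pruning.

The r² estimator is the squared Pearson correlation of unphased genotype
dosages ("composite LD"), the convention of mainstream genotype tooling.
Missing dosages are handled by pairwise-complete deletion; a vector that is
monomorphic among the complete entries has undefined LD (returned as NaN and
excluded from downstream aggregation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset


@dataclass
class ClumpSet:
    """Index SNPs retained by greedy clumping for one disorder/threshold.

    Invariant: every retained variant has p <= ``p_threshold`` and no two
    retained variants on one chromosome within ``window_kb`` have r² above
    ``r2_threshold``.
    """

    disorder: str
    p_threshold: float
    variant_ids: list[str]
    r2_threshold: float = 0.1
    window_kb: float = 250.0

    def __len__(self) -> int:
        return len(self.variant_ids)


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation between two variants (scalar form).

    Returns NaN when either vector is monomorphic among pairwise-complete
    entries or fewer than two complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def r2_one_vs_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """r² of one dosage vector against each column of ``Y``.

    Pairwise-complete over missing entries, vectorized; NaN where undefined.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mx = x != MISSING
    MY = Y != MISSING
    ok = mx[:, None] & MY  # n_samples x n_targets
    n = ok.sum(axis=0).astype(float)
    xv = np.where(ok, x[:, None], 0.0)
    yv = np.where(ok, Y, 0.0)
    sx = xv.sum(axis=0)
    sy = yv.sum(axis=0)
    sxx = (xv * xv).sum(axis=0)
    syy = (yv * yv).sum(axis=0)
    sxy = (xv * yv).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


def pairwise_r2(D: np.ndarray) -> np.ndarray:
    """Full r² matrix over the columns of a dosage block (NaN-safe)."""
    D = np.asarray(D, dtype=float)
    m = D.shape[1]
    out = np.empty((m, m), dtype=float)
    for j in range(m):
        out[j] = r2_one_vs_many(D[:, j], D)
        out[j, j] = 1.0 if not np.isnan(out[j, j]) else np.nan
    return out


def clump(pvalues: np.ndarray, dataset: GenotypeDataset, p_threshold: float,
          r2_threshold: float = 0.1, window_kb: float = 250.0,
          disorder: str = "", ld_sample_idx: np.ndarray | None = None) -> ClumpSet:
    """Greedy p-value-ordered LD clumping.

    Variants with p <= ``p_threshold`` are sorted ascending by p (ties broken
    by chrom, pos); the best remaining variant becomes an index SNP and every
    remaining variant on the same chromosome within ±``window_kb`` with
    r² > ``r2_threshold`` against it is discarded.  LD is computed on all
    samples by default, or on ``ld_sample_idx`` rows when given.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) != dataset.n_variants:
        raise ValueError("pvalues length must match dataset variants")
    D = dataset.dosages if ld_sample_idx is None else dataset.dosages[ld_sample_idx]
    chrom = dataset.variants["chrom"].to_numpy()
    pos = dataset.variants["pos"].to_numpy()
    ids = dataset.variants["id"].to_numpy()

    cand = np.flatnonzero(pvalues <= p_threshold)
    if cand.size == 0:
        return ClumpSet(disorder, p_threshold, [], r2_threshold, window_kb)
    order = cand[np.lexsort((pos[cand], chrom[cand], pvalues[cand]))]
    window = window_kb * 1000.0

    alive = dict.fromkeys(order.tolist())  # insertion-ordered set
    kept: list[int] = []
    while alive:
        j = next(iter(alive))
        del alive[j]
        kept.append(j)
        rest = np.array([k for k in alive
                         if chrom[k] == chrom[j] and abs(pos[k] - pos[j]) <= window])
        if rest.size:
            r2 = r2_one_vs_many(D[:, j], D[:, rest])
            for k in rest[np.nan_to_num(r2, nan=0.0) > r2_threshold]:
                del alive[int(k)]
    kept_idx = np.array(kept)
    # report index SNPs in (chrom, pos) order for stable output
    kept_idx = kept_idx[np.lexsort((pos[kept_idx], chrom[kept_idx]))]
    return ClumpSet(disorder, p_threshold, ids[kept_idx].tolist(), r2_threshold, window_kb)


def prune(dataset: GenotypeDataset, window_kb: float = 100.0,
          r2_threshold: float = 0.1) -> list[str]:
    """Windowed LD pruning to an approximately independent SNP set.

    Left-to-right positional scan per chromosome: a variant is kept iff its
    r² with every previously kept variant within ``window_kb`` is at most the
    threshold.  Undefined r² (monomorphic) does not block retention.
    """
    chrom = dataset.variants["chrom"].to_numpy()
    pos = dataset.variants["pos"].to_numpy()
    ids = dataset.variants["id"].to_numpy()
    D = dataset.dosages
    window = window_kb * 1000.0

    kept: list[int] = []
    order = np.lexsort((pos, chrom))
    kept_by_chrom: dict[str, list[int]] = {}
    for j in order:
        prev = kept_by_chrom.setdefault(chrom[j], [])
        near = [k for k in prev if pos[j] - pos[k] <= window]
        ok = True
        if near:
            r2 = r2_one_vs_many(D[:, j], D[:, near])
            ok = not np.any(np.nan_to_num(r2, nan=0.0) > r2_threshold)
        if ok:
            prev.append(j)
            kept.append(j)
    kept_arr = np.array(sorted(kept, key=lambda j: (chrom[j], pos[j])))
    return ids[kept_arr].tolist() if kept_arr.size else []
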