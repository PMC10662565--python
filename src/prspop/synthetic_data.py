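"""Synthetic multi-population genotypes, GWAS-like summary statistics, and
prevalence tables, with the hidden truth needed for recovery tests.

The generator emulates the statistical structure the analysis assumes:

* **Population differentiation** follows the Balding-Nichols model: each
  SNP has an ancestral frequency p drawn uniformly from a configured range,
  and population k draws its frequency from
  Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), giving between-population variance
  F_k * p * (1-p).
* **Linkage disequilibrium** is block-wise first-order: within a block,
  adjacent loci on a haplotype are Bernoulli variables with exact pairwise
  correlation ``block_r`` (a conditional-probability Markov chain that
  preserves the per-locus marginals), so adjacent dosage r² targets
  ``block_r**2`` and decays geometrically with distance.  Blocks are spaced
  far enough apart to be independent.
* **Causal architecture**: each disorder has ``n_causal`` causal SNPs in
  distinct blocks.  Their per-population risk-allele frequencies are shifted
  on the logit scale along a fixed population gradient, so the expected
  population-mean PRS is ordered by population index — the ordering the
  recovery tests check.
* **Prevalence** is either coupled (affine in the standardized true expected
  mean PRS plus Gaussian noise, floored at zero) or null (independent of the
  genotypes).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (MISSING, GenotypeDataset, PrevalenceTable, SummaryStats,
                         SAMPLE_COLUMNS, SUMSTAT_COLUMNS, VARIANT_COLUMNS)

_BASES = np.array(list("ACGT"))
# ordered allele pairs that are not strand-ambiguous (A/T, C/G excluded)
_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT"
                 if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})]

BLOCK_SPACING_BP = 500_000   # inter-block gap, beyond every LD window used
LOCUS_SPACING_BP = 5_000     # intra-block spacing


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study conditions at desk scale."""

    n_pops: int = 5
    samples_per_pop: int = 100
    n_snps: int = 2000
    fst: tuple = (0.02, 0.05, 0.08, 0.12, 0.16)   # per-population F
    ancestral_range: tuple = (0.1, 0.9)
    block_size: int = 10                 # SNPs per LD block
    block_r: float = 0.8                 # adjacent-locus haplotype correlation
    n_causal: int = 20                   # causal SNPs per disorder
    freq_jitter_sd: float = 0.15         # per-locus logit jitter around block freq
    gradient_strength: float = 0.5      # logit shift of causal risk-allele freq
    prevalence_intercept: float = 5.0    # percent
    prevalence_slope: float = 1.0        # percent per sd of true mean PRS
    prevalence_noise_sd: float = 0.2     # percent
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.fst) != self.n_pops:
            raise ValueError("fst must have one value per population")
        if not all(0 <= f < 1 for f in self.fst):
            raise ValueError("F values must lie in [0, 1)")
        lo, hi = self.ancestral_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral frequencies must lie in (0, 1)")
        if self.block_size < 1:
            raise ValueError("block length must be >= 1")
        if not (0 <= self.block_r < 1):
            raise ValueError("block_r must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Hidden generator state used by recovery tests."""

    ancestral_freq: np.ndarray          # (n_snps,)
    pop_freq: np.ndarray                # (n_pops, n_snps), frequency of a1
    causal_ids: list[str]
    causal_directions: np.ndarray       # +1 risk allele is a1, -1 risk is a2
    expected_mean_prs: np.ndarray       # (n_pops,) true expected country means
    pop_labels: list[str]
    coupling: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "ancestral_freq": self.ancestral_freq.tolist(),
            "pop_freq": self.pop_freq.tolist(),
            "causal_ids": self.causal_ids,
            "causal_directions": self.causal_directions.tolist(),
            "expected_mean_prs": self.expected_mean_prs.tolist(),
            "pop_labels": self.pop_labels,
            "coupling": self.coupling,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _balding_nichols_freqs(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Per-population frequencies around ancestral ``p`` at differentiation F."""
    if F == 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    q = rng.beta(a, b)
    # keep frequencies polymorphic so downstream LD/FST stay defined
    return np.clip(q, 1e-4, 1 - 1e-4)


def _markov_haplotypes(freqs: np.ndarray, block_bounds: list[tuple[int, int]],
                       r: float, n_hap: int, rng: np.random.Generator) -> np.ndarray:
    """Haplotypes with first-order within-block correlation ``r``.

    For adjacent Bernoulli loci with marginals p_prev, p and target
    correlation r, the chain uses
    P(1|prev=1) = p + r*sqrt(p q (1-p_prev)/p_prev) and
    P(1|prev=0) = p - r*sqrt(p q p_prev/(1-p_prev)), which reproduces both
    the marginals and the pairwise correlation exactly when the conditionals
    stay in [0, 1] (they are clamped otherwise).
    """
    m = len(freqs)
    H = np.empty((n_hap, m), dtype=np.int8)
    u = rng.random((n_hap, m))
    for start, stop in block_bounds:
        H[:, start] = u[:, start] < freqs[start]
        for j in range(start + 1, stop):
            p_prev, p = freqs[j - 1], freqs[j]
            q = 1 - p
            root = np.sqrt(p * q)
            p_if1 = np.clip(p + r * root * np.sqrt((1 - p_prev) / p_prev), 0.0, 1.0)
            p_if0 = np.clip(p - r * root * np.sqrt(p_prev / (1 - p_prev)), 0.0, 1.0)
            prev = H[:, j - 1] == 1
            H[:, j] = u[:, j] < np.where(prev, p_if1, p_if0)
    return H


def _layout(n_snps: int, block_size: int) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Chromosome labels, positions and block index ranges."""
    n_blocks = int(np.ceil(n_snps / block_size))
    chrom = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=int)
    bounds = []
    for b in range(n_blocks):
        start = b * block_size
        stop = min(start + block_size, n_snps)
        bounds.append((start, stop))
        chrom[start:stop] = "1"
        base = 1 + b * (BLOCK_SPACING_BP + block_size * LOCUS_SPACING_BP)
        pos[start:stop] = base + np.arange(stop - start) * LOCUS_SPACING_BP
    return chrom, pos, bounds


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genotypes(config: SyntheticConfig) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Draw the multi-population genotype dataset and its hidden truth."""
    rng = np.random.default_rng(config.seed)
    n_snps = config.n_snps
    chrom, pos, bounds = _layout(n_snps, config.block_size)

    # Allele frequencies are anchored per LD block (one ancestral frequency
    # and one Balding-Nichols deviate per block and population) with small
    # per-locus logit jitter: loci in strong LD necessarily have similar
    # frequencies, and the within-block Markov chain can only reach its
    # target correlation when the marginals are close.
    lo, hi = config.ancestral_range
    n_blocks = len(bounds)
    block_of = np.empty(n_snps, dtype=int)
    for b, (start, stop) in enumerate(bounds):
        block_of[start:stop] = b
    block_ancestral = rng.uniform(lo, hi, size=n_blocks)
    jitter = rng.normal(0.0, config.freq_jitter_sd, size=n_snps)
    ancestral = np.clip(_expit(_logit(block_ancestral[block_of]) + jitter),
                        1e-4, 1 - 1e-4)
    pop_freq = np.empty((config.n_pops, n_snps))
    for k, F in enumerate(config.fst):
        block_q = _balding_nichols_freqs(block_ancestral, F, rng)
        offset = _logit(block_q[block_of]) - _logit(block_ancestral[block_of])
        pop_freq[k] = np.clip(_expit(_logit(ancestral) + offset), 1e-4, 1 - 1e-4)

    # causal SNPs: one per block, distinct blocks, directions ±1
    n_blocks = len(bounds)
    if config.n_causal > n_blocks:
        raise ValueError("n_causal exceeds the number of LD blocks")
    causal_blocks = rng.choice(n_blocks, size=config.n_causal, replace=False)
    causal_idx = np.array(
        [rng.integers(bounds[b][0], bounds[b][1]) for b in causal_blocks], dtype=int)
    directions = rng.choice([-1, 1], size=config.n_causal)

    # shift causal risk-allele frequencies along the population gradient
    grad = np.linspace(-1.0, 1.0, config.n_pops)
    for i, j in enumerate(causal_idx):
        shift = config.gradient_strength * grad * directions[i]
        pop_freq[:, j] = np.clip(_expit(_logit(pop_freq[:, j]) + shift), 1e-4, 1 - 1e-4)

    pop_labels = [f"POP{k + 1}" for k in range(config.n_pops)]
    n = config.samples_per_pop
    dosage_blocks = []
    for k in range(config.n_pops):
        H = _markov_haplotypes(pop_freq[k], bounds, config.block_r, 2 * n, rng)
        dosage_blocks.append(H[:n] + H[n:])
    dosages = np.concatenate(dosage_blocks, axis=0).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    alleles = np.array(_ALLELE_PAIRS, dtype=object)[
        rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)]
    variants = pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(n_snps)],
        "chrom": chrom, "pos": pos,
        "a1": alleles[:, 0], "a2": alleles[:, 1],
    })[VARIANT_COLUMNS]
    samples = pd.DataFrame({
        "sample": [f"{pop_labels[k]}_S{i + 1}" for k in range(config.n_pops) for i in range(n)],
        "country": np.repeat(pop_labels, n),
        "superpop": np.repeat(pop_labels, n),
    })[SAMPLE_COLUMNS]
    dataset = GenotypeDataset(variants=variants, samples=samples, dosages=dosages)

    # expected mean PRS per population: 2 * risk-allele frequency per causal SNP
    risk_freq = np.where(directions > 0, pop_freq[:, causal_idx],
                         1.0 - pop_freq[:, causal_idx])
    expected = 2.0 * risk_freq.sum(axis=1)
    truth = SyntheticTruth(
        ancestral_freq=ancestral, pop_freq=pop_freq,
        causal_ids=[f"rs{j + 1}" for j in causal_idx],
        causal_directions=directions.astype(int),
        expected_mean_prs=expected, pop_labels=pop_labels)
    return dataset, truth


def simulate_summary_stats(dataset: GenotypeDataset, truth: SyntheticTruth,
                           config: SyntheticConfig,
                           strand_flip_prob: float = 0.1) -> SummaryStats:
    """GWAS-like summary statistics consistent with the hidden truth.

    Causal SNPs receive genome-wide-significant p-values (log-uniform below
    5e-8) and effects whose sign encodes the stored risk direction; other
    SNPs receive Uniform(0, 1) p-values and coin-flip directions.  The
    effect allele is a1 or a2 at random, and with probability
    ``strand_flip_prob`` the reported alleles are on the opposite strand, so
    harmonization is exercised.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if config.n_causal > config.n_snps:
        raise ValueError("n_causal exceeds n_snps")
    # derive the stats stream from the config seed but independent of genotypes
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    var = dataset.variants
    n = len(var)
    causal_mask = var["id"].isin(truth.causal_ids).to_numpy()
    order = {v: i for i, v in enumerate(truth.causal_ids)}

    pvals = rng.uniform(0, 1, size=n)
    pvals[causal_mask] = 10 ** rng.uniform(-12, np.log10(5e-8), size=causal_mask.sum())
    pvals = np.clip(pvals, 1e-300, 1.0)
    sign_a1 = rng.choice([-1.0, 1.0], size=n)  # effect direction relative to a1
    for j in np.flatnonzero(causal_mask):
        sign_a1[j] = float(truth.causal_directions[order[var["id"].iloc[j]]])
    magnitude = rng.uniform(0.05, 0.3, size=n)

    eff_is_a1 = rng.random(n) < 0.5
    flip = rng.random(n) < strand_flip_prob
    ea = np.where(eff_is_a1, var["a1"], var["a2"]).astype(object)
    oa = np.where(eff_is_a1, var["a2"], var["a1"]).astype(object)
    effect = magnitude * np.where(eff_is_a1, sign_a1, -sign_a1)
    ea = np.array([comp[a] if f else a for a, f in zip(ea, flip)], dtype=object)
    oa = np.array([comp[a] if f else a for a, f in zip(oa, flip)], dtype=object)

    table = pd.DataFrame({
        "id": var["id"], "chrom": var["chrom"], "pos": var["pos"],
        "effect_allele": ea, "other_allele": oa,
        "effect": effect, "pvalue": pvals,
    })[SUMSTAT_COLUMNS]
    return SummaryStats(table=table)


def simulate_prevalence(truth: SyntheticTruth, mode: str = "coupled",
                        b: float | None = None, noise_sd: float | None = None,
                        intercept: float = 5.0, seed: int = 0,
                        disorder: str = "D1") -> PrevalenceTable:
    """Country prevalence (percent), coupled to true mean PRS or null.

    Coupled mode: prevalence_c = intercept + b * z_c + Normal(0, noise_sd),
    floored at 0, with z_c the standardized true expected mean PRS of
    country c (standardizing puts b and noise_sd on a common percent scale
    whatever the causal SNP count).  Null mode: independent Gaussian noise
    around the intercept.
    """
    if mode not in ("coupled", "null"):
        raise ValueError(f"mode must be 'coupled' or 'null', got {mode!r}")
    rng = np.random.default_rng(seed)
    b = 1.0 if b is None else b
    noise_sd = 0.2 if noise_sd is None else noise_sd
    if b < 0:
        import warnings
        warnings.warn("negative prevalence coupling slope b")
    m = truth.expected_mean_prs
    z = (m - m.mean()) / m.std() if m.std() > 0 else np.zeros_like(m)
    if mode == "coupled":
        prev = intercept + b * z + rng.normal(0, noise_sd, size=len(m))
    else:
        prev = intercept + rng.normal(0, 1.0, size=len(m))
    prev = np.maximum(prev, 0.0)
    truth.coupling = {"mode": mode, "b": b, "noise_sd": noise_sd,
                      "intercept": intercept, "seed": int(seed)}
    return PrevalenceTable(table=pd.DataFrame({disorder: prev}, index=truth.pop_labels))


# ---------------------------------------------------------------------------
# on-disk emission (VCF + TSVs + truth JSON)
# ---------------------------------------------------------------------------

def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write the dataset as a minimal VCF 4.2 (GT only; REF=a2, ALT=a1)."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dataset.variants["chrom"].drop_duplicates():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.samples["sample"]) + "\n")
        V = dataset.variants
        D = dataset.dosages
        for j in range(dataset.n_variants):
            gts = "\t".join(gt_codes[int(d)] for d in D[:, j])
            fh.write(f"{V['chrom'].iloc[j]}\t{V['pos'].iloc[j]}\t{V['id'].iloc[j]}\t"
                     f"{V['a2'].iloc[j]}\t{V['a1'].iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def write_bundle(outdir, dataset: GenotypeDataset, stats: SummaryStats,
                 prevalence: PrevalenceTable, truth: SyntheticTruth) -> dict:
    """Write VCF + sample map + summary stats + prevalence + truth JSON."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "sample_map": outdir / "samples.tsv",
        "sumstats": outdir / "sumstats.tsv",
        "prevalence": outdir / "prevalence.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(dataset, paths["vcf"])
    dataset.samples.to_csv(paths["sample_map"], sep="\t", index=False)
    # conventional GWAS column headers so default readers apply unchanged
    gwas_names = {"id": "SNP", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
                  "other_allele": "A2", "effect": "BETA", "pvalue": "P"}
    stats.table.rename(columns=gwas_names).to_csv(paths["sumstats"], sep="\t", index=False)
    prevalence.table.to_csv(paths["prevalence"], sep="\t", index_label="country")
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
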