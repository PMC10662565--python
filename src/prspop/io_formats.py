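"""Readers and writers for every external format the pipeline touches.

All downstream modules work exclusively on the in-memory containers defined
here: a :class:`GenotypeDataset` (sample x variant dosage matrix with variant
metadata and population labels), a :class:`SummaryStats` table of per-variant
GWAS effects, and a :class:`PrevalenceTable` (country x disorder, percent).

Conventions
-----------
* Coordinates are 1-based, inclusive (VCF convention); every window
  computation downstream uses this convention.
* Dosages count copies of the ``a1`` allele and live in ``{0, 1, 2}`` with
  ``-1`` as the explicit missing code.  Missing genotypes are never imputed
  at ingest.
* Only biallelic SNPs are kept; multiallelic records and indels are excluded
  when a VCF is read.
* Odds ratios are converted to the natural-log scale at ingest so a single
  signed effect flows through the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
_SNP_ALLELES = frozenset("ACGT")

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["sample", "country", "superpop"]
SUMSTAT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "effect", "pvalue"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def is_snp_allele(allele: str) -> bool:
    return len(allele) == 1 and allele in _SNP_ALLELES


@dataclass
class GenotypeDataset:
    """Sample x variant dosage matrix with metadata.

    Parameters
    ----------
    variants : pandas.DataFrame
        Columns ``id, chrom, pos, a1, a2``; one row per variant, ids unique.
    samples : pandas.DataFrame
        Columns ``sample, country, superpop``; one row per sample.
    dosages : numpy.ndarray
        ``(n_samples, n_variants)`` int8 array counting copies of ``a1``;
        ``-1`` marks a missing genotype.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        if (self.samples["country"].astype(str).str.len() == 0).any():
            raise ValueError("every sample needs a non-empty country label")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_indexer(self) -> pd.Series:
        """Map variant id -> column index."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["id"])

    def subset_variants(self, keep_idx: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to variant columns ``keep_idx`` (in order)."""
        keep_idx = np.asarray(keep_idx)
        return GenotypeDataset(
            variants=self.variants.iloc[keep_idx],
            samples=self.samples,
            dosages=self.dosages[:, keep_idx],
        )

    def country_groups(self) -> dict[str, np.ndarray]:
        """Country label -> row indices, in first-appearance order."""
        order = self.samples["country"].drop_duplicates().tolist()
        idx = {c: np.flatnonzero((self.samples["country"] == c).to_numpy()) for c in order}
        return idx

    def superpop_groups(self) -> dict[str, np.ndarray]:
        order = self.samples["superpop"].drop_duplicates().tolist()
        return {s: np.flatnonzero((self.samples["superpop"] == s).to_numpy()) for s in order}


@dataclass
class SummaryStats:
    """Per-variant GWAS summary statistics.

    ``table`` columns: ``id, chrom, pos, effect_allele, other_allele, effect,
    pvalue``.  ``effect`` is signed (log odds or beta); ``pvalue`` in (0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if self.table["id"].duplicated().any():
            raise ValueError("summary statistics ids not unique after cleaning")
        p = self.table["pvalue"].to_numpy(float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        same = self.table["effect_allele"] == self.table["other_allele"]
        if same.any():
            raise ValueError("effect_allele must differ from other_allele")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PrevalenceTable:
    """Country x disorder prevalence matrix, percent units."""

    table: pd.DataFrame  # index = country, columns = disorders

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicated country rows in prevalence table")
        if (self.table.to_numpy(float) < 0).any():
            raise ValueError("prevalence values must be >= 0")

    def countries(self) -> list[str]:
        return list(self.table.index)

    def disorders(self) -> list[str]:
        return list(self.table.columns)

    def vector(self, disorder: str, countries: list[str]) -> np.ndarray:
        """Prevalence of one disorder over ``countries`` (hard error on absence)."""
        absent = [c for c in countries if c not in self.table.index]
        if absent:
            raise KeyError(f"countries absent from prevalence table: {absent}")
        if disorder not in self.table.columns:
            raise KeyError(f"disorder absent from prevalence table: {disorder}")
        return self.table.loc[countries, disorder].to_numpy(float)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sample_map(path) -> pd.DataFrame:
    """Read a 2/3-column TSV (sample, country[, superpop])."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] == 2:
        df["superpop"] = df.iloc[:, 1]
    df = df.iloc[:, :3]
    df.columns = SAMPLE_COLUMNS
    return df


def read_vcf(path, sample_map: pd.DataFrame) -> GenotypeDataset:
    """Read GT-based dosages from a VCF into a :class:`GenotypeDataset`.

    Only biallelic SNP records are kept; the ALT allele is counted as ``a1``.
    Samples missing from ``sample_map`` are dropped with a warning; zero
    overlap is a hard error.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare Exception on malformed input
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc

    vcf_samples = list(vcf.samples)
    mapped = sample_map.set_index("sample")
    keep_mask = np.array([s in mapped.index for s in vcf_samples])
    if not keep_mask.any():
        raise FormatError("no overlap between VCF samples and sample map")
    n_dropped = int((~keep_mask).sum())
    if n_dropped:
        logger.warning("dropping %d VCF samples absent from sample map", n_dropped)
    kept_samples = [s for s, k in zip(vcf_samples, keep_mask) if k]

    records, columns = [], []
    n_excluded = 0
    for var in vcf:
        if len(var.ALT) != 1 or not is_snp_allele(var.REF) or not is_snp_allele(var.ALT[0]):
            n_excluded += 1
            continue
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        records.append((vid, str(var.CHROM), int(var.POS), var.ALT[0], var.REF))
        # gts012: 0/1/2 = alt-allele count, 3 = missing
        g = np.asarray(var.gt_types)[keep_mask].astype(np.int8)
        g[g == 3] = MISSING
        columns.append(g)
    if n_excluded:
        logger.info("excluded %d non-biallelic-SNP records", n_excluded)
    if not records:
        raise FormatError(f"no biallelic SNP records in {path}")

    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    dosages = np.stack(columns, axis=1)
    samples = mapped.loc[kept_samples].reset_index()[SAMPLE_COLUMNS]
    return GenotypeDataset(variants=variants, samples=samples, dosages=dosages)


def read_summary_stats(path, column_spec: dict[str, str], effect_is_or: bool = False,
                       sep: str = "\t") -> SummaryStats:
    """Read delimited summary statistics.

    ``column_spec`` maps roles (``id, chrom, pos, effect_allele, other_allele,
    effect, pvalue``) to header names in the file.  With ``effect_is_or`` the
    effect column is an odds ratio and is natural-log transformed.  Duplicate
    ids are removed entirely (all copies); rows with missing or out-of-range
    p-values are dropped.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    needed = ["id", "effect_allele", "other_allele", "effect", "pvalue"]
    for role in needed:
        col = column_spec.get(role)
        if col is None or col not in df.columns:
            raise FormatError(f"summary statistics missing mandatory column for role '{role}'"
                              f" (header name {col!r})")
    out = pd.DataFrame({role: df[col] for role, col in column_spec.items()
                        if col in df.columns})
    for optional in ("chrom", "pos"):
        if optional not in out.columns:
            out[optional] = "" if optional == "chrom" else 0
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = pd.to_numeric(out["pos"], errors="coerce").fillna(0).astype(int)

    dup = out["id"].duplicated(keep=False)
    if dup.any():
        logger.info("removed %d rows with duplicated ids", int(dup.sum()))
        out = out[~dup]
    out["pvalue"] = pd.to_numeric(out["pvalue"], errors="coerce")
    bad_p = ~np.isfinite(out["pvalue"]) | (out["pvalue"] <= 0) | (out["pvalue"] > 1)
    if bad_p.any():
        logger.info("dropped %d rows with missing/invalid p-values", int(bad_p.sum()))
        out = out[~bad_p]
    out["effect"] = pd.to_numeric(out["effect"], errors="coerce")
    out = out[np.isfinite(out["effect"])]
    if effect_is_or:
        if (out["effect"] <= 0).any():
            raise FormatError("odds ratios must be positive")
        out["effect"] = np.log(out["effect"].to_numpy(float))
    out["effect_allele"] = out["effect_allele"].astype(str).str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.upper()
    return SummaryStats(table=out[SUMSTAT_COLUMNS])


def read_prevalence(path, countries: list[str] | None = None) -> PrevalenceTable:
    """Read a country x disorder prevalence TSV (first column = country).

    When ``countries`` is given the table is restricted to them; a requested
    country absent from the file is a hard error, never a silent NA.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    vals = df.apply(pd.to_numeric, errors="raise")
    if (vals.to_numpy(float) < 0).any():
        raise FormatError("negative prevalence value encountered")
    if countries is not None:
        absent = [c for c in countries if c not in vals.index]
        if absent:
            raise FormatError(f"prevalence table missing requested countries: {absent}")
        vals = vals.loc[countries]
    return PrevalenceTable(table=vals)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_results(frame: pd.DataFrame, path, params: dict | None = None,
                  index: bool = False) -> None:
    """Write a result table as TSV with a commented parameter header.

    Every output file is self-describing: the ``# key=value`` header records
    the thresholds, seeds and set counts that produced it.
    """
    with open(path, "w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def read_results(path, index_col=None) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
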