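"""End-to-end orchestration: QC -> harmonize -> clump -> PRS sweep ->
prevalence association -> conservation tests -> PCA, from one YAML config.

Every stage writes self-describing TSVs under the output directory, plus a
JSON manifest (config echo + hash, package version, per-stage counts).  A
re-run with an unchanged config and intact outputs is a no-op (manifest hash
match).  One global seed is expanded into stage-name-keyed substreams so
each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conservation_tests import fst_conservation_test, ld_conservation_test
from .harmonize_qc import harmonize, qc_filter
from .io_formats import (read_prevalence, read_sample_map, read_summary_stats,
                         read_vcf, write_results)
from .ld_core import clump
from .population_structure import (DEFAULT_EXCLUDE_REGIONS, pc_prs_correlation,
                                   run_pca)
from .prevalence_association import associate
from .prs_scoring import DEFAULT_THRESHOLDS, compute_unweighted_prs

logger = logging.getLogger(__name__)

STAGES = ("qc", "harmonize", "clump", "score", "associate", "conserve", "pca")

DEFAULT_SUMSTAT_COLUMNS = {
    "id": "SNP", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
    "other_allele": "A2", "effect": "BETA", "pvalue": "P",
}


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters; defaults are the conventional analysis values."""

    vcf: str = ""
    sample_map: str = ""
    sumstats: dict = dataclasses.field(default_factory=dict)   # disorder -> path
    sumstats_columns: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SUMSTAT_COLUMNS))
    effect_is_or: bool = False
    prevalence: str = ""
    outdir: str = "results"
    seed: int | None = None

    missingness_max: float = 0.02
    maf_min: float = 0.01
    hwe_min: float = 1e-6
    ambiguous_policy: str = "drop"

    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    thresholds: tuple = DEFAULT_THRESHOLDS

    n_perm: int = 1000
    n_sets: int = 100
    direction_scheme: str = "coin"

    flank_kb: float = 100.0
    conserve_n_sets: int = 100
    conserve_set_size: int = 1000
    ref_pop: str = "EUR"

    pca_k: int = 10
    pca_window_kb: float = 100.0
    pca_r2: float = 0.1
    exclude_regions: tuple = DEFAULT_EXCLUDE_REGIONS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.thresholds = tuple(sorted(float(t) for t in self.thresholds))
        for key in ("vcf", "sample_map", "prevalence"):
            path = getattr(self, key)
            if path and not Path(path).exists():
                raise FileNotFoundError(f"{key} path does not exist: {path}")
        for disorder, path in self.sumstats.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"sumstats[{disorder}] does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["exclude_regions"] = [list(r) for r in self.exclude_regions]
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def stage_seed(global_seed: int, stage: str) -> np.random.Generator:
    """Stage-name-keyed substream of the global seed (machine independent)."""
    key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(global_seed), key]))


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    cfg_hash = config.content_hash()
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash and all(
                Path(p).exists() for p in old.get("outputs", {}).values()):
            logger.info("config hash matches existing manifest; skipping recomputation")
            return old

    manifest: dict = {"config": config.to_dict(), "config_hash": cfg_hash,
                      "version": __version__, "stages": [], "counts": {},
                      "outputs": {}}
    base_params = {"seed": config.seed}

    def emit(name: str, frame: pd.DataFrame, params: dict | None = None,
             index: bool = False) -> None:
        path = outdir / f"{name}.tsv"
        write_results(frame, path, {**base_params, **(params or {})}, index=index)
        manifest["outputs"][name] = str(path)

    # ---- load + qc -------------------------------------------------------
    sample_map = read_sample_map(config.sample_map)
    raw = read_vcf(config.vcf, sample_map)
    dataset, qc_report = qc_filter(raw, config.missingness_max, config.maf_min,
                                   config.hwe_min)
    emit("qc_report", qc_report.to_frame())
    manifest["stages"].append("qc")
    manifest["counts"]["variants_input"] = raw.n_variants
    manifest["counts"]["variants_post_qc"] = dataset.n_variants
    manifest["counts"]["samples"] = dataset.n_samples

    prevalence = read_prevalence(config.prevalence)
    countries = list(dataset.country_groups())

    # ---- per-disorder analysis ------------------------------------------
    assoc_rows, prs_rows, snp_counts, pc_rows = [], [], [], []
    conserve_ld_rows, conserve_fst_rows = [], []
    harm_reports = []
    pca = None
    prs_for_pca = {}

    for disorder, path in config.sumstats.items():
        stats = read_summary_stats(path, config.sumstats_columns,
                                   effect_is_or=config.effect_is_or)
        pair, hreport = harmonize(dataset, stats, config.ambiguous_policy)
        hframe = hreport.to_frame()
        hframe.insert(0, "disorder", disorder)
        harm_reports.append(hframe)

        prev_vec = prevalence.vector(disorder, countries)
        genomewide_snps: list[str] = []
        for thr in config.thresholds:
            cs = clump(pair.pvalues, pair.dataset, thr, config.clump_r2,
                       config.clump_window_kb, disorder)
            res = compute_unweighted_prs(pair, cs)
            snp_counts.append({"disorder": disorder, "threshold": thr,
                               "n_snps": res.n_snps})
            prs_rows.append(res.to_frame())
            if thr == min(config.thresholds):
                genomewide_snps = cs.variant_ids
                prs_for_pca[disorder] = res
            if res.empty:
                continue
            rng = stage_seed(config.seed, f"associate:{disorder}:{thr}")
            ar = associate(dataset, res, prev_vec, config.n_perm, config.n_sets,
                           rng, config.direction_scheme)
            assoc_rows.append(ar.to_frame())

        # conservation tests on the genome-wide-threshold PRS SNPs
        snps_in_pool = [s for s in genomewide_snps
                        if s in set(dataset.variants["id"])]
        if snps_in_pool:
            rng = stage_seed(config.seed, f"conserve:{disorder}")
            for r in ld_conservation_test(dataset, snps_in_pool, config.ref_pop,
                                          config.flank_kb, config.conserve_n_sets,
                                          config.conserve_set_size, rng):
                conserve_ld_rows.append({
                    "disorder": disorder, "ref_pop": r.pop_pair[0],
                    "other_pop": r.pop_pair[1], "observed_corr": r.observed_corr,
                    "null_mean": float(np.nanmean(r.null_corrs)),
                    "empirical_p": r.empirical_p, "n_pairs": r.n_pairs,
                    "significant": r.significant})
            rng = stage_seed(config.seed, f"conserve_fst:{disorder}")
            for r in fst_conservation_test(dataset, snps_in_pool, config.ref_pop,
                                           config.conserve_n_sets,
                                           config.conserve_set_size, rng):
                conserve_fst_rows.append({
                    "disorder": disorder, "ref_pop": r.pop_pair[0],
                    "other_pop": r.pop_pair[1], "mean_fst": r.mean_fst,
                    "null_mean": float(np.nanmean(r.null_means)),
                    "empirical_p": r.empirical_p, "significant": r.significant})

    emit("harmonize_report", pd.concat(harm_reports, ignore_index=True))
    manifest["stages"].append("harmonize")
    emit("snp_counts", pd.DataFrame(snp_counts),
         {"clump_r2": config.clump_r2, "clump_window_kb": config.clump_window_kb})
    manifest["stages"].append("clump")
    emit("prs_country", pd.concat(prs_rows, ignore_index=True),
         {"thresholds": list(config.thresholds)})
    manifest["stages"].append("score")
    if assoc_rows:
        emit("association", pd.concat(assoc_rows, ignore_index=True),
             {"n_perm": config.n_perm, "n_sets": config.n_sets})
    manifest["stages"].append("associate")
    if conserve_ld_rows:
        emit("ld_conservation", pd.DataFrame(conserve_ld_rows),
             {"n_sets": config.conserve_n_sets, "set_size": config.conserve_set_size,
              "flank_kb": config.flank_kb})
    if conserve_fst_rows:
        emit("fst_conservation", pd.DataFrame(conserve_fst_rows),
             {"n_sets": config.conserve_n_sets, "set_size": config.conserve_set_size})
    manifest["stages"].append("conserve")

    # ---- PCA -------------------------------------------------------------
    pca = run_pca(dataset, config.exclude_regions, config.pca_window_kb,
                  config.pca_r2, config.pca_k)
    emit("pca_coords", pca.coords)
    emit("pca_eigenvalues",
         pd.DataFrame({"component": [f"PC{i+1}" for i in range(pca.k)],
                       "eigenvalue": pca.eigenvalues}))
    for disorder, res in prs_for_pca.items():
        if res.n_snps > 0:
            pc_rows.append(pc_prs_correlation(pca, res))
    if pc_rows:
        emit("pc_prs_correlation", pd.concat(pc_rows, ignore_index=True))
    manifest["stages"].append("pca")
    manifest["counts"]["pca_variants"] = len(pca.variant_ids)
    manifest["counts"]["snps_per_threshold"] = snp_counts

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
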