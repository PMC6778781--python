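"""End-to-end orchestration: QC -> partitions -> differentiation scan ->
structure -> environmental association -> hit aggregation -> LD windows ->
gene proximity, with a manifest of seeds, versions, and per-stage counts.

All thresholds default to the study's settings (20% missingness cap,
MAF 0.01, elevation splits at 1,500/3,000 m, latitude bands at 30/40 N,
longitude split at 48 E, 10 resampling iterations, 1,000 permutations,
99th/97.5th percentile outliers, 3 PCs, FDR 0.25, 3 ICs, 100 kb LD
half-window with r^2 > 0.45, 10 kb gene flank).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import linalg

from . import __version__
from .association import AssocResult, associate_variable, build_env_matrix
from .fst import FstScanResult, balanced_resample_scan, call_outliers, permutation_pvalues
from .geno_io import (
    GenotypeMatrix,
    read_genotypes,
    read_metadata,
    qc_filter,
    write_vcf,
)
from .genes import overlap_candidates, read_bed, read_candidates, read_gff3
from .ld import filter_dense_panel, ld_report
from .partitioning import standard_partitions
from .structure import genotype_pca, vanraden_kinship

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Frozen-schema run configuration; defaults are the study's values."""

    # inputs
    vcf: str = ""
    metadata: str = ""
    gene_models: str = ""  # GFF3 (.gff/.gff3) or BED
    candidates: str = ""
    dense_vcf: str = ""  # resequencing panel for LD windows (optional)
    outgroup: str = ""
    outdir: str = "clinescan_out"
    # filters
    max_missing: float = 0.20
    maf_min: float = 0.01
    cull_complete_ld: bool = True
    # fst scan
    fst_n_iter: int = 10
    fst_n_perm: int = 1000
    fst_percentiles: tuple[float, float] = (99.0, 97.5)
    # association
    k_pcs: int = 3
    n_ics: int = 3
    fdr: float = 0.25
    # ld windows
    ld_window: int = 100_000
    r2_threshold: float = 0.45
    dense_maf_min: float = 0.01
    dense_max_missing: float = 0.50
    # genes
    gene_flank: int = 10_000
    # rng
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fst_percentiles" in raw:
            raw["fst_percentiles"] = tuple(raw["fst_percentiles"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self).items()},
                fh, sort_keys=False,
            )


@dataclass
class RunResult:
    g_filtered: GenotypeMatrix
    fst_results: list[FstScanResult]
    assoc_results: list[AssocResult]
    hits: pd.DataFrame
    ld_table: pd.DataFrame | None
    candidate_overlap: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def aggregate_hits(
    fst_results: list[FstScanResult],
    assoc_results: list[AssocResult],
    fdr: float = 0.25,
    outlier_flag: str = "outlier_99",
) -> pd.DataFrame:
    """Union of hit SNPs across all comparisons and variables, de-duplicated
    by snp_id with every source analysis recorded.

    Returns columns snp_id, chrom, pos, sources (semicolon-joined),
    n_sources, dual_evidence (seen in both a differentiation comparison and
    an environmental association).
    """
    records: dict[str, dict] = {}

    def add(snp_id, chrom, pos, source, kind):
        rec = records.setdefault(
            snp_id,
            {"snp_id": snp_id, "chrom": chrom, "pos": pos, "sources": [],
             "kinds": set()},
        )
        rec["sources"].append(source)
        rec["kinds"].add(kind)

    for res in fst_results:
        flags = getattr(res, outlier_flag)
        if flags is None:
            raise ValueError(f"{res.comparison_id}: outliers not called")
        for j in np.flatnonzero(flags):
            add(res.snp_ids[j], res.chrom[j], res.pos[j],
                f"fst:{res.comparison_id}", "fst")
    for res in assoc_results:
        sig = res.significant(fdr)
        for _, row in sig.iterrows():
            add(row["snp_id"], row["chrom"], row["pos"],
                f"assoc:{res.variable}", "assoc")

    rows = []
    for rec in records.values():
        rows.append(
            {
                "snp_id": rec["snp_id"],
                "chrom": rec["chrom"],
                "pos": rec["pos"],
                "sources": ";".join(sorted(set(rec["sources"]))),
                "n_sources": len(set(rec["sources"])),
                "dual_evidence": rec["kinds"] >= {"fst", "assoc"},
            }
        )
    out = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "sources", "n_sources",
                       "dual_evidence"]
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def overlap_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise source-overlap counts over the aggregated hit table."""
    source_sets: dict[str, set] = {}
    for _, row in hits.iterrows():
        for s in row["sources"].split(";"):
            source_sets.setdefault(s, set()).add(row["snp_id"])
    names = sorted(source_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            rows.append(
                {
                    "source_a": a,
                    "source_b": b,
                    "n_shared": len(source_sets[a] & source_sets[b]),
                }
            )
    return pd.DataFrame(rows, columns=["source_a", "source_b", "n_shared"])


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage on the configured inputs, writing TSV outputs and
    a manifest under ``config.outdir``."""
    t0 = time.time()
    for key in ("vcf", "metadata"):
        path = getattr(config, key)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"config.{key}: missing input path {path!r}")
    for key in ("gene_models", "candidates", "dense_vcf", "outgroup"):
        path = getattr(config, key)
        if path and not Path(path).exists():
            raise FileNotFoundError(f"config.{key}: missing input path {path!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "clinescan_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    def stage(name, **counts):
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    # --- QC -------------------------------------------------------------
    g_raw = read_genotypes(config.vcf)
    meta = read_metadata(config.metadata)
    meta = meta.loc[[s for s in g_raw.samples if s in meta.index]]
    g, report = qc_filter(
        g_raw, max_missing=config.max_missing,
        cull_complete_ld=config.cull_complete_ld,
    )
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    write_vcf(g, outdir / "filtered.vcf")
    stage("qc", n_input=g_raw.n_snps, n_kept=g.n_snps, n_samples=g.n_samples)

    # --- partitions + differentiation scan ------------------------------
    partitions = standard_partitions(meta)
    pd.concat([p.to_frame() for p in partitions]).to_csv(
        outdir / "partitions.tsv", sep="\t", index=False
    )
    fst_results = []
    for part in partitions:
        res = balanced_resample_scan(
            g, part, n_iter=config.fst_n_iter,
            seed=int(rng.integers(2**31)),
        )
        if config.fst_n_perm > 0:
            res = permutation_pvalues(
                g, part, res, n_perm=config.fst_n_perm,
                seed=int(rng.integers(2**31)),
            )
        res = call_outliers(res, percentiles=config.fst_percentiles)
        res.to_frame().to_csv(
            outdir / f"fst_{part.comparison_id}.tsv", sep="\t", index=False
        )
        fst_results.append(res)
    stage(
        "fst",
        comparisons=len(fst_results),
        n_outliers_99=int(sum(r.outlier_99.sum() for r in fst_results)),
    )

    # --- structure -------------------------------------------------------
    kin = vanraden_kinship(g)
    kin.to_frame().to_csv(outdir / "kinship.tsv", sep="\t")
    eig = linalg.eigh(kin.K)
    pcs, explained = genotype_pca(g, k=config.k_pcs)
    pd.DataFrame(
        pcs, index=g.samples,
        columns=[f"PC{i + 1}" for i in range(pcs.shape[1])],
    ).to_csv(outdir / "pc_scores.tsv", sep="\t")
    stage("structure", k_pcs=config.k_pcs,
          explained=[round(float(e), 4) for e in explained])

    # --- environmental association ---------------------------------------
    env = build_env_matrix(meta, n_ics=config.n_ics, seed=config.seed)
    env = env.loc[g.samples]
    assoc_results = []
    for var in env.columns:
        res = associate_variable(
            g, env[var], pcs, kin.K, maf_min=config.maf_min,
            eig=eig if not env[var].isna().any() else None,
        )
        assoc_results.append(res)
    assoc_table = pd.concat(
        [r.table.assign(variable=r.variable) for r in assoc_results],
        ignore_index=True,
    )
    assoc_table.to_csv(outdir / "association.tsv", sep="\t", index=False)
    stage(
        "assoc",
        n_variables=len(assoc_results),
        n_significant=int(
            sum(len(r.significant(config.fdr)) for r in assoc_results)
        ),
    )

    # --- hit aggregation --------------------------------------------------
    hits = aggregate_hits(fst_results, assoc_results, fdr=config.fdr)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    overlap_summary(hits).to_csv(
        outdir / "hit_overlap.tsv", sep="\t", index=False
    )
    stage("aggregate", n_unique_hits=len(hits),
          n_dual=int(hits["dual_evidence"].sum()))

    # --- LD windows -------------------------------------------------------
    ld_table = None
    if config.dense_vcf:
        dense = filter_dense_panel(
            read_genotypes(config.dense_vcf),
            maf_min=config.dense_maf_min,
            max_missing=config.dense_max_missing,
        )
        gene_models = _read_gene_models(config.gene_models)
        ld_table = ld_report(
            hits, g, dense, gene_models,
            window=config.ld_window, r2_threshold=config.r2_threshold,
        )
        ld_table.to_csv(outdir / "ld_windows.tsv", sep="\t", index=False)
        stage("ld", n_windows=len(ld_table),
              classes=ld_table["ld_class"].value_counts().to_dict())

    # --- gene proximity ---------------------------------------------------
    candidate_overlap = None
    if config.gene_models and config.candidates:
        gene_models = _read_gene_models(config.gene_models)
        candidates = read_candidates(config.candidates)
        hit_src = hits.assign(source=hits["sources"])
        candidate_overlap = overlap_candidates(
            hit_src, gene_models, candidates, flank=config.gene_flank
        )
        candidate_overlap.to_csv(
            outdir / "candidate_overlap.tsv", sep="\t", index=False
        )
        stage("genes", n_candidate_genes_hit=candidate_overlap["gene_id"].nunique())

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return RunResult(
        g_filtered=g,
        fst_results=fst_results,
        assoc_results=assoc_results,
        hits=hits,
        ld_table=ld_table,
        candidate_overlap=candidate_overlap,
        manifest=manifest,
    )


def combined_scan_recovery(
    n_reps: int = 20,
    seed: int = 0,
    n_pops: int = 10,
    n_per_pop: int = 50,
    n_snps: int = 2000,
    target_fst: float = 0.08,
    n_adaptive: int = 20,
    cline_strength: float = 3.0,
    fdr: float = 0.25,
) -> pd.DataFrame:
    """End-to-end recovery experiment for the combined scan.

    Each replicate plants ``n_adaptive`` loci whose allele frequencies
    follow a strong logistic cline along the temperature-like axis (BIO1),
    simulates an island-model panel, and runs the differentiation
    comparison aligned with that axis (the two-level elevation partition)
    plus the mixed-model association with BIO1.  Hits are the union of
    99th-percentile theta outliers and MLM q <= ``fdr`` associations.

    Returns one row per replicate with recall (fraction of planted loci
    recovered) and observed FDR (fraction of hits that are unplanted).
    """
    from .partitioning import partition_elevation
    from .simulate import SimScenario, simulate_panel
    from .association import associate_variable

    master = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        rep_seed = int(master.integers(2**31))
        scenario = SimScenario(
            n_pops=n_pops, n_per_pop=n_per_pop, n_snps=n_snps,
            target_fst=target_fst, n_adaptive=n_adaptive,
            cline_strength=cline_strength, adaptive_env=("BIO1",),
            seed=rep_seed,
        )
        g, meta, truth = simulate_panel(scenario)
        adaptive = truth.adaptive_ids()
        res = call_outliers(
            balanced_resample_scan(
                g, partition_elevation(meta, "two_level"), n_iter=10,
                seed=rep_seed + 1,
            )
        )
        hits = set(res.snp_ids[res.outlier_99])
        kin = vanraden_kinship(g)
        pcs, _ = genotype_pca(g, k=3)
        eig = linalg.eigh(kin.K)
        assoc = associate_variable(
            g, meta["BIO1"], pcs, kin.K, maf_min=0.01, eig=eig
        )
        hits |= set(assoc.significant(fdr)["snp_id"])
        tp = len(hits & adaptive)
        rows.append(
            {
                "replicate": rep,
                "n_hits": len(hits),
                "recall": tp / len(adaptive),
                "fdr": (len(hits) - tp) / len(hits) if hits else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _read_gene_models(path: str) -> pd.DataFrame:
    if str(path).endswith((".gff", ".gff3")):
        return read_gff3(path)
    return read_bed(path)
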