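"""Linkage-disequilibrium profiling in windows around focal SNPs.

For each focal SNP (typically a scan hit genotyped on the sparse array
panel), r^2 is computed against every SNP of a dense (resequencing) panel
within 100 kb on each side.  When the focal SNP is absent from the dense
panel, a proxy is substituted: the in-window dense SNP with the closest
minor allele frequency, ties broken by physical distance and then by lower
position.  Windows are then classified by whether high-LD neighbors stay
inside the gene containing the proxy ("within_gene"), reach outside it
("extended"), never exceed the threshold ("none"), or are absent
("missing_window").

r^2 here is the squared Pearson correlation of dosages, which for fully
inbred lines equals the haplotype-frequency r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, VariantRecord, minor_allele_freq, qc_filter

WINDOW_BP = 100_000  # each side
R2_THRESHOLD = 0.45


@dataclass
class LdWindowReport:
    focal_snp_id: str
    proxy_snp_id: str | None
    proxy_distance: int | None
    proxy_maf_delta: float | None
    neighbors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "pos", "r2"])
    )
    ld_class: str = "missing_window"


def r_squared(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; nan with <2 complete pairs or zero variance."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    ok = ~np.isnan(d1) & ~np.isnan(d2)
    if ok.sum() < 2:
        return np.nan
    x, y = d1[ok], d2[ok]
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return np.nan
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(cov**2 / (vx * vy))


def filter_dense_panel(
    g: GenotypeMatrix, maf_min: float = 0.01, max_missing: float = 0.50
) -> GenotypeMatrix:
    """Pre-filter the dense panel: MAF >= ``maf_min`` and missingness
    strictly below ``max_missing`` (SNPs with >= 50% missing data removed)."""
    filtered, _ = qc_filter(g, max_missing=np.nextafter(max_missing, 0))
    maf = minor_allele_freq(filtered)
    return filtered.take_snps(np.flatnonzero(maf >= maf_min))


def select_proxy(
    focal: VariantRecord,
    focal_maf: float,
    dense_panel: GenotypeMatrix,
    window: int = WINDOW_BP,
) -> tuple[int | None, int, float]:
    """Choose the dense-panel SNP standing in for the focal SNP.

    Returns ``(column index in dense panel, bp distance, |MAF delta|)``;
    ``(None, 0, nan)`` when the window holds no candidates.  A dense SNP
    with the same snp_id is the focal SNP itself and is always used.
    MAF similarity takes precedence over distance; distance breaks MAF
    ties and lower position breaks distance ties.
    """
    ids = dense_panel.variants["snp_id"].values
    exact = np.flatnonzero(ids == focal.snp_id)
    if exact.size:
        return int(exact[0]), 0, 0.0

    chrom = dense_panel.variants["chrom"].values
    pos = dense_panel.variants["pos"].values.astype(int)
    in_window = (chrom == focal.chrom) & (np.abs(pos - focal.pos) <= window)
    cand = np.flatnonzero(in_window)
    if cand.size == 0:
        return None, 0, np.nan

    maf = minor_allele_freq(dense_panel)[cand]
    delta = np.abs(maf - focal_maf)
    dist = np.abs(pos[cand] - focal.pos)
    order = np.lexsort((pos[cand], dist, delta))
    best = cand[order[0]]
    return int(best), int(abs(pos[best] - focal.pos)), float(
        abs(minor_allele_freq(dense_panel, best) - focal_maf)
    )


def ld_window(
    focal: VariantRecord,
    focal_maf: float,
    dense_panel: GenotypeMatrix,
    window: int = WINDOW_BP,
) -> LdWindowReport:
    """Build the neighbor r^2 profile around the (proxy of the) focal SNP."""
    j_proxy, dist, maf_delta = select_proxy(focal, focal_maf, dense_panel, window)
    if j_proxy is None:
        return LdWindowReport(focal.snp_id, None, None, None)

    chrom = dense_panel.variants["chrom"].values
    pos = dense_panel.variants["pos"].values.astype(int)
    proxy_pos = int(pos[j_proxy])
    in_window = (
        (chrom == chrom[j_proxy])
        & (np.abs(pos - proxy_pos) <= window)
        & (np.arange(dense_panel.n_snps) != j_proxy)
    )
    cols = np.flatnonzero(in_window)
    d_proxy = dense_panel.dosage[:, j_proxy]
    rows = []
    for j in cols:
        r2 = r_squared(d_proxy, dense_panel.dosage[:, j])
        if not np.isnan(r2):
            rows.append((dense_panel.variants["snp_id"].iloc[j], int(pos[j]), r2))
    neighbors = pd.DataFrame(rows, columns=["snp_id", "pos", "r2"])
    return LdWindowReport(
        focal_snp_id=focal.snp_id,
        proxy_snp_id=dense_panel.variants["snp_id"].iloc[j_proxy],
        proxy_distance=dist,
        proxy_maf_delta=maf_delta,
        neighbors=neighbors,
        ld_class="missing_window" if neighbors.empty else "unclassified",
    )


def classify_ld(
    report: LdWindowReport,
    gene_models: pd.DataFrame,
    proxy_chrom: str,
    proxy_pos: int,
    r2_threshold: float = R2_THRESHOLD,
) -> str:
    """Assign the LD class for a window report.

    within_gene: every neighbor with r^2 > threshold lies inside the gene
    interval containing the proxy; extended: at least one such neighbor
    lies outside it; none: no neighbor exceeds the threshold;
    missing_window: no neighbors at all.
    """
    if report.neighbors.empty:
        report.ld_class = "missing_window"
        return report.ld_class
    high = report.neighbors[report.neighbors["r2"] > r2_threshold]
    if high.empty:
        report.ld_class = "none"
        return report.ld_class

    gm = gene_models[gene_models["chrom"] == proxy_chrom]
    host = gm[(gm["start"] <= proxy_pos) & (proxy_pos < gm["end"])]
    if host.empty:
        report.ld_class = "extended"
        return report.ld_class
    start = host["start"].min()
    end = host["end"].max()
    inside = (high["pos"] >= start) & (high["pos"] < end)
    report.ld_class = "within_gene" if inside.all() else "extended"
    return report.ld_class


def ld_report(
    hits: pd.DataFrame,
    sparse_panel: GenotypeMatrix,
    dense_panel: GenotypeMatrix,
    gene_models: pd.DataFrame,
    window: int = WINDOW_BP,
    r2_threshold: float = R2_THRESHOLD,
) -> pd.DataFrame:
    """Window report for every hit SNP (rows with snp_id present in the
    sparse panel).  Returns a tidy table, one row per focal SNP."""
    sparse_ids = {s: j for j, s in enumerate(sparse_panel.variants["snp_id"])}
    maf_sparse = minor_allele_freq(sparse_panel)
    pos_dense = dense_panel.variants["pos"].values.astype(int)
    out = []
    for snp_id in hits["snp_id"]:
        j = sparse_ids.get(snp_id)
        if j is None:
            continue
        focal = sparse_panel.variant_record(j)
        rep = ld_window(focal, float(maf_sparse[j]), dense_panel, window)
        if rep.proxy_snp_id is not None:
            jp = int(
                np.flatnonzero(dense_panel.variants["snp_id"].values == rep.proxy_snp_id)[0]
            )
            classify_ld(
                rep, gene_models, focal.chrom, int(pos_dense[jp]), r2_threshold
            )
        out.append(
            {
                "focal_snp_id": rep.focal_snp_id,
                "proxy_snp_id": rep.proxy_snp_id,
                "proxy_distance": rep.proxy_distance,
                "proxy_maf_delta": rep.proxy_maf_delta,
                "n_neighbors": len(rep.neighbors),
                "max_r2": rep.neighbors["r2"].max() if len(rep.neighbors) else np.nan,
                "ld_class": rep.ld_class,
            }
        )
    return pd.DataFrame(out)
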