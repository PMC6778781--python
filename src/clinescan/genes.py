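"""SNP-to-gene proximity mapping, candidate-gene overlap, and haplotype
tabulation at hit loci.

Gene models are held 0-based half-open.  A SNP identifies a gene when it
falls in the gene interval or within 10 kb up- or downstream (boundary
inclusive at exactly the flank distance); strand is ignored because the
rule is strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix

FLANK_BP = 10_000

CANDIDATE_TRAITS = frozenset({"flowering_time", "cold", "drought"})


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start >= end")


def read_gff3(path) -> pd.DataFrame:
    """Gene features from a GFF3 file -> DataFrame(gene_id, chrom, start,
    end, strand), converted to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("Name", f"{parts[0]}:{parts[3]}"))
            rows.append(
                (gene_id, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6])
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def read_bed(path) -> pd.DataFrame:
    """4-column BED (chrom, start, end, name); BED is already 0-based."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id"], usecols=range(4),
    )
    bed["strand"] = "+"
    return bed[["gene_id", "chrom", "start", "end", "strand"]]


def write_gff3(gene_models: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in gene_models.iterrows():
            fh.write(
                f"{r.chrom}\tclinescan\tgene\t{int(r.start) + 1}\t{int(r.end)}\t.\t"
                f"{r.get('strand', '+')}\t.\tID={r.gene_id}\n"
            )


def read_candidates(path) -> pd.DataFrame:
    """Candidate-gene TSV: gene_id, trait, source_species, source_symbol."""
    cand = pd.read_csv(path, sep="\t")
    bad = set(cand["trait"]) - CANDIDATE_TRAITS
    if bad:
        raise ValueError(f"unknown candidate traits: {sorted(bad)}")
    return cand


def snp_to_genes(
    snp_chrom: str,
    snp_pos: int,
    gene_models: pd.DataFrame,
    flank: int = FLANK_BP,
) -> pd.DataFrame:
    """All genes whose [start - flank, end + flank) contains the SNP.

    Overlapping genes all match; an empty frame means unassigned.  A SNP on
    a chromosome absent from the gene models is likewise unassigned.
    """
    gm = gene_models[gene_models["chrom"] == snp_chrom]
    hit = (gm["start"] - flank <= snp_pos) & (snp_pos < gm["end"] + flank)
    return gm[hit]


def overlap_candidates(
    hits: pd.DataFrame,
    gene_models: pd.DataFrame,
    candidates: pd.DataFrame,
    flank: int = FLANK_BP,
) -> pd.DataFrame:
    """Candidate genes touched by at least one hit SNP.

    ``hits`` needs columns snp_id, chrom, pos and a ``source`` column
    naming the analysis that produced each hit (comparison id or
    environmental variable).  Returns one row per (gene, hit SNP) with the
    candidate's trait attached.
    """
    rows = []
    for _, h in hits.iterrows():
        genes = snp_to_genes(h["chrom"], int(h["pos"]), gene_models, flank)
        for _, gm in genes.iterrows():
            rows.append(
                {
                    "gene_id": gm["gene_id"],
                    "snp_id": h["snp_id"],
                    "source": h.get("source", ""),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "trait", "snp_id", "source", "source_species",
                     "source_symbol"]
        )
    assigned = pd.DataFrame(rows)
    merged = assigned.merge(candidates, on="gene_id", how="inner")
    cols = ["gene_id", "trait", "snp_id", "source"]
    extra = [c for c in ("source_species", "source_symbol") if c in merged.columns]
    return merged[cols + extra].drop_duplicates().reset_index(drop=True)


def candidate_trait_counts(overlap: pd.DataFrame) -> pd.Series:
    """Number of distinct candidate genes hit, per trait."""
    if overlap.empty:
        return pd.Series(dtype=int)
    return overlap.groupby("trait")["gene_id"].nunique()


def tabulate_haplotypes(
    g: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    drop_het: bool = True,
) -> pd.DataFrame:
    """Haplotype strings over the SNPs in [start, end) on ``chrom``.

    Homozygous dosages map to single alleles (0 -> REF, 2 -> ALT); samples
    with any heterozygous or missing call in the interval are excluded when
    ``drop_het`` (statistical phasing is out of scope for a >=98% inbred
    panel).  Returns one row per distinct haplotype with its sample count
    and sample list; the excluded-sample count is in ``df.attrs``.
    """
    in_iv = (
        (g.variants["chrom"] == chrom)
        & (g.variants["pos"] >= start)
        & (g.variants["pos"] < end)
    )
    cols = np.flatnonzero(in_iv.to_numpy())
    if cols.size == 0:
        raise ValueError(f"no SNPs in {chrom}:[{start},{end})")
    order = cols[np.argsort(g.variants["pos"].values[cols], kind="mergesort")]
    sub = g.dosage[:, order]
    refs = g.variants["ref"].values[order]
    alts = g.variants["alt"].values[order]

    haplotypes: dict[str, list[str]] = {}
    n_excluded = 0
    for i, sample in enumerate(g.samples):
        row = sub[i]
        if np.isnan(row).any() or (drop_het and (row == 1).any()):
            n_excluded += 1
            continue
        # with drop_het=False, heterozygous calls are kept and marked 'H'
        hap = "".join(
            alts[j] if row[j] == 2 else (refs[j] if row[j] == 0 else "H")
            for j in range(row.size)
        )
        haplotypes.setdefault(hap, []).append(sample)

    out = pd.DataFrame(
        {
            "haplotype": list(haplotypes.keys()),
            "count": [len(v) for v in haplotypes.values()],
            "samples": [",".join(v) for v in haplotypes.values()],
        }
    ).sort_values("count", ascending=False, kind="mergesort").reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["locus"] = f"{chrom}:{start}-{end}"
    return out
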