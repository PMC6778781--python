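"""Genotype and metadata I/O, quality filtering, and allele polarization.

Genotypes are held as a dosage matrix (samples x SNPs) counting copies of
the ALT allele, with ``numpy.nan`` marking missing calls.  Coordinates are
0-based half-open internally; VCF emission converts back to 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

GROWTH_HABITS = frozenset({"spring", "winter", "facultative", "unknown"})
ROW_TYPES = frozenset({"two", "six", "unknown"})
BIO_COLUMNS = tuple(f"BIO{i}" for i in range(1, 20))

_METADATA_COLUMNS = (
    "sample_id",
    "latitude",
    "longitude",
    "elevation",
    "growth_habit",
    "row_type",
) + BIO_COLUMNS


class GenotypeError(ValueError):
    """Fatal problem with genotype input (unreadable, empty, inconsistent)."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP. ``pos`` is 0-based; VCF emission adds 1 back."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise GenotypeError(f"{self.snp_id}: ref == alt ({self.ref_allele})")
        if self.pos < 0:
            raise GenotypeError(f"{self.snp_id}: negative position")


@dataclass
class GenotypeMatrix:
    """Dosage-coded biallelic genotypes for a panel of samples.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    variants : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``;
        ``pos`` is 0-based.
    dosage : numpy.ndarray
        ``(n_samples, n_snps)`` float array with entries in {0, 1, 2, nan}.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise GenotypeError(f"dosage entries outside {{0,1,2,nan}}: {bad}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def variant_record(self, j: int) -> VariantRecord:
        row = self.variants.iloc[j]
        return VariantRecord(row.snp_id, row.chrom, int(row.pos), row.ref, row.alt)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the SNP columns in ``index`` (kept order)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            meta=dict(self.meta),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            variants=self.variants.copy(),
            dosage=self.dosage[index, :],
            meta=dict(self.meta),
        )


@dataclass
class FilterReport:
    """Per-filter removal counts from :func:`qc_filter`."""

    n_input: int = 0
    n_monomorphic: int = 0
    n_high_missing: int = 0
    n_complete_ld: int = 0
    n_kept: int = 0
    max_missing: float = 0.20

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [
                    "input",
                    "monomorphic",
                    f"missingness>{self.max_missing:g}",
                    "complete_ld",
                    "kept",
                ],
                "n_snps": [
                    self.n_input,
                    self.n_monomorphic,
                    self.n_high_missing,
                    self.n_complete_ld,
                    self.n_kept,
                ],
            }
        )


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def read_genotypes(vcf_path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are used; multi-allelic or non-SNP records
    are skipped and counted (``meta['n_skipped']``).  Raises
    :class:`GenotypeError` when the file is unreadable or yields zero
    usable records.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise GenotypeError(f"cannot read VCF {vcf_path}: {exc}") from exc

    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = MISSING
        snp_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        rows.append((snp_id, v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        dosages.append(gt)
    if not rows:
        raise GenotypeError(f"no usable biallelic SNP records in {vcf_path}")
    if n_skipped:
        logger.info("read_genotypes: skipped %d non-biallelic/non-SNP records", n_skipped)
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosage=np.column_stack(dosages) if dosages else np.empty((len(samples), 0)),
        meta={"n_skipped": n_skipped, "source": str(vcf_path)},
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT fields."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        order = np.lexsort((g.variants["pos"].values, g.variants["chrom"].values))
        for j in order:
            row = g.variants.iloc[j]
            calls = [
                code.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosage[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{int(row.pos) + 1}\t{row.snp_id}\t{row.ref}\t"
                f"{row.alt}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# Metadata / outgroup tables
# ---------------------------------------------------------------------------


def read_metadata(tsv_path) -> pd.DataFrame:
    """Read the per-accession metadata TSV, validated and indexed by sample_id."""
    meta = pd.read_csv(tsv_path, sep="\t")
    missing_cols = [c for c in ("sample_id", "latitude", "longitude", "elevation",
                                "growth_habit") if c not in meta.columns]
    if missing_cols:
        raise GenotypeError(f"metadata missing columns: {missing_cols}")
    lat = meta["latitude"].dropna()
    lon = meta["longitude"].dropna()
    if ((lat < -90) | (lat > 90)).any():
        raise GenotypeError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise GenotypeError("longitude outside [-180, 180]")
    bad_habit = set(meta["growth_habit"].dropna()) - GROWTH_HABITS
    if bad_habit:
        raise GenotypeError(f"unknown growth_habit values: {sorted(bad_habit)}")
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_outgroup(tsv_path) -> pd.Series:
    """Outgroup allele table: TSV with columns snp_id, base -> Series."""
    tab = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if not {"snp_id", "base"} <= set(tab.columns):
        raise GenotypeError("outgroup table needs columns snp_id, base")
    return tab.set_index("snp_id")["base"]


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def alt_allele_freq(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP ALT frequency over non-missing calls (nan if all missing)."""
    with np.errstate(invalid="ignore"):
        return np.nansum(g.dosage, axis=0) / (
            2.0 * np.sum(~np.isnan(g.dosage), axis=0)
        )


def minor_allele_freq(g: GenotypeMatrix, snp: int | None = None):
    """MAF = min(f_alt, 1 - f_alt); nan where every call is missing.

    With ``snp`` given, returns a scalar for that column; otherwise the
    full per-SNP vector.
    """
    f = alt_allele_freq(g)
    maf = np.minimum(f, 1.0 - f)
    if snp is not None:
        return float(maf[snp])
    return maf


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def _pairwise_complete_r2(dosage: np.ndarray) -> np.ndarray:
    """r^2 between all column pairs using pairwise-complete observations.

    Returns an (m, m) matrix with nan where fewer than 2 complete pairs or
    zero variance in either column.
    """
    mask = ~np.isnan(dosage)
    x = np.where(mask, dosage, 0.0)
    m = mask.astype(float)
    n = m.T @ m  # pairwise-complete counts
    sx = x.T @ m
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n  # var of column i over pair (i,j) completeness
        vary = varx.T
        r2 = cov**2 / (varx * vary)
        r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


def qc_filter(
    g: GenotypeMatrix,
    max_missing: float = 0.20,
    cull_complete_ld: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove monomorphic SNPs, SNPs with missingness above ``max_missing``,
    and (optionally) one member of each same-chromosome pair in complete LD.

    Complete-LD culling drops, within every pair with r^2 = 1 on
    pairwise-complete dosages, the SNP with higher missingness; ties are
    broken by dropping the later genomic position.  Cross-chromosome r^2 = 1
    is treated as coincidence and both SNPs are kept.
    """
    report = FilterReport(n_input=g.n_snps, max_missing=max_missing)

    miss = np.isnan(g.dosage).mean(axis=0)
    nn = (~np.isnan(g.dosage)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mn = np.nanmin(g.dosage, axis=0, initial=np.inf, where=~np.isnan(g.dosage))
        mx = np.nanmax(g.dosage, axis=0, initial=-np.inf, where=~np.isnan(g.dosage))
    high_missing = (miss > max_missing) | (nn == 0)
    monomorphic = ~high_missing & (nn > 0) & (mn == mx)

    keep = ~(monomorphic | high_missing)
    report.n_monomorphic = int(monomorphic.sum())
    report.n_high_missing = int(high_missing.sum())

    kept_idx = np.flatnonzero(keep)
    if kept_idx.size == 0:
        raise GenotypeError(
            f"all SNPs removed by QC: {report.to_frame().to_dict('records')}"
        )

    if cull_complete_ld and kept_idx.size > 1:
        sub = g.dosage[:, kept_idx]
        chroms = g.variants["chrom"].values[kept_idx]
        poss = g.variants["pos"].values[kept_idx]
        misses = miss[kept_idx]
        drop = np.zeros(kept_idx.size, dtype=bool)
        for chrom in pd.unique(chroms):
            cols = np.flatnonzero(chroms == chrom)
            if cols.size < 2:
                continue
            r2 = _pairwise_complete_r2(sub[:, cols])
            ii, jj = np.where(np.triu(r2 >= 1.0 - 1e-12, k=1))
            # process pairs in genomic order for determinism
            order = np.lexsort((poss[cols][jj], poss[cols][ii]))
            for a, b in zip(ii[order], jj[order]):
                ga, gb = cols[a], cols[b]
                if drop[ga] or drop[gb]:
                    continue
                if misses[ga] > misses[gb]:
                    drop[ga] = True
                elif misses[gb] > misses[ga]:
                    drop[gb] = True
                else:  # tie: drop later genomic position
                    drop[ga if poss[ga] > poss[gb] else gb] = True
        report.n_complete_ld = int(drop.sum())
        kept_idx = kept_idx[~drop]

    report.n_kept = int(kept_idx.size)
    if report.n_kept == 0:
        raise GenotypeError("all SNPs removed by QC (complete-LD culling)")
    logger.info(
        "qc_filter: %d -> %d SNPs (mono %d, missing %d, complete-LD %d)",
        report.n_input, report.n_kept, report.n_monomorphic,
        report.n_high_missing, report.n_complete_ld,
    )
    return g.take_snps(kept_idx), report


# ---------------------------------------------------------------------------
# Outgroup polarization
# ---------------------------------------------------------------------------


def polarize(g: GenotypeMatrix, outgroup: pd.Series | dict) -> pd.DataFrame:
    """Infer ancestral states from an outgroup allele table.

    The ancestral allele is the outgroup base when it matches REF or ALT,
    otherwise unknown.  ``derived_freq`` is the frequency of the
    non-ancestral allele, nan when the ancestral state is unknown.

    Returns a DataFrame with columns
    ``snp_id, ancestral_allele, derived_freq``.
    """
    if isinstance(outgroup, dict):
        outgroup = pd.Series(outgroup)
    f_alt = alt_allele_freq(g)
    anc = []
    derived = []
    for j, row in g.variants.iterrows():
        base = outgroup.get(row.snp_id)
        if base == row.ref:
            anc.append(base)
            derived.append(f_alt[j])
        elif base == row.alt:
            anc.append(base)
            derived.append(1.0 - f_alt[j])
        else:
            anc.append(None)
            derived.append(np.nan)
    return pd.DataFrame(
        {
            "snp_id": g.variants["snp_id"].values,
            "ancestral_allele": anc,
            "derived_freq": derived,
        }
    )
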