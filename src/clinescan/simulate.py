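"""Synthetic structured inbred panels with known truth.

The generator emulates the study system this package targets: a panel of a
few hundred highly self-fertilizing landrace accessions drawn from island-
model populations spread along geographic and climatic gradients, genotyped
at a few thousand biallelic SNPs.  Population allele frequencies follow the
Balding-Nichols model: for ancestral ALT frequency p and differentiation
target F, each population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so
the Weir-Cockerham estimator should recover F in expectation.  Genotypes
are drawn with the selfing-equilibrium inbreeding coefficient
F_is = s / (2 - s), which drives heterozygosity to near zero at s = 0.99.

A minority of "adaptive" SNPs instead follow a logistic cline: the ALT
allele probability of each individual is sigmoid(cline_strength * z), with
z the standardized value of that individual's linked environmental
variable.  These planted loci are what the differentiation scan and the
mixed-model association are expected to recover.

Environmental variables are linear functions of latitude, longitude, and
elevation plus correlated noise, so the BIO-like block has genuinely mixed
sources for ICA to separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import BIO_COLUMNS, GenotypeMatrix

CHROMS = tuple(f"{i}H" for i in range(1, 8))
_BASES = np.array(list("ACGT"))


@dataclass
class SimScenario:
    """Study conditions for one synthetic panel."""

    n_pops: int = 8
    n_per_pop: int = 98
    n_snps: int = 5800
    target_fst: float = 0.10
    selfing_rate: float = 0.99
    n_adaptive: int = 58
    cline_strength: float = 3.0
    adaptive_env: tuple[str, ...] = ("BIO1", "BIO12")
    missing_rate: float = 0.02
    env_noise_sd: float = 0.4  # on the standardized gradient scale
    chrom_length: int = 600_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.n_adaptive > self.n_snps:
            raise ValueError("n_adaptive > n_snps")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_pops * self.n_per_pop

    @property
    def f_inbreeding(self) -> float:
        s = self.selfing_rate
        return s / (2.0 - s)


@dataclass
class SimTruth:
    """Ground truth recorded by :func:`simulate_panel`."""

    ancestral_freq: np.ndarray  # per-SNP ancestral ALT frequency
    pop_freq: np.ndarray  # (n_pops, n_snps) realized per-population ALT freq
    pop_labels: np.ndarray  # per-sample population index
    adaptive: pd.DataFrame  # snp_id, snp_index, env_variable, slope
    ancestral_allele: np.ndarray  # per-SNP ancestral base

    def adaptive_ids(self) -> set[str]:
        return set(self.adaptive["snp_id"])


def _arm_weighted_positions(n: int, length: int, rng) -> np.ndarray:
    """SNP/gene positions dense on chromosome arms, sparse pericentromerically
    (U-shaped Beta(0.4, 0.4) density)."""
    pos = np.sort((rng.beta(0.4, 0.4, size=n) * length).astype(int))
    # resolve duplicates deterministically
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def _population_geography(scenario: SimScenario, rng) -> pd.DataFrame:
    """Population centers along latitude/longitude/elevation gradients that
    populate all the standard partitions (low/wild/high latitude, the 48 E
    split, and all three elevation bands)."""
    k = scenario.n_pops
    lat = np.linspace(24.0, 56.0, k)
    lon = np.linspace(-4.0, 96.0, k)
    # alternate low/mid/high elevations so elevation is not collinear with
    # latitude; ensure presence above 3000 m and below 1500 m
    base_elev = np.array([300.0, 2200.0, 800.0, 3600.0, 1600.0, 400.0, 2800.0, 4100.0])
    elev = base_elev[np.arange(k) % base_elev.size] + rng.normal(0, 50, size=k)
    return pd.DataFrame({"latitude": lat, "longitude": lon, "elevation": elev})


_TEMPERATURE_BIO = BIO_COLUMNS[:11]  # BIO1..BIO11
_PRECIPITATION_BIO = BIO_COLUMNS[11:]  # BIO12..BIO19


def _environmental_variables(geo: pd.DataFrame, scenario: SimScenario, rng) -> pd.DataFrame:
    """BIO-like variables as linear-in-geography signals plus correlated noise."""
    z_lat = (geo["latitude"] - geo["latitude"].mean()) / geo["latitude"].std()
    z_lon = (geo["longitude"] - geo["longitude"].mean()) / geo["longitude"].std()
    z_elev = (geo["elevation"] - geo["elevation"].mean()) / geo["elevation"].std()
    n = len(geo)
    shared_t = rng.normal(0, 1, n)  # regional weather shared across temp vars
    shared_p = rng.normal(0, 1, n)
    out = {}
    for name in _TEMPERATURE_BIO:
        a = rng.uniform(0.6, 1.0)
        b = rng.uniform(0.4, 0.9)
        noise = scenario.env_noise_sd * (0.6 * shared_t + 0.8 * rng.normal(0, 1, n))
        # temperature falls with latitude and elevation
        out[name] = 20.0 - 8.0 * (a * z_lat + b * z_elev) + 5.0 * noise
    for name in _PRECIPITATION_BIO:
        a = rng.uniform(0.5, 1.0)
        b = rng.uniform(0.2, 0.7)
        noise = scenario.env_noise_sd * (0.6 * shared_p + 0.8 * rng.normal(0, 1, n))
        out[name] = 600.0 + 250.0 * (a * z_lon - b * z_lat) + 150.0 * noise
    return pd.DataFrame(out)


def _draw_genotypes(p: np.ndarray, f_is: float, rng) -> np.ndarray:
    """Dosages with inbreeding: P(2)=p^2+pqF, P(1)=2pq(1-F), P(0)=q^2+pqF.

    ``p`` may be per-sample-per-SNP (broadcastable to the output shape).
    """
    q = 1.0 - p
    pr2 = p * p + p * q * f_is
    pr1 = 2.0 * p * q * (1.0 - f_is)
    u = rng.random(size=p.shape)
    dosage = np.where(u < pr2, 2.0, np.where(u < pr2 + pr1, 1.0, 0.0))
    return dosage


def simulate_panel(
    scenario: SimScenario,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Generate the genotype matrix, per-accession metadata, and truth.

    Fully deterministic under ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n, m, k = scenario.n_samples, scenario.n_snps, scenario.n_pops
    f_st = scenario.target_fst
    f_is = scenario.f_inbreeding

    # --- samples, geography, environment -------------------------------
    pop_labels = np.repeat(np.arange(k), scenario.n_per_pop)
    samples = [f"acc{i:04d}" for i in range(n)]
    centers = _population_geography(scenario, rng)
    lat = centers["latitude"].values[pop_labels] + rng.normal(0, 1.2, n)
    lon = centers["longitude"].values[pop_labels] + rng.normal(0, 2.0, n)
    elev = np.clip(
        centers["elevation"].values[pop_labels] + rng.normal(0, 120.0, n), 0, None
    )
    geo = pd.DataFrame({"latitude": lat, "longitude": lon, "elevation": elev})
    env = _environmental_variables(geo, scenario, rng)

    # winter habit concentrated at milder (lower latitude/elevation) sites
    z_lat = (lat - lat.mean()) / lat.std()
    z_elev = (elev - elev.mean()) / elev.std()
    p_winter = 1.0 / (1.0 + np.exp(2.2 + 1.2 * z_lat + 1.0 * z_elev))
    habit = np.where(rng.random(n) < p_winter, "winter", "spring")
    habit = np.where(rng.random(n) < 0.03, "facultative", habit)
    habit = np.where(rng.random(n) < 0.03, "unknown", habit)
    row_type = rng.choice(["two", "six"], size=n, p=[0.3, 0.7])

    meta = pd.DataFrame({"sample_id": samples})
    meta = pd.concat([meta, geo, pd.DataFrame({"growth_habit": habit,
                                               "row_type": row_type}), env], axis=1)
    meta.index = pd.Index(samples, name=None)

    # --- variants -------------------------------------------------------
    per_chrom = np.full(len(CHROMS), m // len(CHROMS))
    per_chrom[: m % len(CHROMS)] += 1
    chroms, positions = [], []
    for c, nc in zip(CHROMS, per_chrom):
        chroms.extend([c] * nc)
        positions.extend(_arm_weighted_positions(nc, scenario.chrom_length, rng))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(m)],
            "chrom": chroms,
            "pos": positions,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )

    # --- allele frequencies (Balding-Nichols) ---------------------------
    p0 = rng.uniform(0.05, 0.95, size=m)
    if f_st > 0:
        a = p0 * (1.0 - f_st) / f_st
        b = (1.0 - p0) * (1.0 - f_st) / f_st
        pop_freq = rng.beta(a, b, size=(k, m))
    else:
        pop_freq = np.broadcast_to(p0, (k, m)).copy()

    # --- adaptive loci: logistic cline in the linked env variable -------
    adaptive_idx = rng.choice(m, size=scenario.n_adaptive, replace=False)
    adaptive_idx.sort()
    env_names = [
        scenario.adaptive_env[j % len(scenario.adaptive_env)]
        for j in range(scenario.n_adaptive)
    ]
    p_ind = pop_freq[pop_labels, :]  # (n, m) per-individual ALT probability
    adaptive_rows = []
    for j, env_name in zip(adaptive_idx, env_names):
        z = env[env_name].to_numpy()
        z = (z - z.mean()) / z.std()
        p_ind[:, j] = 1.0 / (1.0 + np.exp(-scenario.cline_strength * z))
        adaptive_rows.append(
            {
                "snp_id": variants["snp_id"].iloc[j],
                "snp_index": int(j),
                "env_variable": env_name,
                "slope": scenario.cline_strength,
            }
        )

    dosage = _draw_genotypes(p_ind, f_is, rng)
    if scenario.missing_rate > 0:
        dosage[rng.random((n, m)) < scenario.missing_rate] = np.nan

    realized_pop_freq = np.empty((k, m))
    for kk in range(k):
        sub = dosage[pop_labels == kk]
        with np.errstate(invalid="ignore"):
            realized_pop_freq[kk] = np.nansum(sub, axis=0) / (
                2.0 * np.sum(~np.isnan(sub), axis=0)
            )

    ancestral_allele = np.where(p0 <= 0.5, variants["ref"], variants["alt"])
    truth = SimTruth(
        ancestral_freq=p0,
        pop_freq=realized_pop_freq,
        pop_labels=pop_labels,
        adaptive=pd.DataFrame(
            adaptive_rows,
            columns=["snp_id", "snp_index", "env_variable", "slope"],
        ),
        ancestral_allele=ancestral_allele,
    )
    g = GenotypeMatrix(
        samples=samples, variants=variants, dosage=dosage,
        meta={"scenario": scenario},
    )
    return g, meta, truth


def simulate_gene_models(
    n_genes: int,
    chrom_length: int,
    rng: np.random.Generator | int = 0,
    chroms: tuple[str, ...] = CHROMS,
    adaptive_variants: pd.DataFrame | None = None,
    gene_length: tuple[int, int] = (2_000, 6_000),
    central_density: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping gene intervals with arm-weighted density.

    Genes containing planted adaptive SNPs are created first (one per
    adaptive SNP, the SNP inside the gene body) and labeled as the
    candidate subset.  ``central_density`` scales gene density in the
    central third of each chromosome.  Returns ``(gene_models,
    candidates)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    gid = 0
    if adaptive_variants is not None:
        for _, v in adaptive_variants.iterrows():
            length = int(rng.integers(*gene_length))
            offset = int(rng.integers(200, max(length - 200, 201)))
            start = max(int(v["pos"]) - offset, 0)
            rows.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": v["chrom"],
                    "start": start,
                    "end": start + length,
                    "strand": "+",
                    "candidate": True,
                }
            )
            gid += 1

    n_remaining = max(n_genes - len(rows), 0)
    per_chrom = np.full(len(chroms), n_remaining // len(chroms))
    per_chrom[: n_remaining % len(chroms)] += 1
    for c, nc in zip(chroms, per_chrom):
        if nc == 0:
            continue
        # accept/reject against a U-shaped density thinned in the middle
        starts = []
        while len(starts) < nc:
            x = rng.beta(0.4, 0.4)
            if chrom_length / 3 < x * chrom_length < 2 * chrom_length / 3:
                if rng.random() > central_density:
                    continue
            starts.append(int(x * chrom_length))
        for s in sorted(starts):
            length = int(rng.integers(*gene_length))
            rows.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": c,
                    "start": s,
                    "end": s + length,
                    "strand": "+",
                    "candidate": False,
                }
            )
            gid += 1

    gm = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "candidate"]
    )
    # enforce non-overlap per chromosome: drop later-starting overlapping
    # non-candidate genes (candidates always survive)
    keep = []
    for c in gm["chrom"].unique():
        sub = gm[gm["chrom"] == c].sort_values(
            ["start", "candidate"], ascending=[True, False]
        )
        last_end = -1
        for i, r in sub.iterrows():
            if r["start"] >= last_end or r["candidate"]:
                keep.append(i)
                last_end = max(last_end, r["end"])
    gm = gm.loc[sorted(keep)].reset_index(drop=True)
    candidates = gm.loc[gm["candidate"].astype(bool)].reset_index(drop=True)
    return gm.drop(columns="candidate"), candidates.drop(columns="candidate")


def simulate_outgroup(
    g: GenotypeMatrix,
    truth: SimTruth,
    mismatch_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Outgroup allele table (snp_id, base) from the simulated ancestral
    states; with probability ``mismatch_rate`` the outgroup carries a third
    base matching neither allele (unpolarizable site)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bases = truth.ancestral_allele.astype(object).copy()
    flip = rng.random(len(bases)) < mismatch_rate
    for j in np.flatnonzero(flip):
        ref, alt = g.variants["ref"].iloc[j], g.variants["alt"].iloc[j]
        others = [b for b in "ACGT" if b not in (ref, alt)]
        bases[j] = others[int(rng.integers(len(others)))]
    return pd.DataFrame({"snp_id": g.variants["snp_id"], "base": bases})


# ---------------------------------------------------------------------------
# Haplotype-block panels for LD-classification tests
# ---------------------------------------------------------------------------


@dataclass
class LdBlockTruth:
    block_of_snp: np.ndarray
    focal_specs: pd.DataFrame  # focal_snp_id, expected_class


def simulate_ld_blocks(
    n_samples: int = 62,
    n_blocks: int = 30,
    snps_per_block: int = 8,
    block_span: int = 40_000,
    block_gap: int = 250_000,
    flip_rate: float = 0.02,
    chrom: str = "1H",
    rng: np.random.Generator | int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame, LdBlockTruth]:
    """Inbred panel organized into haplotype blocks with known boundaries.

    Each block carries one latent biallelic haplotype per sample; SNPs in a
    block copy it with a small flip rate, so within-block r^2 is high and
    between-block r^2 is near zero.  Blocks alternate between three
    expected LD classes for their central (focal) SNP:

    - ``within_gene``: the host gene spans the whole block;
    - ``extended``: the host gene covers only the block's left half, so
      high-r^2 SNPs remain to its right;
    - ``none``: the focal SNP sits in its own single-SNP block inside a
      gene, with only unlinked neighbors in the window.

    Returns (panel, gene_models, truth).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    classes = ["within_gene", "extended", "none"]
    rows_var, dosage_cols, gene_rows, focal_rows, block_ids = [], [], [], [], []
    snp_counter = 0
    for b in range(n_blocks):
        expected = classes[b % 3]
        base = b * block_gap + 50_000
        offsets = np.sort(rng.choice(block_span, size=snps_per_block, replace=False))
        latent = rng.random(n_samples) < rng.uniform(0.25, 0.75)
        focal_j = snp_counter + snps_per_block // 2
        for idx, o in enumerate(offsets):
            if expected == "none" and idx != snps_per_block // 2:
                # unlinked neighbors: each SNP carries its own latent
                own = rng.random(n_samples) < rng.uniform(0.25, 0.75)
                hap = own ^ (rng.random(n_samples) < flip_rate)
            else:
                hap = latent ^ (rng.random(n_samples) < flip_rate)
            dosage_cols.append(2.0 * hap.astype(float))
            rows_var.append(
                (f"blk{b:03d}_s{snp_counter:04d}", chrom, int(base + o), "A", "G")
            )
            block_ids.append(b)
            snp_counter += 1
        block_start, block_end = base, base + block_span + 1
        if expected == "within_gene":
            gene_rows.append((f"gene_b{b:03d}", chrom, block_start - 500,
                              block_end + 500, "+"))
        elif expected == "extended":
            focal_pos = rows_var[focal_j][2]
            # host gene ends just right of the focal SNP; later block SNPs
            # fall outside it
            gene_rows.append((f"gene_b{b:03d}", chrom, block_start - 500,
                              focal_pos + 1, "+"))
        else:  # none
            pos = rows_var[focal_j][2]
            gene_rows.append((f"gene_b{b:03d}", chrom, pos - 500, pos + 500, "+"))
        focal_rows.append(
            {"focal_snp_id": rows_var[focal_j][0], "expected_class": expected}
        )

    variants = pd.DataFrame(rows_var, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    g = GenotypeMatrix(
        samples=[f"seq{i:03d}" for i in range(n_samples)],
        variants=variants,
        dosage=np.column_stack(dosage_cols),
    )
    gene_models = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    truth = LdBlockTruth(
        block_of_snp=np.asarray(block_ids),
        focal_specs=pd.DataFrame(focal_rows),
    )
    return g, gene_models, truth
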