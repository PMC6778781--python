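"""Population-structure summaries: VanRaden kinship, genotype PCA,
per-sample heterozygosity/inbreeding, and mean pairwise Manhattan distance.

These feed the mixed-model association (kinship + PC covariates) and the
panel-level diversity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, alt_allele_freq


@dataclass
class KinshipMatrix:
    K: np.ndarray
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, index=self.samples, columns=self.samples)


@dataclass
class StructureSummary:
    pc_scores: np.ndarray
    explained_variance: np.ndarray
    het_obs: np.ndarray
    inbreeding_f: np.ndarray
    mean_pairwise_distance: float


def _centered_imputed(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Dosage centered by 2p per SNP with missing set to 0 (mean imputation)."""
    p = alt_allele_freq(g)
    M = g.dosage - 2.0 * p
    M[np.isnan(M)] = 0.0
    return M, p


def vanraden_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix K = M M' / (2 * sum_j p_j (1 - p_j)).

    M is the dosage matrix with column j centered by twice the ALT
    frequency p_j; missing dosages are mean-imputed (for K only).
    """
    M, p = _centered_imputed(g)
    denom = 2.0 * np.nansum(p * (1.0 - p))
    if not denom > 0:
        raise ValueError("kinship denominator is zero (all SNPs monomorphic?)")
    K = M @ M.T / denom
    return KinshipMatrix(K=K, samples=list(g.samples))


def genotype_pca(
    g: GenotypeMatrix, k: int = 3, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the centered (optionally unit-variance scaled)
    dosage matrix via SVD.

    Returns ``(scores, explained_variance_fraction)`` with ``scores`` of
    shape (n_samples, k).  Sign is fixed so each PC's largest-magnitude SNP
    loading is positive.
    """
    if k == 0:
        return np.empty((g.n_samples, 0)), np.empty(0)
    M, _ = _centered_imputed(g)
    if scale:
        sd = M.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        M = M / sd
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(k, S.size)
    total = (S**2).sum()
    explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = U[:, :k] * S[:k]
    # deterministic sign: largest-|loading| SNP positive per component
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            scores[:, j] *= -1.0
    return scores, explained


def het_and_inbreeding(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample observed heterozygosity and inbreeding coefficient.

    het_obs is the fraction of non-missing calls that are heterozygous;
    F = 1 - het_obs / het_exp with het_exp the mean 2 p q over the SNPs
    called in that sample (panel-wide allele frequencies).
    """
    p = alt_allele_freq(g)
    two_pq = 2.0 * p * (1.0 - p)
    called = ~np.isnan(g.dosage)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_obs = np.where(
            n_called > 0,
            np.nansum(g.dosage == 1, axis=1) / n_called,
            np.nan,
        )
        het_exp = (called * np.nan_to_num(two_pq)).sum(axis=1) / n_called
        f = np.where(het_exp > 0, 1.0 - het_obs / het_exp, np.nan)
    return pd.DataFrame(
        {"sample_id": g.samples, "het_obs": het_obs, "het_exp": het_exp, "F": f}
    )


def manhattan_distance(g: GenotypeMatrix) -> np.ndarray:
    """Mean per-SNP |dosage difference| / 2 over co-called SNPs, all pairs.

    Returns the full symmetric (n, n) matrix; identical samples give 0 and
    opposite homozygotes everywhere give 1.  Dosages take only the values
    {0, 1, 2}, so |a - b| decomposes into indicator-matrix products, which
    keeps the computation to a handful of matmuls.
    """
    i0 = (g.dosage == 0).astype(float)
    i1 = (g.dosage == 1).astype(float)
    i2 = (g.dosage == 2).astype(float)
    obs = (i0 + i1 + i2)
    num = i0 @ i1.T + i1 @ i0.T + i1 @ i2.T + i2 @ i1.T + 2.0 * (i0 @ i2.T + i2 @ i0.T)
    den = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / (2.0 * den)
    np.fill_diagonal(d, 0.0)
    return d


def mean_pairwise_distance(g: GenotypeMatrix) -> float:
    d = manhattan_distance(g)
    iu = np.triu_indices_from(d, k=1)
    return float(np.nanmean(d[iu]))


def structure_summary(g: GenotypeMatrix, k: int = 3) -> StructureSummary:
    scores, explained = genotype_pca(g, k=k)
    het = het_and_inbreeding(g)
    return StructureSummary(
        pc_scores=scores,
        explained_variance=explained,
        het_obs=het["het_obs"].values,
        inbreeding_f=het["F"].values,
        mean_pairwise_distance=mean_pairwise_distance(g),
    )
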