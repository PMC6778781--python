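"""Per-SNP Weir & Cockerham (1984) theta with balanced resampling,
permutation nulls, and empirical-percentile outlier calling.

The estimator decomposes allelic variance into among-population (a),
among-individual-within-population (b), and within-individual (c)
components; theta = a / (a + b + c).  Theta may be negative and is never
clamped.  SNPs monomorphic across the compared groups, or with too few
non-missing calls in any group, yield an undefined (nan) theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix
from .partitioning import Partition

_MIN_CALLS_PER_GROUP = 2  # diploid individuals per group per SNP


@dataclass
class FstComponents:
    """Variance components and summary quantities for one SNP."""

    a: float
    b: float
    c: float
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if denom == 0 or not np.isfinite(denom):
            return np.nan
        return self.a / denom


@dataclass
class FstScanResult:
    """Per-SNP averaged theta for one comparison, plus optional permutation
    p-values and outlier flags."""

    comparison_id: str
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    theta_iterations: np.ndarray  # (n_iter, n_snps)
    theta_mean: np.ndarray
    theta_multilocus: float = np.nan  # ratio-of-sums across SNPs (see notes)
    perm_p: np.ndarray | None = None
    perm_p_add1: np.ndarray | None = None
    perm_p_rand: np.ndarray | None = None
    outlier_99: np.ndarray | None = None
    outlier_975: np.ndarray | None = None
    group_sizes: dict = field(default_factory=dict)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "theta_mean": self.theta_mean,
            }
        )
        if self.perm_p is not None:
            out["perm_p"] = self.perm_p
            out["perm_p_add1"] = self.perm_p_add1
            out["perm_p_rand"] = self.perm_p_rand
        if self.outlier_99 is not None:
            out["outlier_99"] = self.outlier_99
        if self.outlier_975 is not None:
            out["outlier_975"] = self.outlier_975
        return out


# ---------------------------------------------------------------------------
# Core estimator (vectorized across SNPs)
# ---------------------------------------------------------------------------


def wc_components_matrix(dosage: np.ndarray, labels: np.ndarray) -> dict:
    """Weir-Cockerham components for every SNP column at once.

    Parameters
    ----------
    dosage : (n_samples, n_snps) array with entries {0,1,2,nan}
    labels : (n_samples,) integer group codes (0..r-1)

    Returns a dict of per-SNP arrays ``a, b, c, theta, n_bar, n_c, p_bar,
    s2, h_bar``; entries are nan where the estimator is undefined (any group
    with fewer than 2 non-missing calls, or no polymorphism among groups).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    r = groups.size
    if r < 2:
        raise ValueError("need at least 2 groups")

    m = dosage.shape[1]
    n_i = np.empty((r, m))
    p_i = np.empty((r, m))
    h_i = np.empty((r, m))
    for k, gidx in enumerate(groups):
        sub = dosage[labels == gidx]
        obs = ~np.isnan(sub)
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * n)
            h = np.nansum(sub == 1, axis=0) / n
        n_i[k] = n
        p_i[k] = np.where(n > 0, p, np.nan)
        h_i[k] = np.where(n > 0, h, np.nan)

    valid = (n_i >= _MIN_CALLS_PER_GROUP).all(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n_i.sum(axis=0)
        n_bar = n_sum / r
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_sum

        pq = p_bar * (1.0 - p_bar)
        inner = pq - (r - 1.0) / r * s2 - h_bar / 4.0
        a = n_bar / n_c * (s2 - inner / (n_bar - 1.0))
        b = n_bar / (n_bar - 1.0) * (
            pq - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0

        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    # monomorphic across groups (no variance anywhere) -> undefined
    poly = (s2 > 0) | (pq > 0) | (h_bar > 0)
    valid &= poly & np.isfinite(denom)
    for arr in (a, b, c, theta, n_bar, n_c, p_bar, s2, h_bar):
        arr[~valid] = np.nan

    return {
        "a": a, "b": b, "c": c, "theta": theta,
        "n_bar": n_bar, "n_c": n_c, "p_bar": p_bar, "s2": s2, "h_bar": h_bar,
    }


def wc_theta(dosages_by_group: list[np.ndarray]) -> FstComponents:
    """Weir-Cockerham components for a single SNP.

    ``dosages_by_group`` is a list of per-group dosage vectors ({0,1,2,nan}).
    """
    if len(dosages_by_group) < 2:
        raise ValueError("need at least 2 groups")
    dosage = np.concatenate([np.asarray(d, dtype=float) for d in dosages_by_group])
    labels = np.concatenate(
        [np.full(len(d), k) for k, d in enumerate(dosages_by_group)]
    )
    comp = wc_components_matrix(dosage[:, None], labels)
    return FstComponents(
        a=float(comp["a"][0]), b=float(comp["b"][0]), c=float(comp["c"][0]),
        n_bar=float(comp["n_bar"][0]), n_c=float(comp["n_c"][0]),
        p_bar=float(comp["p_bar"][0]), s2=float(comp["s2"][0]),
        h_bar=float(comp["h_bar"][0]),
    )


# ---------------------------------------------------------------------------
# Balanced resampling scan
# ---------------------------------------------------------------------------


def _partition_labels(g: GenotypeMatrix, partition: Partition):
    """Row indices and integer labels for samples assigned by the partition."""
    sample_pos = {s: i for i, s in enumerate(g.samples)}
    rows, labels = [], []
    for k, level in enumerate(partition.levels):
        ids = partition.assignment.index[partition.assignment == level]
        for sid in ids:
            if sid in sample_pos:
                rows.append(sample_pos[sid])
                labels.append(k)
    return np.asarray(rows, dtype=int), np.asarray(labels, dtype=int)


def balanced_resample_scan(
    g: GenotypeMatrix,
    partition: Partition,
    n_iter: int = 10,
    seed: int | np.random.Generator = 0,
) -> FstScanResult:
    """Equalized-sample-number theta scan.

    In each of ``n_iter`` iterations every group is subsampled without
    replacement down to the smallest group size; theta is computed per SNP
    and averaged over the iterations in which it is defined.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows, labels = _partition_labels(g, partition)
    sizes = np.bincount(labels)
    n_min = sizes.min()
    if n_min < 2:
        raise ValueError(
            f"{partition.comparison_id}: smallest group has {n_min} samples (<2)"
        )

    theta_iter = np.empty((n_iter, g.n_snps))
    abc_sums = np.zeros(2)  # [sum a, sum a+b+c] over iterations and SNPs
    equal_sizes = bool((sizes == n_min).all())
    for it in range(n_iter):
        if equal_sizes:
            sel_rows, sel_labels = rows, labels
        else:
            keep = []
            for k in range(sizes.size):
                members = np.flatnonzero(labels == k)
                keep.append(rng.choice(members, size=n_min, replace=False))
            keep = np.concatenate(keep)
            sel_rows, sel_labels = rows[keep], labels[keep]
        comp = wc_components_matrix(g.dosage[sel_rows], sel_labels)
        theta_iter[it] = comp["theta"]
        ok = ~np.isnan(comp["a"])
        abc_sums[0] += comp["a"][ok].sum()
        abc_sums[1] += (comp["a"] + comp["b"] + comp["c"])[ok].sum()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        theta_mean = np.nanmean(theta_iter, axis=0)
    theta_multilocus = abc_sums[0] / abc_sums[1] if abc_sums[1] != 0 else np.nan

    return FstScanResult(
        comparison_id=partition.comparison_id,
        snp_ids=g.variants["snp_id"].values.copy(),
        chrom=g.variants["chrom"].values.copy(),
        pos=g.variants["pos"].values.copy(),
        theta_iterations=theta_iter,
        theta_mean=theta_mean,
        theta_multilocus=float(theta_multilocus),
        group_sizes=partition.group_sizes(),
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def permutation_pvalues(
    g: GenotypeMatrix,
    partition: Partition,
    observed: FstScanResult,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    n_iter_per_perm: int = 1,
) -> FstScanResult:
    """Permutation p-values for observed theta_mean.

    Group labels are shuffled across the assigned samples ``n_perm`` times;
    each permutation re-runs the balanced-resampling scan with
    ``n_iter_per_perm`` iterations.  Three p-value variants are reported:

    - ``perm_p``: fraction of permuted thetas >= observed (can be exactly
      0, matching the "p-value = 0" reporting convention); conservative
      when the statistic is discrete and ties are common.
    - ``perm_p_add1``: the (count+1)/(n_perm+1) variant.
    - ``perm_p_rand``: randomized-rank p-value, (#greater + U*(#tied+1)) /
      (n_perm+1) with U ~ Uniform(0,1); exactly uniform under the null
      whatever the tie structure, so it is the calibration diagnostic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows, labels = _partition_labels(g, partition)
    sizes = np.bincount(labels)
    n_min = sizes.min()
    dosage = g.dosage[rows]
    equal_sizes = bool((sizes == n_min).all())

    count_ge = np.zeros(g.n_snps)
    count_gt = np.zeros(g.n_snps)
    obs = observed.theta_mean
    for _ in range(n_perm):
        perm_labels = rng.permutation(labels)
        thetas = np.empty((n_iter_per_perm, g.n_snps))
        for it in range(n_iter_per_perm):
            if equal_sizes:
                sel = slice(None)
                sel_labels = perm_labels
            else:
                keep = []
                for k in range(sizes.size):
                    members = np.flatnonzero(perm_labels == k)
                    keep.append(rng.choice(members, size=n_min, replace=False))
                sel = np.concatenate(keep)
                sel_labels = perm_labels[sel]
            comp = wc_components_matrix(dosage[sel], sel_labels)
            thetas[it] = comp["theta"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            perm_theta = np.nanmean(thetas, axis=0)
        with np.errstate(invalid="ignore"):
            valid = ~np.isnan(perm_theta) & ~np.isnan(obs)
            count_ge += (perm_theta >= obs) & valid
            count_gt += (perm_theta > obs) & valid

    ties = count_ge - count_gt
    u = rng.random(g.n_snps)
    observed.perm_p = np.where(np.isnan(obs), np.nan, count_ge / n_perm)
    observed.perm_p_add1 = np.where(
        np.isnan(obs), np.nan, (count_ge + 1.0) / (n_perm + 1.0)
    )
    observed.perm_p_rand = np.where(
        np.isnan(obs), np.nan, (count_gt + u * (ties + 1.0)) / (n_perm + 1.0)
    )
    return observed


# ---------------------------------------------------------------------------
# Outlier calling
# ---------------------------------------------------------------------------


def percentile_threshold(values: np.ndarray, percentile: float) -> float:
    """Empirical threshold: the k-th largest defined value with
    k = ceil((1 - percentile/100) * m).  Flagging ``value >= threshold``
    then yields exactly k SNPs on tie-free inputs, with ties at the
    threshold all flagged."""
    vals = np.sort(values[~np.isnan(values)])
    m = vals.size
    if m == 0:
        raise ValueError("no defined values to rank")
    # guard against float error, e.g. (1 - 99/100)*100 = 1.0000000000000009
    k = int(np.ceil((100.0 - percentile) / 100.0 * m - 1e-9))
    k = max(1, min(k, m))
    return float(vals[m - k])


def call_outliers(result: FstScanResult, percentiles=(99.0, 97.5)) -> FstScanResult:
    """Flag SNPs whose averaged theta reaches the stated empirical
    percentile(s) of the comparison's distribution."""
    for pct in percentiles:
        thr = percentile_threshold(result.theta_mean, pct)
        with np.errstate(invalid="ignore"):
            flags = result.theta_mean >= thr
        flags &= ~np.isnan(result.theta_mean)
        if pct == 99.0:
            result.outlier_99 = flags
        elif pct == 97.5:
            result.outlier_975 = flags
        else:
            setattr(result, f"outlier_{str(pct).replace('.', '_')}", flags)
    return result
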