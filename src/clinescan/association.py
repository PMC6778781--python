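"""Genotype-environment association with a mixed linear model.

Environmental variables (geography, BIO1-BIO19, independent components)
are treated as "phenotypes".  Variance components sigma_g^2 (polygenic,
via the kinship matrix K) and sigma_e^2 (residual) are estimated once by
REML under the null model (P3D: population parameters previously
determined) and then held fixed for every per-SNP generalized-least-squares
Wald test.  Multiple testing is handled with Benjamini-Hochberg step-up
q-values, by default per environmental variable.

The REML fit uses the EMMA eigendecomposition trick: with K = U S U',
V = sigma_g^2 K + sigma_e^2 I is diagonal in the rotated basis, so the
restricted likelihood reduces to a one-dimensional optimization over the
variance ratio delta = sigma_e^2 / sigma_g^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .geno_io import GenotypeMatrix, alt_allele_freq


# ---------------------------------------------------------------------------
# Environmental matrix handling + ICA
# ---------------------------------------------------------------------------


def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization to mean 0, sd 1 (ddof=0).

    Constant columns come back as all zeros rather than nan.
    """
    mu = env.mean(axis=0)
    sd = env.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (env - mu) / sd


@dataclass
class IcaResult:
    """Linear unmixing of standardized environmental variables.

    sources: (n_samples, c) independent component scores, ordered by the
    variance of the data they reconstruct; loadings: (n_vars, c) mixing
    columns; unmixing: (c, n_vars).
    """

    unmixing: np.ndarray
    sources: np.ndarray
    loadings: np.ndarray
    variable_names: list[str]
    component_names: list[str] = field(default_factory=list)

    def sources_frame(self, index) -> pd.DataFrame:
        return pd.DataFrame(self.sources, index=index, columns=self.component_names)


def run_ica(
    env_std: pd.DataFrame,
    n_components: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> IcaResult:
    """Independent component analysis of the standardized BIO matrix.

    FastICA-class contrast maximization; on non-convergence the fit is
    retried with a new derived seed, up to 5 attempts, then raises.
    Components are ordered by reconstructed-data variance and their sign is
    fixed so the largest-magnitude loading is positive.  Samples with any
    missing value must be excluded beforehand.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if env_std.isna().any().any():
        raise ValueError("ICA input contains missing values; drop those samples")
    if env_std.shape[1] < n_components:
        raise ValueError("n_components exceeds number of variables")

    x = env_std.to_numpy(dtype=float)
    last_exc: Exception | None = None
    for attempt in range(5):
        rs = np.random.SeedSequence([int(seed), attempt]).generate_state(1)[0] % (2**31)
        ica = FastICA(
            n_components=n_components,
            random_state=int(rs),
            max_iter=max_iter,
            tol=tol,
            whiten="unit-variance",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(x)
            except ConvergenceWarning as exc:
                last_exc = exc
                continue
        mixing = ica.mixing_  # (n_vars, c)
        unmixing = ica.components_  # (c, n_vars)
        # order by variance of the data each component reconstructs
        recon_var = (mixing**2).sum(axis=0) * sources.var(axis=0, ddof=0)
        order = np.argsort(recon_var)[::-1]
        sources = sources[:, order]
        mixing = mixing[:, order]
        unmixing = unmixing[order]
        for j in range(n_components):
            i_max = np.argmax(np.abs(mixing[:, j]))
            if mixing[i_max, j] < 0:
                mixing[:, j] *= -1
                sources[:, j] *= -1
                unmixing[j] *= -1
        return IcaResult(
            unmixing=unmixing,
            sources=sources,
            loadings=mixing,
            variable_names=list(env_std.columns),
            component_names=[f"IC{i + 1}" for i in range(n_components)],
        )
    raise RuntimeError(f"ICA failed to converge after 5 attempts: {last_exc}")


def build_env_matrix(
    meta: pd.DataFrame,
    n_ics: int = 3,
    seed: int = 0,
    include_geography: bool = True,
) -> pd.DataFrame:
    """Assemble the environmental "phenotype" matrix: geography, BIO1-19,
    and the top independent components of the standardized BIO block."""
    bio_cols = [c for c in meta.columns if c.startswith("BIO")]
    cols = (["latitude", "longitude", "elevation"] if include_geography else []) + bio_cols
    env = meta[cols].apply(pd.to_numeric, errors="coerce")
    if bio_cols and n_ics > 0:
        bio = env[bio_cols].dropna()
        ica = run_ica(standardize_env(bio), n_components=n_ics, seed=seed)
        ics = ica.sources_frame(bio.index)
        env = env.join(ics)
    return env


# ---------------------------------------------------------------------------
# REML variance components (EMMA-style) and P3D scan
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    log_reml: float
    converged: bool
    flag: str = ""

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan


def _reml_neg_loglik(log_delta, s, y_rot, x_rot, xtx_logdet):
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    xtwy = x_rot.T @ (w * y_rot)
    try:
        beta = linalg.solve(xtwx, xtwy, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf
    resid = y_rot - x_rot @ beta
    rss = float(np.sum(w * resid**2))
    n, p = x_rot.shape
    df = n - p
    if rss <= 0:
        return np.inf
    sign, xtwx_logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        df * (np.log(2.0 * np.pi * rss / df) + 1.0)
        + np.sum(np.log(s + delta))
        + xtwx_logdet
        - xtx_logdet
    )
    return -ll


def fit_null_reml(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML estimates of (sigma_g^2, sigma_e^2) for y ~ intercept +
    covariates + N(0, sigma_g^2 K) + N(0, sigma_e^2 I).

    One-dimensional optimization over log(delta) on a grid followed by
    bounded refinement.  ``eig`` may pass a precomputed ``eigh(K)``.
    Degenerate inputs (constant y, K with no off-diagonal structure) are
    flagged rather than fatal.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    if np.var(y) == 0:
        return VarianceComponents(0.0, 0.0, np.nan, np.nan, True, flag="constant_y")

    s, U = linalg.eigh(K) if eig is None else eig
    s = np.clip(s, 0.0, None)
    y_rot = U.T @ y
    x_rot = U.T @ X
    sign, xtx_logdet = np.linalg.slogdet(X.T @ X)

    if np.ptp(s) < 1e-10 * max(1.0, s.max()):
        # K proportional to I: only the total variance is identified
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        tot = float(resid @ resid) / max(n - X.shape[1], 1)
        return VarianceComponents(
            0.0, tot, np.inf, np.nan, True, flag="kinship_unidentifiable"
        )

    grid = np.linspace(np.log(1e-6), np.log(1e6), 60)
    vals = [_reml_neg_loglik(ld, s, y_rot, x_rot, xtx_logdet) for ld in grid]
    i_best = int(np.argmin(vals))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(lo, hi),
        args=(s, y_rot, x_rot, xtx_logdet),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("REML likelihood non-finite; check inputs")
    delta = float(np.exp(res.x))
    w = 1.0 / (s + delta)
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    beta = linalg.solve(xtwx, x_rot.T @ (w * y_rot), assume_a="pos")
    resid = y_rot - x_rot @ beta
    df = n - X.shape[1]
    sigma_g2 = float(np.sum(w * resid**2)) / df
    sigma_e2 = delta * sigma_g2
    flag = ""
    if delta >= 1e6 * 0.99:
        flag = "sigma_g2_boundary"
    elif delta <= 1e-6 * 1.01:
        flag = "sigma_e2_boundary"
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        log_reml=-float(res.fun),
        converged=bool(res.success),
        flag=flag,
    )


@dataclass
class AssocResult:
    """Per-SNP Wald tests for one environmental variable."""

    variable: str
    table: pd.DataFrame  # snp_id, chrom, pos, maf, beta, se, t, p, q
    vc: VarianceComponents
    n_samples: int
    k_covariates: int

    def significant(self, fdr: float = 0.25) -> pd.DataFrame:
        return self.table[self.table["q"] <= fdr]


def scan_snps(
    g: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None,
    vc: VarianceComponents,
    K: np.ndarray | None = None,
    maf_min: float = 0.01,
    variable: str = "y",
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> AssocResult:
    """P3D scan: GLS fit of y ~ intercept + covariates + dosage under
    V = sigma_g^2 K + sigma_e^2 I, Wald t-test on the dosage coefficient.

    SNPs with MAF <= ``maf_min`` are excluded; missing dosages are
    mean-imputed per SNP for the test.  SNPs collinear with the covariates
    give p = nan (flagged in the ``singular`` column).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != g.n_samples:
        raise ValueError("y length != number of samples")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )

    # whitening transform W = diag(1/sqrt(sigma_g2 s + sigma_e2)) U'
    if K is None or (vc.sigma_g2 == 0 and vc.sigma_e2 >= 0):
        Wy, WX = y, X
        G = g.dosage.copy()
    else:
        s, U = linalg.eigh(K) if eig is None else eig
        s = np.clip(s, 0.0, None)
        d = vc.sigma_g2 * s + vc.sigma_e2
        d = np.clip(d, 1e-12 * max(d.max(), 1.0), None)
        scale = 1.0 / np.sqrt(d)
        Wy = scale * (U.T @ y)
        WX = scale[:, None] * (U.T @ X)
        G = g.dosage.copy()

    maf = np.minimum(alt_allele_freq(g), 1.0 - alt_allele_freq(g))
    passing = maf > maf_min
    # mean-impute missing dosages
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    G[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    if K is not None and not (vc.sigma_g2 == 0 and vc.sigma_e2 >= 0):
        WG = scale[:, None] * (U.T @ G)
    else:
        WG = G

    # residualize on covariates (QR projection)
    Q, _ = np.linalg.qr(WX)
    y_r = Wy - Q @ (Q.T @ Wy)
    G_r = WG - Q @ (Q.T @ WG)

    gss = np.einsum("ij,ij->j", G_r, G_r)
    gty = G_r.T @ y_r
    yss = float(y_r @ y_r)
    p_design = X.shape[1]
    df = n - p_design - 1

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gty / gss
        rss = yss - beta * gty
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(rss / df / gss)
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    singular = gss <= 1e-12
    pvals = np.where(singular, np.nan, pvals)
    # keep p in (0, 1]: underflowed p-values get the smallest positive float
    pvals = np.where(pvals == 0.0, np.nextafter(0, 1), pvals)

    tab = pd.DataFrame(
        {
            "snp_id": g.variants["snp_id"].values,
            "chrom": g.variants["chrom"].values,
            "pos": g.variants["pos"].values,
            "maf": maf,
            "beta": beta,
            "se": se,
            "t": tstat,
            "p": pvals,
            "singular": singular,
        }
    )
    tab = tab[passing].reset_index(drop=True)
    tab["q"] = bh_fdr(tab["p"].to_numpy())
    return AssocResult(
        variable=variable,
        table=tab,
        vc=vc,
        n_samples=n,
        k_covariates=p_design - 1,
    )


def associate_variable(
    g: GenotypeMatrix,
    env: pd.Series,
    covariates: np.ndarray,
    K: np.ndarray,
    maf_min: float = 0.01,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> AssocResult:
    """Null REML fit followed by the P3D scan for one environmental variable.

    Samples with missing values of the variable are dropped, with kinship,
    covariates, and genotypes subset accordingly.
    """
    mask = ~env.isna().to_numpy()
    idx = np.flatnonzero(mask)
    g_sub = g.take_samples(idx) if idx.size < g.n_samples else g
    K_sub = K[np.ix_(idx, idx)] if idx.size < g.n_samples else K
    cov_sub = covariates[idx] if covariates is not None else None
    if idx.size < g.n_samples:
        eig = None  # eigendecomposition no longer valid for the subset
    if eig is None:
        eig = linalg.eigh(K_sub)
    y = env.to_numpy(dtype=float)[idx]
    vc = fit_null_reml(y, cov_sub, K_sub, eig=eig)
    if vc.flag == "constant_y":
        empty = pd.DataFrame(
            columns=["snp_id", "chrom", "pos", "maf", "beta", "se", "t", "p",
                     "singular", "q"]
        )
        return AssocResult(env.name or "y", empty, vc, idx.size, 0)
    return scan_snps(
        g_sub, y, cov_sub, vc, K=K_sub, maf_min=maf_min,
        variable=str(env.name or "y"), eig=eig,
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.  nan inputs are
    excluded from m and returned as nan.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    q[ok] = out
    return q
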