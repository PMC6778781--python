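"""Mixed-model environmental association: ICA, REML, P3D scan, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from clinescan import (
    SimScenario,
    bh_fdr,
    fit_null_reml,
    genotype_pca,
    run_ica,
    scan_snps,
    simulate_panel,
    standardize_env,
    vanraden_kinship,
)
from clinescan.association import associate_variable

from conftest import make_matrix


class TestStandardizeAndIca:
    def test_standardize_zero_mean_unit_sd(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 10.0], "b": [5.0, 5.0, 5.0, 5.0]})
        out = standardize_env(df)
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a"].std(ddof=0) == pytest.approx(1.0)
        assert (out["b"] == 0).all()  # constant column -> zeros, not nan

    def test_recovers_mixed_uniform_sources(self):
        rng = np.random.default_rng(7)
        s = rng.uniform(-1, 1, size=(600, 2))
        mixed = s @ np.array([[1.0, 0.5], [0.5, 1.0]])
        res = run_ica(
            standardize_env(pd.DataFrame(mixed, columns=["x", "y"])),
            n_components=2, seed=0,
        )
        corr = np.abs(np.corrcoef(s.T, res.sources.T)[:2, 2:])
        # each true source matches one component up to permutation/sign
        assert corr.max(axis=1).min() > 0.95

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(200, 5)),
                         columns=list("abcde"))
        r1 = run_ica(standardize_env(x), 3, seed=5)
        r2 = run_ica(standardize_env(x), 3, seed=5)
        np.testing.assert_array_equal(r1.sources, r2.sources)

    def test_missing_values_rejected(self):
        x = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            run_ica(x, 1, seed=0)


def simulate_mixed_y(K, sigma_g2, sigma_e2, rng):
    s, U = linalg.eigh(K)
    z = rng.normal(0, 1, len(s))
    return U @ (np.sqrt(np.clip(s, 0, None) * sigma_g2) * z) + rng.normal(
        0, np.sqrt(sigma_e2), len(s)
    )


@pytest.fixture(scope="module")
def panel_K():
    sc = SimScenario(n_pops=5, n_per_pop=100, n_snps=1000, target_fst=0.1,
                     n_adaptive=0, missing_rate=0.0, seed=3)
    g, _, _ = simulate_panel(sc)
    return g, vanraden_kinship(g).K


class TestFitNullReml:
    def test_variance_ratio_recovery(self, panel_K):
        _, K = panel_K
        rng = np.random.default_rng(4)
        y = simulate_mixed_y(K, 1.0, 1.0, rng)  # ratio 0.5
        vc = fit_null_reml(y, None, K)
        assert vc.sigma_g2 >= 0 and vc.sigma_e2 >= 0
        assert vc.heritability == pytest.approx(0.5, abs=0.15)

    def test_constant_y_flagged(self, panel_K):
        _, K = panel_K
        vc = fit_null_reml(np.ones(K.shape[0]), None, K)
        assert vc.flag == "constant_y"
        assert vc.sigma_g2 == vc.sigma_e2 == 0.0

    def test_identity_kinship_flagged_degenerate(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=60)
        vc = fit_null_reml(y, None, np.eye(60))
        assert vc.flag == "kinship_unidentifiable"
        # total variance lands in the residual component
        assert vc.sigma_e2 == pytest.approx(np.var(y, ddof=1), rel=0.05)


class TestScanSnps:
    def test_perfect_signal_beta_two(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0.0, 1.0, 2.0], size=(40, 5))
        g = make_matrix(d)
        y = 2.0 * d[:, 2]
        vc = fit_null_reml(y, None, np.eye(40))
        res = scan_snps(g, y, None, vc, K=np.eye(40), maf_min=0.0)
        row = res.table.set_index("snp_id").loc["v2"]
        assert row["beta"] == pytest.approx(2.0, abs=1e-8)
        assert row["p"] < 1e-100

    def test_identity_kinship_reduces_to_ols(self):
        sc = SimScenario(n_pops=1, n_per_pop=80, n_snps=150, target_fst=0.0,
                         n_adaptive=0, missing_rate=0.0, selfing_rate=0.0,
                         seed=1)
        g, _, _ = simulate_panel(sc)
        rng = np.random.default_rng(2)
        y = rng.normal(size=g.n_samples)
        K = np.eye(g.n_samples)
        vc = fit_null_reml(y, None, K)
        res = scan_snps(g, y, None, vc, K=K, maf_min=0.0)
        for _, row in res.table.iloc[::10].iterrows():
            j = list(g.variants["snp_id"]).index(row["snp_id"])
            ols = stats.linregress(g.dosage[:, j], y)
            assert row["p"] == pytest.approx(ols.pvalue, abs=1e-8)

    def test_structured_null_type_one_error(self):
        sc = SimScenario(n_pops=8, n_per_pop=50, n_snps=5000, target_fst=0.1,
                         n_adaptive=0, missing_rate=0.0, seed=5)
        g, _, _ = simulate_panel(sc)
        K = vanraden_kinship(g).K
        pcs, _ = genotype_pca(g, 3)
        eig = linalg.eigh(K)
        rng = np.random.default_rng(6)
        y = simulate_mixed_y(K, 1.0, 0.6, rng)
        vc = fit_null_reml(y, pcs, K, eig=eig)
        res = scan_snps(g, y, pcs, vc, K=K, maf_min=0.01, eig=eig)
        alpha = (res.table["p"] < 0.05).mean()
        assert 0.03 <= alpha <= 0.07

    def test_maf_filter_excludes_rare(self):
        d = np.zeros((100, 2))
        d[0, 0] = 2.0  # MAF 0.01 -> excluded at maf_min=0.01
        d[:50, 1] = 2.0
        g = make_matrix(d)
        rng = np.random.default_rng(7)
        y = rng.normal(size=100)
        vc = fit_null_reml(y, None, np.eye(100))
        res = scan_snps(g, y, None, vc, K=np.eye(100), maf_min=0.01)
        assert list(res.table["snp_id"]) == ["v1"]

    def test_collinear_snp_flagged(self):
        d = np.column_stack([np.repeat([0.0, 2.0], 20), np.tile([0.0, 2.0], 20)])
        g = make_matrix(d)
        cov = d[:, 0:1].copy()  # SNP 0 exactly collinear with the covariate
        rng = np.random.default_rng(8)
        y = rng.normal(size=40)
        vc = fit_null_reml(y, cov, np.eye(40))
        res = scan_snps(g, y, cov, vc, K=np.eye(40), maf_min=0.0)
        row = res.table.set_index("snp_id").loc["v0"]
        assert row["singular"]
        assert np.isnan(row["p"])

    def test_planted_cline_snp_recovered(self):
        # a SNP explaining >=20% of y's variance is found at q <= 0.25
        recovered = 0
        n_reps = 10
        for rep in range(n_reps):
            sc = SimScenario(n_pops=5, n_per_pop=100, n_snps=500,
                             target_fst=0.08, n_adaptive=0,
                             missing_rate=0.0, seed=100 + rep)
            g, _, _ = simulate_panel(sc)
            K = vanraden_kinship(g).K
            pcs, _ = genotype_pca(g, 3)
            eig = linalg.eigh(K)
            rng = np.random.default_rng(rep)
            j = int(rng.integers(g.n_snps))
            x = g.dosage[:, j]
            noise = simulate_mixed_y(K, 0.3, 0.5, rng)
            beta = np.sqrt(0.25 * np.var(noise) / np.var(x))
            y = pd.Series(beta * x + noise, index=g.samples, name="env")
            res = associate_variable(g, y, pcs, K, maf_min=0.01, eig=eig)
            hit = res.significant(0.25)["snp_id"]
            if g.variants["snp_id"].iloc[j] in set(hit):
                recovered += 1
        assert recovered >= 0.9 * n_reps


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        q = bh_fdr(np.full(10, 0.01))
        np.testing.assert_allclose(q, 0.01)

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.3])), [0.3])

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=500) ** 2
        q = bh_fdr(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p - 1e-12).all()

    def test_nan_passthrough(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1])
        assert not np.isnan(q[0])
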