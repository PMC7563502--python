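"""Mixed-model equations: BLUP/GBLUP/ssGBLUP solutions and corrected phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import inv

import ssgblup as ss
from conftest import explicit_h, gls_blup_oracle, make_phen


@pytest.fixture(scope="module")
def fitted(small_dataset, small_matrices):
    """Pedigree-BLUP fit and corrected phenotypes on the session dataset."""
    phen = small_dataset[2]
    spec = ss.ModelSpec()
    fit = ss.solve_mme(phen, spec, small_matrices["A_inv"], 3.0, 6.0)
    return phen, spec, fit, ss.corrected_phenotypes(fit)


class TestSolveMme:
    def test_matches_gls_oracle(self, small_dataset, small_matrices):
        phen, spec = small_dataset[2], ss.ModelSpec()
        a = small_matrices["A"]
        fit = ss.solve_mme(phen, spec, small_matrices["A_inv"], 3.0, 6.0)
        b, a_hat = gls_blup_oracle(phen, spec, a.values, a.ids, 3.0, 6.0)
        assert np.allclose(fit.fixed_effects.to_numpy(), b, atol=1e-8)
        assert np.allclose(fit.breeding_values.to_numpy(), a_hat, atol=1e-8)

    def test_shrinkage_limit_recovers_ols(self, small_dataset, small_matrices):
        phen, spec = small_dataset[2], ss.ModelSpec()
        fit = ss.solve_mme(phen, spec, small_matrices["A_inv"], 1e-8, 1.0)
        assert np.max(np.abs(fit.breeding_values)) < 1e-4
        from ssgblup.models import build_design
        x, _, _ = build_design(phen, spec)
        y = phen["trait"].to_numpy()
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.allclose(fit.fixed_effects.to_numpy(), ols, atol=1e-4)

    def test_unphenotyped_progeny_gets_parent_average(self):
        ped = ss.Pedigree(ids=np.array(["s", "d", "kid"]),
                          sire=np.array([-1, -1, 0]),
                          dam=np.array([-1, -1, 1]))
        a_inv = ss.a_inverse(ped)
        phen = make_phen(["s", "d"], [4.0, 8.0])
        fit = ss.solve_mme(phen, ss.ModelSpec.mean_only(), a_inv, 2.0, 3.0)
        bv = fit.breeding_values
        assert bv["kid"] == pytest.approx(0.5 * (bv["s"] + bv["d"]), abs=1e-10)

    def test_mme_blocks_satisfied(self, fitted, small_matrices):
        """Both blocks of the normal equations hold at the solution."""
        phen, spec, fit, _ = fitted
        from ssgblup.models import build_design
        x, _, _ = build_design(phen, spec)
        k_inv = small_matrices["A_inv"]
        idx = k_inv.index_of(phen["id"])
        q = len(k_inv)
        z = np.zeros((len(phen), q))
        z[np.arange(len(phen)), idx] = 1
        y = phen["trait"].to_numpy()
        lam = fit.sigma_e2 / fit.sigma_a2
        b, a = fit.fixed_effects.to_numpy(), fit.breeding_values.to_numpy()
        r1 = x.T @ x @ b + x.T @ z @ a - x.T @ y
        r2 = z.T @ x @ b + (z.T @ z + lam * k_inv.values) @ a - z.T @ y
        scale = np.linalg.norm(np.concatenate([x.T @ y, z.T @ y]))
        assert np.linalg.norm(np.concatenate([r1, r2])) / scale < 1e-8

    def test_shift_invariance(self, small_dataset, small_matrices):
        """Adding a constant to y moves the intercept, not breeding values."""
        phen, spec = small_dataset[2], ss.ModelSpec()
        fit0 = ss.solve_mme(phen, spec, small_matrices["A_inv"], 3.0, 6.0)
        shifted = phen.copy()
        shifted["trait"] = shifted["trait"] + 100.0
        fit1 = ss.solve_mme(shifted, spec, small_matrices["A_inv"], 3.0, 6.0)
        assert np.allclose(fit1.breeding_values, fit0.breeding_values, atol=1e-8)
        assert fit1.fixed_effects["intercept"] == pytest.approx(
            fit0.fixed_effects["intercept"] + 100.0, abs=1e-8)

    def test_rank_deficient_fixed_effects_reported(self, small_dataset,
                                                   small_matrices):
        phen = small_dataset[2].copy()
        phen["dup"] = phen["covariate"]  # exact copy: rank deficient
        spec = ss.ModelSpec(covariates=("covariate", "dup"))
        fit = ss.solve_mme(phen, spec, small_matrices["A_inv"], 3.0, 6.0)
        assert fit.dropped_columns == ["dup"]

    def test_invalid_variances_rejected(self, small_dataset, small_matrices):
        with pytest.raises(ValueError):
            ss.solve_mme(small_dataset[2], ss.ModelSpec(),
                         small_matrices["A_inv"], 0.0, 1.0)


class TestCorrectedPhenotypes:
    def test_definition(self):
        fit = ss.MixedModelFit(
            fixed_effects=pd.Series([0.0], index=["intercept"]),
            breeding_values=pd.Series([1.2], index=["x"]),
            residuals=pd.Series([-0.3], index=["x"]),
            sigma_a2=1.0, sigma_e2=1.0, kind="A_inverse")
        yc = ss.corrected_phenotypes(fit)
        assert yc.values["x"] == pytest.approx(0.9)

    def test_equals_y_minus_xb(self, fitted):
        phen, spec, fit, yc = fitted
        from ssgblup.models import build_design
        x, _, _ = build_design(phen, spec)
        expected = phen["trait"].to_numpy() - x @ fit.fixed_effects.to_numpy()
        assert np.allclose(yc.values.to_numpy(), expected, atol=1e-10)

    def test_mean_only_model_gives_centered_y(self, small_matrices):
        ids = small_matrices["A"].ids[:30]
        rng = np.random.default_rng(0)
        y = rng.normal(10.0, 2.0, size=30)
        phen = make_phen(ids, y)
        fit = ss.solve_mme(phen, ss.ModelSpec.mean_only(),
                           small_matrices["A_inv"], 1e-6, 1.0)
        yc = ss.corrected_phenotypes(fit)
        assert np.allclose(yc.values.to_numpy(), y - y.mean(), atol=1e-4)


class TestGblup:
    def test_identity_g_is_ridge_shrinkage(self):
        """With K = I, GEBV shrink centered phenotypes by sa2/(sa2+se2)."""
        ids = np.array(["a", "b", "c", "d"])
        yc = ss.CorrectedPhenotypes(values=pd.Series([1.0, -1.0, 2.0, -2.0],
                                                     index=ids))
        g = ss.RelationshipMatrix(ids=ids, values=np.eye(4), kind="G_blended",
                                  omega=0.0)
        sa2, se2 = 2.0, 6.0
        fit = ss.gblup(yc, g, sa2, se2)
        y = yc.values.to_numpy()
        shrunk = sa2 / (sa2 + se2) * (y - y.mean())
        assert np.allclose(fit.breeding_values.to_numpy(), shrunk, atol=1e-10)

    def test_exchangeable_animals_get_equal_gebv(self):
        ids = np.array(["t1", "t2", "o"])
        k = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]])
        g = ss.RelationshipMatrix(ids=ids, values=k, kind="G_blended")
        yc = ss.CorrectedPhenotypes(values=pd.Series([1.5, 1.5, -3.0], index=ids))
        fit = ss.gblup(yc, g, 1.0, 1.0)
        assert fit.breeding_values["t1"] == pytest.approx(
            fit.breeding_values["t2"], abs=1e-12)

    def test_matches_gls_oracle(self, fitted, small_matrices, small_dataset):
        _, _, _, yc = fitted
        g_blend = small_matrices["G_blend"]
        fit = ss.gblup(yc, g_blend, 2.0, 4.0)
        geno_ids = [a for a in yc.values.index if a in set(g_blend.ids)]
        phen = make_phen(geno_ids, yc.values.loc[geno_ids].to_numpy())
        b, a_hat = gls_blup_oracle(phen, ss.ModelSpec.mean_only(),
                                   g_blend.values, g_blend.ids, 2.0, 4.0)
        assert np.allclose(fit.fixed_effects.to_numpy(), b, atol=1e-8)
        assert np.allclose(fit.breeding_values.to_numpy(), a_hat, atol=1e-8)


class TestSsgblup:
    def test_no_genotyped_reduces_to_pedigree_blup(self, fitted, small_matrices):
        phen, spec, fit_blup, yc = fitted
        a_inv = small_matrices["A_inv"]
        h_inv = ss.h_inverse(a_inv, small_matrices["A22"],
                             small_matrices["G_blend"], [])
        fit_ss = ss.ssgblup(yc, h_inv, 3.0, 6.0)
        fit_ped = ss.ssgblup(yc, a_inv, 3.0, 6.0)
        assert np.allclose(fit_ss.breeding_values, fit_ped.breeding_values,
                           atol=1e-10)

    def test_all_genotyped_reduces_to_gblup(self):
        cfg = ss.SimConfig(n_founders=24, n_generations=1,
                           matings_per_generation=12, offspring_per_mating=2,
                           n_snps=400, n_phenotyped=48,
                           genotyped_fraction=1.0, missing_rate=0.0, seed=6)
        ped = ss.simulate_pedigree(cfg)
        geno = ss.simulate_genotypes(ped, cfg)  # all animals genotyped
        phen, _ = ss.simulate_phenotypes(ped, geno, cfg)
        a = ss.numerator_relationship(ped)
        a_inv = ss.a_inverse(ped)
        a22 = ss.a22_from_full(a, geno.ids)
        g_blend = ss.blend_g(ss.genomic_relationship(geno), a22, 0.05)
        h_inv = ss.h_inverse(a_inv, a22, g_blend, geno.ids)
        fit = ss.solve_mme(phen, ss.ModelSpec(), a_inv, 3.0, 6.0)
        yc = ss.corrected_phenotypes(fit)
        fg = ss.gblup(yc, g_blend, 2.0, 4.0)
        fs = ss.ssgblup(yc, h_inv, 2.0, 4.0)
        assert np.allclose(fs.breeding_values.loc[fg.breeding_values.index],
                           fg.breeding_values, atol=1e-8)

    def test_mixed_case_matches_joint_matrix_oracle(self, fitted,
                                                    small_matrices,
                                                    small_dataset):
        """ssGBLUP through H^-1 equals GLS on the explicitly built H."""
        _, _, _, yc = fitted
        geno = small_dataset[4]
        h_inv = small_matrices["H_inv"]
        fit = ss.ssgblup(yc, h_inv, 2.5, 5.0)
        h = explicit_h(small_matrices["A"], small_matrices["G_blend"], geno.ids)
        ids = [a for a in yc.values.index]
        phen = make_phen(ids, yc.values.loc[ids].to_numpy())
        b, a_hat = gls_blup_oracle(phen, ss.ModelSpec.mean_only(), h,
                                   h_inv.ids, 2.5, 5.0)
        assert np.allclose(fit.fixed_effects.to_numpy(), b, atol=1e-8)
        assert np.allclose(fit.breeding_values.to_numpy(), a_hat, atol=1e-8)

    def test_genomic_beats_pedigree_for_genotyped_validation(self):
        """corr(GEBV, TBV) for ssGBLUP >= pedigree BLUP on unphenotyped
        genotyped animals, in a majority of seeds."""
        wins = 0
        for seed in range(5):
            cfg = ss.SimConfig(n_founders=60, n_generations=2,
                               matings_per_generation=40, offspring_per_mating=2,
                               n_snps=800, n_phenotyped=120,
                               genotyped_fraction=1.0, missing_rate=0.0,
                               h2_true=0.4, sigma_p_true=4.0, seed=100 + seed)
            ped, geno_full, phen, truth, geno = ss.simulate_dataset(cfg)
            a = ss.numerator_relationship(ped)
            a_inv = ss.a_inverse(ped)
            a22 = ss.a22_from_full(a, geno.ids)
            g_blend = ss.blend_g(ss.genomic_relationship(geno), a22, 0.05)
            h_inv = ss.h_inverse(a_inv, a22, g_blend, geno.ids)
            # mask half of the genotyped animals' phenotypes
            rng = np.random.default_rng(seed)
            val = rng.choice(geno.ids, size=geno.n_animals // 2, replace=False)
            train = phen[~phen["id"].isin(val)]
            sa2 = cfg.h2_true * cfg.sigma_p_true
            se2 = cfg.sigma_p_true - sa2
            fit_ped = ss.solve_mme(train, ss.ModelSpec(), a_inv, sa2, se2)
            fit_ss = ss.solve_mme(train, ss.ModelSpec(), h_inv, sa2, se2)
            tbv = truth.true_breeding_values.loc[val]
            r_ped = np.corrcoef(fit_ped.breeding_values.loc[val], tbv)[0, 1]
            r_ss = np.corrcoef(fit_ss.breeding_values.loc[val], tbv)[0, 1]
            wins += int(r_ss >= r_ped)
        assert wins >= 3
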