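import numpy as np
import pytest

from genarch import ldsc, sem
from genarch import simulate as sim

from conftest import FIVE_FACTOR_MODEL


def oracle_cov(V_diag=1e-4):
    """Noiseless covariance implied by the packaged five-factor truth."""
    truth = sim.study_scale_truth()
    R, _ = sim.implied_covariance(truth)
    k = R.shape[0]
    p = k * (k + 1) // 2
    return truth, ldsc.GeneticCovariance(
        traits=list(sim.STUDY_TRAITS), S=R, V=np.eye(p) * V_diag,
        intercepts=np.eye(k), intercept_se=np.zeros((k, k)))


class TestParser:
    def test_loadings_and_residuals(self):
        m = sem.parse_model("F1 =~ A + B\nF2 =~ C\nA ~~ 0.2*A\nF1 ~~ 0*F2",
                            traits=["A", "B", "C"])
        assert m.factors == ["F1", "F2"]
        assert m.loadings[("A", "F1")] is None
        assert m.residuals["A"] == 0.2
        assert m.factor_cov[("F1", "F2")] == 0.0

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            sem.parse_model("F1 =~ A + Q", traits=["A", "B"])

    def test_df_counts_moments_minus_free_parameters(self):
        m = sem.parse_model(FIVE_FACTOR_MODEL, traits=list(sim.STUDY_TRAITS))
        # 11 loadings + 10 factor correlations + 10 residuals = 31 free
        assert m.n_free == 31
        assert m.degrees_of_freedom() == 55 - 31


class TestCfa:
    def test_oracle_parameters_recovered_from_noiseless_s(self):
        truth, cov = oracle_cov()
        m = sem.parse_model(FIVE_FACTOR_MODEL, traits=list(sim.STUDY_TRAITS))
        fit = sem.fit_cfa(cov, m)
        assert fit.converged
        assert fit.chisq == pytest.approx(0.0, abs=1e-6)
        # standardized loadings match the generating matrix entrywise
        lam_fit = np.abs(fit.loadings)
        lam_true = np.abs(truth.loadings)
        assert np.max(np.abs(lam_fit - lam_true)) < 1e-4
        np.testing.assert_allclose(fit.factor_corr, truth.psi, atol=1e-4)
        np.testing.assert_allclose(fit.residuals, truth.residuals(), atol=1e-4)

    def test_saturated_model_fits_perfectly(self):
        _, cov = oracle_cov()
        fit = sem.fit_cfa(cov, sem.saturated_model(cov.traits))
        assert fit.df == 0
        assert fit.chisq == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == pytest.approx(1.0)
        assert fit.srmr == pytest.approx(0.0, abs=1e-6)

    def test_misspecified_model_ranks_below_truth_on_oracle(self):
        _, cov = oracle_cov()
        good = sem.fit_cfa(cov, sem.parse_model(FIVE_FACTOR_MODEL,
                                                traits=cov.traits))
        bad = sem.fit_cfa(cov, sem.parse_model(
            "F1 =~ " + " + ".join(cov.traits), traits=cov.traits))
        ranking = sem.compare_models([bad, good])
        assert ranking.iloc[0]["model"] == 1
        assert good.aic < bad.aic

    def test_standardized_solution_invariant_to_unit_rescaling(self):
        truth, cov = oracle_cov()
        m = sem.parse_model(FIVE_FACTOR_MODEL, traits=cov.traits)
        fit1 = sem.fit_cfa(cov, m)
        scale = np.array([1.0, 2.0, 0.5, 1.5, 3.0, 1.0, 0.7, 2.5, 1.2, 0.9])
        outer = np.outer(scale, scale)
        idx = ldsc.vech_index(cov.k)
        vfac = np.array([outer[i, j] for i, j in idx])
        cov2 = ldsc.GeneticCovariance(
            traits=cov.traits, S=cov.S * outer,
            V=cov.V * np.outer(vfac, vfac),
            intercepts=cov.intercepts, intercept_se=cov.intercept_se)
        fit2 = sem.fit_cfa(cov2, m)
        np.testing.assert_allclose(np.abs(fit2.loadings), np.abs(fit1.loadings),
                                   atol=1e-6)

    def test_unidentified_model_rejected(self):
        _, cov = oracle_cov()
        text = "\n".join(f"G{i} =~ {t}" for i, t in enumerate(cov.traits))
        # k single-indicator factors with free residuals: 10+45+10 > 55
        with pytest.raises(ValueError, match="identified"):
            sem.fit_cfa(cov, sem.parse_model(text, traits=cov.traits))


class TestFitIndices:
    def test_cfi_hand_example(self):
        # CFI = 1 - (chi2_m - df_m) / (chi2_b - df_b) = 1 - 5/55
        num = max(10.0 - 5, 0.0)
        den = max(100.0 - 45, num, 0.0)
        assert 1 - num / den == pytest.approx(0.9091, abs=1e-4)

    def test_constant_magnitude_residuals_give_that_srmr(self):
        # SRMR is the RMS of standardized residuals: all +-0.1 -> 0.1
        _, cov = oracle_cov()
        m = sem.parse_model(FIVE_FACTOR_MODEL, traits=cov.traits)
        fit = sem.fit_cfa(cov, m)
        par = sem._Parameterisation(m)
        sigma = par.implied(fit.theta)
        rng = np.random.default_rng(0)
        signs = rng.choice([-1.0, 1.0], size=cov.S.shape)
        signs = np.tril(signs) + np.tril(signs, -1).T
        # build S2 so that (S2 - sigma) standardized by S2's own diagonal is
        # exactly +-0.1 everywhere
        diag2 = np.diag(sigma) / (1.0 - 0.1 * np.diag(signs))
        d2 = np.sqrt(diag2)
        perturbed = sigma + 0.1 * signs * np.outer(d2, d2)
        np.fill_diagonal(perturbed, diag2)
        cov2 = ldsc.GeneticCovariance(
            traits=cov.traits, S=perturbed, V=cov.V,
            intercepts=cov.intercepts, intercept_se=cov.intercept_se)
        _, _, _, srmr, _, _ = sem.fit_indices(fit, cov2)
        assert srmr == pytest.approx(0.1, abs=1e-9)

    def test_indices_invariant_to_trait_ordering(self):
        _, cov = oracle_cov()
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(len(cov.traits)))
        cov_p = cov.subset([cov.traits[i] for i in perm])
        m = sem.parse_model(FIVE_FACTOR_MODEL, traits=cov.traits)
        m_p = sem.parse_model(FIVE_FACTOR_MODEL, traits=cov_p.traits)
        fit = sem.fit_cfa(cov, m)
        fit_p = sem.fit_cfa(cov_p, m_p)
        assert fit_p.cfi == pytest.approx(fit.cfi, abs=1e-6)
        assert fit_p.srmr == pytest.approx(fit.srmr, abs=1e-6)


class TestCompareModels:
    def test_identical_fits_tie_in_input_order(self):
        _, cov = oracle_cov()
        m = sem.parse_model(FIVE_FACTOR_MODEL, traits=cov.traits)
        f1 = sem.fit_cfa(cov, m)
        f2 = sem.fit_cfa(cov, m)
        ranking = sem.compare_models([f1, f2])
        assert list(ranking["model"]) == [0, 1]
        assert ranking["delta_aic"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_ranking_is_permutation_of_inputs(self):
        _, cov = oracle_cov()
        fits = [sem.fit_cfa(cov, sem.parse_model(t, traits=cov.traits))
                for t in [FIVE_FACTOR_MODEL,
                          "F1 =~ " + " + ".join(cov.traits)]]
        fits.append(sem.fit_cfa(cov, sem.saturated_model(cov.traits)))
        ranking = sem.compare_models(fits)
        assert sorted(ranking["model"]) == [0, 1, 2]

    def test_different_covariances_rejected(self):
        _, cov = oracle_cov()
        cfgA = sim.SimConfig(m=5000, traits=[sim.TraitSpec(t, 0.3, n=10_000)
                                             for t in ("X", "Y")], seed=2)
        tabs, ld, _ = sim.simulate_panel(cfgA)
        cov2 = ldsc.multivariate_ldsc(tabs, ld, n_blocks=50)
        f1 = sem.fit_cfa(cov, sem.saturated_model(cov.traits))
        f2 = sem.fit_cfa(cov2, sem.saturated_model(cov2.traits))
        with pytest.raises(ValueError, match="same covariance"):
            sem.compare_models([f1, f2])


def test_loading_sandwich_ses_are_calibrated_end_to_end():
    """Across full-pipeline replicates (generator -> LDSC -> CFA) at reduced
    study scale, >=95% of true loadings lie within 2 sandwich SEs of the
    estimate; Heywood replicates are refit with bounded residuals for an
    interpretable solution."""
    truth = sim.study_scale_truth()
    cover = total = 0
    for s in range(20):
        cfg = sim.study_scale_scenario(seed=123456 + s)
        h2_true = np.array([t.h2 for t in cfg.traits])
        lam_u_true = truth.loadings * np.sqrt(h2_true)[:, None]
        tables, ld, _ = sim.simulate_panel(cfg)
        cov = ldsc.multivariate_ldsc(tables, ld)
        model = sem.parse_model(FIVE_FACTOR_MODEL, traits=cov.traits)
        fit = sem.fit_cfa(cov, model)
        if any("Heywood" in w for w in fit.warnings):
            model = sem.parse_model(FIVE_FACTOR_MODEL, traits=cov.traits)
            model.bound_residuals = True
            fit = sem.fit_cfa(cov, model)
        par = sem._Parameterisation(model)
        for p, (i, f) in enumerate(par.free_loadings):
            cover += abs(abs(fit.theta[p]) - abs(lam_u_true[i, f])) \
                < 2 * fit.se[p]
            total += 1
    assert cover / total >= 0.95, (cover, total)


class TestEfa:
    def test_perfect_block_structure_recovers_sqrt_loadings(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.8
        R[2, 3] = R[3, 2] = 0.8
        res = sem.fit_efa(R, 2, trait_names=list("abcd"))
        for i in range(4):
            lead = np.max(np.abs(res.loadings[i]))
            off = np.min(np.abs(res.loadings[i]))
            assert lead == pytest.approx(np.sqrt(0.8), abs=1e-3)
            assert off < 0.01
        assert res.clusters["a"] == res.clusters["b"]
        assert res.clusters["c"] == res.clusters["d"]
        assert res.clusters["a"] != res.clusters["c"]
        assert res.factor_corr[0, 1] == pytest.approx(0.0, abs=0.02)

    def test_identity_matrix_has_no_shared_variance(self):
        res = sem.fit_efa(np.eye(6), 1, trait_names=list("abcdef"))
        assert res.variance_explained < 1 / 5

    def test_noiseless_study_truth_reproduces_four_clusters(self):
        R, _ = sim.implied_covariance(sim.study_scale_truth())
        res = sem.fit_efa(R, 4, trait_names=list(sim.STUDY_TRAITS))
        groups = {}
        for t, c in res.clusters.items():
            groups.setdefault(c, set()).add(t)
        assert sorted(map(sorted, groups.values())) == sorted(map(sorted, [
            ["OCD", "AN", "TS"], ["BIP", "SCZ"], ["ANX", "MDD"],
            ["ADHD", "AUT", "DYX"]]))

    def test_too_many_factors_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            sem.fit_efa(np.eye(3), 3)
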