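import numpy as np
import pandas as pd
import pytest

from clonepart import varcomp
from clonepart.varcomp import (
    SpatialParams,
    TrialData,
    ar1_matrix,
    error_fractions,
    fit,
    reml_loglik,
    residual_covariance,
    sample_variogram,
)
from oracles import dense_reml_oracle, random_instance


class TestAR1:
    def test_zero_rho_is_identity(self):
        assert np.array_equal(ar1_matrix(5, 0.0), np.eye(5))

    def test_two_by_two(self):
        m = ar1_matrix(2, 0.85)
        assert m[0, 1] == pytest.approx(0.85)

    def test_inverse_is_tridiagonal_closed_form(self):
        # classic AR1 inverse: (1/(1-rho^2)) * tridiag(-rho | 1, 1+rho^2 | -rho)
        n, rho = 7, 0.9
        inv = np.linalg.inv(ar1_matrix(n, rho))
        expected = np.zeros((n, n))
        expected[np.diag_indices(n)] = 1 + rho**2
        expected[0, 0] = expected[-1, -1] = 1.0
        expected[np.arange(n - 1), np.arange(1, n)] = -rho
        expected[np.arange(1, n), np.arange(n - 1)] = -rho
        assert np.allclose(inv, expected / (1 - rho**2), atol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ar1_matrix(0, 0.5)
        with pytest.raises(ValueError):
            ar1_matrix(3, 1.0)


class TestResidualCovariance:
    def _layout(self, coords):
        return pd.DataFrame(coords, columns=["master_block", "column", "row"])

    def test_zero_rho_is_diagonal(self):
        layout = self._layout([(1, 1, 1), (1, 2, 1), (1, 1, 2)])
        r = residual_covariance(SpatialParams(0.5, 0.3, 0.0, 0.0), layout)
        assert np.allclose(r, 0.8 * np.eye(3))

    def test_cross_master_block_covariance_zero(self):
        layout = self._layout([(1, 1, 1), (2, 1, 1)])
        r = residual_covariance(SpatialParams(0.1, 1.0, 0.8, 0.8), layout)
        assert r[0, 1] == 0.0

    def test_separable_product_at_offset(self):
        layout = self._layout([(1, 1, 1), (1, 3, 2)])  # offset (2, 1)
        r = residual_covariance(SpatialParams(0.0, 2.0, 0.8, 0.6), layout)
        assert r[0, 1] == pytest.approx(2.0 * 0.8**2 * 0.6)

    def test_duplicate_coordinates_rejected(self):
        layout = self._layout([(1, 1, 1), (1, 1, 1)])
        with pytest.raises(ValueError, match="duplicate"):
            residual_covariance(SpatialParams(1.0, 0.0, 0.0, 0.0), layout)


class TestErrorFractions:
    def test_equal_split(self):
        assert error_fractions(SpatialParams(1.0, 1.0, 0.0, 0.0)) == (0.5, 0.5)

    def test_no_spatial(self):
        assert error_fractions(SpatialParams(2.0, 0.0, 0.0, 0.0)) == (1.0, 0.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            error_fractions(SpatialParams(0.0, 0.0, 0.0, 0.0))


def _iid_frame(y):
    n = len(y)
    return pd.DataFrame(
        {
            "tree_id": [f"t{i}" for i in range(n)],
            "genotype_id": [f"g{i}" for i in range(n)],
            "site": "s",
            "block": 1,
            "master_block": 1,
            "column": np.arange(n) + 1,
            "row": 1,
            "trait": "y",
            "value": y,
        }
    )


class TestREMLLoglik:
    def test_matches_closed_form_for_iid_intercept_model(self):
        # V = sigma^2 I: REML loglik has the textbook closed form
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        data = TrialData.from_trial_frame(_iid_frame(y))
        s2 = 1.7
        params = dict(sigma_u2=0.0, sigma_v2=0.0, sigma_r2=s2, sigma_s2=0.0, rho_c=0.0, rho_r=0.0)
        ll = reml_loglik(params, data, model=1)
        n = 12
        ss = ((y - y.mean()) ** 2).sum()
        closed = -0.5 * (n * np.log(s2) + np.log(n / s2) + ss / s2 + (n - 1) * np.log(2 * np.pi))
        assert ll == pytest.approx(closed, abs=1e-10)

    @pytest.mark.parametrize("two_mb", [False, True])
    def test_matches_dense_oracle_on_random_instances(self, two_mb):
        rng = np.random.default_rng(4 + two_mb)
        for _ in range(5):
            frame, grm, params = random_instance(rng, with_grm=True, two_mb=two_mb)
            data = TrialData.from_trial_frame(frame, grm=grm)
            ll = reml_loglik(params, data, model=2)
            oracle = dense_reml_oracle(params, frame, grm, grm.k, model=2)
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_eigh_and_cholesky_paths_agree(self):
        rng = np.random.default_rng(6)
        frame, grm, params = random_instance(rng)
        data = TrialData.from_trial_frame(frame, grm=grm)
        assert reml_loglik(params, data, 2, method="cholesky") == pytest.approx(
            reml_loglik(params, data, 2, method="eigh"), abs=1e-8
        )

    def test_invariant_to_plot_permutation(self):
        rng = np.random.default_rng(7)
        frame, grm, params = random_instance(rng)
        data = TrialData.from_trial_frame(frame, grm=grm)
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        data2 = TrialData.from_trial_frame(shuffled, grm=grm)
        assert reml_loglik(params, data, 2) == pytest.approx(reml_loglik(params, data2, 2), abs=1e-9)

    def test_model2_without_genotyped_trees_equals_model1(self):
        rng = np.random.default_rng(8)
        frame, _, params = random_instance(rng, with_grm=False)
        data = TrialData.from_trial_frame(frame, grm=None)
        assert reml_loglik(params, data, 2) == pytest.approx(
            reml_loglik({k: v for k, v in params.items() if k != "r_a"}, data, 1), abs=1e-10
        )

    def test_non_positive_definite_returns_minus_inf(self):
        rng = np.random.default_rng(9)
        frame, grm, params = random_instance(rng)
        data = TrialData.from_trial_frame(frame, grm=grm)
        bad = dict(params, sigma_u2=0.0, sigma_v2=0.0, sigma_r2=0.0, sigma_s2=0.0)
        assert reml_loglik(bad, data, 2) == -np.inf


class TestFit:
    def test_implied_constraint_holds_exactly(self, small_fitted_trial):
        f = small_fitted_trial["fit"]
        implied = f.implied_constraint
        assert implied["k_sigma_a2"] + implied["sigma_d2"] == pytest.approx(f.params["sigma_u2"], abs=1e-12)

    def test_estimates_in_plausible_range(self, small_fitted_trial):
        f = small_fitted_trial["fit"]
        assert f.converged
        assert 0.0 <= f.params["r_a"] <= 1.0
        assert f.params["sigma_u2"] == pytest.approx(1.0, abs=0.6)
        assert np.isfinite(f.loglik)

    def test_zero_spatial_variance_boundary_handled(self, small_map):
        from clonepart import grm as grm_mod, simdata
        from conftest import SEG_PROBS

        parents = simdata.simulate_parent_genotypes(small_map, SEG_PROBS, seed=301)
        fam = simdata.simulate_family(
            simdata.FamilyConfig(n_offspring=50, n_genotyped=50, seed=302), small_map, parents
        )
        gv = simdata.assign_genetic_values(
            fam.genotypes,
            simdata.ArchitectureConfig(r_a=0.75, n_causal_add=60, n_causal_dom=60),
            seed=303,
        )
        p = grm_mod.parental_allele_frequencies([parents["mother"].dosage, parents["fatherA"].dosage])
        g = grm_mod.vanraden_g(fam.genotypes.calls.astype(float), p, ids=fam.genotypes.ids)
        site = simdata.SiteSpec(name="z", n_blocks=4, master_blocks=((1, 2), (3, 4)), block_grid=(8, 7))
        noise = simdata.NoiseConfig(sigma_v2=0.05, sigma_r2=0.6, sigma_s2=0.0, rho_c=0.0, rho_r=0.0)
        trial = simdata.simulate_trial(site, gv.u, noise, seed=304, genotype_ids=fam.genotypes.ids)
        data = TrialData.from_trial_frame(trial.frame, grm=g)
        f = fit(data, model=2, n_starts=1, compute_se=False)
        # at sigma_s2 = 0 the split (sigma_r2, sigma_s2, rho) is only identified
        # through the implied spatial covariance: lag-1 covariance must be ~ 0
        # and the total error variance recovered, with no crash at the boundary
        p_hat = f.params
        lag1 = p_hat["sigma_s2"] * max(abs(p_hat["rho_c"]), abs(p_hat["rho_r"]))
        assert lag1 < 0.1
        assert p_hat["sigma_r2"] + p_hat["sigma_s2"] == pytest.approx(0.6, abs=0.25)

    def test_optimum_independent_of_multistart_seed(self, small_fitted_trial):
        data = small_fitted_trial["data"]
        f1 = fit(data, model=2, n_starts=2, optimizer_seed=1, compute_se=False)
        f2 = fit(data, model=2, n_starts=2, optimizer_seed=2, compute_se=False)
        assert abs(f1.params["r_a"] - f2.params["r_a"]) < 1e-4
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


class TestHeterozygosityCovariate:
    def test_covariate_enters_design_and_likelihood(self, small_fitted_trial):
        from clonepart.geno_qc import individual_heterozygosity
        from clonepart.simdata import GenotypeMatrix

        data = small_fitted_trial["data"]
        rng = np.random.default_rng(17)
        calls = rng.integers(0, 3, size=(len(data.genotype_ids), 30)).astype(np.int8)
        gm = GenotypeMatrix(calls=calls, ids=list(data.genotype_ids), snp_ids=[f"s{k}" for k in range(30)])
        het = individual_heterozygosity(gm)
        assert het.between(0, 1).all()
        frame = small_fitted_trial["trial"].frame
        with_cov = TrialData.from_trial_frame(frame, grm=small_fitted_trial["grm"], covariate=het)
        assert with_cov.X.shape[1] == 2
        assert abs(with_cov.X[:, 1].mean()) < 0.05  # centred covariate
        params = dict(small_fitted_trial["fit"].params)
        params.pop("r_d", None)
        assert np.isfinite(reml_loglik(params, with_cov, model=2))


class TestVariogram:
    def _layout(self, nc, nr):
        cells = [(1, c, r) for c in range(1, nc + 1) for r in range(1, nr + 1)]
        return pd.DataFrame(cells, columns=["master_block", "column", "row"])

    def test_identical_residuals_give_zero(self):
        layout = self._layout(5, 5)
        v = sample_variogram(np.full(25, 3.2), layout)
        assert np.allclose(v["gamma"], 0.0)

    def test_iid_residuals_flat_at_variance(self):
        layout = self._layout(40, 40)
        rng = np.random.default_rng(11)
        v = sample_variogram(rng.normal(size=1600), layout, max_lag=5)
        assert v["gamma"].mean() == pytest.approx(1.0, abs=0.08)
        assert v["gamma"].min() > 0.7
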