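"""Function-on-scalar regression engine: design, fitting, inference."""

import numpy as np
import pandas as pd
import pytest

from gaitpower.fosr import (
    ExtrapolationWarning,
    FittedFoSR,
    ModelSpec,
    _REMLProblem,
    build_design,
    fit,
)
from gaitpower.preprocess import PowerWaveform, prepare_waveforms
from gaitpower.synthetic import GeneratorConfig, simulate_dataset


def _truncate(waves, n_points=11):
    return [
        PowerWaveform(w.participant_id, w.study_id, w.joint, w.grid[:n_points], w.values[:n_points])
        for w in waves
    ]


@pytest.fixture(scope="module")
def tiny_instance():
    """20 subjects x 11 cycle points, 2 studies: oracle-scale problem."""
    cfg = GeneratorConfig(n_participants=20, seed=3, n_studies=2)
    covs, waves, _ = simulate_dataset(cfg, joints=("ankle",))
    return covs, _truncate(waves)


class TestModelSpec:
    def test_small_basis_rejected(self):
        with pytest.raises(ValueError, match="k_time"):
            ModelSpec(joint="hip", k_time=3)

    def test_unknown_selection_rejected(self):
        with pytest.raises(ValueError, match="selection"):
            ModelSpec(joint="hip", selection="AIC")

    def test_default_ankle_time_basis_smaller(self):
        assert ModelSpec.for_joint("ankle").k_time == 12
        assert ModelSpec.for_joint("hip").k_time == 20

    def test_stride_frequency_with_speed_and_stride_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            ModelSpec(
                joint="hip",
                covariates=("age", "speed", "stride_length", "height", "stride_frequency"),
            )


class TestBuildDesign:
    def test_column_count_bookkeeping(self, tiny_instance):
        covs, waves = tiny_instance
        spec = ModelSpec(joint="ankle", k_time=4, k_cov=4, k_time3=8)
        design = build_design(waves, covs, spec)
        k_t, k_x = 4, 4
        expected = (
            1  # sex
            + k_t  # intercept curve
            + 4 * (k_x - 1) * k_t  # four constrained bivariate smooths
            + (spec.k_age - 1) * (spec.k_speed - 1) * spec.k_time3
            + 2 * k_t  # two study-intercept curves
        )
        assert design.n_cols == expected

    def test_constrained_columns_sum_to_zero(self, tiny_instance):
        covs, waves = tiny_instance
        design = build_design(waves, covs, ModelSpec(joint="ankle", k_time=4, k_cov=5))
        for name in ("age", "speed", "stride_length", "height"):
            colsums = design.term(name).Z.sum(axis=0)
            np.testing.assert_allclose(colsums, 0.0, atol=1e-8)
        tri = design.term("age_speed")
        from gaitpower.fosr import bspline_design
        for margin, cov_name in (("age", "age"), ("speed", "speed")):
            rows = bspline_design(
                covs[cov_name].to_numpy(dtype=float), tri.meta[f"knots_{margin}"]
            ) @ tri.meta[f"Zc_{margin}"]
            np.testing.assert_allclose(rows.sum(axis=0), 0.0, atol=1e-8)

    def test_missing_covariate_record_rejected(self, tiny_instance):
        covs, waves = tiny_instance
        with pytest.raises(ValueError, match="without covariate records"):
            build_design(waves, covs.iloc[:10], ModelSpec(joint="ankle", k_time=4))

    def test_missing_covariate_column_rejected(self, tiny_instance):
        covs, waves = tiny_instance
        with pytest.raises(ValueError, match="missing columns"):
            build_design(waves, covs.drop(columns=["height"]), ModelSpec(joint="ankle", k_time=4))

    def test_nan_covariate_rejected(self, tiny_instance):
        covs, waves = tiny_instance
        bad = covs.copy()
        bad.loc[bad.index[0], "speed"] = np.nan
        with pytest.raises(ValueError, match="missing covariate values"):
            build_design(waves, bad, ModelSpec(joint="ankle", k_time=4))

    def test_constant_covariate_rejected(self, tiny_instance):
        covs, waves = tiny_instance
        bad = covs.copy()
        bad["height"] = 1.7
        with pytest.raises(ValueError, match="rank-deficient"):
            build_design(waves, bad, ModelSpec(joint="ankle", k_time=4))

    def test_too_few_time_points_rejected(self, tiny_instance):
        covs, waves = tiny_instance
        with pytest.raises(ValueError, match="distinct cycle points"):
            build_design(waves, covs, ModelSpec(joint="ankle", k_time=15))


class TestFitOracle:
    def test_fixed_lambda_matches_dense_normal_equations(self, tiny_instance):
        """Product-form fit == brute-force dense penalized least squares."""
        covs, waves = tiny_instance
        spec = ModelSpec(joint="ankle", k_time=4, k_cov=4, k_time3=8)
        names = [
            c.name for c in _REMLProblem(build_design(waves, covs, spec)).components
        ]
        lam = {n: 2.5 for n in names}
        spec = ModelSpec(joint="ankle", k_time=4, k_cov=4, k_time3=8, fixed_lambda=lam)
        design = build_design(waves, covs, spec)
        fitted = fit(design)

        X = design.row_design(design.covariates, include_study=True)
        y = design.Y.ravel()
        S = np.zeros((design.n_cols, design.n_cols))
        for comp in _REMLProblem(design).components:
            sl = comp.term.slice
            S[sl, sl] += 2.5 * comp.S
        beta_dense = np.linalg.solve(X.T @ X + S, X.T @ y)
        assert np.abs(beta_dense - fitted.beta).max() < 1e-8

    def test_constant_outcome_recovered_exactly(self, tiny_instance):
        covs, waves = tiny_instance
        const = [
            PowerWaveform(w.participant_id, w.study_id, w.joint, w.grid, np.full_like(w.values, 1.3))
            for w in waves
        ]
        design = build_design(const, covs, ModelSpec(joint="ankle", k_time=4, k_cov=4))
        fitted = fit(design)
        np.testing.assert_allclose(fitted.intercept_curve(with_se=False), 1.3, atol=1e-6)
        assert fitted.sigma2 < 1e-10

    def test_reml_gradient_matches_numerical(self, ankle_design_small):
        problem = _REMLProblem(ankle_design_small)
        rho = problem.initial_rho() + np.random.default_rng(0).normal(
            0, 1, len(problem.components)
        )
        _, grad = problem.score(rho)
        num = np.empty_like(grad)
        for k in range(len(rho)):
            e = np.zeros_like(rho)
            e[k] = 1e-5
            num[k] = (
                problem.score(rho + e, with_grad=False)
                - problem.score(rho - e, with_grad=False)
            ) / 2e-5
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-6)

    def test_gcv_selection_runs(self, tiny_instance):
        covs, waves = tiny_instance
        spec = ModelSpec(joint="ankle", k_time=4, k_cov=4, selection="GCV-grid")
        fitted = fit(build_design(waves, covs, spec))
        assert fitted.sigma2 > 0
        assert fitted.selection_info["method"] == "GCV-grid"

    def test_penalty_limit_is_nullspace_regression(self, tiny_instance):
        """As every lambda -> inf the fit converges to OLS on the combined
        penalty null space (polynomial components of each smooth plus sex)."""
        covs, waves = tiny_instance
        spec = ModelSpec(joint="ankle", k_time=4, k_cov=4, k_time3=8)
        design = build_design(waves, covs, spec)
        problem = _REMLProblem(design)
        lam = {c.name: 1e8 for c in problem.components}
        spec_inf = ModelSpec(joint="ankle", k_time=4, k_cov=4, k_time3=8, fixed_lambda=lam)
        design_inf = build_design(waves, covs, spec_inf)
        pred_inf = fit(design_inf).fitted_values()

        X = design.row_design(design.covariates, include_study=True)
        blocks = []
        for term in design.terms:
            idx = [c for c in problem.components if c.term.name is term.name]
            if not idx:
                blocks.append((term.slice, np.eye(term.size)))
                continue
            S_sum = sum(c.S for c in idx)
            w, V = np.linalg.eigh(S_sum)
            null = V[:, w < w.max() * 1e-10]
            if null.shape[1]:
                blocks.append((term.slice, null))
        Xn = np.hstack([X[:, sl] @ N for sl, N in blocks])
        beta_n, *_ = np.linalg.lstsq(Xn, design.Y.ravel(), rcond=None)
        pred_null = (Xn @ beta_n).reshape(design.Y.shape)
        assert np.abs(pred_inf - pred_null).max() < 1e-4


class TestPrediction:
    def test_in_sample_identity(self, ankle_fit_small):
        fitted = ankle_fit_small
        pred = fitted.predict(fitted.design.covariates, include_study=True, with_se=False)
        np.testing.assert_allclose(pred["mean"], fitted.fitted_values(), atol=1e-10)

    def test_sex_difference_is_exactly_beta_sex(self, ankle_fit_small):
        fitted = ankle_fit_small
        base = dict(age=40.0, speed=1.2, stride_length=1.3, height=1.7)
        cov = pd.DataFrame([{**base, "sex": "male"}, {**base, "sex": "female"}])
        pred = fitted.predict(cov, include_study=False, with_se=False)
        diff = pred["mean"][0] - pred["mean"][1]
        est = fitted.sex_effect_test().estimate
        np.testing.assert_allclose(diff, est, atol=1e-10)

    def test_population_equals_mean_of_balanced_study_predictions(self, ankle_fit_small):
        """After centring the study coefficients, the population prediction
        equals the average of per-study predictions (linear-algebra identity)."""
        import copy

        fitted = copy.deepcopy(ankle_fit_small)
        term = fitted.design.term("study")
        coef = fitted.beta[term.slice].reshape(term.q, term.K)
        coef -= coef.mean(axis=0, keepdims=True)
        fitted.beta[term.slice] = coef.ravel()
        base = dict(age=30.0, speed=1.1, stride_length=1.25, height=1.68, sex="female")
        pop = fitted.predict(pd.DataFrame([base]), include_study=False, with_se=False)
        per_study = [
            fitted.predict(
                pd.DataFrame([{**base, "study_id": s}]), include_study=True, with_se=False
            )["mean"][0]
            for s in fitted.design.study_levels
        ]
        np.testing.assert_allclose(pop["mean"][0], np.mean(per_study, axis=0), atol=1e-10)

    def test_extrapolation_warns_and_flags(self, ankle_fit_small):
        cov = pd.DataFrame(
            [dict(age=150.0, speed=1.2, stride_length=1.3, height=1.7, sex="male")]
        )
        with pytest.warns(ExtrapolationWarning):
            pred = ankle_fit_small.predict(cov, with_se=False)
        assert pred["extrapolated"][0]

    def test_unknown_study_rejected(self, ankle_fit_small):
        cov = pd.DataFrame(
            [dict(age=40.0, speed=1.2, stride_length=1.3, height=1.7, sex="male",
                  study_id="studyZ")]
        )
        with pytest.raises(ValueError, match="unknown study id"):
            ankle_fit_small.predict(cov, include_study=True)

    def test_save_load_round_trip(self, ankle_fit_small, tmp_path):
        path = ankle_fit_small.save(tmp_path / "fit.npz")
        back = FittedFoSR.load(path)
        cov = pd.DataFrame(
            [dict(age=40.0, speed=1.2, stride_length=1.3, height=1.7, sex="male")]
        )
        p1 = ankle_fit_small.predict(cov, with_se=True)
        p2 = back.predict(cov, with_se=True)
        np.testing.assert_allclose(p1["mean"], p2["mean"], atol=1e-12)
        np.testing.assert_allclose(p1["se"], p2["se"], atol=1e-12)
        t1, t2 = ankle_fit_small.sex_effect_test(), back.sex_effect_test()
        assert t1.tstat == pytest.approx(t2.tstat)


class TestInference:
    def test_sex_t_sign_flips_with_recoding(self, small_dataset):
        cfg, covs, waves, _ = small_dataset
        ready = prepare_waveforms(waves)
        spec = ModelSpec.for_joint("ankle", "compact", maxiter=40)
        base = fit(build_design(ready, covs, spec))
        flipped_covs = covs.copy()
        flipped_covs["sex"] = np.where(covs["sex"] == "male", "female", "male")
        lam = dict(base.lambdas)
        spec_f = ModelSpec.for_joint("ankle", "compact", fixed_lambda=lam)
        spec_b = ModelSpec.for_joint("ankle", "compact", fixed_lambda=lam)
        t_orig = fit(build_design(ready, covs, spec_b)).sex_effect_test().tstat
        t_flip = fit(build_design(ready, flipped_covs, spec_f)).sex_effect_test().tstat
        assert t_flip == pytest.approx(-t_orig, rel=1e-6)

    def test_posterior_draw_mean_near_estimate(self, ankle_fit_small):
        draws = ankle_fit_small.posterior_draws(50_000, seed=5)
        se = np.sqrt(np.diag(ankle_fit_small.Vb))
        mc_se = se / np.sqrt(50_000)
        err = np.abs(draws.mean(axis=0) - ankle_fit_small.beta)
        assert (err <= 4.0 * mc_se + 1e-12).mean() > 0.99

    def test_zero_draws_empty(self, ankle_fit_small):
        draws = ankle_fit_small.posterior_draws(0, seed=1)
        assert draws.shape == (0, ankle_fit_small.beta.size)

    def test_draws_deterministic_in_seed(self, ankle_fit_small):
        d1 = ankle_fit_small.posterior_draws(50, seed=9)
        d2 = ankle_fit_small.posterior_draws(50, seed=9)
        np.testing.assert_array_equal(d1, d2)

    def test_posterior_covariance_psd_and_symmetric(self, ankle_fit_small):
        Vb = ankle_fit_small.Vb
        np.testing.assert_allclose(Vb, Vb.T, atol=1e-12)
        w = np.linalg.eigvalsh(Vb)
        assert w.min() > -1e-10 * w.max()

    def test_smoothing_uncertainty_inflates_variance(self, ankle_fit_small):
        Vc = ankle_fit_small.smoothing_uncertainty_covariance()
        extra = np.diag(Vc) - np.diag(ankle_fit_small.Vb)
        assert extra.min() > -1e-12
        assert extra.max() > 0

    def test_study_curve_shrinkage(self, ankle_fit_small):
        """Penalized study curves have smaller total L2 norm than raw
        per-study mean deviations (random-effect shrinkage)."""
        fitted = ankle_fit_small
        design = fitted.design
        est = fitted.study_curves()
        est_norm = sum(np.sum(c**2) for c in est.values())
        overall = design.Y.mean(axis=0)
        raw_norm = 0.0
        for level in design.study_levels:
            mask = (design.covariates["study_id"] == level).to_numpy()
            raw_norm += np.sum((design.Y[mask].mean(axis=0) - overall) ** 2)
        assert est_norm < raw_norm

    def test_term_surface_export_round_trips(self, ankle_fit_small, tmp_path):
        import pandas as pd

        paths = ankle_fit_small.export_term_surfaces(tmp_path, n_points=10)
        assert set(paths) == {"intercept", "age", "speed", "stride_length", "height"}
        df = pd.read_csv(paths["speed"])
        surf = ankle_fit_small.evaluate_term("speed", df["speed"].to_numpy())
        np.testing.assert_allclose(df.drop(columns="speed").to_numpy(), surf, atol=1e-10)

    def test_sum_to_zero_constraint_holds_on_fit(self, ankle_fit_small):
        """Fitted smooths average to zero over observed covariate values."""
        fitted = ankle_fit_small
        for name in ("age", "speed", "stride_length", "height"):
            x = fitted.design.covariates[name].to_numpy(dtype=float)
            surf = fitted.evaluate_term(name, x)
            np.testing.assert_allclose(surf.mean(axis=0), 0.0, atol=1e-8)
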