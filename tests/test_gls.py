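"""Heteroscedastic feasible GLS: closed-form equivalence, statsmodels
cross-check, one-sided testing, calibration and recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import partolab as pl
from partolab.gls import COEF_NAMES
from _oracles import gls_closed_form, t_cdf_numeric

GROUP_SIZES = [8, 7, 6, 8]
INDICATORS = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (D_DRG, D_Uterus)


def study_design():
    X = np.array(
        [[d, u] for (d, u), n in zip(INDICATORS, GROUP_SIZES) for _ in range(n)],
        dtype=float,
    )
    groups = np.array([k for k, n in enumerate(GROUP_SIZES) for _ in range(n)])
    return X, groups


def summaries_frame(y):
    X, groups = study_design()
    return pd.DataFrame(
        {
            "animal_id": [f"a{i:02d}" for i in range(len(y))],
            "group": [f"g{k}" for k in groups],
            "d_drg": X[:, 0].astype(int),
            "d_uterus": X[:, 1].astype(int),
            "mean_peak_pressure": y,
        }
    )


class TestBuildDesign:
    def test_study_design_shape_and_df(self, rng):
        y = rng.normal(100, 10, 29)
        design = pl.build_design(summaries_frame(y))
        assert design.X.shape == (29, 3)
        assert np.linalg.matrix_rank(design.X) == 3
        assert np.all(design.X[:, 0] == 1)
        fit = pl.fit_gls(design)
        assert fit.df == 26

    def test_four_groups_two_each(self, rng):
        rows = []
        for k, (d, u) in enumerate(INDICATORS):
            for j in range(2):
                rows.append(
                    {"animal_id": f"g{k}a{j}", "group": f"g{k}", "d_drg": d,
                     "d_uterus": u, "mean_peak_pressure": rng.normal(50, 5)}
                )
        design = pl.build_design(pd.DataFrame(rows))
        assert design.X.shape == (8, 3)
        assert np.linalg.matrix_rank(design.X) == 3

    def test_control_only_cohort_rejected(self, rng):
        rows = [
            {"animal_id": f"a{j}", "group": "ctrl", "d_drg": 0, "d_uterus": 0,
             "mean_peak_pressure": rng.normal(50, 5)}
            for j in range(6)
        ]
        with pytest.raises(ValueError):
            pl.fit_gls(pl.build_design(pd.DataFrame(rows)))

    def test_undefined_outcome_rejected(self):
        df = summaries_frame(np.full(29, 50.0))
        df.loc[3, "mean_peak_pressure"] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            pl.build_design(df)

    def test_single_animal_group_rejected(self, rng):
        df = summaries_frame(rng.normal(100, 10, 29))
        df = df[df["group"].ne("g2") | (df["animal_id"] == "a15")]
        with pytest.raises(ValueError, match="< 2 animals"):
            pl.build_design(df)


class TestEstimator:
    def test_known_omega_matches_closed_form(self, rng):
        # 100 random designs: fixed Omega reduces FGLS to the textbook
        # weighted solve, agreeing with an explicit dense-inverse oracle
        for _ in range(100):
            n, k = int(rng.integers(8, 40)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            omega = rng.uniform(0.2, 5.0, n)
            groups = rng.integers(0, 3, n)
            while np.bincount(groups, minlength=3).min() < 2:
                groups = rng.integers(0, 3, n)
            est = pl.HeteroscedasticGLS().fit(X, y, groups=groups, omega=omega)
            ref = gls_closed_form(np.column_stack([np.ones(n), X]), y, omega)
            assert np.max(np.abs(est.params_ - ref)) < 1e-10

    def test_matches_statsmodels_gls(self, rng):
        import statsmodels.api as sm

        X, groups = study_design()
        y = rng.normal(100, 10, 29)
        omega = rng.uniform(0.5, 4.0, 29)
        est = pl.HeteroscedasticGLS().fit(X, y, groups=groups, omega=omega)
        Xd = sm.add_constant(X)
        ref = sm.GLS(y, Xd, sigma=omega).fit()
        np.testing.assert_allclose(est.params_, ref.params, atol=1e-10)
        # statsmodels treats sigma as known only up to a proportionality
        # constant and rescales by its estimated scale
        np.testing.assert_allclose(
            est.bse_ * np.sqrt(ref.scale), ref.bse, rtol=1e-8
        )

    def test_homoscedastic_fixed_omega_reduces_to_ols(self, rng):
        X, groups = study_design()
        y = rng.normal(100, 10, 29)
        est = pl.HeteroscedasticGLS().fit(X, y, groups=groups, omega=np.ones(29))
        Xd = np.column_stack([np.ones(29), X])
        ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.max(np.abs(est.params_ - ols)) < 1e-10

    def test_two_group_hand_example(self):
        # group A outcomes {1,3} (dummy 0), group B {10,10} (dummy 1):
        # balanced one-dummy design fits group means whatever the weights
        est = pl.HeteroscedasticGLS().fit(
            np.array([[0.0], [0.0], [1.0], [1.0]]), np.array([1.0, 3.0, 10.0, 10.0])
        )
        assert est.intercept_ == pytest.approx(2.0, abs=1e-6)
        assert est.coef_[0] == pytest.approx(8.0, abs=1e-6)

    def test_zero_effect_gives_half_p(self):
        # equal group means make the dummy coefficient exactly zero,
        # so the lower-tail p sits at the t-distribution's median
        est = pl.HeteroscedasticGLS().fit(
            np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]]),
            np.array([10.0, 12.0, 14.0, 10.0, 12.0, 14.0]),
        )
        assert est.params_[1] == pytest.approx(0.0, abs=1e-12)
        assert est.p_values_[1] == pytest.approx(0.5, abs=1e-9)

    def test_rank_deficient_design_rejected(self, rng):
        X = np.ones((10, 2))  # duplicate of the intercept
        with pytest.raises(ValueError):
            pl.HeteroscedasticGLS().fit(X, rng.normal(size=10),
                                        groups=np.repeat([0, 1], 5))

    def test_non_convergence_reported_not_raised(self, rng):
        X, groups = study_design()
        sds = np.array([5.0, 20.0, 40.0, 60.0])[groups]
        y = 100 + sds * rng.standard_normal(29)
        est = pl.HeteroscedasticGLS(max_iter=1).fit(X, y, groups=groups)
        assert est.n_iter_ == 1
        assert est.converged_ is False

    def test_convergence_is_stable(self, rng):
        X, groups = study_design()
        y = 100 + rng.standard_normal(29) * np.array([5, 10, 20, 30])[groups]
        est = pl.HeteroscedasticGLS(tol=1e-10).fit(X, y, groups=groups)
        assert est.converged_
        # refitting from the converged variances changes nothing material
        again = pl.HeteroscedasticGLS().fit(X, y, groups=groups,
                                            omega=est.omega_diag_)
        assert np.max(np.abs(again.params_ - est.params_)) < 1e-6

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(hst.floats(0.01, 1e4), hst.integers(0, 2**31 - 1))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        X, groups = study_design()
        y = 100 + rng.standard_normal(29) * np.array([5, 10, 20, 30])[groups]
        a = pl.HeteroscedasticGLS().fit(X, y, groups=groups)
        b = pl.HeteroscedasticGLS().fit(X, c * y, groups=groups)
        np.testing.assert_allclose(b.params_, c * a.params_, rtol=1e-6)
        np.testing.assert_allclose(b.bse_, c * a.bse_, rtol=1e-6)
        np.testing.assert_allclose(b.t_values_, a.t_values_, rtol=1e-6)
        np.testing.assert_allclose(b.p_values_, a.p_values_, rtol=1e-5)

    def test_balanced_homoscedastic_fgls_approaches_ols(self, rng):
        # with homoscedastic truth the estimated group variances equalize
        # as groups grow, so FGLS and OLS estimates converge to each other
        def mean_gap(n_per_group, reps=20):
            gaps = []
            for _ in range(reps):
                X = np.array(
                    [[d, u] for (d, u) in INDICATORS for _ in range(n_per_group)],
                    float,
                )
                groups = np.repeat(np.arange(4), n_per_group)
                y = 100 + 10 * rng.standard_normal(4 * n_per_group)
                fgls = pl.HeteroscedasticGLS().fit(X, y, groups=groups)
                Xd = np.column_stack([np.ones(len(y)), X])
                ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
                gaps.append(np.max(np.abs(fgls.params_ - ols)))
            return np.mean(gaps)

        small, large = mean_gap(8), mean_gap(200)
        assert large < small
        assert large < 0.2


class TestOneSidedTest:
    def test_lower_tail_matches_numerical_integration(self):
        fit = pl.GLSFit(
            beta=np.array([100.0, -20.0, -10.0]), se=np.array([5.0, 10.0, 5.0]),
            sigma2_by_group={}, omega_diag=np.ones(29),
            t_stats=np.array([20.0, -2.0, -2.0]),
            p_one_sided=np.zeros(3), df=26, converged=True, n_iter=3,
        )
        t, p = pl.one_sided_test(fit, "beta_drg")
        assert t == -2.0
        assert p == pytest.approx(t_cdf_numeric(-2.0, 26), abs=1e-8)
        assert p == pytest.approx(0.0280, abs=5e-5)

    def test_unknown_coefficient_rejected(self):
        fit = pl.GLSFit(
            beta=np.zeros(3), se=np.ones(3), sigma2_by_group={},
            omega_diag=np.ones(5), t_stats=np.zeros(3),
            p_one_sided=np.full(3, 0.5), df=2, converged=True, n_iter=1,
        )
        with pytest.raises(ValueError):
            pl.one_sided_test(fit, "beta_nonsense")

    def test_coef_names_order(self):
        assert COEF_NAMES == ("intercept", "beta_drg", "beta_uterus")


class TestCalibrationAndRecovery:
    def test_parameter_recovery_under_study_design(self, rng):
        # 200 cohorts drawn from the fitted model itself (group sizes
        # 8/7/6/8, heteroscedastic SDs): mean estimates land within
        # 2 Monte-Carlo SE of the generating coefficients
        X, groups = study_design()
        Xd = np.column_stack([np.ones(29), X])
        true = np.array([100.0, -47.11, -16.01])
        sds = np.array([10.0, 25.0, 30.0, 35.0])[groups]
        est = np.array([
            pl.HeteroscedasticGLS()
            .fit(X, Xd @ true + sds * rng.standard_normal(29), groups=groups)
            .params_
            for _ in range(200)
        ])
        mean = est.mean(axis=0)
        mcse = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(mean - true) < 2 * mcse + 1e-12)

    def test_one_sided_type_one_error_in_band(self, rng):
        # exchangeable null at the study's group sizes
        X, groups = study_design()
        rej_drg = rej_ut = 0
        reps = 1000
        for _ in range(reps):
            y = 100 + 20 * rng.standard_normal(29)
            est = pl.HeteroscedasticGLS().fit(X, y, groups=groups)
            rej_drg += est.p_values_[1] < 0.05
            rej_ut += est.p_values_[2] < 0.05
        assert 0.03 <= rej_drg / reps <= 0.07
        assert 0.03 <= rej_ut / reps <= 0.07
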