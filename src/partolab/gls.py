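"""Heteroscedastic generalized least squares for knockout contrasts.

The per-animal outcome P_i (mean peak pressure in the 2-hour post-onset
window, mmHg) is modeled as

    P_i = beta_0 + beta_DRG * D_DRG,i + beta_Uterus * D_Uterus,i + eps_i,
    eps_i ~ N(0, sigma^2_{g(i)}),

where D_DRG and D_Uterus indicate tissue-specific PIEZO1/2 deletion and
g(i) is the animal's treatment group. Errors are independent but their
variance differs by group (viral knockouts are more variable than
germline Cre lines), so estimation is by feasible GLS with a diagonal
covariance Omega = diag(sigma^2_{g(i)}):

    beta_hat = (X' Omega^-1 X)^-1 X' Omega^-1 P.

Group variances are estimated from within-group residual sums of squares
(denominator n_g - variance_ddof, default Bessel-corrected n_g - 1) and
the weighted solve is iterated to convergence; a one-step variant stops
after the first reweighting. Decreasing-effect hypotheses
(H0: beta >= 0 vs H1: beta < 0) are tested with t = beta_hat / SE using a
t reference with df = n - p, where p counts only the 3 mean-model
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "HeteroscedasticGLS",
    "DesignMatrix",
    "GLSFit",
    "build_design",
    "fit_gls",
    "one_sided_test",
]

COEF_NAMES = ("intercept", "beta_drg", "beta_uterus")


class HeteroscedasticGLS(BaseEstimator, RegressorMixin):
    """Feasible GLS with group-wise error variances.

    Parameters
    ----------
    tol : float, default 1e-8
        Convergence tolerance on the maximum relative change in beta
        between reweighting iterations.
    max_iter : int, default 100
        Maximum number of reweighting iterations.
    one_step : bool, default False
        Stop after a single reweighted solve (variances from OLS
        residuals) instead of iterating to convergence.
    variance_ddof : int, default 1
        Delta degrees of freedom in the within-group variance estimator
        sigma_g^2 = RSS_g / (n_g - variance_ddof). The Bessel-corrected
        default keeps the one-sided test's small-sample type-I error close
        to nominal; 0 gives the plain mean of squared residuals.
    alternative : {"less", "two-sided"}, default "less"
        "less" reports the lower-tail probability P(T_{n-p} <= t) for every
        coefficient (the decreasing-effect hypothesis), even when the
        estimate is positive. "two-sided" doubles the smaller tail.
    fit_intercept : bool, default True

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Slope estimates (mmHg), excluding the intercept.
    intercept_ : float
    params_, bse_, t_values_, p_values_ : ndarray, full coefficient vector
        (intercept first when fitted) with standard errors, t statistics
        and p-values per ``alternative``.
    group_variances_ : dict mapping group label -> sigma_g^2.
    omega_diag_ : ndarray, per-observation error variance.
    df_resid_ : int, n - p with p = number of mean-model coefficients.
    n_iter_ : int, converged_ : bool.
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 100,
        one_step: bool = False,
        variance_ddof: int = 1,
        alternative: str = "less",
        fit_intercept: bool = True,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.one_step = one_step
        self.variance_ddof = variance_ddof
        self.alternative = alternative
        self.fit_intercept = fit_intercept

    # -- internal -----------------------------------------------------
    def _validate(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per outcome")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        if self.alternative not in ("less", "two-sided"):
            raise ValueError("alternative must be 'less' or 'two-sided'")
        if groups is None:
            # distinct predictor rows define the variance groups
            _, group_idx = np.unique(X, axis=0, return_inverse=True)
            labels = np.array([f"g{k}" for k in range(group_idx.max() + 1)])
        else:
            labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
        counts = np.bincount(group_idx)
        small = [str(labels[k]) for k in np.flatnonzero(counts < 2)]
        if small:
            raise ValueError(
                f"group(s) {small} have fewer than 2 members; "
                "group variance is inestimable"
            )
        if self.variance_ddof >= counts.min():
            raise ValueError("variance_ddof must be smaller than every group size")
        return X, y, labels, group_idx

    def fit(self, X, y, groups=None, omega=None):
        """Fit the model.

        Parameters
        ----------
        X : array (n, k) of knockout indicators / predictors.
        y : array (n,) of outcomes (mmHg).
        groups : array (n,) of variance-group labels. Defaults to grouping
            by distinct predictor rows.
        omega : optional array (n,) of known per-observation error
            variances. When given, a single exact GLS solve is performed
            (no variance estimation).
        """
        X, y, labels, gidx = self._validate(X, y, groups)
        n = len(y)
        Xd = np.column_stack([np.ones(n), X]) if self.fit_intercept else X.copy()
        p = Xd.shape[1]
        if np.linalg.matrix_rank(Xd) < p:
            raise ValueError("design matrix is rank deficient")
        if n <= p:
            raise ValueError("need more observations than coefficients")

        scale = float(np.mean(y * y)) + 1.0  # variance floor for saturated groups

        def weighted_solve(w):
            # beta solves the weighted normal equations X' W X beta = X' W y;
            # computed via QR on the sqrt-weighted design for stability when
            # weights span many orders of magnitude
            sw = np.sqrt(w)
            beta, _, rank, _ = np.linalg.lstsq(Xd * sw[:, None], y * sw, rcond=None)
            if rank < p:
                raise ValueError("singular weighted normal equations")
            XtWX = (Xd.T * w) @ Xd
            return beta, XtWX

        if omega is not None:
            omega = np.asarray(omega, dtype=float)
            if omega.shape != (n,) or np.any(omega <= 0):
                raise ValueError("omega must be n positive variances")
            beta, XtWX = weighted_solve(1.0 / omega)
            self.converged_, self.n_iter_ = True, 1
            resid = y - Xd @ beta
            s2 = np.array(
                [float(np.mean(omega[gidx == k])) for k in range(len(labels))]
            )
            self.omega_diag_ = omega.copy()
        else:
            beta = np.linalg.lstsq(Xd, y, rcond=None)[0]  # OLS start
            self.converged_ = False
            n_iter = 0
            for n_iter in range(1, self.max_iter + 1):
                resid = y - Xd @ beta
                s2 = np.array(
                    [
                        np.sum(resid[gidx == k] ** 2)
                        / (np.sum(gidx == k) - self.variance_ddof)
                        for k in range(len(labels))
                    ]
                )
                s2 = np.maximum(s2, 1e-12 * scale)
                new_beta, XtWX = weighted_solve(1.0 / s2[gidx])
                rel_change = np.max(
                    np.abs(new_beta - beta) / np.maximum(np.abs(beta), 1e-300)
                )
                beta = new_beta
                if rel_change < self.tol or self.one_step:
                    self.converged_ = rel_change < self.tol or self.one_step
                    break
            self.n_iter_ = n_iter
            resid = y - Xd @ beta
            self.omega_diag_ = s2[gidx]

        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.diag(cov))
        df = n - p
        t = beta / se
        if self.alternative == "less":
            pvals = _st.t.cdf(t, df)
        else:
            pvals = 2.0 * _st.t.sf(np.abs(t), df)

        self.params_ = beta
        self.bse_ = se
        self.t_values_ = t
        self.p_values_ = pvals
        self.df_resid_ = int(df)
        self.group_labels_ = labels
        self.group_variances_ = {str(l): float(v) for l, v in zip(labels, s2)}
        self.cov_params_ = cov
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


# ---------------------------------------------------------------------------
# domain containers and functional wrappers


@dataclass
class DesignMatrix:
    """Design for the knockout contrast model: X = [1, D_DRG, D_Uterus]."""

    X: np.ndarray  # n x 3, first column ones
    y: np.ndarray  # mean peak pressures, mmHg
    group_index: np.ndarray  # n integers
    group_labels: np.ndarray
    animal_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class GLSFit:
    """Result of a feasible-GLS fit of the knockout contrast model."""

    beta: np.ndarray  # (beta0, beta_DRG, beta_Uterus), mmHg
    se: np.ndarray
    sigma2_by_group: dict
    omega_diag: np.ndarray
    t_stats: np.ndarray
    p_one_sided: np.ndarray
    df: int
    converged: bool
    n_iter: int
    coef_names: tuple = COEF_NAMES


def build_design(summaries) -> DesignMatrix:
    """Assemble the GLS design from animal summaries.

    Accepts a list of :class:`~partolab.peaks.AnimalSummary` or a DataFrame
    with columns animal_id, group, d_drg, d_uterus, mean_peak_pressure.
    Rows are ordered by animal_id; every group needs >= 2 animals with a
    defined outcome.
    """
    import pandas as pd

    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame([s.to_row() for s in summaries])
    df = summaries.sort_values("animal_id").reset_index(drop=True)
    if df["mean_peak_pressure"].isna().any():
        bad = df.loc[df["mean_peak_pressure"].isna(), "animal_id"].tolist()
        raise ValueError(
            f"animals {bad} have undefined mean peak pressure; exclude them "
            "explicitly before building the design"
        )
    labels, gidx = np.unique(df["group"].to_numpy(), return_inverse=True)
    counts = np.bincount(gidx)
    if counts.min() < 2:
        small = [str(labels[k]) for k in np.flatnonzero(counts < 2)]
        raise ValueError(f"group(s) {small} have < 2 animals; variance inestimable")
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["d_drg"].to_numpy(dtype=float),
            df["d_uterus"].to_numpy(dtype=float),
        ]
    )
    return DesignMatrix(
        X=X,
        y=df["mean_peak_pressure"].to_numpy(dtype=float),
        group_index=gidx,
        group_labels=labels,
        animal_ids=df["animal_id"].tolist(),
    )


def fit_gls(
    design: DesignMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
    one_step: bool = False,
    variance_ddof: int = 1,
    omega=None,
) -> GLSFit:
    """Functional wrapper over :class:`HeteroscedasticGLS` for a prebuilt
    knockout-contrast design."""
    est = HeteroscedasticGLS(
        tol=tol,
        max_iter=max_iter,
        one_step=one_step,
        variance_ddof=variance_ddof,
        alternative="less",
        fit_intercept=False,  # design already carries the intercept column
    )
    est.fit(
        design.X,
        design.y,
        groups=design.group_labels[design.group_index],
        omega=omega,
    )
    return GLSFit(
        beta=est.params_,
        se=est.bse_,
        sigma2_by_group=est.group_variances_,
        omega_diag=est.omega_diag_,
        t_stats=est.t_values_,
        p_one_sided=est.p_values_,
        df=est.df_resid_,
        converged=est.converged_,
        n_iter=est.n_iter_,
    )


def one_sided_test(fit: GLSFit, coefficient: str) -> tuple[float, float]:
    """Lower-tail t test (H0: beta >= 0 vs H1: beta < 0) for one coefficient.

    Returns (t, p) with p = P(T_{n-p} <= t).
    """
    if coefficient not in fit.coef_names:
        raise ValueError(f"coefficient must be one of {fit.coef_names}")
    j = fit.coef_names.index(coefficient)
    t = float(fit.t_stats[j])
    return t, float(_st.t.cdf(t, fit.df))
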