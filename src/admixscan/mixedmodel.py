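"""Logistic mixed models with a GRM random effect, fit by PQL with AI-REML.

The null model is

    logit P(y_i = 1) = x_i' beta + b_i,   b ~ N(0, sigma2_g * Phi)

with Phi the (ancestry-adjusted) GRM.  Fitting follows the standard
penalized-quasi-likelihood scheme: iterate the working response
Ytilde = eta + (y - mu)/W against the linear mixed model
Ytilde ~ N(X beta, Sigma), Sigma = W^{-1} + sigma2_g Phi, updating sigma2_g
by average-information REML.  Score tests of additional fixed effects need
only the converged projection P = Sigma^{-1} - Sigma^{-1} X (X'Sigma^{-1}X)^{-1}
X' Sigma^{-1}, which the fit object exposes without refitting; at
sigma2_g = 0 every test reduces exactly to its plain logistic counterpart.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2, norm

logger = logging.getLogger(__name__)

_MU_EPS = 1e-6  # separation guard on fitted probabilities


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class ScoreTestResult:
    stat: float
    df: int
    p: float
    degenerate: bool = False


@dataclass
class EffectEstimate:
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_wald: float


@dataclass
class NullModelFit:
    """Converged null fit plus projection quantities for score tests."""

    beta: np.ndarray
    sigma2_g: float
    mu: np.ndarray
    eta: np.ndarray
    X: np.ndarray
    y: np.ndarray
    ytilde: np.ndarray
    weights: np.ndarray
    cov_beta: np.ndarray  # (X' Sigma^-1 X)^-1
    converged: bool = True
    n_iter: int = 0
    covariate_names: list = field(default_factory=list)
    _cho: tuple = None
    _SiX: np.ndarray = None
    _PY: np.ndarray = None
    _reml: float = np.nan

    def project(self, M: np.ndarray) -> np.ndarray:
        """Apply the REML projection P to columns of M."""
        M = np.atleast_2d(M.T).T if M.ndim == 1 else M
        SiM = cho_solve(self._cho, M)
        XtSiM = self._SiX.T @ M
        return SiM - self._SiX @ np.linalg.solve(self.X.T @ self._SiX, XtSiM)

    @property
    def py(self) -> np.ndarray:
        """P @ ytilde; equals the null working-scale score residuals."""
        return self._PY

    def score_test(self, S: np.ndarray) -> ScoreTestResult:
        """Score test of the fixed-effect columns of S against the null.

        Rank-deficient or zero-variance score covariance reduces the degrees
        of freedom; a fully degenerate test returns p = 1 with df 0.
        """
        S = S[:, None] if S.ndim == 1 else S
        U = S.T @ self._PY
        V = S.T @ self.project(S)
        V = 0.5 * (V + V.T)
        w, vec = np.linalg.eigh(V)
        tol = max(V.shape[0], 1) * np.finfo(float).eps * max(w.max(), 0.0)
        keep = w > max(tol, 1e-12)
        df = int(keep.sum())
        if df == 0:
            return ScoreTestResult(stat=0.0, df=0, p=1.0, degenerate=True)
        Uw = vec[:, keep].T @ U
        stat = float(Uw @ (Uw / w[keep]))
        return ScoreTestResult(
            stat=stat, df=df, p=float(chi2.sf(stat, df)), degenerate=df < S.shape[1]
        )

    def reml_criterion(self) -> float:
        """Restricted log-quasi-likelihood at the stored parameters."""
        return self._reml


def _irls_logistic(y: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Plain logistic IRLS; the sigma2_g = 0 reduction and initializer."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    return beta


def fit_null(
    y: np.ndarray,
    X: np.ndarray,
    grm: np.ndarray | None = None,
    covariate_names: list | None = None,
    estimate_variance: bool = True,
    sigma2_init: float = 0.1,
    sigma2_fixed: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    check_psd: bool = True,
) -> NullModelFit:
    """Fit the logistic mixed-model null.

    ``X`` must include the intercept column and be full rank.  ``grm`` may be
    None (equivalent to sigma2_fixed = 0).  Set ``sigma2_fixed`` to constrain
    the variance component (0 reduces the model to plain logistic IRLS).
    Convergence: relative parameter change < tol, else a warning at
    ``max_iter``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("covariate matrix is rank deficient")
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(p)]
    if grm is None:
        sigma2_fixed = 0.0
        Phi = np.zeros((n, n))
    else:
        Phi = np.asarray(grm, dtype=float)
        if Phi.shape != (n, n):
            raise ValueError("GRM dimension mismatch")
        if check_psd:
            try:
                cho_factor(Phi + 1e-6 * np.eye(n))
            except np.linalg.LinAlgError as e:
                raise ValueError("GRM is not positive semi-definite") from e

    beta = _irls_logistic(y, X)
    sigma2 = float(sigma2_fixed) if sigma2_fixed is not None else float(sigma2_init)
    estimate = estimate_variance and sigma2_fixed is None
    sigma2_converged = False
    eta = X @ beta
    b = np.zeros(n)
    separation_warned = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu_raw = expit(eta)
        if not separation_warned and ((mu_raw < _MU_EPS) | (mu_raw > 1 - _MU_EPS)).any():
            warnings.warn("fitted probabilities near 0/1; working weights bounded",
                          ConvergenceWarning)
            separation_warned = True
        mu = np.clip(mu_raw, _MU_EPS, 1 - _MU_EPS)
        W = mu * (1 - mu)
        ytilde = eta + (y - mu) / W
        Sigma = sigma2 * Phi + np.diag(1.0 / W)
        cho = cho_factor(Sigma, lower=True)
        SiX = cho_solve(cho, X)
        XtSiX = X.T @ SiX
        beta_new = np.linalg.solve(XtSiX, SiX.T @ ytilde)
        resid = ytilde - X @ beta_new
        Sir = cho_solve(cho, resid)
        PY = Sir - SiX @ np.linalg.solve(XtSiX, SiX.T @ resid)
        sigma2_new = sigma2
        if estimate and not sigma2_converged:
            APY = Phi @ PY
            PAPY = cho_solve(cho, APY) - SiX @ np.linalg.solve(XtSiX, SiX.T @ APY)
            Si = cho_solve(cho, np.eye(n))
            tr_SiPhi = float(np.sum(Si * Phi))
            tr_corr = float(np.trace(np.linalg.solve(XtSiX, SiX.T @ Phi @ SiX)))
            score = 0.5 * (float(PY @ APY) - (tr_SiPhi - tr_corr))
            ai = 0.5 * float(APY @ PAPY)
            if ai > 1e-12:
                sigma2_new = sigma2 + score / ai
                if sigma2_new < 0:
                    sigma2_new = 0.0  # project to the boundary
            else:
                sigma2_new = max(sigma2, 0.0)
            # freeze the variance component once its updates stall; the
            # remaining iterations only polish beta and are much cheaper
            if abs(sigma2_new - sigma2) < tol * (1 + abs(sigma2)):
                sigma2_converged = True
        b = sigma2_new * (Phi @ PY)
        eta = X @ beta_new + b
        rel = np.max(np.abs(beta_new - beta)) / (1 + np.max(np.abs(beta)))
        rel = max(rel, abs(sigma2_new - sigma2) / (1 + abs(sigma2)))
        beta, sigma2 = beta_new, sigma2_new
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"PQL did not converge in {max_iter} iterations", ConvergenceWarning)

    # final projection state at the converged parameters
    mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
    W = mu * (1 - mu)
    ytilde = eta + (y - mu) / W
    Sigma = sigma2 * Phi + np.diag(1.0 / W)
    cho = cho_factor(Sigma, lower=True)
    SiX = cho_solve(cho, X)
    XtSiX = X.T @ SiX
    beta = np.linalg.solve(XtSiX, SiX.T @ ytilde)
    resid = ytilde - X @ beta
    PY = cho_solve(cho, resid) - SiX @ np.linalg.solve(XtSiX, SiX.T @ resid)
    logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    sign, logdet_xsx = np.linalg.slogdet(XtSiX)
    reml = -0.5 * (logdet_sigma + logdet_xsx + float(resid @ PY))
    return NullModelFit(
        beta=beta,
        sigma2_g=float(max(sigma2, 0.0)),
        mu=mu,
        eta=eta,
        X=X,
        y=y,
        ytilde=ytilde,
        weights=W,
        cov_beta=np.linalg.inv(XtSiX),
        converged=converged,
        n_iter=it,
        covariate_names=list(covariate_names),
        _cho=cho,
        _SiX=SiX,
        _PY=PY,
        _reml=reml,
    )


def estimate_effect(
    y: np.ndarray,
    X: np.ndarray,
    dosage: np.ndarray,
    grm: np.ndarray | None = None,
    alpha: float = 0.05,
    **fit_kwargs,
) -> EffectEstimate:
    """Wald effect estimate (log-odds scale) from a mixed-model refit.

    The dosage is appended to the fixed effects and the full model refit
    (including the variance component); the CI is Wald on the log-odds
    scale, exponentiated to an odds-ratio interval.
    """
    dosage = np.asarray(dosage, dtype=float)
    if np.std(dosage) == 0:
        raise ValueError("dosage is constant; effect not estimable")
    Xa = np.column_stack([X, dosage])
    fit = fit_null(y, Xa, grm, check_psd=False, **fit_kwargs)
    b = float(fit.beta[-1])
    se = float(np.sqrt(fit.cov_beta[-1, -1]))
    zq = norm.ppf(1 - alpha / 2)
    z = b / se
    return EffectEstimate(
        beta=b,
        se=se,
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - zq * se)),
        ci_high=float(np.exp(b + zq * se)),
        p_wald=float(2 * norm.sf(abs(z))),
    )


def build_design(
    covariates,
    global_props: np.ndarray | None = None,
    include_age_sex: bool = False,
) -> tuple[np.ndarray, list]:
    """Null-model design: intercept, global ancestry (AFR, NAM), APOE dosages.

    The EUR proportion is omitted (proportions sum to 1).  Age and sex are
    off by default and enabled for sensitivity analyses.
    """
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    if global_props is not None:
        cols += [global_props[:, 0], global_props[:, 2]]
        names += ["prop_afr", "prop_nam"]
    for c in ("apoe_e2", "apoe_e4"):
        if c in covariates:
            cols.append(np.asarray(covariates[c], dtype=float))
            names.append(c)
    if include_age_sex:
        for c in ("age", "sex"):
            if c in covariates:
                cols.append(np.asarray(covariates[c], dtype=float))
                names.append(c)
    return np.column_stack(cols), names
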