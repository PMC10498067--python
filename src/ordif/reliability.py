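"""Reliability coefficients and one-factor CFA fit indices.

Covers the scale-level summary usually reported next to a DIF analysis:
Cronbach's alpha, Guttman's lambda-6, McDonald's omega from a one-factor
confirmatory model, and the normal-theory ML fit indices (model and
baseline chi-square, RMSEA, SRMR, CFI, TLI), computed overall and per
demographic subgroup.  Items are treated as continuous (Pearson
covariances), the convention behind standard ML indices for Likert
scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FitIndices",
    "OneFactorCFA",
    "cronbach_alpha",
    "guttman_lambda6",
    "fit_one_factor_cfa",
    "subgroup_indices",
]


@dataclass
class FitIndices:
    """Reliability and one-factor fit summary for one item set."""

    cronbach_alpha: float
    guttman_lambda6: float
    omega: float
    rmsea: float
    srmr: float
    cfi: float
    tli: float
    cfi_clipped: float
    tli_clipped: float
    model_chi2: float
    model_df: int
    baseline_chi2: float
    baseline_df: int
    n_used: int
    converged: bool = True
    heywood: bool = False
    saturated: bool = False

    def to_row(self) -> dict:
        return {
            "alpha": self.cronbach_alpha,
            "lambda6": self.guttman_lambda6,
            "omega": self.omega,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
            "cfi": self.cfi_clipped,
            "tli": self.tli_clipped,
            "n": self.n_used,
        }


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an n x J matrix")
    if np.isnan(X).any():
        X = X[~np.isnan(X).any(axis=1)]
    return X


def cronbach_alpha(X) -> float:
    """alpha = (J/(J-1)) * (1 - sum var(item) / var(total))."""
    X = _as_matrix(X)
    n, J = X.shape
    if J < 2:
        raise ValueError("alpha needs at least 2 items")
    item_var = X.var(axis=0, ddof=1)
    if np.any(item_var <= 0):
        raise ValueError("zero-variance item")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    return J / (J - 1) * (1.0 - item_var.sum() / total_var)


def guttman_lambda6(X, ridge: float = 0.0) -> float:
    """lambda6 from squared multiple correlations, on the covariance scale.

    The residual variance of item j given the other items is
    ``1 / (S^-1)_jj`` for covariance matrix S; lambda6 is one minus the
    summed residual variances over the total-score variance.  A singular
    item covariance (e.g. a duplicated item) raises; pass a small
    ``ridge`` to regularise if that is acceptable.
    """
    X = _as_matrix(X)
    J = X.shape[1]
    S = np.cov(X, rowvar=False)
    S = S + ridge * np.eye(J)
    cond = np.linalg.cond(S)
    if cond > 1e12:
        raise ValueError(
            "item covariance matrix is singular (collinear items); "
            "consider the ridge option"
        )
    resid = 1.0 / np.diag(np.linalg.inv(S))
    total_var = X.sum(axis=1).var(ddof=1)
    return 1.0 - resid.sum() / total_var


def _ml_discrepancy(S, lam, psi):
    Sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf, None
    Sinv = np.linalg.inv(Sigma)
    _, logdetS = np.linalg.slogdet(S)
    F = logdet + np.trace(S @ Sinv) - logdetS - S.shape[0]
    return F, Sinv


class OneFactorCFA(BaseEstimator):
    """One-factor confirmatory factor model fitted by normal-theory ML.

    Minimises ``F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - J`` over loadings
    and uniquenesses with ``Sigma = lam lam' + diag(psi)`` (factor variance
    fixed at 1), by L-BFGS-B with the analytic gradient.  Uniquenesses are
    bounded below at a small positive floor; an active floor is reported
    as a Heywood case.
    """

    def __init__(self, psi_floor: float = 1e-3, max_iter: int = 500):
        self.psi_floor = psi_floor
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = _as_matrix(X)
        n, J = X.shape
        if J < 3:
            raise ValueError("one-factor CFA needs at least 3 items")
        S = np.cov(X, rowvar=False)
        if np.linalg.eigvalsh(S)[0] <= 0:
            raise ValueError("sample covariance matrix is not positive definite")

        # principal-axis start
        w, v = np.linalg.eigh(S)
        lam0 = v[:, -1] * np.sqrt(w[-1])
        if lam0.sum() < 0:
            lam0 = -lam0
        psi0 = np.clip(np.diag(S) - lam0**2, 0.05 * np.diag(S), None)
        floors = self.psi_floor * np.diag(S)

        def objective(params):
            lam, psi = params[:J], params[J:]
            Sigma = np.outer(lam, lam) + np.diag(psi)
            sign, logdet = np.linalg.slogdet(Sigma)
            if sign <= 0:
                return 1e10, np.zeros(2 * J)
            Sinv = np.linalg.inv(Sigma)
            _, logdetS = np.linalg.slogdet(S)
            F = logdet + np.trace(S @ Sinv) - logdetS - J
            G = Sinv @ (Sigma - S) @ Sinv
            return F, np.concatenate([2.0 * G @ lam, np.diag(G)])

        bounds = [(None, None)] * J + [(f, None) for f in floors]
        res = minimize(
            objective,
            np.concatenate([lam0, psi0]),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        lam, psi = res.x[:J], res.x[J:]
        if lam.sum() < 0:
            lam = -lam
        self.converged_ = bool(res.success)
        if not self.converged_:
            warnings.warn(f"CFA optimisation did not converge: {res.message}")
        self.heywood_ = bool(np.any(psi <= floors * (1 + 1e-8)))
        if self.heywood_:
            warnings.warn("Heywood case: uniqueness bounded at the positive floor")
        self.loadings_ = lam
        self.uniqueness_ = psi
        self.discrepancy_ = float(res.fun)
        self.S_ = S
        self.n_used_ = n
        return self

    def indices(self, X=None) -> FitIndices:
        check_is_fitted(self, "loadings_")
        S, n = self.S_, self.n_used_
        J = len(self.loadings_)
        lam, psi = self.loadings_, self.uniqueness_
        Sigma = np.outer(lam, lam) + np.diag(psi)

        df = J * (J + 1) // 2 - 2 * J
        chi2 = max(0.0, (n - 1) * self.discrepancy_)
        _, logdetS = np.linalg.slogdet(S)
        Fb = float(np.sum(np.log(np.diag(S))) - logdetS)
        chi2_b = max(0.0, (n - 1) * Fb)
        df_b = J * (J - 1) // 2

        saturated = df == 0
        rmsea = 0.0 if saturated else float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))))
        d = np.sqrt(np.diag(S))
        resid = (S - Sigma) / np.outer(d, d)
        tri = np.tril_indices(J)
        srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))
        if saturated or chi2_b - df_b <= 0:
            cfi = 1.0
            tli = 1.0
        else:
            cfi = 1.0 - (chi2 - df) / (chi2_b - df_b)
            tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
        lam_s = lam / d
        psi_s = psi / np.diag(S)
        omega = float(lam_s.sum() ** 2 / (lam_s.sum() ** 2 + psi_s.sum()))

        if X is not None:
            Xm = _as_matrix(X)
        else:
            Xm = None
        return FitIndices(
            cronbach_alpha=cronbach_alpha(Xm) if Xm is not None else np.nan,
            guttman_lambda6=guttman_lambda6(Xm) if Xm is not None else np.nan,
            omega=omega,
            rmsea=rmsea,
            srmr=srmr,
            cfi=float(cfi),
            tli=float(tli),
            cfi_clipped=float(np.clip(cfi, 0.0, 1.0)),
            tli_clipped=float(np.clip(tli, 0.0, 1.0)),
            model_chi2=float(chi2),
            model_df=int(df),
            baseline_chi2=float(chi2_b),
            baseline_df=int(df_b),
            n_used=int(n),
            converged=self.converged_,
            heywood=self.heywood_,
            saturated=saturated,
        )


def fit_one_factor_cfa(X) -> FitIndices:
    """Fit the one-factor model and return the full index set."""
    est = OneFactorCFA().fit(X)
    return est.indices(X)


def subgroup_indices(responses: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Reliability/CFA index table per subgroup level plus the total sample.

    ``groups`` holds one categorical column per demographic factor; each
    observed level gets a row, and a final ``total`` row covers everyone.
    """
    rows = []
    for col in groups.columns:
        for level in pd.unique(groups[col].dropna()):
            sub = responses.loc[groups[col] == level]
            rows.append(
                {"factor": col, "level": level, **fit_one_factor_cfa(sub).to_row()}
            )
    rows.append({"factor": "total", "level": "", **fit_one_factor_cfa(responses).to_row()})
    return pd.DataFrame(rows)
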