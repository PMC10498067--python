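"""Proportional-odds (cumulative logit) regression for DIF testing.

The DIF procedure compares three nested cumulative-logit models for each
item response ``Y`` (ordered categories), trait score ``theta`` and binary
group ``g``::

    M1:  logit P(Y <= k) = b0k + b1*theta
    M2:  logit P(Y <= k) = b0k + b1*theta + b2*g
    M3:  logit P(Y <= k) = b0k + b1*theta + b2*g + b3*theta*g

Uniform DIF is tested by the 1-df likelihood-ratio test M1 vs M2 (group
main effect), nonuniform DIF by M2 vs M3 (trait-by-group interaction).
Effect sizes are the log-likelihood-ratio pseudo-R-squared change and the
Crane-van Belle-Larson proportional change in the trait slope.

The cumulative probabilities are modelled on the *lower* tail,
``P(Y <= k)``, with the linear predictor entering with a plus sign, so the
trait slope ``b1`` is negative for a positively discriminating item.  All
test statistics and effect sizes are invariant to this sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "OLRFit",
    "ProportionalOddsModel",
    "fit_cumulative_logit",
    "lr_chi2",
    "delta_r",
    "cvbl_delta_beta",
]

_MODEL_TERMS = {"M1": 1, "M2": 2, "M3": 3}


@dataclass
class OLRFit:
    """Result of one cumulative-logit maximum-likelihood fit.

    ``intercepts`` are the cutpoints ``b0k`` for ``P(Y <= k)``,
    ``k = 0..K-2`` over the ``K`` observed categories.  ``beta1`` is the
    trait slope; ``beta2``/``beta3`` are present only for M2/M3.
    """

    model: str
    intercepts: np.ndarray
    beta1: float
    beta2: float | None
    beta3: float | None
    log_likelihood: float
    n_used: int
    n_categories: int
    converged: bool
    n_iter: int
    grad_norm: float
    diagnostics: str = ""
    _design: np.ndarray | None = field(default=None, repr=False, compare=False)
    _y: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def coef(self) -> np.ndarray:
        out = [self.beta1]
        if self.beta2 is not None:
            out.append(self.beta2)
        if self.beta3 is not None:
            out.append(self.beta3)
        return np.asarray(out)

    def category_probs(self) -> np.ndarray:
        """Per-person fitted category probabilities (n x K)."""
        if self._design is None:
            raise ValueError("fit does not retain its design matrix")
        eta = self.intercepts[None, :] + (self._design @ self.coef)[:, None]
        gamma = np.hstack(
            [
                np.zeros((eta.shape[0], 1)),
                expit(eta),
                np.ones((eta.shape[0], 1)),
            ]
        )
        return np.diff(gamma, axis=1)

    def to_record(self) -> dict:
        """Plain-dict form for report writers."""
        rec = {
            "model": self.model,
            "log_likelihood": self.log_likelihood,
            "n_used": self.n_used,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "beta3": self.beta3,
        }
        for k, a in enumerate(self.intercepts):
            rec[f"b0{k}"] = a
        return rec


def _loglik_grad_hess(alpha, beta, X, y, K, want_hess=True):
    """Log-likelihood, gradient and Hessian of the cumulative-logit model.

    Parameters are the cutpoints ``alpha`` (length K-1, increasing) and
    slopes ``beta`` (length p).  ``y`` holds 0-based category codes.
    """
    n, p = X.shape
    xb = X @ beta
    eta = alpha[None, :] + xb[:, None]  # n x (K-1)
    gamma = expit(eta)
    # bracket gamma with the fixed boundaries 0 and 1
    gfull = np.hstack([np.zeros((n, 1)), gamma, np.ones((n, 1))])
    L = gfull[np.arange(n), y + 1] - gfull[np.arange(n), y]
    L = np.clip(L, 1e-300, None)
    ll = float(np.log(L).sum())
    # derivative denominators use a softer floor so L**2 cannot underflow
    L = np.clip(L, 1e-100, None)

    g = gamma * (1.0 - gamma)  # d gamma / d eta
    gp = g * (1.0 - 2.0 * gamma)  # second derivative of sigmoid

    # per-person nonzero eta-derivatives live at cut indices u=y (if y<K-1)
    # and l=y-1 (if y>0)
    has_u = y <= K - 2
    has_l = y >= 1
    iu = np.flatnonzero(has_u)
    il = np.flatnonzero(has_l)
    ku = y[iu]
    kl = y[il] - 1

    d_eta = np.zeros((n, K - 1))
    d_eta[iu, ku] = g[iu, ku] / L[iu]
    d_eta[il, kl] -= g[il, kl] / L[il]

    grad_alpha = d_eta.sum(axis=0)
    row = d_eta.sum(axis=1)
    grad_beta = X.T @ row
    grad = np.concatenate([grad_alpha, grad_beta])
    if not want_hess:
        return ll, grad, None

    # second derivatives w.r.t. eta: 2x2 block per person
    huu = np.zeros(n)
    hll = np.zeros(n)
    hul = np.zeros(n)
    huu[iu] = gp[iu, ku] / L[iu] - (g[iu, ku] / L[iu]) ** 2
    hll[il] = -gp[il, kl] / L[il] - (g[il, kl] / L[il]) ** 2
    both = has_u & has_l
    ib = np.flatnonzero(both)
    hul[ib] = g[ib, y[ib]] * g[ib, y[ib] - 1] / L[ib] ** 2

    q = K - 1 + p
    H = np.zeros((q, q))
    # alpha-alpha block
    np.add.at(H, (ku, ku), huu[iu])
    np.add.at(H, (kl, kl), hll[il])
    kub = y[ib]
    klb = y[ib] - 1
    np.add.at(H, (kub, klb), hul[ib])
    np.add.at(H, (klb, kub), hul[ib])
    # alpha-beta block: row sums of each person's eta-block, scattered by cut
    rs = np.zeros((n, K - 1))
    rs[iu, ku] += huu[iu]
    rs[il, kl] += hll[il]
    rs[ib, kub] += hul[ib]
    rs[ib, klb] += hul[ib]
    Hab = rs.T @ X  # (K-1) x p
    H[: K - 1, K - 1 :] += Hab
    H[K - 1 :, : K - 1] += Hab.T
    # beta-beta block
    s = huu + hll + 2.0 * hul
    H[K - 1 :, K - 1 :] += (X * s[:, None]).T @ X
    return ll, grad, H


class ProportionalOddsModel(BaseEstimator):
    """Cumulative-logit (proportional-odds) regression estimator.

    Fits ``logit P(Y <= k) = alpha_k + X @ beta`` by Newton-Raphson with
    step-halving, using the analytic gradient and Hessian.  Categories are
    re-coded to consecutive 0-based ranks internally; unobserved categories
    are dropped (adjacent collapse of empty codes).

    Parameters
    ----------
    max_iter : maximum Newton iterations.
    tol : convergence criterion on the gradient max-norm.
    max_halvings : step-halvings allowed per Newton step.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8, max_halvings: int = 20):
        self.max_iter = max_iter
        self.tol = tol
        self.max_halvings = max_halvings

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix contains non-finite values")
        levels, ycode = np.unique(y, return_inverse=True)
        K = len(levels)
        if K < 2:
            raise ValueError("response has a single observed category")
        n, p = X.shape

        # start: empirical cumulative log-odds, zero slopes
        cum = np.cumsum(np.bincount(ycode, minlength=K))[:-1] / n
        cum = np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
        alpha = np.log(cum / (1 - cum))
        beta = np.zeros(p)

        ll, grad, H = _loglik_grad_hess(alpha, beta, X, ycode, K)
        converged = False
        diagnostics = ""
        it = 0
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(H, -grad, rcond=None)
            if not np.all(np.isfinite(step)):
                step, *_ = np.linalg.lstsq(H, -grad, rcond=None)
            scale = 1.0
            accepted = False
            for _ in range(self.max_halvings + 1):
                a_new = alpha + scale * step[: K - 1]
                b_new = beta + scale * step[K - 1 :]
                if np.all(np.diff(a_new) > 0) or K == 2:
                    ll_new, g_new, H_new = _loglik_grad_hess(a_new, b_new, X, ycode, K)
                    if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                        alpha, beta = a_new, b_new
                        ll, grad, H = ll_new, g_new, H_new
                        accepted = True
                        break
                scale *= 0.5
            if not accepted:
                diagnostics = "step-halving failed to improve the likelihood"
                break
        else:
            it = self.max_iter
        if not converged and np.max(np.abs(grad)) < self.tol:
            converged = True
        if np.max(np.abs(beta), initial=0.0) > 25:
            # a slope this size means quasi-complete separation in practice
            converged = False
            diagnostics = "possible complete separation (diverging slope)"
        if not converged and not diagnostics:
            diagnostics = "maximum iterations reached"

        self.levels_ = levels
        self.intercepts_ = alpha
        self.coef_ = beta
        self.loglik_ = ll
        self.converged_ = converged
        self.n_iter_ = it
        self.grad_norm_ = float(np.max(np.abs(grad)))
        self.diagnostics_ = diagnostics
        self.n_features_in_ = p
        return self

    def predict_proba(self, X):
        """Category probabilities for new design rows (n x K)."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercepts_[None, :] + (X @ self.coef_)[:, None]
        n = X.shape[0]
        gfull = np.hstack([np.zeros((n, 1)), expit(eta), np.ones((n, 1))])
        return np.diff(gfull, axis=1)


def fit_cumulative_logit(y, theta, g, terms: str = "M3") -> OLRFit:
    """Fit one of the three nested DIF models by maximum likelihood.

    Parameters
    ----------
    y : ordered item responses (any integer coding; re-coded internally).
    theta : trait scores (matching variable).
    g : binary group indicator coded 0/1.
    terms : "M1" (trait only), "M2" (+ group) or "M3" (+ trait x group).
    """
    if terms not in _MODEL_TERMS:
        raise ValueError(f"terms must be one of {sorted(_MODEL_TERMS)}")
    y = np.asarray(y)
    theta = np.asarray(theta, dtype=float)
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta contains non-finite values")
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("group must be coded 0/1")
    cols = [theta]
    if terms in ("M2", "M3"):
        cols.append(g)
    if terms == "M3":
        cols.append(theta * g)
    X = np.column_stack(cols)

    est = ProportionalOddsModel().fit(X, y)
    beta = est.coef_
    return OLRFit(
        model=terms,
        intercepts=est.intercepts_,
        beta1=float(beta[0]),
        beta2=float(beta[1]) if terms in ("M2", "M3") else None,
        beta3=float(beta[2]) if terms == "M3" else None,
        log_likelihood=est.loglik_,
        n_used=len(y),
        n_categories=len(est.levels_),
        converged=est.converged_,
        n_iter=est.n_iter_,
        grad_norm=est.grad_norm_,
        diagnostics=est.diagnostics_,
        _design=X,
        _y=y,
    )


def lr_chi2(sub: OLRFit, full: OLRFit, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio chi-square between nested fits on the same persons.

    Returns ``(chi2, p)`` where ``chi2 = 2 (lnL_full - lnL_sub)``, clipped
    at zero for numerical noise, and ``p`` is the upper-tail probability of
    the chi-square distribution with ``df`` degrees of freedom.
    """
    if sub.n_used != full.n_used:
        raise ValueError(
            f"fits use different persons (n={sub.n_used} vs {full.n_used}); "
            "nesting violated"
        )
    chi2 = max(0.0, 2.0 * (full.log_likelihood - sub.log_likelihood))
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p


def delta_r(
    sub: OLRFit,
    full: OLRFit,
    formula: str = "paper_ratio",
    loglik_null: float | None = None,
) -> float:
    """Pseudo-R-squared DIF effect size between nested fits.

    ``paper_ratio`` (default) is the log-likelihood ratio form

        deltaR = 1 - lnL_full / lnL_sub,

    the change measure conventionally printed alongside hybrid OLR DIF
    tables.  ``mcfadden_difference`` is the difference of McFadden
    pseudo-R-squared values, ``(lnL_sub - lnL_full) / lnL_null``, and needs
    the intercept-only log-likelihood ``loglik_null``.
    """
    if sub.log_likelihood >= 0 or full.log_likelihood >= 0:
        raise ValueError("non-negative log-likelihood: degenerate fit")
    if formula == "paper_ratio":
        return 1.0 - full.log_likelihood / sub.log_likelihood
    if formula == "mcfadden_difference":
        if loglik_null is None:
            raise ValueError("mcfadden_difference requires loglik_null")
        if loglik_null >= 0:
            raise ValueError("non-negative null log-likelihood")
        return (sub.log_likelihood - full.log_likelihood) / loglik_null
    raise ValueError("formula must be 'paper_ratio' or 'mcfadden_difference'")


def cvbl_delta_beta(fit_without_g: OLRFit, fit_with_g: OLRFit) -> float:
    """Crane-van Belle-Larson criterion: |(b1_without - b1_with) / b1_without|.

    The absolute proportional change in the trait slope when the group main
    effect enters the model; the standard uniform-DIF effect size.
    """
    b_wo = fit_without_g.beta1
    b_w = fit_with_g.beta1
    if b_wo == 0:
        raise ValueError("beta1 of the without-group fit is zero; CVBL undefined")
    return abs((b_wo - b_w) / b_wo)
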