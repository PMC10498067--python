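"""Iterative hybrid OLR/IRT differential item functioning analysis.

For every item the analyzer fits the three nested cumulative-logit models
(trait; trait + group; trait + group + interaction) against the current
trait score, tests uniform DIF (M1 vs M2) and nonuniform DIF (M2 vs M3)
with 1-df likelihood-ratio chi-squares, and computes the pseudo-R-squared
changes and the Crane-van Belle-Larson slope-change criterion.

The matching trait is an EAP score from a graded response model rather
than a raw sum score, and it is *purified*: after the initial pass that
scores everyone on all items, each iteration rescores the trait using only
the currently unflagged (anchor) items and re-tests every item, until the
flagged set repeats or an iteration cap is reached.  This keeps biased
items from contaminating the matching variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .grm import GradedResponseModel, ItemParameters, test_characteristic_curve
from .io import (
    REPORT_FLAG_COLUMNS,
    REPORT_STAT_COLUMNS,
    ResponseMatrix,
    RunConfig,
)
from .olr import cvbl_delta_beta, delta_r, fit_cumulative_logit, lr_chi2

__all__ = [
    "DIFResult",
    "DIFReport",
    "DIFAnalyzer",
    "analyze_item",
    "classify_item",
    "run_iterative_dif",
    "export_dif_curves",
]


@dataclass
class DIFResult:
    """Per-item DIF statistics and criterion flags."""

    item_id: str
    chi2_uniform: float = np.nan
    p_uniform: float = np.nan
    chi2_nonuniform: float = np.nan
    p_nonuniform: float = np.nan
    chi2_overall: float = np.nan  # 2-df M1 vs M3, reported, not used for flags
    p_overall: float = np.nan
    deltaR1: float = np.nan
    deltaR2: float = np.nan
    deltaBeta1: float = np.nan
    flag_uniform_sig: bool = False
    flag_nonuniform_sig: bool = False
    flag_large_r2: bool = False
    flag_large_cvbl: bool = False
    usable: bool = True
    message: str = ""

    @property
    def flagged(self) -> bool:
        """Chi-square flag of either DIF type (drives purification)."""
        return self.flag_uniform_sig or self.flag_nonuniform_sig


@dataclass
class DIFReport:
    """Full output of an iterative DIF run."""

    results: list[DIFResult]
    anchor_items: list[str]
    trace: list[frozenset]
    criteria: RunConfig
    termination: str  # fixed_point | cycle | max_iter | all_flagged
    theta_provenance: dict = field(default_factory=dict)

    @property
    def flagged_items(self) -> list[str]:
        return [r.item_id for r in self.results if r.usable and r.flagged]

    def uniform_flagged_items(self) -> list[str]:
        return [r.item_id for r in self.results if r.usable and r.flag_uniform_sig]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "item_id",
            *REPORT_STAT_COLUMNS,
            *REPORT_FLAG_COLUMNS,
            "chi2_overall",
            "p_overall",
            "usable",
        ]
        if not self.results:
            return pd.DataFrame(columns=cols)
        rows = []
        for r in self.results:
            rows.append(
                {
                    "item_id": r.item_id,
                    **{c: getattr(r, c) for c in REPORT_STAT_COLUMNS},
                    **{c: getattr(r, c) for c in REPORT_FLAG_COLUMNS},
                    "chi2_overall": r.chi2_overall,
                    "p_overall": r.p_overall,
                    "usable": r.usable,
                }
            )
        return pd.DataFrame(rows)


def analyze_item(y, theta, g, delta_r_formula: str = "paper_ratio") -> dict:
    """Three-model comparison for one item.

    Returns the uniform (M1 vs M2) and nonuniform (M2 vs M3) 1-df
    likelihood-ratio statistics, the overall 2-df statistic, and the
    effect sizes deltaR1, deltaR2 and deltaBeta1.
    """
    m1 = fit_cumulative_logit(y, theta, g, "M1")
    m2 = fit_cumulative_logit(y, theta, g, "M2")
    m3 = fit_cumulative_logit(y, theta, g, "M3")
    chi2_u, p_u = lr_chi2(m1, m2, df=1)
    chi2_n, p_n = lr_chi2(m2, m3, df=1)
    chi2_o, p_o = lr_chi2(m1, m3, df=2)
    return {
        "chi2_uniform": chi2_u,
        "p_uniform": p_u,
        "chi2_nonuniform": chi2_n,
        "p_nonuniform": p_n,
        "chi2_overall": chi2_o,
        "p_overall": p_o,
        "deltaR1": delta_r(m1, m2, delta_r_formula),
        "deltaR2": delta_r(m2, m3, delta_r_formula),
        "deltaBeta1": cvbl_delta_beta(m1, m2),
        "converged": m1.converged and m2.converged and m3.converged,
    }


def classify_item(stats: dict | DIFResult, criteria: RunConfig, n_items: int = 1) -> dict:
    """Apply the flagging criteria to one item's statistics.

    Chi-square flags use the per-test significance level (optionally
    Bonferroni-adjusted across items); the magnitude flags compare
    ``max(deltaR1, deltaR2)`` against the pseudo-R-squared cutoff and
    ``deltaBeta1`` against the slope-change cutoff.
    """
    if isinstance(stats, DIFResult):
        stats = {k: getattr(stats, k) for k in ("p_uniform", "p_nonuniform", "deltaR1", "deltaR2", "deltaBeta1")}
    alpha = criteria.alpha / n_items if criteria.bonferroni else criteria.alpha
    return {
        "flag_uniform_sig": bool(stats["p_uniform"] < alpha),
        "flag_nonuniform_sig": bool(stats["p_nonuniform"] < alpha),
        "flag_large_r2": bool(
            max(stats["deltaR1"], stats["deltaR2"]) >= criteria.r2_threshold
        ),
        "flag_large_cvbl": bool(stats["deltaBeta1"] > criteria.cvbl_threshold),
    }


class DIFAnalyzer(BaseEstimator):
    """Iterative hybrid OLR/IRT DIF analyzer (scikit-learn style).

    ``fit(X, y)`` takes an n x J matrix of ordered responses (1..m) and a
    binary group label vector; alternatively pass a
    :class:`~ordif.io.ResponseMatrix` as ``X``.  After fitting:

    ``results_``      per-item :class:`DIFResult` list
    ``report_``       the :class:`DIFReport` (trace, anchors, termination)
    ``anchor_items_`` anchor set at convergence
    ``theta_``        purified trait scores of the final iteration
    """

    def __init__(self, config: RunConfig | None = None, **overrides):
        self.config = config
        self.overrides = overrides

    def _resolved_config(self) -> RunConfig:
        cfg = self.config if self.config is not None else RunConfig()
        if self.overrides:
            cfg = replace(cfg, **self.overrides)
        return cfg

    def fit(self, X, y=None):
        cfg = self._resolved_config()
        if isinstance(X, ResponseMatrix):
            rm = X
        else:
            Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
            Xdf.columns = [str(c) for c in Xdf.columns]
            if y is None:
                raise ValueError("group labels y are required")
            rm = ResponseMatrix(Xdf.astype(float), pd.Series(np.asarray(y), name="group"))
        if cfg.missing_policy == "listwise":
            rm = rm.complete_cases()
        g, levels = rm.group_codes()
        items = rm.item_ids
        resp = rm.responses

        grm_all = GradedResponseModel(
            variant=cfg.model_variant, n_quadrature=cfg.n_quadrature
        ).fit(resp)
        estimable = list(grm_all.item_ids_)

        def score(anchors, refit):
            if refit and set(anchors) != set(estimable):
                sub = GradedResponseModel(
                    variant=cfg.model_variant, n_quadrature=cfg.n_quadrature
                ).fit(resp[anchors])
                return sub.score_theta(resp[anchors]), sub
            return grm_all.score_theta(resp, anchors), grm_all

        def one_pass(theta):
            results = []
            for item in items:
                yj = resp[item].to_numpy()
                obs = ~np.isnan(yj)
                try:
                    stats = analyze_item(
                        yj[obs].astype(int), theta[obs], g[obs], cfg.delta_r_formula
                    )
                except ValueError as exc:
                    results.append(
                        DIFResult(item_id=item, usable=False, message=str(exc))
                    )
                    warnings.warn(f"item {item} failed to fit: {exc}")
                    continue
                flags = classify_item(stats, cfg, n_items=len(items))
                stats.pop("converged")
                results.append(DIFResult(item_id=item, **stats, **flags))
            return results

        def purify_set(results):
            out = set()
            for r in results:
                if not r.usable:
                    continue
                if r.flagged or (
                    cfg.purify_on == "chi2_or_effect" and (r.flag_large_r2 or r.flag_large_cvbl)
                ):
                    out.add(r.item_id)
            return frozenset(out)

        anchors = list(estimable)
        theta_est, theta_model = score(anchors, refit=False)
        results = one_pass(theta_est.theta)
        trace = [purify_set(results)]
        termination = "max_iter"
        for _ in range(cfg.max_purification_iters - 1):
            flagged = trace[-1]
            next_anchors = [i for i in estimable if i not in flagged]
            if not next_anchors:
                warnings.warn(
                    "every item is flagged as DIF; keeping the last non-empty "
                    "anchor set — interpret this run with caution"
                )
                termination = "all_flagged"
                break
            if set(next_anchors) == set(anchors):
                termination = "fixed_point"
                break
            anchors = next_anchors
            theta_est, theta_model = score(anchors, cfg.refit_anchors)
            results = one_pass(theta_est.theta)
            trace.append(purify_set(results))
            if trace[-1] == trace[-2]:
                termination = "fixed_point"
                break
            if trace[-1] in trace[:-2]:
                termination = "cycle"
                break

        self.config_ = cfg
        self.group_levels_ = levels
        self.results_ = results
        self.anchor_items_ = anchors
        self.theta_ = theta_est.theta
        self.theta_model_ = theta_model
        self.data_ = rm
        self.group_ = g
        self.report_ = DIFReport(
            results=results,
            anchor_items=anchors,
            trace=trace,
            criteria=cfg,
            termination=termination,
            theta_provenance={
                "model_variant": cfg.model_variant,
                "n_quadrature": cfg.n_quadrature,
                "refit_anchors": cfg.refit_anchors,
            },
        )
        return self

    def to_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "report_")
        return self.report_.to_frame()


def run_iterative_dif(data: ResponseMatrix, config: RunConfig | None = None) -> DIFReport:
    """Run the full iterative purification analysis; returns the report."""
    return DIFAnalyzer(config=config).fit(data).report_


def _group_item_params(y, theta, items_params_m: int):
    """Group-specific graded parameters for one item, regressed on theta.

    With the trait held fixed, the graded item model is a cumulative-logit
    regression of the response on theta: logit P(Y <= k) = c_k - a*theta.
    Returns (a, b) or None when the group shows no positive discrimination.
    """
    fit = fit_cumulative_logit(y, theta, np.zeros_like(theta), "M1")
    a = -fit.beta1
    if a <= 0 or len(fit.intercepts) != items_params_m - 1:
        return None
    return a, fit.intercepts / a


def export_dif_curves(
    report: DIFReport,
    data: ResponseMatrix,
    theta: np.ndarray,
    which: str = "uniform",
    theta_grid=None,
) -> pd.DataFrame:
    """Per-group test characteristic curves over the flagged items.

    Item parameters are re-estimated separately per group by regressing
    each flagged item on the purified trait score (anchors held common
    through the shared theta), then the curves are the per-group expected
    summed scores.  An empty frame (with a note attribute) is returned
    when nothing is flagged.
    """
    if which == "uniform":
        items = report.uniform_flagged_items()
    else:
        items = report.flagged_items
    if theta_grid is None:
        theta_grid = np.linspace(-4, 4, 81)
    if not items:
        out = pd.DataFrame({"theta": []})
        out.attrs["note"] = "no flagged items; nothing to plot"
        return out
    g, levels = data.group_codes()
    m = data.n_categories
    per_item = {}
    for item in items:
        yj = data.responses[item].to_numpy()
        pars = []
        for code in (0, 1):
            obs = (g == code) & ~np.isnan(yj)
            pars.append(_group_item_params(yj[obs].astype(int), theta[obs], m))
        if any(p is None for p in pars):
            warnings.warn(f"item {item}: group-specific refit failed; skipped")
            continue
        per_item[item] = pars
    if not per_item:
        out = pd.DataFrame({"theta": []})
        out.attrs["note"] = "no item allowed a group-specific refit"
        return out
    ok_items = list(per_item)
    curves = {}
    for code, label in enumerate(levels):
        params = ItemParameters(
            np.array([per_item[i][code][0] for i in ok_items]),
            np.vstack([per_item[i][code][1] for i in ok_items]),
            ok_items,
        )
        curves[str(label)] = test_characteristic_curve(
            {label: params}, ok_items, theta_grid
        )[str(label)]
    out = pd.DataFrame({"theta": np.asarray(theta_grid), **curves})
    out.attrs["items"] = ok_items
    return out
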