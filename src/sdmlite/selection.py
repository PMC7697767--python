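"""Binomial GLM fitting and bidirectional stepwise model selection by AIC.

The variable-screening stage of the pipeline: a logistic regression of
presence (1) versus background (0) on candidate bioclimatic variables, and a
classical stepwise search that starts from the full model and repeatedly
applies the single variable addition or removal that lowers the Akaike
Information Criterion (AIC = 2k - 2 log L, k counting the intercept) the
most, stopping when no move improves it.

Predictors are standardized internally for numerical conditioning; reported
coefficients are on the original scale.  Quasi-separated fits — easy to
produce with global presence/background tables — are flagged rather than
fatal: the likelihood is re-maximized with standardized coefficients bounded
to [-15, 15] and the fit carries ``converged=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .grids import variable_columns

__all__ = ["GLMFit", "SelectionTrace", "fit_binomial_glm", "stepwise_aic", "StepwiseAIC"]

#: cap on |standardized coefficient| used for quasi-separated fits
COEF_CAP = 15.0


@dataclass
class GLMFit:
    """A fitted binomial GLM: coefficients on the original predictor scale."""

    variables: list[str]
    intercept: float
    coefficients: dict[str, float]
    log_likelihood: float
    aic: float
    converged: bool

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept)
        for v in self.variables:
            eta += self.coefficients[v] * X[v].to_numpy(dtype=float)
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return special.expit(self.linear_predictor(X))


@dataclass
class SelectionTrace:
    """Record of a stepwise search: one entry per applied move."""

    steps: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)


def _neg_loglik_and_grad(params, X, y):
    eta = X @ params
    ll = y @ eta - np.logaddexp(0.0, eta).sum()
    grad = X.T @ (y - special.expit(eta))
    return -ll, -grad


def fit_binomial_glm(data: pd.DataFrame, variables: list[str]) -> GLMFit:
    """Maximum-likelihood logistic regression of ``label`` on ``variables``.

    ``data`` is a sample matrix with a 0/1 ``label`` column.  Exactly
    collinear predictors (e.g. a duplicated column) raise a ``ValueError``
    naming the offending column.
    """
    y = data["label"].to_numpy(dtype=float)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("need at least one presence and one background row")
    n = len(y)
    X = data[list(variables)].to_numpy(dtype=float) if variables else np.empty((n, 0))
    mu = X.mean(axis=0) if variables else np.empty(0)
    sd = X.std(axis=0) if variables else np.empty(0)
    if variables and (sd == 0).any():
        bad = variables[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"variable {bad!r} is constant")
    Xs = (X - mu) / sd if variables else X
    design = np.column_stack([np.ones(n), Xs])

    # exact collinearity check: a near-zero diagonal of R names the column
    _, r = np.linalg.qr(design)
    rdiag = np.abs(np.diag(r))
    tiny = rdiag < 1e-8 * max(rdiag.max(), 1.0)
    if tiny.any():
        bad = variables[int(np.flatnonzero(tiny)[0]) - 1]
        raise ValueError(f"variable {bad!r} is collinear with the others")

    converged = True
    try:
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(res.params)
        converged = bool(res.converged) and bool(np.all(np.abs(params[1:]) <= COEF_CAP))
        llf = float(res.llf)
    except Exception:
        converged = False
        params = None
        llf = -np.inf

    if not converged:
        # quasi-separation: bounded MLE with capped standardized coefficients
        bounds = [(-50.0, 50.0)] + [(-COEF_CAP, COEF_CAP)] * len(variables)
        x0 = np.zeros(design.shape[1])
        opt = optimize.minimize(
            _neg_loglik_and_grad, x0, args=(design, y), jac=True,
            method="L-BFGS-B", bounds=bounds,
        )
        params = opt.x
        llf = -float(opt.fun)

    beta_std = params[1:]
    beta = beta_std / sd if variables else beta_std
    intercept = float(params[0] - (beta_std * mu / sd).sum()) if variables else float(params[0])
    aic = 2.0 * (1 + len(variables)) - 2.0 * llf
    return GLMFit(
        variables=list(variables),
        intercept=intercept,
        coefficients={v: float(b) for v, b in zip(variables, beta)},
        log_likelihood=llf,
        aic=float(aic),
        converged=converged,
    )


def stepwise_aic(data: pd.DataFrame, candidates: list[str]) -> SelectionTrace:
    """Bidirectional stepwise search by AIC, starting from the full model.

    At each step every single-variable addition and removal is evaluated and
    the move with the largest AIC decrease is applied; ties break to the first
    candidate in input order; the search stops when no move lowers the AIC.
    Non-convergent candidate fits are skipped and recorded in the trace.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    cache: dict[frozenset, GLMFit] = {}

    def fit(subset: list[str]) -> GLMFit:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = fit_binomial_glm(data, subset)
        return cache[key]

    trace = SelectionTrace()
    current = list(candidates)
    cur_fit = fit(current)
    trace.steps.append({"action": "start", "variable": None, "aic": cur_fit.aic})
    while True:
        best = None  # (aic, action, variable, subset)
        for v in candidates:
            if v in current:
                subset = [w for w in current if w != v]
                action = "remove"
            else:
                subset = current + [v]
                action = "add"
            if action == "remove" and not subset:
                subset = []  # intercept-only model is a legal candidate
            try:
                cand = fit(subset)
            except ValueError:
                trace.skipped.append({"action": action, "variable": v,
                                      "reason": "singular fit"})
                continue
            if not cand.converged:
                trace.skipped.append({"action": action, "variable": v,
                                      "reason": "non-convergent fit"})
                continue
            if cand.aic < cur_fit.aic - 1e-10 and (best is None or cand.aic < best[0] - 1e-10):
                best = (cand.aic, action, v, subset)
        if best is None:
            trace.steps.append({"action": "stop", "variable": None, "aic": cur_fit.aic})
            break
        aic, action, v, subset = best
        current = subset
        cur_fit = fit(current)
        trace.steps.append({"action": action, "variable": v, "aic": aic})
    trace.selected = current
    return trace


class StepwiseAIC(SelectorMixin, BaseEstimator):
    """Sklearn-style feature selector wrapping the stepwise-AIC search.

    ``fit(X, y)`` takes a presence/background design (DataFrame or array) and
    a 0/1 label vector; ``transform`` keeps the selected columns.

    Attributes
    ----------
    selected_variables_ : list of str
    trace_ : SelectionTrace
    """

    def fit(self, X, y):
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        data = X.copy()
        data["label"] = np.asarray(y, dtype=int)
        self.trace_ = stepwise_aic(data, list(X.columns))
        self.selected_variables_ = list(self.trace_.selected)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_variables_")
        return np.isin(self.feature_names_in_, self.selected_variables_)


def select_variables(sample: pd.DataFrame) -> SelectionTrace:
    """Stepwise selection over every climate column of a sample matrix."""
    return stepwise_aic(sample, variable_columns(sample))
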