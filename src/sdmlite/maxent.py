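"""A minimal maximum-entropy presence-only model (maxent).

Maxent estimates the distribution over landscape cells that is closest to
uniform (minimum relative entropy) while matching feature expectations at the
occurrence localities.  Writing ``eta(x) = beta . f(x)`` for a linear score
over features, the fitted distribution over the background set is the Gibbs
distribution ``P(x) = exp(eta(x)) / Z`` with ``Z = sum_background exp(eta)``,
and the coefficients maximize the L1-penalized log gain

    G(beta) = mean_presence eta(x) - ln Z - sum_j lambda_j |beta_j| ,

with per-feature penalty ``lambda_j = rm * s_j / sqrt(m)`` (``s_j`` the
feature's standard deviation over presences, ``m`` the presence count,
``rm`` the regularization multiplier, default 1).

This is a deliberately minimal core, not a port of the reference program:
feature classes are linear, quadratic and pairwise-product transforms of the
climate variables (no hinge or threshold features), each variable min-max
scaled to [0, 1] on the training data and clamped to that range at projection
time.  Optimization is monotone proximal gradient ascent (soft-thresholding
with a backtracking step), so the penalized gain trace is non-decreasing and
the solution satisfies the L1 KKT conditions.

Outputs: ``raw`` is the relative occurrence rate (ROR), a probability
distribution summing to 1 over the background; ``logistic`` is the monotone
transform ``c*r / (1 + c*r)`` with ``c = exp(H)``, H the entropy of the
fitted background distribution, which places a typical presence cell near
0.5.
"""

from __future__ import annotations

import itertools
import json

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .grids import ClimateStack

__all__ = ["MaxEntSDM", "build_feature_names", "project_maxent"]

FEATURE_CLASSES = ("linear", "quadratic", "product")


def build_feature_names(variables: list[str], classes) -> list[str]:
    """Deterministic feature order: linear, then squares, then products."""
    names: list[str] = []
    if "linear" in classes:
        names += list(variables)
    if "quadratic" in classes:
        names += [f"{v}^2" for v in variables]
    if "product" in classes:
        names += [f"{a}*{b}" for a, b in itertools.combinations(variables, 2)]
    return names


class MaxEntSDM(BaseEstimator):
    """Minimal maxent species distribution model.

    Parameters
    ----------
    classes : tuple of str
        Feature classes, subset of {"linear", "quadratic", "product"}.
    rm : float
        Regularization multiplier (>= 0); larger means sparser/flatter models.
    tol : float
        Convergence tolerance on the change in penalized gain.
    max_iter : int

    Attributes
    ----------
    beta_ : ndarray, one coefficient per feature
    feature_names_ : list of str
    background_Z_ : float, the normalizer sum(exp(eta)) over the background
    entropy_H_ : float, entropy of the fitted background distribution
    gain_trace_ : list of float, penalized gain per iteration (non-decreasing)
    converged_ : bool
    """

    def __init__(self, classes=FEATURE_CLASSES, rm: float = 1.0,
                 tol: float = 1e-6, max_iter: int = 500):
        self.classes = classes
        self.rm = rm
        self.tol = tol
        self.max_iter = max_iter

    # -- features -----------------------------------------------------------

    def _check_classes(self):
        classes = tuple(self.classes)
        if not classes or any(c not in FEATURE_CLASSES for c in classes):
            raise ValueError(
                f"classes must be a nonempty subset of {FEATURE_CLASSES}"
            )
        return classes

    def build_features(self, X: pd.DataFrame) -> np.ndarray:
        """Clamped, scaled feature matrix for rows of climate values."""
        check_is_fitted(self, "scale_min_")
        missing = [v for v in self.variables_ if v not in X.columns]
        if missing:
            raise KeyError(f"input lacks model variables {missing}")
        raw = X[self.variables_].to_numpy(dtype=float)
        raw = np.clip(raw, self.scale_min_, self.scale_max_)
        span = np.where(self.scale_max_ > self.scale_min_,
                        self.scale_max_ - self.scale_min_, 1.0)
        Z = (raw - self.scale_min_) / span
        blocks = []
        classes = self._check_classes()
        if "linear" in classes:
            blocks.append(Z)
        if "quadratic" in classes:
            blocks.append(Z ** 2)
        if "product" in classes:
            pairs = list(itertools.combinations(range(Z.shape[1]), 2))
            if pairs:
                i, j = map(np.array, zip(*pairs))
                blocks.append(Z[:, i] * Z[:, j])
        return np.hstack(blocks) if blocks else np.empty((len(X), 0))

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        """Fit on a presence/background design.

        ``X`` holds climate values (DataFrame or array), ``y`` is 1 for
        presence rows and 0 for background rows.
        """
        classes = self._check_classes()
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=int)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if (y == 1).sum() < 1 or (y == 0).sum() < 2:
            raise ValueError("need >= 1 presence and >= 2 background rows")
        if X.isna().to_numpy().any():
            raise ValueError("design contains missing values")
        self.variables_ = list(X.columns)
        vals = X.to_numpy(dtype=float)
        self.scale_min_ = vals.min(axis=0)
        self.scale_max_ = vals.max(axis=0)
        self.feature_names_ = build_feature_names(self.variables_, classes)

        F = self.build_features(X)
        Fp, Fb = F[y == 1], F[y == 0]
        m = len(Fp)
        mean_p = Fp.mean(axis=0)
        s = Fp.std(axis=0)
        lam = self.rm * np.maximum(s, 1e-6) / np.sqrt(m)

        beta = np.zeros(F.shape[1])

        def smooth(b):
            eta_b = Fb @ b
            lz = logsumexp(eta_b)
            return mean_p @ b - lz, eta_b, lz

        def penalized(b):
            g, eta_b, lz = smooth(b)
            return g - lam @ np.abs(b), g, eta_b, lz

        cur_gain, cur_smooth, _, _ = penalized(beta)
        trace = [cur_gain]
        if not np.isfinite(cur_gain):
            raise FloatingPointError(
                "non-finite maxent gain; check feature scaling"
            )
        # monotone FISTA: accelerated proximal ascent with backtracking and
        # momentum restart, so the penalized gain trace never decreases
        step = 1.0
        converged = False
        y = beta.copy()
        theta = 1.0
        restarted = True  # the first step is a plain proximal step
        for _ in range(self.max_iter):
            y_smooth, y_eta, y_lz = smooth(y)
            p = np.exp(y_eta - y_lz)
            grad = mean_p - p @ Fb
            z = None
            for _ in range(60):
                z = np.sign(y + step * grad) * np.maximum(
                    np.abs(y + step * grad) - step * lam, 0.0
                )
                z_smooth, _, _ = smooth(z)
                dz = z - y
                # majorization condition for the chosen step
                if np.isfinite(z_smooth) and z_smooth >= y_smooth + grad @ dz - (dz @ dz) / (2 * step):
                    break
                step *= 0.5
            z_gain, _, _, _ = penalized(z)
            if z_gain >= cur_gain - 1e-12:
                delta = z_gain - cur_gain
                theta_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * theta * theta))
                y = z + ((theta - 1.0) / theta_new) * (z - beta)
                beta, cur_gain, theta = z, max(z_gain, cur_gain), theta_new
                trace.append(cur_gain)
                step = min(step * 1.2, 1e4)
                if delta < self.tol and restarted:
                    converged = True
                    break
                restarted = False
                if delta < self.tol:
                    # momentum stalled: next step is a plain proximal step
                    y, theta, restarted = beta.copy(), 1.0, True
            else:
                if restarted:
                    # even the plain step cannot improve: done
                    converged = True
                    break
                y, theta, restarted = beta.copy(), 1.0, True

        self.beta_ = beta
        self.lambda_ = lam
        self.gain_trace_ = trace
        self.converged_ = converged
        # normalizer and entropy of the fitted background distribution,
        # max-shifted for stability
        eta_b = Fb @ beta
        self._eta_shift_ = float(eta_b.max())
        self.background_Z_ = float(np.exp(eta_b - self._eta_shift_).sum())
        p = np.exp(eta_b - self._eta_shift_) / self.background_Z_
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        self.entropy_H_ = float(-plogp.sum())
        return self

    def kkt_violation(self, X, y) -> float:
        """Max violation of the L1 stationarity conditions on the training data.

        Zero (up to tolerance) at an exact maximizer: for active coefficients
        the smooth gradient equals ``lambda * sign(beta)``; for zero
        coefficients it lies within ``[-lambda, lambda]``.
        """
        check_is_fitted(self, "beta_")
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=int)
        F = self.build_features(X)
        Fp, Fb = F[y == 1], F[y == 0]
        eta_b = Fb @ self.beta_
        p = np.exp(eta_b - logsumexp(eta_b))
        grad = Fp.mean(axis=0) - p @ Fb
        active = self.beta_ != 0
        viol = np.zeros_like(grad)
        viol[active] = np.abs(grad[active] - self.lambda_[active] * np.sign(self.beta_[active]))
        viol[~active] = np.maximum(np.abs(grad[~active]) - self.lambda_[~active], 0.0)
        return float(viol.max()) if len(viol) else 0.0

    # -- prediction ---------------------------------------------------------

    def _eta(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_")
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        return self.build_features(X) @ self.beta_

    def predict_raw(self, X) -> np.ndarray:
        """Relative occurrence rate: exp(eta)/Z; sums to 1 over the background."""
        return np.exp(self._eta(X) - self._eta_shift_) / self.background_Z_

    def predict_logistic(self, X) -> np.ndarray:
        """Logistic output c*r/(1 + c*r) with c = exp(entropy_H)."""
        # work in log space: logit = eta + H - ln Z, then expit
        log_cr = self._eta(X) - self._eta_shift_ - np.log(self.background_Z_) + self.entropy_H_
        from scipy.special import expit
        return expit(log_cr)

    def predict(self, X, output: str = "raw") -> np.ndarray:
        if output == "raw":
            return self.predict_raw(X)
        if output == "logistic":
            return self.predict_logistic(X)
        raise ValueError("output must be 'raw' or 'logistic'")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "beta_")
        return json.dumps({
            "model": "maxent",
            "classes": list(self._check_classes()),
            "rm": self.rm,
            "variables": self.variables_,
            "scale_min": self.scale_min_.tolist(),
            "scale_max": self.scale_max_.tolist(),
            "feature_names": self.feature_names_,
            "beta": self.beta_.tolist(),
            "lambda": self.lambda_.tolist(),
            "eta_shift": self._eta_shift_,
            "background_Z": self.background_Z_,
            "entropy_H": self.entropy_H_,
        })

    @classmethod
    def from_json(cls, text: str) -> "MaxEntSDM":
        obj = json.loads(text)
        model = cls(classes=tuple(obj["classes"]), rm=obj["rm"])
        model.variables_ = list(obj["variables"])
        model.scale_min_ = np.asarray(obj["scale_min"], dtype=float)
        model.scale_max_ = np.asarray(obj["scale_max"], dtype=float)
        model.feature_names_ = list(obj["feature_names"])
        model.beta_ = np.asarray(obj["beta"], dtype=float)
        model.lambda_ = np.asarray(obj["lambda"], dtype=float)
        model._eta_shift_ = float(obj["eta_shift"])
        model.background_Z_ = float(obj["background_Z"])
        model.entropy_H_ = float(obj["entropy_H"])
        model.gain_trace_ = []
        model.converged_ = True
        return model


def project_maxent(model: MaxEntSDM, stack: ClimateStack,
                   output: str = "raw") -> np.ndarray:
    """Per-cell maxent prediction grid; nodata (NaN) outside the valid mask."""
    check_is_fitted(model, "beta_")
    sub = stack.subset(model.variables_)
    if not sub.valid_mask.any():
        raise ValueError("stack has no valid cells for the model variables")
    cells = sub.valid_cells()
    X = pd.DataFrame(
        {v: sub.values[i][cells[:, 0], cells[:, 1]]
         for i, v in enumerate(model.variables_)}
    )
    grid = sub.blank_grid()
    grid[cells[:, 0], cells[:, 1]] = model.predict(X, output=output)
    return grid
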