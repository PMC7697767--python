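"""The BIOCLIM percentile-envelope suitability model.

BIOCLIM is a profile method: it stores the empirical distribution of each
climate variable at the training presences and scores a location by how
central its values are within those distributions.  Per variable the
percentile of the cell value is computed with midrank tie handling,

    p = (#train < value + 0.5 * #train == value) / n_train,

folded around the median and doubled: ``s = 2 * min(p, 1 - p)``, so a value
at the training median scores 1 and values drift toward 0 as they approach
the envelope edges; values outside the training min-max score exactly 0.  The
cell score is the minimum over variables (the most limiting variable).

Two tail conventions are provided.  The default ``continuous`` mode keeps the
doubled-percentile score all the way to the envelope edge.  The alternative
``clamped10_90`` mode additionally zeroes any value below the 10th or above
the 90th training percentile, a coarser convention some descriptions of the
algorithm use; it can only lower scores.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .grids import ClimateStack

__all__ = ["BioclimEnvelope", "fit_envelope", "project_envelope"]


class BioclimEnvelope(BaseEstimator):
    """Percentile-envelope suitability model (presence-only).

    Parameters
    ----------
    tails : {"continuous", "clamped10_90"}
        Tail convention, see module docstring.

    Attributes
    ----------
    variables_ : list of str
        Variable codes, in training-column order.
    envelope_ : dict of str -> ndarray
        Sorted training values per variable.
    n_train_ : int
    """

    def __init__(self, tails: str = "continuous"):
        self.tails = tails

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Store sorted per-variable training samples from presence rows.

        ``X`` is a DataFrame (or 2-D array) of climate values at presences; no
        parameters are estimated beyond the empirical distributions.
        """
        if self.tails not in ("continuous", "clamped10_90"):
            raise ValueError(f"unknown tails mode {self.tails!r}")
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        if len(X) == 0:
            raise ValueError("cannot fit an envelope on zero presences")
        if X.isna().to_numpy().any():
            raise ValueError("presence matrix contains missing values")
        self.variables_ = list(X.columns)
        self.envelope_ = {
            v: np.sort(X[v].to_numpy(dtype=float)) for v in self.variables_
        }
        self.n_train_ = len(X)
        return self

    # -- scoring ------------------------------------------------------------

    def percentile_score(self, variable: str, value) -> np.ndarray | float:
        """Midrank percentile of ``value`` within the training distribution."""
        check_is_fitted(self, "envelope_")
        if variable not in self.envelope_:
            raise KeyError(f"variable {variable!r} not in the model")
        train = self.envelope_[variable]
        value = np.asarray(value, dtype=float)
        less = np.searchsorted(train, value, side="left")
        leq = np.searchsorted(train, value, side="right")
        p = (less + 0.5 * (leq - less)) / self.n_train_
        return float(p) if p.ndim == 0 else p

    def _variable_score(self, variable: str, value: np.ndarray) -> np.ndarray:
        train = self.envelope_[variable]
        p = self.percentile_score(variable, value)
        p = np.atleast_1d(np.asarray(p, dtype=float))
        s = 2.0 * np.minimum(p, 1.0 - p)
        value = np.atleast_1d(np.asarray(value, dtype=float))
        s[(value < train[0]) | (value > train[-1])] = 0.0
        if self.tails == "clamped10_90":
            s[(p < 0.1) | (p > 0.9)] = 0.0
        return s

    def predict(self, X) -> np.ndarray:
        """Suitability in [0, 1] per row: min over variables of the tail score."""
        check_is_fitted(self, "envelope_")
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        missing = [v for v in self.variables_ if v not in X.columns]
        if missing:
            raise KeyError(f"input lacks model variables {missing}")
        if X[self.variables_].isna().to_numpy().any():
            raise ValueError("input contains missing values")
        score = np.ones(len(X))
        for v in self.variables_:
            score = np.minimum(score, self._variable_score(v, X[v].to_numpy()))
        return score

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "envelope_")
        return json.dumps({
            "model": "bioclim",
            "tails": self.tails,
            "n_train": self.n_train_,
            "envelope": {v: self.envelope_[v].tolist() for v in self.variables_},
            "variables": self.variables_,
        })

    @classmethod
    def from_json(cls, text: str) -> "BioclimEnvelope":
        obj = json.loads(text)
        model = cls(tails=obj["tails"])
        model.variables_ = list(obj["variables"])
        model.envelope_ = {v: np.asarray(obj["envelope"][v], dtype=float)
                           for v in model.variables_}
        model.n_train_ = int(obj["n_train"])
        return model


def fit_envelope(presences: pd.DataFrame, variables: list[str],
                 tails: str = "continuous") -> BioclimEnvelope:
    """Fit an envelope on the presence rows (label == 1) of a sample matrix."""
    if "label" in presences.columns:
        presences = presences[presences["label"] == 1]
    return BioclimEnvelope(tails=tails).fit(presences[list(variables)])


def project_envelope(model: BioclimEnvelope, stack: ClimateStack) -> np.ndarray:
    """Per-cell suitability grid; nodata (NaN) outside the valid mask."""
    check_is_fitted(model, "envelope_")
    sub = stack.subset(model.variables_)  # raises KeyError on a missing layer
    if not sub.valid_mask.any():
        raise ValueError("stack has no valid cells for the model variables")
    cells = sub.valid_cells()
    X = pd.DataFrame(
        {v: sub.values[i][cells[:, 0], cells[:, 1]]
         for i, v in enumerate(model.variables_)}
    )
    grid = sub.blank_grid()
    grid[cells[:, 0], cells[:, 1]] = model.predict(X)
    return grid
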