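"""Presence-background model evaluation.

AUC here is the Mann-Whitney rank statistic: the probability that a random
presence scores above a random background point, with ties counted half.  The
binarization threshold is chosen by maxSSS — the observed score maximizing
sensitivity + specificity (Youden's J) under the rule "presence iff
score >= t" — the recommended threshold criterion for presence-only data.
Permutation importance shuffles one variable at a time across all rows
(presences and background jointly), re-scores with the unrefitted model and
normalizes the AUC drops to percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import variable_columns

__all__ = [
    "roc_auc",
    "roc_curve_points",
    "max_sss_threshold",
    "apply_threshold",
    "permutation_importance",
    "summarize_occurrence_climate",
    "EvalReport",
    "evaluate_scores",
]


def roc_auc(scores_presence, scores_background) -> float:
    """Rank-based AUC with midrank tie correction, O(n log n).

    Equals ``[sum over pairs of 1(p > a) + 0.5 * 1(p == a)] / (n_p * n_a)``.
    """
    p = np.asarray(scores_presence, dtype=float)
    a = np.asarray(scores_background, dtype=float)
    if len(p) == 0 or len(a) == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([p, a]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(a)))


def _sens_spec_at(p_sorted, a_sorted, t):
    """Vectorized sensitivity/specificity of the rule score >= t."""
    t = np.asarray(t, dtype=float)
    # count form (not 1 - k/n) so equal-rate ties are exact in floats
    sens = (len(p_sorted) - np.searchsorted(p_sorted, t, side="left")) / len(p_sorted)
    spec = np.searchsorted(a_sorted, t, side="left") / len(a_sorted)
    return sens, spec


def max_sss_threshold(scores_presence, scores_background):
    """maxSSS threshold: the observed score maximizing sens + spec.

    Candidates are all distinct observed scores; ties in the objective break
    to the smallest threshold.  Returns ``(threshold, sensitivity,
    specificity)``.
    """
    p = np.sort(np.asarray(scores_presence, dtype=float))
    a = np.sort(np.asarray(scores_background, dtype=float))
    if len(p) == 0 or len(a) == 0:
        raise ValueError("both score lists must be nonempty")
    cand = np.unique(np.concatenate([p, a]))
    # exact integer comparison of sens + spec = [(n_p-k_p)*n_a + k_a*n_p] /
    # (n_p*n_a), so mathematically tied candidates are true ties and the
    # first (smallest) threshold wins
    k_p = np.searchsorted(p, cand, side="left")
    k_a = np.searchsorted(a, cand, side="left")
    total = (len(p) - k_p) * len(a) + k_a * len(p)
    best = int(np.argmax(total))
    sens = (len(p) - k_p[best]) / len(p)
    spec = k_a[best] / len(a)
    return float(cand[best]), float(sens), float(spec)


def roc_curve_points(scores_presence, scores_background) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) at every distinct observed score."""
    p = np.sort(np.asarray(scores_presence, dtype=float))
    a = np.sort(np.asarray(scores_background, dtype=float))
    cand = np.unique(np.concatenate([p, a]))
    sens, spec = _sens_spec_at(p, a, cand)
    return pd.DataFrame({"threshold": cand, "sensitivity": sens,
                         "specificity": spec})


def apply_threshold(grid: np.ndarray, t: float) -> np.ndarray:
    """Binary presence/absence grid: 1 where value >= t, 0 below, NaN kept."""
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    grid = np.asarray(grid, dtype=float)
    out = np.where(grid >= t, 1.0, 0.0)
    out[np.isnan(grid)] = np.nan
    return out


def permutation_importance(model, data: pd.DataFrame, n_reps: int = 10,
                           seed: int = 0) -> pd.DataFrame:
    """Normalized permutation importance (percent) per climate variable.

    For each variable its column is shuffled across all rows (presence and
    background jointly), the unrefitted model re-scores the table and the AUC
    drop relative to the unpermuted AUC is averaged over ``n_reps`` shuffles.
    Negative drops are clipped at zero and the drops are normalized to sum to
    100 (all-zero drops yield all-zero importances).
    """
    variables = [v for v in variable_columns(data)]
    missing = [v for v in getattr(model, "variables_", variables) if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables {missing}")
    rng = np.random.default_rng(seed)
    y = data["label"].to_numpy(dtype=int)
    X = data[variables]
    base_scores = model.predict(X)
    auc0 = roc_auc(base_scores[y == 1], base_scores[y == 0])
    drops = {}
    for v in variables:
        aucs = np.empty(n_reps)
        for r in range(n_reps):
            Xp = X.copy()
            Xp[v] = rng.permutation(Xp[v].to_numpy())
            s = model.predict(Xp)
            aucs[r] = roc_auc(s[y == 1], s[y == 0])
        drops[v] = max(0.0, auc0 - aucs.mean())
    total = sum(drops.values())
    importance = {
        v: (100.0 * d / total if total > 0 else 0.0) for v, d in drops.items()
    }
    out = pd.DataFrame({
        "variable": variables,
        "auc_drop": [drops[v] for v in variables],
        "importance_pct": [importance[v] for v in variables],
    })
    out.attrs["auc_original"] = auc0
    out.attrs["n_reps"] = n_reps
    out.attrs["seed"] = seed
    return out


def summarize_occurrence_climate(presences: pd.DataFrame,
                                 bins: int = 20) -> dict[str, dict]:
    """Per-variable min/max/mean and fixed-width histogram of presence climate."""
    if "label" in presences.columns:
        presences = presences[presences["label"] == 1]
    if len(presences) == 0:
        raise ValueError("no presence rows to summarize")
    out = {}
    for v in variable_columns(presences):
        x = presences[v].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        counts, edges = (np.histogram(x, bins=bins, range=(lo, hi))
                         if hi > lo else np.histogram(x, bins=bins))
        out[v] = {
            "min": lo,
            "max": hi,
            "mean": float(x.mean()),
            "bin_edges": edges.tolist(),
            "counts": counts.tolist(),
        }
    return out


@dataclass
class EvalReport:
    """AUC, ROC points and the maxSSS operating point for one model."""

    auc: float
    threshold_maxsss: float
    sens_at_t: float
    spec_at_t: float
    roc: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "threshold_maxsss": self.threshold_maxsss,
            "sens_at_t": self.sens_at_t,
            "spec_at_t": self.spec_at_t,
        }


def evaluate_scores(scores_presence, scores_background) -> EvalReport:
    """Full presence-background evaluation of one model's scores."""
    auc = roc_auc(scores_presence, scores_background)
    t, sens, spec = max_sss_threshold(scores_presence, scores_background)
    roc = roc_curve_points(scores_presence, scores_background)
    return EvalReport(auc=auc, threshold_maxsss=t, sens_at_t=sens,
                      spec_at_t=spec, roc=roc)
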