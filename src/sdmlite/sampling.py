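"""Pseudoabsence (background) sampling and k-fold partitioning of presences.

Background points stand in for absences in presence-only modelling: random
cells of the landscape, restricted to valid (climate-complete) cells so every
point carries a full climate vector.  Presences are split into k folds of
near-equal size for train/test evaluation; with the study design of 9,246
presences and k=5, holding out a minimal fold leaves 7,397 training points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import ClimateStack

__all__ = ["sample_background", "kfold_partition"]


def sample_background(stack: ClimateStack, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` distinct valid cells uniformly without replacement.

    Returns the cell centers as a DataFrame with ``lon``/``lat`` columns and
    ``attrs`` recording ``n_requested`` and ``seed``.  Deterministic for a
    given (stack, n, seed).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    cells = stack.valid_cells()
    if n > len(cells):
        raise ValueError(
            f"requested {n} background points but the stack has only "
            f"{len(cells)} valid cells"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(cells), size=n, replace=False)
    lon, lat = stack.cell_center(cells[pick, 0], cells[pick, 1])
    out = pd.DataFrame({"lon": lon, "lat": lat})
    out.attrs["n_requested"] = n
    out.attrs["seed"] = seed
    return out


def kfold_partition(n_points: int, k: int, seed: int) -> np.ndarray:
    """Assign each of ``n_points`` to one of ``k`` folds (labels 1..k).

    A random permutation is dealt round-robin, so fold sizes differ by at most
    one; fold 1 receives the extra point(s).  Deterministic per seed.
    """
    if not 2 <= k <= n_points:
        raise ValueError(f"k must be in [2, n_points]; got k={k}, n={n_points}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_points)
    folds = np.empty(n_points, dtype=int)
    folds[perm] = np.arange(n_points) % k + 1
    return folds
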