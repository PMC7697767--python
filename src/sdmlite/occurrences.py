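"""Reading and cleaning georeferenced occurrence records.

Occurrence tables (e.g. GBIF exports) arrive as delimited text with a
longitude and a latitude column and arbitrary other columns.  Cleaning applies
four rules, in order, each with its own provenance count:

1. drop records with a missing (unparseable) longitude or latitude;
2. drop records with coordinates outside [-180, 180] x [-90, 90];
3. drop exact duplicate (lon, lat) pairs, keeping the first in input order;
4. drop records whose containing grid cell is nodata in the reference climate
   stack — the operational reading of "on water", which also guarantees every
   retained point yields a complete climate vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ClimateStack

__all__ = ["OccurrenceSet", "read_occurrences", "clean_occurrences", "write_occurrences"]

#: provenance keys, in rule order
DROP_RULES = ("missing", "range", "duplicate", "water")


@dataclass
class OccurrenceSet:
    """Cleaned presence points plus counts of records dropped per rule."""

    points: pd.DataFrame  # columns lon, lat
    provenance: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in DROP_RULES}
    )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_dropped(self) -> int:
        return sum(self.provenance.values())


def read_occurrences(path, lon_col: str = "lon", lat_col: str = "lat",
                     sep: str | None = None) -> pd.DataFrame:
    """Read a delimited occurrence table into a raw table.

    The named coordinate columns are coerced to float; unparseable entries
    become NaN rather than errors (raw input may be dirty).  ``sep=None``
    sniffs the delimiter (comma default, tab accepted).  The returned frame
    keeps all original columns and adds/overwrites float ``lon``/``lat``.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str)
    for col in (lon_col, lat_col):
        if col not in df.columns:
            raise ValueError(
                f"{path}: column {col!r} not found (have {list(df.columns)})"
            )
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    df = df.drop(columns=[c for c in ("lon", "lat") if c in df.columns])
    df["lon"] = lon
    df["lat"] = lat
    return df


def clean_occurrences(raw: pd.DataFrame, mask: ClimateStack) -> OccurrenceSet:
    """Apply the four cleaning rules against a reference stack's validity mask.

    Rules run in the order missing -> range -> duplicate -> water; every
    record is dropped by at most one rule.  Cleaning is idempotent and the
    output preserves input order.  An empty result is a warning, not an error.
    """
    lon = raw["lon"].to_numpy(dtype=float)
    lat = raw["lat"].to_numpy(dtype=float)
    n = len(raw)
    alive = np.ones(n, dtype=bool)
    prov: dict[str, int] = {}

    missing = ~(np.isfinite(lon) & np.isfinite(lat))
    prov["missing"] = int(missing.sum())
    alive &= ~missing

    out_of_range = alive & ~(
        (lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90)
    )
    prov["range"] = int(out_of_range.sum())
    alive &= ~out_of_range

    # exact equality on the coordinate pair as read — no rounding
    seen: set[tuple[float, float]] = set()
    dup = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(alive):
        key = (lon[i], lat[i])
        if key in seen:
            dup[i] = True
        else:
            seen.add(key)
    prov["duplicate"] = int(dup.sum())
    alive &= ~dup

    idx = np.flatnonzero(alive)
    row, col = mask.point_to_cell(lon[idx], lat[idx])
    row = np.atleast_1d(row)
    col = np.atleast_1d(col)
    on_water = np.ones(len(idx), dtype=bool)
    inside = row >= 0
    on_water[inside] = ~mask.valid_mask[row[inside], col[inside]]
    prov["water"] = int(on_water.sum())
    alive[idx[on_water]] = False

    points = pd.DataFrame({"lon": lon[alive], "lat": lat[alive]})
    if not len(points) and n:
        warnings.warn("cleaning removed every occurrence record", stacklevel=2)
    return OccurrenceSet(points=points.reset_index(drop=True), provenance=prov)


def write_occurrences(points: pd.DataFrame, path, sep: str = ",") -> None:
    points.to_csv(path, sep=sep, index=False, columns=["lon", "lat"])
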