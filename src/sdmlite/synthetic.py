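"""Virtual-species simulation: synthetic climate stacks and occurrences.

Real bioclimatic layers are spatially smooth and inter-correlated, and the
occurrence-climate profiles of a well-sampled species are unimodal — records
concentrate where a few variables sit near the species' optima.  The
generator emulates exactly that structure so every pipeline stage can be
validated against a known truth:

* each layer is seeded Gaussian noise smoothed with a length-scale (spectral
  smoothing via a Gaussian kernel), optionally mixed with a shared latent
  field to induce inter-layer correlation, then affinely rescaled to a
  declared unit range (temperature-like and precipitation-like ranges
  alternate);
* the validity mask is a full rectangle with an optional carved "ocean"
  block of nodata cells;
* the virtual species responds to a subset of variables through a Gaussian
  product, ``truth(x) = prod_v exp(-(x_v - mu_v)^2 / (2 sigma_v^2))`` — a
  product, so every used variable is limiting;
* occurrences are valid cells sampled without replacement with probability
  proportional to truth (or, optionally, the top-truth cells), returned as
  cell centers so the true suitability of every record is exactly computable.

``load_default_fixture`` regenerates the packaged desk-scale study bundle
(60 x 100 grid, 6 layers, 2 niche-driving variables, 400 presences, fixed
seed) from the config shipped with the package.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ClimateStack, write_raster
from .occurrences import OccurrenceSet, write_occurrences

__all__ = [
    "SimConfig",
    "VirtualSpecies",
    "generate_climate_stack",
    "define_virtual_species",
    "sample_occurrences",
    "make_fixture",
    "load_default_fixture",
]

# unit ranges cycled over layers: odd layers temperature-like (deg C),
# even layers precipitation-like (mm)
_LAYER_RANGES = [(-5.0, 28.0), (0.0, 2200.0), (-12.0, 24.0),
                 (100.0, 1800.0), (2.0, 35.0), (0.0, 600.0)]
_LAYER_UNITS = ["degC", "mm", "degC", "mm", "degC", "mm"]


@dataclass
class SimConfig:
    """Configuration of one synthetic study landscape."""

    nrows: int = 60
    ncols: int = 100
    n_layers: int = 6
    length_scale: float = 2.0   # smoothing sigma, in cells
    correlation: float = 0.15   # weight of the shared latent field, in [0, 1)
    n_presences: int = 400
    mode: str = "probabilistic"  # or "top-fraction"
    seed: int = 20201111
    x0: float = -25.0           # north-west corner, decimal degrees
    y0: float = 15.0
    cellsize: float = 0.5
    ocean: tuple | None = ((0, 18), (70, 100))  # (row0,row1),(col0,col1) block
    used_variables: tuple = ("bio1", "bio4")
    optima: tuple = (13.0, 850.0)
    breadths: tuple = (1.0, 60.0)

    def __post_init__(self):
        if min(self.nrows, self.ncols, self.n_layers, self.n_presences) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if self.mode not in ("probabilistic", "top-fraction"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")

    @property
    def codes(self) -> list[str]:
        return [f"bio{i + 1}" for i in range(self.n_layers)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        obj = json.loads(text)
        if obj.get("ocean") is not None:
            obj["ocean"] = tuple(tuple(b) for b in obj["ocean"])
        for key in ("used_variables", "optima", "breadths"):
            obj[key] = tuple(obj[key])
        return cls(**obj)


@dataclass
class VirtualSpecies:
    """A known niche response over a climate stack, with its truth grid."""

    stack: ClimateStack
    used_variables: list[str]
    optima: dict[str, float]
    breadths: dict[str, float]
    truth_grid: np.ndarray = field(repr=False, default=None)


def generate_climate_stack(config: SimConfig) -> ClimateStack:
    """Smooth, correlated, seeded synthetic climate layers on one grid."""
    rng = np.random.default_rng(config.seed)
    shape = (config.nrows, config.ncols)
    shared = rng.standard_normal(shape)
    layers = []
    w = np.sqrt(config.correlation)
    for _ in range(config.n_layers):
        own = rng.standard_normal(shape)
        fieldv = w * shared + np.sqrt(1.0 - config.correlation) * own
        if config.length_scale > 0:
            fieldv = ndimage.gaussian_filter(fieldv, sigma=config.length_scale,
                                             mode="reflect")
        fieldv = (fieldv - fieldv.mean()) / fieldv.std()
        layers.append(fieldv)
    values = []
    for i, fieldv in enumerate(layers):
        lo, hi = _LAYER_RANGES[i % len(_LAYER_RANGES)]
        span = fieldv.max() - fieldv.min()
        values.append(lo + (hi - lo) * (fieldv - fieldv.min()) / span)
    grid = np.stack(values)
    if config.ocean is not None:
        (r0, r1), (c0, c1) = config.ocean
        grid[:, r0:r1, c0:c1] = np.nan
    units = [_LAYER_UNITS[i % len(_LAYER_UNITS)] for i in range(config.n_layers)]
    return ClimateStack(config.codes, grid, config.x0, config.y0,
                        config.cellsize, units=units)


def define_virtual_species(stack: ClimateStack, used_variables, optima,
                           breadths) -> VirtualSpecies:
    """Gaussian-product niche response; truth in [0, 1], nodata preserved."""
    used = list(used_variables)
    unknown = [v for v in used if v not in stack.codes]
    if unknown:
        raise KeyError(f"used variables {unknown} not in the stack")
    if np.any(np.asarray(breadths, dtype=float) <= 0):
        raise ValueError("breadths must be positive")
    mu = {v: float(m) for v, m in zip(used, optima)}
    sig = {v: float(s) for v, s in zip(used, breadths)}
    truth = np.ones(stack.shape)
    for v in used:
        x = stack.layer(v)
        truth = truth * np.exp(-((x - mu[v]) ** 2) / (2.0 * sig[v] ** 2))
    truth[stack.nodata_mask] = np.nan
    return VirtualSpecies(stack=stack, used_variables=used, optima=mu,
                          breadths=sig, truth_grid=truth)


def sample_occurrences(species: VirtualSpecies, n: int, mode: str,
                       seed: int) -> OccurrenceSet:
    """Draw occurrence cells from the truth surface; returns cell centers.

    ``probabilistic``: valid cells without replacement, inclusion probability
    proportional to truth.  ``top-fraction``: the ``n`` highest-truth cells
    (ties broken by row-major order).
    """
    stack = species.stack
    cells = stack.valid_cells()
    truth = species.truth_grid[cells[:, 0], cells[:, 1]]
    if n == 0:
        return OccurrenceSet(points=pd.DataFrame({"lon": [], "lat": []}))
    if mode == "top-fraction":
        if n > len(cells):
            raise ValueError(f"n={n} exceeds the {len(cells)} valid cells")
        order = np.argsort(-truth, kind="stable")[:n]
    elif mode == "probabilistic":
        if n > (truth > 0).sum():
            raise ValueError(
                f"n={n} exceeds the {(truth > 0).sum()} cells of positive truth"
            )
        rng = np.random.default_rng(seed)
        order = rng.choice(len(cells), size=n, replace=False,
                           p=truth / truth.sum())
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    lon, lat = stack.cell_center(cells[order, 0], cells[order, 1])
    return OccurrenceSet(points=pd.DataFrame({"lon": lon, "lat": lat}))


def make_fixture(config: SimConfig, out_dir, fmt: str = "asc") -> dict:
    """Write the full bundle (rasters, occurrences, truth, config) to disk.

    Returns a manifest of written paths.  Regenerating from the stored config
    reproduces identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    stack = generate_climate_stack(config)
    species = define_virtual_species(stack, config.used_variables,
                                     config.optima, config.breadths)
    occ = sample_occurrences(species, config.n_presences, config.mode,
                             config.seed)
    manifest = {"rasters": [], "codes": stack.codes}
    for i, code in enumerate(stack.codes):
        path = os.path.join(out_dir, f"{code}.{fmt}")
        write_raster(stack.values[i], stack, path)
        manifest["rasters"].append(path)
    truth_path = os.path.join(out_dir, f"truth.{fmt}")
    write_raster(species.truth_grid, stack, truth_path)
    manifest["truth"] = truth_path
    occ_path = os.path.join(out_dir, "occurrences.csv")
    write_occurrences(occ.points, occ_path)
    manifest["occurrences"] = occ_path
    config_path = os.path.join(out_dir, "config.json")
    with open(config_path, "w", encoding="utf-8") as fh:
        fh.write(config.to_json())
    manifest["config"] = config_path
    return manifest


def default_config() -> SimConfig:
    """The packaged desk-scale study configuration."""
    text = resources.files("sdmlite").joinpath("data/default_fixture.json").read_text()
    return SimConfig.from_json(text)


def load_default_fixture():
    """Regenerate the packaged fixture; returns (config, stack, species, occurrences)."""
    config = default_config()
    stack = generate_climate_stack(config)
    species = define_virtual_species(stack, config.used_variables,
                                     config.optima, config.breadths)
    occ = sample_occurrences(species, config.n_presences, config.mode,
                             config.seed)
    return config, stack, species, occ
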