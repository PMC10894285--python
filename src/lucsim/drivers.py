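"""Covariate stack for the conversion model.

The probability that a native-vegetation cell is converted to anthropogenic
use within one two-year step is ``1 / (1 + exp(-k))`` where ``k`` is a linear
combination of driver covariates.  This module holds the covariate stack
(static drivers, per-period dynamic drivers, and the endogenous neighborhood
land-cover channel), the binary landscape state, covariate standardization,
and the evaluation of the linear predictor ``k``.

Conventions
-----------
* Grids are row-major 2-D numpy arrays; cell (0, 0) is the north-west corner.
* A landscape raster holds 1 for native vegetation and 0 for anthropogenic use.
* Variable names are a closed vocabulary (``TABLE_ORDER``); ``land_cover`` is
  the only covariate recomputed from the evolving state at every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.special import expit  # noqa: F401  (re-exported convenience)

logger = logging.getLogger(__name__)

#: Reporting order of the model variables (endogenous land cover first,
#: protected areas last).
TABLE_ORDER: tuple[str, ...] = (
    "land_cover",
    "distance_to_roads",
    "distance_to_cities",
    "dry_season_length",
    "elevation",
    "agricultural_potential",
    "distance_to_rivers",
    "cattle",
    "permanent_agriculture",
    "annual_crop_agriculture",
    "protected_areas",
)

#: Raster driver names (everything except the endogenous neighborhood channel).
DRIVER_NAMES: tuple[str, ...] = tuple(n for n in TABLE_ORDER if n != "land_cover")

#: Drivers that change between calibration periods (one layer per period).
DYNAMIC_NAMES: tuple[str, ...] = (
    "cattle",
    "permanent_agriculture",
    "annual_crop_agriculture",
)

#: Covariates never z-standardized: the protected-area indicator stays a raw
#: 0/1 flag so its coefficient is directly comparable across periods, and the
#: neighborhood land-cover fraction is already on [0, 1].
UNSCALED_NAMES: frozenset[str] = frozenset({"protected_areas", "land_cover"})


@dataclass
class LandscapeState:
    """Binary native-vegetation map at one time step.

    ``native`` holds 1 where native vegetation persists and 0 where the cell
    is under anthropogenic use.  ``time`` is the calendar year of the map.
    """

    time: int
    native: np.ndarray

    def __post_init__(self) -> None:
        self.native = np.asarray(self.native, dtype=np.uint8)
        if self.native.ndim != 2:
            raise ValueError("native raster must be 2-D")
        bad = (self.native != 0) & (self.native != 1)
        if bad.any():
            raise ValueError("native raster must be binary (0/1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.native.shape

    def copy(self) -> "LandscapeState":
        return LandscapeState(self.time, self.native.copy())


@dataclass
class CoefficientVector:
    """Intercept plus named driver coefficients of the linear predictor."""

    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")

    def names(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class DriverStack:
    """Aligned covariate rasters plus frozen standardization parameters.

    ``layers`` maps a variable name to either a 2-D array (static driver) or a
    3-D array with one leading layer per calibration period (dynamic driver).
    ``standardization`` maps a name to the (mean, sd) frozen at calibration
    time; an empty map means the stack holds raw, unstandardized values.
    """

    rows: int
    cols: int
    cell_area: float
    layers: dict[str, np.ndarray]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape[-2:] != (self.rows, self.cols):
                raise ValueError(f"layer {name!r} does not match the grid shape")
        for name, (_, sd) in self.standardization.items():
            if sd <= 0:
                raise ValueError(f"layer {name!r} has non-positive sd")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_periods(self) -> int:
        periods = [a.shape[0] for a in self.layers.values() if a.ndim == 3]
        return max(periods) if periods else 1

    def layer_at(self, name: str, period_index: int) -> np.ndarray:
        """Layer of ``name`` for one period.

        Dynamic drivers beyond the last observed period are held fixed at
        their final layer (no update of census-style drivers during
        projection).
        """
        arr = self.layers[name]
        if arr.ndim == 2:
            return arr
        return arr[min(period_index, arr.shape[0] - 1)]

    def active_names(self) -> list[str]:
        """Candidate variable names in reporting order (excluded layers dropped)."""
        out = []
        for name in TABLE_ORDER:
            if name == "land_cover" or (name in self.layers and name not in self.excluded):
                out.append(name)
        return out

    def copy(self) -> "DriverStack":
        return DriverStack(
            self.rows,
            self.cols,
            self.cell_area,
            {k: v.copy() for k, v in self.layers.items()},
            dict(self.standardization),
            list(self.excluded),
        )


_count_cache: dict[tuple[tuple[int, int], int], np.ndarray] = {}


def _window_counts(shape: tuple[int, int], radius: int) -> np.ndarray:
    """Number of in-grid cells of each (2r+1)^2 window (edge-truncated)."""
    key = (shape, radius)
    if key not in _count_cache:
        ones = np.ones(shape, dtype=np.float64)
        size = 2 * radius + 1
        _count_cache[key] = np.rint(
            uniform_filter(ones, size=size, mode="constant", cval=0.0) * size * size
        )
    return _count_cache[key]


def neighborhood_landcover(state: LandscapeState, radius: int = 3) -> np.ndarray:
    """Fraction of anthropogenic cells in the Moore window around each cell.

    The window is the (2r+1) x (2r+1) square centred on the cell, truncated at
    the grid edge; the focal cell itself is excluded from the count.  This is
    the endogenous "land cover" covariate: it is recomputed from the current
    state at every simulation step, so local vegetation suppression feeds back
    into subsequent conversion probabilities.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    anth = (state.native == 0).astype(np.float64)
    size = 2 * radius + 1
    sums = uniform_filter(anth, size=size, mode="constant", cval=0.0) * size * size
    counts = _window_counts(state.shape, radius)
    frac = (sums - anth) / np.maximum(counts - 1.0, 1.0)
    return np.clip(frac, 0.0, 1.0)


def standardize(stack: DriverStack, training_cells: np.ndarray) -> DriverStack:
    """Z-standardize continuous layers over the training cells.

    Each continuous driver is transformed to zero mean and unit standard
    deviation computed over ``training_cells`` (a boolean grid mask); dynamic
    drivers pool all period layers.  Binary / bounded covariates
    (``protected_areas``; the ``land_cover`` fraction) are left raw.  The
    (mean, sd) pairs are frozen on the returned stack and reused verbatim at
    every projection step.  A constant layer (sd = 0) cannot be standardized
    and is excluded from the candidate set with a logged warning.

    Standardizing an already-standardized stack is the identity.
    """
    training_cells = np.asarray(training_cells, dtype=bool)
    if not training_cells.any():
        raise ValueError("training_cells is empty")
    if stack.standardization:
        return stack
    out = stack.copy()
    for name, arr in out.layers.items():
        if name in UNSCALED_NAMES:
            continue
        vals = arr[..., training_cells] if arr.ndim == 3 else arr[training_cells]
        mean = float(np.mean(vals))
        sd = float(np.std(vals))
        if sd == 0.0:
            logger.warning("driver %r is constant on training cells; excluded", name)
            out.excluded.append(name)
            continue
        out.layers[name] = (arr - mean) / sd
        out.standardization[name] = (mean, sd)
    return out


def linear_predictor(
    stack: DriverStack,
    coefficients: CoefficientVector,
    state: LandscapeState,
    period_index: int,
    radius: int = 3,
) -> np.ndarray:
    """Evaluate k(x) = b0 + sum_v b_v z_v(x, t) over native cells.

    ``land_cover`` is computed from ``state``; every other coefficient must
    name a layer present in the stack.  Anthropogenic cells carry no defined
    predictor and are returned as NaN.
    """
    k = np.full(state.shape, coefficients.intercept, dtype=np.float64)
    for name, beta in coefficients.coefficients.items():
        if name != "land_cover" and name not in stack.layers:
            raise KeyError(f"coefficient references missing layer {name!r}")
        if beta == 0.0:
            continue
        if name == "land_cover":
            layer = neighborhood_landcover(state, radius)
        else:
            layer = stack.layer_at(name, period_index)
        k = k + beta * layer
    k[state.native == 0] = np.nan
    return k


def conversion_probability(k: np.ndarray) -> np.ndarray:
    """Logistic conversion probability 1 / (1 + exp(-k))."""
    return expit(k)
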