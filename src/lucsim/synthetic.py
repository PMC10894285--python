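"""Synthetic landscapes with the statistical structure the analysis assumes.

Real inputs for this kind of study (satellite land-cover time series, a
georeferenced rural-property registry, municipal census rasters) are not
redistributable, so this module generates stand-ins with the features the
model relies on: spatially autocorrelated driver fields, Euclidean
distance-to-feature rasters, a heavy-tailed mosaic of contiguous rural
properties spanning size classes C1-C5 with regional Legal Reserve
fractions, and conversion histories produced by the model's own logistic
rule from known coefficients — so calibration can be checked against ground
truth.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.special import expit

from .drivers import (
    DYNAMIC_NAMES,
    CoefficientVector,
    DriverStack,
    LandscapeState,
    linear_predictor,
    standardize,
)
from .scenarios import LEGAL_LR_FRACTIONS, PropertyMap, classify_property

#: Sub-stream labels so each generated component has an independent,
#: reproducible random stream derived from the config seed.
_STREAMS = {"drivers": 1, "pa": 2, "properties": 3, "history": 4, "initial": 5}

#: Source-cell density (cells per source) of the distance rasters.
_SOURCE_DENSITY = {
    "distance_to_roads": 800,
    "distance_to_cities": 2000,
    "distance_to_rivers": 500,
}


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic landscape.

    Defaults describe a 200 x 200 grid of 1 km^2 cells (100 ha each, the
    analysis resolution), four two-year calibration periods starting in
    2008, 10% strictly protected cells, a lognormal property-size law with
    median 300 ha and log-sd 1.5 (heavy-tailed, all five size classes
    realized on the default grid), and two LR regions: an ordinary savanna
    region at the 20% Legal Reserve and a Legal-Amazon transition band at
    35%.  The generating coefficients act on z-standardized drivers; signs
    follow the calibrated pattern (access and agricultural potential drive
    conversion, protection prevents it, anthropogenic neighborhoods attract
    further conversion).
    """

    grid_rows: int = 200
    grid_cols: int = 200
    cell_area: float = 100.0
    n_periods: int = 4
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "distance_to_roads": -0.6,
            "agricultural_potential": 0.5,
            "protected_areas": -1.3,
            "land_cover": 2.5,
        }
    )
    intercept: float = -3.3
    property_size_law: dict[str, float] = field(
        default_factory=lambda: {"log_mean": math.log(300.0), "log_sd": 1.5}
    )
    pa_fraction: float = 0.10
    lr_regions: list[tuple[str, float]] = field(
        default_factory=lambda: [("cerrado", 0.20), ("legal_amazon_cerrado", 0.35)]
    )
    start_year: int = 2008
    seed: int = 0
    smoothing_sigma: float = 5.0
    ar1_rho: float = 0.9
    initial_anthropogenic_fraction: float = 0.0
    neighborhood_radius: int = 3

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid dimensions must be at least 8")
        if not 0.0 <= self.pa_fraction <= 1.0:
            raise ValueError("pa_fraction must lie in [0, 1]")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if self.n_periods < 1:
            raise ValueError("need at least one calibration period")
        if not self.lr_regions:
            raise ValueError("at least one LR region is required")
        for label, lr in self.lr_regions:
            if not any(abs(lr - v) < 1e-9 for v in LEGAL_LR_FRACTIONS):
                raise ValueError(
                    f"region {label!r}: lr_fraction {lr} is not one of the legal "
                    f"values {sorted(LEGAL_LR_FRACTIONS)}"
                )
        if not 0.0 <= self.initial_anthropogenic_fraction < 1.0:
            raise ValueError("initial_anthropogenic_fraction must lie in [0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_rows, self.grid_cols)

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class SyntheticDataset:
    """A complete synthetic study: drivers, states, properties, ground truth.

    ``drivers`` is the standardized stack actually used to generate the
    history (standardization frozen over all cells), ``observed_states``
    holds one landscape per period boundary, and ``truth`` records the
    generating intercept and coefficients for recovery checks.
    """

    drivers: DriverStack
    initial_state: LandscapeState
    observed_states: list[LandscapeState]
    properties: PropertyMap
    truth: dict

    def state_pairs(self) -> list[tuple[LandscapeState, LandscapeState]]:
        """Consecutive (start, end) states of each calibration period."""
        states = [self.initial_state, *self.observed_states]
        return list(zip(states[:-1], states[1:]))


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field (Gaussian-filtered noise)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _distance_raster(rng: np.random.Generator, shape, n_sources: int) -> np.ndarray:
    n_cells = shape[0] * shape[1]
    if n_sources < 1 or n_cells < n_sources:
        raise ValueError("grid too small to place the distance-raster source cells")
    flat = rng.choice(n_cells, size=n_sources, replace=False)
    sources = np.zeros(shape, dtype=bool)
    sources.reshape(-1)[flat] = True
    return distance_transform_edt(~sources)


def protected_mask(config: SyntheticConfig) -> np.ndarray:
    """Contiguous protected-area blobs covering ~pa_fraction of the grid."""
    if config.pa_fraction == 0.0:
        return np.zeros(config.shape, dtype=bool)
    rng = _rng(config, "pa")
    f = _smooth_field(rng, config.shape, config.smoothing_sigma)
    threshold = np.quantile(f, 1.0 - config.pa_fraction)
    return f > threshold


def generate_drivers(config: SyntheticConfig) -> DriverStack:
    """Generate the raw (unstandardized) driver stack.

    Distance rasters are Euclidean distance transforms from randomly seeded
    source cells (grid units); the climatic/terrain/economic fields are
    smoothed Gaussian noise on plausible scales; dynamic census drivers
    drift between periods as AR(1) perturbations of their first layer; the
    protected-area indicator is a binary field of contiguous blobs with mean
    approximately ``pa_fraction``.
    """
    rng = _rng(config, "drivers")
    shape = config.shape
    sigma = config.smoothing_sigma
    layers: dict[str, np.ndarray] = {}

    for name, per_source in _SOURCE_DENSITY.items():
        n_sources = max(1, config.n_cells // per_source)
        layers[name] = _distance_raster(rng, shape, n_sources)

    layers["dry_season_length"] = 5.0 + 1.0 * _smooth_field(rng, shape, sigma)  # months
    layers["elevation"] = 600.0 + 250.0 * _smooth_field(rng, shape, sigma)  # metres
    layers["agricultural_potential"] = 0.5 + 0.2 * _smooth_field(rng, shape, sigma)

    # census-style dynamic drivers: AR(1) anomalies around a static mean field
    dynamic_scales = {
        "cattle": (30.0, 12.0),  # head per km^2
        "permanent_agriculture": (0.10, 0.05),  # municipal area fraction
        "annual_crop_agriculture": (0.20, 0.08),
    }
    rho = config.ar1_rho
    for name in DYNAMIC_NAMES:
        mean, scale = dynamic_scales[name]
        anomaly = _smooth_field(rng, shape, sigma)
        stack = np.empty((config.n_periods,) + shape)
        for t in range(config.n_periods):
            if t:
                innovation = _smooth_field(rng, shape, sigma)
                anomaly = rho * anomaly + math.sqrt(1.0 - rho**2) * innovation
            stack[t] = np.clip(mean + scale * anomaly, 0.0, None)
        layers[name] = stack

    layers["protected_areas"] = protected_mask(config).astype(np.float64)

    return DriverStack(config.grid_rows, config.grid_cols, config.cell_area, layers)


def generate_properties(
    config: SyntheticConfig, protected: np.ndarray | None = None
) -> PropertyMap:
    """Tessellate the non-protected grid into contiguous rural properties.

    Target areas are drawn from the lognormal size law (truncated to the
    grid's capacity, minimum one cell) and realized by seeded region growing
    from random centroids; leftover enclosed cells join an adjacent property,
    so every non-protected cell belongs to exactly one property.  Each
    property inherits the LR fraction of its region (horizontal bands).
    """
    if protected is None:
        protected = protected_mask(config)
    rng = _rng(config, "properties")
    rows, cols = config.shape
    ids = np.full(config.shape, -1, dtype=np.int32)
    free = ~protected
    n_free = int(free.sum())
    if n_free == 0:
        return PropertyMap(ids, _property_table(config, ids, []))

    log_mean = config.property_size_law["log_mean"]
    log_sd = config.property_size_law["log_sd"]

    seeds_rc: list[tuple[int, int]] = []
    next_id = 0
    remaining = n_free
    free_work = free.copy()
    offsets = ((-1, 0), (1, 0), (0, -1), (0, 1))
    while remaining > 0:
        target_ha = float(rng.lognormal(log_mean, log_sd))
        target_cells = max(1, int(round(target_ha / config.cell_area)))
        target_cells = min(target_cells, remaining)
        # seed at a uniformly random still-free cell
        flat_free = np.flatnonzero(free_work.reshape(-1))
        start = int(flat_free[rng.integers(len(flat_free))])
        r0, c0 = divmod(start, cols)
        frontier = [(r0, c0)]
        free_work[r0, c0] = False
        ids[r0, c0] = next_id
        claimed = 1
        while claimed < target_cells and frontier:
            i = int(rng.integers(len(frontier)))
            r, c = frontier.pop(i)
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and free_work[rr, cc]:
                    free_work[rr, cc] = False
                    ids[rr, cc] = next_id
                    frontier.append((rr, cc))
                    claimed += 1
                    if claimed >= target_cells:
                        break
        seeds_rc.append((r0, c0))
        remaining -= claimed
        next_id += 1

    # attach any enclosed leftovers (none by construction, but keep the
    # partition guarantee robust if growth stalls)
    unassigned = free & (ids < 0)
    while unassigned.any():
        changed = False
        for r, c in np.argwhere(unassigned):
            neigh = []
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and ids[rr, cc] >= 0:
                    neigh.append(ids[rr, cc])
            if neigh:
                ids[r, c] = neigh[int(rng.integers(len(neigh)))]
                changed = True
        unassigned = free & (ids < 0)
        if not changed and unassigned.any():  # isolated island: its own property
            r, c = np.argwhere(unassigned)[0]
            ids[r, c] = next_id
            seeds_rc.append((int(r), int(c)))
            next_id += 1
            unassigned = free & (ids < 0)

    return PropertyMap(ids, _property_table(config, ids, seeds_rc))


def _property_table(
    config: SyntheticConfig, ids: np.ndarray, seeds_rc: list[tuple[int, int]]
) -> pd.DataFrame:
    n = len(seeds_rc)
    counts = np.bincount(ids[ids >= 0], minlength=n) if n else np.zeros(0, dtype=int)
    n_regions = len(config.lr_regions)
    band = max(1, math.ceil(config.grid_rows / n_regions))
    rows = []
    for pid in range(n):
        area = counts[pid] * config.cell_area
        region_idx = min(seeds_rc[pid][0] // band, n_regions - 1)
        label, lr = config.lr_regions[region_idx]
        rows.append(
            {
                "area_ha": float(area),
                "size_class": classify_property(area),
                "region": label,
                "lr_fraction": float(lr),
                "extra_protected_fraction": 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["area_ha", "size_class", "region", "lr_fraction", "extra_protected_fraction"]
    )


def initial_landscape(config: SyntheticConfig) -> LandscapeState:
    """Starting landscape: all native, optionally seeded with clustered
    anthropogenic cells (``initial_anthropogenic_fraction``)."""
    native = np.ones(config.shape, dtype=np.uint8)
    f = config.initial_anthropogenic_fraction
    if f > 0.0:
        rng = _rng(config, "initial")
        field_ = _smooth_field(rng, config.shape, config.smoothing_sigma)
        native[field_ > np.quantile(field_, 1.0 - f)] = 0
    return LandscapeState(config.start_year, native)


def generate_history(
    drivers: DriverStack,
    properties: PropertyMap,
    config: SyntheticConfig,
    rng_seed: int | None = None,
) -> SyntheticDataset:
    """Simulate the observed conversion history from known coefficients.

    Drivers are z-standardized over all cells (frozen on the returned
    stack); each of the ``n_periods`` two-year transitions converts every
    native cell independently with probability
    ``logistic(intercept + sum beta_v z_v(x, t))`` — the model's own rule,
    applied forward, with no LR or PA hard constraint (protection enters
    only through its coefficient, as in the observed record).
    """
    unknown = set(config.true_coefficients) - set(drivers.layers) - {"land_cover"}
    if unknown:
        raise ValueError(f"true coefficients reference unknown drivers: {sorted(unknown)}")
    stack = standardize(drivers, np.ones(config.shape, dtype=bool))
    truth_cv = CoefficientVector(config.intercept, dict(config.true_coefficients))

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if rng_seed is None else rng_seed, _STREAMS["history"]])
    )
    state = initial_landscape(config)
    observed: list[LandscapeState] = []
    for t in range(config.n_periods):
        period = min(t, stack.n_periods - 1)
        k = linear_predictor(stack, truth_cv, state, period, radius=config.neighborhood_radius)
        native = state.native == 1
        p = expit(k[native])
        if t == 0 and p.sum() < 1.0:
            raise ValueError(
                "degenerate configuration: fewer than one expected conversion per period"
            )
        u = rng.random(p.shape)
        new_native = state.native.copy()
        flat = np.flatnonzero(native.reshape(-1))
        new_native.reshape(-1)[flat[u < p]] = 0
        state = LandscapeState(state.time + 2, new_native)
        observed.append(state)

    return SyntheticDataset(
        drivers=stack,
        initial_state=initial_landscape(config),
        observed_states=observed,
        properties=properties,
        truth={"intercept": config.intercept, "coefficients": dict(config.true_coefficients)},
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Convenience: drivers + properties + history from one config."""
    drivers = generate_drivers(config)
    properties = generate_properties(
        config, protected=drivers.layers["protected_areas"].astype(bool)
    )
    return generate_history(drivers, properties, config)
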