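"""Rural properties, size classes, and policy-scenario transformations.

Brazil's Native Vegetation Protection Law ties conservation duties to
individual rural properties: each property must keep a Legal Reserve (LR)
fraction of its area under native vegetation (20% in most of the Cerrado;
35%, 50% or 80% inside the Legal Amazon).  Properties are reported in five
size classes: C1 (1-150 ha), C2 (150-400 ha), C3 (400-1000 ha),
C4 (1000-2500 ha) and C5 (> 2500 ha).

A policy scenario is expressed as a transformation of the projection
constraints: LR overrides by region, additional protected areas, and a
large-property rule that freezes an extra fraction of qualifying properties
(e.g. protect 30% of every property larger than 2500 ha).  Avoided loss is
the difference between business-as-usual (BAU) and scenario expected loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drivers import LandscapeState, neighborhood_landcover

logger = logging.getLogger(__name__)

SIZE_CLASSES: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5")

#: Upper bound (ha, inclusive) of each bounded size class.
_CLASS_UPPER = ((150.0, "C1"), (400.0, "C2"), (1000.0, "C3"), (2500.0, "C4"))

#: LR fractions admitted by the NVPL.
LEGAL_LR_FRACTIONS: frozenset[float] = frozenset({0.20, 0.35, 0.50, 0.80})


def classify_property(area_ha: float) -> str:
    """Size class of a property of ``area_ha`` hectares.

    Brackets are inclusive at their upper bound (150 ha -> C1, 2500 ha -> C4);
    C5 is strictly above 2500 ha.  Areas below 1 ha fall outside the
    classification and raise.
    """
    if not np.isfinite(area_ha) or area_ha < 1.0:
        raise ValueError(f"property area {area_ha} ha is below the 1 ha classification floor")
    for upper, cls in _CLASS_UPPER:
        if area_ha <= upper:
            return cls
    return "C5"


@dataclass
class PropertyMap:
    """Property ID raster plus the per-property attribute table.

    ``ids`` is an int32 raster with the property index of each cell and -1
    for cells belonging to no property (protected areas, public land).
    ``table`` is indexed by property id (0..n-1) with columns ``area_ha``,
    ``size_class``, ``region``, ``lr_fraction`` and
    ``extra_protected_fraction`` (a scenario field, 0 under BAU).
    """

    ids: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int32)
        required = {"area_ha", "size_class", "region", "lr_fraction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"property table missing columns {sorted(missing)}")
        if "extra_protected_fraction" not in self.table.columns:
            self.table = self.table.assign(extra_protected_fraction=0.0)
        n = len(self.table)
        if n and not np.array_equal(self.table.index.to_numpy(), np.arange(n)):
            raise ValueError("property table must be indexed 0..n-1")
        if self.ids.max(initial=-1) >= n:
            raise ValueError("id raster references a property outside the table")
        if (self.table["area_ha"] <= 0).any():
            raise ValueError("property areas must be positive")
        frozen = self.table["lr_fraction"] + self.table["extra_protected_fraction"]
        if (frozen > 1.0 + 1e-9).any():
            raise ValueError("lr_fraction + extra_protected_fraction exceeds 1")
        for pid, row in self.table.iterrows():
            if classify_property(row["area_ha"]) != row["size_class"]:
                raise ValueError(
                    f"property {pid}: class {row['size_class']} inconsistent with "
                    f"area {row['area_ha']} ha"
                )

    @property
    def n_properties(self) -> int:
        return len(self.table)

    def cell_counts(self) -> np.ndarray:
        """Number of cells of each property (length n_properties)."""
        inside = self.ids[self.ids >= 0]
        return np.bincount(inside, minlength=self.n_properties)

    def frozen_fraction(self) -> np.ndarray:
        """Effective frozen share per property (LR plus scenario additions)."""
        return (
            self.table["lr_fraction"].to_numpy(dtype=float)
            + self.table["extra_protected_fraction"].to_numpy(dtype=float)
        )

    def floor_cells(self) -> np.ndarray:
        """Minimum native cell count each property must keep.

        Computed as ceil(frozen_fraction x cells) with a small guard against
        floating-point excess (0.2 x 10 must floor to 2 cells, not 3).
        """
        counts = self.cell_counts()
        frac = self.frozen_fraction()
        return np.ceil(frac * counts - 1e-9).astype(np.int64)

    def copy(self) -> "PropertyMap":
        return PropertyMap(self.ids.copy(), self.table.copy())


@dataclass
class ScenarioConfig:
    """A policy scenario as constraint overrides.

    ``lr_overrides`` replaces the LR fraction of whole regions;
    ``pa_additions`` is an optional boolean raster of new strictly protected
    cells; ``large_property_rule`` freezes an extra fraction of every property
    above an area threshold, e.g. ``{"threshold_ha": 2500,
    "protected_fraction": 0.30}``.  Under the default ``additive`` mode the
    rule complements the Legal Reserve (a 30% rule on a 20%-LR property
    freezes 50% of its area); mode ``"max"`` reads the rule as a floor on the
    total frozen share instead.
    """

    name: str = "scenario"
    lr_overrides: dict[str, float] = field(default_factory=dict)
    pa_additions: np.ndarray | None = None
    large_property_rule: dict | None = None

    def __post_init__(self) -> None:
        rule = self.large_property_rule
        if rule is not None:
            if rule.get("threshold_ha", 0) <= 0:
                raise ValueError("large_property_rule threshold must be positive")
            f = rule.get("protected_fraction", 0.0)
            if not 0.0 <= f <= 1.0:
                raise ValueError("protected fraction must lie in [0, 1]")
            rule.setdefault("mode", "additive")
            if rule["mode"] not in ("additive", "max"):
                raise ValueError("large_property_rule mode must be 'additive' or 'max'")


def apply_scenario(
    base,
    properties: PropertyMap,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    state: LandscapeState,
    radius: int = 3,
):
    """Turn a BAU ConstraintSet into the scenario's ConstraintSet.

    LR overrides rewrite ``lr_fraction`` by region.  The large-property rule
    raises the effective frozen share of qualifying properties and pins the
    extra share to concrete cells: the currently native cells with the
    highest native-neighborhood fraction (largest intact remnants), ties
    broken at random.  Scenarios only ever add protection; the returned
    constraints dominate the input.
    """
    from .projection import ConstraintSet  # deferred: projection imports this module

    table = properties.table.copy()
    for region, lr in scenario.lr_overrides.items():
        if not 0.0 < lr <= 1.0:
            raise ValueError(f"lr override for {region!r} outside (0, 1]")
        sel = table["region"] == region
        table.loc[sel, "lr_fraction"] = np.maximum(table.loc[sel, "lr_fraction"], lr)

    protected = base.protected.copy()
    if scenario.pa_additions is not None:
        protected |= np.asarray(scenario.pa_additions, dtype=bool)

    frozen = np.zeros(state.shape, dtype=bool) if base.frozen is None else base.frozen.copy()

    rule = scenario.large_property_rule
    if rule is not None:
        counts = properties.cell_counts()
        qualifying = np.flatnonzero(table["area_ha"].to_numpy() > rule["threshold_ha"])
        if qualifying.size:
            # rank native cells once by intact-neighborhood share, rng tie-break
            nb_native = 1.0 - neighborhood_landcover(state, radius)
            jitter = rng.random(state.shape) * 1e-9
            score = nb_native + jitter
        for pid in qualifying:
            lr = float(table.at[pid, "lr_fraction"])
            f = float(rule["protected_fraction"])
            if rule["mode"] == "additive":
                extra = min(f, 1.0 - lr)
            else:  # total frozen share = max(lr, f)
                extra = max(0.0, f - lr)
            if extra <= 0.0:
                continue
            table.at[pid, "extra_protected_fraction"] = extra
            n_freeze = int(math.ceil(extra * counts[pid] - 1e-9))
            cells = np.flatnonzero(
                (properties.ids.reshape(-1) == pid) & (state.native.reshape(-1) == 1)
            )
            if cells.size < n_freeze:
                logger.warning(
                    "property %d: only %d native cells for a %d-cell freeze; freezing all",
                    pid, cells.size, n_freeze,
                )
                chosen = cells
            else:
                order = np.argsort(-score.reshape(-1)[cells], kind="stable")
                chosen = cells[order[:n_freeze]]
            flat = frozen.reshape(-1)
            flat[chosen] = True

    new_props = PropertyMap(properties.ids.copy(), table)
    return ConstraintSet(
        protected=protected,
        properties=new_props,
        pa_hard=base.pa_hard,
        frozen=frozen,
        label=scenario.name,
    )


def percent_of_baseline(avoided_ha: float, baseline_ha: float) -> float:
    """Avoided loss as a percentage of the baseline (BAU) loss."""
    if baseline_ha <= 0:
        raise ValueError("baseline loss must be positive")
    return 100.0 * avoided_ha / baseline_ha


def share_of_area(loss_ha: float, area_ha: float) -> float:
    """Projected loss as a percentage of a reference area (e.g. the biome)."""
    if area_ha <= 0:
        raise ValueError("reference area must be positive")
    return 100.0 * loss_ha / area_ha


def avoided_loss(bau, scenario_result, year: int) -> dict:
    """Avoided loss of a scenario relative to BAU at one horizon year.

    Returns the avoided hectares, the percentage of BAU loss (one decimal),
    and the integer headline percentage.  A negative avoided loss beyond
    three Monte Carlo standard errors of the difference is flagged as a
    configuration inconsistency (scenarios must only add protection).
    """
    bau_ha = bau.total_loss_ha(year)
    scen_ha = scenario_result.total_loss_ha(year)
    ha = bau_ha - scen_ha
    pct = percent_of_baseline(ha, bau_ha) if bau_ha > 0 else 0.0
    tb = bau.iteration_totals_ha(year)
    ts = scenario_result.iteration_totals_ha(year)
    se = math.sqrt(tb.var(ddof=1) / tb.size + ts.var(ddof=1) / ts.size) if tb.size > 1 else 0.0
    flagged = bool(ha < -3.0 * se - 1e-9)
    if flagged:
        logger.warning("scenario loses more than BAU (%.1f ha); check configuration", -ha)
    return {
        "avoided_ha": float(ha),
        "bau_loss_ha": float(bau_ha),
        "scenario_loss_ha": float(scen_ha),
        "percent_of_bau": round(pct, 1),
        "headline_percent": int(round(pct)),
        "flagged": flagged,
    }
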