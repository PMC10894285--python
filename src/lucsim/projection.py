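"""Monte Carlo projection of native-vegetation loss under legal constraints.

Starting from the last observed landscape, the model advances in two-year
steps.  At each step every convertible native cell is converted independently
with probability ``1 / (1 + exp(-k))``, where ``k`` is evaluated with one
coefficient vector drawn from the calibrated posterior (one draw per
iteration, so each iteration is an internally consistent world).  Protected
areas are a hard mask, and each rural property is frozen once its native
area reaches its Legal Reserve floor; a within-step overshoot of the floor is
cancelled in randomized cell order so the floor is exact.

Running 100 iterations and counting, per cell, the fraction of iterations in
which it has converted by a given year yields the accumulated conversion
probability map (a cell converted in 100 of 100 iterations has probability 1
of conversion by that year).  Models calibrated on different historical
periods are combined by cellwise averaging of their probability maps
(ensemble).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibration import Posterior
from .drivers import CoefficientVector, DriverStack, LandscapeState, linear_predictor
from .scenarios import SIZE_CLASSES, PropertyMap

logger = logging.getLogger(__name__)

STEP_YEARS = 2  # simulation tick: the calibration interval length

#: Ledger group label for cells outside any registered property.
PUBLIC = "public"


@dataclass
class ConstraintSet:
    """Constraints that bound conversion during projection.

    ``protected`` marks strictly protected cells (never convertible while
    ``pa_hard`` is true; with ``pa_hard`` false protection acts only through
    the protected-area covariate, as during calibration).  ``frozen`` holds
    scenario-frozen cells.  LR floors derive from the property map's
    effective frozen fraction.  Cells outside any property and outside PAs
    (untitled public land) are convertible with no floor.
    """

    protected: np.ndarray
    properties: PropertyMap | None = None
    pa_hard: bool = True
    frozen: np.ndarray | None = None
    label: str = "bau"
    _warned_public: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.protected = np.asarray(self.protected, dtype=bool)
        if self.frozen is not None:
            self.frozen = np.asarray(self.frozen, dtype=bool)
            if self.frozen.shape != self.protected.shape:
                raise ValueError("frozen mask does not match the grid")
        if self.properties is not None and self.properties.ids.shape != self.protected.shape:
            raise ValueError("property raster does not match the grid")
        if self.properties is not None:
            frac = self.properties.frozen_fraction()
            if (frac <= 0).any() or (frac > 1 + 1e-9).any():
                raise ValueError("effective frozen fraction must lie in (0, 1]")


def convertible_mask(state: LandscapeState, constraints: ConstraintSet) -> np.ndarray:
    """Cells that may convert this step.

    A cell is convertible iff it is native, not (hard-)protected, not
    scenario-frozen, and its property still holds more native cells than its
    Legal Reserve floor; a property exactly at the floor is frozen.  Cells
    with no property are public land: convertible, logged once.
    """
    mask = state.native == 1
    if constraints.pa_hard:
        mask &= ~constraints.protected
    if constraints.frozen is not None:
        mask &= ~constraints.frozen
    props = constraints.properties
    if props is not None:
        ids = props.ids
        public = mask & (ids < 0)
        if public.any() and not constraints._warned_public:
            logger.warning(
                "%d convertible cells belong to no property (public land, no LR floor)",
                int(public.sum()),
            )
            constraints._warned_public = True
        native_counts = np.bincount(
            ids[(state.native == 1) & (ids >= 0)], minlength=props.n_properties
        )
        open_prop = native_counts > props.floor_cells()
        inside = ids >= 0
        mask[inside] &= open_prop[ids[inside]]
    return mask


def simulate_step(
    state: LandscapeState,
    stack: DriverStack,
    coeff_draw: CoefficientVector,
    constraints: ConstraintSet,
    rng: np.random.Generator,
    period_index: int | None = None,
    radius: int = 3,
) -> LandscapeState:
    """Advance the landscape by one two-year step.

    Each convertible cell converts independently with probability
    ``logistic(k(x))``.  If the conversions drawn for a property would push it
    below its LR floor, the surplus is cancelled in randomized cell order, so
    the floor binds exactly.  The endogenous land-cover covariate is
    recomputed from the updated state at the next call.

    Two full-grid random fields (conversion uniforms, cancellation
    priorities) are drawn unconditionally per step, so paired runs that share
    an rng stream stay synchronized regardless of how constraints differ.
    """
    if period_index is None:
        period_index = stack.n_periods - 1
    u = rng.random(state.shape)
    priority = rng.random(state.shape)

    mask = convertible_mask(state, constraints)
    k = linear_predictor(stack, coeff_draw, state, period_index, radius=radius)
    p = np.zeros(state.shape)
    p[mask] = expit(k[mask])
    candidates = mask & (u < p)

    props = constraints.properties
    if props is not None and candidates.any():
        ids_flat = props.ids.reshape(-1)
        cand_flat = candidates.reshape(-1)
        cand_ids = ids_flat[cand_flat]
        inside = cand_ids >= 0
        if inside.any():
            n_cand = np.bincount(cand_ids[inside], minlength=props.n_properties)
            native_counts = np.bincount(
                props.ids[(state.native == 1) & (props.ids >= 0)],
                minlength=props.n_properties,
            )
            allowed = native_counts - props.floor_cells()
            over = np.flatnonzero(n_cand > allowed)
            if over.size:
                prio_flat = priority.reshape(-1)
                for pid in over:
                    cells = np.flatnonzero(cand_flat & (ids_flat == pid))
                    keep = max(int(allowed[pid]), 0)
                    order = np.argsort(-prio_flat[cells], kind="stable")
                    cand_flat[cells[order[keep:]]] = False
        candidates = cand_flat.reshape(state.shape)

    native = state.native.copy()
    native[candidates] = 0
    return LandscapeState(state.time + STEP_YEARS, native)


@dataclass
class ProjectionResult:
    """Accumulated conversion probabilities plus per-property loss ledgers.

    ``prob[s]`` is the probability that each cell has converted by
    ``years[s]`` (the fraction of Monte Carlo iterations, so single-model
    values lie on the m/n_iterations lattice).  ``iter_counts[i, s, g]`` is
    the cumulative number of cells converted by step ``s`` in iteration ``i``
    within ledger group ``g`` (group 0 = public land, group j+1 = property j).
    """

    years: np.ndarray
    prob: np.ndarray
    iter_counts: np.ndarray
    properties: PropertyMap | None
    cell_area: float
    n_iterations: int
    label: str
    constraints: ConstraintSet | None = None
    final_states: list[LandscapeState] | None = None

    def _year_index(self, year: int) -> int:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise ValueError(f"year {year} is not a projection step ({self.years.tolist()})")
        return int(idx)

    def total_loss_ha(self, year: int) -> float:
        """Expected converted area (ha) by ``year``."""
        return float(self.prob[self._year_index(year)].sum(dtype=np.float64) * self.cell_area)

    def iteration_totals_ha(self, year: int) -> np.ndarray:
        """Total converted area per iteration (ha) by ``year``."""
        idx = self._year_index(year)
        return self.iter_counts[:, idx, :].sum(axis=1, dtype=np.float64) * self.cell_area

    def credible_interval_ha(self, year: int, level: float = 0.95) -> tuple[float, float, float]:
        """Central interval of total loss across iterations: (lo, hi, half-width)."""
        totals = self.iteration_totals_ha(year)
        alpha = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(totals, [alpha, 100.0 - alpha])
        return float(lo), float(hi), float((hi - lo) / 2.0)

    def ledger(self) -> pd.DataFrame:
        """Expected loss ledger: one row per property (and public land) per step."""
        mean_counts = self.iter_counts.mean(axis=0, dtype=np.float64)  # (steps, groups)
        n_groups = mean_counts.shape[1]
        if self.properties is not None:
            classes = np.concatenate(([PUBLIC], self.properties.table["size_class"].to_numpy()))
            regions = np.concatenate(([PUBLIC], self.properties.table["region"].to_numpy()))
        else:
            classes = np.array([PUBLIC] * n_groups)
            regions = np.array([PUBLIC] * n_groups)
        rows = []
        for s, year in enumerate(self.years):
            for g in range(n_groups):
                loss = mean_counts[s, g] * self.cell_area
                if loss == 0.0:
                    continue
                rows.append(
                    {
                        "property_id": g - 1,
                        "class": classes[g],
                        "region": regions[g],
                        "year": int(year),
                        "loss_ha": loss,
                    }
                )
        return pd.DataFrame(rows, columns=["property_id", "class", "region", "year", "loss_ha"])

    def lr_floor_violations(self, initial_state: LandscapeState) -> int:
        """Number of (iteration, property) pairs ending below the LR floor."""
        if self.properties is None:
            return 0
        ids = self.properties.ids
        initial_native = np.bincount(
            ids[(initial_state.native == 1) & (ids >= 0)],
            minlength=self.properties.n_properties,
        )
        floors = self.properties.floor_cells()
        converted = self.iter_counts[:, -1, 1:]  # (iterations, properties)
        remaining = initial_native[None, :] - converted
        # floors above the initial native stock can never be met; those
        # properties are frozen from the start and convert nothing.
        effective = np.minimum(floors, initial_native)
        return int((remaining < effective[None, :]).sum())


def run_projection(
    initial_state: LandscapeState,
    stack: DriverStack,
    posterior: Posterior,
    constraints: ConstraintSet,
    horizon_year: int,
    n_iterations: int = 100,
    seed: int = 0,
    period_index: int | None = None,
    radius: int = 3,
    keep_final_states: bool = False,
) -> ProjectionResult:
    """Monte Carlo projection from the initial state to the horizon year.

    Each iteration draws one coefficient vector from the posterior and
    simulates every two-year step to the horizon.  The accumulated conversion
    probability at a year is the fraction of iterations in which the cell had
    converted by then; the ledger counts conversions per property and step.
    """
    span = horizon_year - initial_state.time
    if span <= 0 or span % STEP_YEARS:
        raise ValueError("horizon must exceed the initial year by a multiple of 2")
    n_steps = span // STEP_YEARS
    years = initial_state.time + STEP_YEARS * np.arange(1, n_steps + 1)

    if posterior.n_draws < n_iterations:
        logger.warning(
            "posterior has %d draws for %d iterations; sampling with replacement",
            posterior.n_draws, n_iterations,
        )

    shape = initial_state.shape
    n_groups = (constraints.properties.n_properties + 1) if constraints.properties else 1
    counts = np.zeros((n_steps,) + shape, dtype=np.uint32)
    iter_counts = np.zeros((n_iterations, n_steps, n_groups), dtype=np.uint32)
    ids_flat = (
        constraints.properties.ids.reshape(-1) if constraints.properties is not None else None
    )
    final_states: list[LandscapeState] | None = [] if keep_final_states else None

    for it in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        draw_idx = int(rng.integers(posterior.n_draws))
        coeffs = posterior.coefficient_vector(draw_idx)
        state = initial_state.copy()
        conv_step = np.full(shape, -1, dtype=np.int32)
        for s in range(n_steps):
            new_state = simulate_step(
                state, stack, coeffs, constraints, rng, period_index=period_index, radius=radius
            )
            newly = (state.native == 1) & (new_state.native == 0)
            conv_step[newly] = s
            if ids_flat is not None:
                new_ids = ids_flat[newly.reshape(-1)]
                iter_counts[it, s] = np.bincount(new_ids + 1, minlength=n_groups)
            else:
                iter_counts[it, s, 0] = int(newly.sum())
            state = new_state
        np.cumsum(iter_counts[it], axis=0, out=iter_counts[it])
        converted = conv_step >= 0
        for s in range(n_steps):
            counts[s][converted & (conv_step <= s)] += 1
        if final_states is not None:
            final_states.append(state)

    prob = counts.astype(np.float64) / float(n_iterations)
    return ProjectionResult(
        years=years,
        prob=prob,
        iter_counts=iter_counts,
        properties=constraints.properties,
        cell_area=stack.cell_area,
        n_iterations=n_iterations,
        label=posterior.period_label or "projection",
        constraints=constraints,
        final_states=final_states,
    )


def ensemble(results: list[ProjectionResult]) -> ProjectionResult:
    """Cellwise average of projections from models of different periods.

    Probabilities are averaged per year; iteration ledgers are pooled, so
    expected ledgers are averaged and intervals integrate all members'
    Monte Carlo worlds.
    """
    if not results:
        raise ValueError("ensemble of zero results")
    first = results[0]
    for r in results[1:]:
        if not np.array_equal(r.years, first.years) or r.prob.shape != first.prob.shape:
            raise ValueError("ensemble members must share grid and horizon")
        if r.iter_counts.shape[1:] != first.iter_counts.shape[1:]:
            raise ValueError("ensemble members must share the property map")
    sizes = {r.n_iterations for r in results}
    if len(sizes) != 1:
        raise ValueError("ensemble members must use the same iteration count")
    prob = np.mean([r.prob for r in results], axis=0, dtype=np.float64)
    iter_counts = np.concatenate([r.iter_counts for r in results], axis=0)
    return ProjectionResult(
        years=first.years.copy(),
        prob=prob,
        iter_counts=iter_counts,
        properties=first.properties,
        cell_area=first.cell_area,
        n_iterations=first.n_iterations,
        label="ensemble",
        constraints=first.constraints,
    )


def loss_summary(result: ProjectionResult, by: str, year: int) -> pd.DataFrame:
    """Expected loss (ha) grouped by size class, region, or property.

    Expected loss of a group is the sum over its cells of accumulated
    conversion probability times cell area; the interval columns are the
    central 95% range of the grouped loss across Monte Carlo iterations.
    """
    if by not in ("class", "region", "property"):
        raise ValueError("by must be one of 'class', 'region', 'property'")
    idx = result._year_index(year)
    cum = result.iter_counts[:, idx, :].astype(np.float64)  # (iterations, groups)
    if result.properties is not None:
        if by == "class":
            labels = np.concatenate(([PUBLIC], result.properties.table["size_class"].to_numpy()))
        elif by == "region":
            labels = np.concatenate(([PUBLIC], result.properties.table["region"].to_numpy()))
        else:
            labels = np.concatenate(([PUBLIC], result.properties.table.index.astype(str)))
    else:
        labels = np.array([PUBLIC])
    frame = pd.DataFrame(cum.T)
    frame["group"] = labels
    grouped = frame.groupby("group", sort=True).sum()  # (groups, iterations)
    per_iter = grouped.to_numpy() * result.cell_area
    lo, hi = np.percentile(per_iter, [2.5, 97.5], axis=1)
    out = pd.DataFrame(
        {
            "group": grouped.index,
            "loss_ha": per_iter.mean(axis=1),
            "lo95_ha": lo,
            "hi95_ha": hi,
        }
    ).reset_index(drop=True)
    if by == "class":
        order = {c: i for i, c in enumerate((PUBLIC,) + SIZE_CLASSES)}
        out = out.sort_values("group", key=lambda s: s.map(order)).reset_index(drop=True)
    return out
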