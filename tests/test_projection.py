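import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from lucsim.calibration import Posterior
from lucsim.drivers import CoefficientVector, DriverStack, LandscapeState
from lucsim.projection import (
    ConstraintSet,
    convertible_mask,
    ensemble,
    loss_summary,
    run_projection,
    simulate_step,
)
from lucsim.scenarios import PropertyMap


def constant_posterior(intercept, coefficients, n_draws=100, period=(2014, 2016)):
    """Degenerate posterior: every draw is the same coefficient vector."""
    names = ["intercept"] + list(coefficients)
    row = np.array([intercept] + list(coefficients.values()))
    return Posterior(
        subset=list(coefficients),
        param_names=names,
        draws=np.tile(row, (n_draws, 1)),
        acceptance_rate=0.5,
        loglik_trace=np.zeros(n_draws),
        period=period,
    )


def property_map(ids, areas_ha, lr, region="cerrado"):
    ids = np.asarray(ids, dtype=np.int32)
    from lucsim.scenarios import classify_property

    table = pd.DataFrame(
        {
            "area_ha": areas_ha,
            "size_class": [classify_property(a) for a in areas_ha],
            "region": region,
            "lr_fraction": lr,
            "extra_protected_fraction": 0.0,
        }
    )
    return PropertyMap(ids, table)


class TestConvertibleMask:
    def _setup(self, native_cells, lr=0.2):
        # one 10-cell (1000 ha) property on a 2x5 grid
        ids = np.zeros((2, 5), dtype=np.int32)
        props = property_map(ids, [1000.0], [lr])
        native = np.zeros((2, 5), dtype=np.uint8)
        native.reshape(-1)[:native_cells] = 1
        state = LandscapeState(2016, native)
        cs = ConstraintSet(protected=np.zeros((2, 5), dtype=bool), properties=props)
        return state, cs

    def test_above_floor_convertible(self):
        # lr 0.2 x 10 cells = 2-cell floor; 7 native > 2 -> convertible
        state, cs = self._setup(native_cells=7)
        assert convertible_mask(state, cs).sum() == 7

    def test_exactly_at_floor_frozen(self):
        state, cs = self._setup(native_cells=2)
        assert convertible_mask(state, cs).sum() == 0

    def test_protected_cells_never_convertible(self):
        state, cs = self._setup(native_cells=7)
        cs.protected[0, 0] = True
        mask = convertible_mask(state, cs)
        assert not mask[0, 0]

    def test_public_land_convertible_without_floor(self):
        ids = np.full((2, 5), -1, dtype=np.int32)
        props = property_map(ids, [], [])
        state = LandscapeState(2016, np.ones((2, 5), dtype=np.uint8))
        cs = ConstraintSet(protected=np.zeros((2, 5), dtype=bool), properties=props)
        assert convertible_mask(state, cs).all()


class TestSimulateStep:
    def _stack(self, shape=(2, 5)):
        return DriverStack(shape[0], shape[1], 100.0, {"elevation": np.zeros(shape)})

    def test_saturated_negative_predictor_changes_nothing(self):
        state = LandscapeState(2016, np.ones((2, 5), dtype=np.uint8))
        cs = ConstraintSet(protected=np.zeros((2, 5), dtype=bool))
        nxt = simulate_step(
            state, self._stack(), CoefficientVector(-50.0, {}), cs,
            np.random.default_rng(0),
        )
        assert np.array_equal(nxt.native, state.native)
        assert nxt.time == 2018

    def test_one_cell_above_floor_converts_then_freezes(self):
        ids = np.zeros((1, 4), dtype=np.int32)
        props = property_map(ids, [400.0], [0.75])  # floor = 3 of 4 cells
        state = LandscapeState(2016, np.ones((1, 4), dtype=np.uint8))
        cs = ConstraintSet(protected=np.zeros((1, 4), dtype=bool), properties=props)
        rng = np.random.default_rng(1)
        nxt = simulate_step(state, self._stack((1, 4)), CoefficientVector(50.0, {}), cs, rng)
        assert nxt.native.sum() == 3  # exactly one conversion despite k=+50
        after = simulate_step(nxt, self._stack((1, 4)), CoefficientVector(50.0, {}), cs, rng)
        assert np.array_equal(after.native, nxt.native)  # frozen at the floor

    def test_same_rng_seed_identical_successor(self):
        state = LandscapeState(2016, np.ones((2, 5), dtype=np.uint8))
        cs = ConstraintSet(protected=np.zeros((2, 5), dtype=bool))
        a = simulate_step(state, self._stack(), CoefficientVector(0.0, {}), cs,
                          np.random.default_rng(7))
        b = simulate_step(state, self._stack(), CoefficientVector(0.0, {}), cs,
                          np.random.default_rng(7))
        assert np.array_equal(a.native, b.native)


class TestRunProjection:
    def _small(self, n_iterations, seed=0, horizon=2020, lr=0.2):
        rng = np.random.default_rng(3)
        stack = DriverStack(4, 4, 100.0, {"elevation": rng.standard_normal((4, 4))})
        state = LandscapeState(2016, np.ones((4, 4), dtype=np.uint8))
        props = property_map(np.zeros((4, 4), dtype=np.int32), [1600.0], [lr])
        cs = ConstraintSet(protected=np.zeros((4, 4), dtype=bool), properties=props)
        posterior = constant_posterior(-1.0, {"elevation": 0.5})
        return run_projection(state, stack, posterior, cs, horizon,
                              n_iterations=n_iterations, seed=seed)

    def test_single_iteration_probabilities_binary(self):
        result = self._small(n_iterations=1)
        assert set(np.unique(result.prob)) <= {0.0, 1.0}

    def test_probability_is_iteration_fraction(self):
        result = self._small(n_iterations=100)
        lattice = result.prob * 100
        assert np.allclose(lattice, np.rint(lattice))

    def test_accumulated_probability_monotone_in_year(self):
        result = self._small(n_iterations=50, horizon=2026)
        assert (np.diff(result.prob, axis=0) >= 0).all()

    def test_seed_determinism(self):
        a = self._small(n_iterations=20, seed=5)
        b = self._small(n_iterations=20, seed=5)
        assert np.array_equal(a.prob, b.prob)
        assert np.array_equal(a.iter_counts, b.iter_counts)

    def test_protected_cells_have_zero_probability(self):
        rng = np.random.default_rng(3)
        stack = DriverStack(4, 4, 100.0, {"elevation": rng.standard_normal((4, 4))})
        state = LandscapeState(2016, np.ones((4, 4), dtype=np.uint8))
        protected = np.zeros((4, 4), dtype=bool)
        protected[:2] = True
        cs = ConstraintSet(protected=protected)
        result = run_projection(state, stack, constant_posterior(3.0, {}), cs, 2030,
                                n_iterations=30, seed=1)
        assert (result.prob[:, protected] == 0).all()
        assert (result.prob[-1, ~protected] > 0).any()

    def test_lr_floor_never_violated(self):
        result = self._small(n_iterations=50, horizon=2040, lr=0.5)
        initial = LandscapeState(2016, np.ones((4, 4), dtype=np.uint8))
        assert result.lr_floor_violations(initial) == 0
        # the floor truly binds: no iteration converts more than 8 of 16 cells
        assert result.iter_counts[:, -1, :].sum(axis=1).max() <= 8

    def test_first_step_mean_matches_analytic_expectation(self):
        # constant coefficients: expected conversions = sum of logistic(k)
        rng = np.random.default_rng(3)
        stack = DriverStack(6, 6, 100.0, {"elevation": rng.standard_normal((6, 6))})
        state = LandscapeState(2016, np.ones((6, 6), dtype=np.uint8))
        cs = ConstraintSet(protected=np.zeros((6, 6), dtype=bool))
        n_iter = 3000
        result = run_projection(state, stack, constant_posterior(-1.5, {"elevation": 0.7}),
                                cs, 2018, n_iterations=n_iter, seed=2)
        p = expit(-1.5 + 0.7 * stack.layers["elevation"])
        expected = p.sum()
        got = result.prob[0].sum() * 1.0
        se = math.sqrt((p * (1 - p)).sum() / n_iter)
        assert abs(got - expected) < 3 * se


class TestEnsemble:
    def test_identity_and_mean(self):
        base = TestRunProjection()._small(n_iterations=20)
        ens = ensemble([base, base, base, base])
        assert np.array_equal(ens.prob, base.prob)
        assert ens.label == "ensemble"
        assert ens.iter_counts.shape[0] == 4 * base.iter_counts.shape[0]

    def test_quarter_probability(self):
        a = TestRunProjection()._small(n_iterations=1, seed=11)
        hot = a.prob.copy()
        hot[:] = 0.0
        cold = ProjectionResultClone = None  # noqa: F841  (clarity below)
        zeros = [clone_with_prob(a, hot) for _ in range(3)]
        ones = clone_with_prob(a, np.ones_like(a.prob))
        ens = ensemble(zeros + [ones])
        assert np.allclose(ens.prob, 0.25)

    def test_ensemble_of_ensembles_is_flat_mean(self):
        parts = [TestRunProjection()._small(n_iterations=10, seed=s) for s in range(4)]
        nested = ensemble([ensemble(parts[:2]), ensemble(parts[2:])])
        flat = ensemble(parts)
        assert np.allclose(nested.prob, flat.prob, atol=1e-7)

    def test_mismatched_horizons_rejected(self):
        a = TestRunProjection()._small(n_iterations=10, horizon=2020)
        b = TestRunProjection()._small(n_iterations=10, horizon=2022)
        with pytest.raises(ValueError):
            ensemble([a, b])


def clone_with_prob(result, prob):
    from dataclasses import replace

    return replace(result, prob=prob)


class TestLossSummary:
    def test_zero_probability_zero_loss(self):
        result = TestRunProjection()._small(n_iterations=10)
        zero = clone_with_prob(result, np.zeros_like(result.prob))
        zero.iter_counts = np.zeros_like(zero.iter_counts)
        table = loss_summary(zero, "class", 2020)
        assert (table["loss_ha"] == 0).all()

    def test_arithmetic_five_cells_at_probability_one(self):
        # 5 cells certain to convert at 100 ha/cell -> 500 ha in the property
        result = TestRunProjection()._small(n_iterations=10)
        counts = np.zeros_like(result.iter_counts)
        counts[:, :, 1] = 5
        full = clone_with_prob(result, result.prob)
        full.iter_counts = counts
        table = loss_summary(full, "property", 2018)
        assert table.loc[table.group == "0", "loss_ha"].item() == pytest.approx(500.0)

    def test_partition_conservation(self):
        result = TestRunProjection()._small(n_iterations=40, horizon=2030)
        total = result.total_loss_ha(2030)
        for by in ("class", "region", "property"):
            grouped = loss_summary(result, by, 2030)["loss_ha"].sum()
            assert grouped == pytest.approx(total, abs=1e-6)


class TestThreeCellEnumerationOracle:
    """Exhaustive absorbing-chain computation on a one-property, 3-cell
    landscape, including the endogenous neighborhood covariate and the exact
    Legal-Reserve floor with uniform cancellation."""

    INTERCEPT = -0.4
    BETA_Z = 0.6
    BETA_LC = 1.2
    Z = np.array([[-0.8, 0.1, 0.9]])
    LR = 0.2  # 3 cells -> floor = 1 cell: at most 2 conversions ever
    STEPS = 3  # 2016 -> 2022

    def _cell_probs(self, native_set):
        """Per-cell conversion probability given the current native set."""
        native = np.zeros((1, 3))
        native[0, list(native_set)] = 1
        # radius-1 neighborhood on a 1x3 grid, focal cell excluded
        anth = 1 - native[0]
        lc = np.array(
            [anth[1], (anth[0] + anth[2]) / 2.0, anth[1]]
        )
        k = self.INTERCEPT + self.BETA_Z * self.Z[0] + self.BETA_LC * lc
        return expit(k)

    def _enumerate(self):
        floor = 1
        dist = {frozenset({0, 1, 2}): 1.0}
        per_cell_converted = []
        for _ in range(self.STEPS):
            new = {}
            for native_set, prob0 in dist.items():
                if prob0 == 0.0:
                    continue
                convertible = list(native_set) if len(native_set) > floor else []
                p = self._cell_probs(native_set)
                for draw in itertools.product([0, 1], repeat=len(convertible)):
                    p_draw = 1.0
                    cand = []
                    for cell, d in zip(convertible, draw):
                        p_draw *= p[cell] if d else 1.0 - p[cell]
                        if d:
                            cand.append(cell)
                    allowed = len(native_set) - floor
                    if len(cand) <= allowed:
                        kept_sets = [tuple(cand)]
                        w = [1.0]
                    else:  # uniform cancellation to the exact floor
                        kept_sets = list(itertools.combinations(cand, allowed))
                        w = [1.0 / len(kept_sets)] * len(kept_sets)
                    for kept, weight in zip(kept_sets, w):
                        nxt = frozenset(native_set - set(kept))
                        new[nxt] = new.get(nxt, 0.0) + prob0 * p_draw * weight
            dist = new
            per_cell_converted.append(
                [
                    sum(pr for s, pr in dist.items() if cell not in s)
                    for cell in range(3)
                ]
            )
        return np.array(per_cell_converted)  # (steps, 3)

    def test_matches_monte_carlo_within_three_standard_errors(self):
        n_iter = 10_000
        stack = DriverStack(1, 3, 100.0, {"elevation": self.Z.copy()})
        state = LandscapeState(2016, np.ones((1, 3), dtype=np.uint8))
        props = property_map(np.zeros((1, 3), dtype=np.int32), [300.0], [self.LR])
        cs = ConstraintSet(protected=np.zeros((1, 3), dtype=bool), properties=props)
        posterior = constant_posterior(
            self.INTERCEPT, {"elevation": self.BETA_Z, "land_cover": self.BETA_LC}
        )
        result = run_projection(state, stack, posterior, cs, 2016 + 2 * self.STEPS,
                                n_iterations=n_iter, seed=17, radius=1)
        exact = self._enumerate()
        got = result.prob[:, 0, :]
        se = np.sqrt(exact * (1 - exact) / n_iter)
        assert np.all(np.abs(got - exact) <= 3 * np.maximum(se, 1e-4))
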