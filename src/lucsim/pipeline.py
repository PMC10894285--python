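"""End-to-end run: generate/calibrate/select/project/ensemble/scenario.

A single RunConfig drives the whole analysis on a synthetic landscape:

1. generate drivers, properties and the observed conversion history;
2. per calibration period, build transition records, split train/test,
   pick the driver subset by held-out likelihood (forward path, MCMC-scored),
   and report the AUC of the selected model on the held-out cells;
3. project each period's posterior from the last observed state to the
   horizon under Legal-Reserve floors and hard protected areas (BAU);
4. ensemble the period projections (cellwise mean);
5. apply each policy scenario and re-simulate with paired iteration seeds,
   reporting avoided loss against BAU.

Every stage seed is derived from the config seed, and the run manifest
records the config hash plus an SHA-256 of every artifact, so re-running
the same config reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .calibration import (
    MCMCConfig,
    build_transitions,
    compute_auc,
    greedy_candidates,
    log_likelihood,
    select_model,
    summarize_contributions,
    train_test_split,
)
from .drivers import TABLE_ORDER, standardize
from .projection import ConstraintSet, ProjectionResult, ensemble, loss_summary, run_projection
from .scenarios import ScenarioConfig, apply_scenario, avoided_loss
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``periods`` are the two-year calibration intervals (derived from the
    synthetic config by default); ``horizon_year`` and ``n_iterations``
    govern the Monte Carlo projection; ``scenarios`` are applied on top of
    the BAU constraints.  ``selection`` is ``"greedy"`` (forward path) or
    ``"single"`` (calibrate the full candidate set without selection).
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    horizon_year: int = 2070
    n_iterations: int = 100
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    scenarios: list[ScenarioConfig] = field(default_factory=list)
    selection: str = "greedy"
    test_fraction: float = 0.3
    seed: int = 0
    scenario_mode: str = "resim"

    def __post_init__(self) -> None:
        if self.selection not in ("greedy", "single"):
            raise ValueError("selection must be 'greedy' or 'single'")
        if self.scenario_mode not in ("resim", "mask"):
            raise ValueError("scenario_mode must be 'resim' or 'mask'")
        last_end = self.periods()[-1][1]
        if self.horizon_year < last_end:
            raise ValueError("horizon must not precede the last calibration period")
        if (self.horizon_year - last_end) % 2:
            raise ValueError("horizon must be an even-year offset from the last period")
        periods = self.periods()
        for s0, e0 in periods:
            if e0 - s0 != 2:
                raise ValueError("calibration periods must span two years")
        for (_, e0), (s1, _) in zip(periods, periods[1:]):
            if s1 < e0:
                raise ValueError("calibration periods must not overlap")

    def periods(self) -> list[tuple[int, int]]:
        start = self.synthetic.start_year
        return [(start + 2 * i, start + 2 * (i + 1)) for i in range(self.synthetic.n_periods)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["lr_regions"] = [list(r) for r in d["synthetic"]["lr_regions"]]
        d["scenarios"] = [
            {
                "name": s.name,
                "lr_overrides": dict(s.lr_overrides),
                "large_property_rule": dict(s.large_property_rule or {}),
            }
            for s in self.scenarios
        ]
        return d


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    dataset: object
    posteriors: dict
    aucs: dict
    selected: dict
    contributions: pd.DataFrame
    bau_results: dict
    bau_ensemble: ProjectionResult
    scenario_reports: dict
    scenario_ensembles: dict


def _calibrate_period(sample, run_config: RunConfig, period_idx: int):
    mcmc = run_config.mcmc
    cfg = MCMCConfig(
        n_iter=mcmc.n_iter,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        proposal_sd=mcmc.proposal_sd,
        prior_sd=mcmc.prior_sd,
        seed=(run_config.seed * 1009 + 17 * period_idx) % (2**31 - 1),
    )
    train, test = train_test_split(
        sample, run_config.test_fraction, seed=cfg.seed ^ 0x5F5F
    )
    if run_config.selection == "greedy":
        candidates = greedy_candidates(train, test, prior_sd=cfg.prior_sd)
    else:
        candidates = [[n for n in sample.var_names]]
    choice = select_model(train, test, candidates, cfg)
    posterior = choice["posterior"]
    # held-out goodness of fit at the posterior mean
    mean_cv = posterior.posterior_mean()
    eta = np.full(test.n_records, mean_cv.intercept)
    for name, beta in mean_cv.coefficients.items():
        eta += beta * test.X[:, test.var_names.index(name)]
    probs = 1.0 / (1.0 + np.exp(-eta))
    auc = compute_auc(probs, test.y) if 0 < test.y.sum() < test.n_records else float("nan")
    return posterior, choice, auc, log_likelihood(test, mean_cv)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full analysis; optionally write artifacts to ``out_dir``."""
    dataset = generate_dataset(config.synthetic)
    stack = dataset.drivers  # standardized, parameters frozen at generation
    protected = stack.layers["protected_areas"].astype(bool)

    posteriors, aucs, selected = {}, {}, {}
    contrib_cols = {}
    for idx, (start, end) in enumerate(config.periods()):
        s0, s1 = dataset.state_pairs()[idx]
        sample = build_transitions(s0, s1, stack, period_index=idx,
                                   radius=config.synthetic.neighborhood_radius)
        posterior, choice, auc, test_ll = _calibrate_period(sample, config, idx)
        label = f"{start}-{end}"
        posteriors[label] = posterior
        aucs[label] = auc
        selected[label] = {"subset": choice["subset"], "scores": choice["scores"],
                           "test_loglik": test_ll}
        contrib_cols[label] = summarize_contributions(posterior).set_index("variable")[
            "median_coefficient"
        ]
        logger.info("period %s: subset=%s AUC=%.3f", label, choice["subset"], auc)
    contributions = pd.DataFrame(contrib_cols).reindex(list(TABLE_ORDER))

    last_state = dataset.observed_states[-1]
    bau_constraints = ConstraintSet(
        protected=protected, properties=dataset.properties, pa_hard=True, label="bau"
    )
    bau_results = {}
    for label, posterior in posteriors.items():
        bau_results[label] = run_projection(
            last_state,
            stack,
            posterior,
            bau_constraints,
            config.horizon_year,
            n_iterations=config.n_iterations,
            seed=config.seed,
            radius=config.synthetic.neighborhood_radius,
        )
    bau_ens = ensemble(list(bau_results.values()))

    scenario_reports, scenario_ensembles = {}, {}
    for scen in config.scenarios:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5C]))
        constraints = apply_scenario(
            bau_constraints, dataset.properties, scen, rng, last_state,
            radius=config.synthetic.neighborhood_radius,
        )
        if config.scenario_mode == "resim":
            scen_results = [
                run_projection(
                    last_state, stack, posterior, constraints, config.horizon_year,
                    n_iterations=config.n_iterations, seed=config.seed,
                    radius=config.synthetic.neighborhood_radius,
                )
                for posterior in posteriors.values()
            ]
            scen_ens = ensemble(scen_results)
        else:  # mask mode: zero BAU probabilities on newly frozen cells
            scen_ens = _masked_scenario(bau_ens, constraints)
        scenario_ensembles[scen.name] = scen_ens
        scenario_reports[scen.name] = avoided_loss(bau_ens, scen_ens, config.horizon_year)

    result = RunResult(
        dataset=dataset,
        posteriors=posteriors,
        aucs=aucs,
        selected=selected,
        contributions=contributions,
        bau_results=bau_results,
        bau_ensemble=bau_ens,
        scenario_reports=scenario_reports,
        scenario_ensembles=scenario_ensembles,
    )
    if out_dir is not None:
        _write_run(config, result, Path(out_dir))
    return result


def _masked_scenario(bau_ens: ProjectionResult, constraints: ConstraintSet) -> ProjectionResult:
    """Static approximation: BAU probabilities with frozen cells zeroed."""
    keep = ~(constraints.frozen if constraints.frozen is not None
             else np.zeros(bau_ens.prob.shape[1:], dtype=bool))
    if constraints.pa_hard:
        keep &= ~constraints.protected
    prob = bau_ens.prob * keep[None, :, :]
    return ProjectionResult(
        years=bau_ens.years.copy(),
        prob=prob,
        iter_counts=bau_ens.iter_counts,  # ledger intervals stay BAU-based in mask mode
        properties=bau_ens.properties,
        cell_area=bau_ens.cell_area,
        n_iterations=bau_ens.n_iterations,
        label=constraints.label,
        constraints=constraints,
    )


def _write_run(config: RunConfig, result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    artifacts: dict[str, str] = {}

    def record(path: Path) -> None:
        artifacts[path.name] = io.file_hash(path)

    ens = result.bau_ensemble
    p = out_dir / "bau_probability_float32.tif"
    io.write_raster(p, ens.prob.astype(np.float32))
    record(p)
    p = out_dir / "bau_probability_u8.tif"
    io.write_raster(p, io.probability_to_uint8(ens.prob))
    record(p)
    p = out_dir / "bau_ledger.csv"
    io.write_ledger(p, ens.ledger())
    record(p)
    p = out_dir / "properties.csv"
    io.write_properties_csv(p, result.dataset.properties)
    record(p)
    p = out_dir / "property_ids.tif"
    io.write_raster(p, result.dataset.properties.ids, nodata=-1)
    record(p)
    p = out_dir / "contributions.csv"
    result.contributions.to_csv(p)
    record(p)
    p = out_dir / "auc.csv"
    pd.Series(result.aucs, name="auc").rename_axis("period").to_csv(p)
    record(p)
    for label, posterior in result.posteriors.items():
        p = out_dir / f"posterior_{label}.csv"
        io.write_posterior_csv(p, posterior)
        record(p)
    for name, scen_ens in result.scenario_ensembles.items():
        p = out_dir / f"scenario_{name}_probability_float32.tif"
        io.write_raster(p, scen_ens.prob.astype(np.float32))
        record(p)
    summaries = {
        "class": loss_summary(ens, "class", config.horizon_year),
        "region": loss_summary(ens, "region", config.horizon_year),
    }
    for by, frame in summaries.items():
        p = out_dir / f"loss_by_{by}.csv"
        frame.to_csv(p, index=False)
        record(p)

    manifest = {
        "config": cfg_dict,
        "config_hash": io.config_hash(cfg_dict),
        "seed": config.seed,
        "period_seeds": {
            label: (config.seed * 1009 + 17 * i) % (2**31 - 1)
            for i, label in enumerate(result.posteriors)
        },
        "selected_subsets": {k: v["subset"] for k, v in result.selected.items()},
        "aucs": {k: (None if np.isnan(v) else float(v)) for k, v in result.aucs.items()},
        "acceptance_rates": {
            k: float(p.acceptance_rate) for k, p in result.posteriors.items()
        },
        "scenario_reports": result.scenario_reports,
        "artifacts": artifacts,
    }
    io.save_yaml(out_dir / "manifest.yaml", manifest)
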