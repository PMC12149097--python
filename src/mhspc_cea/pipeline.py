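"""End-to-end pipeline: simulate/load curves -> reconstruct pseudo-IPD ->
fit and select survival models -> Markov base case -> DSA/PSA ->
threshold price.  Every stage writes plain CSV/YAML artifacts so a run
is fully auditable, and a manifest records the seed and configuration.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence.spawn`` in a fixed stage order (trial
simulation first, PSA second), so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cost_model import ARMS, Parameters, load_parameters
from .econ_eval import DEFAULT_WTP, CEModel, EconResult, price_reduction_pct, threshold_price
from .ipd_reconstruct import clean_curve, read_curve_csv, reconstruct
from .markov_engine import ModelSettings
from .sensitivity import PSAResult, one_way_dsa, run_psa, specs_from_parameters
from .surv_models import comparison_table, fit_all, select_model
from .synthetic_trial import TrialSpec, km_from_ipd, simulate_trial

log = logging.getLogger(__name__)

ENDPOINTS = ("PFS", "OS")


@dataclass
class PipelineConfig:
    """Declarative run configuration.

    Exactly one survival-data source: digitized-curve CSV paths
    (``curve_files``: {(arm, endpoint): (points_csv, risk_csv)}) or a
    synthetic trial spec (``trial``).
    """

    trial: TrialSpec | None = None
    curve_files: dict | None = None
    params_path: str | None = None
    settings: ModelSettings = field(default_factory=ModelSettings)
    criterion: str = "aic"
    digitize_grid_months: float = 0.5
    risk_interval_months: float = 6.0
    n_psa_draws: int = 10_000
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if (self.trial is None) == (self.curve_files is None):
            raise ValueError(
                "config needs exactly one survival-data source: "
                "a synthetic trial spec or digitized curve files")
        if self.criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")


@dataclass
class PipelineResult:
    curves: dict
    ipd: dict
    fits: dict
    selected: dict
    model: CEModel
    base_case: EconResult
    tornado: pd.DataFrame
    psa: PSAResult
    threshold: float
    reduction_pct: float
    params: Parameters
    manifest: dict


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (kept below 2**31)."""
    children = np.random.SeedSequence(seed).spawn(2)
    return {
        "trial": int(children[0].generate_state(1)[0] % (2**31)),
        "psa": int(children[1].generate_state(1)[0] % (2**31)),
    }


def acquire_curves(config: PipelineConfig) -> dict:
    """Stage 1: digitized-style KM curves per (arm, endpoint)."""
    curves = {}
    if config.curve_files is not None:
        for key, (pts, risk) in config.curve_files.items():
            arm, endpoint = key
            curves[key] = read_curve_csv(pts, risk, arm, endpoint)
        return curves
    spec = dataclasses.replace(config.trial, seed=stage_seeds(config.seed)["trial"])
    ipd = simulate_trial(spec)
    t_max = float(ipd["time_months"].max())
    grid = np.arange(0.0, t_max + config.digitize_grid_months,
                     config.digitize_grid_months)
    risk_times = np.arange(0.0, t_max + config.risk_interval_months,
                           config.risk_interval_months)
    for arm in ARMS:
        for endpoint in ENDPOINTS:
            curves[(arm, endpoint)] = km_from_ipd(
                ipd, risk_times, grid=grid, arm=arm, endpoint=endpoint)
    return curves


def reconstruct_all(curves: dict) -> dict:
    return {key: reconstruct(clean_curve(c)) for key, c in curves.items()}


def fit_and_select(ipd: dict, criterion: str = "aic"):
    fits = {key: fit_all(rec) for key, rec in ipd.items()}
    selected = {key: select_model(fs, criterion) for key, fs in fits.items()}
    return fits, selected


def build_model(selected: dict, params: Parameters,
                settings: ModelSettings | None = None) -> CEModel:
    curves = {
        arm: (selected[(arm, "PFS")].survival_at, selected[(arm, "OS")].survival_at)
        for arm in ARMS
    }
    return CEModel(curves, params, settings)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; write artifacts when ``config.outdir`` is set."""
    config.validate()
    params = load_parameters(config.params_path)
    settings = dataclasses.replace(
        config.settings, discount_annual=params["discount_rate"]["value"])

    log.info("stage 1/6: survival curves")
    curves = acquire_curves(config)
    log.info("stage 2/6: pseudo-IPD reconstruction")
    ipd = reconstruct_all(curves)
    log.info("stage 3/6: parametric fitting and %s selection", config.criterion)
    fits, selected = fit_and_select(ipd, config.criterion)
    log.info("stage 4/6: Markov base case")
    model = build_model(selected, params, settings)
    wtp = float(params.get("wtp_usd_per_qaly", DEFAULT_WTP))
    base = model.evaluate(wtp=wtp)
    log.info("stage 5/6: sensitivity analyses")
    specs = specs_from_parameters(params)
    tornado = one_way_dsa(specs, model, wtp=wtp)
    psa = run_psa(specs, model, n_draws=config.n_psa_draws,
                  seed=stage_seeds(config.seed)["psa"])
    log.info("stage 6/6: threshold price")
    base_price = params["costs"]["rezvilutamide"]["value"]
    thr = threshold_price(model.evaluate_at_price, wtp=wtp,
                          price_bounds=(0.0, max(2000.0, 2 * base_price)))
    reduction = price_reduction_pct(base_price, thr)

    manifest = {
        "seed": config.seed,
        "stage_seeds": stage_seeds(config.seed),
        "criterion": config.criterion,
        "n_cycles": settings.n_cycles,
        "wtp": wtp,
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "selected_families": {f"{a}/{e}": selected[(a, e)].family
                              for a, e in selected},
    }
    result = PipelineResult(curves, ipd, fits, selected, model, base,
                            tornado, psa, thr, reduction, params, manifest)
    if config.outdir:
        write_artifacts(result, config.outdir)
    return result


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (arm, endpoint), rec in result.ipd.items():
        rec.to_frame().to_csv(out / f"ipd_{arm}_{endpoint.lower()}.csv", index=False)
    comp = []
    for (arm, endpoint), fs in result.fits.items():
        tab = comparison_table(fs, result.selected[(arm, endpoint)])
        tab.insert(0, "endpoint", endpoint)
        tab.insert(0, "arm", arm)
        comp.append(tab)
    pd.concat(comp, ignore_index=True).to_csv(out / "model_comparison.csv", index=False)

    base = result.base_case
    pd.DataFrame([
        {"arm": a, "cost": base.cost[a], "qaly": base.qaly[a], "ly": base.ly[a]}
        for a in ARMS
    ]).to_csv(out / "base_case_arms.csv", index=False)
    with open(out / "base_case.json", "w") as fh:
        json.dump({**base.rounded(), "icer_unrounded": base.icer,
                   "delta_qaly_unrounded": base.delta_qaly,
                   "threshold_price": result.threshold,
                   "price_reduction_pct": result.reduction_pct}, fh, indent=2)
    result.tornado.to_csv(out / "tornado.csv", index=False)
    result.psa.draws.to_csv(out / "psa_draws.csv", index=False)
    result.psa.ceac.to_csv(out / "ceac.csv", index=False)
    for arm in ARMS:
        trace = result.model.occupancy[arm]
        n = trace.shape[0] - 1
        pd.DataFrame({
            "cycle": np.arange(n + 1),
            "time_years": np.arange(n + 1) * result.model.settings.cycle_years,
            "pi_pfs": trace[:, 0], "pi_pd": trace[:, 1], "pi_death": trace[:, 2],
        }).to_csv(out / f"trace_{arm}.csv", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
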