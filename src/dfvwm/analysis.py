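"""Simulation-experiment orchestration and model-fit summaries.

Runs the full cued-recall simulation for a set of simulated participants
(independent seeded runs of the model through the whole trial set), fits
the standard mixture model to each run's errors per condition (SS1,
Unique, CW, CCW), and compares the across-run mean mixture parameters
with behavioral reference values through per-parameter RMSE and an AIC
computed from the Gaussian likelihood of the deviations:

    AIC = N * ln(MSE) + 2k,   N = 12 (4 conditions x 3 measures)

where k counts each model's free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .architectures import ModelState, build_model1, build_model2, simulate_trial
from .mixture import MixtureFit, fit_standard_mixture
from .params import model1_params, model2_params
from .task import generate_trials

__all__ = [
    "CONDITIONS",
    "N_DATAPOINTS",
    "K_MODEL1",
    "K_MODEL2",
    "BehavioralReference",
    "FitComparison",
    "run_simulated_participants",
    "results_to_frame",
    "fit_by_condition",
    "summarize_runs",
    "rmse_table",
    "aic",
]

CONDITIONS = ("SINGLE", "UNIQUE", "CW", "CCW")
PARAMS = ("mu", "sd", "p_m")

#: comparison bookkeeping used for the AIC model comparison
N_DATAPOINTS = 12  # 4 conditions x 3 mixture parameters
K_MODEL1 = 49  # free parameters of the parallel-encoding model
K_MODEL2 = 56  # free parameters of the scene-level model


@dataclass(frozen=True)
class BehavioralReference:
    """Reference mixture parameters (one value per condition and measure).

    ``values[condition][measure]`` with measures mu, sd, p_m.
    """

    label: str
    values: Dict[str, Dict[str, float]]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values).T


@dataclass
class FitComparison:
    rmse: Dict[str, float]  # per measure
    n_points: int
    k: int
    mse: float
    aic: float


def run_simulated_participants(
    variant: str,
    condition: str,
    n_runs: int = 12,
    base_seed: int = 0,
    counts: Optional[dict] = None,
    preset: str = "default",
    override: Optional[dict] = None,
    progress: bool = False,
) -> List[List["object"]]:
    """Simulate ``n_runs`` participants; returns per-run trial results.

    Each run r generates a fresh randomized trial set and simulates every
    trial with an independent stream seeded ``base_seed + r``.
    """
    runs = []
    for r in range(n_runs):
        rng = np.random.default_rng(base_seed + r)
        if variant in ("m1", "model1", "MODEL1"):
            model = build_model1(model1_params(preset, override))
        elif variant in ("m2", "model2", "MODEL2"):
            model = build_model2(model2_params(preset, override))
        else:
            raise ValueError(f"unknown model variant {variant!r}")
        trials = generate_trials(condition, rng, counts)
        results = []
        for i, tr in enumerate(trials):
            results.append(simulate_trial(model, tr, rng))
            if progress and (i + 1) % 50 == 0:
                print(f"  run {r}: {i + 1}/{len(trials)} trials")
        runs.append(results)
    return runs


def results_to_frame(results, run_id: int = 0) -> pd.DataFrame:
    """One row per trial: ids, condition, role, hues, error, bookkeeping."""
    rows = []
    for r in results:
        rows.append({
            "run": run_id,
            "condition": r.condition,
            "role": r.probed_role,
            "target_hue": r.target_hue,
            "reported_hue": r.reported_hue,
            "signed_error": r.signed_error,
            "response_time": r.response_time,
            "guess": int(r.guess_flag),
            "consolidation_order": ";".join(
                f"{i}@{t:.0f}" for i, t in r.consolidation_order),
        })
    return pd.DataFrame(rows)


def fit_by_condition(results, min_n: int = 20) -> Dict[str, MixtureFit]:
    """Standard mixture fit of one run's errors, per probed condition."""
    fits = {}
    for role in CONDITIONS:
        errs = np.array([r.signed_error for r in results if r.probed_role == role])
        if errs.size == 0:
            continue
        if errs.size < min_n:
            warnings.warn(
                f"condition {role}: only {errs.size} responses (<{min_n}); excluded")
            continue
        fits[role] = fit_standard_mixture(errs, min_n=min_n)
    return fits


def summarize_runs(per_run_fits: Sequence[Dict[str, MixtureFit]]) -> pd.DataFrame:
    """Mean and s.e. of each mixture parameter across runs, per condition."""
    rows = []
    for role in CONDITIONS:
        vals = {p: [] for p in PARAMS}
        for fits in per_run_fits:
            if role not in fits:
                continue
            f = fits[role]
            vals["mu"].append(f.mu)
            vals["sd"].append(f.sd)
            vals["p_m"].append(f.p_m)
        if not vals["mu"]:
            continue
        row = {"condition": role, "n_runs": len(vals["mu"])}
        for p in PARAMS:
            arr = np.asarray(vals[p])
            row[p] = arr.mean()
            row[f"{p}_se"] = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["n_runs", *PARAMS, *(f"{p}_se" for p in PARAMS)])
    return pd.DataFrame(rows).set_index("condition")


def rmse_table(sim_means: pd.DataFrame, reference: BehavioralReference) -> Dict[str, float]:
    """Per-parameter RMSE between simulated means and the reference,
    across the conditions present in the reference."""
    ref = reference.frame()
    missing = [c for c in ref.index if c not in sim_means.index]
    if missing:
        raise ValueError(f"simulation summary lacks conditions {missing}")
    out = {}
    for p in PARAMS:
        dev = np.array([sim_means.loc[c, p] - ref.loc[c, p] for c in ref.index])
        out[p] = float(np.sqrt(np.mean(dev ** 2)))
    return out


def aic(rmse_mu: float, rmse_sd: float, rmse_pm: float, k: int,
        n_conditions: int = 4) -> float:
    """Gaussian-likelihood AIC from the per-parameter RMSEs.

    MSE pools the squared deviations of all N = 3 * n_conditions data
    points; AIC = N ln(MSE) + 2k (natural log).
    """
    if min(rmse_mu, rmse_sd, rmse_pm) < 0 or k <= 0:
        raise ValueError("RMSEs must be >= 0 and k > 0")
    n = 3 * n_conditions
    mse = (n_conditions * (rmse_mu ** 2 + rmse_sd ** 2 + rmse_pm ** 2)) / n
    if mse == 0:
        raise ValueError("MSE is zero; AIC undefined")
    return float(n * np.log(mse) + 2 * k)
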