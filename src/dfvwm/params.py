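"""Default model parameters and presets.

Parameters were hand-tuned, starting from values typical of three-layer
working-memory field models, until the simulator reproduced the target
behavioral pattern (self-sustained memory peaks, repulsion of the
20-degree close pair over a 1-s delay, occasional peak failures at set
size 3, sequential consolidation in the scene-level variant).  All
amplitudes are per-degree weights (convolutions multiply by the grid
spacing), so the same values apply at any sampling resolution.

Two grid presets are provided: ``default`` (2-degree sampling, matching
the 2-degree stimulus color lattice) and ``fast`` (3-degree sampling)
for large batch simulations.  A full parameter dump can be written
alongside every run for provenance.
"""

from __future__ import annotations

import copy
from typing import Optional

import yaml

__all__ = ["model1_params", "model2_params", "merge", "dump_params", "load_params"]


GRID_PRESETS = {
    "default": {"n_color": 180, "n_space": 180, "dt": 2.0},
    "fast": {"n_color": 120, "n_space": 120, "dt": 2.0},
}


_MODEL1 = {
    "grid": dict(GRID_PRESETS["default"]),
    "fields": {
        # 2D sensory field over (space, color); weak lateral interactions:
        # peaks are stable only while input is present
        "CS": {
            "h": -5.0, "tau": 20.0, "q": 0.3, "beta": 4.0,
            "kernel": {"c_exc": 0.05, "sigma_exc": [5.0, 5.0],
                       "c_inh": 0.0, "sigma_inh": [10.0, 10.0], "g_inh": 0.0008},
        },
        # feature attention: weak competition (global inhibition)
        "FA": {
            "h": -5.0, "tau": 20.0, "q": 0.06, "beta": 4.0,
            "kernel": {"c_exc": 0.5, "sigma_exc": 5.0,
                       "c_inh": 0.35, "sigma_inh": 12.0, "g_inh": 0.05},
        },
        # feature contrast (novelty detector)
        "FC": {
            "h": -5.0, "tau": 20.0, "q": 0.06, "beta": 4.0,
            "kernel": {"c_exc": 0.3, "sigma_exc": 5.0,
                       "c_inh": 0.0, "sigma_inh": 12.0, "g_inh": 0.0},
        },
        # shared inhibitory field; faster time constant
        "Inhib": {
            "h": -5.0, "tau": 10.0, "q": 0.2, "beta": 4.0,
            "kernel": None,
        },
        # feature working memory: strong self-excitation sustains peaks
        "FWM": {
            "h": -4.5, "tau": 20.0, "q": 0.45, "beta": 4.0,
            "kernel": {"c_exc": 1.35, "sigma_exc": 4.0,
                       "c_inh": 0.0, "sigma_inh": 12.0, "g_inh": 0.0},
        },
    },
    "couplings": {
        "FA<-CS":    {"projection": "space_sum", "gain": 0.5, "sigma": 2.0},
        "FC<-CS":    {"projection": "space_sum", "gain": 0.6, "sigma": 5.0},
        "FWM<-CS":   {"projection": "space_sum", "gain": 0.1, "sigma": 5.0},
        "FC<-FA":    {"projection": "identity", "gain": 0.5, "sigma": 5.0},
        "FWM<-FC":   {"projection": "identity", "gain": 6.0, "sigma": 5.0},
        "Inhib<-FC": {"projection": "identity", "gain": 0.5, "sigma": 5.0},
        "Inhib<-FWM": {"projection": "identity", "gain": 8.0, "sigma": 10.0},
        "FWM<-Inhib": {"projection": "identity", "gain": -28.0, "sigma": 12.0},
        "FC<-Inhib": {"projection": "identity", "gain": -3.0, "sigma": 10.0},
        "FA<-FWM":   {"projection": "identity", "gain": 1.5, "sigma": 5.0,
                      "gate": "test"},
        "CS<-FA":    {"projection": "expand_over_space", "gain": 4.0, "sigma": 5.0,
                      "gate": "test"},
    },
    "stimulus": {"amp": 8.0, "sigma_space": 5.0, "sigma_color": 4.0},
    "wheel": {"amp": 3.0, "sigma": 5.0},
    "cue": {"boost_amp": 2.5, "boost_width": 40.0, "fa_amp": 1.5,
            "target": "FWM"},
    "response": {"fa_h_boost": 3.0, "threshold": 0.0, "hold_ms": 50.0,
                 "stability_tol": 6.0, "wheel_window": 12.0},
    "control": {"uncued_attenuation": 0.5},
}


_MODEL2_EXTRA = {
    "fields": {
        # feature attention switches to a winner-takes-all regime
        "FA": {"kernel": {"g_inh": 0.3}},
        # spatial attention: winner-takes-all (strong global inhibition)
        "SA": {
            "h": -5.0, "tau": 20.0, "q": 0.06, "beta": 4.0,
            "kernel": {"c_exc": 0.5, "sigma_exc": 8.0,
                       "c_inh": 0.25, "sigma_inh": 20.0, "g_inh": 0.4},
        },
        # inhibition of return: slow spatial memory of attended locations
        "IOR": {
            "h": -1.5, "tau": 50.0, "q": 0.04, "beta": 4.0,
            "kernel": {"c_exc": 0.45, "sigma_exc": 8.0,
                       "c_inh": 0.0, "sigma_inh": 20.0, "g_inh": 0.05},
        },
        # scene-level attention over color: conjunction of FWM and attention
        "SLA": {
            "h": -3.0, "tau": 20.0, "q": 0.06, "beta": 4.0,
            "kernel": {"c_exc": 0.8, "sigma_exc": 5.0,
                       "c_inh": 0.35, "sigma_inh": 12.0, "g_inh": 0.05},
        },
    },
    "nodes": {
        "PD": {"h": -1.5, "tau": 20.0, "self_exc": 1.2, "q": 0.0},
        "CoS": {"h": -1.5, "tau": 20.0, "self_exc": 1.2, "q": 0.0},
    },
    "couplings": {
        # attention is driven by the novelty (feature contrast) field and,
        # more weakly, by the sensory field directly; winner-takes-all
        # competition in FA (strong global inhibition, see FA kernel)
        "FA<-CS": {"projection": "space_sum", "gain": 0.3, "sigma": 5.0},
        "FA<-FC": {"projection": "identity", "gain": 2.0, "sigma": 5.0},
        "FA<-FWM": {"projection": "identity", "gain": 0.0, "sigma": 5.0},
        "FA<-SLA": {"projection": "identity", "gain": 3.0, "sigma": 5.0},
        "SA<-CS": {"projection": "color_sum", "gain": 0.6, "sigma": 5.0},
        # biased competition through the sensory field
        "CS<-SA": {"projection": "expand_over_color", "gain": 0.15, "sigma": 5.0},
        "CS<-FA_sample": {"projection": "expand_over_space", "gain": 0.15,
                          "sigma": 5.0, "source": "FA"},
        # consolidation requires feature attention: FC drive alone is
        # sub-threshold, the attended item's summed drive ignites FWM
        "FWM<-FC": {"projection": "identity", "gain": 6.0, "sigma": 5.0},
        "FWM<-FA": {"projection": "identity", "gain": 2.5, "sigma": 5.0},
        "FC<-Inhib": {"projection": "identity", "gain": -6.0, "sigma": 10.0},
        # scene-level attention: conjunction of memory and attention
        "SLA<-FWM": {"projection": "identity", "gain": 2.0, "sigma": 5.0},
        "SLA<-FA": {"projection": "identity", "gain": 4.0, "sigma": 5.0},
        # IOR charges at the attended location while CoS is active,
        # then self-sustains and suppresses re-selection
        "IOR<-SA": {"projection": "identity", "gain": 24.0, "sigma": 8.0,
                    "gated_by": "CoS"},
        "SA<-IOR": {"projection": "identity", "gain": -3.0, "sigma": 8.0},
        # completion detection and disengagement
        "PD<-SLA": {"projection": "sum", "gain": 1.5},
        "CoS<-PD": {"projection": "node", "gain": 8.0, "gate": "encoding"},
        "FA<-CoS": {"projection": "uniform", "gain": -6.0},
        "SA<-CoS": {"projection": "uniform", "gain": -3.0},
        "SLA<-CoS": {"projection": "uniform", "gain": -6.0},
    },
    "response": {"fa_h_boost": 4.0, "threshold": 0.0, "hold_ms": 50.0,
                 "stability_tol": 6.0, "wheel_window": 12.0},
    # during encoding the memory field's effective resting level is held
    # down, so consolidation requires the attended item's summed drive
    "phase_bias": {"sample": {"FWM": -2.5}},
    "cue": {"boost_amp": 3.0, "boost_width": 40.0, "fa_amp": 0.0,
            "target": "SLA"},
}


def merge(base: dict, override: Optional[dict]) -> dict:
    """Deep-merge override into a copy of base (dicts merged recursively)."""
    out = copy.deepcopy(base)
    if not override:
        return out
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def model1_params(preset: str = "default", override: Optional[dict] = None) -> dict:
    p = copy.deepcopy(_MODEL1)
    p["grid"] = dict(GRID_PRESETS[preset])
    return merge(p, override)


def model2_params(preset: str = "default", override: Optional[dict] = None) -> dict:
    p = merge(_MODEL1, _MODEL2_EXTRA)
    p["grid"] = dict(GRID_PRESETS[preset])
    return merge(p, override)


def dump_params(params: dict, path) -> None:
    """Write the full parameter set as YAML for run provenance."""
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def load_params(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
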