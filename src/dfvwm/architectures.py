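"""Model assembly and single-trial simulation.

Two architectures are provided:

* **Model 1** -- a five-field network: a 2D color-space sensory field
  (CS) feeding a feature pathway of feature attention (FA), feature
  contrast (FC), a shared inhibitory field (Inhib) and feature working
  memory (FWM), all defined over hue.  Items are encoded in parallel;
  memory peaks self-sustain through the delay, and surround inhibition
  between nearby peaks produces similarity-based repulsion.

* **Model 2** -- Model 1 plus a simplified scene-representation
  pathway: spatial attention (SA) and inhibition-of-return (IOR) fields
  over polar angle, a scene-level attention field (SLA) over hue, and
  peak-detector (PD) / condition-of-satisfaction (CoS) nodes.  Winner-
  takes-all competition in the attention fields, completion detection
  via SLA -> PD -> CoS, and IOR-mediated disengagement produce
  autonomous sequential consolidation of the display items.

A trial runs through fixation -> sample -> (delay) -> test.  At test the
response wheel enters CS as a sub-threshold diagonal ridge, the cued
item's memory peak is boosted (directly in FWM for Model 1, via SLA for
Model 2), and a resting-level boost in FA drives selection of the cued
hue, which projects a ridge into CS; the response is read off the
spatial position of the resulting CS peak through the wheel mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import fft as sp_fft

from .fields import (
    EXTENT,
    DynamicNode,
    Field,
    InteractionKernel,
    SigmoidSpec,
    circular_distance,
    detect_peaks,
    euler_step,
    node_step,
    sigmoid,
)
from .task import (
    StimulusSchedule,
    TrialSpec,
    make_stimulus_inputs,
    signed_error,
    wheel_hue,
)

__all__ = [
    "MODEL1",
    "MODEL2",
    "CouplingSpec",
    "ModelState",
    "TrialResult",
    "build_model1",
    "build_model2",
    "cue_boost",
    "readout_response",
    "simulate_trial",
]

MODEL1 = "MODEL1"
MODEL2 = "MODEL2"

_PROJECTIONS = {
    "identity", "space_sum", "color_sum",
    "expand_over_space", "expand_over_color",
    "sum", "uniform", "node",
}


@dataclass(frozen=True)
class CouplingSpec:
    """One directed connection of the architecture graph.

    ``projection`` maps the source output onto the target's geometry;
    the sign of ``gain`` encodes excitatory (+) vs inhibitory (-).
    ``gate`` restricts the coupling to a trial phase ("test" or
    "encoding"); ``gated_by`` multiplies it by a node's output.
    """

    source: str
    target: str
    projection: str
    gain: float
    sigma: float = 0.0
    gate: Optional[str] = None
    gated_by: Optional[str] = None

    def __post_init__(self):
        if self.projection not in _PROJECTIONS:
            raise ValueError(f"unknown projection {self.projection!r}")

    @property
    def excitatory(self) -> bool:
        return self.gain >= 0


def _smooth_matrix(n: int, sigma: float, cache: dict) -> Optional[np.ndarray]:
    """Circulant matrix of a normalized Gaussian smoothing kernel
    (including the grid-spacing factor), for small 1D profiles."""
    if sigma <= 0:
        return None
    key = (n, sigma)
    if key not in cache:
        d = circular_distance(np.arange(n) * (EXTENT / n), 0.0)
        g = np.exp(-0.5 * (d / sigma) ** 2)
        g = g / g.sum()  # integrates to one after the spacing factor
        idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
        cache[key] = g[idx]
    return cache[key]


@dataclass
class TrialResult:
    reported_hue: Optional[float]
    target_hue: float
    signed_error: Optional[float]
    response_time: Optional[float]
    consolidation_order: List[Tuple[int, float]]
    guess_flag: bool
    condition: str = ""
    probed_role: str = ""


class ModelState:
    """The coupled fields and nodes constituting one model variant."""

    def __init__(self, variant: str, params: dict):
        self.variant = variant
        self.params = params
        self.clock = 0.0
        grid = params["grid"]
        self.n_color = int(grid["n_color"])
        self.n_space = int(grid["n_space"])
        self.dt = float(grid["dt"])
        self.fields: Dict[str, Field] = {}
        self.nodes: Dict[str, DynamicNode] = {}
        self.couplings: List[CouplingSpec] = []
        self._smooth_cache: dict = {}
        self._build()

    # -- construction ---------------------------------------------------
    def _field_shape(self, name: str) -> tuple:
        if name == "CS":
            return (self.n_space, self.n_color)
        if name in ("SA", "IOR"):
            return (self.n_space,)
        return (self.n_color,)

    def _build(self):
        fp = self.params["fields"]
        for name, spec in fp.items():
            kern = spec.get("kernel")
            kernel = None
            if kern is not None:
                kernel = InteractionKernel(
                    c_exc=kern.get("c_exc", 0.0),
                    sigma_exc=_as_sigma(kern.get("sigma_exc", 5.0)),
                    c_inh=kern.get("c_inh", 0.0),
                    sigma_inh=_as_sigma(kern.get("sigma_inh", 10.0)),
                    g_inh=kern.get("g_inh", 0.0),
                )
            self.fields[name] = Field(
                label=name,
                shape=self._field_shape(name),
                h=spec["h"],
                tau=spec["tau"],
                q=spec.get("q", 0.0),
                kernel=kernel,
                sigmoid=SigmoidSpec(beta=spec.get("beta", 4.0)),
            )
        for name, spec in self.params.get("nodes", {}).items():
            self.nodes[name] = DynamicNode(
                label=name,
                h=spec["h"],
                tau=spec["tau"],
                self_exc=spec.get("self_exc", 0.0),
                q=spec.get("q", 0.0),
            )
        for name, cspec in self.params["couplings"].items():
            tgt, _, src = name.partition("<-")
            src = cspec.get("source", src)
            cp = CouplingSpec(
                source=src,
                target=tgt,
                projection=cspec["projection"],
                gain=cspec["gain"],
                sigma=cspec.get("sigma", 0.0),
                gate=cspec.get("gate"),
                gated_by=cspec.get("gated_by"),
            )
            self._validate_coupling(cp, name)
            self.couplings.append(cp)

    def _validate_coupling(self, cp: CouplingSpec, name: str):
        known = set(self.fields) | set(self.nodes)
        for end in (cp.source, cp.target):
            if end not in known:
                raise ValueError(f"coupling {name!r} references unknown {end!r}")
        src_dim = 0 if cp.source in self.nodes else len(self.fields[cp.source].shape)
        tgt_dim = 0 if cp.target in self.nodes else len(self.fields[cp.target].shape)
        need = {
            "identity": (1, 1), "space_sum": (2, 1), "color_sum": (2, 1),
            "expand_over_space": (1, 2), "expand_over_color": (1, 2),
            "sum": (1, 0), "uniform": (0, 1), "node": (0, 0),
        }[cp.projection]
        if (src_dim, tgt_dim) != need:
            raise ValueError(
                f"coupling {name!r}: projection {cp.projection} expects "
                f"dims {need}, got ({src_dim}, {tgt_dim})"
            )

    # -- state management -----------------------------------------------
    def reset(self):
        for f in self.fields.values():
            f.u = np.full(f.shape, f.h, dtype=float)
        for nd in self.nodes.values():
            nd.u = float(nd.h)
        self.clock = 0.0

    def zero_noise(self):
        for f in self.fields.values():
            f.q = 0.0
        for nd in self.nodes.values():
            nd.q = 0.0

    def adjacency(self) -> set:
        """Directed edge set {(source, target, 'exc'|'inh')}."""
        return {
            (c.source, c.target, "exc" if c.excitatory else "inh")
            for c in self.couplings if c.gain != 0.0
        }

    # -- dynamics -------------------------------------------------------
    def _smooth(self, profile: np.ndarray, sigma: float) -> np.ndarray:
        m = _smooth_matrix(profile.size, sigma, self._smooth_cache)
        if m is None:
            return profile
        return m @ profile

    def _project(self, cp: CouplingSpec, outputs: dict) -> np.ndarray | float:
        g = outputs[cp.source]
        if cp.projection == "identity":
            return cp.gain * self._smooth(g, cp.sigma)
        if cp.projection == "space_sum":
            prof = g.sum(axis=0) * (EXTENT / self.n_space)
            return cp.gain * self._smooth(prof, cp.sigma)
        if cp.projection == "color_sum":
            prof = g.sum(axis=1) * (EXTENT / self.n_color)
            return cp.gain * self._smooth(prof, cp.sigma)
        if cp.projection == "expand_over_space":
            return cp.gain * self._smooth(g, cp.sigma)[None, :]
        if cp.projection == "expand_over_color":
            return cp.gain * self._smooth(g, cp.sigma)[:, None]
        if cp.projection == "sum":
            src = self.fields[cp.source]
            return cp.gain * float(g.sum()) * src.cell
        if cp.projection in ("uniform", "node"):
            return cp.gain * g
        raise AssertionError(cp.projection)

    def step(
        self,
        cs_input: Optional[np.ndarray],
        phase: str,
        rng: Optional[np.random.Generator],
        extra_inputs: Optional[Dict[str, np.ndarray]] = None,
    ):
        """Advance all fields and nodes by one time step.

        ``phase`` is one of fixation/sample/delay/test and controls the
        phase-gated couplings.  ``extra_inputs`` carries the test-phase
        boosts (cue boost, FA resting-level boost).
        """
        outputs = {n: f.output() for n, f in self.fields.items()}
        for n, nd in self.nodes.items():
            outputs[n] = nd.output()

        inputs: Dict[str, np.ndarray | float] = {
            n: np.zeros(f.shape) for n, f in self.fields.items()
        }
        for n in self.nodes:
            inputs[n] = 0.0
        if cs_input is not None:
            inputs["CS"] = inputs["CS"] + cs_input
        if extra_inputs:
            for n, arr in extra_inputs.items():
                inputs[n] = inputs[n] + arr

        for cp in self.couplings:
            if cp.gate == "test" and phase != "test":
                continue
            if cp.gate == "encoding" and phase == "test":
                continue
            contrib = self._project(cp, outputs)
            if cp.gated_by is not None:
                contrib = contrib * outputs[cp.gated_by]
            inputs[cp.target] = inputs[cp.target] + contrib

        for n, f in self.fields.items():
            euler_step(f, inputs[n], self.dt, rng, output=outputs[n])
        for n, nd in self.nodes.items():
            node_step(nd, float(inputs[n]), self.dt, rng)
        self.clock += self.dt


def _as_sigma(s):
    if isinstance(s, (list, tuple)):
        return tuple(float(x) for x in s)
    return float(s)


def build_model1(params: dict) -> ModelState:
    """Assemble the five-field parallel-encoding model."""
    _require(params, ["CS", "FA", "FC", "Inhib", "FWM"])
    m = ModelState(MODEL1, params)
    if len(m.fields) != 5:
        raise ValueError("Model 1 must have exactly 5 fields")
    return m


def build_model2(params: dict) -> ModelState:
    """Assemble the scene-level model with sequential consolidation."""
    _require(params, ["CS", "FA", "FC", "Inhib", "FWM", "SA", "IOR", "SLA"])
    for nd in ("PD", "CoS"):
        if nd not in params.get("nodes", {}):
            raise ValueError(f"Model 2 requires node parameters for {nd!r}")
    m = ModelState(MODEL2, params)
    if len(m.fields) != 8 or len(m.nodes) != 2:
        raise ValueError("Model 2 must have 8 fields and 2 nodes")
    return m


def _require(params: dict, names):
    missing = [n for n in names if n not in params.get("fields", {})]
    if missing:
        raise ValueError(f"missing field parameters: {missing}")


# -- external inputs ----------------------------------------------------

def _stimulus_array(model: ModelState, hue: float, location: float,
                    scale: float) -> np.ndarray:
    sp = model.params["stimulus"]
    cs = model.fields["CS"]
    ds = circular_distance(cs.coords(0), location)[:, None]
    dc = circular_distance(cs.coords(1), hue)[None, :]
    return (sp["amp"] * scale
            * np.exp(-0.5 * (ds / sp["sigma_space"]) ** 2)
            * np.exp(-0.5 * (dc / sp["sigma_color"]) ** 2))


def _wheel_array(model: ModelState, rotation: float, mirrored: bool) -> np.ndarray:
    wp = model.params["wheel"]
    cs = model.fields["CS"]
    space = cs.coords(0)
    hues = np.array([wheel_hue(s, rotation, mirrored) for s in space])
    dc = circular_distance(cs.coords(1)[None, :], hues[:, None])
    return wp["amp"] * np.exp(-0.5 * (dc / wp["sigma"]) ** 2)


def cue_boost(model: ModelState, cued_hue: float) -> Dict[str, np.ndarray]:
    """Flat local boost around the cued item's hue.

    Model 1 applies it directly to FWM; Model 2 to the scene-level
    attention field.  The boost is flat (it biases peak strength, not
    peak position) and wide enough to partially overlap a neighboring
    close peak.
    """
    cfg = model.params["cue"]
    target = cfg["target"]
    f = model.fields[target]
    d = circular_distance(f.coords(), cued_hue)
    window = d <= cfg["boost_width"] / 2.0
    out = {target: np.where(window, cfg["boost_amp"], 0.0)}
    fa_amp = cfg.get("fa_amp", 0.0)
    if fa_amp:
        # the cue also biases feature attention toward the cued item; the
        # boost is flat, so it selects the item without shifting the
        # reported position, which is carried by the (drifted) memory peak
        out["FA"] = np.where(window, fa_amp, 0.0)
    return out


# -- readout ------------------------------------------------------------

def _wheel_mask(model: ModelState, rotation: float, mirrored: bool,
                window: float) -> np.ndarray:
    """CS sites lying on the response wheel (within ``window`` degrees of
    the diagonal ridge); the response must be a click on the wheel."""
    cs = model.fields["CS"]
    space = cs.coords(0)
    hues = np.array([wheel_hue(s, rotation, mirrored) for s in space])
    dc = circular_distance(cs.coords(1)[None, :], hues[:, None])
    return dc <= window


def _response_peak(model: ModelState, threshold: float,
                   mask: Optional[np.ndarray] = None):
    """Strongest above-threshold CS peak: (space_deg, color_deg, activation)."""
    cs = model.fields["CS"]
    u = cs.u
    if mask is not None:
        u = np.where(mask, u, -np.inf)
    i, j = np.unravel_index(np.argmax(u), u.shape)
    if not u[i, j] > threshold:
        return None
    u = cs.u
    n_s = u.shape[0]
    # sub-grid spatial estimate: circular centroid of supra-threshold
    # activation in a window around the peak (robust to the response
    # peak's diagonal elongation along the wheel)
    half = max(2, int(round(9.0 / (EXTENT / n_s))))
    rows = (i + np.arange(-half, half + 1)) % n_s
    w = np.clip(u[rows, :].max(axis=1) - threshold, 0.0, None)
    if w.sum() <= 0:
        w = np.ones_like(w)
    ang = cs.coords(0)[rows] * np.pi / 180.0
    mean = np.angle(np.sum(w * np.exp(1j * ang)))
    space = (mean * 180.0 / np.pi) % EXTENT
    return float(space), float(cs.coords(1)[j]), float(u[i, j])


class ResponseTracker:
    """Accepts a readout once a CS peak stays above threshold, at a stable
    spatial position, for the configured hold window."""

    def __init__(self, threshold: float, hold_ms: float, tol: float,
                 mask: Optional[np.ndarray] = None):
        self.threshold = threshold
        self.hold_ms = hold_ms
        self.tol = tol
        self.mask = mask
        self._loc = None
        self._since = None

    def update(self, model: ModelState, t: float) -> Optional[float]:
        pk = _response_peak(model, self.threshold, self.mask)
        if pk is None:
            self._loc = None
            self._since = None
            return None
        space = pk[0]
        if (self._loc is not None
                and circular_distance(space, self._loc) <= self.tol):
            if t - self._since >= self.hold_ms:
                return space
        else:
            self._since = t
        self._loc = space
        return None


def readout_response(model: ModelState, wheel_map) -> Optional[float]:
    """Instantaneous readout: spatial position of the strongest
    above-threshold CS peak on the wheel, mapped to a hue."""
    rp = model.params["response"]
    cs = model.fields["CS"]
    hues = np.array([wheel_map(s) for s in cs.coords(0)])
    dc = circular_distance(cs.coords(1)[None, :], hues[:, None])
    mask = dc <= rp.get("wheel_window", 12.0)
    pk = _response_peak(model, rp["threshold"], mask)
    if pk is None:
        return None
    return float(wheel_map(pk[0]))


# -- trial loop ---------------------------------------------------------

def _phase(t: float, trial: TrialSpec, schedule: StimulusSchedule) -> str:
    if t >= schedule.test_onset:
        return "test"
    tm = trial.timings
    if t < tm.sample_on:
        return "fixation"
    if t < tm.sample_off:
        return "sample"
    return "delay"


def simulate_trial(
    model: ModelState,
    trial: TrialSpec,
    rng: np.random.Generator,
    record_interval: Optional[float] = None,
) -> TrialResult:
    """Run one trial end-to-end and return the recall response.

    The model is reset, driven through the trial's stimulus schedule,
    and the response is read out from the sensory field once a stable
    above-threshold peak forms at test.  If no stable response occurs
    before the deadline the trial is scored as a uniform random guess
    (``guess_flag`` set), since the task forces a response on every
    trial.  ``record_interval`` optionally stores field snapshots every
    so many ms in ``model.history`` (for diagnostics/plots).
    """
    model.reset()
    rp = model.params["response"]
    schedule = make_stimulus_inputs(
        trial, model.params.get("control", {}).get("uncued_attenuation", 0.5)
    )
    dt = model.dt

    # piecewise-constant CS input: precompute per epoch
    times = sorted({e.t_on for e in schedule.events}
                   | {e.t_off for e in schedule.events if math.isfinite(e.t_off)}
                   | {0.0, schedule.test_onset})
    epochs = []
    cs_shape = model.fields["CS"].shape
    for k, t0 in enumerate(times):
        t1 = times[k + 1] if k + 1 < len(times) else math.inf
        arr = np.zeros(cs_shape)
        for e in schedule.active(t0 + 1e-9):
            if e.kind == "stimulus":
                arr += _stimulus_array(model, e.hue, e.location, e.scale)
            elif e.kind == "wheel":
                arr += _wheel_array(model, schedule.wheel_rotation,
                                    schedule.wheel_mirrored)
        epochs.append((t0, t1, arr))

    boosts = cue_boost(model, trial.target_hue)
    fa_boost = rp["fa_h_boost"]
    mask = _wheel_mask(model, trial.wheel_rotation, trial.wheel_mirrored,
                       rp.get("wheel_window", 12.0))
    tracker = ResponseTracker(rp["threshold"], rp["hold_ms"],
                              rp["stability_tol"], mask)

    wm = model.fields["FWM"]
    item_masks = [circular_distance(wm.coords(), h) <= 12.0 for h in trial.hues]
    # consolidation = a genuine memory peak near the item's hue; the
    # threshold sits well above the reach of sub-threshold noise
    consol_threshold = 2.0
    consolidated: Dict[int, float] = {}

    model.history = []  # type: ignore[attr-defined]
    epoch_idx = 0
    t = 0.0
    reported = None
    rt = None
    while t < schedule.deadline:
        while epoch_idx + 1 < len(epochs) and t >= epochs[epoch_idx][1]:
            epoch_idx += 1
        cs_input = epochs[epoch_idx][2]
        phase = _phase(t, trial, schedule)
        extra = {}
        for fname, bias in model.params.get("phase_bias", {}).get(phase, {}).items():
            extra[fname] = extra.get(fname, 0.0) + bias
        if phase == "test":
            for fname, arr in boosts.items():
                extra[fname] = extra.get(fname, 0.0) + arr
            extra["FA"] = extra.get("FA", 0.0) + fa_boost
        model.step(cs_input, phase, rng, extra or None)
        t += dt

        if phase != "test" or trial.condition == "control":
            for i, mask in enumerate(item_masks):
                if i not in consolidated and np.any(wm.u[mask] > consol_threshold):
                    consolidated[i] = t
        if record_interval and (round(t / dt) % max(1, round(record_interval / dt)) == 0):
            model.history.append(
                (t, {n: f.u.copy() for n, f in model.fields.items()})
            )
        if phase == "test":
            space = tracker.update(model, t)
            if space is not None:
                reported = wheel_hue(space, trial.wheel_rotation,
                                     trial.wheel_mirrored)
                rt = t - schedule.test_onset
                break

    guess = reported is None
    if guess:
        reported = float(rng.uniform(0.0, 360.0))
        rt = schedule.deadline - schedule.test_onset
    order = sorted(consolidated.items(), key=lambda kv: kv[1])
    return TrialResult(
        reported_hue=float(reported),
        target_hue=float(trial.target_hue),
        signed_error=signed_error(reported, trial.target_hue),
        response_time=float(rt),
        consolidation_order=order if model.variant == MODEL2 else [],
        guess_flag=bool(guess),
        condition=trial.condition,
        probed_role=trial.probed_role,
    )
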