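"""Cued color-recall task: trial structure, stimulus geometry, error metric.

The task shows one (SS1) or three (SS3) colored discs on an invisible
circle around fixation.  On SS3 trials two of the colors are metrically
close -- 20 degrees apart on the hue circle, one clockwise (CW) and one
counter-clockwise (CCW) of their midpoint -- and the third is unique,
170 degrees away from each close color.  After a blank delay (delay
condition) or with no delay (control condition, where the response wheel
overlaps the final 300 ms of the sample display) a spatial cue probes
one item and the response is a click on a color wheel whose orientation
is randomized and mirrored on half the trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import List, Optional

import numpy as np
import pandas as pd

from .fields import circular_diff

__all__ = [
    "Timings",
    "TrialSpec",
    "InputEvent",
    "StimulusSchedule",
    "signed_error",
    "wheel_hue",
    "generate_trials",
    "make_stimulus_inputs",
    "trials_to_frame",
    "trials_from_frame",
]

DELAY = "delay"
CONTROL = "control"

#: number of discrete sample colors and their spacing on the hue circle
N_COLORS = 180
COLOR_STEP = 2.0

#: minimum angular separation between item locations (degrees)
MIN_LOCATION_SEP = 80.0

#: hue separation of the close pair and close-to-unique separation
CLOSE_SEP = 20.0
UNIQUE_SEP = 170.0


@dataclass(frozen=True)
class Timings:
    """Phase durations in ms.  In the control condition the wheel appears
    ``control_wheel_lead`` ms before sample offset and the delay is zero."""

    fixation: float = 500.0
    sample: float = 800.0
    delay: float = 1000.0
    control_overlap: float = 300.0
    response_deadline: float = 2000.0

    @property
    def sample_on(self) -> float:
        return self.fixation

    @property
    def sample_off(self) -> float:
        return self.fixation + self.sample


@dataclass
class TrialSpec:
    condition: str  # DELAY | CONTROL
    set_size: int  # 1 | 3
    hues: List[float]  # degrees on the hue circle, 2-degree lattice
    locations: List[float]  # polar angles, degrees
    roles: List[str]  # SINGLE | UNIQUE | CW | CCW per item
    probed_index: int
    wheel_rotation: float = 0.0
    wheel_mirrored: bool = False
    timings: Timings = dc_field(default_factory=Timings)

    @property
    def probed_role(self) -> str:
        return self.roles[self.probed_index]

    @property
    def target_hue(self) -> float:
        return self.hues[self.probed_index]

    @property
    def target_location(self) -> float:
        return self.locations[self.probed_index]


def signed_error(reported: float, target: float) -> float:
    """Signed circular recall error (reported - target) in (-180, 180].

    Positive errors are clockwise in color space, so repulsion of the
    close pair yields positive errors for CW targets and negative for
    CCW targets; e.g. a report of 83 for a 90-degree target is -7.
    """
    return float(circular_diff(reported, target))


def wheel_hue(spatial_angle: float, rotation: float, mirrored: bool) -> float:
    """Hue shown at a polar angle of the response wheel.

    The wheel maps 360 degrees of polar angle one-to-one onto 360
    degrees of hue, offset by a per-trial rotation and optionally
    mirror-reversed.
    """
    s = -spatial_angle if mirrored else spatial_angle
    return float((rotation + s) % 360.0)


def wheel_angle(hue: float, rotation: float, mirrored: bool) -> float:
    """Inverse of :func:`wheel_hue`: polar angle at which a hue appears."""
    a = (hue - rotation) % 360.0
    return float((-a) % 360.0 if mirrored else a)


def _lattice_hue(rng: np.random.Generator) -> float:
    return float(rng.integers(N_COLORS) * COLOR_STEP)


def _sample_locations(
    n: int,
    rng: np.random.Generator,
    forbidden: Optional[callable] = None,
    max_tries: int = 10000,
) -> List[float]:
    """Uniform polar angles with pairwise separation >= 80 degrees."""
    for _ in range(max_tries):
        locs = rng.uniform(0.0, 360.0, size=n)
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                d = abs(locs[i] - locs[j]) % 360.0
                if min(d, 360.0 - d) < MIN_LOCATION_SEP:
                    ok = False
        if ok and forbidden is not None:
            ok = not any(forbidden(l) for l in locs)
        if ok:
            return [float(l) for l in locs]
    raise RuntimeError("could not place item locations")


def _make_ss3_trial(
    condition: str,
    probe_role: str,
    rng: np.random.Generator,
    timings: Timings,
) -> TrialSpec:
    mid = _lattice_hue(rng)
    cw = (mid + CLOSE_SEP / 2) % 360.0
    ccw = (mid - CLOSE_SEP / 2) % 360.0
    unique = (mid + 180.0) % 360.0  # 170 degrees from each close hue
    hues = [cw, ccw, unique]
    roles = ["CW", "CCW", "UNIQUE"]
    rotation = float(rng.uniform(0.0, 360.0))
    mirrored = bool(rng.integers(2))
    forbidden = None
    if condition == CONTROL:
        # keep stimuli off the wheel diagonal: each item's location must not
        # coincide with where its own hue sits on the wheel
        def forbidden_builder(hue):
            wa = wheel_angle(hue, rotation, mirrored)

            def check(loc, wa=wa):
                d = abs(loc - wa) % 360.0
                return min(d, 360.0 - d) < 30.0

            return check

        checks = [forbidden_builder(h) for h in hues]
        locs = None
        for _ in range(10000):
            cand = _sample_locations(3, rng)
            if not any(chk(l) for chk, l in zip(checks, cand)):
                locs = cand
                break
        if locs is None:
            raise RuntimeError("could not satisfy control-layout constraint")
    else:
        locs = _sample_locations(3, rng)
    return TrialSpec(
        condition=condition,
        set_size=3,
        hues=hues,
        locations=locs,
        roles=roles,
        probed_index=roles.index(probe_role),
        wheel_rotation=rotation,
        wheel_mirrored=mirrored,
        timings=timings,
    )


def _make_ss1_trial(
    condition: str, rng: np.random.Generator, timings: Timings
) -> TrialSpec:
    return TrialSpec(
        condition=condition,
        set_size=1,
        hues=[_lattice_hue(rng)],
        locations=[float(rng.uniform(0.0, 360.0))],
        roles=["SINGLE"],
        probed_index=0,
        wheel_rotation=float(rng.uniform(0.0, 360.0)),
        wheel_mirrored=bool(rng.integers(2)),
        timings=timings,
    )


def generate_trials(
    condition: str,
    rng: np.random.Generator,
    counts: Optional[dict] = None,
    timings: Optional[Timings] = None,
) -> List[TrialSpec]:
    """Build the full randomized trial list for one simulated session.

    Default composition matches the experimental design exactly:

    * delay condition -- 800 trials: 160 SS1 and 640 SS3 (320 probing the
      unique color, 160 each probing the CW and CCW close colors);
    * control condition -- 640 SS3 trials: 320 unique, 160 CW, 160 CCW.

    ``counts`` may override the per-condition trial numbers (keys
    ``SINGLE``, ``UNIQUE``, ``CW``, ``CCW``) for reduced-scale runs.
    Counts are exact for any seed: probes are pre-allocated and the
    trial order shuffled.
    """
    if condition not in (DELAY, CONTROL):
        raise ValueError(f"unknown condition {condition!r}")
    timings = timings or Timings()
    if counts is None:
        if condition == DELAY:
            counts = {"SINGLE": 160, "UNIQUE": 320, "CW": 160, "CCW": 160}
        else:
            counts = {"SINGLE": 0, "UNIQUE": 320, "CW": 160, "CCW": 160}
    trials: List[TrialSpec] = []
    for _ in range(counts.get("SINGLE", 0)):
        trials.append(_make_ss1_trial(condition, rng, timings))
    for role in ("UNIQUE", "CW", "CCW"):
        for _ in range(counts.get(role, 0)):
            trials.append(_make_ss3_trial(condition, role, rng, timings))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


@dataclass(frozen=True)
class InputEvent:
    """One piecewise-constant external-input epoch for the sensory field."""

    t_on: float
    t_off: float  # may be inf (present until trial end)
    kind: str  # "stimulus" | "wheel"
    hue: Optional[float] = None
    location: Optional[float] = None
    scale: float = 1.0  # amplitude multiplier (control-condition attenuation)


@dataclass
class StimulusSchedule:
    events: List[InputEvent]
    test_onset: float  # wheel + cue onset, ms
    deadline: float  # absolute response deadline, ms
    wheel_rotation: float
    wheel_mirrored: bool

    def active(self, t: float) -> List[InputEvent]:
        return [e for e in self.events if e.t_on <= t < e.t_off]


def make_stimulus_inputs(
    trial: TrialSpec, uncued_attenuation: float = 0.5
) -> StimulusSchedule:
    """Time-indexed external-input schedule for the sensory field.

    Delay condition: stimuli on [fixation, fixation+sample); wheel (and
    cue) from fixation+sample+delay.  Control condition: wheel appears
    300 ms before sample offset; during the overlap the two uncued
    stimulus inputs are attenuated, capturing the attentional shift to
    the cued region of space.
    """
    tm = trial.timings
    events: List[InputEvent] = []
    if trial.condition == DELAY:
        test_onset = tm.sample_off + tm.delay
        for h, l in zip(trial.hues, trial.locations):
            if tm.sample > 0:
                events.append(
                    InputEvent(tm.sample_on, tm.sample_off, "stimulus", h, l)
                )
    else:
        test_onset = tm.sample_off - tm.control_overlap
        for i, (h, l) in enumerate(zip(trial.hues, trial.locations)):
            if tm.sample <= 0:
                continue
            events.append(InputEvent(tm.sample_on, test_onset, "stimulus", h, l))
            scale = 1.0 if i == trial.probed_index else uncued_attenuation
            events.append(
                InputEvent(test_onset, tm.sample_off, "stimulus", h, l, scale)
            )
    events.append(
        InputEvent(test_onset, math.inf, "wheel")
    )
    return StimulusSchedule(
        events=events,
        test_onset=test_onset,
        deadline=test_onset + tm.response_deadline,
        wheel_rotation=trial.wheel_rotation,
        wheel_mirrored=trial.wheel_mirrored,
    )


def trials_to_frame(trials: List[TrialSpec]) -> pd.DataFrame:
    """Serialize trial specs to a flat table (one row per trial)."""
    rows = []
    for t in trials:
        rows.append(
            {
                "condition": t.condition,
                "set_size": t.set_size,
                "hues": ";".join(f"{h:g}" for h in t.hues),
                "locations": ";".join(f"{l:.4f}" for l in t.locations),
                "roles": ";".join(t.roles),
                "probed_index": t.probed_index,
                "wheel_rotation": t.wheel_rotation,
                "wheel_mirrored": int(t.wheel_mirrored),
            }
        )
    return pd.DataFrame(rows)


def trials_from_frame(df: pd.DataFrame, timings: Optional[Timings] = None) -> List[TrialSpec]:
    timings = timings or Timings()
    out = []
    for _, r in df.iterrows():
        out.append(
            TrialSpec(
                condition=r["condition"],
                set_size=int(r["set_size"]),
                hues=[float(x) for x in str(r["hues"]).split(";")],
                locations=[float(x) for x in str(r["locations"]).split(";")],
                roles=str(r["roles"]).split(";"),
                probed_index=int(r["probed_index"]),
                wheel_rotation=float(r["wheel_rotation"]),
                wheel_mirrored=bool(int(r["wheel_mirrored"])),
                timings=timings,
            )
        )
    return out
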