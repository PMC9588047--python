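"""Architecture tests: graph structure, trial dynamics, readout.

Simulation-heavy statistical checks live in the acceptance suite; here
the trials are noise-free (deterministic) and fast.
"""

import numpy as np
import pytest

from dfvwm.architectures import (
    ModelState,
    build_model1,
    build_model2,
    cue_boost,
    readout_response,
    simulate_trial,
)
from dfvwm.fields import circular_distance, detect_peaks
from dfvwm.fixtures import MODEL1_EDGES, MODEL2_EXTRA_EDGES
from dfvwm.params import model1_params, model2_params
from dfvwm.task import TrialSpec


@pytest.fixture(scope="module")
def m1():
    m = build_model1(model1_params("fast"))
    m.zero_noise()
    return m


@pytest.fixture(scope="module")
def m2():
    m = build_model2(model2_params("fast"))
    m.zero_noise()
    return m


def _ss3_trial(condition, probe, rotation=40.0, mirrored=False):
    return TrialSpec(condition, 3, [100.0, 80.0, 270.0],
                     [15.0, 135.0, 255.0], ["CW", "CCW", "UNIQUE"], probe,
                     wheel_rotation=rotation, wheel_mirrored=mirrored)


class TestGraphs:
    def test_model1_matches_adjacency_fixture(self, m1):
        assert m1.adjacency() == MODEL1_EDGES.payload

    def test_model2_matches_adjacency_fixture(self, m2):
        # the scene-level model reroutes the cue pathway through SLA:
        # the direct FWM->FA edge is replaced by the scene-level edges
        expected = (MODEL1_EDGES.payload - {("FWM", "FA", "exc")}) | \
            MODEL2_EXTRA_EDGES.payload | {("SLA", "FA", "exc")}
        assert m2.adjacency() == expected

    def test_field_counts(self, m1, m2):
        assert len(m1.fields) == 5 and not m1.nodes
        assert len(m2.fields) == 8 and len(m2.nodes) == 2

    def test_inhib_is_sole_inhibitory_field_in_core(self, m1):
        inh_edges = [(s, t) for s, t, sign in m1.adjacency() if sign == "inh"]
        assert set(inh_edges) == {("Inhib", "FWM"), ("Inhib", "FC")}

    def test_missing_parameters_named(self):
        params = model1_params("fast")
        del params["fields"]["FWM"]
        with pytest.raises(ValueError, match="FWM"):
            build_model1(params)

    def test_zero_gain_couplings_decouple_fields(self):
        params = model1_params("fast")
        for spec in params["couplings"].values():
            spec["gain"] = 0.0
        m = ModelState("MODEL1", params)
        m.zero_noise()
        rng = np.random.default_rng(0)
        stim = np.zeros(m.fields["CS"].shape)
        stim[10, 10] = 10.0
        for _ in range(100):
            m.step(stim, "sample", rng)
        for name in ("FA", "FC", "Inhib", "FWM"):
            f = m.fields[name]
            assert np.allclose(f.u, f.h, atol=1e-9), name


class TestMemoryRegimes:
    def test_wm_peak_survives_1s_without_input_but_sensory_decays(self, m1):
        """Self-sustaining regime in the memory field vs input-driven
        transients in the contrast field."""
        m1.reset()
        rng = np.random.default_rng(0)
        tr = TrialSpec("delay", 1, [90.0], [200.0], ["SINGLE"], 0)
        from dfvwm.task import make_stimulus_inputs
        from dfvwm.architectures import _stimulus_array
        stim = _stimulus_array(m1, 90.0, 200.0, 1.0)
        for _ in range(int(800 / m1.dt)):
            m1.step(stim, "sample", rng)
        assert detect_peaks(m1.fields["FWM"], 0.0)
        assert detect_peaks(m1.fields["FC"], 0.0)  # active while driven
        for _ in range(int(1000 / m1.dt)):
            m1.step(None, "delay", rng)
        peaks = detect_peaks(m1.fields["FWM"], 0.0)
        assert len(peaks) == 1  # memory peak persisted >= 1000 ms
        assert circular_distance(peaks[0][0], 90.0) < 8.0
        assert not detect_peaks(m1.fields["FC"], 0.0)  # transient decayed

    def test_close_pair_separation_nondecreasing_in_delay(self, m1):
        m1.reset()
        rng = np.random.default_rng(0)
        from dfvwm.architectures import _stimulus_array
        stim = (_stimulus_array(m1, 80.0, 15.0, 1.0)
                + _stimulus_array(m1, 100.0, 255.0, 1.0))
        for _ in range(int(800 / m1.dt)):
            m1.step(stim, "sample", rng)
        seps = []
        for k in range(int(1000 / m1.dt)):
            m1.step(None, "delay", rng)
            if k % 50 == 0:
                pks = detect_peaks(m1.fields["FWM"], 0.0)
                assert len(pks) == 2
                locs = sorted(p for p, _ in pks)
                d = locs[1] - locs[0]
                seps.append(min(d, 360.0 - d))
        assert all(b >= a - 1.5 for a, b in zip(seps, seps[1:]))  # 1.5 deg interpolation jitter
        assert seps[-1] > seps[0]  # net repulsion

    def test_far_pair_does_not_repel(self, m1):
        m1.reset()
        rng = np.random.default_rng(0)
        from dfvwm.architectures import _stimulus_array
        stim = (_stimulus_array(m1, 90.0, 15.0, 1.0)
                + _stimulus_array(m1, 260.0, 255.0, 1.0))
        for _ in range(int(800 / m1.dt)):
            m1.step(stim, "sample", rng)
        def sep():
            pks = detect_peaks(m1.fields["FWM"], 0.0)
            assert len(pks) == 2
            locs = sorted(p for p, _ in pks)
            d = locs[1] - locs[0]
            return min(d, 360.0 - d)
        s0 = sep()
        for _ in range(int(1000 / m1.dt)):
            m1.step(None, "delay", rng)
        assert abs(sep() - s0) < 1.0


class TestCueBoost:
    def test_flat_profile_and_width(self, m1):
        boosts = cue_boost(m1, 120.0)
        arr = boosts["FWM"]
        coords = m1.fields["FWM"].coords()
        inside = circular_distance(coords, 120.0) <= 20.0
        amp = m1.params["cue"]["boost_amp"]
        assert np.all(arr[inside] == amp)
        assert np.all(arr[~inside] == 0.0)

    def test_unique_item_boost_overlaps_no_other(self, m1):
        boosts = cue_boost(m1, 270.0)["FWM"]
        coords = m1.fields["FWM"].coords()
        for other in (80.0, 100.0):
            near = circular_distance(coords, other) <= 10.0
            assert np.all(boosts[near] == 0.0)

    def test_close_cue_partially_boosts_neighbor(self, m1):
        # 40-deg window centered on the CW hue reaches sites within 10 deg
        # of the CCW hue, 20 deg away
        boosts = cue_boost(m1, 100.0)["FWM"]
        coords = m1.fields["FWM"].coords()
        near_ccw = circular_distance(coords, 80.0) <= 10.0
        assert boosts[near_ccw].max() > 0.0

    def test_model2_boost_targets_scene_attention(self, m2):
        boosts = cue_boost(m2, 90.0)
        assert "SLA" in boosts and "FWM" not in boosts


class TestTrialsNoiseFree:
    def test_ss1_error_below_2_degrees(self, m1):
        rng = np.random.default_rng(0)
        tr = TrialSpec("delay", 1, [90.0], [200.0], ["SINGLE"], 0,
                       wheel_rotation=10.0)
        res = simulate_trial(m1, tr, rng)
        assert not res.guess_flag
        assert abs(res.signed_error) < 2.0

    def test_repulsion_signs_on_close_pair(self, m1):
        rng = np.random.default_rng(0)
        cw = simulate_trial(m1, _ss3_trial("delay", 0), rng)
        ccw = simulate_trial(m1, _ss3_trial("delay", 1), rng)
        assert cw.signed_error > 2.0
        assert ccw.signed_error < -2.0

    def test_control_bias_small(self, m1):
        rng = np.random.default_rng(0)
        for probe in (0, 1, 2):
            res = simulate_trial(m1, _ss3_trial("control", probe), rng)
            assert not res.guess_flag
            assert abs(res.signed_error) < 4.0

    def test_wheel_mirror_respected(self, m1):
        rng = np.random.default_rng(0)
        res_n = simulate_trial(m1, _ss3_trial("delay", 2, 40.0, False), rng)
        res_m = simulate_trial(m1, _ss3_trial("delay", 2, 40.0, True), rng)
        for res in (res_n, res_m):
            assert abs(res.signed_error) < 3.0  # unique target, no bias

    def test_model1_reports_no_consolidation_order(self, m1):
        rng = np.random.default_rng(0)
        res = simulate_trial(m1, _ss3_trial("delay", 2), rng)
        assert res.consolidation_order == []

    def test_model2_sequential_consolidation(self):
        # noise is part of the mechanism: it breaks the winner-takes-all
        # ties that order the attention sequence
        m = build_model2(model2_params("fast"))
        rng = np.random.default_rng(0)
        res = simulate_trial(m, _ss3_trial("delay", 2), rng)
        assert len(res.consolidation_order) == 3
        times = [t for _, t in res.consolidation_order]
        assert times == sorted(times)
        assert times[-1] <= 1300.0  # all consolidated within the sample


class TestReadout:
    def test_flat_sensory_field_reads_none(self, m1):
        m1.reset()
        assert readout_response(m1, lambda s: s) is None

    def test_planted_peak_reads_wheel_hue(self, m1):
        m1.reset()
        cs = m1.fields["CS"]
        ds = circular_distance(cs.coords(0), 150.0)[:, None]
        dc = circular_distance(cs.coords(1), 150.0)[None, :]
        cs.u = cs.u + 8.0 * np.exp(-0.5 * ((ds / 5.0) ** 2 + (dc / 5.0) ** 2))
        hue = readout_response(m1, lambda s: s)  # identity wheel
        assert hue is not None
        assert circular_distance(hue, 150.0) < 4.0

    def test_mirrored_wheel_map_applies(self, m1):
        # peak planted on the mirrored wheel: at space 150 the mirrored
        # wheel shows hue 210, and that is what gets reported
        m1.reset()
        cs = m1.fields["CS"]
        ds = circular_distance(cs.coords(0), 150.0)[:, None]
        dc = circular_distance(cs.coords(1), 210.0)[None, :]
        cs.u = cs.u + 8.0 * np.exp(-0.5 * ((ds / 5.0) ** 2 + (dc / 5.0) ** 2))
        hue = readout_response(m1, lambda s: (-s) % 360.0)
        assert hue is not None
        assert circular_distance(hue, 210.0) < 4.0

    def test_off_wheel_peak_ignored(self, m1):
        m1.reset()
        cs = m1.fields["CS"]
        # peak whose hue is 90 deg away from the wheel hue at its location
        ds = circular_distance(cs.coords(0), 40.0)[:, None]
        dc = circular_distance(cs.coords(1), 130.0)[None, :]
        cs.u = cs.u + 8.0 * np.exp(-0.5 * ((ds / 5.0) ** 2 + (dc / 5.0) ** 2))
        assert readout_response(m1, lambda s: s) is None
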