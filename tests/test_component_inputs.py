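"""The eight component inputs: kernels, envelopes, assembly, trial setup."""

import math

import numpy as np
import pytest

from sacfield.component_inputs import (
    InputModelOptions,
    InputSpec,
    TrialTimeline,
    assemble_external_drive,
    drive_matrix,
    initial_input_state,
    input_update,
    make_trial_inputs,
    spatial_kernel,
    value_field,
)
from sacfield.field_core import ModelConstants

from conftest import REFERENCE_ASSIGNMENT, make_assignment

C = ModelConstants()
TL = TrialTimeline(target_position_mm=2.0)


def rising_spec(**overrides):
    kw = dict(
        input_id=2, name="test_ramp", reference_event="target_onset",
        onset_delay_ms=0.0, ror=10.0, maxval=8.0, centers_mm=(2.0,),
        polarity=+1, profile="ramp_sustain",
    )
    kw.update(overrides)
    return InputSpec(**kw)


class TestSpatialKernel:
    def test_peak_at_center_node(self):
        k = spatial_kernel(2.0, C)
        node = np.argmin(np.abs(C.node_positions() - 2.0))
        assert k[node] == pytest.approx(1.05)

    def test_value_one_sd_away(self):
        k = spatial_kernel(2.0, C)
        node = np.argmin(np.abs(C.node_positions() - 2.6))
        assert k[node] == pytest.approx(1.05 * math.exp(-0.5), abs=1e-3)
        assert k[node] == pytest.approx(0.6368, abs=1e-3)

    def test_symmetric_about_center_on_torus(self):
        k = spatial_kernel(0.0, C)
        idx = np.arange(C.n_nodes)
        mirrored = k[(-idx) % C.n_nodes]
        assert np.allclose(k, mirrored)


class TestEnvelopes:
    def test_zero_before_onset(self):
        spec = rising_spec(onset_delay_ms=30.0)
        v = value_field(spec, TL.target_onset_ms + 30.0, TL, C)
        assert np.all(v == 0.0)

    def test_rise_rate_is_ror_percent_of_maxval(self):
        # 5 ms after onset at RoR 10%: 5 * 0.8 = 4.0, kernel-scaled 4.2
        spec = rising_spec()
        v = value_field(spec, TL.target_onset_ms + 5.0, TL, C)
        node = np.argmin(np.abs(C.node_positions() - 2.0))
        assert v[node] == pytest.approx(1.05 * 4.0)

    def test_cap_at_kernel_times_maxval(self):
        spec = rising_spec()
        node = np.argmin(np.abs(C.node_positions() - 2.0))
        for dt in (10.0, 25.0, 400.0):
            v = value_field(spec, TL.target_onset_ms + dt, TL, C)
            assert v[node] == pytest.approx(1.05 * 8.0)

    def test_transient_returns_to_zero_within_two_rise_times(self):
        spec = rising_spec(profile="ramp_decay", input_id=1)
        node = np.argmin(np.abs(C.node_positions() - 2.0))
        t_grid = TL.target_onset_ms + np.arange(0.0, 300.0)
        vals = value_field(spec, t_grid, TL, C)[:, node]
        assert vals.max() == pytest.approx(1.05 * 8.0)
        # gone within 200/ror ms of the peak
        peak_idx = int(np.argmax(vals))
        assert np.all(vals[peak_idx + int(200 / spec.ror):] == 0.0)

    def test_incremental_update_matches_closed_form(self):
        # step every input millisecond by millisecond and compare with the
        # vectorised drive construction over the whole trial
        specs, states, onset = make_trial_inputs(
            make_assignment(), TL, C, InputModelOptions()
        )
        t_end = TL.target_onset_ms + C.timeout_ms
        drives = drive_matrix(specs, TL, C, t_end, onset)
        t = 0.0
        for k in range(int(t_end)):
            assembled = assemble_external_drive(states, specs)
            assert np.allclose(assembled, drives[k], atol=1e-12)
            states = [
                input_update(s, sp, t, TL, C, onset) for s, sp in zip(states, specs)
            ]
            t += C.dt_ms

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            rising_spec(profile="bogus")


class TestAssembly:
    def test_all_zero_inputs_assemble_to_zero(self):
        specs = [rising_spec(), rising_spec(polarity=-1, input_id=7)]
        states = [initial_input_state(s, TL, C) for s in specs]
        assert np.all(assemble_external_drive(states, specs) == 0.0)

    def test_single_excitatory_input_passes_through(self):
        spec = rising_spec()
        state = initial_input_state(spec, TL, C)
        state.value = np.full(C.n_nodes, 2.0)
        assert np.allclose(assemble_external_drive([state], [spec]), 2.0)

    def test_equal_and_opposite_inputs_cancel(self):
        exc = rising_spec()
        inh = rising_spec(polarity=-1, input_id=7)
        s1 = initial_input_state(exc, TL, C)
        s2 = initial_input_state(inh, TL, C)
        s1.value = np.full(C.n_nodes, 3.0)
        s2.value = np.full(C.n_nodes, 3.0)
        assert np.all(assemble_external_drive([s1, s2], [exc, inh]) == 0.0)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            assemble_external_drive([], [])


class TestMakeTrialInputs:
    def test_eight_inputs_with_expected_polarity(self):
        specs, states, _ = make_trial_inputs(make_assignment(), TL, C)
        assert [s.input_id for s in specs] == list(range(1, 9))
        assert [s.polarity for s in specs] == [1, 1, 1, 1, 1, 1, -1, -1]
        assert len(states) == 8

    def test_visual_transient_onset_is_species_configured(self):
        specs, _, _ = make_trial_inputs(make_assignment(vt_onset=20.0), TL, C)
        assert specs[0].onset_delay_ms == 20.0
        specs, _, _ = make_trial_inputs(make_assignment(vt_onset=50.0), TL, C)
        assert specs[0].onset_delay_ms == 50.0

    def test_internally_driven_inputs_share_one_onset(self):
        asg = make_assignment(internal_onset=125.0)
        specs, _, onset = make_trial_inputs(asg, TL, C)
        assert onset == TL.target_onset_ms + 125.0
        # 4 and 6 rise at the joint onset; 5, 7 and 8 release at it
        assert specs[3].reference_event == "internal_onset"
        assert specs[5].reference_event == "internal_onset"
        for s in (specs[4], specs[6], specs[7]):
            assert s.release_event == "internal_onset"

    def test_voluntary_motor_is_uncapped_and_monotone(self):
        specs, _, onset = make_trial_inputs(make_assignment(), TL, C)
        vm = specs[3]
        assert math.isinf(vm.maxval)
        t_grid = np.arange(0.0, TL.target_onset_ms + C.timeout_ms)
        node = np.argmin(np.abs(C.node_positions() - 2.0))
        vals = value_field(vm, t_grid, TL, C, onset)[:, node]
        assert np.all(np.diff(vals) >= 0.0)

    def test_no_input_active_before_its_onset(self):
        specs, _, onset = make_trial_inputs(make_assignment(), TL, C)
        for s in specs:
            if s.starts_at_cap:
                continue
            t_on = TL.event_time(s.reference_event, onset) + s.onset_delay_ms
            v = value_field(s, t_on, TL, C, onset)
            assert np.all(v == 0.0)

    def test_excitatory_values_respect_kernel_cap(self):
        specs, _, onset = make_trial_inputs(make_assignment(), TL, C)
        t_grid = np.arange(0.0, TL.target_onset_ms + C.timeout_ms)
        for s in specs:
            if s.polarity < 0 or not math.isfinite(s.maxval):
                continue
            vals = value_field(s, t_grid, TL, C, onset)
            assert np.all(vals <= s.kernel_amp * s.maxval * len(s.centers_mm) + 1e-9)

    def test_incomplete_assignment_rejected(self):
        with pytest.raises(KeyError):
            make_trial_inputs({"vt_onset": 20.0}, TL, C)


class TestTimeline:
    def test_gap_structure_enforced(self):
        with pytest.raises(ValueError):
            TrialTimeline(gap_onset_ms=100.0, target_onset_ms=350.0)
        with pytest.raises(ValueError):
            TrialTimeline(fixation_onset_ms=300.0)
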