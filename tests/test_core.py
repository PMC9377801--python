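"""Single-trial operations: integration, recalibration, error, update."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from premo import (
    ModelState,
    PremoParams,
    TrialSpec,
    crossmodal_shifts,
    decay_shifts,
    integrate_cursor,
    integrate_hand,
    make_clamp_design,
    perceived_positions,
    proprioceptive_error,
    run_schedule,
    step_trial,
    update_state,
)
from premo.errors import ParameterError, ScheduleError

angles = st.floats(-90, 90, allow_nan=False)
weights = st.floats(0.01, 1.0, allow_nan=False)


class TestParams:
    def test_defaults_valid(self):
        p = PremoParams()
        assert 0 < p.w_p <= 1 and 0 <= p.eta_p < 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w_p": 0.0},
            {"w_p": 1.5},
            {"w_v": 0.0},
            {"eta_p": 1.0},
            {"eta_v": -0.1},
            {"beta_p_sat": -1.0},
            {"K": 1.2},
            {"A_ret": -0.5},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            PremoParams(**kwargs)

    def test_weights_derive_from_variances(self):
        p = PremoParams.from_variances(sigma_u2=1.0, sigma_p2=3.0, sigma_v2=0.25)
        assert p.w_p == pytest.approx(0.25, abs=1e-12)
        assert p.w_v == pytest.approx(0.8, abs=1e-12)

    def test_inconsistent_variances_rejected(self):
        with pytest.raises(ParameterError):
            PremoParams(w_p=0.5, sigma_u2=1.0, sigma_p2=3.0)


class TestIntegration:
    @pytest.mark.parametrize(
        "hand, goal, w, expected",
        [(0, 0, 0.25, 0.0), (20, 0, 0.25, 5.0), (7.3, -12.0, 1.0, 7.3)],
    )
    def test_hand_weighted_average(self, hand, goal, w, expected):
        assert integrate_hand(hand, goal, w) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cursor, goal, w, expected",
        [(15, 0, 1.0, 15.0), (15, 0, 0.8, 12.0), (4.0, 4.0, 0.3, 4.0)],
    )
    def test_cursor_weighted_average(self, cursor, goal, w, expected):
        assert integrate_cursor(cursor, goal, w) == pytest.approx(expected)

    @pytest.mark.parametrize("bad_w", [0.0, -0.2, 1.01])
    def test_weight_domain(self, bad_w):
        with pytest.raises(ParameterError):
            integrate_hand(0, 0, bad_w)
        with pytest.raises(ParameterError):
            integrate_cursor(0, 0, bad_w)


class TestCrossmodalShifts:
    def test_no_discrepancy_no_shift(self, default_params):
        assert crossmodal_shifts(3.0, 3.0, default_params) == (0.0, 0.0)

    def test_subsaturation_fixed_ratio(self):
        p = dataclasses.replace(PremoParams(), eta_p=0.5, beta_p_sat=5.0)
        beta_p, _ = crossmodal_shifts(0.0, 2.0, p)
        assert beta_p == pytest.approx(1.0)

    def test_saturation_common_value_for_15_and_30(self, default_params):
        """A 15 and a 30 deg discrepancy produce the same 5 deg
        proprioceptive shift toward the cursor (and 1 deg visual shift)."""
        shifts = [crossmodal_shifts(0.0, d, default_params) for d in (15.0, 30.0)]
        assert shifts[0] == shifts[1]
        assert shifts[0][0] == pytest.approx(5.0)
        assert shifts[0][1] == pytest.approx(-1.0)

    @given(x_p=angles, x_v=angles)
    @settings(deadline=None, max_examples=100)
    def test_magnitudes_never_exceed_saturation(self, x_p, x_v):
        p = PremoParams()
        beta_p, beta_v = crossmodal_shifts(x_p, x_v, p)
        assert abs(beta_p) <= p.beta_p_sat + 1e-9
        assert abs(beta_v) <= p.beta_v_sat + 1e-9

    @given(x_p=angles, x_v=angles)
    @settings(deadline=None, max_examples=100)
    def test_shifts_are_mutually_attractive(self, x_p, x_v):
        """The hand estimate shifts toward the cursor, the cursor toward
        the hand: opposite signs, each reducing the discrepancy."""
        beta_p, beta_v = crossmodal_shifts(x_p, x_v, PremoParams())
        delta = x_v - x_p
        assert beta_p * delta >= 0
        assert beta_v * delta <= 0


class TestPerception:
    def test_additive_decomposition(self):
        ph, pc, pt = perceived_positions(0.0, 12.0, 5.0, -1.0, 0.0)
        assert ph == 5.0 and pc == 11.0 and pt == -1.0

    def test_target_shifts_with_visual_shift(self):
        *_, pt = perceived_positions(0.0, 0.0, 0.0, -1.0, 0.0)
        assert pt == -1.0

    def test_identity_without_shifts(self):
        ph, pc, pt = perceived_positions(2.0, 3.0, 0.0, 0.0, 1.0)
        assert (ph, pc, pt) == (2.0, 3.0, 1.0)

    @pytest.mark.parametrize(
        "pt, ph, expected", [(0.0, 0.0, 0.0), (0.0, 5.0, -5.0), (-1.0, -1.0, 0.0)]
    )
    def test_proprioceptive_error(self, pt, ph, expected):
        assert proprioceptive_error(pt, ph) == expected


class TestUpdateAndDecay:
    def test_zero_error_leaves_state(self):
        s = ModelState(x_p=3.0, beta_p=1.0, beta_v=-0.5)
        assert update_state(s, 0.0, 0.2).x_p == 3.0

    def test_update_arithmetic(self):
        s = update_state(ModelState(), -5.0, 0.2)
        assert s.x_p == pytest.approx(-1.0)

    def test_decay_arithmetic(self):
        assert decay_shifts(4.0, -2.0, 0.9) == (pytest.approx(3.6), pytest.approx(-1.8))

    def test_decay_extremes(self):
        assert decay_shifts(4.0, -1.0, 1.0) == (4.0, -1.0)
        assert decay_shifts(4.0, -1.0, 0.0) == (0.0, 0.0)


class TestStepTrial:
    def test_first_clamp_trial_report_biased_toward_cursor(self, saturated_clamp_params):
        """With the shift saturated, the felt hand on the first clamp
        trial sits +beta_p_sat toward the clamp."""
        spec = TrialSpec(feedback_mode="clamp", perturbation_deg=15.0)
        _, rec = step_trial(ModelState(), spec, saturated_clamp_params)
        assert rec.perceived_hand == pytest.approx(5.0)

    def test_veridical_at_target_is_fixed_point(self, default_params):
        spec = TrialSpec(feedback_mode="veridical")
        state, rec = step_trial(ModelState(), spec, default_params)
        assert rec.prop_error == 0.0
        assert state.x_p == 0.0

    def test_passive_trial_shifts_without_update(self, default_params):
        p = dataclasses.replace(default_params, eta_p=0.4, beta_p_sat=5.0)
        spec = TrialSpec(
            feedback_mode="clamp", perturbation_deg=0.0,
            movement_mode="passive", passive_hand_deg=-10.0,
        )
        state, rec = step_trial(ModelState(), spec, p)
        assert rec.beta_p == pytest.approx(4.0)  # 0.4 * 10, below ceiling
        assert state.x_p == 0.0  # no efference, no map update

    def test_passive_without_hand_angle_rejected(self):
        with pytest.raises(ScheduleError):
            TrialSpec(feedback_mode="clamp", perturbation_deg=0.0,
                      movement_mode="passive")

    def test_record_decomposition_and_update_identity(self, default_params):
        """perceived_hand = x_p_int + beta_p and update = K*prop_error,
        exactly, on every feedback trial of a mixed run."""
        sched = make_clamp_design(5, 40, 15.0, 5)
        for rec in run_schedule(sched, default_params):
            assert rec.perceived_hand == rec.x_p_int + rec.beta_p
            if rec.cursor_deg is not None:
                assert rec.update == default_params.K * rec.prop_error

    def test_frozen_learner_never_moves(self):
        p = dataclasses.replace(PremoParams(), K=0.0)
        recs = run_schedule(make_clamp_design(5, 50, 30.0, 5), p)
        assert all(r.hand_angle == 0.0 for r in recs)

    def test_no_feedback_update_switch(self):
        """With updating disabled on no-feedback trials the hand freezes
        during washout; with it enabled the hand drifts back."""
        sched = make_clamp_design(0, 60, 15.0, 20)
        moving = run_schedule(sched, PremoParams(update_without_feedback=True))
        frozen = run_schedule(sched, PremoParams(update_without_feedback=False))
        assert frozen[-1].hand_angle == frozen[-20].hand_angle
        assert abs(moving[-1].hand_angle) < abs(moving[-20].hand_angle)

    @given(
        k=st.floats(0.1, 0.5),
        w_p=st.floats(0.2, 1.0),
        clamp=st.floats(8.0, 60.0),
    )
    @settings(deadline=None, max_examples=30)
    def test_clamp_fixed_point_aligns_perception(self, k, w_p, clamp):
        """Noise-free clamp simulations converge to perceived hand ==
        perceived target."""
        p = dataclasses.replace(PremoParams(), K=k, w_p=w_p)
        recs = run_schedule(make_clamp_design(0, 2500, clamp, 0), p)
        assert recs[-1].prop_error == pytest.approx(0.0, abs=1e-6)
        assert recs[-1].perceived_hand == pytest.approx(
            recs[-1].perceived_target, abs=1e-6
        )
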