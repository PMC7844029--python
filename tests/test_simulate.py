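"""Synthetic behavior, spike generation, and frame rendering."""

import numpy as np
import pytest

from splinelnp.io import position_coverage
from splinelnp.simulate import (
    BehaviorSpec,
    FrameGeometry,
    GroundTruthCell,
    ProcessParams,
    gaussian_place_field,
    generate_ln_spikes,
    simulate_eye_frames,
    simulate_open_field_behavior,
    simulate_vr_behavior,
)
from splinelnp.tuning import raw_tuning_curve


class TestOpenFieldBehavior:
    def test_deterministic_given_seed(self):
        spec = BehaviorSpec(session_length=60.0, random_seed=5)
        a = simulate_open_field_behavior(spec)
        b = simulate_open_field_behavior(
            BehaviorSpec(session_length=60.0, random_seed=5))
        for key in a.channels:
            np.testing.assert_array_equal(a.channels[key], b.channels[key])

    def test_zero_process_sd_gives_constant_pitch(self):
        spec = BehaviorSpec(session_length=60.0, random_seed=0,
                            pitch=ProcessParams(11.5, 0.0, 2.0))
        s = simulate_open_field_behavior(spec)
        np.testing.assert_allclose(s.channels["H_p"], 11.5)
        np.testing.assert_allclose(s.channels["dH_p"], 0.0)

    def test_pitch_median_matches_published_envelope(self):
        """20-min default session: pitch median within 11.5 +/- 3 sem."""
        s = simulate_open_field_behavior(
            BehaviorSpec(session_length=1200.0, random_seed=11))
        assert abs(np.median(s.channels["H_p"]) - 11.5) <= 3 * 4.1

    def test_position_inside_arena_and_covered(self):
        s = simulate_open_field_behavior(
            BehaviorSpec(session_length=1200.0, random_seed=2))
        assert s.channels["B_x"].min() >= 0
        assert s.channels["B_x"].max() <= 50.0
        assert position_coverage(s) >= 0.70

    def test_session_too_short_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            BehaviorSpec(session_length=30.0)

    def test_nonpositive_arena_rejected(self):
        spec = BehaviorSpec(session_length=60.0,
                            arena={"open_field": (0.0, 50.0)})
        with pytest.raises(ValueError, match="positive"):
            simulate_open_field_behavior(spec)


class TestVrBehavior:
    def test_position_wraps_at_track_length(self):
        s = simulate_vr_behavior(
            BehaviorSpec(session_length=120.0, random_seed=3,
                         arena={"vr_track": {"length": 400.0}}))
        pos = s.channels["B"]
        assert pos.min() >= 0.0 and pos.max() < 400.0
        # displacement equals speed * dt except at wrap points
        d = np.diff(pos)
        wrap = d < -300
        np.testing.assert_allclose(
            d[~wrap], (s.channels["B_s"][:-1] * 0.02)[~wrap], atol=1e-9)
        np.testing.assert_allclose(
            d[wrap] + 400.0, (s.channels["B_s"][:-1] * 0.02)[wrap],
            atol=1e-9)

    def test_zero_speed_spec_freezes_position(self):
        s = simulate_vr_behavior(
            BehaviorSpec(session_length=60.0, random_seed=1,
                         arena={"vr_track": {"length": 400.0}},
                         vr_speed=ProcessParams(0.0, 0.0, 1.0)))
        assert np.ptp(s.channels["B"]) == 0.0
        np.testing.assert_allclose(s.channels["B_s"], 0.0)

    def test_eye_median_matches_published_envelope(self):
        """Across-session mean of the horizontal eye-position median
        falls within -0.11 +/- 3 x 0.032 % eye width."""
        medians = [
            np.median(simulate_vr_behavior(
                BehaviorSpec(session_length=1200.0, random_seed=seed,
                             arena={"vr_track": {"length": 400.0}})
            ).channels["E_h"])
            for seed in range(4)
        ]
        assert abs(np.mean(medians) - (-0.11)) <= 3 * 0.032

    def test_eye_velocity_heavy_tailed(self):
        s = simulate_vr_behavior(
            BehaviorSpec(session_length=600.0, random_seed=9,
                         arena={"vr_track": {"length": 400.0}}))
        v = s.channels["dE_h"]
        q75, q99 = np.percentile(v, [75, 99])
        assert q99 / q75 > 3.0  # far outside a Gaussian's 99/75 ratio


class TestLnSpikes:
    def test_constant_rate_poisson_mean(self, open_field_session):
        cell = GroundTruthCell(bias=np.log(0.1), tuning={})
        spikes = generate_ln_spikes(cell, open_field_session, seed=1)
        n = open_field_session.n_samples
        se = np.sqrt(0.1 / n)
        assert abs(spikes.counts.mean() - 0.1) < 3 * se

    def test_place_field_raw_curve_peaks_at_center(self):
        s = simulate_open_field_behavior(
            BehaviorSpec(session_length=1200.0, random_seed=21))
        cell = GroundTruthCell(
            bias=np.log(0.2),
            tuning={"B": gaussian_place_field((25.0, 25.0), 8.0, 2.0)})
        spikes = generate_ln_spikes(cell, s, seed=2)
        curve = raw_tuning_curve(s.channels["B_x"], spikes.cell(0), "B_x",
                                 value_range=(0, 50))
        peak = curve.bin_centers[np.nanargmax(curve.rates)]
        assert abs(peak - 25.0) < 5.0

    def test_same_seed_identical_spiketrain(self, open_field_session):
        cell = GroundTruthCell(bias=np.log(0.2), tuning={})
        a = generate_ln_spikes(cell, open_field_session, seed=9)
        b = generate_ln_spikes(cell, open_field_session, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_rate_overflow_rejected(self, open_field_session):
        cell = GroundTruthCell(bias=25.0, tuning={})
        with pytest.raises(ValueError, match="20"):
            generate_ln_spikes(cell, open_field_session, seed=0)

    def test_cell_json_round_trip(self):
        from splinelnp.simulate import linear_tuning

        cell = GroundTruthCell(
            bias=np.log(0.15),
            tuning={"B": gaussian_place_field((20.0, 30.0), 8.0, 1.6),
                    "H_p": linear_tuning(0.03, center=11.5)},
            name="c1")
        back = GroundTruthCell.from_json(cell.to_json())
        xy = np.array([[20.0, 30.0], [5.0, 5.0]])
        np.testing.assert_allclose(back.tuning["B"](xy),
                                   cell.tuning["B"](xy))
        assert back.encoded == cell.encoded
        assert back.bias == cell.bias

    def test_hand_written_tuning_not_serializable(self):
        cell = GroundTruthCell(bias=0.0,
                               tuning={"H_p": lambda x: 0.0 * x})
        with pytest.raises(ValueError, match="parametric"):
            cell.to_json()

    def test_missing_encoded_variable_raises(self, open_field_session):
        cell = GroundTruthCell(bias=0.0,
                               tuning={"E_h": lambda x: 0.0 * x})
        with pytest.raises(KeyError, match="E_h"):
            generate_ln_spikes(cell, open_field_session, seed=0)


class TestEyeFrames:
    def test_static_trace_gives_identical_frames(self):
        frames, _ = simulate_eye_frames(np.tile([80.0, 60.0], (5, 1)))
        for f in frames[1:]:
            np.testing.assert_array_equal(f, frames[0])

    def test_out_of_bounds_center_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            simulate_eye_frames(np.array([[500.0, 60.0]]))

    def test_undetectable_pupil_radius_rejected(self):
        with pytest.raises(ValueError, match="window"):
            FrameGeometry(pupil_radius=2.0)
        with pytest.raises(ValueError, match="window"):
            FrameGeometry(pupil_radius=40.0)
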