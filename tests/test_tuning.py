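"""Tuning curves: marginalized model curves, raw curves, stability,
shape and velocity-subtype classification, variable contributions."""

import numpy as np
import pytest

from splinelnp.model import crossvalidate, fit, make_folds
from splinelnp.simulate import (
    BehaviorSpec,
    GroundTruthCell,
    gaussian_bump,
    generate_ln_spikes,
    linear_tuning,
    simulate_open_field_behavior,
)
from splinelnp.splines import VariableConfig, assemble_design, knots_from_data
from splinelnp.tuning import (
    TuningCurve,
    classify_shape,
    classify_velocity_subtype,
    model_tuning_curve,
    raw_tuning_curve,
    tuning_stability,
    variable_contribution,
)


class TestModelTuningCurve:
    def test_zero_weights_give_flat_mean_rate(self, pitch_design_and_cell):
        _, design, _, spikes = pitch_design_and_cell
        counts = spikes.cell(0)[design.retained]
        f = fit(design, counts, ["H_p"])
        f.weights["H_p"][:] = 0.0
        f.b0 = np.log(counts.mean())
        curve = model_tuning_curve(design, f, "H_p")
        np.testing.assert_allclose(
            curve.rates, counts.mean() / design.dt, rtol=1e-9)

    def test_single_variable_gamma_is_exp_b0(self, pitch_design_and_cell):
        """With one fitted variable the scaling factor is the empty
        product: curve = exp(Y w) exp(b0) / dt exactly."""
        _, design, _, spikes = pitch_design_and_cell
        counts = spikes.cell(0)[design.retained]
        f = fit(design, counts, ["H_p"])
        curve = model_tuning_curve(design, f, "H_p")
        from splinelnp.splines import design_block

        cfg = design.configs["H_p"]
        Y = design_block(np.clip(curve.bin_centers, cfg.knots[0],
                                 cfg.knots[-1]), cfg)
        expected = np.exp(Y @ f.weights["H_p"]) * np.exp(f.b0) / design.dt
        np.testing.assert_allclose(curve.rates, expected, rtol=1e-12)

    def test_bump_cell_peak_location(self, pitch_design_and_cell):
        _, design, cell, spikes = pitch_design_and_cell
        counts = spikes.cell(0)[design.retained]
        f = fit(design, counts, ["H_p"])
        curve = model_tuning_curve(design, f, "H_p")
        peak = curve.bin_centers[np.argmax(curve.rates)]
        assert abs(peak - 20.0) < 5.0

    def test_occupancy_weighted_mean_matches_mean_rate(
            self, pitch_design_and_cell):
        """The occupancy-weighted average of the model-derived curve
        recovers the cell's mean rate within 5%."""
        session, design, _, spikes = pitch_design_and_cell
        counts = spikes.cell(0)[design.retained]
        f = fit(design, counts, ["H_p"])
        vals = session.channels["H_p"][design.retained]
        cfg = design.configs["H_p"]
        edges = np.linspace(cfg.knots[0], cfg.knots[-1], 51)
        centers = (edges[:-1] + edges[1:]) / 2
        occ, _ = np.histogram(vals, bins=edges)
        curve = model_tuning_curve(design, f, "H_p", grid=centers)
        weighted = (curve.rates * occ).sum() / occ.sum()
        mean_rate = counts.mean() / design.dt
        assert abs(weighted - mean_rate) / mean_rate < 0.05

    def test_absent_variable_raises(self, pitch_design_and_cell):
        _, design, _, spikes = pitch_design_and_cell
        f = fit(design, spikes.cell(0)[design.retained], ["H_p"])
        with pytest.raises(KeyError):
            model_tuning_curve(design, f, "B_s")


class TestRawTuningCurve:
    def test_rate_is_spikes_over_occupancy(self):
        values = np.array([0.5] * 25 + [1.5] * 25)
        counts = np.array([2] + [0] * 24 + [1] + [0] * 24)
        curve = raw_tuning_curve(values, counts, "x", n_bins=2,
                                 value_range=(0, 2), smooth=False)
        np.testing.assert_allclose(curve.occupancy, [0.5, 0.5])
        np.testing.assert_allclose(curve.rates, [4.0, 2.0])

    def test_zero_occupancy_bins_are_nan(self):
        values = np.array([0.5] * 50)
        counts = np.ones(50, dtype=int)
        curve = raw_tuning_curve(values, counts, "x", n_bins=4,
                                 value_range=(0, 4), smooth=False)
        assert np.isnan(curve.rates[1:]).all()

    def test_homogeneous_poisson_flat(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, 50_000)
        counts = rng.poisson(0.2, 50_000)
        curve = raw_tuning_curve(values, counts, "x", n_bins=20)
        assert np.nanstd(curve.rates) / np.nanmean(curve.rates) < 0.1

    def test_agrees_with_model_curve_on_simulated_cell(
            self, pitch_design_and_cell):
        session, design, cell, spikes = pitch_design_and_cell
        counts_r = spikes.cell(0)[design.retained]
        vals = session.channels["H_p"][design.retained]
        f = fit(design, counts_r, ["H_p"])
        lo, hi = np.percentile(vals, [2, 98])
        raw = raw_tuning_curve(vals, counts_r, "H_p", value_range=(lo, hi))
        model = model_tuning_curve(design, f, "H_p", grid=raw.bin_centers)
        ok = np.isfinite(raw.rates)
        r = np.corrcoef(raw.rates[ok], model.rates[ok])[0, 1]
        assert r > 0.9


class TestStability:
    def _halved_designs(self, seed=61, flip=False):
        session = simulate_open_field_behavior(
            BehaviorSpec(session_length=1000.0, random_seed=seed))
        cfg = lambda s: VariableConfig(
            "H_p", knots_from_data(s.channels["H_p"], n_bins=8))
        half = session.n_samples // 2
        from splinelnp.session import BehaviorSession

        first = BehaviorSession(session.time[:half],
                                {"H_p": session.channels["H_p"][:half]})
        second = BehaviorSession(session.time[half:],
                                 {"H_p": session.channels["H_p"][half:]})
        cell1 = GroundTruthCell(np.log(0.2),
                                {"H_p": gaussian_bump(20.0, 12.0, 1.2)})
        cell2 = (GroundTruthCell(np.log(0.2),
                                 {"H_p": gaussian_bump(20.0, 12.0, -1.2)})
                 if flip else cell1)
        c1 = generate_ln_spikes(cell1, first, seed=1).cell(0)
        c2 = generate_ln_spikes(cell2, second, seed=2).cell(0)
        d1 = assemble_design(first, [cfg(first)])
        d2 = assemble_design(second, [cfg(second)])
        return d1, c1[d1.retained], d2, c2[d2.retained]

    def test_stationary_cell_high_stability(self):
        d1, c1, d2, c2 = self._halved_designs()
        r = tuning_stability(d1, c1, d2, c2, ["H_p"], "H_p")
        assert r > 0.9

    def test_sign_flipped_halves_anticorrelated(self):
        d1, c1, d2, c2 = self._halved_designs(flip=True)
        r = tuning_stability(d1, c1, d2, c2, ["H_p"], "H_p")
        assert r < 0

    def test_identical_halves_perfect(self):
        d1, c1, _, _ = self._halved_designs()
        r = tuning_stability(d1, c1, d1, c1, ["H_p"], "H_p")
        assert r == pytest.approx(1.0, abs=1e-9)


class TestShapeClassification:
    def test_exact_line_is_degree_one(self):
        x = np.linspace(-50, 50, 200)
        res = classify_shape(TuningCurve("E_h", x, 2 + 0.05 * x))
        assert res.degree == 1
        assert res.fraction_explained == pytest.approx(1.0, abs=1e-9)

    def test_noisy_quadratic_is_degree_two(self):
        rng = np.random.default_rng(4)
        x = np.linspace(-1, 1, 200)
        y = x**2 + 0.01 * rng.standard_normal(200)
        res = classify_shape(TuningCurve("E_h", x, y))
        assert res.degree == 2

    def test_white_noise_usually_unclassified(self):
        rng = np.random.default_rng(5)
        x = np.linspace(-1, 1, 200)
        unclassified = sum(
            classify_shape(TuningCurve("E_h", x,
                                       rng.standard_normal(200))).degree
            is None
            for _ in range(100)
        )
        assert unclassified >= 90

    def test_scale_and_offset_invariant(self):
        rng = np.random.default_rng(6)
        x = np.linspace(-1, 1, 200)
        y = x**3 - 0.2 * x + 0.02 * rng.standard_normal(200)
        a = classify_shape(TuningCurve("E_h", x, y))
        b = classify_shape(TuningCurve("E_h", x, 40.0 * y + 7.0))
        assert a.degree == b.degree
        assert a.fraction_explained == pytest.approx(b.fraction_explained,
                                                     abs=1e-9)

    def test_flat_curve_reported_undefined(self):
        x = np.linspace(-1, 1, 200)
        res = classify_shape(TuningCurve("E_h", x, np.full(200, 3.0)))
        assert res.degree is None
        assert "flat" in res.details["reason"]

    def test_insufficient_coverage_unclassified(self):
        x = np.linspace(-50, 50, 200)
        res = classify_shape(TuningCurve("H_p", x, 2 + 0.05 * x),
                             coverage=0.3)
        assert res.degree is None


class TestVelocitySubtype:
    def test_v_shape_is_symmetric_positive_with_valley_at_zero(self):
        x = np.linspace(-100, 100, 200)
        res = classify_velocity_subtype(TuningCurve("dH_a", x,
                                                    2 + 0.05 * np.abs(x)))
        assert res.subtype == "NL_s-pos"
        assert abs(res.preferred_position) < 5.0

    def test_inverse_v_is_symmetric_negative(self):
        x = np.linspace(-100, 100, 200)
        res = classify_velocity_subtype(TuningCurve("dH_a", x,
                                                    8 - 0.05 * np.abs(x)))
        assert res.subtype == "NL_s-neg"

    def test_rectified_ramp_is_asymmetric_positive(self):
        x = np.linspace(-100, 100, 200)
        res = classify_velocity_subtype(
            TuningCurve("dH_a", x, 2 + 0.04 * np.maximum(0, x)))
        assert res.subtype == "NL_as"
        assert res.direction == "positive"

    def test_pure_line_is_linear_asymmetric(self):
        x = np.linspace(-100, 100, 200)
        res = classify_velocity_subtype(TuningCurve("dH_a", x, 3 + 0.02 * x))
        assert res.subtype == "L_as"
        assert res.direction == "positive"

    def test_curve_without_zero_rejected(self):
        x = np.linspace(10, 100, 50)
        with pytest.raises(ValueError, match="zero"):
            classify_velocity_subtype(TuningCurve("dH_a", x, x))


@pytest.fixture(scope="module")
def conjunctive_setup():
    session = simulate_open_field_behavior(
        BehaviorSpec(session_length=900.0, random_seed=71))
    cfgs = [
        VariableConfig("H_p", knots_from_data(
            session.channels["H_p"], n_bins=8)),
        VariableConfig("B_s", knots_from_data(
            session.channels["B_s"], bin_width=5.0)),
    ]
    design = assemble_design(session, cfgs)
    cell = GroundTruthCell(
        bias=np.log(0.15),
        tuning={"H_p": gaussian_bump(20.0, 12.0, 1.3),
                "B_s": linear_tuning(0.02, center=8.0)})
    counts = generate_ln_spikes(cell, session, seed=3).cell(0)
    return design, counts[design.retained]


class TestVariableContribution:

    def test_dominant_variable_contributes_most(self, conjunctive_setup):
        design, counts = conjunctive_setup
        c_hp = variable_contribution(design, counts, ["H_p", "B_s"], "H_p")
        c_bs = variable_contribution(design, counts, ["H_p", "B_s"], "B_s")
        assert c_hp > c_bs
        assert c_hp > 0

    def test_correlation_variant_agrees_in_sign(self, conjunctive_setup):
        """The correlation-based contribution ranks the dominant
        variable above the weak one, like the LLI-based measure."""
        design, counts = conjunctive_setup
        c_hp = variable_contribution(design, counts, ["H_p", "B_s"], "H_p",
                                     method="correlation")
        c_bs = variable_contribution(design, counts, ["H_p", "B_s"], "B_s",
                                     method="correlation")
        assert c_hp > c_bs
        assert c_hp > 0

    def test_single_variable_model_rejected(self, conjunctive_setup):
        design, counts = conjunctive_setup
        with pytest.raises(ValueError, match="at least"):
            variable_contribution(design, counts, ["H_p"], "H_p")

    def test_zero_weight_variable_contributes_nothing(self):
        session = simulate_open_field_behavior(
            BehaviorSpec(session_length=900.0, random_seed=72))
        cfgs = [
            VariableConfig("H_p", knots_from_data(
                session.channels["H_p"], n_bins=8)),
            VariableConfig("dH_a", knots_from_data(
                session.channels["dH_a"], n_bins=8)),
        ]
        design = assemble_design(session, cfgs)
        cell = GroundTruthCell(
            bias=np.log(0.15),
            tuning={"H_p": gaussian_bump(20.0, 12.0, 1.3)})
        counts = generate_ln_spikes(cell, session, seed=4).cell(0)
        counts = counts[design.retained]
        folds = make_folds(design.n_retained, dt=design.dt)
        delta = variable_contribution(design, counts, ["H_p", "dH_a"],
                                      "dH_a", folds=folds)
        full = crossvalidate(design, counts, ["H_p", "dH_a"], folds=folds)
        se = full.fold_lli_per_spike.std(ddof=1) / np.sqrt(10)
        assert abs(delta) < 2 * se + 1e-6
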