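"""Shuffle-based controls: permutation nulls, regenerated spiketrains,
and the two shuffle significance methods."""

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
from splinelnp.validation import (
    ShuffleConfig,
    estimate_false_detection,
    modulation_score,
    regenerate_without_variables,
    shuffle_significance,
    symmetric_shuffle_significance,
    _shuffled_session,
)


@pytest.fixture(scope="module")
def tuned_setup():
    session = simulate_open_field_behavior(
        BehaviorSpec(session_length=600.0, random_seed=51))
    cfgs = [
        VariableConfig("H_p", knots_from_data(
            session.channels["H_p"], n_bins=8)),
        VariableConfig("dH_a", knots_from_data(
            session.channels["dH_a"], n_bins=8)),
    ]
    design = assemble_design(session, cfgs)
    return session, design


class TestShuffledSession:
    def test_permutation_preserves_marginal_exactly(self, tuned_setup):
        session, _ = tuned_setup
        rng = np.random.default_rng(0)
        shuffled = _shuffled_session(session, "H_p", rng)
        np.testing.assert_array_equal(
            np.sort(shuffled.channels["H_p"]),
            np.sort(session.channels["H_p"]))
        # other channels untouched
        np.testing.assert_array_equal(shuffled.channels["H_r"],
                                      session.channels["H_r"])

    def test_permutation_destroys_autocorrelation(self, tuned_setup):
        session, _ = tuned_setup
        rng = np.random.default_rng(1)
        shuffled = _shuffled_session(session, "H_p", rng)

        def lag1(x):
            return np.corrcoef(x[:-1], x[1:])[0, 1]

        assert lag1(session.channels["H_p"]) > 0.9
        assert abs(lag1(shuffled.channels["H_p"])) < 0.05


class TestRegeneration:
    def test_drop_nothing_preserves_expected_rate(self, tuned_setup):
        session, design = tuned_setup
        cell = GroundTruthCell(np.log(0.2),
                               {"H_p": gaussian_bump(20.0, 12.0, 1.2)})
        counts = generate_ln_spikes(cell, session, seed=2).cell(0)
        f = fit(design, counts[design.retained], ["H_p"])
        regen = regenerate_without_variables(f, design, set(), seed=3)
        # same generative model: mean counts agree within Poisson error
        expected = counts[design.retained].mean()
        se = np.sqrt(expected / design.n_retained)
        assert abs(regen.mean() - expected) < 4 * se

    def test_drop_dominant_variable_reduces_heldout_lli(self, tuned_setup):
        session, design = tuned_setup
        cell = GroundTruthCell(np.log(0.2),
                               {"H_p": gaussian_bump(20.0, 12.0, 1.2)})
        counts = generate_ln_spikes(cell, session, seed=4).cell(0)
        counts = counts[design.retained]
        folds = make_folds(design.n_retained, dt=design.dt)
        full = crossvalidate(design, counts, ["H_p"], folds=folds)
        f = fit(design, counts, ["H_p"])
        regen = regenerate_without_variables(f, design, {"H_p"}, seed=5)
        ablated = crossvalidate(design, regen, ["H_p"], folds=folds)
        assert ablated.fold_lli.mean() < full.fold_lli.mean()

    def test_cannot_drop_unfitted_variable(self, tuned_setup):
        _, design = tuned_setup
        f = fit(design, np.zeros(design.n_retained, dtype=int) + 1, ["H_p"])
        with pytest.raises(ValueError, match="not in the fit"):
            regenerate_without_variables(f, design, {"E_h"}, seed=0)


class TestShuffleSignificance:
    def test_linear_cell_significant_within_and_pooled(self, tuned_setup):
        session, design = tuned_setup
        cell = GroundTruthCell(np.log(0.3),
                               {"H_p": linear_tuning(0.04, center=11.5)})
        counts = generate_ln_spikes(cell, session, seed=6).cell(0)
        values = session.channels["H_p"]
        config = ShuffleConfig(n_shuffles=500)
        within = shuffle_significance(values, counts, config, seed=7)
        assert within.significant
        pooled_cfg = ShuffleConfig(n_shuffles=500, mode="pooled")
        pooled = shuffle_significance(values, counts, pooled_cfg,
                                      pooled_null=within.details["own_null"],
                                      seed=8)
        assert pooled.significant

    def test_v_shaped_cell_needs_symmetric_rule(self, tuned_setup):
        """V-shaped tuning defeats the plain linear score but is caught
        by the split-sided symmetric rule."""
        session, _ = tuned_setup
        values = session.channels["dH_a"]
        rng = np.random.default_rng(9)
        rate = 0.05 * np.exp(1.4 * np.minimum(np.abs(values), 120.0) / 120.0)
        counts = rng.poisson(rate)
        config = ShuffleConfig(n_shuffles=300)
        plain = shuffle_significance(values, counts, config, seed=10)
        sym = symmetric_shuffle_significance(values, counts, config,
                                             seed=11)
        assert not plain.significant
        assert sym.significant
        assert sym.symmetric_class == "V"

    def test_constant_rate_not_significant(self, tuned_setup):
        session, _ = tuned_setup
        counts = np.zeros(session.n_samples, dtype=int)
        res = shuffle_significance(session.channels["H_p"], counts,
                                   ShuffleConfig(), seed=12)
        assert not res.significant and np.isnan(res.score)

    def test_circular_shift_preserves_autocorrelation(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(np.exp(np.sin(np.arange(5000) / 50.0)))

        def autocorr(x, lag):
            return np.corrcoef(x[:-lag], x[lag:])[0, 1]

        shifted = np.roll(counts, 1717)
        # away from the single wrap seam the lag structure is identical
        assert autocorr(shifted, 25) == pytest.approx(
            autocorr(counts, 25), abs=0.02)

    def test_min_shift_enforced(self):
        with pytest.raises(ValueError, match="20 s"):
            ShuffleConfig(min_shift_s=5.0)


class TestFalseDetection:
    def test_zero_spike_cell_never_selected_never_errors(self, tuned_setup):
        session, _ = tuned_setup
        from splinelnp.session import SpikeCountSeries

        spikes = SpikeCountSeries(
            np.zeros((1, session.n_samples), dtype=int))
        cfgs = [
            VariableConfig("H_p", knots_from_data(
                session.channels["H_p"], n_bins=8)),
            VariableConfig("dH_a", knots_from_data(
                session.channels["dH_a"], n_bins=8)),
        ]
        out = estimate_false_detection(session, spikes, cfgs, "H_p",
                                       n_reps=3, seed=1)
        assert out["n_detected"] == 0
        assert out["n_failures"] == 0

    def test_unshuffled_strong_variable_detected(self, tuned_setup):
        """Positive control: selection finds a strongly tuned variable
        on intact (unshuffled) data."""
        session, design = tuned_setup
        from splinelnp.model import forward_select

        cell = GroundTruthCell(np.log(0.25),
                               {"H_p": gaussian_bump(20.0, 12.0, 1.4)})
        counts = generate_ln_spikes(cell, session, seed=14).cell(0)
        res = forward_select(design, counts[design.retained])
        assert "H_p" in res.encoded
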