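"""Shared fixtures: small synthetic sessions and designs.

Everything is generated at test time from seeded generators; session
lengths are kept short except where an operation genuinely needs more
data (model fits), so the default run stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from splinelnp.simulate import (
    BehaviorSpec,
    GroundTruthCell,
    gaussian_bump,
    generate_ln_spikes,
    simulate_open_field_behavior,
    simulate_vr_behavior,
)
from splinelnp.splines import (
    VariableConfig,
    assemble_design,
    knots_from_data,
)
from splinelnp.session import BehaviorSession


@pytest.fixture(scope="session")
def open_field_session():
    """Five-minute open-field session, shared by read-only tests."""
    return simulate_open_field_behavior(
        BehaviorSpec(session_length=300.0, random_seed=42)
    )


@pytest.fixture(scope="session")
def vr_session():
    return simulate_vr_behavior(
        BehaviorSpec(session_length=300.0, random_seed=43,
                     arena={"vr_track": {"length": 400.0}})
    )


@pytest.fixture(scope="session")
def pitch_design_and_cell():
    """1-D pitch-only design with a bump-tuned ground-truth cell.

    A 1000-s session gives ~50k retained bins — enough for tight
    parameter-recovery checks while staying fast (single small block).
    """
    session = simulate_open_field_behavior(
        BehaviorSpec(session_length=1000.0, random_seed=7)
    )
    config = VariableConfig(
        "H_p", knots_from_data(session.channels["H_p"], n_bins=8),
        percentile_window=(2.5, 97.5),
    )
    design = assemble_design(session, [config])
    cell = GroundTruthCell(
        bias=np.log(0.15),
        tuning={"H_p": gaussian_bump(20.0, 12.0, 1.2)},
        name="pitch_cell",
    )
    spikes = generate_ln_spikes(cell, session, seed=17)
    return session, design, cell, spikes


def constant_session(n: int, dt: float = 0.02, **channels) -> BehaviorSession:
    """Helper for degenerate-input tests."""
    time = np.arange(n) * dt
    return BehaviorSession(time, {k: np.asarray(v, dtype=float)
                                  for k, v in channels.items()})
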