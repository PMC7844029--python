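"""Control analyses for the encoding-model pipeline.

Three checks of the selection machinery: (1) the false-detection rate
of a variable, estimated by permuting that variable's values over time
(destroying its autocorrelation and any relation to spiking) and
re-running the full forward search; (2) ablated-spiketrain
regeneration, where spikes are redrawn from a fitted model with a
variable block deleted, to confirm the dropped variables are not
re-selected above the false-detection rate; and (3) classical
shuffle-based significance (within-cell or pooled): a Pearson
modulation score against a null of scores from circularly time-shifted
spiketrains (shift > 20 s, 500 shuffles), including the symmetric-
velocity variant that tests the two sides of zero velocity separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import forward_select
from .session import BehaviorSession, SpikeCountSeries
from .splines import DesignMatrix, assemble_design

__all__ = [
    "ShuffleConfig",
    "estimate_false_detection",
    "regenerate_without_variables",
    "modulation_score",
    "shuffle_significance",
    "ShuffleVerdict",
]


@dataclass
class ShuffleConfig:
    n_shuffles: int = 500
    min_shift_s: float = 20.0
    two_sided_percentiles: tuple[float, float] = (2.5, 97.5)
    one_sided_percentiles: tuple[float, float] = (5.0, 95.0)
    mode: str = "within"  # "within" | "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_shift_s < 20.0:
            raise ValueError("minimum temporal shift is 20 s")
        for p in (*self.two_sided_percentiles, *self.one_sided_percentiles):
            if not 0 < p < 100:
                raise ValueError("percentile thresholds must lie in (0, 100)")
        if self.mode not in ("within", "pooled"):
            raise ValueError("mode must be 'within' or 'pooled'")


def _shuffled_session(
    session: BehaviorSession, variable: str, rng: np.random.Generator
) -> BehaviorSession:
    channels = {k: v.copy() for k, v in session.channels.items()}
    if variable == "B" and "B" not in channels:
        perm = rng.permutation(session.n_samples)
        channels["B_x"] = channels["B_x"][perm]
        channels["B_y"] = channels["B_y"][perm]
    else:
        channels[variable] = rng.permutation(channels[variable])
    return BehaviorSession(session.time, channels,
                           {k: v.copy() for k, v in session.valid.items()},
                           dict(session.meta))


def estimate_false_detection(
    session: BehaviorSession,
    spikes: SpikeCountSeries,
    configs: list,
    variable: str,
    n_reps: int = 100,
    seed: int = 0,
    candidates: list[str] | None = None,
) -> dict:
    """Empirical false-detection rate of one variable.

    Per repetition, one cell's session has the target variable's values
    permuted across time; the full forward selection is re-run and a
    detection recorded when the shuffled variable lands in the encoded
    set.  Cells are cycled round-robin over repetitions.  Returns the
    rate with a 95% normal-approximation binomial CI; fit failures are
    counted, not raised.
    """
    rng = np.random.default_rng(seed)
    detected = 0
    failures = 0
    completed = 0
    for rep in range(n_reps):
        cell = rep % spikes.n_cells
        shuffled = _shuffled_session(session, variable, rng)
        try:
            design = assemble_design(shuffled, configs)
            counts = spikes.cell(cell)[design.retained]
            result = forward_select(design, counts, candidates=candidates)
        except Exception:
            failures += 1
            continue
        completed += 1
        if variable in result.encoded:
            detected += 1
    rate = detected / completed if completed else np.nan
    se = np.sqrt(rate * (1 - rate) / completed) if completed else np.nan
    return {
        "variable": variable,
        "rate": rate,
        "ci95": (max(0.0, rate - 1.96 * se), min(1.0, rate + 1.96 * se))
        if completed else (np.nan, np.nan),
        "n_detected": detected,
        "n_completed": completed,
        "n_failures": failures,
    }


def regenerate_without_variables(
    fit_result,
    design: DesignMatrix,
    drop: set[str] | list[str],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Redraw Poisson spikes from a fitted model with variables deleted.

    The rate is rebuilt from the fit with the dropped design blocks and
    weights removed (dropping everything leaves the bias-only model) and
    new counts are drawn for the retained bins.
    """
    drop = set(drop)
    unknown = drop - set(fit_result.variables)
    if unknown:
        raise ValueError(f"cannot drop variables not in the fit: {unknown}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    eta = np.full(design.n_retained, fit_result.b0)
    for v in fit_result.variables:
        if v in drop:
            continue
        eta += design.blocks[v] @ fit_result.weights[v]
    return rng.poisson(np.exp(eta))


def modulation_score(values: np.ndarray, counts: np.ndarray) -> float:
    """Pearson correlation of instantaneous behavior and firing rate."""
    if np.std(counts) == 0 or np.std(values) == 0:
        return np.nan
    return float(np.corrcoef(values, counts)[0, 1])


def _all_shift_correlations(values: np.ndarray, counts: np.ndarray
                            ) -> np.ndarray:
    """corr(values, roll(counts, s)) for every circular shift s, via FFT."""
    n = values.size
    v = values - values.mean()
    c = counts - counts.mean()
    sv, sc = v.std(), c.std()
    if sv == 0 or sc == 0:
        return np.full(n, np.nan)
    # irfft(V * conj(C))[s] = sum_t v[t] c[(t - s) mod n] = v . roll(c, s)
    dots = np.fft.irfft(np.fft.rfft(v) * np.conj(np.fft.rfft(c)), n)
    return dots / (n * sv * sc)


@dataclass
class ShuffleVerdict:
    variable: str
    score: float
    null_low: float
    null_high: float
    significant: bool
    symmetric_class: str | None = None  # "V" | "inverse-V" | None
    details: dict = field(default_factory=dict)


def shuffle_null_scores(
    values: np.ndarray,
    counts: np.ndarray,
    config: ShuffleConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null modulation scores from random circular shifts (> 20 s)."""
    n = values.size
    min_shift = int(round(config.min_shift_s / 0.02))
    if n <= 2 * min_shift:
        raise ValueError("session must be longer than twice the minimum shift")
    all_corr = _all_shift_correlations(values, counts)
    shifts = rng.integers(min_shift, n - min_shift, size=config.n_shuffles)
    return all_corr[shifts]


def shuffle_significance(
    values: np.ndarray,
    counts: np.ndarray,
    config: ShuffleConfig | None = None,
    pooled_null: np.ndarray | None = None,
    variable: str = "",
    seed: int | np.random.Generator | None = None,
) -> ShuffleVerdict:
    """Two-sided percentile test of the linear modulation score.

    Within-cell mode compares the cell's score with its own shifted-null
    percentiles; pooled mode uses a caller-supplied null pooled over
    cells.  A constant firing rate gives an undefined score, reported as
    not significant.
    """
    config = config or ShuffleConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    score = modulation_score(values, counts)
    if np.isnan(score):
        return ShuffleVerdict(variable, np.nan, np.nan, np.nan, False,
                              details={"reason": "constant rate"})
    null = shuffle_null_scores(values, counts, config, rng)
    if config.mode == "pooled":
        if pooled_null is None:
            raise ValueError("pooled mode needs a pooled null distribution")
        null_ref = pooled_null
    else:
        null_ref = null
    lo, hi = np.percentile(null_ref, config.two_sided_percentiles)
    return ShuffleVerdict(
        variable, score, float(lo), float(hi),
        significant=bool(score < lo or score > hi),
        details={"own_null": null},
    )


def symmetric_shuffle_significance(
    values: np.ndarray,
    counts: np.ndarray,
    config: ShuffleConfig | None = None,
    variable: str = "",
    seed: int | np.random.Generator | None = None,
) -> ShuffleVerdict:
    """Symmetric-velocity variant of the shuffle test.

    Correlations are computed separately for velocities below and above
    zero and each is compared with its shifted null at the 5th/95th
    percentiles.  V-shaped tuning: below-zero correlation under the 5th
    percentile and above-zero correlation over the 95th; inverse-V: the
    mirrored pattern.
    """
    config = config or ShuffleConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed if seed is None else seed))
    below = values < 0
    above = values > 0
    if below.sum() < 2 or above.sum() < 2:
        raise ValueError("need samples on both sides of zero velocity")
    n = values.size
    min_shift = int(round(config.min_shift_s / 0.02))
    shifts = rng.integers(min_shift, n - min_shift, size=config.n_shuffles)

    def side_stats(mask):
        obs = modulation_score(values[mask], counts[mask])
        null = np.array([
            modulation_score(values[mask], np.roll(counts, s)[mask])
            for s in shifts
        ])
        lo, hi = np.nanpercentile(null, config.one_sided_percentiles)
        return obs, lo, hi

    r_b, lo_b, hi_b = side_stats(below)
    r_a, lo_a, hi_a = side_stats(above)
    if np.isnan(r_b) or np.isnan(r_a):
        return ShuffleVerdict(variable, np.nan, np.nan, np.nan, False,
                              details={"reason": "constant rate"})
    v_shape = (r_b < lo_b) and (r_a > hi_a)
    inv_v = (r_b > hi_b) and (r_a < lo_a)
    return ShuffleVerdict(
        variable,
        score=float(r_a - r_b),
        null_low=float(lo_b),
        null_high=float(hi_a),
        significant=bool(v_shape or inv_v),
        symmetric_class="V" if v_shape else ("inverse-V" if inv_v else None),
        details={"r_below": r_b, "r_above": r_a},
    )
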