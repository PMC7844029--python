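"""Tuning curves: construction, stability, shape and subtype classification.

Model-derived tuning curves marginalize the fitted LN model over all
other encoded variables: for variable ``i`` evaluated on a fine grid of
M = 200 bins,

    C_i(m) = exp( Y_i(m) . w_i ) * gamma / dt,
    gamma  = exp(b0) * prod_{v != i}  mean_t exp( X_v(t) . w_v ),

so the curve is in spikes/s with the average contribution of the other
variables factored in.  Raw tuning curves are classical
spikes-over-occupancy histograms (20 bins, robust local-regression
smoothing over 7 bins).

Curve shape is classified by a greedy search over polynomials of degree
1-5 on the range-normalized curve; the first degree whose fraction of
error explained relative to a flat baseline reaches 0.9 is assigned.
Velocity curves are subtyped from the two line fits on either side of
zero velocity into linear-asymmetric (L_as), nonlinear-asymmetric
(NL_as) and nonlinear-symmetric (NL_s, V or inverse-V).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import LNModelFit, crossvalidate, make_folds, predict_log_mu
from .splines import DesignMatrix, VariableConfig, design_block

__all__ = [
    "TuningCurve",
    "ShapeClassification",
    "DISPLAY_RANGES",
    "model_tuning_curve",
    "raw_tuning_curve",
    "tuning_stability",
    "classify_shape",
    "classify_velocity_subtype",
    "variable_contribution",
]

M_MODEL = 200  # bins in a model-derived curve
M_RAW = 20  # bins in a raw curve

#: preset display bounds, intersected with the behavioral percentiles
DISPLAY_RANGES: dict[str, tuple[float, float]] = {
    "H_p": (-50.0, 50.0),
    "H_r": (-50.0, 50.0),
    "dH_a": (-100.0, 100.0),
    "E_h": (-3.0, 3.0),
    "E_v": (-2.0, 2.0),
    "dE_h": (-3.0, 3.0),
    "dE_v": (-2.0, 2.0),
}

#: coverage required before a shape is assigned
COVERAGE_HEAD = 0.5
COVERAGE_EYE = 0.8
FRACTION_THRESHOLD = 0.9
SLOPE_RATIO_SYMMETRIC = 0.5


@dataclass
class TuningCurve:
    variable: str
    bin_centers: np.ndarray
    rates: np.ndarray  # spikes/s
    sem: np.ndarray | None = None  # across model folds
    occupancy: np.ndarray | None = None  # seconds per bin (raw curves)

    def restrict(self, low: float, high: float) -> "TuningCurve":
        keep = (self.bin_centers >= low) & (self.bin_centers <= high)
        return TuningCurve(
            self.variable,
            self.bin_centers[keep],
            self.rates[keep],
            None if self.sem is None else self.sem[keep],
            None if self.occupancy is None else self.occupancy[keep],
        )


@dataclass
class ShapeClassification:
    variable: str
    degree: int | None  # 1..5, or None if unclassified
    fraction_explained: float
    coefficients: np.ndarray | None = None
    direction: str | None = None  # upward/downward, etc.
    subtype: str | None = None  # L_as | NL_as | NL_s-pos | NL_s-neg
    preferred_position: float | None = None
    slope_below: float | None = None
    slope_above: float | None = None
    details: dict = field(default_factory=dict)


def display_range(
    variable: str,
    values: np.ndarray,
    percentile_window: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float]:
    """Preset display bounds intersected with behavioral percentiles.

    Azimuth uses the full circle; variables with no preset bound fall
    back to the percentile range alone.
    """
    if variable == "H_a":
        return 0.0, 360.0
    lo_p, hi_p = np.percentile(values, list(percentile_window))
    preset = DISPLAY_RANGES.get(variable)
    if preset is None:
        return float(lo_p), float(hi_p)
    return float(max(lo_p, preset[0])), float(min(hi_p, preset[1]))


def _grid_block(config, grid: np.ndarray):
    if isinstance(config, VariableConfig):
        lo, hi = config.knots[0], config.knots[-1]
        if not config.circular:
            grid = np.clip(grid, lo, hi)
        return design_block(grid, config)
    raise ValueError("model-derived curves are defined per scalar variable")


def model_tuning_curve(
    design: DesignMatrix,
    fit_result: LNModelFit,
    variable: str,
    grid: np.ndarray | None = None,
    n_bins: int = M_MODEL,
    fold_fits: list[LNModelFit] | None = None,
    value_range: tuple[float, float] | None = None,
) -> TuningCurve:
    """Model-derived tuning curve for one encoded variable.

    With a single-variable fit gamma reduces to exp(b0).  If per-fold
    fits are supplied, the across-fold sem of the curve is attached.
    """
    if variable not in fit_result.variables:
        raise KeyError(f"{variable} not in the fitted variable set")
    config = design.configs[variable]
    if grid is None:
        if value_range is None:
            lo, hi = config.knots[0], config.knots[-1]
            if config.circular:
                hi = config.knots[0] + config.period
        else:
            lo, hi = value_range
        grid = np.linspace(lo, hi, n_bins)

    def curve_for(f: LNModelFit) -> np.ndarray:
        Y = _grid_block(config, grid)
        gamma = np.exp(f.b0)
        for v in f.variables:
            if v == variable:
                continue
            gamma *= float(
                np.mean(np.exp(design.blocks[v] @ f.weights[v]))
            )
        return np.exp(Y @ f.weights[variable]) * gamma / design.dt

    rates = curve_for(fit_result)
    sem = None
    if fold_fits:
        stack = np.vstack([curve_for(f) for f in fold_fits])
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return TuningCurve(variable, grid, rates, sem=sem)


def model_tuning_curve_with_folds(
    design: DesignMatrix,
    counts: np.ndarray,
    variables: list[str],
    variable: str,
    value_range: tuple[float, float] | None = None,
    n_bins: int = M_MODEL,
):
    """Convenience: cross-validated fit plus curve with fold-wise sem."""
    from .model import fit as fit_model

    folds = make_folds(design.n_retained, dt=design.dt)
    full = crossvalidate(design, counts, variables, folds=folds)
    all_rows = np.arange(design.n_retained)
    fold_fits = []
    for test_rows in folds:
        mask = np.ones(design.n_retained, dtype=bool)
        mask[test_rows] = False
        fold_fits.append(
            fit_model(design, counts, variables, rows=all_rows[mask],
                      x0=full.params())
        )
    curve = model_tuning_curve(
        design, full, variable, value_range=value_range, n_bins=n_bins,
        fold_fits=fold_fits,
    )
    return curve, full


def raw_tuning_curve(
    values: np.ndarray,
    counts: np.ndarray,
    variable: str,
    dt: float = 0.02,
    n_bins: int = M_RAW,
    value_range: tuple[float, float] | None = None,
    smooth: bool = True,
) -> TuningCurve:
    """Occupancy-normalized firing-rate curve (spikes / occupancy-seconds).

    Zero-occupancy bins are returned as NaN, never interpolated.  The
    curve is smoothed by robust locally weighted linear regression over
    a 7-bin span.
    """
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts)
    if value_range is None:
        value_range = (values.min(), values.max())
    edges = np.linspace(value_range[0], value_range[1], n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    idx = np.clip(np.digitize(values, edges) - 1, 0, n_bins - 1)
    inside = (values >= edges[0]) & (values <= edges[-1])
    occupancy = np.bincount(idx[inside], minlength=n_bins) * dt
    spikes = np.bincount(idx[inside], weights=counts[inside],
                         minlength=n_bins)
    if not np.any(occupancy > 0):
        raise ValueError("no occupancy inside the requested range")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occupancy > 0, spikes / occupancy, np.nan)
    if smooth:
        ok = np.isfinite(rates)
        if ok.sum() >= 7:
            sm = lowess(rates[ok], centers[ok], frac=min(1.0, 7.0 / ok.sum()),
                        it=2, return_sorted=False)
            rates = rates.copy()
            rates[ok] = sm
    return TuningCurve(variable, centers, rates, occupancy=occupancy)


def tuning_stability(
    design_first: DesignMatrix,
    counts_first: np.ndarray,
    design_second: DesignMatrix,
    counts_second: np.ndarray,
    selected: list[str],
    variable: str,
) -> float:
    """Pearson correlation of model-derived curves from the two session
    halves, restricted to the intersection of behavioral ranges; the
    shorter curve is up-sampled by linear interpolation.  Returns NaN
    when the ranges do not overlap.
    """
    from .model import fit as fit_model

    curves = []
    for design, counts in ((design_first, counts_first),
                           (design_second, counts_second)):
        f = fit_model(design, counts, selected)
        cfg = design.configs[variable]
        lo, hi = cfg.knots[0], cfg.knots[-1]
        if cfg.circular:
            hi = cfg.knots[0] + cfg.period
        curves.append(
            model_tuning_curve(design, f, variable, value_range=(lo, hi))
        )
    lo = max(c.bin_centers[0] for c in curves)
    hi = min(c.bin_centers[-1] for c in curves)
    if hi <= lo:
        return np.nan
    a, b = (c.restrict(lo, hi) for c in curves)
    if a.bin_centers.size < 2 or b.bin_centers.size < 2:
        return np.nan
    if a.bin_centers.size < b.bin_centers.size:
        a_rates = np.interp(b.bin_centers, a.bin_centers, a.rates)
        b_rates = b.rates
    else:
        b_rates = np.interp(a.bin_centers, b.bin_centers, b.rates)
        a_rates = a.rates
    if np.std(a_rates) == 0 or np.std(b_rates) == 0:
        return np.nan
    return float(np.corrcoef(a_rates, b_rates)[0, 1])


def _fraction_explained(y: np.ndarray, yhat: np.ndarray) -> float:
    mse_base = np.mean((y - y.mean()) ** 2)
    if mse_base < 1e-12:
        return np.nan
    return 1.0 - np.mean((y - yhat) ** 2) / mse_base


def classify_shape(
    curve: TuningCurve,
    variable: str | None = None,
    coverage: float | None = None,
    max_degree: int = 5,
) -> ShapeClassification:
    """Greedy polynomial classification of a tuning curve.

    The curve is range-normalized to [0, 1] (pitch/roll curves are
    additionally Gaussian-smoothed, 20-bin window); polynomials of
    degree 1..5 are fit by least squares on the standardized abscissa
    and the first degree with fraction of error explained >= 0.9 over
    the flat baseline is assigned.  A flat curve (zero baseline MSE) is
    reported as undefined rather than guessed.
    """
    variable = variable or curve.variable
    if coverage is not None:
        needed = COVERAGE_EYE if variable.startswith(("E", "dE")) else COVERAGE_HEAD
        if coverage < needed:
            return ShapeClassification(
                variable, None, np.nan,
                details={"reason": "insufficient coverage",
                         "coverage": coverage},
            )
    ok = np.isfinite(curve.rates)
    x = curve.bin_centers[ok]
    y = curve.rates[ok].astype(float)
    if y.size < max_degree + 2:
        return ShapeClassification(variable, None, np.nan,
                                   details={"reason": "too few bins"})
    rng_span = y.max() - y.min()
    if rng_span < 1e-12:
        return ShapeClassification(variable, None, np.nan,
                                   details={"reason": "flat curve"})
    y = (y - y.min()) / rng_span
    if variable in ("H_p", "H_r"):
        y = gaussian_filter1d(y, 20.0 / 5.0, mode="nearest")
    # standardized abscissa for conditioning
    xc = (x - x.mean()) / (np.ptp(x) / 2.0)
    for degree in range(1, max_degree + 1):
        coeffs = np.polyfit(xc, y, degree)
        frac = _fraction_explained(y, np.polyval(coeffs, xc))
        if np.isnan(frac):
            return ShapeClassification(variable, None, np.nan,
                                       details={"reason": "flat baseline"})
        if frac >= FRACTION_THRESHOLD:
            direction, preferred = _direction_and_peak(x, y)
            return ShapeClassification(
                variable, degree, float(frac), coefficients=coeffs,
                direction=direction, preferred_position=preferred,
            )
    return ShapeClassification(variable, None, float(frac),
                               details={"reason": "no polynomial <= degree "
                                        f"{max_degree} reached 0.9"})


def _direction_and_peak(x: np.ndarray, y: np.ndarray):
    """Preferred side (sign of the abscissa at the global extremum) and
    the extremum location among detected peaks/valleys."""
    peaks, _ = find_peaks(y)
    valleys, _ = find_peaks(-y)
    cand = np.concatenate([[0, y.size - 1], peaks, valleys]).astype(int)
    best = cand[np.argmax(y[cand])]
    direction = "positive" if x[best] > 0 else "negative"
    return direction, float(x[best])


def classify_velocity_subtype(
    curve: TuningCurve,
    shape: ShapeClassification | None = None,
) -> ShapeClassification:
    """Subtype a velocity tuning curve from its side slopes.

    Degree-1 curves are linear-asymmetric (L_as) with direction from
    the slope sign.  For higher degrees, lines are fit below and above
    zero velocity: opposite-signed slopes whose magnitude ratio is at
    least 0.5 give a symmetric class (NL_s-pos when rate rises with
    speed, NL_s-neg when it falls); otherwise the cell is
    nonlinear-asymmetric (NL_as), preferring the steeper side.  The
    preferred position is the global extremum among peaks and valleys.
    """
    if shape is None:
        shape = classify_shape(curve)
    ok = np.isfinite(curve.rates)
    x = curve.bin_centers[ok]
    y = curve.rates[ok].astype(float)
    if x.min() >= 0 or x.max() <= 0:
        raise ValueError("velocity curve must contain zero inside its range")
    below, above = x < 0, x > 0
    if below.sum() < 2 or above.sum() < 2:
        raise ValueError("too few bins on one side of zero")
    m_below = float(np.polyfit(x[below], y[below], 1)[0])
    m_above = float(np.polyfit(x[above], y[above], 1)[0])
    shape.slope_below, shape.slope_above = m_below, m_above

    peaks, _ = find_peaks(y)
    valleys, _ = find_peaks(-y)
    interior = np.concatenate([peaks, valleys]).astype(int)
    # interior peaks/valleys take precedence; endpoints are fallbacks
    # for monotone curves with no detected extremum
    cand = interior if interior.size else np.array([0, y.size - 1])
    extremum = cand[np.argmax(np.abs(y[cand] - np.median(y)))]
    shape.preferred_position = float(x[extremum])

    if shape.degree == 1:
        slope = float(np.polyfit(x, y, 1)[0])
        shape.subtype = "L_as"
        shape.direction = "positive" if slope > 0 else "negative"
        return shape
    ratio = min(abs(m_below), abs(m_above)) / max(abs(m_below), abs(m_above),
                                                  1e-12)
    if np.sign(m_below) == -np.sign(m_above) and ratio >= SLOPE_RATIO_SYMMETRIC:
        shape.subtype = "NL_s-pos" if m_above > 0 else "NL_s-neg"
        shape.direction = None
    else:
        shape.subtype = "NL_as"
        steeper = m_above if abs(m_above) >= abs(m_below) else m_below
        side = "positive" if abs(m_above) >= abs(m_below) else "negative"
        shape.direction = side
        shape.details["steeper_slope"] = steeper
    return shape


def variable_contribution(
    design: DesignMatrix,
    counts: np.ndarray,
    selected: list[str],
    variable: str,
    folds: list[np.ndarray] | None = None,
    normalized: bool = False,
    method: str = "lli",
) -> float:
    """Unique contribution of one variable to model performance.

    With ``method="lli"`` (default): mean spike-normalized held-out LLI
    of the selected model minus that of the reduced model refit without
    the variable, on the same folds.  ``normalized=True`` divides the
    difference by the selected model's performance (relative-loss
    variant).  With ``method="correlation"``: the Pearson correlation
    between the Gaussian-smoothed spiketrain (20-bin window) and each
    model's predicted rate, selected minus reduced.  Only defined for
    cells encoding the variable and at least one other variable.
    """
    if variable not in selected:
        raise ValueError(f"{variable} is not in the selected set")
    if len(selected) < 2:
        raise ValueError(
            "contribution requires the variable of interest plus at least "
            "one other encoded variable"
        )
    reduced_vars = [v for v in selected if v != variable]
    if method == "correlation":
        from .model import fit as fit_model

        smoothed = gaussian_filter1d(np.asarray(counts, dtype=float),
                                     20.0 / 5.0)

        def score(variables: list[str]) -> float:
            f = fit_model(design, counts, variables)
            rate = np.exp(predict_log_mu(design, f))
            return float(np.corrcoef(smoothed, rate)[0, 1])

        return score(selected) - score(reduced_vars)
    if method != "lli":
        raise ValueError("method must be 'lli' or 'correlation'")
    if folds is None:
        folds = make_folds(design.n_retained, dt=design.dt)
    full = crossvalidate(design, counts, selected, folds=folds)
    reduced = crossvalidate(design, counts, reduced_vars, folds=folds)
    delta = float(np.mean(full.fold_lli_per_spike)
                  - np.mean(reduced.fold_lli_per_spike))
    if normalized:
        denom = float(np.mean(full.fold_lli_per_spike))
        return delta / denom if denom != 0 else np.nan
    return delta
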