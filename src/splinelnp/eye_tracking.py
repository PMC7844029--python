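"""Pupil tracking: normalized eye position and velocity from camera frames.

The pipeline mirrors threshold-based infrared eye tracking: the pupil is
the largest connected region of pixels darker than a hand-picked
threshold inside a search region, accepted only when its pixel count
lies strictly between 50 and 1000; a circle is fit to the region and
its center taken as the pupil location.  The bright corneal reflection
(CR) is detected the same way with the inequality reversed and serves
as a camera-jitter reference: CR deviations from the session mean are
subtracted from pupil position.  Slow camera drift is removed by
subtracting a 1000-point Gaussian-smoothed trace; the top and bottom 1%
of values per coordinate are masked as extremal; positions are
projected onto manually defined horizontal (tear duct to outer canthus)
and vertical eye axes and expressed in % of the eye width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.measure import CircleModel, label, regionprops

__all__ = [
    "PupilFrameResult",
    "EyeAxes",
    "detect_pupil",
    "detect_cr",
    "track_frames",
    "build_eye_timeseries",
    "smooth_and_differentiate",
]

PIXEL_COUNT_MIN = 50  # exclusive bounds on the connected-pixel count
PIXEL_COUNT_MAX = 1000
DRIFT_WINDOW = 1000  # points in the drift-removal Gaussian
EXTREMAL_FRACTION = 0.01  # top and bottom 1% masked per coordinate


@dataclass
class PupilFrameResult:
    """Detection result for one frame; invalid frames carry no center."""

    valid: bool
    center: tuple[float, float] | None = None  # (x, y) px
    radius: float | None = None
    pixel_count: int = 0
    cr_center: tuple[float, float] | None = None


@dataclass
class EyeAxes:
    """Manually defined eye axes in pixel coordinates.

    ``horizontal`` runs from the tear duct to the outer canthus; the
    vertical axis is orthogonal, through the mean horizontal position.
    """

    horizontal_start: tuple[float, float]
    horizontal_end: tuple[float, float]

    def __post_init__(self) -> None:
        h = np.asarray(self.horizontal_end, float) - np.asarray(
            self.horizontal_start, float
        )
        self.eye_width = float(np.linalg.norm(h))
        if self.eye_width <= 0:
            raise ValueError("eye width must be positive")
        self.h_unit = h / self.eye_width
        self.v_unit = np.array([-self.h_unit[1], self.h_unit[0]])


def _fit_circle(coords_rc: np.ndarray) -> tuple[tuple[float, float], float]:
    """Algebraic least-squares circle fit to region pixels (row, col)."""
    xy = coords_rc[:, ::-1].astype(float)  # -> (x, y)
    if len(xy) >= 3 and np.ptp(xy[:, 0]) > 0 and np.ptp(xy[:, 1]) > 0:
        model = CircleModel.from_estimate(xy)
        if model:
            cx, cy = model.center
            return (float(cx), float(cy)), float(model.radius)
    c = xy.mean(axis=0)
    return (float(c[0]), float(c[1])), float(np.sqrt(len(xy) / np.pi))


def _detect_component(
    frame: np.ndarray,
    threshold: float,
    region: tuple[slice, slice] | None,
    darker: bool,
) -> PupilFrameResult:
    frame = np.asarray(frame)
    view = frame if region is None else frame[region]
    mask = view < threshold if darker else view > threshold
    if not mask.any():
        return PupilFrameResult(valid=False)
    labels = label(mask, connectivity=2)
    props = regionprops(labels)
    best = max(props, key=lambda p: p.area)
    count = int(best.area)
    if darker and not (PIXEL_COUNT_MIN < count < PIXEL_COUNT_MAX):
        return PupilFrameResult(valid=False, pixel_count=count)
    coords = best.coords.astype(float)
    if region is not None:
        coords[:, 0] += region[0].start or 0
        coords[:, 1] += region[1].start or 0
    center, radius = _fit_circle(coords)
    return PupilFrameResult(
        valid=True, center=center, radius=radius, pixel_count=count
    )


def detect_pupil(
    frame: np.ndarray,
    intensity_threshold: float,
    search_region: tuple[slice, slice] | None = None,
) -> PupilFrameResult:
    """Largest dark connected component within the search region.

    The frame is valid only when the component's pixel count lies
    strictly between 50 and 1000.
    """
    return _detect_component(frame, intensity_threshold, search_region,
                             darker=True)


def detect_cr(
    frame: np.ndarray,
    intensity_threshold: float,
    boundary_region: tuple[slice, slice] | None = None,
) -> PupilFrameResult:
    """Bright-pixel mirror of :func:`detect_pupil` (no count-range rule)."""
    return _detect_component(frame, intensity_threshold, boundary_region,
                             darker=False)


def track_frames(
    frames: np.ndarray,
    pupil_threshold: float,
    cr_threshold: float,
    search_region: tuple[slice, slice] | None = None,
    cr_region: tuple[slice, slice] | None = None,
) -> list[PupilFrameResult]:
    """Run pupil + CR detection over a frame stack."""
    results = []
    for frame in frames:
        res = detect_pupil(frame, pupil_threshold, search_region)
        cr = detect_cr(frame, cr_threshold, cr_region)
        if res.valid and cr.valid:
            res.cr_center = cr.center
        elif res.valid:
            res = PupilFrameResult(valid=False, pixel_count=res.pixel_count)
        results.append(res)
    return results


def _interpolate_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return x
    if not valid.any():
        raise ValueError("no valid frames to interpolate from")
    idx = np.arange(x.size)
    out = x.copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return out


def build_eye_timeseries(
    results: list[PupilFrameResult],
    axes: EyeAxes,
    max_invalid_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(E_h, E_v, retained-mask) in % of eye width from per-frame results.

    Steps, in order: linear interpolation across invalid frames; CR
    jitter referencing (subtract CR deviations from the CR session
    mean); drift high-pass (subtract the 1000-point-Gaussian-smoothed
    trace; sigma = window / 6); masking of the top and bottom 1% of
    values per coordinate; projection onto the eye axes and conversion
    to % of eye width.  Sessions with more than 25% invalid frames are
    rejected.
    """
    n = len(results)
    if n < DRIFT_WINDOW:
        raise ValueError(
            f"need >= {DRIFT_WINDOW} frames for drift removal, got {n}"
        )
    valid = np.array([r.valid for r in results])
    if (1.0 - valid.mean()) > max_invalid_fraction:
        raise ValueError(
            f"{(1 - valid.mean()):.0%} invalid frames exceeds the "
            f"{max_invalid_fraction:.0%} session-rejection threshold"
        )
    px = np.array([r.center[0] if r.valid else np.nan for r in results])
    py = np.array([r.center[1] if r.valid else np.nan for r in results])
    px = _interpolate_invalid(np.nan_to_num(px), valid)
    py = _interpolate_invalid(np.nan_to_num(py), valid)

    crx = np.array([
        r.cr_center[0] if (r.valid and r.cr_center) else np.nan
        for r in results
    ])
    cry = np.array([
        r.cr_center[1] if (r.valid and r.cr_center) else np.nan
        for r in results
    ])
    has_cr = ~np.isnan(crx)
    if has_cr.any():
        crx = _interpolate_invalid(np.nan_to_num(crx), has_cr)
        cry = _interpolate_invalid(np.nan_to_num(cry), has_cr)
        px = px - (crx - crx.mean())
        py = py - (cry - cry.mean())

    sigma = DRIFT_WINDOW / 6.0  # window ~ +/- 3 sigma
    px = px - gaussian_filter1d(px, sigma, mode="nearest")
    py = py - gaussian_filter1d(py, sigma, mode="nearest")

    keep = np.ones(n, dtype=bool)
    for coord in (px, py):
        lo, hi = np.quantile(coord, [EXTREMAL_FRACTION, 1 - EXTREMAL_FRACTION])
        keep &= (coord >= lo) & (coord <= hi)

    xy = np.column_stack([px, py])
    e_h = xy @ axes.h_unit / axes.eye_width * 100.0
    e_v = xy @ axes.v_unit / axes.eye_width * 100.0
    return e_h, e_v, keep


def smooth_and_differentiate(
    position: np.ndarray,
    dt: float = 0.02,
    sigma_position_s: float = 0.010,
    sigma_velocity_s: float = 0.140,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed position and its smoothed finite-difference
    velocity (units of position / s).

    Position smoothing sigma ~ 10 ms; the velocity trace (central
    first difference of the smoothed position over dt) is smoothed with
    sigma ~ 140 ms, which suppresses saccadic transients.
    """
    position = np.asarray(position, dtype=float)
    pos_s = gaussian_filter1d(position, sigma_position_s / dt, mode="nearest")
    vel = np.gradient(pos_s, dt)
    vel_s = gaussian_filter1d(vel, sigma_velocity_s / dt, mode="nearest")
    return pos_s, vel_s
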