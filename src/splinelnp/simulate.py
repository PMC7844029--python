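"""Synthetic sessions with known ground truth.

Every downstream stage of the pipeline is testable without recorded
data: this module generates (a) open-field foraging behavior whose
pitch / roll / azimuthal-velocity marginals match the published
across-mouse percentile envelopes, (b) virtual-linear-track running
with fixation/saccade-style eye traces, (c) raw 3-axis accelerometer
streams for known head-orientation series (the exact inverse of the
pitch/roll recovery in :mod:`splinelnp.kinematics`), (d) grayscale
eye-camera frames containing a dark pupil disk and a bright corneal
reflection, and (e) Poisson spike trains drawn from known
linear-nonlinear ground-truth models.

All randomness flows through one explicit ``numpy.random.Generator``;
identical (spec, seed) pairs produce bit-identical outputs.

Process families are a modeling choice: mean-reverting
(Ornstein-Uhlenbeck) processes for pitch/roll, a circular random walk
with Gaussian-scale-mixture increments for azimuth (heavy-tailed
angular velocity), a reflected random walk for 2-D position, and a
slow-drift-plus-fixation-jump process for eye position (saccade-like
excursions give the heavy velocity tails).  Their parameters are
calibrated to the published percentile tables and are not meant to be
retuned per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eye_tracking import smooth_and_differentiate
from .kinematics import (
    AccelStream,
    compute_angular_velocities,
    rotation_pitch,
    rotation_roll,
)
from .session import BehaviorSession, SpikeCountSeries

__all__ = [
    "ProcessParams",
    "BehaviorSpec",
    "simulate_open_field_behavior",
    "simulate_vr_behavior",
    "AccelRecording",
    "simulate_accelerometer",
    "FrameGeometry",
    "simulate_eye_frames",
    "GroundTruthCell",
    "generate_ln_spikes",
    "gaussian_place_field",
    "gaussian_bump",
    "von_mises_tuning",
    "linear_tuning",
    "rectified_tuning",
    "polynomial_tuning",
]

DT = 0.02


@dataclass
class ProcessParams:
    """Mean-reverting process parameters: stationary mean / SD (variable
    units) and autocorrelation time constant (s)."""

    mean: float
    sd: float
    tau: float


@dataclass
class EyeParams:
    """Eye-position process along one axis (% of eye width).

    The trace is the sum of an offset, a slow mean-reverting drift, a
    piecewise-constant fixation component whose levels come from a
    skewed Gaussian/half-normal mixture (jumps at shared saccade
    times), and a slow-phase drift at ``drift_per_s`` that resets at
    each saccade (the drift/quick-reset asymmetry gives the published
    negative median horizontal eye velocity).
    """

    offset: float
    slow_sd: float
    slow_tau: float
    core_mean: float
    core_sd: float
    tail_p: float
    tail_scale: float  # half-normal scale; sign picks the heavy side
    drift_per_s: float = 0.0

    @classmethod
    def horizontal(cls) -> "EyeParams":
        return cls(offset=0.08, slow_sd=0.35, slow_tau=2.0,
                   core_mean=-0.15, core_sd=1.15, tail_p=0.10,
                   tail_scale=3.2, drift_per_s=-0.11)

    @classmethod
    def vertical(cls) -> "EyeParams":
        return cls(offset=-0.05, slow_sd=0.27, slow_tau=2.0,
                   core_mean=0.05, core_sd=0.42, tail_p=0.10,
                   tail_scale=-1.7, drift_per_s=0.0)


@dataclass
class BehaviorSpec:
    """Conditions for one synthetic session.

    Defaults reproduce the study conditions: 20-min sessions at 50 Hz;
    open-field pitch/roll means and spreads matching the published
    percentile table; azimuthal velocity a 0.9/0.1 Gaussian scale
    mixture (SDs 45 and 550 deg/s); eye traces matching the published
    eye-position percentiles in % of eye width.
    """

    session_length: float = 1200.0
    sample_rate: float = 50.0
    arena: dict = field(
        default_factory=lambda: {"open_field": (50.0, 50.0)}
    )
    pitch: ProcessParams = field(
        default_factory=lambda: ProcessParams(11.5, 19.0, 2.0)
    )
    roll: ProcessParams = field(
        default_factory=lambda: ProcessParams(-0.8, 24.0, 2.0)
    )
    #: azimuthal angular velocity: (core SD, tail SD, tail probability)
    azimuth_velocity: tuple[float, float, float] = (45.0, 550.0, 0.1)
    speed: ProcessParams = field(
        default_factory=lambda: ProcessParams(10.0, 5.0, 2.0)
    )
    heading_step_sd: float = 15.0  # deg per frame, movement-direction walk
    eye_h: "EyeParams" = field(default_factory=lambda: EyeParams.horizontal())
    eye_v: "EyeParams" = field(default_factory=lambda: EyeParams.vertical())
    saccade_rate: float = 0.6  # Hz, shared jump times for both eye axes
    vr_speed: ProcessParams = field(
        default_factory=lambda: ProcessParams(15.0, 7.0, 1.0)
    )
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.session_length < 60.0:
            raise ValueError(
                "session_length must be >= 60 s for percentile estimation"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.session_length * self.sample_rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


def _ou(
    rng: np.random.Generator, params: ProcessParams, n: int, dt: float
) -> np.ndarray:
    """Exact discretization of an Ornstein-Uhlenbeck process, started at
    its stationary distribution."""
    if params.sd == 0.0:
        return np.full(n, params.mean)
    rho = np.exp(-dt / params.tau)
    innov_sd = params.sd * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = params.mean + params.sd * rng.standard_normal()
    eps = innov_sd * rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = params.mean + rho * (x[t - 1] - params.mean) + eps[t - 1]
    return x


def _reflect(x: np.ndarray, low: float, high: float) -> np.ndarray:
    """Reflect values into [low, high] (triangle-wave folding)."""
    width = high - low
    y = np.mod(x - low, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return y + low


def simulate_open_field_behavior(spec: BehaviorSpec) -> BehaviorSession:
    """Open-field foraging: 2-D position, speed, azimuth, pitch, roll,
    and the three angular velocities at 50 Hz."""
    if "open_field" not in spec.arena:
        raise ValueError("spec.arena must be open_field for this simulator")
    width, height = spec.arena["open_field"]
    if width <= 0 or height <= 0:
        raise ValueError("arena dimensions must be positive")
    rng = np.random.default_rng(spec.random_seed)
    n, dt = spec.n_samples, spec.dt
    time = np.arange(n) * dt

    pitch = _ou(rng, spec.pitch, n, dt)
    roll = _ou(rng, spec.roll, n, dt)

    # azimuth: circular random walk with heavy-tailed angular velocity
    sd_core, sd_tail, p_tail = spec.azimuth_velocity
    tail = rng.random(n - 1) < p_tail
    omega = rng.standard_normal(n - 1) * np.where(tail, sd_tail, sd_core)
    azimuth = np.mod(
        rng.uniform(0, 360) + np.concatenate([[0.0], np.cumsum(omega * dt)]),
        360.0,
    )

    # body: speed process + slowly wandering movement direction,
    # reflected at the walls
    speed = np.abs(_ou(rng, spec.speed, n, dt))
    heading = np.cumsum(
        np.radians(spec.heading_step_sd) * rng.standard_normal(n)
    ) + rng.uniform(0, 2 * np.pi)
    steps = (speed * dt)[:, None] * np.column_stack(
        [np.cos(heading), np.sin(heading)]
    )
    start = np.array([rng.uniform(0, width), rng.uniform(0, height)])
    raw = start + np.vstack([[0.0, 0.0], np.cumsum(steps[:-1], axis=0)])
    x = _reflect(raw[:, 0], 0.0, width)
    y = _reflect(raw[:, 1], 0.0, height)
    b_s = np.concatenate(
        [[0.0], np.hypot(np.diff(x), np.diff(y))]
    ) / dt
    if n > 1:
        b_s[0] = b_s[1]

    channels = {
        "B_x": x,
        "B_y": y,
        "B_s": b_s,
        "H_a": azimuth,
        "H_p": pitch,
        "H_r": roll,
        "dH_a": compute_angular_velocities(azimuth, dt, circular=True),
        "dH_p": compute_angular_velocities(pitch, dt, circular=False),
        "dH_r": compute_angular_velocities(roll, dt, circular=False),
    }
    return BehaviorSession(
        time, channels, meta={"dt": dt, "arena": ("open_field", width, height)}
    )


def _eye_trace(
    rng: np.random.Generator,
    n: int,
    dt: float,
    params: EyeParams,
    jump_times: np.ndarray,
) -> np.ndarray:
    """One eye-axis trace: offset + slow OU + skewed fixation levels +
    resetting slow-phase drift."""
    slow = _ou(rng, ProcessParams(0.0, params.slow_sd, params.slow_tau),
               n, dt)
    n_fix = jump_times.size + 1
    levels = params.core_mean + params.core_sd * rng.standard_normal(n_fix)
    tail = rng.random(n_fix) < params.tail_p
    excursion = np.abs(rng.standard_normal(n_fix)) * abs(params.tail_scale)
    levels = np.where(tail,
                      np.sign(params.tail_scale) * excursion
                      + params.core_mean,
                      levels)
    idx = np.searchsorted(jump_times, np.arange(n), side="right")
    fix = levels[idx]
    # time since the last saccade, for the resetting slow-phase drift
    starts = np.concatenate([[0], jump_times])[idx]
    age = (np.arange(n) - starts) * dt
    return params.offset + slow + fix + params.drift_per_s * age


def simulate_vr_behavior(spec: BehaviorSpec) -> BehaviorSession:
    """Virtual-linear-track running with eye position/velocity traces.

    Position advances by speed * dt and wraps at the track length.  Eye
    position (% of eye width) is a slow mean-reverting drift plus a
    fixation process with saccade-like jumps; velocities are obtained by
    the same smoothing/differentiation applied to tracked eyes.
    """
    if "vr_track" not in spec.arena:
        raise ValueError("spec.arena must be vr_track for this simulator")
    track_length = float(spec.arena["vr_track"].get("length", 400.0))
    if track_length <= 0:
        raise ValueError("track length must be positive")
    rng = np.random.default_rng(spec.random_seed)
    n, dt = spec.n_samples, spec.dt
    time = np.arange(n) * dt

    speed = np.maximum(0.0, _ou(rng, spec.vr_speed, n, dt))
    pos = np.mod(
        rng.uniform(0, track_length)
        + np.concatenate([[0.0], np.cumsum(speed[:-1] * dt)]),
        track_length,
    )

    jumps = np.flatnonzero(rng.random(n) < spec.saccade_rate * dt)
    e_h = _eye_trace(rng, n, dt, spec.eye_h, jumps)
    e_v = _eye_trace(rng, n, dt, spec.eye_v, jumps)
    e_h_s, de_h = smooth_and_differentiate(e_h, dt)
    e_v_s, de_v = smooth_and_differentiate(e_v, dt)

    channels = {
        "B": pos,
        "B_s": speed,
        "E_h": e_h_s,
        "E_v": e_v_s,
        "dE_h": de_h,
        "dE_v": de_v,
    }
    return BehaviorSession(
        time, channels, meta={"dt": dt, "arena": ("vr_track", track_length)}
    )


@dataclass
class AccelRecording:
    """Simulated IMU output: a head-fixed calibration segment followed by
    the freely moving stream, both in the raw sensor frame."""

    calibration: AccelStream
    stream: AccelStream
    calib_orientation: tuple[float, float]  # (theta_r, theta_p) radians


def _gravity_in_head_frame(
    pitch_deg: np.ndarray, roll_deg: np.ndarray
) -> np.ndarray:
    """Unit gravity direction in the head frame for given pitch/roll.

    Inverse of the projection-based recovery: the x-z plane projection
    makes angle ``pitch`` with vertical (nose-up = negative x) and the
    y-z projection makes angle ``roll`` (rightward = positive y).
    """
    p = np.radians(pitch_deg)
    r = np.radians(roll_deg)
    v = np.column_stack([-np.tan(p), np.tan(r), np.ones_like(p)])
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_accelerometer(
    pitch_deg: np.ndarray,
    roll_deg: np.ndarray,
    calib_orientation: tuple[float, float] = (0.0, 0.0),
    sample_rate: float = 30.0,
    noise_sd: float = 0.0,
    drift_per_s: np.ndarray | None = None,
    calib_duration: float = 120.0,
    seed: int = 0,
) -> AccelRecording:
    """Raw 3-axis accelerometer stream for a known head-orientation series.

    ``calib_orientation = (theta_r, theta_p)`` is the sensor mounting
    (radians); the output stream is expressed in the raw sensor frame so
    that the calibration + pitch/roll recovery in
    :mod:`splinelnp.kinematics` returns the inputs.  Optional isotropic
    Gaussian sensor noise (g units) and a constant drift vector (g/s)
    can be added.  Angles at or beyond 90 deg are rejected (gravity
    sensing is gimbal-degenerate there).
    """
    pitch_deg = np.atleast_1d(np.asarray(pitch_deg, dtype=float))
    roll_deg = np.atleast_1d(np.asarray(roll_deg, dtype=float))
    if pitch_deg.shape != roll_deg.shape:
        raise ValueError("pitch and roll series must have equal length")
    if np.any(np.abs(pitch_deg) >= 90) or np.any(np.abs(roll_deg) >= 90):
        raise ValueError("|pitch| and |roll| must be < 90 deg")
    rng = np.random.default_rng(seed)
    theta_r, theta_p = calib_orientation
    # C2 -> C1: inverse of the calibration rotation
    R_back = rotation_roll(theta_r) @ rotation_pitch(theta_p)

    n_cal = max(2, int(round(calib_duration * sample_rate)))
    a_cal = np.tile(R_back @ np.array([0.0, 0.0, 1.0]), (n_cal, 1))
    if noise_sd > 0:
        a_cal = a_cal + noise_sd * rng.standard_normal(a_cal.shape)
    t_cal = np.arange(n_cal) / sample_rate

    a_c2 = _gravity_in_head_frame(pitch_deg, roll_deg)
    a = a_c2 @ R_back.T
    t = np.arange(a.shape[0]) / sample_rate
    if noise_sd > 0:
        a = a + noise_sd * rng.standard_normal(a.shape)
    if drift_per_s is not None:
        a = a + np.outer(t, np.asarray(drift_per_s, dtype=float))
    return AccelRecording(
        calibration=AccelStream(t_cal, a_cal),
        stream=AccelStream(t, a),
        calib_orientation=(theta_r, theta_p),
    )


@dataclass
class FrameGeometry:
    """Geometry of synthetic eye-camera frames (pixel units)."""

    shape: tuple[int, int] = (120, 160)  # rows, cols
    pupil_radius: float = 10.0
    pupil_value: int = 40
    cr_offset: tuple[float, float] = (-18.0, -12.0)  # relative to frame center
    cr_radius: float = 2.5
    cr_value: int = 235
    background: int = 128

    def __post_init__(self) -> None:
        area = np.pi * self.pupil_radius**2
        if not 50 < area < 1000:
            raise ValueError(
                f"pupil radius {self.pupil_radius} px gives ~{area:.0f} "
                "connected pixels, outside the detectable (50, 1000) window"
            )


def simulate_eye_frames(
    centers_xy: np.ndarray,
    geometry: FrameGeometry | None = None,
    camera_jitter: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Grayscale frame stack with a dark pupil disk and bright corneal
    reflection.

    ``centers_xy`` are commanded pupil centers (x, y) in pixels;
    ``camera_jitter`` (optional, same shape) translates pupil and CR
    together, emulating camera motion.  Returns ``(frames, truth)`` with
    frames ``uint8 (n, rows, cols)`` and the ground-truth centers.
    """
    geom = geometry or FrameGeometry()
    centers = np.atleast_2d(np.asarray(centers_xy, dtype=float))
    rows, cols = geom.shape
    if np.any(centers[:, 0] < 0) or np.any(centers[:, 0] >= cols) or np.any(
        centers[:, 1] < 0
    ) or np.any(centers[:, 1] >= rows):
        raise ValueError("commanded pupil centers outside frame bounds")
    jitter = (
        np.zeros_like(centers)
        if camera_jitter is None
        else np.atleast_2d(np.asarray(camera_jitter, dtype=float))
    )
    cr_base = np.array([cols / 2.0 + geom.cr_offset[0],
                        rows / 2.0 + geom.cr_offset[1]])
    yy, xx = np.mgrid[0:rows, 0:cols]
    frames = np.full((centers.shape[0], rows, cols), geom.background,
                     dtype=np.uint8)
    pupil_truth = centers + jitter
    cr_truth = cr_base[None, :] + jitter
    for i in range(centers.shape[0]):
        px, py = pupil_truth[i]
        mask = (xx - px) ** 2 + (yy - py) ** 2 <= geom.pupil_radius**2
        frames[i][mask] = geom.pupil_value
        cx, cy = cr_truth[i]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= geom.cr_radius**2
        frames[i][mask] = geom.cr_value
    truth = {"pupil": pupil_truth, "cr": cr_truth, "geometry": geom}
    return frames, truth


@dataclass
class GroundTruthCell:
    """Generative LN model: log expected count per 20 ms bin is
    ``bias + sum_i tuning_i(value_i(t))``.

    ``tuning`` maps variable symbol to a callable returning the log-rate
    contribution; variables absent from ``tuning`` contribute exactly 0.
    """

    bias: float
    tuning: dict = field(default_factory=dict)
    name: str = "cell"

    @property
    def encoded(self) -> list[str]:
        return sorted(self.tuning)

    def to_json(self) -> str:
        """Serialize a cell built from the parametric constructors below.

        Hand-written tuning callables (no ``spec`` attribute) cannot be
        serialized and raise.
        """
        import json

        tuning = {}
        for symbol, fn in self.tuning.items():
            spec = getattr(fn, "spec", None)
            if spec is None:
                raise ValueError(
                    f"{self.name}: tuning for {symbol} is not a parametric "
                    "constructor and cannot be serialized"
                )
            tuning[symbol] = spec
        return json.dumps({"name": self.name, "bias": self.bias,
                           "tuning": tuning}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthCell":
        import json

        d = json.loads(text)
        constructors = {
            "gaussian_place_field": gaussian_place_field,
            "gaussian_bump": gaussian_bump,
            "von_mises_tuning": von_mises_tuning,
            "linear_tuning": linear_tuning,
            "rectified_tuning": rectified_tuning,
            "polynomial_tuning": polynomial_tuning,
        }
        tuning = {}
        for symbol, spec in d["tuning"].items():
            kwargs = {k: v for k, v in spec.items() if k != "kind"}
            tuning[symbol] = constructors[spec["kind"]](**kwargs)
        return cls(bias=d["bias"], tuning=tuning, name=d.get("name", "cell"))

    def log_rate(self, session: BehaviorSession) -> np.ndarray:
        out = np.full(session.n_samples, self.bias)
        for symbol, fn in self.tuning.items():
            if symbol == "B" and "B" not in session.channels:
                vals = np.column_stack(
                    [session.channels["B_x"], session.channels["B_y"]]
                )
            else:
                if symbol not in session.channels:
                    raise KeyError(
                        f"{self.name}: encoded variable {symbol} missing "
                        "from session"
                    )
                vals = session.channels[symbol]
            contrib = np.asarray(fn(vals), dtype=float)
            if not np.all(np.isfinite(contrib)):
                raise ValueError(
                    f"{self.name}: non-finite tuning contribution for {symbol}"
                )
            out += contrib
        return out


def generate_ln_spikes(
    cell: GroundTruthCell,
    session: BehaviorSession,
    seed: int | np.random.Generator = 0,
) -> SpikeCountSeries:
    """Poisson spike counts per 20 ms bin from a ground-truth LN cell."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    log_mu = cell.log_rate(session)
    if np.any(log_mu > 20.0):
        raise ValueError("log-rate exceeds 20; expected counts overflow")
    counts = rng.poisson(np.exp(log_mu))
    return SpikeCountSeries(counts[None, :], dt=session.dt,
                            cell_ids=[cell.name])


# ---------------------------------------------------------------------------
# parametric tuning-function constructors


def gaussian_place_field(center: tuple[float, float], sigma: float,
                         amplitude: float):
    """2-D Gaussian place field (log-rate amplitude at the field center)."""
    cx, cy = center

    def fn(xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
        return amplitude * np.exp(-d2 / (2.0 * sigma**2))

    fn.spec = {"kind": "gaussian_place_field", "center": [cx, cy],
               "sigma": sigma, "amplitude": amplitude}
    return fn


def gaussian_bump(center: float, sigma: float, amplitude: float):
    def fn(x: np.ndarray) -> np.ndarray:
        return amplitude * np.exp(-((np.asarray(x) - center) ** 2)
                                  / (2.0 * sigma**2))

    fn.spec = {"kind": "gaussian_bump", "center": center, "sigma": sigma,
               "amplitude": amplitude}
    return fn


def von_mises_tuning(preferred_deg: float, kappa: float, amplitude: float):
    """Head-direction tuning, unit-peak von Mises scaled by ``amplitude``."""

    def fn(deg: np.ndarray) -> np.ndarray:
        d = np.radians(np.asarray(deg) - preferred_deg)
        return amplitude * np.exp(kappa * (np.cos(d) - 1.0))

    fn.spec = {"kind": "von_mises_tuning", "preferred_deg": preferred_deg,
               "kappa": kappa, "amplitude": amplitude}
    return fn


def linear_tuning(slope: float, center: float = 0.0):
    def fn(x: np.ndarray) -> np.ndarray:
        return slope * (np.asarray(x) - center)

    fn.spec = {"kind": "linear_tuning", "slope": slope, "center": center}
    return fn


def rectified_tuning(slope: float, threshold: float = 0.0):
    def fn(x: np.ndarray) -> np.ndarray:
        return slope * np.maximum(0.0, np.asarray(x) - threshold)

    fn.spec = {"kind": "rectified_tuning", "slope": slope,
               "threshold": threshold}
    return fn


def polynomial_tuning(coeffs, center: float = 0.0, scale: float = 1.0):
    """Polynomial of the standardized value (x - center) / scale;
    ``coeffs`` in numpy.polyval order (highest degree first)."""

    def fn(x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x) - center) / scale
        return np.polyval(coeffs, z)

    fn.spec = {"kind": "polynomial_tuning", "coeffs": list(coeffs),
               "center": center, "scale": scale}
    return fn
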