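"""Head/body kinematics from raw sensors.

Derives the behavioral variables used by the encoding model from raw
hardware streams: pitch and roll from a head-mounted 3-axis
accelerometer (gravity sensing, after a head-fixed calibration), body
position / speed / azimuth from two headstage LEDs, angular velocities
by wrapped finite differences, and alignment of everything (plus spike
events) onto a common 50 Hz clock with 20 ms spike-count bins.

Sign conventions (the hardware alone does not fix them; applied
consistently package-wide):

* pitch positive = nose up,
* roll positive = rightward (ipsiversive for right-hemisphere recordings),
* azimuth measured counterclockwise from +x in [0, 360) (``atan2``),
* azimuthal velocity positive = counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import BehaviorSession, SpikeCountSeries

__all__ = [
    "AccelStream",
    "ImuCalibration",
    "rotation_roll",
    "rotation_pitch",
    "calibrate_imu",
    "compute_pitch_roll",
    "compute_led_variables",
    "compute_angular_velocities",
    "synchronize_and_bin",
]

N_ROLL = np.array([0.0, 1.0, 0.0])
N_PITCH = np.array([1.0, 0.0, 0.0])
S_START = np.array([0.0, 0.0, 1.0])


@dataclass
class AccelStream:
    """Raw 3-axis accelerometer samples (unit gravity), sensor frame C1."""

    timestamps: np.ndarray  # seconds, strictly increasing, ~30 Hz
    a: np.ndarray  # (n, 3)
    pulse_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (self.timestamps.size, 3):
            raise ValueError("accelerometer array must be (n, 3)")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class ImuCalibration:
    """Head-fixed calibration: rotation from sensor frame C1 to head frame C2."""

    a_calib: np.ndarray  # session-mean accelerometer during calibration
    theta_r: float  # calibration roll (radians)
    theta_p: float  # calibration pitch (radians)
    R: np.ndarray  # 3x3, a_C2 = R @ a_C1


def rotation_roll(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1, 0, 0], [0, c, s], [0, -s, c]])


def rotation_pitch(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]])


def calibrate_imu(calibration: AccelStream) -> ImuCalibration:
    """Estimate the sensor-to-head rotation from a head-fixed segment.

    The calibration roll/pitch come from the segment-mean gravity vector:
    ``theta_r = arctan(a_y / a_z)``,
    ``theta_p = arctan(-a_x / sqrt(a_y^2 + a_z^2))``, and
    ``R = (R_roll(theta_r) @ R_pitch(theta_p))^T``, which maps the mean
    calibration vector onto the head-frame vertical.
    """
    if calibration.timestamps[-1] - calibration.timestamps[0] < 1.0:
        raise ValueError("calibration segment must span >= 1 s")
    a = calibration.a.mean(axis=0)
    norm = np.linalg.norm(a)
    if norm < 0.5:
        raise ValueError(
            f"calibration gravity norm {norm:.3f} g < 0.5 g; calibration invalid"
        )
    theta_r = float(np.arctan2(a[1], a[2]))
    theta_p = float(np.arctan(-a[0] / np.hypot(a[1], a[2])))
    R = (rotation_roll(theta_r) @ rotation_pitch(theta_p)).T
    return ImuCalibration(a_calib=a, theta_r=theta_r, theta_p=theta_p, R=R)


def _plane_angle(a_c2: np.ndarray, normal: np.ndarray, sign_axis: int,
                 sign_flip: bool) -> tuple[np.ndarray, np.ndarray]:
    """Signed angle between the head-frame vertical and the projection of
    ``a_c2`` onto the plane with unit ``normal``.

    The arccos of the normalized dot product gives an unsigned angle;
    the sign is restored from the in-plane coordinate ``sign_axis``.
    Samples with a degenerate projection are flagged invalid.
    """
    proj = a_c2 - np.outer(a_c2 @ normal, normal)
    norms = np.linalg.norm(proj, axis=1)
    ok = norms > 1e-8
    cosang = np.zeros(a_c2.shape[0])
    cosang[ok] = np.clip(proj[ok] @ S_START / norms[ok], -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    signs = np.sign(proj[:, sign_axis])
    if sign_flip:
        signs = -signs
    signs[signs == 0] = 1.0
    return ang * signs, ok


def compute_pitch_roll(
    stream: AccelStream, calib: ImuCalibration
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample pitch and roll (degrees) from a calibrated stream.

    Rotates each sample into the head frame, projects it onto the pitch
    and roll planes, and measures the signed angle to the head-fixed
    starting vector.  Returns ``(pitch, roll, valid)``.
    """
    a_c2 = stream.a @ calib.R.T
    # pitch lives in the x-z plane (normal = roll axis); nose-up gives
    # a negative x component, hence the sign flip
    pitch, ok_p = _plane_angle(a_c2, N_ROLL, sign_axis=0, sign_flip=True)
    roll, ok_r = _plane_angle(a_c2, N_PITCH, sign_axis=1, sign_flip=False)
    return pitch, roll, ok_p & ok_r


def compute_led_variables(
    led1_xy: np.ndarray, led2_xy: np.ndarray, dt: float = 0.02
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Body position, speed, and azimuth head direction from two LEDs.

    Position is the LED midpoint; speed the Euclidean displacement per
    frame over dt; azimuth the ``atan2`` of the LED difference vector
    (led1 - led2), counterclockwise from +x, mapped to [0, 360).
    Samples where either LED is missing (NaN) are masked; the speed at
    sample 0 repeats sample 1's value.

    Returns ``(B_xy, B_s, H_a, valid)``.
    """
    led1 = np.asarray(led1_xy, dtype=float)
    led2 = np.asarray(led2_xy, dtype=float)
    if led1.shape != led2.shape or led1.ndim != 2 or led1.shape[1] != 2:
        raise ValueError("LED tracks must both be (n, 2)")
    valid = ~(np.isnan(led1).any(axis=1) | np.isnan(led2).any(axis=1))
    pos = (led1 + led2) / 2.0
    diff = led1 - led2
    ha = np.mod(np.degrees(np.arctan2(diff[:, 1], diff[:, 0])), 360.0)
    disp = np.vstack([pos[1:] - pos[:-1], [[0.0, 0.0]]])
    speed = np.linalg.norm(disp, axis=1) / dt
    if speed.size > 1:
        speed[-1] = speed[-2]
        speed = np.concatenate([[speed[0]], speed[:-1]])
    pos = np.where(valid[:, None], pos, np.nan)
    return pos, speed, ha, valid


def compute_angular_velocities(
    angles: np.ndarray, dt: float = 0.02, circular: bool = True
) -> np.ndarray:
    """Angular velocity (deg/s) by finite differences.

    For circular variables the shortest signed arc is used, so a step
    from 359 deg to 1 deg reads +100 deg/s at 50 Hz, not -17,900 deg/s.
    The first sample repeats the second so the output matches the input
    length.
    """
    angles = np.asarray(angles, dtype=float)
    d = np.diff(angles)
    if circular:
        d = np.mod(d + 180.0, 360.0) - 180.0
    v = d / dt
    if v.size == 0:
        return np.zeros_like(angles)
    return np.concatenate([[v[0]], v])


def _match_pulses(t_src: np.ndarray, pulses_src: np.ndarray,
                  pulses_dst: np.ndarray) -> np.ndarray:
    """Map source-clock times onto the destination clock via shared pulses."""
    pulses_src = np.asarray(pulses_src, dtype=float)
    pulses_dst = np.asarray(pulses_dst, dtype=float)
    if pulses_src.size != pulses_dst.size:
        raise ValueError(
            f"sync failure: {pulses_src.size} source pulses vs "
            f"{pulses_dst.size} destination pulses"
        )
    if pulses_src.size < 2:
        raise ValueError("need >= 2 shared sync pulses")
    mapped = np.interp(t_src, pulses_src, pulses_dst)
    # linear extrapolation outside the pulse range (np.interp clamps)
    lo = t_src < pulses_src[0]
    hi = t_src > pulses_src[-1]
    slope_lo = (pulses_dst[1] - pulses_dst[0]) / (pulses_src[1] - pulses_src[0])
    slope_hi = ((pulses_dst[-1] - pulses_dst[-2])
                / (pulses_src[-1] - pulses_src[-2]))
    mapped[lo] = pulses_dst[0] + slope_lo * (t_src[lo] - pulses_src[0])
    mapped[hi] = pulses_dst[-1] + slope_hi * (t_src[hi] - pulses_src[-1])
    return mapped


def bin_spikes(
    spike_times: np.ndarray, t_start: float, n_bins: int, dt: float = 0.02
) -> np.ndarray:
    """Counts per half-open bin [t, t + dt); events outside are dropped."""
    spike_times = np.asarray(spike_times, dtype=float)
    idx = np.floor((spike_times - t_start) / dt).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    return np.bincount(idx[ok], minlength=n_bins)


def synchronize_and_bin(
    imu_stream: AccelStream,
    calib: ImuCalibration,
    led_time: np.ndarray,
    led1_xy: np.ndarray,
    led2_xy: np.ndarray,
    spike_times: dict[str, np.ndarray],
    led_pulses: np.ndarray | None = None,
    dt: float = 0.02,
) -> tuple[BehaviorSession, SpikeCountSeries]:
    """Assemble a full open-field session on the 50 Hz LED clock.

    IMU-derived pitch/roll (~30 Hz, irregular) are linearly interpolated
    onto the LED clock after pulse matching; spikes (already on the LED
    clock) are counted into 20 ms bins.
    """
    led_time = np.asarray(led_time, dtype=float)
    pitch, roll, ok = compute_pitch_roll(imu_stream, calib)
    t_imu = imu_stream.timestamps
    if led_pulses is not None:
        t_imu = _match_pulses(t_imu, imu_stream.pulse_times, led_pulses)
    pitch_i = np.interp(led_time, t_imu[ok], pitch[ok])
    roll_i = np.interp(led_time, t_imu[ok], roll[ok])
    pos, speed, ha, led_ok = compute_led_variables(led1_xy, led2_xy, dt)
    channels = {
        "B_x": np.nan_to_num(pos[:, 0]),
        "B_y": np.nan_to_num(pos[:, 1]),
        "B_s": speed,
        "H_a": ha,
        "H_p": pitch_i,
        "H_r": roll_i,
        "dH_a": compute_angular_velocities(ha, dt, circular=True),
        "dH_p": compute_angular_velocities(pitch_i, dt, circular=False),
        "dH_r": compute_angular_velocities(roll_i, dt, circular=False),
    }
    valid = {k: led_ok.copy() for k in ("B_x", "B_y", "B_s", "H_a", "dH_a")}
    session = BehaviorSession(led_time, channels, valid, {"dt": dt})
    counts = np.vstack(
        [
            bin_spikes(st, led_time[0], led_time.size, dt)
            for st in spike_times.values()
        ]
    )
    spikes = SpikeCountSeries(counts, dt=dt, cell_ids=list(spike_times))
    return session, spikes
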