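"""Session and model-result I/O.

All tabular artifacts are plain TSV (diff-friendly); nested objects
(fits, selection results, ground-truth cells) are JSON.  Behavior
tables carry one timestamp column plus one column per variable symbol;
spike tables carry one integer column per cell aligned row-for-row with
the behavior table.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .session import BehaviorSession, SpikeCountSeries

log = logging.getLogger("splinelnp")

__all__ = [
    "write_session",
    "write_spikes",
    "load_session",
    "write_fit",
    "read_fit",
    "position_coverage",
    "write_frames",
    "read_frames",
]


def write_session(session: BehaviorSession, path: str | Path) -> None:
    """Write the behavior table, with session metadata (arena geometry,
    bin width) on a leading comment line."""
    body = session.to_frame().to_csv(sep="\t", index=False,
                                     float_format="%.6f")
    meta = json.dumps({k: v for k, v in session.meta.items()
                       if isinstance(v, (int, float, str, list, tuple))})
    Path(path).write_text(f"# meta: {meta}\n{body}")


def write_spikes(spikes: SpikeCountSeries, path: str | Path) -> None:
    spikes.to_frame().to_csv(path, sep="\t", index=False)


def position_coverage(session: BehaviorSession, bin_cm: float = 6.25) -> float:
    """Fraction of arena position bins visited (2-D sessions) or of
    track bins visited (virtual sessions).

    Bin extents come from the recorded arena geometry in
    ``session.meta`` when available, else from the data span.
    """
    arena = session.meta.get("arena")
    if "B_x" in session.channels:
        x, y = session.channels["B_x"], session.channels["B_y"]
        if arena and arena[0] == "open_field":
            ex, ey = (0.0, float(arena[1])), (0.0, float(arena[2]))
        else:
            ex, ey = (x.min(), x.max()), (y.min(), y.max())
        nx = max(1, int(np.ceil((ex[1] - ex[0]) / bin_cm)))
        ny = max(1, int(np.ceil((ey[1] - ey[0]) / bin_cm)))
        hist, _, _ = np.histogram2d(x, y, bins=[nx, ny], range=[ex, ey])
        return float((hist > 0).mean())
    pos = session.channels["B"]
    if arena and arena[0] == "vr_track":
        extent = (0.0, float(arena[1]))
    else:
        extent = (pos.min(), pos.max())
    nb = max(1, int(np.ceil((extent[1] - extent[0]) / bin_cm)))
    hist, _ = np.histogram(pos, bins=nb, range=extent)
    return float((hist > 0).mean())


def load_session(
    behavior_path: str | Path,
    spikes_path: str | Path | None = None,
    dt: float = 0.02,
    coverage_threshold: float = 0.7,
) -> tuple[BehaviorSession, SpikeCountSeries | None]:
    """Load a behavior table and optional aligned spike table.

    Validates the header, time monotonicity, units (azimuth within
    [0, 360), non-negative speed) and row alignment, and logs a warning
    when position coverage falls below the 70% inclusion rule.
    """
    meta: dict = {}
    with open(behavior_path) as fh:
        first = fh.readline()
    if first.startswith("# meta:"):
        meta = json.loads(first[len("# meta:"):])
    df = pd.read_csv(behavior_path, sep="\t", comment="#")
    if "time_s" not in df.columns:
        raise ValueError(
            f"{behavior_path}: header must contain 'time_s'; "
            f"got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{behavior_path}: non-monotone timestamps")
    if "B_s" in df.columns and np.nanmin(df["B_s"].to_numpy(float)) < 0:
        raise ValueError(f"{behavior_path}: negative body speed")
    session = BehaviorSession.from_frame(df, meta=meta)
    if "B_x" in session.channels or "B" in session.channels:
        cov = position_coverage(session)
        session.meta["position_coverage"] = cov
        if cov < coverage_threshold:
            log.warning(
                "session covered %.0f%% of position bins "
                "(< %.0f%% inclusion rule)", 100 * cov,
                100 * coverage_threshold,
            )
    spikes = None
    if spikes_path is not None:
        sdf = pd.read_csv(spikes_path, sep="\t")
        if len(sdf) != session.n_samples:
            raise ValueError(
                f"spike table has {len(sdf)} rows but behavior has "
                f"{session.n_samples}; tables must align row-for-row"
            )
        arr = sdf.to_numpy()
        if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
            raise ValueError("spike counts must be non-negative integers")
        spikes = SpikeCountSeries.from_frame(sdf, dt=dt)
    return session, spikes


def write_frames(frames: np.ndarray, directory: str | Path) -> list[Path]:
    """Write an 8-bit grayscale frame stack as numbered PNGs."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.asarray(frames, dtype=np.uint8)):
        p = directory / f"frame_{i:05d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_frames(directory: str | Path) -> np.ndarray:
    """Read a numbered PNG frame stack back into (n, rows, cols) uint8."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files under {directory}")
    return np.stack([iio.imread(p) for p in paths])


def write_fit(fit_result, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_result.to_dict(), indent=1))


def read_fit(path: str | Path):
    from .model import LNModelFit

    d = json.loads(Path(path).read_text())
    return LNModelFit(
        variables=d["variables"],
        b0=d["b0"],
        weights={k: np.array(v) for k, v in d["weights"].items()},
        beta=d.get("beta", 1.0),
        converged=d.get("converged", True),
        fold_lli=None if d.get("fold_lli") is None else np.array(d["fold_lli"]),
        fold_lli_per_spike=(
            None if d.get("fold_lli_per_spike") is None
            else np.array(d["fold_lli_per_spike"])
        ),
    )
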