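"""Core in-memory containers: behavior time series and binned spikes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical channel order used when writing session tables
CHANNEL_ORDER = [
    "B_x", "B_y", "B", "B_s", "H_a", "H_p", "H_r",
    "dH_a", "dH_p", "dH_r", "E_h", "E_v", "dE_h", "dE_v",
]


@dataclass
class BehaviorSession:
    """Uniformly sampled multichannel behavior time series.

    Channels are keyed by variable symbol (``B_x``/``B_y`` or ``B`` for
    virtual-track position, ``B_s`` speed, ``H_a`` azimuth in [0, 360),
    ``H_p``/``H_r`` pitch/roll in degrees, ``dH_*`` angular velocities in
    deg/s, ``E_h``/``E_v`` eye position in % eye width, ``dE_*`` eye
    velocity in % eye width / s).  A per-channel boolean validity mask
    marks samples excluded from every downstream fit.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    valid: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        for k, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise ValueError(f"channel {k}: length {v.shape} != {n}")
            self.channels[k] = v
        for k, m in self.valid.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != (n,):
                raise ValueError(f"mask {k}: length mismatch")
            self.valid[k] = m
        if "H_a" in self.channels:
            ha = self.channels["H_a"]
            if np.any((ha < 0) | (ha >= 360)):
                self.channels["H_a"] = np.mod(ha, 360.0)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        if self.time.size < 2:
            return float(self.meta.get("dt", 0.02))
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return self.time[-1] - self.time[0] + self.dt

    def validity(self, symbol: str) -> np.ndarray:
        mask = self.valid.get(symbol)
        if mask is None:
            return np.ones(self.n_samples, dtype=bool)
        return mask

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time}
        order = [c for c in CHANNEL_ORDER if c in self.channels]
        order += [c for c in sorted(self.channels) if c not in order]
        for c in order:
            cols[c] = self.channels[c].copy()
            cols[c][~self.validity(c)] = np.nan
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "BehaviorSession":
        time = df["time_s"].to_numpy(float)
        channels, valid = {}, {}
        for c in df.columns:
            if c == "time_s":
                continue
            v = df[c].to_numpy(float)
            mask = ~np.isnan(v)
            channels[c] = np.nan_to_num(v)
            if not mask.all():
                valid[c] = mask
        return cls(time, channels, valid, meta or {})


@dataclass
class SpikeCountSeries:
    """Per-cell spike counts in fixed-width time bins aligned to a session."""

    counts: np.ndarray  # (n_cells, n_bins) non-negative integers
    dt: float = 0.02
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("spike counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(self.counts.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def cell(self, i: int) -> np.ndarray:
        return self.counts[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.T, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: float = 0.02) -> "SpikeCountSeries":
        return cls(df.to_numpy().T, dt=dt, cell_ids=list(df.columns))
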