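"""Cardinal-spline basis expansion of behavioral variables.

Each behavioral variable is represented at every time bin by an
"animal-state" vector: a sparse row with four (sixteen for 2-D position)
non-zero cardinal-spline weights placed at the control points bracketing
the current variable value.  For a value ``y`` between control points
``z_j`` and ``z_{j+1}`` the fractional position is

    alpha = (y - z_j) / (z_{j+1} - z_j)

and the weights at control points ``j-1, j, j+1, j+2`` are

    [alpha^3, alpha^2, alpha, 1] . M(s)

with the 4x4 cardinal-spline (Catmull-Rom family) matrix ``M(s)`` and
tension parameter ``s``.  The rows of the expansion form a partition of
unity: the four weights always sum to exactly 1, so a constant weight
vector produces a constant rate contribution.

Circular variables (azimuth head direction, virtual-track position) wrap
their control-point indices modulo the number of bins.  Non-circular
variables get two phantom control points, one beyond each end of the
binned range, so the ``j-1`` and ``j+2`` indices always exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "spline_matrix",
    "spline_weights",
    "VariableConfig",
    "Position2DConfig",
    "design_block",
    "DesignMatrix",
    "assemble_design",
]


def spline_matrix(s: float) -> np.ndarray:
    """The 4x4 cardinal-spline blending matrix ``M(s)`` for tension ``s``."""
    return np.array(
        [
            [-s, 2.0 - s, s - 2.0, s],
            [2.0 * s, s - 3.0, 3.0 - 2.0 * s, -s],
            [-s, 0.0, s, 0.0],
            [0.0, 1.0, 0.0, 0.0],
        ]
    )


def spline_weights(alpha: np.ndarray, s: float) -> np.ndarray:
    """Weights at control points ``(j-1, j, j+1, j+2)`` for fractional
    positions ``alpha`` in [0, 1].

    Returns an array of shape ``(*alpha.shape, 4)``; each row sums to 1.
    """
    alpha = np.asarray(alpha, dtype=float)
    powers = np.stack(
        [alpha**3, alpha**2, alpha, np.ones_like(alpha)], axis=-1
    )
    return powers @ spline_matrix(s)


@dataclass
class VariableConfig:
    """Binning / basis specification for one scalar behavioral variable.

    Parameters
    ----------
    symbol:
        Variable name (``"H_p"``, ``"B_s"``, ...).
    knots:
        Ascending control-point values.  For circular variables these are
        the bin anchors over one period (the last interval wraps around).
    circular:
        Whether the variable lives on a circle (azimuth head direction,
        virtual-track position).
    period:
        Period of a circular variable (360 for angles, track length for
        virtual position).  Required when ``circular``.
    s:
        Spline tension; the analysis is insensitive over 0.5-0.7.
    percentile_window:
        (low, high) percentile bounds used to restrict model input to
        well-sampled behavioral epochs (2.5/97.5 open field, 1/99
        head-fixed).  ``None`` disables windowing (circular variables).
    """

    symbol: str
    knots: np.ndarray
    circular: bool = False
    period: float | None = None
    s: float = 0.6
    percentile_window: tuple[float, float] | None = (2.5, 97.5)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 1 or self.knots.size < 4:
            raise ValueError(
                f"{self.symbol}: need >= 4 control points, got {self.knots.size}"
            )
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError(f"{self.symbol}: knots must be strictly increasing")
        if self.circular and self.period is None:
            raise ValueError(f"{self.symbol}: circular variable needs a period")
        if not 0.0 < self.s < 1.0:
            raise ValueError("spline tension s must lie in (0, 1)")

    @classmethod
    def linear(
        cls,
        symbol: str,
        low: float,
        high: float,
        n_bins: int,
        s: float = 0.6,
        percentile_window: tuple[float, float] | None = (2.5, 97.5),
    ) -> "VariableConfig":
        return cls(
            symbol,
            np.linspace(low, high, n_bins),
            circular=False,
            s=s,
            percentile_window=percentile_window,
        )

    @classmethod
    def circular_var(
        cls, symbol: str, period: float, n_bins: int, s: float = 0.6
    ) -> "VariableConfig":
        return cls(
            symbol,
            np.linspace(0.0, period, n_bins, endpoint=False),
            circular=True,
            period=period,
            s=s,
            percentile_window=None,
        )

    @property
    def n_params(self) -> int:
        """Length of the animal-state vector (phantom points included)."""
        if self.circular:
            return self.knots.size
        return self.knots.size + 2

    def state_vectors(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices (n, 4) and weights (n, 4) of the basis expansion.

        Values outside the knot range of a non-circular variable raise;
        callers mask those samples first.
        """
        values = np.asarray(values, dtype=float)
        z = self.knots
        if self.circular:
            vals = np.mod(values - z[0], self.period) + z[0]
            # interval index within the wrapped knot sequence
            j = np.searchsorted(z, vals, side="right") - 1
            j = np.clip(j, 0, z.size - 1)
            z_next = np.where(j + 1 < z.size, z[np.minimum(j + 1, z.size - 1)],
                              z[0] + self.period)
            width = z_next - z[j]
            alpha = (vals - z[j]) / width
            w = spline_weights(alpha, self.s)
            idx = (j[:, None] + np.arange(-1, 3)[None, :]) % z.size
            return idx, w
        if np.any(values < z[0] - 1e-12) or np.any(values > z[-1] + 1e-12):
            raise ValueError(
                f"{self.symbol}: values outside knot range "
                f"[{z[0]}, {z[-1]}]; mask them before expansion"
            )
        vals = np.clip(values, z[0], z[-1])
        j = np.searchsorted(z, vals, side="right") - 1
        j = np.clip(j, 0, z.size - 2)
        alpha = (vals - z[j]) / (z[j + 1] - z[j])
        w = spline_weights(alpha, self.s)
        # +1 shifts into the phantom-extended index space [0, n_knots + 2)
        idx = j[:, None] + np.arange(-1, 3)[None, :] + 1
        return idx, w


@dataclass
class Position2DConfig:
    """Tensor-product spline basis for 2-D open-field body position.

    The 1-D expansion is applied independently to x and y and combined by
    outer product, giving 16 active weights per sample.  Partition of
    unity carries over from the 1-D rows.
    """

    symbol: str
    x: VariableConfig
    y: VariableConfig

    @classmethod
    def for_arena(
        cls,
        width: float,
        height: float,
        bins_per_100cm: int = 15,
        s: float = 0.6,
        symbol: str = "B",
    ) -> "Position2DConfig":
        nx = max(4, int(round(width * bins_per_100cm / 100.0)))
        ny = max(4, int(round(height * bins_per_100cm / 100.0)))
        return cls(
            symbol,
            VariableConfig.linear(f"{symbol}_x", 0.0, width, nx, s, None),
            VariableConfig.linear(f"{symbol}_y", 0.0, height, ny, s, None),
        )

    @property
    def circular(self) -> bool:
        return False

    @property
    def percentile_window(self) -> None:
        return None

    @property
    def n_params(self) -> int:
        return self.x.n_params * self.y.n_params

    def state_vectors(
        self, values: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 2:
            raise ValueError(f"{self.symbol}: expected (n, 2) xy values")
        ix, wx = self.x.state_vectors(values[:, 0])
        iy, wy = self.y.state_vectors(values[:, 1])
        w = (wx[:, :, None] * wy[:, None, :]).reshape(values.shape[0], 16)
        idx = (ix[:, :, None] * self.y.n_params + iy[:, None, :]).reshape(
            values.shape[0], 16
        )
        return idx, w


def design_block(values: np.ndarray, config) -> sp.csr_matrix:
    """Sparse (T x W) design block for one variable."""
    idx, w = config.state_vectors(values)
    n, k = idx.shape
    indptr = np.arange(0, n * k + 1, k)
    mat = sp.csr_matrix(
        (w.ravel(), idx.ravel(), indptr), shape=(n, config.n_params)
    )
    mat.sum_duplicates()
    return mat


@dataclass
class DesignMatrix:
    """Stacked animal-state design for one session.

    ``blocks`` maps variable symbol to its (T_retained x W_i) sparse
    block; ``retained`` indexes the time bins that survived the
    percentile windows and validity masks.
    """

    blocks: dict[str, sp.csr_matrix]
    configs: dict[str, object]
    retained: np.ndarray
    n_total: int
    dt: float = 0.02

    @property
    def n_retained(self) -> int:
        return self.retained.size

    def stacked(self, symbols: list[str]) -> sp.csr_matrix:
        return sp.hstack([self.blocks[s] for s in symbols], format="csr")

    def slices(self, symbols: list[str]) -> dict[str, slice]:
        out, start = {}, 0
        for s in symbols:
            w = self.blocks[s].shape[1]
            out[s] = slice(start, start + w)
            start += w
        return out


def _channel_values(session, config) -> tuple[np.ndarray, np.ndarray]:
    """(values, validity) for a config, joining x/y channels for 2-D position."""
    if isinstance(config, Position2DConfig):
        vx = session.channels[f"{config.symbol}_x"]
        vy = session.channels[f"{config.symbol}_y"]
        valid = session.validity(f"{config.symbol}_x") & session.validity(
            f"{config.symbol}_y"
        )
        return np.column_stack([vx, vy]), valid
    return session.channels[config.symbol], session.validity(config.symbol)


def assemble_design(session, configs: list, min_bins: int = 1000) -> DesignMatrix:
    """Build the design matrix restricted to well-sampled epochs.

    A time bin is retained when every modeled variable is valid and lies
    inside its percentile window (non-circular variables only) and inside
    its knot range.  Raises if fewer than ``min_bins`` bins survive.
    """
    n = session.n_samples
    keep = np.ones(n, dtype=bool)
    for cfg in configs:
        vals, valid = _channel_values(session, cfg)
        keep &= valid
        if isinstance(cfg, Position2DConfig):
            keep &= (
                (vals[:, 0] >= cfg.x.knots[0])
                & (vals[:, 0] <= cfg.x.knots[-1])
                & (vals[:, 1] >= cfg.y.knots[0])
                & (vals[:, 1] <= cfg.y.knots[-1])
            )
            continue
        if cfg.percentile_window is not None:
            lo, hi = np.percentile(
                vals[valid], list(cfg.percentile_window)
            )
            keep &= (vals >= lo) & (vals <= hi)
        if not cfg.circular:
            keep &= (vals >= cfg.knots[0]) & (vals <= cfg.knots[-1])
    retained = np.flatnonzero(keep)
    if retained.size < min_bins:
        raise ValueError(
            f"only {retained.size} time bins retained (< {min_bins}); "
            "session too short or windows too tight"
        )
    blocks = {}
    for cfg in configs:
        vals, _ = _channel_values(session, cfg)
        blocks[cfg.symbol] = design_block(vals[retained], cfg)
    return DesignMatrix(
        blocks=blocks,
        configs={c.symbol: c for c in configs},
        retained=retained,
        n_total=n,
        dt=session.dt,
    )


def knots_from_data(
    values: np.ndarray,
    n_bins: int | None = None,
    bin_width: float | None = None,
    percentile_window: tuple[float, float] = (2.5, 97.5),
) -> np.ndarray:
    """Control points spanning the windowed range of observed values.

    Either a bin count or a bin width (speed uses 5 cm/s) must be given.
    """
    lo, hi = np.percentile(values, list(percentile_window))
    if bin_width is not None:
        n_bins = max(4, int(np.ceil((hi - lo) / bin_width)) + 1)
    if n_bins is None:
        raise ValueError("give n_bins or bin_width")
    return np.linspace(lo, hi, max(4, n_bins))
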