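"""Empirical mode decomposition: extrema, envelopes, sifting, IMF extraction.

EMD adaptively splits a series ``X(t)`` into intrinsic mode functions (IMFs)
``c_1 .. c_N`` plus a residual ``r_N`` with ``X = sum(c_j) + r_N`` holding
element-wise to floating precision.  An IMF oscillates about zero: its extrema
and zero-crossing counts differ by at most one, and the mean of its upper
(through maxima) and lower (through minima) cubic-spline envelopes is zero.

Sifting uses a fixed iteration count (default 10) rather than a convergence
test; the fixed count makes the decomposition unique and reproducible.
Envelope splines are natural cubics through the extrema after mirroring the
two extrema nearest each end across the end point, which tames the spline's
end swings — the known failure mode of envelope-based decompositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .timeseries import TimeSeries

__all__ = [
    "SiftConfig",
    "IMFSet",
    "NotSiftableError",
    "find_extrema",
    "count_zero_crossings",
    "envelope_mean",
    "sift",
    "emd",
    "write_imfset",
    "read_imfset",
]


class NotSiftableError(ValueError):
    """Raised when a signal lacks the extrema needed to build envelopes."""


@dataclass(frozen=True)
class SiftConfig:
    """Sifting controls.

    sift_iterations : fixed number of envelope-subtraction rounds per IMF.
    max_imfs : cap on extracted IMFs (None = until the remainder is
        monotone/flat).
    boundary_mode : end-extension policy for envelope knots; only "mirror"
        is implemented (hook for experimentation).
    """

    sift_iterations: int = 10
    max_imfs: int | None = None
    boundary_mode: str = "mirror"

    def __post_init__(self) -> None:
        if self.sift_iterations < 1:
            raise ValueError("sift_iterations must be >= 1")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1 or None")
        if self.boundary_mode != "mirror":
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass(frozen=True)
class IMFSet:
    """Ordered IMFs ``c_1..c_N`` plus residual for one decomposed series."""

    imfs: np.ndarray = field(repr=False)  # shape (N, n); N may be 0
    residual: np.ndarray = field(repr=False)  # shape (n,)
    dates: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        imfs = np.atleast_2d(np.asarray(self.imfs, dtype=float))
        residual = np.asarray(self.residual, dtype=float)
        if imfs.size == 0:
            imfs = imfs.reshape(0, residual.size)
        if imfs.shape[1] != residual.size:
            raise ValueError("IMF length does not match residual length")
        object.__setattr__(self, "imfs", imfs)
        object.__setattr__(self, "residual", residual)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    @property
    def source_length(self) -> int:
        return self.residual.size

    def reconstruct(self) -> np.ndarray:
        """Element-wise sum of all IMFs and the residual."""
        return self.imfs.sum(axis=0) + self.residual

    def to_frame(self) -> pd.DataFrame:
        cols = {f"imf{k + 1}": self.imfs[k] for k in range(self.n_imfs)}
        cols["residual"] = self.residual
        df = pd.DataFrame(cols)
        if self.dates is not None:
            df.insert(0, "date", self.dates.strftime("%Y-%m-%d"))
        return df


def find_extrema(values) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    A flat plateau bounded on both sides by lower (resp. higher) neighbours
    counts as one extremum at the plateau's first index.  Endpoints, and
    plateaus touching an endpoint, are never extrema.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sequence of length >= 3")
    # compress equal-value runs so a plateau is a single candidate
    keep = np.empty(x.size, dtype=bool)
    keep[0] = True
    np.not_equal(x[1:], x[:-1], out=keep[1:])
    starts = np.nonzero(keep)[0]
    if starts.size < 3:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    rising = x[starts[1:]] > x[starts[:-1]]  # sign of each run-to-run step
    maxima = starts[np.nonzero(rising[:-1] & ~rising[1:])[0] + 1]
    minima = starts[np.nonzero(~rising[:-1] & rising[1:])[0] + 1]
    return maxima, minima


def count_zero_crossings(values) -> int:
    """Sign changes between consecutive nonzero samples.

    A run of exact zeros counts as a single crossing only when the signs
    flanking the run differ.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    s = np.sign(x[x != 0.0])
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _mirror_knots(idx: np.ndarray, val: np.ndarray, n: int):
    """Reflect the two extrema nearest each end across the end points."""
    left_i, left_v = -idx[1::-1], val[1::-1]
    right_i, right_v = 2 * (n - 1) - idx[:-3:-1], val[:-3:-1]
    knots = np.concatenate([left_i, idx, right_i])
    knot_vals = np.concatenate([left_v, val, right_v])
    # mirroring can duplicate a position when an extremum sits at an end
    knots, uniq = np.unique(knots, return_index=True)
    return knots, knot_vals[uniq]


def envelope_mean(values, maxima=None, minima=None) -> np.ndarray:
    """Pointwise mean of the upper and lower cubic-spline envelopes.

    The upper envelope interpolates the local maxima, the lower the local
    minima, each as a natural cubic spline over mirror-extended knots.
    Raises :class:`NotSiftableError` with fewer than two maxima or minima.
    """
    x = np.asarray(values, dtype=float)
    if maxima is None or minima is None:
        maxima, minima = find_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        raise NotSiftableError(
            f"need >= 2 maxima and >= 2 minima (got {len(maxima)}, {len(minima)})"
        )
    n = x.size
    t = np.arange(n)
    upper_k, upper_v = _mirror_knots(np.asarray(maxima), x[maxima], n)
    lower_k, lower_v = _mirror_knots(np.asarray(minima), x[minima], n)
    upper = CubicSpline(upper_k, upper_v, bc_type="natural")(t)
    lower = CubicSpline(lower_k, lower_v, bc_type="natural")(t)
    return 0.5 * (upper + lower)


def sift(values, config: SiftConfig = SiftConfig()) -> np.ndarray:
    """Extract one IMF candidate by repeated envelope-mean subtraction.

    Runs exactly ``config.sift_iterations`` rounds of ``h <- h - m(h)`` where
    ``m`` is the envelope mean; no convergence test.  If the signal becomes
    non-siftable mid-loop the current ``h`` is returned with a warning.
    """
    h = np.array(values, dtype=float)
    for _ in range(config.sift_iterations):
        try:
            m = envelope_mean(h)
        except NotSiftableError:
            warnings.warn(
                "signal became non-siftable before the iteration budget; "
                "returning the current candidate",
                stacklevel=2,
            )
            break
        h -= m
    return h


def _is_siftable(x: np.ndarray) -> bool:
    if x.size < 3:
        return False
    maxima, minima = find_extrema(x)
    return len(maxima) >= 2 and len(minima) >= 2


def emd(series, config: SiftConfig = SiftConfig()) -> IMFSet:
    """Full empirical mode decomposition.

    IMFs are peeled off successive remainders until the remainder has fewer
    than two maxima or fewer than two minima; that remainder is the residual.
    Accepts a :class:`TimeSeries` or a bare array.

    The element-wise sum of the returned IMFs and residual equals the input
    exactly up to floating rounding (each IMF is subtracted, never modelled).
    """
    if isinstance(series, TimeSeries):
        x, dates = series.values, series.dates
    else:
        x, dates = np.asarray(series, dtype=float), None
        if x.ndim != 1:
            raise ValueError("series must be 1-D")
    remainder = x.copy()
    imfs: list[np.ndarray] = []
    cap = config.max_imfs if config.max_imfs is not None else x.size
    while len(imfs) < cap and _is_siftable(remainder):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imf = sift(remainder, config)
        if not np.any(imf):
            break  # degenerate: sifting extracted nothing
        imfs.append(imf)
        remainder = remainder - imf
    stacked = np.array(imfs) if imfs else np.empty((0, x.size))
    return IMFSet(imfs=stacked, residual=remainder, dates=dates)


def write_imfset(imfset: IMFSet, path) -> None:
    """Write as wide CSV ``date,imf1,...,imfN,residual`` (full precision)."""
    imfset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_imfset(path) -> IMFSet:
    """Read the wide CSV written by :func:`write_imfset`."""
    df = pd.read_csv(path, float_precision="round_trip")
    imf_cols = sorted(
        (c for c in df.columns if c.startswith("imf")), key=lambda c: int(c[3:])
    )
    dates = None
    if "date" in df.columns:
        dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    imfs = df[imf_cols].to_numpy(dtype=float).T if imf_cols else np.empty((0, len(df)))
    return IMFSet(imfs=imfs, residual=df["residual"].to_numpy(dtype=float), dates=dates)
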