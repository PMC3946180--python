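"""From a classified decomposition to epidemiological outputs.

The significance test splits the mortality decomposition at mode ``m``:

    X(t) = sum_{i<=m} c_i(t)   +   [ sum_{j>m} c_j(t) + r_N(t) ]
           non-trend (detail)       trend ("normal" mortality)

The excess mortality of an event window is the sum of the non-trend series
over its days.  The trend series is the expected mortality under normal
conditions, so the daily log relative risk is ln(X(t) / trend(t)); ordinary
least-squares regressions of logRR on temperature (raw or anomaly), PM10 and
O3 quantify the association between excess risk and its drivers.  A classical
moving-average seasonal decomposition is provided as the comparator whose
end-window information loss motivates the adaptive decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .emd import IMFSet, SiftConfig, emd
from .eemd import EEMDConfig, batch_eemd
from .significance import TrendPartition, classify_trend
from .spectral import average_period
from .timeseries import TimeSeries

__all__ = [
    "EventWindow",
    "ExcessResult",
    "RegressionSpec",
    "RegressionResult",
    "partition_series",
    "excess_deaths",
    "log_relative_risk",
    "fit_excess_regression",
    "classical_decompose",
    "match_temperature_partition",
    "run_excess_pipeline",
]


@dataclass(frozen=True)
class EventWindow:
    """An inclusive date window [start, end] (both ends counted)."""

    start: pd.Timestamp
    end: pd.Timestamp
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.start > self.end:
            raise ValueError(f"window start {self.start.date()} after end {self.end.date()}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class ExcessResult:
    """Window excess deaths plus the series behind them."""

    window: EventWindow
    daily_excess: pd.Series = field(repr=False)  # non-trend restricted to window
    total_excess: float = 0.0
    total_excess_rounded: int = 0
    non_trend: np.ndarray = field(repr=False, default=None)
    trend: np.ndarray = field(repr=False, default=None)
    log_rr: np.ndarray = field(repr=False, default=None)
    partition: TrendPartition | None = None


@dataclass(frozen=True)
class RegressionSpec:
    """Design of one excess-risk regression: logRR ~ covariates over window."""

    covariates: tuple[str, ...]  # subset of {"maxT", "maxT_non_trend", "PM10", "O3"}
    window: EventWindow

    def __post_init__(self) -> None:
        allowed = {"maxT", "maxT_non_trend", "PM10", "O3"}
        if not self.covariates:
            raise ValueError("need at least one covariate")
        unknown = set(self.covariates) - allowed
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}")


@dataclass(frozen=True)
class RegressionResult:
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    model_p_value: float  # overall F-test
    adjusted_r_squared: float
    n_obs: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def partition_series(
    imfset: IMFSet, partition: TrendPartition
) -> tuple[np.ndarray, np.ndarray]:
    """Non-trend (sum of modes 1..m) and trend (modes m+1..N plus residual)."""
    if partition.n_imfs != imfset.n_imfs:
        raise ValueError(
            f"partition is for N={partition.n_imfs} but decomposition has "
            f"N={imfset.n_imfs}"
        )
    m = partition.m
    non_trend = imfset.imfs[:m].sum(axis=0)
    trend = imfset.imfs[m:].sum(axis=0) + imfset.residual
    return non_trend, trend


def excess_deaths(
    non_trend: TimeSeries, window: EventWindow
) -> tuple[float, int]:
    """Sum of the daily non-trend series over the window (inclusive).

    Returns the raw total and its nearest integer (half away from zero).
    """
    sl = non_trend.window_slice(window.start, window.end)
    total = float(non_trend.values[sl].sum())
    return total, _round_half_away(total)


def log_relative_risk(
    values: np.ndarray, trend: np.ndarray, zero_correction: bool = False
) -> np.ndarray:
    """Daily ``ln(X(t) / trend(t))`` — relative risk on the natural-log scale.

    The trend must be strictly positive (it is an expected death count).
    Zero observed counts give ``-inf`` with a warning; with
    ``zero_correction`` a +0.5 continuity correction is applied to the
    numerator on those days instead.
    """
    x = np.asarray(values, dtype=float)
    trend = np.asarray(trend, dtype=float)
    bad = np.nonzero(trend <= 0)[0]
    if bad.size:
        raise ValueError(
            f"trend must be strictly positive; first violation at index {bad[0]} "
            f"(trend={trend[bad[0]]:g})"
        )
    zeros = x == 0
    if zeros.any():
        if zero_correction:
            x = np.where(zeros, x + 0.5, x)
        else:
            warnings.warn(
                f"{int(zeros.sum())} zero-count day(s) give -inf logRR; "
                "pass zero_correction=True for a +0.5 continuity correction",
                stacklevel=2,
            )
    with np.errstate(divide="ignore"):
        return np.log(x / trend)


def fit_excess_regression(
    spec: RegressionSpec,
    log_rr: TimeSeries,
    covariates: dict[str, TimeSeries],
) -> RegressionResult:
    """OLS fit of logRR on the requested covariates over the window.

    Intercept included; p-values are two-sided t-tests; adjusted R² is the
    usual 1 - (1-R²)(n-1)/(n-p-1); the model p-value is the overall F-test.
    """
    missing = [c for c in spec.covariates if c not in covariates]
    if missing:
        raise ValueError(f"covariate series missing: {missing}")
    sl = log_rr.window_slice(spec.window.start, spec.window.end)
    y = log_rr.values[sl]
    cols = {}
    for name in spec.covariates:
        cov = covariates[name]
        cols[name] = cov.values[cov.window_slice(spec.window.start, spec.window.end)]
    X = pd.DataFrame(cols)
    n, p = X.shape
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} observations in window, got {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("logRR contains non-finite values inside the window")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, Xc).fit()
    return RegressionResult(
        coefficients=dict(fit.params),
        std_errors=dict(fit.bse),
        p_values=dict(fit.pvalues),
        model_p_value=float(fit.f_pvalue),
        adjusted_r_squared=float(fit.rsquared_adj),
        n_obs=n,
    )


def classical_decompose(
    values: np.ndarray, frequency: int = 365
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classical moving-average seasonal decomposition (comparator).

    trend : centred moving average of window ``frequency`` (half-weight end
        terms when the window is even); NaN for ``frequency // 2`` samples at
        each end — the end-window information loss.
    seasonal : per-day-of-cycle average of (X - trend), recentred to mean
        zero and tiled over the whole span.
    random : X - trend - seasonal (NaN where trend is undefined).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * frequency:
        raise ValueError(f"need at least two full cycles (n >= {2 * frequency})")
    half = frequency // 2
    if frequency % 2:
        w = np.full(frequency, 1.0 / frequency)
    else:
        w = np.full(frequency + 1, 1.0 / frequency)
        w[0] = w[-1] = 0.5 / frequency
    trend = np.convolve(x, w, mode="same")
    trend[:half] = np.nan
    trend[n - half :] = np.nan
    detrended = x - trend
    phase = np.arange(n) % frequency
    seasonal_cycle = np.empty(frequency)
    for d in range(frequency):
        vals = detrended[phase == d]
        seasonal_cycle[d] = np.nanmean(vals)
    seasonal_cycle -= seasonal_cycle.mean()
    seasonal = seasonal_cycle[phase]
    random = x - trend - seasonal
    return trend, seasonal, random


def match_temperature_partition(
    temp_imfset: IMFSet, mort_imfset: IMFSet, mort_partition: TrendPartition
) -> int:
    """Split index for the temperature decomposition.

    Temperature modes are grouped into the non-trend block when their
    average periods fall inside the mortality non-trend frequency band: the
    cutoff is the geometric midpoint between the average periods of
    mortality modes m and m+1 (or twice the period of mode m when m = N).
    Falls back to the mortality count m when no temperature mode qualifies.
    """
    n_m = mort_imfset.source_length
    m = mort_partition.m
    try:
        p_m = average_period(mort_imfset.imfs[m - 1], n_m)
        if m < mort_imfset.n_imfs:
            p_next = average_period(mort_imfset.imfs[m], n_m)
            cutoff = math.sqrt(p_m * p_next)
        else:
            cutoff = 2.0 * p_m
    except ValueError:
        return min(m, temp_imfset.n_imfs)
    n_t = temp_imfset.source_length
    m_t = 0
    for k in range(temp_imfset.n_imfs):
        try:
            if average_period(temp_imfset.imfs[k], n_t) < cutoff:
                m_t = k + 1  # contiguous block from mode 1
            else:
                break
        except ValueError:
            break
    return m_t if m_t >= 1 else min(m, temp_imfset.n_imfs)


def run_excess_pipeline(
    series: TimeSeries,
    window: EventWindow,
    method: str = "emd",
    level: int = 95,
    mode: str = "auto",
    n_fit_imfs: int = 3,
    sift_config: SiftConfig = SiftConfig(),
    eemd_config: EEMDConfig = EEMDConfig(),
    zero_correction: bool = False,
) -> ExcessResult:
    """Decompose, classify, partition, and sum excess deaths over a window."""
    if method == "emd":
        imfset = emd(series, sift_config)
    elif method == "eemd":
        imfset = batch_eemd(series, sift_config, eemd_config)
    else:
        raise ValueError(f"method must be 'emd' or 'eemd', got {method!r}")
    partition, _ = classify_trend(imfset, level=level, mode=mode, n_fit_imfs=n_fit_imfs)
    non_trend, trend = partition_series(imfset, partition)
    nt_series = TimeSeries(series.dates, non_trend)
    total, rounded = excess_deaths(nt_series, window)
    sl = series.window_slice(window.start, window.end)
    daily = pd.Series(non_trend[sl], index=series.dates[sl], name="excess")
    log_rr = log_relative_risk(series.values, trend, zero_correction=zero_correction)
    return ExcessResult(
        window=window,
        daily_excess=daily,
        total_excess=total,
        total_excess_rounded=rounded,
        non_trend=non_trend,
        trend=trend,
        log_rr=log_rr,
        partition=partition,
    )
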