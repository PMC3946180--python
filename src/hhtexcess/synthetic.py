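"""Synthetic daily-mortality scenarios with known ground truth.

Every stage of the pipeline is testable without external data: the
generators here produce series with the statistical structure the method
assumes — a slowly drifting baseline, annual seasonality with a winter peak
(Southern-Hemisphere phase), white or serially-correlated noise, and short
additive heatwave death spikes with linked temperature anomalies.  Each
generator returns (or records) the injected components exactly, so recovery
tests compare pipeline output against known truth.

Noise is Gaussian by default, matching the white-noise theory behind the
significance test; a Poisson option exists for realism checks since real
daily death counts are integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "HeatwaveSpec",
    "MortalityScenario",
    "gen_white_noise",
    "gen_correlated_noise",
    "gen_mortality",
    "gen_intermittent",
]


def gen_white_noise(n: int, sd: float, seed: int) -> np.ndarray:
    """i.i.d. Gaussian noise, mean 0, SD ``sd``; deterministic given seed."""
    if n < 1 or sd <= 0:
        raise ValueError("need n >= 1 and sd > 0")
    return np.random.default_rng(seed).normal(0.0, sd, size=n)


def gen_correlated_noise(n: int, kind: str, param: float, seed: int) -> np.ndarray:
    """Serially correlated Gaussian noise with unit marginal variance.

    kind="ar1" : AR(1) recursion with stationary initialisation,
        ``param`` = lag-1 coefficient phi, |phi| < 1.
    kind="fgn" : fractional Gaussian noise via circulant embedding of the
        autocovariance ``gamma(h) = (|h+1|^2H - 2|h|^2H + |h-1|^2H)/2``,
        ``param`` = Hurst exponent H in (0, 1); H = 0.5 is white noise.
    """
    rng = np.random.default_rng(seed)
    if kind == "ar1":
        phi = float(param)
        if not abs(phi) < 1:
            raise ValueError("AR(1) needs |phi| < 1")
        z = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = z[0]  # stationary start: marginal variance 1
        c = np.sqrt(1.0 - phi**2)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + c * z[t]
        return x
    if kind == "fgn":
        H = float(param)
        if not 0 < H < 1:
            raise ValueError("fGn needs 0 < H < 1")
        h = np.arange(n + 1, dtype=float)
        gamma = 0.5 * (
            np.abs(h + 1) ** (2 * H) - 2 * np.abs(h) ** (2 * H) + np.abs(h - 1) ** (2 * H)
        )
        # circulant embedding (Davies-Harte): eigenvalues of the wrapped row
        row = np.concatenate([gamma, gamma[-2:0:-1]])
        lam = np.fft.rfft(row).real
        if lam.min() < -1e-8 * lam.max():
            raise ValueError(f"circulant embedding not nonnegative for H={H}")
        lam = np.clip(lam, 0.0, None)
        m = row.size
        z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
        z[0] = z[0].real * np.sqrt(2)
        z[-1] = z[-1].real * np.sqrt(2)
        spectrum = z * np.sqrt(lam / (2 * m))
        x = np.fft.irfft(spectrum, n=m) * m
        return x[:n]
    raise ValueError(f"unknown noise kind {kind!r}")


def _pulse(duration: int, total_mass: float, shape: str) -> np.ndarray:
    """Daily weights of a spike integrating (summing) to ``total_mass``."""
    if shape == "rectangular":
        w = np.ones(duration)
    elif shape == "triangular":
        w = duration / 2.0 - np.abs(np.arange(duration) - (duration - 1) / 2.0)
    else:
        raise ValueError(f"unknown spike shape {shape!r}")
    return w * (total_mass / w.sum())


@dataclass(frozen=True)
class HeatwaveSpec:
    """One injected heatwave: a short additive death spike plus a heat anomaly.

    start_day : offset (days) from the series start.
    duration : spike length in days.
    total_mass : excess deaths summed over the spike.
    shape : "triangular" (default) or "rectangular" pulse.
    anomaly_peak : peak maxT elevation in deg C over the window.
    """

    start_day: int
    duration: int
    total_mass: float
    shape: str = "triangular"
    anomaly_peak: float = 8.0


@dataclass(frozen=True)
class MortalityScenario:
    """Study conditions for one synthetic city.

    The defaults emulate an eight-year subtropical record: n = 2922 daily
    observations starting 1 July, ~30 deaths/day baseline with a slight
    upward drift, a 3-death winter-peaking annual cycle, white noise of
    SD 5, and one 6-day late-summer heatwave spike of 50 excess deaths
    (in the final year of the record) with a linked temperature anomaly.
    """

    n: int = 2922
    start_date: str = "1996-07-01"
    baseline: float = 30.0
    trend_slope: float = 0.001  # deaths/day drift (~3 deaths over 8 years)
    seasonal_amplitude: float = 3.0
    seasonal_period: float = 365.25
    noise_kind: str = "white"  # white | ar1 | fgn | poisson
    noise_params: dict = field(default_factory=lambda: {"sd": 5.0})
    heatwaves: tuple[HeatwaveSpec, ...] = (
        HeatwaveSpec(start_day=2788, duration=6, total_mass=50.0),
    )
    covariate_links: dict = field(default_factory=dict)  # e.g. {"maxT": 0.5}
    temp_base: float = 25.0
    temp_amplitude: float = 5.0
    temp_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        spans = sorted((h.start_day, h.start_day + h.duration) for h in self.heatwaves)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("heatwave windows must be disjoint")
        for h in self.heatwaves:
            if h.start_day < 0 or h.start_day + h.duration > self.n:
                raise ValueError("heatwave window outside the series range")


def gen_mortality(scenario: MortalityScenario):
    """Generate (mortality, maxT, PM10, O3, truth) for one scenario.

    mortality(t) = baseline + slope*t + A*cos(2*pi*t/period) + noise(t)
                   + spikes(t) [+ link coefficients * covariate anomalies].

    The cosine peaks at t = 0 and the series starts on 1 July, so the
    seasonal peak falls in mid-year — the Southern-Hemisphere winter.  maxT
    carries the opposite seasonal phase plus an anomaly elevated over the
    heatwave windows.  The truth record stores every injected component and
    the exact per-window spike masses.
    """
    sc = scenario
    t = np.arange(sc.n, dtype=float)
    baseline_trend = sc.baseline + sc.trend_slope * t
    seasonal = sc.seasonal_amplitude * np.cos(2 * np.pi * t / sc.seasonal_period)

    if sc.noise_kind == "white":
        noise = gen_white_noise(sc.n, sc.noise_params["sd"], sc.seed)
    elif sc.noise_kind == "ar1":
        noise = sc.noise_params["sd"] * gen_correlated_noise(
            sc.n, "ar1", sc.noise_params["phi"], sc.seed
        )
    elif sc.noise_kind == "fgn":
        noise = sc.noise_params["sd"] * gen_correlated_noise(
            sc.n, "fgn", sc.noise_params["hurst"], sc.seed
        )
    elif sc.noise_kind == "poisson":
        noise = np.zeros(sc.n)  # integer counts drawn at the end
    else:
        raise ValueError(f"unknown noise_kind {sc.noise_kind!r}")

    spikes = np.zeros(sc.n)
    anomaly = np.zeros(sc.n)
    window_masses = []
    for hw in sc.heatwaves:
        sl = slice(hw.start_day, hw.start_day + hw.duration)
        pulse = _pulse(hw.duration, hw.total_mass, hw.shape)
        spikes[sl] += pulse
        shape_unit = _pulse(hw.duration, 1.0, hw.shape)
        anomaly[sl] += hw.anomaly_peak * shape_unit / shape_unit.max()
        window_masses.append(float(pulse.sum()))

    rng = np.random.default_rng([sc.seed, 1])
    temp_seasonal = sc.temp_base - sc.temp_amplitude * np.cos(
        2 * np.pi * t / sc.seasonal_period
    )
    maxT = temp_seasonal + anomaly + rng.normal(0, sc.temp_noise_sd, sc.n)
    pm10 = np.clip(17.0 + rng.normal(0, 4.0, sc.n), 0, None)
    o3 = np.clip(15.0 + rng.normal(0, 4.0, sc.n), 0, None)

    mortality = baseline_trend + seasonal + noise + spikes
    for name, coef in sc.covariate_links.items():
        driver = {"maxT": anomaly, "PM10": pm10 - pm10.mean(), "O3": o3 - o3.mean()}[name]
        mortality = mortality + coef * driver

    if sc.noise_kind == "poisson":
        mortality = rng.poisson(np.clip(mortality, 0, None)).astype(float)

    clipped = mortality < 0
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} negative mortality value(s) clipped to 0",
            stacklevel=2,
        )
        mortality = np.clip(mortality, 0, None)

    dates = pd.date_range(sc.start_date, periods=sc.n, freq="D")
    truth = {
        "baseline_trend": baseline_trend,
        "seasonal": seasonal,
        "noise": noise,
        "spikes": spikes,
        "temp_anomaly": anomaly,
        "heatwaves": [
            {
                "start": str(dates[hw.start_day].date()),
                "end": str(dates[hw.start_day + hw.duration - 1].date()),
                "total_mass": mass,
            }
            for hw, mass in zip(sc.heatwaves, window_masses)
        ],
        "clipped_days": int(clipped.sum()),
    }
    return (
        TimeSeries(dates, mortality),
        TimeSeries(dates, maxT),
        TimeSeries(dates, pm10),
        TimeSeries(dates, o3),
        truth,
    )


def gen_intermittent(
    n: int = 512,
    carrier_period: float = 128.0,
    burst_period: float = 8.0,
    burst_windows: tuple[tuple[int, int], ...] = ((96, 160), (352, 416)),
    amplitudes: tuple[float, ...] = (0.8, 0.8),
    seed: int | None = None,
):
    """Mode-mixing fixture: a slow carrier plus confined high-frequency bursts.

    Returns ``(signal, truth)`` where truth holds the carrier and burst
    components separately.  Deterministic: ``seed`` is accepted for API
    symmetry but unused (no stochastic term).
    """
    if burst_period >= carrier_period:
        raise ValueError("burst_period must be smaller than carrier_period")
    if len(amplitudes) != len(burst_windows):
        raise ValueError("one amplitude per burst window")
    t = np.arange(n, dtype=float)
    carrier = np.sin(2 * np.pi * t / carrier_period)
    burst = np.zeros(n)
    for (s, e), amp in zip(burst_windows, amplitudes):
        if not (0 <= s < e <= n):
            raise ValueError(f"burst window ({s}, {e}) outside range")
        tt = np.arange(s, e, dtype=float)
        burst[s:e] += amp * np.sin(2 * np.pi * tt / burst_period)
    return carrier + burst, {"carrier": carrier, "burst": burst}
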