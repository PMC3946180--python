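"""Hilbert spectral analysis of IMFs.

The analytic signal of an IMF gives a physically meaningful instantaneous
amplitude (its modulus) and instantaneous frequency (the derivative of its
unwrapped phase).  These are only well defined for components that satisfy
the IMF criteria, which is why the decomposition stage enforces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .emd import find_extrema

__all__ = ["InstantaneousSpectrum", "instantaneous_spectrum", "average_period"]

_EDGE = 2  # samples masked at each end: phase differentiation is unreliable there


@dataclass(frozen=True)
class InstantaneousSpectrum:
    """Per-sample frequency (cycles/day) and amplitude for one IMF.

    ``valid`` is False on the edge samples and wherever the frequency is not
    finite.  Negative instantaneous frequencies — physically dubious samples
    that arise where the component locally fails the IMF criteria — are kept
    as computed and flagged in ``negative`` rather than clipped.
    """

    frequency: np.ndarray = field(repr=False)
    amplitude: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)

    @property
    def negative(self) -> np.ndarray:
        return self.valid & (self.frequency < 0)

    def to_frame(self, dates=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frequency": self.frequency,
                "amplitude": self.amplitude,
                "valid": self.valid,
            }
        )
        if dates is not None:
            df.insert(0, "date", pd.DatetimeIndex(dates).strftime("%Y-%m-%d"))
        return df


def instantaneous_spectrum(imf, dt: float = 1.0) -> InstantaneousSpectrum:
    """Analytic-signal amplitude and frequency of one IMF.

    Frequency is the centred finite difference of the unwrapped phase over
    ``2 * pi * dt`` (one-sided at the ends, which are masked anyway).  For a
    constant input the amplitude is 0 and every sample is masked.
    """
    x = np.asarray(imf, dtype=float)
    if x.ndim != 1 or x.size < 16:
        raise ValueError("need a 1-D IMF of length >= 16")
    if np.ptp(x) == 0.0:
        zero = np.zeros(x.size)
        return InstantaneousSpectrum(
            frequency=np.full(x.size, np.nan),
            amplitude=zero,
            valid=np.zeros(x.size, dtype=bool),
        )
    analytic = hilbert(x)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    frequency = np.gradient(phase, dt) / (2.0 * np.pi)
    valid = np.isfinite(frequency)
    valid[:_EDGE] = False
    valid[-_EDGE:] = False
    return InstantaneousSpectrum(frequency=frequency, amplitude=amplitude, valid=valid)


def average_period(imf, n: int | None = None) -> float:
    """Average cycle length in days: ``n / (number of local maxima)``.

    ``n`` defaults to the IMF length (pass the source-series length when the
    IMF was zero-padded).  Raises if the IMF has no local maximum.
    """
    x = np.asarray(imf, dtype=float)
    if n is None:
        n = x.size
    maxima, _ = find_extrema(x)
    if len(maxima) == 0:
        raise ValueError("IMF has no local maxima; average period undefined")
    return float(n) / len(maxima)
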