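"""Ensemble EMD: noise-assisted decomposition for mode-mixing signals.

A single EMD run can mix widely different time scales into one component
when the signal is intermittent (a short burst riding on a slow carrier).
EEMD resolves this by decomposing many noise-perturbed copies of the signal
and averaging: the added white noise populates the time-frequency plane
uniformly, forcing each trial's sifting to respect the dyadic scale grid,
while the noise itself cancels in the ensemble mean.

Ensemble means are generally not exact IMFs, so :func:`post_process` re-sifts
them sequentially (first inner IMF kept, the rest carried forward) to restore
the IMF properties before Hilbert analysis.  :func:`batch_eemd` averages
several independent EEMD+post-processing runs to damp the residual
noise-induced run-to-run fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emd import IMFSet, SiftConfig, emd
from .timeseries import TimeSeries

__all__ = ["EEMDConfig", "eemd", "post_process", "batch_eemd"]


@dataclass(frozen=True)
class EEMDConfig:
    """Ensemble controls.

    ensemble_size : number of noise-perturbed EMD trials averaged (default
        100).
    noise_factor : SD of the added Gaussian noise as a fraction of the input
        SD (default 0.1).
    batches : number of independent EEMD+post-processing runs averaged by
        :func:`batch_eemd` (default 20).
    seed : master seed; every trial derives its own generator from
        (seed, batch, trial) so runs are bit-reproducible.
    """

    ensemble_size: int = 100
    noise_factor: float = 0.1
    batches: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.noise_factor < 0:
            raise ValueError("noise_factor must be >= 0")
        if self.batches < 1:
            raise ValueError("batches must be >= 1")


def _as_values(series):
    if isinstance(series, TimeSeries):
        return series.values, series.dates
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    return x, None


def _mean_of_decompositions(sets: list[IMFSet], dates) -> IMFSet:
    """Element-wise mean after aligning by order index (zero-padding)."""
    n = sets[0].source_length
    n_max = max(s.n_imfs for s in sets)
    comp_sum = np.zeros((n_max, n))
    res_sum = np.zeros(n)
    for s in sets:
        if s.n_imfs:
            comp_sum[: s.n_imfs] += s.imfs
        res_sum += s.residual
    return IMFSet(imfs=comp_sum / len(sets), residual=res_sum / len(sets), dates=dates)


def eemd(
    series,
    sift_config: SiftConfig = SiftConfig(),
    eemd_config: EEMDConfig = EEMDConfig(),
    _batch: int = 0,
) -> IMFSet:
    """Ensemble-mean decomposition of ``series``.

    Each trial adds fresh Gaussian white noise with SD equal to
    ``noise_factor`` times the SD of the input, runs plain EMD, and the
    trial decompositions are averaged component-by-component (shorter
    decompositions are zero-padded to the longest).  The result is
    IMF-like: reconstruction holds up to the unaveraged noise residue,
    ``O(noise_factor * SD / sqrt(ensemble_size))``, but individual
    components may violate the strict IMF criteria (see
    :func:`post_process`).

    With ``noise_factor = 0`` and ``ensemble_size = 1`` this reduces to
    plain EMD exactly.
    """
    x, dates = _as_values(series)
    sd = float(np.std(x))
    sets = []
    for trial in range(eemd_config.ensemble_size):
        if eemd_config.noise_factor > 0:
            rng = np.random.default_rng([eemd_config.seed, _batch, trial])
            noise = rng.normal(0.0, eemd_config.noise_factor * sd, size=x.size)
            sets.append(emd(x + noise, sift_config))
        else:
            sets.append(emd(x, sift_config))
    return _mean_of_decompositions(sets, dates)


def post_process(components: IMFSet, sift_config: SiftConfig = SiftConfig()) -> IMFSet:
    """Re-sift ensemble-mean components back into exact IMFs.

    Working from the highest-frequency component down: the current component
    plus any carry from above is decomposed by plain EMD; its first IMF is
    kept as the final IMF of that order and everything else is carried onto
    the next component.  The final carry joins the residual, so the total
    series is conserved exactly.  Components that yield no IMF become
    all-zero rows and are pruned.
    """
    n = components.source_length
    one = SiftConfig(
        sift_iterations=sift_config.sift_iterations,
        max_imfs=1,
        boundary_mode=sift_config.boundary_mode,
    )
    carry = np.zeros(n)
    final: list[np.ndarray] = []
    for k in range(components.n_imfs):
        g = components.imfs[k] + carry
        inner = emd(g, one)
        if inner.n_imfs:
            final.append(inner.imfs[0])
            carry = inner.residual
        else:
            final.append(np.zeros(n))
            carry = g
    kept = [f for f in final if np.any(f)]
    stacked = np.array(kept) if kept else np.empty((0, n))
    return IMFSet(
        imfs=stacked, residual=components.residual + carry, dates=components.dates
    )


def batch_eemd(
    series,
    sift_config: SiftConfig = SiftConfig(),
    eemd_config: EEMDConfig = EEMDConfig(),
) -> IMFSet:
    """Average of ``batches`` post-processed EEMD runs.

    Each batch uses an independent noise stream derived from the master
    seed, so the whole procedure is deterministic given the config.
    """
    _, dates = _as_values(series)
    runs = []
    for b in range(eemd_config.batches):
        ens = eemd(series, sift_config, eemd_config, _batch=b)
        runs.append(post_process(ens, sift_config))
    return _mean_of_decompositions(runs, dates)
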