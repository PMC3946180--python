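# Methods

## Model and procedure

The pipeline treats a daily death-count series `X(t)` as a superposition of
oscillatory modes plus a slowly varying remainder, with no parametric form
imposed on any component:

1. **EMD.** Sifting extracts intrinsic mode functions (IMFs) one at a time.
   One sifting round subtracts the mean of the upper and lower cubic-spline
   envelopes (through local maxima and minima respectively) from the current
   candidate; an IMF is the candidate after a *fixed* number of rounds.
   After each IMF the remainder is re-sifted; decomposition stops when the
   remainder has fewer than two maxima or fewer than two minima, and that
   remainder is the residual `r_N`. Because every IMF is obtained by
   subtraction, `Σ c_j + r_N = X` holds to floating precision always —
   tested, not assumed.
2. **Significance test.** Observed per-mode energies `E_k = Σ_i c_k(i)²`
   (raw sums, no per-sample normalisation — the choice cancels in the
   log-space deviations as long as model and observations use the same
   convention) are compared against the white-noise reference
   `W_Hk = (E_1/0.719)·2.01^(−k)` for `k ≥ 2`, with upper 95%/99% ordinates
   `log2 W_Hk + 2^(0.474k−2.449)` and `log2 W_Hk + 2^(0.460k−1.919)`.
   The constants come from published Monte-Carlo characterisation of EMD on
   Gaussian noise (Hurst 0.5); we verified the anchoring empirically: over
   200 decompositions of N(0,1) noise (n = 4096), mean `log2 E_k` deviates
   from the anchored line by only 0.04–0.36 for k = 2..7, and the fitted
   slope is ≈ −0.93 against the theoretical −log2 2.01 ≈ −1.007.
3. **Partition.** The first mode whose `log2 E_k` exceeds the operative band
   marks the trend boundary: modes below it form the non-trend ("detail")
   series, it and everything above plus the residual form the trend. Mode 1
   anchors the reference and is never flagged. If nothing exceeds the band,
   every IMF is non-trend and the trend side is the residual alone (`m = N`;
   the alternative of forcing `m < N` would mislabel a noise mode on pure
   noise, so we allow the boundary case).
4. **Epidemiological outputs.** Excess deaths of an inclusive date window =
   sum of the detail series over its days, reported raw and rounded to the
   nearest integer (half away from zero). Log relative risk =
   `ln(X/trend)`; the trend must be positive, zero counts propagate `−inf`
   with a warning unless a +0.5 continuity correction is requested (real
   city-scale counts do not hit zero; the option exists for small-area use).
   Excess-risk regressions are ordinary least squares with intercept;
   adjusted R² and two-sided t-tests as usual.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| sift iterations | 10 | rounds/IMF | fixed-count stoppage makes the decomposition unique and reproducible; configurable for experimentation |
| boundary handling | mirror | — | the two extrema nearest each end are reflected across the end point before spline fitting; tames envelope end swings |
| envelope interpolant | natural cubic spline | — | the canonical choice; the envelope definition itself does not prescribe one |
| significance level | 95 | % | operative band; 99% is always computed and reported alongside |
| mode | auto | — | white-noise anchoring unless the three lowest modes misfit the anchored line (RMS log2 deviation > 1.0), then the generalized least-squares line through the first `n_fit_imfs` modes |
| n_fit_imfs | 3 | modes | "first few low-order modes" for the generalized fit; configurable |
| EEMD ensemble | 100 | trials | noise-assisted averaging standard |
| EEMD noise | 0.1 | × series SD | standard perturbation amplitude |
| EEMD batches | 20 | runs | averaging independent post-processed runs damps residual noise fluctuation |

## Design choices where the procedure was genuinely open

- **Extrema on plateaus**: a flat run bounded by lower (resp. higher)
  neighbours counts once, at its first index; plateaus touching an endpoint
  are not extrema. Deterministic tie-breaking; endpoints are never extrema.
- **Zero crossings**: sign changes between consecutive nonzero samples; a
  run of exact zeros is at most one crossing (only when the flanking signs
  differ).
- **Trend split contiguity**: the non-trend block is contiguous from mode 1;
  a non-exceeding mode above a flagged one is absorbed into the trend side
  (the partition formula presupposes a contiguous low-order block).
- **Generalized-mode bands**: the white-noise margins are reused around the
  fitted line; no dependence-adjusted band widening is attempted.
- **EEMD alignment**: trials are aligned by order index, shorter
  decompositions zero-padded; trial outputs are averaged raw (the added
  noise cancels in expectation).
- **Post-processing**: ensemble means are re-sifted sequentially — the first
  inner IMF of (component k + carry) is kept, the rest carried into
  component k+1, the last carry joins the residual — so conservation is
  exact by construction.
- **Sub-seeding**: every EEMD trial derives its generator from
  (master seed, batch index, trial index), so ensembles and batches are
  bit-reproducible and mutually independent.
- **Temperature anomaly**: the temperature series gets its own
  decomposition; its non-trend block is matched to the mortality non-trend
  frequency band by average-period overlap (cutoff at the geometric midpoint
  between mortality modes m and m+1), falling back to the same count m.
- **Rounding**: nearest integer, half away from zero.
- **Windows**: all date windows are inclusive on both ends.

## The synthetic generator

`synthetic.gen_mortality` emulates an eight-year subtropical daily mortality
record: baseline 30 deaths/day with a +0.001/day drift, a 3-death annual
cosine peaking mid-year (a July series start puts the peak in the Southern-
Hemisphere winter, ~10% seasonal swing — typical of subtropical mortality),
Gaussian noise of SD 5, and additive heatwave spikes (default: one 6-day
triangular pulse of 50 excess deaths in February of the final year) with a
linked maximum-temperature anomaly. AR(1), fractional-Gaussian (circulant
embedding) and Poisson noise variants exist; `gen_intermittent` provides the
mode-mixing fixture (slow carrier, confined fast bursts).

What it does **not** emulate: integer death counts by default (Gaussian
noise matches the method's theory; Poisson is an option), demographic
structure, mortality displacement ("harvesting"), covariate-driven
seasonality interactions, or measurement artefacts such as reporting delays.
Passing recovery tests therefore demonstrates the machinery under the
method's own assumptions, not performance on any particular real city.

## Numerical and degenerate-input notes

- Envelopes need ≥ 2 maxima and ≥ 2 minima; otherwise the signal is
  "not siftable" and becomes (part of) the residual. Constant or monotone
  input yields zero IMFs.
- If a signal becomes non-siftable mid-sift the current candidate is
  returned with a warning.
- Instantaneous frequency is the centred difference of the unwrapped
  analytic-signal phase; the first and last two samples are masked, and
  negative-frequency samples are kept but flagged rather than clipped.
- Average period = series length / number of local maxima of the mode.
- The classical comparator uses a centred moving average (half-weight end
  terms for even windows), per-day-of-cycle seasonal means recentred to
  zero, and is undefined for `frequency // 2` samples at each end — the
  end-window information loss the adaptive decomposition avoids.
- CSV serialisation is full round-trip precision (`%.17g`, with
  round-trip-precise parsing), so conservation invariants are testable from
  disk.

## Problem sizes used in validation

Energy-law, calibration and filter-bank checks use 200 (100 for period
ratios) decompositions at n = 4096; power and pipeline recovery use the
n = 2922 scenario (100 and 50 replicates); the ensemble head-to-head uses
20 seeds × 100 trials at n = 512. These sizes give stable Monte-Carlo
estimates while keeping a full validation run in the minutes range on one
CPU.

## Known limitations

- **Window-sum noise floor.** The excess estimate sums the detail series,
  so day-to-day noise inside the window passes straight through: with noise
  SD σ and a w-day window its standard error is ≈ σ√w regardless of how
  good the decomposition is (≈ 12 deaths for the default scenario). Spike
  recovery is additionally biased low by ~5–15% because sifting spreads a
  sharp pulse into neighbouring modes and slightly beyond the window
  (measured by paired decompositions with and without the spike). Treat
  single-window estimates accordingly; the method reports a point value
  with no uncertainty interval.
- Strict IMF criteria are not guaranteed by fixed-count sifting; a small
  fraction of modes differ by 2 between extrema and zero-crossing counts.
- EEMD components before post-processing are not exact IMFs; Hilbert
  analysis should follow `post_process` (or `batch_eemd`, which includes
  it).
- The significance test assumes the low-order modes are noise-like;
  signals whose highest-frequency mode already carries structure violate
  the anchoring.
- No confidence interval is attached to the excess total (out of scope;
  a GAM-style interval would require a different modelling route).
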