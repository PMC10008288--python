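# Methods

## The model of the data

`envregimes` assumes an environmental variable measured on a regular grid
(daily by default; any declared step works, e.g. 15 minutes) and an ordered
list of biological sampling dates inside the record. Optionally the first
schedule date is an *initialization anchor*: it marks the study start,
bounds the first window on the left, and produces no output row. Every
sampling event then owns one window of antecedent values, and each window
is reduced to 11 indices describing the magnitude, pulse frequency, and
rate of change of the variable over that period.

## Windows

Two rules are implemented.

* **Between samples** (`BetwSamT`, the default): window *i* is
  `(date_{i-1}, date_i]` — half-open on the left, inclusive of the sampling
  date. The convention is chosen so that consecutive windows tile the
  record exactly (no day is double-counted, none is skipped); whether the
  sampling day itself belongs to its window is not fixed by the index
  definitions, and inclusive-end is our documented choice. For an
  unanchored schedule the first window starts at the series origin (with a
  warning) or the first sample is dropped, per the `first_window` setting.
* **Fixed look-back** of `L` steps: `[date_i − (L−1)·step, date_i]`.
  Windows reaching past the series start are truncated to the available
  values with a warning rather than discarded, so an early sampling date
  still yields a row; `min_n` (below) decides whether the shortened window
  supports the variability indices. Look-back lengths are counted in the
  series' native step, so "7" means 7 days on a daily series and 7
  quarter-hours on a 15-minute series — monthly or yearly regimes come from
  monthly or yearly input records, not from calendar arithmetic.

## Index definitions and open numerical choices

With `x_1..x_n` the non-missing window values in time order:

* MA1 = mean, MA2 = median (even *n*: midpoint of the central pair).
* MA3 = 100·s/x̄ with the n−1 sample standard deviation; undefined (missing)
  when x̄ = 0. An exactly constant window returns exactly 0 rather than
  floating-point residue.
* MA4: by default the biased Fisher–Pearson moment skewness m₃/m₂^{3/2}
  (needs n ≥ 3 and non-zero variance; the index is unitless, which the
  moment definition guarantees). The hydrologic alternative mean/median is
  available (`skew_kind: mean_over_median`).
* ML1/MH1/EL1/EH1: thresholds are the 25th/75th and 10th/90th empirical
  percentiles *of the window's own values* — a regime index describes the
  focal period, so thresholds never come from the full record. Percentile
  interpolation defaults to linear between order statistics
  (`percentile_method`, any numpy rule accepted). "Below/above" is a strict
  inequality by default (`strict_inequality`), so a constant window counts
  zero pulses; the definitions' wording does not settle ties, and non-strict
  counting is one flag away. `pulse_mode: timepoints` (default) counts each
  qualifying time step, matching the indices' temporal units;
  `pulse_mode: runs` counts maximal contiguous excursions, the other common
  reading of "pulse event" in the hydrologic tradition (a run interrupted
  by a missing value counts as two).
* RC: mean of successive differences over adjacent non-missing pairs
  (`signed_mean`, the default — on a gapless window it telescopes to
  (xₙ − x₁)/(n − 1)); `abs_mean` averages |Δ| instead for studies that care
  about volatility regardless of direction.
* RH1/RL1: counts of strictly positive / strictly negative successive
  differences; zero differences count in neither, so
  RH1 + RL1 + #zero-diffs = #valid pairs always holds.

Degenerate inputs never abort a run: an index whose precondition fails
(n < `min_n`, default 2; zero variance; no valid pair; an all-missing
window) becomes a missing cell with a logged warning. Missing measurements
are NaN inside a window; distribution-type indices simply drop them, while
sequence-type indices (RC, RH1, RL1, run counting) skip pairs or split runs
across them.

## Input handling

Series CSVs are wide (date + one column per variable) or long
(date, variable, value); dates are ISO-8601; `NA` and empty fields both
read as missing and missing is written as an empty field. A series is
validated against its declared step: `strict` rejects any calendar gap
naming the first missing date, `fill_missing` inserts NaN rows and logs the
gap count — the choice is exposed because sensor archives differ in whether
gaps are encoded or simply absent. Output columns are ordered variables
alphabetically, windows in configuration order, codes in the canonical
order, making repeat runs byte-identical.

## The synthetic generator

`simulate_series` emulates the qualitative shape of daily stream discharge:
log-scale AR(1) around log(baseline) with Gaussian innovations
(`ar_coef` 0.7, `noise_sd` 0.15 by default — day-to-day persistence with
moderate relative noise), plus pulses arriving as a Bernoulli process
(`pulse_rate` 2 per 30 days) that multiply the level by up to `pulse_scale`
(5) and decay with a 3-day e-folding time. The result is strictly positive,
autocorrelated, and right-skewed with occasional spikes. `simulate_schedule`
places 13 dates (anchor at the series start, then roughly every 30 days
with ±3 days of jitter) across the default 365-day record, mirroring a
year-long monthly sampling campaign. All randomness derives from one
explicit seed.

What the generator does *not* emulate: seasonality, rainfall–runoff
physics, measurement error structure, or gaps. Tests passing on these
fixtures therefore demonstrate the correctness of the windowing and index
arithmetic and the directional response of the indices to variability,
pulsedness, and drift — not hydrological realism.

## Verification strategy

The index kernels are checked two independent ways: against hand-derived
closed forms (CV of 1..10, skewness of [1,1,1,7] = 2/√3, enumerated pulse
and change counts) and against a pure-Python brute-force re-derivation of
all 11 indices (`tests/_oracle.py`, no numpy) on 1,000 random windows to
1e-12 relative tolerance. Invariants — conservation of change counts,
nesting of extreme within ordinary pulse counts, shift/scale equivariance,
permutation invariance of the distributional indices — run as property
tests; the shift/scale suites use integer-valued windows so that the
asserted equalities are exact in floating point. Generator knobs are
validated by paired-seed sign tests over 20 seeds (more pulses ⇒ extreme-
high counts not lower; more noise ⇒ CV higher; an added monotone drift,
three baselines over the year, ⇒ rises outnumber falls). Problem sizes
(365-day records, 12–13 windows of ~30 days, window n ≤ 30 for the oracle
sweep) keep the full suite under a few seconds while covering every code
path; the indices are O(n) per window, so nothing about correctness depends
on scale.

## Known limitations

* No timezone or calendar-month arithmetic; look-backs are step counts.
* No duration or timing facets (e.g. longest excursion, Julian date of the
  extreme) — the index set covers magnitude, frequency, and rate of change.
* Percentile thresholds on very small windows (n near `min_n`) are noisy;
  interpret the frequency indices accordingly or raise `min_n`.
* The engine batches multiple variables for convenience, but indices are
  always computed per variable independently; no cross-variable statistics.
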