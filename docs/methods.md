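# Methods

## The Hertz protocol as implemented

Thermoregulation is scored against the null hypothesis of
thermoconformity.  The set-point proxy is the preferred temperature
range (PTR): the central fraction *f* (default 0.5) of gradient
selections, computed as the empirical quantile interval
[(1−f)/2, (1+f)/2] with linear interpolation between order statistics
(the type-7 convention of numpy/R).  The convention matters at the
third decimal at n = 156 — switching quantile types moves the bounds
by ≲0.1 °C — and is exposed rather than hard-coded;
`central_fraction = 1` degrades gracefully to [min, max].  Fewer than
four selections are refused (quartiles of three points are not
meaningful).

The deviation operator is the canonical distance-to-nearer-bound form,
`d(T) = max(0, L−T, T−U)`, zero on the closed interval.  It depends
only on temperature differences, so all indices are invariant under a
common shift of data and bounds (a property the tests assert).

Effectiveness is `E = 1 − mean d_b / mean d_e`, undefined when
`mean d_e = 0` (a habitat that never leaves the set-point range gives
thermoregulation nothing to be effective against); that case raises
rather than returning a sentinel.

### Bootstrap

`d_b` (n = 40 body temperatures in the present-day sample) and `d_e`
(thousands of logger readings) are unpaired by design, so resamples
are drawn independently from each set, preserving each set's size.
E* is computed per resample from that resample's means — E is a ratio
of means and only exists at the sample level, so resampling
pre-computed per-record "E values" would be meaningless.  Reported
point estimates and standard errors are the mean and the sample
standard deviation of the B = 500 pseudo-distribution (matching the
"0.85 ± 0.003" style of reporting).  Resamples with `mean d_e* = 0`
are excluded from the E pseudo-distribution and counted
(`n_undefined`), with a logged warning.  The seed is a mandatory
keyword argument; there is no hidden global randomness anywhere in the
package, and identical inputs and seed give bit-identical summaries.
The bootstrap mean of E* differs from the plug-in E only by O(1/n)
ratio bias, which the convergence test bounds against the Monte-Carlo
error at B = 10 000.

## Statistics layer

Rank tests and OLS delegate to scipy behind the module's own surface;
p-values are two-sided and ties get midranks throughout.
Mann-Whitney U is reported as min(U_a, U_b) (the convention that keeps
the statistic below n_a·n_b/2); the p-value uses exact enumeration for
tie-free samples with min(n) ≤ 20 and the tie-corrected normal
approximation otherwise.  Kruskal-Wallis applies the tie correction;
the all-values-identical corner (tie-correction denominator zero) is
defined as H = 0, p = 1 with a warning rather than NaN.

The Nemenyi post hoc is implemented directly in both classical
variants: studentized-range on mean ranks for equal group sizes and
the tie-corrected chi-square form for unequal sizes ("auto" picks by
balance).  The two-way type×era interaction and the ANCOVA
homogeneity-of-slopes test are model-comparison F-tests computed from
explicit design matrices (full vs. nested reduced model, RSS via least
squares), which isolates the interaction term correctly in unbalanced
layouts (era n's of 87 vs. 40); the unit tests cross-check both
against statsmodels' `compare_f_test` as an independent oracle.
Noise-free degenerate fixtures (RSS_full = 0) are resolved to F = 0 or
F = ∞ by whether the reduced model also fits exactly.

Which location test runs for which era variable is a configuration map
(default: Mann-Whitney for T_b and T_s, ANOVA for T_a), not an
automated normality decision — the routing reproduces a fixed analysis
choice deterministically.

## Synthetic-data generators: what they emulate

The generators' defaults are the study conditions; they are fixed, not
tuning knobs.

**Gradient selections** — 156 truncated-normal draws on the 20–60 °C
gradient span, centre 31.84 °C (the reported set-point midpoint) and
sd 1.0 °C, so the central-50% breadth is ~1.35 °C in expectation
(IQR of a normal = 1.349 sd), bracketing the reported ~1.3 °C
precision.  Selections are assigned round-robin to 24 lizards (12 of
each sex) and hours 09:00–17:00 GMT.

**Field captures** — capture times uniform over the 09:00–18:00 GMT
activity window.  T_a = diel sinusoid (amplitude 3 °C, peak 14:00)
plus Gaussian noise; the curve's base and the noise sd are solved so
the window mean and total variance hit the reported era mean and
sd (sd = SE·√n).  T_s = T_a + offset + noise, with the offset and
noise matched to the era's T_s mean and sd.  T_b is exactly
linear-Gaussian given T_a, using the reported era regression
(1980s: 16.30 + 0.55·T_a, R² 0.301; 2012: 19.78 + 0.42·T_a, R² 0.255);
the residual variance is derived from the target R² as
`slope²·var(T_a)·(1−R²)/R²` rather than being a free knob, because R²
is what the study reports.  The 1980s era draws n = 87 records with 3
missing T_a and 4 missing T_s, mimicking that sample's unequal
per-variable n (87/84/83).  R² targets of exactly 0 or 1 are refused.

**Operative series** — one copper model per microhabitat, a reading
every 5 minutes for 10 days over the 09:00–18:00 window (9 720
readings).  Each microhabitat follows a sinusoidal diel curve plus
noise; sun-exposed categories (flat rock, moss, south-facing rock)
share near-identical warm curves peaking near midday and brushing the
set-point range, east/west rock faces peak morning/afternoon, and
soil, north-facing rock and under-rock are cold and damped with
near-equal means.  The pooled window mean is ~21.8 °C (sd ~6.8),
matching the reported ~21.6 ± 6.7 °C structure.  Closed-form helpers
give the generating model's window mean and its expected mean
deviation from any PTR (censored-normal expectation on a 1-minute
grid), which the tests use as analytic oracles.

The field campaign reported 8 115 raw logger readings, a count no
simple window arithmetic reproduces from 9 models × 5-minute × 10-day
logging; the generator exposes the window and accepts the mismatch
(its default yields 9 720).  Whether the original habitat-quality mean
used all 24 h of logger data or only activity hours is likewise not
derivable; `thermal_quality(..., hours=...)` defaults to the activity
window and takes `None` for all-day.

What the generators do **not** emulate: weather (day-to-day and
between-year variation beyond noise), autocorrelation within logger
series, biophysics of the copper models, any sex or time-of-day effect
on body temperature, and microhabitat availability weighting.  Passing
tests therefore demonstrate that the analysis machinery recovers the
parameters of this idealised generating process at the study's sample
sizes — not that it would be robust to field pathologies the generator
lacks.

## Era comparison and margins

Deltas are later-era minus earlier-era means after per-variable
missing-value drops (an era missing a variable in more than half its
records is an error).  "Buffering" is made numeric as
`delta(T_b)/delta(T_a)` and `delta(T_b)/delta(T_s)` rather than as a
new test.  Under the calibrated defaults the expected deltas are
T_b ≈ 2.5 °C, T_a ≈ 3.8 °C, T_s ≈ 6.0 °C, and the ordering
T_s > T_a > T_b holds in ≥95% of seeded replicates.  (The era means
imply a body-temperature delta of ~2.5 °C; summary statements that
round this to "less than 2 °C" understate their own table — the
report prints the table-based value.)

Safety margins subtract mean body temperature from the sprint-speed
optimum 34.53 ± 0.50 °C reported for lacertids.  The accompanying
performance curve is explicitly illustrative: a piecewise shape rising
as a power law from the critical minimum to 1 at the optimum and
falling linearly to the critical maximum.  Its defaults
(ct_min = 5 °C, ct_max = 42 °C) are synthetic placeholders, not
species measurements — no critical temperatures are reported for this
population — and the curve is excluded from any quantitative claim.
The linear fall over a span (7.5 °C) much shorter than the rise span
(29.5 °C) guarantees the Jensen-type asymmetry (decline steeper than
rise at every matched distance), which the tests assert on a grid.

## Sizes and determinism of the checked claims

Calibration and recovery checks are sized to run on one CPU in a few
minutes: type-I error rates use 2 000 null replicates per test at the
study's group sizes (accepted band 0.03–0.07 at α = 0.05); regression
recovery uses 200 generator seeds; the end-to-end delta-ordering check
uses 60 era replicates with the operative series regenerated for the
first 10.  All random checks run under fixed seeds (hypothesis
profiles are derandomised), so the suite is deterministic.
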