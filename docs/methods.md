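# Methods

## Problem and model

Insect larvae moult through a fixed number of instars, and hard,
sclerotized structures — above all the head capsule — grow by a roughly
constant multiplicative factor at each moult (Dyar's rule; the same
pattern is called Brooks' law for crustaceans). Two consequences drive
everything in this package:

1. A sample of larvae spanning several instars shows *discrete size
   cohorts* in any sclerotized measurement: sorted values form runs
   separated by conspicuous gaps.
2. If `m_i` is the mean size of instar `i`, then `ln m_i` is linear in
   `i`. Writing the per-moult ratio as `r = m_i / m_{i+1}` (so `r ∈ (0,1)`
   and the growth factor is `1/r`), an exact geometric series gives a line
   of slope `−ln r` with `R² = 1`; a conspicuously oversized log-increment
   suggests a stage absent from the sample.

The bundled data are the digitized measurement tables of fossil
*Mycetobia* (Diptera: Anisopodidae) larvae and pupae from Baltic and
Bitterfeld amber: 36 larvae (total length, head-capsule length and width
in µm, published stage assignments) and 54 pupal part measurements
covering 18 pupae of three morphotypes. The tables are stored verbatim as
printed, including a body-length cell of 3 µm against a 320 µm head —
handled by the plausibility filter below, never edited.

## Cleaning and summaries

A record's total length is flagged implausible iff it is shorter than the
same larva's head length (a physical impossibility; it catches exactly the
typo row). Flagged values are excluded from statistics but never deleted,
and the head measurements of a flagged record stay usable. Cleaning is
idempotent. Missingness is per field, not per record.

All storage is in µm; mm appears only in reports, dividing by 1000 and
rounding half-away-from-zero at 1 decimal, the convention of the printed
ranges. With these rules the package reproduces the published descriptive
ranges from the tables: larval body length 1.8–10.2 mm (35 usable values
after the filter), 25 head lengths, 26 head widths, morphotype-1 pupal
abdomen 1.8–3.6 mm and head+thorax 1.0–2.3 mm (n = 14 each). One printed
figure is *not* reproducible from the printed table: the morphotype-1
pupal total range is given as 2.7–5.1 mm, but the table's totals reach
5.9 mm; the package reports what the table yields.

## Gap partition

`sorted_gaps` sorts the values of one variable ascending (stable, so ties
keep their input order) and takes successive differences.
`partition_by_gaps` places a break at every gap strictly greater than
`c ×` the median gap (median of an even-length list = mean of the central
pair); the runs between breaks are the cohorts, labelled 1 from the
smallest. Properties: K is non-increasing in `c`, the labels are invariant
under positive rescaling of the values, and constant data yield one
cohort. `partition_fixed_k` instead breaks at the `K−1` largest gaps,
ties resolved toward the larger value.

The default `c = 3.0` is a calibration to the fossil head widths: the
threshold is then 20.859 µm and exactly the gaps 26.775, 29.007 and
123.702 µm exceed it, giving the four-cohort structure; any `c` in about
[2.9, 3.9] gives the same result. A one-dimensional Gaussian mixture on
log values with BIC selection (`gmm_cohort_diagnostic`) is provided as a
cross-check, never as the default.

**Limitation — this is a small-sample method.** The threshold is tied to
the *global* median gap, while within-cohort gap magnitudes scale with the
cohort mean (under a constant within-instar CV, gaps in the largest of
four cohorts run ≈ `1/r³ ≈ 4.6×` those in the smallest at `r = 0.6`).
With densely sampled cohorts the median gap is set by the smallest
cohorts and tail gaps inside large cohorts cross the threshold, so the
rule over-segments: at 30 specimens per stage (CV 0.08) it essentially
never returns K = 4, and even at fossil-like sample sizes repeated
sampling recovers K only ~10–20 % of the time. The rule is appropriate
for sparse series like the fossil table (26 values, a singleton top
stage); for dense samples use the mixture diagnostic or coarser `c`. The
recovery experiment quantifies this honestly rather than hiding it.

## Stage summaries, fits, ratios

Per-stage statistics use the arithmetic mean on the raw µm scale; the
line is fitted to `(i, ln m_i)` — the log of the mean, not the mean of
logs. A single-specimen stage contributes its actual value, flagged as
such (the fossil fourth instar is one specimen).

Two estimators fit the line:

- **Theil–Sen single median** (the default): slope = median of all
  pairwise slopes `(y_j − y_i)/(x_j − x_i)`, pairs with equal x excluded;
  intercept = median of `y_i − slope·x_i`. This matches the single-median
  convention of R's `mblm`. `R² = 1 − SS_res/SS_tot` is computed about
  the fitted line and can in principle be negative for this estimator.
- **OLS** via least squares, as a cross-check; its R² is the usual
  explained fraction and is affine-invariant in y.

On the fossil data both estimators agree to well within rounding: per-
stage mean head lengths give R² = 0.994 (OLS) and 0.994 (Theil–Sen),
i.e. 0.99 at two decimals; head widths give 0.994/0.992, also 0.99. The
head-width R² was originally reported as 0.98; neither estimator
recovers that figure from the printed table, so 0.99 is what this package
reports and the discrepancy is documented here rather than patched.

Growth ratios (`brooks_ratios`) are `r_i = m_i/m_{i+1}` with reciprocal
growth factors; the headline statistic is their arithmetic mean, reported
with range and CV. Fossil head widths give ratios {0.632, 0.692, 0.579},
mean 0.634 → 0.6 at one decimal, inside the 0.57–0.66 band reported for
an extant relative.

The missing-stage check flags any log-increment exceeding 1.5× the
median increment — the smallest simple multiple that flags a removed
stage in a ratio-2 series yet passes the fossil series. Caveat: with only
three stages there are two increments and the even-median convention
dilutes the signal (median of {ln 4, ln 2} is 1.5·ln 2, so the doubled
increment is only 4/3 of the median and is not flagged); detection is
reliable from four observed stages.

## Synthetic generator

`simulate_instars` draws stage-`i` head widths lognormal with mean
`base_width / r^(i−1)` and coefficient of variation `within_cv`, using the
mean-preserving parameterization `σ² = ln(1+cv²)`, `μ = ln(mean) − σ²/2`.
Head length is width × `length_width_factor` × an independent mean-one
lognormal of the same CV; body length is width × `body_factor` × a mean-one
lognormal of CV `shrink_cv`, the taphonomic-shrinkage term — heads are
sclerotized and keep their dimensions in resin, trunks shrink, which is
why body length shows no clean cohort breaks. Per-field missingness is
optional. Defaults mirror the fossil series: K = 4, r = 0.6, stage-1 mean
width 106 µm, length/width 1.3 and body/width 25 (the smallest fossil
cohort's proportions), CV 0.08 (fossil within-stage CVs are ≈ 0.09–0.11).
No quantitative shrinkage magnitude is known; `shrink_cv = 0.25` in the
shrinkage scenario is illustrative.

Determinism: one master seed; replicate `j` of an experiment uses
`numpy.random.SeedSequence((master_seed, j))`. Identical config ⇒
identical table, byte-for-byte through the CSV writer.

`recovery_experiment` runs simulate → gap partition → cohort-ratio
estimate per replicate and reports the fraction recovering the true K,
the ratio estimates' mean/SD/MAE, and the joint fraction (K correct and
ratio within a tolerance, default ±0.05). Problem sizes used by the test
suite and the acceptance script — 200 replicates of 120 specimens for the
headline experiment, 40–60 replicates for the qualitative contrasts —
run in seconds. What passing synthetic tests show is limited to this
generative model: real assemblages add size-biased entrapment, stage-
dependent sampling and measurement error that the generator deliberately
omits.

## Known limitations

- The gap rule over-segments densely sampled cohorts (see above); the
  published four-cohort fossil partition is reproduced exactly, but the
  rule should not be applied blindly to large samples.
- The head-*length* series does not yield the same break count as the
  width series under the same rule; head width is the authoritative
  partitioning variable, as in the source analysis.
- The printed head-width R² of 0.98 is not recoverable from the printed
  table (both estimators give 0.99).
- No confidence intervals on the Theil–Sen slope and no hypothesis
  tests: the analysis is descriptive, as published.
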