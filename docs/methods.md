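# Methods

`somnotype` re-implements, as a tested and reusable pipeline, the analysis
chain used in behavioural sleep/circadian phenotyping of passive-infrared
(PIR) activity data, together with the companion analyses such studies
lean on: family-quartet variant filtering, agonist dose-response fitting,
and a small inferential layer. Because the original inputs of such studies
(animals, patients, patch-clamp rigs) are not reproducible at the desk,
every input kind has a synthetic generator with planted effects, and the
pipeline is validated by parameter-recovery and calibration experiments
rather than by re-deriving clinical numbers.

## Sleep scoring from immobility

A PIR sensor reports percent-time-active per 10-s bin. Behavioural sleep
is called on sustained immobility: a run of at least 4 consecutive bins
with no detected movement (>= 40 s) is a sleep bout. Two onset
conventions exist in the literature and the rule's two published
phrasings differ on which is meant, so both are first-class:

* `fourth_bin` (default): sleep starts at the 4th immobile bin, so a run
  of R bins contributes R − 3 sleep bins;
* `run_start`: the entire qualifying run is sleep.

Their total-sleep difference is exactly 30 s per sleep bout; outputs echo
the convention used. "Active" means percent-active above a configurable
epsilon (default 0 — any detected movement). Runs truncated by the trace
edges are scored from observed bins only.

## Bout structure

An activity bout is a maximal run of active bins; its intensity is the
mean per-bin percent-active (i.e. the fraction of the bout the sensor was
active). Sleep bouts are maximal runs of sleep-flagged bins. Bout lengths
are tabulated into half-open categories [0, 1 min), [1, 10 min),
[10 min, 1 h), [1 h, inf) — edge ownership is a convention choice, since
the printed labels do not define it. Intensity categories default to
deciles. Category tables carry both raw counts over the observation
window and per-day rates, because published summaries may be either.

## Chi-square periodogram and free-running period

For a candidate period of P analysis bins over N bins of data, the data
are folded into P phase columns and

    Qp = N * sum_h K_h (M_h − M)^2 / sum_i (x_i − M)^2,

with M_h and K_h the mean and count of column h and M the grand mean.
Under a white-noise null Qp is asymptotically chi-square with P − 1
degrees of freedom; each candidate period is compared with the
chi-square 1 − alpha quantile at its own df (alpha = 0.01), giving the
familiar rising significance line. No correction is applied across
candidate periods, matching the single plotted line of the classical
presentation; the white-noise exceedance of the line is ~1% per period
(verified by simulation in the acceptance suite). Incomplete final
cycles are used as-is (column means over unequal counts). A constant
series has Qp defined as 0.

Mouse traces are mean-downsampled to 6-min analysis bins before the
periodogram, giving 0.1 h period resolution over the default 20–28 h
search window; diaries are analysed at their native 1 h over 16–120 h.
The free-running period tau is the candidate period with maximal Qp
within the window, reported only when significant, with ties broken
toward the shorter period. Tau-adjusted daily activity is
(24 / tau) x mean activity per 24 h, which expresses each subject's
activity per cycle of its own internal clock.

A sample-size note: at 0.1 h resolution, peak localisation from 9
recorded cycles sits at the edge of one grid step for realistic trace
noise; 12-day constant-condition blocks give quantisation-limited
recovery. The package therefore uses 12-day DD/LL blocks in its
recovery experiments (the protocol constraint in this literature is a
minimum of 9 days per block; real blocks are typically longer). Blocks
shorter than 9 days are excluded from circadian analysis with a warning.

## Synthetic mouse activity

The generator is a two-state alternating-renewal process (active /
immobile) with circadian gating; it is a calibration-free emulator of
the *structure* of PIR data, not a fit to any real cohort:

* Run lengths are drawn from a four-category log-normal mixture whose
  categories match the bout-length classes above. Default weights
  (activity 0.55/0.33/0.10/0.02, immobility 0.35/0.45/0.18/0.02 across
  the four classes, medians ~25 s to 1.5 h) were chosen once to produce
  a polyphasic animal with a few hundred bouts per day; no quantitative
  bout-length distribution is published, so these are placeholders.
* A circadian oscillator with phase 0 at mid subjective night scales
  active-run lengths by `nocturnality^(gate_strength*cos(phase))` and
  immobile runs by the inverse, and the subjective dusk / dawn
  transitions truncate day-rest / night-activity runs. The truncation is
  what reproduces the sharp activity onsets of real actograms; a pure
  renewal process has onset jitter of tens of minutes and its period
  cannot be recovered at 0.1 h resolution.
* Per-bin percent-active for active bins is normal noise around a mean
  that itself follows the phase (`intensity_depth`, default 0.8), with
  mean 60% and sd 20, clipped to [1, 100]. Immobile bins are exactly 0,
  so generation and sleep scoring agree on what "immobile" means.
* Under LD the oscillator is pinned to the 24 h lighting cycle
  (mid-dark = phase 0); under DD/LL it free-runs at
  tau(lux) = intrinsic_tau_h + aschoff_slope * log10(lux + 1) — a
  linear-in-log-lux (Aschoff-rule-like) lengthening, the simplest form
  consistent with "tau lengthens with brighter constant light". Phase is
  continuous across block boundaries.
* Genotypes differ by `brief_bout_deficit` (multiplies the sub-minute
  mixture weight; 0.6 plants the 40% deficit used in the recovery
  experiments) and by `aschoff_slope` (0.2 h/log10-lux wild-type vs 0.35
  mutant by default, modelling heightened light sensitivity).
* The cohort seed is split hierarchically per subject
  (`numpy.random.SeedSequence.spawn`), so cohorts are reproducible
  subject-wise and bit-identical across runs.

What the generator does *not* model: EEG-defined vigilance states, the
two-process (homeostat + oscillator) architecture, light masking of
activity, ultradian physiology beyond run-length statistics, or
inter-individual variance components beyond sampling noise. Passing
recovery tests therefore show the analysis chain is correct and
calibrated — not that it was validated against real mouse recordings.

Human diaries are an alternating wake/sleep process at a configurable
ultra-long cycle (default 72 h, well outside the circadian range, with
27–28 days of hourly flags), log-normal jitter on episode lengths, and a
realized duty cycle within ~10% of the target.

## Variant filtering

Pre-annotated quartet VCFs (father, mother, two affected sons) pass
through three subset filters with a per-stage funnel report:
protein-altering consequence classes only; rarity (panel AF strictly
greater than 0.005 removed — the boundary value is retained — no cohort
hom/hemizygotes, at most five cohort heterozygotes, no gnomAD
hom/hemizygote); and four inheritance models (simple recessive,
compound heterozygous with one allele from each heterozygous parent,
X-linked recessive, shared de novo). Records missing a genotype in any
member are ineligible for that model rather than an error. Because the
internal reference cohort itself is not distributable, its het/hom
counts are carried per-record in INFO fields.

The shared-de-novo model additionally requires a confident genotype in
all four members. Confidence is the genotype log-likelihood margin
log10 L(best alternative) − log10 L(called genotype), i.e. −PL/10 of the
runner-up genotype; more negative is more confident, and the filter
requires margin < −5 (a Phred margin > 50) in all members. The
literature phrase "log likelihood ratio less than −5" does not fix the
ratio's direction; this convention is a documented design choice, not an
inference about the original caller.

## Group statistics

* Two-way mixed-design RM-ANOVA (between = genotype, within = category
  or light level, one observation per subject x level): the classical
  univariate decomposition with subjects-within-genotype as the error
  stratum for the between effect and the subject x within residual for
  the within and interaction effects. No sphericity correction (equal
  variance is assumed, matching the source convention). Percent of
  total variation is 100 * SS_effect / SS_total. Post-hocs compare the
  genotypes at each within level with a pooled-variance t-test and
  Bonferroni adjustment (raw P x number of levels, capped at 1).
  Missing cells raise — no imputation.
* Welch t-test (Welch–Satterthwaite df) and a Student t-test on
  log-transformed observations (reporting geometric means) for
  strictly positive, multiplicatively varying measures. Both return
  P = 1 for degenerate all-identical inputs.
* Event-amplitude distribution comparison: both samples are binned into
  normalised frequency distributions over a common range (default 21
  bins); a 3-parameter skew-normal density (shape, location, scale) is
  least-squares fitted pooled vs per-group, and the extra-sum-of-squares
  F has df1 = 3 and df2 = total bins − 6 (F(3, 36) at the default).
  Separate fits are seeded from the pooled optimum, so nesting
  (SS_separate <= SS_pooled) holds by construction. This unweighted
  histogram F-test is a field convention, not an exact test: histogram
  noise is heteroscedastic, and simulation shows the null rejects at
  roughly 3–5x the nominal 5% rate. It is kept as specified for
  comparability; treat its P-values as a ranking statistic rather than
  exact error rates. Events with rise time above 2 ms are excluded
  before amplitude comparisons (dendritic filtering).

## Dose-response

The model is the Hill-slope-1 three-parameter sigmoid
Y = bottom + (top − bottom)/(1 + 10^(log10 EC50 − X)) with
X = log10[agonist]; currents are first normalised to the response at a
saturating reference (10 mM glutamate). "Three-parameter" is read as
free bottom/top/EC50 with slope fixed at 1; a fixed-bottom = 0 variant
is available by flag since the original constraint is not stated. The
least-squares fit restarts from three deterministic initial EC50 guesses
(geometric mean, min, max of the tested concentrations) — seedless and
reproducible. On noiseless model data the fit recovers EC50 to ~1e-16
relative and zero residual; with 5%-of-top noise the mean estimate over
200 replicates is biased < 3%. The kainate/glutamate peak ratio
(agonist-efficacy index) is 100 x KA/Glu.

## Numerical and interface choices

* Time is integer seconds from recording start; activity bins are
  half-open [t, t + 10 s) indexed from 0; VCF positions are 1-based.
* Readers are inverses of writers on valid data; activity CSV loading
  enforces a complete uniform grid (gap policy: error by default,
  optional zero-fill with a warning — sensor dropout handling is not
  standardised, so it is explicit rather than inferred).
* Multi-allelic VCF sites are split into biallelic records before
  filtering so frequency thresholds apply per alternate allele;
  genotype likelihoods are carried only for biallelic sites.
* Degenerate inputs (zero rates, empty schedules, non-positive
  concentrations, all-wake diaries) are rejected, not clamped.
* Estimator-style classes (`SleepScorer`, `ChiSquarePeriodogram`,
  `DoseResponseCurve`) follow scikit-learn conventions (constructor
  parameters, `fit`, trailing-underscore fitted attributes,
  `get_params`) so they compose with sklearn tooling; module-level
  functions wrap them for one-call use.

## Known limitations

* The periodogram significance line is per-period; across a whole
  search window the familywise false-positive rate is higher (an
  arrhythmic trace yields a "significant" tau in roughly 10–15% of
  cases at the default window). This matches the source convention and
  is deliberate.
* The skew-normal comparison's calibration caveat above.
* The generator's bout mixture is a placeholder, not a fitted model;
  effect sizes planted with it should be read as "clearly detectable",
  not as biologically calibrated magnitudes.
* X-linked logic assumes hemizygous male genotypes are encoded as
  haploid calls; no X-inactivation or pseudo-autosomal handling.
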