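# Methods

This note records the models, conventions, and design choices behind
`ontosleep`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## DAM ingestion and Zeitgeber alignment

Monitor files follow the common DAM2 dialect: 42 tab-separated fields
per line — running index, date (`DD Mon YY`), time (`HH:MM:SS`), a
status code, six device fields, and 32 channel counts. Month names are
mapped explicitly so parsing is locale-independent; the six device
fields are stored verbatim and written back unchanged, making
write∘read the identity on counts, status, and timestamps. Rows with a
status other than 1 are retained but flagged invalid; downstream sleep
scoring treats them as missing minutes, and a run of zeros cannot
bridge a missing minute (conservative: gaps never create sleep).

Light state is always derived from the declared `LightSchedule`
(lights-on clock time defining ZT0, photoperiod, LD/DD regime per day),
never from the monitor's light sensor: analyses should follow the
declared protocol, not hardware noise.

Alignment trims a recording to whole ZT0→ZT0 days starting at the first
ZT0 *strictly after* the recording start. A recording that begins
exactly at ZT0 therefore still discards its first day — loading-day
data (CO2 anesthesia, acclimation) should never be scored. Output
length is always a multiple of 1440 min and the first row has ZT 0.

## Sleep scoring

Sleep is ≥ 5 consecutive minutes with zero beam-break counts; only
zero-versus-nonzero matters (no movement threshold, no smoothing),
because the 1-min DAM bins already quantize activity. Scoring runs on
the continuous recording so bouts spanning ZT0 are preserved; each
sleep minute is then assigned to its own day.

Phase bookkeeping for a bout spanning the ZT12 lights-off boundary:
its minutes are split between day and night (so day + night always sums
to total sleep), but the bout itself is counted once, in the phase of
its onset. Means of bout length are over bouts counted in the phase and
use full durations. A phase with zero bouts reports mean length 0 with
an explicit undefined flag rather than NaN-propagating.

Dead-fly hygiene: a fly is excluded when its terminal zero-activity run
lasts ≥ 12 h (configurable) or it never moved; every exclusion appears
in a report with the fly's last active minute, never silently.

Sleep profiles use 30-min bins by default, the typical resolution of
published sleep traces; SEM is the across-fly standard error and is 0
for a single fly.

## Ontogeny ratio and hit calling

The ontogeny ratio is the ratio of group means of per-fly daytime sleep
(young over mature). Young and mature flies are different individuals,
so per-fly ratios are not defined; the group-mean form is the only
coherent one. Per-fly values reduce multiple recorded days by either
the first full day or the across-day mean (`day_policy`); the screen
condition used in the acceptance checks records two full days per fly
and averages them, since the mature class is itself defined over days
4–5 (a two-day window) and day-averaging halves the variance of the
ratio estimate at no cost in bias.

Hits are ratios ≤ 1.2, boundary inclusive. Genotypes below the minimum
group size (default 8 per age) or with an undefined ratio (mature mean
0 — an assay failure, not an ontogeny phenotype) are reported but never
called. Output is ranked ascending by ratio with a stable sort.

## Statistics

* Families of comparisons use two-sample two-tailed t tests with the
  Holm–Šidák step-down adjustment, implemented from its closed form:
  for sorted raw p-values, adjusted p(i) = max over j ≤ i of
  1 − (1 − p(j))^(m − j + 1), capped at 1. α = 0.05 throughout.
* Single two-group contrasts use Welch's t (unequal variances) with
  Welch–Satterthwaite degrees of freedom, computed from the closed form
  with the t distribution; the pooled-variance form remains available
  for exact legend-style replication.
* Three or more groups use one-way ANOVA followed by Tukey's HSD on the
  studentized-range distribution.
* Degenerate inputs are explicit: both groups constant and equal →
  t = 0, p = 1 by convention, flagged; constant but unequal → infinite
  t, p = 0, flagged. Tests never silently divide by zero.
* The modifier-screen contrast flags a "rescue" when the co-knockdown
  genotype's ratio exceeds the base knockdown's (by a configurable
  margin, default 0) *and* its young-versus-mature daytime-sleep
  contrast regains Welch significance.

The test suite verifies the Holm–Šidák form against an independent
closed-form evaluation and statsmodels, Welch against
`scipy.stats.ttest_ind(equal_var=False)`, and Tukey against
statsmodels' `MultiComparison`, and simulates the family-wise error of
the corrected family under a global null.

## FFT rhythmicity

Commercial actogram software reports an "FFT value" without a published
formula, so this package defines one and documents it: the per-minute
series is binned (default 30 min), mean-subtracted, and discrete-
Fourier transformed with no zero padding (frequency resolution is
1/window, a reproducible grid). Power is one-sided with interior bins
doubled; each non-DC bin is expressed as a fraction of total non-DC
power. The FFT value is the maximum fraction at periods within the
circadian band (default 18–30 h) and the peak period is that bin's
period. The construction is invariant to additive offsets and positive
rescaling of the series.

The rhythmicity threshold (default 0.04) is an operational default, not
a published constant; with a 7-day window it cleanly separates a
sinusoidally modulated fly from Poisson white noise (whose per-bin
relative power is ~1/168). Any quantitative match to published FFT
tables is therefore not claimed.

## Imaging quantification

* Innervation density = (# ROI pixels ≥ threshold) / (# ROI pixels),
  with the same threshold across a comparison set. The intensity
  threshold for density is dataset-specific (published settings state
  only that they were constant), so it is a required argument, not a
  default.
* 3-D puncta: connected components of voxels ≥ 52 inside the ROI,
  26-neighbour connectivity (the common 3-D object-counter behaviour;
  6/18 available), size gates 2–80 voxels, all bounds inclusive — a
  voxel at exactly 52 and an object of exactly 2 or 80 voxels count.
  ROI volume is the number of ROI voxels with intensity ≥ 1 (the
  object-counter volume settings), so density × volume = count exactly.
* CTCF = integrated density − area × mean background; negative values
  are reported as-is.
* Normalized ROI signal = signal mean / reference mean, with the
  reference mode (adjacent background vs same-ROI counterstain)
  recorded for provenance.
* Binary innervation scoring calls a brain positive when its density
  reaches `min_fraction` — an explicit, labelled assumption, since
  presence/absence criteria are rarely printed — and reports the cohort
  fraction with an exact Clopper–Pearson 95% CI.
* ROIs are supplied as mask files; automatic segmentation of the
  fan-shaped body is deliberately out of scope.

## Gene-set integration

DE selection uses strict inequalities (padj < 0.05, |log2FC| > 1.0 by
default). Two presets ship because analyses of this kind are reported
both with a formal |log2FC| > 1.0 definition and a looser linear
fold-change > 1.2 summary; the formal definition is the default. ChIP
genes are scored by their best peak (minimum p-value, ties by maximum
signal) and ranked with a total ordering (p ascending, signal
descending, gene id) so shuffled inputs give identical output; the top
200 unique genes are taken after per-gene deduplication. Peak-to-gene
annotation is accepted as an input column — peak calling and annotation
belong to upstream tools.

## The synthetic-data generator

The sleep–wake simulator is a semi-Markov alternating-renewal model:
within each 720-min phase block (day or night), a fly alternates sleep
and wake bouts with durations drawn from age- and phase-specific
distributions — sleep as 4 + Geometric (support ≥ 5, always detectable
by the 5-min rule), wake as Geometric (support ≥ 1). Bout-length
distributions are parameterized directly because bout architecture is
the metric of interest.

Lights transitions (ZT0, ZT12) reset behaviour: the bout in progress is
truncated and each block starts in its stationary state — asleep with
probability m_s/(m_s + m_w) and with an equilibrium residual-life first
bout (the geometric tails make the residual law closed-form). This
makes the expected sleep fraction of every block *exactly*
m_s/(m_s + m_w), so daytime sleep and hence the ontogeny ratio are
calibrated analytically: the wild-type constructor sets the young day
fraction to target × mature day fraction. Defaults: mature day fraction
0.35 with 15-min sleep bouts, young day carried by 40-min bouts
(juvenile daytime sleep is consolidation-driven), night fraction 0.8
for both ages, target ratio 1.75 — the middle of the 1.5–2.0 wild-type
band, with young day sleep roughly twice mature day sleep. Waking
activity is Poisson (rate 2/min) with an optional sinusoidal circadian
multiplier; zero-count wake minutes are re-drawn to 1 with probability
0.85 so wake is rarely mistaken for sleep. All generators take explicit
seeds; there is no global random state.

What the generator emulates: age-dependent daytime-sleep consolidation
with controllable ontogeny ratio, fragmentation (shorter bouts at fixed
sleep fractions), arrhythmic variants, monitor packing and DAM file
format, imaging stacks with exactly known puncta, and omics tables with
planted set memberships. What it does not emulate: homeostatic rebound,
light startle transients, inter-fly correlation within a monitor,
aging within a recording, realistic point-spread functions or imaging
artifacts, and correlated DE/peak noise. Passing tests therefore
demonstrate correctness of the measurement pipeline on data satisfying
the model's assumptions, not robustness to every pathology of real
recordings.

Known scoring-versus-truth gaps are intentional and small: a truncated
boundary bout can fall below 5 latent minutes and be lost, and a
zero-count wake minute adjacent to a bout extends it; the suite bounds
the net effect.

## Problem sizes and numerical tolerances

The acceptance checks run at the study's scales chosen for a laptop:
100 replicate control screens at n = 32 flies/age and a 50-genotype
grid at n = 16/group (two recorded days per fly); 1,000 traces for the
bout-detection oracle; 10,000 replicates for the family-wise-error
simulation; 1,000 noise traces for rhythmicity; 100 stacks and 100
round-trip matrices. Cross-implementation agreement is asserted at
1e-8–1e-12; exact quantities (bout sets, counts, set memberships,
round trips) are asserted exactly. The whole suite runs in well under a
minute of simulation-heavy time per module.

## Limitations

* The FFT value and rhythmicity threshold are this package's
  definitions; absolute values are not comparable to proprietary
  software output.
* The ontogeny screen applies no multiple-testing control across
  genotypes (the ratio cutoff is the published practice); an FDR layer
  would be a clearly-labelled extension.
* Sleep-depth/arousal modeling, video scoring, DAMFileScan-style
  artifact repair, and 30-s or multi-beam DAM variants are out of
  scope.
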