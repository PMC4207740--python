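# Methods

This note documents the models, estimators and design choices behind
`chronosleep`: a pipeline for quantifying sleep architecture, slow-wave
activity (SWA), REM theta oscillations, rest-activity profiles, day-night
gene expression and seed-gene networks in a two-genotype mouse
phenotyping design, driven by a synthetic-cohort generator.

## Study design being emulated

Two groups under a 12:12 light-dark schedule (ZT 0 = lights-on):

* a **WT-like** group (n = 7) with a deep diurnal modulation of sleep
  propensity (depth 0.4), REM theta centered at 7.2 Hz, and a high
  nocturnal wheel plateau whose half-maximal decline sits at ZT 18.3;
* a **mutant-like** group (n = 8) with attenuated modulation (depth
  0.15), theta centered at 7.6 Hz, reduced nocturnal running with an
  earlier half-max (ZT 17.1), and attenuated day-night expression
  amplitudes.

Recordings span two days: day 1 is baseline; on day 2 sleep deprivation
(gentle handling emulated as per-epoch enforced wakefulness at 97%
efficiency) covers ZT 0-6.  EEG/EMG are sampled at 256 Hz and scored in
4-s epochs as WAKE, NREM or REM, with independent per-epoch artifact
flags (probability 0.01).

## Hypnogram generator

Vigilance states follow a first-order Markov chain over {WAKE, NREM,
REM}, the minimal structure that reproduces bout alternation.  The base
per-epoch transition matrix

```
            to WAKE   to NREM   to REM
from WAKE    0.955     0.045     0        (WAKE->REM forbidden)
from NREM    0.032     0.950     0.018
from REM     0.060     0.010     0.930
```

yields time budgets near 47% wake / 42% NREM / 11% REM and mean bout
lengths around 1.5 min (wake), 1.3 min (NREM) and 1 min (REM) —
plausible values for adult mice at 4-s resolution.  No bout-length
statistics were available to calibrate against, so these defaults aim at
plausibility, not at any specific animal.

Diurnal modulation multiplies every transition probability *into a sleep
state* (WAKE→NREM, NREM→REM, REM→NREM) by

```
m(t) = 1 + A cos(2*pi*(ZT - phi)/24),     phi = ZT 6
```

and renormalizes each row.  Sleep propensity therefore peaks mid-light.
Modulating only WAKE→NREM was rejected during design: it leaves the REM
light-dark amplitude within sampling noise of zero, whereas REM
propensity in mice is strongly diurnal; extending the factor to all
sleep-entering transitions produces light-dominant REM with a clearly
depth-dependent amplitude.  A modulated probability outside [0, 1]
(e.g. A > 1) is a configuration error naming the offending epoch.

Each animal draws from an independent stream spawned from
(master seed, group index, animal index), so enlarging the cohort never
perturbs existing animals.

## Two-process homeostat and EEG synthesis

A latent Process-S variable drives NREM delta power:

* during WAKE and REM: `S <- min(1, S + dt / tau_rise)`, tau_rise = 18 h;
* during NREM: `S <- S * exp(-dt / tau_decay)`, tau_decay = 4 h;
* `S(ZT0) = 0.6` (end of the active phase).

The EEG is a unit-RMS 1/f ("pink") noise floor (flattened below 0.5 Hz)
plus state components, all per-epoch:

* **NREM**: 0.5-4 Hz band-limited Gaussian noise with RMS gain
  `delta_gain * (0.5 + S)`, delta_gain = 3 — delta dominates NREM and
  inherits the homeostat's rise after deprivation;
* **REM**: Gaussian noise band-passed (4th-order Butterworth) to the
  group's theta center ± 0.5 Hz, RMS gain 3 — a narrowband but
  non-sinusoidal oscillation, so peak-frequency estimation is
  nontrivial;
* **WAKE**: broadband Gaussian noise, gain 1.

EMG is white noise with per-state RMS 3.0 / 1.0 / 0.3 (wake / NREM /
REM), encoding muscle tone and REM atonia.  Artifact-flagged epochs keep
their state label and receive a high-amplitude half-sine transient; they
count toward time budgets but are excluded from all spectral averages.
Signals are synthesized in float32; spectra are computed in float64.

## Spectral analysis

Each 4-s epoch (1024 samples) is split into two non-overlapping 2-s
segments; each segment is multiplied by a periodic Hann window and
periodogram-transformed at its native 0.5 Hz spacing, and the two
periodograms are averaged (a Welch estimate).  Only the bins 0.5-20 Hz
are retained, giving 40 bins.  This two-segment scheme is a declared
choice, not an inference about any acquisition software: a single 4-s
window would natively give 0.25 Hz spacing, and averaging two 2-s
segments is the standard way to land exactly on a 0.5 Hz grid.

* **SWA** = arithmetic mean power over 0.5-4.0 Hz (8 bins, both edges
  inclusive) of NREM epochs.  Per animal, SWA is expressed as a
  percentage of the mean SWA over the **chronologically last 900
  artifact-free NREM epochs of the baseline light period**; fewer than
  900 qualifying epochs is an error unless a lower minimum is passed
  explicitly (short demo recordings).  Time-course bins with fewer than
  10 NREM epochs are reported missing (NaN), never zero.  No exclusion
  of transition-adjacent NREM epochs is applied.
* **TPF** (theta peak frequency) = the grid frequency of maximal power
  in 5.0-10.0 Hz (11 bins) of an interval-averaged artifact-free REM
  spectrum; ties break toward the lower frequency, so the output is
  always a multiple of 0.5 in [5, 10].

Identities maintained: mean normalized SWA over the reference window is
100 by construction; scaling the signal by k scales raw spectra by k^2
and leaves normalized SWA and TPF unchanged; the integrated full-band
density of a windowed segment satisfies Parseval with the Hann power
correction.

## Sleep architecture

State percentages are epoch counts over total epochs per half-open
ZT bin, with 12-h light/dark and 24-h aggregates; artifact epochs count
toward their state.  The light-dark (L-D) amplitude of a state is the
signed difference `state%(L) - state%(D)` in percentage points; a
normalized variant `(L-D)/((L+D)/2)` is available behind a flag since
the quantity is sometimes reported "relative".  Wake rasters are WAKE
fractions per 5-min bin.  Deprivation efficiency is the percentage of
in-window epochs scored WAKE.

Wheel counts (per-minute Poisson; nocturnal plateau declining
logistically through the night, scale 0.6 h) are folded over days into
18-min bins.  The nocturnal half-max time smooths the folded profile
with a 3-bin centered circular moving average (no smoothing rule was
given for the original analysis; 3 bins ≈ 1 h is the minimal symmetric
choice), finds the dark-phase peak and linearly interpolates the first
crossing below 50% of it; a profile that never crosses before lights-on
raises "no crossing".

## Expression screen

The ZT16 vs ZT4 screen tests each gene's log2 values with an
empirical-Bayes **moderated t**: per-gene pooled variances are shrunk
toward a scaled-inverse-chi-square prior fitted across genes by the
method of moments on log variances (prior df via trigamma inversion),
and the t statistic gains the prior degrees of freedom.  This is the
standard microarray approach; a per-gene Welch test is available
(`moderated=False`) but is conservative and underpowered at n = 4
replicates per cell, where the moderated test remains calibrated (null
raw-p rate ≈ 0.05) and recovers planted 1.5-log2 effects essentially
completely.  P-values are Benjamini-Hochberg adjusted across genes; the
selection rule is strict `|linear FC| > 1.5` **and** adjusted p < 0.05.
Fold changes carry the microarray sign convention (-2 means halved at
ZT16).

The generator plants 22 induced transcripts (effect +1.5 log2 at ZT16,
noise SD 0.25): the mutant-like group keeps 25% of each effect except
for a 5-gene "robust" subset (the clock-gene analogue) that keeps 85%
everywhere.  At the default cut-offs the WT screen passes ≈ 22 genes and
the mutant screen ≈ 5 — the attenuation pattern the pipeline is built to
detect.  Attenuation is summarized per gene as the mutant/WT linear FC
ratio, `2^(lfc_mut - lfc_wt)`.

## Network modeling and enrichment

The interaction graph is a user-supplied edge list (identifiers
upper-cased, self-loops dropped, optional synonym map); edges are
undirected by default because curated databases disagree on direction
semantics, with an opt-in directed mode that requires seed→connector→seed
consistency.  The most stringent shortest-path model keeps every seed
present in the graph, all direct seed-seed edges and, with one allowed
intermediate, every non-seed node adjacent to ≥ 2 distinct seeds plus
the edges of those seed-connector-seed paths.  Connector-connector edges
are *not* retained — only edges lying on admitted paths — and this is a
documented choice where reference tools are ambiguous.  Construction is
order-independent and monotone in the seed set.

Enrichment of a query set against GMT term sets over a finite universe
is the hypergeometric upper tail P(X ≥ k), BH-adjusted across terms;
query genes outside the universe are dropped with a logged count.

## Statistics

* **Two-way ANOVA** with interaction: fixed-effects OLS with Type II
  sums of squares (equal to the classical partition for balanced data).
  Repeated measurements over time are deliberately treated as a between
  factor — matching the reported effect/interaction structure — and no
  sphericity correction is applied; perfectly constant data report F = 0,
  p = 1 rather than 0/0.
* **Bonferroni post-hoc**: per level of the crossing factor, a
  two-group t-test (Welch by default; percentage data rarely have equal
  variances), raw p multiplied by the number of levels, capped at 1;
  underpowered levels are flagged, not fatal.
* **Mann-Whitney U** (U reported for the first sample): for combined
  n ≤ 16 the permutation null is enumerated exactly over all C(n, n_x)
  midrank assignments (ties handled exactly), with two-sided
  p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1; larger samples use the
  tie-corrected normal approximation.

## Reproducibility and problem sizes

All randomness flows from a single master seed through named
per-animal streams.  Pipeline outputs are plain text with fixed float
formatting, so identical configs reproduce byte-identical files; the
run manifest records the config hash and per-file SHA-256 digests.

The test-suite and acceptance-script simulations use one to twenty
seeded replicates of 1-2 recording days, 2-h REM blocks for TPF, 2000
genes for the screen and ≤ 12-node graphs for the exhaustive network
oracle — sizes chosen so every check reruns from scratch in seconds to
a couple of minutes while keeping the Monte-Carlo bands (3 SE, binomial
CIs, 18/20 and 19/20 success counts) meaningful.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the analysis
assumes: diurnally modulated Markov bout alternation, state-conditional
spectra, homeostatic SWA rebound, nocturnal activity with a declining
tail, planted expression amplitudes.  It does not attempt EEG
morphology (spindles, K-complexes, phasic REM events), cortical
topography, inter-animal variance components beyond independent seeds,
circadian period deviations from exactly 24 h, or probe-level
microarray artifacts.  Passing tests therefore certify the estimators
and their identities on data with known ground truth — not the
biological conclusions of any particular recording.  Hypnogram
dynamics are first-order Markov; real bout-length distributions are
heavier-tailed, so architecture metrics on real data will be noisier
than the synthetic bands suggest.
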