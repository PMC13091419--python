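# Methods

`hiephys` quantifies how a neonatal hypoxic-ischemic (HI) insult reshapes
adult cortical and hippocampal single-unit activity.  The pipeline takes
sorted spike trains, simultaneously recorded LFPs, averaged spike waveforms
and session metadata for four hemisphere-groups (sham left/right, HI
contralateral, HI ipsilateral) in two regions (retrosplenial cortex,
hippocampal CA1), and produces per-unit and per-group measures of firing,
bursting, pairwise synchrony, spectral band content, spike-field phase
coupling, and longitudinal identity/learning response.  A synthetic-cohort
generator provides fully reproducible inputs with the same statistical
structure, so every stage is testable without the in-vivo recordings.

## Data model and conventions

Spike times are absolute seconds in double precision; all binning uses
half-open bins `[start, end)` so edge spikes count once.  LFPs are uniform
microvolt traces with an explicit sampling rate.  The default analysis rate
for spectral work is 500 Hz after anti-aliased resampling; with 256-point
Welch blocks this gives 1.95 Hz resolution.  (The combination of a 256-point
block, a 0.5-100 Hz analysis range and a 0.4 Hz resolution cannot hold
simultaneously, so the analysis rate is a configuration parameter rather
than a constant.)  Frequency bands are delta 0-4, theta 4-8, alpha 8-12,
beta 12-30, gamma 30-50 Hz; the spike-LFP coupling band is theta-alpha,
4-12 Hz.

## Cell-type and discharge-pattern classification

Putative interneurons (IN) are narrow, fast units: trough-to-peak time below
0.4 ms (cortex) or 0.25 ms (CA1) *and* mean rate above 15 Hz.  Putative
pyramidal neurons (PN) are wide, slow units (at-threshold values fall on the
wide/slow side).  The two off-diagonal quadrants are left unclassified and
excluded from group composition statistics, since only the two diagonal
quadrants are defined classes.

Discharge pattern is decided by chi-square template competition on the
inter-spike-interval histogram (50 equal bins up to the 99th ISI
percentile):

- **regular** — narrow Gaussian at the mean ISI (sd = max(10 % of the mean,
  one bin width));
- **irregular** — exponential at the train's mean rate (Poisson firing);
- **bursting** — two-component mixture: an early quasi-normal peak located
  at the median of the short-ISI subset (intervals below half the mean) plus
  an exponential tail fit to the long-ISI subset, mixed by the short-ISI
  mass fraction.

All template parameters are estimated from the train itself, never
free-fit, so the statistic is reproducible; template bin probabilities are
floored at 1e-6 before forming the statistic.  A single early-peak Gaussian
cannot represent the strongly bimodal ISI distribution of a bursting unit,
which is why the bursting template is a mixture.  Trains under 50 spikes
stay unclassified.  The label depends only on ISIs and is invariant to time
translation.  Calibration on the generator: homogeneous Poisson trains
classify irregular in >= 95 % of seeds, periodic trains regular, and
burst-injected trains bursting across the generator's default burst regime.

## Burst detection (Poisson surprise)

The surprise of a window holding `n` spikes over `T` seconds against a
baseline rate `r` is `S = -ln Pr[N >= n]`, `N ~ Poisson(rT)`, computed
through the regularized incomplete gamma function (`scipy`'s Poisson
survival function) so deep tails do not underflow; natural logarithm, so the
acceptance threshold 5 corresponds to a tail probability below `e^-5`.  The
baseline is the whole-train mean rate (configurable).

Detection seeds wherever local firing outruns the baseline: at any single
ISI below half the mean ISI, or any two adjacent ISIs summing below the mean
(three spikes inside one mean interval); adjacent marks coalesce into
maximal seed runs.  Around each seed the surprise is maximized exhaustively
over all windows intersecting the run, with boundaries allowed up to 15
spikes past either end (spikes outside a seed carry long intervals, so the
maximum never strays far).  Windows reaching `S >= 5` with at least 3 spikes
are accepted; overlapping windows merge only when the merged window's
surprise is no less than either component, otherwise the better window wins.
This bounded-exhaustive variant agrees with full window enumeration on every
one of 1000 randomized small trains in the validation suite, which a purely
greedy extend/trim search does not (it stalls in local optima).  A pure
run-of-three-short-ISIs seed rule was rejected because the minimal 3-spike
burst only has two intervals.

Burst duration is last-spike minus first-spike time; the load summaries are
`% spikes in bursts` and `% time in bursts`.  Note that at threshold 5,
surprise maximization accepts occasional chance windows in featureless
Poisson trains (that is a property of the statistic, not a bug); recovery
tests therefore compare the configured burst load net of a matched-baseline
chance estimate.

## Synchrony

Instantaneous rates are 12.5 ms binned counts divided by the bin width and
smoothed with a Gaussian kernel (default sigma 25 ms = 2 bins; unstated
upstream, chosen to suppress bin noise while preserving burst-scale
structure).  Pairwise synchrony over a task window is the squared Pearson
correlation R^2 of two smoothed rate series; matrices are symmetric with
unit diagonal, zero-variance series yield zero entries with a warning.
Display order comes from average-linkage agglomerative clustering on
distance 1 - R^2; ties are broken by an index-ordered epsilon on the
condensed distances and each dendrogram node is oriented so the subtree
containing the earliest input unit comes first, making the leaf order
deterministic (an identity matrix reproduces the input order).  Matrix
similarity across sessions is the Pearson correlation of strict upper
triangles.

Spike-spike coherence bins both trains at 1000 Hz (configurable; unstated
upstream), mean-subtracts, and applies Welch magnitude-squared coherence
(Hann, 256-sample blocks, 5 % overlap); the scalar per-pair summary is the
mean over 0.5-100 Hz.  Correlograms histogram all pairwise spike-time
differences within the lag range; autocorrelograms exclude self-pairs.

## Fields and phase

Power spectra are Welch estimates (Hann, density scaling) satisfying
Parseval within 5 %; band content is the trapezoidal area under the density
within each band.  Spike-field coherence grids the train on the LFP samples
as a mean-subtracted 0/1 series (simultaneous spikes within one 2 ms sample
collapse, logged) and band means average the coherence over each band's
frequencies (averaging, not peak-picking, was chosen for stability; it is
configurable).  The 5 % block overlap is used verbatim even though 50 % is
more common, because it is the stated analysis parameter.

Band phase comes from a zero-phase 4th-order Butterworth band-pass followed
by the analytic signal; phase 0 sits at the oscillation peak and pi at the
trough (cosine convention).  Spike phases read the nearest LFP sample.
Locking is summarized by:

- **PLV** `R = |n^-1 sum exp(i theta_k)|` with the mean resultant angle;
- **Rayleigh test** `Z = nR^2`, small-sample-corrected
  `p = exp(sqrt(1+4n+4(n^2-(nR)^2)) - (1+2n))`, clipped to [0, 1];
- **Modulation index** — the entropy-based index over 18 phase bins,
  `MI = (ln N - H(p)) / ln N`.

For a unit's spike-field coupling, MI is applied to the spike-phase
histogram (spiking activity as the amplitude distribution over phase bins):
an unlocked unit fills bins evenly (MI near 0), a tightly locked unit
concentrates them (MI toward 1).  The generic phase/envelope form of MI is
also provided for LFP phase-amplitude coupling.  A separately reported
sine-based conversion of PLV to degrees is not a well-defined transform, so
PLV in [0, 1] and the mean angle in degrees are reported side by side.
Printed MI magnitudes from the original recordings are not reproducible
(their normalization is unclear) and are not asserted anywhere.

## Spike detection and waveform features

Wideband traces are zero-phase band-passed 600-6000 Hz.  Spikes are
negative-going crossings of -50 uV cut into 40-sample windows (30 kHz) with
a one-window refractory lockout and the crossing aligned at sample 10 (the
alignment sample is unstated upstream; configurable).  Features: trough to
subsequent peak time (ties to the earlier sample), trough width at half
depth with sub-sample linear interpolation, peak amplitude, and
whole-session mean rate.  Cluster cutting itself is out of scope — the
package consumes pre-sorted units; a sign-fixed, variance-ordered
principal-component projection is provided for visualization only.

## Longitudinal tracking

Unit identity across days is scored by four measures: maximum time-shifted
waveform correlation (Fisher-z-transformed, r clipped to +/-0.9999),
normalized trough-to-peak amplitude change `|A_k - A_1| / A_1`, and KL
divergences between log-binned ISI histograms (100 log bins, 0.5-1e5 ms; a
printed upper limit of "105 ms" is read as 10^5 ms, since a log scale over
0.5-105 ms in 100 bins would be pointless) and between +/-100 ms
autocorrelograms (100 bins).  Histograms get additive smoothing 1e-6 before
normalization, keeping KL finite; the log-transformed KL is also reported
for thresholding.  Stability thresholds are calibrated from within-day
split-half pairs of the same units (99th percentile of the three
dissimilarity scores, 1st percentile of Fisher-z), combined conjunctively —
a pair is stable only if all four measures fall on the stable side — and the
calibration's own failure rate is reported as the false-negative estimate.
The conjunctive rule is one defensible reading of a criterion whose
combination rule is unstated; it is the strictest, so reported stable chains
are conservative.

Learning response over the 7-day x 3-trial rotarod series regresses each
unit's per-session spike-field coherence on session index (restricted to
sessions with task-on time) and classifies by quadrant on (R^2, mean
coherence): high/high reactive, low/low non-reactive, low-R^2/high-coherence
HI-affected.  Default thresholds are the per-feature cohort midrange
(midpoint of min and max).  Cohort medians were considered and rejected as
the default: when the two high-coherence classes form the majority, the
median falls inside the high cluster and splits it, so median thresholds
cannot separate bimodal cohorts regardless of sample size.  Both rules and
explicit thresholds are available.

## Synthetic cohort generator

The generator encodes the study conditions; its defaults are the conditions
under which all recovery tests run.

- **LFP** — one sinusoid per band (at the band centre, seeded random phase)
  plus white noise; sham amplitudes taper 8/5/4/3/2 uV from delta to gamma
  with 5 uV noise, the ipsilateral table triples theta (15 uV) to model the
  pathological theta excess.
- **Spike trains** — homogeneous Poisson background with injected bursts
  (Poisson onsets, Poisson-count sizes, fixed 5 ms intra-burst ISI — fixed
  so the surprise of an injected burst is analytically predictable).
- **Phase locking** — inhomogeneous Poisson by exact thinning of a max-rate
  candidate stream with intensity `rate * exp(kappa cos(phi - mu)) / I0(kappa)`;
  kappa = 0 reduces exactly to homogeneous Poisson and the stationary spike
  phase distribution is von Mises, giving the closed-form PLV oracle
  `I1(kappa)/I0(kappa)`.
- **Shared modulation** — a common ~1 Hz-bandwidth log-rate signal (lowpass
  filtered white noise, clipped at 3 sd, variance-centred so the mean rate
  is preserved) drives pairwise R^2 without duplicating spike times.
- **Waveforms** — two-lobe Gaussian templates on 4 channels with fixed
  gains; (sigma, peak position) are calibrated by a secant/fixed-point loop
  against the *measured* features, so the noiseless round trip through
  feature extraction is exact up to the sample grid.
- **Cohort defaults** — 8 PNs per group/region (4 ipsilateral: the ~50 %
  unit deficit), 5 Hz sham vs 3 Hz ipsilateral PN rates, burst injection
  0.5/min sham vs 6/min ipsilateral (~20 % burst-spike load), shared
  modulation 0.8 and kappa 4 ipsilateral only, one 20 Hz narrow-spiking IN
  per cell, 300 s sessions at 500 Hz LFP rate.  Durations and counts are an
  order of magnitude below the in-vivo sessions — effect directions and
  parameter recovery are what the defaults are sized for, and the
  ipsilateral effect sizes are order-of-magnitude choices, not published
  effect sizes (none are published).
- **Learning series** — reactive coherence ramps 0.10 to 0.70 across 21
  sessions, non-reactive constant 0.10, HI-affected constant 0.60, all with
  sd 0.04 noise; sham latencies ramp 60 s toward the 300 s cap, HI latencies
  stay flat at 60 s.

What the generator does *not* emulate: refractory periods, rate
non-stationarity across a session, electrode drift, spike-sorting
contamination, volume conduction, cross-frequency coupling, or correlated
noise between channels.  Passing tests therefore demonstrate that the
analysis stages recover the statistical structure they target, not that
real recordings are this clean.

## Numerical choices and degenerate inputs

Poisson tails via `logsf` (no explicit summation); coherence clipped to
[0, 1]; empty trains, zero-variance waveforms, all-zero envelopes,
constant-filtered signals and undersized calibration sets all raise with a
message naming the offending object; duplicate spike timestamps collapse
with a warning (a data-quality signal, not an error).  Every generator and
the full pipeline are pure functions of (parameters, seed); the run summary
written next to results records parameters, seed and input digests
sufficient to re-execute a run identically.

## Known limitations

- Inferential group statistics (ANOVA and post hoc tests) are intentionally
  out of scope; the pipeline emits the per-unit tables such tests consume.
- The burst detector's bounded-exhaustive search is validated against full
  enumeration on small trains; for pathological trains whose every interval
  is short (no internal rate contrast) the seed rule finds nothing — by
  construction such trains contain no *local* burst.
- Tort-style MI magnitudes depend on the bin count (18 here) and, for the
  spike-histogram form, on the spike count; comparisons are meaningful
  within a configuration, not across publications.
- Stability calibration needs >= 10 within-day units; percentile thresholds
  are noisy below a few dozen.
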