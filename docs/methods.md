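# Methods

This note documents the models, conventions, numerical choices and known
limitations of `msephys`.  Units: time in seconds (ms where stated), rates
in Hz, LFP in microvolts, angles in degrees at the API surface (radians
internally), stereotaxic coordinates in mm.

## Data model and conventions

Behavioural epochs are half-open intervals [start, end); a spike exactly at
an interval end belongs to the next epoch, never to two.  Spike trains are
strictly increasing and bounded by the recording interval; unsorted input
files are rejected by default (a config flag sorts on load) because silent
sorting can mask upstream spike-sorting errors.  Epoch restriction carries
its effective duration as the summed interval lengths, so rates computed on
restricted trains use behavioural time, not wall time.

## Rhythmicity index

The one-sided autocorrelogram uses 10 ms bins to 500 ms lag with ordered
pairs counted **within one epoch interval only** — a lag spanning excised
time is meaningless.  Bins are half-open [10k, 10(k+1)) ms; a 1e-6 ms
epsilon before flooring keeps lags constructed exactly on an edge from
drifting down a bin.  (A symmetric two-sided autocorrelogram is exactly
proportional, so normalisation and RI are unchanged; asserted in tests.)
Units with fewer than 300 restricted spikes are rejected as under-sampled
(config-overridable).

Normalisation divides by the maximum bin fully inside 100–200 ms — the
first theta side lobe — then clips values above 1 (the near-zero-lag
centre) to 1, so the overall maximum is 1.  A linear trend is then fitted
by OLS over bin centres in 50–500 ms; the clipped centre is excluded from
the trend because it would bias the intercept.  The detrended values are
fitted with g(t) = A·exp(−t²/2σ²)·cos(2πft) by bounded trust-region least
squares with a deterministic multi-start: f₀ ∈ {4.5, 6, 7.5} Hz, A₀ = the
detrended maximum, σ₀ = 100 ms; bounds f ∈ [4, 8] Hz, A ∈ [0, 2],
σ ∈ [20, 1000] ms; the lowest residual wins, ties go to the first start.
No RNG is involved anywhere in the fit.

RI is the mean of |g(t_k)|/trend(t_k) over the analytic extrema
t_k = k/(2f) in 50–500 ms, clipped into [0, 1].  Extrema where the trend
is ≤ 0 are skipped; if all are skipped, RI = 0 with a flag.  R² is
reported on the detrended values and set to 0 when the detrended variance
is at float-noise level (flat input).  Locating extrema analytically
rather than numerically on the fitted curve is exact and reproducible.

A caveat verified numerically: on a synthetic autocorrelogram built from
g(t) plus a flat trend, the OLS trend absorbs a small part of the decaying
envelope (the cosine does not average to zero on the 45-bin grid), so the
fitted (A, σ) and hence RI differ from the generating-function evaluation
by ~1e-2.  Frequency recovery is unaffected (within 0.05 Hz).

## Bursts, rates, speed

The burst ISI threshold is the mean ISI of the same state-restricted spike
set being segmented (the report statistic is RUN burst duration, so the
threshold is a RUN quantity).  An ISI exactly equal to the threshold joins
the burst (the exclusion test is strictly "greater").  ISIs spanning an
epoch gap enter neither the threshold nor the grouping — bursts cannot
bridge excised time.  Degenerate cases (no bursts, both rates zero) return
NaN with a warning so cohort tables keep one row per unit.

Speed modulation bins occupancy and spike counts at 1 cm/s above 2 cm/s
(bin edges [k, k+1)), assigns each spike the speed of the nearest sample,
and fits rate vs bin centre by weighted least squares with weights
√occupancy.  The p-value is the two-sided t-test on the WLS slope (the
correlation-based alternative is asymptotically equivalent; the slope test
is the one reported).  The class rule is positive (r > 0, p < 0.05),
negative (r < 0, p < 0.05), else none.

## Theta phase

Phase is anchored at troughs: the LFP is band-passed 4–12 Hz (zero-phase
Butterworth, order 3) per RUN epoch, troughs are local minima separated by
at least one period of the band's upper edge, and phase interpolates
linearly 0→360° between consecutive troughs.  This makes the phase exact
at the anchor that defines the 0° = trough convention; an analytic-signal
(Hilbert) alternative is available and agrees within two samples on clean
input.  Epochs shorter than two cycles of the band's lower edge are
skipped with a warning.  Zero-phase filtering leaves a small edge
transient: the outermost two or three troughs of an epoch can shift by a
few samples.

Rayleigh uses the standard approximation
p = exp(√(1+4n+4(n²−Rₙ²)) − (1+2n)), Rₙ = nR, with circular SD
√(−2 ln R); cross-checked against an independent circular-statistics
implementation in tests.  Watson's two-sample U² is computed on pooled
circular ranks (rotation-invariant; ties broken by stable ordering) with a
seeded permutation p-value (default 9999 permutations) rather than
asymptotic tables.  The angular–linear correlation follows
r² = (r_xc² + r_xs² − 2 r_xc r_xs r_cs)/(1 − r_cs²) with p from
n·r² ~ χ²(2).

## Ripples and LIA cycles

Ripple detection band-passes 130–240 Hz (the event definition used for the
peri-event analysis; the 130–230 Hz variant used for channel localisation
is available in config), forms the Gaussian-smoothed (~5 ms) magnitude of
the analytic signal, centres it on its REST **median** and scales by
1.4826·MAD of the band-passed REST signal.  Robust statistics keep the
threshold anchored to the noise floor: a plain SD is inflated by the
ripples themselves (costing recall), while the smoothed envelope's own SD
is so small that band-limited noise crosses five of them about once per
100 s.  Events are contiguous regions ≥ 2 SD containing a ≥ 5 SD sample,
merged across < 10 ms gaps, kept if ≥ 20 ms, with the peak at the envelope
argmax.  The 5/2 SD thresholds follow common ripple-detection practice and
are config-exposed.

The ripple-modulation test compares, across events, the in-ripple rate
(spikes within [start, end] / duration) against a **duration-matched**
control rate taken at the left edge of the ±0.4 s surround.  Matching the
denominator is what keeps the two-sample KS test's type-I error near
nominal for an unmodulated unit: rates formed over a ~50 ms event and a
~750 ms surround have different discreteness and the KS test rejects them
under the null.  The peri-event firing-probability histogram (normalised
spike counts per bin, aligned to peak power) is unchanged by this choice.

LIA cycles: the REST LFP is resampled to 1 kHz, slow drift is removed with
a first-order high-pass of time constant 0.08 s (cutoff 1/(2π·0.08) ≈ 2 Hz
— zero crossings of a strictly rectified nonnegative signal would be
degenerate, so the time-constant step is implemented as drift removal
before crossing detection), and falling crossings (x[k−1] > 0 ≥ x[k]) are
accepted greedily with a 200 ms refractory.  The refractory comparison
allows one sample of tolerance because crossing times are only
sample-accurate; without it, exact-period signals quantised to the grid
alternate between dropping and keeping legitimate crossings.

## Classification

Features are exactly two-dimensional — rate-change score and RUN burst
duration — linearly rescaled per column to [−1, 1]; RUN rate is used only
for labelling.  Ward agglomeration on Euclidean distances (scipy linkage)
is cut at four clusters; an exhaustive merge-cost oracle verifies the tree
on small inputs in tests.  Silhouettes use the exact
(b−a)/max(a, b) formula with S = 0 for singleton-cluster members.
Labelling is rule-based on cluster medians (Komal = longer-burst of the
two positive-score clusters, group4 the other; group1 = most negative
score and lowest RUN rate; Teevra the remainder) with a deterministic
nearest-prototype fallback (prototypes (−0.05, 38), (0.21, 57),
(−0.3, 45), (0.27, 45) in rescaled space, one-to-one assignment) when the
rule does not apply cleanly.

## Synthetic sessions

The generator is **burst-based**, not rate-modulated Poisson: the report
metrics (burst duration, RI) are burst-structure statistics, so burst
parameters must be ground truth.  During RUN each theta cycle offers one
Bernoulli burst opportunity with probability rate·cycle/spikes_per_burst
(error if > 1); an accepted burst places spikes_per_burst spikes at fixed
intra-burst ISI with the burst **centre** phase drawn von Mises around the
preferred phase — centring (rather than onset-aligning) makes the spike
circular mean equal the preferred phase, which is what the phase analyses
estimate.  REST bursts occur at cycle-free Poisson times, so REST
rhythmicity is low by construction.  A 0.5 ms refractory is enforced when
merging.  The `poisson` archetype is a homogeneous Poisson control.

The LFP carries a theta cosine during RUN (troughs ground-truthed at
(k+½)/f), band-limited 2–6 Hz irregular activity during REST, embedded
Gaussian-windowed ripple transients (160 Hz, 50 ms, Poisson times, REST
only — ripples are a rest-state event) and broadband noise.  Default
amplitudes (theta 100, LIA 150, ripple 60, noise 10 µV) are typical
pyramidal-layer magnitudes.  Speed is a mean-reverting process around
15 cm/s during RUN and ~0 during REST.

Cohort draws take per-unit rate-change score, RUN rate and burst duration
uniformly from each group's published interquartile range (groups 1/4
burst ranges are not published; 40–50 ms sits between the Teevra and Komal
ranges).  Archetype phase preferences are trough (0°, κ=8) for Teevra and
160° (κ=3) for Komal, matching the published 160° group separation; the
Teevra concentration is chosen high because that group is the most
rhythmic.  One master seed fans out per-component seeds via
`SeedSequence.spawn`.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: theta frequency drift and
phase-precession-like dynamics (the synthetic theta is a constant-frequency
cosine, which makes synthetic Teevra units *more* rhythmic than real ones
— their RI saturates near 1 rather than the realistic ~0.3–0.6), spike
sorting noise and unit contamination, non-stationary rates within a state,
travelling theta waves across electrodes, and sharp-wave polarity
structure.  Session length defaults to 360 s (alternating 30 s blocks) so
a full 89-unit cohort analysis runs in seconds; all rate and burst
statistics are well-estimated at that length.

## Pipeline

`run_pipeline` computes per-unit metrics, applies the strict RI > 0.1
filter, clusters, labels, and compares Teevra vs Komal phase preferences
(Watson U², per-unit circular means) and phase-vs-RI coupling
(angular–linear).  It is deterministic given the session and the seed
(used only by the permutation test); unit counts are conserved and
reported per stage, and an empty post-filter cohort raises an error naming
the filter stage.  Report tables round rates/scores to one decimal and RI
to two, matching the field's reporting convention; full precision is kept
internally.

## Known limitations

* The RI of strongly locked synthetic units saturates at 1.0 (see above);
  comparisons across kappa are therefore tested in the unsaturated range.
* Watson U² uses permutation only; no asymptotic critical values.
* Ripple detection assumes a single reference channel; no cross-channel
  sharp-wave polarity check.
* The anatomical correlation helpers operate on user-supplied coordinate
  tables; no atlas registration is performed.
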