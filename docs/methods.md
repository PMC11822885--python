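# Methods

## The analysis in brief

The package asks a single question of a multichannel intracranial
recording from a delayed word-production task: *when, relative to voice
onset, does the neural signal begin to carry decodable information about
the intent to speak — and where?* The answer is built from causal
(past-only) high-gamma band-power features, a cross-validated nonlinear
classifier, and permutation-based significance, with two companion views:
a demixed-PCA state space separating intent from rest, and a clustering of
electrode envelope dynamics into production-like and perception-like
groups.

Assumptions: high-gamma (70–200 Hz) power tracks local cortical
activation; trial events (stimulus, go cue, voice onset/offset) are
labeled accurately in a shared clock with the neural data; the inter-trial
washout is long enough that "silence" windows contain no residual
task-related processing; electrodes are independent observations for the
clustering and per-electrode maps (no volume-conduction modeling).

## Band power with group-delay correction

High-gamma activity is extracted with a causal, linear-phase FIR band-pass
(Hamming-windowed sinc). The tap count follows the transition-bandwidth
rule `N = round(4·f_s/Δf)` with `Δf = 10 Hz`, i.e. N = 200/400/800 at
f_s = 500/1000/2000 Hz. Causal (one-way) filtering preserves the causal
interpretation of the features but delays the output by the group delay
`τ = (N−1)/(2·f_s)` — 199, 199.5 and 199.75 ms respectively. The squared
Hilbert analytic amplitude is therefore shifted backward by τ rounded to
the nearest sample; with even N this leaves a half-sample residual, well
inside the ±1-sample alignment the test suite enforces. The leading and
trailing τ of the record are masked invalid rather than extrapolated, and
the mask propagates: any feature window or epoch touching masked samples
drops that trial.

Line noise is removed beforehand with 2nd-order IIR notches applied
forward–backward (zero phase) at 60/120/180 Hz. The notch quality factor
is 50: with the forward–backward pass squaring the magnitude response, a
broader notch (Q = 30) measurably dents amplitudes 20 Hz away (>1% at
100 Hz), while Q = 50 keeps out-of-notch amplitudes within 1% and still
attenuates the line frequency by far more than 30 dB. Common-average
referencing uses only channels flagged good; bad channels are excluded
from the reference but still re-referenced.

Alpha (8–12 Hz) and beta (13–30 Hz) power go through the identical chain
when band-specific decoding is requested.

## Feature windows and classes

The decoding feature is mean band power in 100 ms non-overlapping windows,
1 or 4 per trial, concatenated across good electrodes in recorded channel
order. Windows are half-open `[start, end)`; sample indices are
`floor(t·f_s)` with a one-microsample guard so real-arithmetic boundaries
survive floating point. Class anchors:

- **speech intent** — windows end at `voice_onset + offset`; the offset is
  the sweep variable.
- **silence** — windows start 1.5 s after voice offset (0.5 s for
  auditory-cued tasks, whose inter-trial intervals are shorter); never
  offset, so the contrast class is identical across the sweep.
- **instructed delay** (control) — four windows ending 1.0 s after the
  stimulus disappears, covering the mid-delay period (0.9–1.0 s plus the
  three preceding windows). Decoding intent against this class controls
  for comprehension, lexical access and working memory, which are present
  during the delay; only the intent to vocalize is not.

Classes are balanced by subsampling the majority class without replacement
under a seeded generator, so a feature set is a pure function of
(envelope, events, offset, seed).

## Decoding protocol

Per offset: 20 outer iterations; each draws a stratified 80/20
train/test split, standardizes features by training statistics, runs a
5-fold cross-validated grid search over the SVM penalty C ∈ {0.1, 1, 10,
100} and RBF kernel width γ ∈ {0.01, 0.1, 1/d, 1, 10} (d = feature
dimension; grids configurable), refits the winner on the full training
set, and scores the held-out 20%. Ties in the grid search go to the
smallest C, then the smallest γ. The hyperparameter search is repeated
independently in every outer iteration.

Significance: the held-out test labels are shuffled against the fitted
decoder's predictions — 500 shuffles pooled round-robin across the 20
iterations — forming the empirical chance distribution. The p-value is the
add-one estimator `(1 + #{null ≥ observed mean}) / (1 + n_shuffles)`. When
the total number of distinct label arrangements across iterations is at
most `n_shuffles`, the null is enumerated exhaustively and the p-value is
the exact permutation probability. An offset (or electrode) is declared
significant only if its Benjamini–Hochberg-adjusted p clears α = 0.05
*and* its mean accuracy exceeds the null's 95th percentile; the dual gate
reflects that the two criteria are distinct statements and makes the test
conservative. The first significant offset of the sweep (−1.5 to +0.7 s in
0.1 s steps against silence; −0.2 to 0 s against the delay control) is the
latency estimate. Group-level significance pools datasets by averaging
their s-th shuffled accuracies into a group null.

Because the null pools single-shuffle accuracies while the observed
statistic is a 20-iteration mean, the permutation test is conservative on
null data; the type-I suite verifies the post-FDR false-positive rate
stays at or below the nominal 0.05.

## Demixed PCA

Trial-averaged high-gamma envelopes from the two conditions (intent: 0.5 s
before voice onset; silence: 1.0–1.5 s after voice offset) are smoothed
with a centered 4th-order Savitzky–Golay filter of 201 ms (odd sample
count at each rate: 101 at 500 Hz), mean-centered per channel, and split
into a condition-independent (time) marginalization — the across-condition
mean — and the condition-dependent residual. For each marginalization a
ridge-regularized reduced-rank regression of the marginalized data on the
full data yields decoder/encoder pairs; the ridge λ defaults to 1e-6 of
the total variance, enough to keep the solve well-posed without visibly
biasing components (a fixed default is used rather than a data-driven
search; on trial-averaged, smoothed envelopes the fit is insensitive to λ
over several orders of magnitude). Per-component explained variance uses
the standard R²-style credit of the rank-1 reconstruction against the full
centered data, `(2⟨X, F_j d_j X⟩ − ‖F_j d_j X‖²)/‖X‖²`, so components from
both marginalizations are on a common scale and, when the marginalizations
occupy distinct channel directions, sum to the total variance. Explained
variance on real data is a descriptive report field, not a fixed target.

## Envelope clustering

Each electrode's trial-averaged envelope from 1 s before to 0.5 s after
voice onset is smoothed with a Gaussian kernel (SD 25 ms — "width" is
interpreted as the standard deviation, configurable) and z-scored over the
window. K-means (Euclidean, 20 restarts per k) runs for k = 2…10; the
reported k sits at the elbow, formalized as the maximum positive second
difference of the mean within-cluster-distance curve (the original choice
was visual; the second difference is the standard automated surrogate).
Clusters are labeled by their centroid's onset — the first time it exceeds
its own baseline (first 0.25 s) mean + 2 SD: onset before voice onset →
production, at/after → perception, never → unmodulated. K-means is a hard
clustering; an electrode modulating with both production and perception is
assigned to exactly one cluster.

## The synthetic-data generator

`synthio` emulates the statistical structure the analysis assumes, not the
biophysics. Each channel is 1/f (pink) Gaussian background noise (10 µV
RMS) plus coherent 60/120/180 Hz line noise, a shared common-mode pink
component, and — on production/perception channels — band-limited 70–200 Hz
noise whose amplitude follows a raised-cosine ramp (200 ms) to plateau,
starting `production_lead` (default 300 ms, matching pre-vocalization
activation latencies in this literature) before voice onset, or
`perception_lag` (default 100 ms) after it, sustained through the word.
`modulation_snr` is the plateau amplitude in units of the channel's
background amplitude within the band; the default 2.0 reflects the two- to
four-fold high-gamma power increases typical of activated cortex, and the
high-SNR test fixtures use 5.0. Trial timing defaults: stimulus 1.5 s,
instructed delay 1.5 s (it must exceed 1 s for the mid-delay control
window to exist), go-to-voice reaction uniform on 0.3–0.8 s (the jitter is
what makes voice-onset locking distinguishable from cue locking), word
0.6 s, inter-trial interval 2.5 s — long enough that silence windows never
collide with the next trial. A single seed fans out through a
`SeedSequence` tree to per-channel and per-component substreams, so
recordings are bit-reproducible.

What the generator does **not** emulate: cortical geometry and volume
conduction, spike activity, movement or electrode artifacts, per-electrode
variation in high-gamma sub-bands, non-stationary background statistics,
and behavioral error trials. Passing tests therefore establish that the
pipeline recovers planted effects of realistic size and controls its false
positives under the stated noise model — not that real recordings will
yield the same accuracies or latencies.

## Test-suite problem sizes

End-to-end checks run at sizes chosen to exercise the full pipeline while
keeping the suite fast: parameter recovery uses 20 independent datasets of
8 channels × 150 trials at SNR 5 with 200 shuffles and a 2-point penalty
grid (the planted 0.3 s lead is recovered as a first significant offset of
−0.4…−0.2 s — the feature block first overlaps the planted ramp at −0.2);
type-I control uses 200 null datasets of 4 channels × 20 trials with
5 iterations and 100 shuffles each. Unit fixtures are 8 channels ×
40 trials. All sizes are set in the tests themselves, not in the package.

## Known limitations

- The per-electrode adaptive choice of high-gamma sub-bands used in some
  spectral exploration is replaced by the fixed 70–200 Hz band for all
  decoding; the z-scoring baseline for rasters is the displayed epoch
  window pooled across trials.
- Manual artifact review is replaced by a documented threshold utility
  (`exclude_artifacts`) with conservative defaults.
- The delay correction shifts by an integer number of samples; with even
  tap counts a half-sample residual remains (≤ 1 ms at 500 Hz).
- EDF import is available via the optional `mne` dependency; EDF export is
  not provided (the native binary + JSON container is the interchange
  format).
- `compare_contrasts` uses the exact rank-sum distribution only for
  tie-free samples of ≤ 25 per group, else the asymptotic approximation.
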