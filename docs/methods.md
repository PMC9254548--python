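# Methods

This note documents the models, conventions and numerical choices behind
`smrbci`, and what the synthetic-data experiments do and do not establish.

## Signal path

**Montage.** 14 EEG channels over sensorimotor cortex (Fz, FC3, FC1, FCz,
FC2, FC4, C3, C1, Cz, C2, C4, CP1, CPz, CP2) plus two frontal EOG channels,
512 Hz. Laplacian re-referencing subtracts from each channel the mean of
its orthogonal (cross-shaped) nearest neighbors on the 10-20 grid,
restricted to the recorded set; edge channels use whatever orthogonal
neighbors exist. The neighbor relation is validated to be symmetric.

**Spectra.** Analysis windows are 1 s long and slide every 62.5 ms
(window count = floor((T−1)/hop)+1). Each window's one-sided PSD comes from
Welch's method with 256-sample (0.5 s) Hamming-tapered sub-segments at 50%
overlap — the sub-segment length is forced by the 2 Hz bin-spacing
requirement at 512 Hz; overlap and taper are the conventional choices.
Sub-segments are constant-detrended (the mean is removed), which makes the
PSD invariant to DC offsets. Features are raw power by default; a log10
transform is a flag on the classifier, not a pipeline default, because the
discriminancy formula operates on PSD samples with no transform stated.

**Band definitions.** μ = 8–12 Hz, β = 16–26 Hz, both resolved into 2 Hz
bins. Channel-domain features average the bins inside the band.

**Band-pass for covariance.** 4th-order Butterworth applied
forward-backward (zero phase). Window covariance matrices are
C = XXᵀ/(T−1) after per-channel mean removal.

## EOG guard

HEOG = Fp1 − Fp2 and VEOG = (Fp1 + Fp2)/2 are filtered with a zero-lag
second-order Butterworth band-pass at 1–10 Hz; amplitudes are absolute
values of the filtered components. A 32-sample frame whose amplitude
exceeds 30 µV freezes command output until frame end + 2 s; overlapping
detections extend, never shorten, the freeze. The streaming guard keeps a
1 s trailing buffer, mirrors both edges before filtering, and reads back
the newest frame, so detection is causal at frame granularity; the batch
path filters the whole recording once and is the variant used in offline
analysis. The threshold applies to filtered amplitudes, not raw samples.
During a freeze the evidence integrator is *paused*, not reset (a flagged
design choice: the alternative of decaying toward uniform is available via
the integrator's sentinel handling). Windows overlapping a freeze interval
are excluded from every downstream metric.

## Decoder

**Feature ranking.** Two-class canonical variate analysis has a single
canonical axis — the ridge-regularized within-class-whitened mean
difference. Each (channel, bin) feature's discriminant power is its squared
canonical loading (correlation with the canonical scores) times the
canonical correlation; ties break deterministically by channel order then
frequency. Batch selection takes the top-k, with previously used features
force-included when their current score clears a configurable floor — the
stability policy used across re-calibrations.

**Classifier.** Each class is a mixture of M = 2 diagonal-covariance
Gaussian prototypes with uniform within-class weights and equal class
priors. Prototype means are initialized by a 1-D ring SOM over that class's
feature vectors (batch updates, 200 epochs, exponentially shrinking
neighborhood), variances by the within-assignment variance; means and
log-variances are then refined by full-batch gradient descent on the
posterior cross-entropy (learning rate 0.01, max 500 epochs, stopping when
the loss decrease falls below 1e-6). Variances are floored at 1e-6 of the
per-feature data variance, with a warning when the floor binds. The
posterior is computed with log-sum-exp stabilization and verified against
a brute-force Bayes oracle to 1e-10.

**Rejection and integration.** Samples with max posterior below 0.6 are
rejected (boundary inclusive on the accept side). Accepted posteriors p
update the integrator state y ← y + α(p − y), α = 0.1 by default, clipped
to [0,1] and renormalized. Pure convex averaging can never literally reach
1, so a command is delivered when max(y) ≥ 1 − ε_cmd with ε_cmd = 0.025;
the state then resets to (0.5, 0.5) and integration pauses for the 1 s
refractory period, which is what makes two command-worthy bursts 0.4 s
apart deliver exactly one command. Under constant (1,0) evidence the state
follows y_n = 1 − 0.5(1−α)ⁿ, so the first command fires at the smallest n
with y_n ≥ 1 − ε_cmd — n = 29 frames (1.8125 s) at the defaults; the tests
recompute this closed form rather than fixing the number. With no decisive
evidence the state idles near uniform and no command is ever sent (the
intentional non-control state).

## Riemannian geometry

The affine-invariant metric was chosen over log-Euclidean to match the
covariance-geometry literature this analysis builds on. Distances are
computed by Cholesky whitening (eigenvalues of L⁻¹BL⁻ᵀ with A = LLᵀ)
rather than explicit inversion, for conditioning. The Karcher mean uses the
classic tangent-space fixed point M ← M½ exp(mean log(M^{-½} C_i M^{-½})) M½,
initialized at the arithmetic mean, tolerance 1e-8 on the tangent-mean
Frobenius norm, 50 iterations by default. Band-passed 1 s window SCMs are
badly conditioned (out-of-band directions carry almost no power; condition
numbers reach 1e6), and the full-step iteration can oscillate or diverge on
such sets, so the step is halved whenever the tangent residual stops
shrinking; the metric layer also allows up to 150 iterations. Rank-deficient
covariances are shrunk by ε·I with ε = 1e-10 · trace/C and the event is
warned about; windows of 512 samples over 14 channels are numerically
full-rank, so this fires only on degenerate inputs (e.g. duplicated
channels).

## Learning metrics

bcDist = δ(μ_bh, μ_bf)/(σ_bh + σ_bf) within a run; wcDist =
δ(μ_1, μ_r)/(σ_1 + σ_r) for one class between run r and the chronologically
first run of the history, reported class-averaged. In the channels' domain
δ is the Euclidean distance between arithmetic means of 14-vector band
powers and σ the *mean Euclidean distance* of windows to their class mean
(the "average distance around the mean"); in the Riemann domain δ is the
geodesic distance between Karcher means and σ the mean geodesic dispersion.

Two dispersion conventions coexist because the mean-distance denominator
and an exact one-dimensional reduction to the Fisher score
FS = |μ₁−μ₂|/sqrt(s₁²+s₂²) are algebraically incompatible (a sum of mean
absolute deviations is not a quadrature of standard deviations). The
default is the mean-distance convention; `convention="fisher-sd"` uses
quadrature-combined sample SDs, under which the 1-D channels'-domain bcDist
equals FS to machine precision — the equivalence the algebra tests check.

Topographic discriminancy maps average the per-bin Fisher score over the
β-band bins per channel. Decoding performance is sample-by-sample, before
integration, on artifact-free labelled windows: rejection is the share of
samples below the rejection threshold; accuracy is over accepted samples
only and is flagged undefined when everything is rejected.

## Statistics

Trends are Pearson correlations against run index with two-sided p from
t = r·sqrt((n−2)/(1−r²)), evaluated per training period; constant series
report r = 0, p = 1 with a degenerate flag instead of erroring, so batch
reports never abort. Group comparisons (first vs last 15 runs of each
period) use the tie-corrected Kruskal–Wallis omnibus and, when it is
significant at 5%, Tukey–Kramer pairwise comparisons on pooled-rank means
with the studentized-range approximation at infinite degrees of freedom
(rank-based by choice; the raw-value variant is a one-line change in the
caller). Section crossing times use unpaired two-sided Wilcoxon rank-sum
tests per section type. All three wrappers are calibration-tested: their
type-I error stays near the nominal 5% over seeded null replicates
(200 replicates in the suite; the generator contract is stated over ≥ 500).

## Race game

Tracks are seeded uniform permutations of 16 sections, four each of right /
headlight / left / no-input. Both-hands maps to "left", both-feet to
"right"; an opposite-type command within 2 s of the previous delivered game
command is emitted as "headlight" (so a headlight can never be first).
The real game's kinematics are unpublished; the simulator's speeds are
package defaults — base 0.6, boost 2.75, penalty 0.25 units/s over 10-unit
sections, 2 s penalty interval, 240 s cap — chosen so that a perfect pilot
finishes near 110 s, a silent pilot hits the cap, and per-section times
order correct < none < wrong. The accuracy-parameterized pilot draws one
uniform variate per (seed, section), which makes race time monotone
non-increasing in accuracy at fixed seed by construction of the coupling.
Whether penalties stack and the exact deceleration profile are config,
not claims.

## Synthetic EEG generator

The generator is the package's verification substrate: it produces
sessions with the statistical structure the analysis assumes, plus the
ground truth needed for parameter-recovery tests. One session is 15 cued
trials per class, 4.5–5.5 s each, 1.5–2.5 s inter-trial gaps, 0.5 s
cue-to-task latency (task labelling excludes the first 0.5 s after the
cue, since no reaction alignment is specified by the protocol).

Components, per run r:

* **Background**: spatially correlated 1/f noise — per-channel spectrally
  shaped white noise mixed through the Cholesky factor of a squared-
  exponential correlation kernel on the 10-20 grid (correlation scale 1.5
  grid units, 8 µV RMS). Spatial correlation is what makes the Laplacian
  filter do nontrivial work.
* **Baseline rhythms**: per band, three band-limited Gaussian-noise
  sources (not sinusoids, so PSD features have realistic variance) with
  amplitudes spread 1.3:1:0.7, mixed through a fixed random orthonormal
  channel pattern (μ: 3.0, β: 2.5 µV RMS per source).
* **Task modulation**: during a trial of class c, extra band-limited
  carriers are added at that class's channels (hands: C3/C4; feet:
  Cz/FCz/CPz) with amplitude depth·g(r)·3 µV and 0.2 s raised-cosine
  ramps. The separability trajectory g(r) is the programmed ground truth
  recovered by the bcDist/accuracy trend tests; g = 0 yields chance-level
  decoding, depth 0.8 at g ≈ 1 yields > 90% single-sample accuracy.
* **Within-class drift** d(r), per band, with two generative components:
  a multiplicative baseline power shift (gain 0.9 in μ, 0.15 in β) and a
  rotation of the band's mixing pattern in channel space (up to ~1 rad at
  d = 1), plus per-run lognormal power jitter (σ = 0.12) and a small
  random rotation wobble (0.08 rad) representing day-to-day variability.
  μ drift is power-dominant (visible to channel-domain metrics and reset
  by a break), β drift rotation-dominant (visible to the Riemannian
  metrics and retainable) — the generative counterpart of the
  channels-vs-Riemann dissociation the metrics are designed to expose.
* **Break semantics**: after the configured break run, every band's power
  shift restarts from its day-one level; the mixing rotation is kept for
  retained bands (β in the canonical template) and restarted for the rest
  (μ). Retaining the rotation keeps the β covariance structure, so the
  Riemannian β within-class distance is continuous across the break while
  the channel-domain and μ metrics drop — the recovery property the
  acceptance suite checks with rank-sum tests.
* **EOG artifacts**: Poisson blinks (6/min, 150 µV raised-cosine bumps of
  150–400 ms, same sign on both EOG channels, 12% bleed into frontal EEG)
  and saccades (2/min, opposite-sign). Events are logged in the ground
  truth, which is what recall is measured against.

Everything is deterministic given (seed, run index): structural elements
(mixing patterns, rotation planes, the spatial kernel) derive from the
seed alone, per-run noise from seed ⊕ run index, so histories are
reproducible run by run and identical configurations are byte-identical.

All amplitudes and rates are free configuration, fixed once at values a
practitioner would call typical for sensorimotor EEG; they are *not*
estimates of any particular user's signals. The canonical study templates
(`growth_history_config`, `break_history_config`) let separability and
drift ramp linearly and, in the break template, plateau by run 10 —
consolidation before a competition — because a still-rising drift at the
break would confound the across-break comparison with the within-period
trend.

**What the generator does not emulate**: volume conduction from a real
head model, non-stationary noise floors, electrode impedance drift,
EMG, line noise (the hardware chain's 0.1–100 Hz band-pass and 50 Hz
notch are assumed already applied), or session-length fatigue effects.
Passing recovery tests therefore shows the *analysis* is correct and
sensitive to the programmed effects at realistic SNR — not that any
particular real user will show them.

## Problem sizes in the batch runs

The test suite and the acceptance script analyse histories of 28–30 runs
with the full 15-trials-per-class session template, but use a 250 ms
analysis hop (instead of the online 62.5 ms) for the run-level metrics;
this cuts window counts fourfold with no change in the metrics' expected
values, only a modest widening of their run-to-run noise. Unit tests use
smaller sessions (4–5 trials per class) where only the code path, not the
statistical power, is under test.

## Known limitations

* The evidence integrator is an exponential accumulator chosen as the
  simplest dynamics preserving the observable contract (accumulation,
  non-control idling, delivery-at-1 with uniform reset, refractory); the
  original dynamical-system formulation it stands in for is not public.
* The Karcher mean on badly conditioned SCM stacks relies on step
  damping; extremely degenerate stacks may still return the best iterate
  with a warning rather than a converged mean.
* The race simulator preserves orderings, not absolute times, of the real
  game.
* Tukey–Kramer on rank means uses the studentized-range approximation
  with infinite degrees of freedom; exact small-sample behavior is not
  claimed.
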