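# Methods

This note documents the models, conventions and numerical choices behind
`icophys`, in the order data flows through the package.

## Stimulus models

**Frequency grids** are exactly geometric (`numpy.geomspace` with endpoints
pinned), so consecutive ratios are constant to 1e-9 relative tolerance and
octave arithmetic on grid indices is exact.

**Tone trains.** Defaults follow the standard tuning protocol: 50
frequencies spanning 3–70 kHz, 50 ms tones, 450 ms inter-stimulus interval,
20 repeats per frequency, 70 dB SPL. "Alternating" laser pairing is fixed
as: even presentation indices (0-based) are laser ON. The pseudo-random
order is constrained to be laser-balanced — even (ON) and odd (OFF) slots
are each filled with an independently shuffled multiset containing every
frequency `n_repeats/2` times — so that, for even repeat counts, every
frequency appears equally often in both conditions. An unconstrained
permutation would leave per-frequency ON/OFF counts binomially imbalanced,
which leaks stimulus preference into the ON−OFF contrast of tuned units.

**Click trains.** Six 50 ms clicks at 50 ms ISI, 450 ms between trains,
alternating trains paired with a 1 s laser pulse leading the train by
250 ms.

**Dynamic random chords (DRC).** 20 ms chords of 50 bands (5–40 kHz); each
chord × band level is i.i.d. uniform. Given only a mean (50 dB SPL) and SD
(20 dB), the unique uniform distribution with those moments is used:
`[mean − √3·SD, mean + √3·SD] ≈ [15.4, 84.6] dB`; an explicit range can be
supplied instead. Laser epochs (250 ms every 1 s by default) are placed at
the **end** of each cycle, so the equal-length window immediately preceding
every laser onset — which the ON/OFF chunking requires — always lies inside
the stimulus. The cycle phase is configurable.

No audio is rendered: all analyses operate on event times and chord-level
matrices, so the stimulus objects are symbolic schedules. Time is seconds
from session start; every interval is half-open `[onset, onset+duration)`.

## The generative model (simulator)

Units are linear–nonlinear–Poisson. The stimulus drive is either Gaussian
tuning on log2 frequency, `A·exp(−log2(f/BF)²/(2σ²))`, active during the
(latency-shifted) tone window, or a planted STRF applied to chord-level
deviations with lags strictly preceding the spike bin — the same lag
convention the estimator uses, so recovery tests compare like with like.
The nonlinearity is half-wave rectification applied after summation; spikes
are drawn by thinning a homogeneous Poisson proposal against the
piecewise-constant rate evaluated at 1 ms resolution.

The laser effect is deliberately separable, mirroring how feedback effects
are reported: while the effect window (laser pulse shifted by a latency,
default 5 ms — no effect latency is established, so a small physiologically
plausible value is used and exposed) is active, the spontaneous rate gets
an additive offset `spont_delta` (Hz) and the stimulus-driven component is
multiplied by `evoked_gain`. The gain never touches the spontaneous
component and the offset never touches the evoked component; both are free
testing parameters, not estimates of biology.

Population defaults are chosen to be realistic for IC units: spontaneous
2–8 Hz, peak evoked 15–45 Hz (yielding evoked magnitudes around 8–24 Hz,
the scale seen in recordings), bandwidth 0.3–1.0 octaves, onset latency
5–15 ms, best frequencies log-uniform over the central 80% of the stimulus
range. Planted STRFs are Gaussian bumps with σ = 2.5 lag bins × 2.0
frequency bins (temporal FWHM ≈ 29 ms, matching reported lobe widths) at
random positions, scaled so the chord-driven rate SD is ~10 Hz.

What the generator does **not** emulate: refractoriness and spike-history
effects, adaptation, rate nonstationarity, across-unit correlated
variability (unless injected), off-BF inhibitory sidebands, and any real
coupling between spontaneous and evoked changes. Passing recovery tests
therefore demonstrates that the analysis chain is correct and calibrated
for Poisson-like data with separable laser effects — not that real IC
neurons satisfy those assumptions.

## Response metrics

Windows are half-open relative to tone onset; a spike exactly at onset is
evoked. The evoked window is 75 ms from onset. The spontaneous window ends
at onset and is protocol-dependent: 20 ms for the feedback protocol (so the
−100 ms and −20 ms laser-onset conditions are comparable) and 50 ms for
interneuron-style protocols.

**Preferred-frequency selection.** Per-unit metrics are computed over
trials of the 7 frequencies with the highest evoked response. The selection
curve is the **pooled** (ON+OFF) tuning curve. Selecting on one condition's
trials and then comparing conditions on those same trials is winner's-curse
biased: the selected condition's rates are inflated by selection noise,
which manifests as a spurious evoked-magnitude "decrease" of several Hz
under a null laser effect. Pooled selection shares the selection noise
equally between conditions and leaves the ON−OFF contrast unbiased;
`top_frequencies` accepts any tuning curve for users who want the
single-condition variant.

**Responsiveness screen.** A unit is kept if its mean evoked rate over
top-7 laser-OFF trials is ≥ the spontaneous mean + 2 SD, where mean and SD
are over the same trials' per-trial 50 ms pre-onset rates. Zero-variance,
zero-evoked units are excluded with a degenerate flag. Multi-unit quality
requires <1% of inter-spike intervals below 1 ms.

**Sparseness** uses raw 75 ms-window rates (not spontaneous-subtracted):
non-negativity keeps the statistic inside `[0, 1 − 1/n]`, and the additive
laser offset then shows up as the expected sparseness decrease. Subtraction
is available but can produce negative inputs.

**Ranked linear fits.** The 50 per-frequency mean rates are independently
sorted ascending within each condition and ON is regressed on OFF by OLS —
the rank-matched response-function construction, which insulates slope and
intercept from best-frequency shifts. Slope < 1 indicates a divisive
component; intercept > 0 an additive one. The unsorted pointwise pairing is
available via `ranked=False`.

**Stratification.** Subgroup flags (spontaneous/magnitude increase or
decrease) compare the ON−OFF change against 1 SD of the unit's own
laser-OFF per-trial values, from the −100 ms reference session; the
across-trial (rather than across-unit) SD is used because the flags are
per-unit. Ties everywhere break toward the lowest frequency / earliest
index.

**Click and laser-only windows** (not standardized anywhere): click-evoked
rate is the mean over the train span; click spontaneous is a 250 ms window
ending at laser onset (laser trials) or the matched pre-train window.
Laser-alone responses use `[onset, onset + max(duration, 25 ms))` against
the matched window on interleaved no-laser sweeps, with the change also
expressed in units of the OFF-sweep SD.

## STRF estimation and significance

Each 1 s laser cycle contributes an ON chunk (the 250 ms laser epoch) and
an OFF chunk (the 250 ms immediately before laser onset). Chord levels are
upsampled to 5 ms bins by nearest-neighbour replication (the chord duration
must divide by the lag bin) and expressed as deviations from the nominal
mean level. The estimator is the mean pre-spike deviation window minus the
mean window over all valid anchor bins (bias correction), combined across
stimulus files with per-file spike-count weighting (unweighted averaging is
available). Spikes whose 100 ms (default) lag history would cross a chunk
boundary are discarded rather than padded, so ON and OFF stimulus history
never mix; every spike is accounted for as ON, OFF, or discarded. The lag
extent must not exceed the chunk length; lag bin 5 ms and max lag 100 ms
are defaults, both configurable.

Significance is a scrambled-spike permutation test. Scrambling is a per-file
circular shift by a uniform random offset, preserving spike count and ISI
structure. Per repetition, an ensemble of 20 scrambles yields a per-pixel
null mean and SD; the real STRF is z-scored against them, thresholded at
|z| ≥ 3, and clusters (8-connectivity, signed) smaller than the 95th
percentile of the null maximum-cluster-size distribution are rejected. The
repetition runs 100 times by default and pixels significant in more than
90% of repetitions form the final mask (the >90/100 persistence rule; the
threshold scales as `round(0.9·n_reps)` when fewer repetitions are used).
The z-threshold, cluster criterion and null-ensemble size are package
choices — the original cluster-statistics settings are not published — and
all are exposed in configuration.

Lobes are 8-connected components of same-signed significant pixels. Peak
time/frequency come from the extreme pixel (ties → earliest lag, lowest
frequency); temporal width is the lag extent; frequency width is the octave
extent. ON/OFF lobes of the same sign match when the shared pixel count is
at least 50% of the smaller lobe (boundary inclusive), greedily by
descending overlap; persistence is matched-OFF / total-OFF per sign.

## Statistics

The paired Wilcoxon sign-rank test drops zero differences and midranks
ties; for ≤ 25 effective pairs the exact permutation distribution of the
rank sum is computed by polynomial convolution (doubled ranks keep midranks
integral), two-sided p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))); above 25 a
normal approximation with continuity and tie corrections is used.
`scipy.stats.wilcoxon` serves as an independent cross-check in the test
suite, never as the implementation. Laser-alone change distributions are
z-scored by their own mean/SD and tested against N(0,1) with a one-sample
KS test, reporting mean and median in SD units. Noise correlations are
Pearson correlations of per-trial counts (20 ms spontaneous / 75 ms evoked
windows), computed within laser condition; zero-variance pairs are flagged
undefined. Raw p values are reported (no multiple-testing correction, to
match the reporting style this pipeline mirrors); Benjamini–Hochberg is
available but off by default.

## Pipeline and reproducibility

One master seed drives everything; each stage derives its seed by stable
SHA-256 hashing of the stage name, so stages are decoupled and reruns are
bit-identical (the determinism test compares output tables byte-for-byte).
Configurations round-trip through YAML; discarded spikes, trials and units
are always counted in the log and provenance record. Degenerate inputs
(all-zero tuning curves, zero-variance regressors, <2 spikes, all-tied
pairs) return flagged NaN/degenerate results rather than raising, except
where no meaningful output exists (no valid spikes, no qualifying trials).

## Problem sizes in the test and acceptance runs

Full-scale checks use the protocol-scale stimuli (40 min DRC of 120,000
chords; 50 frequencies × 20 repeats of tones). Calibration and recovery
ensembles are sized to finish on one CPU in minutes while keeping the
statistical checks meaningful: 20-unit STRF recovery at 40 min; 20-unit
null significance calibration at 25 permutation repetitions (persistence
threshold scaled accordingly, with the 100-vs-90 monotonicity checked
directly on persistence counts); 30-unit gain recovery; 20 replicates of
the null end-to-end chain, whose pooled significant fraction is compared
against the 99% binomial upper bound at α — the appropriate tolerance for
a rate estimated from finitely many Bernoulli outcomes. The acceptance
script reports the same quantities at a half-length (20 min) DRC for the
STRF block; cosine similarity of recovered STRFs is intrinsically scale-
dependent (estimator noise falls with spike count, and the spike-triggered
average is broadened by the within-chord stimulus autocorrelation), so the
script reports the value it measured at its own scale.

## Known limitations

* The STA estimator is unregularized by design; its lag profile is the true
  kernel convolved with the chord autocorrelation (chords are held for four
  5 ms bins), which bounds the achievable cosine similarity to a sharp
  planted kernel below 1 even with unlimited data.
* The permutation test's circular-shift null preserves ISI structure but
  not slow rate drift; strongly nonstationary units would need the
  shuffle-ISI alternative or longer files.
* The simulator's Poisson assumption understates the trial-to-trial
  variability of real units (no refractoriness, no super-Poisson noise), so
  real-data power will be lower than recovery tests suggest.
* Anatomical labels (DCIC/CNIC, single/multi, cortical layer) are consumed
  as metadata only; nothing in the package infers them.
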