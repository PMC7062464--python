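# icophys

Analysis toolkit for auditory electrophysiology experiments in which
cortico-collicular feedback (or cortical interneuron activity) is modulated
optogenetically on interleaved trials while responses are recorded in the
inferior colliculus (IC). It reimplements the full analysis chain as a
tested, reusable library, and pairs it with a spike-train simulator with
known ground truth so every estimator in the chain can be validated as an
estimator: simulate a population with a planted effect, run the analysis,
and check that the effect is recovered.

Who it is for: electrophysiologists analysing trial-interleaved
optogenetic designs (laser ON vs laser OFF), and anyone who needs a
spike-triggered-average STRF pipeline with a permutation significance test
on plain-text spike/stimulus interchange files.

## What it computes

**Stimuli** (`icophys.stimuli`) — pure-tone tuning trains (log-spaced
frequencies, pseudo-random order, alternating trials laser-paired), click
trains, and dynamic random chords (DRCs): per-chord, per-band levels drawn
i.i.d. uniform with specified mean and SD, with periodic laser epochs.
Schedules round-trip through tab-delimited text; DRCs through HDF5.

**Simulation** (`icophys.simulate`) — linear–nonlinear–Poisson units:

    rate(t) = max(0, spont + Σ_{l,f} k[l,f] · dev(t−l, f))        (chords)
    rate(t) = max(0, spont + A·exp(−log2(f/BF)² / 2σ²) · box(t))  (tones)

with the laser effect modelled separably: an additive spontaneous offset
Δ (Hz) and a multiplicative gain g on the stimulus-driven component while
the (latency-shifted) laser window is active. Spikes are drawn by thinning.

**Metrics** (`icophys.metrics`) — per laser condition: spontaneous rate
(pre-tone window on top-7 preferred-frequency trials), tone-evoked response
magnitude (75 ms window minus spontaneous), best frequency, tuning-curve
sparseness

    S = 1 − (Σᵢ FRᵢ / n)² / (Σᵢ FRᵢ² / n),

rank-matched linear fits of ON on OFF tuning (slope < 1 ⇒ divisive gain,
intercept > 0 ⇒ additive offset), responsiveness screening (evoked ≥
spontaneous + 2 SD), multi-unit quality (<1% ISIs under 1 ms), and >1 SD
subgroup stratification.

**STRFs** (`icophys.strf`) — spike-triggered average over laser ON / OFF
chunks of each 1 s laser cycle, with scrambled-spike permutation
significance (per repetition: z-score against a circular-shift null
ensemble, cluster-extent correction; pixels significant in >90% of
repetitions are kept), signed-lobe segmentation, cross-condition lobe
matching (≥50% overlap of the smaller lobe), and lobe morphometrics.

**Statistics** (`icophys.stats`) — pairwise noise correlations, the paired
Wilcoxon sign-rank test (exact for n ≤ 25, midranks, zeros dropped), a
one-sample KS test of mean/SD-normalized changes against N(0,1), and
population summary tables (mean ± SEM, median, p, stars).

**Pipeline** (`icophys.pipeline`, `icophys` CLI) — seeded end-to-end runs
(`simulate → metrics → strf → stats`) emitting reproducible TSV report
bundles with provenance; subcommands `simulate`, `metrics`, `strf`,
`stats`, `run`, `validate`.

## Worked example

Thirty simulated units with a planted laser effect — evoked gain 0.8
(divisive) and +2 Hz spontaneous offset (additive) — analysed with the same
chain used for recorded data:

```python
import warnings
from icophys import stimuli, simulate, metrics, stats

grid = stimuli.make_frequency_grid(50, 3000, 70000)
sched = stimuli.make_tone_schedule(grid, n_repeats=20, laser_onset_rel=-0.100, seed=0)
mod = simulate.ModulationModel(spont_delta=2.0, evoked_gain=0.8)
units = simulate.make_population(30, modulation=mod, seed=0)
rec = simulate.simulate_tone_session(units, sched, seed=0)
table = metrics.compute_unit_metrics(rec, sched)
summary = stats.population_summary(table)
print(summary[["measure", "n", "mean_on", "mean_off", "pvalue", "stars"]])
print("median ranked-fit slope    ", round(table.fit_slope.median(), 3))
print("median ranked-fit intercept", round(table.fit_intercept.median(), 3), "Hz")
```

prints

```
         measure  n  mean_on  mean_off  pvalue stars
     spontaneous 30   7.3810    5.2619  0.0049    **
evoked_magnitude 30  16.7333   19.8492  0.0016    **
      sparseness 30   0.2122    0.2867  0.0000   ***

median ranked-fit slope     0.857
median ranked-fit intercept 2.428 Hz
```

Reading the output: spontaneous activity rises under the laser (the planted
+2 Hz additive offset), tone-evoked magnitude falls (the planted 0.8 gain),
sparseness drops (a raised floor plus compressed peak flattens tuning), and
the rank-matched fit separates the two components — slope ≈ 0.86 near the
planted divisive gain, intercept ≈ +2.4 Hz near the planted additive
offset.

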