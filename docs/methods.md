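# Methods

## The experimental design being emulated

Head-fixed mice learn a sound–water association: a 50 ms sound is
followed, at a fixed 100 ms latency after sound offset (150 ms from
onset), by a water droplet at a spout; inter-trial intervals are drawn
uniformly from 5–10 s to prevent rhythmic anticipation. Training
paradigms are broadband noise (single spout), two tones, or two
four-tone chords (chord 1: 2.0/2.7/3.6/4.9 kHz, right spout; chord 2:
8.9/12.1/16.3/21.9 kHz, left spout). Testing sessions interleave the
trained sound(s) with a battery of eleven pure tones (2–40 kHz,
log-spaced). Neural data come from two-photon calcium imaging (Cal-520
or GCaMP6f, one field of view per animal) and loose-patch recordings of
single cells (20 kHz sampling).

## Burst definition and indicator thresholds

A bursting response is a sound-triggered event of **≥ 3 spikes within
(onset, onset + 150 ms]** whose spike peak amplitudes decay over the
event. The decay criterion is operationalised as a log-linear
least-squares fit `A·exp(−(t−t₁)/τ)` over the in-window peaks with
fitted τ > 0 and last peak < first peak; an onset-coincident spike is
excluded by the half-open window. These conventions make the detector
bit-stable and are verified against a brute-force window-scan oracle.

On the imaging side a burst is detected by single-trial (or, for cell
classification, trial-averaged) Δf/f at or above **1.5 for Cal-520** or
**1.0 for GCaMP6f**, inclusive. The thresholds are constants of the
method; the generator's forward model is calibrated *to* them (below),
not the other way round.

## Imaging quantification

* Motion correction: frame-by-frame integer-pixel rigid alignment
  minimising the mean squared intensity difference with a template (the
  average of the selected template frames, default the first 10), over
  a bounded search grid (default ±8 px), ties broken toward the smaller
  shift and then row-major. No subpixel or nonrigid correction. The
  implementation equals an exhaustive-search oracle on small stacks.
* Δf/f = (f − f₀)/f₀ with f₀ the 25th percentile of the entire
  recording, using linear interpolation between order statistics.
* Single-trial response amplitude = max Δf/f in (onset, onset + 1000 ms]
  minus the mean Δf/f in [onset − 500 ms, onset). The measurement
  windows are not prescribed by the design; 1000 ms matches the
  behavioural scoring window, and both are configurable. Trial-averaged
  amplitude is the arithmetic mean over ≥ 3 trials.
* Transients: joint thresholding on peak amplitude (default 0.3 Δf/f)
  and maximum rise rate (default 2 /s), events separated by a return
  below half the amplitude threshold. Defaults are free parameters.

## The synthetic-experiment generator

The generator is first-class, tested code; its defaults are the study
conditions. Where the design pins a value, that value is the default;
where it does not, the choice below was made once, on the stated
rationale.

**Spike trains.** On a preferred-stimulus trial a cell bursts with
probability 0.9. Spikes per burst follow a shifted geometric law on
[3, 27] with mean ≈ 8 (the observed event range is 1–27 spikes; the
exact law is unpublished). First-spike latency is lognormal
(median 29 ms, σ_log 0.6, truncated to [5, 60] ms) and within-burst
ISIs lognormal (median 11 ms, σ_log 0.5, truncated to [3, 45] ms),
implying instantaneous rates of roughly 65–125 Hz for the central
quartiles; the truncations guarantee the first three spikes fall inside
the 150 ms detection window. Spike peak amplitudes decay as
`5·exp(−(t−t₁)/60 ms)` with 8% lognormal jitter. Non-burst trials carry
0–2 spikes at loose latencies.

**Fluorescence forward model.** Each spike adds a unit-peak
rise/decay double-exponential kernel (Cal-520: 30/300 ms; GCaMP6f:
50/400 ms, 40 Hz frame rate, ~resonant-scanner regime) scaled by a
per-spike Δf/f increment, plus Gaussian noise (s.d. 0.06 Δf/f) on a
baseline of 100 a.u. Kernel constants are free parameters; the
per-spike increment is **solved numerically so the indicator threshold
falls midway between a canonical 3-spike and 4-spike event** (median
burst timing, measured with the imaging stage's own amplitude
convention). This realises the published calibration: 1–2 spike events
never reach threshold (0% false positives), ≥ 4 spike events
essentially always do, and the threshold sits between the 3- and
4-spike amplitude medians.

**Population responsiveness.** Per-cell, per-stimulus response traits:

* Non-bursting responsiveness is lognormal (median 0.35 Δf/f, σ_log
  0.5), truncated above at ⅔ of the indicator threshold so that
  baseline activity cannot cross the burst criterion after trial
  averaging (the truncation removes < 2% of mass, and pooled
  trial-averaged amplitudes still pass a KS lognormality check at
  n = 1000, α = 0.01).
* Bursts to a trained **complex** sound follow a lognormal trait law
  anchored at the observed holistic-cell median 2.93 (quartiles
  2.31–4.25), truncated to [2.2, 5.0]. The lower truncation makes every
  planted bursting cell recoverable by trial-averaged thresholding; the
  upper tail cut reflects that the anchor is a median/IQR, not a
  license for extreme outliers.
* Bursts to **pure tones** (analytic cells; quasi-holistic component
  tones) are clearly supra-threshold but weaker and tighter:
  lognormal (median 2.6, σ_log 0.25, truncated [2.2, 4.0]). Training
  amplifies the trained-sound response specifically (~3-fold), so tone
  bursts should not share the trained-sound amplitude tail. With equal
  laws the decoding stage occasionally misclassified single trials even
  with all bursting cells recruited, which contradicts the observed
  perfect bursting-cell decoding.
* Holistic cells' sub-threshold tone responses use median 0.37 and the
  non-preferred chord 0.41 (σ_log 0.45), reproducing the observed
  best-tone (≈ 0.61 via max-of-four) and non-preferred-chord medians
  and a sum-of-components near 1.49 — hence the nonlinear-summation
  contrast (preferred chord ≫ sum of components).
* On a preferred-stimulus trial **without** a burst the cell responds at
  `min(0.3 × trait, 0.63 × threshold)` — the singlet/doublet amplitude
  scale its own calibration assigns to 1–2 spikes — rather than naive
  baseline.

Trial amplitudes multiply the trait by lognormal jitter (σ_log 0.15).
Within a session, each trial's waveform is the kernel sum of that
trial's spikes rescaled so its noiseless single-trial amplitude equals
the drawn trait: per-cell indicator loading absorbs amplitude
variability while spike timing stays consistent with the ephys side.
The per-spike (unscaled) mode remains available and is what the
calibration analyses use.

**Behaviour.** Evoked licking follows a logistic satiation schedule
p(trial) from 0.95 to 0.08, centred at trial 35 with scale 4 trials:
≥ 0.9 over trials 1–20 and ≤ 0.15 after trial 50, matching the observed
motivational decay, which is independent of burst reliability by
construction. Lick latency is lognormal (median 250 ms, σ_log 0.8,
truncated [50, 900] ms — the upper cut keeps a scheduled lick inside
the 1000 ms scoring window). Spontaneous bouts initiate at 0.03 per
1000 ms inter-trial bin, never inside the post-stimulus window; bout
contacts repeat every ~140 ms for 300–800 ms. First contacts land on
the wrong spout with probability 0.05.

**Movies.** Disk ROIs on a uniform background, intensity following the
cells' Δf/f, each frame translated by planted integer shifts with
zero-filled borders plus pixel noise — sufficient to test that motion
correction inverts the planted shifts.

## Behaviour scoring

A successful evoked lick is a **bout initiation** within 1000 ms of
sound onset; only the first in-window contact counts, and on two-spout
rigs it must hit the assigned spout. A bout that started before the
sound and continues into the window is not evoked (the design does not
state this case; exclusion mirrors the spontaneous-licking rule). Bouts
are delimited by ≥ 500 ms contact gaps. A pumped droplet persists until
the first subsequent lick consumes it or the next trial replaces it;
only trials up to consumption of the 20th droplet are effective and
enter the session probability. An animal is trained when the evoked
probability is ≥ 80%. The subsession analysis bins 10 consecutive
trials and deliberately skips droplet truncation — it tracks behaviour
past satiation, with aggregate ranges 1–20, 21–50 and 51–80.

## Classification and decoding

Classification uses trial-averaged amplitudes. Complex sounds are
examined in structure order, so a cell quasi-holistic for both chords is
assigned chord 1; a cell bursting to a complex sound *and all* its
components has no named category and is labelled qHB with a warning.

One-shot decoding trains on one random trial per class and tests on one
different random trial per class; with a single training point per
class the maximum-margin separator is exactly the perpendicular
bisector, so the implementation classifies by nearest training point
(ties, arising only from coincident training points, score ½). Tests
verify draw-by-draw agreement with a hard-margin linear SVM.
Recruitment curves fill policy groups in order; each of the 50 cell
selections draws one random permutation within each group and evaluates
every N_p as a prefix via cumulative dot products (the recruited set at
any N_p is a uniform random subset of the partially-filled group, and
the whole curve costs one cumulative sum per selection). 50 train/test
draws are drawn per selection; reported A_c is the mean ± s.d. across
selections. The classifier never receives cell labels; only the
scheduler uses them.

Hypermouse concatenation merges, for each stimulus, the k-th
chronological trial of every field of view, truncating to the smallest
per-stimulus trial count.

## Population statistics

Lognormal fits are maximum likelihood on log-amplitudes (non-positive
values excluded with their count logged — their treatment in the source
histograms is unstated), with a KS statistic of the logs against the
fitted normal as goodness. The bootstrap test resamples with
replacement 10,000 times (pairs, when paired) and reports twice the
proportion of resampled changes inconsistent in direction with the
observed change (opposite sign or zero), capped at 1; with no
inconsistent resample the p-value is the 1/B resolution floor, and an
observed change of exactly zero gives p = 1. Routine tests (Wilcoxon,
Fisher, χ², ANOVA) are delegated to standard statistical libraries.

## Scenario sizes and determinism

Built-in scenarios use 9 trials per stimulus (testing sessions used a
small per-stage trial count; nine consecutive trials is the documented
example). The chord hypermouse plants 528 NB / 19 AB / 2 qHB-c1 /
3 HB-c1 / 3 qHB-c2 / 15 HB-c2 cells over 19 FOVs; the broadband-noise
hypermouse 614/37/8/22 over 22 FOVs; the trained Cal-520 cohort 1112
cells (52 bursting) over 18 FOVs; the naive control 1314 cells
(2 bursting). The burst/lick dissociation uses 50 replicate 80-trial
single-cell sessions. All stages derive their randomness from one seed
through `numpy.random.SeedSequence` spawning, and identical seeds give
byte-identical reports.

## What passing tests do and do not show

The generator emulates the *statistical structure* the analysis
assumes: trial-locked responses, indicator-calibrated amplitudes,
lognormal population responsiveness, independent burst/motivation
processes, rigid translations. It does not emulate slow drift in f₀,
neuropil contamination, correlated (shared-noise) trial-to-trial
variability within a field of view, non-rigid tissue motion, spike
inference errors, or cells whose class is genuinely ambiguous near
threshold. Passing tests therefore validate the pipeline's rules and
numerics — not robustness of the biology's conclusions to artifacts the
generator does not model. Known limitations: taxonomy recovery is exact
only because planted traits keep a margin from the thresholds (cells
are recoverable by construction); trial-averaged amplitude measurements
carry a small positive bias from taking a windowed maximum over noisy
frames, which the lognormality of *measured* histograms inherits as a
mild distortion.
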