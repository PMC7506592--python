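# Methods

`erpnat` re-implements, as a tested pipeline, an ERP analysis of whether a
recommendation agent framed as *human* or as *AI* is judged a natural source
of advice for symbolic (status/identity-driven) consumption. The measured
quantities are the P1 (~100 ms, positive) and N170 (~170 ms, negative)
visual evoked components at the text-specific left parieto-occipital site P7
and the face-specific right site P8, plus 7-point self-report scales. No raw
data from the original study were deposited, so the package ships a
synthetic-data generator with fully known ground truth; every claim the test
suite makes is about this generator's output, run through the real pipeline.

## Paradigm and data model

Each simulated subject contributes a continuous Cz-referenced recording at
1000 Hz with a prime–target structure: 60 target trials (30 human-framed,
30 AI-framed, randomly ordered), a 2000 ms target, 3000 ms post-target
blank, and a 5000 ms response deadline. The behavioural response (1 =
natural, 2 = unnatural) is a Bernoulli draw per trial
(`p_natural_given_human = 0.85`, `p_natural_given_AI = 0.20`; the original
report gives no response proportions, so these are configuration, not
reconstruction). Reaction times are log-normal (median 800 ms, σ = 0.35)
truncated at the deadline. Event onsets are logged 11 ms before the true
stimulus appearance, reproducing the display-latency offset the epoching
stage corrects.

## Signal generation

* **Components.** Gaussian bumps (SD = width/4; P1: latency 100 ms, width
  60 ms; N170: latency 170 ms, width 50 ms) are injected at P7 and P8 with
  per-cell (identity × site) amplitudes, plus a shared per-trial latency
  jitter (SD 5 ms).
* **Ground-truth convention.** A profile amplitude is defined on the
  *adaptive-mean* scale: bumps are peak-scaled by the inverse discrete
  attenuation factor (mean of the Gaussian over peak ± halfwidth, ≈ 0.93
  for P1 at the 10 ms default halfwidth), and injected as
  average-reference-neutral source patterns — the bump at the target site
  is counterweighted across the other scalp channels so the instantaneous
  scalp mean of the injected signal is zero. With vanishing noise the full
  pipeline (including filtering) returns the profile amplitudes to within
  1%; without these two conventions, average re-referencing and the
  peak-interval mean would each bias recovery by several percent to ~15%.
* **Noise.** Per-channel white Gaussian noise, default SD 5 μV per sample
  (an optional 1/f-shaped variant is available). This is cleaner than raw
  scalp EEG; it is calibrated so that ~25-epoch subject averages have
  residual extraction noise ≈ 0.2–0.25 μV, small enough for extremum-based
  extraction to be approximately unbiased (see *Known limitations*).
* **Artifacts.** Blinks (300 ms half-sine, bipolar swing ≈ 220 μV, 40%
  copy on frontal channels, ~4/min), horizontal eye movements (trapezoid,
  ~80 μV, ~2/min) and optional whole-record bad channels (5 Hz square wave,
  300 μV peak-to-peak) are injected so each screening rule is exercised at
  realistic rates (roughly 10–20% of epochs rejected).
* **Ratings.** Two instruments (attitude, perceived unnaturalness), three
  integer items each per agent, scored 1–7 with higher = more negative.
  Items are `clip(round(mean + subject shift + noise), 1, 7)` with item SD
  0.8 and a subject shift (SD 0.5) shared across agents, which cancels in
  within-subject contrasts. Population means (human 3.05 / AI 3.83
  attitude; 2.91 / 3.57 unnaturalness) carry the study-scale human < AI
  negativity gap.

## Cohort model

Per-subject cell amplitudes are drawn as population mean + a subject offset
(SD 2 μV, shared across a component's four cells, modelling stable
individual amplitude differences) + an independent per-cell deviation
(SD 0.8 μV, the quantity that limits within-subject contrasts). Population
cell means follow the study-scale pattern — P1: 4.41 μV at P7 vs 5.76 μV at
P8 for both identities; N170: −0.83 (human/text), −2.09 (human/face),
−2.27 (AI/text), −1.90 (AI/face) μV. Draws are clipped at a ±0.2 μV
polarity floor: a P1 is positive and an N170 negative by definition, and a
fixed-polarity extremum measure cannot recover a sign-flipped "component".
About 15% of subjects get one bad scalp channel.

## Preprocessing

The stage order is fixed and enforced (out-of-order calls raise):

1. **Filter** — 0.3–30 Hz zero-phase FIR band-pass (windowed-sinc kernel,
   length ≈ 3.3/low_hz seconds, capped at a third of the record;
   reflect-padded edges). Kernel symmetry gives exactly zero phase, so
   component latencies are untouched.
2. **Segment** — epochs −200 to +1000 ms (half-open, 0-based samples,
   ms→samples by rounding) around target onset + 11 ms, keeping only the
   two analysis conditions: human-natural (human identity, response 1) and
   AI-unnatural (AI identity, response 2). Discordant trials are dropped
   and counted before artifact screening; epochs that would leave the
   record are dropped with a warning.
3. **Artifact screening** — a trace's statistic is the max−min of its
   80 ms boxcar-smoothed version (centred window, shrinking at edges); a
   sliding-window range variant is available behind
   `ArtifactCriteria.method`. A scalp channel is bad in a segment if its
   statistic exceeds 200 μV; a channel bad in >20% of segments is bad in
   all segments (applied before the count rule, so globally bad channels
   count toward rejection); a segment is rejected for >10 bad channels, a
   vertical-ocular bipolar range >140 μV (blink), or a horizontal-ocular
   bipolar range >55 μV (eye movement). Screening is pure, idempotent and
   monotone in artifact magnitude.
4. **Bad-channel replacement** — inverse-distance-weighted mean of the
   good immediate neighbours (chord distance on the unit sphere; equal
   distances give equal weights). A bad channel with no good neighbour
   rejects the epoch (`uninterpolatable`).
5. **Baseline correction** — subtract the −200–0 ms mean per epoch and
   channel.
6. **Average re-reference** — subtract the instantaneous mean across scalp
   channels (ocular channels keep their reference); the scalp channel sum
   is zero at every sample afterwards.

Subject averages are arithmetic means over retained epochs per condition;
the grand average is the unweighted mean across complete subjects. A subject
lacking retained epochs in a condition is excluded from the amplitude table
with a log entry.

## Amplitude extraction

The adaptive mean finds the extremum of the component's polarity inside its
search window (P1: 70–130 ms; N170: 150–200 ms; earliest sample wins ties)
and averages over peak ± 10 ms clipped to the window. The 10 ms halfwidth is
conventional for sharp early components and configurable; linearity under
positive scaling and the polarity contract (N170 ≤ 0 on purely negative
deflections) are property-tested.

## Statistics

* **Normality gate.** Shapiro–Wilk per measure family (valid for
  3 ≤ n ≤ 2000). Rating contrasts, being coarse integer-derived scores,
  typically fail it and route to the Wilcoxon test; amplitudes go to the
  RM-ANOVA.
* **Wilcoxon signed-rank.** Zero differences dropped, tied magnitudes
  mid-ranked, tie-corrected normal approximation *without* continuity
  correction (the convention of the commercial package family the original
  analysis used); Z is signed by W⁺ − E[W], and mean ranks are reported per
  sign group. For ≤12 effective pairs the exact sign-permutation
  distribution is used instead (computed by convolution; validated against
  an independent implementation to 10⁻¹²). Without the continuity
  correction the approximation's two-sided p can deviate from the exact p
  by up to ~0.13 at n ≤ 9 and ~0.04 at n = 12 — which is exactly why the
  router switches to enumeration there.
* **2×2 RM-ANOVA.** Univariate within-subject decomposition with subject
  as a random blocking factor; each effect is tested against its own
  effect × subject term, so df = (1, n−1), sphericity is moot, and each F
  equals the squared paired t on that effect's contrast scores (asserted to
  10⁻⁹). Partial η² = SS_eff/(SS_eff+SS_err) = F·df₁/(F·df₁+df₂), labelled
  small/medium/large at 0.01/0.06/0.14 (half-open intervals). When an
  effect's SS and error SS are both numerically zero (exactly additive
  data), the result is reported as F = 0, p = 1 rather than 0/0 noise.
* **Post hocs.** When the interaction is significant, the four simple
  effects of the 2×2 are tested by paired t against the Bonferroni
  criterion α/4 (0.0125 at α = 0.05).

## Test and acceptance problem sizes

Cell-mean recovery runs the full signal pipeline on one simulated cohort of
27 subjects (the study's n): every cell mean must land within 2 cohort SEs
of the injected truth, and the injected ordinal pattern must survive
extraction. The 200-replicate detection-power check (P1 modality main
effect; N170 interaction; both ≥80% at α = 0.05) runs on amplitude tables
drawn from the cohort model directly, with per-cell measurement noise set to
the residual SD measured in the full-pipeline cohort (≈ 0.25 μV) — the
amplitude table is the exact sufficient input of the ANOVA, so this factors
the expensive signal simulation out of the replicate loop without changing
what is tested. Type-I error calibration (1000 null replicates, rejection
rate 5% ± 2% for Wilcoxon and all three ANOVA effects) runs at the same
amplitude level.

## What passing tests do and do not show

The generator's noise is white (optionally 1/f), artifacts are stereotyped
templates, components are Gaussian and latency-stationary, and channel
geometry is a sparse 16-electrode net. Passing tests therefore demonstrate
that the pipeline's bookkeeping, thresholds, algebra and inference are
correct and that the method recovers known truth under its own assumptions —
not that the thresholds are optimal for real recordings, nor that real N170
effects of this size would be detected at n = 27 against real EEG noise,
spatially correlated artifacts, or alpha-band oscillations.

## Known limitations

* Extremum-anchored measures (peak, adaptive mean) are biased in the
  polarity direction when the component is weak relative to the residual
  noise of the subject average; at the default calibration this bias is
  ≤ ~0.2 μV. It grows roughly with the noise SD and cancels only partially
  in within-subject contrasts.
* The normal-approximation Wilcoxon p is unreliable below ~10 effective
  pairs; the exact path covers this range, but callers forcing
  `method="approx"` at tiny n inherit the discrepancy.
* Bad-channel interpolation uses immediate neighbours only; on the sparse
  default montage an interpolated P7/P8 partially absorbs neighbouring
  counterweight signal, so subjects with a bad channel adjacent to an
  analysis site carry a small extra amplitude error.
* EDF export quantises to 16 bits over each channel's observed range
  (≈ 0.01–0.03 μV steps here) and zero-pads the record to whole seconds.
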