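# Methods

`cbpupil` implements an analysis pipeline for event-related pupillometry in
computerized choice-blindness experiments, in which a participant's choice
between two images is occasionally swapped (manipulated, "M" trials) and the
question is whether unreported manipulations were nevertheless *detected*
(covert detection).  The pipeline covers synthetic cohort generation, pupil
preprocessing, behavioral report scoring, time-series and window statistics,
mixed models, a leave-one-subject-out (LOSO) pupil classifier, and power
simulation.  This note records the models, the parameters that matter, the
numerical choices, and the limits of what the synthetic data can show.

## Session model

A session has 30 trials: 8 M-trials at fixed positions (7, 10, 14, 16, 20,
22, 26, 29), 8 non-manipulated (NM) trials at positions drawn uniformly
without replacement from the remaining slots, and 14 baseline trials
(selection, fixation, 5 s test image; no ratings or report phase).  Trial
phases have fixed nominal durations — pair presentation 3 s (colored
photographs profile) or 5 s (monochrome faces profile), ratings 4 s,
fixation 2.5 s, test image 5 s, verbal report 6 s, ITI 2 s — so test-image
onsets are deterministic given the schedule.  Real response phases are
self-paced; fixing them trades realism for exact reproducibility of onsets,
which every downstream test relies on.  The ratings (4 s) and report (6 s)
durations are free choices in the plausible range for a two-rating keypress
phase and a short verbal explanation.

## Behavioral generative model

Each subject draws a reporting phenotype — all-report, some-report,
no-report — with probabilities 8/41, 23/41, 10/41, the observed group sizes
in the reference cohort.  On each M-trial (order k = 1..8):

* detection ~ Bernoulli(logit⁻¹(b₀ + b_trial·k + b_conf·confidence +
  b_dissim·[dissimilar pair])), defaults b₀ = 0, b_trial = 0.25,
  b_conf = 0.15, b_dissim = 0.8 — detection rises with trial order,
  decision confidence and pair dissimilarity, and averages ≈ 0.9;
* concurrent report only if detected: probability 0.98 (all-report), 0.02
  (no-report), or logit⁻¹(−1.2 + 0.45·k) (some-report), so reporting also
  rises with order; a small fraction (0.05) of detected-but-unreported
  trials is coded "possible detection";
* retrospective identification only if detected:
  logit⁻¹(m₀ + m_mem) with a memorability offset m_mem = 2.2
  (photograph-like stimuli, ≈ 0.90) or −0.2 (face-like, ≈ 0.45);
  independent false positives on non-M pairs at rate 0.033.

The generator never produces a report without detection; this is the
ground-truth invariant behind the covert-detection summaries.  These
constants are loose calibrations to the published group sizes and pooled
rates, not estimates: no quantitative behavioral model is available to fit.

## Pupil generative model

The continuous 1000 Hz trace is

    pupil(t) = baseline + drift(t) + Σ_trials a_i · h(t − onset_i) + ε(t)

with h the canonical pupil impulse response h(t) = t^w·exp(−w·t/t_max),
w = 10.1, t_max = 0.93 s, unit peak, 4 s support (the standard canonical
parameterization; evaluated in log space because t^10.1 overflows).
Amplitudes: a_i = amp_base (30 a.u.) on every test image, plus
amp_delta_detect (30 a.u.) on detected M-trials and amp_delta_undetect
(default 0) on undetected ones — so "covert detection" pupil signatures
come from detected-but-unreported trials.  Drift is a random walk generated
at 10 Hz (scale 8 a.u./√s) interpolated to the native rate (band-limited by
construction); noise is white Gaussian (15 a.u.); subject baselines are
N(3000, 300²) a.u.  Blinks arrive as a Poisson process (0.25 Hz) with
lognormal durations (median 120 ms); the pupil is forced to the
missing-data sentinel across the interval with 50 ms cosine ramps, and the
interval is logged as a blink event.  Saccades (Poisson 1.5 Hz, logged as
40 ms events) inject a small biphasic transient (0.1 × noise SD) so the
nuisance regression has something real to remove.

**Response timing.**  The detection response is a single impulse at
test-image onset.  Because the canonical kernel peaks at 0.93 s and has
decayed to ≈ 0.2% of peak by 2 s, synthetic effects are expressed mainly at
0.4–2 s: the pointwise 0–5 s tests detect them easily, while the 2–4 s
window statistic — defined this way to mirror the published procedure —
captures only the kernel tail, and the LOSO classifier built on window
means performs near chance on synthetic cohorts.  Real detection responses
are later and more sustained (recognition takes time and surprise outlasts
it), which is why the window analysis is informative on real data.  Tests
of the window stages therefore validate *unbiasedness* (recovery of the
small injected window contrast within Monte-Carlo CIs), not sensitivity.

## Preprocessing

Fixed order, each stage stamping the recording and refusing out-of-order
input: blink interpolation → band-pass → standardize → downsample →
nuisance regression → epoching → QC.

* **Interpolation**: blink/missing intervals padded by 150 ms on both
  sides, linear interpolation between nearest valid neighbours, constant
  extension at edges; interpolated samples stay invalid in the mask.
* **Band-pass**: third-order Butterworth, 0.02–4 Hz, zero-phase
  (forward–backward), implemented as second-order sections — the
  polynomial transfer form is numerically unstable at 0.02 Hz/1000 Hz.
  Zero-phase filtering avoids latency shifts in epochs; reflective padding
  10 s.  Probe: the band-pass distorts the canonical kernel by < 0.2%
  sup-norm on a session-length record.
* **Standardization**: division by the SD of valid filtered samples
  (session-level; the filter has removed the mean).  Per-trial baseline
  z-scoring was rejected because a 100-sample baseline SD is unstable and
  would inflate variance heterogeneously; per-trial baseline *mean*
  subtraction happens at epoching.  The scale (a.u. per z) is retained so
  analyses can report absolute units.
* **Downsampling**: decimation 1000 → 100 Hz (anti-aliasing guaranteed by
  the 4 Hz low-pass); a decimated sample is invalid if any native sample
  in its 10-sample block was.  The native-rate mask is carried along for
  QC.
* **Nuisance regression**: one regressor per event kind — unit impulses at
  event *end* times (recovery onset; the simplest reading of
  kernel-based artifact removal) convolved with the canonical kernel —
  OLS over valid samples, residual returned.  No temporal derivatives.
  With no events the stage is a warned pass-through.
* **Epoching**: −1..5 s around test onset at 100 Hz (601 samples; t = 0 at
  index 100), per-trial baseline mean over [−1, 0) subtracted.  The
  invalid fraction per trial is computed on the native-rate mask over the
  same window.
* **QC**: trial excluded iff strictly more than one third of the window is
  invalid (> 2 s of 6 s; exactly 2 s is retained); subject excluded iff at
  least half of the trials (15 of 30) are excluded.  The "at least 15"
  reading resolves the ambiguity between "more than half" and "15 of 30"
  in favour of the explicit count.

End-to-end check: on noise-free cohorts with unit injected amplitude the
M − NM mean epoch reproduces the kernel within 2% sup-norm (measured
≈ 0.1–0.4%).

## Statistics

* **Pointwise tests**: subjects are aggregated first (trial-mean trace per
  condition per subject), then a paired t-test per time point over 0–5 s
  (501 points), one-sided for directional contrasts (M > NM, M > baseline).
  Benjamini–Hochberg FDR at q = 0.05 within one contrast's 501 points
  (families are not pooled across contrasts).  Under 1,000 simulated null
  cohorts the any-discovery rate was ≤ q + 0.02 (the 0.02 is the
  pre-registered Monte-Carlo allowance at that replicate count).
* **Window analysis**: 2–4 s window mean per subject × condition,
  normalized by *subtracting* the subject's baseline-trial window mean
  (a ratio would distort conditions that fall below baseline).  Battery:
  each M-family condition (M, CR, NCR, RR, NR) vs baseline and vs NM
  one-sided, M-subcategories pairwise two-sided, NM vs baseline two-sided;
  comparisons with < 2 paired subjects are reported not-estimable.  No
  multiplicity correction across the battery (raw p per comparison).
* **Report GLMM**: logistic mixed model with subject random intercept,
  fixed effects trial order, confidence, similarity.  Maximum likelihood
  with the random effect integrated by 25-node Gauss–Hermite quadrature
  (written in-house: statsmodels offers no ML binomial mixed model), Wald
  CIs from the numerical Hessian, odds ratios = exp(β).  Agreement with
  lme4's adaptive-quadrature fit is < 0.02 on coefficients and SEs in the
  test suite.  Separation and non-convergence are flagged, never silent.
* **Pupil LMM**: statsmodels MixedLM (REML by default) on trial-level
  window values; ICC = σ²_subj/(σ²_subj + σ²_resid); singular fits
  flagged.  Recovery tolerance for the injected ICC = 0.25 at 200 subjects
  is ± 0.08, i.e. 3 Monte-Carlo SDs of this estimator (SD 0.025, measured
  at design time).
* **SDT**: d′ = Φ⁻¹(H) − Φ⁻¹(F); per-subject d′ (then averaged) is the
  primary output, pooled-rate d′ secondary.  Log-linear correction (+0.5
  per cell) only when a raw rate is 0 or 1; uncorrected extreme rates
  raise.  The retrospective false-alarm denominator is the 22 non-M pairs
  on the memory sheet (configurable).
* **LOSO classifier**: threshold = midpoint of class means from all other
  subjects, pooled over trials (trial-weighted; a mean-of-subject-means
  variant is switchable); ties go to the reference class (conservative
  toward chance); majority proportion computed on the full included-trial
  set; exact one-sided binomial tail for significance.
* **Power**: paired differences ~ N(d, 1), one-sample t; analytic
  companion via the noncentral t (df = n − 1, ncp = d√n).  20,000
  replicates put the Monte-Carlo SE near 0.3 pp; simulation and closed
  form agree within 3 SE throughout the tested grid.

## Problem sizes and degenerate inputs

Test-suite simulations use the study's native scales (1000 Hz, 30-trial
sessions) with cohort sizes chosen per purpose: 3–4 subjects for pipeline
mechanics, 200 subjects for parameter-recovery CIs, 1,000–2,000 replicates
for behavioral Monte-Carlo and type-I rates.  Degenerate inputs are
contracts, not accidents: all-invalid recordings, zero-variance signals,
non-monotone timestamps, cutoffs beyond Nyquist, rank-deficient nuisance
designs, constant outcomes (separation), folds missing a class, and zero
denominators all either raise or return flagged results.

## Known limitations

* The behavioral constants are plausibility calibrations; recovered
  odds ratios validate the *fitting machinery*, not any empirical claim.
* Fixed-duration response phases remove reaction-time variability, making
  onset spacing more regular than in real sessions.
* No gaze-position/foreshortening correction and no subject-specific IRF
  estimation; the canonical kernel is assumed shared.
* Published model coefficients (β, OR, ICC point estimates, classifier
  accuracies, d′ means) depend on the original recordings and are not
  reproduced here; the pipeline's correctness on those quantities is
  established by recovery and oracle tests instead.
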