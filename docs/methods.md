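# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `erpwp`. Everything stated
here is computed by the package's tests or examples; nothing is quoted from
external results.

## Design

A session presents 240 auditory stimuli (80 per word-type condition:
WORDS, SIMILAR, NONSENSE) drawn from a 48-sound inventory (4 Hungarian
two-syllable items per condition × 2 speakers × 2 recorded versions), in a
semi-randomized order in which neither the same condition nor the same
speaker occurs more than 3 times in a row, with stimulus onset asynchrony
uniform on [2.5, 3.0] s (≈ 11-minute sessions). The run-length constraint
is enforced separately per attribute (condition, speaker); a joint reading
is possible but less natural, and the separate form is what the generator
validates. EEG is recorded at 1000 Hz from Fz, Cz, F7, F8 referenced to
Pz; F7−F8 forms the horizontal EOG.

## Preprocessing

* **Filtering.** Cascaded 4th-order Butterworth high-pass and low-pass
  sections applied forward-backward (`sosfiltfilt`, zero phase). Cutoffs
  per cleaning variant: 0.01/40 Hz (multi-level), 0.3/40 Hz
  (amplitude-based), 0.3/20 Hz (visualization). The filter family and
  order are a documented choice — only the cutoffs are fixed by the
  procedure being reproduced. The two-pass 4th-order magnitude response at
  50 Hz with a 40 Hz cutoff is 1/(1+1.25⁸) ≈ 0.14, which the tests assert
  exactly rather than an idealized brick-wall figure.
* **Epoching.** Trials span −200…+1000 ms around onset, both endpoints
  included (1201 samples at 1000 Hz); time 0 is the onset sample; epochs
  are half-open sample ranges internally, closed ms windows at the API.
* **Detrend, baseline.** Per trial and channel, a least-squares line fit
  over the *entire* epoch is removed first, then the mean of [−200, 0] ms
  is subtracted. Both operations are idempotent and their order matches
  the procedure being reproduced. A consequence worth knowing (see
  Limitations): detrending an epoch that contains a genuine late component
  rotates the whole trial slightly, leaking a fraction of a strong late
  condition contrast into other latencies with opposite sign.

## Artifact rejection

A trial is rejected when, on any checked channel, (a) any sample exceeds
the absolute threshold (strict >), or (b) any 100 ms sliding window
(101 samples inclusive, stepped by one sample) has max−min exceeding the
range threshold (strict >). The multi-level variant checks Fz, Cz, F7, F8
and hEOG and additionally rejects trials whose [onset−0.5 s, onset+1.0 s]
interval has strictly positive overlap with an annotated movement; the
amplitude-based variant checks Fz and Cz only. Rejection is monotone in
the thresholds, and the vectorized implementation is tested against an
exhaustive per-window oracle. Subjects enter statistics only with ≥ 10
clean trials in every condition. The human steps of a multi-level pipeline
(video annotation, visual inspection, EOG-correlation screening by eye)
are represented solely as consumption of an annotation file; no rater
behaviour is modelled, and the EOG-to-scalp correlation screen is not
implemented because no quantitative threshold for it exists.

## Statistics

* **rm-ANOVA.** Fully within-subject two-way decomposition (word-type ×
  electrode); each effect is tested against its own effect-by-subject
  stratum; partial η² = SS_e/(SS_e+SS_err). For 3-level factors the
  Huynh–Feldt ε̂ (from the Greenhouse–Geisser ε̂ of the double-centred
  covariance, single-group adjustment, truncated to [1/(k−1), 1])
  multiplies both degrees of freedom. Two-level effects are spherical by
  construction. Note the correction is only guaranteed to *raise* p where
  it matters (around and below p ≈ 0.05); for F ≪ 1 shrinking both dfs can
  lower p slightly.
* **Window scan.** Grid of 19 100 ms windows, 0–1000 ms, 50 ms step.
  Omnibus gate: word-type main effect *or* word-type × electrode
  interaction significant at α = 0.05 (HF-corrected where applicable).
  Pairwise planned contrasts (two-way rm-ANOVAs on each condition pair)
  run only in gated windows; a pair is flagged when its main effect or
  interaction is significant. Maximal chains of consecutive flagged grid
  windows merge into one selected window (first onset to last offset); a
  single flagged window still yields a selected window. No multiplicity
  correction across windows by default — faithful to the analysis being
  reproduced — with an optional Holm correction on the gate
  (`correction="holm"`).
* **Bayes factors.** BF₀₁ compares mean + random subject intercepts
  (null) against the same model plus word-type as a fixed effect, under
  JZS priors: Jeffreys on σ², flat on the grand mean, g-priors on
  standardized effects with g = r²/χ²₁, r = 0.5 (fixed) and 1.0 (random).
  Fixed-effect levels use orthonormal sum-to-zero contrasts. Conditional
  on g the marginal likelihood is closed-form; the balanced design makes
  the subject and condition blocks orthogonal, so each model marginal is a
  1–2 dimensional g-integral evaluated by seeded Monte Carlo (default
  100 000 draws), with the proportional error propagated from both
  marginals. The estimator is validated against an independent
  deterministic quadrature of the same integrals. The two-level case is
  *close to but not identical with* the paired-t JZS Bayes factor: the
  shared error variance couples the subject-sum and difference scores, and
  the two differ by roughly 10–15% at n = 17 — the tests check both the
  exact oracle (tight) and the paired-t reduction (loose).
* **Moderation.** Subjects at or above the covariate median form the high
  group (with the scale's ceiling effect this reproduces an 8-versus-9
  split of 17). The rank-sum test reports W as the first (low) group's
  Mann–Whitney U; p is exact (no ties, n ≤ 50); r = Z/√N from the tie- and
  continuity-corrected normal approximation; the CI is the Hodges–Lehmann
  interval from the exact null distribution of U. All conventions are
  frozen against R's `wilcox.test(x, y, conf.int=TRUE)`.
* **Direction concordance.** Per analysis window, the number of subjects
  whose individual difference matches the grand-average sign, plus the
  overlap of matching subjects across windows.

## Synthetic cohorts

`synth` generates what the analysis assumes, with ground truth:

* **Noise.** Per-channel 1/f^α noise (α = 1) mixed with 30% white
  variance, total 10 µV per sample, exactly jointly Gaussian (spectral
  shaping with ensemble normalization); slow sinusoidal drift (5 µV) below
  0.05 Hz.
* **ERP components.** Gaussian bumps (center, sd width, per-condition peak
  amplitude, per-channel gain): a −2 µV bump at 100 ms and a −4 µV bump at
  250 ms (condition-neutral, the general auditory response), and a late
  word-type component at 725 ± 60 ms with peaks +1.5 µV (WORDS, SIMILAR)
  and −1.5 µV (NONSENSE) — a 3 µV peak contrast, Fz gain 1.0, Cz 0.7.
* **Between-subject structure.** A per-subject amplitude multiplier
  ~N(1, 0.35) (floored at 0.2), and usage-frequency moderation of the late
  contrast: the condition deviations scale by
  1 + slope·(u − ū)/contrast, slope 9 µV per covariate unit, ū = 4.8,
  floored at 0. Low-usage dogs thus carry little or no familiarity effect;
  high-usage dogs a larger one. The slope was set by a design power
  analysis so the median-split rank-sum recovers the moderation in well
  over 70% of cohorts (realized median r ≈ −0.55); a slope calibrated to a
  typical r of exactly 0.5 would sit at the significance boundary with
  ~50% power.
* **Covariates.** Owner-reported usage frequency with a ceiling effect —
  ~53% of owners at the scale maximum 5.0, the rest ≈ N(4.6, 0.23) — so
  median splits reproduce the published group statistics (high group mean
  5, s.d. 0).
* **Artifacts.** Blinks (Poisson 0.15 Hz, 160 µV Gaussian bumps on F7/F8,
  ×0.15 on Fz/Cz) and movement bursts (Poisson 0.35 Hz, 0.3–0.8 s, a
  ±200 µV slow deflection coherent across channels plus 25% broadband),
  each logged with its true interval. These rates were chosen so the two
  cleaning variants reject trials at the same order as the study they
  emulate (≈ 40% amplitude-based, ≈ 60% multi-level, with the multi-level
  variant strictly stricter). The slow deflection core matters: a purely
  broadband burst would vanish under the 40 Hz low-pass and never trip the
  amplitude screen.

What the generator does **not** model: biophysical head geometry, trial-
to-trial autocorrelation of the ERP, rater behaviour, condition-dependent
muscle artifacts, or real dog EEG beyond component timing and polarity.
True dog ERP amplitudes and SNR are unpublished; all amplitude choices are
synthetic and documented here. Passing tests therefore demonstrate that
the *pipeline* behaves correctly under a plausible generative model — not
that real dog data would yield these numbers.

## Calibration and recovery (what the test suite measures)

* Per-window type-I error of the scan's word-type test on 500 null
  cohorts (17 subjects, pure noise): within [0.03, 0.07].
* The +3 µV late contrast is recovered as a WORDS/NONSENSE selected
  window overlapping 650–800 ms in ≥ 80 of 100 epoch-level cohorts, and
  the usage moderation by the median-split rank-sum in ≥ 70%.
* Structural pattern: late selected windows for both x-vs-NONSENSE pairs
  in both cleaning variants at a fixed seed; WORDS-vs-SIMILAR — a true
  null — is flagged in gated windows at no more than ~the nominal
  compound α (main-or-interaction ≈ 9.75%), with Bayes factors leaning
  toward the null. The problem sizes above (500/100/12 replicate cohorts,
  epoch-level simulation for the replicate studies, one full continuous-
  recording cohort for the end-to-end run) are the package's standard
  validation sizes.

## Numerical choices and degenerate inputs

* Sliding-window extrema via 1-D min/max filters, restricted to fully
  contained windows; inclusive 101-sample windows at 1000 Hz.
* "Exceeding" a threshold is a strict inequality everywhere, and interval
  overlap must be strictly positive — boundary contact never rejects.
* ε̂ falls back to the lower bound 1/(k−1) with a warning when the score
  covariance is degenerate; zero-variance ANOVA cells give F = 0, p = 1.
* A paired t-test on identical samples returns t = 0, p = 1; a constant
  nonzero difference (zero variance) raises.
* EDF output is 16-bit with a symmetric per-channel physical range
  (quantization ≈ range/65536), one-second records, zero-padded to whole
  seconds; reading uses MNE.
* All randomness flows through explicit integer seeds or
  `numpy.random.SeedSequence` spawning; cohorts are byte-reproducible.

## Known limitations

* Detrend leakage: with a strong, purely-late synthetic component, the
  per-trial linear detrend redistributes a fraction of the late contrast
  across the epoch (opposite sign, growing toward the epoch edges). With
  realistic between-subject variability this stays mostly below the
  significance threshold, but very clean cohorts can show extra selected
  windows for the affected pairs outside the injected latency. This is a
  property of the procedure, not a bug, and real analyses inherit it.
* The omnibus-gated pairwise contrasts at α = 0.05 with no multiplicity
  correction imply a ~10% per-gated-window false-flag rate for a truly
  null pair; across the many windows a strong effect gates, occasional
  spurious selections for the null pair are expected rather than
  exceptional.
* The Bayes factor Monte Carlo error grows for extreme data; the
  proportional error is always reported and the iteration count is
  configurable.
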