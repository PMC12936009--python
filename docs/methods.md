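# Methods

`pbmnet` implements an analysis pipeline for predicting, early in a course of
home-based transcranial photobiomodulation (tPBM), which participants with
cognitive decline will *not* respond to the treatment, using resting
prefrontal fNIRS recorded by the stimulation device itself during the first
~20 sessions.  Because the clinical recordings behind the original study are
not publicly available, the package pairs the analysis with a synthetic-data
generator that plants the statistical structure the analysis assumes, so
every stage is testable end to end.

## Outcome definition: GCS, ΔGCS, responders

Nine cognitive metrics (DST-F, DST-B, VFT, three K-AVLT components, Stroop
time, DSC, RMT) are measured before and after the 12-week course.  Metrics
with a significant cohort-level improvement (paired t-test, two-sided
p < 0.05, improving direction after orientation alignment) are z-scored —
time-based scores are sign-flipped first so higher always means better — and
averaged into a Global Cognitive Score (GCS).  ΔGCS = GCS_post − GCS_pre; a
subject is a **responder** iff ΔGCS ≥ 0.5 (inclusive).

Normalization basis: per-metric mean/SD pooled over the cohort's pre *and*
post values (one scale for both time points), overridable to pre-only.  When
external normalization statistics are supplied (e.g. the generator's
population parameters), scoring at zero noise recovers the planted ΔGCS
exactly; with cohort-derived statistics recovery is exact only up to the
cohort's empirical scale.

## Preprocessing

Per 900 s session, for each of 15 channels at 810/850 nm:

1. **MBLL.** ΔOD(λ, t) = −log10(I/Ī) with the session-mean intensity as
   reference (the reference fixes only an additive constant, absorbed by the
   baseline step); a 2x2 solve with compendium-style extinction coefficients
   (810 nm: 0.883/0.747, 850 nm: 1.058/0.691 cm⁻¹ mM⁻¹ for HbO/HbR), 3 cm
   separation, DPF 6.0 at both wavelengths.  The absolute µM scale is
   uncertain at the level of these constants, but every downstream statistic
   is correlation-based and therefore scale-invariant.
2. **Wavelet motion correction.**  Daubechies-5 decomposition at maximum
   depth; within each detail level, coefficients farther than 1.5 x IQR from
   the level median are zeroed.  Two guards keep the correction from eating
   signal: levels with fewer than 32 coefficients are left untouched (too few
   samples for a stable IQR; those levels carry slow physiology, not motion),
   and boundary coefficients (half a filter length at each end) are exempt,
   since the signal-extension transient makes them spurious outliers.  The
   method strongly attenuates spikes; sustained baseline shifts lose their
   sharp transient but necessarily retain some in-band energy (a known
   limitation of coefficient-thresholding corrections).
3. **Band-pass.**  Butterworth band-pass 0.01–0.09 Hz with an order-6
   transfer function, applied forward–backward (zero phase; single-pass is a
   flag).  Order matters: despiking precedes filtering, because filtering
   first would smear broadband artifacts into the passband.
4. **Segmentation.**  The [10 s, 890 s) segment is kept (half-open windows,
   sample = floor(t x rate)); the per-channel mean over [5 s, 10 s) of the
   *filtered* series is subtracted; ΔHbT = ΔHbO + ΔHbR exactly.

**Quality screening** replaces the study's visual inspection with a
deterministic heuristic: a trial is flagged if any channel saturates (≥1% of
samples at the rail), flatlines (relative SD < 1e-6), or shows more than 20
robust outliers (>5 scaled MADs) in its first differences — differencing
makes a persistent baseline shift count once rather than per displaced
sample.  A subject is excluded iff strictly more than five trials are
flagged.  Trial count is standardized to 15 by uniform sampling without
replacement from the first 20 usable trials, re-sorted chronologically.

## Connectivity and graph indices

Per trial and chromophore (ΔHbO, ΔHbR, ΔHbT): Pearson correlations between
all channel pairs over the full segment; binarization at thresholds
0.40–0.90 in steps of 0.01 with a strict `>` on the signed r (ties and
negative correlations never connect; absolute-value binarization is
deliberately not the default).  Indices per binary graph:

- degree centrality DC(i) = Σ_j a(i, j); network value = mean over nodes;
- global efficiency GE = (1/(N(N−1))) Σ_{i≠j} 1/d(i, j), BFS distances,
  unreachable pairs contributing 0;
- clustering coefficient CC(i) = 2L_i/(Z_i(Z_i−1)), 0 when Z_i < 2; network
  value = mean over all N nodes.

The kernels are batched (boolean matrix powers for distances, the diagonal
of A³ for triangle counts) so the full 51-threshold x 15-trial x
3-chromophore sweep is a few 15x15 matrix products; the test suite pins them
exactly to networkx and to brute-force enumeration.

The 15 trials are averaged in chronological triples into five periods;
Δperiod k = period k − period 1 (k = 2..5).

## Biomarker model

For each chromophore x index, the binarization threshold is chosen to
minimize the group x period interaction p of a two-way mixed (split-plot)
ANOVA (group between subjects, period within; ties resolved toward the
smallest threshold).  The ANOVA is implemented in vectorized
sums-of-squares form so the whole 459-cell scan is a single pass; it agrees
with `pingouin.mixed_anova` to machine precision on balanced and unbalanced
designs.  We report the interaction with its own degrees of freedom,
(P−1, (N−2)(P−1)) = (4, 108) at N = 29 — the df printed in the source study,
F(4, 28), is not consistent with a 29-subject mixed design.  Sphericity is
uncorrected by default.

At the chosen thresholds, ΔGCS is regressed (OLS) on each of 45 candidate
predictors (baseline value and Δperiods 2–5 for the nine chromophore x
index combinations).  Predictors with slope p < α (0.05 for whole-dataset
analysis; relaxed to 0.1 inside cross-validation training sets) become
biomarkers, grouped by period.

**Classification.**  Each biomarker predicts ΔGCS affinely from the
subject's predictor and flags the subject when the prediction falls below
the cutoff (default 0.35, configurable).  Periods vote: one biomarker — its
flag decides; two — unanimity; three — majority; more than three — at least
two flags.  The final identification is the union of period flags.  The
unanimity rule for two biomarkers is interpretive (the source study's "hard
voting" with two indices is ambiguous); it is documented here and
configurable in code.  The voting protocol is equivalently expressed
through a *voting score* — the cutoff value at which the subject's label
flips (the minimum over periods of the m-th smallest per-period
prediction) — which makes cutoff sweeps and ROC analysis over the voting
rule exact and cheap.

## Validation

- **LOSO-CV.**  Threshold optimization, regressions and biomarker selection
  are re-derived per fold from the training subjects only (the suite
  asserts fold models are bitwise identical however the held-out subject's
  rows are altered).  The classification cutoff is either fixed or
  optimized per fold by maximizing min(sensitivity, specificity) of the
  training voting decisions over candidate cutoffs (midpoints of sorted
  scores plus the 0.35 anchor; ties resolve toward the anchor, then the
  smallest value).
- **Confusion metrics** treat non-responder as the positive class; undefined
  ratios are reported as not-available, never as 0.  Note: from the printed
  whole-dataset counts (11 true among 13 flagged), PPV is 11/13 = 84.62%;
  the 78.67% printed in the source study is arithmetically inconsistent
  with those counts, and this package reports the value computed from
  counts.
- **ROC/AUC** sweeps the flag rule `score < cutoff`; ties get half credit
  (the Mann–Whitney convention; the suite checks against scikit-learn).
  The per-subject continuous score for whole-dataset curves is the minimum
  predicted ΔGCS across selected biomarkers (the most pessimistic
  prediction) — an interpretive choice, since no continuous score is defined
  in the source analysis.
- **Max-t permutation correction**, one-tailed in the negative direction:
  observed t from each family member's Pearson correlation with ΔGCS; the
  null permutes ΔGCS and records the minimum t across the family per
  permutation; corrected p = (1 + #{min t ≤ t_m})/(n_perm + 1) (the "+1"
  convention, so p is never 0 and corrected p ≥ raw p).  The family is the
  five period-level statistics of one chromophore x index; a config option
  widens it.

## Synthetic cohorts

The generator emulates the study design: 14 responders + 15 non-responders,
≥20 sessions each, 900 s at 8.138 Hz, 15 channels from a 5-source/7-detector
3 cm prefrontal montage, and a nine-metric battery.

- True ΔGCS: responders ~ N(0.9, 0.3) truncated at ≥0.5; non-responders
  ~ N(0.1, 0.25) truncated below 0.5 — realistic overlap either side of the
  cutoff.
- Each subject has a latent inter-channel correlation matrix (base level
  0.60 with symmetric per-pair jitter, SD 0.08, repaired to the nearest
  unit-diagonal PSD matrix).  For responders the level declines linearly
  across sessions by effect_slope x ΔGCS in total over the 20 sessions;
  non-responders stay flat.  This is the planted coupling the pipeline must
  recover as negative Δperiod↔ΔGCS regressions.
- Sessions are synthesized in the hemodynamic domain — band-limited
  (0.01–0.09 Hz) correlated slow activity (0.5 µM), cardiac ~1 Hz (0.25 µM;
  deliberately alias-prone at 8.138 Hz, as in the real device), respiratory
  ~0.3 Hz (0.15 µM), Mayer ~0.1 Hz (0.20 µM), 1/f noise (0.25 µM), and
  Poisson motion artifacts (rate 2/session; spikes 5–20 x SD, 1–3 samples;
  baseline steps 2–8 x SD persisting to session end) — then pushed through
  the forward MBLL to dual-wavelength intensities.  ΔHbR is −0.35 x the
  structured ΔHbO component plus its own noise share.
- The battery gives seven of the nine metrics a cohort-level response (VFT
  and RMT stay flat — an arbitrary choice, since the study's supplement is
  not reproduced here); per-metric change is ΔGCS in population-SD units
  plus N(0, 0.25) noise.
- Seeding is hierarchical (master → per-subject → per-session), so adding a
  subject never changes another subject's data; cohorts are bit-exact
  reproducible.  Generator internals run in float32 (noise dwarfs rounding);
  the public forward model defaults to float64 so the forward/inverse MBLL
  round trip is exact to ~1e-12.

`effect_slope = 0.45` is the calibrated default: it was chosen once by
Monte-Carlo calibration so that the full pipeline's LOSO min(sensitivity,
specificity) exceeds 0.5 in well over 80% of replicate cohorts, and it
produces single-predictor R² values for the late-period biomarkers
(median ≈ 0.25) in the same range as those the analysis is designed around.
The home-recording noise amplitudes are calibration knobs, not empirical
claims.

**What the generator does not emulate:** photon transport and scalp
coupling, spatially structured (distance-dependent) connectivity,
non-stationary or task-evoked hemodynamics, learning effects in the
battery, and session-to-session placement variability.  Passing tests show
the *pipeline* recovers planted effects under the assumed statistical
model; they are not evidence about real fNIRS recordings.

## Problem sizes and numerical choices

- Replicate-level Monte-Carlo checks (parameter recovery, null
  calibrations) run cohorts with 240–300 s sessions rather than 900 s; all
  other generator parameters stay at the study conditions.  Shorter
  sessions raise correlation sampling noise, making these checks
  conservative in effect-recovery terms while keeping a 100-replicate run
  tractable on one CPU.
- Degenerate inputs: zero-variance channels get zeroed correlation rows
  (never NaN); an ANOVA cell with no within-cell variance reports p = 1
  with a warning; constant predictors are skipped; subjects whose
  biomarkers all abstain default to "responder" with a warning.
- The mixed-ANOVA interaction p is uniform under label permutation of an
  exchangeable cohort, which the suite verifies.  When half the cohort
  carries a strong period drift, relabeling produces a *conservative*
  parametric p (the trajectory mixture inflates the error mean square) —
  expected behaviour of the F-test, worth knowing when interpreting
  permutation checks on strongly structured data.
- Thresholds outside the 0.40–0.90 grid are rejected rather than rounded,
  to guard against silent grid drift.

## Known limitations

- The wavelet correction only partially removes sustained baseline shifts;
  heavy shift contamination inflates band-limited RMS (the suite bounds
  this at the study session length).
- With 45 candidate regressions and a global planted effect, training-set
  selection at p < 0.1 admits many correlated biomarkers; the per-fold
  optimized cutoff compensates, but specificity remains the weaker axis at
  small n — mirroring the source analysis, where the fixed 0.35 cutoff
  favours sensitivity.
- The 0.35 default cutoff and the voting rules for 2-biomarker periods are
  interpretive readings of the source protocol; both are configuration
  options, not derived quantities.
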