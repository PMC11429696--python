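# Methods

This note documents the models, parameter choices, numerical conventions, and
known limitations of the gazevote pipeline, in the order data flows through it.

## Data model and ingestion conventions

The atomic gaze event is the fixation, ingested as already-parsed events
(onset, offset, x, y); saccade detection from raw samples is out of scope. All
times are integer milliseconds relative to stimulus onset, removing wall-clock
ambiguity. Pixel coordinates are 0-based with the origin at the top-left;
regions of interest (ROIs) are axis-aligned rectangles, half-open on their max
edges, so boundary behavior is deterministic: a fixation exactly on an ROI's
right or bottom edge belongs to neither box.

Fixations that straddle the end of the 2.5 s presentation are truncated at the
presentation duration and contribute their truncated dwell; fixations starting
at or after it are dropped. All analyses use the presentation window only.
Ties in onset time are kept in file order and flagged with a warning.

Vote shares are two-party normalized at ingestion (each candidate's share
divided by the pair's sum, times 100) so each pair sums to exactly 100; the
raw share is retained on the record. Reports always state this decision.

## Gaze scoring

Subjects look more at the eventual loser, so the predicted winner under every
rule is the *less*-looked-at candidate: fewer in-box fixations, smaller summed
in-box dwell, or the side not fixated first. Design choices, made once:

- **Ties earn half credit** and stay in the denominator. Chance is then exactly
  0.5 under any tie rate, which makes the null calibration clean. Trials with
  zero in-box fixations are ties under every rule.
- **Accuracy unit is the session**: one proportion per session, then mean ±
  SEM and a two-sided one-sample t test against 0.5 across sessions. With zero
  between-session variance the t statistic is undefined and is reported as
  null rather than fabricated.
- **Rank tests**: Wilcoxon signed-rank for paired (within-race) contrasts with
  zero differences dropped; Wilcoxon rank-sum for unpaired contrasts. The
  exact null distribution is used for tie-free samples of up to 12 per group,
  the tie-corrected normal approximation above that. The exact branch is
  verified against brute-force enumeration of the null in the test suite.

## Facial morphometrics

Nine named landmarks fix the measurement semantics: zygion = widest cheekbone
point, gonion = widest jaw point, face_top = mid-brow, lower_face_top =
upper-lip midpoint, chin_bottom, plus the two pupil centers. Widths and
heights are Euclidean point-to-point distances (robust to slight head tilt),
normalized by the inter-pupillary distance; jaw prominence, FWHR, and LFP are
the usual ratios. Two conventions were genuinely open and are fixed here:

- FWHR uses **total** face height (mid-brow to chin) because that is the
  height measurement the pipeline ingests; the classical FWHR uses upper-face
  height. Comparisons with published FWHR values should account for this.
- Rater aggregation happens at the **metric** level (per-feature arithmetic
  mean across raters), and inter-rater agreement is the mean pairwise Pearson
  correlation across candidates, per feature, averaged over rater pairs and
  then features. Other concordance statistics (ICC variants) would be drop-in
  replacements; the choice is isolated in `rater_concordance`.

All ratios are invariant to translation, uniform scaling, and mirroring of the
landmark set (property-tested). Degenerate landmark sets (non-positive widths
or heights, midline points out of order) are rejected at construction.

## Election analysis

Correlations are Pearson (Spearman on request) with Fisher-z 95% confidence
intervals and t-distribution p-values. Partial correlation residualizes both
variables on a **single** control by simple regression and correlates the
residuals (p with n − 3 df); the analyses control one variable at a time, and
multi-control partials are deliberately out of scope. The joint appearance
model is OLS of two-party vote share on jaw prominence and competence,
reporting unadjusted R².

State lean: swing iff |presidential margin| < 10 percentage points (strict),
red at ≥ +10, blue at ≤ −10, positive margins Republican. This partitions the
real line, property-tested over the full range.

Stratified summaries report per-group mean ± SEM; two groups get a rank-sum
contrast, three or more a one-way ANOVA with Tukey's HSD for the pairwise
contrasts. Raw p-values are reported throughout; the only multiplicity
adjustment is Tukey's, inside an ANOVA family — there is no global FDR
control, and reports should be read accordingly.

Parameter-recovery checks use a race-level difference regression (share
difference on feature differences) rather than the candidate-level joint
model: the two candidate rows of one race are perfectly anticorrelated (shares
sum to 100), so candidate-level OLS confidence intervals are not valid for
coverage statements, while race-level differences have independent errors and
recover the generating coefficients directly.

## Synthetic-data generator

The generator's defaults are the study conditions; they are not tuned per run.

**Roster.** The default stimulus set fixes the pair composition exactly: 124
gubernatorial races (90 male-male, 32 mixed, 2 female-female; 74 races with an
incumbent; years 1995–2006) and 149 senatorial races (111/34/4; 120 with an
incumbent; years 2000–2008) — 273 pairs, 201 male-male, 66 mixed-gender, 546
candidates. A random-roster mode (`n_races`, `p_female` = 78/546,
`p_incumbent_race` = 194/273) generates unconstrained rosters for property
tests and calibration probes. Ages are Normal(52, 8) clipped to [30, 85];
reference presidential margins Normal(0, 12) points; smiles are coded 0/1/2
with 92.3% smiling.

**Faces.** Each candidate has a latent masculinity, Normal(±0.5, 1) by gender
(about one pooled SD of dimorphism). The four base measurements load linearly
on it, in IPD units: jaw width 1.60 + 0.060·m, cheekbone width 2.20 + 0.030·m,
face height 1.90 − 0.015·m, lower face height 0.76 + 0.020·m, each with
independent Gaussian noise (SDs 0.045/0.045/0.050/0.030). The intercepts are
typical adult proportions; the slopes give every masculinity cue detectable
dimorphism in the expected direction. Per-rater landmark tables add
Normal(0, 0.025) rater noise on the normalized measurements and invert the
measurement model (`landmarks_from_metrics`, an exact inverse of
`compute_metrics` up to the template's arbitrary degrees of freedom); with two
raters this yields an inter-rater concordance near 0.8.

**Competence and votes.** Competence loads on jaw prominence
(slope 4.5 per jaw-prominence unit, noise SD 0.99, giving a jaw–competence
correlation near 0.14 at unit competence SD). Vote shares follow
`share_a = 50 + (beta · diff)/2 + Normal(0, 6.8)` on within-race differences
in jaw prominence, competence, incumbency (4 pp advantage), and age (1 pp per
decade), clipped to (0.5, 99.5) and renormalized to sum to 100 (clipping is
rare at the default noise scale and is counted in the truth sidecar). The jaw
and competence coefficients (124.8 and 5.25) are the output of the package's
own closed-form moment calibration (`calibrate_vote_betas`), solved so the
population correlation structure matches the study's: r(jaw, share) = 0.27
and r(competence, share) = 0.337, the marginal implied by the study's partial
correlations (0.25, 0.31) together with r(jaw, competence) = 0.14.
The calibrator estimates the needed moments from a large probe roster and
then solves the two-equation system exactly.

**Gaze.** Per trial, the in-box fixation count is Poisson(8) (about 250 ms
fixations plus saccades inside 2.5 s); each fixation falls on the left side
with probability `logistic(side_bias + a_d·loser_sign + a_jaw·(J_R − J_L) +
a_fem·(fem_L − fem_R) + a_age·Δdecades)`. The default uses the **emergent**
route — `a_d = 0`, `a_jaw = 6`, `a_fem = 0.4`, `a_age = 0.1` — so the
loser-directed bias arises because gaze avoids prominent jaws and prominent
jaws win; the direct term exists for calibration. Durations are
Gamma(shape 4, mean 250 ms); onsets are sequential with a fixed 30 ms
inter-fixation gap (a stand-in for saccade time, not a modeling claim) after a
200 ms initial latency, truncated at 2500 ms. Every trial begins with a
central fixation at the trial-initiation spot, which lies outside both ROIs —
it is ignored by ROI scoring but guarantees every trial is represented in the
fixation table even when no image fixation survives. Fixation positions are
box centers plus small jitter clipped inside the box (events are assigned by
construction; position is cosmetic).

**Calibration oracles.** `analytic_pair_accuracy` computes the exact expected
fixation-count-rule accuracy for one race by summing the Poisson count
distribution (truncated at residual mass 10⁻¹², remainder assigned its
large-count limit) against the binomial allocation; it is validated against
its own brute-force Monte Carlo and is strictly increasing in the allocation
coefficient. `solve_loser_allocation` inverts it by root-finding.

**What the generator does not emulate.** Fixation-count and dwell
distributions of real data (Poisson/Gamma are conveniences), sequential
dependencies between fixations, photograph idiosyncrasies (expression, pose,
lighting) beyond the coded covariates, correlations between incumbency and
appearance, and between-monkey heterogeneity. Passing tests therefore
demonstrate the pipeline's correctness and calibration under the assumed
statistical structure, not distributional fidelity to any recorded dataset.

## Sessions and problem sizes

One monkey-day comprises one session per office, each office's race set shown
exactly once in shuffled order with random side assignment; the default is 3
monkeys × 2 days = 6 monkey-days = 12 office-sessions. Accuracy summaries use
office-sessions (n = 12); the chance-calibration runs group by monkey-day so a
"session" is the full 273-trial day. The test suite uses 200 such sessions for
the null band, 100 replicate seeds for coverage and non-significance counts,
500 races per seed for parameter recovery, and 25 replicate rosters for the
reported correlation structure — sizes chosen so Monte Carlo error is small
relative to every asserted band while the whole suite runs in minutes.

## Known limitations

- The half-credit tie policy and the session-level accuracy unit are
  conventions; alternative accounting (excluding ties) would shift accuracies
  by a small amount and is not implemented.
- FWHR uses total face height (above); absolute FWHR values are therefore
  lower than upper-face-height FWHRs in the literature.
- Concordance is a Pearson-based statistic, not an ICC; with few candidates or
  restricted range it can understate agreement.
- The vote model is linear with Gaussian noise and no year/state effects;
  two-party normalization discards third-party dynamics.
- Partial correlations handle one control at a time by design.
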