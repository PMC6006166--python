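# Methods

`pefmri` implements a complete reward prediction-error (PE) analysis chain
for a three-group cross-sectional fMRI study — healthy controls, an at-risk
mental state (ARMS) group and a first-episode psychosis (FEP) group — on
fully synthetic data. This note documents the models, the generator, the
numerical choices, and what the test suite does and does not establish.

## Task model

The probabilistic monetary learning task presents three stimulus pairs, each
`n_per_pair` times (default 30, i.e. 90 trials):

| pair | high-prob stimulus | low-prob stimulus |
|---|---|---|
| reward | £1 win p=0.8, neutral p=0.2 | win p=0.2 |
| bivalent | ±£1 with p=0.5 each (both stimuli) | — |
| neutral | feedback A p=0.8, feedback B p=0.2 | A p=0.2 |

Pseudo-randomisation draws the next trial type proportionally to remaining
counts while forbidding runs longer than 4 of one type; the side of the
high-probability stimulus is counterbalanced exactly (half left, half right)
within pair type, which is why `n_per_pair` must be even. The "correct"
stimulus of the bivalent pair is an arbitrary but fixed designation used
only by the preference analyses.

## Learning model

A single-learning-rate Rescorla–Wagner (Q-learning) agent:
δ_t = r_t − Q(chosen), Q(chosen) ← Q(chosen) + α·δ_t, with softmax choice
P(choose i) = σ(β·(Q_i − Q_j)). Initial values are 0; only monetary value
enters the update (neutral feedback of either kind is r = 0); the unchosen
stimulus is never updated; value tables are independent across pairs.
Richer variants (dual learning rates, perseveration kernels, Bayesian
fitting) are deliberate non-goals.

Fitting is bounded maximum likelihood over α ∈ [0.001, 0.999],
β ∈ [0.01, 20] by Nelder–Mead from 10 random restarts plus a centre start;
ties break by lowest NLL then lowest β; a solution on the box boundary is
flagged unconverged. At the default 90 trials the α estimate is noisy but
nearly unbiased at the group level (mean α̂ ≈ 0.33 for true α = 0.3 over 50
agents) and preserves between-subject ranking (Spearman ρ > 0.5).

### Asymptotics that motivate the contrast

At steady state E[Q] of the high-probability reward stimulus approaches its
win rate 0.8, so a reward-pair win elicits δ ≈ 0.2, while bivalent values
hover near 0 and a bivalent win elicits δ ≈ 1. Contrasting the two £1-win
events therefore isolates high-vs-low positive PE while being exactly
balanced in outcome value: a purely value-coding response contributes
identically to both regressors and cancels (verified to machine precision
in the tests).

## Behavioural analyses

Correct-choice rates, six-bin learning curves, and win-stay/lose-shift
(WSLS) probabilities are computed per pair type. WSLS transitions are
consecutive presentations of the same pair (intervening other-pair trials
do not break the chain — the alternative windowing is not specified in the
field's standard descriptions, and this choice maximises usable
transitions); a "win" is +£1 for reward/bivalent pairs and feedback kind A
(colour match) for neutral pairs; undefined rates (zero denominator) are
NaN, never 0. The mixed ANOVA (between group × within trial type) uses a
weighted-means sums-of-squares decomposition on the balanced within-subject
design; permutation p-values (group: subject-label shuffles; within and
interaction: within-subject level shuffles; ≥1000 draws) are primary, with
classical F-distribution p-values as a cross-check. The implementation is
validated against an independent brute-force decomposition and against
`pingouin.mixed_anova`.

## First-level model

Seven task regressors (three cue onsets by pair type; neutral outcomes
pooled over reward and neutral trials; reward wins; bivalent wins; bivalent
losses), all 2 s events, convolved with the canonical double-gamma HRF
(peak delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio
1/6 — the shape matches SPM's canonical HRF to r > 0.999). Each task
regressor carries a finite-difference temporal-derivative column (14 task
columns); six motion columns, a linear trend and an intercept complete the
design. Timing: TR = 2 s, one trial per 10 s (cue at 0 s, outcome at 4 s
within the trial), 20 s washout — a typical 3T EPI protocol; the spatial
grid is 2 mm isotropic. Fitting is voxelwise OLS (no prewhitening — a
stated non-goal; the AR(1) noise slightly miscalibrates single-subject
standard errors but group inference never uses them). The PE contrast is
COPE = β(bivalent win) − β(reward win); cue, loss, derivative and nuisance
columns carry zero weight.

The alternative model-based path — a demeaned trial-wise δ parametric
modulator from the fitted Q-model (`rl.pe_series`) — agrees in sign with
the contrast path on PE-coupled synthetic subjects (tested).

## Synthetic cohort generator

Defaults emulate the target study conditions: 39 controls, 30 at-risk,
14 FEP; 30 trials per pair.

* **Agents**: α ~ N(0.30, 0.10²) clipped to [0.02, 0.98], β ~ N(2.8, 1.0²)
  clipped to [0.1, 20] for controls and at-risk; FEP β-mean 2.2 (slightly
  noisier choices, echoing their lower win-stay/higher lose-shift).
  Calibration was by forward simulation against the target group
  behaviour: reward-pair correct ≈ 74–75%, overall win-stay ≈ 0.69.
  **Known limitations**: without a perseveration term this model family
  floors lose-shift near 0.50 (target ≈ 0.44), and with neutral feedback
  coded r = 0 the neutral-pair preference stays at chance (target 55%).
* **RTs**: log-normal, pair-type means 1122.83 / 1358.99 / 1329.30 ms
  (reward/bivalent/neutral), subject log-SD 0.20, trial log-SD 0.30, both
  variance-corrected so expected means equal the configured means. RTs are
  never used by the fitter.
* **ROIs** (geometric stand-ins on an MNI-like 2 mm grid): midbrain
  ellipsoid centred (0, −14, −10) mm with semi-axes (8, 8, 6) mm;
  striatum as two boxes centred (±26, 8, 2) mm, half-sizes (8, 10, 8) mm;
  right-DLPFC sphere of radius 10 mm centred (50, 30, 28) mm (515 voxels).
  The `full` grid is 48×56×44; a `reduced` field of view (38×35×31,
  midbrain + DLPFC only) serves desk-scale permutation studies.
* **BOLD forward model**: inside each ROI every voxel carries the δ-scaled
  win-event signal with a subject×ROI coupling drawn from a group-specific
  Gaussian *in COPE units* (midbrain 24.44/50.12, 0.66/54.86, −55.03/50.70;
  DLPFC 32.90/62.82, 36.29/53.03, −45.13/48.40 for controls/at-risk/FEP;
  striatum identical across groups). The gain is normalised per subject by
  the noise-free contrast projection of their own PE signal, so at zero
  noise the GLM returns exactly the configured coupling; the population
  mean of that projection (0.585) is kept as a fallback constant. One
  coupling value per subject per ROI is a declared simplification — true
  within-ROI heterogeneity is not modelled. Outside the ROIs, voxels carry
  generic cue/outcome signal at fixed amplitude. All voxels receive AR(1)
  noise (φ = 0.3, marginal SD 100 — giving per-voxel COPE noise SD ≈ 19 and
  total per-voxel subject SD ≈ 54, commensurate with the target cluster
  SDs), cosine drift (amplitude 10, period 128 s, random phase) and a weak
  motion artefact built from the same random-walk columns supplied to the
  design.
* **Symptom scores**: CAARMS-total-like Gaussians truncated at 0
  (at-risk 15.10/6.75, FEP 23.86/6.48, controls 2/2 as a sub-clinical
  floor), uncorrelated with coupling by construction.

What passing tests show — and don't: the generator demonstrates that the
analysis chain recovers the group structure it encodes; it says nothing
about registration, physiological noise, motion-correlated signal or
atlas-definition effects, which are all out of scope.

## Group inference

Per ROI, one-way ANOVA F (or two-group pseudo-t) at each voxel, with the
pooled within-group variance image Gaussian-smoothed at 3 mm FWHM
(edge-renormalised inside the mask) before forming the statistic. TFCE with
E = 0.5, H = 2, 6-connectivity and dh = max(observed statistic)/100 (the
standard published settings); permutation maps integrate on the same
threshold grid extended to the global maximum so every map's integral is
covered. FWE correction is by the permutation distribution of the
mask-wide maximum TFCE with the observed labelling included in the null
set, so corrected p ≥ 1/(n_perm+1) and corrected ≥ uncorrected everywhere;
p = 0.05 counts as significant. When fewer distinct labelings exist than
requested permutations, all are enumerated and the result flagged
exhaustive. Default 5000 permutations (pipeline), 300–500 in the test
suite. Under a complete null the family-wise false-positive rate is
calibrated (≈ 0.05 over 200 replicate datasets, tested).

Planned one-tailed pairwise comparisons (controls > at-risk, at-risk > FEP,
controls > FEP) are run on per-subject cluster means over the
ANOVA-significant voxels via two-sample permutation tests (10,000 label
shuffles). An empty significant set is an explicit result, not an error.
Spearman correlations (tie-corrected) relate cluster means to symptom
scores within the clinical groups.

A note on power: at the configured coupling moments the one-tailed
controls-vs-at-risk midbrain comparison has ≈ 58% power at α = 0.05
(n = 39 vs 30, difference ≈ 24 COPE units, SD ≈ 52), so individual cohort
replications are expected to split on that comparison even though the
*ordering* of the extracted means is stable (≈ 97% of replications). The
replication tests distinguish these two claims.

## Pipeline

`pefmri all --config cfg.yaml` runs simulate → behave → firstlevel →
grouplevel → report. All stage seeds derive deterministically from the
master seed (SHA-256 of `seed:stage`), so a re-run reproduces behavioural
tables byte-for-byte and permutation p-values exactly. The first-level
stage simulates and fits ROI voxels only (COPE maps are zero outside the
masks); `write_bold: true` additionally materialises full 4D NIfTI volumes.
Problem sizes in the shipped tests (reduced grid, 100–500 permutations,
6–20-subject smoke cohorts) were chosen to keep a laptop-scale run under a
minute per cohort; the defaults in the config (full cohort, 5000
permutations) reproduce the study-scale analysis in a few minutes.
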