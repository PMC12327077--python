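# Methods

This document records the modeled experiment, the forward simulation, the
estimation pipeline, and the numerical choices. Module names in parentheses
refer to `src/rulefmri/`.

## 1. Experimental design (`design.py`)

Each subject completes 24 experimental blocks (plus 3 practice blocks, which
are excluded from analysis) distributed over 4 scanner runs, 6 blocks per run
with exactly 2 blocks of each learning condition per run. The three
conditions are `instruction` (the correct stimulus–response mapping is shown),
`trial_and_error` (the subject guesses and receives feedback), and
`observation` (the subject watches a previous learner's trial-and-error run).

A block introduces 4 novel stimuli, each presented 8 times: repetitions 1–4
form the learning stage, 5–8 the implementation stage. Presentations are
organized in repetition chunks — every stimulus appears once per chunk, in
freshly shuffled order — giving 32 trials per block and 768 experimental
trials per subject. Across 24 experimental + 3 practice blocks, 108 unique
stimuli appear, none repeated across blocks.

Trial timing: stimulus (1.5 s), response window, feedback where applicable,
and jittered inter-trial intervals; cue screens announce each block's
condition. TR = 2.07 s; the first 3 scans of each run are discarded.

Behavior: trial-and-error responses come from an `eliminate_tried` learner
(errors never repeat a previously tried wrong response); observation blocks
replay a source subject's trial-and-error behavior, yoked in cohort sets of
5 subjects. After behavior is known, repetitions are *recoded by accuracy*:
a stimulus's repetition counter advances only after its first correct
response, so repetition k always means "k-th exposure with the rule
available".

## 2. BOLD simulation (`simulate.py`)

The simulator generates per-run voxel time series on a small 3-D grid with a
known ground truth:

* **Hemodynamics.** A canonical double-gamma HRF (peak ≈ 5 s, undershoot
  ≈ 15 s, unit peak height, ≈ 32 s support) convolved with per-trial boxcars.
* **Identity patterns.** Each region spec draws, per stimulus, a learning
  pattern and an implementation pattern with correlation ρ
  (`cross_stage_consistency`); patterns scale with `identity_snr`. ρ is the
  dial that makes cross-stage pattern similarity exist or not while leaving
  stage-specific similarity intact.
* **Amplitude trends.** Per-condition linear slopes over repetitions inject
  univariate learning effects; ground-truth per-trial amplitudes are stored.
* **Noise.** AR(1) Gaussian noise (unit marginal s.d., lag-1 ≈ 0.3 by
  default) plus low-frequency drift. Drift is drawn in the discrete-cosine
  basis of the *retained* scan window (evaluated backward across the
  discarded volumes) so the analysis high-pass filter can remove it exactly —
  a deliberate choice that makes noiseless tests exact.

### Realism limits

The simulation is a test harness, not a biophysical model: no motion, no
physiological noise, no spatial autocorrelation beyond region structure, no
susceptibility artifacts, and linear superposition of responses. Group
effects are homogeneous across simulated subjects except for noise.
Quantities estimated on simulated data therefore bound algorithmic
correctness, not empirical effect sizes.

## 3. Single-trial estimation (`lss.py`)

Least-Squares-Separate: one GLM per experimental trial (768 models), each
with 7 event regressors — the target trial; all same-condition other trials
collapsed; the two other conditions' trials collapsed (one regressor each);
and three condition-cue regressors — plus run-wise discrete-cosine high-pass
(200 s cutoff) and a constant. Each model is fit on the run containing the
target trial. Downstream patterns are per-trial t-maps (beta ÷ SE); betas
are available via `stat="beta"`.

**Fast solver.** Because all of a condition's models share every column
except the target/others split, the solver residualizes once against the
shared nuisance span (QR) and then solves each model's remaining 2 × 2
normal equations in closed form, vectorized over trials. It is verified
against a naive per-model least-squares implementation to 1e-10.

**Approximation bias.** Collapsing the remaining trials into one regressor
is the standard LSS compromise: with dense default timing (2–4 s ITIs) the
recovered trial amplitudes correlate with injected truth at ≈ 0.77 *even
without noise*. Recovery tests therefore use either (a) condition-constant
amplitudes, which lie in the collapsed model's span (exact recovery), or
(b) trial spacing beyond the 32 s HRF support, where r > 0.99 at noise
s.d. 0.1.

## 4. Pattern similarity (`similarity.py`)

For one block and repetition pair (i, j): r_same = mean Pearson correlation
over stimuli between the stimulus's patterns at i and j; r_diff = mean over
all ordered pairs s ≠ s′; the statistic is r_same − r_diff, averaged over
the scheme's pairs and then over each condition's blocks. Schemes:
learning {2,3,4} (3 pairs), implementation {5..8} (6 pairs), cross-stage
(12 learning × implementation pairs; within-stage pairs excluded), and
pooled variants for the searchlight. Repetition 1 is excluded; correct and
incorrect trials enter alike at their recoded repetition (excluding errors
would break the repetition-chunk balance; an opt-in `exclude_incorrect`
policy drops affected pairs with a warning).

## 5. Searchlight and ROIs (`searchlight.py`, `roi.py`)

The searchlight evaluates the block-averaged pooled pattern-similarity
statistic in a voxel-lattice sphere around every in-mask center (radius 3
voxels = 123 offsets; spheres clipped at the volume edge; centers whose
sphere falls below a voxel floor are NaN). ROI utilities build mm-radius
spheres on arbitrary affines, intersect masks, and split thresholded t-maps
into 26-connected clusters.

## 6. Group statistics (`stats.py`)

* **rm-ANOVA** (fully within-subject, 1–2 factors) via orthonormal contrast
  bases and Kronecker products; Greenhouse–Geisser
  ε = tr(Σ)² / (q·tr(Σ²)) clipped to [1/q, 1], applied to the F dfs.
  Verified against hand-worked closed forms and `pingouin`.
* **Post-hoc** estimated-marginal-mean contrasts with a max-|t|
  multivariate-t adjustment (`mvt_max_abs_p`): Monte-Carlo equicoordinate
  probability with a shared chi-square denominator; converges to the Šidák
  bound under independence and is clipped to [unadjusted, Bonferroni].
* **Permutation cluster correction**: voxelwise one-sample t, one-sided
  cluster-forming threshold, 26-connectivity, sign-flip null of the maximum
  cluster size, corrected p = (1 + #{null ≥ size}) / (n_perm + 1).
* **Conjunctions**: minimum-statistic over t-maps, conjunction-null
  (each map past α) or global-null (min past α^(1/m)) thresholds.

## 7. Numerical choices

* All estimators are plain OLS via QR/`lstsq`; no regularization anywhere.
* Derived RNG seeds come from `numpy.random.SeedSequence` and stay below
  2³¹; every public simulation entry point is deterministic given its seed.
* Oracle tolerances: exact linear-algebra identities at 1e-8–1e-12;
  Monte-Carlo calibrations at ±4–5 percentage points around nominal α.

## 8. Limitations

* Desk-scale grids (8³–10³ voxels, 6-block subjects in most tests) keep the
  suite within minutes; statistical power at these sizes differs from a real
  80-subject study.
* The LSS collapse bias (§3) is inherent to the estimator, not a bug; see
  the recovery tests for its measured size.
* No slice-timing, motion, or physiological-noise correction exists because
  the simulator generates none of those artifacts.
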