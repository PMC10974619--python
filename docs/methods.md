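# Methods

This note documents the models implemented in `limbaug`, the synthetic
data they are exercised on, and the numerical choices behind both. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline model

The package assumes the standard marker-augmentation setting: a
pose-estimation front end supplies 13 lower-body keypoints per frame as
3D positions in meters (right-handed axes, X anterior, Y up, Z to the
subject's right; Z-up files are rotated on import), and a paired
photogrammetric or mesh-based reference supplies 18 anatomical
landmarks for training. The learned mapping is *local in the subject's
own frame*: all coordinates are expressed relative to the midpoint of
the two hip keypoints and divided by the subject's stature, so that the
network never sees absolute position or scale. The same hip midpoint
and stature (stored as `CenteringOffsets`) invert the transform at
inference, returning world-frame meters.

### Pre-processing

1. **SACR substitution.** The left/right PSIS landmarks are replaced by
   their per-frame midpoint SACR, reducing 18 landmarks to 17 (the form
   the ISB pelvis construction needs). Idempotent.
2. **Centering and scaling** as above; the hip midpoint of the
   transformed keypoints is exactly the origin in every frame.
3. **Min–max normalization** of stature and body mass against ranges
   computed over the *training* subjects; the ranges are stored inside
   every trained model (`NormalizationSpec`) so inference reproduces
   training-time inputs exactly. Out-of-range subjects extrapolate
   beyond [0, 1] and are logged, not rejected.
4. **Rotation augmentation** (training only): rotated copies of each
   centered trial about the vertical axis, applied identically to
   keypoints and landmarks. The angle list is a configuration choice;
   8 evenly spaced angles by default, 2 (0°/180°) in the desk-scale
   experiments below.
5. **Feature assembly.** Per frame: `[sex, weight_norm, height_norm]`
   followed by the 13 keypoints in fixed alphabetical order, X/Y/Z each
   (42 values); targets are the 17 processed landmarks, alphabetical,
   X/Y/Z (51 values). Sequence models consume 16-frame windows (stride
   1 by default); trials shorter than one window are left-padded by
   repeating the first frame, with the padding flagged and the padded
   predictions discarded.

### Architectures

All three share the 42 → 51 contract; parameters are Glorot-uniform
initialized from a seeded generator, so builds are bit-reproducible.

* **MLP** — three blocks of dense → batch normalization → activation
  (256 tanh, 128 relu, 224 relu) and a linear 51-unit head, applied per
  frame. Batch normalization uses momentum 0.99 and ε = 1e-3 on the
  running statistics.
* **LSTM** — two standard LSTM layers of 128 units (forget-gate bias
  initialized to 1) over the 16-frame window, then a per-frame linear
  head; sequence-to-sequence, so every window frame is supervised.
* **Transformer** — linear embedding of each frame's 42 features to the
  hidden width (224 = 14 heads × 16 at full width), scaled by √d and
  summed with a sine positional table, then 6 post-norm encoder blocks
  (multi-head self-attention + residual + layer norm, 2×-wide relu
  feed-forward + residual + layer norm) and a per-frame linear head.

  The token construction was a genuinely open design point. Two
  layouts are implemented: `token_layout="frame"` (default; one token
  per frame, attention over time) and `token_layout="frame-axis"` (the
  window viewed as 13 keypoint channels plus 3 anthropometric
  pseudo-channels replicated across X/Y/Z, a pointwise 1×1 projection
  of the 16 channels to the hidden width, and one token per
  (frame, axis) pair — 48 tokens). On the synthetic testbed both
  layouts converge identically per optimizer step, but the 48-token
  layout costs ~3× more per step; the frame layout is therefore the
  default. The √d embedding scaling keeps the content signal dominant
  over the additive positional table (without it, a unit-amplitude
  positional signal swamps the ~0.2-magnitude coordinate embeddings).

Inference for the sequence models runs stride-1 sliding windows and
averages all window predictions covering a frame — deterministic and
robust at trial edges.

### Training

The full-scale defaults (`TrainingConfig.default_for`) follow the
published recipes this package reimplements: MSE loss throughout;
RMSprop at 2e-5 for 100 epochs (batch 64) for the MLP; Adam at 7e-5 for
200 epochs (batch 32) for the LSTM and 300 epochs (batch 64) for the
Transformer; no early stopping or validation checkpointing. Optimizer
internals use the common defaults (RMSprop ρ = 0.9; Adam β = 0.9/0.999;
ε = 1e-7). Training is deterministic given a seed (initialization and
batch shuffling both derive from it), raises on NaN loss with the
offending batch, and warns if the final epoch loss is not below the
first.

**Desk-scale configurations** (`SCALED_TRAINING`) exist because those
learning rates are matched to a training corpus of hundreds of
thousands of augmented frames, where a single epoch takes thousands of
optimizer steps. The synthetic recovery study below is more than an
order of magnitude smaller, and at the reduced epoch counts
(MLP 100, LSTM 30, Transformer 30) the published rates leave all three
networks far from convergence. The desk-scale schedules keep each
architecture's optimizer and batch size and rescale the learning-rate
schedule to the problem size: MLP RMSprop 2e-3 with 0.94/epoch decay;
LSTM Adam 2e-3 with 0.9/epoch decay and training-window stride 2;
Transformer Adam 8e-3 with 2-epoch linear warmup, 0.93/epoch decay and
stride 1. Width-reduced variants (`AugmenterSpec.reduced`) shrink the
LSTM to 32 units and the Transformer to hidden 32 / 2 layers / 4 heads;
the MLP keeps its published widths.

The memorization check (one (feature, target) pair copied 64 times,
2000 single-batch epochs) runs at RMSprop 1e-3: with identical samples
batch normalization passes no batch signal, so only bias paths train,
and the check verifies optimizer and backpropagation correctness rather
than any particular published rate.

## Kinematics

Anatomical frames are built directly from the 17 landmarks every frame
(no technical-cluster tracking; the trochanterion is carried as a
technical marker but unused in the default frames):

* **Pelvis** — origin at the ASIS midpoint; Z along L→R ASIS; X in the
  ASIS/SACR plane, orthogonal to Z, pointing away from SACR (anterior);
  Y = Z × X.
* **Hip joint centers** — fixed points of the pelvis regressed from
  pelvis width PW = |R-ASIS − L-ASIS| and depth PD = |ASIS midpoint −
  SACR|: x = −0.24·PD − 9.9 mm, y = −0.30·PW − 10.9 mm,
  z = ±(0.33·PW + 7.3 mm) in the pelvis frame (Harrington-style
  coefficients; the table is configurable because regression variants
  abound in the literature).
* **Femur** — origin at the HJC; Y up the shaft toward it from the
  epicondyle midpoint; Z from the epicondylar axis orthogonalized
  against Y; X = Y × Z. **Shank** — likewise from the malleoli.
  **Foot** — origin at the ankle (malleoli) center; Z is the malleolar
  axis; X the heel→toe direction projected orthogonal to it;
  Y = Z × X. Medio-lateral axes always point to the *subject's* right,
  on both sides.
* **Joint angles** — Cardan Z–X′–Y″ decomposition of
  R_parentᵀ·R_child: flexion–extension about Z, abduction–adduction
  about the rotated X (range-limited to ±90°), axial rotation about the
  twice-rotated Y. Left-side AB-AD and ROT are sign-flipped so positive
  means adduction / internal rotation on both sides; mirror-image
  motion therefore yields exactly swapped L/R angle series. Frames
  within 0.5° of gimbal lock are flagged via logging, not rejected.

Note a structural property of this (standard) foot convention: because
the foot frame borrows the malleolar axis from the shank, the
reconstructed ankle joint is a one-degree-of-freedom hinge — ankle
AB-AD/ROT arise only from disagreement between raw and orthogonalized
malleolar axes (zero in exact data, small under prediction error).

## Synthetic data generator

The generator stands in for a mesh-derived motion dataset and defines
the package's study conditions. It emulates exactly the structural
assumptions the pipeline relies on, with all randomness derived from
explicit seeds:

* **Rigid, homologous landmarks.** Landmarks are constant offsets in
  their parent segment frames (pelvis, femur, shank, foot), scaled
  linearly with stature from common anthropometric proportions (pelvis
  width 0.14 H, thigh 0.245 H, shank 0.246 H, foot 0.152 H). Landmark
  positions carry *no* measurement noise — they play the role of
  mesh-vertex ground truth. Within-segment inter-landmark distances are
  constant to machine precision.
* **Analytic motion.** Per movement, joint angles follow sums of
  sinusoids (per-subject amplitude jitter, anti-phase left/right for
  locomotion, in-phase for symmetric movements) plus pelvis
  translation/sway; gait/running/jump run at 60 fps, the others at
  30 fps, and the A-pose is static up to centimetric sway. Forward
  kinematics uses the same hip-joint-center regression and frame
  conventions as the kinematics module, so the generating angles are
  recovered to numerical precision from noiseless landmarks — the
  package's central cross-module oracle. The ankle is scripted as a
  pure hinge, consistent with the foot-frame convention above.
* **Keypoints.** Each keypoint is a fixed convex combination of
  landmarks (e.g. hip ≈ 0.5·ASIS + 0.3·TRO + 0.2·SACR) plus, for
  points outside the lower-limb hull (nose, shoulders, heel), a
  constant segment-local offset scaled with stature — emulating the
  systematic offset between pose-network joints and anatomical
  landmarks — then iid Gaussian noise per axis (default SD 5 mm, the
  scale of multi-view triangulation error) and an optional per-keypoint
  temporal jitter (default off).
* **Subjects.** Sex ~ Bernoulli(½); stature ~ N(1.70 m, 0.12 m)
  truncated to (1.40, 2.05); mass couples to stature at 80 kg/m with a
  10 kg residual SD — moments typical of an adult volunteer cohort.
  Datasets allocate subjects to train/test in 57:14 proportions, split
  strictly by subject.

What the generator does *not* emulate — soft-tissue artifact,
pose-detector failure modes (occlusion, left/right swaps), fps-dependent
noise correlation, non-stationary movement variability — bounds what
passing tests show: they validate the pipeline's correctness and its
recovery capability under the stated noise model, not performance on
real video-derived data.

### Desk-scale recovery study

The synthetic benchmark used by the acceptance suite and
`scripts/acceptance.py`: 20 subjects × four 30-fps movements (squats,
jumping jacks, forward jump, turn jump) × 10 s, 5 mm keypoint noise,
two-angle (0°/180°) training augmentation, width-reduced
LSTM/Transformer, desk-scale training schedules. Success criterion:
held-out mean landmark error within 1 cm ≈ twice the keypoint noise
floor (the common-mode hip-noise component alone contributes ~0.6 cm of
irreducible mean Euclidean error). Problem sizes were chosen so the
whole study trains all three architectures in under ten minutes on one
CPU core.

## Error metrics and mixed models

* **Position error** — per-landmark Euclidean distance averaged over
  the trial, in cm. **Angle error** — RMSD per (joint, axis, side), in
  degrees. Aggregation tables average raw records per cell; "Across"
  margins are means of the underlying records (not of cell means), so
  unbalanced designs weight by record count.
* **Mixed models** — one record per subject × trial × landmark (or ×
  joint × axis × side); fixed factors with sum-to-zero contrasts
  (position: model, movement, landmark, model:movement,
  model:landmark; angle: model, movement, joint, axis, side,
  model:movement, model:joint, model:axis, joint:axis,
  model:joint:axis) and a random intercept per subject, fitted by REML
  through statsmodels MixedLM. Because a near-zero subject variance
  puts the optimum on the parameter boundary where individual
  optimizers misbehave, fitting tries several optimizers and keeps the
  best-likelihood solution.
* **ANOVA** — Type-III sums of squares on the GLS-whitened regression:
  each subject block is decorrelated with the estimated
  compound-symmetry covariance (scaled to preserve the residual
  variance), and each term's SS is the RSS increase from dropping its
  columns from the full design. Type-III (not sequential) because the
  interactions make factor order arbitrary.
* **R²** — Nakagawa–Schielzeth: marginal = var(Xβ̂)/(var(Xβ̂) + τ² +
  σ²); conditional adds τ² to the numerator.
* **Anthropometrics comparison** — ML refits without/with sex, stature
  and mass as fixed covariates, compared by likelihood ratio. The
  covariates are constant within subject, so their effective sample is
  the number of subjects; at cohort sizes in the tens the χ²(3)
  reference is markedly anticonservative. The default therefore maps
  the LR statistic to an F(3, m−4) reference (the exact
  LR ↔ F correspondence in the between-subject regression stratum);
  the plain χ² test remains available as `method="chisq"`.

## Numerical choices

* Network computation in float32 (ample for SGD; halves memory
  traffic); kinematics and statistics in float64.
* The autodiff engine is a minimal reverse-mode tape over numpy with
  copy-free gradient adoption (a second contribution to the same node
  allocates a fresh sum, so sibling gradients are never aliased
  in-place).
* Checkpoints are single `.npz` archives (spec + normalization JSON,
  weights, training log) with an explicit version field; corrupted or
  version-mismatched files raise.
* Degenerate geometry (collinear pelvis points, coincident landmarks)
  raises with the frame index; gimbal proximity only warns.
* Windowing of trials shorter than one window left-pads by repeating
  the first frame rather than dropping the trial.

## Known limitations

* The synthetic keypoint↔landmark relationship is far more learnable
  than real pose-detector output; desk-scale errors (~0.6–0.9 cm) are
  not predictions of real-data performance.
* The ankle hinge convention suppresses genuine subtalar motion; real
  foot models with foot-fixed medio-lateral axes would recover it.
* Mixed-model inference assumes Gaussian, homoscedastic errors;
  position errors are non-negative and mildly skewed, which the
  simulation mirrors only via truncation at zero.
* The full-scale training recipes are carried as defaults but are not
  exercised end-to-end here; reproducing published full-scale error
  tables requires the original video-derived dataset and its training
  budget.
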