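# Methods

## Model

Three independently trained classifiers cooperate on a grayscale patch
`x`. The gate emits finding-type weights `(wc, wm)` from a two-class
softmax, so `wc + wm = 1` holds structurally rather than by post-hoc
renormalisation. The two experts and the conventional baseline emit
3-class probabilities (cancer, benign, normal) from a three-class softmax.
The mixture output is `y = wc·cExp(x) + wm·mExp(x)`, a convex combination
of probability vectors and therefore itself a probability vector. The
equal-weight ensemble baseline pins the gate at (0.5, 0.5); the
conventional baseline is a single network trained on every
diagnosis-labelled patch.

Training-data routing: the gate sees every lesion patch labelled by its
finding type (a patch tagged with both findings contributes one instance
per tag — instance duplication rather than a multi-label head, keeping all
four networks ordinary softmax classifiers); each expert sees its own
finding's patches plus all normals; the conventional net sees everything.

## Evaluation protocol

One patient-grouped, diagnosis-stratified K-fold partition (K = 5) is
drawn once from the master seed. Patients within each diagnostic stratum
are shuffled and dealt round-robin, so per-stratum fold sizes differ by at
most one patient and no patient's patches ever straddle folds. The K-fold
cycle is repeated R times (default 5; desk-scale runs use 1–2), varying
only network-initialisation and data-order seeds; repetitions reuse the
single partition so that "integrate the out-of-fold predictions over
folds" stays well defined. Per-patch predictions are averaged over the R
repetitions; all per-repetition vectors are retained for audit, and the
training-set membership of every (repetition, fold) model is recorded so
leakage can be checked exhaustively.

Grouping by patient is a deliberate strengthening: splitting at the patch
level would let two patches of one synthetic patient (or two lesions of one
real breast) fall on opposite sides of a fold boundary.

## ROC statistics

AUC is the Mann–Whitney statistic computed via midranks in O(n log n);
the rank-sum form of the estimate keeps the numerator an exact
half-integer, so the value is bit-identical to brute-force pairwise
enumeration, ties included. Uncertainty uses DeLong's
structural-components estimator: `var(AUC) = S10/m + S01/n` with S10, S01
the ddof-1 variances of the per-positive and per-negative mean-psi
components. The paired test for two models scored on the same patches
includes the cross-model component covariances; `z` is referred to the
standard normal, two-sided. When the variance of the difference is exactly
zero and the AUCs agree, p = 1 by convention. Confidence intervals are
normal-approximation intervals on the AUC scale, clipped to [0, 1]; the
binary reduction of the 3-class output is the raw cancer probability
(not renormalised against benign), and per-finding AUCs compare cancer vs
benign within the tagged subset, excluding normals by default (they carry
no finding tag; a switch includes them).

## Synthetic patches

The generator emulates the two finding types at 64 px (configurable; all
pixel-valued parameters are stated at a 64 px side and scale linearly with
`image_size`, so 512 px renders are geometrically similar). Background is
a uniform base level (0.35) plus Gaussian-filtered white noise
(correlation length 6 px, amplitude 0.35 before filtering — smoothing
shrinks it to a low-contrast fibroglandular texture) plus white noise
(sd 0.02). Lesions are hyperintense, matching mammographic appearance.

Calcifications: benign clusters draw ~4 round dots of 2.2–3.2 px scattered
over a 22 px radius; malignant clusters ~13 smaller (0.8–2.4 px),
elongated, size-variable dots within 8 px. Masses: a blob of radius
~0.21·side; benign margins are blurred by 0.7 px with a smooth elliptical
boundary; malignant masses add low-order radial boundary harmonics
(relative amplitude 0.22), 8 spicules of ~11 px, and 2.8 px margin blur.
These effect sizes were chosen so that simple reference statistics (dot
count, boundary roughness `perimeter²/4π·area`, largest-blob area)
separate the arms cleanly at the defaults — strong, clean signal on
purpose: the test bed must make expert specialisation *possible* so that
failures indicate pipeline defects, not an undetectable signal.

Randomness is counter-based: each patch has its own generator seeded by
(master seed, cell index, patch index), so datasets are pure functions of
the configuration and enlarging one cell never reshuffles other patches.
Synthetic patients hold two consecutive patches of one generation cell.

What the generator does **not** emulate: breast-density variation,
full-field anatomy, scanner physics, overlapping tissue structures,
inter-reader label noise, or the class imbalance and hard borderline cases
of clinical archives. Passing tests therefore demonstrate that the
pipeline is correct and that gating exploits finding-specific signal when
it exists — not that any particular AUC transfers to clinical data.

## Backbones and optimisation

The desk-scale backbone is a from-scratch NumPy CNN: four 3×3 conv + ReLU
+ 2×2 max-pool blocks (8/16/32/32 channels), global average pooling and a
linear head, He initialisation, trained with Adam on cross-entropy.
Gradients are hand-derived (im2col convolutions) and verified against
finite differences in the test suite. Inputs are standardised with fixed
constants ((x−0.5)/0.25). A ResNet18 configuration with optional ImageNet
initialisation, grayscale replicated to three channels and resized to
224 px with ImageNet channel statistics, sits behind the optional `torch`
extra and shares the training-loop interface.

Full-scale defaults follow the reference protocol: batch 64, 30 epochs,
Adam with learning rate 1e-5 and zero weight decay. `fast_mode` swaps in
desk-scale overrides — 32 px inputs, 20 epochs (the training loss
plateaus there on default synthetic data), learning rate 1e-3. The higher
rate is not cosmetic: with a tiny network and tens of gradient steps,
1e-5 cannot move the loss measurably, so the full-scale rate would make
every desk-scale model an initialisation-quality predictor. No
augmentation, early stopping or LR schedule by default.

Training is deterministic given (config, seed) under fixed BLAS
threading: initialisation, data order and hence the whole loss curve
repeat exactly.

## Problem sizes

Desk-scale experiments use 600 patches (240 cancer / 120 benign / 240
normal, findings split evenly) — enough for ≥5 benign patients per fold
after patient grouping and for stable AUC ordering across seeds, while a
full repeated-CV run stays in the minutes range on one core. Bookkeeping
and leakage audits run at 50 patches; DeLong calibration uses 2,000
simulated null datasets of n = 200 and a 10,000-draw bootstrap.

## Known limitations

* The gate is trained only on lesion patches but applied to every patch at
  inference; on normal patches its weights are extrapolation (harmless for
  the 3-class output, since both experts saw normals).
* The NumPy backbone targets clarity and determinism over speed; it is not
  a path to full-resolution (512 px) training, which is what the ResNet18
  extra is for.
* The DeLong CI is a normal approximation and degenerates (zero width) at
  AUC = 1, which perfectly separated synthetic runs do reach.
* Patient structure in the synthetic data is simplistic (two patches per
  patient, one class per patient), so the grouped-CV machinery is
  exercised but not stress-tested against realistic patient topologies.
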