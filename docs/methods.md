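# Methods

## The model

`unlearn` trains a task network on pooled multi-scanner imaging data while
*removing* scanner (and, optionally, confound) information from an internal
feature representation. The network has three parts with disjoint parameter
sets:

- a **feature extractor** (Θ_repr) ending in a fully connected layer whose
  activations Q_repr are the representation to be harmonised;
- a **label predictor** (Θ_p) mapping Q_repr to the main-task output — a
  scalar age, softmax logits over 1-year age bins, or (for the U-Net) a
  per-pixel tissue distribution;
- a **domain classifier** (Θ_d) mapping Q_repr to an N-way softmax over
  scanners, plus one analogous classifier head (Θ_c_j) per confound.

Training alternates three sub-steps per batch, each with its own optimiser
and a fresh forward pass, always in this order:

1. **Task step** — minimise the main-task loss over Θ_repr ∪ Θ_p on the
   labelled subset. In unlearning mode the loss is evaluated per scanner and
   the per-scanner means are summed, so no single large cohort dominates; in
   the plain-training baseline the usual pooled mean is used.
2. **Domain step** — minimise the softmax cross-entropy of the domain
   classifier over Θ_d only, on the unlearning subset: fit the best scanner
   classifier for the *current, fixed* features.
3. **Confusion step** — minimise, over Θ_repr only, the confusion loss
   `-(1/S) Σ_s (1/N) Σ_k log p_sk`, whose minimum ln N is attained exactly
   when the (fixed) domain classifier outputs are uniform for every sample.

Confound heads add a classification/confusion pair per confound after the
scanner sub-steps. The domain step always precedes the confusion step: the
confusion gradient is only informative through a classifier that has found
the scanner information. Before unlearning starts, the network is pretrained
with steps 1+2 until the task converges (early stopping on validation task
loss), so the domain classifier is accurate when unlearning begins.

Continuous variables are removed by binning: ages become Gaussian soft
labels N(μ, σ²) evaluated at 1-year bin centres and renormalised (σ = 10
years by default), the task loss becomes KL(true ‖ predicted), and the same
classification/confusion pair applies.

Success is measured by a **probe**: a freshly initialised two-layer
classifier trained to convergence on the frozen, column-standardised
features. Accuracy at chance (100/N %) means the information is gone. For
end-to-end experiments the probe head is fitted on training-set features
and its accuracy is reported on a held-out phantom set: residual
"information" that does not generalise beyond the samples the extractor was
trained on is memorisation, not scanner signal. A single probe fit carries
a few percentage points of optimisation noise, so the bundled experiments
report the mean over three independent probe-head initialisations.

## Desk-scale stabilisations of the adversarial game

The iterative scheme is a minimax game, and at small scale the naive
one-optimiser-fits-all rendering diverges or stalls. The package makes five
deliberate choices, all configurable:

- **Per-stage learning rates.** The adversary must track the features, so
  the domain head trains faster (`lr_domain`, default 3e-3 in the bundled
  experiments) than the extractor moves during unlearning
  (`lr_confusion`), and the task step slows down after pretraining
  (`lr_task_unlearn`).
- **SGD for the confusion step** (`confusion_optimizer="sgd"`). Adaptive
  optimisers take magnitude-normalised steps, so near equilibrium they keep
  kicking the features in noise directions at full step size; plain SGD
  steps shrink with the gradient and anneal the game.
- **Head refitting** (`refit_domain_each_epoch`). At every unlearning epoch
  the classifier heads are re-converged on cached frozen features (cheap:
  no convolutional passes). The confusion step then acts through a
  near-optimal adversary, which is what makes it remove information rather
  than merely dodge a stale classifier.
- **Feature standardisation for the heads.** Classifier heads consume
  z-scored features (statistics refreshed at each refit). Without this,
  scanner information hiding in low-amplitude feature directions produces
  vanishing confusion gradients while a standardising probe still reads it.
- **Validation-probe checkpoint selection** (`select_best_unlearning`).
  The adversarial trajectory does not converge monotonically; the epoch
  whose probe-grade *validation* scanner accuracy (plus confound
  accuracies, when confounds are configured) is lowest — among epochs whose
  validation task loss stays within `unlearn_task_tolerance` of the
  pretraining baseline — is kept. The three best epochs are re-measured
  with an independent probe seed before the final choice, so the selection
  is not the minimum of one noisy trajectory. An adaptive governor
  (`adaptive_confusion`) additionally damps the confusion step when the
  task loss inflates and restores the best checkpoint after a feature
  collapse.

These are renderings of the scheme's stated intent (an accurate domain
classifier before every confusion update; stability of the iterative game)
rather than changes to the objective; each can be disabled.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha`, `beta` | 1, 10 | weights of the domain and confusion losses |
| `gamma_j`, `phi_j` | 1, 10 | per-confound classification/confusion weights |
| `sigma` | 10 years | soft-age-label spread |
| `feature_dim` | 64 (16 in bundled experiments) | length of Q_repr |
| `batch_size` | 32 | every batch contains ≥ 1 sample per scanner |
| `lr` | 1e-4 (1e-3 in bundled experiments) | task-stage learning rate |
| `pretrain_patience` | 10 epochs | early-stopping patience on validation task loss |
| `attach` | "A" | U-Net unlearning point: final convolution (A), bottleneck (B), or both (A+B) |

With adaptive optimisers the loss weights α, β mostly matter through the
relative per-stage learning rates; with the SGD confusion step β scales the
step directly.

## Volume preprocessing

Real volumes are cubic-spline resampled to 1 mm isotropic, centre-cropped or
zero-padded to a 128 mm field of view (preserving physical scale; the choice
of a fixed FOV resolves the ambiguity of fitting arbitrary head sizes on a
128³ grid), reduced to every fourth axial slice (32 slices) and standardised
to zero mean, unit SD over the full grid (no brain mask). One-hot label maps
are resampled trilinearly per class, thresholded at 0.5, and ties at exactly
0.5 go to the lowest class index (realised by a first-maximum argmax, since
linear interpolation preserves the channel sum of one).

## The phantom generator

`unlearn.synthetic` renders 2-D head-like phantoms with three tissue
compartments: an outer CSF ring, a grey-matter annulus, a white-matter disc
and a central CSF cavity. The biological signal is geometric and nonlinear
in age — the cavity widens quickly through mid-adulthood and then
decelerates, while annulus thinning accelerates in older age — so no single
geometric dial extrapolates across the whole range, and sex applies a small
elliptical deformation. Scanner effects are layered multiplicatively:
gamma-like contrast change, a smooth low-order cosine bias field, global
intensity scaling, then additive Gaussian noise. Default magnitudes are kept
in the regime multi-site T1 studies show after standardisation (noise
levels within a factor ~2, gamma 0.9–1.25, bias 5–15%): clearly detectable
by a classifier yet removable without destroying the age signal — the
operating regime the method assumes. Study designs control per-site counts,
age ranges (including fixed-overlap designs), sex–site or sex–age
correlation (e.g. 80/20) and per-site label availability; all randomness
descends from one seed through spawned per-site generators.

What the generator does *not* emulate: 3-D anatomy, MR physics (k-space,
relaxometry), registration/extraction artefacts, pathology, or
scanner-by-anatomy interactions. Passing the bundled experiments therefore
shows that the training machinery removes detectable acquisition signatures
while preserving a geometric covariate at desk scale — not that any
particular clinical dataset would harmonise equally well.

## Numerical choices

Natural logarithms throughout; probabilities inside logs floored at 1e-8;
soft Dice with ε = 1e-5 and the background class excluded from the tissue
average; KL direction KL(true ‖ predicted); age point estimates by
expectation over bin centres (argmax available); cubic splines for volume
resampling, trilinear for label maps; He initialisation seeded per model;
batch composition allots per-scanner quotas by largest remainder (minimum
one) and cycles reshuffled per-scanner orders, so epoch length follows the
largest site and every one of its samples appears each epoch.

## Known limitations

- The adversarial equilibrium is stochastic: a minority of training seeds
  stall with substantial residual scanner information, which is why
  checkpoint selection operates on a probe-grade validation measurement.
- In the biased-overlap design, restricting unlearning to the overlapping
  age window reliably improves on naive unlearning, but plain training is
  not reliably *worse* than unlearning here: converged networks on these
  phantoms generalise across the age range rather than leaning on the
  scanner shortcut, so the catastrophic standard-training failure seen on
  real cohorts is only partially reproduced at this scale.
- Unlearning costs roughly a two-to-three-fold increase in training time
  per epoch (three forward/backward passes plus head refits).
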