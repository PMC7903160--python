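# unlearn — adversarial removal of scanner and confound information

Pooling MRI data across scanners and sites inflates non-biological variance:
a classifier can usually tell which scanner acquired an image, and that
signal leaks into downstream predictions. `unlearn` harmonises multi-site
data *inside* a task network. While the network learns its main task (brain
age regression or tissue segmentation), an iterative adversarial scheme
alternates between

1. fitting the task (per-scanner balanced loss, so the largest cohort does
   not dominate),
2. fitting a **domain classifier** on the feature representation Q_repr
   (how much scanner information remains), and
3. minimising a **confusion loss** `-(1/S) Σ_s (1/N) Σ_k log p_sk` over the
   feature extractor only, which is minimal (ln N) exactly when the domain
   classifier's softmax outputs are uniform — i.e. when Q_repr carries no
   scanner information.

The same classifier/confusion pairing removes additional confounds (e.g.
sex), and continuous variables are handled with Gaussian soft labels over
1-year age bins and a KL task loss. Success is measured by a post-hoc
**probe**: a fresh classifier trained on the frozen features — accuracy at
chance (100/N %) means the information is gone.

The package is aimed at methods researchers who want a fully testable,
desk-scale implementation: it ships a synthetic multi-scanner phantom
generator (age-dependent geometry, per-scanner contrast/bias/noise
signatures, configurable age-overlap and confound correlations), training
for 2-D conv-regression and U-Net segmentation backbones on a compact numpy
autodiff, NIfTI/CSV I/O for real volumes, and the probe metrics.

## Worked example

```python
from unlearn import StudyDesign, TrainConfig, UnlearningModel, generate_dataset

design = StudyDesign(n_sites=3, per_site_n=[100, 100, 100], size=32, seed=7)
dataset = generate_dataset(design)

config = TrainConfig(task="regression", mode="unlearn", feature_dim=32,
                     width_scale=0.5, head_hidden=64, lr=1e-3, lr_domain=3e-3,
                     lr_confusion=1e-4, lr_task_unlearn=3e-4,
                     pretrain_max_epochs=25, pretrain_patience=6,
                     unlearn_epochs=30, seed=0)
results = UnlearningModel(dataset, config).fit()
print(results.summary())
probe = results.probe(seed=0)
print(f"scanner probe: {probe.accuracy:.1f}% (chance {probe.chance:.1f}%)")
per_site, pooled = results.mae()
print(f"validation MAE: {pooled:.2f} years")
```

prints

```
            Scanner-unlearning results
==================================================
task:              regression
mode:              unlearn
sites (N):         3   chance = 33.33%
training samples:  240
epochs run:        55
loss weights:      alpha=1.0  beta=10.0
val task loss:     36.4242
val scanner acc:   53.3% at best epoch   (chance 33.3%)
==================================================
scanner probe: 60.4% (chance 33.3%)
validation MAE: 2.83 years
```

The probe accuracy is the harmonisation metric: before unlearning a probe
on these features is nearly perfect; after this short demonstration run it
has dropped to 60% and the age error is unchanged. At the full bundled
experiment size (300 phantoms per site, 60 unlearning epochs,
`unlearn.experiments.harmonisation_experiment`) the held-out probe falls
from 99.3% (normal training) to 41.3% against a 33.3% chance level while
MAE grows only from 2.32 to 2.58 years — mirroring the behaviour reported
for real multi-site cohorts, where scanner classification drops from
near-perfect to chance after unlearning.

The same objects drive segmentation (`task="segmentation"`, U-Net backbone
with attach points A/B/A+B), semi-supervised training (samples without task
labels still feed the unlearning losses), subset policies
(`UnlearningPolicy(mode="overlap")` for age-biased sites,
`mode="balanced_subset"` for confound-correlated cohorts) and confound
heads (`TrainConfig(confounds=[{"name": "sex", "n_classes": 2}])`).

A thin CLI mirrors the library for shell use:

```bash
unlearn simulate --out data/ --n-sites 3 --n-per-site 100 --seed 1
unlearn train    --data data/ --out run/ --mode unlearn --seed 0
unlearn probe    --data data/ --model run/model.npz
unlearn evaluate --data data/ --model run/model.npz
```

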