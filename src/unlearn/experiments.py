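"""Pre-registered desk-scale experiments.

Each function runs one complete study — synthetic data generation, training
in one or more regimes, and evaluation — under fixed, documented conditions,
and returns the headline numbers as a dict.  The experiments mirror, at
desk scale, the study designs of multi-site harmonisation work: fully
supervised age prediction across three scanners, age-biased two-site
designs, scanner-correlated sex confounds, and semi-supervised tissue
segmentation with one unlabelled site.

Problem sizes (300 phantoms per site for the main experiment, 32x32 pixels,
tens of epochs) are chosen so each experiment runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import evaluation as ev
from .io import TrainConfig
from .model import UnlearningModel
from .synthetic import (ScannerEffect, StudyDesign, default_effects,
                        generate_dataset)
from .training import UnlearningPolicy, select_unlearning_subset

__all__ = [
    "harmonisation_experiment",
    "biased_overlap_experiment",
    "confound_removal_experiment",
    "semisupervised_segmentation_experiment",
]

# shared training hyperparameters for the age-regression experiments
_REG = dict(task="regression", feature_dim=32, width_scale=0.5, head_hidden=64,
            batch_size=32, lr=1e-3, lr_domain=3e-3, lr_confusion=1e-4,
            lr_task_unlearn=3e-4, confusion_optimizer="sgd",
            unlearn_task_tolerance=1.5, pretrain_max_epochs=30,
            pretrain_patience=8)


def _mean_probe(res, test, probe_seed: int, target: str = "scanner",
                n_repeats: int = 3) -> float:
    """Probe accuracy averaged over probe-head initialisations.

    A single probe fit carries a few points of optimisation noise; the mean
    over independent head seeds is the reported measurement."""
    accs = [res.probe(seed=probe_seed + i, target=target,
                      eval_dataset=test).accuracy for i in range(n_repeats)]
    return float(np.mean(accs))


def harmonisation_experiment(seed: int = 0, n_per_site: int = 300,
                             unlearn_epochs: int = 60,
                             probe_seed: int | None = None) -> dict:
    """Fully supervised three-scanner age prediction, normal vs unlearning.

    Trains on 3 sites x ``n_per_site`` phantoms (32x32) with distinct
    scanner effects, evaluates per-scanner MAE and the post-hoc scanner
    probe (head fitted on training features, accuracy on a held-out
    phantom set) for both training modes.
    """
    if probe_seed is None:
        probe_seed = seed
    train = generate_dataset(StudyDesign(n_sites=3, per_site_n=[n_per_site] * 3,
                                         size=32, seed=11))
    test = generate_dataset(StudyDesign(n_sites=3, per_site_n=[100] * 3,
                                        size=32, seed=12))
    out = {"chance": ev.chance_level(3)}
    for mode, epochs in [("normal", 0), ("unlearn", unlearn_epochs)]:
        cfg = TrainConfig(**_REG, mode=mode, unlearn_epochs=epochs, seed=seed)
        res = UnlearningModel(train, cfg).fit()
        _, mae = res.mae(test)
        out[f"probe_{mode}"] = _mean_probe(res, test, probe_seed)
        out[f"mae_{mode}"] = mae
    out["mae_ratio"] = out["mae_unlearn"] / out["mae_normal"]
    return out


# strong contrast difference between the two scanners: the regime where an
# unharmonised intensity readout does not transfer between sites
_BIASED_EFFECTS = [
    ScannerEffect(1.00, 0.05, (0.9, -0.3, 0.5, 0.1), 0.05, 0.75),
    ScannerEffect(1.15, 0.12, (-0.7, 0.8, -0.2, 0.6), 0.08, 1.60),
]


def biased_overlap_experiment(seeds=(0, 1, 2), overlap=(45.0, 55.0)) -> dict:
    """Two sites with a 10-year age overlap (large young site, small old site).

    Compares held-out full-range MAE of normal training, naive unlearning
    (all samples) and overlap-restricted unlearning, across training seeds.
    """
    test = generate_dataset(StudyDesign(
        n_sites=2, per_site_n=[100, 100], size=32, effects=_BIASED_EFFECTS,
        age_ranges=[(20.0, 80.0)] * 2, seed=22))

    def one(mode, policy, seed):
        ds = generate_dataset(StudyDesign(
            n_sites=2, per_site_n=[280, 40], size=32, effects=_BIASED_EFFECTS,
            age_ranges=[(20.0, 55.0), (45.0, 80.0)], seed=21))
        if policy is not None:
            select_unlearning_subset(ds, policy)
        cfg = TrainConfig(**{**_REG, "batch_size": 16,
                             "pretrain_max_epochs": 25, "pretrain_patience": 6,
                             "select_best_unlearning": False},
                          mode=mode,
                          unlearn_epochs=0 if mode == "normal" else 30,
                          seed=seed)
        res = UnlearningModel(ds, cfg).fit()
        _, mae = res.mae(test)
        return mae

    rows = []
    for seed in seeds:
        rows.append({
            "seed": seed,
            "mae_normal": one("normal", None, seed),
            "mae_naive": one("unlearn", UnlearningPolicy(mode="all"), seed),
            "mae_overlap": one("unlearn", UnlearningPolicy(mode="overlap"), seed),
        })
    overlap_wins = sum(r["mae_overlap"] <= r["mae_naive"] for r in rows)
    naive_wins = sum(r["mae_naive"] <= r["mae_normal"] for r in rows)
    return {"per_seed": rows,
            "overlap_le_naive_majority": overlap_wins > len(rows) / 2,
            "naive_le_normal_majority": naive_wins > len(rows) / 2}


def confound_removal_experiment(seed: int = 0, correlation: float = 0.8,
                                unlearn_epochs: int = 60,
                                probe_seed: int | None = None) -> dict:
    """Sex correlated with scanner at 80/20; scanner+sex unlearning on a
    sex-balanced subset vs normal training.

    Reports held-out scanner and sex probe accuracies and task MAE for both
    modes.
    """
    if probe_seed is None:
        probe_seed = seed
    effects = default_effects(2)

    def make_train():
        return generate_dataset(StudyDesign(
            n_sites=2, per_site_n=[250, 250], size=32, effects=effects,
            sex_site_correlation=correlation, seed=31))

    test = generate_dataset(StudyDesign(n_sites=2, per_site_n=[80, 80], size=32,
                                        effects=effects, seed=32))
    out = {"chance_scanner": ev.chance_level(2), "chance_sex": 50.0}

    cfg_n = TrainConfig(**_REG, mode="normal", unlearn_epochs=0, seed=seed)
    res_n = UnlearningModel(make_train(), cfg_n).fit()
    out["scanner_probe_normal"] = _mean_probe(res_n, test, probe_seed)
    out["sex_probe_normal"] = _mean_probe(res_n, test, probe_seed, target="sex")
    _, out["mae_normal"] = res_n.mae(test)

    train = make_train()
    select_unlearning_subset(train, UnlearningPolicy(
        mode="balanced_subset", confound="sex", seed=seed))
    cfg_u = TrainConfig(**_REG, mode="unlearn", unlearn_epochs=unlearn_epochs,
                        seed=seed,
                        confounds=[{"name": "sex", "n_classes": 2,
                                    "gamma": 1.0, "phi": 10.0}])
    res_u = UnlearningModel(train, cfg_u).fit()
    out["scanner_probe_unlearn"] = _mean_probe(res_u, test, probe_seed)
    out["sex_probe_unlearn"] = _mean_probe(res_u, test, probe_seed, target="sex")
    _, out["mae_unlearn"] = res_u.mae(test)
    out["mae_ratio"] = out["mae_unlearn"] / out["mae_normal"]
    return out


# wide appearance gap for the segmentation study: an intensity readout tuned
# on one scanner degrades visibly on the other
_SEG_EFFECTS = [
    ScannerEffect(1.00, 0.05, (0.9, -0.3, 0.5, 0.1), 0.05, 0.60),
    ScannerEffect(1.15, 0.20, (-0.7, 0.8, -0.2, 0.6), 0.08, 2.00),
]


def semisupervised_segmentation_experiment(seed: int = 2,
                                           unlearn_epochs: int = 50) -> dict:
    """Tissue segmentation with zero labels at site B.

    Site B images still feed the unlearning losses (which need no task
    labels); compares held-out site-B Dice of normal training (site-A labels
    only) and unlearning.
    """
    def make_train():
        return generate_dataset(StudyDesign(
            n_sites=2, per_site_n=[50, 50], size=32, effects=_SEG_EFFECTS,
            task="segmentation", label_availability=[1.0, 0.0], seed=41))

    test = generate_dataset(StudyDesign(n_sites=2, per_site_n=[30, 30], size=32,
                                        effects=_SEG_EFFECTS,
                                        task="segmentation", seed=42))
    site_b = test.subset(np.flatnonzero(test.domain_index == 1))

    def mean_dice(res, ds):
        preds = res.predict_segmentation(ds)
        per = [np.mean(list(ev.per_tissue_dice(p, s.main_label,
                                               ignore=(0,)).values()))
               for p, s in zip(preds, ds)]
        return float(np.mean(per))

    cfg = dict(task="segmentation", feature_dim=16, width_scale=0.5,
               head_hidden=64, n_classes=4, attach="A", batch_size=8,
               lr=3e-3, lr_domain=3e-3, lr_confusion=5e-5, lr_task_unlearn=1e-3,
               confusion_optimizer="sgd", unlearn_task_tolerance=1.15,
               pretrain_max_epochs=40, pretrain_patience=10)
    res_n = UnlearningModel(make_train(), TrainConfig(**cfg, mode="normal",
                                                      unlearn_epochs=0,
                                                      seed=seed)).fit()
    res_u = UnlearningModel(make_train(), TrainConfig(**cfg, mode="unlearn",
                                                      unlearn_epochs=unlearn_epochs,
                                                      seed=seed)).fit()
    return {"dice_site_b_normal": mean_dice(res_n, site_b),
            "dice_site_b_unlearn": mean_dice(res_u, site_b)}
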