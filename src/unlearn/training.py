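"""Pretraining and the three-stage iterative unlearning procedure.

Each training batch runs up to three consecutive optimisation sub-steps, in a
fixed order, each with a fresh forward pass and its own optimiser scoped to
one parameter partition:

1. main-task loss (per-scanner balanced) -> updates theta_repr and theta_p,
   on the samples that have main-task labels (``in_p``);
2. domain-classification cross-entropy -> updates theta_d only, on the
   unlearning subset (``in_u``) — fits the best domain classifier for the
   current features;
3. confusion loss -> updates theta_repr only, again on ``in_u`` — pushes the
   (fixed) domain classifier's softmax outputs towards uniformity.

The domain classifier is always updated before the confusion step.  Optional
confound heads add an analogous classification/confusion pair per confound
after the scanner sub-steps.  Before unlearning starts, the network is
pretrained with stages 1+2 until the main task converges, so the domain
classifier is accurate when unlearning begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import losses as L
from .io import MultiSiteDataset, TrainConfig
from .models import (RegressionModel, UNetModel, attach_confound_classifiers,
                     build_regression_model, build_unet_model)
from .nn import Adam, SGD
from .autodiff import Tensor, log_softmax

__all__ = [
    "UnlearningPolicy",
    "TrainingState",
    "make_batches",
    "select_unlearning_subset",
    "pretrain",
    "unlearning_step",
    "fit",
    "predict_ages",
]


# ---------------------------------------------------------------------------
# Batch composition
# ---------------------------------------------------------------------------


def make_batches(dataset: MultiSiteDataset, batch_size: int, seed: int,
                 mask: np.ndarray | None = None) -> list[np.ndarray]:
    """Index batches with at least one sample from every (masked) domain.

    Per-batch domain quotas are proportional to domain size (minimum one), so
    smaller domains are oversampled by cycling a reshuffled order, and the
    epoch length is governed by the largest domain: every one of its samples
    appears at least once per epoch.  Deterministic given ``seed``.
    """
    didx = dataset.domain_index
    if mask is None:
        mask = np.ones(len(dataset), dtype=bool)
    pools = {d: np.flatnonzero(mask & (didx == d)) for d in np.unique(didx[mask])}
    domains = sorted(pools)
    if batch_size < len(domains):
        raise ValueError(f"batch_size {batch_size} < number of domains {len(domains)}")
    counts = {d: pools[d].size for d in domains}
    total = sum(counts.values())
    quotas = {d: max(1, int(batch_size * counts[d] / total)) for d in domains}
    while sum(quotas.values()) < batch_size:
        d = max(domains, key=lambda d: counts[d] / quotas[d])
        quotas[d] += 1
    while sum(quotas.values()) > batch_size:
        cands = [d for d in domains if quotas[d] > 1]
        d = min(cands, key=lambda d: counts[d] / quotas[d])
        quotas[d] -= 1

    d_big = max(domains, key=lambda d: counts[d])
    n_batches = math.ceil(counts[d_big] / quotas[d_big])
    rng = np.random.default_rng(seed)
    streams = {}
    for d in domains:
        order = pools[d].copy()
        rng.shuffle(order)
        streams[d] = [order, 0]

    def draw(d: int, k: int) -> np.ndarray:
        order, pos = streams[d]
        out = []
        while k:
            take = min(k, order.size - pos)
            out.append(order[pos : pos + take].copy())  # copy: shuffle below mutates order
            pos += take
            k -= take
            if pos == order.size:
                rng.shuffle(order)
                pos = 0
        streams[d][1] = pos
        return np.concatenate(out)

    batches = []
    for _ in range(n_batches):
        b = np.concatenate([draw(d, quotas[d]) for d in domains])
        rng.shuffle(b)
        batches.append(b)
    return batches


# ---------------------------------------------------------------------------
# Subset-selection policies
# ---------------------------------------------------------------------------


@dataclass
class UnlearningPolicy:
    """Which samples feed the unlearning (and per-confound) loss functions."""

    mode: str = "all"              # all | overlap | balanced_subset | custom_flags
    age_window: tuple | None = None
    confound: str | None = None
    seed: int = 0


def _sample_ages(dataset: MultiSiteDataset) -> np.ndarray:
    out = []
    for s in dataset:
        age = s.confound_labels.get("age")
        if age is None and isinstance(s.main_label, (int, float)):
            age = float(s.main_label)
        out.append(np.nan if age is None else float(age))
    return np.array(out)


def select_unlearning_subset(dataset: MultiSiteDataset,
                             policy: UnlearningPolicy) -> MultiSiteDataset:
    """Update ``in_u``/``in_c`` flags in place according to the policy.

    ``in_p`` flags are never touched: the main task always sees all labelled
    data; only the unlearning losses are restricted.
    """
    didx = dataset.domain_index
    if policy.mode == "all":
        for s in dataset:
            s.in_u = True
    elif policy.mode == "overlap":
        ages = _sample_ages(dataset)
        if policy.age_window is not None:
            lo, hi = policy.age_window
        else:
            lo = max(ages[didx == d].min() for d in range(dataset.n_domains))
            hi = min(ages[didx == d].max() for d in range(dataset.n_domains))
        if lo > hi:
            raise ValueError("age distributions do not overlap")
        flags = (ages >= lo) & (ages <= hi)
        for d in range(dataset.n_domains):
            if not np.any(flags & (didx == d)):
                raise ValueError(f"overlap window leaves domain {d + 1} empty")
        for s, f in zip(dataset, flags):
            s.in_u = bool(f)
    elif policy.mode == "balanced_subset":
        if policy.confound is None:
            raise ValueError("balanced_subset needs a confound name")
        vals = dataset.confound(policy.confound)
        cats = np.unique(vals[~np.isnan(vals.astype(float))])
        rng = np.random.default_rng(policy.seed)
        chosen = np.zeros(len(dataset), dtype=bool)
        for d in range(dataset.n_domains):
            in_dom = didx == d
            per_cat = {c: np.flatnonzero(in_dom & (vals == c)) for c in cats}
            m = min(idx.size for idx in per_cat.values())
            if m == 0:
                raise ValueError(
                    f"domain {d + 1} lacks a category of confound {policy.confound!r}")
            for idx in per_cat.values():
                pick = rng.choice(idx, size=m, replace=False)
                chosen[pick] = True
        for s, f in zip(dataset, chosen):
            s.in_c[policy.confound] = bool(f)
    elif policy.mode == "custom_flags":
        pass
    else:
        raise ValueError(f"unknown policy mode {policy.mode!r}")
    if not any(s.in_u for s in dataset):
        raise ValueError("unlearning subset is empty")
    return dataset


# ---------------------------------------------------------------------------
# Training state and sub-steps
# ---------------------------------------------------------------------------


def _zero_all(params) -> None:
    for p in params:
        p.grad = None


def _masked_dice(probs: Tensor, onehot: np.ndarray, mask: np.ndarray) -> Tensor:
    m = mask.astype(np.float64)[:, None, None, None]
    return L.multiclass_dice_loss(probs * m, onehot * m, class_axis=1,
                                  background_index=0)


class TrainingState:
    """Model, optimisers (one per parameter group), phase and loss history."""

    def __init__(self, dataset: MultiSiteDataset, config: TrainConfig,
                 val_dataset: MultiSiteDataset | None = None):
        self.config = config
        self.task = config.task
        if val_dataset is None and config.val_fraction > 0:
            dataset_train, val_dataset = dataset.split(config.val_fraction, config.seed)
        else:
            dataset_train = dataset
        self.train = dataset_train
        self.val = val_dataset
        self.phase = "pretrain"
        self.epoch = 0
        self.history: list[dict] = []

        shape = dataset_train.samples[0].image.shape
        n_dom = dataset_train.n_domains
        if config.task == "segmentation":
            self.model = build_unet_model(shape, config.n_classes, n_dom,
                                          attach=config.attach,
                                          feature_dim=config.feature_dim,
                                          width_scale=config.width_scale,
                                          head_hidden=config.head_hidden,
                                          seed=config.seed)
        else:
            n_out = 1
            if config.task == "soft_regression":
                lo, hi = config.bin_range
                self.bin_centers = np.arange(lo, hi + 1.0)
                n_out = self.bin_centers.size
            self.model = build_regression_model(shape, n_dom,
                                                feature_dim=config.feature_dim,
                                                width_scale=config.width_scale,
                                                n_outputs=n_out,
                                                head_hidden=config.head_hidden,
                                                seed=config.seed)
        if config.confounds:
            attach_confound_classifiers(
                self.model, {c.name: c.n_classes for c in config.confounds},
                head_hidden=config.head_hidden)
        self.weights = L.LossWeights(
            alpha=config.alpha, beta=config.beta,
            gamma={c.name: c.gamma for c in config.confounds},
            phi={c.name: c.phi for c in config.confounds})

        part = self.model.partition()
        self._all_params = part.all_parameters()
        lr_d = config.lr_domain if config.lr_domain is not None else config.lr
        lr_c = config.lr_confusion if config.lr_confusion is not None else config.lr
        conf_opt = SGD if config.confusion_optimizer == "sgd" else Adam
        self.opt_task = Adam(part.theta_repr + part.theta_p, lr=config.lr)
        self.opt_domain = Adam(part.theta_d, lr=lr_d)
        self.opt_confusion = conf_opt(part.theta_repr, lr=lr_c)
        self.opt_c = {n: Adam(ps, lr=lr_d) for n, ps in part.theta_c.items()}
        self.opt_cconf = {n: conf_opt(part.theta_repr, lr=lr_c)
                          for n in part.theta_c}

        # feature standardisation buffers for the classifier heads; refreshed
        # at each refit so low-amplitude scanner directions still produce
        # full-sized classification/confusion gradients
        self._feat_mu: np.ndarray | None = None
        self._feat_sd: np.ndarray | None = None

        self._prepare_targets()

    # -- cached training arrays ---------------------------------------------

    def _prepare_targets(self) -> None:
        ds = self.train
        self.X = ds.images
        self.didx = ds.domain_index
        if self.task == "segmentation":
            maps = np.stack([np.asarray(s.main_label if s.main_label is not None
                                        else np.zeros(s.image.shape, dtype=int))
                             for s in ds])
            k = self.config.n_classes
            self.Y_onehot = np.eye(k)[maps].transpose(0, 3, 1, 2)
        else:
            ages = np.array([np.nan if s.main_label is None else float(s.main_label)
                             for s in ds])
            self.ages = ages
            if self.task == "soft_regression":
                self.Y_soft = np.stack([
                    L.make_soft_label(a, self.config.bin_range, self.config.sigma).probs
                    if np.isfinite(a) else np.zeros(self.bin_centers.size)
                    for a in ages])
        self.conf_vals = {c.name: ds.confound(c.name).astype(float)
                          for c in self.config.confounds}

    # -- loss evaluation ----------------------------------------------------

    @property
    def _balance_task(self) -> bool:
        if self.config.balanced_task_loss is not None:
            return self.config.balanced_task_loss
        return self.config.mode == "unlearn"

    def _task_loss(self, idx: np.ndarray) -> Tensor:
        if self._balance_task:
            w = L.per_scanner_weights(self.didx[idx])
        else:
            w = np.full(idx.size, 1.0 / idx.size)
        if self.task == "segmentation":
            logits = self.model.seg_logits(self.X[idx])
            probs = log_softmax(logits, axis=1).exp()
            onehot = self.Y_onehot[idx]
            if not self._balance_task:
                return _masked_dice(probs, onehot, np.ones(idx.size, dtype=bool))
            total = None
            for d in np.unique(self.didx[idx]):
                term = _masked_dice(probs, onehot, self.didx[idx] == d)
                total = term if total is None else total + term
            return total
        feats = self.model.features(self.X[idx])
        out = self.model.predict_task(feats)
        if self.task == "soft_regression":
            t = self.Y_soft[idx]
            ls = log_softmax(out, axis=1)
            ce = (ls * t).sum(axis=1) * -1.0
            ent = np.where(t > 0, t * np.log(np.maximum(t, L.PROB_FLOOR)), 0.0).sum(axis=1)
            return (ce * w).sum() + float((ent * w).sum())
        pred = out.reshape(out.shape[0])
        err = (pred - self.ages[idx]) * (pred - self.ages[idx])
        return (err * w).sum()

    def _standardise(self, feats):
        if self._feat_mu is None:
            return feats
        return (feats - self._feat_mu) * (1.0 / self._feat_sd)

    def _domain_logits(self, idx: np.ndarray) -> Tensor:
        feats = self._standardise(self.model.features(self.X[idx]))
        return self.model.domain_logits(feats)

    # -- the three sub-steps ------------------------------------------------

    def stage_task(self, idx_p: np.ndarray) -> float | None:
        if idx_p.size == 0:
            return None
        _zero_all(self._all_params)
        loss = self._task_loss(idx_p)
        loss.backward()
        self.opt_task.step()
        return loss.item()

    def stage_domain(self, idx_u: np.ndarray, iters: int | None = None) -> float:
        """Fit the domain classifier on the current (fixed) features.

        ``iters`` optimiser iterations (fresh forward pass each) keep the
        classifier close to its optimum for the present feature
        representation, which is what makes the following confusion step
        informative."""
        if idx_u.size == 0:
            raise ValueError("empty unlearning subset in batch")
        iters = self.config.domain_steps if iters is None else iters
        loss_val = np.nan
        for _ in range(max(1, iters)):
            _zero_all(self._all_params)
            loss = L.domain_ce_from_logits(self._domain_logits(idx_u),
                                           self.didx[idx_u])
            (loss * self.weights.alpha).backward()
            self.opt_domain.step()
            loss_val = loss.item()
        return loss_val

    def stage_confusion(self, idx_u: np.ndarray) -> float:
        _zero_all(self._all_params)
        loss = L.confusion_from_logits(self._domain_logits(idx_u))
        (loss * self.weights.beta).backward()
        self.opt_confusion.step()
        return loss.item()

    def stage_confound(self, name: str, idx_c: np.ndarray) -> tuple[float, float]:
        labels = self.conf_vals[name][idx_c].astype(int)
        _zero_all(self._all_params)
        logits = self.model.confound_logits(
            name, self._standardise(self.model.features(self.X[idx_c])))
        lc = L.domain_ce_from_logits(logits, labels)
        (lc * self.weights.gamma[name]).backward()
        self.opt_c[name].step()
        _zero_all(self._all_params)
        logits = self.model.confound_logits(
            name, self._standardise(self.model.features(self.X[idx_c])))
        lcconf = L.confusion_from_logits(logits)
        (lcconf * self.weights.phi[name]).backward()
        self.opt_cconf[name].step()
        return lc.item(), lcconf.item()

    def refit_heads(self, seed: int) -> None:
        """Re-converge the classifier heads on cached frozen features.

        The confusion step removes information through the *current* domain
        classifier, so it is only as effective as that classifier is close to
        optimal for the present representation.  Training the head to
        convergence on cached features is cheap (no convolutional passes) and
        keeps the adversary sharp at desk scale."""
        rng = np.random.default_rng(seed)
        idx_u = np.flatnonzero(self.train.in_u)
        feats = self.model.features_np(self.X[idx_u])
        self._feat_mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        self._feat_sd = sd
        self._fit_head_on_features(self.model.domain_head,
                                   (feats - self._feat_mu) / self._feat_sd,
                                   self.didx[idx_u], rng,
                                   max_epochs=200, patience=10, lr=1e-3)
        for c in self.config.confounds:
            mask = self.train.in_c(c.name)
            idx_c = np.flatnonzero(mask if mask.any() else self.train.in_u)
            feats_c = (self.model.features_np(self.X[idx_c]) - self._feat_mu) / self._feat_sd
            self._fit_head_on_features(self.model.confound_heads[c.name], feats_c,
                                       self.conf_vals[c.name][idx_c].astype(int), rng)

    def _fit_head_on_features(self, head, feats: np.ndarray, labels: np.ndarray,
                              rng, max_epochs: int = 60, batch: int = 64,
                              patience: int = 6, lr: float | None = None) -> None:
        if lr is None:
            lr = self.config.lr_domain if self.config.lr_domain is not None else self.config.lr
        opt = Adam(head.parameters(), lr=lr)
        best, stale = np.inf, 0
        for _ in range(max_epochs):
            order = rng.permutation(feats.shape[0])
            losses = []
            for i in range(0, order.size, batch):
                b = order[i : i + batch]
                opt.zero_grad()
                loss = L.domain_ce_from_logits(head(Tensor(feats[b])), labels[b])
                loss.backward()
                opt.step()
                losses.append(loss.item())
            mean_loss = float(np.mean(losses))
            if mean_loss < best - 1e-4:
                best, stale = mean_loss, 0
            else:
                stale += 1
                if stale >= patience:
                    break

    # -- validation metrics --------------------------------------------------

    def residual_scanner_accuracy(self, seed: int) -> float:
        """Scanner accuracy (%) of a fresh probe-grade classifier.

        Trains a freshly initialised head on standardised frozen training
        features and evaluates on the validation split — the same measure the
        post-hoc probe reports, so unlearning checkpoints are selected by the
        quantity that defines harmonisation success."""
        from .nn import MLPHead

        rng = np.random.default_rng(seed)
        idx = np.flatnonzero(self.train.in_u)
        f_tr = self.model.features_np(self.X[idx])
        y_tr = self.didx[idx]
        ds = self.val if self.val is not None else self.train
        f_va = self.model.features_np(ds.images)
        y_va = ds.domain_index
        mu, sd = f_tr.mean(axis=0), f_tr.std(axis=0)
        sd[sd == 0] = 1.0
        head = MLPHead(f_tr.shape[1], self.config.head_hidden,
                       self.train.n_domains, rng)
        # probe-strength fit: long patience so the measurement is as strong an
        # adversary as the post-hoc probe itself
        self._fit_head_on_features(head, (f_tr - mu) / sd, y_tr, rng,
                                   max_epochs=200, patience=10, lr=1e-3)
        logits = head(Tensor((f_va - mu) / sd)).data
        return 100.0 * float((logits.argmax(axis=1) == y_va).mean())

    def residual_excess(self, seed: int) -> tuple[float, dict]:
        """Total above-chance residual accuracy of scanner plus confound probes.

        The unlearning checkpoint-selection metric: each configured confound
        contributes a probe-grade residual measurement the same way the
        scanner does."""
        from .nn import MLPHead

        accs = {"scanner": self.residual_scanner_accuracy(seed)}
        excess = accs["scanner"] - 100.0 / self.train.n_domains
        ds = self.val if self.val is not None else self.train
        rng = np.random.default_rng(seed + 999)
        for c in self.config.confounds:
            idx = np.flatnonzero(self.train.in_u)
            f_tr = self.model.features_np(self.X[idx])
            y_tr = self.conf_vals[c.name][idx].astype(int)
            f_va = self.model.features_np(ds.images)
            y_va = ds.confound(c.name).astype(int)
            mu, sd = f_tr.mean(axis=0), f_tr.std(axis=0)
            sd[sd == 0] = 1.0
            head = MLPHead(f_tr.shape[1], self.config.head_hidden, c.n_classes, rng)
            self._fit_head_on_features(head, (f_tr - mu) / sd, y_tr, rng,
                                       max_epochs=200, patience=10, lr=1e-3)
            logits = head(Tensor((f_va - mu) / sd)).data
            accs[c.name] = 100.0 * float((logits.argmax(axis=1) == y_va).mean())
            excess += accs[c.name] - 100.0 / c.n_classes
        return excess, accs

    def scanner_validation_accuracy(self) -> float:
        """Held-out accuracy (%) of the current domain classifier.

        Meaningful right after :meth:`refit_heads`; used to monitor how much
        scanner information remains as unlearning progresses."""
        ds = self.val if self.val is not None else self.train
        feats = self.model.features_np(ds.images)
        if self._feat_mu is not None:
            feats = (feats - self._feat_mu) / self._feat_sd
        logits = self.model.domain_head(Tensor(feats)).data
        return 100.0 * float((logits.argmax(axis=1) == ds.domain_index).mean())

    def validation_task_loss(self) -> float:
        ds = self.val if self.val is not None else self.train
        return evaluate_task_loss(self, ds)

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self._all_params]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self._all_params, snap):
            p.data = d.copy()


def evaluate_task_loss(state: TrainingState, dataset: MultiSiteDataset,
                       chunk: int = 64) -> float:
    """Per-scanner task loss (Lp) of the current model on a dataset."""
    keep = np.flatnonzero(dataset.in_p)
    if keep.size == 0:
        return float("nan")
    didx = dataset.domain_index[keep]
    X = dataset.images[keep]
    model, task = state.model, state.task
    if task == "segmentation":
        maps = np.stack([dataset.samples[i].main_label for i in keep])
        onehot = np.eye(state.config.n_classes)[maps].transpose(0, 3, 1, 2)
        groups = ([didx == d for d in np.unique(didx)] if state._balance_task
                  else [np.ones(didx.size, dtype=bool)])
        total = 0.0
        for sel in groups:
            probs = model.seg_probs(X[sel], chunk=chunk)
            total += L.multiclass_dice_loss(probs, onehot[sel], class_axis=1,
                                            background_index=0)
        return float(total)
    preds = predict_ages(state, X)
    ages = np.array([float(dataset.samples[i].main_label) for i in keep])
    if state._balance_task:
        w = L.per_scanner_weights(didx)
    else:
        w = np.full(didx.size, 1.0 / didx.size)
    if task == "soft_regression":
        soft = np.stack([L.make_soft_label(a, state.config.bin_range,
                                           state.config.sigma).probs for a in ages])
        probs = _predict_bin_probs(state, X, chunk)
        kls = np.array([L.kl_task_loss(p, t) for p, t in zip(probs, soft)])
        return float((w * kls).sum())
    return float((w * (preds - ages) ** 2).sum())


def _predict_bin_probs(state: TrainingState, X: np.ndarray, chunk: int = 64) -> np.ndarray:
    out = []
    for i in range(0, X.shape[0], chunk):
        logits = state.model.predict_task(state.model.features(X[i : i + chunk]))
        out.append(np.exp(log_softmax(logits, axis=1).data))
    return np.concatenate(out)


def predict_ages(state: TrainingState, X: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Predicted age in years per sample (expectation for the soft-label task)."""
    if state.task == "soft_regression":
        probs = _predict_bin_probs(state, X, chunk)
        probs = probs / probs.sum(axis=1, keepdims=True)
        return np.array([L.age_point_estimate(p, state.bin_centers) for p in probs])
    out = []
    for i in range(0, X.shape[0], chunk):
        out.append(state.model.predict_task(
            state.model.features(X[i : i + chunk])).data[:, 0])
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Epoch drivers
# ---------------------------------------------------------------------------


def _epoch_batches(state: TrainingState, epoch_seed: int, unlearn: bool):
    """One index-batch stream per loss subset (p, u, each confound)."""
    cfg = state.config
    ds = state.train
    streams = {"p": make_batches(ds, cfg.batch_size, epoch_seed, mask=ds.in_p)}
    if unlearn:
        streams["u"] = make_batches(ds, cfg.batch_size, epoch_seed + 1, mask=ds.in_u)
        for j, c in enumerate(cfg.confounds):
            mask = ds.in_c(c.name)
            if not mask.any():
                mask = ds.in_u
            streams[c.name] = make_batches(ds, cfg.batch_size,
                                           epoch_seed + 2 + j, mask=mask)
    return streams


def unlearning_step(state: TrainingState, batch_p: np.ndarray,
                    batch_u: np.ndarray, batches_c: dict | None = None) -> dict:
    """One full iterative step: task, domain-classifier, confusion sub-steps
    (in that fixed order), then confound pairs in declared order."""
    out = {"lp": state.stage_task(batch_p)}
    out["ld"] = state.stage_domain(batch_u)
    out["lconf"] = state.stage_confusion(batch_u)
    for name, idx in (batches_c or {}).items():
        lc, lcc = state.stage_confound(name, idx)
        out[f"lc_{name}"], out[f"lcconf_{name}"] = lc, lcc
    return out


def pretrain(state: TrainingState) -> TrainingState:
    """Alternate task and domain-classifier updates until the main task
    converges (early stopping on the validation task loss)."""
    cfg = state.config
    best, best_snap, stale = np.inf, state.snapshot(), 0
    for epoch in range(cfg.pretrain_max_epochs):
        streams = _epoch_batches(state, cfg.seed * 100003 + epoch, unlearn=True)
        n_steps = max(len(v) for v in streams.values())
        lps, lds = [], []
        for i in range(n_steps):
            bp = streams["p"][i % len(streams["p"])]
            bu = streams["u"][i % len(streams["u"])]
            lp = state.stage_task(bp)
            lds.append(state.stage_domain(bu))
            if lp is not None:
                lps.append(lp)
        val_lp = state.validation_task_loss()
        if not np.isfinite(val_lp):
            raise FloatingPointError("non-finite validation loss during pretraining")
        state.epoch += 1
        state.history.append({"phase": "pretrain", "epoch": state.epoch,
                              "lp": float(np.mean(lps)), "ld": float(np.mean(lds)),
                              "lconf": np.nan, "val_lp": val_lp})
        if val_lp < best - 1e-9:
            best, best_snap, stale = val_lp, state.snapshot(), 0
        else:
            stale += 1
            if stale >= cfg.pretrain_patience:
                break
    state.restore(best_snap)
    state.phase = "unlearn"
    return state


def _normal_train(state: TrainingState) -> TrainingState:
    """Plain training: task loss only, same early-stopping rule."""
    cfg = state.config
    best, best_snap, stale = np.inf, state.snapshot(), 0
    for epoch in range(cfg.pretrain_max_epochs + cfg.unlearn_epochs):
        streams = _epoch_batches(state, cfg.seed * 100003 + epoch, unlearn=False)
        lps = [state.stage_task(b) for b in streams["p"]]
        val_lp = state.validation_task_loss()
        if not np.isfinite(val_lp):
            raise FloatingPointError("non-finite validation loss")
        state.epoch += 1
        state.history.append({"phase": "normal", "epoch": state.epoch,
                              "lp": float(np.mean([l for l in lps if l is not None])),
                              "val_lp": val_lp})
        if val_lp < best - 1e-9:
            best, best_snap, stale = val_lp, state.snapshot(), 0
        else:
            stale += 1
            if stale >= cfg.pretrain_patience:
                break
    state.restore(best_snap)
    return state


def fit(dataset: MultiSiteDataset, config: TrainConfig,
        val_dataset: MultiSiteDataset | None = None) -> TrainingState:
    """Train a model on a multi-site dataset.

    ``config.mode == "normal"`` trains the feature extractor and label
    predictor only; ``"unlearn"`` pretrains (stages 1+2) and then runs the
    three-stage iterative unlearning for ``config.unlearn_epochs`` epochs.
    Samples without main-task labels contribute only to the unlearning
    stages (semi-supervised operation).
    """
    state = TrainingState(dataset, config, val_dataset)
    if config.mode == "normal":
        return _normal_train(state)
    if config.mode != "unlearn":
        raise ValueError(f"unknown mode {config.mode!r}")
    pretrain(state)
    cfg = config
    if cfg.lr_task_unlearn is not None:
        # the main task is converged after pretraining; a slower task stage
        # keeps the representation quasi-stationary for the adversarial pair
        part = state.model.partition()
        state.opt_task = Adam(part.theta_repr + part.theta_p, lr=cfg.lr_task_unlearn)
    base_val_lp = state.validation_task_loss()
    candidates: list[tuple[float, list]] = []   # (val scanner acc, snapshot)
    best_snap = None
    lr_c0 = state.opt_confusion.lr
    best_acc_seen, stalled = np.inf, 0
    for epoch in range(cfg.unlearn_epochs):
        if cfg.refit_domain_each_epoch and epoch == 0:
            state.refit_heads((cfg.seed + 1) * 70001)
        streams = _epoch_batches(state, cfg.seed * 900007 + epoch, unlearn=True)
        n_steps = max(len(v) for v in streams.values())
        logs: dict[str, list] = {}
        for i in range(n_steps):
            bp = streams["p"][i % len(streams["p"])]
            bu = streams["u"][i % len(streams["u"])]
            bc = {c.name: streams[c.name][i % len(streams[c.name])]
                  for c in cfg.confounds}
            rec = unlearning_step(state, bp, bu, bc)
            for k, v in rec.items():
                if v is not None:
                    logs.setdefault(k, []).append(v)
        val_lp = state.validation_task_loss()
        if not np.isfinite(val_lp):
            raise FloatingPointError("non-finite validation loss during unlearning")
        if cfg.adaptive_confusion:
            # governor on the adversarial game: back off the confusion step
            # when the main task starts degrading, creep back up when safe,
            # and recover from a feature collapse by restoring the best state
            if val_lp > 4.0 * base_val_lp and candidates:
                state.restore(min(candidates, key=lambda t: t[0])[1])
                state.opt_confusion.lr *= 0.5
                val_lp = state.validation_task_loss()
            elif val_lp > cfg.unlearn_task_tolerance * base_val_lp:
                state.opt_confusion.lr *= 0.7
            elif val_lp < 1.1 * base_val_lp:
                state.opt_confusion.lr = min(state.opt_confusion.lr * 1.15, lr_c0)
            for opt in state.opt_cconf.values():
                opt.lr = state.opt_confusion.lr
        state.epoch += 1
        row = {"phase": "unlearn", "epoch": state.epoch, "val_lp": val_lp}
        row.update({k: float(np.mean(v)) for k, v in logs.items()})
        row["total"] = L.total_unlearning_loss(
            row.get("lp", np.nan), row.get("ld", np.nan), row.get("lconf", np.nan),
            {c.name: (row.get(f"lc_{c.name}", 0.0), row.get(f"lcconf_{c.name}", 0.0))
             for c in cfg.confounds},
            state.weights)
        if cfg.refit_domain_each_epoch:
            # re-converge the adversary on the epoch's final features: both the
            # next epoch's starting point and an honest residual-information
            # measurement for checkpoint selection
            state.refit_heads((cfg.seed + 1) * 70001 + epoch + 1)
            if cfg.confounds:
                acc, accs = state.residual_excess((cfg.seed + 1) * 31013 + epoch)
                row["val_domain_acc"] = accs["scanner"]
                for name, a in accs.items():
                    if name != "scanner":
                        row[f"val_{name}_acc"] = a
            else:
                acc = state.residual_scanner_accuracy((cfg.seed + 1) * 31013 + epoch)
                row["val_domain_acc"] = acc
            if acc < best_acc_seen - 1.0:
                best_acc_seen, stalled = acc, 0
            else:
                stalled += 1
                if cfg.adaptive_confusion and stalled >= 10:
                    # the game is stuck: escalate the confusion step
                    state.opt_confusion.lr *= 1.5
                    lr_c0 = max(lr_c0, state.opt_confusion.lr)
                    stalled = 0
            if (cfg.select_best_unlearning
                    and val_lp <= cfg.unlearn_task_tolerance * base_val_lp):
                candidates.append((acc, state.snapshot()))
                candidates.sort(key=lambda t: t[0])
                del candidates[3:]          # keep the three best epochs
        state.history.append(row)
    if candidates:
        # re-measure the shortlisted checkpoints with an independent probe
        # seed; picking the minimum of one noisy trajectory alone would be
        # optimistically biased
        remeasured = []
        for i, (acc, snap) in enumerate(candidates):
            state.restore(snap)
            if cfg.confounds:
                acc2, _ = state.residual_excess((cfg.seed + 1) * 47777 + i)
            else:
                acc2 = state.residual_scanner_accuracy((cfg.seed + 1) * 47777 + i)
            remeasured.append(((acc + acc2) / 2.0, snap))
        best_snap = min(remeasured, key=lambda t: t[0])[1]
        state.restore(best_snap)
    return state


def history_frame(state: TrainingState) -> pd.DataFrame:
    return pd.DataFrame(state.history)
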