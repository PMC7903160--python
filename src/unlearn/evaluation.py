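"""Harmonisation and task metrics.

The central harmonisation metric is the *probe*: a freshly initialised
classifier trained post hoc on the frozen feature representation.  Its
held-out accuracy measures how much scanner (or confound) information
remains — the closer to chance (100/N %), the better the harmonisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import losses as L
from .nn import Adam, MLPHead
from .autodiff import Tensor

__all__ = [
    "ProbeResult",
    "chance_level",
    "probe_scanner_information",
    "per_scanner_mae",
    "per_tissue_dice",
    "metrics_frame",
]


@dataclass
class ProbeResult:
    """Held-out accuracy of a probe classifier on frozen features."""

    accuracy: float            # percent correct on the held-out split
    chance: float              # percent, = 100 / n_classes
    confusion: np.ndarray      # rows: true class, cols: predicted
    n_eval: int

    @property
    def above_chance(self) -> float:
        return self.accuracy - self.chance


def chance_level(n_domains: int) -> float:
    """Random-chance accuracy in percent: 100/N."""
    if n_domains < 2:
        raise ValueError("need at least two domains")
    return 100.0 / n_domains


def probe_scanner_information(features: np.ndarray, labels, *, seed: int = 0,
                              split: float = 0.2, hidden: int = 32,
                              lr: float = 1e-3, batch_size: int = 64,
                              max_epochs: int = 200, patience: int = 10,
                              eval_features: np.ndarray | None = None,
                              eval_labels=None) -> ProbeResult:
    """Train a fresh classifier head on frozen features; report held-out accuracy.

    ``features`` must already be detached from any model (no gradients flow
    into the extractor).  The head matches the training-time domain
    classifier (two fully connected layers) and is trained to convergence
    (early stopping on its training loss).  Works for any integer label set,
    so the same probe measures residual confound information.

    With ``eval_features``/``eval_labels`` given, the head is trained on all
    of ``features`` and evaluated on the separate set (the protocol used for
    end-to-end experiments: probe fitted on training features, accuracy
    reported on held-out data).  Otherwise a stratified ``split`` fraction of
    ``features`` is held out.
    """
    X = np.asarray(features, dtype=np.float64)
    y_raw = np.asarray(labels)
    classes, y = np.unique(y_raw, return_inverse=True)
    n_cls = classes.size
    if n_cls < 2:
        raise ValueError("probe needs at least two classes")
    rng = np.random.default_rng(seed)

    # standardise feature columns (constant columns stay zero)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    if eval_features is not None:
        Xe = (np.asarray(eval_features, dtype=np.float64) - mu) / sd
        ye = np.searchsorted(classes, np.asarray(eval_labels))
        train_idx = np.arange(X.shape[0])
        test_idx = None
    else:
        # stratified split within the provided features
        held: list[int] = []
        for c in range(n_cls):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            k = max(1, int(round(split * idx.size)))
            if k >= idx.size:
                raise ValueError(f"class {classes[c]} absent from a split")
            held.extend(idx[:k])
        test_idx = np.array(sorted(held))
        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        Xe, ye = Xs[test_idx], y[test_idx]

    head = MLPHead(X.shape[1], hidden, n_cls, rng)
    opt = Adam(head.parameters(), lr=lr)
    best, stale = np.inf, 0
    for _ in range(max_epochs):
        order = train_idx.copy()
        rng.shuffle(order)
        losses = []
        for i in range(0, order.size, batch_size):
            b = order[i : i + batch_size]
            opt.zero_grad()
            logits = head(Tensor(Xs[b]))
            loss = L.domain_ce_from_logits(logits, y[b])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        mean_loss = float(np.mean(losses))
        if mean_loss < best - 1e-5:
            best, stale = mean_loss, 0
        else:
            stale += 1
            if stale >= patience:
                break

    logits = head(Tensor(Xe)).data
    pred = logits.argmax(axis=1)
    acc = 100.0 * float((pred == ye).mean())
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    for t, p in zip(ye, pred):
        confusion[t, p] += 1
    return ProbeResult(accuracy=acc, chance=chance_level(n_cls),
                       confusion=confusion, n_eval=int(ye.size))


def per_scanner_mae(predicted_ages, true_ages, domain_labels) -> tuple[dict, float]:
    """Mean absolute error in years, per domain and pooled over all samples."""
    pred = np.asarray(predicted_ages, dtype=np.float64)
    true = np.asarray(true_ages, dtype=np.float64)
    dom = np.asarray(domain_labels)
    err = np.abs(pred - true)
    per_domain = {}
    for d in np.unique(dom):
        mask = dom == d
        if not mask.any():
            raise ValueError(f"no samples for domain {d}")
        key = int(d) if np.issubdtype(np.asarray(d).dtype, np.integer) else d
        per_domain[key] = float(err[mask].mean())
    return per_domain, float(err.mean())


def per_tissue_dice(predicted_map: np.ndarray, label_map: np.ndarray,
                    ignore: tuple = ()) -> dict:
    """Hard Dice per class between two categorical maps on the same grid."""
    pred = np.asarray(predicted_map)
    lab = np.asarray(label_map)
    if pred.shape != lab.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {lab.shape}")
    out = {}
    for c in np.unique(np.concatenate([np.unique(pred), np.unique(lab)])):
        if c in ignore:
            continue
        p, t = pred == c, lab == c
        denom = p.sum() + t.sum()
        out[c if isinstance(c, str) else int(c)] = (
            1.0 if denom == 0 else 2.0 * float((p & t).sum()) / float(denom))
    return out


def metrics_frame(per_domain: dict, metric: str) -> pd.DataFrame:
    """Tidy one-row-per-domain metric table for downstream plotting."""
    return pd.DataFrame([{"domain": d, "metric": metric, "value": v}
                         for d, v in per_domain.items()])
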