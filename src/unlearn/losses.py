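"""Loss functions for iterative adversarial unlearning.

The scheme combines a per-scanner main-task loss, a domain-classification
cross-entropy that measures how much scanner information remains in the
feature representation, and a confusion loss whose minimum (ln N) is attained
exactly when the domain classifier's softmax outputs are uniform.  Additional
classification/confusion pairs remove confounds (e.g. sex); continuous
variables are handled by Gaussian soft labels over 1-year bins and a KL
divergence task loss.

All logarithms are natural.  Probabilities inside logs are floored at
``PROB_FLOOR`` so degenerate inputs give finite losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, log_softmax

PROB_FLOOR = 1e-8

__all__ = [
    "PROB_FLOOR",
    "LossWeights",
    "SoftAgeLabel",
    "per_scanner_weights",
    "per_scanner_task_loss",
    "domain_classification_loss",
    "confusion_loss",
    "domain_ce_from_logits",
    "confusion_from_logits",
    "total_unlearning_loss",
    "multiclass_dice_loss",
    "make_soft_label",
    "kl_task_loss",
    "kl_from_logits",
    "age_point_estimate",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the adversarial objective.

    ``alpha`` scales the domain-classification loss, ``beta`` the confusion
    loss; ``gamma[j]``/``phi[j]`` scale the j-th confound's classification and
    confusion losses.
    """

    alpha: float = 1.0
    beta: float = 10.0
    gamma: dict = field(default_factory=dict)
    phi: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = [self.alpha, self.beta, *self.gamma.values(), *self.phi.values()]
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if set(self.gamma) != set(self.phi):
            raise ValueError("gamma and phi must name the same confounds")


@dataclass(frozen=True)
class SoftAgeLabel:
    """Gaussian soft label over 1-year age bins."""

    bin_centers: np.ndarray
    probs: np.ndarray
    mu: float
    sigma: float


# ---------------------------------------------------------------------------
# Per-scanner main-task loss
# ---------------------------------------------------------------------------


def per_scanner_weights(domain_labels) -> np.ndarray:
    """Per-sample weights 1/S_n realising the scanner-balanced task loss.

    The weighted sum of per-sample losses equals the sum over scanners of the
    within-scanner mean loss, so no single large dataset dominates the
    optimisation.
    """
    domain_labels = np.asarray(domain_labels)
    w = np.empty(domain_labels.shape[0], dtype=np.float64)
    for d in np.unique(domain_labels):
        mask = domain_labels == d
        w[mask] = 1.0 / mask.sum()
    return w


def per_scanner_task_loss(predictions, labels, domain_labels, base_loss=None) -> float:
    """Sum over scanners of the mean per-sample loss within that scanner.

    ``base_loss(pred, label)`` defaults to the squared error.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if predictions.shape[0] == 0:
        raise ValueError("empty input")
    if base_loss is None:
        base_loss = lambda p, y: (p - y) ** 2  # noqa: E731
    per_sample = np.array([base_loss(p, y) for p, y in zip(predictions, labels)])
    w = per_scanner_weights(domain_labels)
    return float((w * per_sample).sum())


# ---------------------------------------------------------------------------
# Domain classification and confusion losses
# ---------------------------------------------------------------------------


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim == 1:
        probs = probs[None]
    if np.any(probs < 0) or np.any(probs > 1 + 1e-9):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return probs


def domain_classification_loss(domain_probs, domain_labels) -> float:
    """Mean categorical cross-entropy -log p(true scanner) over the batch."""
    probs = _check_probs(domain_probs)
    labels = np.asarray(domain_labels, dtype=int)
    if probs.shape[0] == 0:
        raise ValueError("at least one unlearning sample is required")
    p_true = probs[np.arange(probs.shape[0]), labels]
    return float(-np.log(np.maximum(p_true, PROB_FLOOR)).mean())


def confusion_loss(domain_probs) -> float:
    """Mean over samples of -(1/N) sum_k log p_k; minimum ln N at uniformity."""
    probs = _check_probs(domain_probs)
    if probs.shape[0] == 0:
        raise ValueError("at least one unlearning sample is required")
    n = probs.shape[1]
    return float(-np.log(np.maximum(probs, PROB_FLOOR)).sum(axis=1).mean() / n)


def domain_ce_from_logits(logits: Tensor, domain_labels) -> Tensor:
    """Cross-entropy of Eq.-style domain classification, from logits."""
    labels = np.asarray(domain_labels, dtype=int)
    ls = log_softmax(logits, axis=1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(labels.shape[0]), labels] = 1.0
    return (ls * onehot).sum() * (-1.0 / labels.shape[0])


def confusion_from_logits(logits: Tensor) -> Tensor:
    """Confusion loss from logits; minimised when softmax outputs are uniform."""
    s, n = logits.shape
    ls = log_softmax(logits, axis=1)
    return ls.sum() * (-1.0 / (s * n))


def total_unlearning_loss(lp, ld, lconf, confound_terms, weights: LossWeights) -> float:
    """Bookkeeping aggregate Lp + a*Ld + b*Lconf + sum_j(g_j*Lc_j + phi_j*LCconf_j).

    The optimiser never minimises this directly — each component is applied to
    its own parameter partition — but the aggregate is what the iterative
    scheme implicitly minimises and is logged per epoch.
    """
    total = float(lp) + weights.alpha * float(ld) + weights.beta * float(lconf)
    for name, (lc, lcconf) in confound_terms.items():
        total += weights.gamma[name] * float(lc) + weights.phi[name] * float(lcconf)
    return total


# ---------------------------------------------------------------------------
# Segmentation: soft multi-class Dice
# ---------------------------------------------------------------------------


def multiclass_dice_loss(class_probs, one_hot_labels, class_axis: int = -1,
                         eps: float = 1e-5, background_index: int | None = None):
    """1 minus the mean soft Dice over (foreground) classes.

    Works on plain arrays (returns a float) and on autodiff tensors (returns a
    tensor), since only elementwise arithmetic and sums are used.  With
    ``background_index`` set, that class is excluded from the average (the
    tissue-segmentation convention: CSF/GM/WM only).
    """
    shape = class_probs.shape
    ndim = len(shape)
    axis = class_axis % ndim
    n_classes = shape[axis]
    reduce_axes = tuple(a for a in range(ndim) if a != axis)

    inter = (class_probs * one_hot_labels).sum(axis=reduce_axes)
    card = class_probs.sum(axis=reduce_axes) + one_hot_labels.sum(axis=reduce_axes)
    dice = (inter * 2.0 + eps) / (card + eps)  # length n_classes

    keep = [k for k in range(n_classes) if k != background_index]
    picker = np.zeros(n_classes)
    picker[keep] = 1.0 / len(keep)
    mean_dice = (dice * picker).sum()
    out = 1.0 - mean_dice
    return out if isinstance(out, Tensor) else float(out)


# ---------------------------------------------------------------------------
# Continuous variables: Gaussian soft labels and KL divergence
# ---------------------------------------------------------------------------


def make_soft_label(age: float, bin_range: tuple = (0.0, 100.0), sigma: float = 10.0) -> SoftAgeLabel:
    """Gaussian N(age, sigma^2) evaluated at 1-year bin centers, renormalised."""
    lo, hi = bin_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside bin range {bin_range}")
    centers = np.arange(lo, hi + 1.0)
    dens = np.exp(-0.5 * ((centers - age) / sigma) ** 2)
    return SoftAgeLabel(centers, dens / dens.sum(), float(age), float(sigma))


def kl_task_loss(predicted_probs, true_label) -> float:
    """KL(true || predicted) in nats; the soft-label regression task loss."""
    t = true_label.probs if isinstance(true_label, SoftAgeLabel) else np.asarray(true_label)
    p = np.maximum(np.asarray(predicted_probs, dtype=np.float64), PROB_FLOOR)
    t = np.asarray(t, dtype=np.float64)
    terms = np.where(t > 0, t * (np.log(np.maximum(t, PROB_FLOOR)) - np.log(p)), 0.0)
    return float(terms.sum())


def kl_from_logits(logits: Tensor, true_probs: np.ndarray) -> Tensor:
    """Mean KL(true || softmax(logits)) over the batch, from logits."""
    t = np.asarray(true_probs, dtype=np.float64)
    ls = log_softmax(logits, axis=1)
    ent = float(np.where(t > 0, t * np.log(np.maximum(t, PROB_FLOOR)), 0.0).sum())
    return ((ls * t).sum() * -1.0 + ent) * (1.0 / t.shape[0])


def age_point_estimate(predicted_probs, bin_centers, method: str = "expectation") -> float:
    """Collapse a predicted age distribution to a scalar age in years."""
    p = np.asarray(predicted_probs, dtype=np.float64)
    centers = np.asarray(bin_centers, dtype=np.float64)
    if not np.isclose(p.sum(), 1.0, atol=1e-6) or np.any(p < 0):
        raise ValueError("invalid probability distribution")
    if method == "argmax":
        return float(centers[int(p.argmax())])
    return float((p * centers).sum())
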