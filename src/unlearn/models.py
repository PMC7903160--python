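"""Network architectures with explicit parameter partitions.

Every model is split into a *feature extractor* (theta_repr) whose final
activations form the feature representation Qrepr, a *label predictor*
(theta_p) for the main task, a *domain classifier* (theta_d) and optional
per-confound classifier heads (theta_c_j).  The iterative unlearning scheme
depends on these partitions being disjoint and exhaustive, so the partition
is a first-class object that can be validated and asserted against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .nn import Adam, Conv2d, Dense, MLPHead, Sequential

__all__ = [
    "ParameterPartition",
    "RegressionModel",
    "UNetModel",
    "build_regression_model",
    "build_unet_model",
    "attach_confound_classifiers",
    "remove_confound_classifier",
    "save_model",
    "load_model",
]


@dataclass
class ParameterPartition:
    theta_repr: list = field(default_factory=list)
    theta_p: list = field(default_factory=list)
    theta_d: list = field(default_factory=list)
    theta_c: dict = field(default_factory=dict)   # confound name -> params

    def groups(self) -> dict:
        out = {"theta_repr": self.theta_repr, "theta_p": self.theta_p,
               "theta_d": self.theta_d}
        for name, params in self.theta_c.items():
            out[f"theta_c[{name}]"] = params
        return out

    def all_parameters(self) -> list[Tensor]:
        return [p for group in self.groups().values() for p in group]

    def validate(self) -> None:
        ids: set[int] = set()
        for params in self.groups().values():
            for p in params:
                if id(p) in ids:
                    raise ValueError("parameter partition sets are not disjoint")
                ids.add(id(p))


def _softmax_np(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class _BaseModel:
    """Shared head plumbing for both architectures."""

    def __init__(self):
        self.confound_heads: dict[str, MLPHead] = {}
        self._head_rng: np.random.Generator | None = None

    def domain_logits(self, feats: Tensor) -> Tensor:
        return self.domain_head(feats)

    def confound_logits(self, name: str, feats: Tensor) -> Tensor:
        return self.confound_heads[name](feats)

    def domain_probs(self, X: np.ndarray) -> np.ndarray:
        return _softmax_np(self.domain_logits(self.features(X)).data, axis=1)

    def features_np(self, X: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Frozen feature representation, computed without building gradients."""
        out = []
        for i in range(0, X.shape[0], chunk):
            out.append(self.features(X[i : i + chunk]).data)
        return np.concatenate(out, axis=0)


class RegressionModel(_BaseModel):
    """Convolutional encoder -> fully connected Qrepr -> task / domain heads.

    A miniature VGG-style stack: two conv+pool blocks feeding a first fully
    connected layer whose activations are Qrepr (the unlearning attach
    point).  The label predictor maps Qrepr to a scalar age or to softmax
    logits over age bins; the domain classifier maps Qrepr to an N-way
    softmax.
    """

    kind = "regression"

    def __init__(self, input_shape: tuple, n_domains: int, feature_dim: int = 64,
                 width_scale: float = 1.0, n_outputs: int = 1,
                 head_hidden: int = 32, seed: int = 0):
        super().__init__()
        if feature_dim <= 0:
            raise ValueError("feature_dim must be positive")
        if n_domains < 2:
            raise ValueError("need at least two domains")
        h, w = input_shape
        if h % 4 or w % 4:
            raise ValueError("input height/width must be divisible by 4")
        rng = np.random.default_rng(seed)
        c = max(4, int(round(8 * width_scale)))
        self.meta = dict(input_shape=list(input_shape), n_domains=n_domains,
                         feature_dim=feature_dim, width_scale=width_scale,
                         n_outputs=n_outputs, head_hidden=head_hidden, seed=seed)
        self.n_domains = n_domains
        self.feature_dim = feature_dim
        flat = 2 * c * (h // 4) * (w // 4)
        self.encoder = Sequential(
            Conv2d(1, c, rng, pool=True),
            Conv2d(c, 2 * c, rng, pool=True),
        )
        self.fc_repr = Dense(flat, feature_dim, rng, relu=True)
        self.predictor = Sequential(
            Dense(feature_dim, head_hidden, rng, relu=True),
            Dense(head_hidden, n_outputs, rng),
        )
        self.domain_head = MLPHead(feature_dim, head_hidden, n_domains, rng)
        self._head_rng = rng

    def features(self, X: np.ndarray) -> Tensor:
        x = Tensor(np.asarray(X, dtype=np.float64)[:, None])
        fmap = self.encoder(x)
        return self.fc_repr(fmap.reshape(fmap.shape[0], -1))

    def predict_task(self, feats: Tensor) -> Tensor:
        return self.predictor(feats)

    def partition(self) -> ParameterPartition:
        part = ParameterPartition(
            theta_repr=self.encoder.parameters() + self.fc_repr.parameters(),
            theta_p=self.predictor.parameters(),
            theta_d=self.domain_head.parameters(),
            theta_c={n: h.parameters() for n, h in self.confound_heads.items()},
        )
        part.validate()
        return part


class UNetModel(_BaseModel):
    """2-D U-Net with skip connections and configurable unlearning attach point.

    The domain classifier consumes Qrepr taken at the final convolution (A),
    the bottleneck (B), or the concatenation of one fully connected layer per
    branch (A+B).  The branch FC layers belong to the domain classifier's
    partition; theta_repr is the U-Net body and theta_p the segmentation head.
    """

    kind = "unet"

    def __init__(self, input_shape: tuple, n_classes: int, n_domains: int,
                 attach: str = "A", feature_dim: int = 64, width_scale: float = 1.0,
                 head_hidden: int = 32, seed: int = 0):
        super().__init__()
        if attach not in ("A", "B", "A+B"):
            raise ValueError(f"invalid attach point {attach!r}; use 'A', 'B' or 'A+B'")
        if n_domains < 2:
            raise ValueError("need at least two domains")
        h, w = input_shape
        if h % 4 or w % 4:
            raise ValueError("input height/width must be divisible by 4")
        rng = np.random.default_rng(seed)
        c = max(4, int(round(8 * width_scale)))
        self.meta = dict(input_shape=list(input_shape), n_classes=n_classes,
                         n_domains=n_domains, attach=attach, feature_dim=feature_dim,
                         width_scale=width_scale, head_hidden=head_hidden, seed=seed)
        self.n_domains = n_domains
        self.attach = attach
        self.feature_dim = feature_dim
        self.enc1 = Conv2d(1, c, rng)
        self.enc2 = Conv2d(c, 2 * c, rng)
        self.bottleneck = Conv2d(2 * c, 4 * c, rng)
        self.dec1 = Conv2d(4 * c + 2 * c, 2 * c, rng)
        self.dec2 = Conv2d(2 * c + c, c, rng)          # final convolution (A)
        self.seg_head = Conv2d(c, n_classes, rng, kernel=1, relu=False)
        self.fc_a = Dense(c, feature_dim, rng, relu=True)
        self.fc_b = Dense(4 * c, feature_dim, rng, relu=True)
        feat_len = 2 * feature_dim if attach == "A+B" else feature_dim
        self.domain_head = MLPHead(feat_len, head_hidden, n_domains, rng)
        self._head_rng = rng

    # -- forward ------------------------------------------------------------

    def _body(self, X: np.ndarray):
        from .autodiff import maxpool2d, upsample2d

        x = Tensor(np.asarray(X, dtype=np.float64)[:, None])
        s1 = self.enc1(x)
        s2 = self.enc2(maxpool2d(s1))
        b = self.bottleneck(maxpool2d(s2))
        d1 = self.dec1(concat([upsample2d(b), s2], axis=1))
        d2 = self.dec2(concat([upsample2d(d1), s1], axis=1))
        return d2, b

    def seg_logits(self, X: np.ndarray) -> Tensor:
        final, _ = self._body(X)
        return self.seg_head(final)

    def features(self, X: np.ndarray) -> Tensor:
        final, bottle = self._body(X)
        pooled_a = final.mean(axis=(2, 3))
        pooled_b = bottle.mean(axis=(2, 3))
        if self.attach == "A":
            return self.fc_a(pooled_a)
        if self.attach == "B":
            return self.fc_b(pooled_b)
        return concat([self.fc_a(pooled_a), self.fc_b(pooled_b)], axis=1)

    def seg_probs(self, X: np.ndarray, chunk: int = 32) -> np.ndarray:
        out = []
        for i in range(0, X.shape[0], chunk):
            out.append(_softmax_np(self.seg_logits(X[i : i + chunk]).data, axis=1))
        return np.concatenate(out, axis=0)

    def partition(self) -> ParameterPartition:
        body = (self.enc1.parameters() + self.enc2.parameters()
                + self.bottleneck.parameters() + self.dec1.parameters()
                + self.dec2.parameters())
        branch_fcs = []
        if self.attach in ("A", "A+B"):
            branch_fcs += self.fc_a.parameters()
        if self.attach in ("B", "A+B"):
            branch_fcs += self.fc_b.parameters()
        part = ParameterPartition(
            theta_repr=body,
            theta_p=self.seg_head.parameters(),
            theta_d=branch_fcs + self.domain_head.parameters(),
            theta_c={n: h.parameters() for n, h in self.confound_heads.items()},
        )
        part.validate()
        return part


# ---------------------------------------------------------------------------
# Builders (the public construction surface)
# ---------------------------------------------------------------------------


def build_regression_model(input_shape: tuple, n_domains: int, feature_dim: int = 64,
                           width_scale: float = 1.0, n_outputs: int = 1,
                           head_hidden: int = 32, seed: int = 0) -> RegressionModel:
    return RegressionModel(input_shape, n_domains, feature_dim, width_scale,
                           n_outputs, head_hidden, seed)


def build_unet_model(input_shape: tuple, n_classes: int, n_domains: int,
                     attach: str = "A", feature_dim: int = 64,
                     width_scale: float = 1.0, head_hidden: int = 32,
                     seed: int = 0) -> UNetModel:
    return UNetModel(input_shape, n_classes, n_domains, attach, feature_dim,
                     width_scale, head_hidden, seed)


def attach_confound_classifiers(model: _BaseModel, confound_specs: dict,
                                head_hidden: int = 32) -> _BaseModel:
    """Add one classifier head per confound; each head gets its own theta_c_j.

    ``confound_specs`` maps confound name -> number of classes (continuous
    confounds must be pre-binned).
    """
    feat_len = (2 * model.feature_dim
                if getattr(model, "attach", None) == "A+B" else model.feature_dim)
    for name, n_classes in confound_specs.items():
        if name in model.confound_heads:
            raise ValueError(f"duplicate confound name {name!r}")
        model.confound_heads[name] = MLPHead(feat_len, head_hidden, int(n_classes),
                                             model._head_rng)
    model.partition()  # re-validate
    return model


def remove_confound_classifier(model: _BaseModel, name: str) -> _BaseModel:
    del model.confound_heads[name]
    return model


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_model(model: _BaseModel, path, config: dict | None = None) -> None:
    """Save parameters plus enough metadata to rebuild the model."""
    part = model.partition()
    params = part.all_parameters()
    meta = {"kind": model.kind, "meta": model.meta,
            "confounds": {n: h.layers[-1].bias.shape[0]
                          for n, h in model.confound_heads.items()},
            "config": config or {}}
    arrays = {f"p{i}": p.data for i, p in enumerate(params)}
    np.savez(str(path), _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> _BaseModel:
    with np.load(str(path)) as npz:
        meta = json.loads(bytes(npz["_meta"].tobytes()).decode())
        model_cls = RegressionModel if meta["kind"] == "regression" else UNetModel
        m = meta["meta"]
        if meta["kind"] == "regression":
            model = model_cls(tuple(m["input_shape"]), m["n_domains"],
                              m["feature_dim"], m["width_scale"], m["n_outputs"],
                              m["head_hidden"], m["seed"])
        else:
            model = model_cls(tuple(m["input_shape"]), m["n_classes"],
                              m["n_domains"], m["attach"], m["feature_dim"],
                              m["width_scale"], m["head_hidden"], m["seed"])
        if meta["confounds"]:
            attach_confound_classifiers(model, meta["confounds"],
                                        head_hidden=m["head_hidden"])
        params = model.partition().all_parameters()
        for i, p in enumerate(params):
            p.data = npz[f"p{i}"].astype(np.float64)
    return model
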