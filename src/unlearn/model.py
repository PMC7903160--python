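"""Model/Results facade over the training machinery.

``UnlearningModel`` is constructed from a :class:`~unlearn.io.MultiSiteDataset`
(or a DataFrame of image arrays plus metadata) and a config; ``fit()`` runs
the requested training mode and returns an :class:`UnlearningResults` object
carrying the trained network, the loss history, task metrics and probe
diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import training as tr
from .io import MultiSiteDataset, Sample, TrainConfig

__all__ = ["UnlearningModel", "UnlearningResults"]


class UnlearningModel:
    """Adversarial scanner-unlearning model for a multi-site imaging dataset."""

    def __init__(self, dataset: MultiSiteDataset, config: TrainConfig | None = None):
        self.dataset = dataset
        self.config = config or TrainConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: TrainConfig | None = None,
                       image_col: str = "image", domain_col: str = "domain_label",
                       label_col: str = "age") -> "UnlearningModel":
        """Build from a DataFrame with one image array per row plus metadata."""
        samples = []
        extra = [c for c in frame.columns
                 if c not in (image_col, domain_col, label_col)]
        for _, row in frame.iterrows():
            label = row[label_col] if label_col in frame.columns else None
            if label is not None and np.isscalar(label) and pd.isna(label):
                label = None
            samples.append(Sample(
                image=np.asarray(row[image_col]),
                domain_label=int(row[domain_col]),
                main_label=label,
                confound_labels={c: row[c] for c in extra},
                in_p=label is not None))
        return cls(MultiSiteDataset(samples), config)

    def fit(self, mode: str | None = None, seed: int | None = None,
            policy: tr.UnlearningPolicy | None = None) -> "UnlearningResults":
        cfg = self.config
        if mode is not None or seed is not None:
            kw = {**cfg.__dict__}
            if mode is not None:
                kw["mode"] = mode
            if seed is not None:
                kw["seed"] = seed
            cfg = TrainConfig(**kw)
        if policy is not None:
            tr.select_unlearning_subset(self.dataset, policy)
        state = tr.fit(self.dataset, cfg)
        return UnlearningResults(state)


class UnlearningResults:
    """Fitted model, loss history and evaluation helpers."""

    def __init__(self, state: tr.TrainingState):
        self.state = state
        self.model = state.model
        self.config = state.config
        self.history = tr.history_frame(state)

    # -- predictions ---------------------------------------------------------

    def features(self, dataset: MultiSiteDataset) -> np.ndarray:
        """Frozen feature representation Qrepr per sample."""
        return self.model.features_np(dataset.images)

    def predict_ages(self, dataset: MultiSiteDataset) -> np.ndarray:
        return tr.predict_ages(self.state, dataset.images)

    def predict_segmentation(self, dataset: MultiSiteDataset) -> np.ndarray:
        return self.model.seg_probs(dataset.images).argmax(axis=1)

    # -- diagnostics ---------------------------------------------------------

    def probe(self, dataset: MultiSiteDataset | None = None,
              target: str = "scanner", seed: int = 0,
              eval_dataset: MultiSiteDataset | None = None) -> ev.ProbeResult:
        """Residual-information probe on frozen features.

        ``target`` is ``"scanner"`` or the name of a confound column.  With
        ``eval_dataset`` given, the probe head is trained on ``dataset``'s
        features and its accuracy reported on ``eval_dataset`` (the held-out
        protocol used for end-to-end experiments); otherwise a stratified
        split of ``dataset`` is held out.
        """
        ds = dataset if dataset is not None else self.state.train

        def lab(d):
            arr = d.domain_index if target == "scanner" else d.confound(target)
            return arr.astype(int)

        feats = self.features(ds)
        if eval_dataset is not None:
            return ev.probe_scanner_information(
                feats, lab(ds), seed=seed,
                eval_features=self.features(eval_dataset),
                eval_labels=lab(eval_dataset))
        return ev.probe_scanner_information(feats, lab(ds), seed=seed)

    def mae(self, dataset: MultiSiteDataset | None = None) -> tuple[dict, float]:
        ds = dataset if dataset is not None else self.state.val or self.state.train
        keep = np.flatnonzero(ds.in_p)
        sub = ds.subset(keep) if keep.size != len(ds) else ds
        preds = self.predict_ages(sub)
        return ev.per_scanner_mae(preds, sub.main_labels(), sub.domain_index + 1)

    def dice(self, dataset: MultiSiteDataset | None = None,
             ignore_background: bool = True) -> dict:
        """Mean hard Dice per tissue class over a dataset."""
        ds = dataset if dataset is not None else self.state.val or self.state.train
        keep = np.flatnonzero(ds.in_p)
        sub = ds.subset(keep) if keep.size != len(ds) else ds
        preds = self.predict_segmentation(sub)
        per_class: dict[int, list] = {}
        for pred, s in zip(preds, sub):
            d = ev.per_tissue_dice(pred, s.main_label,
                                   ignore=(0,) if ignore_background else ())
            for c, v in d.items():
                per_class.setdefault(c, []).append(v)
        return {c: float(np.mean(v)) for c, v in sorted(per_class.items())}

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "            Scanner-unlearning results",
            "=" * 50,
            f"task:              {cfg.task}",
            f"mode:              {cfg.mode}",
            f"sites (N):         {self.state.train.n_domains}"
            f"   chance = {ev.chance_level(self.state.train.n_domains):.2f}%",
            f"training samples:  {len(self.state.train)}",
            f"epochs run:        {self.state.epoch}",
            f"loss weights:      alpha={cfg.alpha}  beta={cfg.beta}",
        ]
        val_lp = tr.evaluate_task_loss(self.state,
                                       self.state.val or self.state.train)
        lines.append(f"val task loss:     {val_lp:.4f}")
        if cfg.mode == "unlearn" and "val_domain_acc" in self.history.columns:
            accs = self.history["val_domain_acc"].dropna()
            if len(accs):
                n = self.state.train.n_domains
                lines.append(f"val scanner acc:   {accs.min():.1f}% at best epoch"
                             f"   (chance {100.0 / n:.1f}%)")
        lines.append("=" * 50)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<UnlearningResults task={self.config.task} "
                f"mode={self.config.mode} epochs={self.state.epoch}>")
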