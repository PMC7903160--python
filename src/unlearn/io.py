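"""Data model, volume preprocessing, NIfTI/CSV I/O and run configuration.

The central container is :class:`MultiSiteDataset`: an ordered collection of
:class:`Sample` objects drawn from N scanners ("domains").  Each sample
carries a domain label (1..N), an optional main-task label (age in years or a
categorical tissue map) and optional confound labels, plus the subset flags
that the unlearning scheme uses: ``in_p`` (contributes to the main-task
loss), ``in_u`` (used for scanner unlearning) and per-confound ``in_c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "VolumeFormatError",
    "HeaderError",
    "NormalisationError",
    "GridMismatchError",
    "Sample",
    "MultiSiteDataset",
    "TrainConfig",
    "load_volume",
    "save_volume",
    "preprocess_volume",
    "preprocess_labelmap",
    "normalise",
    "save_dataset",
    "load_dataset",
]

TARGET_GRID = 128          # mm field of view after 1 mm resampling
SLICE_STEP = 4             # every fourth axial slice is retained
N_SLICES = TARGET_GRID // SLICE_STEP


class VolumeFormatError(ValueError):
    """Input volume has the wrong dimensionality."""


class HeaderError(ValueError):
    """NIfTI header could not be read or is inconsistent."""


class NormalisationError(ValueError):
    """Volume has zero variance and cannot be standardised."""


class GridMismatchError(ValueError):
    """Label map is not aligned with its volume grid."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class Sample:
    """One image with its domain label, optional task/confound labels and flags.

    ``domain_label`` is 1-based (scanner n in {1..N}); array indexing helpers
    on the dataset convert to 0-based.
    """

    image: np.ndarray
    domain_label: int
    main_label: object = None          # float age, per-voxel class map, or None
    confound_labels: dict = field(default_factory=dict)
    in_p: bool = True
    in_u: bool = True
    in_c: dict = field(default_factory=dict)
    sample_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if not np.all(np.isfinite(self.image)):
            raise ValueError("sample image contains non-finite values")
        if self.domain_label < 1:
            raise ValueError("domain_label must be a 1-based scanner index")
        if self.in_p and self.main_label is None:
            raise ValueError("in_p requires a main-task label")


class MultiSiteDataset:
    """Ordered collection of samples from N scanners."""

    def __init__(self, samples: list[Sample], n_domains: int | None = None,
                 strict: bool = True):
        if not samples:
            raise ValueError("dataset must contain at least one sample")
        self.samples = list(samples)
        labels = np.array([s.domain_label for s in self.samples])
        self.n_domains = int(n_domains if n_domains is not None else labels.max())
        if labels.max() > self.n_domains:
            raise ValueError("domain label exceeds n_domains")
        missing = set(range(1, self.n_domains + 1)) - set(labels.tolist())
        if strict and missing:
            raise ValueError(f"every domain 1..{self.n_domains} needs >=1 sample "
                             f"(missing {sorted(missing)})")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def per_domain_counts(self) -> dict[int, int]:
        counts = {n: 0 for n in range(1, self.n_domains + 1)}
        for s in self.samples:
            counts[s.domain_label] += 1
        return counts

    # -- array views --------------------------------------------------------

    @property
    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.samples])

    @property
    def domain_index(self) -> np.ndarray:
        """0-based domain index per sample."""
        return np.array([s.domain_label - 1 for s in self.samples], dtype=int)

    @property
    def in_p(self) -> np.ndarray:
        return np.array([s.in_p for s in self.samples], dtype=bool)

    @property
    def in_u(self) -> np.ndarray:
        return np.array([s.in_u for s in self.samples], dtype=bool)

    def in_c(self, confound: str) -> np.ndarray:
        return np.array([s.in_c.get(confound, False) for s in self.samples], dtype=bool)

    def main_labels(self) -> np.ndarray:
        vals = [s.main_label for s in self.samples]
        return np.stack(vals) if isinstance(vals[0], np.ndarray) else np.array(
            [np.nan if v is None else v for v in vals], dtype=np.float64
        )

    def confound(self, name: str) -> np.ndarray:
        return np.array([s.confound_labels.get(name, np.nan) for s in self.samples])

    # -- structural helpers -------------------------------------------------

    def subset(self, indices) -> "MultiSiteDataset":
        # evaluation subsets (e.g. one site only) may legitimately miss domains
        return MultiSiteDataset([self.samples[i] for i in np.asarray(indices, dtype=int)],
                                n_domains=self.n_domains, strict=False)

    def split(self, fraction: float, seed: int) -> tuple["MultiSiteDataset", "MultiSiteDataset"]:
        """Stratified-by-domain split; returns (1-fraction, fraction) parts."""
        rng = np.random.default_rng(seed)
        hold: list[int] = []
        didx = self.domain_index
        for d in range(self.n_domains):
            idx = np.flatnonzero(didx == d)
            rng.shuffle(idx)
            k = max(1, int(round(fraction * idx.size)))
            hold.extend(idx[:k].tolist())
        hold_set = set(hold)
        keep = [i for i in range(len(self)) if i not in hold_set]
        return self.subset(keep), self.subset(sorted(hold))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class ConfoundSpec:
    name: str
    n_classes: int
    gamma: float = 1.0
    phi: float = 10.0


@dataclass
class TrainConfig:
    """Everything a run needs; serialisable to/from YAML and logged per run."""

    task: str = "regression"           # regression | soft_regression | segmentation
    mode: str = "unlearn"              # normal | unlearn
    feature_dim: int = 64
    width_scale: float = 1.0
    head_hidden: int = 32
    n_classes: int = 4                 # segmentation classes incl. background
    attach: str = "A"                  # U-Net attach point: A | B | A+B
    batch_size: int = 32
    lr: float = 1e-4
    lr_domain: float | None = None     # domain-classifier stage; default = lr
    lr_confusion: float | None = None  # feature-extractor confusion stage; default = lr
    lr_task_unlearn: float | None = None  # task stage during unlearning; default = lr
    domain_steps: int = 1              # optimiser iterations inside stage 2 per batch
    refit_domain_each_epoch: bool = True  # re-converge classifier heads on cached
                                          # frozen features at each unlearning epoch
    confusion_optimizer: str = "sgd"   # sgd | adam; sgd anneals near equilibrium
    select_best_unlearning: bool = True   # keep the epoch with least validation
                                          # scanner accuracy (task loss within tol)
    unlearn_task_tolerance: float = 1.3   # max val task-loss inflation vs pretrain
    adaptive_confusion: bool = True    # damp the confusion step when the task
                                       # degrades; recover from collapses
    balanced_task_loss: bool | None = None  # per-scanner-balanced main loss;
                                            # default True for unlearn mode,
                                            # False (plain pooled) for normal
    alpha: float = 1.0
    beta: float = 10.0
    confounds: list = field(default_factory=list)   # list[ConfoundSpec]
    sigma: float = 10.0                # soft-label spread, years
    bin_range: tuple = (0.0, 100.0)
    pretrain_max_epochs: int = 40
    pretrain_patience: int = 10
    unlearn_epochs: int = 20
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.confounds = [c if isinstance(c, ConfoundSpec) else ConfoundSpec(**c)
                          for c in self.confounds]
        names = [c.name for c in self.confounds]
        if len(names) != len(set(names)):
            raise ValueError("duplicate confound names")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["bin_range"] = list(d["bin_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["bin_range"] = tuple(d.get("bin_range", (0.0, 100.0)))
        return cls(**d)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def load_volume(path) -> tuple[np.ndarray, tuple]:
    """Read a 3-D NIfTI volume; returns (array, voxel sizes in mm)."""
    import nibabel as nib

    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - nibabel internals vary
        raise HeaderError(f"unreadable NIfTI header/data: {path}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3-D volume, got shape {data.shape}")
    return data, tuple(float(z) for z in zooms[:3])


def save_volume(array: np.ndarray, path, voxel_sizes=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    array = np.asarray(array)
    vox = (list(voxel_sizes) + [1.0, 1.0, 1.0])[:3]
    affine = np.diag(vox + [1.0])
    nib.save(nib.Nifti1Image(array.astype(np.float64), affine), str(path))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def normalise(x: np.ndarray) -> np.ndarray:
    """Standardise to zero mean, unit standard deviation over the full grid."""
    sd = x.std()
    # relative threshold so interpolation ripple on a constant volume still
    # counts as degenerate
    if sd < 1e-10 * max(1.0, abs(float(x.mean()))):
        raise NormalisationError("zero-variance volume cannot be normalised")
    return (x - x.mean()) / sd


def _crop_pad(x: np.ndarray, target: int) -> np.ndarray:
    """Centre crop/pad every axis to ``target`` voxels (zero padding)."""
    for ax in range(x.ndim):
        n = x.shape[ax]
        if n > target:
            lo = (n - target) // 2
            x = np.take(x, range(lo, lo + target), axis=ax)
        elif n < target:
            before = (target - n) // 2
            pads = [(0, 0)] * x.ndim
            pads[ax] = (before, target - n - before)
            x = np.pad(x, pads)
    return x


def _resample_to_1mm(x: np.ndarray, voxel_sizes, order: int) -> np.ndarray:
    voxel_sizes = np.asarray(voxel_sizes, dtype=np.float64)
    if x.ndim != 3:
        raise VolumeFormatError(f"expected 3-D input, got shape {x.shape}")
    if np.any(voxel_sizes <= 0):
        raise ValueError("voxel sizes must be positive")
    if np.allclose(voxel_sizes, 1.0):
        return x.astype(np.float64)
    return ndimage.zoom(x.astype(np.float64), voxel_sizes, order=order)


def preprocess_volume(volume: np.ndarray, voxel_sizes=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Resample to 1 mm isotropic on a 128 mm field of view, keep every fourth
    axial slice (32 slices) and standardise to zero mean, unit SD.

    Cubic-spline resampling; the field of view is centre-cropped/padded so the
    physical size of the object is preserved.
    """
    x = _resample_to_1mm(np.asarray(volume), voxel_sizes, order=3)
    x = _crop_pad(x, TARGET_GRID)
    x = x[:, :, ::SLICE_STEP]
    return normalise(x)


def preprocess_labelmap(labelmap: np.ndarray, voxel_sizes=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Trilinearly resample a one-hot label map and threshold at 0.5.

    Input shape (H, W, D, K).  Returns categorical labels on the same
    retained-slice grid as :func:`preprocess_volume`.  A voxel whose largest
    interpolated value is shared between classes (e.g. exactly 0.5/0.5) is
    assigned the lowest class index.
    """
    lm = np.asarray(labelmap, dtype=np.float64)
    if lm.ndim != 4:
        raise GridMismatchError(f"expected one-hot map (H,W,D,K), got {lm.shape}")
    if not np.allclose(lm.sum(axis=-1), 1.0, atol=1e-6):
        raise GridMismatchError("label map channels must sum to 1 (one-hot)")
    channels = []
    for k in range(lm.shape[-1]):
        ch = _resample_to_1mm(lm[..., k], voxel_sizes, order=1)
        ch = _crop_pad(ch, TARGET_GRID)[:, :, ::SLICE_STEP]
        channels.append(ch)
    stacked = np.stack(channels, axis=-1)
    # argmax returns the first (lowest) index on ties, which realises the
    # documented 0.5 tie-break rule for interpolated one-hot maps.
    return stacked.argmax(axis=-1)


# ---------------------------------------------------------------------------
# Dataset <-> disk (NIfTI volumes + CSV sidecar)
# ---------------------------------------------------------------------------


def save_dataset(dataset: MultiSiteDataset, directory) -> None:
    """Write each image (and any label map) as NIfTI plus a metadata CSV."""
    import os

    import pandas as pd

    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, s in enumerate(dataset):
        sid = s.sample_id or f"sub-{i:05d}"
        img = s.image if s.image.ndim == 3 else s.image[..., None]
        save_volume(img, os.path.join(directory, f"{sid}.nii.gz"))
        row = {
            "sample_id": sid,
            "domain_label": s.domain_label,
            "in_p": int(s.in_p),
            "in_u": int(s.in_u),
        }
        if isinstance(s.main_label, np.ndarray):
            lab = s.main_label if s.main_label.ndim == 3 else s.main_label[..., None]
            save_volume(lab.astype(np.float64), os.path.join(directory, f"{sid}_seg.nii.gz"))
            row["age"] = s.confound_labels.get("age", np.nan)
        else:
            row["age"] = np.nan if s.main_label is None else s.main_label
        for name, val in s.confound_labels.items():
            if name != "age":
                row[name] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(directory, "participants.csv"), index=False)


def load_dataset(directory, task: str = "regression") -> MultiSiteDataset:
    """Rebuild a :class:`MultiSiteDataset` written by :func:`save_dataset`."""
    import os

    import pandas as pd

    meta = pd.read_csv(os.path.join(directory, "participants.csv"))
    samples = []
    base_cols = {"sample_id", "domain_label", "in_p", "in_u", "age"}
    for _, row in meta.iterrows():
        img, _ = load_volume(os.path.join(directory, f"{row.sample_id}.nii.gz"))
        img = img[..., 0] if img.shape[-1] == 1 else img
        confounds = {c: row[c] for c in meta.columns if c not in base_cols}
        seg_path = os.path.join(directory, f"{row.sample_id}_seg.nii.gz")
        if task == "segmentation" and os.path.exists(seg_path):
            seg, _ = load_volume(seg_path)
            main = (seg[..., 0] if seg.shape[-1] == 1 else seg).astype(int)
            confounds["age"] = float(row.age)
        else:
            main = None if np.isnan(row.age) else float(row.age)
        in_p = bool(row.in_p) and main is not None
        samples.append(Sample(image=img, domain_label=int(row.domain_label),
                              main_label=main, confound_labels=confounds,
                              in_p=in_p, in_u=bool(row.in_u),
                              sample_id=str(row.sample_id)))
    return MultiSiteDataset(samples)
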