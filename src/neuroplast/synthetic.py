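"""Procedural stimulus and synthetic neural-recording generators.

Every downstream analysis (training, injury, RDMs, neural predictivity) is
testable without external downloads because the inputs are generated here:

* :func:`generate_dataset` builds a balanced, labeled image classification
  problem whose classes are distinct procedural pattern families (shape
  identity x color x texture frequency), mirroring the structure of the
  standard 10-class 32x32 RGB benchmarks: balanced classes, a fixed disjoint
  train/test split, and pixel values in [0, 1].
* :func:`generate_recordings` builds a stimuli x neurons response matrix as a
  fixed random linear readout of model activations plus Gaussian noise — a
  stand-in for biological recordings with a known, recoverable structure.

Both are bitwise-deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .model_core import ActivationMatrix

__all__ = [
    "StimulusSpec",
    "ImageSet",
    "StimulusDataset",
    "RecordingsMatrix",
    "generate_dataset",
    "generate_recordings",
    "save_dataset",
    "load_dataset",
    "save_recordings",
    "load_recordings",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the procedural stimulus generator.

    Defaults mirror the shape of the common 10-class 32x32 RGB object
    benchmark (10 balanced classes, 3 channels); sample counts default to a
    desk-scale size that trains on one CPU in minutes.  ``noise_sd`` is
    additive Gaussian pixel noise on a [0, 1] intensity scale, clipped after
    addition.
    """

    n_classes: int = 10
    image_size: int = 32
    n_channels: int = 3
    samples_per_class_train: int = 150
    samples_per_class_test: int = 50
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.image_size < 4:
            raise ValueError(f"image_size must be >= 4, got {self.image_size}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.samples_per_class_train < 0 or self.samples_per_class_test < 0:
            raise ValueError("per-class sample counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")


@dataclass
class ImageSet:
    """A labeled set of images: ``images`` is (N, C, H, W) float32 in [0, 1]."""

    images: np.ndarray
    labels: np.ndarray
    n_classes: int
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if not self.ids:
            self.ids = [f"s{i:05d}" for i in range(len(self.images))]

    def __len__(self):
        return len(self.images)

    def subsample_per_class(self, per_class: int, seed: int = 0) -> "ImageSet":
        """Class-stratified subsample (used for fixed readout stimulus sets)."""
        rng = np.random.default_rng(seed)
        keep = []
        for c in range(self.n_classes):
            idx = np.flatnonzero(self.labels == c)
            if len(idx) < per_class:
                raise ValueError(f"class {c} has only {len(idx)} samples")
            keep.append(rng.choice(idx, size=per_class, replace=False))
        keep = np.sort(np.concatenate(keep))
        return ImageSet(
            self.images[keep], self.labels[keep], self.n_classes,
            [self.ids[i] for i in keep],
        )


@dataclass
class StimulusDataset:
    """Train/test split produced by :func:`generate_dataset`."""

    train: ImageSet
    test: ImageSet
    spec: StimulusSpec


@dataclass
class RecordingsMatrix:
    """Stimuli x neurons response matrix standing in for neural recordings."""

    values: np.ndarray
    region_label: str = "synthetic"

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# procedural pattern families
# ---------------------------------------------------------------------------

def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    return np.array(
        [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    )


def _shape_mask(kind: int, xx, yy, rng) -> np.ndarray:
    """Boolean foreground mask for one sample; coordinates in [-1, 1]."""
    cx, cy = rng.uniform(-0.25, 0.25, size=2)
    r = rng.uniform(0.35, 0.55)
    theta = rng.uniform(0, np.pi)
    if kind == 0:  # disk
        return (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
    if kind == 1:  # square
        return np.maximum(np.abs(xx - cx), np.abs(yy - cy)) < r
    if kind == 2:  # diamond
        return np.abs(xx - cx) + np.abs(yy - cy) < 1.2 * r
    if kind == 3:  # ring
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        return (d2 < (r + 0.12) ** 2) & (d2 > (r - 0.18) ** 2)
    if kind == 4:  # cross
        w = 0.18 + 0.1 * (r - 0.35)
        return (np.abs(xx - cx) < w) | (np.abs(yy - cy) < w)
    if kind == 5:  # oriented stripes, low frequency
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(4.0 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) + phase) > 0
    if kind == 6:  # oriented stripes, high frequency
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(8.0 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) + phase) > 0
    if kind == 7:  # checkerboard
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        return np.sin(5.0 * np.pi * xx + p1) * np.sin(5.0 * np.pi * yy + p2) > 0
    if kind == 8:  # wedge (triangle)
        return (yy - cy > -r) & (yy - cy < 1.6 * (r - np.abs(xx - cx)) - r)
    # kind == 9: oriented bar
    d = rng.uniform(-0.2, 0.2)
    return np.abs(xx * np.cos(theta) + yy * np.sin(theta) - d) < 0.22


def _render_class_sample(cls: int, n_classes: int, size: int, channels: int,
                         noise_sd: float, rng) -> np.ndarray:
    # Class identity = procedural shape/texture family; the color *family* is
    # only weakly class-linked (wide hue jitter around overlapping class hue
    # centers), so color alone cannot identify a class — mirroring natural
    # object categories, where shape carries the discriminative signal.
    ax = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(ax, ax)
    kind = cls % 10
    hue = (cls / max(n_classes, 1) + rng.uniform(-0.2, 0.2)) % 1.0
    fg = _hsv_to_rgb(hue, rng.uniform(0.55, 0.95), rng.uniform(0.75, 1.0))
    bg = _hsv_to_rgb(rng.uniform(0, 1), rng.uniform(0.1, 0.4), rng.uniform(0.1, 0.35))
    mask = _shape_mask(kind, xx, yy, rng)
    img = np.empty((3, size, size))
    for c in range(3):
        img[c] = np.where(mask, fg[c], bg[c])
    if channels == 1:
        img = img.mean(axis=0, keepdims=True)
    elif channels != 3:
        reps = int(np.ceil(channels / 3))
        img = np.tile(img, (reps, 1, 1))[:channels]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _generate_split(spec: StimulusSpec, per_class: int, rng, prefix: str) -> ImageSet:
    n = spec.n_classes * per_class
    images = np.empty((n, spec.n_channels, spec.image_size, spec.image_size),
                      dtype=np.float32)
    labels = np.empty(n, dtype=np.int64)
    ids = []
    i = 0
    for cls in range(spec.n_classes):
        for k in range(per_class):
            images[i] = _render_class_sample(
                cls, spec.n_classes, spec.image_size, spec.n_channels,
                spec.noise_sd, rng,
            )
            labels[i] = cls
            ids.append(f"{prefix}_c{cls:02d}_{k:04d}")
            i += 1
    return ImageSet(images, labels, spec.n_classes, ids)


def generate_dataset(spec: StimulusSpec) -> StimulusDataset:
    """Generate a balanced labeled train/test image dataset.

    Each class is a distinct procedural pattern family (shape x color x
    texture frequency) with per-sample position/scale/orientation jitter and
    additive clipped Gaussian pixel noise.  The train and test splits are
    drawn from disjoint random streams, so they share no images; identical
    specs (including seed) give bitwise-identical arrays.
    """
    ss = np.random.SeedSequence([int(spec.seed), 0x5D1])
    train_rng, test_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    train = _generate_split(spec, spec.samples_per_class_train, train_rng, "train")
    test = _generate_split(spec, spec.samples_per_class_test, test_rng, "test")
    return StimulusDataset(train=train, test=test, spec=spec)


def generate_recordings(activations: "ActivationMatrix | np.ndarray",
                        n_neurons: int, noise_sd: float = 0.0, seed: int = 0,
                        region_label: str = "synthetic") -> RecordingsMatrix:
    """Synthesize a recordings matrix as a linear readout of activations.

    ``recordings = activations @ M + noise`` with ``M`` a fixed random
    Gaussian map (scaled by 1/sqrt(features)) drawn from ``seed``.  With
    ``noise_sd=0`` every neuron is an exact linear combination of activation
    features, so a linear predictivity analysis can recover it perfectly.
    """
    values = getattr(activations, "values", activations)
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("activations must be a non-empty stimuli x features matrix")
    if n_neurons < 1:
        raise ValueError(f"n_neurons must be >= 1, got {n_neurons}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5D2]))
    n_features = values.shape[1]
    mapping = rng.standard_normal((n_features, n_neurons)) / np.sqrt(n_features)
    recorded = values @ mapping
    if noise_sd > 0:
        recorded = recorded + rng.normal(0.0, noise_sd, size=recorded.shape)
    return RecordingsMatrix(values=recorded, region_label=region_label)


# ---------------------------------------------------------------------------
# on-disk formats: per-class PNGs + CSV manifest; recordings as HDF5 or CSV
# ---------------------------------------------------------------------------

def save_dataset(dataset: StimulusDataset, outdir: str | Path) -> Path:
    from PIL import Image

    outdir = Path(outdir)
    rows = []
    for split_name, image_set in (("train", dataset.train), ("test", dataset.test)):
        for img, label, sid in zip(image_set.images, image_set.labels, image_set.ids):
            rel = Path(split_name) / f"class{label:02d}" / f"{sid}.png"
            path = outdir / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            arr = np.round(img * 255).astype(np.uint8)
            if arr.shape[0] == 1:
                Image.fromarray(arr[0], mode="L").save(path)
            else:
                Image.fromarray(arr[:3].transpose(1, 2, 0), mode="RGB").save(path)
            rows.append({"filename": str(rel), "label": int(label), "split": split_name})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir


def load_dataset(indir: str | Path, n_classes: int | None = None) -> StimulusDataset:
    from PIL import Image

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    n_classes = n_classes or int(manifest["label"].max()) + 1
    sets = {}
    for split_name, group in manifest.groupby("split"):
        images, labels, ids = [], [], []
        for _, row in group.iterrows():
            arr = np.asarray(Image.open(indir / row["filename"]), dtype=np.float32) / 255.0
            if arr.ndim == 2:
                arr = arr[None]
            else:
                arr = arr.transpose(2, 0, 1)
            images.append(arr)
            labels.append(int(row["label"]))
            ids.append(Path(row["filename"]).stem)
        sets[split_name] = ImageSet(
            np.stack(images), np.asarray(labels, dtype=np.int64), n_classes, ids
        )
    spec = StimulusSpec(n_classes=n_classes)  # original generator params not stored
    return StimulusDataset(train=sets["train"], test=sets["test"], spec=spec)


def save_recordings(recordings: RecordingsMatrix, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("recordings", data=recordings.values)
            ds.attrs["region_label"] = recordings.region_label
    else:
        pd.DataFrame(recordings.values).to_csv(path, index=False)
    return path


def load_recordings(path: str | Path, region_label: str = "synthetic") -> RecordingsMatrix:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["recordings"]
            return RecordingsMatrix(ds[()], ds.attrs.get("region_label", region_label))
    values = pd.read_csv(path).to_numpy(dtype=np.float64)
    return RecordingsMatrix(values, region_label)
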