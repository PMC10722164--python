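"""Build, train, and probe sequential convolutional classifiers.

A network is described by a :class:`NetworkSpec` (convolutional blocks with
optional batch norm and pooling, then dense layers), built deterministically
from a seed, trained with SGD + momentum, and probed by top-1 accuracy and by
activation extraction from any named layer.  Parameter accounting separates
*eligible* synapses — the multiplicative weights of convolutional and dense
layers, the ones the injury model may ablate — from ineligible parameters
(biases, normalization affine terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import yaml

from ._engine import (
    SGD,
    BatchNorm2d,
    Conv2d,
    Dense,
    Flatten,
    MaxPool2d,
    ReLU,
    Sequential,
    softmax_cross_entropy,
)

if TYPE_CHECKING:  # pragma: no cover
    from .injury import AblationMask

__all__ = [
    "ConvBlock",
    "NetworkSpec",
    "TrainingConfig",
    "ParameterAccount",
    "ActivationMatrix",
    "build_network",
    "count_parameters",
    "train",
    "evaluate_accuracy",
    "extract_activations",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ConvBlock:
    """One convolution (+ optional batch norm, ReLU, and trailing 2x2 pool)."""

    out_channels: int
    kernel_size: int = 3
    padding: int = 1
    batch_norm: bool = True
    pool: bool = False


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description; round-trips losslessly through YAML."""

    blocks: tuple[ConvBlock, ...]
    hidden: tuple[int, ...] = ()
    n_classes: int = 10
    input_shape: tuple[int, int, int] = (3, 32, 32)

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(
            b if isinstance(b, ConvBlock) else ConvBlock(**b) for b in self.blocks
        ))
        object.__setattr__(self, "hidden", tuple(self.hidden))
        object.__setattr__(self, "input_shape", tuple(self.input_shape))
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "blocks": [vars(b).copy() for b in self.blocks],
            "hidden": list(self.hidden),
            "n_classes": self.n_classes,
            "input_shape": list(self.input_shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            blocks=tuple(ConvBlock(**b) for b in d["blocks"]),
            hidden=tuple(d.get("hidden", ())),
            n_classes=d["n_classes"],
            input_shape=tuple(d.get("input_shape", (3, 32, 32))),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- stock architectures --------------------------------------------
    @classmethod
    def desk_scale(cls, n_classes: int = 10,
                   input_shape: tuple[int, int, int] = (3, 32, 32)) -> "NetworkSpec":
        """Three conv blocks (16/32/64) + one dense hidden layer (~90k weights).

        Small enough to train on one CPU in minutes, deep enough to expose
        layered readouts for representational analyses.
        """
        return cls(
            blocks=(
                ConvBlock(16, pool=True),
                ConvBlock(32, pool=True),
                ConvBlock(64, pool=True),
            ),
            hidden=(64,),
            n_classes=n_classes,
            input_shape=input_shape,
        )

    @classmethod
    def vgg19_bn(cls, n_classes: int = 10,
                 input_shape: tuple[int, int, int] = (3, 32, 32)) -> "NetworkSpec":
        """VGG19 with batch normalization, 32x32 variant (~20.04M parameters).

        Sixteen 3x3 conv layers in five pooled blocks (64/128/256/512/512
        channels) and a single 512 -> n_classes head.  Used for parameter
        accounting at full scale; training it is out of desk-scale reach.
        """
        widths = [64, 64, None, 128, 128, None, 256, 256, 256, 256, None,
                  512, 512, 512, 512, None, 512, 512, 512, 512, None]
        blocks = []
        for i, w in enumerate(widths):
            if w is None:
                continue
            pool = i + 1 < len(widths) and widths[i + 1] is None
            blocks.append(ConvBlock(w, pool=pool))
        return cls(blocks=tuple(blocks), hidden=(), n_classes=n_classes,
                   input_shape=input_shape)


@dataclass(frozen=True)
class TrainingConfig:
    """SGD hyper-parameters; defaults are the standard protocol this model
    family is trained with (lr 0.001, momentum 0.9, batch 128; 3 epochs is
    the retraining budget after each injury step)."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 128
    epochs: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class ParameterAccount:
    """Per-layer eligible (ablatable) vs ineligible parameter counts."""

    eligible: dict[str, int]
    ineligible: dict[str, int]
    policy: str = "conv_dense_weights"

    @property
    def total_eligible(self) -> int:
        return int(sum(self.eligible.values()))

    @property
    def total_ineligible(self) -> int:
        return int(sum(self.ineligible.values()))

    @property
    def total(self) -> int:
        return self.total_eligible + self.total_ineligible


@dataclass
class ActivationMatrix:
    """Stimuli x features activations from one named layer."""

    values: np.ndarray
    layer_name: str
    stimulus_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("activations must be 2-D (stimuli x features)")
        if not self.stimulus_ids:
            self.stimulus_ids = [f"s{i:05d}" for i in range(len(self.values))]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    def to_hdf5(self, path: str | Path) -> Path:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("activations", data=self.values)
            ds.attrs["layer_name"] = self.layer_name
            f.create_dataset("stimulus_ids",
                             data=np.array(self.stimulus_ids, dtype="S"))
            if self.labels is not None:
                f.create_dataset("labels", data=self.labels)
        return path

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "ActivationMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            labels = f["labels"][()] if "labels" in f else None
            return cls(
                values=f["activations"][()],
                layer_name=f["activations"].attrs["layer_name"],
                stimulus_ids=[s.decode() for s in f["stimulus_ids"][()]],
                labels=labels,
            )


# ---------------------------------------------------------------------------
# building & accounting
# ---------------------------------------------------------------------------

def build_network(spec: NetworkSpec, seed: int = 0,
                  dtype=np.float32) -> Sequential:
    """Construct a freshly initialized network from a spec.

    Weight initialization is He-normal from a generator seeded by ``seed``;
    identical (spec, seed) pairs give bitwise-identical weights.  Shape
    inconsistencies (e.g. pooling an odd spatial size) are rejected with the
    index of the offending layer.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11E7]))
    layers = []
    c, h, w = spec.input_shape
    in_ch = c
    for i, blk in enumerate(spec.blocks, start=1):
        layers.append(Conv2d(f"conv{i}", in_ch, blk.out_channels,
                             blk.kernel_size, blk.padding, rng=rng, dtype=dtype))
        if blk.batch_norm:
            layers.append(BatchNorm2d(f"bn{i}", blk.out_channels, dtype=dtype))
        layers.append(ReLU(f"relu{i}"))
        if blk.pool:
            layers.append(MaxPool2d(f"pool{i}"))
        in_ch = blk.out_channels
    layers.append(Flatten("flatten"))
    # feature count after the conv stack; report the offending layer on error
    shape = spec.input_shape
    for i, layer in enumerate(layers[:-1]):
        try:
            shape = layer.output_shape(shape)
        except ValueError as exc:
            raise ValueError(f"layer {i} ({layer.name}): {exc}") from exc
    n_features = int(np.prod(shape))
    for j, width in enumerate(spec.hidden, start=1):
        layers.append(Dense(f"fc{j}", n_features, width, rng=rng, dtype=dtype))
        layers.append(ReLU(f"relu_fc{j}"))
        n_features = width
    layers.append(Dense("output", n_features, spec.n_classes, rng=rng, dtype=dtype))
    net = Sequential(layers, spec.input_shape)
    net.spec = spec
    return net


def count_parameters(network: Sequential,
                     policy: str = "conv_dense_weights") -> ParameterAccount:
    """Exact per-layer parameter accounting under an eligibility policy.

    ``"conv_dense_weights"`` (default): eligible synapses are exactly the
    multiplicative weight tensors of convolutional and dense layers; biases
    and normalization parameters are ineligible.  ``"all"``: every trainable
    parameter counts as eligible (the alternative reading under which a
    network's full parameter total is the ablation base).
    """
    if policy not in {"conv_dense_weights", "all"}:
        raise ValueError(f"unknown eligibility policy {policy!r}")
    eligible: dict[str, int] = {}
    ineligible: dict[str, int] = {}
    for layer in network.layers:
        for key, param in layer.params.items():
            tag = f"{layer.name}.{key}"
            if policy == "all" or (layer.has_weight and key == "W"):
                eligible[tag] = int(param.size)
            else:
                ineligible[tag] = int(param.size)
    return ParameterAccount(eligible=eligible, ineligible=ineligible, policy=policy)


# ---------------------------------------------------------------------------
# training & evaluation
# ---------------------------------------------------------------------------

def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dataset, "images"):
        return dataset.images, dataset.labels
    images, labels = dataset
    return np.asarray(images), np.asarray(labels)


def _check_labels(network: Sequential, labels: np.ndarray) -> None:
    n_classes = network.layers[-1].out_features
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(
            f"label outside class range [0, {n_classes}): "
            f"min={labels.min()}, max={labels.max()}"
        )


def train(network: Sequential, dataset, config: TrainingConfig,
          mask: "AblationMask | None" = None) -> list[dict]:
    """Train in place with SGD + momentum; returns per-epoch history.

    When ``mask`` is given (and non-empty), ablated entries are excluded from
    learning by a two-sided pin: their gradients are zeroed before the
    optimizer step *and* their values are reset to exactly zero after it, so
    neither momentum carry-over nor any other optimizer state can revive a
    dead synapse.  History entries carry the mean minibatch loss and the
    training accuracy accumulated over the epoch's minibatches.
    """
    images, labels = _as_arrays(dataset)
    if len(images) == 0:
        raise ValueError("training dataset is empty")
    _check_labels(network, labels)
    if mask is not None:
        mask.validate_against(network)

    opt = SGD(network, lr=config.learning_rate, momentum=config.momentum)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7124]))
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(images))
        losses, correct = [], 0
        for start in range(0, len(images), config.batch_size):
            idx = order[start : start + config.batch_size]
            x = images[idx]
            y = labels[idx]
            logits = network.forward(x, training=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, y)
            network.backward(dlogits)
            if mask is not None:
                mask.zero_grads(network)
            opt.step()
            if mask is not None:
                mask.zero_weights(network)
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == y).sum())
        history.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": correct / len(images),
        })
    return history


def evaluate_accuracy(network: Sequential, dataset, batch_size: int = 512) -> float:
    """Top-1 accuracy in [0, 1]; inference mode, deterministic for fixed weights."""
    images, labels = _as_arrays(dataset)
    if len(images) == 0:
        raise ValueError("evaluation dataset is empty")
    _check_labels(network, labels)
    correct = 0
    for start in range(0, len(images), batch_size):
        logits = network.forward(images[start : start + batch_size], training=False)
        correct += int((logits.argmax(axis=1) == labels[start : start + batch_size]).sum())
    return correct / len(images)


def extract_activations(network: Sequential, images, layer_name: str,
                        labels: np.ndarray | None = None,
                        stimulus_ids: Iterable[str] | None = None,
                        batch_size: int = 512) -> ActivationMatrix:
    """Forward images in inference mode and collect one layer's activations.

    ``layer_name`` may be ``"penultimate"`` (input to the final dense
    transform).  Rows follow input order; features are the flattened layer
    output.  Unknown names are rejected with the list of valid ones.
    """
    if hasattr(images, "images"):
        if labels is None:
            labels = images.labels
        if stimulus_ids is None:
            stimulus_ids = getattr(images, "ids", None)
        images = images.images
    try:
        resolved = network.resolve_layer(layer_name)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    chunks = []
    for start in range(0, len(images), batch_size):
        _, captured = network.forward(
            images[start : start + batch_size], training=False, capture={resolved}
        )
        chunks.append(captured[resolved].reshape(len(captured[resolved]), -1))
    values = np.concatenate(chunks, axis=0)
    return ActivationMatrix(
        values=values,
        layer_name=resolved,
        stimulus_ids=list(stimulus_ids) if stimulus_ids is not None else [],
        labels=None if labels is None else np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# checkpoints: weights (+ optional mask) in one .npz file
# ---------------------------------------------------------------------------

def save_checkpoint(network: Sequential, path: str | Path,
                    mask: "AblationMask | None" = None) -> Path:
    path = Path(path)
    payload: dict[str, np.ndarray] = {}
    for lname, lstate in network.state_dict().items():
        for key, arr in lstate.items():
            payload[f"param/{lname}/{key}"] = arr
    if mask is not None:
        for lname, m in mask.masks.items():
            payload[f"mask/{lname}"] = m
        payload["mask_meta"] = np.array([mask.iteration, mask.seed or 0])
    np.savez(path, **payload)
    return path


def load_checkpoint(network: Sequential, path: str | Path):
    """Load weights (and the ablation mask, if stored) into ``network``.

    Returns the mask or ``None``.
    """
    from .injury import AblationMask

    data = np.load(Path(path))
    state: dict[str, dict[str, np.ndarray]] = {}
    masks: dict[str, np.ndarray] = {}
    meta = None
    for key in data.files:
        if key.startswith("param/"):
            _, lname, pkey = key.split("/", 2)
            state.setdefault(lname, {})[pkey] = data[key]
        elif key.startswith("mask/"):
            masks[key.split("/", 1)[1]] = data[key]
        elif key == "mask_meta":
            meta = data[key]
    network.load_state_dict(state)
    if masks:
        return AblationMask(masks=masks, iteration=int(meta[0]), seed=int(meta[1]))
    return None
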