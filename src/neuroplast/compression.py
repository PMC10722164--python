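"""Structured L1 filter pruning to a target FLOP speedup.

The compressed baseline models a constrained "cognitive reserve": whole
convolutional filters (and dense hidden units) with the smallest L1 weight
norms are removed greedily, one at a time with FLOP re-evaluation, with
dependency propagation through sequential architectures — removing a filter
deletes its bias and normalization parameters and the matching input channels
(or dense columns) of the next weighted layer — until the forward-pass cost
has dropped by the requested factor.  The pruned network is then fine-tuned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._engine import BatchNorm2d, Conv2d, Dense, Flatten, MaxPool2d, Sequential
from .model_core import ConvBlock, NetworkSpec, TrainingConfig, train

__all__ = [
    "CompressionPlan",
    "FlopAccount",
    "CompressionError",
    "estimate_flops",
    "network_to_spec",
    "rank_filters",
    "compress_to_speedup",
]


@dataclass
class FlopAccount:
    """Per-layer multiply-accumulate counts for one forward pass.

    The convention is MACs: a k x k convolution producing ``out_c`` maps of
    area ``A`` from ``in_c`` channels costs ``k*k*in_c*out_c*A``; a dense
    layer costs ``in * out``.  Nonlinearities, pooling and normalization are
    counted as zero.
    """

    per_layer: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.per_layer.values()))


@dataclass
class CompressionPlan:
    """Removal record: per layer, unit indices in original coordinates,
    in the order they were removed."""

    removed: dict[str, list[int]] = field(default_factory=dict)
    target: float = 1.0
    achieved: float = 1.0

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())


class CompressionError(RuntimeError):
    """Target speedup unreachable; carries the best achievable factor."""

    def __init__(self, target: float, best_achievable: float):
        super().__init__(
            f"target speedup {target:g}x unreachable under pruning constraints; "
            f"best achievable {best_achievable:.3f}x"
        )
        self.target = target
        self.best_achievable = best_achievable


def estimate_flops(spec: NetworkSpec,
                   input_shape: tuple[int, int, int] | None = None) -> FlopAccount:
    """FLOP (MAC) account of one forward pass of a spec at an input shape."""
    c, h, w = input_shape or spec.input_shape
    per_layer: dict[str, int] = {}
    for i, blk in enumerate(spec.blocks, start=1):
        hout = h + 2 * blk.padding - blk.kernel_size + 1
        wout = w + 2 * blk.padding - blk.kernel_size + 1
        per_layer[f"conv{i}"] = (
            blk.kernel_size * blk.kernel_size * c * blk.out_channels * hout * wout
        )
        c, h, w = blk.out_channels, hout, wout
        if blk.pool:
            h, w = h // 2, w // 2
    n_features = c * h * w
    for j, width in enumerate(spec.hidden, start=1):
        per_layer[f"fc{j}"] = n_features * width
        n_features = width
    per_layer["output"] = n_features * spec.n_classes
    return FlopAccount(per_layer=per_layer)


def network_to_spec(network: Sequential) -> NetworkSpec:
    """Reconstruct a NetworkSpec from a (possibly pruned) network's layers."""
    blocks: list[ConvBlock] = []
    hidden: list[int] = []
    n_classes = None
    for layer in network.layers:
        if isinstance(layer, Conv2d):
            blocks.append(ConvBlock(
                out_channels=layer.out_channels,
                kernel_size=layer.kernel_size,
                padding=layer.padding,
                batch_norm=False,
            ))
        elif isinstance(layer, BatchNorm2d):
            blocks[-1] = ConvBlock(**{**vars(blocks[-1]), "batch_norm": True})
        elif isinstance(layer, MaxPool2d):
            blocks[-1] = ConvBlock(**{**vars(blocks[-1]), "pool": True})
        elif isinstance(layer, Dense):
            if layer.name == "output":
                n_classes = layer.out_features
            else:
                hidden.append(layer.out_features)
    return NetworkSpec(
        blocks=tuple(blocks), hidden=tuple(hidden),
        n_classes=n_classes, input_shape=network.input_shape,
    )


def _prunable_layers(network: Sequential) -> list:
    """Conv layers and hidden dense layers (never the output layer)."""
    return [l for l in network.weight_layers() if l.name != "output"]


def rank_filters(network: Sequential, normalize: bool = False
                 ) -> list[tuple[str, int, float]]:
    """Global ascending ordering of (layer, unit) by L1 norm of unit weights.

    Conv units are filters (one output channel's kernel stack), dense units
    are rows of the weight matrix.  ``normalize`` divides by unit size
    (per-layer-comparable mode); the default compares raw norms, the usual
    magnitude-pruning convention.  Ties break by (layer index, unit index),
    giving a stable total order.
    """
    entries = []
    layer_order = {l.name: i for i, l in enumerate(network.layers)}
    for layer in _prunable_layers(network):
        w = layer.params["W"]
        flat = np.abs(w.reshape(w.shape[0], -1)).sum(axis=1)
        if normalize:
            flat = flat / w[0].size
        for idx, norm in enumerate(flat):
            entries.append((layer.name, idx, float(norm)))
    entries.sort(key=lambda e: (e[2], layer_order[e[0]], e[1]))
    return entries


def _next_weight_layer(network: Sequential, name: str):
    """The next conv/dense layer downstream, plus whether a Flatten intervenes."""
    seen = False
    through_flatten = False
    for layer in network.layers:
        if layer.name == name:
            seen = True
            continue
        if not seen:
            continue
        if isinstance(layer, Flatten):
            through_flatten = True
        if layer.has_weight:
            return layer, through_flatten
    return None, through_flatten


def _spatial_at_flatten(network: Sequential) -> int:
    """H*W of the feature map entering Flatten (for conv->dense propagation)."""
    shape = network.input_shape
    for layer in network.layers:
        if isinstance(layer, Flatten):
            return int(shape[1] * shape[2])
        shape = layer.output_shape(shape)
    raise ValueError("network has no Flatten layer")


def _bn_after(network: Sequential, conv_name: str):
    idx = [l.name for l in network.layers].index(conv_name)
    for layer in network.layers[idx + 1:]:
        if isinstance(layer, BatchNorm2d):
            return layer
        if layer.has_weight:
            break
    return None


def _remove_unit(network: Sequential, layer_name: str, idx: int) -> None:
    """Delete one output unit and propagate through the downstream layer."""
    layer = network[layer_name]
    if layer.params["W"].shape[0] <= 1:
        raise ValueError(f"cannot remove the last unit of layer {layer_name!r}")
    spatial = _spatial_at_flatten(network) if isinstance(layer, Conv2d) else None
    layer.params["W"] = np.delete(layer.params["W"], idx, axis=0)
    layer.params["b"] = np.delete(layer.params["b"], idx)
    if isinstance(layer, Conv2d):
        layer.out_channels -= 1
        bn = _bn_after(network, layer_name)
        if bn is not None:
            for key in ("gamma", "beta"):
                bn.params[key] = np.delete(bn.params[key], idx)
            bn.running_mean = np.delete(bn.running_mean, idx)
            bn.running_var = np.delete(bn.running_var, idx)
            bn.channels -= 1
    else:
        layer.out_features -= 1
    nxt, through_flatten = _next_weight_layer(network, layer_name)
    if nxt is None:
        return
    if isinstance(nxt, Conv2d):
        nxt.params["W"] = np.delete(nxt.params["W"], idx, axis=1)
        nxt.in_channels -= 1
    else:
        if isinstance(layer, Conv2d) and through_flatten:
            cols = np.arange(idx * spatial, (idx + 1) * spatial)
        else:
            cols = [idx]
        nxt.params["W"] = np.delete(nxt.params["W"], cols, axis=1)
        nxt.in_features = nxt.params["W"].shape[1]


def compress_to_speedup(network: Sequential, target: float,
                        finetune_config: TrainingConfig | None = None,
                        dataset=None, normalize: bool = False,
                        ) -> tuple[Sequential, CompressionPlan]:
    """Prune lowest-L1 units until FLOPs drop by ``target``x, then fine-tune.

    Greedy: one unit at a time, globally lowest L1 norm first, FLOPs
    re-evaluated after every removal; the output layer is never touched and
    no layer is emptied.  Raises :class:`CompressionError` (carrying the best
    achievable factor) if the target cannot be reached.  If ``dataset`` is
    given, the pruned network is fine-tuned with ``finetune_config``
    (defaults to the standard training configuration).
    """
    if target < 1.0:
        raise ValueError(f"target speedup must be >= 1, got {target}")
    pruned = network.copy()
    base_flops = estimate_flops(network_to_spec(pruned)).total
    plan = CompressionPlan(target=float(target))
    # alive[layer] maps current index -> original index
    alive = {l.name: list(range(l.params["W"].shape[0]))
             for l in _prunable_layers(pruned)}
    achieved = 1.0
    while achieved < target:
        candidates = [
            (name, idx, norm) for name, idx, norm in rank_filters(pruned, normalize)
            if pruned[name].params["W"].shape[0] > 1
        ]
        if not candidates:
            raise CompressionError(target, achieved)
        name, idx, _ = candidates[0]
        _remove_unit(pruned, name, idx)
        plan.removed.setdefault(name, []).append(alive[name].pop(idx))
        achieved = base_flops / estimate_flops(network_to_spec(pruned)).total
    plan.achieved = float(achieved)
    # the pruned stack is a fresh graph; rebuild shape bookkeeping
    pruned = Sequential(pruned.layers, pruned.input_shape)
    pruned.spec = network_to_spec(pruned)
    if dataset is not None:
        train(pruned, dataset.train, finetune_config or TrainingConfig())
    return pruned, plan
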