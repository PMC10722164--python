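"""Progressive, irreversible, uniformly dispersed synaptic ablation.

The injury model removes a fraction ``gamma`` of the *surviving* eligible
weights at each iteration, pooled globally across all convolutional and dense
weight tensors, so after ``n`` iterations the cumulative injured fraction is
``1 - (1 - gamma)^n``.  Ablation is irreversible: the mask is monotone (bits
only ever turn on) and any network the mask is applied to carries an exact
zero at every ablated coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._engine import Sequential

__all__ = [
    "InjurySchedule",
    "AblationMask",
    "cumulative_injured_fraction",
    "remaining_parameter_count",
    "apply_injury_step",
    "apply_mask",
]


def _validate_gamma(gamma: float) -> None:
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")


def _validate_n(n: int) -> None:
    if n < 0 or int(n) != n:
        raise ValueError(f"n must be a non-negative integer, got {n}")


@dataclass(frozen=True)
class InjurySchedule:
    """Per-iteration ablation rate ``gamma`` and iteration count.

    Defaults (gamma=0.2, 15 iterations) take the cumulative injured fraction
    from 20% at the first iteration to 96.5% at the last.
    """

    gamma: float = 0.2
    n_iterations: int = 15

    def __post_init__(self):
        _validate_gamma(self.gamma)
        _validate_n(self.n_iterations)

    def cumulative_fractions(self) -> np.ndarray:
        """Cumulative injured fraction after iterations 1..n."""
        n = np.arange(1, self.n_iterations + 1)
        return 1.0 - (1.0 - self.gamma) ** n


def cumulative_injured_fraction(gamma: float, n: int) -> float:
    """Cumulative fraction of initial synapses dead after ``n`` iterations."""
    _validate_gamma(gamma)
    _validate_n(n)
    return 1.0 - (1.0 - gamma) ** n


def remaining_parameter_count(total: float, gamma: float, n: int) -> float:
    """Surviving parameter count ``total * (1 - gamma)^n`` (continuous)."""
    _validate_gamma(gamma)
    _validate_n(n)
    if total < 0:
        raise ValueError(f"total must be non-negative, got {total}")
    return total * (1.0 - gamma) ** n


@dataclass
class AblationMask:
    """Cumulative boolean map over eligible weight tensors (True = dead).

    ``masks`` is keyed by layer name and shaped like that layer's weight
    tensor.  The mask is the authoritative record of which synapses have
    died; :func:`apply_mask` imprints it on a network.
    """

    masks: dict[str, np.ndarray]
    iteration: int = 0
    seed: int | None = None

    @classmethod
    def empty_for(cls, network: Sequential, seed: int | None = None) -> "AblationMask":
        return cls(
            masks={
                l.name: np.zeros(l.params["W"].shape, dtype=bool)
                for l in network.weight_layers()
            },
            iteration=0,
            seed=seed,
        )

    # -- bookkeeping ----------------------------------------------------
    @property
    def n_total(self) -> int:
        return int(sum(m.size for m in self.masks.values()))

    @property
    def n_ablated(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))

    @property
    def n_surviving(self) -> int:
        return self.n_total - self.n_ablated

    @property
    def injured_fraction(self) -> float:
        return self.n_ablated / self.n_total if self.n_total else 0.0

    def is_empty(self) -> bool:
        return self.n_ablated == 0

    def copy(self) -> "AblationMask":
        return AblationMask(
            masks={k: v.copy() for k, v in self.masks.items()},
            iteration=self.iteration,
            seed=self.seed,
        )

    def per_layer_counts(self) -> dict[str, tuple[int, int]]:
        """layer -> (ablated, total)."""
        return {k: (int(m.sum()), int(m.size)) for k, m in self.masks.items()}

    def includes(self, other: "AblationMask") -> bool:
        """Set inclusion: every synapse dead in ``other`` is dead here too."""
        return all(
            bool(np.all(self.masks[k] | ~other.masks[k]))
            for k in self.masks
        )

    # -- interaction with networks --------------------------------------
    def validate_against(self, network: Sequential) -> None:
        for layer in network.weight_layers():
            m = self.masks.get(layer.name)
            if m is None:
                raise ValueError(f"mask missing tensor for layer {layer.name!r}")
            if m.shape != layer.params["W"].shape:
                raise ValueError(
                    f"mask shape mismatch for tensor {layer.name!r}: "
                    f"{m.shape} vs {layer.params['W'].shape}"
                )

    def zero_weights(self, network: Sequential) -> None:
        for layer in network.weight_layers():
            layer.params["W"][self.masks[layer.name]] = 0.0

    def zero_grads(self, network: Sequential) -> None:
        for layer in network.weight_layers():
            if "W" in layer.grads:
                layer.grads["W"][self.masks[layer.name]] = 0.0


def apply_injury_step(mask: AblationMask, gamma: float,
                      rng: np.random.Generator,
                      rounding: str = "nearest") -> AblationMask:
    """One iteration of uniformly dispersed ablation; returns a new mask.

    Exactly ``round(gamma * surviving)`` surviving entries — pooled across
    all eligible tensors — are drawn uniformly without replacement and marked
    dead.  Previously dead entries are untouched (monotonicity).  ``rounding``
    is ``"nearest"`` (ties to even, the unbiased default), ``"floor"`` or
    ``"ceil"``.  Deterministic given the generator state.
    """
    _validate_gamma(gamma)
    new = mask.copy()
    order = sorted(new.masks)  # stable global coordinate order
    flat = np.concatenate([new.masks[k].ravel() for k in order])
    surviving = np.flatnonzero(~flat)
    if surviving.size == 0:
        warnings.warn("no surviving synapses; injury step is a no-op")
        return new
    if rounding == "nearest":
        n_new = int(round(gamma * surviving.size))
    elif rounding == "floor":
        n_new = int(np.floor(gamma * surviving.size))
    elif rounding == "ceil":
        n_new = int(np.ceil(gamma * surviving.size))
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    n_new = min(n_new, surviving.size)
    chosen = rng.choice(surviving, size=n_new, replace=False)
    flat[chosen] = True
    offset = 0
    for k in order:
        m = new.masks[k]
        m[...] = flat[offset : offset + m.size].reshape(m.shape)
        offset += m.size
    new.iteration = mask.iteration + 1
    assert new.includes(mask), "ablation mask must be monotone"
    return new


def apply_mask(network: Sequential, mask: AblationMask) -> Sequential:
    """Imprint the mask: ablated coordinates set to exactly 0, rest untouched."""
    mask.validate_against(network)
    mask.zero_weights(network)
    return network


def mask_summary_frame(masks: list[AblationMask]):
    """Mask-summary table: iteration, per-layer ablated counts, cumulative fraction."""
    import pandas as pd

    rows = []
    for m in masks:
        row = {"iteration": m.iteration, "cumulative_fraction": m.injured_fraction}
        for layer, (ablated, total) in m.per_layer_counts().items():
            row[f"ablated_{layer}"] = ablated
        rows.append(row)
    return pd.DataFrame(rows)
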