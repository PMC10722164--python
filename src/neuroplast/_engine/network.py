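"""Sequential network container: named layers, state dicts, activation capture."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer

__all__ = ["Sequential"]


class Sequential:
    """An ordered stack of named layers forming a classifier.

    ``penultimate`` is accepted as a layer-name alias everywhere activations
    are requested; it resolves to the input of the final dense transform,
    the conventional readout point for representational analyses.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int, int]):
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self._by_name = {l.name: l for l in layers}
        # shape check at build time; raises with the offending layer's index
        shape = self.input_shape
        self._shapes = {}
        for i, layer in enumerate(layers):
            try:
                shape = layer.output_shape(shape)
            except ValueError as exc:
                raise ValueError(f"layer {i} ({layer.name}): {exc}") from exc
            self._shapes[layer.name] = shape

    # -- introspection --------------------------------------------------
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __getitem__(self, name: str) -> Layer:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def penultimate_name(self) -> str:
        """Name of the layer feeding the final dense (classification) layer."""
        last = self.layers[-1]
        if not last.has_weight:
            raise ValueError("network does not end in a dense layer")
        idx = len(self.layers) - 2
        if idx < 0:
            raise ValueError("network has a single layer; no penultimate point")
        return self.layers[idx].name

    def resolve_layer(self, name: str) -> str:
        if name == "penultimate":
            return self.penultimate_name
        if name not in self._by_name:
            raise KeyError(
                f"unknown layer {name!r}; valid names: {self.layer_names()} "
                f"(or 'penultimate')"
            )
        return name

    def weight_layers(self) -> list[Layer]:
        """Layers carrying an ablatable multiplicative weight tensor."""
        return [l for l in self.layers if l.has_weight]

    # -- execution ------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                capture: set[str] | None = None):
        """Run the network; optionally capture named layers' outputs.

        Returns ``logits`` or ``(logits, {name: activation})`` when
        ``capture`` is given.
        """
        captured = {}
        out = x
        for layer in self.layers:
            out = layer.forward(out, training=training)
            if capture and layer.name in capture:
                captured[layer.name] = out
        if capture is not None:
            return out, captured
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    # -- state ----------------------------------------------------------
    def state_dict(self) -> dict[str, dict[str, np.ndarray]]:
        return {l.name: l.state() for l in self.layers if l.state()}

    def load_state_dict(self, state: dict[str, dict[str, np.ndarray]]) -> None:
        for name, layer_state in state.items():
            self._by_name[name].load_state(layer_state)

    def copy(self) -> "Sequential":
        return copy.deepcopy(self)
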