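"""Model containers: Sequential chains and branching composite blocks.

``Sequential`` supports training (backward) when every member layer does.
Composite blocks (residual bottleneck, fire module, inception module) are
inference + parameter-counting structures used by the large backbones.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param, ReLU


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = "seq"):
        self.layers = list(layers)
        self.name = name

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def inventory(self):
        out = []
        for layer in self.layers:
            out.extend(layer.inventory())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad = None

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{i}:{p.name}": p.value.copy()
                for i, p in enumerate(self.params())}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.asarray(weights[f"{i}:{p.name}"], dtype=np.float32)


class Residual(Layer):
    """out = relu(main(x) + shortcut(x)); shortcut may be identity (None)."""

    def __init__(self, main: Sequential, shortcut: Sequential | None = None):
        self.main = main
        self.shortcut = shortcut
        self.relu = ReLU()

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def forward(self, x, training=False):
        y = self.main.forward(x, training=training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training=training)
        return self.relu.forward(y + s, training=training)

    def inventory(self):
        inv = self.main.inventory()
        if self.shortcut is not None:
            inv += self.shortcut.inventory()
        return inv + ["ReLU"]


class Parallel(Layer):
    """Run branches on the same input and concatenate along channels."""

    def __init__(self, branches: list[Sequential]):
        self.branches = branches

    def params(self):
        out = []
        for b in self.branches:
            out.extend(b.params())
        return out

    def forward(self, x, training=False):
        return np.concatenate(
            [b.forward(x, training=training) for b in self.branches], axis=-1)

    def inventory(self):
        out = []
        for b in self.branches:
            out.extend(b.inventory())
        return out
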