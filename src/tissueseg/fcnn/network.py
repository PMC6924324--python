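"""Network specification, construction and checkpointing.

The default architecture is a seven-convolution fully convolutional
classifier with three interleaved 2x2 max-pool stages, so the output grid is
downsampled 8x relative to the input.  All convolutions are same-padded and
stride 1; ReLU everywhere except a final channel softmax producing two class
maps (non-tissue, tissue) that sum to one per position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .layers import Conv2D, MaxPool2, softmax

#: (type, kernel, filters) rows of the default architecture
DEFAULT_LAYERS = (
    ("conv", 5, 16),
    ("pool",),
    ("conv", 5, 32),
    ("pool",),
    ("conv", 3, 64),
    ("pool",),
    ("conv", 3, 64),
    ("conv", 3, 1024),
    ("conv", 1, 512),
    ("conv", 1, 2),
)


@dataclass(frozen=True)
class NetworkSpec:
    """Layer list of the fully convolutional classifier."""

    layers: tuple = DEFAULT_LAYERS
    in_channels: int = 3

    def __post_init__(self):
        convs = [l for l in self.layers if l[0] == "conv"]
        pools = [l for l in self.layers if l[0] == "pool"]
        if len(convs) + len(pools) != len(self.layers):
            raise ValueError("layers must be 'conv' or 'pool' entries")
        if not convs or convs[-1][2] != 2:
            raise ValueError("last convolution must emit 2 class channels")
        for l in convs:
            if len(l) != 3 or l[1] % 2 != 1 or l[2] < 1:
                raise ValueError(f"malformed conv entry: {l}")

    @property
    def downsample_factor(self) -> int:
        return 2 ** sum(1 for l in self.layers if l[0] == "pool")

    @property
    def receptive_field(self) -> int:
        rf, stride = 1, 1
        for l in self.layers:
            if l[0] == "conv":
                rf += (l[1] - 1) * stride
            else:
                rf += stride
                stride *= 2
        return rf

    @property
    def min_input(self) -> int:
        """Smallest input side that still yields one output position."""
        return self.downsample_factor

    def param_count(self) -> int:
        total, cin = 0, self.in_channels
        for l in self.layers:
            if l[0] == "conv":
                _, k, cout = l
                total += k * k * cin * cout + cout
                cin = cout
        return total


class TissueFCNN:
    """The trainable model: an ordered stack of conv / pool layers."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.layers = []
        cin = spec.in_channels
        convs = [l for l in spec.layers if l[0] == "conv"]
        n_done = 0
        for l in spec.layers:
            if l[0] == "conv":
                n_done += 1
                relu = n_done < len(convs)  # softmax replaces ReLU on the last
                self.layers.append(Conv2D(l[1], cin, l[2], rng, relu=relu))
                cin = l[2]
            else:
                self.layers.append(MaxPool2())

    # ------------------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W, 3) float32 in [0, 1] -> logits (N, H/8, W/8, 2)."""
        if x.ndim != 4 or x.shape[3] != self.spec.in_channels:
            raise ValueError("expected an (N, H, W, C) batch")
        if min(x.shape[1], x.shape[2]) < self.spec.min_input:
            raise ValueError(
                f"input sides must be >= {self.spec.min_input} px"
            )
        y = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            y = layer.forward(y, train=train)
        return y

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; channel 1 is tissue."""
        return softmax(self.forward_logits(x, train=False))

    def backward(self, dlogits: np.ndarray):
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    # ------------------------------------------------------------------
    def parameters(self):
        """Flat list of (layer_index, name, array) for the optimizer."""
        out = []
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params():
                out.append((i, name, arr))
        return out

    def gradients(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, arr in layer.grads():
                out.append((i, name, arr))
        return out

    def state_dict(self):
        return {f"{i}.{name}": arr.copy() for i, name, arr in self.parameters()}

    def load_state_dict(self, state):
        for i, name, arr in self.parameters():
            arr[...] = state[f"{i}.{name}"]

    def param_count(self) -> int:
        return sum(arr.size for _, _, arr in self.parameters())

    # ------------------------------------------------------------------
    def save(self, path):
        """Checkpoint: spec + weights + seed in one .npz file."""
        meta = json.dumps(
            {"layers": [list(l) for l in self.spec.layers],
             "in_channels": self.spec.in_channels,
             "seed": self.seed}
        )
        arrays = {f"{i}.{name}": arr for i, name, arr in self.parameters()}
        np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                            **arrays)

    @classmethod
    def load(cls, path) -> "TissueFCNN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(
                NetworkSpec(tuple(tuple(l) for l in meta["layers"]),
                            meta["in_channels"]),
                meta["seed"],
            )
            state = {k: data[k] for k in data.files if k != "__meta__"}
        model.load_state_dict(state)
        return model


def build_network(spec: NetworkSpec = None, seed: int = 0) -> TissueFCNN:
    """Construct a seeded, He-initialized model from a layer specification."""
    return TissueFCNN(spec or NetworkSpec(), seed)
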