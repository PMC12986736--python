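"""Nested-skip encoder-decoder segmentation network (U-Net++ topology).

The network is a four-level encoder-decoder whose skip connections are
re-designed as a dense grid of intermediate nodes: node X(i, j) at depth i
and skip stage j receives the concatenation of all previous nodes at the
same depth, X(i, 0..j-1), plus the 2x-upsampled output of X(i+1, j-1). Each
node is two (conv 3x3 -> batch norm -> ReLU) units. A He-initialized 1x1
convolution head produces one sigmoid logit per pixel; the head must carry
gradient at initialization (a zero-initialized head would block all
learning signal into the body). With deep supervision enabled, heads are
attached to every top-row node X(0, 1..4) and their logits averaged.

Built on the NumPy layers in :mod:`.nn`; forward/backward traverse the node
grid in topological order with explicit gradient accumulation.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError
from .config import SegTrainConfig
from .nn import Adam, BatchNorm, Conv1x1, Conv3x3, MaxPool2, ReLU, Upsample2, sigmoid

__all__ = ["UNetPlusPlus", "build_model"]

_DEPTH = 4
_BASE_WIDTHS = (32, 64, 128, 256, 512)


class _ConvBlock:
    """conv3x3 -> BN -> ReLU, twice."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [
            Conv3x3(cin, cout, rng), BatchNorm(cout), ReLU(),
            Conv3x3(cout, cout, rng), BatchNorm(cout), ReLU(),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train) if isinstance(layer, BatchNorm) else layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [pair for layer in self.layers for pair in layer.params()]


class UNetPlusPlus:
    """Nested-skip segmenter over (N, H, W, 3) inputs in [0, 1]."""

    def __init__(self, config: SegTrainConfig):
        if config.input_size % (2**_DEPTH) != 0:
            raise ParameterError("input_size incompatible with the pooling depth")
        self.config = config
        self.trained = False
        rng = np.random.default_rng(config.seed)
        w = [max(2, int(round(b * config.width_multiplier))) for b in _BASE_WIDTHS]
        self.widths = w

        self.blocks: dict[tuple[int, int], _ConvBlock] = {}
        self.pools = {i: MaxPool2() for i in range(1, _DEPTH + 1)}
        self.ups = {}
        for i in range(_DEPTH + 1):
            cin = 3 if i == 0 else w[i - 1]
            self.blocks[(i, 0)] = _ConvBlock(cin, w[i], rng)
        for j in range(1, _DEPTH + 1):
            for i in range(_DEPTH + 1 - j):
                cin = j * w[i] + w[i + 1]
                self.blocks[(i, j)] = _ConvBlock(cin, w[i], rng)
                self.ups[(i, j)] = Upsample2()

        self.heads = {}
        head_stages = range(1, _DEPTH + 1) if config.deep_supervision else [_DEPTH]
        for j in head_stages:
            self.heads[j] = Conv1x1(w[0], 1, rng, zero_init=False)

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        pairs = []
        for block in self.blocks.values():
            pairs.extend(block.params())
        for head in self.heads.values():
            pairs.extend(head.params())
        return pairs

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all weights and BN running stats."""
        out = {}
        for key, block in self.blocks.items():
            for li, layer in enumerate(block.layers):
                prefix = f"block{key[0]}_{key[1]}_l{li}"
                for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                    if hasattr(layer, name):
                        out[f"{prefix}_{name}"] = getattr(layer, name)
        for j, head in self.heads.items():
            out[f"head{j}_W"] = head.W
            out[f"head{j}_b"] = head.b
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        for name, value in self.state_arrays().items():
            value[...] = arrays[name]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (N, H, W)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != x.shape[2] or x.shape[1] != self.config.input_size:
            raise ParameterError(
                f"expected (N, {self.config.input_size}, {self.config.input_size}, 3) input"
            )
        nodes = {}
        nodes[(0, 0)] = self.blocks[(0, 0)].forward(x, train)
        for i in range(1, _DEPTH + 1):
            nodes[(i, 0)] = self.blocks[(i, 0)].forward(
                self.pools[i].forward(nodes[(i - 1, 0)]), train
            )
        for j in range(1, _DEPTH + 1):
            for i in range(_DEPTH + 1 - j):
                up = self.ups[(i, j)].forward(nodes[(i + 1, j - 1)])
                inp = np.concatenate([nodes[(i, jj)] for jj in range(j)] + [up], axis=3)
                nodes[(i, j)] = self.blocks[(i, j)].forward(inp, train)
        self._nodes = nodes if train else None

        logits = [self.heads[j].forward(nodes[(0, j)])[..., 0] for j in self.heads]
        return np.mean(logits, axis=0) if len(logits) > 1 else logits[0]

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        grads: dict[tuple[int, int], np.ndarray] = {}
        share = 1.0 / len(self.heads)
        for j, head in self.heads.items():
            g = head.backward((dlogits * share)[..., None].astype(np.float32))
            grads[(0, j)] = grads.get((0, j), 0.0) + g
        for j in range(_DEPTH, 0, -1):
            for i in range(_DEPTH + 1 - j):
                if (i, j) not in grads:
                    continue
                dinp = self.blocks[(i, j)].backward(grads.pop((i, j)))
                w = self.widths
                offset = 0
                for jj in range(j):
                    chunk = dinp[..., offset : offset + w[i]]
                    grads[(i, jj)] = grads.get((i, jj), 0.0) + chunk
                    offset += w[i]
                dup = self.ups[(i, j)].backward(dinp[..., offset:])
                grads[(i + 1, j - 1)] = grads.get((i + 1, j - 1), 0.0) + dup
        for i in range(_DEPTH, 0, -1):
            dpool = self.pools[i].backward(self.blocks[(i, 0)].backward(grads.pop((i, 0))))
            grads[(i - 1, 0)] = grads.get((i - 1, 0), 0.0) + dpool
        self.blocks[(0, 0)].backward(grads.pop((0, 0)))
        self._nodes = None

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Per-pixel tongue probability in [0, 1], shape (N, H, W)."""
        out = []
        for k in range(0, x.shape[0], batch_size):
            out.append(sigmoid(self.forward(x[k : k + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def make_optimizer(self) -> Adam:
        return Adam(self.params(), lr=self.config.learning_rate)


def build_model(config: SegTrainConfig) -> UNetPlusPlus:
    """Construct the segmenter for a config; weights depend only on the seed."""
    return UNetPlusPlus(config)
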