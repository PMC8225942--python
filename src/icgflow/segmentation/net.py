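"""NumPy implementation of the dual-decoder U-Net.

Encoder: ``encoder_depth`` levels of two 3x3 convolutions (ReLU) followed by
2x2 max pooling; a two-convolution bottleneck; then two structurally
identical decoders, each level a 2x2 up-convolution, concatenation of the
matching encoder feature map, and two 3x3 convolutions; a final 1x1
convolution per decoder produces two-class logits.

Gradients are computed by hand, layer by layer. Feature maps are float32 in
channels-last (N, H, W, C) layout internally — convolutions reduce to one
matrix product per kernel tap on contiguous slices, which is what keeps a
pure-NumPy network trainable in minutes on a CPU. The public interface
(``forward``/``backward``) speaks (N, C, H, W).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["MultiTaskUNet", "build_multitask_unet"]


def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


class _Conv3x3:
    """Same-padding 3x3 convolution; weights (9, Cin, Cout)."""

    def __init__(self, rng, c_in: int, c_out: int):
        self.w = _he(rng, (9, c_in, c_out), c_in * 9)
        self.b = np.zeros(c_out, np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self.xp = xp
        out = np.empty((n, h, w, self.w.shape[2]), np.float32)
        out[...] = self.b
        for k in range(9):
            ki, kj = divmod(k, 3)
            out += xp[:, ki:ki + h, kj:kj + w, :] @ self.w[k]
        return out

    def backward(self, g):
        n, h, w, c_out = g.shape
        c_in = self.w.shape[1]
        gm = g.reshape(-1, c_out)
        dxp = np.zeros_like(self.xp)
        for k in range(9):
            ki, kj = divmod(k, 3)
            sl = np.ascontiguousarray(self.xp[:, ki:ki + h, kj:kj + w, :])
            self.dw[k] = sl.reshape(-1, c_in).T @ gm
            dxp[:, ki:ki + h, kj:kj + w, :] += g @ self.w[k].T
        self.db[...] = gm.sum(axis=0)
        self.xp = None
        return dxp[:, 1:-1, 1:-1, :]

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _Conv1x1:
    def __init__(self, rng, c_in: int, c_out: int):
        self.w = _he(rng, (c_in, c_out), c_in)
        self.b = np.zeros(c_out, np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self.x = x
        return x @ self.w + self.b

    def backward(self, g):
        c_in, c_out = self.w.shape
        self.dw[...] = self.x.reshape(-1, c_in).T @ g.reshape(-1, c_out)
        self.db[...] = g.reshape(-1, c_out).sum(axis=0)
        dx = g @ self.w.T
        self.x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self.m = x > 0
        return np.where(self.m, x, np.float32(0.0))

    def backward(self, g):
        out = np.where(self.m, g, np.float32(0.0))
        self.m = None
        return out

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        cand = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4)).reshape(
            n, h // 2, w // 2, c, 4)
        self.idx = np.argmax(cand, axis=-1)
        self.in_shape = x.shape
        return np.take_along_axis(cand, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, h, w, c = self.in_shape
        dcand = np.zeros((n, h // 2, w // 2, c, 4), np.float32)
        np.put_along_axis(dcand, self.idx[..., None], g[..., None], axis=-1)
        dx = dcand.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self.idx = None
        return np.ascontiguousarray(dx).reshape(n, h, w, c)

    def params(self):
        return []


class _UpConv2:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, rng, c_in: int, c_out: int):
        self.w = _he(rng, (c_in, 4 * c_out), c_in)
        self.b = np.zeros(c_out, np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_out = c_out

    def forward(self, x):
        self.x = x
        n, h, w, c = x.shape
        y = (x @ self.w).reshape(n, h, w, 2, 2, self.c_out)
        y = np.ascontiguousarray(y.transpose(0, 1, 3, 2, 4, 5))
        return y.reshape(n, 2 * h, 2 * w, self.c_out) + self.b

    def backward(self, g):
        n, H, W, c_out = g.shape
        h, w = H // 2, W // 2
        gr = np.ascontiguousarray(
            g.reshape(n, h, 2, w, 2, c_out).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(n, h, w, 4 * c_out)
        c_in = self.w.shape[0]
        self.dw[...] = self.x.reshape(-1, c_in).T @ gr.reshape(-1, 4 * c_out)
        self.db[...] = g.reshape(-1, c_out).sum(axis=0)
        dx = gr @ self.w.T
        self.x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _BatchNorm:
    """Per-channel batch normalization over (N, H, W).

    Training uses batch statistics and keeps exponential running averages
    for inference; a cold-start network trained for only 150 iterations
    depends on this to converge.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, np.float32)
        self.beta = np.zeros(c, np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, np.float32)
        self.run_var = np.ones(c, np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if self.training:
            self.xhat = xhat.astype(np.float32)
            self.inv = inv.astype(np.float32)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, g):
        m = g.shape[0] * g.shape[1] * g.shape[2]
        self.dgamma[...] = (g * self.xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = g.sum(axis=(0, 1, 2))
        dxhat = g * self.gamma
        dx = (self.inv / m) * (m * dxhat
                               - dxhat.sum(axis=(0, 1, 2))
                               - self.xhat * (dxhat * self.xhat).sum(axis=(0, 1, 2)))
        self.xhat = None
        return dx.astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state(self):
        return [self.run_mean, self.run_var]


class _ConvBlock:
    """conv3x3 -> BN -> ReLU -> conv3x3 -> BN -> ReLU."""

    def __init__(self, rng, c_in, c_out):
        self.layers = [_Conv3x3(rng, c_in, c_out), _BatchNorm(c_out), _ReLU(),
                       _Conv3x3(rng, c_out, c_out), _BatchNorm(c_out), _ReLU()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class _Decoder:
    def __init__(self, rng, widths):
        # widths e.g. (16, 32, 64, 128); bottleneck runs at widths[-1]
        self.ups = []
        self.blocks = []
        prev = widths[-1]
        for wch in reversed(widths):
            self.ups.append(_UpConv2(rng, prev, wch))
            self.blocks.append(_ConvBlock(rng, 2 * wch, wch))
            prev = wch
        self.head = _Conv1x1(rng, widths[0], 2)

    def forward(self, x, skips):
        self.split = []
        for up, block, skip in zip(self.ups, self.blocks, reversed(skips)):
            x = up.forward(x)
            self.split.append(skip.shape[-1])
            x = block.forward(np.concatenate([skip, x], axis=-1))
        return self.head.forward(x)

    def backward(self, g):
        g = self.head.backward(g)
        gskips = []
        for up, block, csk in zip(reversed(self.ups), reversed(self.blocks),
                                  reversed(self.split)):
            gc = block.backward(g)
            gskips.append(np.ascontiguousarray(gc[..., :csk]))
            g = up.backward(np.ascontiguousarray(gc[..., csk:]))
        return g, gskips  # ordered shallow -> deep like the skips

    def params(self):
        ps = []
        for up, block in zip(self.ups, self.blocks):
            ps += up.params() + block.params()
        return ps + self.head.params()


class MultiTaskUNet:
    """Shared encoder, two decoders (all vessels / recipient vessel)."""

    def __init__(self, widths=(16, 32, 64, 128), seed: int = 0):
        self.widths = tuple(widths)
        self.depth = len(self.widths)
        rng = np.random.default_rng(seed)
        self.enc_blocks = []
        c_in = 1
        for wch in self.widths:
            self.enc_blocks.append(_ConvBlock(rng, c_in, wch))
            c_in = wch
        self.pools = [_MaxPool2() for _ in self.widths]
        self.bottleneck = _ConvBlock(rng, self.widths[-1], self.widths[-1])
        self.dec_all = _Decoder(rng, self.widths)
        self.dec_receip = _Decoder(rng, self.widths)

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (N, 1, H, W) float32 in [0, 1]; H, W divisible by 2**depth.

        Returns two-class logits (N, 2, H, W) for each head.
        """
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (N, 1, H, W)")
        div = 2 ** self.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(f"input spatial size must be divisible by {div}")
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).astype(np.float32)
        self.skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            h = block.forward(h)
            self.skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        logits_all = self.dec_all.forward(h, self.skips)
        logits_receip = self.dec_receip.forward(h, self.skips)
        return (logits_all.transpose(0, 3, 1, 2),
                logits_receip.transpose(0, 3, 1, 2))

    def backward(self, g_all: np.ndarray, g_receip: np.ndarray) -> None:
        ga = np.ascontiguousarray(g_all.transpose(0, 2, 3, 1)).astype(np.float32)
        gr = np.ascontiguousarray(g_receip.transpose(0, 2, 3, 1)).astype(np.float32)
        gb1, gs1 = self.dec_all.backward(ga)
        gb2, gs2 = self.dec_receip.backward(gr)
        g = self.bottleneck.backward(gb1 + gb2)
        for block, pool, gsa, gsb in zip(reversed(self.enc_blocks), reversed(self.pools),
                                         reversed(gs1), reversed(gs2)):
            g = pool.backward(g) + gsa + gsb
            g = block.backward(g)
        self.skips = None

    def params(self):
        ps = []
        for block in self.enc_blocks:
            ps += block.params()
        ps += self.bottleneck.params()
        ps += self.dec_all.params() + self.dec_receip.params()
        return ps

    def _bn_layers(self):
        blocks = list(self.enc_blocks) + [self.bottleneck] \
            + self.dec_all.blocks + self.dec_receip.blocks
        for block in blocks:
            for layer in block.layers:
                if isinstance(layer, _BatchNorm):
                    yield layer

    def set_training(self, flag: bool) -> None:
        """Toggle batch-norm between batch statistics and running averages."""
        for bn in self._bn_layers():
            bn.training = flag

    # ------------------------------------------------------------------
    def save(self, path) -> Path:
        """Single-file weights (.npz) + JSON sidecar with the architecture."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        path.parent.mkdir(parents=True, exist_ok=True)
        state = [a for bn in self._bn_layers() for a in bn.state()]
        np.savez(path, *([p for p, _ in self.params()] + state))
        path.with_suffix(".json").write_text(json.dumps({"widths": list(self.widths)}))
        return path

    @classmethod
    def load(cls, path) -> "MultiTaskUNet":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(widths=meta["widths"])
        with np.load(path) as data:
            arrays = [data[k] for k in data.files]
        slots = [p for p, _ in model.params()] \
            + [a for bn in model._bn_layers() for a in bn.state()]
        for slot, a in zip(slots, arrays):
            slot[...] = a.astype(slot.dtype)
        return model


def build_multitask_unet(config=None) -> MultiTaskUNet:
    """Construct the dual-decoder network from a :class:`SegConfig`."""
    if config is None:
        from icgflow.segmentation.config import SegConfig

        config = SegConfig()
    return MultiTaskUNet(widths=config.widths, seed=config.seed)
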