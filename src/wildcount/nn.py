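"""Minimal convolutional-network engine on numpy (NHWC layout).

Forward convolutions are evaluated as nine shifted matrix products (one per
kernel tap), which keeps all heavy arithmetic inside BLAS without
materializing an im2col buffer; the weight gradient uses a single im2col
GEMM. Everything is float32 and deterministic for a fixed seed on a fixed
thread count.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv:
    """k x k same-padding convolution with optional fused ReLU.

    He-normal initialization (std = sqrt(2 / fan_in)), the standard choice
    for ReLU networks.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        c_in: int,
        c_out: int,
        k: int = 3,
        relu: bool = True,
        need_dx: bool = True,
    ):
        std = np.sqrt(2.0 / (k * k * c_in))
        self.W = rng.normal(0.0, std, size=(k, k, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.relu = relu
        self.need_dx = need_dx  # first layer can skip the input gradient
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None
        # persistent scratch buffers (keyed by shape): freshly allocated
        # arrays of this size cost more in page faults than the copy itself
        self._bufs: dict = {}

    def _scratch(self, key: str, shape: tuple) -> np.ndarray:
        buf = self._bufs.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, np.float32)
            self._bufs[key] = buf
        return buf

    def _pad(self, x: np.ndarray, p0: int, p1: int, key: str) -> np.ndarray:
        """Zero-pad into a reused buffer (only the border is re-zeroed)."""
        N, H, Wd, C = x.shape
        buf = self._scratch(key, (N, H + p0 + p1, Wd + p0 + p1, C))
        if p0:
            buf[:, :p0].fill(0.0)
            buf[:, :, :p0].fill(0.0)
        if p1:
            buf[:, H + p0 :].fill(0.0)
            buf[:, :, Wd + p0 :].fill(0.0)
        buf[:, p0 : p0 + H, p0 : p0 + Wd] = x
        return buf

    # im2col buffers larger than this fall back to the tap loop
    _COL_BYTES_MAX = 512 * 2**20

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        p0 = (k - 1) // 2
        p1 = k - 1 - p0
        N, H, Wd, C = x.shape
        Co = self.W.shape[-1]
        if k == 1:
            out = x @ self.W[0, 0] + self.b
            col = x if train else None
        else:
            if train:
                xp = self._pad(x, p0, p1, "xp")
            else:
                xp = np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)))
            if train and xp.nbytes * k * k <= self._COL_BYTES_MAX:
                # one im2col GEMM; the col matrix is reused for the weight
                # gradient, and its wider inner dimension (k*k*C) keeps BLAS
                # efficient even for narrow layers
                view = sliding_window_view(xp, (k, k), axis=(1, 2))
                col = self._scratch("col", (N, H, Wd, k, k, C))
                np.copyto(col, view.transpose(0, 1, 2, 4, 5, 3))
                col = col.reshape(N * H * Wd, k * k * C)
                out = (col @ self.W.reshape(k * k * C, Co)).reshape(N, H, Wd, Co)
                out += self.b
            else:
                col = xp if train else None  # fallback: cache padded input
                out = np.empty((N, H, Wd, Co), dtype=np.float32)
                out[:] = self.b
                for ky in range(k):
                    for kx in range(k):
                        out += xp[:, ky : ky + H, kx : kx + Wd, :] @ self.W[ky, kx]
        if self.relu:
            mask = out > 0
            out *= mask
        else:
            mask = None
        if train:
            self._cache = (col, x.shape, mask)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        col, x_shape, mask = self._cache
        if self.relu:
            dy = dy * mask
        k = self.k
        p0 = (k - 1) // 2
        N, H, Wd, _ = dy.shape
        c_in = self.W.shape[2]
        dy_flat = dy.reshape(-1, dy.shape[-1])
        # gradients are written in place: the optimizer holds references
        self.db[...] = dy_flat.sum(axis=0)
        if k == 1:
            self.dW[0, 0] = col.reshape(-1, c_in).T @ dy_flat
            self._cache = None
            return dy @ self.W[0, 0].T if self.need_dx else None
        if col.ndim == 2:  # cached im2col matrix from the forward pass
            self.dW[...] = (col.T @ dy_flat).reshape(k, k, c_in, -1)
        else:  # fallback: col is the padded input; per-tap weight gradient
            xp = col
            for ky in range(k):
                for kx in range(k):
                    patch = np.ascontiguousarray(
                        xp[:, ky : ky + H, kx : kx + Wd, :]
                    )
                    self.dW[ky, kx] = patch.reshape(-1, c_in).T @ dy_flat
        if not self.need_dx:
            self._cache = None
            return None
        # input gradient as a convolution of dy with the flipped kernel,
        # evaluated through the same im2col GEMM as the forward pass
        p1 = k - 1 - p0
        Hx, Wx = x_shape[1], x_shape[2]
        co = self.W.shape[-1]
        dyp = self._pad(dy, p1, p0, "dyp") if p0 == p1 else np.pad(
            dy, ((0, 0), (p1, p0), (p1, p0), (0, 0))
        )
        if dyp.nbytes * k * k <= self._COL_BYTES_MAX:
            view = sliding_window_view(dyp, (k, k), axis=(1, 2))
            dcol = self._scratch("dcol", (N, Hx, Wx, k, k, co))
            np.copyto(dcol, view.transpose(0, 1, 2, 4, 5, 3))
            dcol = dcol.reshape(N * Hx * Wx, k * k * co)
            w_flip = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # k,k,Co,C
            dx = (dcol @ w_flip.reshape(k * k * co, c_in)).reshape(
                N, Hx, Wx, c_in
            )
        else:
            dx = np.zeros((N, Hx, Wx, c_in), dtype=np.float32)
            for ky in range(k):
                for kx in range(k):
                    dx += dyp[:, ky : ky + Hx, kx : kx + Wx, :] @ (
                        self.W[k - 1 - ky, k - 1 - kx].T
                    )
        self._cache = None
        return dx

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool2:
    """2x2 max pooling with stride 2."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, H, Wd, C = x.shape
        xr = x.reshape(N, H // 2, 2, Wd // 2, 2, C)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, Wd // 2, C, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        N, H, Wd, C = x_shape
        onehot = np.eye(4, dtype=np.float32)[idx]
        dxr = onehot * dy[..., None]
        dx = (
            dxr.reshape(N, H // 2, Wd // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, H, Wd, C)
        )
        self._cache = None
        return dx

    params: list = []


class UpsampleNearest2:
    """2x nearest-neighbor upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, H, Wd, C = dy.shape
        return dy.reshape(N, H // 2, 2, Wd // 2, 2, C).sum(axis=(2, 4))

    params: list = []


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= self.lr * (self.m[i] / bias1) / (np.sqrt(self.v[i] / bias2) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class UNet:
    """U-shaped symmetric encoder-decoder with skip connections.

    ``depth`` pooling steps halve the resolution on the contracting path;
    the expanding path mirrors them with nearest-neighbor upsampling followed
    by a halving convolution, concatenating the matching encoder feature map
    at each level. A 1x1 convolution plus sigmoid yields the per-pixel
    presence probability.
    """

    def __init__(self, depth: int, base_filters: int, n_bands: int,
                 dropout_rate: float = 0.0, seed: int = 0,
                 output_bias: float = 0.0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.dropout_rate = float(dropout_rate)
        self.seed = seed
        self.enc_blocks = []
        c_in = n_bands
        for lvl in range(depth):
            c = base_filters * 2**lvl
            first = Conv(rng, c_in, c, need_dx=lvl > 0)
            self.enc_blocks.append([first, Conv(rng, c, c)])
            c_in = c
        c_bot = base_filters * 2**depth
        self.bottleneck = [Conv(rng, c_in, c_bot), Conv(rng, c_bot, c_bot)]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups = [UpsampleNearest2() for _ in range(depth)]
        self.up_convs = []
        self.dec_blocks = []
        c_in = c_bot
        for lvl in reversed(range(depth)):
            c = base_filters * 2**lvl
            self.up_convs.append(Conv(rng, c_in, c))  # halves channels after upsample
            self.dec_blocks.append([Conv(rng, 2 * c, c), Conv(rng, c, c)])
            c_in = c
        self.out_conv = Conv(rng, c_in, 1, k=1, relu=False)
        # prior-probability bias: starting from "everything is background"
        # skips the uniform-probability warmup phase on imbalanced masks
        self.out_conv.b[:] = output_bias
        self._drop_rng = np.random.default_rng(rng.integers(2**31))
        self._cache: dict | None = None

    # ---- plumbing -----------------------------------------------------
    def _layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.bottleneck
        for conv, block in zip(self.up_convs, self.dec_blocks):
            yield conv
            yield from block
        yield self.out_conv

    @property
    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.append(layer.W.copy())
            out.append(layer.b.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self._layers():
            layer.W[...] = next(it)
            layer.b[...] = next(it)

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W, bands) float32 -> probabilities (N, H, W, 1)."""
        skips = []
        h = x
        for lvl in range(self.depth):
            for conv in self.enc_blocks[lvl]:
                h = conv.forward(h, train)
            skips.append(h)
            h = self.pools[lvl].forward(h, train)
        for conv in self.bottleneck:
            h = conv.forward(h, train)
        drop_mask = None
        if train and self.dropout_rate > 0:
            drop_mask = (
                self._drop_rng.random(h.shape) >= self.dropout_rate
            ).astype(np.float32) / (1.0 - self.dropout_rate)
            h = h * drop_mask
        skip_channels = []
        for i, lvl in enumerate(reversed(range(self.depth))):
            h = self.ups[i].forward(h, train)
            h = self.up_convs[i].forward(h, train)
            skip = skips[lvl]
            skip_channels.append(skip.shape[-1])
            h = np.concatenate([skip, h], axis=-1)
            for conv in self.dec_blocks[i]:
                h = conv.forward(h, train)
        z = self.out_conv.forward(h, train)
        p = sigmoid(z)
        if train:
            self._cache = {"p": p, "skip_channels": skip_channels,
                           "drop_mask": drop_mask}
        return p

    def backward(self, dp: np.ndarray) -> None:
        """Backpropagate dL/dp through the sigmoid and the whole network."""
        cache = self._cache
        p = cache["p"]
        dz = (dp * p * (1.0 - p)).astype(np.float32)
        dh = self.out_conv.backward(dz)
        dskips = [None] * self.depth
        for i in reversed(range(self.depth)):
            # decoder stages in reverse creation order
            for conv in reversed(self.dec_blocks[i]):
                dh = conv.backward(dh)
            c_skip = cache["skip_channels"][i]
            dskip, dh = dh[..., :c_skip], dh[..., c_skip:]
            dskips[self.depth - 1 - i] = dskip
            dh = self.up_convs[i].backward(dh)
            dh = self.ups[i].backward(dh)
        if cache["drop_mask"] is not None:
            dh = dh * cache["drop_mask"]
        for conv in reversed(self.bottleneck):
            dh = conv.backward(dh)
        for lvl in reversed(range(self.depth)):
            dh = self.pools[lvl].backward(dh)
            dh = dh + dskips[lvl]
            for conv in reversed(self.enc_blocks[lvl]):
                dh = conv.backward(dh)
        self._cache = None
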