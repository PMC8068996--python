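"""Modified 3D U-Net for volumetric capillary segmentation, in pure numpy.

The architecture is the classic U-Net encoder/decoder with every filter
extended to three dimensions: four contracting blocks (two 3x3x3
convolutions with ReLU, each followed by batch normalization, then 2x2x2
max pooling), a bottleneck, and four expanding blocks (2x up-sampling
realised as nearest-neighbor resize plus a 2x2x2 convolution — a learned
transposed convolution is available as an option — skip concatenation with
the matching contracting block, then two 3x3x3 conv+BN pairs).  All
convolutions are padded so spatial size is preserved; the head is a 1x1x1
convolution with a sigmoid, so the output volume has the input's shape
with per-voxel scores in [0, 1].

Forward and backward passes are written explicitly (im2col convolutions,
batch-norm backprop, max-pool argmax routing) and optimised with Adam on a
binary cross-entropy loss over the sigmoid logits.  This keeps the model
dependency-free and fully reproducible on a CPU; it is intended for
desk-scale experiments, not for the full-scale training recipe (1500
epochs, batch 4, learning rate 1e-4, per-epoch random subset sampling from
a pre-generated pool), which is documented in the methods note.

Tensors are ``(N, C, Z, Y, X)``; ``UNetSpec.input_dims`` is ``(lx, ly, lz)``
to match the volume modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "UNet3D",
    "TrainResult",
    "build_unet",
    "sample_epoch_subset",
    "train",
    "predict_volume",
    "expected_parameter_count",
]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal layer protocol: forward/backward plus named parameters."""

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(_Layer):
    """3D convolution via im2col; padding preserves spatial size.

    ``pad`` gives (before, after) per spatial axis; (1, 1) for 3x3x3 same
    padding, (0, 1) for the even 2x2x2 kernel, (0, 0) for 1x1x1.
    """

    def __init__(self, c_in, c_out, kernel, pad, rng, dtype=np.float32):
        self.kernel = kernel
        self.pad = pad
        k3 = int(np.prod(kernel))
        scale = np.sqrt(2.0 / (c_in * k3))  # He init for ReLU nets
        self.w = (rng.standard_normal((c_out, c_in * k3)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out
        self._cols = None
        self._xshape = None

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, training):
        self._xshape = x.shape
        n, c, *_ = x.shape
        pads = [(0, 0), (0, 0)] + [tuple(self.pad)] * 3
        xp = np.pad(x, pads)
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        # (N, C, Z, Y, X, kz, ky, kx) -> (N, Z, Y, X, C*k3)
        win = np.moveaxis(win, 1, 4)
        zo, yo, xo = win.shape[1:4]
        cols = np.ascontiguousarray(win).reshape(n * zo * yo * xo, -1)
        out = cols @ self.w.T + self.b
        if training:
            self._cols = cols
        out = out.reshape(n, zo, yo, xo, self.c_out)
        return np.moveaxis(out, 4, 1)

    def backward(self, dout):
        n, f, zo, yo, xo = dout.shape
        dmat = np.moveaxis(dout, 1, 4).reshape(-1, f)
        self.dw[...] = dmat.T @ self._cols
        self.db[...] = dmat.sum(axis=0)
        dcols = dmat @ self.w  # (Npix, C*k3)
        kz, ky, kx = self.kernel
        dcols = dcols.reshape(n, zo, yo, xo, self.c_in, kz, ky, kx)
        pz, py, px = self.pad, self.pad, self.pad
        zp = zo + pz[0] + pz[1]
        yp = yo + py[0] + py[1]
        xp_ = xo + px[0] + px[1]
        dxp = np.zeros((n, self.c_in, zp, yp, xp_), dtype=dout.dtype)
        for iz in range(kz):
            for iy in range(ky):
                for ix in range(kx):
                    dxp[:, :, iz : iz + zo, iy : iy + yo, ix : ix + xo] += (
                        np.moveaxis(dcols[..., iz, iy, ix], 4, 1)
                    )
        self._cols = None
        return dxp[
            :,
            :,
            pz[0] : zp - pz[1],
            py[0] : yp - py[1],
            px[0] : xp_ - px[1],
        ]


class ConvTranspose3D(_Layer):
    """Learned 2x2x2 stride-2 up-convolution (each input voxel paints a
    2x2x2 output block)."""

    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * 8))
        self.w = (rng.standard_normal((c_in, c_out, 2, 2, 2)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, training):
        if training:
            self._x = x
        n, c, z, y, xdim = x.shape
        f = self.w.shape[1]
        # out[n, f, 2z+i, 2y+j, 2x+k] = sum_c x[n,c,z,y,x] * w[c,f,i,j,k]
        out = np.einsum("nczyx,cfijk->nfziyjxk", x, self.w, optimize=True)
        out = out.reshape(n, f, 2 * z, 2 * y, 2 * xdim)
        return out + self.b[None, :, None, None, None]

    def backward(self, dout):
        n, f, z2, y2, x2 = dout.shape
        z, y, x = z2 // 2, y2 // 2, x2 // 2
        blocks = dout.reshape(n, f, z, 2, y, 2, x, 2)
        blocks = np.einsum("nfziyjxk->nfzyxijk", blocks)
        self.dw[...] = np.einsum(
            "nczyx,nfzyxijk->cfijk", self._x, blocks, optimize=True
        )
        self.db[...] = dout.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("nfzyxijk,cfijk->nczyx", blocks, self.w, optimize=True)
        self._x = None
        return dx


class BatchNorm3D(_Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, training):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        if training:
            self._cache = (xhat, invstd)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dout):
        xhat, invstd = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = dout.size / dout.shape[1]
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma.reshape(shape)
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape) / m
        ) * invstd.reshape(shape)
        return dx


class ReLU(_Layer):
    def forward(self, x, training):
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool3D(_Layer):
    """2x2x2 max pooling with exact argmax gradient routing."""

    def forward(self, x, training):
        n, c, z, y, xd = x.shape
        blocks = x.reshape(n, c, z // 2, 2, y // 2, 2, xd // 2, 2)
        blocks = np.einsum("nczaybxd->nczyxabd", blocks).reshape(
            n, c, z // 2, y // 2, xd // 2, 8
        )
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._xshape = x.shape
        return out

    def backward(self, dout):
        n, c, z, y, xd = self._xshape
        grid = np.zeros((n, c, z // 2, y // 2, xd // 2, 8), dtype=dout.dtype)
        np.put_along_axis(grid, self._idx[..., None], dout[..., None], axis=-1)
        grid = grid.reshape(n, c, z // 2, y // 2, xd // 2, 2, 2, 2)
        grid = np.einsum("nczyxabd->nczaybxd", grid)
        return grid.reshape(n, c, z, y, xd)


class UpsampleNearest3D(_Layer):
    def forward(self, x, training):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dout):
        n, c, z, y, x = dout.shape
        return (
            dout.reshape(n, c, z // 2, 2, y // 2, 2, x // 2, 2)
            .sum(axis=(3, 5, 7))
        )


class Dropout(_Layer):
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self.rate <= 0:
            return dout
        return dout * self._mask


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyper-parameters.

    input_dims   : (lx, ly, lz) of the input volume; every axis must be
                   divisible by 2**depth.
    base_filters : Nf of the first contracting block; doubles per level.
    depth        : number of contracting (= expanding) blocks.
    dropout_rate : dropout after each block's convolutions (0 disables).
    up_mode      : "nearest" (resize + 2x2x2 conv) or "transposed".
    """

    input_dims: tuple[int, int, int] = (128, 128, 64)
    base_filters: int = 16
    depth: int = 4
    dropout_rate: float = 0.1
    up_mode: str = "nearest"
    in_channels: int = 1
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.up_mode not in ("nearest", "transposed"):
            raise ValueError(f"unknown up_mode {self.up_mode!r}")
        names = ("x", "y", "z")
        for name, d in zip(names, self.input_dims):
            if d % (2**self.depth):
                raise ValueError(
                    f"input axis {name} ({d}) is not divisible by "
                    f"2**depth = {2**self.depth}"
                )

    @property
    def filters(self) -> list[int]:
        return [self.base_filters * 2**i for i in range(self.depth + 1)]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters.

    The full-scale study protocol is 1500 epochs, batch size 4, learning
    rate 1e-4 with Adam, and per-epoch random subsets of (1000, 300)
    volumes for the smooth-background model and (800, 200) for the
    speckled one.  Desk-scale runs shrink epochs and subset sizes, not the
    optimizer settings.
    """

    epochs: int = 1500
    batch_size: int = 4
    learning_rate: float = 1e-4
    subset_train: int = 1000
    subset_val: int = 300
    seed: int = 0


class UNet3D:
    """The assembled network; see the module docstring for the layout."""

    def __init__(self, spec: UNetSpec):
        self.spec = spec
        self.dtype = np.dtype(spec.dtype)
        rng = np.random.default_rng(0xACC)
        self._dropout_rng = np.random.default_rng(0xD07)
        f = spec.filters
        d = spec.depth
        mk = lambda cin, cout, k, p: Conv3D(cin, cout, k, p, rng, self.dtype)

        def conv_bn(cin, cout):
            return [mk(cin, cout, (3, 3, 3), (1, 1)), ReLU(), BatchNorm3D(cout, dtype=self.dtype)]

        self.enc_blocks: list[list[_Layer]] = []
        cin = spec.in_channels
        for i in range(d):
            block = conv_bn(cin, f[i]) + conv_bn(f[i], f[i])
            if spec.dropout_rate > 0:
                block.append(Dropout(spec.dropout_rate, self._dropout_rng))
            self.enc_blocks.append(block)
            cin = f[i]
        self.pools = [MaxPool3D() for _ in range(d)]
        self.bottleneck = conv_bn(f[d - 1], f[d]) + conv_bn(f[d], f[d])
        self.dec_up: list[list[_Layer]] = []
        self.dec_blocks: list[list[_Layer]] = []
        cin = f[d]
        for i in reversed(range(d)):
            if spec.up_mode == "nearest":
                up: list[_Layer] = [
                    UpsampleNearest3D(),
                    mk(cin, f[i], (2, 2, 2), (0, 1)),
                ]
            else:
                up = [ConvTranspose3D(cin, f[i], rng, self.dtype)]
            self.dec_up.append(up)
            block = conv_bn(2 * f[i], f[i]) + conv_bn(f[i], f[i])
            if spec.dropout_rate > 0:
                block.append(Dropout(spec.dropout_rate, self._dropout_rng))
            self.dec_blocks.append(block)
            cin = f[i]
        self.head = mk(f[0], 1, (1, 1, 1), (0, 0))

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self) -> list[_Layer]:
        layers: list[_Layer] = []
        for b in self.enc_blocks:
            layers += b
        layers += self.pools
        layers += self.bottleneck
        for up, b in zip(self.dec_up, self.dec_blocks):
            layers += up + b
        layers.append(self.head)
        return layers

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for li, layer in enumerate(self._all_layers()):
            for name, p, g in layer.params():
                out.append((f"layer{li}.{name}", p, g))
        return out

    def parameter_count(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Return sigmoid logits of shape (N, 1, Z, Y, X)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                x = layer.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        for layer in self.bottleneck:
            x = layer.forward(x, training)
        self._skip_channels = []
        for up, block, skip in zip(self.dec_up, self.dec_blocks, reversed(skips)):
            for layer in up:
                x = layer.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for layer in block:
                x = layer.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, block, cs in zip(
            reversed(self.dec_up), reversed(self.dec_blocks),
            reversed(self._skip_channels),
        ):
            for layer in reversed(block):
                d = layer.backward(d)
            dskip, d = d[:, :cs], d[:, cs:]
            dskips.append(dskip)
            for layer in reversed(up):
                d = layer.backward(d)
        for layer in reversed(self.bottleneck):
            d = layer.backward(d)
        # dskips were collected shallowest-first; the encoder unwinds
        # deepest-first, so consume them in reverse
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + dskip
            for layer in reversed(block):
                d = layer.backward(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel scores in [0, 1] (sigmoid of the logits), eval mode."""
        z = self.forward(x, training=False)
        return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))

    def shape_trace(self, batch: int = 1) -> list[tuple[str, tuple[int, ...]]]:
        """Per-block output shapes for a dummy forward pass."""
        lx, ly, lz = self.spec.input_dims
        x = np.zeros((batch, self.spec.in_channels, lz, ly, lx), dtype=self.dtype)
        trace: list[tuple[str, tuple[int, ...]]] = [("input", x.shape)]
        skips = []
        for i, (block, pool) in enumerate(zip(self.enc_blocks, self.pools)):
            for layer in block:
                x = layer.forward(x, False)
            skips.append(x)
            x = pool.forward(x, False)
            trace.append((f"contracting_{i}", x.shape))
        for layer in self.bottleneck:
            x = layer.forward(x, False)
        trace.append(("bottleneck", x.shape))
        for i, (up, block, skip) in enumerate(
            zip(self.dec_up, self.dec_blocks, reversed(skips))
        ):
            for layer in up:
                x = layer.forward(x, False)
            x = np.concatenate([skip, x], axis=1)
            for layer in block:
                x = layer.forward(x, False)
            trace.append((f"expanding_{i}", x.shape))
        x = self.head.forward(x, False)
        trace.append(("output", x.shape))
        return trace

    # -- persistence -------------------------------------------------------

    def save_weights(self, path: str | Path) -> None:
        arrays = {name: p for name, p, _ in self.parameters()}
        for li, layer in enumerate(self._all_layers()):
            if isinstance(layer, BatchNorm3D):
                arrays[f"layer{li}.running_mean"] = layer.running_mean
                arrays[f"layer{li}.running_var"] = layer.running_var
        np.savez(path, **arrays)

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as data:
            for name, p, _ in self.parameters():
                p[...] = data[name]
            for li, layer in enumerate(self._all_layers()):
                if isinstance(layer, BatchNorm3D):
                    layer.running_mean[...] = data[f"layer{li}.running_mean"]
                    layer.running_var[...] = data[f"layer{li}.running_var"]


def build_unet(spec: UNetSpec) -> UNet3D:
    return UNet3D(spec)


def expected_parameter_count(spec: UNetSpec) -> int:
    """Closed-form parameter count (convolution weights + biases + BN
    scale/shift), derived block by block from the architecture."""
    f = spec.filters
    d = spec.depth

    def conv(cin, cout, k3):
        return cin * k3 * cout + cout

    def bn(c):
        return 2 * c

    total = 0
    cin = spec.in_channels
    for i in range(d):  # contracting
        total += conv(cin, f[i], 27) + bn(f[i]) + conv(f[i], f[i], 27) + bn(f[i])
        cin = f[i]
    total += conv(f[d - 1], f[d], 27) + bn(f[d])
    total += conv(f[d], f[d], 27) + bn(f[d])
    cin = f[d]
    for i in reversed(range(d)):  # expanding
        total += conv(cin, f[i], 8)  # up-convolution (2x2x2), either mode
        total += conv(2 * f[i], f[i], 27) + bn(f[i])
        total += conv(f[i], f[i], 27) + bn(f[i])
        cin = f[i]
    total += conv(f[0], 1, 1)  # sigmoid head
    return total


# ---------------------------------------------------------------------------
# training harness
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in params]
        self.v = [np.zeros_like(p) for _, p, _ in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (name, p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p[...] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    """Numerically stable binary cross-entropy; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    t = target.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    dz = (1.0 / (1.0 + np.exp(-z)) - t) / z.size
    return float(loss), dz.astype(logits.dtype)


def sample_epoch_subset(
    pool: Sequence, size: int, rng: np.random.Generator
) -> list:
    """Uniform sample without replacement from the data pool for one epoch."""
    if size > len(pool):
        raise ValueError(f"subset size {size} exceeds pool size {len(pool)}")
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[int(i)] for i in idx]


@dataclass
class TrainResult:
    model: UNet3D
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)


def _to_batch(volumes: Sequence[np.ndarray], dtype) -> np.ndarray:
    arrs = []
    for v in volumes:
        a = np.asarray(v, dtype=np.float64)
        if a.dtype != np.float64 or a.max() > 1.0:
            a = a / 255.0
        arrs.append(a)
    return np.stack(arrs)[:, None].astype(dtype)


def train(
    spec: UNetSpec,
    config: TrainConfig,
    data: Sequence[tuple[np.ndarray, np.ndarray]],
    val_data: Sequence[tuple[np.ndarray, np.ndarray]] = (),
    model: Optional[UNet3D] = None,
    checkpoint_path: Optional[str | Path] = None,
) -> TrainResult:
    """Desk-scale training loop.

    ``data`` holds (input, gt) volume pairs as (Z, Y, X) arrays (uint8 on
    the 8-bit scale or floats in [0, 1]; GT becomes a {0, 1} target).  Each
    epoch samples a subset of the pool (capped at the pool size), shuffles
    it into minibatches and takes Adam steps on the BCE loss.  Per-epoch
    train/val losses are recorded; a non-finite loss aborts with a
    diagnostic.  Fixed seeds give identical loss curves on CPU.
    """
    if model is None:
        model = build_unet(spec)
    rng = np.random.default_rng(config.seed)
    model._dropout_rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    result = TrainResult(model=model)
    n_train = min(config.subset_train, len(data))
    n_val = min(config.subset_val, len(val_data))
    for epoch in range(config.epochs):
        subset = sample_epoch_subset(data, n_train, rng)
        order = rng.permutation(len(subset))
        losses = []
        for start in range(0, len(subset), config.batch_size):
            batch = [subset[i] for i in order[start : start + config.batch_size]]
            x = _to_batch([b[0] for b in batch], model.dtype)
            t = _to_batch([(np.asarray(b[1]) > 0) * 1.0 for b in batch], model.dtype)
            logits = model.forward(x, training=True)
            loss, dz = bce_with_logits(logits, t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            model.backward(dz)
            opt.step()
            losses.append(loss)
        result.train_losses.append(float(np.mean(losses)))
        if n_val:
            vsub = sample_epoch_subset(val_data, n_val, rng)
            vlosses = []
            for v in vsub:
                x = _to_batch([v[0]], model.dtype)
                t = _to_batch([(np.asarray(v[1]) > 0) * 1.0], model.dtype)
                logits = model.forward(x, training=False)
                vlosses.append(bce_with_logits(logits, t)[0])
            result.val_losses.append(float(np.mean(vlosses)))
        if checkpoint_path is not None:
            model.save_weights(checkpoint_path)
    return result


def predict_volume(model: UNet3D, volume: np.ndarray) -> np.ndarray:
    """Per-voxel capillary scores for one volume.

    ``volume`` is (Z, Y, X) on the 8-bit scale or in [0, 1].  Stacks
    shallower than the model's z-dimension are zero-padded at the bottom
    (predictions are per-frame, so blank padding frames do not disturb the
    real ones); the returned stack always has the model's full input shape.
    """
    lx, ly, lz = model.spec.input_dims
    v = np.asarray(volume, dtype=np.float64)
    if v.max() > 1.0:
        v = v / 255.0
    if v.ndim != 3 or v.shape[1] != ly or v.shape[2] != lx:
        raise ValueError(
            f"volume shape {v.shape} does not match model frames ({ly}, {lx})"
        )
    if v.shape[0] > lz:
        raise ValueError(f"stack depth {v.shape[0]} exceeds model depth {lz}")
    if v.shape[0] < lz:
        pad = np.zeros((lz - v.shape[0], ly, lx))
        v = np.concatenate([v, pad], axis=0)
    return model.predict(v[None, None])[0, 0]
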