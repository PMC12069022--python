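"""A compact 3-D U-Net implemented directly on numpy.

No deep-learning framework is available in the target environment, so
forward and backward passes are hand-written. Convolutions are expressed
as 27 shifted-slab matrix products, which routes essentially all work
through BLAS and is fast enough for the tiny networks used here
(depth 2, 8 base channels).

Tensors are ``(channels, D, H, W)`` float32. Spatial dims must be
divisible by ``2**depth``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Conv3", "Conv1", "ConvBlock", "UNet3D", "Adam", "dice_bce_loss"]

_F32 = np.float32

_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


class Conv3:
    """3x3x3 convolution, stride 1, zero padding 1."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (27 * cin))
        self.w = (rng.standard_normal((27, cin, cout)) * scale).astype(_F32)
        self.b = np.zeros(cout, dtype=_F32)
        self.gw = None
        self.gb = None
        self._xp = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cin, D, H, W = x.shape
        cout = self.w.shape[2]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        n = D * H * W
        y = np.broadcast_to(self.b, (n, cout)).copy()
        for idx, (dz, dy, dx) in enumerate(_OFFSETS):
            xs = xp[:, dz : dz + D, dy : dy + H, dx : dx + W]
            y += xs.reshape(cin, n).T @ self.w[idx]
        if train:
            self._xp = xp
        return np.ascontiguousarray(y.T.reshape(cout, D, H, W))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp = self._xp
        cin = xp.shape[0]
        cout, D, H, W = gy.shape
        n = D * H * W
        gN = gy.reshape(cout, n).T  # (n, cout)
        self.gb = gy.sum(axis=(1, 2, 3))
        self.gw = np.empty_like(self.w)
        gxp = np.zeros_like(xp)
        for idx, (dz, dy, dx) in enumerate(_OFFSETS):
            xs = xp[:, dz : dz + D, dy : dy + H, dx : dx + W]
            self.gw[idx] = xs.reshape(cin, n) @ gN
            gxp[:, dz : dz + D, dy : dy + H, dx : dx + W] += (
                (gN @ self.w[idx].T).T.reshape(cin, D, H, W)
            )
        self._xp = None
        return gxp[:, 1:-1, 1:-1, 1:-1]

    def parameters(self):
        return [("w", self), ("b", self)]


class Conv1:
    """1x1x1 convolution (channel mixing)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.w = (rng.standard_normal((cin, cout)) * scale).astype(_F32)
        self.b = np.zeros(cout, dtype=_F32)
        self.gw = None
        self.gb = None
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cin, D, H, W = x.shape
        n = D * H * W
        y = x.reshape(cin, n).T @ self.w + self.b
        if train:
            self._x = x
        return np.ascontiguousarray(y.T.reshape(-1, D, H, W))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        cin, D, H, W = x.shape
        n = D * H * W
        gN = gy.reshape(-1, n).T
        self.gb = gy.sum(axis=(1, 2, 3))
        self.gw = x.reshape(cin, n) @ gN
        self._x = None
        return np.ascontiguousarray((gN @ self.w.T).T.reshape(cin, D, H, W))


def _relu_forward(x):
    return np.maximum(x, 0.0)


def _avgpool2(x):
    c, D, H, W = x.shape
    return x.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2).mean(axis=(2, 4, 6))


def _avgpool2_backward(g, shape):
    c, D, H, W = shape
    out = np.empty(shape, dtype=g.dtype)
    v = out.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
    v[:] = (g / 8.0)[:, :, None, :, None, :, None]
    return out


def _upsample2(x):
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(g):
    c, D, H, W = g.shape
    return g.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(2, 4, 6))


class ConvBlock:
    """Two (Conv3 -> ReLU) stages."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = Conv3(cin, cout, rng)
        self.c2 = Conv3(cout, cout, rng)
        self._m1 = None
        self._m2 = None

    def forward(self, x, train: bool = True):
        h = _relu_forward(self.c1.forward(x, train))
        if train:
            self._m1 = h > 0
        y = _relu_forward(self.c2.forward(h, train))
        if train:
            self._m2 = y > 0
        return y

    def backward(self, gy):
        gy = gy * self._m2
        gh = self.c2.backward(gy)
        gh *= self._m1
        self._m1 = self._m2 = None
        return self.c1.backward(gh)

    @property
    def convs(self):
        return [self.c1, self.c2]


class UNet3D:
    """Encoder-decoder with skip concatenation and a sigmoid output head."""

    def __init__(self, in_channels: int = 1, base_channels: int = 8, depth: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.base_channels = base_channels
        self.depth = depth
        self.enc = []
        c_prev = in_channels
        for d in range(depth):
            c = base_channels * (2**d)
            self.enc.append(ConvBlock(c_prev, c, rng))
            c_prev = c
        self.bottleneck = ConvBlock(c_prev, base_channels * (2**depth), rng)
        self.dec = []
        for d in reversed(range(depth)):
            c = base_channels * (2**d)
            self.dec.append(ConvBlock(c * 2 + c, c, rng))  # skip + upsampled
        self.head = Conv1(base_channels, 1, rng)
        self._cache = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """``x``: (D, H, W) or (1, D, H, W) float input -> probability map."""
        if x.ndim == 3:
            x = x[None]
        x = x.astype(_F32, copy=False)
        for s in x.shape[1:]:
            if s % (2**self.depth):
                raise ValueError(
                    f"spatial dims {x.shape[1:]} must be divisible by {2 ** self.depth}"
                )
        skips = []
        h = x
        for blk in self.enc:
            h = blk.forward(h, train)
            skips.append(h)
            h = _avgpool2(h)
        h = self.bottleneck.forward(h, train)
        for blk, skip in zip(self.dec, reversed(skips)):
            up = _upsample2(h)
            h = np.concatenate([skip, up], axis=0)
            h = blk.forward(h, train)
        z = self.head.forward(h, train)[0]
        p = expit(z.astype(np.float64))
        if train:
            self._cache = {"skip_channels": [s.shape[0] for s in skips], "p": p}
        return p

    def backward(self, gz: np.ndarray) -> None:
        """Backpropagate from dL/dz (gradient w.r.t. the output logit).

        Populates each convolution's parameter gradients; the input
        gradient is discarded.
        """
        skip_channels = self._cache["skip_channels"]
        g = self.head.backward(gz[None].astype(_F32))
        # decoder: dec[i] consumed skips[depth-1-i]
        g_skips = [None] * self.depth
        for i in range(self.depth - 1, -1, -1):
            g = self.dec[i].backward(g)
            c_skip = skip_channels[self.depth - 1 - i]
            g_skips[self.depth - 1 - i] = g[:c_skip]
            g = _upsample2_backward(np.ascontiguousarray(g[c_skip:]))
        g = self.bottleneck.backward(g)
        for d in range(self.depth - 1, -1, -1):
            gs = g_skips[d]
            g = _avgpool2_backward(g, gs.shape) + gs
            g = self.enc[d].backward(g)
        self._cache = None

    # -- parameter plumbing --------------------------------------------------

    def _convs(self):
        convs = []
        for blk in self.enc:
            convs.extend(blk.convs)
        convs.extend(self.bottleneck.convs)
        for blk in self.dec:
            convs.extend(blk.convs)
        convs.append(self.head)
        return convs

    def parameters(self):
        """Flat list of parameter arrays (shared references)."""
        out = []
        for c in self._convs():
            out.append(c.w)
            out.append(c.b)
        return out

    def gradients(self):
        out = []
        for c in self._convs():
            out.append(c.gw)
            out.append(c.gb)
        return out

    def get_state(self) -> dict:
        return {f"p{i}": a.copy() for i, a in enumerate(self.parameters())}

    def set_state(self, state: dict) -> None:
        for i, c in enumerate(self._convs()):
            c.w = state[f"p{2 * i}"].astype(_F32).copy()
            c.b = state[f"p{2 * i + 1}"].astype(_F32).copy()


def dice_bce_loss(p: np.ndarray, t: np.ndarray, smooth: float = 1.0):
    """Soft-Dice + binary cross-entropy; returns (loss, dL/dlogit).

    ``p`` are sigmoid probabilities, ``t`` the {0,1} target. The returned
    gradient is taken w.r.t. the pre-sigmoid logit.
    """
    t = t.astype(np.float64)
    n = p.size
    eps = 1e-7
    pc = np.clip(p, eps, 1 - eps)
    bce = -np.mean(t * np.log(pc) + (1 - t) * np.log(1 - pc))
    g_bce = (p - t) / n

    inter = float((p * t).sum())
    sp, st = float(p.sum()), float(t.sum())
    num = 2.0 * inter + smooth
    den = sp + st + smooth
    dice_loss = 1.0 - num / den
    g_dice_p = -(2.0 * t * den - num) / den**2
    g_dice = g_dice_p * p * (1.0 - p)

    return bce + dice_loss, (g_bce + g_dice).astype(_F32)


class Adam:
    """Adam optimizer over a UNet3D's parameter list."""

    def __init__(self, net: UNet3D, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.parameters()]
        self.v = [np.zeros_like(p) for p in net.parameters()]

    def step(self) -> None:
        self.t += 1
        params = self.net.parameters()
        grads = self.net.gradients()
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
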