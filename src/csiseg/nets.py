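"""Compact CPU conv-net engine: autodiff, U-Net variants, box detector.

A small reverse-mode automatic-differentiation core over numpy arrays
(``Tensor`` + the handful of ops a U-Net needs: same-padding 3×3/1×1
convolution via im2col, ReLU, sigmoid, 2×2 max-pool, nearest 2× upsampling,
channel concatenation, elementwise add/multiply) and, on top of it:

* ``UNet`` — encoder–decoder with skip connections, optional additive
  attention gates on the skips, configurable depth/width, 1- or 3-channel
  input (the 2.5D variant is the basic 2D network with 3 input channels);
* ``dice_bce_with_logits`` — soft-Dice + binary cross-entropy loss with an
  analytic gradient in the logits (checked against finite differences);
* ``HeatmapBoxDetector`` — a single-class box predictor for DRRs: a tiny
  U-Net scores per-pixel "inside the box" probability; the predicted box is
  the bounding box of the largest thresholded component.

Everything runs in float32 on one CPU; with a fixed seed, training and
inference are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage


# ---------------------------------------------------------------------------
# autodiff core
# ---------------------------------------------------------------------------

class Tensor:
    """A node in the reverse-mode graph; ``data`` is a float32 ndarray.

    Leaves with ``requires_grad=False`` (network inputs) do not receive a
    gradient, which lets the first convolution skip its input backward pass.
    """

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate ``grad`` (dL/dself) through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), (x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, (x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    # x: (N, C, H, W) -> (N*H*W, C*k*k), stride 1, same padding
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    N, C, H, W = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Stride-1 same-padding correlation. x: (N,C,H,W); W: (Co,Ci,k,k)."""
    Co, Ci, k, _ = W.data.shape
    N, C, H, Wd = x.data.shape
    if C != Ci:
        raise ValueError(f"conv2d: input has {C} channels, kernel expects {Ci}")
    pad = k // 2
    cols = _im2col(x.data, k, pad)
    Wm = W.data.reshape(Co, Ci * k * k)
    out_data = (cols @ Wm.T).reshape(N, H, Wd, Co).transpose(0, 3, 1, 2)
    out_data = out_data + b.data.reshape(1, Co, 1, 1)
    out = Tensor(out_data, (x, W, b))

    def bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(N * H * Wd, Co)
        W._accumulate((g2.T @ cols).reshape(Co, Ci, k, k))
        b._accumulate(g.sum(axis=(0, 2, 3)))
        if not (x._backward is None and not x._parents and not x.requires_grad):
            # dL/dx = correlation of g with the flipped, channel-swapped kernel
            Wflip = W.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Ci, Co, k, k)
            gcols = _im2col(g, k, pad)
            dx = (gcols @ Wflip.reshape(Ci, Co * k * k).T)
            x._accumulate(dx.reshape(N, H, Wd, Ci).transpose(0, 3, 1, 2))

    out._backward = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 needs even spatial dims")
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(N, C, H // 2, W // 2, 4)
    arg = r.argmax(axis=4)
    out = Tensor(np.take_along_axis(r, arg[..., None], axis=4)[..., 0], (x,))

    def bw(g):
        dr = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dr, arg[..., None], g[..., None], axis=4)
        dr = dr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dr.reshape(N, C, H, W))

    out._backward = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))

    def bw(g):
        N, C, H2, W2 = g.shape
        x._accumulate(
            g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        )

    out._backward = bw
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), (a, b))

    def bw(g):
        a._accumulate(g[:, :na])
        b._accumulate(g[:, na:])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def dice_bce_with_logits(
    logits: Tensor,
    target: np.ndarray,
    dice_weight: float = 1.0,
    bce_weight: float = 1.0,
    smooth: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Soft-Dice + BCE loss and its analytic gradient in the logits.

    Returns ``(loss, dL/dlogits)``; call ``logits.backward(grad)`` with the
    second element to train.
    """
    z = logits.data.astype(np.float64)
    t = np.asarray(target, dtype=np.float64)
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    n = z.size

    bce = -(t * np.log(p + 1e-12) + (1 - t) * np.log(1 - p + 1e-12)).mean()
    d_bce = (p - t) / n

    inter = (p * t).sum()
    denom = p.sum() + t.sum() + smooth
    dice = (2 * inter + smooth) / denom
    # d(1-dice)/dp_i, then chain through the sigmoid
    d_dice_dp = -(2 * t * denom - (2 * inter + smooth)) / denom**2
    d_dice = d_dice_dp * p * (1 - p)

    loss = bce_weight * bce + dice_weight * (1.0 - dice)
    grad = bce_weight * d_bce + dice_weight * d_dice
    return float(loss), grad.astype(np.float32)


# ---------------------------------------------------------------------------
# layers / models
# ---------------------------------------------------------------------------

class Conv2d:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                   size=(cout, cin, k, k)))
        self.b = Tensor(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.W, self.b)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class ConvBlock:
    """conv3x3-ReLU twice."""

    def __init__(self, cin: int, cout: int, rng):
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.c2 = Conv2d(cout, cout, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.c2(relu(self.c1(x))))

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters()


class AttentionGate:
    """Additive attention on a skip connection.

    ``alpha = sigma(psi(relu(Wx x + Wg g)))``; the skip features are scaled
    by the per-pixel coefficient before concatenation.
    """

    def __init__(self, c_skip: int, c_gate: int, c_inter: int, rng):
        self.Wx = Conv2d(c_skip, c_inter, 1, rng)
        self.Wg = Conv2d(c_gate, c_inter, 1, rng)
        self.psi = Conv2d(c_inter, 1, 1, rng)

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        a = sigmoid(self.psi(relu(add(self.Wx(x), self.Wg(g)))))
        return mul(x, a)

    def parameters(self):
        return self.Wx.parameters() + self.Wg.parameters() + self.psi.parameters()


class UNet:
    """Encoder–decoder with skip connections; optional attention gates.

    ``widths`` sets the channel count per level; len(widths)−1 poolings, so
    input spatial dims must be divisible by ``2 ** (len(widths) - 1)``.
    """

    def __init__(self, in_channels: int = 1, widths: tuple[int, ...] = (8, 16, 32),
                 attention: bool = False, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.widths = tuple(widths)
        self.attention = attention
        self.enc = []
        c = in_channels
        for w in widths[:-1]:
            self.enc.append(ConvBlock(c, w, rng))
            c = w
        self.bottleneck = ConvBlock(c, widths[-1], rng)
        self.dec = []
        self.gates = []
        c = widths[-1]
        for w in reversed(widths[:-1]):
            if attention:
                self.gates.append(AttentionGate(w, c, max(1, w // 2), rng))
            self.dec.append(ConvBlock(c + w, w, rng))
            c = w
        self.head = Conv2d(c, 1, 1, rng)

    @property
    def factor(self) -> int:
        return 2 ** (len(self.widths) - 1)

    def forward(self, x: np.ndarray) -> Tensor:
        """x: (N, C, H, W) float in [0, 1]; returns logits (N, 1, H, W)."""
        t = Tensor(x, requires_grad=False)
        skips = []
        for block in self.enc:
            t = block(t)
            skips.append(t)
            t = maxpool2(t)
        t = self.bottleneck(t)
        for i, block in enumerate(self.dec):
            t = upsample2(t)
            skip = skips[-(i + 1)]
            if self.attention:
                skip = self.gates[i](skip, t)
            t = block(concat_channels(skip, t))
        return self.head(t)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.forward(x).data
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def parameters(self) -> list[Tensor]:
        params = []
        for block in self.enc + [self.bottleneck] + self.dec + self.gates:
            params += block.parameters()
        params += self.head.parameters()
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = arr


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# DRR box detector
# ---------------------------------------------------------------------------

@dataclass
class DetectorConfig:
    seed: int = 0
    batch_size: int = 32
    epochs: int = 600  # maximum; small phantom runs use far fewer
    lr: float = 5e-3
    widths: tuple[int, ...] = (8, 16, 32)
    threshold: float = 0.5
    downscale: int = 2  # detection runs on 1/downscale-resolution DRRs


def _pad_to_factor(img: np.ndarray, f: int) -> tuple[np.ndarray, tuple[int, int]]:
    H, W = img.shape[-2:]
    ph, pw = (-H) % f, (-W) % f
    if ph or pw:
        img = np.pad(img, [(0, 0)] * (img.ndim - 2) + [(0, ph), (0, pw)])
    return img, (H, W)


class HeatmapBoxDetector:
    """Single-box DRR detector: per-pixel interior score → bounding box.

    A tiny U-Net scores every pixel's probability of lying inside the
    organ's box; the prediction is the bounding box of the largest
    8-connected component above threshold, its confidence the mean score
    inside the box.  Deterministic for a fixed seed.
    """

    def __init__(self, config: DetectorConfig | None = None):
        self.config = config or DetectorConfig()
        self.net = UNet(in_channels=3, widths=self.config.widths,
                        attention=False, seed=self.config.seed)
        self.loss_trace: list[float] = []

    def _features(self, image) -> np.ndarray:
        px = np.asarray(image.pixels, dtype=np.float32) / 255.0
        if px.ndim == 2:
            px = np.repeat(px[:, :, None], 3, axis=2)
        x = px.transpose(2, 0, 1)  # (3, H, W)
        ds = self.config.downscale
        if ds > 1:
            H, W = x.shape[1:]
            ph, pw = (-H) % ds, (-W) % ds
            if ph or pw:
                x = np.pad(x, ((0, 0), (0, ph), (0, pw)))
            x = x.reshape(3, x.shape[1] // ds, ds, x.shape[2] // ds, ds).mean(axis=(2, 4))
        return x

    def fit(self, images, boxes) -> "HeatmapBoxDetector":
        if len(images) == 0:
            raise ValueError("empty training set")
        if len(images) != len(boxes):
            raise ValueError("images and boxes must pair up")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        f = self.net.factor
        ds = cfg.downscale
        # training images may differ in size (cropped DRRs); zero-pad all of
        # them to a common grid — the net is fully convolutional, so predict
        # still accepts any size
        feats = [self._features(img) for img in images]
        Hm = max(x.shape[1] for x in feats)
        Wm = max(x.shape[2] for x in feats)
        Hm, Wm = Hm + (-Hm) % f, Wm + (-Wm) % f
        targets = []
        for i, box in enumerate(boxes):
            x = feats[i]
            t = np.zeros(x.shape[1:], dtype=np.float32)
            u0, u1 = box.u_range[0] // ds, -(-box.u_range[1] // ds)
            v0, v1 = box.v_range[0] // ds, -(-box.v_range[1] // ds)
            t[u0:u1, v0:v1] = 1.0
            ph, pw = Hm - x.shape[1], Wm - x.shape[2]
            feats[i] = np.pad(x, ((0, 0), (0, ph), (0, pw)))
            targets.append(np.pad(t, ((0, ph), (0, pw)))[None])
        X = np.stack(feats)
        T = np.stack(targets)
        opt = Adam(self.net.parameters(), lr=cfg.lr)
        n = len(X)
        self.loss_trace = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                opt.zero_grad()
                logits = self.net.forward(X[idx])
                loss, grad = dice_bce_with_logits(logits, T[idx])
                logits.backward(grad)
                opt.step()
                ep_loss += loss * len(idx)
            self.loss_trace.append(ep_loss / n)
        return self

    def predict(self, image):
        from .localization import Box2D  # local import avoids a cycle

        ds = self.config.downscale
        x = self._features(image)
        Hd, Wd = x.shape[1:]
        x, _ = _pad_to_factor(x, self.net.factor)
        p = self.net.predict_proba(x[None])[0, 0, :Hd, :Wd]
        hot = p >= self.config.threshold
        if not hot.any():
            return None
        lab, _ = ndimage.label(hot, structure=np.ones((3, 3), dtype=bool))
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        comp = lab == np.argmax(sizes)
        idx = np.argwhere(comp)
        u = (int(idx[:, 0].min()), int(idx[:, 0].max()) + 1)
        v = (int(idx[:, 1].min()), int(idx[:, 1].max()) + 1)
        conf = float(np.clip(p[u[0]:u[1], v[0]:v[1]].mean(), 0.0, 1.0))
        H, W = image.shape
        u = (min(u[0] * ds, H - 1), min(u[1] * ds, H))
        v = (min(v[0] * ds, W - 1), min(v[1] * ds, W))
        return Box2D(image.plane, u, v, confidence=conf)


    # -- checkpointing ------------------------------------------------------
    def save(self, path) -> None:
        cfg = self.config
        np.savez(path, seed=cfg.seed, batch_size=cfg.batch_size,
                 epochs=cfg.epochs, lr=cfg.lr, widths=np.asarray(cfg.widths),
                 threshold=cfg.threshold, downscale=cfg.downscale,
                 **self.net.state_dict())

    @classmethod
    def load(cls, path) -> "HeatmapBoxDetector":
        with np.load(path, allow_pickle=False) as data:
            cfg = DetectorConfig(
                seed=int(data["seed"]), batch_size=int(data["batch_size"]),
                epochs=int(data["epochs"]), lr=float(data["lr"]),
                widths=tuple(int(w) for w in data["widths"]),
                threshold=float(data["threshold"]),
                downscale=int(data["downscale"]))
            det = cls(cfg)
            det.net.load_state_dict(
                {k: data[k] for k in data.files if k.startswith("p")})
        return det


def train_detector(images, boxes, config: DetectorConfig | None = None
                   ) -> HeatmapBoxDetector:
    """Fit a single-class DRR box detector (see :class:`HeatmapBoxDetector`)."""
    return HeatmapBoxDetector(config).fit(images, boxes)
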