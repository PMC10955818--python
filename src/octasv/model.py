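"""Encoder-decoder network for learned OCTA construction, in pure NumPy.

The network maps a C-channel stack of adjacent OCT B-scans (C = 1 or 3,
channels ordered (s-1, s, s+1)) to a single-channel OCTA B-scan, training
against conventional temporal speckle-variance angiograms.  It is a plain
convolutional U-Net: per level two 3x3 conv + ReLU blocks, 2x2 average
pooling down, nearest-neighbor upsampling with skip concatenation up, and
a final 1x1 convolution with a sigmoid squashing outputs into [0, 1].

Forward and backward passes are written directly against NumPy (im2col
convolutions, hand-derived gradients, Adam), which keeps training fully
deterministic for a given seed.  Both losses the study design compares are
provided: mean squared error and a differentiable SSIM loss sharing the
exact valid-window Gaussian formulation of :mod:`octasv.metrics`.

Arrays are NCHW throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .io import AngiogramVolume, OCTVolume
from .metrics import gaussian_window
from .octa import assemble_neighbor_stack


@dataclass
class ModelSpec:
    in_channels: int = 3
    base_width: int = 16
    depth: int = 3          # encoder levels (including bottleneck)
    skip_connections: bool = True

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 or 3")
        if self.base_width < 1 or self.depth < 1:
            raise ValueError("base_width and depth must be positive")


@dataclass
class TrainConfig:
    loss: str = "ssim"      # mse | ssim
    lr: float = 1e-3
    epochs: int = 10
    batch: int = 8
    patch_size: int = 64
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.loss not in ("mse", "ssim"):
            raise ValueError("loss must be 'mse' or 'ssim'")
        if min(self.lr, self.epochs, self.batch, self.patch_size) <= 0:
            raise ValueError("training parameters must be positive")


# ---------------------------------------------------------------------------
# layers


_DTYPE = np.float32  # training precision; ample for these losses


class _Conv:
    """kxk convolution, zero padding (k-1)/2, stride 1, via im2col + GEMM."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k)).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)
        self.k = k
        self.pad = (k - 1) // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, c*k*k, h*w)
        cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * k * k, h * w)
        self._cols, self._xshape = cols, x.shape
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = np.matmul(wmat, cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.pad
        cout = self.W.shape[0]
        dflat = np.ascontiguousarray(dout, dtype=_DTYPE).reshape(n, cout, h * w)
        self.dW += np.matmul(dflat, self._cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.W.shape)
        self.db += dflat.sum(axis=(0, 2))
        wmat = self.W.reshape(cout, -1)
        dcols = np.matmul(wmat.T, dflat).reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_DTYPE)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, di, dj]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d):
        return d * self._mask


class _Pool2:
    """2x2 average pooling."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, d):
        n, c, h, w = self._shape
        return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) * 0.25


class _Up2:
    """Nearest-neighbor 2x upsampling (adjoint: 2x2 block sum)."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, d):
        n, c, h, w = d.shape
        return d.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Small configurable U-Net; see :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d, wdt = spec.depth, spec.base_width
        widths = [wdt * 2**i for i in range(d)]
        self.enc: list[tuple[_Conv, _ReLU, _Conv, _ReLU]] = []
        cin = spec.in_channels
        for i in range(d):
            c1 = _Conv(cin, widths[i], 3, rng)
            c2 = _Conv(widths[i], widths[i], 3, rng)
            self.enc.append((c1, _ReLU(), c2, _ReLU()))
            cin = widths[i]
        self.pools = [_Pool2() for _ in range(d - 1)]
        self.ups = [_Up2() for _ in range(d - 1)]
        self.dec: list[tuple[_Conv, _ReLU, _Conv, _ReLU]] = []
        for i in range(d - 2, -1, -1):
            cat = widths[i + 1] + (widths[i] if spec.skip_connections else 0)
            c1 = _Conv(cat, widths[i], 3, rng)
            c2 = _Conv(widths[i], widths[i], 3, rng)
            self.dec.append((c1, _ReLU(), c2, _ReLU()))
        self.head = _Conv(widths[0], 1, 1, rng)
        # set by `train` so prediction can reuse the training normalization
        self.input_scale: float = 1.0
        self.target_scale: float = 1.0

    # -- parameter plumbing -------------------------------------------------

    @property
    def convs(self) -> list[_Conv]:
        out = []
        for blk in self.enc + self.dec:
            out += [blk[0], blk[2]]
        out.append(self.head)
        return out

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self.convs)

    def zero_grad(self) -> None:
        for c in self.convs:
            c.dW[:] = 0
            c.db[:] = 0

    # -- passes -------------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """[n, C, h, w] -> [n, 1, h, w], outputs in (0, 1).

        h and w must be divisible by 2**(depth-1).
        """
        div = 2 ** (self.spec.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(f"spatial size {x.shape[2:]} not divisible by {div}")
        skips = []
        for i, (c1, r1, c2, r2) in enumerate(self.enc):
            x = r2.forward(c2.forward(r1.forward(c1.forward(x))))
            if i < len(self.enc) - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = []
        for j, (c1, r1, c2, r2) in enumerate(self.dec):
            x = self.ups[j].forward(x)
            if self.spec.skip_connections:
                skip = skips.pop()
                self._skip_channels.append(skip.shape[1])
                x = np.concatenate([x, skip], axis=1)
            x = r2.forward(c2.forward(r1.forward(c1.forward(x))))
        z = self.head.forward(x)
        self._y = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
        return self._y

    def backward(self, dy: np.ndarray) -> None:
        d = dy * self._y * (1.0 - self._y)
        d = self.head.backward(d)
        skip_grads = []
        for j in range(len(self.dec) - 1, -1, -1):
            c1, r1, c2, r2 = self.dec[j]
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
            if self.spec.skip_connections:
                nskip = self._skip_channels[j]
                d, dskip = d[:, :-nskip], d[:, -nskip:]
                skip_grads.append(dskip)
            d = self.ups[j].backward(d)
        for i in range(len(self.enc) - 1, -1, -1):
            c1, r1, c2, r2 = self.enc[i]
            if i < len(self.enc) - 1:
                d = self.pools[i].backward(d)
                if self.spec.skip_connections:
                    # skip_grads[k] holds the gradient for enc[k]'s output
                    # (decoder backward visits deepest-last)
                    d = d + skip_grads[i]
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))


def build_model(spec: ModelSpec, seed: int = 0) -> UNet:
    """Construct a U-Net with He-initialized weights (deterministic in seed)."""
    return UNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# losses


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


_SSIM_C1 = 0.01**2  # L = 1
_SSIM_C2 = 0.03**2


def ssim_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """1 - mean SSIM (L = 1) over valid Gaussian windows, with gradient.

    Accepts [n, 1, h, w] batches or bare 2-D images in [0, 1].  The value
    matches ``1 - metrics.ssim_map(pred, target, L=1)[0]``; the gradient is
    the analytic derivative of the SSIM map mean w.r.t. ``pred``.
    """
    squeeze = pred.ndim == 2
    p = pred[None, None] if squeeze else pred
    t = target[None, None] if squeeze else target
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    w = gaussian_window()[None, None]

    def F(im):
        return fftconvolve(im, w, mode="valid", axes=(-2, -1))

    mx, my = F(p), F(t)
    sxx = F(p * p) - mx * mx
    syy = F(t * t) - my * my
    sxy = F(p * t) - mx * my
    A1 = 2 * mx * my + _SSIM_C1
    A2 = 2 * sxy + _SSIM_C2
    B1 = mx * mx + my * my + _SSIM_C1
    B2 = sxx + syy + _SSIM_C2
    S = (A1 * A2) / (B1 * B2)
    loss = 1.0 - float(S.mean())

    dS = -1.0 / S.size  # d(loss)/dS at each window
    g_mu = dS * S * (2 * my / A1 - 2 * mx / B1) + dS * (-S / B2) * (-2 * mx) + dS * (2 * S / A2) * (-my)
    g_m2 = dS * (-S / B2)
    g_m11 = dS * (2 * S / A2)

    def FT(gm):  # adjoint of valid correlation with a symmetric kernel
        return fftconvolve(gm, w, mode="full", axes=(-2, -1))

    dp = FT(g_mu) + 2 * p * FT(g_m2) + t * FT(g_m11)
    return loss, (dp[0, 0] if squeeze else dp)


_LOSSES = {"mse": mse_loss, "ssim": ssim_loss}


# ---------------------------------------------------------------------------
# optimizer & training


class _Adam:
    def __init__(self, convs: list[_Conv], lr: float):
        self.convs = convs
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state = [
            (np.zeros_like(c.W), np.zeros_like(c.W), np.zeros_like(c.b), np.zeros_like(c.b))
            for c in convs
        ]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for c, (mW, vW, mb, vb) in zip(self.convs, self.state):
            for p, g, m, v in ((c.W, c.dW, mW, vW), (c.b, c.db, mb, vb)):
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    model: UNet,
    inputs: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig,
    val_inputs: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
) -> dict:
    """Train on paired arrays: inputs [n, C, h, w], targets [n, 1, h, w].

    Both must already be normalized to [0, 1] (see
    :func:`octasv.ablation.build_dataset`).  Deterministic given
    ``cfg.seed`` (data order; weight init is fixed at model construction).
    Returns {"train_loss": per-epoch means, "val_loss": per-epoch values}.
    """
    if len(inputs) == 0:
        raise ValueError("empty dataset")
    if inputs.shape[0] != targets.shape[0]:
        raise ValueError("inputs/targets length mismatch")
    loss_fn = _LOSSES[cfg.loss]
    # Output-bias initialization: start the squashed output at the target
    # mean, so sparse targets do not drive the sigmoid into saturation
    # before spatial structure can form.
    if not np.any(model.head.b):
        mean_t = float(np.clip(targets.mean(), 1e-4, 1 - 1e-4))
        model.head.b[:] = np.log(mean_t / (1 - mean_t))
    opt = _Adam(model.convs, cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    n = inputs.shape[0]
    curve: list[float] = []
    val_curve: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch):
            idx = order[start : start + cfg.batch]
            x, t = inputs[idx], targets[idx]
            pred = model.forward(x)
            loss, dpred = loss_fn(pred, t)
            model.zero_grad()
            model.backward(dpred)
            opt.step()
            losses.append(loss)
        curve.append(float(np.mean(losses)))
        if val_inputs is not None and len(val_inputs):
            vp = model.forward(val_inputs)
            val_curve.append(loss_fn(vp, val_targets)[0])
    return {"train_loss": curve, "val_loss": val_curve}


def _pad_to_multiple(img: np.ndarray, div: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape[-2:]
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        img = np.pad(img, [(0, 0)] * (img.ndim - 2) + [(0, ph), (0, pw)], mode="reflect")
    return img, (h, w)


def predict_volume(
    model: UNet,
    vol: OCTVolume,
    edge_policy: str = "reflect",
    single_repeat: bool = True,
    batch: int = 8,
) -> AngiogramVolume:
    """Run per-slow-position inference over neighbor stacks.

    Inputs are scaled by the model's stored ``input_scale``.  The network
    regresses amplitude-compressed flow contrast (sqrt of speckle
    variance, scaled by ``target_scale``); the output is decompressed back
    into variance units.
    """
    C = model.spec.in_channels
    div = 2 ** (model.spec.depth - 1)
    stacks = []
    for s in range(vol.S):
        st = assemble_neighbor_stack(vol, s, C=C, edge_policy=edge_policy,
                                     single_repeat=single_repeat)
        stacks.append(np.moveaxis(st.data, -1, 0))  # [C, Z, X]
    x = np.asarray(stacks) / model.input_scale
    np.clip(x, 0.0, 1.0, out=x)
    x, (z0, x0) = _pad_to_multiple(x, div)
    preds = []
    for start in range(0, len(x), batch):
        preds.append(model.forward(x[start : start + batch])[:, 0])
    out = (np.concatenate(preds)[:, :z0, :x0].astype(np.float64) * model.target_scale) ** 2
    return AngiogramVolume(out, provenance="model", n_scans=C)


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: UNet, path) -> None:
    import json

    arrays = {}
    for i, c in enumerate(model.convs):
        arrays[f"W{i}"] = c.W
        arrays[f"b{i}"] = c.b
    meta = {
        "in_channels": model.spec.in_channels,
        "base_width": model.spec.base_width,
        "depth": model.spec.depth,
        "skip_connections": model.spec.skip_connections,
        "input_scale": model.input_scale,
        "target_scale": model.target_scale,
    }
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_model(path) -> UNet:
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["_meta"]))
    spec = ModelSpec(
        in_channels=int(meta["in_channels"]),
        base_width=int(meta["base_width"]),
        depth=int(meta["depth"]),
        skip_connections=bool(meta["skip_connections"]),
    )
    model = UNet(spec, seed=0)
    for i, c in enumerate(model.convs):
        c.W = data[f"W{i}"]
        c.b = data[f"b{i}"]
    model.input_scale = float(meta["input_scale"])
    model.target_scale = float(meta["target_scale"])
    return model
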