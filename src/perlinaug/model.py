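"""Scaled-down encoder-decoder CNN for per-pixel six-class patch labeling.

The architecture family follows the FusionNet pattern — an encoding
(downscaling) path of convolution + residual blocks with 2x2 max-pooling, a
bridge, and a symmetric decoding (upscaling) path with skip connections that
add encoder features back in — but at desk scale: depth 2 and 16 base
filters by default, with 4x4 convolution kernels throughout and a 1x1
classification head producing per-pixel softmax probabilities over the six
texture classes.

The backend is a small pure-numpy network (im2col convolutions, manual
backpropagation, Adam).  It is single-threaded and bit-deterministic given
the seeds, which is what the reproducibility contract of this package needs;
it makes no attempt at GPU-scale throughput.

Inputs whose sides are not divisible by ``2**depth`` are reflect-padded to
the next multiple on the way in and the output grid is cropped back to the
input size (a 20x20 patch passes depth 2 untouched, since 20 is divisible by
4, and is padded to 24x24 at depth 3).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .augment import AugmentedPatch, Patch, make_batch
from .data import DatasetSplit
from .textures import HU_RANGE

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "FusionNetSmall",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the scaled-down network."""

    depth: int = 2
    base_filters: int = 16
    kernel_size: int = 4
    n_classes: int = 6
    use_residual: bool = True
    use_skip_connections: bool = True
    auto_pad: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size < 2:
            raise ValueError("kernel_size must be >= 2")
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop hyperparameters."""

    batch_size: int = 16
    max_steps: int = 400
    eval_interval: int = 25
    early_stop_patience: int = 6
    learning_rate: float = 2e-3
    seed: int = 0
    augmentation_mode: str = "perlin"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.augmentation_mode not in ("perlin", "conventional", "none"):
            raise ValueError(f"unknown augmentation_mode: {self.augmentation_mode!r}")


# ---------------------------------------------------------------------------
# layers


class _Conv2d:
    """Stride-1 'same' convolution via im2col (asymmetric pad for even kernels)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.pl = (k - 1) // 2
        self.pr = k - 1 - self.pl
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k = self.k
        xp = np.pad(x, ((0, 0), (0, 0), (self.pl, self.pr), (self.pl, self.pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.W.T + self.b
        return np.ascontiguousarray(out.transpose(0, 2, 1).reshape(B, self.c_out, H, W))

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        k = self.k
        gf = g.reshape(B, self.c_out, H * W).transpose(0, 2, 1)
        self.grads[0][...] = np.tensordot(gf, self._cols, axes=([0, 1], [0, 1]))
        self.grads[1][...] = gf.sum(axis=(0, 1))
        dcols = (gf @ self.W).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + k - 1, W + k - 1))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + H, kj : kj + W] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, self.pl : self.pl + H, self.pl : self.pl + W]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class _MaxPool2:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(B, C, H // 2, W // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        scat = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(scat, self._idx[..., None], g[..., None], axis=-1)
        return scat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)


class _Upsample2:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, C, H, W = g.shape
        return g.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class _ResBlock:
    """conv -> relu -> conv with an identity shortcut (optional) and a final relu."""

    def __init__(self, channels: int, k: int, rng: np.random.Generator, residual: bool):
        self.conv1 = _Conv2d(channels, channels, k, rng)
        self.relu1 = _ReLU()
        self.conv2 = _Conv2d(channels, channels, k, rng)
        self.relu2 = _ReLU()
        self.residual = residual
        self.params = self.conv1.params + self.conv2.params
        self.grads = self.conv1.grads + self.conv2.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(y + x if self.residual else y)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(g)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return dx + g if self.residual else dx


class _ConvRelu:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.conv = _Conv2d(c_in, c_out, k, rng)
        self.relu = _ReLU()
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu.forward(self.conv.forward(x))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.relu.backward(g))


# ---------------------------------------------------------------------------
# network


class FusionNetSmall:
    """Encoder-decoder with residual blocks and additive skip connections."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 window: tuple[float, float] = HU_RANGE):
        self.config = config
        self.window = window
        rng = np.random.default_rng(np.random.SeedSequence([0x5EED, int(seed)]))
        k, F, d = config.kernel_size, config.base_filters, config.depth

        self.enc_in: list[_ConvRelu] = []
        self.enc_res: list[_ResBlock] = []
        self.pools: list[_MaxPool2] = []
        c = 1
        for level in range(d):
            c_out = F * 2**level
            self.enc_in.append(_ConvRelu(c, c_out, k, rng))
            self.enc_res.append(_ResBlock(c_out, k, rng, config.use_residual))
            self.pools.append(_MaxPool2())
            c = c_out
        self.bridge_in = _ConvRelu(c, F * 2**d, k, rng)
        self.bridge_res = _ResBlock(F * 2**d, k, rng, config.use_residual)
        c = F * 2**d

        self.ups: list[_Upsample2] = []
        self.dec_in: list[_ConvRelu] = []
        self.dec_res: list[_ResBlock] = []
        for level in reversed(range(d)):
            c_out = F * 2**level
            self.ups.append(_Upsample2())
            self.dec_in.append(_ConvRelu(c, c_out, k, rng))
            self.dec_res.append(_ResBlock(c_out, k, rng, config.use_residual))
            c = c_out
        self.head = _Conv2d(c, config.n_classes, 1, rng)

        self._layers = (
            self.enc_in + self.enc_res + [self.bridge_in, self.bridge_res]
            + self.dec_in + self.dec_res + [self.head]
        )
        self.params = [p for layer in self._layers for p in layer.params]
        self.grads = [g for layer in self._layers for g in layer.grads]

    # -- geometry ----------------------------------------------------------
    def _pad_amount(self, n: int) -> int:
        m = 2**self.config.depth
        return (-n) % m

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, H, W) normalized intensities -> (B, n_classes, H, W) logits."""
        B, C, H, W = x.shape
        ph, pw = self._pad_amount(H), self._pad_amount(W)
        if ph or pw:
            if not self.config.auto_pad:
                raise ValueError(
                    f"input {H}x{W} is not divisible by 2**depth="
                    f"{2**self.config.depth}; pad to {H + ph}x{W + pw}"
                )
            a, b = ph // 2, ph - ph // 2
            c_, d_ = pw // 2, pw - pw // 2
            x = np.pad(x, ((0, 0), (0, 0), (a, b), (c_, d_)), mode="reflect")
        self._crop = (ph // 2, H, pw // 2, W)

        skips = []
        for enc, res, pool in zip(self.enc_in, self.enc_res, self.pools):
            x = res.forward(enc.forward(x))
            skips.append(x)
            x = pool.forward(x)
        x = self.bridge_res.forward(self.bridge_in.forward(x))
        self._skip_used = []
        for up, dec, res, skip in zip(self.ups, self.dec_in, self.dec_res, reversed(skips)):
            x = dec.forward(up.forward(x))
            if self.config.use_skip_connections:
                x = x + skip
            x = res.forward(x)
        logits = self.head.forward(x)
        a, H0, c_, W0 = self._crop
        return logits[:, :, a : a + H0, c_ : c_ + W0]

    def backward(self, dlogits: np.ndarray) -> None:
        a, H0, c_, W0 = self._crop
        B, C = dlogits.shape[:2]
        ph = self._pad_amount(H0)
        pw = self._pad_amount(W0)
        full = np.zeros((B, C, H0 + ph, W0 + pw))
        full[:, :, a : a + H0, c_ : c_ + W0] = dlogits
        g = self.head.backward(full)
        skip_grads: list[np.ndarray] = []
        for idx in reversed(range(len(self.dec_res))):
            g = self.dec_res[idx].backward(g)
            if self.config.use_skip_connections:
                skip_grads.append(g)
            else:
                skip_grads.append(None)
            g = self.ups[idx].backward(self.dec_in[idx].backward(g))
        g = self.bridge_in.backward(self.bridge_res.backward(g))
        # decoder stage idx consumed encoder skip level depth-1-idx, so the
        # reverse-appended skip_grads list is indexed directly by level
        for level in reversed(range(len(self.enc_in))):
            g = self.pools[level].backward(g)
            sg = skip_grads[level]
            if sg is not None:
                g = g + sg
            g = self.enc_in[level].backward(self.enc_res[level].backward(g))

    # -- inference helpers -------------------------------------------------
    def _normalize(self, pixels: np.ndarray) -> np.ndarray:
        lo, hi = self.window
        return np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)

    def predict_probs(self, pixels: np.ndarray) -> np.ndarray:
        """Raw-intensity (H, W) or (B, H, W) -> per-pixel class probabilities.

        Returns (H, W, n_classes) or (B, H, W, n_classes); probabilities at
        every pixel sum to 1.
        """
        arr = np.asarray(pixels, dtype=np.float64)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        x = self._normalize(arr)[:, None, :, :]
        # chunked forward: the im2col buffers cached per layer scale with the
        # batch, so large tile batches are processed in slices
        chunks = []
        for start in range(0, x.shape[0], 64):
            logits = self.forward(x[start : start + 64])
            chunks.append(_softmax(logits).transpose(0, 2, 3, 1))
        probs = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
        return probs[0] if single else probs

    def snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, s in zip(self.params, snap):
            p[...] = s


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(config: ModelConfig | None = None, seed: int = 0,
                window: tuple[float, float] = HU_RANGE) -> FusionNetSmall:
    """Construct the network with seeded He-normal initialization."""
    return FusionNetSmall(config or ModelConfig(), seed=seed, window=window)


def predict(model: FusionNetSmall, patch: Patch | np.ndarray):
    """Per-pixel prediction for one patch.

    Returns ``(labels, probs)``: the argmax label grid (ties broken toward
    the lowest class index) and the (H, W, n_classes) probability grid.
    """
    pixels = patch.pixels if isinstance(patch, (Patch, AugmentedPatch)) else np.asarray(patch)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2D patch, got shape {pixels.shape}")
    probs = model.predict_probs(pixels)
    return probs.argmax(axis=-1), probs


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        self.params, self.grads, self.lr = params, grads, lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _heldout_pixel_accuracy(model: FusionNetSmall, test_patches) -> float:
    pixels = np.stack([p.pixels for p in test_patches])
    probs = model.predict_probs(pixels)
    pred = probs.argmax(axis=-1)
    truth = np.stack(
        [p.labels if isinstance(p, AugmentedPatch)
         else np.full(p.shape, int(p.label)) for p in test_patches]
    )
    return float(np.mean(pred == truth) * 100.0)


def _draw_plain_batch(pool, batch_size: int, seed: int) -> list[AugmentedPatch]:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), size=batch_size)
    return [
        AugmentedPatch(
            pixels=pool[i].pixels,
            labels=np.full(pool[i].shape, int(pool[i].label), dtype=np.int64),
            provenance=(int(pool[i].label),),
        )
        for i in idx
    ]


def train(
    model: FusionNetSmall,
    split: DatasetSplit,
    tcfg: TrainConfig | None = None,
    aug_params: dict | None = None,
):
    """Train on seeded augmented batches with early stopping.

    Every ``eval_interval`` steps the held-out pixel accuracy is measured on
    the (never augmented) test set; training stops once it has failed to
    improve for ``early_stop_patience`` consecutive evaluations, or at
    ``max_steps``.  The model is restored to the best checkpoint before
    returning, so its held-out accuracy equals the maximum in the history.

    Step s's batch seed is ``(seed * 1000003 + s) % 2**31``.  Returns
    ``(model, history)`` with one history record per evaluation:
    ``{"step", "train_loss", "val_accuracy"}``.
    """
    tcfg = tcfg or TrainConfig()
    if len(split.train) == 0 or len(split.test) == 0:
        raise ValueError("split must have non-empty train and test sets")
    history: list[dict] = []
    if tcfg.max_steps <= 0:
        return model, history

    opt = _Adam(model.params, model.grads, tcfg.learning_rate)
    pool = list(split.train)
    best_acc = -np.inf
    best_snap = model.snapshot()
    stale = 0
    loss_window: list[float] = []

    for step in range(1, tcfg.max_steps + 1):
        bseed = (tcfg.seed * 1000003 + step) % 2**31
        if tcfg.augmentation_mode == "none":
            batch = _draw_plain_batch(pool, tcfg.batch_size, bseed)
        else:
            batch = make_batch(pool, tcfg.batch_size, mode=tcfg.augmentation_mode,
                               noise_params=aug_params, seed=bseed)
        x = model._normalize(np.stack([b.pixels for b in batch]))[:, None]
        y = np.stack([b.labels for b in batch])

        logits = model.forward(x)
        probs = _softmax(logits)
        B, C, H, W = probs.shape
        onehot = np.eye(C)[y].transpose(0, 3, 1, 2)
        loss = float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged (non-finite loss) at step {step}")
        loss_window.append(loss)
        model.backward((probs - onehot) / (B * H * W))
        opt.step()

        if step % tcfg.eval_interval == 0 or step == tcfg.max_steps:
            acc = _heldout_pixel_accuracy(model, split.test)
            history.append(
                {"step": step, "train_loss": float(np.mean(loss_window)), "val_accuracy": acc}
            )
            loss_window = []
            if acc > best_acc:
                best_acc = acc
                best_snap = model.snapshot()
                stale = 0
            else:
                stale += 1
                if stale >= tcfg.early_stop_patience:
                    break

    model.restore(best_snap)
    return model, history


# ---------------------------------------------------------------------------
# serialization


def save_model(model: FusionNetSmall, path: str | Path) -> None:
    """Write weights (.npz) plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), *model.params)
    meta = {"config": asdict(model.config), "window": list(model.window),
            "n_parameters": model.n_parameters()}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> FusionNetSmall:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = build_model(ModelConfig(**meta["config"]), window=tuple(meta["window"]))
    with np.load(path.with_suffix(".npz")) as npz:
        for p, key in zip(model.params, npz.files):
            p[...] = npz[key]
    return model
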