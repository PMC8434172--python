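"""Epidermis segmentation: Dice metrics, Dice-style losses, and a small
trainable encoder–decoder.

The segmenter is a 3-level U-Net-style fully-convolutional network with
skip connections, sized for desk-scale phantoms; larger pretrained
backbones can be plugged in behind the same :class:`SegmenterModel`
handle. Training uses SGD with momentum, batch size 8 by default, and one
of three losses: pixel-wise cross-entropy, mean per-class Dice loss, or
weighted generalized Dice loss (weights default to inverse squared class
volume), which copes with the strong epidermis/background pixel imbalance.
Augmentation during training: random horizontal reflection and ±10-pixel
translations in both directions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .types import EpidermisMask, UltrasoundImage, require_same_shape

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics and losses
# ---------------------------------------------------------------------------

def dice_index(a: EpidermisMask, b: EpidermisMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    require_same_shape(a.grid, b.grid, "masks")
    na, nb = int(a.grid.sum()), int(b.grid.sum())
    if na + nb == 0:
        return 1.0
    inter = int((a.grid & b.grid).sum())
    return 2.0 * inter / (na + nb)


def generalized_dice_loss(
    pred: np.ndarray,
    target: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> float:
    """Weighted generalized Dice loss.

    ``pred``: per-class probabilities, shape (C, ...) summing to 1 over C.
    ``target``: one-hot ground truth of the same shape.
    ``class_weights``: positive weights per class; default inverse squared
    class volume (1/|target_c|²), the formulation that rebalances rare
    classes such as a thin epidermis band.

    Returns ``1 − 2·Σ_c w_c Σ p·t / Σ_c w_c Σ (p+t)``; 0 iff the
    prediction equals the one-hot target exactly.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"pred/target shape mismatch: {pred.shape} vs {target.shape}")
    C = pred.shape[0]
    psum = pred.reshape(C, -1)
    tsum = target.reshape(C, -1)
    if class_weights is None:
        vol = tsum.sum(axis=1)
        class_weights = 1.0 / np.maximum(vol, 1.0) ** 2
    w = np.asarray(class_weights, dtype=np.float64)
    if w.shape != (C,) or not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("class weights must be finite and positive, one per class")
    num = 2.0 * (w * (psum * tsum).sum(axis=1)).sum()
    den = (w * (psum + tsum).sum(axis=1)).sum()
    return float(1.0 - num / den)


def _gdl_grad_wrt_prob(pred, target, w):
    """Analytic gradient of the generalized Dice loss w.r.t. pred probs."""
    C = pred.shape[0]
    psum = pred.reshape(C, -1)
    tsum = target.reshape(C, -1)
    num = 2.0 * (w * (psum * tsum).sum(axis=1)).sum()
    den = (w * (psum + tsum).sum(axis=1)).sum()
    # d/dp_ci [1 - num/den] = -(2 w_c t_ci den - num w_c) / den^2
    g = -(2.0 * w[:, None] * tsum * den - num * w[:, None]) / den**2
    return g.reshape(pred.shape)


# ---------------------------------------------------------------------------
# Training configuration and model
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    """Hyperparameters for epidermis-segmenter training."""

    loss: str = "generalized_dice_weighted"  # cross_entropy | dice | generalized_dice_weighted
    batch_size: int = 8
    max_epochs: int = 10          # reduced default for desk-scale phantoms
    learning_rate: float = 0.05
    momentum: float = 0.9
    augment: bool = True          # horizontal reflection + ±10 px translations
    base_channels: int = 8
    crop_size: int = 128          # random training crops (net is fully conv)
    # Small cross-entropy term added to the Dice-family losses (the usual
    # Dice+CE compound): pure Dice losses lose their gradient once the
    # softmax saturates toward all-background, and the CE term keeps
    # per-pixel signal alive. 0 disables it.
    ce_stabilizer: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.loss not in ("cross_entropy", "dice", "generalized_dice_weighted"):
            raise ValueError(f"unknown loss {self.loss!r}")


class UNetSmall:
    """3-level encoder–decoder with skip connections, 2-class output.

    Channel widths ``c, 2c, 4c`` down the encoder. Spatial dims must be
    divisible by 4. Explicit forward/backward so the training loop stays a
    plain numpy program.
    """

    def __init__(self, base_channels: int = 8, rng=None) -> None:
        rng = rng or np.random.default_rng()
        c = base_channels
        self.enc1 = nn.Conv2D(1, c, 3, rng)
        self.enc2 = nn.Conv2D(c, 2 * c, 3, rng)
        self.bott = nn.Conv2D(2 * c, 4 * c, 3, rng)
        self.dec2 = nn.Conv2D(4 * c + 2 * c, 2 * c, 3, rng)
        self.dec1 = nn.Conv2D(2 * c + c, c, 3, rng)
        self.head = nn.Conv2D(c, 2, 1, rng)
        self.r = [nn.ReLU() for _ in range(5)]
        self.p1, self.p2 = nn.MaxPool2(), nn.MaxPool2()
        self.u2, self.u1 = nn.Upsample2(), nn.Upsample2()
        self.c = c

    def _convs(self):
        return [self.enc1, self.enc2, self.bott, self.dec2, self.dec1, self.head]

    def forward(self, x: np.ndarray) -> np.ndarray:
        e1 = self.r[0].forward(self.enc1.forward(x))
        e2 = self.r[1].forward(self.enc2.forward(self.p1.forward(e1)))
        b = self.r[2].forward(self.bott.forward(self.p2.forward(e2)))
        d2 = self.r[3].forward(self.dec2.forward(
            np.concatenate([self.u2.forward(b), e2], axis=1)))
        d1 = self.r[4].forward(self.dec1.forward(
            np.concatenate([self.u1.forward(d2), e1], axis=1)))
        return self.head.forward(d1)  # logits (N, 2, H, W)

    def backward(self, grad_logits: np.ndarray) -> None:
        c = self.c
        g = self.head.backward(grad_logits)
        g = self.dec1.backward(self.r[4].backward(g))
        g_u1, g_e1_skip = g[:, : 2 * c], g[:, 2 * c:]
        g = self.dec2.backward(self.r[3].backward(self.u1.backward(g_u1)))
        g_u2, g_e2_skip = g[:, : 4 * c], g[:, 4 * c:]
        g = self.bott.backward(self.r[2].backward(self.u2.backward(g_u2)))
        g = self.p2.backward(g) + g_e2_skip
        g = self.enc2.backward(self.r[1].backward(g))
        g = self.p1.backward(g) + g_e1_skip
        self.enc1.backward(self.r[0].backward(g))

    def parameters(self):
        out = []
        for conv in self._convs():
            out.extend(zip(conv.params, conv.grads))
        return out

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, conv in enumerate(self._convs()):
            arrays[f"W{i}"], arrays[f"b{i}"] = conv.W, conv.b
        np.savez(Path(path), **arrays)

    def load(self, path: str | Path) -> None:
        data = np.load(Path(path))
        for i, conv in enumerate(self._convs()):
            conv.W[...] = data[f"W{i}"]
            conv.b[...] = data[f"b{i}"]


@dataclass
class SegmenterModel:
    """Trained-segmenter handle: network + training log."""

    net: UNetSmall
    config: SegTrainConfig
    train_log: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        self.net.save(path)

    def predict_probs(self, image: UltrasoundImage) -> np.ndarray:
        """Foreground (epidermis) probability grid at the image size."""
        x, pad = _pad_to_mult4(image.pixels)
        logits = self.net.forward(x[None, None])
        p = nn.softmax(np.moveaxis(logits[0], 0, -1))[..., 1]
        return p[: image.shape[0], : image.shape[1]]


def _pad_to_mult4(img: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    ph, pw = (-h) % 4, (-w) % 4
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)))
    return img, (ph, pw)


def _loss_and_grad(logits: np.ndarray, target_onehot: np.ndarray,
                   loss_name: str, ce_stabilizer: float = 0.0
                   ) -> tuple[float, np.ndarray]:
    """Per-pixel softmax + chosen loss; returns loss and grad w.r.t. logits.

    ``logits``/``target_onehot``: (N, 2, H, W). For the Dice-family losses
    ``ce_stabilizer`` adds that multiple of the pixel-wise cross-entropy.
    """
    n, C = logits.shape[0], logits.shape[1]
    z = np.moveaxis(logits, 1, -1)                       # (N, H, W, C)
    prob = nn.softmax(z)
    p = np.moveaxis(prob, -1, 1)                         # (N, C, H, W)
    t = target_onehot
    npix = np.prod(t.shape) / C
    ce_loss = float(-(t * np.log(p + 1e-12)).sum() / npix)
    ce_grad = (p - t) / npix

    if loss_name == "cross_entropy":
        return ce_loss, ce_grad

    # Dice-family: accumulate per sample, chain through softmax.
    losses, dlogits = [], np.empty_like(p)
    for i in range(n):
        if loss_name == "generalized_dice_weighted":
            vol = t[i].reshape(C, -1).sum(axis=1)
            w = 1.0 / np.maximum(vol, 1.0) ** 2
        else:  # plain dice: equal class weights
            w = np.ones(C)
        losses.append(generalized_dice_loss(p[i], t[i], w))
        dp = _gdl_grad_wrt_prob(p[i], t[i], w)
        # softmax Jacobian: dL/dz_c = p_c (dL/dp_c - sum_k p_k dL/dp_k)
        dot = (p[i] * dp).sum(axis=0, keepdims=True)
        dlogits[i] = p[i] * (dp - dot)
    loss = float(np.mean(losses)) + ce_stabilizer * ce_loss
    return loss, dlogits / n + ce_stabilizer * ce_grad


def _augment_pair(img: np.ndarray, msk: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random horizontal reflection and ±10 px translation (zero fill)."""
    if rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    dy, dx = rng.integers(-10, 11, size=2)
    img = ndimage.shift(img, (dy, dx), order=0, cval=0.0)
    msk = ndimage.shift(msk.astype(float), (dy, dx), order=0, cval=0.0) > 0.5
    return img, msk


def _random_crop(img: np.ndarray, msk: np.ndarray, size: int, rng
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Random size x size crop biased to contain the whole epidermis band
    when it fits (the net is fully convolutional, so training on crops and
    predicting on full frames is consistent)."""
    h, w = img.shape
    if h <= size and w <= size:
        return img, msk
    size_h, size_w = min(size, h), min(size, w)
    rows = np.flatnonzero(msk.any(axis=1))
    if rows.size:
        lo = max(int(rows[-1]) + 1 - size_h, 0)
        hi = min(int(rows[0]), h - size_h)
        y0 = int(rng.integers(lo, hi + 1)) if hi >= lo else int(rng.integers(0, h - size_h + 1))
    else:
        y0 = int(rng.integers(0, h - size_h + 1))
    x0 = int(rng.integers(0, w - size_w + 1))
    return img[y0:y0 + size_h, x0:x0 + size_w], msk[y0:y0 + size_h, x0:x0 + size_w]


def train_segmenter(samples, config: SegTrainConfig | None = None) -> SegmenterModel:
    """Train the small encoder–decoder on phantom (image, mask) samples.

    ``samples``: iterable with ``.image`` (:class:`UltrasoundImage`) and
    ``.mask`` (:class:`EpidermisMask`). Deterministic for a fixed
    ``config.seed``. Warns (but proceeds) if the data contains only one
    pixel class.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    for s in samples:
        if s.mask.is_empty:
            raise ValueError("training masks must be non-empty")
    config = config or SegTrainConfig()
    fg = sum(int(s.mask.grid.sum()) for s in samples)
    bg = sum(s.mask.grid.size for s in samples) - fg
    if fg == 0 or bg == 0:
        warnings.warn("training data contains a single pixel class", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    net = UNetSmall(config.base_channels, rng)
    opt = nn.SGDMomentum(net.parameters(), lr=config.learning_rate,
                         momentum=config.momentum)
    model = SegmenterModel(net=net, config=config)

    imgs = [_pad_to_mult4(s.image.pixels)[0] for s in samples]
    msks = [_pad_to_mult4(s.mask.grid.astype(np.float64))[0] > 0.5 for s in samples]
    n = len(imgs)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            xb, tb = [], []
            for i in idx:
                im, mk = imgs[i], msks[i]
                if config.augment:
                    im, mk = _augment_pair(im, mk, rng)
                im, mk = _random_crop(im, mk, config.crop_size, rng)
                im, _ = _pad_to_mult4(im)
                mk = _pad_to_mult4(mk.astype(np.float64))[0] > 0.5
                xb.append(im)
                tb.append(np.stack([~mk, mk]).astype(np.float64))
            x = np.stack(xb)[:, None]
            t = np.stack(tb)
            logits = net.forward(x)
            loss, dlogits = _loss_and_grad(logits, t, config.loss,
                                           config.ce_stabilizer)
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        model.train_log.append(epoch_loss / n)
        logger.debug("segmenter epoch %d: loss %.4f", epoch, model.train_log[-1])
    return model


def segment(model: SegmenterModel, image: UltrasoundImage,
            threshold: float = 0.5) -> EpidermisMask:
    """Predict the epidermis mask for one image.

    The soft foreground probability is thresholded, then only the largest
    connected component is kept (the downstream skin-layer-map and ROI
    geometry assume a single epidermis band). Raises if the prediction is
    empty, instructing the caller to fall back to a ground-truth mask or
    skip the sample.
    """
    p = model.predict_probs(image)
    binary = p >= threshold
    if not binary.any():
        raise ValueError(
            "segmenter produced an empty mask; fall back to the ground-truth "
            "mask or skip this sample"
        )
    labels, nlab = ndimage.label(binary)
    if nlab > 1:
        sizes = ndimage.sum_labels(binary, labels, index=range(1, nlab + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    return EpidermisMask(binary)
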