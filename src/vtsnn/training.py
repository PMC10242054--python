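"""Training regimes for the spiking U-net: ITBP and STBP.

Both regimes minimise a squared-error objective with Adam, differ only
in where the error is measured and how far gradients travel:

* ITBP (independent-temporal backpropagation) encodes the clean label
  into bit planes and compares them to the raw output spike planes with
  a significance-weighted squared loss,

      L = (1/N) * sum_t 2^t * ||o_t - o_hat_t||_F^2,

  while the membrane state carried between time steps is severed from
  the gradient graph — credit is assigned spatially within each step,
  never across steps.

* STBP (spatio-temporal backpropagation) decodes the output planes with
  the (differentiable) weighted sum of the bit-plane codec and compares
  the real-valued reconstruction to the clean image,

      L = (1/N) * ||y - y_hat||_F^2,

  with gradients flowing through both space and the carried state.

Gradients enter the spike trains through the surrogate derivative of the
firing rule in either case.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import _autodiff as ad
from .codec import CodecConfig, GrayImage, SpikePlaneStack, uwd_decode, uwe_encode
from .evalenergy import MetricReport, psnr
from .network import SpikingModel

__all__ = [
    "BackpropMode",
    "TrainConfig",
    "LossReport",
    "Adam",
    "itbp_loss",
    "stbp_loss",
    "train_step",
    "fit",
    "evaluate",
]


class BackpropMode(str, Enum):
    ITBP = "ITBP"
    STBP = "STBP"


@dataclass
class TrainConfig:
    """Optimisation settings (Adam, lr 0.001, batch 50 by convention)."""

    mode: BackpropMode = BackpropMode.ITBP
    learning_rate: float = 1e-3
    batch_size: int = 50
    epochs: int = 1
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        self.mode = BackpropMode(self.mode)
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LossReport:
    """A scalar loss plus, for ITBP, its per-plane breakdown.

    ``per_plane`` is indexed by stored plane (MSB first); its entries sum
    to ``total * N``.
    """

    total: float
    N: int
    per_plane: np.ndarray | None = None


class Adam:
    """Adaptive-moment gradient descent over a list of weight tensors."""

    def __init__(self, params: list[ad.Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _plane_weights(T: int) -> np.ndarray:
    """Loss weight 2^t keyed to a plane's significance t; storage is MSB
    first, so stored index i carries weight 2^(T-1-i)."""
    return 2.0 ** np.arange(T - 1, -1, -1)


def _stack_planes(x) -> np.ndarray:
    return x.planes if isinstance(x, SpikePlaneStack) else np.asarray(x)


def itbp_loss(target_planes, output_planes, N: int = 1) -> LossReport:
    """Significance-weighted squared error between binary plane stacks."""
    t_arr = _stack_planes(target_planes).astype(np.float64)
    o_arr = _stack_planes(output_planes).astype(np.float64)
    if t_arr.shape != o_arr.shape:
        raise ValueError(f"plane shape mismatch: {t_arr.shape} vs {o_arr.shape}")
    T = t_arr.shape[0]
    diff2 = (t_arr - o_arr) ** 2
    per_plane = _plane_weights(T) * diff2.reshape(T, -1).sum(axis=1)
    return LossReport(total=float(per_plane.sum() / N), N=N, per_plane=per_plane)


def stbp_loss(label, decoded, N: int = 1) -> LossReport:
    """Plain squared Frobenius error between label and decoded image."""
    y = label.pixels if isinstance(label, GrayImage) else np.asarray(label)
    yhat = decoded.pixels if isinstance(decoded, GrayImage) else np.asarray(decoded)
    if y.shape != yhat.shape:
        raise ValueError(f"image shape mismatch: {y.shape} vs {yhat.shape}")
    total = float(((y.astype(np.float64) - yhat) ** 2).sum() / N)
    return LossReport(total=total, N=N)


# -- batched encode/forward helpers --------------------------------------

def encode_batch(images: np.ndarray, T: int = 8) -> np.ndarray:
    """Vectorised bit-plane encoding of a (N, H, W) integer batch to
    (T, N, H, W, 1) float planes, MSB first; bit-identical to the
    per-image codec."""
    images = np.asarray(images)
    shifts = np.arange(T - 1, -1, -1, dtype=np.int64)
    planes = (images.astype(np.int64)[None] >> shifts[:, None, None, None]) & 1
    return planes[..., None].astype(np.float64)


def decode_weighted_sum(outputs: list[ad.Tensor], T: int) -> ad.Tensor:
    """Differentiable bit-plane decode: sum_t 2^sig(t) * o_t.

    Real-valued and gradient-carrying — this is the decode-inside-the-
    loss path of STBP.
    """
    weights = _plane_weights(T)
    acc = ad.scale(outputs[0], weights[0])
    for t in range(1, T):
        acc = ad.add(acc, ad.scale(outputs[t], weights[t]))
    return acc


def _as_batch(images) -> np.ndarray:
    if isinstance(images, GrayImage):
        images = images.pixels
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    return images


def train_step(model: SpikingModel, noisy_image, clean_image,
               config: TrainConfig, optimizer: Adam | None = None) -> LossReport:
    """One gradient step on a batch (or single image).

    ITBP: forward with inter-step state detached, significance-weighted
    plane loss against the encoded clean label. STBP: forward with full
    temporal graph, squared error against the clean image after the
    differentiable weighted-sum decode.
    """
    noisy = _as_batch(noisy_image)
    clean = _as_batch(clean_image)
    if noisy.shape != clean.shape:
        raise ValueError(f"noisy/clean shape mismatch: {noisy.shape} vs {clean.shape}")
    if optimizer is None:
        optimizer = Adam(model.parameters(), lr=config.learning_rate,
                         beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    T = model.spec.time_steps
    N = noisy.shape[0]
    planes_in = encode_batch(noisy, T)
    optimizer.zero_grad()
    if config.mode is BackpropMode.ITBP:
        outs = model.forward_tensor(planes_in, detach_time=True)
        target = encode_batch(clean, T)
        weights = _plane_weights(T)
        loss = None
        per_plane = np.empty(T)
        for t in range(T):
            term = ad.tsum(ad.square(ad.sub(outs[t], ad.Tensor(target[t]))))
            per_plane[t] = weights[t] * term.data
            term = ad.scale(term, weights[t] / N)
            loss = term if loss is None else ad.add(loss, term)
        report = LossReport(total=float(loss.data), N=N, per_plane=per_plane)
    else:
        outs = model.forward_tensor(planes_in, detach_time=False)
        decoded = decode_weighted_sum(outs, T)
        y = ad.Tensor(clean.astype(np.float64)[..., None])
        loss = ad.scale(ad.tsum(ad.square(ad.sub(decoded, y))), 1.0 / N)
        report = LossReport(total=float(loss.data), N=N)
    loss.backward()
    optimizer.step()
    return report


def fit(model: SpikingModel, clean, noisy, config: TrainConfig,
        callback=None) -> list[dict]:
    """Epoch loop: seeded shuffling, mini-batches, Adam updates.

    ``clean``/``noisy`` are aligned (N, H, W) integer arrays (or lists of
    GrayImage). Returns one record per epoch with the mean training loss.
    """
    clean = np.stack([im.pixels if isinstance(im, GrayImage) else np.asarray(im)
                      for im in clean]) if not isinstance(clean, np.ndarray) else clean
    noisy = np.stack([im.pixels if isinstance(im, GrayImage) else np.asarray(im)
                      for im in noisy]) if not isinstance(noisy, np.ndarray) else noisy
    if len(clean) != len(noisy):
        raise ValueError("clean and noisy sets must be index-aligned")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    n = len(clean)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            rep = train_step(model, noisy[idx], clean[idx], config, opt)
            total += rep.total * len(idx)
        record = {"epoch": epoch, "mean_loss": total / n}
        history.append(record)
        if callback is not None:
            callback(record)
    return history


def evaluate(model: SpikingModel, clean, noisy, batch_size: int = 50,
             codec: CodecConfig | None = None) -> list[MetricReport]:
    """Encode -> forward -> decode -> PSNR against the clean image.

    This is the deployment path shared by both regimes: the lossless
    bit-plane codec wraps the network at test time regardless of how it
    was trained. Never mutates weights.
    """
    clean = _as_batch(clean) if not isinstance(clean, list) else np.stack(
        [im.pixels if isinstance(im, GrayImage) else np.asarray(im) for im in clean])
    noisy = _as_batch(noisy) if not isinstance(noisy, list) else np.stack(
        [im.pixels if isinstance(im, GrayImage) else np.asarray(im) for im in noisy])
    if len(clean) == 0:
        raise ValueError("empty dataset")
    if codec is None:
        codec = CodecConfig(n_bits=model.spec.time_steps, T=model.spec.time_steps)
    T = model.spec.time_steps
    weights = _plane_weights(T).astype(np.int64)
    reports: list[MetricReport] = []
    for lo in range(0, len(clean), batch_size):
        cb, nb = clean[lo:lo + batch_size], noisy[lo:lo + batch_size]
        outs = model.forward_tensor(encode_batch(nb, T))
        out_planes = np.stack([o.data for o in outs])  # (T, N, H, W, 1)
        decoded = np.tensordot(weights, out_planes[..., 0], axes=(0, 0))
        for i in range(len(cb)):
            reports.append(psnr(cb[i], decoded[i].astype(np.int64)))
    return reports
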