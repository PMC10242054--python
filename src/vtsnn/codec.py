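"""Bit-exact spike codecs for grayscale images.

The central pair is Undistorted Weighted-Encoding / Decoding (UWE/UWD):
an n-bit pixel is decomposed into n binary spike planes, one per bit of
significance, most-significant plane first. Encoding is the successive
subtraction of powers of two (the digital behaviour of a SAR ADC);
decoding is the weighted sum

    Y = O x_0 A,    A = [2^(T-1), 2^(T-2), ..., 2^0]

expressed as a tensor n-mode product, which reproduces the source image
exactly — the codec is lossless for every integer image.

Two comparison codecs are included: time-to-first-spike (TTFS), a latency
code that is lossy after time quantisation, and membrane-potential
decoding (MPD), a real-valued readout through geometrically decaying
weights (theta = 0.8) and tanh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "GrayImage",
    "SpikePlaneStack",
    "CodecConfig",
    "TTFSRounding",
    "n_mode_product",
    "uwe_encode",
    "uwd_decode",
    "ttfs_encode",
    "mpd_decode",
]


class TTFSRounding(str, Enum):
    FLOOR = "floor"
    NEAREST = "nearest"


@dataclass
class GrayImage:
    """An H x W integer image with pixels in [0, 2**n_bits - 1]."""

    pixels: np.ndarray
    n_bits: int = 8

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage expects a 2-D array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("GrayImage must have H >= 1 and W >= 1")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            if not np.all(self.pixels == np.round(self.pixels)):
                raise ValueError("GrayImage pixels must be integer-valued")
            self.pixels = self.pixels.astype(np.int64)
        hi = (1 << self.n_bits) - 1
        if self.pixels.min() < 0 or self.pixels.max() > hi:
            raise ValueError(
                f"pixels out of range [0, {hi}] for {self.n_bits}-bit image "
                f"(found [{self.pixels.min()}, {self.pixels.max()}])")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class SpikePlaneStack:
    """A T x H x W binary stack of spike planes.

    ``order_convention`` is ``"msb_first"`` for weighted bit-plane stacks
    (plane 0 carries the largest weight) and ``"temporal"`` for latency
    codes, where plane index is simply the time step. ``plane_weights``
    is the decoding weight per stored plane (powers of two for UWE/UWD),
    or None for codes with no weighted-sum inverse.
    """

    planes: np.ndarray
    plane_weights: np.ndarray | None = None
    order_convention: str = "msb_first"

    def __post_init__(self):
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError(f"SpikePlaneStack expects T x H x W, got shape {self.planes.shape}")
        vals = np.unique(self.planes)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("spike planes must be strictly binary (0/1)")
        if self.plane_weights is not None:
            self.plane_weights = np.asarray(self.plane_weights)
            if len(self.plane_weights) != self.planes.shape[0]:
                raise ValueError("plane_weights length must equal the number of planes")
            if np.any(np.diff(self.plane_weights) >= 0):
                raise ValueError("plane_weights must be strictly decreasing")

    @property
    def T(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self):
        return self.planes.shape


@dataclass
class CodecConfig:
    """Parameters shared by the codecs.

    n_bits: bit depth of the images (T = n_bits for UWE/UWD).
    mpd_theta: geometric decay of the MPD readout weights.
    ttfs_rounding: how the real-valued TTFS latency is quantised.
    """

    n_bits: int = 8
    T: int = 8
    mpd_theta: float = 0.8
    ttfs_rounding: TTFSRounding = TTFSRounding.FLOOR

    def __post_init__(self):
        if not (0.0 < self.mpd_theta < 1.0):
            raise ValueError("mpd_theta must lie strictly in (0, 1)")
        self.ttfs_rounding = TTFSRounding(self.ttfs_rounding)

    @property
    def decode_matrix(self) -> np.ndarray:
        """1 x T weight row [2^(T-1), ..., 2^0] for the n-mode decode."""
        return (2 ** np.arange(self.T - 1, -1, -1, dtype=np.int64))[None, :]


def n_mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Multiply the mode-``mode`` unfolding of ``tensor`` by ``matrix``.

    With P of shape (I_0, ..., I_{N-1}) and B of shape (J, I_mode), the
    result Q = P x_mode B has shape (..., J, ...) and unfolds as
    Q_(mode) = B @ P_(mode).
    """
    tensor = np.asarray(tensor)
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if not (0 <= mode < tensor.ndim):
        raise ValueError(f"mode {mode} out of range for {tensor.ndim}-way tensor")
    if matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"dimension mismatch: matrix has {matrix.shape[1]} columns but "
            f"tensor has size {tensor.shape[mode]} along mode {mode}")
    moved = np.moveaxis(tensor, mode, 0)
    unfolded = moved.reshape(tensor.shape[mode], -1)
    result = matrix @ unfolded
    new_shape = (matrix.shape[0],) + moved.shape[1:]
    return np.moveaxis(result.reshape(new_shape), 0, mode)


def uwe_encode(image: GrayImage | np.ndarray, config: CodecConfig | None = None) -> SpikePlaneStack:
    """Encode an n-bit image into n binary spike planes, MSB first.

    Plane of storage index i holds bit (n-1-i): successive subtraction of
    2^(n-1), 2^(n-2), ..., 1 from each pixel emits a spike whenever the
    residual covers the current weight. The weighted sum of the planes
    reproduces the image exactly.
    """
    if config is None:
        config = CodecConfig()
    if not isinstance(image, GrayImage):
        image = GrayImage(np.asarray(image), n_bits=config.n_bits)
    if image.n_bits != config.n_bits:
        raise ValueError(f"image bit depth {image.n_bits} != codec n_bits {config.n_bits}")
    n = config.n_bits
    residual = image.pixels.astype(np.int64).copy()
    planes = np.empty((n,) + image.shape, dtype=np.uint8)
    for i, weight in enumerate(2 ** np.arange(n - 1, -1, -1)):
        fired = residual >= weight
        planes[i] = fired
        residual = residual - weight * fired
    return SpikePlaneStack(planes, plane_weights=2 ** np.arange(n - 1, -1, -1),
                           order_convention="msb_first")


def uwd_decode(spikes: SpikePlaneStack | np.ndarray, config: CodecConfig | None = None) -> GrayImage:
    """Exact inverse of :func:`uwe_encode` via the mode-0 product with A."""
    if config is None:
        config = CodecConfig()
    planes = spikes.planes if isinstance(spikes, SpikePlaneStack) else np.asarray(spikes)
    if planes.ndim != 3:
        raise ValueError(f"expected T x H x W spikes, got shape {planes.shape}")
    if planes.shape[0] != config.T:
        raise ValueError(f"stack has {planes.shape[0]} planes, codec expects T = {config.T}")
    if not np.all(np.isin(np.unique(planes), (0, 1))):
        raise ValueError("spike planes must be strictly binary (0/1)")
    decoded = n_mode_product(planes.astype(np.int64), config.decode_matrix, mode=0)
    return GrayImage(decoded[0], n_bits=config.T)


def ttfs_encode(image: GrayImage | np.ndarray, T: int = 8,
                rounding: TTFSRounding = TTFSRounding.FLOOR) -> SpikePlaneStack:
    """Time-to-first-spike latency code: one spike per pixel at

        t = ((max(x) - x) / max(x)) * T

    quantised per ``rounding``; brighter pixels spike earlier, and a
    computed latency t >= T falls outside the window and emits nothing.
    Lossy for T < 2**n_bits — distinct intensities can share a latency.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if pixels.min() < 0:
        raise ValueError("TTFS requires a nonnegative image")
    planes = np.zeros((T,) + pixels.shape, dtype=np.uint8)
    peak = pixels.max()
    if peak == 0:
        warnings.warn("all-zero image: TTFS emits no spikes", stacklevel=2)
        return SpikePlaneStack(planes, plane_weights=None, order_convention="temporal")
    t_real = (peak - pixels.astype(np.float64)) / peak * T
    rounding = TTFSRounding(rounding)
    t_idx = np.floor(t_real) if rounding is TTFSRounding.FLOOR else np.round(t_real)
    t_idx = t_idx.astype(np.int64)
    inside = t_idx < T
    rows, cols = np.nonzero(inside)
    planes[t_idx[inside], rows, cols] = 1
    return SpikePlaneStack(planes, plane_weights=None, order_convention="temporal")


def mpd_decode(spikes: SpikePlaneStack | np.ndarray, config: CodecConfig | None = None) -> np.ndarray:
    """Membrane-potential decoding: tanh of a theta-weighted spike sum.

    The plane of significance s receives weight theta^(T-1-s), so the
    most significant (first-stored) plane is weighted theta^0 = 1 and
    weights decay geometrically toward the least significant plane. The
    tanh readout keeps the output strictly inside (-1, 1) and makes it
    monotone nondecreasing in every spike bit.
    """
    if config is None:
        config = CodecConfig()
    planes = spikes.planes if isinstance(spikes, SpikePlaneStack) else np.asarray(spikes)
    if planes.ndim != 3:
        raise ValueError(f"expected T x H x W spikes, got shape {planes.shape}")
    if not np.all(np.isin(np.unique(planes), (0, 1))):
        raise ValueError("spike planes must be strictly binary (0/1)")
    T = planes.shape[0]
    weights = config.mpd_theta ** np.arange(T)  # index 0 = most significant
    weighted = np.tensordot(weights, planes.astype(np.float64), axes=(0, 0))
    return np.tanh(weighted)
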