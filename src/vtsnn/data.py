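"""Synthetic image generation, Gaussian corruption and standard readers.

The synthetic generator emulates the structure of small digit-style
benchmarks: a dark background with a few bright smoothed strokes (line
segments, arcs, filled rectangles), 8-bit, 28x28 by default, so the full
pipeline is exercisable without downloads. Noise is additive i.i.d.
Gaussian per pixel with standard deviation eta on the [0, 1] image
scale, clipped and re-quantised to integers — eta is a noise *standard
deviation*, not a variance, so eta = 0.8 still leaves visible signal.

IDX is the container format of the classic MNIST distribution: a
big-endian header (magic 0x00000803 for unsigned-byte rank-3 data)
followed by raw bytes. A reader and writer are included for optional
full-scale runs on real data.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .codec import GrayImage

__all__ = [
    "NoiseConfig",
    "DatasetBundle",
    "add_gaussian_noise",
    "generate_synthetic",
    "read_idx",
    "write_idx",
    "load_image",
    "save_image",
]


@dataclass
class NoiseConfig:
    """Gaussian corruption: eta = std dev on the unit image scale.

    Noisy pixels are clip(x/peak + N(0, eta^2), 0, 1), re-quantised to
    the image's bit depth.
    """

    eta: float
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")


@dataclass
class DatasetBundle:
    """Index-aligned clean/noisy image pairs."""

    clean: list
    noisy: list

    def __post_init__(self):
        if len(self.clean) != len(self.noisy):
            raise ValueError("clean and noisy lists must have equal length")
        for c, n in zip(self.clean, self.noisy):
            if c.shape != n.shape:
                raise ValueError("paired images must share a shape")

    def __len__(self) -> int:
        return len(self.clean)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.stack([im.pixels for im in self.clean]),
                np.stack([im.pixels for im in self.noisy]))


def add_gaussian_noise(image: GrayImage | np.ndarray, config: NoiseConfig,
                       rng: np.random.Generator | None = None) -> GrayImage:
    """Seeded additive Gaussian noise on the unit scale, clip + round."""
    if not isinstance(image, GrayImage):
        image = GrayImage(np.asarray(image))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    peak = (1 << image.n_bits) - 1
    unit = image.pixels / peak
    noisy = unit + rng.normal(0.0, config.eta, size=unit.shape)
    quantised = np.rint(np.clip(noisy, 0.0, 1.0) * peak).astype(np.int64)
    return GrayImage(quantised, n_bits=image.n_bits)


def _draw_segment(img: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape
    x0, y0 = rng.uniform(3, w - 4), rng.uniform(3, h - 4)
    angle = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.3, 0.8) * min(h, w)
    steps = int(length * 2)
    xs = x0 + np.cos(angle) * np.linspace(0, length, steps)
    ys = y0 + np.sin(angle) * np.linspace(0, length, steps)
    ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    img[ys[ok].astype(int), xs[ok].astype(int)] = 1.0


def _draw_arc(img: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape
    cx, cy = rng.uniform(5, w - 5), rng.uniform(5, h - 5)
    r = rng.uniform(0.15, 0.4) * min(h, w)
    a0 = rng.uniform(0, 2 * np.pi)
    span = rng.uniform(np.pi / 2, 2 * np.pi)
    theta = np.linspace(a0, a0 + span, int(r * span) + 8)
    xs, ys = cx + r * np.cos(theta), cy + r * np.sin(theta)
    ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    img[ys[ok].astype(int), xs[ok].astype(int)] = 1.0


def _draw_rect(img: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape
    rh, rw = int(rng.uniform(2, h / 4)), int(rng.uniform(2, w / 4))
    y, x = rng.integers(0, h - rh), rng.integers(0, w - rw)
    img[y:y + rh, x:x + rw] = 1.0


def generate_synthetic(n_images: int, H: int = 28, W: int = 28, seed: int = 0,
                       eta: float = 0.2, n_bits: int = 8) -> DatasetBundle:
    """Seeded digit-like images (bright smoothed strokes on black) paired
    with Gaussian-corrupted copies at noise level ``eta``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if H < 8 or W < 8:
        raise ValueError("image dimensions must be >= 8")
    rng = np.random.default_rng(seed)
    peak = (1 << n_bits) - 1
    shapes = (_draw_segment, _draw_arc, _draw_rect)
    clean, noisy = [], []
    cfg = NoiseConfig(eta=eta, seed=seed)
    for _ in range(n_images):
        canvas = np.zeros((H, W))
        for _ in range(rng.integers(2, 5)):
            shapes[rng.integers(0, len(shapes))](canvas, rng)
        canvas = gaussian_filter(canvas, sigma=0.7)
        if canvas.max() > 0:
            canvas = canvas / canvas.max()
        img = GrayImage(np.rint(canvas * peak).astype(np.int64), n_bits=n_bits)
        clean.append(img)
        noisy.append(add_gaussian_noise(img, cfg, rng=rng))
    return DatasetBundle(clean=clean, noisy=noisy)


# -- IDX container (the MNIST file format) -------------------------------

_IDX_MAGIC_U8_3D = 0x00000803


def read_idx(path) -> list[GrayImage]:
    """Read a rank-3 unsigned-byte IDX file as a list of 8-bit images."""
    with open(path, "rb") as fh:
        header = fh.read(16)
        if len(header) < 16:
            raise ValueError("truncated IDX file: incomplete header")
        magic, n, rows, cols = struct.unpack(">IIII", header)
        if magic != _IDX_MAGIC_U8_3D:
            raise ValueError(f"bad IDX magic 0x{magic:08x} "
                             f"(expected 0x{_IDX_MAGIC_U8_3D:08x})")
        body = fh.read(n * rows * cols)
        if len(body) != n * rows * cols:
            raise ValueError("truncated IDX file: payload shorter than header claims")
    data = np.frombuffer(body, dtype=np.uint8).reshape(n, rows, cols)
    return [GrayImage(im.astype(np.int64)) for im in data]


def write_idx(images, path) -> None:
    """Write 8-bit images to a rank-3 unsigned-byte IDX file."""
    arrays = [im.pixels if isinstance(im, GrayImage) else np.asarray(im)
              for im in images]
    stack = np.stack(arrays).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_MAGIC_U8_3D, *stack.shape))
        fh.write(stack.tobytes())


# -- single-image I/O (PNG / PGM) ----------------------------------------

def load_image(path) -> GrayImage:
    """Load an 8-bit grayscale image (PNG, PGM, ...)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.int64)
    return GrayImage(arr)


def save_image(image: GrayImage | np.ndarray, path) -> None:
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    Image.fromarray(pixels.astype(np.uint8)).save(path)
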