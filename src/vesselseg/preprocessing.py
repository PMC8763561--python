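"""Fundus image preprocessing: grayscale, CLAHE, gamma correction.

The network consumes a single contrast-enhanced channel.  The chain is

    RGB -> luminance grayscale -> CLAHE (clip 10.0, 8x8 tiles) -> gamma 1.0

with the result optionally normalised to [0, 1].  The defaults reproduce
the published recipe; note that gamma 1.0 makes the last step the
identity, so it only matters when a user overrides it.

CLAHE here follows the classic contrast-limited scheme (per-tile
histogram, clip-and-redistribute, per-tile CDF mapping, bilinear blending
between neighbouring tile mappings) in the OpenCV dialect where the clip
limit is an absolute multiplier of the uniform histogram level.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import FundusSample

__all__ = [
    "PreprocessConfig",
    "rgb_to_gray",
    "clahe",
    "gamma_correct",
    "preprocess",
]

#: ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


class ParameterError(ValueError):
    pass


class DimensionError(ValueError):
    pass


@dataclasses.dataclass
class PreprocessConfig:
    """Settings of the preprocessing chain (defaults = published recipe)."""

    clahe_clip: float = 10.0
    clahe_grid: tuple[int, int] = (8, 8)
    gamma: float = 1.0
    normalize: bool = True
    gray_method: str = "luminance"  # or "green": extract the green channel

    def validate(self):
        if self.clahe_clip <= 0:
            raise ParameterError("clahe_clip must be positive")
        if min(self.clahe_grid) < 1:
            raise ParameterError("clahe_grid dims must be >= 1")
        if self.gamma <= 0:
            raise ParameterError("gamma must be positive")
        if self.gray_method not in ("luminance", "green"):
            raise ParameterError(f"unknown gray_method {self.gray_method!r}")


def rgb_to_gray(image: np.ndarray, method: str = "luminance") -> np.ndarray:
    """Collapse an 8-bit RGB image to one channel.

    ``luminance`` uses the BT.601 weights 0.299/0.587/0.114 with
    round-half-away-from-zero rounding; ``green`` extracts the green
    channel (the highest-contrast channel for retinal vessels).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DimensionError(f"expected H x W x 3 input, got shape {image.shape}")
    if method == "green":
        return image[..., 1].astype(np.uint8)
    luma = image.astype(np.float64) @ _LUMA
    return np.floor(luma + 0.5).astype(np.uint8)


def _tile_edges(n: int, tiles: int) -> np.ndarray:
    """Tile boundaries covering [0, n); edge tiles may be smaller."""
    return np.linspace(0, n, tiles + 1).round().astype(int)


def clahe(image: np.ndarray, clip: float = 10.0,
          grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of an 8-bit image."""
    if clip <= 0:
        raise ParameterError("clip must be positive")
    gh, gw = grid
    if gh < 1 or gw < 1:
        raise ParameterError("grid dims must be >= 1")
    image = np.asarray(image, dtype=np.uint8)
    H, W = image.shape
    rows = _tile_edges(H, gh)
    cols = _tile_edges(W, gw)

    luts = np.empty((gh, gw, 256), dtype=np.float64)
    centers_r = np.empty(gh)
    centers_c = np.empty(gw)
    for i in range(gh):
        centers_r[i] = 0.5 * (rows[i] + rows[i + 1] - 1)
        for j in range(gw):
            tile = image[rows[i]:rows[i + 1], cols[j]:cols[j + 1]]
            area = tile.size
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            limit = max(clip * area / 256.0, 1.0)
            excess = np.maximum(hist - limit, 0.0).sum()
            hist = np.minimum(hist, limit) + excess / 256.0
            cdf = np.cumsum(hist)
            luts[i, j] = cdf * (255.0 / area)
    for j in range(gw):
        centers_c[j] = 0.5 * (cols[j] + cols[j + 1] - 1)

    # bilinear blend of the four surrounding tile mappings per pixel
    r = np.arange(H, dtype=np.float64)
    c = np.arange(W, dtype=np.float64)
    i1 = np.clip(np.searchsorted(centers_r, r), 0, gh - 1)
    i0 = np.maximum(i1 - 1, 0)
    j1 = np.clip(np.searchsorted(centers_c, c), 0, gw - 1)
    j0 = np.maximum(j1 - 1, 0)
    denom_r = np.where(i1 > i0, centers_r[i1] - centers_r[i0], 1.0)
    tr = np.clip((r - centers_r[i0]) / denom_r, 0.0, 1.0)
    denom_c = np.where(j1 > j0, centers_c[j1] - centers_c[j0], 1.0)
    tc = np.clip((c - centers_c[j0]) / denom_c, 0.0, 1.0)

    px = image  # (H, W) intensities index the 256-entry LUTs
    ri0 = i0[:, None]
    ri1 = i1[:, None]
    cj0 = j0[None, :]
    cj1 = j1[None, :]
    v00 = luts[ri0, cj0, px]
    v01 = luts[ri0, cj1, px]
    v10 = luts[ri1, cj0, px]
    v11 = luts[ri1, cj1, px]
    wr = tr[:, None]
    wc = tc[None, :]
    out = ((1 - wr) * ((1 - wc) * v00 + wc * v01)
           + wr * ((1 - wc) * v10 + wc * v11))
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law remapping out = 255 * (in/255)**gamma via a lookup table.

    gamma = 1.0 is bit-exact identity; any positive gamma preserves the
    ordering of intensities.
    """
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    image = np.asarray(image, dtype=np.uint8)
    levels = np.arange(256, dtype=np.float64)
    lut = np.floor(255.0 * (levels / 255.0) ** gamma + 0.5).astype(np.uint8)
    return lut[image]


def preprocess(sample: FundusSample | np.ndarray,
               config: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: grayscale -> CLAHE -> gamma (-> normalise to [0, 1])."""
    config = config or PreprocessConfig()
    config.validate()
    image = sample.image if isinstance(sample, FundusSample) else np.asarray(sample)
    gray = rgb_to_gray(image, method=config.gray_method)
    gray = clahe(gray, clip=config.clahe_clip, grid=config.clahe_grid)
    gray = gamma_correct(gray, config.gamma)
    if config.normalize:
        return gray.astype(np.float64) / 255.0
    return gray
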