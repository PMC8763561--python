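"""Seeded generator of fundus-like images with ground-truth vessel masks.

Real fundus photographs show a bright circular field of view (FOV) on a
dark frame, a smoothly varying orange background, and a tree of dark
vessels that thin toward their tips, often carrying a bright specular
stripe along the centerline (the "centerline reflex").  The generator
emulates exactly these traits so that the preprocessing, patching,
training and evaluation stages can be exercised end to end without any
dataset download:

* vessel centerlines are recursive branching random walks started on the
  FOV rim and directed inward, with per-generation length decay and
  width taper;
* vessels are rendered darker than the background, with the contrast
  concentrated in the green channel as in real fundus images;
* a 1-pixel bright centerline stripe simulates the reflex confound;
* the background is a low-frequency random texture plus white noise;
* pixels outside the FOV disc are near-black.

Identical specs (including the seed) produce bit-identical samples.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import FundusSample

__all__ = ["SyntheticSpec", "generate_sample", "generate_dataset",
           "drive_spec", "chase_spec"]


class ParameterError(ValueError):
    pass


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic fundus sample."""

    dims: tuple[int, int] = (584, 565)  # DRIVE geometry
    n_trees: int = 8  # vessel roots on the FOV rim
    width_range: tuple[float, float] = (1.5, 4.5)  # root half-widths, px
    contrast: float = 60.0  # vessel/background intensity gap (8-bit)
    reflex_amplitude: float = 30.0  # brightness of the centerline stripe
    noise_sigma: float = 6.0  # additive Gaussian noise, 8-bit units
    fov_radius_frac: float = 0.46  # disc radius / min(H, W)
    generations: int = 6  # branching depth
    seed: int = 0

    def validate(self):
        if min(self.dims) < 32:
            raise ParameterError(f"dims {self.dims} too small")
        if self.n_trees < 1 or self.generations < 1:
            raise ParameterError("need at least one tree and one generation")


def drive_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """DRIVE-like geometry (584 x 565)."""
    return SyntheticSpec(dims=(584, 565), seed=seed, **overrides)


def chase_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """CHASE_DB1-like geometry (999 x 960)."""
    return SyntheticSpec(dims=(999, 960), seed=seed, **overrides)


def _stamp_disk(canvas: np.ndarray, r: float, c: float, radius: float):
    """Set canvas pixels within ``radius`` of (r, c) to 1 (in place)."""
    H, W = canvas.shape
    rad = max(radius, 0.5)
    r0, r1 = int(max(0, math.floor(r - rad))), int(min(H, math.ceil(r + rad) + 1))
    c0, c1 = int(max(0, math.floor(c - rad))), int(min(W, math.ceil(c + rad) + 1))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] |= ((yy - r) ** 2 + (xx - c) ** 2) <= rad * rad


def _grow_branch(mask, centerline, rng, r, c, heading, half_width, length,
                 generation, spec, center, fov_radius):
    """Random-walk one vessel segment, then recurse into two children."""
    step = 2.0
    n_steps = max(int(length / step), 3)
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.12)
        r += step * math.sin(heading)
        c += step * math.cos(heading)
        if (r - center[0]) ** 2 + (c - center[1]) ** 2 > (0.98 * fov_radius) ** 2:
            return
        _stamp_disk(mask, r, c, half_width)
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < centerline.shape[0] and 0 <= ci < centerline.shape[1]:
            centerline[ri, ci] = True
        half_width *= 0.998
    if generation >= spec.generations or half_width < 0.6:
        return
    for sign in (-1.0, 1.0):
        split = sign * math.radians(rng.uniform(20.0, 60.0))
        _grow_branch(mask, centerline, rng, r, c, heading + split,
                     half_width * rng.uniform(0.6, 0.85), length * 0.7,
                     generation + 1, spec, center, fov_radius)


def generate_sample(spec: SyntheticSpec) -> FundusSample:
    """Render one synthetic fundus photograph with its vessel/FOV masks."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.dims
    center = ((H - 1) / 2.0, (W - 1) / 2.0)
    fov_radius = spec.fov_radius_frac * min(H, W)

    yy, xx = np.ogrid[:H, :W]
    fov = (((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
           <= fov_radius**2).astype(np.uint8)

    mask = np.zeros((H, W), dtype=bool)
    centerline = np.zeros((H, W), dtype=bool)
    for _ in range(spec.n_trees):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        r0 = center[0] + 0.92 * fov_radius * math.sin(phi)
        c0 = center[1] + 0.92 * fov_radius * math.cos(phi)
        heading = phi + math.pi + rng.normal(0.0, 0.3)  # point inward
        half_width = rng.uniform(*spec.width_range)
        length = rng.uniform(0.5, 0.9) * fov_radius
        _grow_branch(mask, centerline, rng, r0, c0, heading, half_width,
                     length, 1, spec, center, fov_radius)
    mask &= fov.astype(bool)
    centerline &= mask

    # smooth low-frequency background texture around a fundus-orange base
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(H, W)),
                              sigma=min(H, W) / 12.0)
    tmax = np.abs(texture).max()
    texture = texture / tmax * 18.0 if tmax > 0 else texture
    base = {"r": 190.0, "g": 120.0, "b": 60.0}

    img = np.empty((H, W, 3), dtype=np.float64)
    # vessel darkening dominated by the green channel (low red contrast
    # mimics the poor vessel/background separation of real photographs)
    channel_contrast = {"r": 0.35, "g": 1.0, "b": 0.55}
    soft = gaussian_filter(mask.astype(np.float64), sigma=0.7)
    soft = soft / soft.max() if soft.max() > 0 else soft
    for ch, name in enumerate(("r", "g", "b")):
        plane = base[name] + texture
        plane = plane - spec.contrast * channel_contrast[name] * soft
        plane[centerline] += spec.reflex_amplitude
        img[..., ch] = plane
    img += rng.normal(0.0, spec.noise_sigma, size=(H, W, 3))
    img *= fov[..., None] * 0.98 + 0.02  # near-black outside the disc
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return FundusSample(image=img, label=mask.astype(np.uint8), fov=fov,
                        identifier=f"synthetic_{spec.seed:04d}")


def generate_dataset(n: int, spec: SyntheticSpec | None = None) -> list[FundusSample]:
    """n samples with consecutive seeds spec.seed, spec.seed+1, ..."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    spec = spec or SyntheticSpec()
    out = []
    for i in range(n):
        s = dataclasses.replace(spec, seed=spec.seed + i)
        out.append(generate_sample(s))
    return out
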