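"""Dataset containers and image readers/writers.

The on-disk layout mirrors DRIVE's conventions: an ``images/`` folder of
RGB fundus photographs, a ``1st_manual/`` folder of binary vessel masks
and an optional ``mask/`` folder of field-of-view (FOV) discs.  Synthetic
datasets written by this package use the aliases ``images/``, ``masks/``
and ``fov/``.  Files are paired by the leading identifier of the file
name (everything before the first ``.`` or ``_``-suffix mismatch is
avoided by using identical stems).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif")

LABEL_DIR_ALIASES = ("1st_manual", "masks", "labels")
FOV_DIR_ALIASES = ("mask", "fov")


class DatasetError(ValueError):
    pass


@dataclasses.dataclass
class FundusSample:
    """One fundus photograph with optional vessel label and FOV mask."""

    image: np.ndarray  # H x W x 3 uint8 (or H x W float after preprocessing)
    label: np.ndarray | None = None  # H x W in {0,1}
    fov: np.ndarray | None = None  # H x W in {0,1}
    identifier: str = ""

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for name, mask in (("label", self.label), ("fov", self.fov)):
            if mask is not None and mask.shape != (h, w):
                raise DatasetError(
                    f"{name} dims {mask.shape} do not match image dims {(h, w)}"
                    f" for sample {self.identifier!r}"
                )

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


def _binarize(mask: np.ndarray) -> np.ndarray:
    if mask.ndim == 3:
        mask = mask[..., 0]
    return (mask > 0).astype(np.uint8)


def _read_image(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return np.asarray(arr)


def _index_dir(root: Path, names: tuple[str, ...]) -> dict[str, Path]:
    for name in names:
        d = root / name
        if d.is_dir():
            return {
                p.name.split(".")[0].removesuffix("_manual1").removesuffix("_mask"): p
                for p in sorted(d.iterdir())
                if p.suffix.lower() in IMAGE_EXTENSIONS
            }
    return {}


def read_dataset(root, require_labels: bool = False) -> list[FundusSample]:
    """Load all paired samples under ``root``.

    Unpaired label/FOV files are skipped with a warning; an empty image
    folder is an error.
    """
    import warnings

    root = Path(root)
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise DatasetError(f"no images/ directory under {root}")
    images = {
        p.name.split(".")[0].removesuffix("_training").removesuffix("_test"): p
        for p in sorted(img_dir.iterdir())
        if p.suffix.lower() in IMAGE_EXTENSIONS
    }
    if not images:
        raise DatasetError(f"no images found under {img_dir}")
    labels = _index_dir(root, LABEL_DIR_ALIASES)
    fovs = _index_dir(root, FOV_DIR_ALIASES)

    samples = []
    for ident, path in images.items():
        image = _read_image(path)
        if image.ndim != 3 or image.shape[2] != 3:
            raise DatasetError(f"{path} is not an RGB image")
        label = fov = None
        if ident in labels:
            label = _binarize(_read_image(labels[ident]))
        elif require_labels:
            warnings.warn(f"skipping {ident}: no label mask found")
            continue
        if ident in fovs:
            fov = _binarize(_read_image(fovs[ident]))
        try:
            samples.append(FundusSample(image=image, label=label, fov=fov,
                                        identifier=ident))
        except DatasetError as exc:
            raise DatasetError(f"{path}: {exc}") from exc
    if not samples:
        raise DatasetError(f"no usable samples under {root}")
    return samples


def write_dataset(samples: list[FundusSample], root) -> None:
    """Write samples in the synthetic layout (images/, masks/, fov/)."""
    root = Path(root)
    for sub in ("images", "masks", "fov"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    for s in samples:
        iio.imwrite(root / "images" / f"{s.identifier}.png", s.image)
        if s.label is not None:
            iio.imwrite(root / "masks" / f"{s.identifier}.png",
                        (s.label * 255).astype(np.uint8))
        if s.fov is not None:
            iio.imwrite(root / "fov" / f"{s.identifier}.png",
                        (s.fov * 255).astype(np.uint8))


def write_gray(path, image: np.ndarray) -> None:
    """Write a grayscale image; float arrays in [0,1] are scaled to 8 bits."""
    if image.dtype != np.uint8:
        image = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), image)


def read_gray(path) -> np.ndarray:
    arr = _read_image(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr
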