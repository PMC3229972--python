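"""Image containers and grayscale TIFF input/output.

Pixel intensities are carried in memory as 64-bit floats in arbitrary
fluorescence units (a.u.) on the closed interval [0, 1].  Integer images
read from disk are scaled by their bit depth (8-bit by 255, 16-bit by
65535), so a saturated 16-bit pixel maps to exactly 1.0 a.u.  Writing
quantizes back to 16-bit, which bounds the round-trip error by one grey
level (1/65535).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

log = logging.getLogger("nucleoquant")

MAX_8BIT = 255
MAX_16BIT = 65535

#: canonical channel names, in measurement order
CHANNELS = ("dna", "protein", "if")

#: file suffix per channel used by the simulator and CLI
CHANNEL_SUFFIX = {"dna": "dapi", "protein": "protein", "if": "if"}


@dataclasses.dataclass
class ImageSet:
    """Named, equally sized 2-D channels of one field of view.

    Parameters
    ----------
    channels
        Mapping of channel name (``dna``, ``protein``, optionally ``if``)
        to a 2-D float array of a.u. values in [0, 1].
    pixel_size
        Physical units per pixel; optional, carried as metadata only.
    bit_depth
        Bit depth of the source images (8 or 16).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageSet needs at least one channel")
        if "dna" not in self.channels:
            raise ValueError("ImageSet requires a 'dna' channel")
        shapes = {ch: np.asarray(im).shape for ch, im in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channels must be 2-D, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel dimensions differ: {shapes}")
        eps = 1e-9
        for ch, im in self.channels.items():
            im = np.asarray(im, dtype=np.float64)
            if im.size == 0:
                raise ValueError(f"channel {ch!r} is empty")
            lo, hi = float(im.min()), float(im.max())
            if lo < -eps or hi > 1.0 + eps:
                raise ValueError(
                    f"channel {ch!r} has values outside [0, 1] a.u. "
                    f"(min {lo:.4g}, max {hi:.4g}); scale on read"
                )
            self.channels[ch] = im

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclasses.dataclass
class LabelMask:
    """Integer label image: 0 = background, 1..n = nucleus ids.

    Ids are consecutive; use :func:`nucleoquant.segmentation.relabel_consecutive`
    to normalize an arbitrary integer mask.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("label mask must be a non-empty 2-D array")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        if lab.min() < 0:
            raise ValueError("label mask has negative ids")
        ids = np.unique(lab)
        ids = ids[ids > 0]
        n = int(lab.max())
        if ids.size != n or (ids.size and not np.array_equal(ids, np.arange(1, n + 1))):
            raise ValueError(
                "label ids must be consecutive 1..n; run relabel_consecutive first"
            )
        self.labels = lab.astype(np.int32, copy=False)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _scale_for_dtype(arr: np.ndarray) -> tuple[np.ndarray, int]:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / MAX_8BIT, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / MAX_16BIT, 16
    if np.issubdtype(arr.dtype, np.floating):
        # assume already on [0, 1]
        return arr.astype(np.float64), 16
    raise ValueError(f"unsupported TIFF sample format {arr.dtype}")


def read_image(path: str | Path) -> tuple[np.ndarray, int]:
    """Read one grayscale TIFF, return (float image in [0,1] a.u., bit depth)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: multi-sample (RGB/stack) TIFF not supported; "
            "split channels into separate grayscale files first"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return _scale_for_dtype(arr)


def read_image_set(paths: Mapping[str, str | Path], pixel_size: float | None = None) -> ImageSet:
    """Read named grayscale TIFF channels into one :class:`ImageSet`.

    All channels must have identical dimensions; 8- and 16-bit integer
    data are scaled to [0, 1] a.u.
    """
    channels: dict[str, np.ndarray] = {}
    depth = 16
    for name, path in paths.items():
        channels[name], depth = read_image(path)
    shapes = {n: c.shape for n, c in channels.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"channel image sizes differ: {shapes}")
    return ImageSet(channels=channels, pixel_size=pixel_size, bit_depth=depth)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Quantize a float [0,1] a.u. image to 16-bit grayscale TIFF."""
    img = np.asarray(image, dtype=np.float64)
    q = np.round(np.clip(img, 0.0, 1.0) * MAX_16BIT).astype(np.uint16)
    tifffile.imwrite(str(path), q)


def write_image_set(images: ImageSet, directory: str | Path, prefix: str) -> dict[str, Path]:
    """Write one 16-bit TIFF per channel (``<prefix>_dapi.tif`` etc.)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name, img in images.channels.items():
        p = directory / f"{prefix}_{CHANNEL_SUFFIX.get(name, name)}.tif"
        write_image(img, p)
        out[name] = p
    return out


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    if mask.n_objects > MAX_16BIT:
        raise ValueError("more than 65535 objects; cannot store as 16-bit mask")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> LabelMask:
    arr = tifffile.imread(str(path))
    return LabelMask(labels=arr.astype(np.int32))
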