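"""Tissue segmentation, grid patching, and patch quality filtering.

The segmentation pipeline follows standard whole-slide practice: downscale,
convert RGB to HSV, threshold the saturation channel (tissue is saturated,
glass is not), smooth the binary mask with a median filter, close small gaps
morphologically, then drop connected components below an area threshold.
Patches are taken on a non-overlapping grid at full resolution and kept when
their centre falls inside a retained tissue region; a final RGB filter
rejects blank and contaminated (black marker / dust) patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label

from .errors import ConfigurationError, DimensionMismatchError


@dataclass(frozen=True)
class SegParams:
    downscale_factor: int = 20
    saturation_threshold: int = 8  # 0-255 scale
    median_blur_kernel: int = 7  # odd
    closing_kernel: int = 4
    min_region_area: int = 100  # pixels at downscaled resolution

    def __post_init__(self) -> None:
        if self.downscale_factor < 1:
            raise ConfigurationError("downscale_factor must be >= 1")
        if not 0 <= self.saturation_threshold <= 255:
            raise ConfigurationError("saturation_threshold must be in [0, 255]")
        if self.median_blur_kernel < 1 or self.median_blur_kernel % 2 == 0:
            raise ConfigurationError("median_blur_kernel must be odd and >= 1")
        if self.closing_kernel < 1:
            raise ConfigurationError("closing_kernel must be >= 1")
        if self.min_region_area < 0:
            raise ConfigurationError("min_region_area must be >= 0")


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, downscaled resolution, retained regions only
    region_labels: np.ndarray  # int label image, 0 = background
    retained: tuple[int, ...]  # labels of retained regions
    downscale_factor: int

    @property
    def n_regions(self) -> int:
        return len(self.retained)


@dataclass(frozen=True)
class PatchParams:
    patch_size: int = 224
    magnification: str = "20x"
    stride: int | None = None  # default: patch_size (non-overlapping)

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ConfigurationError("patch_size must be >= 1")
        if self.stride is not None and self.stride < 1:
            raise ConfigurationError("stride must be >= 1")

    @property
    def effective_stride(self) -> int:
        return self.patch_size if self.stride is None else self.stride


@dataclass(frozen=True)
class FilterParams:
    blank_mean_threshold: float = 230.0  # mean RGB above this => blank
    dark_pixel_value: int = 50  # all channels below this => near-black pixel
    dark_fraction_threshold: float = 0.30  # fraction of near-black => contaminated

    def __post_init__(self) -> None:
        if not 0 <= self.blank_mean_threshold <= 255:
            raise ConfigurationError("blank_mean_threshold must be in [0, 255]")
        if not 0 <= self.dark_pixel_value <= 255:
            raise ConfigurationError("dark_pixel_value must be in [0, 255]")
        if not 0.0 <= self.dark_fraction_threshold <= 1.0:
            raise ConfigurationError("dark_fraction_threshold must be in [0, 1]")


def downscale_mean(image: np.ndarray, factor: int) -> np.ndarray:
    """Integer-factor downscaling by block (area) averaging; trailing rows and
    columns that do not fill a block are cropped."""
    if factor == 1:
        return image.astype(np.float64)
    h, w = image.shape[:2]
    hh, ww = (h // factor) * factor, (w // factor) * factor
    img = image[:hh, :ww].astype(np.float64)
    if img.ndim == 2:
        return img.reshape(hh // factor, factor, ww // factor, factor).mean(axis=(1, 3))
    c = img.shape[2]
    return img.reshape(hh // factor, factor, ww // factor, factor, c).mean(axis=(1, 3))


def segment_tissue(image: np.ndarray, params: SegParams = SegParams()) -> TissueMask:
    """Segment foreground tissue; see module docstring for the fixed order."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ConfigurationError("segment_tissue expects an RGB image (H, W, 3)")
    if min(image.shape[:2]) < params.downscale_factor:
        raise ConfigurationError("image smaller than one downscale block")

    small = downscale_mean(image, params.downscale_factor)
    sat = rgb2hsv(np.clip(small, 0, 255) / 255.0)[..., 1] * 255.0
    binary = sat > params.saturation_threshold
    binary = ndimage.median_filter(
        binary.astype(np.uint8), size=params.median_blur_kernel
    ).astype(bool)
    structure = np.ones((params.closing_kernel, params.closing_kernel), dtype=bool)
    binary = ndimage.binary_closing(binary, structure=structure)

    labels = cc_label(binary, connectivity=2)
    retained = []
    for lab in range(1, labels.max() + 1):
        if int((labels == lab).sum()) >= params.min_region_area:
            retained.append(lab)
    mask = np.isin(labels, retained)
    return TissueMask(
        mask=mask,
        region_labels=labels,
        retained=tuple(retained),
        downscale_factor=params.downscale_factor,
    )


@dataclass(frozen=True)
class PatchCoord:
    """Top-left corner of a patch, 0-based level-0 pixels; x = column, y = row."""

    x: int
    y: int


def extract_patches(
    image: np.ndarray,
    mask: TissueMask,
    params: PatchParams = PatchParams(),
    *,
    return_blocks: bool = False,
) -> list[PatchCoord] | tuple[list[PatchCoord], list[np.ndarray]]:
    """Enumerate grid patches whose centre lies in a retained tissue region.

    Patch extents are half-open [x, x+size) x [y, y+size), fully inside the
    image; coordinates lie on the stride grid anchored at (0, 0).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    f = mask.downscale_factor
    if mask.mask.shape[0] != h // f or mask.mask.shape[1] != w // f:
        raise DimensionMismatchError("mask was not produced from this image")
    size, stride = params.patch_size, params.effective_stride
    coords: list[PatchCoord] = []
    blocks: list[np.ndarray] = []
    for y in range(0, h - size + 1, stride):
        for x in range(0, w - size + 1, stride):
            cy, cx = (y + size // 2) // f, (x + size // 2) // f
            if (
                0 <= cy < mask.mask.shape[0]
                and 0 <= cx < mask.mask.shape[1]
                and mask.mask[cy, cx]
            ):
                coords.append(PatchCoord(x=x, y=y))
                if return_blocks:
                    blocks.append(image[y : y + size, x : x + size])
    if return_blocks:
        return coords, blocks
    return coords


def filter_patches(
    blocks: list[np.ndarray], params: FilterParams = FilterParams()
) -> tuple[list[int], list[tuple[int, str]]]:
    """Partition patches into kept indices and (index, reason) rejections.

    Reasons: ``"contaminated"`` when the near-black pixel fraction exceeds the
    threshold (markers, dust), else ``"blank"`` when the mean RGB intensity is
    above the blank threshold. Input order is preserved in both lists.
    """
    kept: list[int] = []
    rejected: list[tuple[int, str]] = []
    for i, block in enumerate(blocks):
        block = np.asarray(block)
        if block.ndim != 3 or block.shape[2] != 3:
            raise ConfigurationError(f"patch {i} is not an RGB block")
        dark = np.all(block < params.dark_pixel_value, axis=2).mean()
        if dark > params.dark_fraction_threshold:
            rejected.append((i, "contaminated"))
        elif block.mean() > params.blank_mean_threshold:
            rejected.append((i, "blank"))
        else:
            kept.append(i)
    return kept, rejected
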