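"""Patch-importance scoring from the self-attention matrix.

The importance of patch i is the mean log attention weight

    W_i = (1/N_x) * sum_j log(A_ij)

taken literally over the second index of A (``mode="literal"``). Because the
intended axis — attention given versus attention received — is genuinely
ambiguous in this construction, a ``mode="received"`` variant averaging over
the first index is also provided. Entries are clamped at 1e-12 before the
log since softmax can underflow to exact zero in finite precision. All
weights are <= 0 (logs of values in (0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DimensionMismatchError

_CLAMP = 1e-12


@dataclass
class PatchImportance:
    W: np.ndarray  # (N_x,), each entry <= 0
    axis_convention: str  # "literal" | "received"
    slide_id: str = "slide"


def patch_importance(
    A: np.ndarray, mode: str = "literal", slide_id: str = "slide"
) -> PatchImportance:
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionMismatchError("A must be square")
    if mode not in ("literal", "received"):
        raise ConfigurationError("mode must be 'literal' or 'received'")
    logA = np.log(np.clip(A, _CLAMP, None))
    axis = 1 if mode == "literal" else 0
    W = logA.mean(axis=axis)
    return PatchImportance(W=W, axis_convention=mode, slide_id=slide_id)


def top_patches(importance: PatchImportance, k: int) -> np.ndarray:
    """Indices of the k largest weights, descending; ties -> lower index first.

    ``k >= N_x`` returns every index.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    W = importance.W
    order = np.lexsort((np.arange(W.size), -W))
    return order[: min(k, W.size)]


def attention_heatmap(
    importance: PatchImportance,
    patch_coords: np.ndarray,
    slide_extent: tuple[int, int],
    stride: int = 224,
    normalise: bool = False,
) -> np.ndarray:
    """Map weights back onto the patch grid.

    Returns a (rows, cols) float grid at stride resolution; cells with no
    patch are NaN. With ``normalise=True`` filled cells are min-max scaled to
    [0, 1] (constant weights map to 0).
    """
    coords = np.asarray(patch_coords)
    W = importance.W
    if coords.shape != (W.size, 2):
        raise DimensionMismatchError("patch_coords must align with W")
    width, height = slide_extent
    rows = max(1, -(-height // stride))
    cols = max(1, -(-width // stride))
    grid = np.full((rows, cols), np.nan)
    for (x, y), w in zip(coords, W):
        if not (0 <= x < width and 0 <= y < height):
            raise ConfigurationError(f"coordinate ({x}, {y}) outside slide extent")
        grid[y // stride, x // stride] = w
    if normalise and W.size:
        filled = ~np.isnan(grid)
        lo, hi = np.nanmin(grid), np.nanmax(grid)
        grid[filled] = 0.0 if hi == lo else (grid[filled] - lo) / (hi - lo)
    return grid
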