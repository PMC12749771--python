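"""Pluggable patch-feature extraction.

The production pipeline this package models extracts patch embeddings with a
pre-trained image-translation model followed by a pathology foundation model.
Those weights are external; here the extractor is a registry contract so the
rest of the pipeline is agnostic to where features come from. Bundled
extractors: ``identity`` (synthetic bags already carry features) and
``random_projection`` (seeded projection of flattened pixels, for exercising
the image path end-to-end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError, DimensionMismatchError
from .synthetic import FeatureBag


@dataclass(frozen=True)
class ExtractorSpec:
    name: str
    output_dim: int = 768
    requires_images: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")


_REGISTRY: dict[str, Callable[..., np.ndarray]] = {}


def register_extractor(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Register ``fn(patches, spec, **kwargs) -> (n, output_dim) array``."""
    _REGISTRY[name] = fn


def _identity(bag: FeatureBag, spec: ExtractorSpec) -> np.ndarray:
    if bag.features.shape[1] != spec.output_dim:
        raise DimensionMismatchError(
            f"bag feature dim {bag.features.shape[1]} != extractor "
            f"output_dim {spec.output_dim}"
        )
    return bag.features


def _random_projection(
    patches: np.ndarray, spec: ExtractorSpec, *, seed: int = 0
) -> np.ndarray:
    patches = np.asarray(patches, dtype=np.float64)
    n = patches.shape[0]
    flat = patches.reshape(n, -1) / 255.0
    rng = np.random.default_rng(seed)
    proj = rng.standard_normal((flat.shape[1], spec.output_dim)) / np.sqrt(
        flat.shape[1]
    )
    return flat @ proj


register_extractor("identity", _identity)
register_extractor("random_projection", _random_projection)


def extract_features(
    source: FeatureBag | np.ndarray,
    spec: ExtractorSpec,
    *,
    slide_id: str | None = None,
    patch_coords: np.ndarray | None = None,
    **kwargs,
) -> FeatureBag:
    """Run the registered extractor and wrap the result as a FeatureBag.

    One feature row per input patch, in input order, width ``spec.output_dim``.
    """
    if spec.name not in _REGISTRY:
        raise LookupError(f"no extractor registered under '{spec.name}'")
    fn = _REGISTRY[spec.name]
    if spec.requires_images or not isinstance(source, FeatureBag):
        if isinstance(source, FeatureBag):
            raise ConfigurationError(
                f"extractor '{spec.name}' requires pixel patches, got a FeatureBag"
            )
        feats = fn(source, spec, **kwargs)
        n = np.asarray(source).shape[0]
        if patch_coords is None:
            patch_coords = np.zeros((n, 2), dtype=np.int64)
        sid = slide_id or "slide"
    else:
        feats = fn(source, spec, **kwargs)
        n = source.n_patches
        patch_coords = source.patch_coords
        sid = slide_id or source.slide_id
    feats = np.asarray(feats, dtype=np.float64)
    if feats.shape != (n, spec.output_dim):
        raise DimensionMismatchError(
            f"extractor returned shape {feats.shape}, expected {(n, spec.output_dim)}"
        )
    return FeatureBag(sid, feats, patch_coords)
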