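"""Synthetic cohort generator.

Emulates the statistical structure of an intraoperative cryosection cohort:
patients arrive with one or more biopsies in order; each biopsy yields a slide
that a pathologist calls Pass or No-Pass; every slide is represented as a bag
of patch feature vectors. Mutant patients' slides contain a fraction of
"signal" patches whose features are mean-shifted along a gene-specific unit
direction; No-Pass slides carry a sparser, weaker signal plus a mild
"peritumoural" shift on part of the background patches; each centre adds a
constant batch offset. None of this claims histological realism — it gives
every downstream stage a ground truth to recover.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaVersionError

COHORT_SCHEMA_VERSION = 1

_DEFAULT_GENES = ("ATRX", "H3K27M", "TP53")
# Mutant prevalences loosely matching diffuse midline glioma cohorts:
# H3K27M defines the entity (majority mutant), TP53 roughly half, ATRX a third.
_DEFAULT_PREVALENCE = {"ATRX": 0.30, "H3K27M": 0.60, "TP53": 0.45}
# P(biopsy k is No-Pass); the sequence stops at the first Pass or at max_biopsies.
_DEFAULT_NOPASS_RATES = (0.45, 0.35, 0.25, 0.15, 0.10, 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator."""

    n_patients: int = 100
    feature_dim: int = 768
    genes: tuple[str, ...] = _DEFAULT_GENES
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    signal_fraction_pass: float = 0.30
    signal_fraction_nopass: float = 0.10
    effect_size: float = 1.0
    peritumoural_effect: float = 0.30
    peritumoural_fraction: float = 0.20
    bag_size_range: tuple[int, int] = (30, 80)
    n_centres: int = 3
    centre_offset_scale: float = 0.10
    nopass_rate_by_order: tuple[float, ...] = _DEFAULT_NOPASS_RATES
    max_biopsies: int = 6
    pa_prevalence: float = 0.10
    pa_effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.feature_dim < 1:
            raise ConfigurationError("feature_dim must be >= 1")
        if not self.genes:
            raise ConfigurationError("genes must be non-empty")
        for g in self.genes:
            p = self.prevalence.get(g)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence[{g}] must be in [0, 1]")
        for name in (
            "signal_fraction_pass",
            "signal_fraction_nopass",
            "peritumoural_fraction",
            "pa_prevalence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.signal_fraction_nopass > self.signal_fraction_pass:
            raise ConfigurationError(
                "signal_fraction_nopass must not exceed signal_fraction_pass"
            )
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("bag_size_range must satisfy 1 <= min <= max")
        if self.n_centres < 1:
            raise ConfigurationError("n_centres must be >= 1")
        for r in self.nopass_rate_by_order:
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("nopass_rate_by_order entries must be in [0, 1]")
        if self.max_biopsies < 1:
            raise ConfigurationError("max_biopsies must be >= 1")
        if self.effect_size < 0 or self.peritumoural_effect < 0:
            raise ConfigurationError("effect sizes must be >= 0")


@dataclass(frozen=True)
class SlideRecord:
    """Metadata for one slide (one biopsy of one patient)."""

    slide_id: str
    patient_id: str
    biopsy_order: int  # 1-based arrival order within the patient
    pass_status: str  # "Pass" | "No-Pass"
    gene_labels: dict[str, str]  # gene -> "mutant" | "wild-type"
    pa_label: bool
    centre_id: str


@dataclass
class FeatureBag:
    """One slide's bag of patch feature vectors.

    ``signal_mask`` marks ground-truth signal patches and exists only for
    synthetic bags.
    """

    slide_id: str
    features: np.ndarray  # (N_x, feature_dim)
    patch_coords: np.ndarray  # (N_x, 2) level-0 pixel (x, y) of patch top-left
    signal_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ConfigurationError("features must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ConfigurationError("features must be finite")
        self.patch_coords = np.asarray(self.patch_coords, dtype=np.int64)
        if self.patch_coords.shape != (self.features.shape[0], 2):
            raise ConfigurationError("patch_coords must have one (x, y) row per patch")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def gene_directions(config: CohortConfig) -> dict[str, np.ndarray]:
    """Fixed unit signal directions, one per gene plus one for the PA label.

    Drawn from a seed-derived stream and orthogonalised (QR) so per-gene
    signals do not interfere.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    names = list(config.genes) + ["__PA__"]
    raw = rng.standard_normal((config.feature_dim, len(names)))
    if config.feature_dim >= len(names):
        q, _ = np.linalg.qr(raw)
        dirs = q[:, : len(names)].T
    else:  # more labels than dimensions: fall back to normalised raw vectors
        dirs = (raw / np.linalg.norm(raw, axis=0, keepdims=True)).T
    return {name: dirs[i].copy() for i, name in enumerate(names)}


def _centre_offsets(config: CohortConfig) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    return config.centre_offset_scale * rng.standard_normal(
        (config.n_centres, config.feature_dim)
    )


def generate_feature_bag(
    gene_labels: dict[str, str],
    pass_status: str,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    pa_label: bool = False,
    centre_index: int = 0,
    slide_id: str = "slide",
    directions: dict[str, np.ndarray] | None = None,
    centre_offsets: np.ndarray | None = None,
) -> FeatureBag:
    """Draw one slide bag.

    Background patches are standard normal; signal patches are shifted by
    ``effect_size`` along the (summed) directions of the mutant genes. The
    number of signal patches is round-half-up(fraction * N_x). No-Pass slides
    of mutant patients additionally shift a fraction of background patches by
    the weaker peritumoural effect.
    """
    if pass_status not in ("Pass", "No-Pass"):
        raise ConfigurationError("pass_status must be 'Pass' or 'No-Pass'")
    for g in config.genes:
        if gene_labels.get(g) not in ("mutant", "wild-type"):
            raise ConfigurationError(f"gene_labels[{g}] must be mutant/wild-type")
    if directions is None:
        directions = gene_directions(config)
    if centre_offsets is None:
        centre_offsets = _centre_offsets(config)

    lo, hi = config.bag_size_range
    n = int(rng.integers(lo, hi + 1))
    x = rng.standard_normal((n, config.feature_dim))

    shift = np.zeros(config.feature_dim)
    for g in config.genes:
        if gene_labels[g] == "mutant":
            shift += config.effect_size * directions[g]
    if pa_label:
        shift += config.pa_effect_size * directions["__PA__"]

    mask = np.zeros(n, dtype=bool)
    has_signal = bool(np.any(shift))
    if has_signal:
        frac = (
            config.signal_fraction_pass
            if pass_status == "Pass"
            else config.signal_fraction_nopass
        )
        n_sig = min(n, _round_half_up(frac * n))
        idx = rng.permutation(n)[:n_sig]
        mask[idx] = True
        x[mask] += shift
        if pass_status == "No-Pass" and config.peritumoural_effect > 0:
            bg = np.flatnonzero(~mask)
            n_peri = _round_half_up(config.peritumoural_fraction * bg.size)
            peri = rng.permutation(bg)[:n_peri]
            x[peri] += config.peritumoural_effect * (
                shift / max(np.linalg.norm(shift), 1e-12)
            )

    x += centre_offsets[centre_index % config.n_centres]

    # synthetic grid coordinates on a 224-pixel lattice
    w = max(1, int(math.ceil(math.sqrt(n))))
    coords = np.stack([(np.arange(n) % w) * 224, (np.arange(n) // w) * 224], axis=1)
    return FeatureBag(slide_id, x, coords, signal_mask=mask)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SlideRecord], list[FeatureBag]]:
    """Generate a full cohort, deterministic given ``config.seed``.

    Each patient keeps biopsying until a Pass slide is drawn or
    ``max_biopsies`` is reached; P(No-Pass at order k) follows
    ``nopass_rate_by_order``. Gene labels are patient-level and identical on
    every slide of that patient.
    """
    directions = gene_directions(config)
    offsets = _centre_offsets(config)
    records: list[SlideRecord] = []
    bags: list[FeatureBag] = []
    for i in range(config.n_patients):
        prng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1, i))
        )
        patient_id = f"P{i:04d}"
        labels = {
            g: ("mutant" if prng.random() < config.prevalence[g] else "wild-type")
            for g in config.genes
        }
        pa = bool(prng.random() < config.pa_prevalence)
        centre = int(prng.integers(config.n_centres))
        for k in range(1, config.max_biopsies + 1):
            rate = (
                config.nopass_rate_by_order[k - 1]
                if k - 1 < len(config.nopass_rate_by_order)
                else 0.0
            )
            is_nopass = prng.random() < rate and k < config.max_biopsies
            status = "No-Pass" if is_nopass else "Pass"
            slide_id = f"{patient_id}_S{k}"
            records.append(
                SlideRecord(
                    slide_id=slide_id,
                    patient_id=patient_id,
                    biopsy_order=k,
                    pass_status=status,
                    gene_labels=dict(labels),
                    pa_label=pa,
                    centre_id=f"C{centre}",
                )
            )
            bags.append(
                generate_feature_bag(
                    labels,
                    status,
                    config,
                    prng,
                    pa_label=pa,
                    centre_index=centre,
                    slide_id=slide_id,
                    directions=directions,
                    centre_offsets=offsets,
                )
            )
            if status == "Pass":
                break
    return records, bags


# ---------------------------------------------------------------------------
# synthetic slide images (fixtures for the preprocessing stage)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageConfig:
    """Parameters of a synthetic RGB slide image."""

    width: int = 1024
    height: int = 1024
    patch_size: int = 224
    n_blobs: int = 2
    blob_radius_range: tuple[int, int] = (120, 260)
    n_marker_strokes: int = 0
    n_holes: int = 0
    n_dust: int = 0

    def __post_init__(self) -> None:
        if self.width < self.patch_size or self.height < self.patch_size:
            raise ConfigurationError(
                "image dimensions must be at least one patch_size"
            )
        if self.n_blobs < 0:
            raise ConfigurationError("n_blobs must be >= 0")


def generate_slide_image(
    config: ImageConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (RGB uint8 image, boolean tissue mask).

    White background with saturated elliptical "tissue" blobs; optional black
    marker strokes, near-white holes punched into tissue, and dust specks.
    The mask marks true tissue pixels (holes excluded).
    """
    h, w = config.height, config.width
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]

    for _ in range(config.n_blobs):
        rx = int(rng.integers(*config.blob_radius_range))
        ry = int(rng.integers(*config.blob_radius_range))
        cx = int(rng.integers(rx, w - rx)) if w > 2 * rx else w // 2
        cy = int(rng.integers(ry, h - ry)) if h > 2 * ry else h // 2
        blob = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        # saturated eosin-like tint, slight per-blob variation
        colour = np.array(
            [
                190 + rng.integers(-20, 20),
                90 + rng.integers(-20, 20),
                170 + rng.integers(-20, 20),
            ],
            dtype=np.int64,
        ).clip(0, 255)
        img[blob] = colour
        mask |= blob

    for _ in range(config.n_holes):
        r = int(rng.integers(8, 24))
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            break
        j = int(rng.integers(ys.size))
        hole = (xx - xs[j]) ** 2 + (yy - ys[j]) ** 2 <= r**2
        img[hole] = 252
        mask &= ~hole

    for _ in range(config.n_marker_strokes):
        x0, y0 = int(rng.integers(w)), int(rng.integers(h))
        length = int(rng.integers(60, 200))
        thickness = int(rng.integers(3, 9))
        horizontal = bool(rng.integers(2))
        if horizontal:
            stroke = (np.abs(yy - y0) < thickness) & (xx >= x0) & (xx < x0 + length)
        else:
            stroke = (np.abs(xx - x0) < thickness) & (yy >= y0) & (yy < y0 + length)
        img[stroke] = 10

    for _ in range(config.n_dust):
        x0, y0 = int(rng.integers(w)), int(rng.integers(h))
        speck = (xx - x0) ** 2 + (yy - y0) ** 2 <= int(rng.integers(2, 5)) ** 2
        img[speck] = 30

    return img, mask


# ---------------------------------------------------------------------------
# cohort container I/O: directory with metadata CSV + one .npz per slide
# ---------------------------------------------------------------------------


def write_cohort(
    records: list[SlideRecord], bags: list[FeatureBag], path: str | Path
) -> None:
    """Write a cohort directory: ``metadata.csv``, ``cohort.json``, ``features/``."""
    if len(records) != len(bags):
        raise ConfigurationError("records and bags must have equal length")
    path = Path(path)
    (path / "features").mkdir(parents=True, exist_ok=True)
    genes = sorted({g for r in records for g in r.gene_labels}) if records else []
    rows = []
    for r, b in zip(records, bags):
        if r.slide_id != b.slide_id:
            raise ConfigurationError("records and bags must align by slide_id")
        row = {
            "slide_id": r.slide_id,
            "patient_id": r.patient_id,
            "biopsy_order": r.biopsy_order,
            "pass_status": r.pass_status,
            "pa_label": int(r.pa_label),
            "centre_id": r.centre_id,
        }
        for g in genes:
            row[g] = r.gene_labels.get(g, "wild-type")
        rows.append(row)
        arrays = {"features": b.features, "patch_coords": b.patch_coords}
        if b.signal_mask is not None:
            arrays["signal_mask"] = b.signal_mask
        np.savez(path / "features" / f"{r.slide_id}.npz", **arrays)
    pd.DataFrame(rows).to_csv(path / "metadata.csv", index=False)
    (path / "cohort.json").write_text(
        json.dumps({"schema_version": COHORT_SCHEMA_VERSION, "genes": genes})
    )


def read_cohort(path: str | Path) -> tuple[list[SlideRecord], list[FeatureBag]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    meta_path = path / "cohort.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no cohort at {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != COHORT_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"cohort schema version {meta.get('schema_version')} != "
            f"{COHORT_SCHEMA_VERSION}"
        )
    genes = meta["genes"]
    records: list[SlideRecord] = []
    bags: list[FeatureBag] = []
    try:
        df = pd.read_csv(path / "metadata.csv")
    except pd.errors.EmptyDataError:
        return records, bags
    for _, row in df.iterrows():
        records.append(
            SlideRecord(
                slide_id=row["slide_id"],
                patient_id=row["patient_id"],
                biopsy_order=int(row["biopsy_order"]),
                pass_status=row["pass_status"],
                gene_labels={g: row[g] for g in genes},
                pa_label=bool(row["pa_label"]),
                centre_id=row["centre_id"],
            )
        )
        with np.load(path / "features" / f"{row['slide_id']}.npz") as z:
            bags.append(
                FeatureBag(
                    slide_id=row["slide_id"],
                    features=z["features"],
                    patch_coords=z["patch_coords"],
                    signal_mask=z["signal_mask"] if "signal_mask" in z else None,
                )
            )
    return records, bags


def cohort_config_to_json(config: CohortConfig) -> str:
    d = dataclasses.asdict(config)
    d["genes"] = list(d["genes"])
    return json.dumps(d, sort_keys=True)
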