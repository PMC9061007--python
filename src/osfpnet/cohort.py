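"""Synthetic carotid-plaque cohort generator.

Emulates the geometric and statistical structure of a bilateral
transverse/longitudinal B-mode plaque dataset: four grayscale ROIs per
subject (left/right carotid x transverse/longitudinal section), arbitrary
pixel sizes, near-square transverse ROIs and elongated longitudinal ROIs,
and fully developed speckle texture.

Texture model
-------------
Each ROI is multiplicative speckle over a smooth background:

    I(x) = clip( B(x) * R(x), 0, 255 )

where ``B`` is a constant echogenicity level plus Gaussian-smoothed
low-frequency variation (tissue heterogeneity) and ``R`` is unit-mean
Rayleigh noise — the classical model of fully developed B-mode speckle.
The class effect follows the clinical association of hypoechoic,
heterogeneous plaques with symptomatic disease: the symptomatic class has
its mean echogenicity lowered and its background heterogeneity amplitude
raised, both in proportion to ``effect_size``.  Because speckle is
multiplicative, absolute intensity variance tracks brightness; the
heterogeneity effect therefore shows up in the *relative* local variation
(coefficient of variation), which is higher for the symptomatic class.
``effect_size=0`` makes the two classes statistically identical; the effect
direction is an assumption, not a measured property of clinical plaques.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "CohortSpec",
    "PlaqueImage",
    "SubjectRecord",
    "generate_cohort",
    "write_cohort",
    "MANIFEST_COLUMNS",
    "VIEW_KEYS",
]

#: view keys in path order: left/right x transverse/longitudinal
VIEW_KEYS = ("LT", "LL", "RT", "RL")
MANIFEST_COLUMNS = ["subject_id", "label", "img_LT", "img_LL", "img_RT", "img_RL"]

#: minimum side length accepted by the feature-extraction backbone
MIN_INPUT = 48

# texture parameters: baseline echogenicity and heterogeneity of the
# asymptomatic class; per-unit-effect shifts for the symptomatic class
_BASE_MEAN = 135.0
_MEAN_SHIFT_PER_EFFECT = 12.0
_BASE_HETERO = 8.0
_HETERO_GAIN_PER_EFFECT = 1.5
_HETERO_SIGMA_PX = 8.0  # correlation length of the slow background, px


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_subjects: int = 333
    symptomatic_fraction: float = 0.35  # ~117:216, the clinical class imbalance
    transverse_size_range: tuple[int, int] = (64, 160)
    longitudinal_height_range: tuple[int, int] = (64, 96)
    longitudinal_aspect_range: tuple[float, float] = (2.5, 5.0)
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 5:
            raise ValueError(f"n_subjects must be >= 5 (5-fold CV), got {self.n_subjects}")
        if not 0.0 < self.symptomatic_fraction < 1.0:
            raise ValueError(
                f"symptomatic_fraction must be in (0,1), got {self.symptomatic_fraction}"
            )
        for name, (lo, hi) in (
            ("transverse_size_range", self.transverse_size_range),
            ("longitudinal_height_range", self.longitudinal_height_range),
            ("longitudinal_aspect_range", self.longitudinal_aspect_range),
        ):
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.transverse_size_range[0] < MIN_INPUT:
            raise ValueError(
                f"transverse sides must be >= {MIN_INPUT}, got {self.transverse_size_range}"
            )
        if self.longitudinal_height_range[0] < MIN_INPUT:
            raise ValueError(
                f"longitudinal heights must be >= {MIN_INPUT}, "
                f"got {self.longitudinal_height_range}"
            )
        if self.longitudinal_aspect_range[0] < 2.0:
            raise ValueError(
                f"longitudinal aspect (W/H) must be >= 2, got {self.longitudinal_aspect_range}"
            )
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be nonnegative, got {self.effect_size}")


@dataclass
class PlaqueImage:
    """One grayscale ROI with its laterality and imaging section."""

    pixels: np.ndarray  # (H, W) uint8
    side: str  # 'L' | 'R'
    section: str  # 'T' (transverse) | 'L' (longitudinal)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be a 2-D uint8 array")
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.section not in ("T", "L"):
            raise ValueError(f"section must be 'T' or 'L', got {self.section!r}")
        h, w = self.pixels.shape
        if h < MIN_INPUT or w < MIN_INPUT:
            raise ValueError(f"image {h}x{w} below the {MIN_INPUT}-px minimum side")
        aspect = w / h
        if self.section == "T" and not (0.75 <= aspect <= 1.33):
            raise ValueError(
                f"transverse ROI aspect W/H={aspect:.2f} outside [0.75, 1.33] ({h}x{w})"
            )
        if self.section == "L" and aspect < 2.0:
            raise ValueError(
                f"longitudinal ROI aspect W/H={aspect:.2f} below 2 ({h}x{w})"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SubjectRecord:
    """A subject's four plaque ROIs plus the symptomatic/asymptomatic label."""

    subject_id: str
    label: int  # 1 = symptomatic (positive class), 0 = asymptomatic
    images: dict[str, PlaqueImage]

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if set(self.images) != set(VIEW_KEYS):
            raise ValueError(
                f"subject {self.subject_id}: expected exactly views {VIEW_KEYS}, "
                f"got {sorted(self.images)}"
            )
        for key, img in self.images.items():
            if img.side != key[0] or img.section != ("T" if key[1] == "T" else "L"):
                raise ValueError(
                    f"subject {self.subject_id}: image under key {key} has "
                    f"side={img.side} section={img.section}"
                )

    def quadruple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Pixel arrays in path order (LT, LL, RT, RL)."""
        return tuple(self.images[k].pixels for k in VIEW_KEYS)


def _speckle_image(rng: np.random.Generator, h: int, w: int,
                   mean_level: float, hetero: float) -> np.ndarray:
    slow = gaussian_filter(rng.standard_normal((h, w)), sigma=_HETERO_SIGMA_PX)
    sd = slow.std()
    if sd > 0:
        slow /= sd
    background = mean_level + hetero * slow
    speckle = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=(h, w))  # unit mean
    return np.clip(background * speckle, 0, 255).astype(np.uint8)


def _draw_transverse_shape(rng: np.random.Generator, lo: int, hi: int) -> tuple[int, int]:
    # draw W/H inside [0.78, 1.30], a margin within the [0.75, 1.33] band so
    # that +-1 px rounding under the 0.8-1.2x augmentation scales stays valid
    h = int(rng.integers(lo, hi + 1))
    w_lo = max(lo, math.ceil(0.78 * h))
    w_hi = min(hi, math.floor(1.30 * h))
    w = int(rng.integers(w_lo, w_hi + 1))
    return h, w


def _draw_longitudinal_shape(rng, h_range, aspect_range) -> tuple[int, int]:
    h = int(rng.integers(h_range[0], h_range[1] + 1))
    aspect = rng.uniform(*aspect_range)
    return h, int(round(aspect * h))


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a labeled synthetic cohort; bit-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n_sym = round(spec.n_subjects * spec.symptomatic_fraction)
    labels = np.zeros(spec.n_subjects, dtype=int)
    labels[:n_sym] = 1
    rng.shuffle(labels)

    mean_sym = _BASE_MEAN - _MEAN_SHIFT_PER_EFFECT * spec.effect_size
    het_sym = _BASE_HETERO * (1.0 + _HETERO_GAIN_PER_EFFECT * spec.effect_size)

    records = []
    for i, label in enumerate(labels):
        mean = mean_sym if label else _BASE_MEAN
        het = het_sym if label else _BASE_HETERO
        images = {}
        for key in VIEW_KEYS:
            side, section = key[0], key[1]
            if section == "T":
                h, w = _draw_transverse_shape(rng, *spec.transverse_size_range)
            else:
                h, w = _draw_longitudinal_shape(
                    rng, spec.longitudinal_height_range, spec.longitudinal_aspect_range
                )
            images[key] = PlaqueImage(
                _speckle_image(rng, h, w, mean, het), side, "T" if section == "T" else "L"
            )
        records.append(SubjectRecord(f"S{i:04d}", int(label), images))
    return records


def write_cohort(records: list[SubjectRecord], out_dir) -> Path:
    """Write one PNG per ROI and a CSV manifest; returns the manifest path.

    Manifest columns: subject_id, label, img_LT, img_LL, img_RT, img_RL
    (image paths relative to the manifest's directory).
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id, "label": rec.label}
        for key in VIEW_KEYS:
            rel = Path("images") / f"{rec.subject_id}_{key}.png"
            Image.fromarray(rec.images[key].pixels, mode="L").save(out_dir / rel)
            row[f"img_{key}"] = str(rel)
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
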