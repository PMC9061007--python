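"""Cohort loading, training-set augmentation and batch-size-1 serving.

Augmentation follows the x7 recipe: the original ROI quadruple plus four
uniformly scaled copies (factors 0.8, 0.9, 1.1, 1.2) and a horizontally and
a vertically flipped copy.  A transform is applied consistently to all four
views of a subject, and the label is preserved, so 333 subjects (1332
images) become 2331 subject variants (9324 images).

Augmented variants carry their base subject id plus a ``__<tag>`` suffix;
:func:`base_subject_id` recovers the patient identity so that the
cross-validation driver can guarantee no variant of a test subject ever
enters training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .cohort import MANIFEST_COLUMNS, MIN_INPUT, VIEW_KEYS, PlaqueImage, SubjectRecord

__all__ = [
    "AugmentationSpec",
    "load_manifest",
    "augment",
    "subject_batches",
    "base_subject_id",
]


@dataclass(frozen=True)
class AugmentationSpec:
    scale_factors: tuple[float, ...] = (0.8, 0.9, 1.1, 1.2)
    flips: tuple[str, ...] = ("horizontal", "vertical")
    include_original: bool = True

    def __post_init__(self):
        for f in self.scale_factors:
            if f <= 0:
                raise ValueError(f"scale factors must be positive, got {f}")
        for fl in self.flips:
            if fl not in ("horizontal", "vertical"):
                raise ValueError(f"flips must be 'horizontal'/'vertical', got {fl!r}")

    @property
    def multiplier(self) -> int:
        """Subject variants produced per input subject (7 by default)."""
        return len(self.scale_factors) + len(self.flips) + (1 if self.include_original else 0)


def base_subject_id(subject_id: str) -> str:
    """Patient identity of a (possibly augmented) record id."""
    return subject_id.split("__", 1)[0]


def load_manifest(path) -> list[SubjectRecord]:
    """Read a cohort manifest and its PNGs back into subject records."""
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} missing columns {missing_cols}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        label = row["label"]
        if label not in (0, 1):
            raise ValueError(f"subject {sid}: label must be 0 or 1, got {label!r}")
        images = {}
        for key in VIEW_KEYS:
            img_path = path.parent / str(row[f"img_{key}"])
            if not img_path.exists():
                raise FileNotFoundError(
                    f"subject {sid}: image file {img_path} not found"
                )
            pixels = np.asarray(Image.open(img_path).convert("L"))
            images[key] = PlaqueImage(pixels, key[0], "T" if key[1] == "T" else "L")
        records.append(SubjectRecord(sid, int(label), images))
    return records


def _scale_image(img: PlaqueImage, factor: float, subject_id: str) -> PlaqueImage:
    h = int(round(img.height * factor))
    w = int(round(img.width * factor))
    if h < MIN_INPUT or w < MIN_INPUT:
        raise ValueError(
            f"subject {subject_id}: scaling by {factor} gives {h}x{w}, "
            f"below the {MIN_INPUT}-px minimum"
        )
    resized = Image.fromarray(img.pixels, mode="L").resize((w, h), Image.BILINEAR)
    return PlaqueImage(np.asarray(resized), img.side, img.section)


def _flip_image(img: PlaqueImage, direction: str) -> PlaqueImage:
    px = np.fliplr(img.pixels) if direction == "horizontal" else np.flipud(img.pixels)
    return PlaqueImage(np.ascontiguousarray(px), img.side, img.section)


def augment(records: list[SubjectRecord],
            spec: AugmentationSpec | None = None) -> list[SubjectRecord]:
    """Expand each subject into its transform variants (training split only).

    Each variant applies one transform — a uniform rescale or a flip — to
    all four views; the original is passed through unchanged when
    ``include_original`` is set.
    """
    if not records:
        raise ValueError("augment needs a nonempty record list")
    spec = spec or AugmentationSpec()
    out = []
    for rec in records:
        if spec.include_original:
            out.append(rec)
        for f in spec.scale_factors:
            images = {k: _scale_image(v, f, rec.subject_id) for k, v in rec.images.items()}
            out.append(SubjectRecord(f"{rec.subject_id}__s{f:g}", rec.label, images))
        for fl in spec.flips:
            images = {k: _flip_image(v, fl) for k, v in rec.images.items()}
            out.append(SubjectRecord(f"{rec.subject_id}__f{fl[0]}", rec.label, images))
    return out


def subject_batches(records: list[SubjectRecord], shuffle_seed: int | None = None):
    """Yield one subject per step: ((LT, LL, RT, RL) pixel arrays, label).

    Views keep their native, heterogeneous sizes — nothing is padded or
    resized — which is why the training batch size is 1.  Iteration order is
    the record order, or a seeded shuffle when ``shuffle_seed`` is given.
    """
    order = np.arange(len(records))
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(order)
    for i in order:
        rec = records[i]
        yield rec.quadruple(), rec.label
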