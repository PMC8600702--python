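"""Core data containers: labeled ultrasound images and datasets.

An :class:`ImageSample` is a single B-mode lesion image (``uint8`` pixel grid,
one or three channels) together with its biopsy-style ground-truth label.
A :class:`LabeledDataset` is an ordered collection of samples with class-count
bookkeeping, plus PNG/manifest round-trip helpers.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from PIL import Image

BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)

#: integer encoding used everywhere downstream (malignant is the positive class)
LABEL_TO_INT = {BENIGN: 0, MALIGNANT: 1}


@dataclass
class ImageSample:
    """One lesion image with a binary label and provenance id.

    ``pixels`` is always a ``(height, width, channels)`` uint8 array with
    values in [0, 255]; three-channel samples obtained from grayscale use
    plain replication of the gray plane across channels.
    """

    pixels: np.ndarray
    label: str
    sample_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(f"pixels must be (H, W, 1|3), got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        self.pixels = px

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def label_int(self) -> int:
        return LABEL_TO_INT[self.label]


@dataclass
class LabeledDataset:
    """Ordered list of :class:`ImageSample` with class-count bookkeeping."""

    samples: list[ImageSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    @property
    def class_counts(self) -> dict[str, int]:
        counts = Counter(s.label for s in self.samples)
        return {lab: counts.get(lab, 0) for lab in LABELS}

    def labels_int(self) -> np.ndarray:
        return np.array([s.label_int for s in self.samples], dtype=np.int64)

    def append(self, sample: ImageSample) -> None:
        if any(s.sample_id == sample.sample_id for s in self.samples):
            raise ValueError(f"duplicate sample_id {sample.sample_id!r}")
        self.samples.append(sample)

    def extend(self, samples: Iterable[ImageSample]) -> None:
        for s in samples:
            self.append(s)

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in indices])

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[ImageSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> ImageSample:
        return self.samples[i]

    # ------------------------------------------------------------------ IO

    def save_png(self, root: str | Path, seed: int | None = None) -> Path:
        """Write ``<root>/<label>/<sample_id>.png`` plus a CSV manifest.

        Returns the manifest path. 8-bit PNG; single-channel samples are
        written as grayscale PNGs, three-channel as RGB.
        """
        root = Path(root)
        rows = []
        for s in self.samples:
            d = root / s.label
            d.mkdir(parents=True, exist_ok=True)
            path = d / f"{s.sample_id}.png"
            arr = s.pixels[:, :, 0] if s.channels == 1 else s.pixels
            Image.fromarray(arr).save(path)
            rows.append((s.sample_id, s.label, str(path.relative_to(root)), seed))
        manifest = root / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "label", "path", "seed"])
            w.writerows(rows)
        return manifest

    @classmethod
    def load_png(cls, root: str | Path) -> "LabeledDataset":
        """Read a ``<root>/benign|malignant/*.png`` layout back into memory.

        Uses the manifest when present (preserving order), otherwise scans
        the two class directories in sorted order.
        """
        root = Path(root)
        manifest = root / "manifest.csv"
        entries: list[tuple[str, str, Path]] = []
        if manifest.exists():
            with open(manifest, newline="") as fh:
                for row in csv.DictReader(fh):
                    entries.append((row["sample_id"], row["label"], root / row["path"]))
        else:
            for label in LABELS:
                for p in sorted((root / label).glob("*.png")):
                    entries.append((p.stem, label, p))
        samples = []
        for sid, label, path in entries:
            arr = np.asarray(Image.open(path))
            samples.append(ImageSample(pixels=arr, label=label, sample_id=sid))
        return cls(samples)
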