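"""Labelled image collections and class-subfolder disk IO."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["LabeledImages", "save_image_folder", "load_image_folder"]


@dataclass
class LabeledImages:
    """Images as a float array in [0, 1] with integer class labels.

    ``images`` has shape (n, size, size) for grayscale or
    (n, size, size, channels).
    """

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images and labels lengths differ")
        if not self.class_names:
            k = int(self.labels.max()) + 1 if self.labels.size else 0
            self.class_names = [f"C{i + 1}" for i in range(k)]

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx) -> "LabeledImages":
        return LabeledImages(self.images[idx], self.labels[idx],
                             list(self.class_names))

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.num_classes)


def save_image_folder(collection: LabeledImages, path) -> Path:
    """Write one PNG subfolder per class; returns the root path."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    counters = {}
    for img, lab in zip(collection.images, collection.labels):
        name = collection.class_names[lab]
        sub = root / name
        sub.mkdir(exist_ok=True)
        i = counters.get(name, 0)
        counters[name] = i + 1
        arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr.squeeze()).save(sub / f"{name}_{i:05d}.png")
    return root


def load_image_folder(path, image_size: int | None = None,
                      grayscale: bool = True) -> LabeledImages:
    """Read a class-subfolder tree of PNG/JPEG images.

    Subfolder names become class names (sorted); images are optionally
    resized to ``image_size`` squares and scaled to [0, 1].
    """
    root = Path(path)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subfolders under {root}")
    images, labels, names = [], [], []
    for ci, sub in enumerate(class_dirs):
        names.append(sub.name)
        files = sorted(f for f in sub.iterdir()
                       if f.suffix.lower() in (".png", ".jpg", ".jpeg"))
        for f in files:
            im = Image.open(f)
            im = im.convert("L" if grayscale else "RGB")
            if image_size:
                im = im.resize((image_size, image_size), Image.BILINEAR)
            images.append(np.asarray(im, dtype=np.float32) / 255.0)
            labels.append(ci)
    return LabeledImages(np.stack(images), np.asarray(labels), names)
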