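"""Desk-scale synthetic stand-ins for a field-collected crop image set.

Three families of fixtures:

* **Image datasets** — multi-class gratings-plus-blob images with a
  difficulty dial. Each class has a fixed template (a sinusoidal
  grating at a class-specific frequency and orientation plus a Gaussian
  blob at a class-specific position); a sample is its class template
  corrupted by pixel noise and, at higher noise levels, partial mixing
  with a confuser class's template. At ``noise_sd = 0`` samples equal
  their templates and a nearest-template classifier is perfect; as
  ``noise_sd`` grows the oracle accuracy falls smoothly, so search
  quality is measurable without real photographs.

* **Split/augmentation protocol** — the stratified 7:2:1
  train/validation/test partition and the flip/shift/zoom augmentation
  that doubles (or k-folds) a dataset while keeping the originals.

* **Analytic benchmark objectives** — cheap deterministic functions of
  a configuration's encoding (``smooth``, ``deceptive``, ``noisy``)
  with the global optimum established by exhaustive enumeration at
  construction, so the Bayesian-optimization stack is testable with no
  training at all. A seeded epoch-trace mixture generator exercises
  the unpromising-trial detector the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .data import LabeledImages
from .space import (HyperparamConfig, HyperparamSpace, encode,
                    enumerate_configs)
from .training import EpochTrace, ReferenceCurve, update_reference_curve

__all__ = [
    "SyntheticDatasetSpec", "generate_dataset", "class_templates",
    "template_oracle_predict", "split_dataset", "augment",
    "BenchmarkObjective", "make_benchmark", "make_trace_mixture",
]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for one synthetic image dataset."""

    num_classes: int = 8
    per_class: int = 100
    image_size: int = 32
    noise_sd: float = 0.3
    grating_amp: float = 0.2
    blob_amp: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.per_class < 10:
            raise ValueError("per_class must be >= 10")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "num_classes": self.num_classes, "per_class": self.per_class,
            "image_size": self.image_size, "noise_sd": self.noise_sd,
            "grating_amp": self.grating_amp, "blob_amp": self.blob_amp,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticDatasetSpec":
        return cls(**d)


def class_templates(spec: SyntheticDatasetSpec) -> np.ndarray:
    """(K, S, S) array of noiseless class templates."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s] / s
    out = np.empty((spec.num_classes, s, s), dtype=np.float32)
    for c in range(spec.num_classes):
        theta = np.pi * c / spec.num_classes
        freq = 2.0 + 1.5 * (c % 4)
        grating = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
        bx = 0.25 + 0.5 * ((c * 37) % spec.num_classes) / max(spec.num_classes - 1, 1)
        by = 0.25 + 0.5 * ((c * 53 + 3) % spec.num_classes) / max(spec.num_classes - 1, 1)
        blob = np.exp(-(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * 0.12 ** 2)))
        out[c] = 0.5 + spec.grating_amp * grating + spec.blob_amp * blob
    return np.clip(out, 0.0, 1.0)


def generate_dataset(spec: SyntheticDatasetSpec) -> LabeledImages:
    """Balanced, seeded image collection per the spec.

    A sample of class c is ``(1 - m) t_c + m t_c' + noise`` where t are
    templates, c' a random confuser class, the mixing weight
    ``m = min(|N(0, noise_sd)|, 0.9)`` and the pixel noise is
    ``N(0, noise_sd / 2)``. All stochasticity therefore vanishes at
    ``noise_sd = 0``.
    """
    rng = np.random.default_rng(spec.seed)
    t = class_templates(spec)
    k, s = spec.num_classes, spec.image_size
    n = k * spec.per_class
    images = np.empty((n, s, s), dtype=np.float32)
    labels = np.repeat(np.arange(k), spec.per_class)
    for i, c in enumerate(labels):
        confuser = int(rng.integers(0, k - 1))
        confuser += confuser >= c
        m = min(abs(rng.normal(0.0, spec.noise_sd)), 0.9)
        img = (1.0 - m) * t[c] + m * t[confuser]
        img = img + rng.normal(0.0, spec.noise_sd / 2.0, size=(s, s))
        images[i] = np.clip(img, 0.0, 1.0)
    return LabeledImages(images, labels)


def template_oracle_predict(images: np.ndarray,
                            spec: SyntheticDatasetSpec) -> np.ndarray:
    """Nearest-class-template classification (L2); the generator's oracle."""
    t = class_templates(spec).reshape(spec.num_classes, -1)
    x = np.asarray(images, dtype=np.float32).reshape(len(images), -1)
    d2 = ((x[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


# -- split and augmentation protocol -------------------------------------

def split_dataset(collection: LabeledImages, ratio=(7, 2, 1), seed: int = 0
                  ) -> tuple[LabeledImages, LabeledImages, LabeledImages]:
    """Per-class stratified train/validation/test partition.

    Validation and test counts per class are floor allocations of the
    normalized ratio; the remainder goes to training. The three splits
    are disjoint and exhaust the input.
    """
    ratio = tuple(float(r) for r in ratio)
    if len(ratio) != 3 or any(r < 0 for r in ratio) or sum(ratio) <= 0:
        raise ValueError("ratio must be three nonnegative values, sum > 0")
    total = sum(ratio)
    rng = np.random.default_rng(seed)
    tr_idx, va_idx, te_idx = [], [], []
    for c in range(collection.num_classes):
        idx = np.flatnonzero(collection.labels == c)
        if idx.size < 10 and ratio[1] > 0 and ratio[2] > 0:
            warnings.warn(f"class {c} has only {idx.size} samples; "
                          "splits may be empty", stacklevel=2)
        idx = rng.permutation(idx)
        n = idx.size
        n_va = int(n * ratio[1] / total)
        n_te = int(n * ratio[2] / total)
        n_tr = n - n_va - n_te
        tr_idx.append(idx[:n_tr])
        va_idx.append(idx[n_tr:n_tr + n_va])
        te_idx.append(idx[n_tr + n_va:])
    cat = lambda parts: np.concatenate(parts) if parts else np.empty(0, int)
    return (collection.subset(cat(tr_idx)), collection.subset(cat(va_idx)),
            collection.subset(cat(te_idx)))


_AUG_OPS = ("flip", "shift", "zoom")


def _apply_op(img: np.ndarray, op: str, rng: np.random.Generator) -> np.ndarray:
    if op == "flip":
        return img[:, ::-1].copy()
    if op == "shift":
        dy, dx = rng.integers(-3, 4, size=2)
        return np.roll(np.roll(img, dy, axis=0), dx, axis=1)
    if op == "zoom":
        s = img.shape[0]
        z = rng.uniform(1.05, 1.25)
        big = ndimage.zoom(img, z, order=1)
        off = (big.shape[0] - s) // 2
        return np.clip(big[off:off + s, off:off + s], 0.0, 1.0)
    raise ValueError(f"unknown augmentation op {op!r}")


def augment(collection: LabeledImages, factor: int = 2,
            ops: Sequence[str] = _AUG_OPS, seed: int = 0) -> LabeledImages:
    """Expand a collection to ``factor`` times its size.

    Originals are retained; each extra copy applies one seeded random
    op (moving, flipping, or zooming) to each image. Labels are
    preserved.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    ops = tuple(ops)
    for op in ops:
        if op not in _AUG_OPS:
            raise ValueError(f"unknown augmentation op {op!r}")
    if factor == 1:
        return collection
    rng = np.random.default_rng(seed)
    imgs = [collection.images]
    labs = [collection.labels]
    for _ in range(factor - 1):
        batch = np.empty_like(collection.images)
        for i, img in enumerate(collection.images):
            op = ops[rng.integers(len(ops))]
            batch[i] = _apply_op(img, op, rng)
        imgs.append(batch)
        labs.append(collection.labels)
    return LabeledImages(np.concatenate(imgs), np.concatenate(labs),
                         list(collection.class_names))


# -- analytic benchmark objectives ---------------------------------------

@dataclass(frozen=True)
class BenchmarkObjective:
    """A cheap deterministic objective over the configuration space.

    ``value_fn`` maps a configuration to [0, 1]; the optimum is found
    by exhaustive enumeration at construction, so searches can be
    scored against the exact global maximum.
    """

    name: str
    space: HyperparamSpace
    value_fn: Callable[[HyperparamConfig], float] = field(repr=False)
    known_optimum: HyperparamConfig
    known_optimum_value: float

    def __call__(self, config: HyperparamConfig) -> float:
        return self.value_fn(config)


def _anchor_config(space: HyperparamSpace, rank: float) -> HyperparamConfig:
    """A config at relative position `rank` within each value set."""
    pick = lambda vals, r: vals[min(int(round(r * (len(vals) - 1))), len(vals) - 1)]
    ln = max(space.layer_counts)
    h = ln - 1
    dr = tuple(pick(space.dropout_values, rank) for _ in range(h))
    nn = tuple(pick(space.neuron_values, rank) for _ in range(h))
    return HyperparamConfig(
        ln=ln, dr=dr, nn=nn,
        omega1=pick(space.omega1_values, rank),
        beta=pick(space.beta_values, rank))


def make_benchmark(name: str, space: HyperparamSpace, seed: int = 0,
                   cap: int = 10**6) -> BenchmarkObjective:
    """Construct a named analytic objective over `space`.

    * ``smooth`` — a single Gaussian basin in the encoded coordinates,
      peak value 1 at an interior grid point.
    * ``deceptive`` — a narrow global basin plus a broad lower local
      basin centred elsewhere.
    * ``noisy`` — smooth plus seeded per-configuration observation
      noise (sd 0.01), frozen at construction.
    """
    configs = enumerate_configs(space, cap=cap)
    target = encode(_anchor_config(space, 0.6), space)

    def smooth_fn(c: HyperparamConfig) -> float:
        z = encode(c, space)
        return float(np.exp(-np.sum((z - target) ** 2) / (2 * 0.6 ** 2)))

    if name == "smooth":
        fn = smooth_fn
    elif name == "deceptive":
        local = encode(_anchor_config(space, 0.1), space)

        # narrow global basin + broad lower basin; amplitudes keep the
        # sum below 1 and the argmax unique (no clipping plateau)
        def fn(c: HyperparamConfig) -> float:
            z = encode(c, space)
            g = 0.75 * np.exp(-np.sum((z - target) ** 2) / (2 * 0.35 ** 2))
            l = 0.55 * np.exp(-np.sum((z - local) ** 2) / (2 * 0.9 ** 2))
            return float(g + l)
    elif name == "noisy":
        rng = np.random.default_rng(seed)
        noise = {c: float(rng.normal(0.0, 0.01)) for c in configs}

        def fn(c: HyperparamConfig) -> float:
            return float(np.clip(smooth_fn(c) + noise[c], 0.0, 1.0))
    else:
        raise ValueError(f"unknown benchmark {name!r}; "
                         "choose smooth, deceptive, or noisy")

    values = [fn(c) for c in configs]
    best = int(np.argmax(values))
    return BenchmarkObjective(name=name, space=space, value_fn=fn,
                              known_optimum=configs[best],
                              known_optimum_value=values[best])


# -- epoch-trace mixtures for the pruning detector ------------------------

def make_trace_mixture(n_traces: int = 100, bad_fraction: float = 0.3,
                       epochs: int = 20, offset: float = 0.15,
                       trace_noise_sd: float = 0.03, seed: int = 0
                       ) -> tuple[list[EpochTrace], np.ndarray, ReferenceCurve]:
    """Seeded mixture of normal and plateauing validation-error traces.

    The reference curve is a decaying error profile; normal traces
    scatter around it with sd ``trace_noise_sd``, plateauing (bad)
    traces sit ``offset`` above it. Returns (traces, is_bad flags,
    reference curve built from three clean prototype runs).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(epochs)
    ref_profile = 0.15 + 0.6 * np.exp(-t / 5.0)
    proto = [EpochTrace(val_error=list(ref_profile +
                                       rng.normal(0, trace_noise_sd / 2, epochs)))
             for _ in range(3)]
    reference = update_reference_curve(proto)
    n_bad = int(round(n_traces * bad_fraction))
    is_bad = np.zeros(n_traces, dtype=bool)
    is_bad[rng.permutation(n_traces)[:n_bad]] = True
    traces = []
    for i in range(n_traces):
        shift = offset if is_bad[i] else 0.0
        err = ref_profile + shift + rng.normal(0, trace_noise_sd, epochs)
        traces.append(EpochTrace(val_error=list(np.clip(err, 0.0, 1.0))))
    return traces, is_bad, reference
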