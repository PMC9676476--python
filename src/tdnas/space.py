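"""Three-level hyperparameter space for the fully connected head.

The search space is a finite grid over three levels:

* architectural — ``ln``, the total number of fully connected layers
  (the output layer included);
* internal — per hidden layer, a dropout rate ``dr_i`` and a neuron
  count ``nn_i``;
* external — the judgment-criterion weights ``omega1`` (accuracy weight,
  with ``omega2 = 1 - omega1``) and the F-score parameter ``beta``.

The output layer is implicit in every configuration: its width equals
``num_classes`` and it carries no dropout, so a configuration with
``ln`` layers has ``ln - 1`` searchable hidden layers.

Configurations are encoded as fixed-length numeric vectors for the
Gaussian-process surrogate: one ordinal (min-max scaled) coordinate per
grid dimension, neuron counts on a log2 axis, and sentinel 0 for hidden
layer slots absent at small ``ln``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "HyperparamSpace",
    "HyperparamConfig",
    "default_space",
    "enumerate_configs",
    "count_configs",
    "encode",
    "decode",
]

#: Default grid values (architectural / internal / external levels).
DEFAULT_LAYER_COUNTS = (1, 2, 3)
DEFAULT_DROPOUT_VALUES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_NEURON_VALUES = (512, 1024, 2048, 4096)
DEFAULT_OMEGA1_VALUES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
DEFAULT_BETA_VALUES = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class HyperparamConfig:
    """One point in the search space.

    Parameters
    ----------
    ln : int
        Total fully connected layer count, output layer included.
    dr : tuple of float
        Dropout rate per hidden layer, length ``ln - 1``.
    nn : tuple of int
        Neuron count per hidden layer, length ``ln - 1``.
    omega1 : float
        Accuracy weight in the judgment criterion; ``omega2 = 1 - omega1``.
    beta : float
        F-score parameter.
    """

    ln: int
    dr: tuple[float, ...]
    nn: tuple[int, ...]
    omega1: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dr", tuple(float(v) for v in self.dr))
        object.__setattr__(self, "nn", tuple(int(v) for v in self.nn))
        if self.ln < 1:
            raise ValueError("at least one fully connected layer is required")
        if len(self.dr) != self.ln - 1 or len(self.nn) != self.ln - 1:
            raise ValueError(
                f"dr/nn must have length ln-1={self.ln - 1}; "
                f"got {len(self.dr)}/{len(self.nn)}"
            )

    @property
    def omega2(self) -> float:
        return 1.0 - self.omega1

    def to_dict(self) -> dict:
        return {
            "ln": self.ln,
            "dr": list(self.dr),
            "nn": list(self.nn),
            "omega1": self.omega1,
            "beta": self.beta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparamConfig":
        return cls(
            ln=int(d["ln"]),
            dr=tuple(d["dr"]),
            nn=tuple(d["nn"]),
            omega1=float(d.get("omega1", 1.0)),
            beta=float(d.get("beta", 1.0)),
        )


def _sorted_unique(values: Sequence[float]) -> tuple:
    out = tuple(sorted(set(values)))
    if not out:
        raise ValueError("value set must be non-empty")
    return out


@dataclass(frozen=True)
class HyperparamSpace:
    """The finite grid the search runs over."""

    layer_counts: tuple[int, ...] = DEFAULT_LAYER_COUNTS
    dropout_values: tuple[float, ...] = DEFAULT_DROPOUT_VALUES
    neuron_values: tuple[int, ...] = DEFAULT_NEURON_VALUES
    omega1_values: tuple[float, ...] = DEFAULT_OMEGA1_VALUES
    beta_values: tuple[float, ...] = DEFAULT_BETA_VALUES
    num_classes: int = 8
    search_external: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_counts",
                           tuple(int(v) for v in _sorted_unique(self.layer_counts)))
        object.__setattr__(self, "dropout_values", _sorted_unique(self.dropout_values))
        object.__setattr__(self, "neuron_values",
                           tuple(int(v) for v in _sorted_unique(self.neuron_values)))
        object.__setattr__(self, "omega1_values", _sorted_unique(self.omega1_values))
        object.__setattr__(self, "beta_values", _sorted_unique(self.beta_values))
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if min(self.layer_counts) < 1:
            raise ValueError("layer counts must be >= 1")
        for v in self.dropout_values:
            if not 0.0 <= v < 1.0:
                raise ValueError(f"dropout rate {v} outside [0, 1)")
        for v in self.omega1_values:
            if not 0.0 < v <= 1.0:
                raise ValueError(f"omega1 {v} outside (0, 1]")
        for v in self.beta_values:
            if v <= 0:
                raise ValueError(f"beta {v} must be positive")

    @property
    def max_hidden(self) -> int:
        """Largest number of searchable hidden layers (max ln minus output)."""
        return max(self.layer_counts) - 1

    @property
    def encoded_dim(self) -> int:
        """Length of the encoded vector: ln, per-slot dr and nn, omega1, beta."""
        return 1 + 2 * self.max_hidden + 2

    def contains(self, config: HyperparamConfig) -> bool:
        return (
            config.ln in self.layer_counts
            and all(v in self.dropout_values for v in config.dr)
            and all(v in self.neuron_values for v in config.nn)
            and config.omega1 in self.omega1_values
            and config.beta in self.beta_values
        )

    def validate(self, config: HyperparamConfig) -> None:
        if not self.contains(config):
            raise ValueError(f"configuration {config} is not in this space")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "layer_counts": list(self.layer_counts),
            "dropout_values": list(self.dropout_values),
            "neuron_values": list(self.neuron_values),
            "omega1_values": list(self.omega1_values),
            "beta_values": list(self.beta_values),
            "num_classes": self.num_classes,
            "search_external": self.search_external,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparamSpace":
        return cls(**{k: d[k] for k in (
            "layer_counts", "dropout_values", "neuron_values",
            "omega1_values", "beta_values", "num_classes", "search_external",
        ) if k in d})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "HyperparamSpace":
        return cls.from_dict(yaml.safe_load(text))


def default_space(num_classes: int = 8, search_external: bool = True) -> HyperparamSpace:
    """The standard three-level grid.

    With ``search_external=False`` the external level is pinned to
    ``omega1 = 1`` (accuracy-only criterion) and ``beta = 1``.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if search_external:
        return HyperparamSpace(num_classes=num_classes, search_external=True)
    return HyperparamSpace(
        omega1_values=(1.0,),
        beta_values=(1.0,),
        num_classes=num_classes,
        search_external=False,
    )


def count_configs(space: HyperparamSpace) -> int:
    """Exact configuration count without enumerating."""
    n_dr = len(space.dropout_values)
    n_nn = len(space.neuron_values)
    arch = sum((n_dr * n_nn) ** (ln - 1) for ln in space.layer_counts)
    return arch * len(space.omega1_values) * len(space.beta_values)


def iter_configs(space: HyperparamSpace) -> Iterator[HyperparamConfig]:
    """Lazy enumeration in deterministic (ln, nn, dr, omega1, beta) order."""
    for ln in space.layer_counts:
        h = ln - 1
        for nn in itertools.product(space.neuron_values, repeat=h):
            for dr in itertools.product(space.dropout_values, repeat=h):
                for w1 in space.omega1_values:
                    for b in space.beta_values:
                        yield HyperparamConfig(ln=ln, dr=dr, nn=nn,
                                               omega1=w1, beta=b)


def enumerate_configs(space: HyperparamSpace, cap: int = 10**6) -> list[HyperparamConfig]:
    """Every valid configuration exactly once, deterministic order.

    Refuses (with the exact count in the message) when the space exceeds
    ``cap`` configurations.
    """
    n = count_configs(space)
    if n > cap:
        raise ValueError(
            f"space holds {n} configurations, exceeding the cap of {cap}; "
            "raise `cap` or restrict the space"
        )
    return list(iter_configs(space))


# -- ordinal encoding ----------------------------------------------------

def _scale(value: float, lo: float, hi: float) -> float:
    return 0.0 if hi == lo else (value - lo) / (hi - lo)


def _unscale_snap(z: float, values: Sequence[float]) -> float:
    lo, hi = values[0], values[-1]
    v = lo if hi == lo else lo + z * (hi - lo)
    return min(values, key=lambda a: abs(a - v))


def encode(config: HyperparamConfig, space: HyperparamSpace) -> np.ndarray:
    """Encode a configuration as a fixed-length vector in [0, 1]^d.

    Coordinates: ``[ln, dr_1..dr_H, nn_1..nn_H, omega1, beta]`` with
    ``H = space.max_hidden``; each dimension min-max scaled over its value
    set (neuron counts on a log2 axis); absent hidden slots are sentinel 0.
    """
    space.validate(config)
    H = space.max_hidden
    x = np.zeros(space.encoded_dim)
    lc = space.layer_counts
    x[0] = _scale(config.ln, lc[0], lc[-1])
    dv = space.dropout_values
    for i, v in enumerate(config.dr):
        x[1 + i] = _scale(v, dv[0], dv[-1])
    nv = space.neuron_values
    lo2, hi2 = math.log2(nv[0]), math.log2(nv[-1])
    for i, v in enumerate(config.nn):
        x[1 + H + i] = _scale(math.log2(v), lo2, hi2)
    wv, bv = space.omega1_values, space.beta_values
    x[1 + 2 * H] = _scale(config.omega1, wv[0], wv[-1])
    x[2 + 2 * H] = _scale(config.beta, bv[0], bv[-1])
    return x


def decode(x: np.ndarray, space: HyperparamSpace) -> HyperparamConfig:
    """Inverse of :func:`encode`; snaps each coordinate to the nearest grid value."""
    x = np.asarray(x, dtype=float)
    if x.shape != (space.encoded_dim,):
        raise ValueError(f"expected vector of length {space.encoded_dim}, got {x.shape}")
    H = space.max_hidden
    ln = int(round(_unscale_snap(x[0], space.layer_counts)))
    h = ln - 1
    dr = tuple(_unscale_snap(x[1 + i], space.dropout_values) for i in range(h))
    nv = space.neuron_values
    logs = [math.log2(v) for v in nv]
    nn = []
    for i in range(h):
        z = x[1 + H + i]
        lv = logs[0] if logs[-1] == logs[0] else logs[0] + z * (logs[-1] - logs[0])
        nn.append(min(nv, key=lambda a: abs(math.log2(a) - lv)))
    omega1 = _unscale_snap(x[1 + 2 * H], space.omega1_values)
    beta = _unscale_snap(x[2 + 2 * H], space.beta_values)
    return HyperparamConfig(ln=ln, dr=dr, nn=tuple(nn), omega1=omega1, beta=beta)


def encode_all(configs: Sequence[HyperparamConfig], space: HyperparamSpace) -> np.ndarray:
    """Stack encodings of many configurations into an (n, d) matrix."""
    return np.vstack([encode(c, space) for c in configs]) if configs else \
        np.empty((0, space.encoded_dim))
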