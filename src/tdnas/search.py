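"""The target-dependent architecture-search loop and its baselines.

The main loop is Bayesian optimization over the finite configuration
grid: initialize with a handful of stratified random trials, then
repeat (fit GP surrogate on all observed (encoding, jc) pairs ->
posterior over unevaluated candidates -> pick the expected-improvement
argmax -> train/evaluate it -> append) until a dynamic quit condition
fires (candidate queue empty, iteration budget reached, or — optionally
— a stagnation patience).

The naive baseline evaluates configurations in grid or seeded-random
order with no surrogate, recording trials in the same format, so the
two are directly comparable under paired seeds.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .acquisition import EmptyPoolError, select_next
from .gp import GPSurrogate
from .metrics import EvalResult
from .space import (HyperparamConfig, HyperparamSpace, encode, encode_all,
                    enumerate_configs)
from .training import (BackboneSpec, EpochTrace, ReferenceCurve, build_model,
                       extract_features, train_validate,
                       update_reference_curve, COMPLETED, UNPROMISING_ABORTED)

__all__ = [
    "TrialRecord", "QuitConditions", "SearchState", "TrainingObjective",
    "dyn_quit", "run_tdnas", "run_hps", "summarize",
    "FAILED",
]

FAILED = "failed"

#: Full enumeration is used as the acquisition pool up to this size;
#: larger spaces get a seeded uniform sample of unevaluated configs.
POOL_ENUM_LIMIT = 20_000
POOL_SAMPLE_SIZE = 5_000


@dataclass
class TrialRecord:
    """One evaluated configuration."""

    index: int
    config: HyperparamConfig
    encoded: np.ndarray
    jc_value: float
    eval: Optional[EvalResult] = None
    trace: Optional[EpochTrace] = None
    status: str = COMPLETED
    seed: int = 0
    wall_time: float = 0.0

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "config": self.config.to_dict(),
            "encoded": [float(v) for v in self.encoded],
            "jc_value": self.jc_value,
            "eval": self.eval.to_dict() if self.eval else None,
            "trace": self.trace.to_dict() if self.trace else None,
            "status": self.status,
            "seed": self.seed,
            "wall_time": self.wall_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(
            index=d["index"],
            config=HyperparamConfig.from_dict(d["config"]),
            encoded=np.asarray(d["encoded"], dtype=float),
            jc_value=d["jc_value"],
            eval=EvalResult.from_dict(d["eval"]) if d.get("eval") else None,
            trace=EpochTrace.from_dict(d["trace"]) if d.get("trace") else None,
            status=d.get("status", COMPLETED),
            seed=d.get("seed", 0),
            wall_time=d.get("wall_time", 0.0),
        )


@dataclass
class QuitConditions:
    """Inputs to the dynamic quit decision."""

    max_iterations: int = 60
    no_improve_patience: int = 15
    no_improve_enabled: bool = False

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class SearchState:
    """Trial history plus incumbent bookkeeping."""

    history: list[TrialRecord] = field(default_factory=list)
    incumbent: Optional[TrialRecord] = None
    iterations_since_improvement: int = 0
    remaining_candidates: int = 0

    def append(self, record: TrialRecord) -> None:
        self.history.append(record)
        if self.incumbent is None or record.jc_value > self.incumbent.jc_value:
            self.incumbent = record
            self.iterations_since_improvement = 0
        else:
            self.iterations_since_improvement += 1

    @property
    def f_best(self) -> float:
        return self.incumbent.jc_value if self.incumbent else 0.0


def dyn_quit(state: SearchState, conditions: QuitConditions) -> bool:
    """True iff the queue is empty, the budget is reached, or (when
    enabled) the incumbent has stagnated for the patience window."""
    if state.remaining_candidates == 0:
        return True
    if len(state.history) >= conditions.max_iterations:
        return True
    if (conditions.no_improve_enabled
            and state.iterations_since_improvement >= conditions.no_improve_patience):
        return True
    return False


# -- objectives ----------------------------------------------------------

ObjectiveOutput = tuple[float, Optional[EvalResult], Optional[EpochTrace], str]


def _call_objective(objective: Callable, config: HyperparamConfig,
                    seed: int) -> ObjectiveOutput:
    """Normalize objective outputs: scalar jc or a full trial tuple."""
    try:
        out = objective(config, seed)
    except TypeError:
        out = objective(config)
    if isinstance(out, tuple):
        jc, ev, trace, status = out
        return float(jc), ev, trace, status
    return float(out), None, None, COMPLETED


class TrainingObjective:
    """Trains one model per configuration on a fixed dataset.

    Features are extracted once through the frozen backbone and shared
    by every trial. When pruning is enabled, a running reference curve
    (mean per-epoch validation error of completed trials) is maintained
    and handed to each new trial as its abort monitor.
    """

    def __init__(self, train_data, val_data, backbone: BackboneSpec,
                 num_classes: int, epochs: int = 50, lr: float = 0.01,
                 batch_size: int = 32, pruning: bool = True,
                 margin: float = 0.02, patience: int = 3,
                 feature_seed: int = 0):
        Xtr, ytr = train_data
        Xva, yva = val_data
        Xtr = np.asarray(Xtr)
        Xva = np.asarray(Xva)
        if Xtr.ndim >= 3:
            Xtr = extract_features(Xtr, backbone, seed=feature_seed)
            Xva = extract_features(Xva, backbone, seed=feature_seed)
        self.train = (Xtr, np.asarray(ytr))
        self.val = (Xva, np.asarray(yva))
        self.backbone = backbone
        self.num_classes = num_classes
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.pruning = pruning
        self.margin = margin
        self.patience = patience
        self._completed_traces: list[EpochTrace] = []
        self.reference = ReferenceCurve()

    def __call__(self, config: HyperparamConfig, seed: int = 0) -> ObjectiveOutput:
        model = build_model(config, self.backbone, self.num_classes)
        monitor = self.reference if (self.pruning and not self.reference.empty) \
            else None
        result, trace, status = train_validate(
            model, self.train, self.val, epochs=self.epochs, lr=self.lr,
            monitor=monitor, margin=self.margin, patience=self.patience,
            seed=seed, batch_size=self.batch_size)
        if status == COMPLETED:
            self._completed_traces.append(trace)
            self.reference = update_reference_curve(self._completed_traces)
        return result.jc, result, trace, status


# -- search drivers ------------------------------------------------------

def _trial_seeds(root_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(root_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _init_indices(n_total: int, n_init: int, rng: np.random.Generator) -> list[int]:
    """Latin-hypercube-style: one uniform draw per equal stratum of the
    enumeration order — distinct by construction."""
    n_init = min(n_init, n_total)
    edges = np.linspace(0, n_total, n_init + 1)
    return [int(rng.integers(int(edges[i]), max(int(edges[i + 1]), int(edges[i]) + 1)))
            for i in range(n_init)]


def _evaluate_into(state: SearchState, objective, config, encoded, seed,
                   n_failed: list) -> None:
    t0 = time.perf_counter()
    try:
        jc, ev, trace, status = _call_objective(objective, config, seed)
    except Exception:  # failed trial: scored 0 so the surrogate avoids it
        jc, ev, trace, status = 0.0, None, None, FAILED
        n_failed[0] += 1
    record = TrialRecord(index=len(state.history), config=config,
                         encoded=np.asarray(encoded, dtype=float),
                         jc_value=jc, eval=ev, trace=trace, status=status,
                         seed=seed, wall_time=time.perf_counter() - t0)
    state.append(record)
    if n_failed[0] > max(0.25 * len(state.history), 2):
        raise RuntimeError(
            f"{n_failed[0]} of {len(state.history)} trials failed; "
            "objective appears broken — aborting the search")


def run_tdnas(space: HyperparamSpace, objective: Callable,
              conditions: QuitConditions | None = None, n_init: int = 5,
              seed: int = 0) -> tuple[TrialRecord, list[TrialRecord]]:
    """Bayesian-optimization search; returns (incumbent, history)."""
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    conditions = conditions or QuitConditions()
    configs = enumerate_configs(space)
    X_all = encode_all(configs, space)
    n_total = len(configs)
    rng = np.random.default_rng(seed)
    seeds = _trial_seeds(seed, conditions.max_iterations)

    state = SearchState(remaining_candidates=n_total)
    n_failed = [0]
    for i in _init_indices(n_total, n_init, rng):
        if dyn_quit(state, conditions):
            break
        _evaluate_into(state, objective, configs[i], X_all[i],
                       seeds[len(state.history)], n_failed)
        state.remaining_candidates -= 1

    evaluated = {c: True for c in (r.config for r in state.history)}
    while not dyn_quit(state, conditions):
        gp = GPSurrogate().fit(
            np.vstack([r.encoded for r in state.history]),
            [r.jc_value for r in state.history])
        unevaluated = [i for i, c in enumerate(configs) if c not in evaluated]
        if not unevaluated:
            break
        if len(unevaluated) > POOL_ENUM_LIMIT:
            pick = rng.choice(len(unevaluated), size=POOL_SAMPLE_SIZE,
                              replace=False)
            pool_idx = [unevaluated[j] for j in sorted(pick)]
        else:
            pool_idx = unevaluated
        try:
            acq = select_next(gp, X_all[pool_idx], state.f_best)
        except EmptyPoolError:
            break
        chosen = pool_idx[acq.index]
        _evaluate_into(state, objective, configs[chosen], X_all[chosen],
                       seeds[len(state.history)], n_failed)
        evaluated[configs[chosen]] = True
        state.remaining_candidates -= 1
    return state.incumbent, state.history


def run_hps(space: HyperparamSpace, objective: Callable,
            strategy: str = "random", budget: int = 60, seed: int = 0
            ) -> tuple[TrialRecord, list[TrialRecord]]:
    """Surrogate-free baseline: grid (enumeration order) or seeded-random
    order, one trial per configuration up to the budget."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if strategy not in ("grid", "random"):
        raise ValueError("strategy must be 'grid' or 'random'")
    configs = enumerate_configs(space)
    order = np.arange(len(configs))
    if strategy == "random":
        order = np.random.default_rng(seed).permutation(order)
    order = order[:budget]
    seeds = _trial_seeds(seed, len(order))
    state = SearchState(remaining_candidates=len(configs))
    n_failed = [0]
    for k, i in enumerate(order):
        _evaluate_into(state, objective, configs[i],
                       encode(configs[i], space), seeds[k], n_failed)
        state.remaining_candidates -= 1
    return state.incumbent, state.history


# -- reporting -----------------------------------------------------------

def summarize(history: Sequence[TrialRecord],
              epochs_per_trial: int | None = None) -> dict:
    """Search report: incumbent, incumbent curve, abort and epoch accounting."""
    if not history:
        raise ValueError("empty history")
    best = max(history, key=lambda r: r.jc_value)
    inc, cur = [], -np.inf
    for r in history:
        cur = max(cur, r.jc_value)
        inc.append(cur)
    n_aborted = sum(r.status == UNPROMISING_ABORTED for r in history)
    n_failed = sum(r.status == FAILED for r in history)
    epochs_run = [r.trace.epochs_run if r.trace else 0 for r in history]
    if epochs_per_trial is None:
        epochs_per_trial = max(epochs_run) if any(epochs_run) else 0
    budgeted = epochs_per_trial * len(history)
    executed = int(sum(epochs_run))
    return {
        "n_trials": len(history),
        "best_config": best.config.to_dict(),
        "best_jc": best.jc_value,
        "best_accuracy": best.eval.accuracy if best.eval else None,
        "incumbent_curve": inc,
        "n_unpromising_aborted": n_aborted,
        "unpromising_fraction": n_aborted / len(history),
        "n_failed": n_failed,
        "epochs_budgeted": budgeted,
        "epochs_executed": executed,
        "epochs_saved": max(budgeted - executed, 0),
    }


def write_trials_jsonl(history: Sequence[TrialRecord], path) -> None:
    with open(path, "w") as fh:
        for r in history:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_trials_jsonl(path) -> list[TrialRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(TrialRecord.from_dict(json.loads(line)))
    return out
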