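"""Patient-grouped nested cross-validation and hyperparameter search.

The plan is a 3x3 nested CV over patients: three outer folds; within each
outer fold's training patients, three inner folds.  Hyperparameters are
searched on the inner folds (full grid or successive halving, the rung
logic at the core of Hyperband) and configurations are selected by the best
mean validation AUPRC, the metric of choice under heavy class imbalance.
No test-set patient ever enters a tuning fold, and imputation/scaling
statistics must be re-fitted inside each training fold by the caller's
``evaluate_fn``.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CvPlan",
    "SearchSpace",
    "TrialResult",
    "grid_search",
    "make_cv_plan",
    "select_best",
    "successive_halving",
    "train_with_early_stopping",
]


@dataclass(frozen=True)
class CvPlan:
    """Outer folds and per-outer inner folds, each a tuple of patient ids."""

    outer_folds: tuple[tuple, ...]
    inner_folds: tuple[tuple[tuple, ...], ...]  # [outer][inner] -> patient ids
    seed: int

    def outer_train(self, i: int) -> list:
        return [p for j, fold in enumerate(self.outer_folds) if j != i for p in fold]

    def inner_train(self, i: int, j: int) -> list:
        return [
            p
            for jj, fold in enumerate(self.inner_folds[i])
            if jj != j
            for p in fold
        ]


def _partition(items: list, k: int, rng) -> tuple[tuple, ...]:
    order = rng.permutation(len(items))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(items[idx])
    return tuple(tuple(f) for f in folds)


def make_cv_plan(patient_ids, k_outer: int = 3, k_inner: int = 3,
                 seed: int = 0) -> CvPlan:
    """Patient-disjoint folds with sizes within +/-1; reproducible by seed."""
    patients = sorted(set(patient_ids), key=str)
    if len(patients) < k_outer * k_inner:
        raise ValueError(
            f"need >= {k_outer * k_inner} patients, got {len(patients)}"
        )
    rng = np.random.default_rng(seed)
    outer = _partition(patients, k_outer, rng)
    inner = []
    for i in range(k_outer):
        train_patients = [p for j, f in enumerate(outer) if j != i for p in f]
        inner.append(_partition(train_patients, k_inner, rng))
    return CvPlan(outer, tuple(inner), seed)


@dataclass(frozen=True)
class SearchSpace:
    """Named axes of candidate values; the grid is their Cartesian product."""

    axes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("every axis must be non-empty")

    def grid(self) -> list[dict]:
        names = list(self.axes)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]

    def sample(self, n: int, seed: int) -> list[dict]:
        rng = np.random.default_rng(seed)
        names = list(self.axes)
        out = []
        for _ in range(n):
            out.append({k: self.axes[k][rng.integers(len(self.axes[k]))] for k in names})
        return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclass
class TrialResult:
    config: dict
    fold_auprc: list[float]
    fold_auroc: list[float]
    epochs_run: int = 0
    best_epoch: int = 0
    budget: int | None = None

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.fold_auprc))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))


def _rank(trials: list[TrialResult]) -> list[TrialResult]:
    return sorted(
        trials,
        key=lambda t: (-t.mean_auprc, -t.mean_auroc, config_hash(t.config)),
    )


def grid_search(space: SearchSpace, evaluate_fn, plan: CvPlan,
                outer_index: int = 0) -> list[TrialResult]:
    """Evaluate the full Cartesian product on the inner folds of one outer
    fold and rank by mean inner AUPRC.

    ``evaluate_fn(config, train_patients, val_patients, budget=None)`` must
    return ``(auprc, auroc, epochs_run, best_epoch)`` after fitting on the
    training patients only.
    """
    trials = []
    for config in space.grid():
        fold_auprc, fold_auroc, epochs, best = [], [], 0, 0
        for j, val_fold in enumerate(plan.inner_folds[outer_index]):
            train = plan.inner_train(outer_index, j)
            auprc, auroc, e, b = evaluate_fn(config, train, list(val_fold))
            fold_auprc.append(auprc)
            fold_auroc.append(auroc)
            epochs, best = max(epochs, e), max(best, b)
        trials.append(TrialResult(config, fold_auprc, fold_auroc, epochs, best))
    return _rank(trials)


def successive_halving(
    space: SearchSpace,
    evaluate_fn,
    plan: CvPlan,
    budget_epochs: int,
    eta: int = 3,
    n_configs: int | None = None,
    outer_index: int = 0,
    seed: int = 0,
) -> list[TrialResult]:
    """Successive halving over sampled configurations.

    Starts from ``n_configs`` candidates (default eta^rungs covering the
    budget), trains each at an epoch budget that grows by ``eta`` per rung,
    and keeps the top 1/eta per rung until one candidate remains or the
    budget is exhausted.  Deterministic given ``seed``.
    """
    if budget_epochs < eta:
        raise ValueError("budget too small for one rung")
    n_rungs = int(np.floor(np.log(budget_epochs) / np.log(eta)))
    if n_configs is None:
        n_configs = eta**n_rungs
    grid = space.grid()
    if n_configs >= len(grid):
        candidates = grid
    else:
        candidates = space.sample(n_configs, seed)
    trials_by_id: dict[str, TrialResult] = {}
    rung_budget = max(budget_epochs // (eta**n_rungs), 1)
    survivors = list(candidates)
    while survivors:
        if len(survivors) == 1:
            rung_budget = budget_epochs  # sole survivor trains at full budget
        rung_trials = []
        for config in survivors:
            fold_auprc, fold_auroc, epochs, best = [], [], 0, 0
            for j, val_fold in enumerate(plan.inner_folds[outer_index]):
                train = plan.inner_train(outer_index, j)
                auprc, auroc, e, b = evaluate_fn(
                    config, train, list(val_fold), budget=rung_budget
                )
                fold_auprc.append(auprc)
                fold_auroc.append(auroc)
                epochs, best = max(epochs, e), max(best, b)
            tr = TrialResult(config, fold_auprc, fold_auroc, epochs, best,
                             budget=rung_budget)
            rung_trials.append(tr)
            trials_by_id[config_hash(config)] = tr
        rung_trials = _rank(rung_trials)
        if len(rung_trials) == 1 or rung_budget >= budget_epochs:
            break
        keep = max(len(rung_trials) // eta, 1)
        survivors = [t.config for t in rung_trials[:keep]]
        rung_budget = min(rung_budget * eta, budget_epochs)
    return _rank(list(trials_by_id.values()))


def train_with_early_stopping(model, val_inputs, val_labels, patience: int = 10,
                              max_epochs: int = 100, seed: int | None = None):
    """Fit a :class:`~trapod.models.PodModel` with validation-based early
    stopping (stop after ``patience`` epochs without loss improvement,
    restore best-epoch weights)."""
    return model.fit(val_inputs=val_inputs, val_labels=val_labels,
                     max_epochs=max_epochs, patience=patience, seed=seed)


def select_best(trials: list[TrialResult]) -> TrialResult:
    """Argmax of mean outer-validation AUPRC; ties broken by AUROC, then by
    config hash."""
    if not trials:
        raise ValueError("no trials to select from")
    return _rank(trials)[0]


def assert_no_leakage(plan: CvPlan, test_patients) -> None:
    """Raise if any test patient appears in any tuning fold."""
    test = set(test_patients)
    for fold in plan.outer_folds:
        leak = test & set(fold)
        if leak:
            raise AssertionError(f"test patients leaked into tuning folds: {sorted(leak)[:5]}")
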