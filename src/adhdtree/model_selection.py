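"""Selection of the minimum leaf size m, plus k-fold CV reporting.

m is an absolute (not relative) complexity parameter, so it is tuned by
leave-one-out cross-validation: LOOCV trains on datasets of size n-1, the
closest possible to the full training set.  The default search range is
m in [5, 20], the upper end being roughly 10% of a ~200-subject training
set.  Among equally accurate values the smallest m is chosen.

A stratified k-fold CV summary (default k = 4) is reported alongside as a
stability check of the final model's accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import CohortError
from .feature_extraction import FeatureTable
from .tree_induction import grow, predict


@dataclass
class MSelectionReport:
    accuracies: dict  # m -> LOOCV accuracy
    chosen_m: int
    n_evaluations: int


def loocv_accuracy(table: FeatureTable, m: int) -> float:
    """Leave-one-out accuracy of trees grown with minimum leaf size ``m``."""
    n = table.n
    if n < 2:
        raise CohortError("LOOCV needs at least 2 subjects")
    records = table.values.to_dict("records")
    labels = list(table.labels)
    correct = 0
    all_idx = np.arange(n)
    for i in range(n):
        sub = table.subset_rows(np.delete(all_idx, i))
        model = grow(sub, m)
        pred, _ = predict(model, records[i])
        correct += pred == labels[i]
    return correct / n


def select_m(table: FeatureTable, m_min: int = 5, m_max: int = 20) -> MSelectionReport:
    """Evaluate LOOCV accuracy for every m in [m_min, m_max] and pick the best.

    The chosen m attains the maximum LOOCV accuracy; among maxima the
    smallest m wins.
    """
    if m_min > m_max:
        raise CohortError("m_min must be <= m_max")
    if table.n <= m_max:
        raise CohortError(f"need more than m_max={m_max} subjects, got {table.n}")
    accuracies = {m: loocv_accuracy(table, m) for m in range(m_min, m_max + 1)}
    best = max(accuracies.values())
    chosen = min(m for m, a in accuracies.items() if a == best)
    return MSelectionReport(
        accuracies=accuracies, chosen_m=chosen, n_evaluations=len(accuracies) * table.n
    )


def _stratified_folds(labels, k: int, rng: np.random.Generator) -> list:
    """Seeded label-stratified partition of row positions into k folds."""
    labels = np.asarray(labels)
    folds = [[] for _ in range(k)]
    for cls in ("TD", "ADHD"):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [sorted(f) for f in folds]


def kfold_accuracy(table: FeatureTable, m: int, k: int = 4, seed: int = 0):
    """Stratified k-fold CV accuracy; returns ``(mean, sd)`` across folds.

    The standard deviation is the population one (divide by k).
    """
    if k < 2:
        raise CohortError("k must be >= 2")
    if table.n < k:
        raise CohortError("need at least k subjects")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(list(table.labels), k, rng)
    records = table.values.to_dict("records")
    labels = list(table.labels)
    accs = []
    for fold in folds:
        if not fold:
            raise CohortError("empty fold; reduce k")
        train_idx = [i for i in range(table.n) if i not in set(fold)]
        model = grow(table.subset_rows(train_idx), m)
        hits = [predict(model, records[i])[0] == labels[i] for i in fold]
        accs.append(float(np.mean(hits)))
    return float(np.mean(accs)), float(np.std(accs))
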