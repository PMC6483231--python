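"""Correlation-based feature selection (CFS) with a bootstrap-ensemble wrapper.

CFS scores a candidate subset S of k features by the merit

    M(S) = k * rbar_cf / sqrt(k + k (k - 1) * rbar_ff)

where rbar_cf is the mean absolute Pearson correlation between the subset's
features and the class (TD = 0, ADHD = 1) and rbar_ff the mean absolute
pairwise feature-feature correlation.  High class relevance raises merit,
mutual redundancy lowers it; no correlation threshold is needed.  The
categorical gender feature is encoded F = 0 / M = 1 for correlations only.

The search over subsets is a best-first forward search: starting from the
empty set, subsets are expanded by single-feature additions in order of
merit, stopping after a fixed number of consecutive expansions that fail to
improve the best merit found.

Robustness comes from an ensemble wrapper: selection is repeated on
bootstrap resamples of the training subjects (default 20 resamples, each a
with-replacement draw of 75% of the instances) and features kept when their
selection frequency reaches the aggregation threshold (default an inclusive
25%).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort_io import CohortError
from .feature_extraction import FeatureTable

_EPS = 1e-12


@dataclass(frozen=True)
class EnsembleConfig:
    n_resamples: int = 20
    resample_fraction: float = 0.75
    with_replacement: bool = True
    frequency_threshold: float = 0.25
    stall: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise CohortError("n_resamples must be >= 1")
        if not 0 < self.resample_fraction <= 1:
            raise CohortError("resample_fraction must be in (0, 1]")
        if not 0 < self.frequency_threshold <= 1:
            raise CohortError("frequency_threshold must be in (0, 1]")
        if self.stall < 1:
            raise CohortError("stall must be >= 1")


@dataclass
class SelectionResult:
    per_resample_sets: list
    frequency: dict
    selected: tuple


def encode_labels(labels) -> np.ndarray:
    """TD -> 0, ADHD -> 1."""
    return np.asarray([1.0 if l == "ADHD" else 0.0 for l in labels])


def encode_feature(column, kind: str) -> np.ndarray:
    """Numeric passthrough; categorical gender encoded F -> 0, M -> 1."""
    if kind == "categorical":
        return np.asarray([1.0 if v == "M" else 0.0 for v in column])
    return np.asarray(column, dtype=float)


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd * xd).sum())
    sy = np.sqrt((yd * yd).sum())
    if sx <= _EPS * max(1.0, np.abs(x).max(initial=0.0)) or sy == 0.0:
        return 0.0  # zero-variance column carries no correlation
    return float(abs((xd * yd).sum() / (sx * sy)))


def feature_class_correlation(column, labels, kind: str = "numeric") -> float:
    """Absolute Pearson correlation between one feature and the class labels."""
    y = encode_labels(labels)
    if y.size < 3:
        raise CohortError("feature_class_correlation needs n >= 3")
    if y.min() == y.max():
        raise CohortError("both classes must be present")
    return _abs_pearson(encode_feature(column, kind), y)


class CorrelationCache:
    """Precomputed |r| feature-class vector and feature-feature matrix."""

    def __init__(self, table: FeatureTable):
        self.names = table.feature_names
        self.index = {f: i for i, f in enumerate(self.names)}
        y = encode_labels(table.labels)
        if y.size < 3:
            raise CohortError("CFS needs n >= 3")
        if y.min() == y.max():
            raise CohortError("CFS needs both classes present")
        X = np.column_stack(
            [encode_feature(table.values[f], table.kinds[f]) for f in self.names]
        )
        Xd = X - X.mean(axis=0)
        norms = np.sqrt((Xd * Xd).sum(axis=0))
        ok = norms > _EPS * np.maximum(1.0, np.abs(X).max(axis=0))
        safe = np.where(ok, norms, 1.0)
        U = Xd / safe
        yd = y - y.mean()
        yu = yd / np.sqrt((yd * yd).sum())
        self.rcf = np.where(ok, np.abs(U.T @ yu), 0.0)
        rff = np.abs(U.T @ U)
        rff[~ok, :] = 0.0
        rff[:, ~ok] = 0.0
        np.fill_diagonal(rff, 1.0)
        self.rff = rff

    def merit(self, subset) -> float:
        idx = np.asarray([self.index[f] for f in subset], dtype=int)
        k = idx.size
        if k == 0:
            raise CohortError("cfs merit is undefined for an empty subset")
        rcf_mean = float(self.rcf[idx].mean())
        if k == 1:
            return rcf_mean
        sub = self.rff[np.ix_(idx, idx)]
        rff_mean = float((sub.sum() - k) / (k * (k - 1)))
        return merit_from_correlations(k, rcf_mean, rff_mean)


def merit_from_correlations(k: int, rcf_mean: float, rff_mean: float) -> float:
    """CFS merit from subset size and the two mean absolute correlations."""
    denom = np.sqrt(k + k * (k - 1) * rff_mean)
    return float(k * rcf_mean / denom) if denom > 0 else 0.0


def cfs_merit(subset, table: FeatureTable) -> float:
    """Merit of an explicit feature subset on a table."""
    return CorrelationCache(table).merit(tuple(subset))


def exhaustive_best_subset(table: FeatureTable):
    """Brute-force maximum-merit subset (intended for <= ~15 features).

    Ties are broken toward smaller subsets, then lexicographically by
    feature position, matching the deterministic search tie-breaks.
    """
    cache = CorrelationCache(table)
    p = len(cache.names)
    best = None
    best_merit = -np.inf
    for code in range(1, 1 << p):
        subset = tuple(cache.names[i] for i in range(p) if code >> i & 1)
        m = cache.merit(subset)
        if m > best_merit + _EPS:
            best, best_merit = subset, m
    return set(best), best_merit


def cfs_search(table: FeatureTable, stall: int = 5):
    """Best-first forward search maximizing CFS merit.

    Maintains a priority queue of candidate subsets; each expansion adds
    every unused feature to the current best open subset.  The search stops
    after ``stall`` consecutive expansions without improving the best merit
    seen, and returns the best-merit subset found.
    """
    cache = CorrelationCache(table)
    names = cache.names
    counter = 0
    # heap entries: (-merit, insertion counter, subset as sorted index tuple)
    heap = [(0.0, counter, ())]
    visited = {()}
    best_subset = ()
    best_merit = 0.0
    stalled = 0
    while heap and stalled < stall:
        _, _, subset = heapq.heappop(heap)
        improved = False
        in_subset = set(subset)
        for i in range(len(names)):
            if i in in_subset:
                continue
            child = tuple(sorted(in_subset | {i}))
            if child in visited:
                continue
            visited.add(child)
            m = cache.merit(tuple(names[j] for j in child))
            if m > best_merit + _EPS:
                best_subset, best_merit = child, m
                improved = True
            counter += 1
            heapq.heappush(heap, (-m, counter, child))
        stalled = 0 if improved else stalled + 1
    return {names[i] for i in best_subset}


def aggregate_selections(per_resample_sets, n_resamples: int, threshold: float, universe):
    """Apply the inclusive frequency-threshold aggregation rule."""
    counts = {f: 0 for f in universe}
    for s in per_resample_sets:
        for f in s:
            if f not in counts:
                raise CohortError(f"selected feature {f!r} not in the feature universe")
            counts[f] += 1
    freq = {f: c / n_resamples for f, c in counts.items()}
    selected = tuple(f for f in universe if freq[f] >= threshold - _EPS)
    return freq, selected


def ensemble_select(table: FeatureTable, config: EnsembleConfig = EnsembleConfig()) -> SelectionResult:
    """Run CFS on seeded bootstrap resamples and aggregate by frequency.

    Each resample draws round(resample_fraction * n) subjects (with
    replacement by default); a resample containing a single class is redrawn
    (up to 100 attempts).  Deterministic given ``config.seed``.
    """
    y = encode_labels(table.labels)
    if y.min() == y.max():
        raise CohortError("ensemble_select needs both classes in the full table")
    rng = np.random.default_rng(config.seed)
    n = table.n
    n_draw = max(1, round(config.resample_fraction * n))
    sets = []
    for _ in range(config.n_resamples):
        for attempt in range(100):
            idx = rng.choice(n, size=n_draw, replace=config.with_replacement)
            if y[idx].min() != y[idx].max():
                break
        else:
            raise CohortError("could not draw a two-class resample in 100 attempts")
        sub = table.subset_rows(idx)
        sets.append(cfs_search(sub, stall=config.stall))
    freq, selected = aggregate_selections(
        sets, config.n_resamples, config.frequency_threshold, table.feature_names
    )
    return SelectionResult(per_resample_sets=sets, frequency=freq, selected=selected)
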