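"""Shared test utilities: table builders and independent oracles.

Oracles here deliberately avoid the package's internal code paths
(correlation caches, vectorized entropy) so they can serve as independent
references: plain math.log2 sums, explicit midpoint scans, brute-force
subset enumeration over numpy-computed correlations.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from adhdtree.feature_extraction import FeatureTable


def make_table(X, labels, names=None, gender=None) -> FeatureTable:
    """Build a FeatureTable from a numeric matrix (+ optional gender column)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names or [f"f{j}" for j in range(p)]
    values = pd.DataFrame(X, columns=names, index=[f"s{i}" for i in range(n)])
    kinds = {c: "numeric" for c in names}
    if gender is not None:
        values.insert(0, "gender", list(gender))
        kinds["gender"] = "categorical"
    labels = pd.Series(list(labels), index=values.index, name="dx")
    return FeatureTable(values=values, kinds=kinds, labels=labels)


def entropy_oracle(counts) -> float:
    """Direct pure-Python evaluation of the entropy formula."""
    n = sum(counts)
    return -sum(c / n * math.log2(c / n) for c in counts if c)


def gain_oracle(parent, children) -> float:
    n = sum(parent)
    return entropy_oracle(parent) - sum(
        sum(c) / n * entropy_oracle(c) for c in children
    )


def split_oracle(values, y01, m):
    """Exhaustive scan over all midpoints between distinct sorted values."""
    order = np.argsort(values, kind="stable")
    v, y = np.asarray(values, float)[order], np.asarray(y01, int)[order]
    n = v.size
    parent = (int((y == 0).sum()), int((y == 1).sum()))
    best = None
    for i in range(1, n):
        if v[i] <= v[i - 1]:
            continue
        if i < m or n - i < m:
            continue
        theta = (v[i - 1] + v[i]) / 2.0
        left = y[:i]
        right = y[i:]
        g = gain_oracle(
            parent,
            [
                (int((left == 0).sum()), int((left == 1).sum())),
                (int((right == 0).sum()), int((right == 1).sum())),
            ],
        )
        if best is None or g > best[1] + 1e-12:
            best = (theta, g)
    return best


def merit_oracle(table: FeatureTable, subset) -> float:
    """CFS merit of a subset computed from scratch with numpy correlations."""
    y = np.array([1.0 if l == "ADHD" else 0.0 for l in table.labels])
    cols = []
    for f in subset:
        col = table.values[f]
        if table.kinds[f] == "categorical":
            cols.append(np.array([1.0 if v == "M" else 0.0 for v in col]))
        else:
            cols.append(np.asarray(col, float))
    k = len(cols)

    def corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return abs(float(np.corrcoef(a, b)[0, 1]))

    rcf = np.mean([corr(c, y) for c in cols])
    if k == 1:
        return float(rcf)
    rff = np.mean([corr(cols[i], cols[j]) for i, j in combinations(range(k), 2)])
    return float(k * rcf / math.sqrt(k + k * (k - 1) * rff))


def exhaustive_merit_oracle(table: FeatureTable) -> float:
    """Maximum CFS merit over all non-empty subsets (brute force).

    Correlations are computed once with np.corrcoef, then all 2^p - 1
    subsets are enumerated directly from them.
    """
    names = table.feature_names
    y = np.array([1.0 if l == "ADHD" else 0.0 for l in table.labels])
    cols = []
    for f in names:
        col = table.values[f]
        if table.kinds[f] == "categorical":
            cols.append(np.array([1.0 if v == "M" else 0.0 for v in col]))
        else:
            cols.append(np.asarray(col, float))
    full = np.abs(np.corrcoef(np.vstack(cols + [y])))
    rcf = full[-1, :-1]
    rff = full[:-1, :-1]
    p = len(names)
    best = -np.inf
    for code in range(1, 1 << p):
        idx = [i for i in range(p) if code >> i & 1]
        k = len(idx)
        mc = rcf[idx].mean()
        if k == 1:
            best = max(best, mc)
            continue
        mf = (rff[np.ix_(idx, idx)].sum() - k) / (k * (k - 1))
        best = max(best, k * mc / math.sqrt(k + k * (k - 1) * mf))
    return float(best)
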