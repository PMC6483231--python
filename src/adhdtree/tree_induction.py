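"""Decision-tree induction with an entropy / information-gain criterion.

Trees are grown by recursive greedy partitioning.  A node t holding N(t)
training instances, N_c(t) of class c, has entropy (impurity)

    i(t) = - sum_c  N_c(t)/N(t) * log2( N_c(t)/N(t) )

with empty-class terms contributing 0.  A candidate split of t into
children t_1..t_K is scored by the information gain

    gain = i(t) - sum_k  N(t_k)/N(t) * i(t_k).

Numeric features split binarily at midpoints between consecutive distinct
sorted values (value <= theta goes left); the categorical gender feature
splits multiway, one branch per category.  A split is admissible only when
every child holds at least m training instances — m, the minimum leaf size,
is the single complexity parameter of the model.  Growth stops at pure
nodes, when no admissible split exists, or when the best gain is zero.

Determinism: equal gains are broken by feature order in the table, then by
the smaller threshold; leaf-label ties are broken toward the parent's
majority class, then toward ADHD (a slight bias toward sensitivity, which
suits the diagnostic setting).  No post-pruning is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CohortError, RoiAtlas
from .feature_extraction import FeatureTable, parse_roi_feature

_GAIN_TOL = 1e-12


@dataclass(frozen=True)
class ClassCounts:
    """Per-class instance counts at a node (two-class: TD / ADHD)."""

    n_td: int
    n_adhd: int

    def __post_init__(self) -> None:
        if self.n_td < 0 or self.n_adhd < 0:
            raise CohortError("class counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_td + self.n_adhd

    def as_dict(self) -> dict:
        return {"TD": self.n_td, "ADHD": self.n_adhd}


def entropy(counts: ClassCounts) -> float:
    """Node impurity i(t) in bits; 0 for a pure node, 1 for a balanced one."""
    n = counts.total
    if n == 0:
        raise CohortError("entropy is undefined for an empty node")
    h = 0.0
    for c in (counts.n_td, counts.n_adhd):
        if c:
            p = c / n
            h -= p * np.log2(p)
    return float(h)


def information_gain(parent: ClassCounts, children) -> float:
    """Impurity reduction of splitting ``parent`` into ``children``.

    The children's class counts must sum exactly to the parent's.
    """
    children = list(children)
    if sum(c.n_td for c in children) != parent.n_td or sum(
        c.n_adhd for c in children
    ) != parent.n_adhd:
        raise CohortError("children class counts must sum to the parent's")
    n = parent.total
    return float(
        entropy(parent) - sum(c.total / n * entropy(c) for c in children if c.total)
    )


def _entropy01(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized two-class entropy from positive-class counts."""
    pos = np.asarray(pos, dtype=float)
    n = np.asarray(n, dtype=float)
    p = pos / n
    q = 1.0 - p
    hp = np.where(p > 0, p, 1.0)
    hq = np.where(q > 0, q, 1.0)
    return -p * np.log2(hp) - q * np.log2(hq)


def _encode01(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "biuf":
        return y.astype(int)
    return np.asarray([1 if l == "ADHD" else 0 for l in y], dtype=int)


def best_numeric_split(values, labels, m: int):
    """Best admissible binary split of a numeric feature, or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; a threshold is admissible when both children (value <= theta and
    value > theta) hold at least m instances.  Returns ``(threshold, gain)``
    for the maximal-gain admissible threshold (ties toward the smaller
    threshold), or None when no admissible threshold exists.
    """
    v = np.asarray(values, dtype=float)
    y = _encode01(labels)
    n = v.size
    if n != y.size:
        raise CohortError("values and labels must have equal length")
    if m < 1:
        raise CohortError("m must be >= 1")
    if n < 2 * m:
        return None
    order = np.argsort(v, kind="stable")
    vs = v[order]
    ys = y[order]
    cum = np.cumsum(ys)
    i = np.arange(1, n)  # left-child size for a cut before sorted position i
    candidate = (vs[1:] > vs[:-1]) & (i >= m) & (n - i >= m)
    if not candidate.any():
        return None
    total_pos = int(cum[-1])
    h_parent = _entropy01(total_pos, n)
    left_pos = cum[:-1]
    gains = (
        h_parent
        - (i / n) * _entropy01(left_pos, i)
        - ((n - i) / n) * _entropy01(total_pos - left_pos, n - i)
    )
    gains = np.where(candidate, gains, -np.inf)
    # smallest threshold among gains tied to within float tolerance
    best = int(np.argmax(gains >= gains.max() - _GAIN_TOL))
    threshold = float((vs[best] + vs[best + 1]) / 2.0)
    return threshold, float(gains[best])


@dataclass
class TreeNode:
    counts: ClassCounts
    feature: str = None
    kind: str = None
    threshold: float = None
    categories: tuple = None
    children: list = None
    prediction: str = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class DecisionTreeModel:
    root: TreeNode
    m: int
    feature_names: list
    kinds: dict


def _counts_of(y: np.ndarray) -> ClassCounts:
    pos = int(y.sum())
    return ClassCounts(n_td=int(y.size - pos), n_adhd=pos)


def _majority(counts: ClassCounts, parent_majority: str) -> str:
    if counts.n_adhd > counts.n_td:
        return "ADHD"
    if counts.n_td > counts.n_adhd:
        return "TD"
    return parent_majority if parent_majority is not None else "ADHD"


def grow(table: FeatureTable, m: int) -> DecisionTreeModel:
    """Grow a tree on a feature table with minimum leaf size ``m``."""
    if m < 1:
        raise CohortError("m must be >= 1")
    if table.n < 1:
        raise CohortError("cannot grow a tree on an empty table")
    names = table.feature_names
    kinds = table.kinds
    y = _encode01(table.labels)
    numeric = {}
    categorical = {}
    categories = {}
    for f in names:
        if kinds[f] == "numeric":
            numeric[f] = table.values[f].to_numpy(dtype=float)
        else:
            col = np.asarray(table.values[f], dtype=object)
            categorical[f] = col
            categories[f] = tuple(sorted(set(col)))

    def build(idx: np.ndarray, parent_majority: str) -> TreeNode:
        counts = _counts_of(y[idx])
        majority = _majority(counts, parent_majority)
        if counts.n_td == 0 or counts.n_adhd == 0:
            return TreeNode(counts=counts, prediction=majority)
        best = None  # (gain, feature, kind, threshold, list of child index arrays)
        for f in names:
            if f in numeric:
                res = best_numeric_split(numeric[f][idx], y[idx], m)
                if res is None:
                    continue
                threshold, gain = res
                if best is None or gain > best[0] + _GAIN_TOL:
                    mask = numeric[f][idx] <= threshold
                    best = (gain, f, "numeric", threshold, [idx[mask], idx[~mask]])
            else:
                col = categorical[f][idx]
                parts = [idx[col == c] for c in categories[f]]
                if any(p.size < m for p in parts):
                    continue
                gain = information_gain(counts, [_counts_of(y[p]) for p in parts])
                if best is None or gain > best[0] + _GAIN_TOL:
                    best = (gain, f, "categorical", None, parts)
        if best is None or best[0] <= _GAIN_TOL:
            return TreeNode(counts=counts, prediction=majority)
        gain, f, kind, threshold, parts = best
        children = [build(p, majority) for p in parts]
        return TreeNode(
            counts=counts,
            feature=f,
            kind=kind,
            threshold=threshold,
            categories=categories[f] if kind == "categorical" else None,
            children=children,
        )

    root = build(np.arange(table.n), None)
    return DecisionTreeModel(root=root, m=m, feature_names=list(names), kinds=dict(kinds))


def predict(model: DecisionTreeModel, features):
    """Classify one subject; returns ``(label, decision_chain)``.

    ``features`` maps feature name to value; it must supply every feature
    the traversed chain requires.  The decision chain is the ordered list of
    ``(feature, comparison, branch_value)`` steps taken; values exactly at a
    numeric threshold take the ``<=`` branch.
    """
    node = model.root
    chain = []
    while not node.is_leaf:
        if node.feature not in features:
            raise CohortError(f"prediction requires feature {node.feature!r}")
        value = features[node.feature]
        if node.kind == "numeric":
            if float(value) <= node.threshold:
                chain.append((node.feature, "<=", node.threshold))
                node = node.children[0]
            else:
                chain.append((node.feature, ">", node.threshold))
                node = node.children[1]
        else:
            if value not in node.categories:
                raise CohortError(
                    f"unknown category {value!r} for feature {node.feature!r}"
                )
            j = node.categories.index(value)
            chain.append((node.feature, "==", value))
            node = node.children[j]
    return node.prediction, chain


def predict_table(model: DecisionTreeModel, table: FeatureTable) -> list:
    """Predicted labels for every row of a feature table."""
    records = table.values.to_dict("records")
    return [predict(model, r)[0] for r in records]


def training_accuracy(model: DecisionTreeModel, table: FeatureTable) -> float:
    pred = predict_table(model, table)
    return float(np.mean([p == t for p, t in zip(pred, table.labels)]))


# -- rendering ---------------------------------------------------------------


def _display_name(feature: str, atlas: RoiAtlas = None) -> str:
    rid = parse_roi_feature(feature)
    if rid is not None and atlas is not None:
        return f"variance of {atlas.label(rid)}"
    return feature


def _counts_str(c: ClassCounts) -> str:
    return f"[TD={c.n_td}, ADHD={c.n_adhd}]"


def _text_lines(node: TreeNode, atlas, depth: int) -> list:
    pad = "  " * depth
    if node.is_leaf:
        return [f"{pad}=> {node.prediction}  {_counts_str(node.counts)}"]
    lines = []
    name = _display_name(node.feature, atlas)
    if node.kind == "numeric":
        branches = [f"{name} <= {node.threshold:.6g}?", f"{name} > {node.threshold:.6g}?"]
    else:
        branches = [f"{name} == {c}?" for c in node.categories]
    for label, child in zip(branches, node.children):
        lines.append(f"{pad}{label}  {_counts_str(child.counts)}")
        lines.extend(_text_lines(child, atlas, depth + 1))
    return lines


def _node_to_dict(node: TreeNode) -> dict:
    d = {"counts": node.counts.as_dict()}
    if node.is_leaf:
        d["prediction"] = node.prediction
    else:
        d["feature"] = node.feature
        d["kind"] = node.kind
        if node.kind == "numeric":
            d["threshold"] = node.threshold
        else:
            d["categories"] = list(node.categories)
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> TreeNode:
    counts = ClassCounts(n_td=d["counts"]["TD"], n_adhd=d["counts"]["ADHD"])
    if "children" not in d:
        return TreeNode(counts=counts, prediction=d["prediction"])
    return TreeNode(
        counts=counts,
        feature=d["feature"],
        kind=d["kind"],
        threshold=d.get("threshold"),
        categories=tuple(d["categories"]) if "categories" in d else None,
        children=[_node_from_dict(c) for c in d["children"]],
    )


def model_to_dict(model: DecisionTreeModel) -> dict:
    return {
        "m": model.m,
        "feature_names": list(model.feature_names),
        "kinds": dict(model.kinds),
        "root": _node_to_dict(model.root),
    }


def model_from_dict(d: dict) -> DecisionTreeModel:
    return DecisionTreeModel(
        root=_node_from_dict(d["root"]),
        m=int(d["m"]),
        feature_names=list(d["feature_names"]),
        kinds=dict(d["kinds"]),
    )


def model_from_json(s: str) -> DecisionTreeModel:
    return model_from_dict(json.loads(s))


def _dot_lines(node: TreeNode, atlas, counter: list, lines: list) -> int:
    nid = counter[0]
    counter[0] += 1
    if node.is_leaf:
        lines.append(f'  n{nid} [shape=box, label="{node.prediction}\\n{_counts_str(node.counts)}"];')
        return nid
    name = _display_name(node.feature, atlas)
    lines.append(f'  n{nid} [label="{name}\\n{_counts_str(node.counts)}"];')
    if node.kind == "numeric":
        edge_labels = [f"<= {node.threshold:.6g}", f"> {node.threshold:.6g}"]
    else:
        edge_labels = [f"= {c}" for c in node.categories]
    for label, child in zip(edge_labels, node.children):
        cid = _dot_lines(child, atlas, counter, lines)
        lines.append(f'  n{nid} -> n{cid} [label="{label}"];')
    return nid


def render(model: DecisionTreeModel, atlas: RoiAtlas = None, fmt: str = "text") -> str:
    """Render a model as literal questions (text), Graphviz DOT, or JSON.

    The JSON form round-trips: ``model_from_json(render(m, fmt="json"))``
    reconstructs an identical model, and re-rendering it is byte-identical.
    """
    if fmt == "text":
        if model.root.is_leaf:
            return _text_lines(model.root, atlas, 0)[0]
        header = _counts_str(model.root.counts)
        return "\n".join([header] + _text_lines(model.root, atlas, 0))
    if fmt == "json":
        return json.dumps(model_to_dict(model), sort_keys=True, indent=2)
    if fmt == "dot":
        lines = ["digraph tree {"]
        _dot_lines(model.root, atlas, [0], lines)
        lines.append("}")
        return "\n".join(lines)
    raise CohortError(f"unknown render format {fmt!r} (expected text, dot or json)")


# -- structural inspection ---------------------------------------------------


def iter_nodes(model: DecisionTreeModel):
    stack = [model.root]
    while stack:
        node = stack.pop()
        yield node
        if not node.is_leaf:
            stack.extend(node.children)


def leaf_sizes(model: DecisionTreeModel) -> list:
    return [n.counts.total for n in iter_nodes(model) if n.is_leaf]


def split_features(model: DecisionTreeModel) -> set:
    return {n.feature for n in iter_nodes(model) if not n.is_leaf}


def validate_model(model: DecisionTreeModel) -> None:
    """Assert the structural invariants of a trained tree.

    Every leaf holds at least m instances (unless the whole training set was
    smaller than m), children's counts sum to their parent's, every executed
    split has non-negative gain, and leaf predictions are majority classes.
    """
    for node in iter_nodes(model):
        if node.is_leaf:
            if node is not model.root and node.counts.total < model.m:
                raise CohortError(f"leaf of size {node.counts.total} violates m={model.m}")
            c = node.counts
            if c.n_adhd > c.n_td and node.prediction != "ADHD":
                raise CohortError("leaf prediction is not a majority class")
            if c.n_td > c.n_adhd and node.prediction != "TD":
                raise CohortError("leaf prediction is not a majority class")
        else:
            kids = [c.counts for c in node.children]
            gain = information_gain(node.counts, kids)  # also checks count sums
            if gain < -1e-9:
                raise CohortError("executed split has negative gain")
            if node.feature not in model.feature_names:
                raise CohortError(f"split feature {node.feature!r} unknown to the model")
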