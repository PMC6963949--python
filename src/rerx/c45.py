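"""C4.5 decision-tree induction and rule export.

Implements the classic algorithm: splits are scored by gain ratio
(information gain over split information, both in bits), continuous
attributes get binary ``<= t / > t`` splits at midpoints between
consecutive distinct sorted values, categorical attributes split
multi-way (one branch per level, consumed once per path), and subtrees
are pruned by replacing them with a leaf whenever the leaf's pessimistic
error -- an upper binomial confidence bound on the training error -- does
not exceed the subtree's.  Root-to-leaf paths convert to if-then rules,
optionally simplified by greedily dropping conditions that do not
increase the rule's pessimistic error ("C4.5 rules" post-processing).

Within an attribute the cut point is chosen by information gain (the
classic convention; choosing by ratio favours extreme, low-split-info
cuts); attributes then compete on gain ratio, optionally restricted to
candidates whose gain reaches the mean gain of all positive candidates.
Ties break on schema order, then on the smaller threshold, so a fixed
cohort and configuration always yield the identical tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import beta as _beta

from .ruleset import EQ, GT, IN, LE, Condition, Rule, RuleSet
from .schema import Cohort, Schema

__all__ = [
    "TreeConfig", "TreeNode", "DegenerateSplitError",
    "entropy_bits", "split_scores", "gain_ratio",
    "best_continuous_split", "build_tree", "prune_tree", "tree_to_rules",
    "pessimistic_error_rate", "tree_to_json",
]


class DegenerateSplitError(ValueError):
    """A candidate split leaves fewer than two non-empty branches."""


@dataclass(frozen=True)
class TreeConfig:
    """C4.5 hyperparameters (classic-release defaults)."""

    min_leaf_size: int = 2
    confidence_factor: float = 0.25
    max_depth: int | None = None
    min_gain: float = 0.0
    mean_gain_guard: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.confidence_factor < 1:
            raise ValueError("confidence_factor must lie in (0, 1)")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")


@dataclass
class TreeNode:
    """Leaf or internal node.

    Internal nodes carry one ``(Condition, child)`` pair per branch:
    two for continuous splits, one per level for categorical splits.
    Leaves carry the majority class with training sample/error counts.
    """

    n_samples: int
    n_errors: int
    class_label: str
    branches: tuple[tuple[Condition, "TreeNode"], ...] = ()
    split_attribute: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.branches

    def depth(self) -> int:
        return 0 if self.is_leaf else 1 + max(c.depth() for _, c in self.branches)

    def n_leaves(self) -> int:
        return 1 if self.is_leaf else sum(c.n_leaves() for _, c in self.branches)

    def predict_record(self, record, schema: Schema | None = None) -> str:
        node = self
        while not node.is_leaf:
            for cond, child in node.branches:
                if cond.matches(record, schema):
                    node = child
                    break
            else:  # value outside every branch (cannot happen for conformant data)
                return node.class_label
        return node.class_label


# --- entropy and gain-ratio scores ------------------------------------------

def entropy_bits(counts) -> float:
    """Shannon entropy, in bits, of a class-count vector."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n <= 0:
        return 0.0
    p = c[c > 0] / n
    return float(-(p * np.log2(p)).sum())


def split_scores(table) -> tuple[float, float, float]:
    """(gain, split information, gain ratio) of a branches x classes count table.

    Empty branches are ignored.  The ratio is 0 when the gain is not
    positive, and 0 when the split information vanishes (single
    non-empty branch).
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0]
    n = t.sum()
    if n <= 0 or len(t) < 2:
        return 0.0, 0.0, 0.0
    total = t.sum(axis=0)
    w = t.sum(axis=1) / n
    gain = entropy_bits(total) - float(sum(wi * entropy_bits(row) for wi, row in zip(w, t)))
    split_info = float(-(w * np.log2(w)).sum())
    if gain <= 0 or split_info <= 0:
        return max(gain, 0.0) if gain > 0 else 0.0, split_info, 0.0
    return gain, split_info, gain / split_info


def gain_ratio(split: Condition, cohort: Cohort) -> float:
    """Gain ratio of the binary partition induced by one condition.

    Raises :class:`DegenerateSplitError` when either side of the
    partition is empty (such splits are excluded from candidacy).
    """
    mask = split.mask(cohort.data, cohort.schema)
    if not mask.any() or mask.all():
        raise DegenerateSplitError(f"condition {split.to_text()!r} leaves an empty branch")
    y = cohort.labels.to_numpy()
    levels = list(cohort.schema.class_levels)
    table = [[(y[m] == lvl).sum() for lvl in levels] for m in (mask, ~mask)]
    return split_scores(table)[2]


# --- internal columnar view ---------------------------------------------------

class _Data:
    def __init__(self, cohort: Cohort, attributes: Sequence[str]):
        self.schema = cohort.schema
        self.levels = list(cohort.schema.class_levels)
        self.y = np.asarray(
            [self.levels.index(v) for v in cohort.labels], dtype=np.intp)
        self.attributes = list(attributes)
        self.cont: dict[str, np.ndarray] = {}
        self.cat: dict[str, np.ndarray] = {}
        self.cat_levels: dict[str, tuple[str, ...]] = {}
        for name in attributes:
            attr = cohort.schema[name]
            col = cohort.data[name].to_numpy()
            if attr.is_continuous:
                self.cont[name] = col.astype(float)
            else:
                lv = attr.levels
                lut = {l: i for i, l in enumerate(lv)}
                self.cat[name] = np.asarray([lut[v] for v in col], dtype=np.intp)
                self.cat_levels[name] = lv

    @property
    def n_classes(self) -> int:
        return len(self.levels)


def _counts(y: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(y, minlength=k)


def _best_threshold(x: np.ndarray, y: np.ndarray, k: int, min_leaf: int):
    """Best cut of a continuous column by information gain.

    Returns (threshold, gain, split_info) or None.  Candidates are
    midpoints between consecutive distinct sorted values with at least
    ``min_leaf`` records on each side; ties take the smallest threshold.
    """
    n = len(x)
    if n < 2 * min_leaf:
        return None
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cuts = np.nonzero(xs[:-1] < xs[1:])[0]
    cuts = cuts[(cuts + 1 >= min_leaf) & (n - cuts - 1 >= min_leaf)]
    if cuts.size == 0:
        return None
    onehot = np.zeros((n, k))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    left = cum[cuts]
    total = cum[-1]
    right = total - left
    nl = left.sum(axis=1)
    nr = right.sum(axis=1)

    def h(rows):
        s = rows.sum(axis=1, keepdims=True)
        p = np.divide(rows, s, out=np.zeros_like(rows), where=s > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log2(p), 0.0)
        return terms.sum(axis=1)

    h_total = entropy_bits(total)
    gains = h_total - (nl / n) * h(left) - (nr / n) * h(right)
    wl, wr = nl / n, nr / n
    split_info = -(wl * np.log2(wl) + wr * np.log2(wr))
    i = int(np.argmax(gains))  # first max = smallest threshold
    thr = float((xs[cuts[i]] + xs[cuts[i] + 1]) / 2.0)
    return thr, float(gains[i]), float(split_info[i])


def best_continuous_split(attribute: str, cohort: Cohort,
                          config: TreeConfig | None = None):
    """Best binary split of one continuous attribute.

    Returns ``(Condition(attribute <= t), gain_ratio)`` for the cut
    maximizing information gain, or ``None`` when all values are
    identical or no cut has positive gain.
    """
    config = config or TreeConfig()
    if not cohort.schema[attribute].is_continuous:
        raise ValueError(f"attribute {attribute!r} is not continuous")
    data = _Data(cohort, [attribute])
    res = _best_threshold(data.cont[attribute], data.y, data.n_classes,
                          config.min_leaf_size)
    if res is None or res[1] <= 0:
        return None
    thr, gain, split_info = res
    ratio = gain / split_info if split_info > 0 else 0.0
    return Condition(attribute, LE, threshold=thr), ratio


def _categorical_scores(codes: np.ndarray, y: np.ndarray, n_levels: int,
                        k: int, min_leaf: int):
    table = np.zeros((n_levels, k))
    np.add.at(table, (codes, y), 1.0)
    sizes = table.sum(axis=1)
    nonempty = sizes > 0
    if nonempty.sum() < 2 or (sizes >= min_leaf).sum() < 2:
        return None
    gain, split_info, _ = split_scores(table)
    return table, gain, split_info


def _build(data: _Data, idx: np.ndarray, allowed: list[str],
           config: TreeConfig, depth: int) -> TreeNode:
    y = data.y[idx]
    counts = _counts(y, data.n_classes)
    label_i = int(np.argmax(counts))  # tie -> first class level
    label = data.levels[label_i]
    n = len(idx)
    n_err = int(n - counts[label_i])
    leaf = TreeNode(n, n_err, label)
    if n_err == 0 or n < 2 * config.min_leaf_size:
        return leaf
    if config.max_depth is not None and depth >= config.max_depth:
        return leaf

    candidates = []  # (gain, ratio, schema_index, kind, payload)
    for name in allowed:
        si = data.schema.names.index(name)
        if name in data.cont:
            res = _best_threshold(data.cont[name][idx], y, data.n_classes,
                                  config.min_leaf_size)
            if res is None or res[1] <= config.min_gain:
                continue
            thr, gain, split_info = res
            ratio = gain / split_info if split_info > 0 else 0.0
            if ratio > 0:
                candidates.append((gain, ratio, si, "cont", thr))
        else:
            res = _categorical_scores(data.cat[name][idx], y,
                                      len(data.cat_levels[name]),
                                      data.n_classes, config.min_leaf_size)
            if res is None:
                continue
            _, gain, split_info = res
            if gain <= config.min_gain or split_info <= 0:
                continue
            candidates.append((gain, gain / split_info, si, "cat", None))
    if not candidates:
        return leaf
    if config.mean_gain_guard and len(candidates) > 1:
        mean_gain = sum(c[0] for c in candidates) / len(candidates)
        admissible = [c for c in candidates if c[0] >= mean_gain - 1e-12]
    else:
        admissible = candidates
    # max ratio; ties -> lowest schema index, then smallest threshold
    best = max(admissible,
               key=lambda c: (c[1], -c[2], -(c[4] if c[4] is not None else 0.0)))
    _, _, si, kind, thr = best
    name = data.schema.names[si]

    branches = []
    if kind == "cont":
        x = data.cont[name][idx]
        for cond, m in ((Condition(name, LE, threshold=thr), x <= thr),
                        (Condition(name, GT, threshold=thr), x > thr)):
            branches.append((cond, _build(data, idx[m], allowed, config, depth + 1)))
    else:
        codes = data.cat[name][idx]
        remaining = [a for a in allowed if a != name]  # nominal consumed once per path
        for li, level in enumerate(data.cat_levels[name]):
            m = codes == li
            cond = Condition(name, EQ, level=level)
            if m.any():
                branches.append((cond, _build(data, idx[m], remaining, config, depth + 1)))
            else:
                branches.append((cond, TreeNode(0, 0, label)))
    return TreeNode(n, n_err, label, tuple(branches), split_attribute=name)


def build_tree(cohort: Cohort, attributes: Sequence[str] | None = None,
               config: TreeConfig | None = None) -> TreeNode:
    """Induce a C4.5 tree on a labeled cohort over the given attributes."""
    if len(cohort) == 0:
        raise ValueError("cannot build a tree on an empty cohort")
    config = config or TreeConfig()
    attributes = list(attributes) if attributes is not None else cohort.schema.names
    data = _Data(cohort, attributes)
    return _build(data, np.arange(len(cohort)), attributes, config, 0)


# --- pessimistic pruning ------------------------------------------------------

def pessimistic_error_rate(n_errors: int, n: int, confidence_factor: float) -> float:
    """Upper binomial confidence bound on the true error rate.

    The bound solves ``P(X <= n_errors | p) = confidence_factor`` for a
    Binomial(n, p), i.e. the Clopper-Pearson upper limit
    ``BetaInv(1 - CF; E + 1, N - E)``; for ``E = 0`` this reduces to the
    classic ``1 - CF**(1/N)``.
    """
    if n == 0:
        return 0.0
    if n_errors >= n:
        return 1.0
    return float(_beta.ppf(1.0 - confidence_factor, n_errors + 1, n - n_errors))


def _estimated_errors(node: TreeNode, cf: float) -> float:
    if node.is_leaf:
        return node.n_samples * pessimistic_error_rate(node.n_errors, node.n_samples, cf)
    return sum(_estimated_errors(c, cf) for _, c in node.branches)


def _prune(node: TreeNode, cf: float) -> TreeNode:
    if node.is_leaf:
        return node
    pruned = replace(node, branches=tuple((c, _prune(ch, cf)) for c, ch in node.branches))
    leaf_est = node.n_samples * pessimistic_error_rate(node.n_errors, node.n_samples, cf)
    subtree_est = _estimated_errors(pruned, cf)
    if leaf_est <= subtree_est + 1e-12:
        return TreeNode(node.n_samples, node.n_errors, node.class_label)
    return pruned


def prune_tree(tree: TreeNode, cohort: Cohort | None = None,
               config: TreeConfig | None = None) -> TreeNode:
    """Bottom-up subtree replacement by pessimistic-error comparison.

    The counts stored at build time are used; passing the training
    cohort re-derives them (useful after the tree has been transplanted).
    Pruning is a topological contraction and never increases training
    accuracy.
    """
    config = config or TreeConfig()
    if cohort is not None:
        tree = _recount(tree, cohort)
    return _prune(tree, config.confidence_factor)


def _recount(node: TreeNode, cohort: Cohort) -> TreeNode:
    df = cohort.data
    y = cohort.labels.to_numpy()

    def walk(nd: TreeNode, mask: np.ndarray) -> TreeNode:
        n = int(mask.sum())
        n_err = int((y[mask] != nd.class_label).sum())
        if nd.is_leaf:
            return TreeNode(n, n_err, nd.class_label)
        branches = tuple(
            (cond, walk(child, mask & cond.mask(df, cohort.schema)))
            for cond, child in nd.branches)
        return TreeNode(n, n_err, nd.class_label, branches, nd.split_attribute)

    return walk(node, np.ones(len(df), dtype=bool))


# --- rules export -------------------------------------------------------------

def _canonical_path(conditions: list[Condition]) -> tuple[Condition, ...]:
    """Merge per-attribute threshold conditions along one path.

    ``> a`` and ``<= b`` on the same attribute fold into ``in (a, b]``;
    repeated bounds keep the tightest (``A <= 5`` then ``A <= 7`` is
    ``A <= 5``).
    """
    lower: dict[str, float] = {}
    upper: dict[str, float] = {}
    cats: list[Condition] = []
    order: list[str] = []
    for c in conditions:
        if c.op == LE:
            upper[c.attribute] = min(upper.get(c.attribute, np.inf), c.threshold)
        elif c.op == GT:
            lower[c.attribute] = max(lower.get(c.attribute, -np.inf), c.threshold)
        elif c.op == IN:
            lower[c.attribute] = max(lower.get(c.attribute, -np.inf), c.low)
            upper[c.attribute] = min(upper.get(c.attribute, np.inf), c.high)
        else:
            cats.append(c)
        if c.attribute not in order:
            order.append(c.attribute)
    out: list[Condition] = []
    for name in order:
        lo, hi = lower.get(name), upper.get(name)
        if lo is not None and hi is not None:
            out.append(Condition(name, IN, low=lo, high=hi))
        elif hi is not None:
            out.append(Condition(name, LE, threshold=hi))
        elif lo is not None:
            out.append(Condition(name, GT, threshold=lo))
    out.extend(cats)
    return tuple(out)


def _paths(node: TreeNode, prefix: list[Condition], acc: list):
    if node.is_leaf:
        acc.append((prefix[:], node))
        return
    for cond, child in node.branches:
        prefix.append(cond)
        _paths(child, prefix, acc)
        prefix.pop()


def _rule_pessimistic_error(conds: tuple[Condition, ...], consequent: str,
                            cohort: Cohort, cf: float) -> tuple[float, int]:
    m = np.ones(len(cohort), dtype=bool)
    for c in conds:
        m &= c.mask(cohort.data, cohort.schema)
    n = int(m.sum())
    if n == 0:
        return 1.0, 0
    e = int((cohort.labels.to_numpy()[m] != consequent).sum())
    return pessimistic_error_rate(e, n, cf), n


def tree_to_rules(tree: TreeNode, cohort: Cohort | None = None,
                  simplify: bool = False,
                  config: TreeConfig | None = None,
                  schema: Schema | None = None) -> RuleSet:
    """Convert root-to-leaf paths into an if-then rule set.

    Without ``simplify`` the rules mirror the leaves left-to-right and
    are mutually exclusive and jointly exhaustive.  With ``simplify``
    (requires the training cohort) each rule greedily drops conditions
    whose removal does not increase its pessimistic training error; the
    simplified rules are ordered most-accurate-first and followed by a
    majority-class default rule so coverage is retained.
    """
    config = config or TreeConfig()
    schema = schema or (cohort.schema if cohort is not None else None)
    acc: list = []
    _paths(tree, [], acc)
    rules = [Rule(f"R{i + 1}", _canonical_path(conds), leaf.class_label)
             for i, (conds, leaf) in enumerate(acc)]
    if not simplify:
        return RuleSet(tuple(rules), schema=schema, provenance="tree")

    if cohort is None:
        raise ValueError("simplification requires the training cohort")
    cf = config.confidence_factor
    out = []
    for rule in rules:
        conds = list(rule.conditions)
        err, n_cov = _rule_pessimistic_error(tuple(conds), rule.consequent, cohort, cf)
        improved = True
        while improved and conds:
            improved = False
            trials = [
                (_rule_pessimistic_error(tuple(conds[:i] + conds[i + 1:]),
                                         rule.consequent, cohort, cf), i)
                for i in range(len(conds))]
            (best_err, best_n), best_i = min(trials, key=lambda t: (t[0][0], -t[0][1]))
            if best_err <= err + 1e-12:
                del conds[best_i]
                err, n_cov = best_err, best_n
                improved = True
        out.append((err, -n_cov, rule.consequent, tuple(conds)))
    out.sort(key=lambda t: (t[0], t[1]))

    ordered = [Rule(f"R{i + 1}", conds, consequent)
               for i, (_, _, consequent, conds) in enumerate(out)]
    interim = RuleSet(tuple(ordered), schema=schema)
    from .ruleset import predict_frame  # local import to avoid cycle at module load
    _, ids = predict_frame(interim, cohort.data)
    uncovered = ids == None  # noqa: E711
    if uncovered.any():
        residue = cohort.labels.to_numpy()[uncovered]
        default_label = max(schema.class_levels if schema else set(residue),
                            key=lambda l: (residue == l).sum())
    else:
        default_label = cohort.majority_class()
    ordered.append(Rule(f"R{len(ordered) + 1}", (), default_label))
    return RuleSet(tuple(ordered), schema=schema, provenance="tree+simplify")


def tree_to_json(tree: TreeNode, indent: int | None = 1) -> str:
    """Nested-node JSON export with training counts, for inspection."""

    def conv(node: TreeNode):
        base = {"n": node.n_samples, "errors": node.n_errors, "class": node.class_label}
        if node.is_leaf:
            return base
        base["split_attribute"] = node.split_attribute
        base["branches"] = [
            {"condition": cond.to_text(), "child": conv(child)}
            for cond, child in node.branches]
        return base

    return json.dumps(conv(tree), indent=indent)
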