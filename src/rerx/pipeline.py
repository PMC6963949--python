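"""The continuous Re-RX pipeline: network -> pruning -> tree -> recursion.

Recursive-rule extraction (Re-RX) turns a trained neural network into an
if-then rule set: a backpropagation network is trained and pruned to its
relevant attributes, a C4.5 tree is induced on the samples the network
classifies correctly (over the surviving attributes), the tree becomes
rules, and every rule whose training support reaches ``delta1`` while its
error exceeds ``delta2`` is refined by recursively re-running the whole
stack on just the records that rule covers.  A child rule's conditions
are conjoined with its parent's, so the flattened rule set keeps
first-match semantics and full coverage.  The *continuous* variant admits
both discrete and continuous attributes into the tree; the classic
variant trees on discrete attributes first.

Thresholds are always expressed in raw measurement units (the network's
internal standardization never leaks into rules), so extracted cut-offs
are directly interpretable, e.g. a UACR split in mg/g Cr.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from .c45 import TreeConfig, _canonical_path, build_tree, prune_tree, tree_to_rules
from .network import NetConfig, TrainedNetwork, prune_attributes, train_network
from .ruleset import (
    UNCOVERED,
    Rule,
    RuleSet,
    apply_rules,
    predict_frame,
    rule_stats,
)
from .schema import Cohort

__all__ = ["RerxConfig", "ExtractionResult", "LevelTrace", "RuleTrace",
           "extract_rules", "predict", "predict_cohort"]


class RerxConfig(BaseModel):
    """Hyperparameters of the full extraction pipeline.

    ``delta1`` (cover rate) and ``delta2`` (error rate) gate the
    recursion: a rule is subdivided when support >= delta1 and
    error > delta2.  ``use_continuous=True`` selects the continuous
    variant (trees may split on any active attribute).
    """

    delta1: float = Field(default=0.10, gt=0, le=1)
    delta2: float = Field(default=0.10, gt=0, le=1)
    max_recursion_depth: int = Field(default=3, ge=1)
    use_continuous: bool = True
    simplify_rules: bool = True
    tree_targets: str = Field(default="correct_subset",
                              pattern="^(correct_subset|network_labels)$")
    net: NetConfig = NetConfig()
    tree: TreeConfig = TreeConfig()

    model_config = {"arbitrary_types_allowed": True}


@dataclass
class RuleTrace:
    rule_id: str
    consequent: str
    support: float
    error: float
    n_covered: int
    subdivided: bool = False
    warning: Optional[str] = None
    child: Optional["LevelTrace"] = None


@dataclass
class LevelTrace:
    depth: int
    n_records: int
    active_attributes: list[str]
    network_accuracy: Optional[float]
    rules: list[RuleTrace] = field(default_factory=list)

    def max_depth(self) -> int:
        deepest = self.depth
        for rt in self.rules:
            if rt.child is not None:
                deepest = max(deepest, rt.child.max_depth())
        return deepest

    def to_json(self, indent: int | None = 1) -> str:
        return json.dumps(asdict(self), indent=indent)


@dataclass
class ExtractionResult:
    """Flattened rule set plus the recursion trace and scoring metadata."""

    rules: RuleSet
    trace: LevelTrace
    majority_class: str
    training_accuracy: float
    scores_by_rule: dict  # rule id -> Laplace-corrected class-2 purity
    default_score: float
    network: Optional[TrainedNetwork] = None


def _single_rule(label: str, n: int) -> list[Rule]:
    return [Rule("R1", (), label)]


def _tree_attributes(net: TrainedNetwork, cohort: Cohort, use_continuous: bool) -> list[str]:
    active = net.active_attributes
    if use_continuous:
        return list(active)
    discrete = [a for a in active if not cohort.schema[a].is_continuous]
    return discrete or list(active)


def _level(cohort: Cohort, config: RerxConfig, seed: int, depth: int
           ) -> tuple[list[Rule], LevelTrace, Optional[TrainedNetwork]]:
    labels = cohort.labels.to_numpy()
    present = sorted(set(labels), key=list(cohort.schema.class_levels).index)
    if len(present) < 2:
        trace = LevelTrace(depth, len(cohort), [], None,
                           [RuleTrace("R1", present[0], 1.0, 0.0, len(cohort))])
        return _single_rule(present[0], len(cohort)), trace, None

    rng = np.random.default_rng(seed)
    net_seed = int(rng.integers(2**31))

    net = train_network(cohort, config.net, seed=net_seed)
    net = prune_attributes(net, cohort, seed=net_seed)

    correct = net.predict_labels(cohort.data) == labels
    if config.tree_targets == "correct_subset":
        sub = cohort.subset(correct)
        usable = (len(sub) >= 2 * config.tree.min_leaf_size
                  and sub.labels.nunique() == 2)
        tree_cohort = sub if usable else cohort
    else:
        data = cohort.data.copy()
        data["class"] = net.predict_labels(cohort.data)
        tree_cohort = Cohort(cohort.schema, data)

    attrs = _tree_attributes(net, cohort, config.use_continuous)
    tree = prune_tree(build_tree(tree_cohort, attrs, config.tree), config=config.tree)
    level_rules = tree_to_rules(tree, cohort=tree_cohort,
                                simplify=config.simplify_rules, config=config.tree)

    stats = rule_stats(level_rules, cohort)
    trace = LevelTrace(depth, len(cohort), list(attrs), net.training_accuracy)
    out: list[Rule] = []
    for rule, st in zip(level_rules, stats):
        child_seed = int(rng.integers(2**31))  # drawn for every rule: order-stable
        rt = RuleTrace(rule.id, rule.consequent, st.support, st.error, st.n_covered)
        trace.rules.append(rt)
        needs_split = st.support >= config.delta1 and st.error > config.delta2
        if not needs_split:
            out.append(rule)
            continue
        if depth >= config.max_recursion_depth:
            rt.warning = "recursion depth bound reached; rule kept as-is"
            out.append(rule)
            continue
        _, ids = predict_frame(level_rules, cohort.data)
        covered = ids == rule.id
        subset = cohort.subset(covered)
        if len(subset) >= len(cohort) or subset.labels.nunique() < 2 or len(subset) < 4:
            rt.warning = "covered subset not subdividable; rule kept as-is"
            out.append(rule)
            continue
        child_rules, child_trace, _ = _level(subset, config, child_seed, depth + 1)
        child_set = RuleSet(tuple(child_rules), schema=cohort.schema)
        pred, _ = predict_frame(child_set, subset.data)
        child_acc = float((pred == subset.labels.to_numpy()).mean())
        parent_acc = 1.0 - st.error
        if child_acc + 1e-12 < parent_acc:
            rt.warning = "subdivision did not improve training accuracy; rule kept as-is"
            out.append(rule)
            continue
        rt.subdivided = True
        rt.child = child_trace
        for child in child_rules:
            out.append(Rule(f"{rule.id}.{child.id}",
                            _canonical_path(list(rule.conditions) + list(child.conditions)),
                            child.consequent))
    return out, trace, net


def extract_rules(cohort: Cohort, config: RerxConfig | None = None,
                  seed: int | None = None) -> ExtractionResult:
    """Run the full continuous Re-RX pipeline on a labeled cohort."""
    config = config or RerxConfig()
    if len(cohort) == 0:
        raise ValueError("cannot extract rules from an empty cohort")
    if seed is None:
        seed = config.net.init_seed
    flat, trace, net = _level(cohort, config, seed, depth=1)
    rules = RuleSet(
        tuple(Rule(f"R{i + 1}", r.conditions, r.consequent)
              for i, r in enumerate(flat)),
        schema=cohort.schema,
        provenance=f"continuous Re-RX (seed={seed}, delta1={config.delta1}, "
                   f"delta2={config.delta2})")

    y = cohort.labels.to_numpy()
    majority = cohort.majority_class()
    pred, ids = predict_frame(rules, cohort.data)
    pred[pred == UNCOVERED] = majority
    train_acc = float((pred == y).mean())

    class2 = cohort.schema.class_levels[1]
    scores = {}
    for rule in rules:
        m = ids == rule.id
        n = int(m.sum())
        n2 = int((y[m] == class2).sum())
        scores[rule.id] = (n2 + 1.0) / (n + 2.0)
    default_score = (float((y == class2).sum()) + 1.0) / (len(y) + 2.0)
    return ExtractionResult(rules, trace, majority, train_acc, scores,
                            default_score, net)


def predict(result: ExtractionResult, record) -> str:
    """Classify one record with the extracted rules (majority fallback)."""
    match = apply_rules(result.rules, record)
    return result.majority_class if match.label == UNCOVERED else match.label


def predict_cohort(result: ExtractionResult, df) -> np.ndarray:
    labels, _ = predict_frame(result.rules, df)
    labels[labels == UNCOVERED] = result.majority_class
    return labels
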