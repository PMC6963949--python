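"""If-then diagnostic rule sets: model, parser, serializer, evaluator.

A rule is an ordered conjunction of conditions over the cohort schema
with a class consequent; a rule set is evaluated with first-match
semantics (rule sets exported from a single decision tree are mutually
exclusive, so their predictions are order-invariant).  Conditions come in
four forms::

    HbA1c <= 5.8            threshold, inclusive
    HbA1c > 6.4             threshold, exclusive
    HbA1c in (5.8, 6.1]     half-open interval (low, high]
    Mexican-American = no   category equality

The ``=`` operator works both on a categorical schema attribute
(``race_ethnicity = Non-Hispanic Black``) and, as an indicator, on a
*level* of a nominal attribute (``Non-Hispanic Black = yes`` is true when
the record's race/ethnicity equals that level).  The latter form is how
published rule tables phrase one-hot conditions.

The canonical 15-rule prediabetes-vs-diabetes reference model ships as a
package fixture, exposed by :func:`canonical_ruleset`; it contains the
lower-albuminuria UACR cut-offs 6.1 and 71.00 mg/g Cr.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .schema import CLASS_COLUMN, Cohort, Schema, default_schema

__all__ = [
    "LE", "GT", "IN", "EQ", "UNCOVERED",
    "Condition", "Rule", "RuleSet", "RuleMatch", "RuleStats", "RuleStatsReport",
    "RuleParseError", "canonical_ruleset", "apply_rules", "predict_frame",
    "rule_stats", "extract_thresholds", "parse_rules", "serialize_rules",
]

LE = "<="
GT = ">"
IN = "in"
EQ = "="
UNCOVERED = "uncovered"


class RuleParseError(ValueError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


@dataclass(frozen=True)
class Condition:
    """One atomic test on a record."""

    attribute: str
    op: str
    threshold: float | None = None
    low: float | None = None
    high: float | None = None
    level: str | None = None

    def __post_init__(self) -> None:
        if self.op in (LE, GT):
            if self.threshold is None:
                raise ValueError(f"{self.op!r} condition needs a threshold")
        elif self.op == IN:
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError("interval condition needs low < high")
        elif self.op == EQ:
            if self.level is None:
                raise ValueError("equality condition needs a level")
        else:
            raise ValueError(f"unknown operator {self.op!r}")

    def _column(self, schema: Schema | None, columns) -> tuple[str, str | None]:
        """Resolve to (column name, indicator level or None)."""
        if self.attribute in columns:
            return self.attribute, None
        if schema is not None:
            owner = schema.nominal_level_owner(self.attribute)
            if owner is not None and owner.name in columns:
                return owner.name, self.attribute
        raise KeyError(f"condition references unknown attribute {self.attribute!r}")

    def mask(self, df: pd.DataFrame, schema: Schema | None = None) -> np.ndarray:
        """Vectorized truth value of this condition over a record table."""
        col_name, indicator = self._column(schema, df.columns)
        col = df[col_name]
        if indicator is not None:
            if self.op != EQ or self.level not in ("yes", "no"):
                raise ValueError(
                    f"indicator condition on {self.attribute!r} must be '= yes' or '= no'")
            eq = (col == indicator).to_numpy()
            return eq if self.level == "yes" else ~eq
        if self.op == LE:
            return (col <= self.threshold).to_numpy()
        if self.op == GT:
            return (col > self.threshold).to_numpy()
        if self.op == IN:
            return ((col > self.low) & (col <= self.high)).to_numpy()
        return (col.astype(object) == self.level).to_numpy()

    def matches(self, record: Mapping, schema: Schema | None = None) -> bool:
        col_name, indicator = self._column(schema, record.keys()
                                           if hasattr(record, "keys") else record.index)
        value = record[col_name]
        if indicator is not None:
            eq = value == indicator
            return eq if self.level == "yes" else not eq
        if self.op == LE:
            return value <= self.threshold
        if self.op == GT:
            return value > self.threshold
        if self.op == IN:
            return self.low < value <= self.high
        return value == self.level

    def to_text(self) -> str:
        if self.op in (LE, GT):
            return f"{self.attribute} {self.op} {_fmt(self.threshold)}"
        if self.op == IN:
            return f"{self.attribute} in ({_fmt(self.low)}, {_fmt(self.high)}]"
        return f"{self.attribute} = {self.level}"

    def to_json_obj(self) -> dict:
        if self.op in (LE, GT):
            return {"attr": self.attribute, "op": self.op, "value": self.threshold}
        if self.op == IN:
            return {"attr": self.attribute, "op": IN, "low": self.low, "high": self.high}
        return {"attr": self.attribute, "op": EQ, "level": self.level}

    @classmethod
    def from_json_obj(cls, obj: dict) -> "Condition":
        op = obj["op"]
        if op in (LE, GT):
            return cls(obj["attr"], op, threshold=float(obj["value"]))
        if op == IN:
            return cls(obj["attr"], IN, low=float(obj["low"]), high=float(obj["high"]))
        if op == EQ:
            return cls(obj["attr"], EQ, level=str(obj["level"]))
        raise ValueError(f"unknown operator {op!r} in rule JSON")


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions with a class consequent.

    A rule with no conditions is a default rule and matches everything.
    """

    id: str
    conditions: tuple[Condition, ...]
    consequent: str

    @property
    def is_default(self) -> bool:
        return len(self.conditions) == 0

    def matches(self, record, schema: Schema | None = None) -> bool:
        return all(c.matches(record, schema) for c in self.conditions)

    def mask(self, df: pd.DataFrame, schema: Schema | None = None) -> np.ndarray:
        m = np.ones(len(df), dtype=bool)
        for c in self.conditions:
            m &= c.mask(df, schema)
        return m

    def to_text(self) -> str:
        body = " AND ".join(c.to_text() for c in self.conditions) or "TRUE"
        return f"IF {body} THEN {self.consequent}"


@dataclass
class RuleSet:
    """An ordered rule list bound (optionally) to a schema."""

    rules: tuple[Rule, ...]
    schema: Schema | None = field(default=None, compare=False, repr=False)
    provenance: str = field(default="", compare=False)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterable[Rule]:
        return iter(self.rules)

    def __getitem__(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    def attribute_names(self) -> set[str]:
        return {c.attribute for r in self.rules for c in r.conditions}


@dataclass(frozen=True)
class RuleMatch:
    label: str
    rule_id: str | None


@dataclass(frozen=True)
class RuleStats:
    rule_id: str
    support: float
    error: float
    n_covered: int


@dataclass(frozen=True)
class RuleStatsReport:
    per_rule: tuple[RuleStats, ...]
    uncovered_fraction: float

    def __iter__(self):
        return iter(self.per_rule)


def apply_rules(rules: RuleSet, record) -> RuleMatch:
    """First-match evaluation of one record; explicit 'uncovered' result."""
    for rule in rules:
        if rule.matches(record, rules.schema):
            return RuleMatch(rule.consequent, rule.id)
    return RuleMatch(UNCOVERED, None)


def predict_frame(rules: RuleSet, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized first-match evaluation over a record table.

    Returns ``(labels, rule_ids)``; unmatched records get ``UNCOVERED`` /
    ``None``.
    """
    labels = np.full(len(df), UNCOVERED, dtype=object)
    ids = np.full(len(df), None, dtype=object)
    unassigned = np.ones(len(df), dtype=bool)
    for rule in rules:
        if not unassigned.any():
            break
        hit = unassigned & rule.mask(df, rules.schema)
        labels[hit] = rule.consequent
        ids[hit] = rule.id
        unassigned &= ~hit
    return labels, ids


def rule_stats(rules: RuleSet, cohort: Cohort) -> RuleStatsReport:
    """Per-rule support and error under first-match semantics.

    Support is the fraction of the cohort the rule matches first; error
    is the fraction of those records whose label differs from the rule's
    consequent (0 by convention for rules covering nothing).
    """
    if len(cohort) == 0:
        raise ValueError("rule_stats requires a non-empty cohort")
    y = cohort.labels.to_numpy()
    _, ids = predict_frame(rules, cohort.data)
    n = len(cohort)
    out = []
    for rule in rules:
        covered = ids == rule.id
        n_cov = int(covered.sum())
        err = float((y[covered] != rule.consequent).mean()) if n_cov else 0.0
        out.append(RuleStats(rule.id, n_cov / n, err, n_cov))
    uncovered = float((ids == None).sum()) / n  # noqa: E711 -- object array
    return RuleStatsReport(tuple(out), uncovered)


def extract_thresholds(rules: RuleSet, attribute: str) -> list[float]:
    """All numeric cut-offs a rule set places on one continuous attribute.

    Interval conditions contribute both endpoints.  Results are
    deduplicated and ascending, and invariant under rule reordering.
    """
    if rules.schema is not None:
        if attribute not in rules.schema:
            raise KeyError(f"unknown attribute {attribute!r}")
        if not rules.schema[attribute].is_continuous:
            raise ValueError(f"attribute {attribute!r} is not continuous")
    elif len(rules) and attribute not in rules.attribute_names():
        raise KeyError(f"unknown attribute {attribute!r}")
    values: set[float] = set()
    for rule in rules:
        for c in rule.conditions:
            if c.attribute != attribute:
                continue
            if c.op in (LE, GT):
                values.add(float(c.threshold))
            elif c.op == IN:
                values.update((float(c.low), float(c.high)))
    return sorted(values)


# --- text format -----------------------------------------------------------

_COND_RE = re.compile(
    r"^\s*(?P<attr>.+?)\s+(?P<op><=|>|in|=)\s+(?P<rhs>.+?)\s*$")
_INTERVAL_RE = re.compile(
    r"^\(\s*(?P<low>[-+0-9.eE]+)\s*,\s*(?P<high>[-+0-9.eE]+)\s*\]$")


def serialize_rules(rules: RuleSet) -> str:
    """Human-readable ``IF ... AND ... THEN class`` listing, one rule per line."""
    return "\n".join(r.to_text() for r in rules) + "\n"


def parse_rules(text: str, schema: Schema | None = None,
                provenance: str = "parsed") -> RuleSet:
    """Parse the rule-text grammar ``IF <cond> (AND <cond>)* THEN <class>``.

    Rule ids are assigned sequentially (R1, R2, ...).  ``IF TRUE THEN c``
    denotes a default rule.  Lines starting with ``#`` and blank lines
    are ignored.  Malformed input raises :class:`RuleParseError` with the
    line and column of the offending token.
    """
    rules: list[Rule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not line.startswith("IF "):
            raise RuleParseError("rule must start with 'IF'", lineno, 1 + raw.find(line[0]))
        if " THEN " not in line:
            raise RuleParseError("missing 'THEN'", lineno, len(raw))
        body, consequent = line[3:].rsplit(" THEN ", 1)
        consequent = consequent.strip()
        if not consequent:
            raise RuleParseError("empty consequent", lineno, len(raw))
        conditions: list[Condition] = []
        if body.strip() != "TRUE":
            for part in body.split(" AND "):
                col = raw.find(part) + 1
                m = _COND_RE.match(part)
                if not m:
                    raise RuleParseError(f"cannot parse condition {part.strip()!r}",
                                         lineno, col)
                attr, op, rhs = m.group("attr"), m.group("op"), m.group("rhs")
                try:
                    if op in (LE, GT):
                        conditions.append(Condition(attr, op, threshold=float(rhs)))
                    elif op == IN:
                        iv = _INTERVAL_RE.match(rhs)
                        if not iv:
                            raise ValueError(f"bad interval {rhs!r}; expected (a, b]")
                        conditions.append(Condition(attr, IN,
                                                    low=float(iv.group("low")),
                                                    high=float(iv.group("high"))))
                    else:
                        conditions.append(Condition(attr, EQ, level=rhs))
                except ValueError as exc:
                    raise RuleParseError(str(exc), lineno, col) from exc
        rules.append(Rule(f"R{len(rules) + 1}", tuple(conditions), consequent))
    return RuleSet(tuple(rules), schema=schema, provenance=provenance)


# --- JSON format -----------------------------------------------------------

def rules_to_json(rules: RuleSet, indent: int | None = 1) -> str:
    payload = {
        "provenance": rules.provenance,
        "rules": [
            {"id": r.id,
             "conditions": [c.to_json_obj() for c in r.conditions],
             "then": r.consequent}
            for r in rules
        ],
    }
    return json.dumps(payload, indent=indent)


def rules_from_json(text: str, schema: Schema | None = None) -> RuleSet:
    payload = json.loads(text)
    rules = tuple(
        Rule(obj["id"],
             tuple(Condition.from_json_obj(c) for c in obj["conditions"]),
             obj["then"])
        for obj in payload["rules"]
    )
    return RuleSet(rules, schema=schema, provenance=payload.get("provenance", ""))


def canonical_ruleset() -> RuleSet:
    """The published 15-rule prediabetes-vs-diabetes reference model.

    Interval conditions are encoded half-open ``(low, high]``, the only
    gap- and overlap-free reading of the published intervals given the
    neighbouring ``<=`` / ``>`` rules.  Contains the two lower-albuminuria
    UACR cut-offs, 6.1 and 71.00 mg/g Cr.
    """
    text = resources.files("rerx.data").joinpath("canonical_rules.json").read_text("utf-8")
    rs = rules_from_json(text, schema=default_schema())
    rs.provenance = "canonical 15-rule reference model"
    return rs
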