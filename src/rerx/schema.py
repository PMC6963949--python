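"""Tabular cohort data model and CSV input/output.

A :class:`Schema` describes the predictor attributes of a diabetes /
prediabetes cohort (continuous, binary, nominal and ordinal variables)
together with the binary class attribute.  A :class:`Cohort` couples a
schema with an ordered :class:`pandas.DataFrame` of records; record order
is stable so that seeded cross-validation splits are reproducible.

The default schema models the 19 predictor variables of the NHANES-style
diabetes dataset (demographics, anthropometry, blood pressure, lipids,
glycaemia, insulin, urinary albumin-to-creatinine ratio, lifestyle) plus a
``class`` label with levels ``diabetes`` / ``prediabetes``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CLASS_COLUMN = "class"
DIABETES = "diabetes"
PREDIABETES = "prediabetes"
CLASS_LEVELS = (DIABETES, PREDIABETES)

KINDS = ("continuous", "binary", "nominal", "ordinal")


class SchemaError(ValueError):
    """A cohort, record or file does not conform to its schema."""


class OutOfRangeWarning(UserWarning):
    """A continuous value read from a file lies outside the schema range."""


@dataclass(frozen=True)
class Attribute:
    """One predictor variable.

    Parameters
    ----------
    name:
        Identifier used in rules, CSV headers and cohort columns.
    kind:
        ``continuous``, ``binary``, ``nominal`` or ``ordinal``.
    units:
        Free-text units (e.g. ``mg/g Cr``, ``mg/dL``, ``%``); empty for
        categorical variables.
    levels:
        Ordered category labels; required for non-continuous kinds.
    range:
        ``(min, max)`` clip range for continuous kinds.
    """

    name: str
    kind: str
    units: str = ""
    levels: tuple[str, ...] = ()
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown attribute kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous":
            if self.range is None or not self.range[0] < self.range[1]:
                raise SchemaError(f"continuous attribute {self.name!r} needs min < max range")
        else:
            if len(self.levels) < 2:
                raise SchemaError(f"{self.kind} attribute {self.name!r} needs >=2 levels")

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"


@dataclass(frozen=True)
class Schema:
    """An ordered collection of predictor attributes plus the class labels."""

    attributes: tuple[Attribute, ...]
    class_levels: tuple[str, ...] = CLASS_LEVELS

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names in schema")
        if len(self.class_levels) < 2:
            raise SchemaError("schema needs >=2 class levels")

    def __iter__(self) -> Iterable[Attribute]:
        return iter(self.attributes)

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.attributes)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def continuous(self) -> list[Attribute]:
        return [a for a in self.attributes if a.is_continuous]

    def categorical(self) -> list[Attribute]:
        return [a for a in self.attributes if not a.is_continuous]

    def nominal_level_owner(self, level: str) -> Attribute | None:
        """Return the categorical attribute owning ``level``, if any.

        Used to evaluate indicator conditions such as
        ``Non-Hispanic Black = yes`` against the nominal race attribute.
        """
        for a in self.categorical():
            if level in a.levels:
                return a
        return None


RACE_LEVELS = (
    "Mexican-American",
    "Other Hispanic",
    "Non-Hispanic White",
    "Non-Hispanic Black",
    "Other race",
)
TOBACCO_LEVELS = ("every day", "some days", "not at all")


def default_schema() -> Schema:
    """The 19-variable NHANES-style diabetes dataset schema."""
    return Schema(
        attributes=(
            Attribute("age", "continuous", "years", range=(20.0, 80.0)),
            Attribute("sex", "binary", levels=("male", "female")),
            Attribute("race_ethnicity", "nominal", levels=RACE_LEVELS),
            Attribute("SBP", "continuous", "mmHg", range=(62.0, 228.0)),
            Attribute("DBP", "continuous", "mmHg", range=(0.0, 118.0)),
            Attribute("waist", "continuous", "cm", range=(40.2, 177.9)),
            Attribute("BMI", "continuous", "kg/m^2", range=(12.1, 82.9)),
            Attribute("total_cholesterol", "continuous", "mg/dL", range=(69.0, 813.0)),
            Attribute("UACR", "continuous", "mg/g Cr", range=(0.21, 9600.0)),
            Attribute("HbA1c", "continuous", "%", range=(3.5, 17.5)),
            Attribute("tobacco", "ordinal", levels=TOBACCO_LEVELS),
            Attribute("alcohol", "continuous", "drinks/day", range=(1.0, 25.0)),
            Attribute("exercise_to_lose_weight", "binary", levels=("no", "yes")),
            Attribute("triglycerides", "continuous", "mg/dL", range=(13.0, 4233.0)),
            Attribute("LDL", "continuous", "mg/dL", range=(14.0, 375.0)),
            Attribute("HDL", "continuous", "mg/dL", range=(8.0, 138.0)),
            Attribute("FPG", "continuous", "mg/dL", range=(51.0, 421.0)),
            Attribute("insulin", "continuous", "uU/mL", range=(0.14, 682.48)),
            Attribute("total_bilirubin", "continuous", "mg/dL", range=(0.1, 7.1)),
        )
    )


@dataclass
class Cohort:
    """A schema plus an ordered record table.

    ``data`` holds one column per attribute plus (optionally) a
    ``class`` column.  Row order is preserved by every operation so that
    a seed fully determines downstream fold assignments.
    """

    schema: Schema
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort missing attribute columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def labeled(self) -> bool:
        return CLASS_COLUMN in self.data.columns

    @property
    def labels(self) -> pd.Series:
        if not self.labeled:
            raise SchemaError("cohort is unlabeled")
        return self.data[CLASS_COLUMN]

    def class_counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {lvl: int(vc.get(lvl, 0)) for lvl in self.schema.class_levels}

    def majority_class(self) -> str:
        counts = self.class_counts()
        return max(counts, key=lambda k: (counts[k], -self.schema.class_levels.index(k)))

    def subset(self, mask: np.ndarray | pd.Series) -> "Cohort":
        return Cohort(self.schema, self.data.loc[np.asarray(mask)].copy())

    def records(self) -> Iterable[dict]:
        return self.data.to_dict("records")


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV with '.' decimal separator.

    The round trip through :func:`read_cohort` is lossless for categories
    and lossless to 1e-9 for continuous values (``repr`` floats are exact).
    """
    cohort.data.to_csv(path, index=False, float_format=None)


def read_cohort(path, schema: Schema, *, drop_incomplete: bool = False,
                require_labels: bool = False) -> Cohort:
    """Read a cohort CSV and validate it against ``schema``.

    Missing predictor cells raise a :class:`SchemaError` by default
    (``drop_incomplete=True`` drops those rows instead).  Continuous
    values outside the schema range emit :class:`OutOfRangeWarning` but
    are retained, since real-world files drift from the catalogued ranges.
    """
    df = pd.read_csv(path)
    missing_cols = [n for n in schema.names if n not in df.columns]
    if missing_cols:
        raise SchemaError(f"file is missing required columns: {missing_cols}")
    if require_labels and CLASS_COLUMN not in df.columns:
        raise SchemaError(f"file is missing the {CLASS_COLUMN!r} column")

    pred = df[schema.names]
    incomplete = pred.isna().any(axis=1)
    if incomplete.any():
        if drop_incomplete:
            df = df.loc[~incomplete].reset_index(drop=True)
        else:
            bad = pred.columns[pred.isna().any()].tolist()
            raise SchemaError(
                f"{int(incomplete.sum())} rows have missing predictor cells "
                f"(columns: {bad}); pass drop_incomplete=True to drop them"
            )

    for attr in schema.attributes:
        col = df[attr.name]
        if attr.is_continuous:
            values = pd.to_numeric(col, errors="coerce")
            if values.isna().any() and not col.isna().any():
                raise SchemaError(f"non-numeric values in continuous column {attr.name!r}")
            lo, hi = attr.range
            out = ((values < lo) | (values > hi)) & values.notna()
            if out.any():
                warnings.warn(
                    f"{int(out.sum())} values of {attr.name!r} outside "
                    f"[{lo}, {hi}]; values retained",
                    OutOfRangeWarning,
                    stacklevel=2,
                )
            df[attr.name] = values.astype(float)
        else:
            bad_levels = sorted(set(col.dropna().astype(str)) - set(attr.levels))
            if bad_levels:
                raise SchemaError(
                    f"column {attr.name!r} has unknown levels {bad_levels}; "
                    f"expected {list(attr.levels)}"
                )
            df[attr.name] = col.astype(str).where(col.notna(), other=None)

    if CLASS_COLUMN in df.columns:
        bad = sorted(set(df[CLASS_COLUMN].dropna().astype(str)) - set(schema.class_levels))
        if bad:
            raise SchemaError(f"unknown class labels {bad}")
    return Cohort(schema, df)
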