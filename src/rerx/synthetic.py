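"""Synthetic NHANES-like diabetes/prediabetes cohort generator.

The real study data are survey extracts that cannot be redistributed, so
this module draws cohorts from class-conditional distributions whose
parameters reproduce the published per-class summary statistics: normal
(mean, sd) draws for near-symmetric continuous variables, log-normal
draws parameterized by the printed median for right-skewed variables
(UACR, fasting plasma glucose, insulin, alcohol, triglycerides), and
categorical draws from the printed per-class frequencies.  Attributes are
drawn independently within class -- the published tables carry no
correlation structure -- and continuous draws are clipped to the
catalogued variable ranges.

Class labels are assigned by construction (exact class counts, default
942 diabetes / 524 prediabetes), not by re-applying the ADA definitions;
:func:`ada_label` is provided separately for validation studies.
"""

from __future__ import annotations

import json
import math
from typing import Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .schema import (
    CLASS_COLUMN,
    DIABETES,
    PREDIABETES,
    Cohort,
    Schema,
    default_schema,
)

__all__ = [
    "NormalParam",
    "LogNormalParam",
    "CategoricalParam",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "ada_label",
    "SKEWED_ATTRIBUTES",
]

#: Right-skewed continuous attributes, summarized by medians rather than means.
SKEWED_ATTRIBUTES = ("UACR", "FPG", "insulin", "alcohol", "triglycerides")


class NormalParam(BaseModel):
    """Near-symmetric continuous attribute: normal(mean, sd), clipped."""

    kind: Literal["normal"] = "normal"
    mean: float
    sd: float = Field(gt=0)


class LogNormalParam(BaseModel):
    """Right-skewed continuous attribute: log-normal with exact median.

    The median of a log-normal is ``exp(mu)``, so ``mu = log(median)``
    preserves the printed median exactly; ``log_sd`` sets the spread on
    the log scale.
    """

    kind: Literal["lognormal"] = "lognormal"
    median: float = Field(gt=0)
    log_sd: float = Field(gt=0)


class CategoricalParam(BaseModel):
    """Binary/nominal/ordinal attribute: category probability vector."""

    kind: Literal["categorical"] = "categorical"
    probs: dict[str, float]

    @field_validator("probs")
    @classmethod
    def _check_probs(cls, v: dict[str, float]) -> dict[str, float]:
        if any(p < 0 for p in v.values()):
            raise ValueError("category probabilities must be non-negative")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category probabilities sum to {total}, not 1")
        return v


AttrParam = Union[NormalParam, LogNormalParam, CategoricalParam]


def _renorm(d: dict[str, float]) -> dict[str, float]:
    total = sum(d.values())
    out = {k: v / total for k, v in d.items()}
    # absorb float residue into the largest entry so the sum is exactly 1
    key = max(out, key=out.get)
    out[key] += 1.0 - sum(out.values())
    return out


class CohortSpec(BaseModel):
    """Class-conditional generative parameters for a synthetic cohort."""

    n_diabetes: int = Field(ge=0)
    n_prediabetes: int = Field(ge=0)
    diabetes: dict[str, AttrParam]
    prediabetes: dict[str, AttrParam]
    clip_ranges: dict[str, tuple[float, float]]
    seed: int | None = None

    @model_validator(mode="after")
    def _check_symmetry(self) -> "CohortSpec":
        if set(self.diabetes) != set(self.prediabetes):
            raise ValueError("diabetes and prediabetes parameter sets name different attributes")
        return self

    def class_params(self, label: str) -> dict[str, AttrParam]:
        if label == DIABETES:
            return self.diabetes
        if label == PREDIABETES:
            return self.prediabetes
        raise ValueError(f"unknown class label {label!r}")

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        return cls.model_validate(json.loads(text))


def default_cohort_spec() -> CohortSpec:
    """The published per-class summary statistics as a generative spec.

    Continuous near-symmetric variables carry the printed (mean, sd);
    the five skewed variables carry the printed median with a log-scale
    sd of 0.8 (UACR), 0.25 (FPG, insulin) or 0.5 (triglycerides,
    alcohol); categorical variables carry the printed per-class
    percentages, renormalized to sum to one.  Class sizes default to the
    study's 942 diabetes / 524 prediabetes.
    """
    schema = default_schema()
    clip = {a.name: a.range for a in schema.continuous()}

    def N(mean, sd):
        return NormalParam(mean=mean, sd=sd)

    def LN(median, log_sd):
        return LogNormalParam(median=median, log_sd=log_sd)

    def C(**probs):
        return CategoricalParam(probs=_renorm(probs))

    diabetes: dict[str, AttrParam] = {
        "age": N(60.01, 13.54),
        "sex": CategoricalParam(probs=_renorm({"male": 0.5074, "female": 0.4925})),
        "race_ethnicity": CategoricalParam(probs=_renorm({
            "Mexican-American": 0.2154,
            "Other Hispanic": 0.09235,
            "Non-Hispanic White": 0.3885,
            "Non-Hispanic Black": 0.2303,
            "Other race": 0.0732,
        })),
        "SBP": N(130.57, 20.15),
        "DBP": N(68.15, 14.99),
        "waist": N(107.73, 15.73),
        "BMI": N(31.74, 6.93),
        "total_cholesterol": N(183.31, 40.37),
        "UACR": LN(14.85, 0.8),
        "HbA1c": N(7.38, 1.81),
        "tobacco": CategoricalParam(probs=_renorm({
            "every day": 0.1433, "some days": 0.0222, "not at all": 0.8343})),
        "alcohol": LN(1.0, 0.5),
        "exercise_to_lose_weight": CategoricalParam(
            probs=_renorm({"yes": 0.2664, "no": 0.7335})),
        "triglycerides": LN(145.92, 0.5),
        "LDL": N(104.18, 34.82),
        "HDL": N(49.93, 13.63),
        "FPG": LN(139.8, 0.25),
        "insulin": LN(12.74, 0.25),
        "total_bilirubin": N(0.72, 0.28),
    }
    prediabetes: dict[str, AttrParam] = {
        "age": N(55.04, 15.79),
        "sex": CategoricalParam(probs=_renorm({"male": 0.4580, "female": 0.5419})),
        # the published prediabetes race row carries a stray duplicate
        # "Hispanic" entry; the five level-matching entries sum to ~100%
        "race_ethnicity": CategoricalParam(probs=_renorm({
            "Mexican-American": 0.1374,
            "Other Hispanic": 0.0687,
            "Non-Hispanic White": 0.5133,
            "Non-Hispanic Black": 0.1851,
            "Other race": 0.0954,
        })),
        "SBP": N(125.47, 18.10),
        "DBP": N(69.18, 13.14),
        "waist": N(104.66, 15.75),
        "BMI": N(30.95, 7.05),
        "total_cholesterol": N(198.19, 40.73),
        "UACR": LN(8.85, 0.8),
        "HbA1c": N(5.92, 1.05),
        "tobacco": CategoricalParam(probs=_renorm({
            "every day": 0.1488, "some days": 0.0190, "not at all": 0.8320})),
        "alcohol": LN(1.0, 0.5),
        "exercise_to_lose_weight": CategoricalParam(
            probs=_renorm({"yes": 0.3034, "no": 0.6965})),
        "triglycerides": LN(134.76, 0.5),
        "LDL": N(118.79, 36.29),
        "HDL": N(52.47, 14.88),
        "FPG": LN(108.0, 0.25),
        "insulin": LN(12.1, 0.25),
        "total_bilirubin": N(0.730, 0.28),
    }
    return CohortSpec(
        n_diabetes=942,
        n_prediabetes=524,
        diabetes=diabetes,
        prediabetes=prediabetes,
        clip_ranges=clip,
    )


def _draw(param: AttrParam, n: int, rng: np.random.Generator,
          clip: tuple[float, float] | None):
    if isinstance(param, NormalParam):
        x = rng.normal(param.mean, param.sd, size=n)
    elif isinstance(param, LogNormalParam):
        x = rng.lognormal(math.log(param.median), param.log_sd, size=n)
    else:
        levels = list(param.probs)
        p = np.array([param.probs[k] for k in levels])
        return rng.choice(np.array(levels, dtype=object), size=n, p=p / p.sum())
    if clip is not None:
        x = np.clip(x, clip[0], clip[1])
    return x


def generate_cohort(spec: CohortSpec, seed: int | None = None,
                    schema: Schema | None = None) -> Cohort:
    """Draw a labeled cohort from ``spec``.

    Class labels are assigned first with exact counts (all diabetes rows,
    then all prediabetes rows); each attribute is then drawn
    class-conditionally and independently.  The same ``(spec, seed)``
    yields a bit-identical cohort.
    """
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    schema = schema or default_schema()
    missing = [n for n in schema.names if n not in spec.diabetes]
    if missing:
        raise ValueError(f"spec lacks parameters for attributes: {missing}")
    rng = np.random.default_rng(seed)

    blocks = []
    for label, n in ((DIABETES, spec.n_diabetes), (PREDIABETES, spec.n_prediabetes)):
        params = spec.class_params(label)
        cols: dict[str, np.ndarray] = {}
        for attr in schema.attributes:
            cols[attr.name] = _draw(params[attr.name], n, rng,
                                    spec.clip_ranges.get(attr.name))
        cols[CLASS_COLUMN] = np.full(n, label, dtype=object)
        blocks.append(pd.DataFrame(cols))
    data = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    return Cohort(schema, data)


def ada_label(fpg: float, hba1c: float) -> str:
    """Classify one (FPG mg/dL, HbA1c %) pair by the ADA glycaemic criteria.

    Diabetes: FPG >= 126 mg/dL or HbA1c >= 6.5%.  Prediabetes:
    FPG 100-125 mg/dL (impaired fasting glucose) or HbA1c 5.7-6.4%.
    Otherwise ``"neither"``.
    """
    if not (fpg > 0 and hba1c > 0):
        raise ValueError("FPG and HbA1c must be positive")
    if fpg >= 126 or hba1c >= 6.5:
        return DIABETES
    if 100 <= fpg <= 125 or 5.7 <= hba1c <= 6.4:
        return PREDIABETES
    return "neither"
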