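import numpy as np
import pandas as pd
import pytest

from rerx import Cohort, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def bland_value(attr):
    """A fixed, in-range value for one attribute."""
    if attr.is_continuous:
        lo, hi = attr.range
        return (lo + hi) / 2.0
    return attr.levels[0]


def make_cohort(schema, labels, **columns):
    """Build a cohort where unspecified attributes are constant and bland."""
    n = len(labels)
    data = {}
    for attr in schema:
        if attr.name in columns:
            data[attr.name] = np.asarray(columns[attr.name], dtype=object
                                         if not attr.is_continuous else float)
        else:
            data[attr.name] = np.full(n, bland_value(attr),
                                      dtype=object if not attr.is_continuous else float)
    data["class"] = np.asarray(labels, dtype=object)
    return Cohort(schema, pd.DataFrame(data))


def full_record(schema, **overrides):
    rec = {attr.name: bland_value(attr) for attr in schema}
    rec.update(overrides)
    return rec


def draw_uniform_features(schema, n, rng):
    """Class-independent feature draws for planted-rule studies.

    HbA1c and FPG are drawn over clinically plausible windows so planted
    cut-offs at 6.4 % and 125 mg/dL sit well inside the data; all other
    attributes are uninformative distractors.
    """
    cols = {}
    for a in schema:
        if a.is_continuous:
            lo, hi = a.range
            cols[a.name] = rng.uniform(lo, min(hi, lo + (hi - lo) * 0.3), n)
        else:
            cols[a.name] = rng.choice(a.levels, n)
    cols["HbA1c"] = rng.uniform(5.0, 8.0, n)
    cols["FPG"] = rng.uniform(80.0, 180.0, n)
    return pd.DataFrame(cols)


def planted_labeler_2rule(df):
    return np.where(df["HbA1c"] > 6.4, "diabetes", "prediabetes")


def planted_labeler_3rule(df):
    return np.where((df["HbA1c"] > 6.4) | (df["FPG"] > 125.0),
                    "diabetes", "prediabetes")


def planted_cohort(schema, n, labeler, noise, rng):
    df = draw_uniform_features(schema, n, rng)
    y = labeler(df)
    if noise > 0:
        flip = rng.random(n) < noise
        y = np.where(flip, np.where(y == "diabetes", "prediabetes", "diabetes"), y)
    df["class"] = y
    return Cohort(schema, df)
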