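"""Measurement harness: repeated stratified CV and between-group tests.

The pipeline is scored the way diagnostic-rule studies report it:
repeated stratified k-fold cross-validation (default 10 runs of 5-fold)
yielding training/test accuracy (%), extracted-rule counts and AUC-ROC
per run x fold cell, aggregated as mean +/- sd over all cells.  AUC for a
hard rule classifier needs a score, so each record is scored with the
Laplace-corrected training purity of the rule that matched it.  Group
comparisons mirror a baseline-characteristics table: Welch's two-sample
t-test for near-symmetric continuous attributes, Wilcoxon rank-sum for
right-skewed ones, chi-square for categorical frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .pipeline import ExtractionResult, RerxConfig, extract_rules
from .ruleset import predict_frame
from .schema import Cohort, DIABETES, PREDIABETES
from .synthetic import SKEWED_ATTRIBUTES

__all__ = ["CVReport", "GroupComparison", "cross_validate", "auc_roc",
           "rule_based_scores", "compare_groups"]


def auc_roc(scores, labels, positive_label: str = PREDIABETES) -> float:
    """Area under the ROC curve for class-propensity scores.

    Equals the Mann-Whitney probability that a random positive outscores
    a random negative, counting ties as 1/2.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    pos = y == positive_label
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(pos.astype(int), s))


def rule_based_scores(result: ExtractionResult, df: pd.DataFrame) -> np.ndarray:
    """Class-2 propensity per record: the matched rule's training purity."""
    _, ids = predict_frame(result.rules, df)
    return np.asarray([result.scores_by_rule.get(i, result.default_score)
                       for i in ids], dtype=float)


@dataclass
class CVReport:
    """Per run x fold cells plus mean +/- sd aggregates.

    ``cells`` columns: run, fold, train_acc_pct, test_acc_pct, n_rules,
    auc_pct.  ``pooled_auc_pct`` is the AUC of all held-out scores pooled
    across cells, reported alongside the per-cell mean.
    """

    cells: pd.DataFrame
    pooled_auc_pct: float
    k: int
    runs: int

    def aggregate(self) -> dict:
        out = {}
        for col in ("train_acc_pct", "test_acc_pct", "n_rules", "auc_pct"):
            v = self.cells[col].to_numpy(dtype=float)
            out[col] = {"mean": float(v.mean()),
                        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0}
        out["pooled_auc_pct"] = self.pooled_auc_pct
        return out

    def summary_line(self) -> str:
        a = self.aggregate()
        return (f"[{self.runs} x {self.k} CV] "
                f"TR ACC {a['train_acc_pct']['mean']:.2f} +/- {a['train_acc_pct']['sd']:.2f} %  "
                f"TS ACC {a['test_acc_pct']['mean']:.2f} +/- {a['test_acc_pct']['sd']:.2f} %  "
                f"# rules {a['n_rules']['mean']:.2f}  "
                f"AUC-ROC {a['auc_pct']['mean']:.1f} % (pooled {self.pooled_auc_pct:.1f} %)")

    def to_json(self, indent: int | None = 1) -> str:
        return json.dumps({"k": self.k, "runs": self.runs,
                           "aggregate": self.aggregate(),
                           "cells": self.cells.to_dict("records")}, indent=indent)


def cross_validate(cohort: Cohort, config: RerxConfig | None = None,
                   k: int = 5, runs: int = 10, seed: int = 0) -> CVReport:
    """Repeated stratified k-fold CV of the full extraction pipeline.

    Rules are extracted on each training split and evaluated on the
    held-out split; aggregates are over all ``runs x k`` cells.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or RerxConfig()
    counts = cohort.class_counts()
    if min(counts.values()) < k:
        raise ValueError(
            f"class counts {counts} cannot be stratified into {k} folds; "
            "use a larger cohort or fewer folds")
    rng = np.random.default_rng(seed)
    y = cohort.labels.to_numpy()
    rows = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for run in range(runs):
        fold_seed = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            extract_seed = int(rng.integers(2**31))
            train = Cohort(cohort.schema, cohort.data.iloc[tr].reset_index(drop=True))
            test = Cohort(cohort.schema, cohort.data.iloc[te].reset_index(drop=True))
            result = extract_rules(train, config, seed=extract_seed)
            from .pipeline import predict_cohort
            tr_acc = float((predict_cohort(result, train.data)
                            == train.labels.to_numpy()).mean())
            te_acc = float((predict_cohort(result, test.data)
                            == test.labels.to_numpy()).mean())
            scores = rule_based_scores(result, test.data)
            auc = auc_roc(scores, test.labels.to_numpy())
            pooled_scores.append(scores)
            pooled_labels.append(test.labels.to_numpy())
            rows.append({"run": run, "fold": fold,
                         "train_acc_pct": 100.0 * tr_acc,
                         "test_acc_pct": 100.0 * te_acc,
                         "n_rules": len(result.rules),
                         "auc_pct": 100.0 * auc})
    pooled = 100.0 * auc_roc(np.concatenate(pooled_scores),
                             np.concatenate(pooled_labels))
    return CVReport(pd.DataFrame(rows), pooled, k=k, runs=runs)


@dataclass
class GroupComparison:
    """Baseline-characteristics table: per-attribute summaries and tests."""

    table: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def to_json(self, indent: int | None = 1) -> str:
        return json.dumps({"notes": self.notes,
                           "rows": self.table.to_dict("records")}, indent=indent)


def _summary(values: np.ndarray, skewed: bool) -> str:
    if skewed:
        return f"median {np.median(values):.2f}"
    return f"{values.mean():.2f} ({values.std(ddof=1):.2f})"


def compare_groups(cohort: Cohort, skewed_attributes=None, paired: bool = False,
                   bonferroni: bool = False) -> GroupComparison:
    """Compare the two diagnostic groups attribute by attribute.

    Near-symmetric continuous attributes: Welch's two-sample t-test on
    the class means (a paired t-test is available for matched designs but
    independent cohorts cannot be paired).  Skewed attributes (defaults:
    UACR, FPG, insulin, alcohol, triglycerides): Wilcoxon rank-sum.
    Categorical attributes: chi-square on the level frequencies.
    Constant attributes are flagged and not tested.
    """
    if skewed_attributes is None:
        skewed_attributes = set(SKEWED_ATTRIBUTES)
    y = cohort.labels.to_numpy()
    g1 = cohort.data[y == DIABETES]
    g2 = cohort.data[y == PREDIABETES]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both classes must be present")
    notes = ["Welch two-sample t-test used for independent groups"]
    if paired:
        if len(g1) != len(g2):
            raise ValueError("paired comparison requires equal group sizes")
        notes = ["paired t-test requested"]
    rows = []
    for attr in cohort.schema.attributes:
        a, b = g1[attr.name], g2[attr.name]
        if attr.is_continuous:
            av, bv = a.to_numpy(float), b.to_numpy(float)
            skewed = attr.name in skewed_attributes
            if np.ptp(np.concatenate([av, bv])) == 0:
                rows.append({"attribute": attr.name, "kind": attr.kind,
                             "diabetes": _summary(av, skewed),
                             "prediabetes": _summary(bv, skewed),
                             "test": "none (constant)", "statistic": np.nan,
                             "p_value": np.nan})
                continue
            if skewed:
                stat, p = sps.mannwhitneyu(av, bv, alternative="two-sided")
                test = "rank-sum"
            elif paired:
                stat, p = sps.ttest_rel(av, bv)
                test = "paired t"
            else:
                stat, p = sps.ttest_ind(av, bv, equal_var=False)
                test = "Welch t"
            rows.append({"attribute": attr.name, "kind": attr.kind,
                         "diabetes": _summary(av, skewed),
                         "prediabetes": _summary(bv, skewed),
                         "test": test, "statistic": float(stat),
                         "p_value": float(p)})
        else:
            counts = np.array([[(a == lvl).sum() for lvl in attr.levels],
                               [(b == lvl).sum() for lvl in attr.levels]], dtype=float)
            keep = counts.sum(axis=0) > 0
            counts = counts[:, keep]
            summ1 = " ".join(f"{lvl}: {100 * (a == lvl).mean():.1f}%" for lvl in attr.levels)
            summ2 = " ".join(f"{lvl}: {100 * (b == lvl).mean():.1f}%" for lvl in attr.levels)
            if counts.shape[1] < 2:
                rows.append({"attribute": attr.name, "kind": attr.kind,
                             "diabetes": summ1, "prediabetes": summ2,
                             "test": "none (constant)", "statistic": np.nan,
                             "p_value": np.nan})
                continue
            stat, p, _, _ = sps.chi2_contingency(counts)
            rows.append({"attribute": attr.name, "kind": attr.kind,
                         "diabetes": summ1, "prediabetes": summ2,
                         "test": "chi-square", "statistic": float(stat),
                         "p_value": float(p)})
    table = pd.DataFrame(rows)
    if bonferroni:
        m = table["p_value"].notna().sum()
        table["p_adjusted"] = (table["p_value"] * m).clip(upper=1.0)
        notes.append(f"Bonferroni correction over {m} tests")
    return GroupComparison(table, notes)
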