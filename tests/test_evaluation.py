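"""Cross-validation harness, AUC-ROC, rule scores and group comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

from rerx import (
    Cohort,
    RerxConfig,
    auc_roc,
    compare_groups,
    cross_validate,
    default_cohort_spec,
    extract_rules,
    generate_cohort,
    rule_based_scores,
)

from conftest import make_cohort, planted_cohort, planted_labeler_2rule


def pair_counting_auc(scores, labels, positive="prediabetes"):
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = sum(1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg)
    return total / (len(pos) * len(neg))


def test_auc_extremes():
    labels = ["prediabetes"] * 3 + ["diabetes"] * 3
    assert auc_roc([1, 1, 1, 0, 0, 0], labels) == 1.0
    assert auc_roc([0, 0, 0, 1, 1, 1], labels) == 0.0


def test_auc_matches_pair_counting_on_toy_vector():
    labels = ["prediabetes", "diabetes", "prediabetes",
              "diabetes", "prediabetes", "diabetes"]
    scores = [0.9, 0.9, 0.6, 0.4, 0.2, 0.1]
    assert auc_roc(scores, labels) == pytest.approx(
        pair_counting_auc(scores, labels))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    scores = rng.random(50)
    labels = np.where(rng.random(50) < 0.4, "prediabetes", "diabetes")
    base = auc_roc(scores, labels)
    assert auc_roc(np.exp(3 * scores), labels) == pytest.approx(base)
    assert auc_roc(np.log(scores + 1e-9), labels) == pytest.approx(base)


def test_auc_rejects_single_class_and_nonfinite():
    with pytest.raises(ValueError):
        auc_roc([0.1, 0.2], ["diabetes", "diabetes"])
    with pytest.raises(ValueError):
        auc_roc([np.nan, 0.2], ["diabetes", "prediabetes"])


def test_rule_scores_reflect_purity_and_ranking(schema):
    rng = np.random.default_rng(1)
    cohort = planted_cohort(schema, 800, planted_labeler_2rule, 0.0, rng)
    result = extract_rules(cohort, RerxConfig(), seed=1)
    scores = rule_based_scores(result, cohort.data)
    y = cohort.labels.to_numpy()
    # pure prediabetes rules score near 1, pure diabetes rules near 0
    assert scores[y == "prediabetes"].mean() > 0.9
    assert scores[y == "diabetes"].mean() < 0.1
    # scores sort records consistently with per-rule purity
    assert auc_roc(scores, y) > 0.99


def test_default_rule_on_balanced_residue_scores_half(schema):
    labels = ["diabetes", "prediabetes"] * 20
    cohort = make_cohort(schema, labels)
    result = extract_rules(cohort, RerxConfig(net=type(RerxConfig().net)(epochs=5)),
                           seed=2)
    scores = rule_based_scores(result, cohort.data)
    assert np.allclose(scores, 0.5, atol=0.15)


def test_cv_on_separable_planted_cohort_is_perfect(schema):
    rng = np.random.default_rng(2)
    cohort = planted_cohort(schema, 600, planted_labeler_2rule, 0.0, rng)
    report = cross_validate(cohort, RerxConfig(), k=5, runs=1, seed=3)
    assert report.aggregate()["test_acc_pct"]["mean"] >= 99.0
    assert len(report.cells) == 5


def test_cv_on_shuffled_labels_matches_majority_rate():
    """Permutation null: no signal means accuracy near the majority rate."""
    cohort = generate_cohort(default_cohort_spec(), seed=8)
    rng = np.random.default_rng(1)
    y = cohort.labels.to_numpy().copy()
    rng.shuffle(y)
    cohort.data["class"] = y
    report = cross_validate(cohort, RerxConfig(), k=5, runs=1, seed=2)
    majority = 100.0 * 942 / 1466
    assert abs(report.aggregate()["test_acc_pct"]["mean"] - majority) <= 3.0


def test_fold_partition_and_stratification(schema):
    rng = np.random.default_rng(3)
    cohort = planted_cohort(schema, 300, planted_labeler_2rule, 0.1, rng)
    from sklearn.model_selection import StratifiedKFold
    y = cohort.labels.to_numpy()
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    seen = np.zeros(len(y), dtype=int)
    overall = (y == "diabetes").mean()
    for _, te in skf.split(np.zeros(len(y)), y):
        seen[te] += 1
        frac = (y[te] == "diabetes").mean()
        assert abs(frac * len(te) - overall * len(te)) <= 1.0
    assert (seen == 1).all()


def test_report_aggregates_recompute_from_cells(schema):
    rng = np.random.default_rng(4)
    cohort = planted_cohort(schema, 300, planted_labeler_2rule, 0.1, rng)
    report = cross_validate(cohort, RerxConfig(), k=3, runs=2, seed=5)
    assert len(report.cells) == 6
    agg = report.aggregate()
    for col in ("train_acc_pct", "test_acc_pct", "n_rules", "auc_pct"):
        v = report.cells[col].to_numpy(dtype=float)
        assert agg[col]["mean"] == v.mean()
        assert agg[col]["sd"] == v.std(ddof=1)


def test_cv_input_validation(schema):
    rng = np.random.default_rng(5)
    cohort = planted_cohort(schema, 60, planted_labeler_2rule, 0.0, rng)
    with pytest.raises(ValueError):
        cross_validate(cohort, k=1)
    tiny = make_cohort(schema, ["diabetes"] * 20 + ["prediabetes"] * 2)
    with pytest.raises(ValueError, match="larger cohort|folds"):
        cross_validate(tiny, k=5)


def test_identical_groups_are_not_significant(schema):
    half = make_cohort(schema, ["diabetes"] * 30)
    data = half.data.copy()
    rng = np.random.default_rng(6)
    for attr in schema.continuous():
        data[attr.name] = rng.uniform(attr.range[0], attr.range[1], 30)
    mirrored = data.copy()
    mirrored["class"] = "prediabetes"
    import pandas as pd
    cohort = Cohort(schema, pd.concat([data, mirrored], ignore_index=True))
    comp = compare_groups(cohort)
    tested = comp.table[comp.table["p_value"].notna()]
    assert (tested["p_value"] > 0.9).all()


def test_synthetic_cohort_group_comparison_recovers_effects():
    cohort = generate_cohort(default_cohort_spec(), seed=9)
    comp = compare_groups(cohort)
    table = comp.table.set_index("attribute")
    assert table.loc["HbA1c", "p_value"] < 1e-4
    assert table.loc["FPG", "test"] == "rank-sum"
    assert table.loc["FPG", "p_value"] < 1e-4
    assert table.loc["race_ethnicity", "test"] == "chi-square"
    # uninformative-by-construction attribute: alcohol shares its law
    assert table.loc["alcohol", "p_value"] > 0.01


def test_chi_square_matches_hand_computation(schema):
    labels = ["diabetes"] * 40 + ["prediabetes"] * 40
    sex = ["male"] * 30 + ["female"] * 10 + ["male"] * 15 + ["female"] * 25
    cohort = make_cohort(schema, labels, sex=sex)
    comp = compare_groups(cohort)
    row = comp.table.set_index("attribute").loc["sex"]
    stat, p = sps.chi2_contingency([[30, 10], [15, 25]])[:2]
    assert row["statistic"] == pytest.approx(stat)
    assert row["p_value"] == pytest.approx(p)


def test_constant_attribute_flagged_not_tested(schema):
    cohort = make_cohort(schema, ["diabetes"] * 10 + ["prediabetes"] * 10)
    comp = compare_groups(cohort)
    row = comp.table.set_index("attribute").loc["waist"]
    assert "constant" in row["test"]
    assert np.isnan(row["p_value"])


def test_bonferroni_flag_adds_adjusted_column():
    cohort = generate_cohort(
        default_cohort_spec().model_copy(
            update={"n_diabetes": 100, "n_prediabetes": 100}), seed=10)
    comp = compare_groups(cohort, bonferroni=True)
    assert "p_adjusted" in comp.table.columns
    ok = comp.table["p_adjusted"].notna()
    assert (comp.table.loc[ok, "p_adjusted"] >= comp.table.loc[ok, "p_value"] - 1e-12).all()
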