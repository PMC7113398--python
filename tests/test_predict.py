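"""Feature matrices, CV median-split evaluation, wrapper selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, RegressorMixin

from hlasurv.predict import (
    FeatureSetSpec,
    RegressorSpec,
    cv_evaluate,
    external_validate,
    make_feature_matrix,
    make_preset,
    wrapper_select,
)
from hlasurv.simulate import ClinicalEffects, SimulationConfig, simulate_cohort


class LookupRegressor(BaseEstimator, RegressorMixin):
    """Oracle: returns a pre-stored target for each known feature row."""

    def __init__(self, table=None):
        self.table = table  # mapping rounded-row-tuple -> value

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.table[tuple(np.round(row, 6))] for row in X])


class ConstantRegressor(BaseEstimator, RegressorMixin):
    def __init__(self, value=50.0):
        self.value = value

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(X.shape[0], self.value)


class NoiseRegressor(BaseEstimator, RegressorMixin):
    """Predictions independent of the features (and of survival)."""

    def __init__(self, seed=0):
        self.seed = seed

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.random.default_rng(self.seed + X.shape[0]).normal(50, 10, X.shape[0])


@pytest.fixture(scope="module")
def effect_cohort():
    cfg = SimulationConfig(
        n_patients=400,
        superallele_freqs={
            "HLA-B*50": 0.3,
            "HLA-A*24": 0.25,
            "HLA-A*01": 0.3,
            "HLA-DQB1*03": 0.5,
        },
        planted_loghr={"HLA-B*50": 1.0, "HLA-A*24": 0.6, "HLA-A*01": -0.7},
        clinical_effects=ClinicalEffects(
            age_per_decade=0.2, stage_3_4=0.6, with_tumor=1.0, breslow_gt3=0.6
        ),
        baseline_scale=80.0,
        censoring_rate=0.015,
        admin_cap=150.0,
        seed=99,
    )
    return simulate_cohort(cfg)[0]


def test_preset_column_counts(effect_cohort):
    screened = ["HLA-B*50", "HLA-A*24", "HLA-A*01", "HLA-DQB1*03"]
    X1, _, _ = make_feature_matrix(effect_cohort, make_preset("SET1"))
    assert X1.shape[1] == 5
    X2, _, _ = make_feature_matrix(effect_cohort, make_preset("SET2", screened))
    assert X2.shape[1] == 5 + len(screened)
    spec_c1 = make_preset("CLASS1_ONLY", screened)
    assert set(spec_c1.superalleles) == {"HLA-B*50", "HLA-A*24", "HLA-A*01"}
    spec_a = make_preset("EXTERNAL_SET_A", screened)
    assert spec_a.clinical_fields == ("age", "gender", "stage")
    assert make_preset("NO_STAGE_STATUS", screened).clinical_fields == (
        "age", "gender", "breslow",
    )


def test_preset_unknown_name():
    with pytest.raises(ValueError, match="preset"):
        make_preset("SET99")


def test_feature_matrix_superallele_columns_binary(effect_cohort):
    X, y, ev = make_feature_matrix(
        effect_cohort, FeatureSetSpec(("age",), ("HLA-B*50",))
    )
    assert set(np.unique(X["HLA-B*50"])) <= {0.0, 1.0}
    assert len(X) == len(y) == len(ev)


def test_feature_matrix_missing_superallele_raises(effect_cohort):
    with pytest.raises(KeyError, match="HLA-B*99".replace("*", r"\*")):
        make_feature_matrix(effect_cohort, FeatureSetSpec(("age",), ("HLA-B*99",)))


def test_feature_matrix_empty_spec_rejected(effect_cohort):
    with pytest.raises(ValueError, match="empty"):
        make_feature_matrix(effect_cohort, FeatureSetSpec((), ()))


def test_oracle_regressor_beats_noise(effect_cohort):
    """Predicting the true outcome stratifies at least as well as noise."""
    spec = FeatureSetSpec()
    X, y, _ = make_feature_matrix(effect_cohort, spec)
    table = {tuple(np.round(row, 6)): val for row, val in zip(X.to_numpy(), y.to_numpy())}
    assert len(table) == len(X)  # rows unique, lookup well defined
    oracle = cv_evaluate(effect_cohort, spec, LookupRegressor(table), seed=5)
    noise = cv_evaluate(effect_cohort, spec, NoiseRegressor(seed=5), seed=5)
    assert not oracle.degenerate
    assert oracle.group_hr.hr > 1
    assert oracle.group_hr.p < 1e-4
    assert noise.degenerate or oracle.group_hr.hr >= noise.group_hr.hr


def test_constant_prediction_degenerate_flagged(effect_cohort):
    ev = cv_evaluate(effect_cohort, FeatureSetSpec(), ConstantRegressor(), seed=1)
    assert ev.degenerate
    assert ev.group_hr is None
    assert np.isnan(ev.hr)


def test_cv_reproducible_and_partitioning(effect_cohort):
    spec = make_preset("SET2", ["HLA-B*50", "HLA-A*01"])
    reg = RegressorSpec("lasso", {"alpha": 0.1})
    a = cv_evaluate(effect_cohort, spec, reg, seed=7)
    b = cv_evaluate(effect_cohort, spec, reg, seed=7)
    pd.testing.assert_series_equal(a.fold_assignment, b.fold_assignment)
    pd.testing.assert_series_equal(a.oof_pred, b.oof_pred)
    assert a.hr == b.hr
    # every patient predicted exactly once; labels partition the cohort
    assert a.oof_pred.notna().all()
    assert a.labels.sum() + (~a.labels).sum() == len(a.oof_pred)
    c = cv_evaluate(effect_cohort, spec, reg, seed=8)
    assert not a.fold_assignment.equals(c.fold_assignment)


def test_median_split_sizes_nearly_balanced(effect_cohort):
    ev = cv_evaluate(
        effect_cohort, FeatureSetSpec(), RegressorSpec("lasso", {"alpha": 0.1}), seed=3
    )
    n = len(ev.labels)
    ties = int((ev.oof_pred == ev.cutoff).sum())
    assert abs(int(ev.labels.sum()) - n // 2) <= ties + 1


def test_per_fold_mode_reports_fold_hrs(effect_cohort):
    ev = cv_evaluate(
        effect_cohort, FeatureSetSpec(), RegressorSpec("lasso", {"alpha": 0.1}),
        seed=3, per_fold=True,
    )
    assert ev.fold_hrs is not None and len(ev.fold_hrs) == 5


def test_wrapper_trajectory_strictly_increasing(effect_cohort):
    res = wrapper_select(
        effect_cohort,
        FeatureSetSpec(),
        ["HLA-B*50", "HLA-A*24", "HLA-A*01", "HLA-DQB1*03"],
        RegressorSpec("lasso", {"alpha": 0.05}),
        seed=2,
    )
    traj = res.hr_trajectory
    assert all(b > a for a, b in zip(traj, traj[1:]))
    assert len(traj) == len(res.selected) + 1
    assert len(res.selected) <= 4


def test_wrapper_no_improvement_returns_empty(effect_cohort):
    # constant predictions can never improve on the base HR
    res = wrapper_select(
        effect_cohort, FeatureSetSpec(), ["HLA-B*50"], ConstantRegressor(), seed=0
    )
    assert res.selected == []
    assert len(res.hr_trajectory) == 1


def test_wrapper_empty_pool_rejected(effect_cohort):
    with pytest.raises(ValueError):
        wrapper_select(effect_cohort, FeatureSetSpec(), [], RegressorSpec("lasso"), seed=0)


def test_external_validate_identity_and_independent(effect_cohort):
    cfg2 = SimulationConfig(
        n_patients=300,
        superallele_freqs={
            "HLA-B*50": 0.3, "HLA-A*24": 0.25, "HLA-A*01": 0.3, "HLA-DQB1*03": 0.5,
        },
        planted_loghr={"HLA-B*50": 1.0, "HLA-A*24": 0.6, "HLA-A*01": -0.7},
        clinical_effects=ClinicalEffects(
            age_per_decade=0.2, stage_3_4=0.6, with_tumor=1.0, breslow_gt3=0.6
        ),
        baseline_scale=80.0,
        censoring_rate=0.015,
        admin_cap=150.0,
        seed=100,  # fresh draw from the same generating process
    )
    test_cohort, _ = simulate_cohort(cfg2)
    spec = make_preset("SET2", ["HLA-B*50", "HLA-A*24", "HLA-A*01"])
    reg = RegressorSpec("lasso", {"alpha": 0.05})
    same = external_validate(effect_cohort, effect_cohort, spec, reg, seed=1)
    assert not same["test_degenerate"]
    assert same["test"].hr > 1
    indep = external_validate(effect_cohort, test_cohort, spec, reg, seed=1)
    assert not indep["test_degenerate"]
    assert indep["test"].hr > 1


def test_external_validate_missing_feature_errors(effect_cohort):
    cfg = SimulationConfig(
        n_patients=120,
        superallele_freqs={"HLA-A*02": 0.5, "HLA-DQB1*03": 0.5},
        baseline_scale=70.0,
        seed=5,
    )
    other, _ = simulate_cohort(cfg)
    spec = FeatureSetSpec(("age",), ("HLA-B*50",))
    with pytest.raises(KeyError, match="HLA-B*50".replace("*", r"\*")):
        external_validate(effect_cohort, other, spec, RegressorSpec("lasso", {"alpha": 0.1}))
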