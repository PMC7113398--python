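"""OS-regression models, cross-validated HR evaluation, wrapper selection.

Regressors (lasso, ridge, random forest, decision tree) are trained to
predict overall-survival months from clinical covariates and binary
superallele carriage.  A model is scored by stratification power, not
squared error: out-of-fold predictions from 5-fold cross-validation are
pooled, split at their median (high-risk = predicted OS strictly below
the median; ties go low-risk), and the Cox hazard ratio with log-rank p
is computed between the resulting groups on the true outcomes.

The wrapper is a greedy forward search over candidate superalleles: at
each step every remaining candidate is appended to the current feature
set and evaluated; the best candidate is adopted only if it strictly
raises the HR, so the recorded HR trajectory is strictly increasing and
the search always terminates.  Fold assignment is frozen for the whole
search so candidate comparisons are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV, Ridge, RidgeCV
from sklearn.tree import DecisionTreeRegressor

from .cohort import Cohort, encode_clinical_binary
from .nomenclature import CLASS_I, parse_allele
from .survstats import GroupHR, group_hazard_ratio

__all__ = [
    "CLINICAL_FIELDS",
    "FeatureSetSpec",
    "RegressorSpec",
    "CVEvaluation",
    "WrapperResult",
    "make_preset",
    "make_feature_matrix",
    "make_regressor",
    "cv_evaluate",
    "wrapper_select",
    "external_validate",
]

log = logging.getLogger(__name__)

CLINICAL_FIELDS = ("age", "gender", "stage", "tumor_status", "breslow")

_FIELD_COLUMNS = {
    "age": "age",
    "gender": "female",
    "stage": "stage_3_4",
    "tumor_status": "with_tumor",
    "breslow": "breslow_depth",
}


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which clinical fields and superalleles enter the design matrix."""

    clinical_fields: tuple[str, ...] = CLINICAL_FIELDS
    superalleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.clinical_fields) - set(CLINICAL_FIELDS)
        if unknown:
            raise ValueError(f"unknown clinical fields: {sorted(unknown)}")

    def with_superallele(self, sa: str) -> "FeatureSetSpec":
        return replace(self, superalleles=self.superalleles + (sa,))


PRESET_NAMES = (
    "SET1",
    "SET2",
    "NO_STATUS",
    "NO_STAGE",
    "NO_STAGE_STATUS",
    "CLASS1_ONLY",
    "EXTERNAL_SET_A",
    "EXTERNAL_SET_B",
)


def make_preset(
    name: str,
    screened: Sequence[str] = (),
    selected: Sequence[str] = (),
) -> FeatureSetSpec:
    """Expand a named feature-set preset.

    ``screened`` is the SF+SU superallele list from the screen (needed
    by every preset except SET1); ``selected`` is a wrapper-selected
    list (needed by EXTERNAL_SET_B).  Expansions are deterministic and
    logged.
    """
    name = name.upper()
    screened = tuple(screened)
    if name == "SET1":
        spec = FeatureSetSpec(CLINICAL_FIELDS, ())
    elif name == "SET2":
        spec = FeatureSetSpec(CLINICAL_FIELDS, screened)
    elif name == "NO_STATUS":
        spec = FeatureSetSpec(
            tuple(f for f in CLINICAL_FIELDS if f != "tumor_status"), screened
        )
    elif name == "NO_STAGE":
        spec = FeatureSetSpec(tuple(f for f in CLINICAL_FIELDS if f != "stage"), screened)
    elif name == "NO_STAGE_STATUS":
        spec = FeatureSetSpec(
            tuple(f for f in CLINICAL_FIELDS if f not in ("stage", "tumor_status")),
            screened,
        )
    elif name == "CLASS1_ONLY":
        class1 = tuple(s for s in screened if parse_allele(s).gene in CLASS_I)
        spec = FeatureSetSpec(CLINICAL_FIELDS, class1)
    elif name == "EXTERNAL_SET_A":
        spec = FeatureSetSpec(("age", "gender", "stage"), screened)
    elif name == "EXTERNAL_SET_B":
        spec = FeatureSetSpec(("age", "gender", "stage"), tuple(selected))
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    log.info("preset %s -> clinical=%s, %d superalleles", name, spec.clinical_fields,
             len(spec.superalleles))
    return spec


def make_feature_matrix(
    cohort: Cohort,
    spec: FeatureSetSpec,
    binarize_continuous: bool = False,
    fill_missing_superalleles: bool = False,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Build (X, os_months, event) for a feature-set spec.

    Gender / stage / tumor status enter as the standard indicators;
    age and Breslow depth enter as raw numerics unless
    ``binarize_continuous`` (then the >60 / >3 mm indicators).
    Superalleles are 0/1 carriage columns.  Rows with any missing
    required feature are dropped (logged).  Superalleles absent from
    the cohort raise unless ``fill_missing_superalleles``.
    """
    if not spec.clinical_fields and not spec.superalleles:
        raise ValueError("empty feature set")
    enc = encode_clinical_binary(cohort)
    cols = {}
    for fld in spec.clinical_fields:
        if fld in ("age", "breslow") and not binarize_continuous:
            cols[_FIELD_COLUMNS[fld]] = cohort.clinical[_FIELD_COLUMNS[fld]]
        else:
            binmap = {"age": "age_gt60", "breslow": "breslow_gt3"}
            col = binmap.get(fld, _FIELD_COLUMNS[fld])
            cols[col] = enc[col]
    X = pd.DataFrame(cols, index=cohort.clinical.index)

    missing_sa = [s for s in spec.superalleles if s not in cohort.presence.columns]
    if missing_sa and not fill_missing_superalleles:
        raise KeyError(f"superalleles missing from cohort presence matrix: {missing_sa}")
    for sa in spec.superalleles:
        if sa in cohort.presence.columns:
            X[sa] = cohort.presence[sa].astype(float)
        else:
            X[sa] = 0.0

    keep = X.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d patients with missing features", n_drop)
    X = X.loc[keep]
    if X.empty:
        raise ValueError("all rows dropped: every patient misses some required feature")
    y = cohort.os_months.loc[keep].astype(float)
    ev = cohort.event.loc[keep].astype(int)
    return X, y, ev


@dataclass(frozen=True)
class RegressorSpec:
    """A regressor kind plus hyperparameters.

    With no explicit penalty, lasso/ridge choose it by inner
    cross-validation on the training folds; forest/tree use library
    defaults with the run seed.
    """

    kind: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("lasso", "ridge", "random_forest", "decision_tree"):
            raise ValueError(f"unknown regressor kind {self.kind!r}")


def make_regressor(spec: RegressorSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.kind == "lasso":
        if "alpha" in hp:
            return Lasso(max_iter=50_000, **hp)
        return LassoCV(cv=3, alphas=30, max_iter=50_000, random_state=seed, **hp)
    if spec.kind == "ridge":
        if "alpha" in hp:
            return Ridge(**hp)
        return RidgeCV(alphas=np.logspace(-3, 3, 13), **hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=seed, **hp)
    return DecisionTreeRegressor(random_state=seed, **hp)


def _resolve_regressor(regressor, seed: int):
    """A RegressorSpec builds a fresh estimator; anything else is cloned."""
    if isinstance(regressor, RegressorSpec):
        return make_regressor(regressor, seed)
    return clone(regressor)


@dataclass
class CVEvaluation:
    """Pooled out-of-fold median-split evaluation of one model."""

    fold_assignment: pd.Series
    oof_pred: pd.Series
    cutoff: float
    labels: pd.Series  # True = high-risk (predicted OS < median)
    group_hr: GroupHR | None
    degenerate: bool
    fold_hrs: list[GroupHR | None] | None = None

    @property
    def hr(self) -> float:
        return np.nan if self.group_hr is None else self.group_hr.hr


def _assign_folds(index: pd.Index, k: int, seed: int) -> pd.Series:
    rng = np.random.default_rng(seed)
    n = len(index)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return pd.Series(folds, index=index, name="fold")


def cv_evaluate(
    cohort: Cohort,
    spec: FeatureSetSpec,
    regressor: RegressorSpec,
    k: int = 5,
    seed: int = 0,
    fold_assignment: pd.Series | None = None,
    per_fold: bool = False,
    ties: str = "efron",
) -> CVEvaluation:
    """k-fold CV; pooled out-of-fold predictions split at their median.

    High-risk = predicted OS strictly below the pooled median (ties at
    the median go low-risk).  ``fold_assignment`` overrides the seeded
    random partition (used by the wrapper to pair comparisons).  With
    ``per_fold`` the per-fold median-split HRs are recorded as well.
    """
    X, y, ev = make_feature_matrix(cohort, spec)
    n = len(X)
    if n < 2 * k:
        raise ValueError(f"need at least {2*k} usable patients for {k}-fold CV, have {n}")
    if fold_assignment is None:
        folds = _assign_folds(X.index, k, seed)
    else:
        folds = fold_assignment.loc[X.index]
    oof = pd.Series(np.nan, index=X.index, name="oof_pred")
    for f in sorted(folds.unique()):
        test = folds == f
        model = _resolve_regressor(regressor, seed)
        try:
            model.fit(X.loc[~test].to_numpy(), y.loc[~test].to_numpy())
        except Exception as exc:
            raise RuntimeError(f"regressor failed on fold {f}: {exc}") from exc
        oof.loc[test] = model.predict(X.loc[test].to_numpy())
    cutoff = float(np.median(oof.to_numpy()))
    labels = (oof < cutoff).rename("high_risk")
    degenerate = labels.all() or not labels.any()
    ghr = None
    if not degenerate:
        # a sharp predictor can quasi-separate the split; report the flagged
        # fit rather than erroring out of an evaluation
        ghr = group_hazard_ratio(
            y.to_numpy(), ev.to_numpy(), labels.to_numpy(), ties=ties,
            on_separation="return",
        )
    fold_hrs = None
    if per_fold:
        fold_hrs = []
        for f in sorted(folds.unique()):
            test = folds == f
            pf = oof.loc[test]
            lab = (pf < float(np.median(pf.to_numpy()))).to_numpy()
            if lab.all() or not lab.any() or ev.loc[test].sum() == 0:
                fold_hrs.append(None)
                continue
            fold_hrs.append(
                group_hazard_ratio(
                    y.loc[test].to_numpy(), ev.loc[test].to_numpy(), lab,
                    ties=ties, on_separation="return",
                )
            )
    return CVEvaluation(
        fold_assignment=folds,
        oof_pred=oof,
        cutoff=cutoff,
        labels=labels,
        group_hr=ghr,
        degenerate=bool(degenerate),
        fold_hrs=fold_hrs,
    )


@dataclass
class WrapperResult:
    selected: list[str]
    hr_trajectory: list[float]  # base HR first, then after each adoption
    evaluations: list[CVEvaluation]

    @property
    def final_hr(self) -> float:
        return self.hr_trajectory[-1]


def wrapper_select(
    cohort: Cohort,
    base_spec: FeatureSetSpec,
    candidates: Sequence[str],
    regressor: RegressorSpec,
    k: int = 5,
    seed: int = 0,
    refreeze_folds: bool = False,
) -> WrapperResult:
    """Greedy forward HR-maximizing superallele selection.

    Starting from ``base_spec``, each step evaluates every remaining
    candidate appended to the current set and adopts the one with the
    highest HR provided it strictly exceeds the incumbent HR; the
    search stops at the first step with no improvement.  Fold
    assignment is fixed across the whole search unless
    ``refreeze_folds`` re-randomizes it (seeded) at every step.
    """
    if len(candidates) == 0:
        raise ValueError("candidate pool is empty")
    X0, _, _ = make_feature_matrix(
        cohort,
        replace(base_spec, superalleles=base_spec.superalleles + tuple(candidates)),
    )
    folds = _assign_folds(X0.index, k, seed)

    current = base_spec
    base_eval = cv_evaluate(cohort, current, regressor, k=k, seed=seed, fold_assignment=folds)
    incumbent = -np.inf if base_eval.degenerate else base_eval.hr
    trajectory = [incumbent]
    evaluations = [base_eval]
    selected: list[str] = []
    remaining = list(dict.fromkeys(candidates))
    step = 0
    while remaining:
        step += 1
        if refreeze_folds:
            folds = _assign_folds(X0.index, k, seed + step)
        best_sa, best_eval, best_hr = None, None, -np.inf
        for sa in remaining:
            ev = cv_evaluate(
                cohort, current.with_superallele(sa), regressor,
                k=k, seed=seed, fold_assignment=folds,
            )
            hr = -np.inf if ev.degenerate else ev.hr
            if hr > best_hr:
                best_sa, best_eval, best_hr = sa, ev, hr
        if best_sa is None or best_hr <= incumbent:
            break
        current = current.with_superallele(best_sa)
        selected.append(best_sa)
        remaining.remove(best_sa)
        incumbent = best_hr
        trajectory.append(best_hr)
        evaluations.append(best_eval)
        log.info("wrapper step %d: adopted %s (HR %.3f)", step, best_sa, best_hr)
    return WrapperResult(selected=selected, hr_trajectory=trajectory, evaluations=evaluations)


def external_validate(
    train_cohort: Cohort,
    test_cohort: Cohort,
    spec: FeatureSetSpec,
    regressor: RegressorSpec,
    k: int = 5,
    seed: int = 0,
    fill_missing_superalleles: bool = False,
) -> dict:
    """Train on one cohort, stratify another by its own prediction median.

    Returns ``{"train_cv": CVEvaluation, "test": GroupHR | None,
    "test_labels": Series, "test_degenerate": bool}``.  The model is
    refit on the full training cohort for the external predictions;
    the training entry reports the in-cohort CV evaluation.
    """
    train_cv = cv_evaluate(train_cohort, spec, regressor, k=k, seed=seed)
    Xtr, ytr, _ = make_feature_matrix(train_cohort, spec)
    Xte, yte, evte = make_feature_matrix(
        test_cohort, spec, fill_missing_superalleles=fill_missing_superalleles
    )
    missing_cols = [c for c in Xtr.columns if c not in Xte.columns]
    if missing_cols:
        raise KeyError(f"test cohort lacks feature columns: {missing_cols}")
    model = _resolve_regressor(regressor, seed)
    model.fit(Xtr.to_numpy(), ytr.to_numpy())
    pred = model.predict(Xte[Xtr.columns].to_numpy())
    cutoff = float(np.median(pred))
    labels = pd.Series(pred < cutoff, index=Xte.index, name="high_risk")
    degenerate = bool(labels.all() or not labels.any())
    test_hr = None
    if not degenerate:
        test_hr = group_hazard_ratio(
            yte.to_numpy(), evte.to_numpy(), labels.to_numpy(), on_separation="return"
        )
    return {
        "train_cv": train_cv,
        "test": test_hr,
        "test_labels": labels,
        "test_degenerate": degenerate,
    }
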