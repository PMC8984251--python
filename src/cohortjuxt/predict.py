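"""Within- and cross-center prediction of the post-treatment score.

The target is the TQ total score at the final visit (TQ_t1).  The basic
predictors are the pre-treatment variables shared by both centers -- age,
gender (male = 1, female = 0) and the admission score TQ_t0 -- optionally
augmented by one of the four adherence feature sets.  Patients without a
complete TQ at both time points, or with unknown gender, are excluded.

Four model families are compared: ordinary least squares (LR), lasso,
ridge and a radial-kernel support vector regressor (SVR).  Hyperparameters
are chosen by 10-fold cross-validated grid search (minimizing MSE) inside
the training split only; the held-out data never influences selection.
Penalized and kernel models see standardized features (training-split
statistics); plain least squares runs on the raw scale.  Reports carry
MAE, MSE and R-squared for all four families on the evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .adherence import adherence_features
from .cohort_model import Cohort, filter_complete, total_score

__all__ = [
    "FeatureSpec",
    "FamilyResult",
    "PredictionReport",
    "AUGMENTATIONS",
    "MODEL_FAMILIES",
    "assemble",
    "metrics",
    "fit_within",
    "fit_cross",
    "ablation",
]

AUGMENTATIONS = ("none", "set1", "set2", "set3", "set4")
MODEL_FAMILIES = ("LR", "lasso", "ridge", "SVR")

GENDER_CODING = "male=1,female=0"


@dataclass(frozen=True)
class FeatureSpec:
    """Basic predictors (age, gender, TQ_t0) plus one adherence augmentation."""

    augmentation: str = "none"
    questionnaire: str = "TQ"

    def __post_init__(self):
        if self.augmentation not in AUGMENTATIONS:
            raise ValueError(f"unknown augmentation {self.augmentation!r}")

    @property
    def label(self) -> str:
        if self.augmentation == "none":
            return "basic"
        return f"basic+{self.augmentation}"


@dataclass(frozen=True)
class FamilyResult:
    family: str
    params: dict
    mae: float
    mse: float
    r2: float
    coefficients: dict | None = None  # populated for LR


@dataclass
class PredictionReport:
    train_label: str
    test_label: str
    feature_spec: str
    families: dict[str, FamilyResult]
    best_family: str
    n_train: int
    n_test: int
    gender_coding: str = GENDER_CODING
    seed: int | None = None

    @property
    def best(self) -> FamilyResult:
        return self.families[self.best_family]


def metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(MAE, MSE, R-squared) of predictions against observed values."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.size == 0 or yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if np.ptp(yt) == 0:
        raise ValueError("constant y_true: R-squared is undefined")
    return (
        float(mean_absolute_error(yt, yp)),
        float(mean_squared_error(yt, yp)),
        float(r2_score(yt, yp)),
    )


def assemble(cohort: Cohort, spec: FeatureSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and target vector for one cohort under one feature spec.

    Keeps patients with a complete TQ at both time points and known gender.
    The augmentation columns are restricted to shared questionnaires and
    categories, so the same columns exist for any cohort on the same
    catalog -- the requirement for cross-center transfer.
    """
    q = spec.questionnaire
    complete = filter_complete(cohort, q, ("t0", "t1"))
    catalog = cohort.catalog
    rows = []
    index = []
    for rec in sorted(complete.records, key=lambda r: r.patient_id):
        if rec.gender not in ("f", "m"):
            continue
        row = {
            "age": float(rec.age),
            "male": 1.0 if rec.gender == "m" else 0.0,
            f"{q}_t0": float(total_score(rec, catalog, q, "t0")),
        }
        if spec.augmentation != "none":
            f = adherence_features(rec, catalog)
            if spec.augmentation == "set1":
                row["set1"] = float(f.set1)
            elif spec.augmentation == "set2":
                row.update({f"set2_{k}": float(v) for k, v in sorted(f.set2.items())})
            elif spec.augmentation == "set3":
                row.update({f"set3_{k}": float(v) for k, v in sorted(f.set3.items())})
            elif spec.augmentation == "set4":
                row["set4"] = float(f.set4)
        row["_target"] = float(total_score(rec, catalog, q, "t1"))
        rows.append(row)
        index.append(rec.patient_id)
    if not rows:
        raise ValueError("no usable patients after exclusions")
    df = pd.DataFrame(rows, index=index)
    y = df.pop("_target")
    return df, y


def _candidates(cv_grids: dict | None = None) -> dict[str, tuple]:
    """(estimator, parameter grid) per model family.

    The grids are conventional wide defaults; pass ``cv_grids`` to
    override any family's grid.
    """
    alphas = np.logspace(-3, 3, 13)
    grids = {
        "LR": (LinearRegression(), {}),
        "lasso": (
            Pipeline([("scale", StandardScaler()), ("model", Lasso(max_iter=50000))]),
            {"model__alpha": alphas},
        ),
        "ridge": (
            Pipeline([("scale", StandardScaler()), ("model", Ridge())]),
            {"model__alpha": alphas},
        ),
        "SVR": (
            Pipeline([("scale", StandardScaler()), ("model", SVR(kernel="rbf"))]),
            {
                "model__C": [0.1, 1.0, 10.0, 100.0],
                "model__gamma": ["scale", 1e-3, 1e-2, 1e-1, 1.0],
            },
        ),
    }
    if cv_grids:
        for family, grid in cv_grids.items():
            grids[family] = (grids[family][0], grid)
    return grids


def _select_and_fit(X_train, y_train, families, cv_folds, seed, cv_grids=None):
    """Grid-search each family on the training data; refit on all of it."""
    if len(X_train) < cv_folds:
        raise ValueError(
            f"{len(X_train)} training rows cannot support {cv_folds}-fold CV"
        )
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fitted = {}
    for family in families:
        est, grid = _candidates(cv_grids)[family]
        if grid:
            search = GridSearchCV(
                est, grid, cv=cv, scoring="neg_mean_squared_error", refit=True
            )
            search.fit(X_train, y_train)
            fitted[family] = (search.best_estimator_, dict(search.best_params_))
        else:
            fitted[family] = (est.fit(X_train, y_train), {})
    return fitted


def _evaluate(fitted, X_test, y_test) -> dict[str, FamilyResult]:
    out = {}
    for family, (model, params) in fitted.items():
        mae, mse, r2 = metrics(y_test, model.predict(X_test))
        coefficients = None
        if family == "LR":
            coefficients = {"intercept": float(model.intercept_)}
            coefficients.update(
                {c: float(v) for c, v in zip(X_test.columns, model.coef_)}
            )
        out[family] = FamilyResult(
            family=family, params=params, mae=mae, mse=mse, r2=r2,
            coefficients=coefficients,
        )
    return out


def _report(train_label, test_label, spec, results, n_train, n_test, seed):
    best = max(results.values(), key=lambda r: r.r2).family
    return PredictionReport(
        train_label=train_label,
        test_label=test_label,
        feature_spec=spec.label,
        families=results,
        best_family=best,
        n_train=n_train,
        n_test=n_test,
        seed=seed,
    )


def fit_within(
    cohort: Cohort,
    spec: FeatureSpec,
    test_size: float = 0.2,
    cv_folds: int = 10,
    seed: int = 0,
    families=MODEL_FAMILIES,
    cv_grids: dict | None = None,
    label: str | None = None,
) -> PredictionReport:
    """Single-center experiment: seeded held-out split, CV model selection.

    Each family's hyperparameters are tuned by ``cv_folds``-fold CV on the
    training split; every family is then refit on the full training split
    and scored on the held-out patients.  The report carries all families
    and flags the one with the best held-out R-squared.
    """
    X, y = assemble(cohort, spec)
    if len(X) < 20:
        raise ValueError(f"need at least 20 usable patients, got {len(X)}")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, random_state=seed
    )
    fitted = _select_and_fit(X_train, y_train, families, cv_folds, seed, cv_grids)
    results = _evaluate(fitted, X_test, y_test)
    name = label or "/".join(cohort.centers)
    return _report(name, name, spec, results, len(X_train), len(X_test), seed)


def _gender_subset(cohort: Cohort, gender: str) -> Cohort:
    if gender == "all":
        return cohort
    if gender not in ("f", "m"):
        raise ValueError(f"gender filter must be 'all', 'f' or 'm', got {gender!r}")
    return Cohort(
        records=[r for r in cohort.records if r.gender == gender],
        catalog=cohort.catalog,
        provenance=dict(cohort.provenance),
    )


def fit_cross(
    train_cohort: Cohort,
    test_cohort: Cohort,
    spec: FeatureSpec,
    train_gender: str = "all",
    test_gender: str = "all",
    cv_folds: int = 10,
    seed: int = 0,
    families=MODEL_FAMILIES,
    cv_grids: dict | None = None,
) -> PredictionReport:
    """Transfer experiment: select and fit on one cohort, score on the other.

    Model selection happens entirely within the training cohort; the test
    cohort is only ever used for scoring.  Either side can be restricted to
    one gender.
    """
    X_train, y_train = assemble(_gender_subset(train_cohort, train_gender), spec)
    X_test, y_test = assemble(_gender_subset(test_cohort, test_gender), spec)
    if list(X_train.columns) != list(X_test.columns):
        raise ValueError(
            "train and test cohorts disagree on feature columns; the "
            "augmentation must be restricted to shared questionnaires/categories"
        )
    fitted = _select_and_fit(X_train, y_train, families, cv_folds, seed, cv_grids)
    results = _evaluate(fitted, X_test, y_test)
    train_label = f"{'/'.join(train_cohort.centers)}:{train_gender}"
    test_label = f"{'/'.join(test_cohort.centers)}:{test_gender}"
    return _report(train_label, test_label, spec, results, len(X_train), len(X_test), seed)


def ablation(
    train_cohort: Cohort,
    test_cohort: Cohort | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    families=MODEL_FAMILIES,
) -> list[PredictionReport]:
    """Full experiment grid over the five feature specs.

    Within-center mode (``test_cohort is None``): one report per feature
    spec on a held-out split of ``train_cohort``.  Cross-center mode: the
    three training regimes (all patients, female only, male only) are
    evaluated on the matching test subgroups -- the all-trained model on
    all/f/m test patients, the single-gender models on their own gender.
    """
    specs = [FeatureSpec(augmentation=a) for a in AUGMENTATIONS]
    reports = []
    if test_cohort is None:
        for spec in specs:
            reports.append(
                fit_within(train_cohort, spec, cv_folds=cv_folds, seed=seed,
                           families=families)
            )
        return reports
    regimes = [("all", ("all", "f", "m")), ("f", ("f",)), ("m", ("m",))]
    for train_gender, test_genders in regimes:
        for spec in specs:
            for test_gender in test_genders:
                reports.append(
                    fit_cross(
                        train_cohort,
                        test_cohort,
                        spec,
                        train_gender=train_gender,
                        test_gender=test_gender,
                        cv_folds=cv_folds,
                        seed=seed,
                        families=families,
                    )
                )
    return reports
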