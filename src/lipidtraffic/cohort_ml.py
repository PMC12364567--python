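"""Serum-cohort stage: balanced-split sex classification and fold-change tables.

A heavily male-skewed cohort is split by drawing an equal number of
subjects per sex for training (to avoid biasing the classifier toward the
majority class); everything else forms the test set.  A seeded
random-forest is trained on the lipid features (BMI and age included as
covariate features unless corrected away), evaluated on the held-out
subjects, and each variable is summarised by a rank-test p-value and its
fold change relative to the male group.

BMI correction replaces every lipid feature by its residual from a
univariate linear fit on BMI, with coefficients estimated on training
subjects only (leak-free) and applied to all subjects; BMI itself is then
removed from the feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    roc_auc_score,
    roc_curve,
)

from . import stats as _stats

__all__ = [
    "METADATA_COLUMNS",
    "CohortModelReport",
    "feature_columns",
    "balanced_split",
    "bmi_correct",
    "fit_and_evaluate",
    "variable_fold_changes",
]

#: Non-feature columns of a cohort table.  ``bmi`` and ``age`` double as
#: covariate features for the uncorrected model.
METADATA_COLUMNS = ("sex",)


def feature_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in METADATA_COLUMNS]


def _check_cohort(cohort: pd.DataFrame) -> None:
    if "sex" not in cohort.columns:
        raise ValueError("cohort needs a 'sex' column")
    if cohort.index.has_duplicates:
        raise ValueError("duplicated subject ids")
    labels = sorted(cohort["sex"].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two sex labels, got {labels}")


def balanced_split(
    cohort: pd.DataFrame, n_per_class: int, seed: int | None = None
) -> tuple[pd.Index, pd.Index]:
    """Draw ``n_per_class`` training subjects per sex; the rest is the test set.

    The partition is disjoint and exhaustive, and deterministic for a
    fixed seed.
    """
    _check_cohort(cohort)
    rng = np.random.default_rng(seed)
    train: list = []
    for label in sorted(cohort["sex"].unique()):
        ids = np.sort(cohort.index[cohort["sex"] == label].to_numpy())
        if n_per_class > len(ids):
            raise ValueError(
                f"n_per_class={n_per_class} exceeds class {label!r} size {len(ids)}"
            )
        train.extend(rng.choice(ids, size=n_per_class, replace=False))
    train_idx = pd.Index(sorted(train))
    test_idx = cohort.index.difference(train_idx).sort_values()
    return train_idx, test_idx


def bmi_correct(
    cohort: pd.DataFrame,
    train_ids: pd.Index,
    method: str = "residualize",
    log_scale: bool = False,
) -> pd.DataFrame:
    """Remove the BMI signal from the lipid features.

    ``"residualize"`` replaces each feature by its residual from a
    univariate least-squares fit on BMI (coefficients from training
    subjects only, applied to everyone) and drops the BMI column;
    ``"drop"`` only removes the BMI column.

    Abundance effects of BMI are usually multiplicative; for strictly
    positive features ``log_scale=True`` residualizes log-abundance on
    BMI instead, which removes such exponential dependence completely
    where a linear fit on the raw scale would leave curvature behind.
    The corrected features are then on the log scale.
    """
    if "bmi" not in cohort.columns:
        raise ValueError("cohort has no 'bmi' column")
    if method == "drop":
        return cohort.drop(columns=["bmi"])
    if method != "residualize":
        raise ValueError(f"unknown method {method!r}")
    bmi = cohort["bmi"].astype(float)
    bmi_train = bmi.loc[train_ids]
    if float(bmi_train.std(ddof=0)) == 0.0:
        raise ValueError("zero-variance BMI in the training set")
    out = cohort.copy()
    feats = [c for c in feature_columns(cohort) if c != "bmi"]
    x = bmi_train.to_numpy()
    design = np.column_stack([np.ones_like(x), x])
    for col in feats:
        values = cohort[col].astype(float)
        if log_scale and col != "age":
            if (values <= 0).any():
                raise ValueError(f"log-scale correction needs {col!r} > 0")
            values = np.log(values)
        y = values.loc[train_ids].to_numpy()
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        out[col] = values - (coef[0] + coef[1] * bmi)
    return out.drop(columns=["bmi"])


@dataclass
class CohortModelReport:
    """Balanced-split classifier metrics plus importances and ROC points."""

    positive_class: str
    train_sizes: dict[str, int]
    test_sizes: dict[str, int]
    accuracy_pct: float
    balanced_accuracy_pct: float
    auc_pct: float
    confusion: pd.DataFrame  # rows = true, cols = predicted
    importances: pd.DataFrame | None = None
    roc_points: pd.DataFrame | None = None
    model_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "train_sizes": self.train_sizes,
            "test_sizes": self.test_sizes,
            "accuracy_pct": self.accuracy_pct,
            "balanced_accuracy_pct": self.balanced_accuracy_pct,
            "auc_pct": self.auc_pct,
            "confusion": self.confusion.to_dict(),
            "model_params": self.model_params,
        }


def fit_and_evaluate(
    cohort: pd.DataFrame,
    partition: tuple[pd.Index, pd.Index],
    n_estimators: int = 500,
    max_features: str | float = "sqrt",
    seed: int | None = None,
    threshold: float = 0.5,
    compute_importance: bool = True,
    importance_repeats: int = 5,
) -> CohortModelReport:
    """Train a seeded random forest on the training split and evaluate held out.

    Accuracy uses a 0.5 score threshold (balanced accuracy reported
    alongside, as the test set is imbalanced); AUC comes from the
    continuous class score; the importance ranking is permutation-based on
    the test set.
    """
    _check_cohort(cohort)
    train_ids, test_ids = partition
    feats = feature_columns(cohort)
    y = cohort["sex"]
    if y.loc[train_ids].nunique() < 2:
        raise ValueError("single-class training set")
    classes = sorted(y.unique())
    positive = classes[-1]
    x_train = cohort.loc[train_ids, feats].to_numpy(dtype=float)
    x_test = cohort.loc[test_ids, feats].to_numpy(dtype=float)
    y_train = (y.loc[train_ids] == positive).to_numpy()
    y_test = (y.loc[test_ids] == positive).to_numpy()
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(x_train, y_train)
    pos_col = list(clf.classes_).index(True)
    score = clf.predict_proba(x_test)[:, pos_col]
    pred = score >= threshold
    cm = confusion_matrix(y_test, pred, labels=[False, True])
    acc = float(cm.trace() / cm.sum() * 100.0)
    bal = float(balanced_accuracy_score(y_test, pred) * 100.0)
    auc = float(roc_auc_score(y_test, score) * 100.0)
    confusion = pd.DataFrame(
        cm,
        index=[f"true_{classes[0]}", f"true_{positive}"],
        columns=[f"pred_{classes[0]}", f"pred_{positive}"],
    )
    importances = None
    if compute_importance:
        perm = permutation_importance(
            clf, x_test, y_test, scoring="roc_auc",
            n_repeats=importance_repeats, random_state=seed, n_jobs=1,
        )
        importances = (
            pd.DataFrame(
                {
                    "feature": feats,
                    "importance": perm.importances_mean,
                    "importance_sd": perm.importances_std,
                }
            )
            .sort_values("importance", ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )
    fpr, tpr, thr = roc_curve(y_test, score)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return CohortModelReport(
        positive_class=positive,
        train_sizes={c: int((y.loc[train_ids] == c).sum()) for c in classes},
        test_sizes={c: int((y.loc[test_ids] == c).sum()) for c in classes},
        accuracy_pct=acc,
        balanced_accuracy_pct=bal,
        auc_pct=auc,
        confusion=confusion,
        importances=importances,
        roc_points=roc_points,
        model_params={
            "n_estimators": n_estimators,
            "max_features": max_features,
            "seed": seed,
            "threshold": threshold,
        },
    )


def variable_fold_changes(
    cohort: pd.DataFrame,
    reference: str = "male",
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable fold change relative to the reference sex, with p-values.

    Fold change = mean(other sex) / mean(reference); p from the two-sided
    rank test, floored at the reporting limit; a Benjamini-Hochberg
    adjusted column is emitted alongside the raw values.  Variables whose
    reference mean is non-positive are flagged incalculable.
    """
    _check_cohort(cohort)
    labels = sorted(cohort["sex"].unique())
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among sexes {labels}")
    other = [l for l in labels if l != reference][0]
    feats = features if features is not None else feature_columns(cohort)
    ref_block = cohort.loc[cohort["sex"] == reference, feats].astype(float)
    oth_block = cohort.loc[cohort["sex"] == other, feats].astype(float)
    rows = []
    for col in feats:
        mu_ref = float(ref_block[col].mean())
        mu_oth = float(oth_block[col].mean())
        incalculable = mu_ref <= 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = _stats.floor_pvalue(_stats.group_test(ref_block[col], oth_block[col]))
        rows.append(
            {
                "variable": col,
                "fold_change": np.nan if incalculable else mu_oth / mu_ref,
                "pvalue": p,
                "incalculable": incalculable,
            }
        )
    out = pd.DataFrame(rows)
    out["pvalue_bh"] = _stats.bh_adjust(out["pvalue"])
    return out
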