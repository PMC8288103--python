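"""Surgical-outcome prediction from abnormality z-scores.

Protocol: each candidate feature (one region x metric |z| value per
patient, or a combined summed-|z| predictor) is fed alone to a classifier
from one of six families — decision tree (TR), linear discriminant (DM),
logistic regression (LR), RBF-kernel SVM, k-nearest-neighbor (KNN) and a
bagged-tree ensemble (ENS) — under stratified 5-fold cross-validation
repeated 50 times with distinct shuffles.  Per repetition the pooled
out-of-fold scores give the AUC and the pooled out-of-fold class
predictions give accuracy / sensitivity / specificity; means and SDs are
taken over repetitions.  The *good* surgical outcome class (ILAE 1-2) is
the positive class throughout.

Feature selection for the combined predictors is, by default, performed on
the full data as in the source protocol (which leaks selection
information); ``nested=True`` repeats the selection inside each training
fold instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MODEL_FAMILIES",
    "PredictionResult",
    "ConfusionSummary",
    "crossval_single_feature",
    "roc_optimal_point",
    "combine_predictors",
    "confusion_summary",
    "select_outcome_predictors",
]

MODEL_FAMILIES = ("TR", "DM", "LR", "SVM", "KNN", "ENS")


def _make_model(family: str, seed: int):
    if family == "TR":
        clf = DecisionTreeClassifier(random_state=seed)
    elif family == "DM":
        clf = LinearDiscriminantAnalysis()
    elif family == "LR":
        clf = LogisticRegression(max_iter=1000)
    elif family == "SVM":
        clf = SVC(kernel="rbf", random_state=seed)
    elif family == "KNN":
        clf = KNeighborsClassifier(n_neighbors=5)
    elif family == "ENS":
        clf = BaggingClassifier(DecisionTreeClassifier(random_state=seed),
                                n_estimators=30, random_state=seed)
    else:
        raise ValueError(f"unknown model family {family!r}; "
                         f"choose from {MODEL_FAMILIES}")
    return make_pipeline(StandardScaler(), clf)


@dataclass
class PredictionResult:
    """Repeated-CV classification summary for one feature."""

    feature: str
    family: str
    n_repeats: int
    auc_mean: float
    auc_sd: float
    accuracy_mean: float          # percentages
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    optimal_threshold: float
    per_repeat_confusion: np.ndarray = field(repr=False, default=None)
    # rows: (TP, FN, FP, TN) per repetition


@dataclass
class ConfusionSummary:
    """Mean +- SD confusion counts over repetitions, rates in percent."""

    tp_mean: float
    tp_sd: float
    fn_mean: float
    fn_sd: float
    fp_mean: float
    fp_sd: float
    tn_mean: float
    tn_sd: float
    positives: int
    negatives: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp_mean / self.positives

    @property
    def miss_rate(self) -> float:
        return 100.0 * self.fn_mean / self.positives

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn_mean / self.negatives

    @property
    def fall_out(self) -> float:
        return 100.0 * self.fp_mean / self.negatives

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp_mean + self.tn_mean) \
            / (self.positives + self.negatives)


def crossval_single_feature(feature, labels, family: str = "DM", k: int = 5,
                            n_repeats: int = 50, seed: int = 0,
                            ) -> PredictionResult:
    """Repeated stratified k-fold CV of a single scalar feature.

    ``labels`` are booleans with True = good outcome (the positive class).
    Repetition r shuffles with seed ``seed + r``; AUC is computed on the
    pooled out-of-fold scores of that repetition.
    """
    X = np.asarray(feature, dtype=float).reshape(-1, 1)
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    # deterministic 1e-8 relative jitter keeps zero-variance training
    # classes well-posed (LDA's covariance solve degenerates otherwise)
    jitter_rng = np.random.default_rng(seed)
    X = X + jitter_rng.standard_normal(X.shape) * (np.std(X) + 1e-12) * 1e-8
    n_min = min(y.sum(), (~y).sum())
    if k > n_min:
        raise ValueError(f"k={k} exceeds the smaller class size {n_min}")
    aucs, accs, sens, specs = [], [], [], []
    confusion = np.zeros((n_repeats, 4))
    for r in range(n_repeats):
        rs = seed + r
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        scores = np.empty(len(y))
        preds = np.empty(len(y), dtype=bool)
        for train, test in skf.split(X, y):
            model = _make_model(family, rs)
            model.fit(X[train], y[train])
            if hasattr(model, "predict_proba"):
                proba = model.predict_proba(X[test])
                pos_col = list(model.classes_).index(True)
                scores[test] = proba[:, pos_col]
            else:
                df = model.decision_function(X[test])
                # decision_function is signed toward classes_[1]
                scores[test] = df if model.classes_[1] else -df
            preds[test] = model.predict(X[test])
        aucs.append(roc_auc_score(y, scores))
        tp = int(np.sum(preds & y))
        fn = int(np.sum(~preds & y))
        fp = int(np.sum(preds & ~y))
        tn = int(np.sum(~preds & ~y))
        confusion[r] = (tp, fn, fp, tn)
        accs.append(100.0 * (tp + tn) / len(y))
        sens.append(100.0 * tp / y.sum())
        specs.append(100.0 * tn / (~y).sum())
    threshold, _, _, _ = roc_optimal_point(X[:, 0], y)
    return PredictionResult(
        feature="feature", family=family, n_repeats=n_repeats,
        auc_mean=float(np.mean(aucs)), auc_sd=float(np.std(aucs)),
        accuracy_mean=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        sensitivity_mean=float(np.mean(sens)),
        sensitivity_sd=float(np.std(sens)),
        specificity_mean=float(np.mean(specs)),
        specificity_sd=float(np.std(specs)),
        optimal_threshold=float(threshold),
        per_repeat_confusion=confusion)


def roc_optimal_point(scores, labels) -> tuple[float, float, float, bool]:
    """Threshold maximizing Youden's J; ties broken toward specificity.

    Returns (threshold, sensitivity, specificity, degenerate).  Constant
    scores are degenerate: J = 0 and the flag is set.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.all(scores == scores[0]):
        return float(scores[0]), 1.0, 0.0, True
    fpr, tpr, thresholds = roc_curve(y, scores)
    j = tpr - fpr
    best_j = j.max()
    # among maximal-J points prefer the lowest FPR (highest specificity)
    candidates = np.where(np.isclose(j, best_j))[0]
    best = candidates[np.argmin(fpr[candidates])]
    return (float(thresholds[best]), float(tpr[best]), float(1 - fpr[best]),
            False)


def combine_predictors(z: pd.DataFrame, predictor_set,
                       subjects=None) -> pd.Series:
    """Per-subject summed |z| over a (region, metric) predictor set."""
    predictor_set = list(predictor_set)
    if not predictor_set:
        raise ValueError("predictor set must be non-empty")
    keys = pd.MultiIndex.from_tuples(predictor_set)
    sel = z.set_index(["region", "metric"])
    sel = sel.loc[sel.index.isin(keys)]
    out = sel.groupby("subject")["abs_z"].sum(min_count=1)
    if subjects is not None:
        out = out.reindex(subjects)
    return out


def confusion_summary(per_repeat_confusion: np.ndarray, positives: int,
                      negatives: int) -> ConfusionSummary:
    """Mean +- SD of TP/FN/FP/TN over repetitions."""
    c = np.asarray(per_repeat_confusion, dtype=float).reshape(-1, 4)
    if not np.allclose(c[:, 0] + c[:, 1], positives) \
            or not np.allclose(c[:, 2] + c[:, 3], negatives):
        raise ValueError("confusion counts inconsistent with class sizes")
    means = c.mean(axis=0)
    sds = c.std(axis=0)
    return ConfusionSummary(
        tp_mean=means[0], tp_sd=sds[0], fn_mean=means[1], fn_sd=sds[1],
        fp_mean=means[2], fp_sd=sds[2], tn_mean=means[3], tn_sd=sds[3],
        positives=positives, negatives=negatives)


def per_feature_predictions(z: pd.DataFrame, cohort: pd.DataFrame,
                            features=None, families=MODEL_FAMILIES,
                            k: int = 5, n_repeats: int = 10,
                            seed: int = 0) -> pd.DataFrame:
    """Per-feature repeated-CV performance across model families.

    Each (region, metric) |z| feature is classified alone by every family;
    the result table carries both an AUC ranking and an accuracy ranking,
    since the best-model-per-feature choice depends on the criterion.
    """
    cohort_ix = cohort.set_index("id") if "id" in cohort.columns else cohort
    patients = cohort_ix[cohort_ix.group == "patient"]
    labels = (patients.outcome <= 2).to_numpy()
    data = z[z.subject.isin(patients.index)]
    if features is None:
        features = sorted({(r, m) for r, m in zip(data.region, data.metric)})
    rows = []
    for region, metric in features:
        vals = data[(data.region == region) & (data.metric == metric)] \
            .set_index("subject")["abs_z"].reindex(patients.index)
        feature = vals.fillna(0.0).to_numpy()
        for family in families:
            res = crossval_single_feature(feature, labels, family, k,
                                          n_repeats, seed)
            rows.append({
                "region": region, "metric": metric, "family": family,
                "auc": res.auc_mean, "auc_sd": res.auc_sd,
                "accuracy": res.accuracy_mean, "accuracy_sd": res.accuracy_sd,
                "sensitivity": res.sensitivity_mean,
                "specificity": res.specificity_mean,
            })
    out = pd.DataFrame(rows)
    out["rank_by_auc"] = out.auc.rank(ascending=False, method="min").astype(int)
    out["rank_by_accuracy"] = out.accuracy.rank(
        ascending=False, method="min").astype(int)
    return out.sort_values("rank_by_auc").reset_index(drop=True)


def crossval_combined_nested(z: pd.DataFrame, cohort: pd.DataFrame,
                             metrics, family: str = "DM", k: int = 5,
                             n_repeats: int = 10, seed: int = 0,
                             alpha: float = 0.05, d_threshold: float = 0.5,
                             n_perm: int = 100) -> PredictionResult:
    """Combined predictor with feature selection *inside* each training fold.

    The default protocol selects predictors on the full data, which leaks
    outcome information into the feature; here the (region, metric) set is
    re-selected from the training patients of every fold, giving an honest
    generalization estimate.  Selection uses the same rule (|Cohen's d| >
    d_threshold and permutation p < alpha on the |z| values), falling back
    to all features when nothing passes in a fold.
    """
    from .stats import cohens_d, permutation_test

    cohort_ix = cohort.set_index("id") if "id" in cohort.columns else cohort
    patients = cohort_ix[cohort_ix.group == "patient"]
    labels = (patients.outcome <= 2).to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    data = z[z.subject.isin(patients.index) & z.metric.isin(metrics)]
    wide = data.pivot_table(index="subject", columns=["region", "metric"],
                            values="abs_z").reindex(patients.index).fillna(0.0)
    X = wide.to_numpy()
    rng = np.random.default_rng(seed)
    aucs, accs, sens, specs = [], [], [], []
    confusion = np.zeros((n_repeats, 4))
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        scores = np.empty(len(labels))
        preds = np.empty(len(labels), dtype=bool)
        for train, test in skf.split(X, labels):
            cols = []
            for j in range(X.shape[1]):
                xg = X[train][labels[train], j]
                xb = X[train][~labels[train], j]
                if len(xg) < 2 or len(xb) < 2:
                    continue
                try:
                    d = cohens_d(xb, xg)
                except ValueError:
                    continue
                if abs(d) <= d_threshold:
                    continue
                p = permutation_test(xb, xg, n_perm=n_perm,
                                     seed=int(rng.integers(2 ** 31)))
                if p < alpha:
                    cols.append(j)
            if not cols:
                cols = list(range(X.shape[1]))
            feat_train = X[np.ix_(train, cols)].sum(axis=1).reshape(-1, 1)
            feat_test = X[np.ix_(test, cols)].sum(axis=1).reshape(-1, 1)
            model = _make_model(family, seed + r)
            model.fit(feat_train, labels[train])
            if hasattr(model, "predict_proba"):
                proba = model.predict_proba(feat_test)
                scores[test] = proba[:, list(model.classes_).index(True)]
            else:
                df = model.decision_function(feat_test)
                scores[test] = df if model.classes_[1] else -df
            preds[test] = model.predict(feat_test)
        aucs.append(roc_auc_score(labels, scores))
        tp = int(np.sum(preds & labels))
        fn = int(np.sum(~preds & labels))
        fp = int(np.sum(preds & ~labels))
        tn = int(np.sum(~preds & ~labels))
        confusion[r] = (tp, fn, fp, tn)
        accs.append(100.0 * (tp + tn) / len(labels))
        sens.append(100.0 * tp / labels.sum())
        specs.append(100.0 * tn / (~labels).sum())
    return PredictionResult(
        feature="ALL(nested)", family=family, n_repeats=n_repeats,
        auc_mean=float(np.mean(aucs)), auc_sd=float(np.std(aucs)),
        accuracy_mean=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        sensitivity_mean=float(np.mean(sens)),
        sensitivity_sd=float(np.std(sens)),
        specificity_mean=float(np.mean(specs)),
        specificity_sd=float(np.std(specs)),
        optimal_threshold=np.nan, per_repeat_confusion=confusion)


def select_outcome_predictors(z: pd.DataFrame, cohort: pd.DataFrame,
                              alpha: float = 0.05, d_threshold: float = 0.5,
                              n_perm: int = 1000, seed: int = 0,
                              metrics=None) -> list[tuple[str, str]]:
    """(region, metric) features separating good- from bad-outcome patients.

    A feature is selected when the good/bad |z| groups differ with
    permutation p < alpha and |Cohen's d| > d_threshold.  Run on the full
    data this mirrors the source protocol's (leaky) selection; for an
    honest estimate re-run inside CV folds.
    """
    from .stats import cohens_d, permutation_test

    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    patients = cohort[cohort.group == "patient"]
    good = [s for s in patients.index if patients.loc[s, "outcome"] <= 2]
    bad = [s for s in patients.index if patients.loc[s, "outcome"] > 2]
    data = z[z.subject.isin(patients.index)]
    if metrics is not None:
        data = data[data.metric.isin(metrics)]
    rng = np.random.default_rng(seed)
    selected = []
    for (region, metric), sub in data.groupby(["region", "metric"]):
        vals = sub.set_index("subject")["abs_z"]
        xg = vals.reindex(good).dropna().to_numpy()
        xb = vals.reindex(bad).dropna().to_numpy()
        if len(xg) < 2 or len(xb) < 2:
            continue
        try:
            d = cohens_d(xb, xg)
        except ValueError:
            continue
        if abs(d) <= d_threshold:
            continue
        p = permutation_test(xb, xg, n_perm=n_perm,
                             seed=int(rng.integers(2 ** 31)))
        if p < alpha:
            selected.append((str(region), str(metric)))
    return selected
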