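"""Unifying-diagnosis prediction from admission features.

The admission picture is assembled from four blocks — demographics (``de_``),
dictionary-extracted symptom flags (``sy_``), per-lab five-number summaries
of in-stay time series (``le_``: min, max, median, mean, variance), and
severity indicators (``sev_``) — then one-hot encoded and min–max normalised.

Features are screened by information gain IG(x) = H(Y) − H(Y|x) in bits
(numeric features first discretised to equal-frequency bins), keeping those
with IG strictly above δ₂. Classifiers are evaluated under stratified Z-fold
cross-validation; feature selection, median imputation and minority-class
oversampling are refit inside each training fold so held-out rows can never
influence them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone, is_classifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

DEFAULT_DELTA2 = 0.005
DEFAULT_BINS = 10
DEFAULT_Z = 10

CLASSIFIER_NAMES = ("logistic", "tree", "forest", "svm", "xgboost")

#: The 16 symptom flags extracted from chief-complaint / history text.
SYMPTOM_NAMES = (
    "fever",
    "abdominal_pain",
    "shortness_of_breath",
    "nausea_and_vomiting",
    "weakness",
    "diarrhea",
    "dizziness",
    "palpitation",
    "cough",
    "fatigue",
    "discomfort",
    "dysuria",
    "shock",
    "weight_change",
    "loss_of_appetite",
    "night_sweating",
)

#: Surface forms per symptom; multi-word terms match consecutive tokens.
SYMPTOM_TERMS: dict[str, tuple[str, ...]] = {
    "fever": ("fever", "fevers", "febrile", "pyrexia"),
    "abdominal_pain": ("abdominal pain", "abd pain", "stomach pain", "belly pain"),
    "shortness_of_breath": ("shortness of breath", "sob", "dyspnea", "dyspnoea"),
    "nausea_and_vomiting": ("nausea", "vomiting", "emesis", "n/v"),
    "weakness": ("weakness", "weak"),
    "diarrhea": ("diarrhea", "diarrhoea", "loose stools"),
    "dizziness": ("dizziness", "dizzy", "lightheaded", "lightheadedness"),
    "palpitation": ("palpitation", "palpitations"),
    "cough": ("cough", "coughing"),
    "fatigue": ("fatigue", "fatigued", "tiredness"),
    "discomfort": ("discomfort", "malaise"),
    "dysuria": ("dysuria", "painful urination"),
    "shock": ("shock",),
    "weight_change": ("weight loss", "weight gain", "weight change"),
    "loss_of_appetite": ("loss of appetite", "anorexia", "poor appetite"),
    "night_sweating": ("night sweats", "night sweating", "night sweat"),
}

NEGATION_TERMS = ("no", "not", "denies", "denied", "without", "negative", "non")


def lab_five_tuple(series: Iterable[float]) -> tuple[float, float, float, float, float]:
    """(min, max, median, mean, population variance) of a lab time series.

    Timestamps are irrelevant to these order statistics. An empty series
    yields a NaN tuple, handled downstream by training-fold imputation.
    """
    values = np.asarray(list(series), dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return (np.nan,) * 5
    return (
        float(values.min()),
        float(values.max()),
        float(np.median(values)),
        float(values.mean()),
        float(values.var()),  # ddof=0: descriptive within-stay variance
    )


def _tokenize(text: str) -> list[str]:
    return re.findall(r"[a-z0-9/]+", text.lower())


def extract_symptoms(
    text: str,
    dictionary: Mapping[str, Sequence[str]] | None = None,
    negation_terms: Sequence[str] = NEGATION_TERMS,
    window: int = 3,
) -> dict[str, int]:
    """Flag symptoms mentioned in a clinical snippet, honouring local negation.

    A symptom is 1 when any dictionary term matches (case-insensitive, over
    tokens) and no negation term occurs within ``window`` tokens before the
    match inside the same clause (clauses split on ,.;: — "denies fever,
    reports cough" negates only fever). Empty text yields all zeros.
    """
    dictionary = dictionary if dictionary is not None else SYMPTOM_TERMS
    clauses = [_tokenize(c) for c in re.split(r"[,.;:\n]", (text or "").lower())]
    neg = set(negation_terms)
    flags = {name: 0 for name in dictionary}
    for name, terms in dictionary.items():
        for term in terms:
            term_tokens = _tokenize(term)
            m = len(term_tokens)
            hit = False
            for tokens in clauses:
                for start in range(len(tokens) - m + 1):
                    if tokens[start : start + m] != term_tokens:
                        continue
                    preceding = tokens[max(0, start - window) : start]
                    if not any(t in neg for t in preceding):
                        hit = True
                        break
                if hit:
                    break
            if hit:
                flags[name] = 1
                break
    return flags


def _prefix_block(block: pd.DataFrame, prefix: str) -> pd.DataFrame:
    cols = {
        c: c if str(c).startswith(prefix) else f"{prefix}{c}" for c in block.columns
    }
    return block.rename(columns=cols)


def fuse_features(
    demographics: pd.DataFrame,
    symptoms: pd.DataFrame,
    labs: pd.DataFrame,
    severity: pd.DataFrame,
    normalize: bool = True,
) -> pd.DataFrame:
    """Concatenate feature blocks; one-hot nominal columns, min–max numerics.

    All blocks must be indexed by the same patient ids; orphans are rejected
    by name. Binary 0/1 columns pass through min–max scaling unchanged.
    """
    blocks = [
        _prefix_block(demographics, "de_"),
        _prefix_block(symptoms, "sy_"),
        _prefix_block(labs, "le_"),
        _prefix_block(severity, "sev_"),
    ]
    base = set(blocks[0].index)
    for block in blocks[1:]:
        orphans = base.symmetric_difference(block.index)
        if orphans:
            raise ValueError(
                f"feature blocks disagree on patient ids: {sorted(orphans)[:10]}"
            )
    fused = pd.concat([b.loc[blocks[0].index] for b in blocks], axis=1)
    nominal = [
        c
        for c in fused.columns
        if fused[c].dtype == object or isinstance(fused[c].dtype, pd.CategoricalDtype)
    ]
    if nominal:
        fused = pd.get_dummies(fused, columns=nominal, dtype=float)
    fused = fused.astype(float)
    if normalize:
        lo, hi = fused.min(), fused.max()
        span = (hi - lo).replace(0.0, np.nan)
        fused = (fused - lo) / span
        fused = fused.fillna(0.0)
    return fused


def split_blocks(table: pd.DataFrame) -> tuple[pd.DataFrame, ...]:
    """Split a prefix-tagged feature table back into its four blocks."""
    out = []
    for prefix in ("de_", "sy_", "le_", "sev_"):
        cols = [c for c in table.columns if str(c).startswith(prefix)]
        if not cols:
            raise ValueError(f"feature table has no columns with prefix {prefix!r}")
        out.append(table[cols])
    return tuple(out)


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(x, y, bins: int = DEFAULT_BINS) -> float:
    """IG(x) = H(Y) − H(Y|x) in bits, discretising numeric x to equal-frequency bins."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return 0.0
    x = pd.Series(np.asarray(x).ravel())
    if pd.api.types.is_numeric_dtype(x) and x.nunique(dropna=True) > bins:
        x = pd.qcut(x, bins, duplicates="drop")
    x = x.astype(object).where(x.notna(), "__missing__")
    h_y = _entropy_bits(y)
    h_y_given_x = 0.0
    n = len(y)
    for _, idx in pd.Series(range(n)).groupby(x.values, observed=True):
        h_y_given_x += len(idx) / n * _entropy_bits(y[idx.values])
    return max(0.0, h_y - h_y_given_x)


def select_features(
    X: pd.DataFrame,
    y,
    delta2: float = DEFAULT_DELTA2,
    bins: int = DEFAULT_BINS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep features with IG strictly above δ₂; returns (X′, IG per kept column).

    Call this on training data only when cross-validating (the bundled
    classifier does so automatically).
    """
    if delta2 < 0:
        raise ValueError("delta2 must be non-negative")
    ig = pd.Series(
        {col: information_gain(X[col], y, bins=bins) for col in X.columns},
        name="information_gain",
    )
    kept = ig[ig > delta2]
    if kept.empty:
        raise ValueError(
            f"no feature has information gain above delta2={delta2}; lower delta2"
        )
    return X[list(kept.index)], kept.sort_values(ascending=False)


def make_classifier(name: str, seed: int | None = None):
    """Instantiate one of the five reference classifiers by name."""
    if name == "logistic":
        return LogisticRegression(max_iter=2000)
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "svm":
        return SVC(probability=True, random_state=seed)
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100,
            max_depth=4,
            tree_method="hist",
            eval_metric="mlogloss",
            random_state=seed or 0,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown classifier {name!r}; use one of {CLASSIFIER_NAMES}")


class UnifyingDiagnosisClassifier(BaseEstimator, ClassifierMixin):
    """Leakage-safe multi-class classifier for unifying-diagnosis labels.

    ``fit`` performs, on the training data only: median imputation (with
    missingness indicator columns), information-gain feature selection at
    threshold ``delta2``, and seeded random oversampling of minority classes
    to the majority count, before fitting the base estimator.

    Parameters
    ----------
    base : str or estimator
        One of "logistic", "tree", "forest", "svm", "xgboost", or any sklearn
        classifier instance (cloned at fit time).
    delta2 : float
        Information-gain threshold; features with IG ≤ delta2 are dropped.
    bins : int
        Equal-frequency bins for discretising numeric features in IG.
    oversample : bool
        Oversample minority classes in the training data.
    random_state : int or None
        Seeds oversampling and the base estimator where applicable.
    """

    def __init__(
        self,
        base="forest",
        delta2: float = DEFAULT_DELTA2,
        bins: int = DEFAULT_BINS,
        oversample: bool = True,
        random_state: int | None = None,
    ):
        self.base = base
        self.delta2 = delta2
        self.bins = bins
        self.oversample = oversample
        self.random_state = random_state

    def _build_base(self):
        if isinstance(self.base, str):
            return make_classifier(self.base, seed=self.random_state)
        if is_classifier(self.base):
            return clone(self.base)
        raise ValueError("base must be a classifier name or sklearn classifier")

    def _impute(self, X: pd.DataFrame, fit: bool) -> pd.DataFrame:
        X = X.copy()
        if fit:
            self.missing_cols_ = [c for c in X.columns if X[c].isna().any()]
            self.medians_ = X.median()
        for col in self.missing_cols_:
            X[f"miss_{col}"] = X[col].isna().astype(float)
        return X.fillna(self.medians_)

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = self._impute(X, fit=True)
        X_sel, self.information_gain_ = select_features(
            X, y_idx, delta2=self.delta2, bins=self.bins
        )
        self.selected_features_ = list(X_sel.columns)
        Xm, ym = X_sel.to_numpy(dtype=float), y_idx
        if self.oversample:
            rng = np.random.default_rng(self.random_state)
            counts = np.bincount(ym)
            target = counts.max()
            idx = [np.flatnonzero(ym == k) for k in range(len(counts))]
            extra = [
                rng.choice(rows, size=target - len(rows), replace=True)
                for rows in idx
                if len(rows) < target
            ]
            if extra:
                add = np.concatenate(extra)
                Xm = np.vstack([Xm, Xm[add]])
                ym = np.concatenate([ym, ym[add]])
        self.estimator_ = self._build_base()
        self.estimator_.fit(Xm, ym)
        return self

    def _matrix(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        X = self._impute(X, fit=False)
        return X[self.selected_features_].to_numpy(dtype=float)

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.classes_[self.estimator_.predict(self._matrix(X))]

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._matrix(X))


@dataclass
class PredictionReport:
    """Cross-validated metrics plus the selection/importance audit trail."""

    metrics: pd.DataFrame  # index: classifier; columns: auc, acc, pre, rec, f1, cv_error
    fold_errors: dict[str, list[float]]
    confusions: dict[str, list[np.ndarray]]
    selected: pd.Series  # IG of features selected on the full data (report only)
    importances: pd.Series | None
    classes: np.ndarray


def _weighted_auc(y_true, proba, classes) -> float:
    if len(classes) == 2:
        return float(roc_auc_score(y_true, proba[:, 1]))
    return float(
        roc_auc_score(
            y_true, proba, multi_class="ovr", average="weighted", labels=classes
        )
    )


def train_and_evaluate(
    X: pd.DataFrame,
    y,
    classifiers: Sequence = CLASSIFIER_NAMES,
    Z: int = DEFAULT_Z,
    seed: int = 0,
    delta2: float = DEFAULT_DELTA2,
    bins: int = DEFAULT_BINS,
    oversample: bool = True,
) -> PredictionReport:
    """Stratified Z-fold cross-validation of the named classifiers.

    Precision, recall, F1 and one-vs-rest AUC are support-weighted over
    classes (making recall coincide with accuracy); CVError is the mean of
    the per-fold 0/1 mismatch rates. Metrics are computed on the pooled
    out-of-fold predictions.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < Z:
        raise ValueError(
            f"smallest class has {counts.min()} members < Z={Z}; use a smaller Z"
        )
    skf = StratifiedKFold(n_splits=Z, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    rows = {}
    fold_errors: dict[str, list[float]] = {}
    confusions: dict[str, list[np.ndarray]] = {}
    for clf in classifiers:
        name = clf if isinstance(clf, str) else type(clf).__name__
        model = UnifyingDiagnosisClassifier(
            base=clf,
            delta2=delta2,
            bins=bins,
            oversample=oversample,
            random_state=seed,
        )
        pred = np.empty(len(y), dtype=classes.dtype)
        proba = np.zeros((len(y), len(classes)))
        errors, cms = [], []
        for train_idx, test_idx in splits:
            fold = clone(model)
            fold.fit(X.iloc[train_idx], y[train_idx])
            yp = fold.predict(X.iloc[test_idx])
            pred[test_idx] = yp
            pp = fold.predict_proba(X.iloc[test_idx])
            # align fold class columns onto the global class list
            for ci, cls in enumerate(fold.classes_):
                proba[test_idx, np.flatnonzero(classes == cls)[0]] = pp[:, ci]
            errors.append(float(np.mean(yp != y[test_idx])))
            cms.append(confusion_matrix(y[test_idx], yp, labels=classes))
        rows[name] = {
            "auc": _weighted_auc(y, proba, classes),
            "acc": float(accuracy_score(y, pred)),
            "pre": float(precision_score(y, pred, average="weighted", zero_division=0)),
            "rec": float(recall_score(y, pred, average="weighted", zero_division=0)),
            "f1": float(f1_score(y, pred, average="weighted", zero_division=0)),
            "cv_error": float(np.mean(errors)),
        }
        fold_errors[name] = errors
        confusions[name] = cms

    # full-data IG ranking (reporting only; per-fold selection happened above)
    imputer = UnifyingDiagnosisClassifier(delta2=delta2, bins=bins)
    Xi = imputer._impute(X, fit=True)
    ig = pd.Series(
        {col: information_gain(Xi[col], y, bins=bins) for col in Xi.columns},
        name="information_gain",
    )
    selected = ig[ig > delta2].sort_values(ascending=False)

    importances = None
    wants_forest = any(isinstance(c, str) and c == "forest" for c in classifiers)
    if wants_forest and not selected.empty:
        forest = make_classifier("forest", seed=seed)
        forest.fit(Xi[list(selected.index)].to_numpy(dtype=float), y)
        importances = feature_importance(forest, list(selected.index))

    return PredictionReport(
        metrics=pd.DataFrame(rows).T,
        fold_errors=fold_errors,
        confusions=confusions,
        selected=selected,
        importances=importances,
        classes=classes,
    )


def feature_importance(forest, feature_names: Sequence[str]) -> pd.Series:
    """Impurity-based importance ranking of a fitted random forest."""
    imp = pd.Series(forest.feature_importances_, index=list(feature_names))
    return imp.sort_values(ascending=False)
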