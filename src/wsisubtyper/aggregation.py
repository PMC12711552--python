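"""Patch-to-slide aggregation: voting, histogram and TF-IDF features,
and the five weighted slide-level classifiers.

Each whole-slide image is summarized by the ordered stream of its
patch-level predictions — the slide is the "document", the patch calls
("SCC"/"AC") are its "tokens".  Three aggregation routes turn that bag
into a slide-level subtype call:

* majority voting over tokens (no learning);
* a normalized histogram of the patch AC-probabilities;
* TF-IDF weighting of token n-grams (orders 1-3), capped to the 10
  n-grams with the highest document frequency.  Two token types cannot
  span ten dimensions with unigrams alone, so short n-grams of the
  row-major token sequence supply the vocabulary; tf is the raw n-gram
  count, idf is the smoothed ``ln((1+n)/(1+df)) + 1``, rows are
  L2-normalized.

Feature vectors feed logistic regression, random forest, SVM, AdaBoost
or XGBoost with inverse-class-frequency weights (``w_c = N / (2 n_c)``)
and 5-fold case-grouped cross-validated hyperparameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionBag", "FeatureVector", "ClassWeights", "majority_vote",
    "histogram_features", "TfidfBagVectorizer", "tfidf_features",
    "compute_class_weights", "fit_slide_classifier", "predict_slide",
    "SlideClassifier", "DEFAULT_GRIDS", "bags_from_predictions",
]

TOKENS = ("SCC", "AC")


@dataclass
class PredictionBag:
    """Per-slide ordered stream of patch labels and AC-probabilities."""

    slide_id: str
    tokens: list
    probs: np.ndarray
    case_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.tokens) != len(self.probs) or len(self.tokens) == 0:
            raise ValueError("tokens and probs must be parallel and nonempty")
        for t, p in zip(self.tokens, self.probs):
            if t not in TOKENS:
                raise ValueError(f"unknown token {t!r}")
            if (t == "AC") != (p >= 0.5):
                raise ValueError(
                    f"token {t} inconsistent with p_ac={p} at the 0.5 threshold")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class FeatureVector:
    """Fixed-length slide feature with its provenance scheme."""

    values: np.ndarray
    scheme: str  # "histogram" | "tfidf"
    dim: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dim = self.values.shape[-1]


@dataclass
class ClassWeights:
    """Inverse-frequency class weights, normalized so Σ w_c n_c = N."""

    w_scc: float
    w_ac: float

    def __post_init__(self) -> None:
        if self.w_scc <= 0 or self.w_ac <= 0:
            raise ValueError("class weights must be positive")

    def as_dict(self) -> dict:
        return {0: self.w_scc, 1: self.w_ac}


def majority_vote(bag: PredictionBag) -> str:
    """Slide label = the most frequent patch token; exact ties go to AC
    (the minority class, mirroring the class-weighting intent)."""
    n_ac = sum(1 for t in bag.tokens if t == "AC")
    n_scc = len(bag) - n_ac
    return "AC" if n_ac >= n_scc else "SCC"


def histogram_features(bag: PredictionBag, n_bins: int = 10) -> FeatureVector:
    """Normalized equal-width histogram of the bag's AC-probabilities."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, _ = np.histogram(bag.probs, bins=n_bins, range=(0.0, 1.0))
    return FeatureVector(values=counts / len(bag), scheme="histogram")


def _ngrams(tokens: Sequence[str], ngram_range: tuple[int, int]):
    lo, hi = ngram_range
    for n in range(lo, hi + 1):
        for i in range(len(tokens) - n + 1):
            yield " ".join(tokens[i:i + n])


class TfidfBagVectorizer:
    """TF-IDF over token n-grams with a document-frequency-capped vocabulary.

    n-gram counting and vocabulary selection (top ``dim`` by document
    frequency, ties broken lexicographically) are done here; the smoothed
    idf and L2 row normalization are delegated to scikit-learn's
    ``TfidfTransformer`` (smooth_idf, norm="l2").
    """

    def __init__(self, ngram_range: tuple[int, int] = (1, 3), dim: int = 10):
        self.ngram_range = ngram_range
        self.dim = dim
        self.vocabulary_: Optional[list[str]] = None
        self._transformer = None

    def _count_matrix(self, bags: Sequence[PredictionBag]) -> np.ndarray:
        index = {g: j for j, g in enumerate(self.vocabulary_)}
        counts = np.zeros((len(bags), len(self.vocabulary_)))
        for i, bag in enumerate(bags):
            grams = list(_ngrams(bag.tokens, self.ngram_range))
            if not grams:
                logger.warning("bag %s shorter than the minimum n-gram; zero vector",
                               bag.slide_id)
            for g in grams:
                j = index.get(g)
                if j is not None:
                    counts[i, j] += 1
        return counts

    def fit(self, bags: Sequence[PredictionBag]) -> "TfidfBagVectorizer":
        from sklearn.feature_extraction.text import TfidfTransformer

        if len(bags) < 2:
            raise ValueError("need at least 2 bags to fit a meaningful idf")
        df: dict[str, int] = {}
        for bag in bags:
            for g in set(_ngrams(bag.tokens, self.ngram_range)):
                df[g] = df.get(g, 0) + 1
        self.vocabulary_ = [g for g, _ in
                            sorted(df.items(), key=lambda kv: (-kv[1], kv[0]))[:self.dim]]
        self._transformer = TfidfTransformer(norm="l2", smooth_idf=True,
                                             sublinear_tf=False)
        self._transformer.fit(self._count_matrix(bags))
        return self

    def transform(self, bags: Sequence[PredictionBag]) -> np.ndarray:
        if self.vocabulary_ is None:
            raise RuntimeError("vectorizer is not fitted")
        return np.asarray(
            self._transformer.transform(self._count_matrix(bags)).todense())

    def fit_transform(self, bags: Sequence[PredictionBag]) -> np.ndarray:
        return self.fit(bags).transform(bags)

    @property
    def idf_(self) -> np.ndarray:
        return self._transformer.idf_


def tfidf_features(bags: Sequence[PredictionBag],
                   ngram_range: tuple[int, int] = (1, 3),
                   dim: int = 10) -> tuple[np.ndarray, TfidfBagVectorizer]:
    """Fit a TF-IDF vectorizer on a corpus of bags and return the matrix."""
    if len(bags) == 0:
        raise ValueError("empty corpus")
    vec = TfidfBagVectorizer(ngram_range=ngram_range, dim=dim)
    return vec.fit_transform(bags), vec


def compute_class_weights(labels: Sequence[str]) -> ClassWeights:
    """Inverse-frequency weights ``w_c = N / (2 n_c)`` over SCC/AC labels."""
    labels = list(labels)
    n = len(labels)
    n_ac = sum(1 for l in labels if l == "AC")
    n_scc = n - n_ac
    if n_ac == 0 or n_scc == 0:
        raise ValueError("both classes must be present to compute class weights")
    return ClassWeights(w_scc=n / (2.0 * n_scc), w_ac=n / (2.0 * n_ac))


DEFAULT_GRIDS = {
    "lr": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 5]},
    "adaboost": {"n_estimators": [50, 200]},
    "xgb": {"max_depth": [2, 4], "n_estimators": [100, 300],
            "learning_rate": [0.05, 0.1]},
}


@dataclass
class SlideClassifier:
    """A fitted slide-level model: estimator + feature scheme + CV table."""

    estimator: object
    algo: str
    scheme: str
    cv_table: pd.DataFrame
    vectorizer: Optional[TfidfBagVectorizer] = None
    n_bins: int = 10
    threshold: float = 0.5


def _build_estimator(algo: str, weights: Optional[ClassWeights], seed: int):
    from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC
    from xgboost import XGBClassifier

    cw = weights.as_dict() if weights else None
    if algo == "lr":
        return LogisticRegression(max_iter=2000, class_weight=cw, random_state=seed)
    if algo == "svm":
        return SVC(probability=True, class_weight=cw, random_state=seed)
    if algo == "rf":
        return RandomForestClassifier(class_weight=cw, random_state=seed)
    if algo == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if algo == "xgb":
        spw = (weights.w_ac / weights.w_scc) if weights else 1.0
        return XGBClassifier(scale_pos_weight=spw, eval_metric="logloss",
                             random_state=seed, n_jobs=1)
    raise ValueError(f"unknown algorithm {algo!r}; expected lr/rf/svm/adaboost/xgb")


def fit_slide_classifier(features: np.ndarray, labels: Sequence[str],
                         algo: str = "lr",
                         weights: Optional[ClassWeights] = None,
                         cv_grid: Optional[dict] = None,
                         groups: Optional[Sequence] = None,
                         scheme: str = "tfidf",
                         seed: int = 0) -> SlideClassifier:
    """Grid-search a slide-level classifier with stratified case-grouped 5-fold CV.

    Folds are grouped by case when ``groups`` is given so multiple slides
    of one patient never straddle a fold boundary.  Returns the refit
    best model plus the per-grid-point mean CV AUROC table.
    """
    from sklearn.model_selection import (GridSearchCV, StratifiedGroupKFold,
                                         StratifiedKFold)

    X = np.asarray(features, dtype=float)
    y = np.array([1 if l == "AC" else 0 for l in labels])
    for cls_idx, name in ((1, "AC"), (0, "SCC")):
        if (y == cls_idx).sum() < 5:
            raise ValueError(
                f"5-fold CV needs at least 5 slides of class {name}; "
                f"got {(y == cls_idx).sum()}")
    grid = cv_grid if cv_grid is not None else DEFAULT_GRIDS[algo]
    est = _build_estimator(algo, weights, seed)
    if groups is not None:
        cv = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=seed)
        split = list(cv.split(X, y, groups=np.asarray(groups)))
    else:
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        split = list(cv.split(X, y))
    fit_params = {}
    if algo == "adaboost" and weights is not None:
        fit_params["sample_weight"] = np.where(y == 1, weights.w_ac, weights.w_scc)
    search = GridSearchCV(est, grid, scoring="roc_auc", cv=split, refit=True)
    search.fit(X, y, **fit_params)
    table = pd.DataFrame(search.cv_results_["params"])
    table["mean_cv_auroc"] = search.cv_results_["mean_test_score"]
    return SlideClassifier(estimator=search.best_estimator_, algo=algo,
                           scheme=scheme, cv_table=table)


def featurize_bag(bag: PredictionBag, model: SlideClassifier) -> np.ndarray:
    if model.scheme == "histogram":
        return histogram_features(bag, model.n_bins).values
    if model.scheme == "tfidf":
        if model.vectorizer is None:
            raise ValueError("tfidf model has no fitted vectorizer attached")
        return model.vectorizer.transform([bag])[0]
    raise ValueError(f"unknown scheme {model.scheme!r}")


def predict_slide(model: SlideClassifier, bag_or_features) -> tuple[float, str]:
    """Slide-level (p_ac, label) for a bag or a precomputed feature vector."""
    if isinstance(bag_or_features, PredictionBag):
        x = featurize_bag(bag_or_features, model)
    elif isinstance(bag_or_features, FeatureVector):
        if bag_or_features.scheme != model.scheme:
            raise ValueError(
                f"feature scheme {bag_or_features.scheme!r} does not match the "
                f"model's {model.scheme!r}")
        x = bag_or_features.values
    else:
        x = np.asarray(bag_or_features, dtype=float)
    p_ac = float(model.estimator.predict_proba(x.reshape(1, -1))[0, 1])
    return p_ac, ("AC" if p_ac >= model.threshold else "SCC")


def bags_from_predictions(predictions, slide_id: str,
                          case_id: Optional[str] = None) -> PredictionBag:
    """Assemble a bag from :class:`~wsisubtyper.cnn.PatchPrediction` objects,
    keeping row-major scan order."""
    return PredictionBag(
        slide_id=slide_id, case_id=case_id,
        tokens=[p.label for p in predictions],
        probs=np.array([p.p_ac for p in predictions]))
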