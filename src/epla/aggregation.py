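"""WSI-level aggregation of patch likelihoods: the EPLA core.

A slide is a *bag* of patch MSI likelihoods in [0,1].  Two independent
representations summarize the bag:

* PALHI — the occurrence histogram of the likelihoods over 100 equal-width
  bins, classified with gradient-boosted trees (xgboost);
* BoW — each likelihood is quantized to one of 100 "words", the slide becomes
  an L2-normalized TF-IDF vector, classified with Gaussian Naive Bayes.

The two slide scores are combined convexly (``alpha * palhi + (1-alpha) * bow``)
with the weight chosen by a grid scan on out-of-fold training scores.  The
concatenated 200-dimensional slide representation carries the feature names
FEA#001..FEA#100 (histogram bins) and FEA#101..FEA#200 (TF-IDF words).

A deep-learning majority-voting baseline (slide call = majority of thresholded
patch predictions) is provided for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from xgboost import XGBClassifier

from .evaluation import roc_auc, youden_cutoff

N_BINS = 100
N_WORDS = 100

#: Hyperparameter grid searched by cross-validation when fitting PALHI.
PALHI_GRID = {
    "max_depth": (2, 3, 4),
    "n_estimators": (50, 100, 200),
    "learning_rate": (0.05, 0.1, 0.3),
}


def feature_names() -> list[str]:
    """FEA#001..FEA#200: histogram bins then TF-IDF words."""
    return [f"FEA#{i:03d}" for i in range(1, N_BINS + N_WORDS + 1)]


def _check_bag(bag) -> np.ndarray:
    bag = np.asarray(bag, dtype=float).ravel()
    if bag.size == 0:
        raise ValueError("empty likelihood bag")
    if bag.min() < 0 or bag.max() > 1:
        raise ValueError("likelihoods must lie in [0,1]")
    return bag


def build_histogram(likelihoods, n_bins: int = N_BINS) -> np.ndarray:
    """Normalized occurrence histogram over equal-width bins on [0,1].

    Bin i (1-based) covers [(i-1)/n, i/n), the last bin closed so that a
    likelihood of exactly 1.0 lands in it.  Frequencies sum to 1.
    """
    bag = _check_bag(likelihoods)
    counts, _ = np.histogram(bag, bins=n_bins, range=(0.0, 1.0))
    return counts / bag.size


def likelihood_word(p) -> np.ndarray:
    """Word index of a likelihood: ceil(100 p), clamped to [1, 100]."""
    w = np.ceil(np.asarray(p, dtype=float) * N_WORDS).astype(int)
    return np.clip(w, 1, N_WORDS)


@dataclass
class BowVocabulary:
    """Smoothed inverse-document-frequency weights over the 100 likelihood words."""

    idf: np.ndarray
    n_slides_fit: int
    n_words: int = N_WORDS

    def to_dict(self) -> dict:
        return {
            "idf": self.idf.tolist(),
            "n_slides_fit": self.n_slides_fit,
            "n_words": self.n_words,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BowVocabulary":
        return cls(np.asarray(d["idf"]), d["n_slides_fit"], d["n_words"])


def fit_bow_vocabulary(cohort_likelihoods, n_words: int = N_WORDS) -> BowVocabulary:
    """Fit idf(w) = ln((1+N)/(1+df(w))) + 1 over a corpus of likelihood bags.

    df(w) is the number of slides containing word w; the +1 smoothing keeps
    idf finite and positive for words absent from the corpus.
    """
    bags = list(cohort_likelihoods)
    if not bags:
        raise ValueError("need at least one bag to fit a vocabulary")
    df = np.zeros(n_words)
    for bag in bags:
        words = np.unique(likelihood_word(_check_bag(bag)))
        df[words - 1] += 1
    n = len(bags)
    idf = np.log((1 + n) / (1 + df)) + 1
    return BowVocabulary(idf=idf, n_slides_fit=n)


def build_tfidf(bag, vocab: BowVocabulary) -> np.ndarray:
    """L2-normalized tf·idf vector of a bag over the 100-word vocabulary."""
    bag = _check_bag(bag)
    words = likelihood_word(bag)
    tf = np.bincount(words - 1, minlength=vocab.n_words) / bag.size
    v = tf * vocab.idf
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def signature_vector(bag, vocab: BowVocabulary) -> np.ndarray:
    """Concatenated 200-feature slide representation (PALHI block, BoW block)."""
    return np.concatenate([build_histogram(bag), build_tfidf(bag, vocab)])


def signature_matrix(bags: dict[str, np.ndarray], vocab: BowVocabulary) -> pd.DataFrame:
    """Slides x FEA#001..FEA#200 matrix, rows ordered by the dict's keys."""
    rows = {sid: signature_vector(bag, vocab) for sid, bag in bags.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=feature_names())


def _check_two_classes(labels):
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("single-class training set")
    return labels


def _new_xgb(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
    )


def fit_palhi(
    train_signatures,
    labels,
    cv_folds: int = 5,
    seed: int = 0,
    param_grid: dict = PALHI_GRID,
):
    """Gradient-boosted-tree classifier on the 100-bin histogram block.

    Hyperparameters (tree depth, number of trees, learning rate) are chosen by
    stratified cross-validation maximizing mean WSI-level AUC; ties go to the
    first grid point in deterministic iteration order.  Returns the refit
    classifier with ``cv_table_`` (per-grid-point mean AUC) and ``best_params_``
    attached.
    """
    x = np.asarray(train_signatures, dtype=float)
    y = _check_two_classes(labels)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    min_class = int(min(np.bincount(y)))
    if min_class < 2:
        # too few slides in one class to cross-validate: fall back to the
        # middle of the grid
        params = {"max_depth": 3, "n_estimators": 100, "learning_rate": 0.1}
        model = _new_xgb(params, seed)
        model.fit(x, y)
        model.best_params_ = params
        model.cv_table_ = pd.DataFrame()
        return model
    skf = StratifiedKFold(
        n_splits=min(cv_folds, min_class), shuffle=True, random_state=seed
    )
    folds = list(skf.split(x, y))

    grid_points = [
        {"max_depth": d, "n_estimators": n, "learning_rate": lr}
        for d in param_grid["max_depth"]
        for n in param_grid["n_estimators"]
        for lr in param_grid["learning_rate"]
    ]
    cv_rows = []
    best = None
    for params in grid_points:
        aucs = []
        for tr, va in folds:
            if len(np.unique(y[va])) < 2:
                continue
            clf = _new_xgb(params, seed)
            clf.fit(x[tr], y[tr])
            aucs.append(roc_auc(clf.predict_proba(x[va])[:, 1], y[va]))
        mean_auc = float(np.mean(aucs))
        cv_rows.append({**params, "mean_cv_auc": mean_auc})
        if best is None or mean_auc > best[0] + 1e-12:
            best = (mean_auc, params)
    model = _new_xgb(best[1], seed)
    model.fit(x, y)
    model.best_params_ = best[1]
    model.cv_table_ = pd.DataFrame(cv_rows)
    return model


def fit_bow(train_signatures, labels) -> GaussianNB:
    """Gaussian Naive Bayes on the 100 TF-IDF features (variance smoothing 1e-9)."""
    x = np.asarray(train_signatures, dtype=float)
    y = _check_two_classes(labels)
    model = GaussianNB(var_smoothing=1e-9)
    model.fit(x, y)
    return model


def out_of_fold_scores(
    palhi_block, bow_block, labels, cv_folds: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Leak-free out-of-fold PALHI and BoW scores on the training set.

    Each fold's scores come from models fit on the remaining folds only; the
    PALHI hyperparameter search runs inside each training fold.
    """
    hist = np.asarray(palhi_block, dtype=float)
    tfidf = np.asarray(bow_block, dtype=float)
    y = _check_two_classes(labels)
    min_class = int(min(np.bincount(y)))
    if min_class < 2:
        raise ValueError("need at least 2 slides per class for out-of-fold scores")
    skf = StratifiedKFold(
        n_splits=min(cv_folds, min_class), shuffle=True, random_state=seed
    )
    palhi_oof = np.empty(len(y))
    bow_oof = np.empty(len(y))
    for tr, va in skf.split(hist, y):
        pm = fit_palhi(hist[tr], y[tr], cv_folds=max(2, cv_folds - 1), seed=seed)
        bm = fit_bow(tfidf[tr], y[tr])
        palhi_oof[va] = pm.predict_proba(hist[va])[:, 1]
        bow_oof[va] = bm.predict_proba(tfidf[va])[:, 1]
    return palhi_oof, bow_oof


def fit_ensemble_weight(
    palhi_cv_scores, bow_cv_scores, labels, grid_step: float = 0.01
) -> float:
    """Convex weight alpha maximizing AUC of alpha*palhi + (1-alpha)*bow.

    Scores must be out-of-fold training predictions (never test data).  The
    scan runs over {0, grid_step, ..., 1}; among tied maxima the alpha closest
    to 0.5 wins (then the smaller alpha on exact distance ties).
    """
    p = np.asarray(palhi_cv_scores, dtype=float)
    b = np.asarray(bow_cv_scores, dtype=float)
    if p.shape != b.shape:
        raise ValueError("component score vectors must have equal length")
    y = _check_two_classes(labels)
    alphas = np.round(np.arange(0, 1 + grid_step / 2, grid_step), 10)
    aucs = np.array([roc_auc(a * p + (1 - a) * b, y) for a in alphas])
    best_auc = aucs.max()
    tied = alphas[aucs >= best_auc - 1e-12]
    return float(tied[np.lexsort((tied, np.abs(tied - 0.5)))[0]])


@dataclass
class WSIPrediction:
    """Component and ensemble slide scores with the thresholded MS call."""

    slide_id: str
    palhi_score: float
    bow_score: float
    ensemble_score: float
    alpha: float
    predicted_label: str
    cutoff: float


@dataclass
class EplaModel:
    """Fitted WSI-level classifier bundle: vocabulary, PALHI, BoW, alpha, cutoff."""

    vocab: BowVocabulary
    palhi: XGBClassifier
    bow: GaussianNB
    alpha: float
    cutoff: float = 0.5

    def component_scores(self, bag) -> tuple[float, float]:
        sig = signature_vector(bag, self.vocab)
        hist, tfidf = sig[:N_BINS], sig[N_BINS:]
        p = float(self.palhi.predict_proba(hist[None, :])[0, 1])
        b = float(self.bow.predict_proba(tfidf[None, :])[0, 1])
        return p, b

    def score_bags(self, bags: dict[str, np.ndarray]) -> pd.DataFrame:
        """Ensemble scores for a cohort of bags, indexed by slide_id."""
        rows = {}
        for sid, bag in bags.items():
            p, b = self.component_scores(bag)
            rows[sid] = (p, b, self.alpha * p + (1 - self.alpha) * b)
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["palhi_score", "bow_score", "ensemble_score"]
        )

    def score_signature_matrix(self, x: np.ndarray) -> np.ndarray:
        """Ensemble scores from precomputed 200-feature rows."""
        x = np.asarray(x, dtype=float)
        p = self.palhi.predict_proba(x[:, :N_BINS])[:, 1]
        b = self.bow.predict_proba(x[:, N_BINS:])[:, 1]
        return self.alpha * p + (1 - self.alpha) * b


def fit_epla(
    bags: dict[str, np.ndarray],
    labels: pd.Series,
    cv_folds: int = 5,
    seed: int = 0,
) -> EplaModel:
    """Fit the full WSI-level stack on training bags.

    Fits the BoW vocabulary, both component classifiers, the ensemble weight
    on out-of-fold scores, and a Youden cutoff on training ensemble scores.
    """
    sids = list(bags)
    y = labels.loc[sids].to_numpy()
    vocab = fit_bow_vocabulary([bags[s] for s in sids])
    sig = signature_matrix(bags, vocab).loc[sids].to_numpy()
    hist, tfidf = sig[:, :N_BINS], sig[:, N_BINS:]
    palhi_oof, bow_oof = out_of_fold_scores(hist, tfidf, y, cv_folds, seed)
    alpha = fit_ensemble_weight(palhi_oof, bow_oof, y)
    palhi = fit_palhi(hist, y, cv_folds=cv_folds, seed=seed)
    bow = fit_bow(tfidf, y)
    train_scores = alpha * palhi_oof + (1 - alpha) * bow_oof
    cutoff, _, _ = youden_cutoff(train_scores, y)
    return EplaModel(vocab=vocab, palhi=palhi, bow=bow, alpha=alpha, cutoff=cutoff)


def predict_wsi(
    bag, vocab, palhi_model, bow_model, alpha, cutoff, slide_id: str = ""
) -> WSIPrediction:
    """Score one bag through both pipelines and threshold the convex ensemble."""
    model = EplaModel(vocab=vocab, palhi=palhi_model, bow=bow_model, alpha=alpha, cutoff=cutoff)
    p, b = model.component_scores(bag)
    ens = alpha * p + (1 - alpha) * b
    return WSIPrediction(
        slide_id=slide_id,
        palhi_score=p,
        bow_score=b,
        ensemble_score=ens,
        alpha=alpha,
        predicted_label="MSI" if ens >= cutoff else "MSS",
        cutoff=cutoff,
    )


def majority_vote_baseline(bag, patch_threshold: float = 0.5) -> tuple[float, str]:
    """Deep-learning majority-voting baseline.

    The vote fraction (share of patches with likelihood >= patch_threshold)
    doubles as the continuous ROC score; the slide is called MSI only on a
    strict majority (> 0.5).
    """
    bag = _check_bag(bag)
    frac = float((bag >= patch_threshold).mean())
    return frac, ("MSI" if frac > 0.5 else "MSS")


def bags_from_table(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Group a patch-likelihood table (slide_id, grid_x, grid_y, likelihood) into bags."""
    return {
        sid: grp["likelihood"].to_numpy()
        for sid, grp in table.groupby("slide_id", sort=True)
    }
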