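"""ROI summaries, clinical correlations, and ROC-based classification.

After group inference, mean standardised (dynamic) ReHo is extracted
from each significant cluster, Pearson correlations link those ROI
values to clinical covariates (THI score, hearing-loss duration, PTA,
...), binary logistic regression turns ROI values into a predictive
probability for diagnosis, and ROC curves / AUCs quantify the
discriminative value — individually and with all features combined
under SVM, decision-tree, random-forest, KNN and logistic models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import ScalarMap

logger = logging.getLogger("rehodyn.clinical")

__all__ = [
    "RocResult",
    "extract_roi_means",
    "roi_feature_table",
    "pearson_corr",
    "correlation_table",
    "logistic_predictive_prob",
    "roc_auc",
    "compare_classifiers",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("svm", "decision_tree", "random_forest", "knn", "logistic")


@dataclass
class RocResult:
    """ROC curve and its area.

    The curve starts at (0, 0), ends at (1, 1), and TPR is
    non-decreasing; the AUC equals the Mann–Whitney probability that a
    random positive outranks a random negative (ties count 1/2).
    """

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    model: str = "scores"
    cv_scheme: str = "in-sample"
    seed: int | None = None


def extract_roi_means(smap: ScalarMap, roi_mask: np.ndarray) -> float:
    """Arithmetic mean of the map over the ROI's defined voxels."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != smap.shape:
        raise ValueError("ROI mask shape must match the map")
    sel = roi_mask & smap.mask & np.isfinite(smap.data)
    if not sel.any():
        raise ValueError("ROI mask selects no defined voxels")
    return float(smap.data[sel].mean())


def roi_feature_table(
    maps: dict[str, list[ScalarMap]],
    rois: dict[str, np.ndarray],
    subject_ids: list[str],
) -> pd.DataFrame:
    """Per-subject ROI means, columns named ``<metric>__<roi>``.

    ``maps`` holds one list of per-subject maps per metric (e.g.
    ``{"reho": [...], "dreho": [...]}``); every list must align with
    ``subject_ids``.
    """
    data: dict[str, list[float]] = {}
    for metric, subject_maps in maps.items():
        if len(subject_maps) != len(subject_ids):
            raise ValueError(f"metric {metric!r}: {len(subject_maps)} maps for {len(subject_ids)} subjects")
        for roi_name, roi_mask in rois.items():
            data[f"{metric}__{roi_name}"] = [
                extract_roi_means(m, roi_mask) for m in subject_maps
            ]
    return pd.DataFrame(data, index=pd.Index(subject_ids, name="subject_id"))


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from the t transform (n - 2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must be non-constant")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: list[str],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """All ROI-by-covariate Pearson correlations (rows with NaN dropped).

    ROI preselection stands in for multiplicity control by default, as
    is common for cluster-restricted correlation analyses; an optional
    Bonferroni correction over the table is available.
    """
    rows = []
    for roi in features.columns:
        for cov in covariates:
            pair = pd.DataFrame({"roi": features[roi].to_numpy(),
                                 "cov": pd.to_numeric(clinical[cov], errors="coerce").to_numpy()}).dropna()
            if len(pair) < 3:
                continue
            r, p = pearson_corr(pair["roi"], pair["cov"])
            rows.append({"roi": roi, "covariate": cov, "r": r, "p": p, "n": len(pair)})
    table = pd.DataFrame(rows, columns=["roi", "covariate", "r", "p", "n"])
    if bonferroni and len(table):
        table["p_bonferroni"] = np.minimum(table["p"] * len(table), 1.0)
    return table


def logistic_predictive_prob(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
) -> np.ndarray:
    """In-sample predicted probabilities from a binary logistic fit.

    The fit is maximum likelihood (no penalty) with an intercept; under
    perfect separation the unpenalised likelihood has no maximiser, so
    the fit falls back to a ridge-penalised solution and logs a warning.
    The probabilities serve as the single "predictive probability"
    covariate that the ROC analysis consumes.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    model = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-10)
    model.fit(X, y)
    # unpenalised coefficients diverge under separation: detect via huge
    # coefficients or non-convergence and fall back to ridge
    if (not np.isfinite(model.coef_).all() or np.abs(model.coef_).max() > 1e6
            or model.n_iter_[0] >= 2000):
        logger.warning("logistic fit did not converge (likely separation); using ridge fallback")
        model = LogisticRegression(C=1.0, max_iter=2000)
        model.fit(X, y)
    logger.info("logistic fit converged in %d iterations", int(model.n_iter_[0]))
    return model.predict_proba(X)[:, 1]


def roc_auc(scores, labels, model: str = "scores",
            cv_scheme: str = "in-sample", seed: int | None = None) -> RocResult:
    """ROC curve and AUC by the Mann–Whitney pairwise formulation.

    AUC = P(score_pos > score_neg) + 0.5 P(tie), computed exactly over
    all positive-negative pairs; the curve comes from sweeping every
    score threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    pos, neg = scores[y == classes[1]], scores[y == classes[0]]
    # exact pairwise (Mann-Whitney) AUC, ties counted one half
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    auc = float(wins / (pos.size * neg.size))
    fpr, tpr, _ = roc_curve(y, scores, pos_label=classes[1])
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, model=model, cv_scheme=cv_scheme, seed=seed)


def _make_models(seed: int) -> dict[str, object]:
    # fixed, documented hyperparameters: deterministic results, no tuning
    return {
        "svm": make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, random_state=seed)),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5)),
        "logistic": make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000)),
    }


def _scores_of(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, 1]
        except AttributeError:
            pass
    return model.decision_function(X)


def compare_classifiers(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    models: tuple[str, ...] = CLASSIFIER_NAMES,
    n_splits: int = 5,
    seed: int = 0,
    in_sample: bool = False,
) -> pd.DataFrame:
    """AUC per model, stratified k-fold CV by default (fold scores pooled).

    ``in_sample=True`` instead fits on all data and scores the training
    set, mirroring single-cohort reports that do not hold data out; the
    output names the evaluation mode either way.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    unknown = set(models) - set(CLASSIFIER_NAMES)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    min_class = int(np.bincount(pd.factorize(y)[0]).min())
    if not in_sample and n_splits > min_class:
        logger.warning("reducing n_splits from %d to %d (smallest class size)", n_splits, min_class)
        n_splits = min_class
    rows = []
    for name in models:
        model = _make_models(seed)[name]
        if in_sample:
            model.fit(X, y)
            scores = _scores_of(model, X)
            scheme = "in-sample"
        else:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            scores = np.empty(len(y))
            for train, test in skf.split(X, y):
                model.fit(X[train], y[train])
                scores[test] = _scores_of(model, X[test])
            scheme = f"stratified {n_splits}-fold CV"
        res = roc_auc(scores, y, model=name, cv_scheme=scheme, seed=seed)
        rows.append({"model": name, "auc": res.auc, "scheme": scheme, "seed": seed})
    return pd.DataFrame(rows, columns=["model", "auc", "scheme", "seed"])
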