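"""Classification, chance calibration, fusion, and statistical tests.

Label convention throughout: transition = 1 (positive), maintenance = 0.
Sensitivity is transition recall, specificity maintenance recall.  The
empirical chance level follows the binomial method of Combrisson &
Jerbi: the smallest accuracy whose probability under guessing
(Binomial(n, 0.5)) falls below alpha — strictly above 50% for finite n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .reduce_select import StandardizeOnly

__all__ = ["ClassifierSpec", "EvalResult", "build_classifier", "crossvalidate",
           "empirical_chance", "fuse_scores", "subsample_balance",
           "band_ttests", "cross_condition", "decision_scores"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Serializable classifier description.

    ``svm-rbf``: RBF-kernel SVM; when ``tune`` is true, C is picked by an
    inner 5-fold grid search (kernel width stays at scikit-learn's
    'scale' heuristic).  ``ann``: a 10-hidden-node tanh MLP trained with
    a batch quasi-Newton rule to an error goal of 1e-5 (capped at 2000
    iterations).
    """

    kind: str = "svm-rbf"
    C: float = 1.0
    gamma: object = "scale"
    tune: bool = False
    C_grid: tuple = (0.1, 1.0, 10.0)
    hidden_nodes: int = 10
    error_goal: float = 1e-5
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("svm-rbf", "ann"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def build_classifier(spec: ClassifierSpec, tuned: bool | None = None):
    """Instantiate the scikit-learn estimator a spec describes."""
    if spec.kind == "svm-rbf":
        base = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma, random_state=spec.seed)
        if (spec.tune if tuned is None else tuned) and len(spec.C_grid) > 1:
            return GridSearchCV(base, {"C": list(spec.C_grid)}, cv=5,
                                scoring="accuracy", n_jobs=None)
        return base
    return MLPClassifier(hidden_layer_sizes=(spec.hidden_nodes,),
                         activation="tanh", solver="lbfgs",
                         tol=spec.error_goal, max_iter=spec.max_iter,
                         random_state=spec.seed)


def decision_scores(clf, X: np.ndarray) -> np.ndarray:
    """Continuous score oriented so positive means transition."""
    est = clf.best_estimator_ if hasattr(clf, "best_estimator_") else clf
    if hasattr(est, "decision_function"):
        s = est.decision_function(X)
    else:
        proba = est.predict_proba(X)
        s = proba[:, list(est.classes_).index(1)] - proba[:, list(est.classes_).index(0)]
        return s
    if list(est.classes_) == [1, 0]:        # keep orientation: positive => class 1
        s = -s
    return np.asarray(s)


@dataclass
class EvalResult:
    """Cross-validated performance with empirical-chance calibration."""
    accuracy: float                 # %
    accuracy_sd: float              # % across folds
    sensitivity: float              # % transition recall
    specificity: float              # % maintenance recall
    chance: float                   # % empirical chance level
    n: int
    fold_accuracy: np.ndarray = field(default_factory=lambda: np.array([]))
    fold_detail: pd.DataFrame | None = None
    predictions: np.ndarray | None = None   # out-of-fold predicted labels
    scores: np.ndarray | None = None        # out-of-fold continuous scores
    reducer_detail: list = field(default_factory=list)

    @property
    def above_chance(self) -> float:
        return self.accuracy - self.chance


def _fold_metrics(y_true, y_pred) -> tuple[float, float, float]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    acc = float(np.mean(y_pred == y_true))
    pos = y_true == 1
    sens = float(np.mean(y_pred[pos] == 1)) if pos.any() else np.nan
    spec = float(np.mean(y_pred[~pos] == 0)) if (~pos).any() else np.nan
    return acc, sens, spec


def crossvalidate(features: np.ndarray, labels: np.ndarray,
                  spec: ClassifierSpec | None = None, k: int = 10,
                  seed: int = 0, reducer=None) -> EvalResult:
    """Stratified k-fold cross-validation with per-fold model selection.

    Any reduction (PCA with inner-CV C_v, F-ratio selection) is refit
    inside each training partition; test rows never inform it.  Metrics
    are pooled over the out-of-fold predictions; the across-fold SD of
    accuracy is reported alongside.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if spec is None:
        spec = ClassifierSpec()
    if reducer is None:
        reducer = StandardizeOnly()
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        if counts.min() < 2:
            raise ValueError("each class needs at least two samples")
        k = int(counts.min())
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_pred = np.empty_like(y)
    oof_score = np.empty(len(y), dtype=float)
    fold_rows = []
    reducer_detail = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        red = reducer.clone()
        red.fit(X[tr], y[tr])
        clf = build_classifier(spec)
        clf.fit(red.transform(X[tr]), y[tr])
        Xte = red.transform(X[te])
        pred = clf.predict(Xte)
        oof_pred[te] = pred
        oof_score[te] = decision_scores(clf, Xte)
        acc, sens, spc = _fold_metrics(y[te], pred)
        fold_rows.append({"fold": fold, "n": len(te), "accuracy": acc * 100,
                          "sensitivity": sens * 100, "specificity": spc * 100})
        reducer_detail.append(red.describe())
    acc, sens, spc = _fold_metrics(y, oof_pred)
    detail = pd.DataFrame(fold_rows)
    return EvalResult(
        accuracy=acc * 100, accuracy_sd=float(detail["accuracy"].std(ddof=1)),
        sensitivity=sens * 100, specificity=spc * 100,
        chance=empirical_chance(len(y)), n=len(y),
        fold_accuracy=detail["accuracy"].to_numpy(), fold_detail=detail,
        predictions=oof_pred, scores=oof_score, reducer_detail=reducer_detail)


def empirical_chance(n_samples: int, alpha: float = 0.05) -> float:
    """Binomial empirical chance level, in percent.

    Smallest accuracy a = k/n such that P[Binom(n, 0.5) >= k] < alpha.
    Approaches 50% from above as n grows.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    ks = np.arange(n_samples + 1)
    sf = stats.binom.sf(ks - 1, n_samples, 0.5)     # P[X >= k]
    k_star = int(ks[np.argmax(sf < alpha)])
    return 100.0 * k_star / n_samples


def fuse_scores(S_l: np.ndarray, S_r: np.ndarray, labels: np.ndarray,
                p_grid: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 2))
                ) -> pd.DataFrame:
    """Weighted fusion of left/right hemisphere scores: S_f = p S_l + (1-p) S_r.

    Scores are oriented positive-means-transition and thresholded at
    zero.  Returns the accuracy(%)-vs-p profile; the p = 1 row is the
    left-hemisphere-only result, p = 0 the right-only one.
    """
    S_l = np.asarray(S_l, dtype=float)
    S_r = np.asarray(S_r, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(S_l) == len(S_r) == len(y)):
        raise ValueError("score vectors and labels must have equal length")
    rows = []
    for p in p_grid:
        fused = p * S_l + (1 - p) * S_r
        pred = (fused > 0).astype(int)
        rows.append({"p": p, "accuracy": float(np.mean(pred == y)) * 100})
    return pd.DataFrame(rows)


def subsample_balance(features: np.ndarray, labels: np.ndarray,
                      spec: ClassifierSpec | None = None, n_repeats: int = 10,
                      seed: int = 0, k: int = 10, reducer=None,
                      groups: np.ndarray | None = None
                      ) -> tuple[EvalResult, pd.DataFrame | None]:
    """Average cross-validation over random majority-class subsamples.

    Each repeat draws, without replacement, a majority-class subset the
    size of the minority class, runs :func:`crossvalidate`, and metrics
    are averaged.  ``groups`` (e.g. the maintenance subwindow offset per
    sample; use -1 for transition rows) yields a per-group detection
    table averaged over repeats — the temporal-evolution profile.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("minority class is empty")
    minority = int(np.argmin(counts))
    majority = 1 - minority
    if counts[minority] == counts[majority]:
        n_repeats = 1
    rng = np.random.default_rng(seed)
    results: list[EvalResult] = []
    group_rows = []
    for rep in range(n_repeats):
        maj_idx = np.flatnonzero(y == majority)
        take = rng.choice(maj_idx, size=counts[minority], replace=False)
        idx = np.sort(np.r_[np.flatnonzero(y == minority), take])
        res = crossvalidate(X[idx], y[idx], spec, k=k, seed=seed + rep,
                            reducer=reducer)
        results.append(res)
        if groups is not None:
            g = np.asarray(groups)[idx]
            for gv in np.unique(g):
                sel = g == gv
                correct = res.predictions[sel] == y[idx][sel]
                group_rows.append({"repeat": rep, "group": gv,
                                   "detection": float(np.mean(correct)) * 100,
                                   "n": int(sel.sum())})
    avg = EvalResult(
        accuracy=float(np.mean([r.accuracy for r in results])),
        accuracy_sd=float(np.mean([r.accuracy_sd for r in results])),
        sensitivity=float(np.mean([r.sensitivity for r in results])),
        specificity=float(np.mean([r.specificity for r in results])),
        chance=results[0].chance, n=results[0].n)
    profile = None
    if groups is not None:
        profile = (pd.DataFrame(group_rows)
                   .groupby("group", as_index=False)
                   .agg(detection=("detection", "mean"), n=("n", "mean")))
    return avg, profile


def band_ttests(transition_power: np.ndarray, maintenance_power: np.ndarray,
                bands: Sequence[str], alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests of whole-epoch band power, Bonferroni over bands.

    Inputs are (n_events, n_bands) arrays with rows paired by event
    (each event contributes one transition and one maintenance epoch).
    Significance threshold: alpha / n_bands (0.05/6 ≈ 0.0083 for the six
    canonical bands); degrees of freedom n_events - 1.
    """
    T = np.asarray(transition_power, dtype=float)
    M = np.asarray(maintenance_power, dtype=float)
    if T.shape != M.shape:
        raise ValueError("transition and maintenance arrays must be paired "
                         f"(shapes {T.shape} vs {M.shape})")
    if T.shape[1] != len(bands):
        raise ValueError("one column per band required")
    thresh = alpha / len(bands)
    rows = []
    for j, b in enumerate(bands):
        t, p = stats.ttest_rel(T[:, j], M[:, j])
        rows.append({"band": b, "t": float(t), "p": float(p),
                     "df": T.shape[0] - 1, "significant": bool(p < thresh)})
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = thresh
    return out


def cross_condition(features_by_stimulus: Mapping[str, tuple[np.ndarray, np.ndarray]],
                    spec: ClassifierSpec | None = None, reducer=None,
                    seed: int = 0) -> pd.DataFrame:
    """Train on one stimulus type, test on the others.

    ``features_by_stimulus`` maps stimulus factor (e.g. NC/SAM/SFM,
    presentation modes pooled) to (X, y).  Returns a tidy frame with one
    row per (train, test) pair; the diagonal is marked 'Training' and
    carries no metrics.  All model selection happens on the training
    stimulus only.
    """
    if spec is None:
        spec = ClassifierSpec()
    stimuli = list(features_by_stimulus)
    rows = []
    for train_stim in stimuli:
        Xtr, ytr = features_by_stimulus[train_stim]
        if len(np.unique(ytr)) < 2:
            for test_stim in stimuli:
                note = "Training" if test_stim == train_stim else "insufficient-train"
                rows.append({"train": train_stim, "test": test_stim,
                             "accuracy": np.nan, "sensitivity": np.nan,
                             "specificity": np.nan, "note": note})
            continue
        red = (reducer.clone() if reducer is not None else StandardizeOnly())
        red.fit(np.asarray(Xtr, float), np.asarray(ytr, int))
        clf = build_classifier(spec)
        clf.fit(red.transform(Xtr), ytr)
        for test_stim in stimuli:
            if test_stim == train_stim:
                rows.append({"train": train_stim, "test": test_stim,
                             "accuracy": np.nan, "sensitivity": np.nan,
                             "specificity": np.nan, "note": "Training"})
                continue
            Xte, yte = features_by_stimulus[test_stim]
            if set(np.unique(yte)) - {0, 1}:
                raise ValueError("labels must be 0/1")
            pred = clf.predict(red.transform(Xte))
            acc, sens, spc = _fold_metrics(yte, pred)
            rows.append({"train": train_stim, "test": test_stim,
                         "accuracy": acc * 100, "sensitivity": sens * 100,
                         "specificity": spc * 100, "note": ""})
    return pd.DataFrame(rows)
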