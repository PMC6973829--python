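"""Dimension reduction and univariate feature selection.

Two routes feed the classifiers:

* PCA whose retained dimension is set by the cumulative variance C_v,
  itself chosen on an inner 10-fold cross-validation over a grid from
  95 to 99.9% — used with the sensor-space local features.
* F-ratio ranking (between-class variance over total within-class
  variance, per feature) with the top-k features retained — used with
  the 89-region source features, where PCA's mixing would obscure which
  region a discriminative feature came from.  k is chosen on an inner
  10-fold CV over a geometric grid.

Both are fit strictly on training rows; selection reports aggregate
which bands/regions the retained features came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = ["CV_GRID", "K_GRID", "Projection", "SelectionReport",
           "fit_pca", "choose_cv", "f_ratio", "select_features",
           "PCAByInnerCV", "FRatioSelector"]

#: Cumulative-variance grid (%), endpoints 95 and 99.9.
CV_GRID: tuple[float, ...] = (95.0, 96.0, 97.0, 98.0, 99.0, 99.5, 99.9)
#: Geometric grid for the number of F-ratio-selected features.
K_GRID: tuple[int, ...] = (8, 16, 32, 64, 128)


@dataclass
class Projection:
    """A fitted PCA basis truncated at a cumulative-variance target."""
    mean: np.ndarray
    components: np.ndarray          # (retained_dim, n_features)
    explained_ratio: np.ndarray     # full spectrum, nonincreasing
    retained_dim: int
    cumulative_variance: float      # % target this truncation satisfies
    fitted_on: str = "train"

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.components.T

    def inverse_transform(self, S: np.ndarray) -> np.ndarray:
        return np.asarray(S) @ self.components + self.mean


def fit_pca(train_features: np.ndarray) -> tuple[PCA, np.ndarray]:
    """Fit a full PCA on training rows; returns (model, cumulative %)."""
    X = np.asarray(train_features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two training samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance training data")
    pca = PCA(svd_solver="full").fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_) * 100.0
    return pca, cum


def _dim_for_cv(cum: np.ndarray, cv: float) -> int:
    """Smallest number of components whose cumulative variance >= cv%."""
    d = int(np.searchsorted(cum, cv - 1e-9) + 1)
    return min(d, len(cum))


def projection_at(pca: PCA, cum: np.ndarray, cv: float) -> Projection:
    d = _dim_for_cv(cum, cv)
    return Projection(pca.mean_, pca.components_[:d],
                      pca.explained_variance_ratio_, d, cv)


def choose_cv(train_features: np.ndarray, train_labels: np.ndarray,
              grid: Sequence[float] = CV_GRID, classifier=None,
              inner_k: int = 10, seed: int = 0) -> tuple[float, int]:
    """Pick the cumulative-variance target by inner cross-validation.

    For each grid value, the training partition is 10-fold
    cross-validated with PCA truncated at that value; the grid value with
    the best mean inner accuracy wins, ties going to the smaller retained
    dimension.  Outer test rows never enter.
    """
    from .evaluate import ClassifierSpec, build_classifier   # local: avoid cycle

    grid = tuple(grid)
    if not grid:
        raise ValueError("empty cumulative-variance grid")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("inner CV needs both classes present")
    if classifier is None:
        classifier = ClassifierSpec()
    if len(grid) == 1:
        pca, cum = fit_pca(StandardScaler().fit_transform(X))
        return grid[0], _dim_for_cv(cum, grid[0])

    inner_k = min(inner_k, int(np.bincount(y).min()))
    if inner_k < 2:
        # too few samples for an inner split: keep nearly all variance
        pca, cum = fit_pca(StandardScaler().fit_transform(X))
        cv = max(grid)
        return cv, _dim_for_cv(cum, cv)
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    scores = np.zeros(len(grid))
    dims = np.zeros(len(grid))
    for tr, te in skf.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        pca, cum = fit_pca(Xtr)
        for gi, cv in enumerate(grid):
            proj = projection_at(pca, cum, cv)
            clf = build_classifier(classifier, tuned=False)
            clf.fit(proj.transform(Xtr), y[tr])
            scores[gi] += np.mean(clf.predict(proj.transform(Xte)) == y[te])
            dims[gi] += proj.retained_dim
    scores /= inner_k
    dims /= inner_k
    # best accuracy; ties toward smaller mean retained dimension
    order = sorted(range(len(grid)), key=lambda i: (-scores[i], dims[i]))
    best = order[0]
    pca, cum = fit_pca(StandardScaler().fit_transform(X))
    return grid[best], _dim_for_cv(cum, grid[best])


def f_ratio(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-class variance over total within-class variance of a feature.

    Affine-invariant; returns ``inf`` when the classes have distinct
    means but zero within-class scatter (a perfectly separating feature,
    ranked first).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("F-ratio is defined for exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least two samples")
    grand = v.mean()
    ss_between = sum((y == c).sum() * (v[y == c].mean() - grand) ** 2 for c in classes)
    ss_within = sum(((v[y == c] - v[y == c].mean()) ** 2).sum() for c in classes)
    if ss_within == 0:
        return float("inf") if ss_between > 0 else 0.0
    return float(ss_between / ss_within)


def f_ratios(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised per-column F-ratio (same convention as :func:`f_ratio`)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("F-ratio is defined for exactly two classes")
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        ssb += Xc.shape[0] * (Xc.mean(axis=0) - grand) ** 2
        ssw += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = ssb / ssw
    r[(ssw == 0) & (ssb > 0)] = np.inf
    r[(ssw == 0) & (ssb == 0)] = 0.0
    return r


@dataclass
class SelectionReport:
    """Which features an F-ratio selection kept, and where they live."""
    f_ratio: np.ndarray
    selected: np.ndarray                      # sorted indices of the top-k
    band_distribution: dict = field(default_factory=dict)
    region_distribution: dict = field(default_factory=dict)

    def to_frame(self, index=None) -> pd.DataFrame:
        n = len(self.f_ratio)
        sel = np.zeros(n, dtype=bool)
        sel[self.selected] = True
        df = pd.DataFrame({"feature_id": np.arange(n), "f_ratio": self.f_ratio,
                           "selected": sel})
        if index is not None:
            df["band"] = [ix[0] for ix in index]
            df["region"] = [ix[1] for ix in index]
            df["segment"] = [ix[2] for ix in index]
        return df


def select_features(train_features: np.ndarray, train_labels: np.ndarray,
                    k: int, index: Sequence[tuple] | None = None) -> SelectionReport:
    """Keep the k features with the largest F-ratio (ties: lower index).

    If a feature ``index`` of (band, region, segment) triples is given,
    the report includes the marginal distribution of the selected set
    over bands and over regions (each summing to 1).
    """
    X = np.asarray(train_features, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > X.shape[1]:
        raise ValueError(f"k = {k} exceeds feature dimension {X.shape[1]}")
    r = f_ratios(X, train_labels)
    # stable sort on -r keeps lower indices first among ties
    order = np.argsort(-r, kind="stable")
    selected = np.sort(order[:k])
    report = SelectionReport(r, selected)
    if index is not None:
        bands = [index[i][0] for i in selected]
        regions = [index[i][1] for i in selected]
        report.band_distribution = {b: bands.count(b) / k for b in dict.fromkeys(ix[0] for ix in index)}
        report.region_distribution = {g: regions.count(g) / k for g in dict.fromkeys(ix[1] for ix in index)}
    return report


# ---------------------------------------------------------------------------
# Per-fold reducers used inside cross-validation
# ---------------------------------------------------------------------------

class PCAByInnerCV:
    """Standardise + PCA with C_v chosen by inner 10-fold CV (per fold)."""

    def __init__(self, grid: Sequence[float] = CV_GRID, classifier=None,
                 inner_k: int = 10, seed: int = 0):
        self.grid = tuple(grid)
        self.classifier = classifier
        self.inner_k = inner_k
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PCAByInnerCV":
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.chosen_cv_, self.retained_dim_ = choose_cv(
            X, y, self.grid, self.classifier, self.inner_k, self.seed)
        pca, cum = fit_pca(Xs)
        self.projection_ = projection_at(pca, cum, self.chosen_cv_)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.projection_.transform(self.scaler_.transform(X))

    def clone(self) -> "PCAByInnerCV":
        return PCAByInnerCV(self.grid, self.classifier, self.inner_k, self.seed)

    def describe(self) -> dict:
        return {"cv": self.chosen_cv_, "dim": self.retained_dim_}


class FRatioSelector:
    """Standardise + top-k F-ratio selection, k chosen by inner 10-fold CV."""

    def __init__(self, k: int | None = None, k_grid: Sequence[int] = K_GRID,
                 classifier=None, inner_k: int = 10, seed: int = 0,
                 index: Sequence[tuple] | None = None):
        self.k = k
        self.k_grid = tuple(k_grid)
        self.classifier = classifier
        self.inner_k = inner_k
        self.seed = seed
        self.index = index

    def _choose_k(self, X: np.ndarray, y: np.ndarray) -> int:
        from .evaluate import ClassifierSpec, build_classifier

        grid = [k for k in self.k_grid if k <= X.shape[1]] or [X.shape[1]]
        if len(grid) == 1:
            return grid[0]
        spec = self.classifier or ClassifierSpec()
        inner_k = min(self.inner_k, int(np.bincount(y).min()))
        if inner_k < 2:
            return grid[0]
        skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=self.seed)
        scores = np.zeros(len(grid))
        for tr, te in skf.split(X, y):
            r = f_ratios(X[tr], y[tr])
            order = np.argsort(-r, kind="stable")
            for gi, k in enumerate(grid):
                cols = np.sort(order[:k])
                clf = build_classifier(spec, tuned=False)
                clf.fit(X[tr][:, cols], y[tr])
                scores[gi] += np.mean(clf.predict(X[te][:, cols]) == y[te])
        best = sorted(range(len(grid)), key=lambda i: (-scores[i], grid[i]))[0]
        return grid[best]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FRatioSelector":
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        k = self.k if self.k is not None else self._choose_k(Xs, y)
        self.report_ = select_features(Xs, y, k, index=self.index)
        self.k_ = k
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.scaler_.transform(X)[:, self.report_.selected]

    def clone(self) -> "FRatioSelector":
        return FRatioSelector(self.k, self.k_grid, self.classifier,
                              self.inner_k, self.seed, self.index)

    def describe(self) -> dict:
        return {"k": self.k_,
                "band_distribution": self.report_.band_distribution,
                "region_distribution": self.report_.region_distribution}


class StandardizeOnly:
    """Plain train-fold standardisation (no reduction)."""

    def fit(self, X, y=None):
        self.scaler_ = StandardScaler().fit(X)
        return self

    def transform(self, X):
        return self.scaler_.transform(X)

    def clone(self):
        return StandardizeOnly()

    def describe(self) -> dict:
        return {}
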