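"""Sparse PLS discriminant analysis: per-component keepX variable selection,
centroid-distance classification, balanced error rate, and repeated
stratified-CV tuning with feature-selection stability."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class SPLSDAModel:
    classes: tuple[str, ...]
    keepX: tuple[int, ...]
    feature_names: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    weights: np.ndarray  # p x ncomp, sparse columns
    loadings: np.ndarray  # p x ncomp, X deflation loadings
    scores: np.ndarray  # n x ncomp latent scores of training data
    centroids: pd.DataFrame  # class x ncomp
    train_labels: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def selected_features(self, component: int | None = None) -> list[str]:
        if component is None:
            mask = (self.weights != 0).any(axis=1)
        else:
            mask = self.weights[:, component] != 0
        return [f for f, m_ in zip(self.feature_names, mask) if m_]

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        Xs = (X.loc[:, list(self.feature_names)].to_numpy(dtype=float) - self.x_mean) / self.x_sd
        T = np.zeros((Xs.shape[0], self.n_components))
        for c in range(self.n_components):
            T[:, c] = Xs @ self.weights[:, c]
            Xs = Xs - np.outer(T[:, c], self.loadings[:, c])
        return T


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def fit_splsda(
    X: pd.DataFrame, y, n_components: int, keepX: list[int]
) -> SPLSDAModel:
    """Fit a sparse PLS-DA model.

    Per component the PLS weight vector (dominant singular vector of X'Y) is
    soft-thresholded to its keepX largest-magnitude entries, scores are
    computed, and X is deflated in regression mode; Y is left undeflated.
    Deterministic: no randomness in the fit.
    """
    if len(keepX) != n_components:
        raise ValueError("keepX length must equal n_components")
    y = np.asarray(y, dtype=object).astype(str)
    features = tuple(map(str, X.columns))
    Xs, x_mean, x_sd = _standardize(X.to_numpy(dtype=float))
    n, p = Xs.shape
    if any(k > p for k in keepX):
        raise ValueError(f"keepX exceeds n_features={p}")
    classes = tuple(sorted(set(y)))
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, v in counts.items() if v < 2]
    if small:
        raise ValueError(f"class(es) with <2 samples: {small}")
    Y = np.stack([(y == c).astype(float) for c in classes], axis=1)
    Ys, _, _ = _standardize(Y)

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Xd = Xs.copy()
    for c in range(n_components):
        M = Xd.T @ Ys
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        w = u[:, 0]
        # sign convention: largest-|w| entry positive, for determinism
        w = w * np.sign(w[np.argmax(np.abs(w))])
        k = keepX[c]
        if k < p:
            absw = np.abs(w)
            thresh = np.partition(absw, p - k - 1)[p - k - 1]
            w = np.sign(w) * np.maximum(absw - thresh, 0.0)
            if (w != 0).sum() > k:  # thresh ties: keep the first k by magnitude
                order = np.argsort(-np.abs(w), kind="mergesort")
                w[order[k:]] = 0.0
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate component: all weights thresholded to 0")
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        pl = Xd.T @ t / tt if tt > 0 else np.zeros(p)
        Xd = Xd - np.outer(t, pl)
        W[:, c], P[:, c], T[:, c] = w, pl, t

    centroids = pd.DataFrame(
        [T[y == c].mean(axis=0) for c in classes],
        index=list(classes),
        columns=[f"comp{i + 1}" for i in range(n_components)],
    )
    return SPLSDAModel(
        classes=classes,
        keepX=tuple(keepX),
        feature_names=features,
        x_mean=x_mean,
        x_sd=x_sd,
        weights=W,
        loadings=P,
        scores=T,
        centroids=centroids,
        train_labels=y,
    )


def balanced_error_rate(y_true, y_pred) -> float:
    """Mean over classes of the per-class misclassification rate."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    rates = [
        float((y_pred[y_true == c] != c).mean()) for c in sorted(set(y_true))
    ]
    return float(np.mean(rates))


def classify_centroid(model: SPLSDAModel, X_new: pd.DataFrame, y_true=None):
    """Nearest-centroid prediction in the latent space (Euclidean).

    Ties are broken toward the lexicographically first class and flagged.
    Returns (predictions, BER or None, tie flags).
    """
    T = model.transform(X_new)
    cents = model.centroids.to_numpy()
    d = np.linalg.norm(T[:, None, :] - cents[None, :, :], axis=2)
    order = np.argsort(d, axis=1, kind="mergesort")  # classes sorted; first min wins
    pred = np.array([model.classes[i] for i in order[:, 0]])
    ties = np.isclose(np.partition(d, 1, axis=1)[:, 0], np.partition(d, 1, axis=1)[:, 1])
    ber = balanced_error_rate(y_true, pred) if y_true is not None else None
    return pd.Series(pred, index=X_new.index), ber, pd.Series(ties, index=X_new.index)


@dataclass
class TuningResult:
    grid: pd.DataFrame  # component, keepX, mean_ber
    chosen_keepX: tuple[int, ...]
    n_components: int
    ber_per_ncomp: pd.Series
    ber: float
    stability: pd.Series  # feature -> selection frequency across CV fits


def _cv_ber(X, y, n_components, keepX, folds, repeats, seed, collect=None) -> float:
    y = np.asarray(y).astype(str)
    bers = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train, test in skf.split(X, y):
            model = fit_splsda(X.iloc[train], y[train], n_components, keepX)
            _, ber, _ = classify_centroid(model, X.iloc[test], y[test])
            bers.append(ber)
            if collect is not None:
                collect.append(model.selected_features())
    return float(np.mean(bers))


def tune_splsda(
    X: pd.DataFrame,
    y,
    max_components: int,
    keepX_grid: list[int],
    folds: int = 3,
    repeats: int = 50,
    seed: int = 0,
) -> TuningResult:
    """Sequential per-component keepX tuning by repeated stratified CV.

    For each component in turn every candidate keepX is evaluated by mean BER
    (centroid distance) with previously chosen components fixed; ties prefer
    fewer features. The number of components is the BER-minimizing prefix
    (ties prefer fewer). Stability is the per-feature selection frequency
    over all fold-fits of the chosen setting.
    """
    y = np.asarray(y).astype(str)
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"class(es) smaller than folds={folds}: {counts[counts < folds].index.tolist()}"
        )
    chosen: list[int] = []
    rows = []
    ber_per_ncomp = {}
    for comp in range(1, max_components + 1):
        best = None
        for k in sorted(keepX_grid):
            ber = _cv_ber(X, y, comp, chosen + [k], folds, repeats, seed)
            rows.append({"component": comp, "keepX": k, "mean_ber": ber})
            if best is None or ber < best[0] - 1e-12:
                best = (ber, k)
        chosen.append(best[1])
        ber_per_ncomp[comp] = best[0]
    ber_series = pd.Series(ber_per_ncomp)
    n_components = int(ber_series.idxmin())  # idxmin -> first (fewest comps) on ties
    chosen = chosen[:n_components]

    selections: list[list[str]] = []
    final_ber = _cv_ber(X, y, n_components, chosen, folds, repeats, seed, collect=selections)
    freq = pd.Series(0.0, index=[str(c) for c in X.columns])
    for sel in selections:
        freq.loc[sel] += 1.0
    stability = freq / len(selections)
    return TuningResult(
        grid=pd.DataFrame(rows),
        chosen_keepX=tuple(chosen),
        n_components=n_components,
        ber_per_ncomp=ber_series,
        ber=final_ber,
        stability=stability.sort_values(ascending=False, kind="mergesort"),
    )


def expression_pattern(X: pd.DataFrame, y, features: list[str]) -> pd.DataFrame:
    """Sign pattern of per-class mean Z-scores for selected features
    (up/down call per class)."""
    y = np.asarray(y).astype(str)
    Z = X.loc[:, features].apply(lambda c: (c - c.mean()) / (c.std(ddof=1) or 1.0))
    out = {}
    for c in sorted(set(y)):
        mean_z = Z[y == c].mean(axis=0)
        out[c] = np.where(mean_z > 0, "up", "down")
    return pd.DataFrame(out, index=features)
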