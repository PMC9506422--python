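"""Unsupervised structure recovery: high-variance protein filter, consensus
clustering (bootstrap resampling + PAM on Pearson distance), silhouette-based
K selection, PCA coordinates, and PVCA-style variance attribution."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .core import IntensityMatrix


def high_variance_filter(m: IntensityMatrix, sd_thr: float = 1.25) -> IntensityMatrix:
    """Keep proteins whose across-sample SD exceeds ``sd_thr`` (strict); no
    Z-scoring is applied."""
    sd = m.values.std(axis=1, ddof=1)
    keep = sd > sd_thr
    if not keep.any():
        raise ValueError(f"no protein with SD > {sd_thr}; lower the threshold")
    return m.with_values(m.values.loc[keep])


def pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of X."""
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def pam(dist: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Partitioning around medoids (build + swap) on a precomputed distance
    matrix; returns integer labels 0..k-1."""
    n = dist.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        best_gain, best_c = -np.inf, -1
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(d_near - dist[:, c], 0.0).sum()
            if gain > best_gain:
                best_gain, best_c = gain, c
        medoids.append(best_c)
    # SWAP
    medoids = list(medoids)
    for _ in range(max_iter):
        cost = dist[:, medoids].min(axis=1).sum()
        best = (0.0, None, None)
        for mi, m_ in enumerate(medoids):
            others = medoids[:mi] + medoids[mi + 1 :]
            d_rest = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = np.minimum(d_rest, dist[:, h]).sum()
                delta = cost - new_cost
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
    return np.argmin(dist[:, medoids], axis=1)


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]
    assignments: dict[int, pd.Series]
    silhouette: dict[int, float] = field(default_factory=dict)
    skipped_reps: int = 0

    @property
    def k_values(self) -> list[int]:
        return sorted(self.consensus)


def consensus_cluster(
    m: IntensityMatrix,
    k_range=range(2, 8),
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of samples.

    Each rep subsamples samples and proteins without replacement at the given
    inclusion probabilities and clusters the subsample with PAM on
    1 - Pearson distance for every K. consensus(i, j) = co-cluster count /
    co-sample count. The final assignment per K is complete-linkage
    hierarchical clustering of 1 - consensus.
    """
    k_range = list(k_range)
    samples = list(m.samples)
    n = len(samples)
    if n < max(k_range) + 1:
        raise ValueError(f"need >= {max(k_range) + 1} samples, have {n}")
    X = m.values.to_numpy(dtype=float).T  # samples x proteins
    nf = X.shape[1]
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(np.floor(p_item * n)))
    f_sub = max(1, int(np.floor(p_feature * nf)))

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sample = {k: np.zeros((n, n)) for k in k_range}
    skipped = 0
    for _ in range(reps):
        items = rng.choice(n, size=n_sub, replace=False)
        feats = rng.choice(nf, size=f_sub, replace=False)
        sub = X[np.ix_(items, feats)]
        dist = pearson_distance(sub)
        pair = np.ix_(items, items)
        for k in k_range:
            if k > n_sub:
                skipped += 1
                continue
            labels = pam(dist, k)
            same = np.equal.outer(labels, labels).astype(float)
            co_cluster[k][pair] += same
            co_sample[k][pair] += 1.0

    consensus, assignments = {}, {}
    for k in k_range:
        with np.errstate(invalid="ignore"):
            cons = np.divide(
                co_cluster[k], co_sample[k], out=np.zeros((n, n)), where=co_sample[k] > 0
            )
        cons = (cons + cons.T) / 2.0
        np.fill_diagonal(cons, 1.0)
        consensus[k] = pd.DataFrame(cons, index=samples, columns=samples)
        d = 1.0 - cons
        np.fill_diagonal(d, 0.0)
        Z = linkage(squareform(d, checks=False), method="complete")
        assignments[k] = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=samples)
    cr = ConsensusResult(consensus=consensus, assignments=assignments, skipped_reps=skipped)
    for k in k_range:
        cr.silhouette[k] = _avg_silhouette(consensus[k], assignments[k])
    return cr


def _avg_silhouette(consensus: pd.DataFrame, labels: pd.Series) -> float:
    d = 1.0 - consensus.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    lab = labels.to_numpy()
    if len(np.unique(lab)) < 2:
        return -1.0
    return float(np.mean(silhouette_samples(d, lab, metric="precomputed")))


def select_k(cr: ConsensusResult) -> tuple[int, pd.DataFrame]:
    """K with the highest average silhouette width on 1 - consensus; ties go
    to the smaller K. Returns (K, silhouette table)."""
    if len(cr.assignments) < 2:
        raise ValueError("need >= 2 candidate K values")
    table = pd.DataFrame(
        {"K": list(cr.silhouette), "avg_silhouette": list(cr.silhouette.values())}
    ).sort_values("K", kind="mergesort")
    best = table.loc[table["avg_silhouette"].idxmax(), "K"]  # idxmax -> first max
    return int(best), table.reset_index(drop=True)


def pca_coordinates(m: IntensityMatrix, n_components: int = 5, zscore: bool = True):
    """Sample coordinates on the leading principal components plus explained
    variance ratios."""
    V = m.values
    if zscore:
        sd = V.std(axis=1, ddof=1)
        V = V.loc[sd > 0]
        V = V.sub(V.mean(axis=1), axis=0).div(V.std(axis=1, ddof=1), axis=0)
    X = V.to_numpy(dtype=float).T
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(S))
    coords = pd.DataFrame(
        U[:, :n_components] * S[:n_components],
        index=m.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    evr = S**2 / (S**2).sum()
    return coords, pd.Series(evr[:n_components], index=coords.columns)


def pvca(
    m: IntensityMatrix,
    factors: pd.DataFrame,
    var_explained_stop: float = 0.6,
) -> pd.Series:
    """Attribute expression variance to annotated factors.

    PCA on the per-protein Z-scored matrix; leading PCs are retained until
    cumulative explained variance reaches ``var_explained_stop``; each
    retained PC is regressed on all factors jointly and its variance is
    partitioned by sum-of-squares share (eta-squared) plus residual; per-PC
    fractions are weighted by the PC's eigenvalue share and normalized to
    sum to 1.
    """
    import statsmodels.api as sm

    factors = factors.loc[list(m.samples)]
    if factors.isna().any().any():
        raise ValueError("missing factor labels")
    cols = list(factors.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if _same_partition(factors[a], factors[b]):
                raise ValueError(f"confounded factors: {a!r} and {b!r}")

    V = m.values
    sd = V.std(axis=1, ddof=1)
    V = V.loc[sd > 0]
    Z = V.sub(V.mean(axis=1), axis=0).div(V.std(axis=1, ddof=1), axis=0)
    X = Z.to_numpy(dtype=float).T
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    evr = S**2 / (S**2).sum()
    n_keep = int(np.searchsorted(np.cumsum(evr), var_explained_stop) + 1)
    n_keep = min(n_keep, len(S))
    pcs = U[:, :n_keep] * S[:n_keep]
    weights = evr[:n_keep] / evr[:n_keep].sum()

    dummies = {
        c: pd.get_dummies(factors[c].astype(str), drop_first=True, dtype=float)
        for c in cols
    }
    attribution = pd.Series(0.0, index=cols + ["residual"])
    for j in range(n_keep):
        y = pcs[:, j]
        full = sm.OLS(y, sm.add_constant(pd.concat(dummies.values(), axis=1).to_numpy())).fit()
        ss_resid = float((full.resid**2).sum())
        ss_total_fit = ss_resid
        ss_factor = {}
        for c in cols:
            # type-II: extra SS of the factor given all other factors
            others = [dummies[o] for o in cols if o != c]
            if others:
                reduced = sm.OLS(
                    y, sm.add_constant(pd.concat(others, axis=1).to_numpy())
                ).fit()
                ss = float((reduced.resid**2).sum()) - ss_resid
            else:
                base = sm.OLS(y, np.ones((len(y), 1))).fit()
                ss = float((base.resid**2).sum()) - ss_resid
            ss_factor[c] = max(ss, 0.0)
            ss_total_fit += ss_factor[c]
        frac = {c: ss_factor[c] / ss_total_fit for c in cols}
        frac["residual"] = ss_resid / ss_total_fit
        for key, v in frac.items():
            attribution[key] += weights[j] * v
    return attribution / attribution.sum()


def _same_partition(a: pd.Series, b: pd.Series) -> bool:
    da = pd.factorize(a)[0]
    db = pd.factorize(b)[0]
    return len(set(zip(da, db))) == len(set(da)) == len(set(db))
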