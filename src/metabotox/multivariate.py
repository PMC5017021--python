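"""NIPALS principal component analysis with cross-validated Q2, and
hierarchical clustering of fold-change trajectories.

The PCA follows the chemometrics convention: the data matrix (rows =
observations/injections, columns = features) is mean-centred and
unit-variance scaled by default, components are extracted one at a time by
the NIPALS power iteration with deflation, and the model is judged by R2
(explained variance of the preprocessed matrix) and Q2 (its cross-validated
predictive counterpart, 1 - PRESS/SS).  Q2 values from different
cross-validation schemes are not numerically interchangeable; the one here
is the leave-out row-projection scheme documented in :func:`q2_crossval`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

SCALINGS = ("uv", "pareto", "none")


def _preprocess(X: np.ndarray, scaling: str, center: bool) -> np.ndarray:
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}")
    X = np.asarray(X, dtype=float).copy()
    if center:
        X -= X.mean(axis=0)
    if scaling != "none":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column under variance scaling")
        X /= sd if scaling == "uv" else np.sqrt(sd)
    return X


def _nipals_component(X: np.ndarray, tol: float = 1e-10, max_iter: int = 2000):
    """One NIPALS component: returns (scores t, loadings p, n_iter).

    Convergence on the relative change of the score vector (the score
    vector converges linearly while the eigenvalue t't converges
    quadratically, so the vector criterion is the binding one).
    """
    start = int(np.argmax((X**2).sum(axis=0)))
    t = X[:, start].copy()
    if not np.any(t):
        t = X[:, 0] + 1e-12
    it = 0
    for it in range(1, max_iter + 1):
        p = X.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = X @ p
        eig = t_new @ t_new
        dt = t_new - t
        t = t_new
        if eig == 0 or (dt @ dt) < tol * tol * eig:
            break
    return t, p, it


@dataclass
class PCAResults:
    """Fitted PCA: scores, loadings and per-component variance summaries."""

    scores: np.ndarray  # n x A
    loadings: np.ndarray  # m x A
    r2: np.ndarray  # per component
    r2cum: np.ndarray
    q2: np.ndarray | None = None
    q2cum: np.ndarray | None = None
    scaling: str = "uv"
    center: bool = True

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self, index=None) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=index, columns=cols)

    def loadings_frame(self, index=None) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.n_components)]
        return pd.DataFrame(self.loadings, index=index, columns=cols)

    def summary(self) -> str:
        lines = [f"NIPALS PCA ({self.n_components} components, scaling={self.scaling})"]
        header = "  comp    R2     R2cum"
        if self.q2 is not None:
            header += "     Q2     Q2cum"
        lines.append(header)
        for a in range(self.n_components):
            row = f"  PC{a+1:<3d} {self.r2[a]:6.3f}  {self.r2cum[a]:6.3f}"
            if self.q2 is not None:
                row += f"  {self.q2[a]:6.3f}  {self.q2cum[a]:6.3f}"
            lines.append(row)
        return "\n".join(lines)


class NipalsPCA:
    """NIPALS PCA model over an observations x features matrix.

    Parameters
    ----------
    X : array-like, shape (n, m)
    n_components : int
        Must satisfy ``A <= min(n - 1, m)`` when centring.
    scaling : {"uv", "pareto", "none"}
    center : bool
    """

    def __init__(self, X, n_components: int, scaling: str = "uv", center: bool = True):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be two-dimensional")
        limit = min(X.shape[0] - (1 if center else 0), X.shape[1])
        if n_components < 0 or n_components > limit:
            raise ValueError(f"n_components must be in [0, {limit}]")
        self.X_raw = X
        self.A = n_components
        self.scaling = scaling
        self.center = center
        self.Xp = _preprocess(X, scaling, center)

    def fit(self) -> PCAResults:
        X = self.Xp.copy()
        tss = (X**2).sum()
        n, m = X.shape
        T = np.zeros((n, self.A))
        P = np.zeros((m, self.A))
        r2 = np.zeros(self.A)
        for a in range(self.A):
            t, p, _ = _nipals_component(X)
            T[:, a] = t
            P[:, a] = p
            X -= np.outer(t, p)
            r2[a] = (t @ t) / tss if tss > 0 else 0.0
        return PCAResults(
            scores=T,
            loadings=P,
            r2=r2,
            r2cum=np.cumsum(r2),
            scaling=self.scaling,
            center=self.center,
        )

    def crossval_q2(self, folds: int = 7, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Cross-validated Q2 per component and cumulative.

        Rows are assigned to folds round-robin after a seeded shuffle.  For
        component a, starting from the residual matrix after a-1 full-data
        components, each fold's loading vector is fit on the remaining rows
        and the held-out rows are predicted by projection; Q2_a = 1 -
        PRESS_a / SS_(a-1) and Q2cum = 1 - prod(PRESS_a / SS_(a-1)).
        """
        n = self.Xp.shape[0]
        if folds < 2:
            raise ValueError("need at least 2 folds")
        if folds > n:
            raise ValueError("fold count exceeds number of rows")
        rng = np.random.default_rng(seed)
        fold_of = np.empty(n, dtype=int)
        fold_of[rng.permutation(n)] = np.arange(n) % folds

        X = self.Xp.copy()
        q2 = np.zeros(self.A)
        ratio = np.ones(self.A)
        for a in range(self.A):
            ss_prev = (X**2).sum()
            press = 0.0
            for f in range(folds):
                hold = fold_of == f
                t_tr, p_tr, _ = _nipals_component(X[~hold])
                t_pred = X[hold] @ p_tr
                press += ((X[hold] - np.outer(t_pred, p_tr)) ** 2).sum()
            ratio[a] = press / ss_prev if ss_prev > 0 else 1.0
            q2[a] = 1.0 - ratio[a]
            t, p, _ = _nipals_component(X)
            X -= np.outer(t, p)
        q2cum = 1.0 - np.cumprod(ratio)
        return q2, q2cum


def fit_pca(X, n_components: int, scaling: str = "uv", center: bool = True) -> PCAResults:
    """Fit a NIPALS PCA (functional wrapper around :class:`NipalsPCA`)."""
    return NipalsPCA(X, n_components, scaling, center).fit()


def q2_crossval(
    X, n_components: int, folds: int = 7, scaling: str = "uv", center: bool = True, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated Q2 (per component, cumulative) for a NIPALS PCA."""
    return NipalsPCA(X, n_components, scaling, center).crossval_q2(folds, seed)


def fit_pca_with_q2(
    X, n_components: int, folds: int = 7, scaling: str = "uv", center: bool = True, seed: int = 0
) -> PCAResults:
    model = NipalsPCA(X, n_components, scaling, center)
    res = model.fit()
    res.q2, res.q2cum = model.crossval_q2(folds, seed)
    return res


@dataclass
class ClusterTree:
    """Agglomerative clustering of fold-change trajectories.

    ``linkage_matrix`` is a scipy linkage matrix (merge pairs + heights);
    ``leaf_order`` is the standard recursive dendrogram leaf ordering.
    """

    linkage_matrix: np.ndarray
    leaf_order: list
    labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def ordered_labels(self) -> list:
        return [self.labels[i] for i in self.leaf_order]


def cluster_metabolites(
    log2fc_matrix: pd.DataFrame, linkage: str = "average", metric: str = "euclidean"
) -> ClusterTree:
    """Hierarchically cluster metabolites by their log2 fold-change
    trajectories (rows = metabolites, columns = conditions/time points)."""
    values = np.asarray(log2fc_matrix, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 metabolites to cluster")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in fold-change matrix")
    Z = hierarchy.linkage(pdist(values, metric=metric), method=linkage)
    order = hierarchy.leaves_list(Z).tolist()
    labels = (
        list(log2fc_matrix.index)
        if isinstance(log2fc_matrix, pd.DataFrame)
        else list(range(values.shape[0]))
    )
    return ClusterTree(Z, order, labels)
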