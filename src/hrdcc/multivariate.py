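"""Lactation-phase discrimination: PCA, sparse PLS-DA, one-vs-rest AUROC.

The lactation is cut into six 50-DIM phases (1-50, 51-100, ..., 251-305).
A samples x features matrix is assembled from milk and blood population
percentages, milk viability and serum biomarkers (mammary epithelial
cells excluded), standardised to zero mean and unit variance.  PCA is
computed by singular-value decomposition; sparse PLS-DA follows the
NIPALS scheme with soft-thresholding of the X loading-weight vector so
that exactly ``keepX`` features stay active per component.  Phase
discrimination is summarised as the Mann-Whitney AUROC of the model's
one-vs-rest class score on the fitted data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def bin_phases(dim: int | np.ndarray) -> np.ndarray | int:
    """50-DIM phase label: ceil(DIM / 50) capped at 6."""
    arr = np.asarray(dim)
    if np.any(arr < 1):
        raise ValueError("DIM must be >= 1")
    if np.any(arr > 305):
        warnings.warn("DIM beyond 305 clamped to phase 6")
    phases = np.minimum(np.ceil(arr / 50.0).astype(int), 6)
    return int(phases) if np.isscalar(dim) else phases


@dataclass
class PhaseMatrix:
    """Standardised samples x features matrix with phase labels."""
    X: pd.DataFrame                 # standardized feature values
    phases: np.ndarray
    scope: str
    meta: pd.DataFrame              # animal_id, dim per row

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def assemble_matrix(hrdcc: pd.DataFrame, biomarkers: pd.DataFrame | None,
                    samples: pd.DataFrame, scope: str = "all") -> PhaseMatrix:
    """Build the feature matrix for one scope.

    ``hrdcc`` is the long gating table (sample_id, node, percent,
    denominator, mode); percent-of-parent values are used.  A row is one
    (animal, DIM) visit; visits missing any required matrix or analyte
    are dropped.  MEC never enters the matrix.  Columns are standardised
    to mean 0, SD 1.
    """
    if scope not in ("all", "milk", "blood", "lab"):
        raise ValueError(f"unknown scope {scope!r}")
    use = hrdcc[(hrdcc.denominator == "parent") & (hrdcc.node != "mec")]
    merged = use.merge(samples[["sample_id", "animal_id", "dim", "matrix"]],
                       on="sample_id")
    merged["feature"] = merged.matrix + ":" + merged.node
    wide_parts = []
    want_matrices = {"all": ("milk", "blood"), "milk": ("milk",),
                     "blood": ("blood",), "lab": ()}[scope]
    for matrix in want_matrices:
        part = merged[merged.matrix == matrix].pivot_table(
            index=["animal_id", "dim"], columns="feature", values="percent")
        wide_parts.append(part)
    if scope in ("all", "lab"):
        if biomarkers is None:
            raise ValueError("biomarkers required for scope 'all' or 'lab'")
        lab = biomarkers.pivot_table(index=["animal_id", "dim"],
                                     columns="analyte", values="value")
        lab.columns = [f"lab:{c}" for c in lab.columns]
        wide_parts.append(lab)
    wide = pd.concat(wide_parts, axis=1, join="inner")
    n_before = len(wide)
    wide = wide.dropna(axis=0)
    if len(wide) < n_before:
        warnings.warn(f"dropped {n_before - len(wide)} incomplete visits")
    if wide.empty:
        raise ValueError("no complete visits for scope " + scope)
    sds = wide.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant feature columns: {constant}")
    X = (wide - wide.mean()) / sds
    meta = X.index.to_frame(index=False)
    phases = bin_phases(meta["dim"].to_numpy())
    return PhaseMatrix(X.reset_index(drop=True), phases, scope, meta)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(pm: PhaseMatrix, n_components: int = 2,
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based principal components of the standardised matrix.

    Returns (scores, loadings, explained-variance %); the explained
    percentages over all components sum to 100.
    """
    X = pm.X.to_numpy()
    X = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    evr = 100.0 * s ** 2 / np.sum(s ** 2)
    k = min(n_components, len(s))
    return u[:, :k] * s[:k], vt[:k].T, evr


# ---------------------------------------------------------------------------
# sparse PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class SplsdaModel:
    n_components: int
    keep_x: int
    classes: np.ndarray
    weights: np.ndarray           # p x ncomp sparse X loading-weights, unit norm
    x_loadings: np.ndarray        # p x ncomp
    y_loadings: np.ndarray        # K x ncomp
    scores: np.ndarray            # n x ncomp
    explained_x_variance: np.ndarray   # % per component
    feature_names: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    selected: list[str] = field(default_factory=list)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Dummy-Y regression prediction; column k scores class k."""
        W, P, Q = self.weights, self.x_loadings, self.y_loadings
        R = W @ np.linalg.pinv(P.T @ W)
        B = R @ Q.T
        return (np.asarray(X) - self.x_mean) @ B + self.y_mean


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    if keep >= len(w):
        return w
    absw = np.abs(w)
    lam = np.sort(absw)[-(keep + 1)]
    out = np.sign(w) * np.maximum(absw - lam, 0.0)
    if np.count_nonzero(out) < keep:      # exact ties at the cut
        order = np.argsort(absw)[::-1][:keep]
        out = np.zeros_like(w)
        out[order] = np.sign(w[order]) * (absw[order] - lam)
    return out


def splsda_fit(pm: PhaseMatrix, labels: np.ndarray | None = None,
               n_components: int = 2, keep_x: int = 5,
               tol: float = 1e-6, max_iter: int = 500) -> SplsdaModel:
    """Fit sparse PLS-DA on the phase matrix.

    The class matrix is dummy-coded and centred; each component iterates
    NIPALS loading-weight updates with soft-thresholding that retains the
    ``keep_x`` largest-magnitude X weights, normalises, and converges at
    ``tol`` or ``max_iter``; X and Y are deflated by regression on the
    component score.
    """
    labels = pm.phases if labels is None else np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if keep_x < 1:
        raise ValueError("keepX must be >= 1")
    X0 = pm.X.to_numpy().astype(float)
    n, p = X0.shape
    if keep_x > p:
        raise ValueError(f"keepX={keep_x} exceeds {p} features")
    Y0 = (labels[:, None] == classes[None, :]).astype(float)
    x_mean, y_mean = X0.mean(axis=0), Y0.mean(axis=0)
    X, Y = X0 - x_mean, Y0 - y_mean
    total_var = np.sum(X ** 2)

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((len(classes), n_components))
    T = np.zeros((n, n_components))
    evx = np.zeros(n_components)
    for h in range(n_components):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        w_old = np.zeros(p)
        for _ in range(max_iter):
            w = X.T @ u
            w = _soft_threshold_keep(w, keep_x)
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("degenerate component: zero loading weights")
            w /= norm
            t = X @ w
            c = Y.T @ t / (t @ t)
            u = Y @ c / (c @ c)
            if np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        t = X @ w
        tt = t @ t
        p_vec = X.T @ t / tt
        q_vec = Y.T @ t / tt
        X = X - np.outer(t, p_vec)
        Y = Y - np.outer(t, q_vec)
        W[:, h], P[:, h], Q[:, h], T[:, h] = w, p_vec, q_vec, t
        evx[h] = 100.0 * tt * (p_vec @ p_vec) / total_var

    active = np.flatnonzero(np.any(W != 0, axis=1))
    selected = [pm.feature_names[i] for i in active]
    return SplsdaModel(n_components, keep_x, classes, W, P, Q, T, evx,
                       pm.feature_names, x_mean, y_mean, selected)


def auroc_one_vs_rest(model: SplsdaModel, pm: PhaseMatrix,
                      labels: np.ndarray | None = None,
                      phase: int | None = None) -> float:
    """Mann-Whitney AUROC of the fitted class score for ``phase`` against
    all other samples, on the fitted data."""
    labels = pm.phases if labels is None else np.asarray(labels)
    if phase is None:
        raise ValueError("phase must be given")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    if phase not in model.classes:
        raise ValueError(f"phase {phase} absent from model classes")
    k = int(np.flatnonzero(model.classes == phase)[0])
    scores = model.predict_scores(pm.X.to_numpy())[:, k]
    return auroc_from_scores(scores, labels == phase)


def auroc_from_scores(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUROC."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos, n_neg = positive.sum(), (~positive).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative samples")
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def top_features(model: SplsdaModel, k: int) -> list[str]:
    """Features ranked by |component-1 loading weight|, ties broken by
    component 2; truncated (with a warning) if fewer were selected."""
    if k == 0:
        return []
    w1 = np.abs(model.weights[:, 0])
    w2 = np.abs(model.weights[:, 1]) if model.n_components > 1 else np.zeros_like(w1)
    active = np.flatnonzero((w1 > 0) | (w2 > 0))
    order = active[np.lexsort((-w2[active], -w1[active]))]
    names = [model.feature_names[i] for i in order]
    if k > len(names):
        warnings.warn(f"only {len(names)} selected features; truncating")
    return names[:k]
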