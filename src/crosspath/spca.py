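"""Sparse principal-component model with cross-species projection.

The model minimizes

    1/2 ||X - X B A^T||_F^2 + alpha' ||B||_1 + beta'/2 ||B||_F^2,  A^T A = I,

over a sparse loading matrix ``B`` (pathways x k) and an orthonormal rotation
``A``, by alternating a proximal-gradient (soft-threshold) step in ``B`` with
an orthogonal-Procrustes step in ``A`` (the variable-projection scheme).  At
``alpha = beta = 0`` the solution spans the top-k principal axes, so the
model degrades gracefully to plain PCA.

The user-facing penalties are dimensionless: ``alpha' = alpha * sigma_1^2``
and ``beta' = beta * sigma_1^2`` with ``sigma_1`` the leading singular value
of ``X``, the convention of the variable-projection reference
implementations.  This makes a grid such as 1e-6 .. 1 meaningful regardless
of the size or scale of the data (the per-step soft threshold is then
``alpha`` itself, directly comparable to loading magnitudes of order one).

The model is always fit on the animal-model (training species) data; the
other species is *projected* into the same coordinate system by ``Y B``.
Because sparse components need not be orthogonal, variance is attributed
sequentially (QR-adjusted variance): each component is credited only with
score variance orthogonal to its predecessors.

The sparsity penalty ``alpha`` is chosen by leave-one-out cross-validation:
the largest grid value whose mean cumulative variance captured by the first
three components still clears a threshold (default 50% of total variance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SparsePCModel",
    "AlphaSelectionResult",
    "ProjectionResult",
    "fit_spca",
    "explained_variance",
    "select_alpha",
    "project",
]


@dataclass
class SparsePCModel:
    loadings: pd.DataFrame          # B, pathways x k
    rotation: np.ndarray            # A, pathways x k, orthonormal columns
    alpha: float
    beta: float
    explained_variance_fractions: np.ndarray  # per component, training data
    total_variance: float
    n_iter: int = 0
    final_objective_delta: float = 0.0

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def pathway_names(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def component_names(self) -> list[str]:
        return list(self.loadings.columns)

    def nonzero_pathways(self, components, tol: float = 1e-8) -> list[str]:
        """Pathways with |loading| > tol in at least one listed component."""
        cols = [self.loadings.columns[i] for i in components]
        if not cols:
            return []
        mask = (self.loadings[cols].abs() > tol).any(axis=1)
        return sorted(self.loadings.index[mask])

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "beta": self.beta,
            "explained_variance_fractions": [float(v) for v in self.explained_variance_fractions],
            "total_variance": self.total_variance,
            "n_iter": self.n_iter,
            "pathways": self.pathway_names,
            "components": self.component_names,
            "loadings": self.loadings.to_numpy().tolist(),
            "rotation": self.rotation.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SparsePCModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            loadings=pd.DataFrame(d["loadings"], index=d["pathways"], columns=d["components"]),
            rotation=np.asarray(d["rotation"], dtype=float),
            alpha=d["alpha"],
            beta=d["beta"],
            explained_variance_fractions=np.asarray(d["explained_variance_fractions"]),
            total_variance=d["total_variance"],
            n_iter=d["n_iter"],
        )


@dataclass
class AlphaSelectionResult:
    grid: np.ndarray                # descending
    mean_cumvar: np.ndarray         # per grid alpha, mean over LOOCV folds
    var_cumvar: np.ndarray          # per grid alpha, variance over folds
    threshold: float
    chosen: float | None            # None = no grid value met the threshold

    def require_chosen(self) -> float:
        if self.chosen is None:
            raise RuntimeError(
                f"no alpha on the grid reached mean cumulative variance >= {self.threshold}"
            )
        return self.chosen


@dataclass
class ProjectionResult:
    scores: pd.DataFrame            # samples x k
    variance_fractions: np.ndarray  # per component, of the projected data
    model: SparsePCModel = field(repr=False, default=None)


def _as_matrix(X) -> tuple[np.ndarray, list, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[0])), list(range(X.shape[1]))


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _adjusted_variances(scores: np.ndarray) -> np.ndarray:
    """Sequential (QR) variance attribution for possibly correlated scores."""
    n, k = scores.shape
    centered = scores - scores.mean(axis=0, keepdims=True)
    if n < 2 or not np.any(centered):
        return np.zeros(k)
    r = np.linalg.qr(centered, mode="r")
    return np.diag(r)[:k] ** 2 / (n - 1)


def fit_spca(
    X,
    k: int,
    alpha: float,
    beta: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SparsePCModel:
    """Fit the sparse PC model on an (samples x pathways) standardized matrix.

    Initialization is the top-k PCA loadings of ``X`` (deterministic), so the
    whole fit is deterministic.  Components are ordered by adjusted explained
    variance, and each (B, A) column pair gets a deterministic sign (largest
    absolute loading positive).
    """
    Xm, sample_ids, pathway_names = _as_matrix(X)
    n, p = Xm.shape
    if not np.isfinite(Xm).all():
        raise ValueError("non-finite input matrix")
    if k < 1 or k > min(n - 1, p):
        raise ValueError(f"k={k} out of range for {n} samples x {p} features")
    if alpha < 0 or beta < 0:
        raise ValueError("penalties must be non-negative")

    _, svals, Vt = np.linalg.svd(Xm, full_matrices=False)
    B = Vt[:k].T.copy()
    A = B.copy()
    # penalties are specified in units of the leading squared singular value
    dmax_sq = svals[0] ** 2 if svals[0] > 0 else 1.0
    alpha_eff = alpha * dmax_sq
    beta_eff = beta * dmax_sq
    step = 1.0 / (dmax_sq + beta_eff)

    # Gram products; routed through the thin data matrix when n << p
    if 2 * n < p:
        def gram(M):
            return Xm.T @ (Xm @ M)
    else:
        G = Xm.T @ Xm

        def gram(M):
            return G @ M

    # objective via traces: with A^T A = I,
    #   1/2 ||X - X B A^T||^2 = 1/2 ||X||^2 - tr(A^T G B) + 1/2 tr(B^T G B)
    x_sq = 0.5 * float(np.sum(Xm * Xm))

    def cheap_obj(B, A, GB):
        return (
            x_sq
            - float(np.sum(A * GB))
            + 0.5 * float(np.sum(B * GB))
            + alpha_eff * float(np.sum(np.abs(B)))
            + 0.5 * beta_eff * float(np.sum(B * B))
        )

    GB = gram(B)
    obj = cheap_obj(B, A, GB)
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # B-step: one proximal (soft-threshold) gradient step at fixed A
        grad = GB - gram(A) + beta_eff * B
        B = _soft(B - step * grad, step * alpha_eff)
        # A-step: orthogonal Procrustes, i.e. the polar factor of G B;
        # computed through the k x k Gram eigendecomposition when G B has
        # full column rank (cheap), by SVD otherwise
        GB = gram(B)
        E = GB.T @ GB
        evals, evecs = np.linalg.eigh(E)
        if evals[0] > 1e-10 * max(evals[-1], 1.0):
            A = GB @ (evecs * (1.0 / np.sqrt(evals))) @ evecs.T
        else:
            U, _, Vt2 = np.linalg.svd(GB, full_matrices=False)
            A = U @ Vt2
        new_obj = cheap_obj(B, A, GB)
        delta = abs(obj - new_obj) / max(abs(obj), 1.0)
        obj = new_obj
        if delta < tol:
            break

    # order components by adjusted variance, fix signs deterministically
    adj = _adjusted_variances(Xm @ B)
    order = np.argsort(-adj, kind="stable")
    B, A, adj = B[:, order], A[:, order], adj[order]
    for j in range(k):
        col = B[:, j]
        anchor = np.argmax(np.abs(col))
        sign = np.sign(col[anchor]) if col[anchor] != 0 else 1.0
        B[:, j] *= sign
        A[:, j] *= sign

    centered = Xm - Xm.mean(axis=0, keepdims=True)
    total = float(np.sum(centered * centered) / max(n - 1, 1))
    fractions = _adjusted_variances(Xm @ B) / total if total > 0 else np.zeros(k)
    comp_names = [f"sPC{j + 1}" for j in range(k)]
    return SparsePCModel(
        loadings=pd.DataFrame(B, index=pathway_names, columns=comp_names),
        rotation=A,
        alpha=float(alpha),
        beta=float(beta),
        explained_variance_fractions=fractions,
        total_variance=total,
        n_iter=it,
        final_objective_delta=float(delta),
    )


def explained_variance(model: SparsePCModel, X, adjusted: bool = True) -> np.ndarray:
    """Per-component variance fractions of ``X`` under the model's loadings.

    ``adjusted=True`` (default) credits each component only with score
    variance orthogonal to its predecessors (QR-sequential); ``adjusted=False``
    reports plain per-column score variance for sensitivity checks.
    """
    Xm, _, pathway_names = _as_matrix(X)
    if pathway_names != model.pathway_names and isinstance(X, pd.DataFrame):
        raise ValueError("pathway order mismatch between model and matrix")
    n = Xm.shape[0]
    centered = Xm - Xm.mean(axis=0, keepdims=True)
    total = float(np.sum(centered * centered) / max(n - 1, 1))
    scores = Xm @ model.loadings.to_numpy()
    if total <= 0:
        logger.warning("zero-variance matrix; variance fractions reported as 0")
        return np.zeros(model.k)
    if adjusted:
        return _adjusted_variances(scores) / total
    return scores.var(axis=0, ddof=1) / total


def select_alpha(
    X,
    grid,
    k: int,
    threshold: float = 0.5,
    n_components_criterion: int = 3,
    beta: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> AlphaSelectionResult:
    """LOOCV choice of the sparsity penalty.

    For each grid alpha and each leave-one-out fold, the model is refit on the
    retained samples and the cumulative variance captured by the first
    ``n_components_criterion`` components of the training fold is recorded.
    The chosen alpha is the *largest* (sparsest) grid value whose mean
    cumulative variance is still >= ``threshold``.  Each fold is re-centered
    (not re-scaled) before fitting, since dropping a sample shifts the column
    means away from zero.
    """
    Xm, _, _ = _as_matrix(X)
    n = Xm.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for LOOCV alpha selection")
    grid = np.sort(np.asarray(list(grid), dtype=float))[::-1]
    means, variances = [], []
    for alpha in grid:
        cumvars = []
        for i in range(n):
            fold = np.delete(Xm, i, axis=0)
            fold = fold - fold.mean(axis=0, keepdims=True)
            k_fold = min(k, fold.shape[0] - 1, fold.shape[1])
            m = fit_spca(fold, k_fold, alpha, beta=beta, tol=tol, max_iter=max_iter)
            top = m.explained_variance_fractions[: n_components_criterion]
            cumvars.append(float(np.sum(top)))
        cumvars = np.asarray(cumvars)
        means.append(float(cumvars.mean()))
        variances.append(float(cumvars.var(ddof=1)))
    means = np.asarray(means)
    chosen = None
    meets = np.flatnonzero(means >= threshold)
    if len(meets) > 0:
        chosen = float(grid[meets[0]])  # grid descending: first hit is largest alpha
    return AlphaSelectionResult(
        grid=grid,
        mean_cumvar=means,
        var_cumvar=np.asarray(variances),
        threshold=threshold,
        chosen=chosen,
    )


def project(model: SparsePCModel, Y) -> ProjectionResult:
    """Project new (samples x pathways) data into the model's component space.

    Scores are the plain matrix product ``Y B``; variance fractions are the
    QR-adjusted score variances over the total variance of ``Y``.
    """
    Ym, sample_ids, pathway_names = _as_matrix(Y)
    if isinstance(Y, pd.DataFrame) and pathway_names != model.pathway_names:
        raise ValueError("pathway order mismatch between model and projected data")
    scores = Ym @ model.loadings.to_numpy()
    fractions = explained_variance(model, Ym if not isinstance(Y, pd.DataFrame) else Y)
    return ProjectionResult(
        scores=pd.DataFrame(scores, index=sample_ids, columns=model.component_names),
        variance_fractions=fractions,
        model=model,
    )
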