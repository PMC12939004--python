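"""From-scratch PCA, principal component regression, NIPALS partial
least squares, and Monte-Carlo cross-validation for model-order choice.

All models work on mean-centered data internally and store the column
means and response mean, so prediction maps raw pixel intensities to
pressing-loss percentages.

PCA is computed by the economy singular value decomposition of the
centered matrix; for wide matrices (p >> n, e.g. 65536 pixel features
against tens of samples) this costs O(n^2 p) and never forms the p x p
covariance.  Components whose singular value falls below 1e-12 of the
largest are treated as numerical rank deficiency and discarded.

The PLS algorithm is classical univariate-response NIPALS: each
component takes the weight vector proportional to X'y, scores t = Xw,
x-loadings p = X't/(t't), y-loading q = y't/(t't), then deflates both
X and y.  For a single response the inner iteration converges in one
step, so ``tol`` / ``max_iter`` only guard a future multivariate
extension.  The final regression vector is beta = W (P'W)^-1 q.

Monte-Carlo cross-validation repeats a random calibration/validation
split (default 8:2), fits PLS at every candidate order on the
calibration part, and averages held-out RMSE per order over splits;
the order with the smallest mean RMSE wins, smaller order on ties.
Per-split seeds are the master seed plus a fixed increment, so growing
``n_splits`` never reshuffles earlier splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import DesignMatrix, center, random_split

__all__ = [
    "PCAModel", "PCRModel", "PLSModel", "MCCVResult",
    "pca_fit", "select_k", "pcr_fit", "pls_nipals_fit", "predict",
    "mccv_select_lv",
]

#: Singular values below this fraction of the largest are rank deficiency.
RANK_TOL = 1e-12


@dataclass(frozen=True)
class PCAModel:
    """Principal components of a centered matrix.

    ``loadings`` has orthonormal columns (p x k); ``scores`` = Xc @
    loadings; ``explained_ratio`` are fractional variance contributions
    relative to the total variance of Xc (all retained + discarded
    directions), so they sum to 1 over the full numerical rank.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_ratio: np.ndarray
    cumulative_ratio: np.ndarray
    column_means: np.ndarray

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class PCRModel:
    """Least squares of the response on the first k principal-component scores."""

    pca: PCAModel
    gamma: np.ndarray       # coefficients on scores
    intercept: float
    k: int
    beta: np.ndarray        # equivalent coefficients on centered pixels
    y_mean: float


@dataclass(frozen=True)
class PLSModel:
    """NIPALS partial least squares with A latent variables."""

    W: np.ndarray           # p x A weight vectors (unit norm)
    P: np.ndarray           # p x A x-loadings
    q: np.ndarray           # A-vector of y-loadings
    T: np.ndarray           # n x A calibration scores
    beta: np.ndarray        # p-vector on centered pixels
    intercept: float
    A: int
    column_means: np.ndarray
    y_mean: float


@dataclass(frozen=True)
class MCCVResult:
    """Mean held-out RMSE per candidate order and the chosen order."""

    rmse_curve: np.ndarray
    chosen_A: int
    n_splits: int
    ratio: float
    seed: int


def _svd_centered(Xc: np.ndarray):
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size and s[0] > 0:
        rank = int(np.sum(s > RANK_TOL * s[0]))
    else:
        rank = 0
    return U, s, Vt, rank


def pca_fit(Xc: np.ndarray, k_max: int | None = None,
            column_means: np.ndarray | None = None) -> PCAModel:
    """PCA of a centered matrix via economy SVD.

    ``explained_ratio[j] = s_j^2 / sum(s^2)``.  ``k_max`` beyond the
    numerical rank is truncated with a warning.
    """
    Xc = np.asarray(Xc, dtype=np.float64)
    U, s, Vt, rank = _svd_centered(Xc)
    if rank == 0:
        raise ValueError("matrix has rank 0 (constant rows?)")
    if k_max is None:
        k = rank
    else:
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        if k_max > rank:
            warnings.warn(f"k_max={k_max} exceeds numerical rank {rank}; truncating",
                          stacklevel=2)
        k = min(k_max, rank)
    total = float(np.sum(s**2))
    ratio = s[:k] ** 2 / total
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    means = (np.asarray(column_means, dtype=np.float64)
             if column_means is not None else np.zeros(Xc.shape[1]))
    return PCAModel(loadings=loadings, scores=scores,
                    explained_ratio=ratio, cumulative_ratio=np.cumsum(ratio),
                    column_means=means)


def select_k(cumulative_ratio: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest k whose cumulative variance contribution reaches the threshold."""
    cum = np.asarray(cumulative_ratio, dtype=np.float64)
    if cum.size == 0:
        raise ValueError("empty cumulative ratio")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    hits = np.nonzero(cum >= threshold)[0]
    if hits.size == 0:
        warnings.warn(
            f"cumulative ratio never reaches {threshold}; using full rank {cum.size}",
            stacklevel=2)
        return int(cum.size)
    return int(hits[0]) + 1


def _ensure_centered(d: DesignMatrix) -> DesignMatrix:
    return d if d.is_centered else center(d)


def pcr_fit(d: DesignMatrix, k: int) -> PCRModel:
    """Principal component regression with k components.

    Scores are mutually orthogonal, so the least-squares coefficients
    decouple: gamma_j = (t_j . y) / (t_j . t_j).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dc = _ensure_centered(d)
    U, s, Vt, rank = _svd_centered(dc.X)
    if k > rank:
        raise ValueError(f"k={k} exceeds numerical rank {rank}")
    T = U[:, :k] * s[:k]
    gamma = (T.T @ dc.y) / (s[:k] ** 2)
    total = float(np.sum(s**2))
    ratio = s[:k] ** 2 / total
    pca = PCAModel(loadings=Vt[:k].T, scores=T, explained_ratio=ratio,
                   cumulative_ratio=np.cumsum(ratio), column_means=dc.centering)
    beta = Vt[:k].T @ gamma
    intercept = float(dc.y_mean - dc.centering @ beta)
    return PCRModel(pca=pca, gamma=gamma, intercept=intercept, k=k,
                    beta=beta, y_mean=float(dc.y_mean))


def pls_nipals_fit(d: DesignMatrix, A: int,
                   tol: float = 1e-10, max_iter: int = 500) -> PLSModel:
    """Univariate-response NIPALS partial least squares with A components.

    Deflates both X and y each component.  A beyond the data's capacity
    (weight or score norm vanishing) is truncated with a warning; a
    constant response is rejected.
    """
    if A < 1:
        raise ValueError("A must be >= 1")
    dc = _ensure_centered(d)
    X = dc.X.copy()
    y = dc.y.copy()
    if np.allclose(y, 0.0):
        raise ValueError("response has zero variance")
    n, p = X.shape
    x_scale = float(np.abs(X).max()) or 1.0

    Ws, Ps, qs, Ts = [], [], [], []
    for _ in range(A):
        w = X.T @ y
        nw = float(np.linalg.norm(w))
        if nw <= tol * x_scale * float(np.linalg.norm(y) + 1.0):
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= (tol * x_scale) ** 2:
            break
        p_load = (X.T @ t) / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_load)
        y = y - q_a * t
        Ws.append(w); Ps.append(p_load); qs.append(q_a); Ts.append(t)

    if not Ws:
        raise ValueError("no PLS component could be extracted")
    if len(Ws) < A:
        warnings.warn(f"A={A} exceeds extractable components; truncated to {len(Ws)}",
                      stacklevel=2)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.asarray(qs)
    T = np.column_stack(Ts)
    beta = W @ np.linalg.solve(P.T @ W, q)
    intercept = float(dc.y_mean - dc.centering @ beta)
    return PLSModel(W=W, P=P, q=q, T=T, beta=beta, intercept=intercept,
                    A=W.shape[1], column_means=dc.centering,
                    y_mean=float(dc.y_mean))


def predict(model: PCRModel | PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Apply stored centering and the affine map; the model is never mutated."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if isinstance(model, PCRModel):
        means, beta = model.pca.column_means, model.beta
    elif isinstance(model, PLSModel):
        means, beta = model.column_means, model.beta
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    if X_new.shape[1] != means.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {means.shape[0]}")
    return (X_new - means) @ beta + model.y_mean


def predict_sequential(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """PLS prediction by sequential latent-variable accumulation.

    Numerically independent route from the collapsed ``beta`` vector;
    used to cross-check the regression-vector assembly.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    Xc = X_new - model.column_means
    yhat = np.full(X_new.shape[0], model.y_mean)
    for a in range(model.A):
        t = Xc @ model.W[:, a]
        yhat = yhat + model.q[a] * t
        Xc = Xc - np.outer(t, model.P[:, a])
    return yhat


def _pls_beta_per_order(dc: DesignMatrix, A_max: int):
    """Fit NIPALS once, return (betas per order, intercepts, n extracted)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = pls_nipals_fit(dc, A_max)
    betas, intercepts = [], []
    for a in range(1, model.A + 1):
        beta = model.W[:, :a] @ np.linalg.solve(
            model.P[:, :a].T @ model.W[:, :a], model.q[:a])
        betas.append(beta)
        intercepts.append(float(model.y_mean - model.column_means @ beta))
    return betas, intercepts, model.A


def mccv_select_lv(d: DesignMatrix, A_max: int, n_splits: int = 1000,
                   ratio: float = 0.8, seed: int = 0) -> MCCVResult:
    """Choose the PLS order by Monte-Carlo cross-validation.

    For each split, fits PLS on the calibration part at every order up
    to ``A_max`` (capped at the part's capacity, with one warning) and
    scores held-out RMSE; the curve is the mean over splits and the
    chosen order its argmin (smallest order on ties).
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    acc = np.zeros(A_max)           # sum of per-split held-out RMSE per order
    capped = False
    for i in range(n_splits):
        sp = random_split(d.n, ratio, (seed + 1 + i) % 2**31)
        cal = DesignMatrix(X=d.X[sp.calibration_indices],
                           y=d.y[sp.calibration_indices])
        Xv = d.X[sp.validation_indices]
        yv = d.y[sp.validation_indices]
        betas, intercepts, a_got = _pls_beta_per_order(center(cal), A_max)
        capped = capped or (a_got < A_max)
        for a in range(A_max):
            j = min(a, a_got - 1)   # orders beyond capacity fall back to max fit
            resid = yv - (Xv @ betas[j] + intercepts[j])
            acc[a] += np.sqrt(float(resid @ resid) / yv.size)
    if capped:
        warnings.warn(f"A_max={A_max} exceeded calibration capacity on some splits; "
                      "curve capped at the largest extractable order", stacklevel=2)
    rmse_curve = acc / n_splits
    chosen = int(np.argmin(rmse_curve)) + 1
    return MCCVResult(rmse_curve=rmse_curve, chosen_A=chosen,
                      n_splits=n_splits, ratio=ratio, seed=seed)
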