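"""Independent reference implementations used only to check the package.

These deliberately take different algorithmic routes from the library:
SIMPLS instead of NIPALS for partial least squares, an explicit
covariance eigendecomposition instead of SVD for PCA, and breadth-first
flood fill instead of scikit-image for connected components.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def simpls_beta(X, y, A):
    """SIMPLS (de Jong 1993) regression vector for a single response.

    For one response variable SIMPLS and NIPALS span the same Krylov
    subspace and give identical coefficients in exact arithmetic.
    Returns (beta, intercept) on the raw-input scale.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    p = X.shape[1]
    s = Xc.T @ yc
    R = np.zeros((p, A))
    V = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        r = s.copy()
        t = Xc @ r
        nt = np.linalg.norm(t)
        t /= nt
        r /= nt
        pl = Xc.T @ t
        q[a] = yc @ t
        v = pl.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pl)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        R[:, a] = r
        V[:, a] = v
    beta = R @ q
    return beta, float(ym - xm @ beta)


def eig_pca_ratios(Xc):
    """Explained-variance ratios from an explicit covariance eigendecomposition."""
    C = (Xc.T @ Xc) / 1.0
    vals = np.linalg.eigvalsh(C)[::-1]
    vals = np.clip(vals, 0.0, None)
    return vals / vals.sum()


def bfs_components(mask):
    """8-connected component areas by breadth-first flood fill.

    Returns a list of component sizes and a parallel list of
    touches-border flags, largest component first.
    """
    mask = np.asarray(mask, dtype=bool)
    nr, nc = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(nr):
        for c0 in range(nc):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            area = 0
            touches = False
            dq = deque([(r0, c0)])
            seen[r0, c0] = True
            while dq:
                r, c = dq.popleft()
                area += 1
                if r in (0, nr - 1) or c in (0, nc - 1):
                    touches = True
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            dq.append((rr, cc))
            comps.append((area, touches))
    comps.sort(reverse=True)
    return [a for a, _ in comps], [t for _, t in comps]


def ols_predict(X_cal, y_cal, X_new):
    """Ordinary least squares with intercept via lstsq, on raw inputs."""
    n = X_cal.shape[0]
    A = np.column_stack([np.ones(n), X_cal])
    coef, *_ = np.linalg.lstsq(A, y_cal, rcond=None)
    return np.column_stack([np.ones(X_new.shape[0]), X_new]) @ coef
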