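"""Design-matrix assembly, centering and calibration/validation splits.

Selected slices are flattened row-major into an ``n x p`` pixel-feature
matrix (p = image_size**2) paired one-to-one with the pressing-loss
response.  Columns are mean-centered only — pixel features share one
intensity unit, and unit-variance scaling would amplify background
noise pixels — with the column means and response mean stored for
prediction-time reuse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import GrayMatrix

__all__ = ["DesignMatrix", "Split", "build_design", "center", "random_split",
           "unflatten_row", "save_design", "load_design"]


@dataclass(frozen=True)
class DesignMatrix:
    """Pixel features ``X`` (n x p) paired index-wise with responses ``y``.

    ``centering`` / ``y_mean`` are None on a raw matrix and hold the
    subtracted means after :func:`center`.
    """

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    centering: np.ndarray | None = None
    y_mean: float | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} entries")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        ids = list(self.sample_ids) or [f"S{i:03d}" for i in range(X.shape[0])]
        if len(ids) != X.shape[0]:
            raise ValueError("sample_ids length mismatch")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def is_centered(self) -> bool:
        return self.centering is not None


@dataclass(frozen=True)
class Split:
    """A disjoint calibration/validation partition of sample indices."""

    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_indices, dtype=np.intp)
        val = np.asarray(self.validation_indices, dtype=np.intp)
        if np.intersect1d(cal, val).size:
            raise ValueError("calibration and validation sets overlap")
        object.__setattr__(self, "calibration_indices", cal)
        object.__setattr__(self, "validation_indices", val)


def build_design(selected_slices: list[GrayMatrix],
                 responses: list[float] | np.ndarray,
                 sample_ids: list[str] | None = None) -> DesignMatrix:
    """Stack one selected slice per sample into the flattened design matrix.

    Row i of X is the row-major flattening of slice i; all slices must
    share one image size.
    """
    responses = np.asarray(responses, dtype=np.float64).ravel()
    if len(selected_slices) != responses.shape[0]:
        raise ValueError(
            f"{len(selected_slices)} slices but {responses.shape[0]} responses")
    shapes = {m.shape for m in selected_slices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    X = np.stack([m.values.ravel(order="C") for m in selected_slices])
    ids = sample_ids if sample_ids is not None else \
        [m.source_id or f"S{i:03d}" for i, m in enumerate(selected_slices)]
    return DesignMatrix(X=X, y=responses, sample_ids=list(ids))


def unflatten_row(d: DesignMatrix, i: int) -> np.ndarray:
    """Inverse of the row-major flattening (square images)."""
    side = int(round(np.sqrt(d.p)))
    if side * side != d.p:
        raise ValueError(f"p={d.p} is not a perfect square")
    return d.X[i].reshape(side, side)


def center(d: DesignMatrix) -> DesignMatrix:
    """Mean-center columns of X and the response, storing the means."""
    mu = d.X.mean(axis=0)
    ym = float(d.y.mean())
    return DesignMatrix(X=d.X - mu, y=d.y - ym, sample_ids=d.sample_ids,
                        centering=mu, y_mean=ym)


def random_split(n: int, ratio: float, seed: int) -> Split:
    """Uniform random calibration/validation partition without replacement.

    ``|calibration| = round(ratio * n)``; both parts must be nonempty.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2 to split")
    n_cal = int(round(ratio * n))
    if n_cal < 1 or n_cal > n - 1:
        raise ValueError(f"degenerate split: {n_cal} of {n} in calibration")
    perm = np.random.default_rng(seed).permutation(n)
    return Split(calibration_indices=np.sort(perm[:n_cal]),
                 validation_indices=np.sort(perm[n_cal:]),
                 ratio=ratio, seed=seed)


def save_design(d: DesignMatrix, path: str | Path) -> Path:
    """Write X/y to an .npz container with a JSON sidecar of metadata."""
    path = Path(path)
    np.savez(path, X=d.X, y=d.y,
             centering=d.centering if d.centering is not None else np.array([]))
    side = path.with_suffix(".json")
    side.write_text(json.dumps({
        "sample_ids": d.sample_ids,
        "y_mean": d.y_mean,
        "centered": d.is_centered,
        "n": d.n, "p": d.p,
    }, indent=2))
    return path


def load_design(path: str | Path) -> DesignMatrix:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as z:
        X, y, cen = z["X"], z["y"], z["centering"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return DesignMatrix(X=X, y=y, sample_ids=meta["sample_ids"],
                        centering=cen if meta["centered"] else None,
                        y_mean=meta["y_mean"])
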