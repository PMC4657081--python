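"""Rogers-Tanimoto-derived distance between real-valued feature vectors.

For feature vectors v_x and v_y the dissimilarity is

    dis(v_x, v_y) = 1 - (v_x . v_y) / (v_x . v_x + v_y . v_y - v_x . v_y)

which is symmetric, zero on identical nonzero vectors, and bounded in
[0, 1] whenever the entries are nonnegative.  To keep entries nonnegative
(raw features such as dG are negative) the package always min-max scales
features to [0, 1] per column before computing distances or clustering;
:class:`MinMaxParams` carries the learned scaling so a trained model can
apply it to new data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DimensionError, UndefinedDistanceError


def rt_distance(vx: Sequence[float], vy: Sequence[float]) -> float:
    """Rogers-Tanimoto dissimilarity between two equal-length vectors."""
    x = np.asarray(vx, dtype=float)
    y = np.asarray(vy, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise DimensionError(f"vector shapes differ: {x.shape} vs {y.shape}")
    xy = float(x @ y)
    denom = float(x @ x) + float(y @ y) - xy
    if denom == 0.0:
        raise UndefinedDistanceError("denominator is zero (both vectors all-zero)")
    return 1.0 - xy / denom


def rt_distance_matrix(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise Rogers-Tanimoto distances between rows of X and rows of C.

    Vectorized form used by clustering; a zero-vs-zero pair (denominator
    0) is assigned distance 0, since the two points coincide.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if X.shape[1] != C.shape[1]:
        raise DimensionError(
            f"feature dimensions differ: {X.shape[1]} vs {C.shape[1]}"
        )
    xy = X @ C.T
    xx = np.einsum("ij,ij->i", X, X)[:, None]
    cc = np.einsum("ij,ij->i", C, C)[None, :]
    denom = xx + cc - xy
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - np.where(denom > 0, xy / np.where(denom > 0, denom, 1.0), 1.0)
    # denom - xy = ||x - c||^2 >= 0, so d >= 0 exactly; clamp float noise
    return np.maximum(d, 0.0)


@dataclass
class MinMaxParams:
    """Per-column min-max scaling parameters learned on training data."""

    mins: np.ndarray
    ranges: np.ndarray  # max - min; 0 marks a constant column

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxParams":
        X = np.asarray(X, dtype=float)
        mins = X.min(axis=0)
        ranges = X.max(axis=0) - mins
        return cls(mins=mins, ranges=ranges)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scale columns to [0, 1]; constant columns map to 0, and values
        outside the training range are clipped so scaled space stays
        nonnegative (a requirement of the distance's range property)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mins.shape[0]:
            raise DimensionError(
                f"expected {self.mins.shape[0]} features, got {X.shape[1]}"
            )
        safe = np.where(self.ranges > 0, self.ranges, 1.0)
        out = (X - self.mins) / safe
        out[:, self.ranges == 0] = 0.0
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "ranges": self.ranges.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxParams":
        return cls(mins=np.asarray(d["mins"]), ranges=np.asarray(d["ranges"]))
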