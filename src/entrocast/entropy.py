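"""Entropy weighting of forecasters and the weighted combination itself.

The combination model fuses the point forecasts of ``m`` base methods with a
convex weight vector derived from the Shannon entropy of each method's
historical performance profile.  The chain is:

1. build an ``m × n`` performance matrix over ``n`` evaluation time points;
2. min-max normalize each row (benefit or cost orientation);
3. convert each row to proportions ``f_ij = r_ij / Σ_j r_ij`` and compute the
   normalized entropy ``p_i = −(1/ln n) Σ_j f_ij ln f_ij``;
4. weight ``λ_i = (1 − p_i) / (m − Σ p_i)``.

A method whose normalized profile is uniform carries no discriminating
information (``p_i = 1``) and receives zero weight; a more dispersed profile
(lower entropy) receives more.  The weights are non-negative and sum to one
on every code path, so the combined forecast always lies in the convex hull
of the member forecasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntropyWeights",
    "normalize_matrix",
    "entropy",
    "entropy_weights",
    "combine",
    "weights_from_history",
    "BASES",
]

BASES = ("accuracy_benefit", "abs_error_cost")


@dataclass(frozen=True)
class EntropyWeights:
    """Full audit record of one weight computation.

    Attributes
    ----------
    matrix : (m, n) performance observations, one row per method.
    r : row-normalized matrix in [0, 1].
    f : per-row proportions (each row sums to 1).
    entropies : normalized entropy p_i per method, in [0, 1].
    weights : convex weights λ_i (non-negative, summing to 1).
    basis : how the performance matrix was built, or "custom".
    degenerate_rows : indices of constant rows mapped to all-ones.
    """

    matrix: np.ndarray
    r: np.ndarray
    f: np.ndarray
    entropies: np.ndarray
    weights: np.ndarray
    basis: str
    degenerate_rows: tuple[int, ...]


def normalize_matrix(X, orientation: str = "benefit") -> tuple[np.ndarray, tuple[int, ...]]:
    """Row-wise min-max normalization of a performance matrix.

    ``benefit`` rows map their maximum to 1 (bigger is better); ``cost`` rows
    map their minimum to 1.  A constant row is undefined under min-max; it is
    mapped to all-ones — the maximal-entropy profile, which the downstream
    weighting drives to zero weight — and reported in the degeneracy flags.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 evaluation points per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("performance matrix has non-finite entries")
    if orientation not in ("benefit", "cost"):
        raise ValueError(f"orientation must be 'benefit' or 'cost', got {orientation!r}")
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = tuple(int(i) for i in np.flatnonzero(span.ravel() == 0))
    span = np.where(span == 0, 1.0, span)
    r = (X - lo) / span if orientation == "benefit" else (hi - X) / span
    for i in degenerate:
        r[i, :] = 1.0
    return r, degenerate


def entropy(r, n_points: int | None = None) -> float:
    """Normalized Shannon entropy of one normalized performance row.

    The row is first converted to proportions ``f_j = r_j / Σ r_j``; zero
    proportions contribute nothing (the ``0·ln 0 = 0`` convention).  The
    ``1/ln n`` factor scales the result into [0, 1]: 1 for a uniform row,
    0 for a point mass.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1:
        raise ValueError("entropy expects a single row")
    if np.any(r < 0):
        raise ValueError("normalized row must be non-negative")
    total = r.sum()
    if total == 0:
        raise ValueError("all-zero row: proportions undefined")
    n = len(r) if n_points is None else n_points
    if n < 2:
        raise ValueError("need at least 2 points for a normalized entropy")
    f = r / total
    nz = f > 0
    return float(-(f[nz] * np.log(f[nz])).sum() / np.log(n))


def entropy_weights(entropies) -> np.ndarray:
    """Convex weights from per-method entropies: λ_i = (1 − p_i)/(m − Σp_i).

    If every method is maximally entropic (all ``p_i = 1``) the formula is
    0/0; the documented fallback is equal weights with a warning.
    """
    p = np.asarray(entropies, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("entropies must be a non-empty vector")
    if np.any((p < 0) | (p > 1 + 1e-12)):
        raise ValueError(f"entropies must lie in [0, 1], got {p}")
    m = len(p)
    denom = m - p.sum()
    if denom <= 1e-12:
        warnings.warn(
            "all methods maximally entropic; falling back to equal weights",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(m, 1.0 / m)
    lam = (1.0 - p) / denom
    lam = np.clip(lam, 0.0, None)
    return lam / lam.sum()


def combine(forecasts, weights) -> np.ndarray:
    """Weighted sum of the methods' forecasts, step by step.

    ``forecasts`` is ``(m, h)`` — one row per method; ``weights`` has length
    ``m``, is non-negative and sums to 1 (checked to 1e-9).
    """
    F = np.atleast_2d(np.asarray(forecasts, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) != F.shape[0]:
        raise ValueError(f"{len(w)} weights for {F.shape[0]} forecast rows")
    if np.any(w < 0):
        raise ValueError("negative combination weight")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()!r}, expected 1")
    return w @ F


def _performance_matrix(y: np.ndarray, Yhat: np.ndarray, basis: str) -> tuple[np.ndarray, str]:
    rel_err = np.abs(y[None, :] - Yhat) / y[None, :]
    if basis == "accuracy_benefit":
        return np.clip(1.0 - rel_err, 0.0, None), "benefit"
    if basis == "abs_error_cost":
        return rel_err, "cost"
    raise ValueError(f"basis must be one of {BASES}, got {basis!r}")


def weights_from_history(y, Yhat, basis: str = "accuracy_benefit") -> EntropyWeights:
    """Derive combination weights from the methods' historical predictions.

    Parameters
    ----------
    y
        Actual values over the evaluation window (strictly positive).
    Yhat
        ``(m, n)`` matrix of the m methods' predictions at those n points.
    basis
        How performance is scored at each time point:
        ``accuracy_benefit`` (default) — relative accuracy
        ``max(0, 1 − |y − ŷ|/y)``, treated as a benefit quantity;
        ``abs_error_cost`` — relative error ``|y − ŷ|/y`` as a cost quantity.
        The choice is recorded in the returned record for auditability.
    """
    y = np.asarray(y, dtype=float)
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    if y.ndim != 1 or Yhat.shape[1] != len(y):
        raise ValueError(f"shape mismatch: y {y.shape}, Yhat {Yhat.shape}")
    if len(y) < 2:
        raise ValueError("need at least 2 evaluation points")
    if np.any(y <= 0):
        raise ValueError("actual values must be strictly positive")
    X, orientation = _performance_matrix(y, Yhat, basis)
    r, degenerate = normalize_matrix(X, orientation)
    p = np.array([entropy(row) for row in r])
    lam = entropy_weights(p)
    f = r / r.sum(axis=1, keepdims=True)
    return EntropyWeights(
        matrix=X,
        r=r,
        f=f,
        entropies=p,
        weights=lam,
        basis=basis,
        degenerate_rows=degenerate,
    )
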