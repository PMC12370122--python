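"""Continuous-time Markov chain machinery for the three-state CIAF process.

States are indexed 1..n in the public API (1 = undernourished, 2 = nourished,
3 = overnourished for the malnutrition model); matrices are ordinary numpy
arrays indexed 0..n-1.  An intensity matrix Q has non-negative off-diagonal
rates per month and each diagonal entry equal to the negative sum of the rest
of its row, so that P(t) = expm(tQ) is row-stochastic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.linalg import expm

__all__ = [
    "IntensityMatrix",
    "build_intensity_matrix",
    "validate_intensity_matrix",
    "transition_probability",
    "transition_probability_grid",
    "mean_sojourn",
    "next_state_distribution",
    "total_length_of_stay",
    "expected_prevalence",
]

#: default mask: all six off-diagonal transitions of the 3-state model allowed
FULL_MASK_3 = ~np.eye(3, dtype=bool)

_ROW_SUM_TOL = 1e-12
_STOCHASTIC_TOL = 1e-10


@dataclass(frozen=True)
class IntensityMatrix:
    """A validated transition-intensity matrix with its allowed-transition mask."""

    matrix: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        q = np.asarray(self.matrix, dtype=float)
        mask = self.mask
        if mask is None:
            mask = ~np.eye(q.shape[0], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        validate_intensity_matrix(q, mask)
        object.__setattr__(self, "matrix", q)
        object.__setattr__(self, "mask", mask)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.array(self.matrix, dtype=dtype)

    def to_json(self) -> str:
        return json.dumps(
            {"matrix": self.matrix.tolist(), "mask": self.mask.astype(int).tolist()},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "IntensityMatrix":
        obj = json.loads(text)
        return cls(np.asarray(obj["matrix"], float), np.asarray(obj["mask"], bool))

    def to_csv(self, path) -> None:
        n = self.n_states
        labels = [f"state_{i + 1}" for i in range(n)]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "IntensityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float))


def validate_intensity_matrix(q: np.ndarray, mask: np.ndarray | None = None) -> None:
    """Raise ValueError unless ``q`` is a valid intensity matrix (optionally masked)."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError(f"intensity matrix must be square, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("intensity matrix contains non-finite entries")
    off = q[~np.eye(q.shape[0], dtype=bool)]
    if np.any(off < 0):
        raise ValueError("off-diagonal transition rates must be non-negative")
    row_sums = q.sum(axis=1)
    if np.any(np.abs(row_sums) > _ROW_SUM_TOL * max(1.0, np.abs(q).max())):
        raise ValueError(f"rows of an intensity matrix must sum to 0, got {row_sums}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != q.shape:
            raise ValueError("mask shape does not match matrix shape")
        if np.any(np.diag(mask)):
            raise ValueError("mask must be False on the diagonal")
        if np.any(q[~mask & ~np.eye(q.shape[0], dtype=bool)] != 0):
            raise ValueError("disallowed transitions must have rate exactly 0")


def build_intensity_matrix(rates, mask=None) -> IntensityMatrix:
    """Assemble an intensity matrix from off-diagonal rates.

    Parameters
    ----------
    rates
        Either a square array whose off-diagonal entries are the rates
        (the diagonal is ignored and recomputed), or a dict mapping 1-based
        ``(h, j)`` state pairs to rates.
    mask
        Optional boolean allowed-transition matrix.  Defaults to all
        off-diagonal transitions allowed (rates absent from a dict are 0).

    The diagonal is always filled with the negative row sum of the
    off-diagonal entries, so rows sum to zero by construction.
    """
    if isinstance(rates, dict):
        n = 3 if mask is None else np.asarray(mask).shape[0]
        q = np.zeros((n, n))
        for (h, j), rate in rates.items():
            if h == j:
                raise ValueError("diagonal rates cannot be specified directly")
            q[h - 1, j - 1] = rate
    else:
        q = np.array(rates, dtype=float)
    np.fill_diagonal(q, 0.0)
    if np.any(q < 0):
        raise ValueError("off-diagonal transition rates must be non-negative")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if np.any(q[~mask]):
            raise ValueError("non-zero rate supplied for a masked transition")
        q = np.where(mask, q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return IntensityMatrix(q, mask)


def _as_matrix(q) -> np.ndarray:
    return q.matrix if isinstance(q, IntensityMatrix) else np.asarray(q, dtype=float)


def transition_probability(q, t: float) -> np.ndarray:
    """P(t) = expm(tQ): the matrix of state-to-state probabilities over t months."""
    qm = _as_matrix(q)
    if t < 0:
        raise ValueError(f"time horizon must be non-negative, got {t}")
    p = expm(t * qm)
    return _enforce_stochastic(p)


def _enforce_stochastic(p: np.ndarray) -> np.ndarray:
    """Clip numerical noise; refuse to hide real drift from row-stochasticity."""
    drift = max(np.abs(p.sum(axis=-1) - 1.0).max(), max(-p.min(), 0.0))
    if drift > _STOCHASTIC_TOL:
        raise ArithmeticError(
            f"transition-probability matrix drifted from row-stochastic by {drift:.3e}"
        )
    p = np.clip(p, 0.0, 1.0)
    return p / p.sum(axis=-1, keepdims=True)


def transition_probability_grid(q, times) -> np.ndarray:
    """P(t) for an array of horizons, shape (len(times), n, n).

    Uses one eigendecomposition of Q when it is well conditioned, falling
    back to per-horizon scaling-and-squaring otherwise.
    """
    qm = _as_matrix(q)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("time horizons must be non-negative")
    n = qm.shape[0]
    try:
        w, v = np.linalg.eig(qm)
        vinv = np.linalg.inv(v)
        if np.linalg.cond(v) < 1e8:
            e = np.exp(np.multiply.outer(times, w))
            p = np.einsum("ij,tj,jk->tik", v, e, vinv).real
            return np.stack([_enforce_stochastic(pi) for pi in p])
    except (np.linalg.LinAlgError, ArithmeticError):
        pass
    return np.stack([expm(t * qm) for t in times]).reshape(len(times), n, n)


def mean_sojourn(q) -> np.ndarray:
    """Mean time in each state before any transition: -1/q_hh (inf if absorbing)."""
    qm = _as_matrix(q)
    diag = np.diag(qm)
    with np.errstate(divide="ignore"):
        out = np.where(diag < 0, -1.0 / np.where(diag < 0, diag, -1.0), np.inf)
    return out


def next_state_distribution(q) -> np.ndarray:
    """Embedded jump-chain probabilities q_hj / (-q_hh), diagonal 0.

    Rows for absorbing states (no exit) are returned as NaN rather than
    raising: the caller decides how to report an undefined row.
    """
    qm = _as_matrix(q)
    diag = np.diag(qm)
    n = qm.shape[0]
    out = np.full((n, n), np.nan)
    for h in range(n):
        if diag[h] < 0:
            out[h] = qm[h] / (-diag[h])
            out[h, h] = 0.0
    return out


def total_length_of_stay(q, start_state: int, t1: float, t2: float,
                         step: float = 0.1) -> np.ndarray:
    """Expected months spent in each state over [t1, t2] starting from ``start_state``.

    Integrates the occupancy probabilities t -> P(t)[start, k] by composite
    Simpson quadrature on a grid of spacing <= ``step``; the components sum to
    t2 - t1 (conservation) because each P(t) row sums to one.

    ``start_state`` is 1-based.
    """
    qm = _as_matrix(q)
    if not 0 <= t1 < t2:
        raise ValueError(f"need 0 <= t1 < t2, got ({t1}, {t2})")
    n_pts = max(int(np.ceil((t2 - t1) / step)), 2)
    if n_pts % 2:  # Simpson wants an even number of panels
        n_pts += 1
    grid = np.linspace(t1, t2, n_pts + 1)
    occ = transition_probability_grid(qm, grid)[:, start_state - 1, :]
    return simpson(occ, x=grid, axis=0)


def expected_prevalence(q, initial, times) -> pd.DataFrame:
    """Model-expected prevalence (%) of each state over a time grid.

    ``initial`` may be a probability vector or a vector of counts; it is
    normalised.  Returns a tidy frame with columns t, state, expected_pct.
    """
    qm = _as_matrix(q)
    p0 = np.asarray(initial, dtype=float)
    if np.any(p0 < 0) or p0.sum() <= 0:
        raise ValueError("initial distribution must be non-negative with positive sum")
    p0 = p0 / p0.sum()
    times = np.asarray(times, dtype=float)
    pt = transition_probability_grid(qm, times)
    prev = 100.0 * np.einsum("h,thj->tj", p0, pt)
    n = qm.shape[0]
    return pd.DataFrame(
        {
            "t": np.repeat(times, n),
            "state": np.tile(np.arange(1, n + 1), len(times)),
            "expected_pct": prev.ravel(),
        }
    )
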