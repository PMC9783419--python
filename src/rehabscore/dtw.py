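"""Dynamic Time Warping: distance, optimal matching path, normalization.

Two sequences X (length M) and Y (length N) of equal-dimension elements are
aligned by a warping path W = [(i_1, j_1), ..., (i_L, j_L)] that starts at
(0, 0), ends at (M-1, N-1) and advances i, j or both by exactly 1 at each
step (monotonic continuity). With the squared Euclidean local distance
d(x, y) = ||x - y||^2, the cumulative matching distance satisfies

    D(i, j) = d(x_i, y_j) + min(D(i-1, j-1), D(i-1, j), D(i, j-1))

and DTW(X, Y) = D(M-1, N-1), the minimum cumulative distance over all
admissible paths. Path lengths satisfy max(M, N) <= L <= M + N - 1.

The dynamic-programming accumulation is JIT-compiled when numba is
available; an exhaustive path-enumeration oracle (`brute_force_dtw`) is
provided for small instances and is deliberately independent of the DP
route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "WarpingPath",
    "DtwResult",
    "local_distance",
    "dtw_distance",
    "brute_force_dtw",
    "normalize_distance",
]


def _as_sequence(X) -> np.ndarray:
    """Coerce a sequence of scalars or fixed-dimension vectors to (L, d)."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("sequence must be 1-D (scalars) or 2-D (vectors)")
    if arr.shape[0] == 0:
        raise ValueError("sequence must be non-empty")
    return arr


def local_distance(x, y) -> float:
    """Squared Euclidean distance between two equal-dimension elements."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"element dimension mismatch: {x.shape} vs {y.shape}")
    d = x - y
    return float(d @ d)


def _accumulate_py(C: np.ndarray) -> np.ndarray:
    M, N = C.shape
    D = np.empty((M, N))
    D[0, 0] = C[0, 0]
    for j in range(1, N):
        D[0, j] = D[0, j - 1] + C[0, j]
    for i in range(1, M):
        D[i, 0] = D[i - 1, 0] + C[i, 0]
        for j in range(1, N):
            D[i, j] = C[i, j] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return D


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _accumulate = njit(cache=True)(_accumulate_py)
except ImportError:  # pragma: no cover
    _accumulate = _accumulate_py


@dataclass(frozen=True)
class WarpingPath:
    """Monotone, continuous alignment between two sequences (0-based pairs)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("path must be non-empty")

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, M: int, N: int) -> None:
        """Check start/end anchoring, step admissibility and length bounds."""
        if self.pairs[0] != (0, 0):
            raise ValueError("path must start at (0, 0)")
        if self.pairs[-1] != (M - 1, N - 1):
            raise ValueError("path must end at (M-1, N-1)")
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            di, dj = i1 - i0, j1 - j0
            if (di, dj) not in ((1, 0), (0, 1), (1, 1)):
                raise ValueError(f"inadmissible step ({di}, {dj})")
        L = len(self.pairs)
        if not (max(M, N) <= L <= M + N - 1):
            raise ValueError("path length outside [max(M,N), M+N-1]")


@dataclass(frozen=True)
class DtwResult:
    """DTW distance with the optimal path and the accumulated-cost matrix."""

    distance: float
    path: WarpingPath
    accumulated_matrix: np.ndarray


def dtw_distance(X, Y) -> DtwResult:
    """DTW distance and optimal matching path between two sequences.

    Parameters
    ----------
    X, Y:
        Sequences of scalars (1-D) or of equal-dimension vectors (2-D,
        shape (length, dim)).

    Returns
    -------
    DtwResult
        `distance` is the minimum cumulative squared-Euclidean matching
        distance; `path` is an optimal path recovered by backtracking
        (ties broken diagonal > vertical > horizontal); the accumulated
        matrix D has D[0, 0] = d(x_0, y_0) and running sums along the
        first row/column.
    """
    Xa, Ya = _as_sequence(X), _as_sequence(Y)
    if Xa.shape[1] != Ya.shape[1]:
        raise ValueError(
            f"element dimension mismatch: {Xa.shape[1]} vs {Ya.shape[1]}"
        )
    C = cdist(Xa, Ya, "sqeuclidean")
    D = _accumulate(C)
    path = _backtrack(D)
    return DtwResult(distance=float(D[-1, -1]), path=path, accumulated_matrix=D)


def _backtrack(D: np.ndarray) -> WarpingPath:
    M, N = D.shape
    i, j = M - 1, N - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, vert, horiz = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            best = min(diag, vert, horiz)
            if diag == best:  # prefer diagonal, then vertical, then horizontal
                i, j = i - 1, j - 1
            elif vert == best:
                i -= 1
            else:
                j -= 1
        rev.append((i, j))
    return WarpingPath(tuple(reversed(rev)))


_BRUTE_FORCE_LIMIT = 64  # M*N cap; path count grows like the Delannoy numbers


def brute_force_dtw(X, Y) -> float:
    """Exhaustive minimum matching distance over every admissible path.

    Enumerates all monotone, continuous paths without memoization; usable
    only for tiny instances (M*N <= 64). Serves as an independent oracle
    for the dynamic-programming implementation.
    """
    Xa, Ya = _as_sequence(X), _as_sequence(Y)
    if Xa.shape[1] != Ya.shape[1]:
        raise ValueError("element dimension mismatch")
    M, N = Xa.shape[0], Ya.shape[0]
    if M * N > _BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute-force enumeration refused for M*N = {M * N} > {_BRUTE_FORCE_LIMIT}"
        )
    C = cdist(Xa, Ya, "sqeuclidean")
    best = [np.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += C[i, j]
        if acc >= best[0]:
            return
        if i == M - 1 and j == N - 1:
            best[0] = acc
            return
        if i + 1 < M and j + 1 < N:
            walk(i + 1, j + 1, acc)
        if i + 1 < M:
            walk(i + 1, j, acc)
        if j + 1 < N:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return float(best[0])


def normalize_distance(value: float, x_min: float, x_max: float) -> float:
    """Linearly rescale a distance to [0, 1], clipping out-of-range values.

    x_min is the distance of a perfect reproduction of the template (0 by
    construction) and x_max the distance of no movement at all; raw patient
    distances can exceed x_max (e.g. violent tremor), hence the clip.
    """
    if not x_max > x_min:
        raise ValueError("x_max must exceed x_min")
    return float(np.clip((value - x_min) / (x_max - x_min), 0.0, 1.0))
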