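"""Elastic, shape-respecting distances between unequal-length trajectories.

Two related dissimilarities are provided, both defined on the ordered node
sequences of polygonal curves P = (u_1..u_p), Q = (v_1..v_q):

* **Dynamic time warping (DTW)** — the minimum over all warping paths
  (monotone, continuous alignments with both endpoints matched) of the
  *sum* of local distances along the path.  DTW is not a metric: the
  triangle inequality can fail.
* **Discrete Fréchet distance** — the minimum over couplings (the same
  class of alignments) of the *maximum* local distance within the
  coupling ("least of the longest").  This is a metric on node sequences
  and an upper bound for the continuous Fréchet distance.

Both are computed by the standard O(pq) dynamic programs.  The local
distance is the absolute difference of values (1-D Euclidean); time stamps
provide ordering only, not coordinates, so profiles with irregular visit
times and unequal lengths compare directly.  Set ``use_times=True`` to
instead measure locally in the (time, value) plane — a sensitivity option,
not the default analysis.

A plain Euclidean distance on equal-length profiles is included for
reference comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .profiles import ProfileSet, Trajectory

__all__ = [
    "Coupling",
    "WarpingPath",
    "DistanceMatrix",
    "dtw_distance",
    "dtw_warping_path",
    "frechet_distance",
    "frechet_coupling",
    "euclidean_distance",
    "pairwise_matrix",
    "rescale",
    "suggest_rescale_factor",
]

_METRICS = ("dtw", "frechet", "euclidean")


def _as_points(x, use_times: bool) -> np.ndarray:
    """Coerce a trajectory or value sequence to an (n, k) point array."""
    if isinstance(x, Trajectory):
        if use_times:
            return np.column_stack([x.times_array, x.values_array])
        return x.values_array[:, None]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("expected a trajectory, 1-D values, or (n, k) points")
    if arr.shape[0] == 0:
        raise ValueError("empty trajectory")
    return arr


def _check_alignment_pairs(pairs: Sequence[tuple[int, int]]) -> tuple:
    pairs = tuple((int(a), int(b)) for a, b in pairs)
    if not pairs:
        raise ValueError("alignment must contain at least one pair")
    if pairs[0] != (0, 0):
        raise ValueError("alignment must start at (0, 0)")
    for (a0, b0), (a1, b1) in zip(pairs, pairs[1:]):
        if (a1 - a0, b1 - b0) not in ((0, 1), (1, 0), (1, 1)):
            raise ValueError(
                f"indices must each advance by 0 or 1 and pairs must be "
                f"distinct (got {(a0, b0)} -> {(a1, b1)})"
            )
    return pairs


@dataclass(frozen=True)
class Coupling:
    """An ordered alignment of two curves' node indices (0-based).

    Starts at (0, 0), ends at (p-1, q-1); each index advances by 0 or 1 per
    step and consecutive pairs are distinct, so measurement ordering is
    preserved.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", _check_alignment_pairs(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class WarpingPath:
    """A DTW alignment: the same index constraints as a coupling, plus its
    cumulative cost (sum of local distances along the path)."""

    pairs: tuple[tuple[int, int], ...]
    cost: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", _check_alignment_pairs(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities over an ordered subject set."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        m = np.asarray(self.matrix, dtype=float)
        n = len(labels)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        if n and not np.allclose(m, m.T, rtol=0.0, atol=1e-12 * max(1.0, np.abs(m).max())):
            raise ValueError("matrix must be symmetric")
        if n and np.any(np.diag(m) != 0.0):
            raise ValueError("matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        m = np.ascontiguousarray((m + m.T) / 2.0)
        np.fill_diagonal(m, 0.0)
        m.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        """Write a square CSV with a subject-id header row and column (12
        significant digits)."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("," + ",".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "," + ",".join(f"{x:.12g}" for x in row) + "\n")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        labels = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != labels:
            raise ValueError(f"{path}: row and column labels differ")
        return cls(labels=labels, matrix=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# dynamic-programming kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _local(p, q, i, j):
    s = 0.0
    for k in range(p.shape[1]):
        diff = p[i, k] - q[j, k]
        s += diff * diff
    return np.sqrt(s)


@njit(cache=True)
def _dtw_table(p, q):
    n, m = p.shape[0], q.shape[0]
    acc = np.empty((n, m))
    acc[0, 0] = _local(p, q, 0, 0)
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + _local(p, q, 0, j)
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + _local(p, q, i, 0)
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + _local(p, q, i, j)
    return acc


@njit(cache=True)
def _frechet_table(p, q):
    n, m = p.shape[0], q.shape[0]
    acc = np.empty((n, m))
    acc[0, 0] = _local(p, q, 0, 0)
    for j in range(1, m):
        d = _local(p, q, 0, j)
        acc[0, j] = acc[0, j - 1] if acc[0, j - 1] > d else d
    for i in range(1, n):
        d = _local(p, q, i, 0)
        acc[i, 0] = acc[i - 1, 0] if acc[i - 1, 0] > d else d
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            d = _local(p, q, i, j)
            acc[i, j] = best if best > d else d
    return acc


@njit(cache=True)
def _pairwise_kernel(flat, offsets, lengths, width, use_max):
    """All pairwise DTW (use_max=False) or discrete Fréchet (use_max=True)
    distances over ragged sequences packed into ``flat``."""
    n = offsets.shape[0]
    out = np.zeros((n, n))
    acc = np.empty((2, width))
    for a in range(n):
        pa = flat[offsets[a] : offsets[a] + lengths[a]]
        for b in range(a + 1, n):
            qb = flat[offsets[b] : offsets[b] + lengths[b]]
            la, lb = pa.shape[0], qb.shape[0]
            prev = acc[0]
            cur = acc[1]
            prev[0] = abs(pa[0] - qb[0])
            for j in range(1, lb):
                d = abs(pa[0] - qb[j])
                if use_max:
                    prev[j] = prev[j - 1] if prev[j - 1] > d else d
                else:
                    prev[j] = prev[j - 1] + d
            for i in range(1, la):
                d = abs(pa[i] - qb[0])
                if use_max:
                    cur[0] = prev[0] if prev[0] > d else d
                else:
                    cur[0] = prev[0] + d
                for j in range(1, lb):
                    best = prev[j - 1]
                    if prev[j] < best:
                        best = prev[j]
                    if cur[j - 1] < best:
                        best = cur[j - 1]
                    d = abs(pa[i] - qb[j])
                    if use_max:
                        cur[j] = best if best > d else d
                    else:
                        cur[j] = best + d
                tmp = prev
                prev = cur
                cur = tmp
            out[a, b] = prev[lb - 1]
            out[b, a] = prev[lb - 1]
    return out


def _backtrack(acc: np.ndarray, p: np.ndarray, q: np.ndarray, minimax: bool):
    """Recover one optimal alignment; ties prefer the diagonal step, then
    advancing i, then advancing j."""
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    pairs = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            here = acc[i, j]
            if minimax:
                target = min(acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
            else:
                target = here - _local_py(p, q, i, j)
            if _close(acc[i - 1, j - 1], target):
                i, j = i - 1, j - 1
            elif _close(acc[i - 1, j], target):
                i -= 1
            else:
                j -= 1
        pairs.append((i, j))
    pairs.reverse()
    return tuple(pairs)


def _local_py(p: np.ndarray, q: np.ndarray, i: int, j: int) -> float:
    return float(np.sqrt(np.sum((p[i] - q[j]) ** 2)))


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= 1e-9 * (1.0 + abs(a) + abs(b))


# ---------------------------------------------------------------------------
# public distance functions
# ---------------------------------------------------------------------------


def dtw_distance(p, q, use_times: bool = False) -> float:
    """Dynamic time warping distance: minimum over warping paths of the sum
    of local distances, unnormalized, with the symmetric step pattern
    (i-1,j), (i,j-1), (i-1,j-1) and each cell's local cost counted once."""
    pa, qa = _as_points(p, use_times), _as_points(q, use_times)
    return float(_dtw_table(pa, qa)[-1, -1])


def dtw_warping_path(p, q, use_times: bool = False) -> tuple[float, WarpingPath]:
    """DTW distance together with one optimal warping path (deterministic
    tie-breaking: diagonal, then i-advance, then j-advance)."""
    pa, qa = _as_points(p, use_times), _as_points(q, use_times)
    acc = _dtw_table(pa, qa)
    dist = float(acc[-1, -1])
    pairs = _backtrack(acc, pa, qa, minimax=False)
    return dist, WarpingPath(pairs=pairs, cost=dist)


def frechet_distance(p, q, use_times: bool = False) -> float:
    """Discrete Fréchet distance: minimum over couplings of the maximum
    node-pair distance within the coupling."""
    pa, qa = _as_points(p, use_times), _as_points(q, use_times)
    return float(_frechet_table(pa, qa)[-1, -1])


def frechet_coupling(p, q, use_times: bool = False) -> tuple[float, Coupling]:
    """Discrete Fréchet distance together with one achieving coupling."""
    pa, qa = _as_points(p, use_times), _as_points(q, use_times)
    acc = _frechet_table(pa, qa)
    dist = float(acc[-1, -1])
    pairs = _backtrack(acc, pa, qa, minimax=True)
    return dist, Coupling(pairs=pairs)


def euclidean_distance(p, q) -> float:
    """L2 norm of the value difference vector; requires equal lengths.

    Euclidean distance is the lock-step reference: it cannot compare
    profiles of different lengths and is invariant to a common permutation
    of time points, so it ignores shape.
    """
    pa, qa = _as_points(p, False), _as_points(q, False)
    if pa.shape[0] != qa.shape[0]:
        raise ValueError(
            "Euclidean distance requires that all profiles be of the same "
            f"length (got {pa.shape[0]} and {qa.shape[0]})"
        )
    return float(np.linalg.norm(pa - qa))


def pairwise_matrix(
    profile_set: ProfileSet, metric: str = "dtw", use_times: bool = False
) -> DistanceMatrix:
    """All pairwise distances over a profile set.

    Each unordered pair is computed once and mirrored; the diagonal is
    exactly zero.  ``metric`` is one of ``"dtw"``, ``"frechet"``,
    ``"euclidean"`` (the latter requires equal-length profiles).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    labels = profile_set.subject_ids
    n = len(labels)
    if n == 0:
        return DistanceMatrix(labels=(), matrix=np.zeros((0, 0)))
    if metric == "euclidean":
        seqs = profile_set.value_sequences()
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(
                "Euclidean distance requires that all profiles be of the "
                f"same length (lengths present: {sorted(lengths)})"
            )
        stacked = np.vstack(seqs)
        diff = stacked[:, None, :] - stacked[None, :, :]
        m = np.sqrt(np.sum(diff * diff, axis=2))
        np.fill_diagonal(m, 0.0)
        return DistanceMatrix(labels=labels, matrix=m)
    if use_times:
        # (time, value)-plane variant: per-pair tables, no ragged packing
        pts = [
            _as_points(t, use_times=True) for t in profile_set.trajectories
        ]
        m = np.zeros((n, n))
        table = _dtw_table if metric == "dtw" else _frechet_table
        for a in range(n):
            for b in range(a + 1, n):
                m[a, b] = m[b, a] = float(table(pts[a], pts[b])[-1, -1])
        return DistanceMatrix(labels=labels, matrix=m)
    seqs = profile_set.value_sequences()
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
    flat = np.concatenate(seqs).astype(float)
    m = _pairwise_kernel(
        flat, offsets, lengths, int(lengths.max()), metric == "frechet"
    )
    return DistanceMatrix(labels=labels, matrix=m)


def rescale(matrix: DistanceMatrix, factor: float) -> DistanceMatrix:
    """Multiply every entry by a positive factor.

    Rescaling never changes the base clustering a matrix induces (linkage
    order is scale invariant); it changes the weight a view carries when
    several views are ensembled on a common scale.
    """
    if not factor > 0:
        raise ValueError(f"rescale factor must be > 0, got {factor}")
    return DistanceMatrix(
        labels=matrix.labels, matrix=matrix.matrix * float(factor)
    )


def suggest_rescale_factor(
    target: DistanceMatrix, source: DistanceMatrix
) -> float:
    """Factor that matches ``source``'s median off-diagonal distance to
    ``target``'s — a starting point for putting two biomarker views on a
    comparable scale before consensus."""
    def _median_off(m: DistanceMatrix) -> float:
        iu = np.triu_indices(len(m), k=1)
        vals = m.matrix[iu]
        return float(np.median(vals)) if vals.size else 0.0

    src = _median_off(source)
    if src == 0.0:
        raise ValueError("source matrix has zero median distance")
    return _median_off(target) / src
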