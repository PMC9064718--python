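"""Brute-force reference computations for the elastic distances.

These enumerate every admissible alignment (warping path / coupling)
between two short curves and take the exact optimum, independently of the
dynamic programs in :mod:`trajensemble.distances`.  The number of
alignments between curves of lengths p and q is the Delannoy number
D(p-1, q-1), which grows fast: these oracles are for validation on curves
of length ≲ 8 only.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "enumerate_alignments",
    "dtw_brute_force",
    "frechet_brute_force",
]

_STEPS = ((1, 1), (1, 0), (0, 1))


def enumerate_alignments(
    p_len: int, q_len: int
) -> Iterator[tuple[tuple[int, int], ...]]:
    """Yield every monotone alignment from (0,0) to (p_len-1, q_len-1).

    Steps advance i, j, or both by 1 (the warping-path / coupling
    constraint set: matched endpoints, monotone, no index skipped).
    """
    if p_len < 1 or q_len < 1:
        raise ValueError("curves must be non-empty")

    def _extend(i: int, j: int, prefix: list[tuple[int, int]]):
        if i == p_len - 1 and j == q_len - 1:
            yield tuple(prefix)
            return
        for di, dj in _STEPS:
            ni, nj = i + di, j + dj
            if ni < p_len and nj < q_len:
                prefix.append((ni, nj))
                yield from _extend(ni, nj, prefix)
                prefix.pop()

    yield from _extend(0, 0, [(0, 0)])


def _local_matrix(p, q) -> np.ndarray:
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    if pa.ndim == 1:
        pa = pa[:, None]
    if qa.ndim == 1:
        qa = qa[:, None]
    diff = pa[:, None, :] - qa[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def _optimize(p, q, use_max: bool) -> float:
    d = _local_matrix(p, q)
    n, m = d.shape
    best = np.inf

    def _extend(i: int, j: int, acc: float):
        nonlocal best
        if acc >= best:  # both sum and max accumulate monotonically
            return
        if i == n - 1 and j == m - 1:
            best = acc
            return
        for di, dj in _STEPS:
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                step = d[ni, nj]
                _extend(ni, nj, max(acc, step) if use_max else acc + step)

    d00 = d[0, 0]
    _extend(0, 0, d00)
    return float(best)


def dtw_brute_force(p, q) -> float:
    """Exact DTW distance by exhaustive enumeration of warping paths."""
    return _optimize(p, q, use_max=False)


def frechet_brute_force(p, q) -> float:
    """Exact discrete Fréchet distance by exhaustive enumeration of couplings."""
    return _optimize(p, q, use_max=True)
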