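"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from trajensemble.distances import DistanceMatrix
from trajensemble.hierarchy import Dendrogram, complete_linkage
from trajensemble.profiles import ProfileSet, Trajectory


def make_profile(sid: str, values, times=None, marker: str = "m") -> Trajectory:
    values = list(values)
    if times is None:
        times = list(range(len(values)))
    return Trajectory(
        subject_id=sid, marker=marker, times=tuple(times), values=tuple(values)
    )


def make_profile_set(value_lists, marker: str = "m") -> ProfileSet:
    return ProfileSet(
        trajectories=tuple(
            make_profile(f"s{i}", vals, marker=marker)
            for i, vals in enumerate(value_lists)
        ),
        marker=marker,
    )


def random_distance_matrix(
    rng: np.random.Generator, n: int, tie_decimals: int | None = None
) -> DistanceMatrix:
    """Random symmetric zero-diagonal matrix; rounding to ``tie_decimals``
    deliberately creates tied distances."""
    m = rng.uniform(0.5, 10.0, size=(n, n))
    m = (m + m.T) / 2.0
    if tie_decimals is not None:
        m = np.round(m, tie_decimals)
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels=tuple(f"s{i}" for i in range(n)), matrix=m)


def random_dendrogram(rng: np.random.Generator, n: int) -> Dendrogram:
    """Random hierarchy: complete linkage of a random distance matrix, with
    occasional ties to exercise tie-breaking."""
    ties = 1 if rng.random() < 0.3 else None
    return complete_linkage(random_distance_matrix(rng, n, tie_decimals=ties))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)


@pytest.fixture
def three_point_dendrogram() -> Dendrogram:
    """The worked 3-leaf example: D(1,2)=1, D(1,3)=5, D(2,3)=4 under
    complete linkage -> merge {1,2} at 1, then all at 5."""
    d = DistanceMatrix(
        labels=("s0", "s1", "s2"),
        matrix=np.array([[0, 1, 5], [1, 0, 4], [5, 4, 0]], dtype=float),
    )
    return complete_linkage(d)
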