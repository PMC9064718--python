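"""Agglomerative hierarchies, ultrametric descriptors, cuts and Newick I/O.

A dendrogram on n leaves is stored as an ordered list of n-1 merges with
non-decreasing heights (scipy node-numbering convention: leaves are
0..n-1, the i-th merge creates node n+i).  A totally indexed agglomerative
hierarchy is in bijection with an ultrametric — a dissimilarity obeying
δ(i,k) ≤ max(δ(i,j), δ(j,k)) for every triple — and this module provides
both directions: descriptor matrices (cophenetic distance, cluster
membership divergence) from a dendrogram, and exact reconstruction of the
dendrogram from an ultrametric.

The agglomeration is implemented here rather than delegated so that ties
in merge distances break deterministically (lexicographically smallest
pair of cluster representatives, a cluster being represented by its
smallest leaf index); heights then match scipy's complete linkage exactly
whenever distances are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "Dendrogram",
    "UltrametricMatrix",
    "linkage",
    "complete_linkage",
    "cophenetic_matrix",
    "membership_divergence_matrix",
    "cut",
    "is_ultrametric",
    "dendrogram_from_ultrametric",
    "write_newick",
    "read_newick",
]

_LINKAGES = ("complete", "single", "average")


@dataclass(frozen=True)
class Dendrogram:
    """A totally indexed agglomerative hierarchy.

    ``merges[i] = (left, right, height)`` creates internal node
    ``n_leaves + i`` from nodes ``left`` and ``right`` (leaf nodes are
    0..n_leaves-1).  Heights are non-decreasing in merge order.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        leaves = tuple(str(x) for x in self.leaves)
        n = len(leaves)
        merges = tuple(
            (int(a), int(b), float(h)) for a, b, h in self.merges
        )
        if len(set(leaves)) != n:
            raise ValueError("leaf ids must be unique")
        if len(merges) != max(n - 1, 0):
            raise ValueError(
                f"{n} leaves require {n - 1} merges, got {len(merges)}"
            )
        used: set[int] = set()
        scale = max((h for _, _, h in merges), default=0.0)
        prev = -np.inf
        for i, (a, b, h) in enumerate(merges):
            node = n + i
            for child in (a, b):
                if not 0 <= child < node:
                    raise ValueError(
                        f"merge {i}: child {child} out of range [0, {node})"
                    )
                if child in used:
                    raise ValueError(f"merge {i}: node {child} merged twice")
                used.add(child)
            if a == b:
                raise ValueError(f"merge {i}: identical children {a}")
            if h < prev - 1e-9 * max(1.0, scale):
                raise ValueError(
                    f"merge heights must be non-decreasing "
                    f"(merge {i}: {h} after {prev})"
                )
            prev = h
        object.__setattr__(self, "leaves", leaves)
        object.__setattr__(self, "merges", merges)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges], dtype=float)

    def leaf_sets(self) -> list[frozenset[int]]:
        """Leaf-index set under every node, indexed by node id."""
        n = self.n_leaves
        sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        for a, b, _ in self.merges:
            sets.append(sets[a] | sets[b])
        return sets


@dataclass(frozen=True)
class UltrametricMatrix:
    """A symmetric zero-diagonal matrix satisfying the ultrametric inequality
    (to tolerance); the matrix form of a dendrogram descriptor or of a
    consensus result."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        dm = DistanceMatrix(labels=self.labels, matrix=self.matrix)
        ok, worst = is_ultrametric(dm.matrix)
        if not ok:
            raise ValueError(
                f"matrix violates the ultrametric inequality at triple {worst}"
            )
        object.__setattr__(self, "labels", dm.labels)
        object.__setattr__(self, "matrix", dm.matrix)

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        DistanceMatrix(labels=self.labels, matrix=self.matrix).to_csv(path)


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------


def linkage(d: DistanceMatrix, method: str = "complete") -> Dendrogram:
    """Agglomerative hierarchical clustering of a distance matrix.

    At each step the globally closest active pair merges; the inter-cluster
    distance is the maximum (complete), minimum (single) or size-weighted
    mean (average) over cross pairs.  Equal merge distances break by the
    lexicographically smallest (smallest-leaf-index) representative pair,
    making the output deterministic.
    """
    if method not in _LINKAGES:
        raise ValueError(f"method must be one of {_LINKAGES}, got {method!r}")
    n = len(d)
    if n < 2:
        raise ValueError(f"need at least 2 subjects to cluster, got {n}")
    work = d.matrix.copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    node_id = np.arange(n)          # current dendrogram node per slot
    rep = np.arange(n)              # smallest leaf index per slot
    size = np.ones(n, dtype=np.int64)
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        h = masked.min()
        ties = np.argwhere(masked == h)
        # representative-pair lexicographic tie-break
        cand = sorted(
            (tuple(sorted((int(rep[i]), int(rep[j])))), int(i), int(j))
            for i, j in ties
            if i < j
        )
        _, i, j = cand[0]
        merges.append((int(node_id[i]), int(node_id[j]), float(h)))
        if method == "complete":
            new_row = np.maximum(work[i], work[j])
        elif method == "single":
            new_row = np.minimum(work[i], work[j])
        else:
            new_row = (size[i] * work[i] + size[j] * work[j]) / (
                size[i] + size[j]
            )
        work[i] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        active[j] = False
        node_id[i] = n + step
        rep[i] = min(rep[i], rep[j])
        size[i] += size[j]
    return Dendrogram(leaves=d.labels, merges=tuple(merges))


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Complete-linkage agglomeration (the analysis default)."""
    return linkage(d, method="complete")


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


def _descriptor(h: Dendrogram, use_size: bool) -> UltrametricMatrix:
    n = h.n_leaves
    m = np.zeros((n, n))
    sets = [frozenset([i]) for i in range(n)]
    for a, b, height in h.merges:
        left, right = sets[a], sets[b]
        fill = float(len(left) + len(right)) if use_size else height
        rows = np.fromiter(left, dtype=np.int64)
        cols = np.fromiter(right, dtype=np.int64)
        m[np.ix_(rows, cols)] = fill
        m[np.ix_(cols, rows)] = fill
        sets.append(left | right)
    return UltrametricMatrix(labels=h.leaves, matrix=m)


def cophenetic_matrix(h: Dendrogram) -> UltrametricMatrix:
    """Cophenetic distances: entry (i, j) is the height of the lowest merge
    joining leaves i and j.  Always ultrametric."""
    return _descriptor(h, use_size=False)


def membership_divergence_matrix(h: Dendrogram) -> UltrametricMatrix:
    """Cluster membership divergence: entry (i, j) is the leaf count of the
    smallest dendrogram cluster containing both i and j (diagonal 0)."""
    return _descriptor(h, use_size=True)


def cut(h: Dendrogram, k: int) -> np.ndarray:
    """Flat k-group labels from removing the k-1 highest merges.

    Clusters are numbered 1..k by their smallest contained leaf index, so
    the labeling is deterministic.  Because only the merge *order* matters,
    cut labels are invariant under positive rescaling of the input
    distances.
    """
    n = h.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sets = h.leaf_sets()
    for a, b, _ in h.merges[: n - k]:
        ra = find(min(sets[a]))
        rb = find(min(sets[b]))
        parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(i) for i in range(n)})
    number = {r: c + 1 for c, r in enumerate(roots)}
    return np.array([number[find(i)] for i in range(n)], dtype=np.int64)


# ---------------------------------------------------------------------------
# ultrametric machinery
# ---------------------------------------------------------------------------


def is_ultrametric(
    m: np.ndarray, tol: float | None = None
) -> tuple[bool, tuple[int, int, int] | None]:
    """Check δ(i,k) ≤ max(δ(i,j), δ(j,k)) + tol over all triples.

    Returns (verdict, worst violating triple (i, j, k) or None).  The
    default tolerance is 1e-8 × (max entry).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    n = m.shape[0]
    if tol is None:
        tol = 1e-8 * (float(m.max()) if n else 0.0)
    worst_val = -np.inf
    worst: tuple[int, int, int] | None = None
    for j in range(n):
        # violation of apex pair (i,k) witnessed by j
        bound = np.maximum.outer(m[:, j], m[j, :])
        viol = m - bound
        viol[j, :] = -np.inf
        viol[:, j] = -np.inf
        np.fill_diagonal(viol, -np.inf)
        idx = int(np.argmax(viol))
        i, k = divmod(idx, n)
        if viol[i, k] > worst_val:
            worst_val = viol[i, k]
            worst = (i, j, k)
    if worst_val <= tol:
        return True, None
    return False, worst


def dendrogram_from_ultrametric(
    u: UltrametricMatrix | DistanceMatrix, tol: float | None = None
) -> Dendrogram:
    """Recover the unique hierarchy encoded by an ultrametric matrix.

    Agglomerates at the sorted distinct values of the matrix (single
    linkage, which on an exact ultrametric reproduces it as its cophenetic
    matrix).  Equal heights across disjoint groups merge sequentially in
    leaf-index order, producing a binary tree for a polytomy.
    """
    ok, worst = is_ultrametric(u.matrix, tol=tol)
    if not ok:
        raise ValueError(
            f"input is not ultrametric within tolerance (worst triple {worst})"
        )
    dm = DistanceMatrix(labels=u.labels, matrix=u.matrix)
    return linkage(dm, method="single")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NEWICK_HEADER = (
    "[trajensemble dendrogram: ultrametric tree; node age = merge height / 2,"
    " so cophenetic distance = 2 x MRCA age]"
)


def write_newick(h: Dendrogram, path=None) -> str:
    """Serialize a dendrogram as a rooted ultrametric Newick tree.

    Branch lengths place every node at age = merge height / 2 (leaves at
    age 0), so the root-to-leaf path length is half the maximum cophenetic
    distance.  Halving is exact in binary floating point and lengths are
    written with full repr precision, so heights survive a round trip
    exactly.  Returns the Newick string; writes it to ``path`` if given.
    """
    n = h.n_leaves
    for leaf in h.leaves:
        if any(c in leaf for c in "(),:;[]' \t\n"):
            raise ValueError(f"leaf id {leaf!r} not representable in Newick")
    age = [0.0] * n + [hh / 2.0 for _, _, hh in h.merges]
    text: list[str] = list(h.leaves)
    for idx, (a, b, _) in enumerate(h.merges):
        node = n + idx
        la = age[node] - age[a]
        lb = age[node] - age[b]
        text.append(f"({text[a]}:{la!r},{text[b]}:{lb!r})")
    out = _NEWICK_HEADER + "\n" + text[-1] + ";\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(out)
    return out


def read_newick(source) -> Dendrogram:
    """Parse a Newick tree written by :func:`write_newick` back into a
    dendrogram.

    ``source`` is a path or a Newick string.  The tree must be ultrametric
    under the writer's age convention; the hierarchy is rebuilt from the
    implied cophenetic distances, which reproduces the merges exactly.
    """
    text = str(source)
    if "(" not in text:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    # strip [...] comments
    out_chars: list[str] = []
    depth = 0
    for c in text:
        if c == "[":
            depth += 1
        elif c == "]":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced ] in Newick input")
        elif depth == 0:
            out_chars.append(c)
    s = "".join(out_chars).strip()
    if not s.endswith(";"):
        raise ValueError("Newick input must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node():
        nonlocal pos
        children = []
        if s[pos] == "(":
            pos += 1
            while True:
                children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        name = s[start:pos].strip()
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            length = float(s[start:pos])
        return {"name": name, "length": length, "children": children}

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick input: {s[pos:]!r}")

    leaves: list[str] = []
    pair_height: dict[tuple[int, int], float] = {}

    def walk(node) -> tuple[list[int], float]:
        """Return (leaf indices, node age)."""
        if not node["children"]:
            leaves.append(node["name"] or f"leaf{len(leaves)}")
            return [len(leaves) - 1], 0.0
        groups = []
        age = None
        for child in node["children"]:
            idxs, child_age = walk(child)
            node_age = child_age + child["length"]
            if age is None:
                age = node_age
            elif abs(node_age - age) > 1e-9 * (1.0 + abs(age)):
                raise ValueError(
                    "tree is not ultrametric: children disagree on node age "
                    f"({node_age} vs {age})"
                )
            groups.append(idxs)
        merged: list[int] = []
        for g in groups:
            for i in merged:
                for jj in g:
                    pair_height[(min(i, jj), max(i, jj))] = 2.0 * age
            merged.extend(g)
        return merged, float(age)

    idxs, _ = walk(root)
    n = len(leaves)
    if n == 1:
        return Dendrogram(leaves=tuple(leaves), merges=())
    m = np.zeros((n, n))
    for (i, j), hh in pair_height.items():
        m[i, j] = m[j, i] = hh
    return dendrogram_from_ultrametric(
        UltrametricMatrix(labels=tuple(leaves), matrix=m)
    )
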