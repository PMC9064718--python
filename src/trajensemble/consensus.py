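"""Consensus of several hierarchies by least-squares ultrametric fitting.

Each biomarker "view" yields a base dendrogram; rendering every dendrogram
as an ultrametric descriptor matrix (cophenetic distance by default) turns
consensus into a constrained least-squares problem: find the ultrametric
U minimizing

    L(U) = Σ_b w_b Σ_{i<j} (u_ij − d^b_ij)²

over the m descriptor matrices d^b.  The ultrametric constraint is
enforced by SUMT (Sequential Unconstrained Minimization Technique, after
de Soete): minimize L(U) + r·Φ(U), where Φ penalizes the squared amount
by which any triple violates u_ik ≤ max(u_ij, u_jk), with the penalty
weight r escalating geometrically across outer iterations.  The converged
matrix is snapped to an exact ultrametric by single-linkage (subdominant)
closure — the identity on matrices that are already ultrametric — and the
consensus dendrogram is rebuilt from it, which the hierarchy/ultrametric
bijection makes unique.

Because the views enter through squared distances, their descriptor
scales act as implicit weights; harmonizing scales (e.g. rescaling one
view's distances) is the caller's job and a warning is emitted when view
maxima differ by more than 10×.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .hierarchy import (
    Dendrogram,
    UltrametricMatrix,
    cophenetic_matrix,
    dendrogram_from_ultrametric,
    is_ultrametric,
    membership_divergence_matrix,
)

__all__ = [
    "ConsensusProblem",
    "SUMTConfig",
    "ConsensusResult",
    "ConsensusConvergenceError",
    "build_problem",
    "consensus_ultrametric",
]


@dataclass(frozen=True)
class ConsensusProblem:
    """m ultrametric descriptor matrices over one label set, with positive
    per-view weights (default equal)."""

    descriptors: tuple[UltrametricMatrix, ...]
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        descriptors = tuple(self.descriptors)
        if not descriptors:
            raise ValueError("at least one descriptor matrix is required")
        labels = descriptors[0].labels
        for d in descriptors[1:]:
            if d.labels != labels:
                raise ValueError(
                    "descriptor matrices must share labels and order"
                )
        weights = tuple(self.weights) or (1.0,) * len(descriptors)
        if len(weights) != len(descriptors):
            raise ValueError(
                f"{len(weights)} weights for {len(descriptors)} descriptors"
            )
        if any(w <= 0 for w in weights):
            raise ValueError("weights must be positive")
        object.__setattr__(self, "descriptors", descriptors)
        object.__setattr__(self, "weights", tuple(float(w) for w in weights))

    @property
    def labels(self) -> tuple[str, ...]:
        return self.descriptors[0].labels


@dataclass(frozen=True)
class SUMTConfig:
    """SUMT schedule: inner unconstrained minimizations of L + r·Φ with r
    starting at ``initial_penalty`` and multiplied by ``penalty_growth``
    each outer iteration, at most ``outer_iters`` times.

    Convergence requires the worst single triple violation of the inner
    solution to fall below ``ultrametric_tolerance`` × (max entry) before
    the exact single-linkage snap.  ``n_restarts`` > 0 adds seeded random
    perturbations of the initial point and keeps the best solution.
    """

    initial_penalty: float = 1.0
    penalty_growth: float = 10.0
    outer_iters: int = 10
    inner_gtol: float = 1e-8
    ultrametric_tolerance: float = 1e-3
    n_restarts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.penalty_growth > 1.0:
            raise ValueError("penalty_growth must be > 1")
        if self.outer_iters < 1:
            raise ValueError("outer_iters must be >= 1")


@dataclass(frozen=True)
class ConsensusResult:
    """Finalized consensus: the exact ultrametric, its dendrogram, the
    least-squares objective L at the finalized matrix, and the SUMT trace."""

    ultrametric: UltrametricMatrix
    dendrogram: Dendrogram
    objective: float
    objective_trace: tuple[float, ...]
    phi_trace: tuple[float, ...]


class ConsensusConvergenceError(RuntimeError):
    """SUMT failed to reach an (almost) ultrametric iterate; carries the
    best iterate found in ``best_matrix``."""

    def __init__(self, message: str, best_matrix: np.ndarray):
        super().__init__(message)
        self.best_matrix = best_matrix


def build_problem(
    dendrograms,
    descriptor: str = "cophenetic",
    weights=None,
) -> ConsensusProblem:
    """Render a list of dendrograms (identical leaf sets required) into a
    consensus problem via ``"cophenetic"`` or ``"membership_divergence"``
    descriptor matrices, aligned to the first dendrogram's leaf order."""
    dendrograms = list(dendrograms)
    if not dendrograms:
        raise ValueError("at least one dendrogram is required")
    ref = dendrograms[0].leaves
    ref_set = set(ref)
    for h in dendrograms[1:]:
        if set(h.leaves) != ref_set:
            diff = sorted(ref_set.symmetric_difference(h.leaves))
            raise ValueError(f"dendrogram leaf sets differ on subjects: {diff}")
    if descriptor == "cophenetic":
        fn = cophenetic_matrix
    elif descriptor == "membership_divergence":
        fn = membership_divergence_matrix
    else:
        raise ValueError(
            "descriptor must be 'cophenetic' or 'membership_divergence', "
            f"got {descriptor!r}"
        )
    mats = []
    for h in dendrograms:
        u = fn(h)
        perm = [u.labels.index(lab) for lab in ref]
        m = u.matrix[np.ix_(perm, perm)]
        mats.append(UltrametricMatrix(labels=ref, matrix=m))
    return ConsensusProblem(
        descriptors=tuple(mats), weights=tuple(weights or ())
    )


# ---------------------------------------------------------------------------
# objective / penalty machinery (upper-triangle parameterization)
# ---------------------------------------------------------------------------


def _to_matrix(x: np.ndarray, n: int) -> np.ndarray:
    u = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    u[iu] = x
    return u + u.T


def _ls_objective(x, dvecs, weights):
    resid = x[None, :] - dvecs
    val = float(np.sum(weights[:, None] * resid * resid))
    grad = 2.0 * np.sum(weights[:, None] * resid, axis=0)
    return val, grad


def _penalty(x, n, iu):
    """Φ and its gradient over ordered triples (i, j, k), i.e. each
    unordered apex pair (i, k) with witness j is counted twice."""
    u = _to_matrix(x, n)
    phi = 0.0
    grad = np.zeros((n, n))
    for j in range(n):
        bound = np.maximum.outer(u[:, j], u[j, :])
        viol = u - bound
        viol[j, :] = 0.0
        viol[:, j] = 0.0
        np.fill_diagonal(viol, 0.0)
        np.clip(viol, 0.0, None, out=viol)
        phi += float(np.sum(viol * viol))
        grad += 2.0 * viol
        from_row = u[:, j][:, None] >= u[j, :][None, :]
        grad[:, j] -= 2.0 * np.sum(viol * from_row, axis=1)
        grad[j, :] -= 2.0 * np.sum(viol * (~from_row), axis=0)
    return phi, grad[iu] + grad.T[iu]


def _max_violation(u: np.ndarray) -> float:
    worst = 0.0
    n = u.shape[0]
    for j in range(n):
        bound = np.maximum.outer(u[:, j], u[j, :])
        viol = u - bound
        viol[j, :] = 0.0
        viol[:, j] = 0.0
        np.fill_diagonal(viol, 0.0)
        worst = max(worst, float(viol.max()))
    return worst


def _subdominant(u: np.ndarray, labels) -> tuple[UltrametricMatrix, Dendrogram]:
    """Single-linkage closure: the largest ultrametric below u (identity when
    u is already ultrametric)."""
    from .distances import DistanceMatrix
    from .hierarchy import linkage

    dm = DistanceMatrix(labels=labels, matrix=u)
    h = linkage(dm, method="single")
    return cophenetic_matrix(h), h


def consensus_ultrametric(
    problem: ConsensusProblem, config: SUMTConfig = SUMTConfig()
) -> ConsensusResult:
    """Fit the least-squares consensus ultrametric by SUMT.

    Initialization is the weighted mean of the descriptors (the
    unconstrained optimum); if that mean is itself ultrametric the method
    returns it unchanged.  Returns the finalized (exactly ultrametric)
    matrix, its dendrogram, the objective L there, and the per-outer-
    iteration traces of L and Φ.
    """
    labels = problem.labels
    n = len(labels)
    weights = np.asarray(problem.weights, dtype=float)
    scales = [float(d.matrix.max()) for d in problem.descriptors]
    if len(scales) > 1 and max(scales) > 10.0 * max(min(scales), 1e-300):
        warnings.warn(
            f"descriptor scale maxima differ by more than 10x ({scales}); "
            "consider rescaling the views before consensus",
            stacklevel=2,
        )
    if n < 2:
        u = UltrametricMatrix(labels=labels, matrix=np.zeros((n, n)))
        return ConsensusResult(
            ultrametric=u,
            dendrogram=Dendrogram(leaves=labels, merges=()),
            objective=0.0,
            objective_trace=(0.0,),
            phi_trace=(0.0,),
        )
    iu = np.triu_indices(n, k=1)
    dvecs = np.stack([d.matrix[iu] for d in problem.descriptors])
    x_mean = np.sum(weights[:, None] * dvecs, axis=0) / weights.sum()

    starts = [x_mean]
    if config.n_restarts > 0:
        rng = np.random.default_rng(config.seed)
        spread = float(np.std(dvecs)) or 1.0
        for _ in range(config.n_restarts):
            starts.append(
                x_mean + rng.normal(0.0, 0.05 * spread, size=x_mean.shape)
            )

    scale = max(float(np.max(dvecs)), 1e-300)
    tol_abs = config.ultrametric_tolerance * scale

    best: tuple[float, np.ndarray, list, list] | None = None
    for x0 in starts:
        x = x0.copy()
        r = config.initial_penalty
        obj_trace: list[float] = []
        phi_trace: list[float] = []
        converged = False
        for _ in range(config.outer_iters):
            def fun(xv, r=r):
                ls, gls = _ls_objective(xv, dvecs, weights)
                phi, gphi = _penalty(xv, n, iu)
                return ls + r * phi, gls + r * gphi

            res = minimize(
                fun,
                x,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500, "gtol": config.inner_gtol},
            )
            x = res.x
            ls_val, _ = _ls_objective(x, dvecs, weights)
            phi_val, _ = _penalty(x, n, iu)
            obj_trace.append(float(ls_val))
            phi_trace.append(float(phi_val))
            if _max_violation(_to_matrix(x, n)) <= tol_abs:
                converged = True
                break
            r *= config.penalty_growth
        if not converged:
            continue
        ls_val, _ = _ls_objective(x, dvecs, weights)
        if best is None or ls_val < best[0]:
            best = (float(ls_val), x, obj_trace, phi_trace)

    if best is None:
        raise ConsensusConvergenceError(
            f"SUMT did not reach an ultrametric iterate within "
            f"{config.outer_iters} outer iterations "
            f"(tolerance {config.ultrametric_tolerance} x max entry)",
            best_matrix=_to_matrix(x, n),
        )

    _, x, obj_trace, phi_trace = best
    u_raw = np.clip(_to_matrix(x, n), 0.0, None)
    u_final, dendro = _subdominant(u_raw, labels)
    ls_final, _ = _ls_objective(u_final.matrix[iu], dvecs, weights)
    ok, _ = is_ultrametric(u_final.matrix)
    assert ok, "finalized consensus must be exactly ultrametric"
    return ConsensusResult(
        ultrametric=u_final,
        dendrogram=dendro,
        objective=float(ls_final),
        objective_trace=tuple(obj_trace),
        phi_trace=tuple(phi_trace),
    )
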