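"""End-to-end pipelines.

* :func:`run_cbf_benchmark` — the CBF missingness study: generate a base
  training set, optionally sparsify, draw MCAR patterns, cluster under
  each distance, and score external indices against the true shape
  labels, aggregated as mean (sd) across draws.
* :func:`run_univariate` — the single-biomarker pipeline: optional
  minimum-visit filter and value preprocessing, pairwise elastic
  distances, complete-linkage clustering, a flat k-group cut, and
  internal validity indices.
* :func:`run_ensemble` — the multi-view pipeline: per-view univariate
  dendrograms (with optional per-view distance rescaling to harmonize
  scales), cophenetic descriptors, SUMT consensus, a consensus cut, and
  cross-tabulations of each view's cut against the consensus.

All randomness flows from a single master seed via
``numpy.random.SeedSequence`` spawning, so every run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation as ev
from .consensus import (
    ConsensusResult,
    SUMTConfig,
    build_problem,
    consensus_ultrametric,
)
from .distances import DistanceMatrix, pairwise_matrix, rescale
from .hierarchy import Dendrogram, cut, linkage
from .profiles import ProfileSet, censor_limits, filter_min_visits, log10_values
from .synthetic_data import CBFConfig, MCARConfig, apply_mcar, generate_cbf, sparsify

logger = logging.getLogger("trajensemble")

__all__ = [
    "BenchmarkConfig",
    "BenchmarkResult",
    "run_cbf_benchmark",
    "UnivariateResult",
    "run_univariate",
    "ViewSpec",
    "EnsembleResult",
    "run_ensemble",
    "write_labels_csv",
]


# ---------------------------------------------------------------------------
# CBF benchmark harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkConfig:
    """One benchmark run: a CBF variant (full, or sparse via
    ``sparse_step``), a list of missingness fractions, distances to
    compare, and the clustering settings.

    The base profile set is generated once per master seed and held fixed
    across the ``n_reps`` missingness draws (set
    ``regenerate_base_per_rep`` to redraw it each rep for variance
    decomposition).  A zero fraction is a single evaluation of the base
    set, so its sd column is 0.  Euclidean distance is only valid at
    fraction 0, where all profiles still share one length.
    """

    cbf: CBFConfig = CBFConfig()
    sparse_step: int | None = None
    missing_fractions: tuple[float, ...] = (0.0, 0.25, 0.5)
    n_reps: int = 500
    metrics: tuple[str, ...] = ("dtw", "frechet")
    linkage_method: str = "complete"
    k: int = 3
    seed: int = 0
    regenerate_base_per_rep: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(f > 0 for f in self.missing_fractions) and "euclidean" in self.metrics:
            raise ValueError(
                "euclidean distance cannot be evaluated under missingness "
                "(profiles become unequal length); restrict it to fraction 0"
            )
        object.__setattr__(
            self, "missing_fractions", tuple(self.missing_fractions)
        )
        object.__setattr__(self, "metrics", tuple(self.metrics))


@dataclass(frozen=True)
class BenchmarkResult:
    """Mean (sd) of adjusted Rand, Fowlkes–Mallows and purity per
    (variant, fraction, metric) cell, as a tidy DataFrame."""

    table: pd.DataFrame
    config: BenchmarkConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _derive_seed(seed_seq: np.random.SeedSequence) -> int:
    """A 31-bit child seed from a SeedSequence (safe for any seed-taking API)."""
    return int(seed_seq.generate_state(1, dtype=np.uint64)[0] >> np.uint64(33))


_INDEX_FNS = {
    "adj_rand": ev.adjusted_rand,
    "fowlkes_mallows": ev.fowlkes_mallows,
    "purity": ev.purity,
}


def _score_rep(labeled, metric: str, method: str, k: int) -> dict[str, float]:
    dm = pairwise_matrix(labeled.profile_set, metric=metric)
    labels = cut(linkage(dm, method=method), k)
    return {
        name: fn(labels, np.asarray(labeled.labels))
        for name, fn in _INDEX_FNS.items()
    }


def run_cbf_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Run the CBF clustering benchmark and aggregate external indices."""
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    base_seed, mcar_ss, regen_ss = ss.spawn(3)
    variant = "sparse" if config.sparse_step else "full"

    def _base(seed_seq) -> "LabeledProfileSet":
        cbf = dataclasses.replace(
            config.cbf, seed=_derive_seed(seed_seq)
        )
        out = generate_cbf(cbf)
        if config.sparse_step:
            out = sparsify(out, config.sparse_step)
        return out

    base = _base(base_seed)
    rows = []
    for fraction in config.missing_fractions:
        if fraction == 0.0:
            scores = [_score_rep(base, m, config.linkage_method, config.k)
                      for m in config.metrics]
            for metric, sc in zip(config.metrics, scores):
                row = {"variant": variant, "fraction": 0.0, "metric": metric,
                       "n_reps": 1}
                for name, v in sc.items():
                    row[f"{name}_mean"] = v
                    row[f"{name}_sd"] = 0.0
                rows.append(row)
            continue
        rep_seeds = mcar_ss.spawn(config.n_reps)
        regen_seeds = regen_ss.spawn(config.n_reps)
        per_metric: dict[str, list[dict[str, float]]] = {
            m: [] for m in config.metrics
        }
        for rep in range(config.n_reps):
            rep_base = _base(regen_seeds[rep]) if config.regenerate_base_per_rep else base
            mcar = MCARConfig(
                fraction=fraction,
                seed=_derive_seed(rep_seeds[rep]),
            )
            masked = apply_mcar(rep_base, mcar)
            for metric in config.metrics:
                per_metric[metric].append(
                    _score_rep(masked, metric, config.linkage_method, config.k)
                )
        for metric in config.metrics:
            df = pd.DataFrame(per_metric[metric])
            row = {"variant": variant, "fraction": fraction, "metric": metric,
                   "n_reps": config.n_reps}
            for name in _INDEX_FNS:
                row[f"{name}_mean"] = float(df[name].mean())
                row[f"{name}_sd"] = float(df[name].std(ddof=1)) if len(df) > 1 else 0.0
            rows.append(row)
        logger.info(
            "benchmark %s fraction=%.2f done (%.1fs)",
            variant, fraction, time.perf_counter() - t0,
        )
    return BenchmarkResult(table=pd.DataFrame(rows), config=config)


# ---------------------------------------------------------------------------
# univariate pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnivariateResult:
    """Labels (1..k, subject order), the dendrogram, the distance matrix it
    came from, and a report with internal indices."""

    labels: np.ndarray
    dendrogram: Dendrogram
    distance_matrix: DistanceMatrix
    report: dict


def run_univariate(
    profiles: ProfileSet,
    metric: str = "dtw",
    k: int = 3,
    min_visits: int | None = None,
    log10: bool = False,
    censor: tuple[float, float] | None = None,
    linkage_method: str = "complete",
    use_times: bool = False,
    compute_indices: bool = True,
) -> UnivariateResult:
    """Cluster one biomarker's profiles into k shape groups.

    Pipeline: optional ≥min_visits filter → optional quantitation-limit
    clamp → optional log10 transform → pairwise elastic distances →
    agglomerative linkage → flat cut at k.  Internal indices (average
    silhouette, Dunn) are computed on the same distance matrix; their
    requirement of ≥ 2 clusters propagates, so ``k=1`` with
    ``compute_indices=True`` raises.
    """
    t0 = time.perf_counter()
    work = profiles
    if min_visits is not None:
        work = filter_min_visits(work, min_visits)
    if censor is not None:
        work = censor_limits(work, *censor)
    if log10:
        work = log10_values(work)
    if len(work) < 2:
        raise ValueError(
            f"need at least 2 profiles after filtering, got {len(work)}"
        )
    dm = pairwise_matrix(work, metric=metric, use_times=use_times)
    dendro = linkage(dm, method=linkage_method)
    labels = cut(dendro, k)
    report = {
        "marker": work.marker,
        "metric": metric,
        "linkage": linkage_method,
        "k": k,
        "n_subjects": len(work),
        "cluster_sizes": {
            int(c): int((labels == c).sum()) for c in np.unique(labels)
        },
        "seconds": round(time.perf_counter() - t0, 3),
    }
    if compute_indices:
        report["avg_silhouette"] = ev.silhouette_avg(dm, labels)
        report["dunn_index"] = ev.dunn_index(dm, labels)
    logger.info(
        "univariate %s/%s k=%d on n=%d (%.2fs)",
        work.marker, metric, k, len(work), time.perf_counter() - t0,
    )
    return UnivariateResult(
        labels=labels, dendrogram=dendro, distance_matrix=dm, report=report
    )


# ---------------------------------------------------------------------------
# ensemble pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViewSpec:
    """One biomarker view entering the ensemble: its profiles, the distance
    to use, preprocessing, a multiplicative distance rescale factor used
    to harmonize scales across views, and the k of its own univariate cut
    (reported alongside the consensus)."""

    profiles: ProfileSet
    metric: str = "dtw"
    rescale_factor: float = 1.0
    log10: bool = False
    censor: tuple[float, float] | None = None
    min_visits: int | None = None
    k: int = 3
    name: str = ""


@dataclass(frozen=True)
class EnsembleResult:
    """Consensus labels and dendrogram plus the per-view univariate results
    and the cross-tabulations between views and against the consensus."""

    consensus_labels: np.ndarray
    consensus: ConsensusResult
    views: tuple[UnivariateResult, ...]
    view_names: tuple[str, ...]
    crosstabs: dict
    report: dict


def run_ensemble(
    views,
    k: int = 4,
    sumt: SUMTConfig = SUMTConfig(),
    compute_indices: bool = True,
) -> EnsembleResult:
    """Aggregate several biomarker views into one consensus clustering.

    Per view: univariate pipeline to a dendrogram, with the view's
    distance matrix rescaled by its ``rescale_factor`` first (rescaling
    never changes the view's own clustering, only its weight in the
    consensus).  The cophenetic descriptor matrices are then fitted with
    a SUMT consensus ultrametric, cut at ``k`` (default 4).

    Cross-tabulations emitted: each view's univariate cut against the
    consensus cut, and the first two views against each other together
    with the Pearson chi-square of that table.
    """
    views = [
        v if isinstance(v, ViewSpec) else ViewSpec(*v) for v in views
    ]
    if not views:
        raise ValueError("at least one view is required")
    ref_ids = None
    uni_results: list[UnivariateResult] = []
    names: list[str] = []
    dendrograms = []
    for i, v in enumerate(views):
        res = run_univariate(
            v.profiles,
            metric=v.metric,
            k=v.k,
            min_visits=v.min_visits,
            log10=v.log10,
            censor=v.censor,
            compute_indices=compute_indices,
        )
        ids = res.distance_matrix.labels
        if ref_ids is None:
            ref_ids = ids
        elif set(ids) != set(ref_ids):
            diff = sorted(set(ids).symmetric_difference(ref_ids))
            raise ValueError(f"views disagree on subjects: {diff}")
        if v.rescale_factor != 1.0:
            res = UnivariateResult(
                labels=res.labels,
                dendrogram=linkage(
                    rescale(res.distance_matrix, v.rescale_factor),
                    method="complete",
                ),
                distance_matrix=rescale(res.distance_matrix, v.rescale_factor),
                report={**res.report, "rescale_factor": v.rescale_factor},
            )
        uni_results.append(res)
        names.append(v.name or v.profiles.marker or f"view{i}")
        dendrograms.append(res.dendrogram)

    problem = build_problem(dendrograms, descriptor="cophenetic")
    cons = consensus_ultrametric(problem, sumt)
    cons_labels_full = cut(cons.dendrogram, k)
    cons_labels = cons_labels_full[
        [cons.dendrogram.leaves.index(sid) for sid in ref_ids]
    ]

    crosstabs: dict = {}
    for name, res in zip(names, uni_results):
        aligned = _align_labels(res, ref_ids)
        crosstabs[f"{name}_vs_consensus"] = ev.cross_tabulate(
            aligned, cons_labels
        )
    if len(views) >= 2:
        a = _align_labels(uni_results[0], ref_ids)
        b = _align_labels(uni_results[1], ref_ids)
        table = ev.cross_tabulate(a, b)
        crosstabs[f"{names[0]}_vs_{names[1]}"] = table
        stat, df = ev.chi_square(table)
        chi = {"statistic": stat, "df": df}
    else:
        chi = None
    report = {
        "k": k,
        "views": [r.report for r in uni_results],
        "view_names": names,
        "consensus_objective": cons.objective,
        "phi_trace": list(cons.phi_trace),
        "objective_trace": list(cons.objective_trace),
        "cluster_sizes": {
            int(c): int((cons_labels == c).sum())
            for c in np.unique(cons_labels)
        },
        "chi_square_between_views": chi,
    }
    return EnsembleResult(
        consensus_labels=cons_labels,
        consensus=cons,
        views=tuple(uni_results),
        view_names=tuple(names),
        crosstabs=crosstabs,
        report=report,
    )


def _align_labels(res: UnivariateResult, ref_ids) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(res.distance_matrix.labels)}
    return res.labels[[pos[sid] for sid in ref_ids]]


def write_labels_csv(subject_ids, labels, path) -> None:
    """Write flat cluster labels as ``subject_id,cluster`` CSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("subject_id,cluster\n")
        for sid, lab in zip(subject_ids, labels):
            fh.write(f"{sid},{lab}\n")
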