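"""Synthetic data: the CBF clustering benchmark and a CD4 / viral-load cohort.

Two generators make every downstream stage testable without any external
download:

* **Cylinder–bell–funnel (CBF)** — the classic three-class simulated
  time-series benchmark (Saito's formulation).  Each profile has
  ``length`` equispaced noisy points; class shapes are a flat plateau
  (cylinder), a linear ramp up (bell) and a linear ramp down (funnel)
  over a random support [a, b].  Companions impose sparsity (keep every
  k-th point) and missing-completely-at-random (MCAR) deletion of an
  exact fraction of the value-matrix cells.

* **Longitudinal HIV-style cohort** — subjects in latent progression
  groups, each with a CD4 count trajectory and a viral-load trajectory
  on a shared visit schedule (months {0, 6, 12, 18, 24}) with integer
  visit jitter, geometric dropout, an enrollment CD4 floor, and
  viral-load quantitation limits.  Group archetypes follow the four
  progression patterns a bivariate analysis is meant to tease apart:
  low-CD4/high-VL, medium-CD4/rising-VL, high-CD4/suppressed-VL, and a
  small high-CD4/high-VL "recently infected" group.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .profiles import (
    LabeledProfileSet,
    ProfileSet,
    Trajectory,
    censor_limits,
)

__all__ = [
    "CBFConfig",
    "MCARConfig",
    "TrendParams",
    "GroupSpec",
    "CohortConfig",
    "generate_cbf",
    "sparsify",
    "apply_mcar",
    "generate_cohort",
    "default_cohort_config",
    "noise_free_cohort_config",
    "low_noise_cohort_config",
]


# ---------------------------------------------------------------------------
# CBF benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CBFConfig:
    """Configuration for the cylinder–bell–funnel generator.

    ``n_per_class`` profiles per shape class, each with ``length``
    equispaced points at times 1..length; ``noise_sd`` scales both the
    per-profile amplitude perturbation and the per-point noise (standard
    normals at the default 1.0).
    """

    n_per_class: int = 10
    length: int = 128
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MCARConfig:
    """Missing-completely-at-random deletion of an exact cell fraction.

    Exactly round(fraction × N × T) cells of the N×T value matrix are
    removed uniformly without replacement; the whole removal set is
    redrawn if any profile would drop below ``min_points_per_profile``.
    """

    fraction: float = 0.25
    seed: int = 0
    min_points_per_profile: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")
        if self.min_points_per_profile < 1:
            raise ValueError("min_points_per_profile must be >= 1")


_CBF_CLASSES = ("cylinder", "bell", "funnel")


def generate_cbf(config: CBFConfig) -> LabeledProfileSet:
    """Generate a labeled CBF profile set (3 × n_per_class profiles).

    Shapes, with χ the indicator of the random support [a, b]
    (a ~ U{16..32}, b−a ~ U{32..96}), amplitude 6+η, η ~ N(0, noise_sd²),
    and per-point noise ε(t) ~ N(0, noise_sd²):

    * cylinder: (6+η)·χ[a,b](t) + ε(t)
    * bell:     (6+η)·χ[a,b](t)·(t−a)/(b−a) + ε(t)
    * funnel:   (6+η)·χ[a,b](t)·(b−t)/(b−a) + ε(t)
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(1, config.length + 1, dtype=float)
    trajectories: list[Trajectory] = []
    labels: list[str] = []
    counter = 0
    for cls in _CBF_CLASSES:
        for _ in range(config.n_per_class):
            a = float(rng.integers(16, 33))
            b = a + float(rng.integers(32, 97))
            eta = rng.normal(0.0, 1.0) * config.noise_sd
            eps = rng.normal(0.0, 1.0, size=config.length) * config.noise_sd
            chi = ((t >= a) & (t <= b)).astype(float)
            if cls == "cylinder":
                shape = chi
            elif cls == "bell":
                shape = chi * (t - a) / (b - a)
            else:
                shape = chi * (b - t) / (b - a)
            values = (6.0 + eta) * shape + eps
            trajectories.append(
                Trajectory(
                    subject_id=f"{cls[0]}{counter:03d}",
                    marker="cbf",
                    times=tuple(t),
                    values=tuple(values),
                )
            )
            labels.append(cls)
            counter += 1
    return LabeledProfileSet(
        profile_set=ProfileSet(trajectories=tuple(trajectories), marker="cbf"),
        labels=tuple(labels),
    )


def sparsify(labeled: LabeledProfileSet, step: int) -> LabeledProfileSet:
    """Keep every ``step``-th point (positions 1, 1+step, 1+2·step, … in
    1-based terms) of every profile; labels unchanged."""
    if step < 1:
        raise ValueError("step must be >= 1")
    shortest = min(len(t) for t in labeled.profile_set)
    if step > shortest:
        raise ValueError(
            f"step {step} exceeds shortest profile length {shortest}"
        )
    out = []
    for traj in labeled.profile_set:
        idx = range(0, len(traj), step)
        out.append(
            Trajectory(
                subject_id=traj.subject_id,
                marker=traj.marker,
                times=tuple(traj.times[i] for i in idx),
                values=tuple(traj.values[i] for i in idx),
                censor_flags=tuple(traj.censor_flags[i] for i in idx),
            )
        )
    return LabeledProfileSet(
        profile_set=ProfileSet(
            trajectories=tuple(out), marker=labeled.profile_set.marker
        ),
        labels=labeled.labels,
    )


def apply_mcar(
    labeled: LabeledProfileSet, config: MCARConfig, max_redraws: int = 1000
) -> LabeledProfileSet:
    """Delete an exact number of cells uniformly at random from the profile
    value matrix.

    Requires all profiles to share one length T (matrix-shaped data).  The
    removal count is round(fraction · N · T), ties rounding up.  Removal is
    without replacement over cells, so per-profile missingness varies —
    some profiles lose little, others a lot.  Surviving points keep their
    original times, hence time order.
    """
    lengths = {len(t) for t in labeled.profile_set}
    if len(lengths) != 1:
        raise ValueError(
            f"MCAR requires equal-length profiles, lengths present {sorted(lengths)}"
        )
    n = len(labeled)
    t_len = lengths.pop()
    total = n * t_len
    n_remove = int(np.floor(config.fraction * total + 0.5))
    if total - n_remove < n * config.min_points_per_profile:
        raise ValueError(
            f"removing {n_remove} of {total} cells cannot leave every profile "
            f">= {config.min_points_per_profile} points"
        )
    rng = np.random.default_rng(config.seed)
    for _ in range(max_redraws):
        removed = rng.choice(total, size=n_remove, replace=False)
        keep = np.ones(total, dtype=bool)
        keep[removed] = False
        keep = keep.reshape(n, t_len)
        if keep.sum(axis=1).min() >= config.min_points_per_profile:
            break
    else:
        raise ValueError(
            f"could not satisfy min_points_per_profile={config.min_points_per_profile} "
            f"in {max_redraws} redraws"
        )
    out = []
    for row, traj in zip(keep, labeled.profile_set):
        idx = np.flatnonzero(row)
        out.append(
            Trajectory(
                subject_id=traj.subject_id,
                marker=traj.marker,
                times=tuple(traj.times[i] for i in idx),
                values=tuple(traj.values[i] for i in idx),
                censor_flags=tuple(traj.censor_flags[i] for i in idx),
            )
        )
    return LabeledProfileSet(
        profile_set=ProfileSet(
            trajectories=tuple(out), marker=labeled.profile_set.marker
        ),
        labels=labeled.labels,
    )


# ---------------------------------------------------------------------------
# CD4 / viral-load cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendParams:
    """Linear group trend for one marker: value(t) = intercept + slope·t
    + subject effect (N(0, subject_sd²), one draw per subject) + visit
    noise (N(0, noise_sd²) per point).  Viral load trends are on the
    log10 scale."""

    intercept: float
    slope: float
    subject_sd: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class GroupSpec:
    """One latent progression group: its size and the CD4 / log10-VL trends."""

    name: str
    size: int
    cd4: TrendParams
    vl: TrendParams

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"group {self.name!r}: size must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic longitudinal cohort.

    Visits are the scheduled months plus integer jitter uniform on
    [-visit_jitter_months, +visit_jitter_months], clipped to [0, 25];
    after the baseline visit a subject drops out before each subsequent
    scheduled visit with probability ``dropout_prob_per_visit``
    (geometric follow-up).  Baseline CD4 below ``baseline_cd4_min`` is
    resampled (enrollment eligibility).  VL values are exponentiated from
    the log10 trend and clamped to ``vl_limits``.
    """

    groups: tuple[GroupSpec, ...]
    scheduled_months: tuple[int, ...] = (0, 6, 12, 18, 24)
    visit_jitter_months: int = 1
    dropout_prob_per_visit: float = 0.096
    vl_limits: tuple[float, float] = (400.0, 750_000.0)
    baseline_cd4_min: float = 350.0
    max_month: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        if not 0.0 <= self.dropout_prob_per_visit <= 1.0:
            raise ValueError("dropout_prob_per_visit must be in [0, 1]")
        if self.visit_jitter_months < 0:
            raise ValueError("visit_jitter_months must be >= 0")
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(
            self, "scheduled_months", tuple(self.scheduled_months)
        )
        object.__setattr__(
            self, "vl_limits", tuple(float(x) for x in self.vl_limits)
        )

    def to_yaml(self, path) -> None:
        def _plain(x):
            if isinstance(x, dict):
                return {k: _plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_plain(v) for v in x]
            return x

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        groups = tuple(
            GroupSpec(
                name=g["name"],
                size=g["size"],
                cd4=TrendParams(**g["cd4"]),
                vl=TrendParams(**g["vl"]),
            )
            for g in raw.pop("groups")
        )
        raw = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(groups=groups, **raw)


# Archetypes for the four progression patterns.  CD4 in cells/uL, VL on the
# log10 copies/mL scale; slopes per month over a 24-month window.
_ARCHETYPES = {
    "low_cd4_high_vl": dict(
        cd4=dict(intercept=430.0, slope=-7.0), vl=dict(intercept=4.8, slope=0.01)
    ),
    "mid_cd4_rising_vl": dict(
        cd4=dict(intercept=600.0, slope=-3.0), vl=dict(intercept=3.1, slope=0.05)
    ),
    "high_cd4_low_vl": dict(
        cd4=dict(intercept=820.0, slope=-1.5), vl=dict(intercept=2.4, slope=0.0)
    ),
    "high_cd4_high_vl": dict(
        cd4=dict(intercept=790.0, slope=-2.5), vl=dict(intercept=4.5, slope=-0.04)
    ),
}

_DEFAULT_SIZES = (40, 21, 8, 4)
_DEFAULT_SUBJECT_SD = {"cd4": 45.0, "vl": 0.25}
_DEFAULT_NOISE_SD = {"cd4": 50.0, "vl": 0.35}


def _make_config(
    seed: int,
    noise_scale: float,
    group_sizes,
    group_names,
    visit_jitter_months: int,
    dropout_prob_per_visit: float,
) -> CohortConfig:
    names = tuple(group_names)
    sizes = tuple(group_sizes)
    if len(sizes) != len(names):
        raise ValueError(f"need {len(names)} group sizes, got {len(sizes)}")
    groups = []
    for name, size in zip(names, sizes):
        arch = _ARCHETYPES[name]
        groups.append(
            GroupSpec(
                name=name,
                size=size,
                cd4=TrendParams(
                    subject_sd=_DEFAULT_SUBJECT_SD["cd4"] * noise_scale,
                    noise_sd=_DEFAULT_NOISE_SD["cd4"] * noise_scale,
                    **arch["cd4"],
                ),
                vl=TrendParams(
                    subject_sd=_DEFAULT_SUBJECT_SD["vl"] * noise_scale,
                    noise_sd=_DEFAULT_NOISE_SD["vl"] * noise_scale,
                    **arch["vl"],
                ),
            )
        )
    return CohortConfig(
        groups=tuple(groups),
        visit_jitter_months=visit_jitter_months,
        dropout_prob_per_visit=dropout_prob_per_visit,
        seed=seed,
    )


def default_cohort_config(
    seed: int = 0, group_sizes=None, group_names=None
) -> CohortConfig:
    """Realistic-noise cohort: four archetype groups sized (40, 21, 8, 4)
    (roughly 1/10 of the consensus group sizes a 646-subject cohort
    splits into), jitter ±1 month, per-visit dropout 0.096 (≈74% of
    subjects keep ≥4 visits, matching a 646-of-875 retention)."""
    names = group_names or tuple(_ARCHETYPES)
    sizes = group_sizes or _DEFAULT_SIZES[: len(names)]
    return _make_config(seed, 1.0, sizes, names, 1, 0.096)


def low_noise_cohort_config(
    seed: int = 0, group_sizes=None, group_names=None
) -> CohortConfig:
    """Quarter-noise variant of the default cohort (same trends and visit
    process); used for parameter-recovery checks."""
    names = group_names or tuple(_ARCHETYPES)
    sizes = group_sizes or _DEFAULT_SIZES[: len(names)]
    return _make_config(seed, 0.25, sizes, names, 1, 0.05)


def noise_free_cohort_config(
    seed: int = 0, group_sizes=None, group_names=None
) -> CohortConfig:
    """Degenerate cohort: no noise, no jitter, no dropout — every subject in
    a group has the identical trajectory, so any sensible pipeline must
    recover the groups exactly."""
    names = group_names or tuple(_ARCHETYPES)
    sizes = group_sizes or _DEFAULT_SIZES[: len(names)]
    return _make_config(seed, 0.0, sizes, names, 0, 0.0)


def generate_cohort(
    config: CohortConfig,
) -> tuple[LabeledProfileSet, LabeledProfileSet]:
    """Generate the bivariate cohort: (CD4 view, VL view).

    Both views share subject ids, order, visit times and group labels.
    Returns two :class:`LabeledProfileSet`; labels are the group names.
    """
    rng = np.random.default_rng(config.seed)
    cd4_trajs: list[Trajectory] = []
    vl_trajs: list[Trajectory] = []
    labels: list[str] = []
    counter = 0
    for group in config.groups:
        for _ in range(group.size):
            sid = f"s{counter:04d}"
            counter += 1
            months = _draw_visits(rng, config)
            t = np.asarray(months, dtype=float)

            cd4_subject = rng.normal(0.0, 1.0) * group.cd4.subject_sd
            cd4_noise = rng.normal(0.0, 1.0, size=len(t)) * group.cd4.noise_sd
            cd4 = group.cd4.intercept + group.cd4.slope * t + cd4_subject + cd4_noise
            # enrollment eligibility: resample baseline until CD4 >= floor
            while cd4[0] < config.baseline_cd4_min:
                cd4_subject = rng.normal(0.0, 1.0) * group.cd4.subject_sd
                cd4_noise[0] = rng.normal(0.0, 1.0) * group.cd4.noise_sd
                cd4 = (
                    group.cd4.intercept
                    + group.cd4.slope * t
                    + cd4_subject
                    + cd4_noise
                )
            cd4 = np.maximum(cd4, 1.0)  # counts cannot go negative

            vl_subject = rng.normal(0.0, 1.0) * group.vl.subject_sd
            vl_noise = rng.normal(0.0, 1.0, size=len(t)) * group.vl.noise_sd
            log_vl = group.vl.intercept + group.vl.slope * t + vl_subject + vl_noise
            vl = np.power(10.0, log_vl)

            cd4_trajs.append(
                Trajectory(sid, "cd4", tuple(t), tuple(cd4))
            )
            vl_trajs.append(
                Trajectory(sid, "vl", tuple(t), tuple(vl))
            )
            labels.append(group.name)
    cd4_set = ProfileSet(trajectories=tuple(cd4_trajs), marker="cd4")
    vl_set = censor_limits(
        ProfileSet(trajectories=tuple(vl_trajs), marker="vl"),
        *config.vl_limits,
    )
    return (
        LabeledProfileSet(profile_set=cd4_set, labels=tuple(labels)),
        LabeledProfileSet(profile_set=vl_set, labels=tuple(labels)),
    )


def _draw_visits(rng: np.random.Generator, config: CohortConfig) -> list[int]:
    """Scheduled months ± integer jitter (clipped to [0, max_month]),
    truncated by geometric dropout after baseline."""
    months: list[int] = []
    for v, scheduled in enumerate(sorted(config.scheduled_months)):
        if v > 0 and rng.random() < config.dropout_prob_per_visit:
            break
        j = config.visit_jitter_months
        jitter = int(rng.integers(-j, j + 1)) if j > 0 else 0
        month = int(np.clip(scheduled + jitter, 0, config.max_month))
        if months and month <= months[-1]:
            month = months[-1] + 1  # jitter collision: push to next month
        if month > config.max_month:
            break
        months.append(month)
    return months


def write_labels_csv(labeled: LabeledProfileSet, path) -> None:
    """Write the ground-truth labels as ``subject_id,label`` CSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("subject_id,label\n")
        for sid, lab in zip(labeled.subject_ids, labeled.labels):
            fh.write(f"{sid},{lab}\n")
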