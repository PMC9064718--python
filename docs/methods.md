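# Methods

This note records the models, algorithmic choices, parameter defaults and
known limitations of `trajensemble`. Everything quantitative stated here
is computed by the package's tests, examples or acceptance script.

## Data model

A trajectory is one subject's strictly time-ordered value sequence for
one marker; visit times are stored (months, reals accepted) but by
default only supply the ordering. No interpolation or imputation is ever
performed: the elastic distances compare unequal-length sequences
directly. Values at assay quantitation limits are clamped and flagged
(`at_lower_limit` / `at_upper_limit`) rather than dropped, so censored
viral-load measurements are clustered as observed. Subject order is the
order of first appearance in the input and indexes every downstream
matrix and label vector.

## Elastic distances

Both distances act on the node sequences of the two profiles under the
classic monotone-alignment constraint set: the alignment starts at the
first pair of nodes, ends at the last, and each index advances by 0 or 1
per step.

- **DTW** minimizes the *sum* of local distances along the alignment.
  Dialect: symmetric steps (i−1,j), (i,j−1), (i−1,j−1); each cell's local
  cost counted once; no window constraint; no path-length normalization.
  This is the plain "minimum cumulative distance" definition; it keeps
  δ_F ≤ δ_DTW structurally (a max over the DTW-optimal path is at most
  its sum), which the suite asserts on random pairs.
- **Discrete Fréchet** minimizes the *maximum* local distance over the
  same alignment class; it satisfies the triangle inequality (asserted on
  random triples), DTW does not and is not asserted to.
- Local distance is |value difference| (1-D Euclidean). An explicitly
  opt-in variant (`use_times=True`) measures locally in the (time, value)
  plane for sensitivity analysis; it is not the default because the
  analysis deliberately avoids exact time referencing.
- Tie-breaking when recovering an optimal path/coupling: prefer the
  diagonal predecessor, then the i-advance, then the j-advance — output
  alignments are deterministic.
- Correctness anchor: for curve lengths ≤ 6 both dynamic programs equal
  exhaustive enumeration of all alignments (Delannoy-many), run as a
  500-case seeded suite.

Pairwise matrices are computed once per unordered pair and mirrored; the
inner loops are numba-compiled (two-row tables over ragged packed
sequences), which is what makes 500-replicate benchmark sweeps cheap.

## Hierarchies and ultrametrics

Agglomeration (complete by default; single and average provided) is
implemented directly so that equal merge distances break
deterministically: among tied closest pairs, merge the pair whose
(smallest-leaf-index) representatives are lexicographically smallest.
On distance matrices with distinct entries the heights agree with
scipy's implementation to machine precision (cross-checked in tests).

Flat k-cuts remove the k−1 highest merges and number clusters 1..k by
smallest contained leaf index; cuts are invariant under positive
rescaling of the input distances.

Descriptor matrices: cophenetic distance (height of the lowest common
merge; the default) and cluster membership divergence (leaf count of the
smallest common cluster). Both are exactly ultrametric by construction.
`dendrogram_from_ultrametric` recovers the unique hierarchy from an
ultrametric via single linkage (which reproduces an exact ultrametric as
its cophenetic matrix); the round trip cophenetic → reconstruct →
cophenetic is asserted to be the identity over 1000 random hierarchies.
The ultrametric test uses tolerance 1e−8 × (max entry) by default and
reports the worst violating triple.

Newick export places each node at age = merge height / 2 (leaves at 0),
so the tree is ultrametric and cophenetic distance = 2 × MRCA age;
halving is exact in binary floating point and branch lengths are written
at full precision, so heights survive a round trip. The reader parses
only this dialect (bracket comments stripped) and rebuilds the hierarchy
from the implied cophenetic matrix.

## Consensus (SUMT least-squares ultrametric)

Given m descriptor matrices d¹..dᵐ with positive weights w (equal by
default), the consensus minimizes L(U) = Σ_b w_b Σ_{i<j} (u_ij − dᵇ_ij)²
over ultrametrics U. The constraint is handled by sequential
unconstrained minimization: minimize L + r·Φ where
Φ(U) = Σ over ordered triples with u_ik > max(u_ij, u_jk) of
(u_ik − max)², with r starting at 1 and ×10 per outer iteration (at most
10 outer iterations).

Numerical choices:

- Parameterization: the n(n−1)/2 upper-triangle entries.
- Inner minimizer: L-BFGS-B with analytic gradients of both L and Φ
  (gradient tolerance 1e−8, ≤ 500 inner iterations). A quasi-Newton
  descent was preferred over a hand-rolled conjugate-gradient loop: it is
  equally deterministic and removes step-size heuristics from the
  package's responsibility. Optional seeded perturbed restarts
  (`n_restarts`) keep the best solution; the default is 0 restarts, so
  runs are deterministic.
- Initialization: the weighted mean of the descriptors — the
  unconstrained optimum. If the mean is already ultrametric the method
  terminates there, making "consensus of identical (or scalar-multiple)
  inputs" an exact fixed point, which the suite asserts.
- Convergence: the worst single triple violation of the inner solution
  must fall below 1e−3 × (max entry); otherwise an error carrying the
  best iterate is raised.
- Finalization: single-linkage (subdominant ultrametric) closure of the
  converged matrix — the largest ultrametric below it, and the identity
  on matrices already ultrametric — followed by exact dendrogram
  reconstruction. The returned objective is L evaluated at the finalized
  matrix. Tests assert the result is always exactly ultrametric and its
  objective never exceeds that of any input descriptor.

Scale harmonization across views is deliberately the caller's job (the
squared-loss weights views by their descriptor scales); the HIV-style
workflow rescales the log10-VL distance matrix by a multiplicative
factor of 300 before ensembling, and `suggest_rescale_factor` offers a
median-distance-ratio starting point. A warning is emitted when view
maxima differ by more than 10×. k for the consensus cut is always
explicit (default 4 in the ensemble workflow, 3 for univariate cuts);
the package never auto-selects k.

## Synthetic data

**CBF benchmark.** The canonical cylinder/bell/funnel formulation:
c(t) = (6+η)·χ[a,b](t) + ε(t), b(t) = (6+η)·χ[a,b](t)·(t−a)/(b−a) + ε(t),
f(t) = (6+η)·χ[a,b](t)·(b−t)/(b−a) + ε(t), with a uniform on {16..32},
b−a uniform on {32..96}, η and ε(t) standard normal scaled by
`noise_sd` (default 1), on 128 equispaced points (times 1..128). The
sparse variant keeps every fourth point (32 points). MCAR removes
exactly round(fraction·N·T) cells (ties up) uniformly without
replacement from the N×T value matrix, redrawing the whole pattern in
the rare case a profile would fall below `min_points_per_profile`
(default 1) — so per-profile missingness varies naturally. Removal
margins are checked by a chi-square goodness-of-fit over 1000 seeds.

**Cohort generator.** Subjects belong to latent progression groups, each
with linear CD4 and log10-VL trends plus a per-subject random intercept
and per-visit noise. Defaults:

| group | size | CD4 (cells/µL) | log10 VL |
|---|---|---|---|
| low_cd4_high_vl | 40 | 430 − 7·t | 4.8 + 0.01·t |
| mid_cd4_rising_vl | 21 | 600 − 3·t | 3.1 + 0.05·t |
| high_cd4_low_vl | 8 | 820 − 1.5·t | 2.4 (flat, mostly below limit) |
| high_cd4_high_vl | 4 | 790 − 2.5·t | 4.5 − 0.04·t |

Sizes are ~1/10 of the consensus group sizes a 646-subject cohort splits
into; the last group is the small "recently infected" pattern whose CD4
trajectories mimic the high-CD4 group while VL separates them — the
generator's target phenomenon. Subject-level sds: CD4 45, VL 0.25;
visit-noise sds: CD4 50, VL 0.35 (the `low_noise` preset scales all four
by 0.25; the `noise_free` preset zeroes them plus jitter and dropout).
Visits: scheduled months {0,6,12,18,24} ± integer jitter (±1 month,
collisions pushed to the next month), clipped to [0,25]; after baseline
a subject drops out before each subsequent visit with probability 0.096,
chosen so ≈74% of subjects retain ≥4 visits (matching a 646-of-875
retention); baseline CD4 < 350 (the enrollment floor) is resampled. VL
is exponentiated and clamped to the quantitation limits [400, 750000].

What the generator does *not* emulate: missing-not-at-random visit
processes, treatment effects, nonlinear (e.g. acute-phase) trajectories,
measurement batch effects, and within-subject autocorrelation beyond the
random intercept. Passing recovery tests therefore shows the pipeline
recovers *linear-trend shape groups under MCAR-like irregularity*, not
that it would resolve arbitrary real-cohort structure.

## Benchmark harness and problem sizes

A benchmark run holds one generated base set fixed per master seed and
draws `n_reps` fresh MCAR patterns (the 0% row is a single evaluation);
`regenerate_base_per_rep` exists for variance decomposition. All seeds
derive from the master seed via `SeedSequence` spawning; runs are
bit-reproducible.

Because a single base set's mean adjusted Rand varies widely (between
base sets, sd ≈ 0.1–0.2), reproduction checks aggregate over regenerated
base sets. The test suite uses 16 base sets × 120 draws per condition;
the acceptance script uses 8 (full variant) or 12 (sparse) base sets ×
500 draws. These sizes give grand means with standard errors well below
the between-base-set spread they are compared against.

## Known limitations

- The agglomeration is O(n³) dense; fine for cohort-scale n (≤ a few
  thousand), not for very large profile sets.
- The SUMT penalty is nonconvex; the returned consensus is a stationary
  point reached from the mean initialization (optionally the best of
  seeded restarts), not a certified global optimum.
- DTW distances here are unnormalized sums, so profiles with many more
  points accumulate larger distances; within a marker view this is the
  intended behavior (all profiles share a visit process), across views
  it is exactly why rescaling is exposed.
- Euclidean distance is provided for reference only and requires
  equal-length profiles.
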