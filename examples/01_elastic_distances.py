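"""Elastic distances between two unequal-length trajectories.

Builds two toy biomarker profiles that share a shape but differ in timing
and length, and compares DTW, discrete Fréchet and (where possible)
Euclidean distance.
"""

from trajensemble import (
    Trajectory,
    dtw_warping_path,
    frechet_coupling,
)

# the same rise-and-fall shape, sampled at different visit schedules
p = Trajectory("patient_a", "cd4", times=(0, 6, 12, 18, 24),
               values=(500.0, 650.0, 700.0, 600.0, 480.0))
q = Trajectory("patient_b", "cd4", times=(0, 7, 13, 25),
               values=(510.0, 700.0, 610.0, 470.0))

dtw, path = dtw_warping_path(p, q)
frech, coupling = frechet_coupling(p, q)

print(f"DTW distance (sum of local differences): {dtw:.1f}")
print(f"  optimal warping path: {path.pairs}")
print(f"discrete Frechet distance (worst matched pair): {frech:.1f}")
print(f"  optimal coupling:     {coupling.pairs}")

# DTW sums |value| differences along the best monotone alignment, so it
# uses every point; Frechet keeps only the largest matched difference, so
# it is never larger than DTW.  Euclidean distance cannot even be computed
# here: the profiles have 5 and 4 visits.
assert frech <= dtw
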