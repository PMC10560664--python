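"""Fixation detection and the Voronoi fixation-distribution index.

Detects fixations with the dispersion-threshold (I-DT) algorithm on a
synthetic trial, then quantifies how spread out they are: the unit square
is tessellated by the Voronoi diagram of the fixation centroids and the
index is the median normalized cell area. Concentrated gaze produces many
tiny cells and a small index ("visual centralization"); dispersed gaze a
larger one.
"""

import numpy as np

from gazeload import default_aoi_set, detect_fixations_idt, fixation_distribution
from gazeload.synthetic import render_samples, simulate_fixation_sequence

aoi = default_aoi_set()

for label, scale in (("concentrated (high load)", 0.13), ("dispersed (no load)", 0.24)):
    fds = []
    n_fix = []
    rng = np.random.default_rng(3)  # common random numbers across conditions
    for _ in range(10):
        seq = simulate_fixation_sequence(30.0, 0.65, scale, aoi, rng)
        t, x, y, valid = render_samples(seq, rng)
        fx = detect_fixations_idt(t, x, y, valid)
        n_fix.append(len(fx))
        fds.append(fixation_distribution(fx))
    print(
        f"{label:<26s} background SD {scale:.2f}  "
        f"~{np.mean(n_fix):.0f} fixations/trial  FD index {np.nanmean(fds):.4f}"
    )

print(
    "\nThe smaller background spread yields the smaller fixation-distribution "
    "index — the same direction the cognitive-load manipulation produces."
)
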