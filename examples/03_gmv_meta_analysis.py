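"""Coordinate-based gray-matter meta-analysis with TFCE-FWE inference.

Reconstructs study effect maps (Hedges g) from peak tables sampled off a
known atrophy blob, pools them with a random-effects model, and controls
family-wise error by sign-flip permutation of whole studies.
"""

import numpy as np

import pleiomap as pm
from pleiomap.gmv_meta import GridSpec, cluster_table, permutation_fwe, reconstruct_effect_map

truth, affine = pm.make_truth_map()  # one negative blob at (48, 48, 48) mm
peaks = pm.simulate_study_peaks(truth, affine, n_studies=20, jitter_mm=4.0, seed=7)
print(f"{peaks['study_id'].nunique()} studies, {len(peaks)} reported peaks")

grid = GridSpec(truth.shape, affine)
maps = [
    reconstruct_effect_map(peaks[peaks["study_id"] == s], grid)
    for s in peaks["study_id"].unique()
]
res = permutation_fwe(maps, n_perm=200, seed=1)
peak_idx = np.unravel_index(np.argmax(np.abs(res.zmap)), res.zmap.shape)
peak_mm = affine[:3, :3] @ np.array(peak_idx) + affine[:3, 3]
print(f"pooled-z peak at {peak_mm} mm (true blob center: 48, 48, 48)")
print(f"minimum TFCE-FWE p: {res.fwe_p.min():.4f} "
      f"(floor 1/(n_perm+1) = {1 / 201:.4f})")

table = cluster_table(res, maps, grid)
print("\ncluster table (peak mm, z, size, heterogeneity, Egger):")
print(table.round(3).to_string(index=False))
print(
    "Q and I² quantify between-study spread at the cluster peak; the Egger "
    "intercept flags funnel asymmetry — here a real feature of the "
    "generator, which draws peak t-values independently of sample size, so "
    "smaller studies carry larger standardized effects."
)
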