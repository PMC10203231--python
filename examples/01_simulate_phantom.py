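"""Build an atlas phantom with known regional CVR and coupled task amplitudes.

The phantom is a 68-parcel labelled grid; each parcel carries a lognormal
cerebrovascular reactivity (CVR, %BOLD/mmHg) and each subject a multiplicative
vascular scale. Task response amplitudes follow the linear coupling
task_amp = 0.2 + 0.5 * (CVR * dPetCO2) + noise, which the downstream ROI
regressions try to recover.
"""

import numpy as np

from cvrkit import draw_ground_truth, generate_phantom

atlas = generate_phantom(n_parcels=68, grid_shape=(24, 24, 18), seed=7)
truth = draw_ground_truth(atlas, n_subjects=10, seed=7)

sizes = [int((atlas.label_volume == lab).sum()) for lab in atlas.label_table]
print(f"atlas: {atlas.n_parcels} parcels on {atlas.grid_shape}, "
      f"parcel sizes {min(sizes)}-{max(sizes)} voxels")
print(f"regional CVR: median {np.median(truth.cvr_true):.3f} %BOLD/mmHg "
      f"(range {truth.cvr_true.min():.3f}-{truth.cvr_true.max():.3f})")
print(f"breath-hold plateau PSC implied by CVR: median "
      f"{np.median(truth.bh_psc_true):.2f} %BOLD")
print(f"task amplitudes: median {np.median(truth.task_amp_true):.2f} %BOLD, "
      f"generated with slope {truth.coupling_slope} and intercept {truth.coupling_intercept}")
print("A slope of 0.5 %/% means a region with 1% more breath-hold response "
      "shows 0.5% more task response.")
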