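"""Group-level vascular correction with per-subject covariate images.

Subjects share an activation pattern scaled by an individual vascular gain.
A plain one-sample t-test treats the gain spread as noise; entering each
subject's reactivity image as a voxel-wise covariate absorbs it and raises
the group t — the sensitivity benefit of hypercapnic normalization.
"""

import numpy as np

from cvrkit import compare_sensitivity, group_ttest, voxelwise_covariate_correction

rng = np.random.default_rng(8)
shape = (10, 10, 8)
n_subjects = 15
xx, yy, zz = np.meshgrid(*[np.linspace(-1, 1, g) for g in shape], indexing="ij")
pattern = np.exp(-(xx**2 + yy**2 + zz**2) / 0.4)

gains = 1 + rng.normal(0, 0.35, size=n_subjects)  # inter-subject vascular spread
contrasts = gains[:, None, None, None] * pattern + rng.normal(0, 0.15, size=(n_subjects,) + shape)
covariates = gains[:, None, None, None] * (0.5 + pattern)

uncorrected = group_ttest(contrasts)
corrected = voxelwise_covariate_correction(contrasts, covariates)
report = compare_sensitivity({"uncorrected": uncorrected, "voxel_covariate": corrected},
                             voxel_p=0.001)

print(f"peak t uncorrected:  {report.peak_t['uncorrected']:.2f} (dof {uncorrected.dof})")
print(f"peak t corrected:    {report.peak_t['voxel_covariate']:.2f} (dof {corrected.dof})")
print(f"suprathreshold voxels at p<0.001: {report.n_suprathreshold}")
print(f"gain from correction: {report.delta_peak_t['voxel_covariate']:+.2f} peak t, "
      f"{report.delta_voxels['voxel_covariate']:+d} voxels")
print("Correction helps exactly when the covariate carries the inter-subject "
      "amplitude variance; with an irrelevant covariate the maps coincide.")
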