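"""Simulate a landmark cohort and run the shape-preparation stage.

Builds a symmetric face-like template, simulates 80 individuals with smooth
latent shape variation and covariate effects, symmetrizes each configuration,
aligns everything with GPA, flags outliers and removes covariate effects.
"""

import numpy as np

from facendo import shapeprep as prep
from facendo import synthdata as syn

template = syn.make_template(p=100, seed=1)
spec = syn.CohortSpec(n_individuals=80, seed=2)
configs, covariates, _ = syn.simulate_cohort(template, spec)

sym = np.stack([prep.make_symmetric(c, template.pair_map) for c in configs])
aligned = prep.gpa(sym, remove_scale=True)
report = prep.qc_scores(aligned, z_threshold=2.0)

covs = covariates.copy()
covs["size"] = aligned.centroid_sizes  # facial size joins the covariate block
adjusted = prep.adjust_covariates(aligned.shapes, covs.to_numpy(float))

print(f"template: {template.p} landmarks, mirror pairs verified")
print(f"aligned sample: n={aligned.n}, consensus centroid norm "
      f"{np.linalg.norm(aligned.consensus.mean(axis=0)):.2e}")
print(f"QC: {int(report.flags.sum())} of {aligned.n} faces flagged at |z| > 2 "
      "(Mahalanobis outliers that would be manually checked)")
# symmetric faces pin midline x-coordinates near zero variance, so test the
# covariate-residual cross-products on the variable coordinates only
C = covs.to_numpy(float)
Cc = (C - C.mean(axis=0)) / C.std(axis=0)
resid = adjusted - adjusted.mean(axis=0)
varying = resid.std(axis=0) > 1e-6
corr = Cc.T @ resid[:, varying] / (len(C) * resid[:, varying].std(axis=0))
print(f"max |corr(residual shape, covariate)| = {np.abs(corr).max():.2e} "
      "(~0: covariate effects fully removed)")
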