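"""End-to-end run: simulate -> prep -> segment -> traits -> GWAS -> PRS.

Runs the whole pipeline at a reduced size and prints the manifest counts
surviving each stage.  Equivalent to `facendo run --out <dir>` with a config
file; artifacts (trait tables, loci, scores, VCF, manifest) land in outdir.
"""

import json

from facendo import RunConfig, run_all

config = RunConfig(
    seed=3, p=150, n_us=60, n_uk=60, n_parents=40, n_controls=80,
    n_discovery=150, n_snps=120, n_perm=999, pa_reps=50, prs_grid_step=1e-2,
)
manifest = run_all(config, "scratch/example_run")
print(json.dumps(manifest["stages"], indent=2, default=float))
print("\n63 segments -> traits with permutation p-values -> per-cohort GWAS "
      "meta-analysis and loci -> PRS threshold scan; every artifact is a TSV "
      "plus manifest.json in scratch/example_run/")
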