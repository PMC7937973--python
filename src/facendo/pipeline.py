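"""End-to-end orchestration: simulate -> prep -> segment -> traits -> score
-> GWAS -> PRS, with a manifest recording seeds, parameters and the counts
surviving each stage.

The run emulates the study design: an "unselected" discovery sample (two
cohorts, adjusted separately, combined for segmentation), a "parents vs
unselected" contrast sample defining the endophenotypic traits, genotypes in
which a causal SNP set shifts shape along a trait direction, and an external
discovery GWAS providing polygenic-score weights for the same causal set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import endophenotype as endo
from . import gwas as gwasmod
from . import prs as prsmod
from . import segmentation as seg
from . import shapeprep as prep
from . import synthdata as synth
from .io import write_hierarchy_tsv, write_landmarks_tsv, write_vcf

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """All stage parameters with defaults at the study's stated values where
    one exists (levels=5, n_perm=10000, alpha=0.05, +-500 kb GWAS clumping,
    genome-wide 5e-8, PRS r2=0.1 / +-250 kb, grid 5e-8..1 step 5e-5); sample
    sizes and the genetic architecture are desk-scale choices."""

    seed: int = 1
    # template / cohorts
    p: int = 250
    n_us: int = 120
    n_uk: int = 120
    n_parents: int = 80
    n_controls: int = 160
    n_discovery: int = 400
    latent_rank: int = 10
    latent_sd: float = 0.5
    noise_sd: float = 0.01
    effect_size: float = 1.0
    shape_genetic_scale: float = 0.5
    # segmentation
    levels: int = 5
    pa_reps: int = 100
    pa_percentile: float = 95.0
    # endophenotypes
    n_perm: int = 10_000
    alpha: float = 0.05
    # genotypes
    n_snps: int = 400
    maf_range: tuple = (0.1, 0.5)
    ld_block_rho: float = 0.4
    block_size: int = 8
    n_causal: int = 8
    h2: float = 0.3
    # gwas
    gwas_window_bp: int = 500_000
    genomewide_alpha: float = 5e-8
    # prs
    prs_r2: float = 0.1
    prs_window_bp: int = 250_000
    prs_grid_step: float = 5e-5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "maf_range" in data:
            data["maf_range"] = tuple(data["maf_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["maf_range"] = list(d["maf_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _prep_cohort(configs, template, covariates):
    """Symmetrize, align and covariate-adjust one cohort's configurations."""
    sym = np.stack([prep.make_symmetric(c, template.pair_map) for c in configs])
    aligned = prep.gpa(sym, remove_scale=True)
    covs = covariates.copy()
    covs["size"] = aligned.centroid_sizes
    adjusted = prep.adjust_covariates(aligned.shapes, covs.to_numpy(dtype=float))
    return aligned, adjusted, covs


def run_all(config: RunConfig, outdir, write_artifacts: bool = True) -> dict:
    """Execute every stage in order and return the manifest (also written to
    ``outdir/manifest.json`` along with the stage artifacts)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(12)]
    manifest: dict = {"config": asdict(config), "seeds": seeds, "stages": {}}
    manifest["config"]["maf_range"] = list(config.maf_range)

    # --- stage 1: template and cohorts -----------------------------------
    template = synth.make_template(p=config.p, seed=seeds[0])
    trait_direction = synth.localized_direction(template, seed=seeds[1])

    n_euro = config.n_us + config.n_uk
    euro_spec = synth.CohortSpec(
        n_individuals=n_euro,
        n_group1=0,
        latent_rank=config.latent_rank,
        latent_sd=config.latent_sd,
        noise_sd=config.noise_sd,
        seed=seeds[2],
    )
    euro_configs, euro_covs, _ = synth.simulate_cohort(template, euro_spec)

    parent_spec = synth.CohortSpec(
        n_individuals=config.n_parents + config.n_controls,
        n_group1=config.n_parents,
        latent_rank=config.latent_rank,
        latent_sd=config.latent_sd,
        noise_sd=config.noise_sd,
        effect_direction=trait_direction,
        effect_size=config.effect_size,
        seed=seeds[3],
    )
    parent_configs, parent_covs, parent_group = synth.simulate_cohort(template, parent_spec)

    # --- stage 2: genotypes; causal SNPs shift shape along the trait ------
    n_total = n_euro + config.n_discovery
    rng_c = np.random.default_rng(seeds[4])
    causal = np.sort(rng_c.choice(config.n_snps, size=config.n_causal, replace=False))
    gspec = synth.GenoSpec(
        n_snps=config.n_snps,
        maf_range=config.maf_range,
        ld_block_rho=config.ld_block_rho,
        block_size=config.block_size,
        causal_snps=causal,
        h2_target=config.h2,
        seed=seeds[5],
    )
    all_geno = synth.simulate_genotypes(n_total, gspec)
    idx_us = np.arange(config.n_us)
    idx_uk = np.arange(config.n_us, n_euro)
    idx_disc = np.arange(n_euro, n_total)
    geno = {
        "US": all_geno.subset_individuals(idx_us),
        "UK": all_geno.subset_individuals(idx_uk),
    }
    disc_geno = all_geno.subset_individuals(idx_disc)

    genetic = synth.genetic_trait_scores(all_geno, gspec)[: n_euro]
    euro_flat = euro_configs.reshape(n_euro, -1)
    euro_flat += np.outer(genetic * config.shape_genetic_scale, trait_direction)
    euro_configs = euro_flat.reshape(n_euro, config.p, 3)

    # --- stage 3: shape prep (per-cohort adjustment, then combine) --------
    us_aligned, us_adj, us_covs = _prep_cohort(
        euro_configs[idx_us], template, euro_covs.iloc[idx_us].reset_index(drop=True)
    )
    uk_aligned, uk_adj, uk_covs = _prep_cohort(
        euro_configs[idx_uk], template, euro_covs.iloc[idx_uk].reset_index(drop=True)
    )
    euro_adj = np.vstack([us_adj, uk_adj])
    par_aligned, par_adj, _ = _prep_cohort(parent_configs, template, parent_covs)
    qc = prep.qc_scores(
        prep.AlignedSample(
            shapes=euro_adj,
            consensus=us_aligned.consensus,
            centroid_sizes=np.concatenate(
                [us_aligned.centroid_sizes, uk_aligned.centroid_sizes]
            ),
        )
    )
    manifest["stages"]["prep"] = {
        "n_euro": int(n_euro),
        "n_parent_sample": int(len(parent_group)),
        "n_qc_flagged": int(qc.flags.sum()),
    }

    # --- stage 4: segmentation on the combined unselected sample ----------
    sim = seg.build_similarity(euro_adj, p=config.p)
    hierarchy = seg.spectral_hierarchy(sim, levels=config.levels, seed=seeds[6])
    models = {
        s.segment_id: seg.fit_segment_model(
            euro_adj,
            hierarchy,
            s.segment_id,
            pa_reps=config.pa_reps,
            pa_percentile=config.pa_percentile,
            seed=seeds[7] + s.segment_id,
            min_k=1,  # traits need at least the leading PC in every segment
        )
        for s in hierarchy.segments
    }
    manifest["stages"]["segmentation"] = {
        "n_segments": len(hierarchy),
        "levels": config.levels,
        "retained_dims": {int(k): int(m.k) for k, m in models.items()},
    }

    # --- stage 5: endophenotype traits from the parent contrast -----------
    par_cfg = par_adj.reshape(len(parent_group), config.p, 3)
    traits = []
    parent_pc = {}
    for s in hierarchy.segments:
        scores = seg.project_many(models[s.segment_id], par_cfg)
        parent_pc[s.segment_id] = scores
        traits.append(
            endo.fit_trait(
                s.segment_id,
                scores,
                parent_group,
                n_perm=config.n_perm,
                seed=seeds[8] + s.segment_id,
            )
        )
    euro_cfg = euro_adj.reshape(n_euro, config.p, 3)
    euro_pc = {s.segment_id: seg.project_many(models[s.segment_id], euro_cfg)
               for s in hierarchy.segments}
    all_scores = endo.score_table(traits, euro_pc)
    m_eff_all, bonf_all = endo.effective_tests(all_scores, alpha=config.alpha)
    selected, n_bonf = endo.select_traits(traits, alpha=config.alpha, bonferroni=bonf_all)
    if not selected:
        raise RuntimeError("endophenotype stage: no trait passed nominal selection")
    sel_scores = all_scores[[f"seg{t.segment_id}" for t in selected]]
    m_eff_sel, prs_alpha = endo.effective_tests(sel_scores, alpha=config.alpha)
    manifest["stages"]["endophenotype"] = {
        "n_traits": len(traits),
        "n_selected": len(selected),
        "n_bonferroni": int(n_bonf),
        "m_eff_all": int(m_eff_all),
        "bonferroni_threshold": bonf_all,
        "m_eff_selected": int(m_eff_sel),
        "prs_threshold": prs_alpha,
    }

    # --- stage 6: GWAS per cohort, IVW meta, clumping ----------------------
    assoc = pd.concat(
        [
            gwasmod.association_scan(sel_scores.iloc[idx_us].reset_index(drop=True), geno["US"], "US"),
            gwasmod.association_scan(sel_scores.iloc[idx_uk].reset_index(drop=True), geno["UK"], "UK"),
        ],
        ignore_index=True,
    )
    meta = gwasmod.meta_analyze(assoc)
    gw, sw = gwasmod.thresholds(config.genomewide_alpha, n_traits=len(selected))
    loci = gwasmod.clump(meta, window_bp=config.gwas_window_bp, p_threshold=gw)
    n_assoc_gw = int((meta.groupby(["trait", "snp"])["p"].min() < gw).sum())
    manifest["stages"]["gwas"] = {
        "n_snps_tested": int(meta["snp"].nunique()),
        "genomewide": gw,
        "studywide": sw,
        "n_loci": len(loci),
        "n_significant_associations": n_assoc_gw,
        "n_loci_studywide": sum(l.best_p < sw for l in loci),
    }

    # --- stage 7: PRS ------------------------------------------------------
    liability = synth.simulate_trait_scores(disc_geno, gspec, seed=seeds[9])
    sumstats = synth.make_discovery_sumstats(disc_geno, liability)
    grid = prsmod.default_threshold_grid(
        config.genomewide_alpha, 1.0, config.prs_grid_step
    )
    prs_results = {}
    for label, idx in (("US", idx_us), ("UK", idx_uk)):
        clumped = prsmod.ld_clump(
            sumstats, geno[label], r2_thresh=config.prs_r2, window_bp=config.prs_window_bp
        )
        aligned_ss = prsmod.align_effects(clumped, geno[label])
        mat = prsmod.prs_matrix(geno[label], aligned_ss, grid)
        scan = prsmod.prs_scan(mat, sel_scores.iloc[idx].reset_index(drop=True))
        prs_results[label] = {
            "n_clumped": len(clumped),
            "min_p": scan.attrs.get("min_p", {}),
        }
        if write_artifacts:
            scan.to_csv(out / f"prs_scan_{label}.tsv", sep="\t", index=False)
    manifest["stages"]["prs"] = {
        "n_thresholds": int(grid.size),
        "threshold": prs_alpha,
        **{
            label: {
                "n_clumped": res["n_clumped"],
                "n_traits_significant": int(
                    sum(p < prs_alpha for p in res["min_p"].values())
                ),
            }
            for label, res in prs_results.items()
        },
    }

    # --- artifacts ---------------------------------------------------------
    if write_artifacts:
        config.to_yaml(out / "config.yaml")
        write_landmarks_tsv(out / "parent_landmarks.tsv", parent_configs)
        write_hierarchy_tsv(out / "hierarchy.tsv", hierarchy)
        write_vcf(out / "genotypes_us.vcf", geno["US"])
        pd.DataFrame(
            {
                "segment_id": [t.segment_id for t in traits],
                "r2": [t.r2 for t in traits],
                "p_perm": [t.p_perm for t in traits],
                "selected": [t in selected for t in traits],
            }
        ).to_csv(out / "traits.tsv", sep="\t", index=False)
        all_scores.to_csv(out / "euro_scores.tsv", sep="\t", index=False)
        meta.to_csv(out / "gwas_meta.tsv", sep="\t", index=False)
        sumstats.to_csv(out / "discovery_sumstats.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "lead_snp": l.lead_snp,
                    "chrom": l.chrom,
                    "pos": l.pos,
                    "best_trait": l.best_trait,
                    "best_p": l.best_p,
                    "n_members": len(l.members),
                }
                for l in loci
            ]
        ).to_csv(out / "loci.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
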