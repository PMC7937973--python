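"""Quantitative-trait SNP association, fixed-effect meta-analysis and clumping.

Genotypes are coded additively by the count of the MAJOR allele (0/1/2;
hemizygous males on the X chromosome are coded 0/2 so scale matches females).
Per cohort, each endophenotype score is regressed on each SNP dosage with
simple OLS (t-statistic on n-2 df); cohorts are combined by inverse-variance
weighting, and lead SNPs below genome-wide significance are clumped into loci
within a +-500 kb window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeTable",
    "Locus",
    "code_genotype",
    "snp_regression",
    "association_scan",
    "ivw_meta",
    "meta_analyze",
    "clump",
    "thresholds",
    "overlap_percentage",
]

GENOMEWIDE_ALPHA = 5e-8


@dataclass
class GenotypeTable:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    ``dosages[i, j]`` counts copies of the major allele of SNP j in individual
    i.  ``snp_meta`` is a DataFrame with columns ``snp, chrom, pos,
    allele_major, allele_minor, maf`` (pos 1-based).  ``sex`` is 1 for male,
    0 for female (used only for X-chromosome coding on input).
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sex: np.ndarray | None = None
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[1] != len(self.snp_meta):
            raise ValueError("dosage columns and snp_meta rows disagree")
        if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, mask_or_idx) -> "GenotypeTable":
        meta = self.snp_meta.iloc[mask_or_idx].reset_index(drop=True)
        return GenotypeTable(self.dosages[:, mask_or_idx], meta, self.sex, self.ids)

    def subset_individuals(self, idx) -> "GenotypeTable":
        sex = None if self.sex is None else np.asarray(self.sex)[idx]
        ids = [self.ids[i] for i in np.atleast_1d(idx)] if self.ids else []
        return GenotypeTable(self.dosages[idx], self.snp_meta.copy(), sex, ids)


@dataclass
class Locus:
    lead_snp: str
    chrom: str
    pos: int
    window: tuple[int, int]
    members: list
    best_trait: str
    best_p: float


def code_genotype(alleles, major: str, chrom: str, sex: int) -> int:
    """Additive major-allele dosage for one genotype call.

    ``alleles`` is the observed call: two alleles for diploid sites, one for a
    hemizygous male X call.  Autosomes and female X count major-allele copies
    in {0, 1, 2}; a hemizygous male X call maps to 2 (major) or 0 (minor) so
    the coding scale matches the female 0/1/2.
    """
    alleles = list(alleles)
    is_x = str(chrom).upper() in {"X", "23", "CHRX"}
    if is_x and sex == 1:
        if len(alleles) == 2:
            if alleles[0] != alleles[1]:
                raise ValueError("heterozygous call for a hemizygous male X site")
            alleles = alleles[:1]
        return 2 if alleles[0] == major else 0
    if len(alleles) != 2:
        raise ValueError("diploid site requires two alleles")
    return sum(a == major for a in alleles)


def snp_regression(score: np.ndarray, dosage: np.ndarray):
    """Simple linear regression of an endophenotype score on one SNP dosage.

    OLS with intercept: the score is the dependent variable, the genotype the
    independent one.  Returns (beta, se, t, p, n) with a two-sided t-test on
    n-2 degrees of freedom.  Monomorphic SNPs are rejected.
    """
    y = np.asarray(score, dtype=float)
    g = np.asarray(dosage, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    n = y.size
    if n < 3:
        raise ValueError("need n >= 3 complete observations")
    gc = g - g.mean()
    sxx = gc @ gc
    if sxx < 1e-12:
        raise ValueError("monomorphic SNP (constant dosage)")
    yc = y - y.mean()
    beta = (gc @ yc) / sxx
    resid = yc - beta * gc
    sigma2 = (resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        # perfect fit: report the numerically smallest representable p
        return float(beta), np.finfo(float).tiny, np.inf, np.finfo(float).tiny, n
    t = float(beta / se)
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    p = max(p, np.finfo(float).tiny)
    return float(beta), se, t, p, n


def association_scan(
    scores: pd.DataFrame, genotypes: GenotypeTable, cohort: str = "cohort"
) -> pd.DataFrame:
    """Vectorised per-trait, per-SNP OLS over a whole cohort.

    ``scores`` is individuals x traits (row order matching the genotype
    table).  Returns a long DataFrame with one row per (trait, SNP):
    columns trait, snp, chrom, pos, beta, se, t, p, n, cohort.  Monomorphic
    SNPs are skipped.
    """
    G = genotypes.dosages
    n = G.shape[0]
    if len(scores) != n:
        raise ValueError("scores and genotypes disagree on n individuals")
    Gc = G - G.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    poly = sxx > 1e-12
    meta = genotypes.snp_meta
    out = []
    for trait in scores.columns:
        y = scores[trait].to_numpy(dtype=float)
        yc = y - y.mean()
        syy = yc @ yc
        sxy = yc @ Gc
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(poly, sxy / np.where(poly, sxx, 1.0), np.nan)
            rss = syy - beta**2 * sxx
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / (n - 2) / np.where(poly, sxx, 1.0))
            t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.maximum(p, np.finfo(float).tiny)
        df = pd.DataFrame(
            {
                "trait": trait,
                "snp": meta["snp"].to_numpy(),
                "chrom": meta["chrom"].to_numpy(),
                "pos": meta["pos"].to_numpy(),
                "beta": beta,
                "se": se,
                "t": t,
                "p": p,
                "n": n,
                "cohort": cohort,
            }
        )
        out.append(df[poly])
    return pd.concat(out, ignore_index=True)


def ivw_meta(betas, ses):
    """Fixed-effect inverse-variance-weighted meta-analysis.

    w_i = se_i^-2; beta = sum(w b)/sum(w); se = sum(w)^-1/2; z = beta/se with
    a two-sided normal p.  A single study is returned unchanged (z replacing t).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("empty meta-analysis input")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = s**-2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return beta, se, float(z), p


def meta_analyze(assoc: pd.DataFrame) -> pd.DataFrame:
    """IVW meta-analysis of a long per-cohort association table.

    Rows are grouped by (trait, snp); only SNPs present in every cohort are
    meta-analysed (mirroring the intersection of cohort SNP panels).
    """
    n_cohorts = assoc["cohort"].nunique()
    rows = []
    for (trait, snp), grp in assoc.groupby(["trait", "snp"], sort=False):
        if len(grp) < n_cohorts:
            continue
        beta, se, z, p = ivw_meta(grp["beta"].to_numpy(), grp["se"].to_numpy())
        rows.append(
            {
                "trait": trait,
                "snp": snp,
                "chrom": grp["chrom"].iloc[0],
                "pos": int(grp["pos"].iloc[0]),
                "beta": beta,
                "se": se,
                "z": z,
                "p": p,
                "n": int(grp["n"].sum()),
            }
        )
    return pd.DataFrame(rows)


def clump(
    assoc: pd.DataFrame,
    window_bp: int = 500_000,
    p_threshold: float = GENOMEWIDE_ALPHA,
) -> list[Locus]:
    """Greedy distance-based clumping of significant SNPs into loci.

    The per-SNP best p-value across traits is computed first.  Repeatedly the
    unassigned SNP with the smallest p below ``p_threshold`` becomes a lead
    (ties broken by chromosome then position); every unassigned SNP on the
    same chromosome within +-``window_bp`` (inclusive) joins its locus.  Loci
    are disjoint by construction.
    """
    required = {"snp", "chrom", "pos", "p"}
    if not required.issubset(assoc.columns):
        raise ValueError(f"association table must have columns {sorted(required)}")
    if "trait" in assoc.columns:
        idx = assoc.groupby("snp")["p"].idxmin()
        best = assoc.loc[idx, ["snp", "chrom", "pos", "p", "trait"]].copy()
    else:
        best = assoc[["snp", "chrom", "pos", "p"]].copy()
        best["trait"] = ""
    best = best.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    assigned = np.zeros(len(best), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(best)):
        if assigned[i] or best.at[i, "p"] >= p_threshold:
            continue
        lead = best.iloc[i]
        lo, hi = int(lead["pos"]) - window_bp, int(lead["pos"]) + window_bp
        in_win = (
            (~assigned)
            & (best["chrom"] == lead["chrom"]).to_numpy()
            & (best["pos"].to_numpy() >= lo)
            & (best["pos"].to_numpy() <= hi)
        )
        members = best.loc[in_win, "snp"].tolist()
        assigned |= in_win
        loci.append(
            Locus(
                lead_snp=str(lead["snp"]),
                chrom=str(lead["chrom"]),
                pos=int(lead["pos"]),
                window=(lo, hi),
                members=members,
                best_trait=str(lead["trait"]),
                best_p=float(lead["p"]),
            )
        )
    return loci


def thresholds(alpha_gw: float = GENOMEWIDE_ALPHA, n_traits: int = 1):
    """Genome-wide and study-wide (Bonferroni over traits) thresholds."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return alpha_gw, alpha_gw / n_traits


def overlap_percentage(n_overlapping: int, n_total: int) -> int:
    """Share of loci overlapping a reference set, as a rounded percentage."""
    if not 0 <= n_overlapping <= n_total:
        raise ValueError("need 0 <= n_overlapping <= n_total")
    return int(round(100.0 * n_overlapping / n_total))
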