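"""Polygenic risk scoring against endophenotype scores.

Discovery summary statistics (SNP/CHR/BP/A1/A2/BETA/SE/P; A1 = effect allele)
are LD-clumped against the target cohort's own genotypes (greedy by ascending
p, removing SNPs within +-250 kb with r^2 > 0.1 to a retained index SNP).
Scores are weighted allele sums over the SNPs passing each p-value inclusion
threshold; SNP sets are nested across the increasing threshold grid.  Each
(trait, threshold) pair is then tested by OLS with the PRS as response and
the endophenotype score as predictor, and the minimum p across thresholds is
reported per trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import GenotypeTable

__all__ = [
    "SUMSTAT_COLUMNS",
    "ld_r2",
    "ld_clump",
    "align_effects",
    "prs_score",
    "prs_matrix",
    "default_threshold_grid",
    "prs_scan",
]

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]


def ld_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation between two SNPs' dosage vectors."""
    a = np.asarray(dosage_i, dtype=float)
    b = np.asarray(dosage_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must cover the same individuals")
    if a.std() < 1e-12 or b.std() < 1e-12:
        raise ValueError("constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _check_sumstats(sumstats: pd.DataFrame) -> pd.DataFrame:
    missing = set(SUMSTAT_COLUMNS) - set(sumstats.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns {sorted(missing)}")
    return sumstats


def ld_clump(
    sumstats: pd.DataFrame,
    ref: GenotypeTable,
    r2_thresh: float = 0.1,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Greedy LD clumping of summary statistics against a genotype reference.

    Summary SNPs are intersected with the reference panel (mismatched SNPs
    dropped).  Working through SNPs by ascending p (ties by chromosome,
    position), each index SNP is retained and every not-yet-retained SNP on
    the same chromosome within +-``window_bp`` with r^2 > ``r2_thresh`` to it
    is removed.  Returns the retained rows of ``sumstats``.
    """
    ss = _check_sumstats(sumstats)
    panel = ref.snp_meta.set_index("snp")
    keep = ss["SNP"].isin(panel.index)
    ss = ss[keep].reset_index(drop=True)
    if ss.empty:
        raise ValueError("no summary-statistic SNP found in the reference panel")
    col = {snp: j for j, snp in enumerate(ref.snp_meta["snp"])}
    order = ss.sort_values(["P", "CHR", "BP"], kind="mergesort").index.to_numpy()
    removed = np.zeros(len(ss), dtype=bool)
    retained = np.zeros(len(ss), dtype=bool)
    chroms = ss["CHR"].astype(str).to_numpy()
    pos = ss["BP"].to_numpy()
    G = ref.dosages
    for i in order:
        if removed[i]:
            continue
        retained[i] = True
        near = (
            ~removed
            & ~retained
            & (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        if not near.any():
            continue
        gi = G[:, col[ss.at[i, "SNP"]]]
        for j in np.flatnonzero(near):
            gj = G[:, col[ss.at[j, "SNP"]]]
            if gj.std() < 1e-12 or gi.std() < 1e-12:
                continue
            if ld_r2(gi, gj) > r2_thresh:
                removed[j] = True
    return ss[retained].reset_index(drop=True)


def align_effects(sumstats: pd.DataFrame, ref: GenotypeTable) -> pd.DataFrame:
    """Align summary-statistic effects to the reference dosage coding.

    The reference dosage counts the major allele; where a summary SNP's effect
    allele (A1) is the *other* allele the beta sign is flipped, so the aligned
    beta always applies to the counted allele.  SNPs whose allele pair does
    not match the reference are dropped and counted in the returned frame's
    ``attrs["n_dropped_mismatch"]``.
    """
    ss = _check_sumstats(sumstats).copy()
    meta = ref.snp_meta.set_index("snp")
    keep, beta_aligned = [], []
    dropped = 0
    for _, row in ss.iterrows():
        snp = row["SNP"]
        if snp not in meta.index:
            dropped += 1
            keep.append(False)
            beta_aligned.append(np.nan)
            continue
        counted = meta.at[snp, "allele_major"]
        other = meta.at[snp, "allele_minor"]
        if row["A1"] == counted and row["A2"] == other:
            keep.append(True)
            beta_aligned.append(row["BETA"])
        elif row["A1"] == other and row["A2"] == counted:
            keep.append(True)
            beta_aligned.append(-row["BETA"])
        else:
            dropped += 1
            keep.append(False)
            beta_aligned.append(np.nan)
    ss["BETA_ALIGNED"] = beta_aligned
    out = ss[np.asarray(keep)].reset_index(drop=True)
    out.attrs["n_dropped_mismatch"] = dropped
    return out


def prs_score(
    genotypes: GenotypeTable, sumstats: pd.DataFrame, threshold: float
) -> np.ndarray:
    """Per-individual polygenic score at one inclusion threshold.

    score_i = sum over SNPs with P <= threshold of aligned beta x dosage_ij;
    missing dosages are imputed at twice the counted-allele frequency.
    Summary statistics are aligned first if ``BETA_ALIGNED`` is absent.
    """
    ss = sumstats if "BETA_ALIGNED" in sumstats.columns else align_effects(sumstats, genotypes)
    inc = ss[ss["P"] <= threshold]
    scores = np.zeros(genotypes.n)
    if inc.empty:
        return scores
    col = {snp: j for j, snp in enumerate(genotypes.snp_meta["snp"])}
    meta = genotypes.snp_meta
    for _, row in inc.iterrows():
        j = col[row["SNP"]]
        d = genotypes.dosages[:, j].copy()
        if np.isnan(d).any():
            # counted allele is the major allele: frequency 1 - maf
            freq = 1.0 - float(meta.at[j, "maf"])
            d[np.isnan(d)] = 2.0 * freq
        scores += row["BETA_ALIGNED"] * d
    return scores


def default_threshold_grid(
    p_min: float = 5e-8, p_max: float = 1.0, step: float = 5e-5
) -> np.ndarray:
    """Increasing p-value inclusion thresholds from p_min to p_max by step."""
    grid = np.concatenate([[p_min], np.arange(step, p_max + step / 2, step)])
    grid = np.unique(np.clip(grid, p_min, p_max))
    return grid


def prs_matrix(
    genotypes: GenotypeTable, sumstats: pd.DataFrame, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """PRS for every individual at every inclusion threshold (nested SNP sets).

    Scores are accumulated over SNPs sorted by p so each threshold reuses the
    previous one's sum; thresholds with identical SNP sets share columns'
    values but are all reported.
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    ss = sumstats if "BETA_ALIGNED" in sumstats.columns else align_effects(sumstats, genotypes)
    ss = ss.sort_values("P", kind="mergesort").reset_index(drop=True)
    col = {snp: j for j, snp in enumerate(genotypes.snp_meta["snp"])}
    meta = genotypes.snp_meta
    n = genotypes.n
    running = np.zeros(n)
    out = np.empty((n, grid.size))
    snp_i = 0
    pvals = ss["P"].to_numpy()
    for t_i, thr in enumerate(grid):
        while snp_i < len(ss) and pvals[snp_i] <= thr:
            row = ss.iloc[snp_i]
            j = col[row["SNP"]]
            d = genotypes.dosages[:, j].copy()
            if np.isnan(d).any():
                freq = 1.0 - float(meta.at[j, "maf"])
                d[np.isnan(d)] = 2.0 * freq
            running = running + row["BETA_ALIGNED"] * d
            snp_i += 1
        out[:, t_i] = running
    return pd.DataFrame(out, columns=grid, index=genotypes.ids or None)


def prs_scan(prs: pd.DataFrame, endo_scores: pd.DataFrame) -> pd.DataFrame:
    """Association scan of PRS against endophenotype scores.

    For every (trait, threshold): OLS with the PRS as the dependent variable
    and the endophenotype score as the independent variable.  Thresholds whose
    PRS column is constant (no SNP passes) are skipped.  Returns a long table
    (trait, threshold, beta, se, t, p) plus per-trait minimum p in
    ``attrs["min_p"]``.
    """
    if len(prs) != len(endo_scores):
        raise ValueError("PRS and endophenotype scores disagree on individuals")
    P = prs.to_numpy(dtype=float)
    keep = P.std(axis=0) > 1e-12
    thrs = np.asarray(prs.columns, dtype=float)[keep]
    P = P[:, keep]
    n = P.shape[0]
    Pc = P - P.mean(axis=0)
    spp = np.einsum("ij,ij->j", Pc, Pc)
    frames = []
    for trait in endo_scores.columns:
        x = endo_scores[trait].to_numpy(dtype=float)
        xc = x - x.mean()
        sxx = xc @ xc
        if sxx < 1e-12:
            continue
        beta = (xc @ Pc) / sxx
        rss = np.maximum(spp - beta**2 * sxx, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        with np.errstate(divide="ignore"):
            t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        p = np.maximum(2.0 * stats.t.sf(np.abs(t), df=n - 2), np.finfo(float).tiny)
        frames.append(
            pd.DataFrame(
                {"trait": trait, "threshold": thrs, "beta": beta, "se": se, "t": t, "p": p}
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not out.empty:
        out.attrs["min_p"] = out.groupby("trait")["p"].min().to_dict()
    return out
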