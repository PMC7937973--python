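"""Endophenotype trait definition, permutation testing and scoring.

A trait is the single direction of effect returned by a one-component PLSR of
segment PC scores (response) on the binary group label (predictor), oriented
toward the "parents" group mean.  With a univariate centred predictor this
direction is, in closed form, the normalised covariance vector between label
and PC scores — i.e. parallel to the group-mean difference.  Its effect size
R^2 (pooled over the PC responses) is tested by label permutation.  Individual
faces are scored by the cosine distance between their segment PC vector and
the trait direction: low distance means the endophenotypic trait is present.

The effective number of independent traits (for Bonferroni correction) is the
Li-Ji eigenvalue count of the trait-score correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EndophenotypeTrait",
    "plsr_contrast",
    "permutation_test",
    "fit_trait",
    "select_traits",
    "cosine_score",
    "score_table",
    "effective_tests",
]


@dataclass
class EndophenotypeTrait:
    segment_id: int
    direction: np.ndarray  # unit vector in the segment's PC space
    r2: float
    p_perm: float
    oriented_toward: str = "parents"


def _contrast_stats(pc_scores: np.ndarray, group: np.ndarray):
    Y = np.asarray(pc_scores, dtype=float)
    g = np.asarray(group, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if g.shape != (Y.shape[0],):
        raise ValueError("group vector length mismatch")
    if len(np.unique(g)) != 2:
        raise ValueError("group must be binary with both groups non-empty")
    Yc = Y - Y.mean(axis=0)
    xc = g - g.mean()
    return Y, Yc, xc, g


def plsr_contrast(
    pc_scores: np.ndarray, group, parent_label=None
) -> tuple[np.ndarray, float]:
    """One-component PLSR of PC scores on a binary group label.

    Returns the unit direction of effect (oriented so that moving along it
    increases the predicted group-1 "parents" mean) and the pooled effect size
    R^2 = 1 - SS_res/SS_tot over all PC responses.  For a single centred
    binary predictor the PLS weight vector reduces to cov(group, scores), so
    the direction is exactly parallel to the group-mean difference.
    """
    Y, Yc, xc, g = _contrast_stats(pc_scores, group)
    w = Yc.T @ xc  # covariance vector; the 1-component PLS loading direction
    norm = np.linalg.norm(w)
    if norm < 1e-300:
        raise ValueError("zero between-group covariance; direction undefined")
    direction = w / norm
    sxx = xc @ xc
    ss_tot = float(np.sum(Yc**2))
    r2 = float(norm**2 / (sxx * ss_tot))
    # orientation: along the direction, the parent-group mean must exceed the
    # rest; the result is invariant to exchanging which group carries label 1
    if parent_label is None:
        parent_label = g.max()
    parents = g == parent_label
    diff = Y[parents].mean(axis=0) - Y[~parents].mean(axis=0)
    if diff @ direction < 0:
        direction = -direction
    return direction, r2


def permutation_test(
    pc_scores: np.ndarray,
    group,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the PLSR contrast effect size.

    The group labels are permuted ``n_perm`` times and R^2 recomputed;
    p = (1 + #{R^2_perm >= R^2_obs}) / (1 + n_perm), so the smallest
    attainable p is 1/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Y, Yc, xc, _ = _contrast_stats(pc_scores, group)
    sxx = xc @ xc
    ss_tot = float(np.sum(Yc**2))
    r2_obs = float(np.sum((Yc.T @ xc) ** 2) / (sxx * ss_tot))
    rng = np.random.default_rng(seed)
    n = xc.size
    # permuting labels preserves sxx and ss_tot; only the cross term changes
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perms = xc[order].T  # (n, n_perm)
    cross = Yc.T @ perms  # (k, n_perm)
    r2_perm = np.sum(cross**2, axis=0) / (sxx * ss_tot)
    return float((1 + np.sum(r2_perm >= r2_obs)) / (1 + n_perm))


def fit_trait(
    segment_id: int,
    pc_scores: np.ndarray,
    group,
    n_perm: int = 10_000,
    seed: int = 0,
) -> EndophenotypeTrait:
    """Direction, effect size and permutation p-value for one segment."""
    direction, r2 = plsr_contrast(pc_scores, group)
    p = permutation_test(pc_scores, group, n_perm=n_perm, seed=seed)
    return EndophenotypeTrait(segment_id=segment_id, direction=direction, r2=r2, p_perm=p)


def select_traits(
    traits, alpha: float = 0.05, bonferroni: float | None = None
) -> tuple[list, int]:
    """Nominally significant traits, preserving segment order.

    Returns the traits with permutation p < ``alpha`` and, when a Bonferroni
    threshold (alpha / m_eff from :func:`effective_tests`) is supplied, the
    count of traits that also pass it.
    """
    selected = [t for t in traits if t.p_perm < alpha]
    n_bonf = 0
    if bonferroni is not None:
        n_bonf = sum(t.p_perm < bonferroni for t in traits)
    return selected, n_bonf


def cosine_score(trait: EndophenotypeTrait, pc_vector: np.ndarray) -> float:
    """Cosine distance between an individual's PC vector and the trait direction.

    1 - cos(angle), in [0, 2]; invariant to positive rescaling of the
    individual's vector.  Low values mean the trait is present.
    """
    v = np.asarray(pc_vector, dtype=float)
    nv = np.linalg.norm(v)
    if nv < 1e-300:
        raise ValueError("zero PC vector")
    d = trait.direction
    return float(1.0 - (d @ v) / (np.linalg.norm(d) * nv))


def score_table(traits, pc_scores_by_segment: dict, ids=None) -> pd.DataFrame:
    """Cosine-distance scores for many individuals across selected traits.

    ``pc_scores_by_segment`` maps segment_id -> (n, k) PC score matrix (all
    individuals in the same row order).  Columns are labelled ``seg<id>``.
    """
    cols = {}
    for t in traits:
        S = np.asarray(pc_scores_by_segment[t.segment_id], dtype=float)
        norms = np.linalg.norm(S, axis=1)
        if np.any(norms < 1e-300):
            raise ValueError("zero PC vector for some individual")
        cols[f"seg{t.segment_id}"] = 1.0 - (S @ t.direction) / norms
    return pd.DataFrame(cols, index=ids)


def effective_tests(scores, alpha: float = 0.05) -> tuple[int, float]:
    """Effective number of independent traits (Li-Ji) and Bonferroni threshold.

    From the eigenvalues lambda of the Pearson correlation matrix of the
    per-individual trait scores:  m_eff = round(sum_i [1(lambda_i >= 1) +
    (lambda_i - floor(lambda_i))]); the threshold is alpha / m_eff.
    Constant score columns are dropped with a warning.
    """
    S = pd.DataFrame(scores)
    if S.shape[1] < 2 or S.shape[0] < 3:
        raise ValueError("need >= 2 traits and >= 3 individuals")
    sds = S.std(ddof=1)
    constant = sds[sds < 1e-12].index
    if len(constant):
        import warnings

        warnings.warn(f"dropping constant trait column(s): {list(constant)}")
        S = S.drop(columns=constant)
        if S.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant traits remain")
    corr = np.corrcoef(S.to_numpy(), rowvar=False)
    # round against floating error: the floor in the Li-Ji count is
    # discontinuous at integers (lambda = 3 - 1e-16 must count as 3)
    lam = np.round(np.maximum(np.linalg.eigvalsh(corr), 0.0), 9)
    m_eff = int(round(float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))))
    m_eff = max(1, min(m_eff, S.shape[1]))
    return m_eff, alpha / m_eff
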