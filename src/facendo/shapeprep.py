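"""Landmark preprocessing: reflection/symmetrization, generalized Procrustes
analysis, Mahalanobis outlier QC and PLSR covariate adjustment.

All operations work on dense corresponded landmark configurations: each
individual is a ``p x 3`` array whose rows are homologous across individuals
(the same template point on every face).  Symmetric shape is obtained by
averaging each configuration with its relabelled mirror image, after which a
generalized Procrustes analysis (GPA) removes position, orientation and
(optionally) scale.  Residual confounding with covariates such as sex, age,
height, weight and facial size is removed with a partial-least-squares
regression of shape on the covariate block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "AlignedSample",
    "QCReport",
    "reflect",
    "symmetrize",
    "make_symmetric",
    "gpa",
    "align_to",
    "qc_scores",
    "adjust_covariates",
]


@dataclass
class AlignedSample:
    """Result of a generalized Procrustes superimposition.

    Attributes
    ----------
    shapes : (n, 3p) ndarray
        Row ``i`` is individual ``i``'s aligned configuration, flattened
        landmark-major (x1, y1, z1, x2, ...).
    consensus : (p, 3) ndarray
        Procrustes mean shape, centred at the origin.
    centroid_sizes : (n,) ndarray
        Centroid size of each *input* configuration (prior to any scaling);
        exported downstream as the "facial size" covariate.
    """

    shapes: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def p(self) -> int:
        return self.consensus.shape[0]

    def configs(self) -> np.ndarray:
        """Aligned configurations as an (n, p, 3) array."""
        return self.shapes.reshape(self.n, self.p, 3)


@dataclass
class QCReport:
    z_scores: np.ndarray
    missingness_scores: np.ndarray
    flags: np.ndarray  # boolean per individual
    z_threshold: float
    missingness_threshold: float


def _as_config(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"expected a (p, 3) configuration, got shape {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("configuration contains non-finite coordinates")
    return coords


def reflect(coords: np.ndarray, pair_map: np.ndarray) -> np.ndarray:
    """Mirror a configuration across the sagittal (x=0) plane.

    The sign of the x coordinate is changed and rows are re-indexed by the
    template's left-right ``pair_map`` so that landmark identity is preserved:
    a left landmark becomes its right homologue.  ``reflect`` is an involution
    and perfectly symmetric configurations are its fixed points.
    """
    coords = _as_config(coords)
    pair_map = np.asarray(pair_map)
    if pair_map.shape != (coords.shape[0],):
        raise ValueError(
            f"pair_map length {pair_map.shape} does not match p={coords.shape[0]}"
        )
    if not np.array_equal(pair_map[pair_map], np.arange(coords.shape[0])):
        raise ValueError("pair_map is not an involution")
    out = coords.copy()
    out[:, 0] = -out[:, 0]
    return out[pair_map]


def symmetrize(original: np.ndarray, reflected: np.ndarray) -> np.ndarray:
    """Pointwise average of a configuration and its (aligned) reflection.

    Both inputs must already be superimposed in a common frame; see
    :func:`make_symmetric` for the full reflect-align-average convenience.
    """
    original = _as_config(original)
    reflected = _as_config(reflected)
    if original.shape != reflected.shape:
        raise ValueError("original and reflected configurations differ in shape")
    return 0.5 * (original + reflected)


def make_symmetric(coords: np.ndarray, pair_map: np.ndarray) -> np.ndarray:
    """Symmetric component of one configuration.

    The original and its relabelled reflection are co-superimposed (two-shape
    GPA onto their joint mean, scale retained) and averaged; a final
    projection onto the mirror-symmetric subspace makes the result an exact
    fixed point of :func:`reflect`.  Assumes the input is roughly in template
    orientation (sagittal plane near x=0), which holds for template-mapped
    configurations.
    """
    refl = reflect(coords, pair_map)
    aligned = gpa([coords, refl], remove_scale=False, canonical=False)
    a, b = aligned.configs()
    sym = symmetrize(a, b)
    sym = 0.5 * (sym + reflect(sym, pair_map))
    # restore the centroid (x zeroed: a symmetric face sits on the midline)
    centroid = np.asarray(coords, dtype=float).mean(axis=0).copy()
    centroid[0] = 0.0
    return sym + centroid


def _proper_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det=+1) minimising ||X R - target||_F for centred X, target."""
    U, _, Vt = np.linalg.svd(X.T @ target)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation putting the consensus on its principal axes.

    Sign of each axis is fixed so the coordinate of largest magnitude is
    positive; determinant is forced to +1 by flipping the last axis.  This
    removes the global-rotation gauge freedom of GPA, making the procedure
    equivariant: pre-rotating every input leaves the output unchanged.
    """
    evals, evecs = np.linalg.eigh(consensus.T @ consensus)
    order = np.argsort(evals)[::-1]
    R = evecs[:, order]
    proj = consensus @ R
    for j in range(3):
        col = proj[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            R[:, j] *= -1.0
    if np.linalg.det(R) < 0:
        R[:, 2] *= -1.0
    return R


def gpa(
    configs,
    remove_scale: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    canonical: bool = True,
    ids=None,
) -> AlignedSample:
    """Generalized Procrustes analysis.

    Iteratively centres each configuration, optionally scales it, rotates it
    (proper rotations only; reflections are handled explicitly by the pairing
    map upstream) onto the running consensus, and recomputes the consensus
    until it moves by less than ``tol`` in Frobenius norm.  The Procrustes
    objective (sum of squared distances to the consensus) is non-increasing.

    Parameters
    ----------
    configs : sequence of (p, 3) arrays or (n, p, 3) array
    remove_scale : bool
        Scale each configuration to unit centroid size (and re-estimate the
        optimal per-configuration scale at every iteration).  Centroid sizes
        of the raw inputs are always reported.
    canonical : bool
        Rotate the final solution so the consensus lies on its principal axes
        (deterministic orientation).
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("configs must be an (n, p, 3) stack of configurations")
    n, p, _ = arr.shape
    if n < 2:
        raise ValueError("GPA needs at least two configurations")

    centred = arr - arr.mean(axis=1, keepdims=True)
    sizes = np.linalg.norm(centred, axis=(1, 2))
    if np.any(sizes < 1e-12):
        bad = int(np.argmin(sizes))
        raise ValueError(f"configuration {bad} is degenerate (all landmarks coincident)")
    X = centred / sizes[:, None, None] if remove_scale else centred.copy()

    consensus = X[0].copy()
    consensus /= np.linalg.norm(consensus)
    for _ in range(max_iter):
        for i in range(n):
            R = _proper_rotation(X[i], consensus)
            X[i] = X[i] @ R
            if remove_scale:
                s = np.tensordot(X[i], consensus) / np.tensordot(X[i], X[i])
                X[i] = X[i] * s
        new = X.mean(axis=0)
        new -= new.mean(axis=0)
        if remove_scale:
            new /= np.linalg.norm(new)
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            break
        consensus = new

    if canonical:
        R = _canonical_rotation(consensus)
        consensus = consensus @ R
        X = X @ R

    return AlignedSample(
        shapes=X.reshape(n, 3 * p),
        consensus=consensus,
        centroid_sizes=sizes,
        ids=list(ids) if ids is not None else [],
    )


def align_to(coords: np.ndarray, target: np.ndarray, remove_scale: bool = True) -> np.ndarray:
    """Superimpose one configuration onto a fixed target (ordinary Procrustes).

    Centres ``coords``, rotates (proper rotation) and optionally scales it to
    best fit the centred ``target``.  Used to project new individuals into an
    existing consensus/model frame.
    """
    coords = _as_config(coords)
    target = np.asarray(target, dtype=float)
    Xc = coords - coords.mean(axis=0)
    Tc = target - target.mean(axis=0)
    size = np.linalg.norm(Xc)
    if size < 1e-12:
        raise ValueError("degenerate configuration")
    if remove_scale:
        Xc = Xc / size
    R = _proper_rotation(Xc, Tc)
    Xr = Xc @ R
    if remove_scale:
        s = np.tensordot(Xr, Tc) / np.tensordot(Xr, Xr)
        Xr = Xr * s
    return Xr


def qc_scores(
    sample: AlignedSample,
    z_threshold: float = 2.0,
    reduced_dim: int | None = None,
    missingness: np.ndarray | None = None,
    missingness_threshold: float = 0.1,
    variance_kept: float = 0.98,
) -> QCReport:
    """Outlier QC from Mahalanobis distance to the sample mean shape.

    Distances are computed in a PCA-reduced space (``reduced_dim`` components,
    or enough to cover ``variance_kept`` of the variance) so the covariance is
    invertible, then standardised: ``z = (d - mean d) / sd d``.  Individuals
    with ``z > z_threshold`` or missingness above its threshold are flagged.
    """
    shapes = sample.shapes
    n = shapes.shape[0]
    centred = shapes - shapes.mean(axis=0)
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    evals = s**2 / (n - 1)
    nonzero = int(np.sum(s > 1e-10 * s[0]))
    if reduced_dim is None:
        frac = np.cumsum(evals) / evals.sum()
        reduced_dim = min(int(np.searchsorted(frac, variance_kept) + 1), nonzero, n - 1)
    if reduced_dim >= n:
        raise ValueError(f"reduced_dim={reduced_dim} must be < n={n}")
    reduced_dim = min(reduced_dim, nonzero)
    # scores / sqrt(eigenvalue) are whitened coordinates
    whitened = U[:, :reduced_dim] * np.sqrt(n - 1)
    dist = np.linalg.norm(whitened, axis=1)
    z = (dist - dist.mean()) / dist.std(ddof=1)
    miss = np.zeros(n) if missingness is None else np.asarray(missingness, dtype=float)
    flags = (z > z_threshold) | (miss > missingness_threshold)
    return QCReport(z, miss, flags, z_threshold, missingness_threshold)


def adjust_covariates(
    shapes: np.ndarray,
    covariates,
    n_components: int | None = None,
) -> np.ndarray:
    """Remove linear covariate effects from shape with PLSR.

    A partial-least-squares regression of the shape block on the centred
    covariate block is fitted with ``n_components`` = number of covariates
    (capped at the covariate rank, with a warning if deficient); the fitted
    effect is subtracted and the grand mean retained.  At the full component
    count on full-rank covariates this equals least-squares residualisation,
    so residual columns are exactly uncorrelated with every covariate.
    """
    shapes = np.asarray(shapes, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, c = C.shape
    if shapes.shape[0] != n:
        raise ValueError("shapes and covariates disagree on n")
    if n <= c:
        raise ValueError(f"need n > number of covariates ({n} <= {c})")
    Cc = C - C.mean(axis=0)
    rank = np.linalg.matrix_rank(Cc)
    if rank == 0:
        return shapes.copy()
    ncomp = c if n_components is None else n_components
    if ncomp > rank:
        if n_components is not None or rank < c:
            warnings.warn(
                f"covariates have rank {rank} < requested {ncomp} components; capping",
                stacklevel=2,
            )
        ncomp = rank
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(Cc, shapes)
    fitted = pls.predict(Cc)
    return shapes - fitted + shapes.mean(axis=0)
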