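"""Data-driven global-to-local facial segmentation.

Landmark-landmark covariation is summarised with Escoufier's RV coefficient,
a [0, 1] generalisation of squared correlation to blocks of variables (here
each landmark's three coordinates).  The resulting structural similarity
matrix is cut by recursive two-way spectral bisection (normalized Laplacian,
Fiedler-vector embedding, seeded 2-means) for a fixed number of rounds: five
rounds below the whole face yield 1+2+4+8+16+32 = 63 nested segments.  Each
segment is then superimposed on its own and summarised by a PCA whose
dimension is chosen by Horn's parallel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .shapeprep import align_to, gpa

__all__ = [
    "SimilarityMatrix",
    "Segment",
    "SegmentHierarchy",
    "SegmentModel",
    "rv_coefficient",
    "build_similarity",
    "spectral_hierarchy",
    "parallel_analysis",
    "fit_segment_model",
    "project",
    "project_many",
]


@dataclass
class SimilarityMatrix:
    """Symmetric landmark-by-landmark RV similarity with unit diagonal."""

    values: np.ndarray
    landmark_ids: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity must be square")
        self.values = v
        self.landmark_ids = np.asarray(self.landmark_ids)


@dataclass
class Segment:
    segment_id: int
    level: int
    landmarks: np.ndarray  # sorted indices into the template
    parent_id: int | None


@dataclass
class SegmentHierarchy:
    """Binary segment tree in heap numbering: root 1, children of i are 2i, 2i+1."""

    segments: list

    def __getitem__(self, segment_id: int) -> Segment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_levels(self) -> int:
        return max(s.level for s in self.segments)

    def children(self, segment_id: int) -> list:
        return [s for s in self.segments if s.parent_id == segment_id]


@dataclass
class SegmentModel:
    """Per-segment Procrustes mean and orthonormal PCA basis.

    ``basis`` is (3m, k) with orthonormal columns; ``eigenvalues`` are the k
    retained PCA eigenvalues in non-increasing order.
    """

    segment_id: int
    landmarks: np.ndarray
    mean_shape: np.ndarray  # (m, 3)
    basis: np.ndarray  # (3m, k)
    eigenvalues: np.ndarray  # (k,)

    @property
    def k(self) -> int:
        return self.basis.shape[1]


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Escoufier's RV coefficient between two column blocks.

    RV = tr(S_xy S_yx) / sqrt(tr(S_xx^2) tr(S_yy^2)) on the centred blocks'
    cross-product matrices; equivalently the cosine between the configuration
    matrices X_c X_c' and Y_c Y_c'.  Equals 1 when Y is X times an orthogonal
    matrix and approaches 0 for uncorrelated blocks.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0] or X.shape[0] < 3:
        raise ValueError("blocks must share n >= 3 rows")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.linalg.norm(Xc.T @ Xc)
    syy = np.linalg.norm(Yc.T @ Yc)
    if sxx < 1e-300 or syy < 1e-300:
        raise ValueError("zero-variance block")
    sxy = np.linalg.norm(Xc.T @ Yc) ** 2
    return float(sxy / (sxx * syy))


def build_similarity(shapes: np.ndarray, p: int | None = None) -> SimilarityMatrix:
    """RV similarity between every pair of landmarks.

    ``shapes`` is (n, 3p) landmark-major.  Entry (i, j) is the RV coefficient
    of landmark i's and landmark j's 3-column coordinate blocks, computed in
    one blocked cross-product pass.  Zero-variance landmarks are assigned zero
    similarity off-diagonal with a warning.
    """
    shapes = np.asarray(shapes, dtype=float)
    n, q = shapes.shape
    if p is None:
        p = q // 3
    if 3 * p != q:
        raise ValueError("shapes width is not 3*p")
    Xc = shapes - shapes.mean(axis=0)
    C = Xc.T @ Xc  # (3p, 3p)
    # ||C_ij||_F^2 for every 3x3 block
    blocks = C.reshape(p, 3, p, 3)
    sq = np.einsum("iajb,iajb->ij", blocks, blocks)
    diag = np.sqrt(np.diag(sq))  # ||C_ii||_F
    bad = diag < 1e-300
    if bad.any():
        import warnings

        warnings.warn(f"{int(bad.sum())} zero-variance landmark(s); similarity set to 0")
        diag = np.where(bad, 1.0, diag)
    rv = sq / np.outer(diag, diag)
    rv[bad, :] = 0.0
    rv[:, bad] = 0.0
    np.fill_diagonal(rv, 1.0)
    rv = np.clip(0.5 * (rv + rv.T), 0.0, 1.0)
    return SimilarityMatrix(values=rv, landmark_ids=np.arange(p))


def _fiedler_bisect(S: np.ndarray, rng_seed: int, min_size: int = 1) -> np.ndarray:
    """Two-way normalized-cut split of a similarity submatrix.

    Returns a boolean mask over the submatrix rows (True = side B).  Uses the
    eigenvector of the second-smallest eigenvalue of the symmetric normalized
    Laplacian, clustered by 2-means with 10 restarts.  If 2-means yields a
    side below ``min_size`` (tiny tight clusters do occur in real covariance
    structure), the split falls back to the minimum-normalized-cut threshold
    along the sorted Fiedler embedding subject to the size constraint, so a
    deep hierarchy never starves.
    """
    m = S.shape[0]
    d = S.sum(axis=1)
    d = np.maximum(d, 1e-12)
    Dinv = 1.0 / np.sqrt(d)
    L = np.eye(m) - Dinv[:, None] * S * Dinv[None, :]
    L = 0.5 * (L + L.T)
    evals, evecs = np.linalg.eigh(L)
    fiedler = evecs[:, 1]
    # scale back to the random-walk embedding for balanced volumes
    embedding = Dinv * fiedler
    km = KMeans(n_clusters=2, n_init=10, random_state=rng_seed)
    labels = km.fit_predict(embedding[:, None])
    mask = labels != labels[0]
    if min(mask.sum(), (~mask).sum()) >= min_size:
        return mask
    # constrained fallback: sweep cut points on the sorted embedding and take
    # the feasible split minimising ncut = cut * (1/vol(A) + 1/vol(B))
    order = np.argsort(embedding, kind="mergesort")
    So = S[np.ix_(order, order)]
    vol = d[order]
    total_vol = vol.sum()
    best, best_cut = np.inf, None
    assoc = 0.0  # within-A association, A = first i sorted rows
    vol_a = 0.0
    for i in range(1, m):
        row = So[i - 1]
        assoc += 2.0 * row[: i - 1].sum() + row[i - 1]
        vol_a += vol[i - 1]
        if i < min_size or m - i < min_size:
            continue
        cut = vol_a - assoc
        vol_b = total_vol - vol_a
        ncut = cut * (1.0 / max(vol_a, 1e-12) + 1.0 / max(vol_b, 1e-12))
        if ncut < best:
            best, best_cut = ncut, i
    if best_cut is None:
        return mask  # no feasible cut; caller validates sizes and errors
    out = np.zeros(m, dtype=bool)
    out[order[best_cut:]] = True
    if out[0]:
        out = ~out  # side containing row 0 is always A
    return out


def spectral_hierarchy(
    sim: SimilarityMatrix, levels: int = 5, seed: int = 0, min_landmarks: int = 3
) -> SegmentHierarchy:
    """Recursive spectral bisection of the RV similarity into a binary tree.

    ``levels`` bisection rounds below the full face give 2^(levels+1) - 1
    segments in total (five rounds -> 63).  Every segment at every level is
    recorded; children partition their parent.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    p = sim.values.shape[0]
    root = Segment(segment_id=1, level=0, landmarks=np.arange(p), parent_id=None)
    segments = [root]
    frontier = [root]
    for level in range(1, levels + 1):
        # children must retain enough landmarks to support all remaining rounds
        child_min = min_landmarks * 2 ** (levels - level)
        new_frontier = []
        for seg in frontier:
            idx = seg.landmarks
            if idx.size < 2 * child_min:
                raise ValueError(
                    f"segment {seg.segment_id} has {idx.size} landmarks; too small to "
                    f"split into children of >= {child_min}"
                )
            sub = sim.values[np.ix_(idx, idx)]
            mask = _fiedler_bisect(sub, rng_seed=seed + seg.segment_id, min_size=child_min)
            if mask.sum() < child_min or (~mask).sum() < child_min:
                raise ValueError(
                    f"split of segment {seg.segment_id} produced a child below "
                    f"{child_min} landmarks"
                )
            left = Segment(2 * seg.segment_id, level, np.sort(idx[~mask]), seg.segment_id)
            right = Segment(2 * seg.segment_id + 1, level, np.sort(idx[mask]), seg.segment_id)
            segments.extend([left, right])
            new_frontier.extend([left, right])
        frontier = new_frontier
    return SegmentHierarchy(segments=segments)


def _similarity_mode_fields(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3m, d) of the translation+rotation tangent space at
    the consensus.  Procrustes-aligned data is confined to the orthogonal
    complement of these modes; a parallel-analysis null must respect that."""
    m = consensus.shape[0]
    cols = []
    for ax in range(3):
        t = np.zeros((m, 3))
        t[:, ax] = 1.0
        cols.append(t.ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0.0]]),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0.0]]),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0.0]]),
    ]
    centred = consensus - consensus.mean(axis=0)
    for G in gens:
        cols.append((centred @ G.T).ravel())
    T = np.column_stack(cols)
    q, r = np.linalg.qr(T)
    return q[:, np.abs(np.diag(r)) > 1e-10]


def parallel_analysis(
    data: np.ndarray,
    n_reps: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
    project_out: np.ndarray | None = None,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Horn's parallel analysis on a centred data matrix.

    Each replicate permutes every column independently across rows, destroying
    inter-column covariance while keeping marginals; the retained dimension is
    the number of leading observed eigenvalues exceeding the given percentile
    of the permuted eigenvalue of the same rank.  ``project_out`` (columns of
    an orthonormal basis) is removed from both the observed and the permuted
    data; this keeps the null comparable when the data is confined to a
    subspace, as Procrustes-aligned coordinates are.
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    if project_out is not None:
        Xc = Xc - (Xc @ project_out) @ project_out.T

    def _eigs(M: np.ndarray) -> np.ndarray:
        # eigenvalues of the covariance via the smaller Gram matrix
        if M.shape[1] <= M.shape[0]:
            ev = np.linalg.eigvalsh(M.T @ M)
        else:
            ev = np.linalg.eigvalsh(M @ M.T)
        return np.maximum(ev[::-1], 0.0) / (n - 1)

    obs = _eigs(Xc)
    rng = np.random.default_rng(seed)
    null = np.empty((n_reps, obs.size))
    obs_total = obs.sum()
    for r in range(n_reps):
        perm = rng.permuted(Xc, axis=0)
        perm -= perm.mean(axis=0)
        ev = _eigs(perm)
        if project_out is not None:
            perm = perm - (perm @ project_out) @ project_out.T
            ev = _eigs(perm)
            # permutation breaks the subspace confinement, so the projection
            # strips variance from the null that the observed data never had;
            # rescale to a common total-variance budget
            tot = ev.sum()
            if tot > 0:
                ev = ev * (obs_total / tot)
        null[r, : ev.size] = ev[: obs.size]
    cutoff = np.percentile(null, percentile, axis=0)
    exceeds = obs > cutoff
    k = int(np.argmin(exceeds)) if not exceeds.all() else int(exceeds.size)
    return k, obs, cutoff


def fit_segment_model(
    shapes: np.ndarray,
    hierarchy: SegmentHierarchy,
    segment_id: int,
    pa_reps: int = 100,
    pa_percentile: float = 95.0,
    seed: int = 0,
    min_k: int = 0,
) -> SegmentModel:
    """Fit a segment's shape space: per-segment GPA then PCA with parallel analysis.

    The segment's landmarks are extracted from every individual and re-aligned
    by a fresh GPA removing position and orientation (scale was already
    removed by the whole-face superimposition, so relative segment size is
    retained as shape information); the aligned coordinates are decomposed by
    PCA.  The retained dimension k is set by Horn's parallel analysis; a
    segment retaining no component is rejected.
    """
    shapes = np.asarray(shapes, dtype=float)
    n = shapes.shape[0]
    if n < 10:
        raise ValueError("need n >= 10 individuals to fit a segment model")
    seg = hierarchy[segment_id]
    if seg.landmarks.size < 3:
        raise ValueError(f"segment {segment_id} has fewer than 3 landmarks")
    configs = shapes.reshape(n, -1, 3)[:, seg.landmarks, :]
    aligned = gpa(configs, remove_scale=False)
    A = aligned.shapes
    Ac = A - A.mean(axis=0)
    modes = _similarity_mode_fields(aligned.consensus)
    k, obs, _ = parallel_analysis(
        Ac, n_reps=pa_reps, percentile=pa_percentile, seed=seed, project_out=modes
    )
    if k == 0:
        if min_k > 0:
            import warnings

            warnings.warn(
                f"parallel analysis retained no component for segment {segment_id}; "
                f"keeping the leading {min_k}"
            )
            k = min_k
        else:
            raise ValueError(
                f"parallel analysis retained no component for segment {segment_id}"
            )
    k = min(k, n - 1, A.shape[1])
    U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
    basis = Vt[:k].T
    eigenvalues = (s[:k] ** 2) / (n - 1)
    return SegmentModel(
        segment_id=segment_id,
        landmarks=seg.landmarks,
        mean_shape=aligned.consensus.copy(),
        basis=basis,
        eigenvalues=eigenvalues,
    )


def project(model: SegmentModel, config: np.ndarray) -> np.ndarray:
    """PC scores of one individual in a segment's shape space.

    The segment's landmarks are extracted, superimposed onto the model mean
    (translation and proper rotation; scale is shape information here) and
    projected on the orthonormal basis.  Scores are invariant to rigid
    motions of the input and recover basis coefficients exactly:
    project(mean + c * basis_col_j) = c * e_j.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[1] != 3:
        raise ValueError("config must be (p, 3)")
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite coordinates")
    sub = config[model.landmarks]
    aligned = align_to(sub, model.mean_shape, remove_scale=False)
    centred_mean = model.mean_shape - model.mean_shape.mean(axis=0)
    v = (aligned - centred_mean).ravel()
    return v @ model.basis


def project_many(model: SegmentModel, configs: np.ndarray) -> np.ndarray:
    """PC scores for a stack of configurations; rows align with individuals."""
    configs = np.asarray(configs, dtype=float)
    return np.vstack([project(model, c) for c in configs])
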