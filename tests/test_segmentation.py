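import numpy as np
import pytest

from facendo import segmentation as seg
from facendo.segmentation import Segment, SegmentHierarchy


class TestRVCoefficient:
    def test_self_similarity_is_one(self, rng):
        X = rng.normal(size=(50, 3))
        assert seg.rv_coefficient(X, X) == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(40, 3))
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0],
            ]
        )
        assert seg.rv_coefficient(X, X @ R) == pytest.approx(1.0)

    def test_configuration_matrix_identity(self):
        # oracle: RV = <XcXc', YcYc'>_F / (||XcXc'||_F ||YcYc'||_F)
        g = np.random.default_rng(7)
        for _ in range(20):
            X, Y = g.normal(size=(5, 3)), g.normal(size=(5, 3))
            Xc, Yc = X - X.mean(0), Y - Y.mean(0)
            gx, gy = Xc @ Xc.T, Yc @ Yc.T
            oracle = np.sum(gx * gy) / (np.linalg.norm(gx) * np.linalg.norm(gy))
            assert abs(seg.rv_coefficient(X, Y) - oracle) < 1e-10

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            seg.rv_coefficient(np.ones((10, 3)), rng.normal(size=(10, 3)))


class TestSimilarity:
    def test_duplicated_landmark_entry_is_one(self, rng):
        block = rng.normal(size=(100, 3))
        shapes = np.hstack([block, block, rng.normal(size=(100, 3))])
        sim = seg.build_similarity(shapes)
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_independent_landmarks_low_similarity(self):
        g = np.random.default_rng(8)
        shapes = g.normal(size=(5000, 60))  # 20 independent landmarks
        sim = seg.build_similarity(shapes)
        off = sim.values[~np.eye(20, dtype=bool)]
        assert np.median(off) < 0.05

    def test_planted_groups_within_exceeds_between(self):
        g = np.random.default_rng(9)
        zA = g.normal(size=(400, 1))
        zB = g.normal(size=(400, 1))
        blocks = []
        for i in range(6):
            z = zA if i < 3 else zB
            blocks.append(z @ g.normal(size=(1, 3)) + 0.3 * g.normal(size=(400, 3)))
        sim = seg.build_similarity(np.hstack(blocks))
        within = [sim.values[i, j] for i in range(3) for j in range(3) if i != j]
        between = [sim.values[i, j] for i in range(3) for j in range(3, 6)]
        assert min(within) > max(between)


class TestHierarchy:
    def test_one_level_gives_three_segments(self, aligned_sample):
        sim = seg.build_similarity(aligned_sample.shapes)
        h = seg.spectral_hierarchy(sim, levels=1, seed=0)
        assert len(h) == 3

    def test_five_levels_give_sixty_three_segments(self, aligned_sample):
        sim = seg.build_similarity(aligned_sample.shapes)
        h = seg.spectral_hierarchy(sim, levels=5, seed=0)
        assert len(h) == 63
        assert h.n_levels == 5

    def test_block_diagonal_similarity_recovered_at_first_split(self):
        p = 40
        S = np.zeros((p, p))
        S[:25, :25] = 0.8
        S[25:, 25:] = 0.8
        np.fill_diagonal(S, 1.0)
        sim = seg.SimilarityMatrix(values=S, landmark_ids=np.arange(p))
        h = seg.spectral_hierarchy(sim, levels=1, seed=3)
        children = sorted(h.children(1), key=lambda s: s.landmarks.min())
        assert np.array_equal(children[0].landmarks, np.arange(25))
        assert np.array_equal(children[1].landmarks, np.arange(25, 40))

    def test_children_partition_parent(self, aligned_sample):
        sim = seg.build_similarity(aligned_sample.shapes)
        h = seg.spectral_hierarchy(sim, levels=3, seed=1)
        for s in h.segments:
            kids = h.children(s.segment_id)
            if kids:
                merged = np.sort(np.concatenate([k.landmarks for k in kids]))
                assert np.array_equal(merged, s.landmarks)

    def test_deterministic_given_seed(self, aligned_sample):
        sim = seg.build_similarity(aligned_sample.shapes)
        h1 = seg.spectral_hierarchy(sim, levels=2, seed=5)
        h2 = seg.spectral_hierarchy(sim, levels=2, seed=5)
        for a, b in zip(h1.segments, h2.segments):
            assert np.array_equal(a.landmarks, b.landmarks)

    def test_too_small_segment_rejected(self, rng):
        S = np.eye(8) * 0.5 + 0.5
        sim = seg.SimilarityMatrix(values=S, landmark_ids=np.arange(8))
        with pytest.raises(ValueError, match="too small"):
            seg.spectral_hierarchy(sim, levels=2, seed=0)


def _single_segment_hierarchy(p):
    return SegmentHierarchy([Segment(1, 0, np.arange(p), None)])


class TestSegmentModel:
    def test_planted_rank_three_recovered(self):
        m = 12
        hierarchy = _single_segment_hierarchy(m)
        base = np.random.default_rng(0).normal(size=(m, 3))
        base += -base.mean(0) + np.array([0, 0, 5.0])  # keep it non-degenerate
        hits = 0
        for rep in range(20):
            g = np.random.default_rng(100 + rep)
            latents = g.normal(size=(3, 3 * m))
            # small deformations: the superimposition is near-linear there
            z = g.normal(size=(120, 3)) * [0.10, 0.09, 0.08]
            shapes = base.ravel() + z @ latents + g.normal(0, 0.002, size=(120, 3 * m))
            model = seg.fit_segment_model(shapes, hierarchy, 1, pa_reps=50, seed=rep)
            hits += model.k == 3
        assert hits == 20

    def test_pure_noise_retains_at_most_one(self):
        m = 8
        hierarchy = _single_segment_hierarchy(m)
        base = np.random.default_rng(1).normal(size=(m, 3)) + [0, 0, 5.0]
        small = 0
        for rep in range(20):
            g = np.random.default_rng(200 + rep)
            shapes = base.ravel() + g.normal(0, 0.05, size=(400, 3 * m))
            try:
                model = seg.fit_segment_model(shapes, hierarchy, 1, pa_reps=50, seed=rep)
                k = model.k
            except ValueError:  # zero components retained
                k = 0
            small += k <= 1
        assert small >= 19

    def test_pca_contract(self, aligned_sample):
        sim = seg.build_similarity(aligned_sample.shapes)
        h = seg.spectral_hierarchy(sim, levels=1, seed=0)
        model = seg.fit_segment_model(aligned_sample.shapes, h, 2, pa_reps=50, seed=0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        gram = model.basis.T @ model.basis
        assert np.allclose(gram, np.eye(model.k), atol=1e-8)
        # retained variance cannot exceed the segment's total variance
        seg_cfg = aligned_sample.configs()[:, h[2].landmarks, :]
        from facendo.shapeprep import gpa

        total = gpa(seg_cfg, remove_scale=False).shapes.var(axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() <= total + 1e-10


class TestProject:
    @pytest.fixture(scope="class")
    def model(self, aligned_sample):
        sim = seg.build_similarity(aligned_sample.shapes)
        h = seg.spectral_hierarchy(sim, levels=1, seed=0)
        return seg.fit_segment_model(aligned_sample.shapes, h, 1, pa_reps=50, seed=0)

    def test_mean_shape_projects_to_zero(self, model):
        scores = seg.project(model, model.mean_shape)
        assert np.abs(scores).max() < 1e-8

    def test_basis_reconstruction(self, model):
        offset = model.mean_shape.ravel() + 2.0 * model.basis[:, 0]
        scores = seg.project(model, offset.reshape(-1, 3))
        expected = np.zeros(model.k)
        expected[0] = 2.0
        assert np.allclose(scores, expected, atol=1e-6)

    def test_rotation_invariance_of_scores(self, model, aligned_sample):
        cfg = aligned_sample.configs()[4]
        theta = 0.4
        R = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        scores_a = seg.project(model, cfg)
        scores_b = seg.project(model, cfg @ R + [3.0, -1.0, 2.0])
        assert np.allclose(scores_a, scores_b, atol=1e-6)

    def test_nonfinite_rejected(self, model):
        bad = model.mean_shape.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            seg.project(model, bad)
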