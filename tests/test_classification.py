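"""sci-Hi-C imputation + mask scoring and chromatin-tracing classification."""

import numpy as np
import pytest

from chromoclust import classification as cl
from chromoclust.cluster_features import cluster_contact_matrix
from chromoclust.distmat import center_distance_matrix, downsample_coverage
from chromoclust.cluster_features import average_distance_matrix
from chromoclust.synthetic_data import (
    SimulationConfig,
    positive_control,
    sample_scihic_cells,
)


class TestImputation:
    def test_fixed_point_residual(self, rng):
        raw = rng.integers(0, 3, size=(30, 30)).astype(float)
        raw = np.triu(raw) + np.triu(raw, 1).T
        conv = cl.convolve_contacts(raw, w=2)
        m = cl.transition_matrix(conv)
        r = cl.random_walk_with_restart(m, restart_p=0.5, tol=1e-6)
        resid = np.linalg.norm((0.5 * (r @ m) + 0.5 * np.eye(30)) - r)
        assert resid <= 1e-6

    def test_rwr_matches_closed_form_linear_solve(self, rng):
        # R_inf = p (I - (1-p) M)^-1 for a row-stochastic M
        a = rng.random((10, 10)) + 0.1
        m = a / a.sum(axis=1, keepdims=True)
        r = cl.random_walk_with_restart(m, restart_p=0.5, tol=1e-12)
        closed = 0.5 * np.linalg.inv(np.eye(10) - 0.5 * m)
        np.testing.assert_allclose(r, closed, atol=1e-10)

    def test_convolution_is_box_filter(self, rng):
        raw = rng.random((15, 15))
        conv = cl.convolve_contacts(raw, w=1)
        # interior entry: sum of the 3x3 neighborhood
        assert conv[7, 7] == pytest.approx(raw[6:9, 6:9].sum())
        # zero padding at the corner
        assert conv[0, 0] == pytest.approx(raw[:2, :2].sum())

    def test_row_percentile_binarization_keeps_quarter(self, rng):
        r = rng.random((20, 20))
        b = cl.binarize_by_row_percentile(r, 75.0)
        assert set(np.unique(b)) <= {0, 1}
        assert (b.sum(axis=1) <= np.ceil(0.25 * 20)).all()

    def test_all_zero_row_warns(self):
        conv = np.ones((4, 4))
        conv[2] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            m = cl.transition_matrix(conv)
        np.testing.assert_array_equal(m[2], 0.0)


class TestMasks:
    def test_scaled_population_gives_empty_masks(self, rng):
        pop = rng.integers(1, 50, size=(12, 12)).astype(float)
        pop = (pop + pop.T) / 2
        cluster = pop * (100 / 1000)  # S_A / S_Pop scaling, d == 0
        masks = cl.build_masks(cluster, pop, 100, 1000)
        assert masks.superiority.sum() == 0
        assert masks.inferiority.sum() == 0

    def test_undefined_entries_in_neither_mask(self):
        cluster = np.array([[0.0, 0.0], [0.0, 1.0]])
        pop = np.array([[4.0, 4.0], [4.0, 4.0]])
        masks = cl.build_masks(cluster, pop, 1, 1)
        assert masks.superiority[0, 0] == 0 and masks.inferiority[0, 0] == 0
        assert np.isnan(masks.difference[0, 1])

    def test_hand_3x3_difference(self):
        cluster = np.array([[1.0, 1.0, 2.0], [1.0, 4.0, 1.0], [2.0, 1.0, 8.0]])
        pop = np.array([[32.0, 64.0, 2.0], [64.0, 4.0, 1.0], [2.0, 1.0, 4.0]])
        masks = cl.build_masks(cluster, pop, 1, 1)
        d = np.log2(pop / cluster)
        np.testing.assert_allclose(masks.difference, d)
        assert masks.superiority[0, 0] == 1  # log2(32) = 5
        assert masks.inferiority[2, 2] == 1  # log2(0.5) = -1


class TestScoring:
    def _masks(self, n=10):
        sup = np.zeros((n, n), np.int8)
        inf = np.zeros((n, n), np.int8)
        sup[0, 1] = sup[1, 0] = 1
        inf[2, 3] = inf[3, 2] = 1
        diff = np.zeros((n, n))
        return cl.ClusterMasks(superiority=sup, inferiority=inf, difference=diff)

    def test_all_ones_cell_unassigned(self):
        masks = {0: self._masks(), 1: self._masks()}
        cell = np.ones((10, 10))
        res = cl.score_scihic(cell, masks)
        assert res.assigned is None
        assert all(s == pytest.approx(1.0) for s in res.scores.values())

    def test_inferiority_hits_win(self):
        m0 = self._masks()
        m1 = cl.ClusterMasks(
            superiority=m0.inferiority.copy(), inferiority=m0.superiority.copy(),
            difference=np.zeros((10, 10)),
        )
        cell = np.zeros((10, 10))
        cell[2, 3] = cell[3, 2] = 1  # hits m0's inferiority and m1's superiority
        res = cl.score_scihic(cell, {0: m0, 1: m1})
        assert res.assigned == 0
        probs = res.probabilities
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_empty_mask_warns(self):
        empty = cl.ClusterMasks(
            superiority=np.zeros((4, 4), np.int8),
            inferiority=np.zeros((4, 4), np.int8),
            difference=np.zeros((4, 4)),
        )
        with pytest.warns(UserWarning, match="empty mask"):
            cl.score_scihic(np.ones((4, 4)), {0: empty})


class TestControls:
    def test_shuffle_preserves_total_and_diagonal(self, rng):
        raw = rng.integers(0, 4, size=(15, 15)).astype(float)
        raw = np.triu(raw) + np.triu(raw, 1).T
        out = cl.randomize_control(raw, seed=1)
        assert out.sum() == raw.sum()
        np.testing.assert_array_equal(np.diag(out), np.diag(raw))
        assert np.allclose(out, out.T)

    def test_symmetrize_min(self):
        m = np.array([[0, 3], [5, 0]], float)
        out = cl.symmetrize_min(m)
        np.testing.assert_array_equal(out, [[0, 3], [3, 0]])
        np.testing.assert_array_equal(cl.symmetrize_min(out), out)


class TestTracingClassification:
    @pytest.fixture(scope="class")
    def cluster_dms(self):
        cfg = SimulationConfig(n_clusters=3, n_beads=30, structures_per_cluster=40,
                               sigmas=(0.3,), seed=21)
        structs, labels, _ = positive_control(cfg)
        dms = {
            k: average_distance_matrix([s for s, l in zip(structs, labels) if l == k])
            for k in range(3)
        }
        return cfg, structs, labels, dms

    def test_structure_equal_to_cluster_mean_scores_e(self, cluster_dms):
        _, _, _, dms = cluster_dms
        res = cl.classify_structure(dms[0], dms)
        assert res.scores[0] == pytest.approx(np.e)
        assert res.assigned == 0

    def test_anticorrelated_scores_inverse_e(self):
        n = 10
        iu = np.triu_indices(n, 1)
        base = np.zeros((n, n))
        base[iu] = np.linspace(0, 1, len(iu[0]))
        base = base + base.T
        anti = base.max() - base
        np.fill_diagonal(anti, 0)
        res = cl.classify_structure(base, {0: anti})
        assert res.scores[0] == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_scale_invariance(self, cluster_dms):
        cfg, structs, labels, dms = cluster_dms
        dm = center_distance_matrix(structs[0])
        r1 = cl.classify_structure(dm, dms)
        r2 = cl.classify_structure(dm * 7.3, dms)
        for k in dms:
            assert r1.scores[k] == pytest.approx(r2.scores[k], rel=1e-9)

    def test_noisy_structures_classified_to_generating_cluster(self, cluster_dms):
        cfg, structs, labels, dms = cluster_dms
        correct = total = 0
        for s, l in zip(structs[::4], labels[::4]):
            res = cl.classify_structure(center_distance_matrix(s), dms)
            if res.assigned is not None:
                total += 1
                correct += res.assigned == l
        assert total > 0
        assert correct / total >= 0.99

    def test_downsampled_matching_still_works(self, cluster_dms):
        cfg, structs, labels, dms = cluster_dms
        # emulate sparse imaged loci: every 3rd bin
        down_dms = {k: downsample_coverage(v, step=600_000, bin_width=200_000)[0]
                    for k, v in dms.items()}
        s, l = structs[5], labels[5]
        dm, _ = downsample_coverage(center_distance_matrix(s), step=600_000,
                                    bin_width=200_000)
        res = cl.classify_structure(dm, down_dms)
        assert res.assigned == l

    def test_too_few_loci(self):
        with pytest.raises(ValueError):
            cl.classify_structure(np.zeros((2, 2)), {0: np.zeros((2, 2))})


class TestTranscriptionRatio:
    def test_uniform_transcription_zero(self):
        trans = np.ones((12, 4))
        labels = np.array([0] * 6 + [1] * 6)
        out = cl.transcription_ratio(trans, labels, locus=2)
        assert out[0] == pytest.approx(0.0) and out[1] == pytest.approx(0.0)

    def test_double_mean_gives_one(self):
        trans = np.ones((10, 2))
        trans[:5, 0] = 8.0 / 3.0  # cluster 0 mean = 2x overall mean (4/3... )
        labels = np.array([0] * 5 + [1] * 5)
        out = cl.transcription_ratio(trans, labels, locus=0)
        overall = np.mean(trans[:, 0])
        assert out[0] == pytest.approx(np.log2(np.mean(trans[:5, 0]) / overall))

    def test_matches_direct_computation(self, rng):
        trans = rng.random((20, 3)) + 0.1
        labels = rng.integers(-1, 3, size=20)
        while len(set(labels) - {-1}) < 2:
            labels = rng.integers(-1, 3, size=20)
        out = cl.transcription_ratio(trans, labels, locus=1)
        clustered = labels != -1
        overall = trans[clustered, 1].mean()
        for c, v in out.items():
            assert v == pytest.approx(np.log2(trans[labels == c, 1].mean() / overall))


class TestEndToEndScihic:
    def test_planted_cells_beat_randomized_controls(self):
        """Cells sampled from planted cluster contact maps are assigned to the
        generating cluster far above the shuffled-control assignment rate."""
        from scipy.stats import binomtest

        cfg = SimulationConfig(n_clusters=3, n_beads=40, structures_per_cluster=60,
                               sigmas=(0.3,), seed=31)
        structs, labels, _ = positive_control(cfg)
        clusters = {k: [s for s, l in zip(structs, labels) if l == k] for k in range(3)}
        cms = {k: cluster_contact_matrix(v) for k, v in clusters.items()}
        pop_cm = sum(cms.values())
        sizes = {k: len(v) for k, v in clusters.items()}
        masks = {
            k: cl.build_masks(cms[k], pop_cm, sizes[k], sum(sizes.values()))
            for k in range(3)
        }
        probs = {k: cms[k] / sizes[k] for k in cms}
        n_cells, correct, assigned = 30, 0, 0
        ctrl_assigned = 0
        for k in range(3):
            cells = sample_scihic_cells(probs[k], n_cells // 3, depth=300.0, seed=100 + k)
            for ci, cell in enumerate(cells):
                imputed = cl.impute_scihic(cell, w=2)
                res = cl.score_scihic(imputed, masks)
                if res.assigned is not None:
                    assigned += 1
                    correct += res.assigned == k
                ctrl = cl.randomize_control(cell, seed=ci)
                ctrl_res = cl.score_scihic(cl.impute_scihic(ctrl, w=2), masks)
                if ctrl_res.assigned is not None:
                    ctrl_assigned += 1
        assert assigned > 0
        accuracy = correct / assigned
        # generating-cluster recovery well above the 1/3 chance level
        assert binomtest(correct, assigned, 1 / 3, alternative="greater").pvalue < 0.01
        assert accuracy > 0.5
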