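"""Contact/distance matrices, insulation, boundaries, P(s), RG, RAD, A/B."""

import numpy as np
import pytest

from chromoclust import cluster_features as cf
from chromoclust.distmat import normalize_minmax, center_distance_matrix
from chromoclust.genome_model import NucleusGeometry
from chromoclust.synthetic_data import SimulationConfig, make_reference_conformations, positive_control

from conftest import make_structure


class TestContactMatrix:
    def test_inclusive_threshold_boundary(self):
        s = make_structure([[0, 0, 0], [354.0, 0, 0]], r_bead=118.0)
        assert cf.contact_matrix(s)[0, 1] == 1  # 354 == 3 * 118
        s2 = make_structure([[0, 0, 0], [355.0, 0, 0]], r_bead=118.0)
        assert cf.contact_matrix(s2)[0, 1] == 0

    def test_cluster_sum_of_identical_structures(self, rng):
        s = make_structure(rng.normal(0, 300, size=(8, 3)))
        cm = cf.cluster_contact_matrix([s] * 10)
        np.testing.assert_array_equal(cm, 10 * cf.contact_matrix(s))

    def test_ensemble_conservation(self, rng):
        structs = [make_structure(rng.normal(0, 400, size=(6, 3)), sid=f"s{i}") for i in range(9)]
        labels = np.array([0, 0, 0, 1, 1, 1, -1, -1, 2])
        total = cf.cluster_contact_matrix(structs)
        parts = sum(
            cf.cluster_contact_matrix([s for s, l in zip(structs, labels) if l == c])
            for c in (0, 1, 2)
        ) + cf.cluster_contact_matrix([s for s, l in zip(structs, labels) if l == -1])
        np.testing.assert_array_equal(total, parts)


class TestAverageDistanceMatrix:
    def test_single_structure_is_its_normalized_matrix(self, rng):
        s = make_structure(rng.normal(size=(7, 3)))
        dm = cf.average_distance_matrix([s])
        np.testing.assert_allclose(dm, normalize_minmax(center_distance_matrix(s)))

    def test_two_structure_mean(self, rng):
        a = make_structure(rng.normal(size=(7, 3)))
        b = make_structure(rng.normal(size=(7, 3)))
        dm = cf.average_distance_matrix([a, b])
        expect = 0.5 * (
            normalize_minmax(center_distance_matrix(a))
            + normalize_minmax(center_distance_matrix(b))
        )
        np.testing.assert_allclose(dm, expect)


def naive_insulation(m, variant, l, thr=0.45):
    """O(n l^2) double-loop reference implementation."""
    m = np.asarray(m, float)
    if variant == "distance":
        m = (m > thr).astype(float)
    n = len(m)
    out = np.full(n, np.nan)
    for i in range(l, n - l + 1):
        lm = sum(m[a, b] for a in range(i - l, i) for b in range(a + 1, i))
        rm = sum(m[a, b] for a in range(i, i + l) for b in range(a + 1, i + l))
        cross = sum(m[a, b] for a in range(i - l, i) for b in range(i, i + l))
        out[i] = (lm + rm - cross) if variant == "contact" else (cross - lm - rm)
    return out


class TestInsulation:
    @pytest.mark.parametrize("variant", ["contact", "distance"])
    def test_matches_naive_double_loop(self, rng, variant):
        for n in (20, 30):
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            got = cf.insulation_profile(m, variant, window=5)
            expect = naive_insulation(m, variant, 5)
            np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_block_matrix_max_at_junction(self):
        n = 30
        dm = np.full((n, n), 0.2)
        dm[:15, 15:] = 0.9
        dm[15:, :15] = 0.9
        np.fill_diagonal(dm, 0)
        prof = cf.insulation_profile(dm, "distance", window=6)
        assert np.nanargmax(prof) == 15

    def test_uniform_matrix_flat_profile(self):
        m = np.full((24, 24), 0.3)
        prof = cf.insulation_profile(m, "distance", window=5)
        vals = prof[~np.isnan(prof)]
        assert np.allclose(vals, vals[0])

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            cf.insulation_profile(np.zeros((10, 10)), "distance", window=6)

    def test_ends_are_nan(self, rng):
        m = rng.random((20, 20))
        prof = cf.insulation_profile((m + m.T) / 2, "contact", window=4)
        assert np.isnan(prof[:4]).all() and np.isnan(prof[-3:]).all()


def _planted_dm(boundaries, n=60, rng=None):
    """Block distance matrix with small within-domain, large cross distances."""
    cuts = [0] + list(boundaries) + [n]
    dm = np.full((n, n), 0.8)
    for s, e in zip(cuts[:-1], cuts[1:]):
        dm[s:e, s:e] = 0.2
    if rng is not None:
        noise = rng.normal(0, 0.03, size=(n, n))
        dm = np.clip(dm + (noise + noise.T) / 2, 0, 1)
    np.fill_diagonal(dm, 0)
    return dm


class TestBoundaries:
    def test_two_domain_boundary_recovered(self, rng):
        dm = _planted_dm([25], rng=rng)
        got = cf.call_boundaries(dm, coarse_window=15, fine_window=5)
        assert len(got) == 1 and abs(got[0] - 25) <= 1

    def test_three_domain_boundaries_recovered(self, rng):
        dm = _planted_dm([20, 40], rng=rng)
        got = cf.call_boundaries(dm, coarse_window=10, fine_window=4)
        assert len(got) == 2
        assert abs(got[0] - 20) <= 1 and abs(got[1] - 40) <= 1

    def test_homogeneous_matrix_no_boundaries(self):
        dm = np.full((60, 60), 0.5)
        np.fill_diagonal(dm, 0)
        assert cf.call_boundaries(dm, coarse_window=15, fine_window=5) == []

    def test_boundary_free_planted_cluster(self, rng):
        dm = _planted_dm([], rng=rng)
        assert cf.call_boundaries(dm, coarse_window=15, fine_window=5) == []

    def test_territory_domains_labeling(self):
        doms = cf.territory_domains([], 10)
        assert len(doms) == 1 and doms[0]["label"] == "a"
        doms = cf.territory_domains([775], 855)
        assert len(doms) == 2
        assert doms[0]["end_bp"] == 775 * 200_000
        doms = cf.territory_domains([3, 7], 10)
        assert [d["label"] for d in doms] == ["a", "b", "c"]


class TestContactProbability:
    def test_planted_long_range_block_elevates_tail(self, rng):
        n = 40
        near = np.zeros((n, n), int)
        for i in range(n):
            for j in range(n):
                if 0 < abs(i - j) <= 2:
                    near[i, j] = 10
        far = near.copy()
        far[:5, -5:] = 8
        far[-5:, :5] = 8
        mids_n, p_near = cf.contact_probability_curve(near, 10)
        mids_f, p_far = cf.contact_probability_curve(far, 10)
        assert p_far[-1] > p_near[-1]
        # diagonal excluded: a pure-diagonal matrix has zero probability
        diag = np.eye(n, dtype=int) * 5
        _, p_diag = cf.contact_probability_curve(diag, 5)
        assert np.all(p_diag == 0)

    def test_homopolymer_curve_decreases_at_large_s(self):
        cfg = SimulationConfig(n_clusters=1, n_beads=40, structures_per_cluster=1, seed=3)
        from chromoclust.synthetic_data import negative_control

        structs = negative_control(cfg, n_structures=30)
        cm = cf.cluster_contact_matrix(structs)
        _, probs = cf.contact_probability_curve(cm, len(structs))
        assert probs[0] > probs[-1]


class TestRadiusOfGyration:
    def test_coincident_beads_zero(self):
        s = make_structure(np.zeros((5, 3)))
        assert cf.rg_profile(s)[2] == 0.0

    def test_collinear_closed_form(self):
        a = 7.0
        s = make_structure([[i * a, 0, 0] for i in range(5)])
        # beads at spacing a on a line: rg = a*sqrt(2)
        assert cf.rg_profile(s)[2] == pytest.approx(a * np.sqrt(2.0), rel=1e-12)

    def test_scales_linearly(self, rng):
        s = make_structure(rng.normal(size=(9, 3)))
        s3 = make_structure(3.0 * s.coords)
        np.testing.assert_allclose(cf.rg_profile(s3), 3.0 * cf.rg_profile(s), rtol=1e-9)
        assert cf.structure_rg(s3) == pytest.approx(3.0 * cf.structure_rg(s))

    def test_ends_nan(self, rng):
        prof = cf.rg_profile(make_structure(rng.normal(size=(9, 3))))
        assert np.isnan(prof[[0, 1, -2, -1]]).all()


class TestRadialTracks:
    def test_rad_values(self):
        geom = NucleusGeometry(shape="sphere", r_nuc=5000.0)
        s = make_structure([[0, 0, 0], [3000.0, 0, 0]])
        rad = cf.radial_track([s], geom)
        np.testing.assert_allclose(rad, [0.0, 0.6])

    def test_constant_radial_position_nan_variability(self):
        geom = NucleusGeometry(shape="sphere", r_nuc=5000.0)
        structs = [make_structure([[1000.0, 0, 0], [0, 2000.0, 0]]) for _ in range(5)]
        sv = cf.variability_track(structs, geom)
        assert np.isnan(sv).all()

    def test_log2_ratio_track(self):
        c = np.array([1.0, 2.0, 4.0, 0.0])
        e = np.array([1.0, 1.0, 1.0, 1.0])
        out = cf.log2_ratio_track(c, e)
        np.testing.assert_allclose(out[:3], [0.0, 1.0, 2.0])
        assert np.isnan(out[3])
        # sign flips under inversion
        np.testing.assert_allclose(cf.log2_ratio_track(e[:3], c[:3]), -out[:3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cf.log2_ratio_track(np.ones(3), np.ones(4))


class TestABCompartments:
    def test_checkerboard_recovers_block_indicator(self):
        n = 40
        block = np.array([1 if (i // 10) % 2 == 0 else -1 for i in range(n)])
        cm = np.where(np.outer(block, block) > 0, 20, 2).astype(float)
        np.fill_diagonal(cm, 0)
        tracks = cf.ab_compartments(cm, reference_track=block.astype(float))
        pc1 = tracks["PC1"]
        corr = np.corrcoef(pc1, block)[0, 1]
        assert abs(corr) > 0.99
        assert corr > 0  # sign oriented by the reference

    def test_sign_orientation_flips_with_reference(self):
        n = 40
        block = np.array([1 if (i // 10) % 2 == 0 else -1 for i in range(n)])
        cm = np.where(np.outer(block, block) > 0, 20, 2).astype(float)
        np.fill_diagonal(cm, 0)
        up = cf.ab_compartments(cm, reference_track=block.astype(float))["PC1"]
        down = cf.ab_compartments(cm, reference_track=-block.astype(float))["PC1"]
        np.testing.assert_allclose(up, -down)

    def test_uniform_matrix_warns(self):
        cm = np.ones((20, 20))
        with pytest.warns(UserWarning, match="degenerate"):
            cf.ab_compartments(cm)
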