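"""Procrustes alignment: rotations, distances, sliding, GPA, species means."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from morphdiv.align import (GeneralizedProcrustes, centroid_size, gpa_align,
                            optimal_rotation, procrustes_distance,
                            slide_semilandmarks, species_means)
from morphdiv.simulate import default_config, generate_dataset, make_template
from morphdiv.tps import SliderTriple

from conftest import random_configuration, similarity_transform, table_for


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestCentroidSize:
    def test_unit_square_corners(self):
        pts = [[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]]
        assert centroid_size(pts) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_single_point_is_zero(self):
        assert centroid_size([[3.0, -7.0]]) == 0.0

    def test_homogeneous_of_degree_one(self, rng):
        pts = rng.normal(size=(10, 2))
        assert centroid_size(3.0 * pts) == pytest.approx(3.0 * centroid_size(pts))


class TestOptimalRotation:
    def test_identity_for_equal_configs(self, rng):
        A = rng.normal(size=(6, 2))
        A -= A.mean(0)
        np.testing.assert_allclose(optimal_rotation(A, A), np.eye(2), atol=1e-12)

    def test_recovers_thirty_degrees(self, rng):
        A = rng.normal(size=(8, 2))
        A -= A.mean(0)
        R = rot(np.pi / 6)
        np.testing.assert_allclose(optimal_rotation(A, A @ R.T), R, atol=1e-9)

    def test_matches_grid_search_on_noisy_pair(self, rng):
        A = rng.normal(size=(9, 2))
        B = A @ rot(1.1).T + rng.normal(scale=0.3, size=(9, 2))
        A -= A.mean(0)
        B -= B.mean(0)
        R = optimal_rotation(A, B)
        rss = ((A @ R.T - B) ** 2).sum()
        grid = np.arange(0, 2 * np.pi, 1e-4)
        rss_grid = min(((A @ rot(t).T - B) ** 2).sum() for t in grid)
        assert rss <= rss_grid + 1e-6

    def test_determinant_plus_one_even_for_reflected_target(self, rng):
        A = rng.normal(size=(7, 2))
        A -= A.mean(0)
        B = A * [1.0, -1.0]  # reflection: best proper rotation must not mirror
        R = optimal_rotation(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


class TestProcrustesDistance:
    def test_similarity_invariance(self, rng):
        A = rng.normal(size=(12, 2))
        B = similarity_transform(rng, A)
        assert procrustes_distance(A, B) < 1e-9

    def test_symmetry(self, rng):
        for _ in range(10):
            A = rng.normal(size=(6, 2))
            B = rng.normal(size=(6, 2))
            assert procrustes_distance(A, B) == pytest.approx(
                procrustes_distance(B, A), abs=1e-9)

    def test_matches_brute_force_rotation_scan(self):
        A = np.array([[0.0, 0.0], [2.0, 0.1], [1.7, 1.4], [-0.3, 0.9]])
        B = np.array([[0.1, -0.2], [1.8, 0.4], [2.1, 1.9], [0.0, 1.2]])
        d = procrustes_distance(A, B)
        Ac = A - A.mean(0)
        Bc = B - B.mean(0)
        Ac /= np.sqrt((Ac**2).sum())
        Bc /= np.sqrt((Bc**2).sum())
        grid = np.arange(0, 2 * np.pi, 1e-5)
        best = min(np.sqrt(((Ac @ rot(t).T - Bc) ** 2).sum()) for t in grid)
        assert d == pytest.approx(best, abs=1e-8)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            procrustes_distance(np.zeros((4, 2)), np.ones((4, 2)))


class TestSliding:
    def triple(self):
        return [SliderTriple(0, 1, 2)]

    def test_config_equal_to_consensus_is_unchanged(self, rng):
        C = rng.normal(size=(5, 2))
        np.testing.assert_allclose(
            slide_semilandmarks(C, C, self.triple()), C, atol=1e-12)

    def test_pure_tangential_displacement_snaps_to_consensus(self):
        C = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.5, 3.0]])
        P = C.copy()
        P[1, 0] += 0.37  # displace slider along the chord (x axis)
        out = slide_semilandmarks(P, C, self.triple())
        np.testing.assert_allclose(out[1], C[1], atol=1e-12)

    def test_oblique_displacement_projects_orthogonally(self):
        C = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.5, 3.0]])
        P = C.copy()
        P[1] += [0.3, 0.4]  # tangential 0.3 + normal 0.4
        out = slide_semilandmarks(P, C, self.triple())
        np.testing.assert_allclose(out[1], [1.0, 0.4], atol=1e-12)
        before = ((P[1] - C[1]) ** 2).sum()
        after = ((out[1] - C[1]) ** 2).sum()
        assert before - after == pytest.approx(0.3**2, abs=1e-12)

    def test_matches_independent_1d_minimization(self, rng):
        for _ in range(50):
            C = rng.normal(size=(6, 2))
            P = rng.normal(size=(6, 2))
            out = slide_semilandmarks(P, C, [SliderTriple(2, 3, 4)])
            u = P[4] - P[2]
            u = u / np.linalg.norm(u)
            res = minimize_scalar(
                lambda t: ((P[3] + t * u - C[3]) ** 2).sum(),
                bounds=(-100, 100), method="bounded",
                options={"xatol": 1e-12})
            np.testing.assert_allclose(out[3], P[3] + res.x * u, atol=1e-7)

    def test_zero_length_chord_leaves_slider_with_warning(self):
        P = np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-length"):
            out = slide_semilandmarks(P, P + 1.0, self.triple())
        np.testing.assert_array_equal(out[1], P[1])


class TestGPA:
    def test_similarity_copies_align_exactly(self, rng):
        base = rng.normal(size=(10, 2))
        X = np.stack([similarity_transform(rng, base) for _ in range(20)])
        est = GeneralizedProcrustes().fit(X)
        assert est.converged_
        spread = est.coordinates_ - est.coordinates_[0]
        assert np.abs(spread).max() < 1e-8
        assert procrustes_distance(est.mean_shape_, base) < 1e-8

    def test_preshape_invariants_hold(self, rng):
        X = rng.normal(size=(8, 7, 2))
        est = GeneralizedProcrustes().fit(X)
        for P in list(est.coordinates_) + [est.mean_shape_]:
            assert np.abs(P.mean(axis=0)).max() < 1e-8
            assert np.sqrt((P**2).sum()) == pytest.approx(1.0, abs=1e-8)

    def test_plain_gpa_rerun_is_idempotent(self, rng):
        X = rng.normal(size=(9, 6, 2))
        est = GeneralizedProcrustes().fit(X)
        est2 = GeneralizedProcrustes().fit(est.coordinates_)
        assert est2.converged_
        assert procrustes_distance(est.mean_shape_, est2.mean_shape_) < 1e-7
        np.testing.assert_allclose(est2.coordinates_, est.coordinates_,
                                   atol=1e-7)

    def test_two_configs_equidistant_from_consensus(self, rng):
        X = rng.normal(size=(2, 8, 2))
        est = GeneralizedProcrustes().fit(X)
        d0 = procrustes_distance(est.coordinates_[0], est.mean_shape_)
        d1 = procrustes_distance(est.coordinates_[1], est.mean_shape_)
        assert d0 == pytest.approx(d1, abs=1e-8)

    def test_ss_non_increasing_with_and_without_sliding(self, rng):
        tmpl, triples = make_template("lateral")
        for use_sliders in (False, True):
            X = np.stack([
                tmpl.points + rng.normal(scale=0.5, size=tmpl.points.shape)
                for _ in range(8)
            ])
            est = GeneralizedProcrustes(
                sliders=triples if use_sliders else None).fit(X)
            assert np.all(np.diff(est.ss_history_) <= 1e-10)

    def test_alignment_invariant_to_rigid_nuisance(self, rng):
        tmpl, triples = make_template("dorsal")
        X = np.stack([
            tmpl.points + rng.normal(scale=0.3, size=tmpl.points.shape)
            for _ in range(12)
        ])
        est = GeneralizedProcrustes(sliders=triples).fit(X)
        Xn = np.stack([similarity_transform(rng, x) for x in X])
        est_n = GeneralizedProcrustes(sliders=triples).fit(Xn)
        np.testing.assert_allclose(est_n.coordinates_, est.coordinates_, atol=1e-6)

    def test_transform_aligns_new_specimens(self, rng):
        X = rng.normal(size=(10, 6, 2))
        est = GeneralizedProcrustes().fit(X)
        new = similarity_transform(rng, X[3])
        aligned = est.transform(new[None])[0]
        np.testing.assert_allclose(aligned, est.coordinates_[3], atol=1e-6)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            GeneralizedProcrustes().fit(rng.normal(size=(1, 5, 2)))
        with pytest.raises(ValueError, match="slider index"):
            GeneralizedProcrustes(sliders=[(0, 99, 1)]).fit(
                rng.normal(size=(3, 5, 2)))


class TestConfigurationWrappers:
    def test_gpa_align_rejects_mixed_structures(self, rng):
        a = random_configuration(rng, k_fixed=4, curve_sizes=(3,))
        b = random_configuration(rng, k_fixed=4, curve_sizes=(2,), specimen_id="s2")
        with pytest.raises(ValueError, match="point structure"):
            gpa_align([a, b])

    def test_centroid_sizes_preserved_in_mm(self, rng):
        configs = [random_configuration(rng, specimen_id=f"s{i}") for i in range(4)]
        aligned = gpa_align(configs)
        for cfg, size in zip(configs, aligned.centroid_sizes):
            assert size == pytest.approx(centroid_size(cfg.points), abs=1e-9)

    def test_species_means_arithmetic(self, rng):
        configs = [
            random_configuration(rng, specimen_id=f"s{i}",
                                 species=f"sp{i // 2}", family="F")
            for i in range(6)
        ]
        aligned = gpa_align(configs)
        sms = species_means(aligned, table_for(configs))
        assert sms.species == ["sp0", "sp1", "sp2"]
        np.testing.assert_allclose(
            sms.mean_coordinates[1],
            aligned.coordinates[2:4].mean(axis=0), atol=1e-12)

    def test_single_specimen_species_pass_through(self, rng):
        configs = [
            random_configuration(rng, specimen_id=f"s{i}", species=f"sp{i}")
            for i in range(3)
        ]
        aligned = gpa_align(configs)
        sms = species_means(aligned, table_for(configs))
        np.testing.assert_allclose(sms.mean_coordinates, aligned.coordinates,
                                   atol=1e-12)

    def test_missing_specimen_raises(self, rng):
        configs = [random_configuration(rng, specimen_id=f"s{i}") for i in range(3)]
        table = table_for(configs).iloc[:2]
        aligned = gpa_align(configs)
        with pytest.raises(KeyError, match="missing"):
            species_means(aligned, table)
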