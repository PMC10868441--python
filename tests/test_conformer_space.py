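"""Conformer-space distances, ensemble width and similarity."""

import numpy as np
import pytest

from ensemblekit.conformer_space import (
    distance_matrix, drmsd, ensemble_msd, internal_distance_vectors,
    shannon_entropy, similarity, similarity_matrix,
)
from ensemblekit.generator import GeneratorConfig, RamachandranLibrary, Basin, generate_ensemble
from ensemblekit.io import CATrace, ca_trace

from conftest import random_weights


def brute_force_drmsd(a, b):
    n = len(a)
    acc = 0.0
    pairs = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            da = np.linalg.norm(a[i] - a[j])
            db = np.linalg.norm(b[i] - b[j])
            acc += (da - db) ** 2
            pairs += 1
    return np.sqrt(acc / pairs)


class TestEntropy:
    @pytest.mark.parametrize("weights, expected", [
        ([1.0], 0.0),
        (np.full(10, 0.1), 1.0),
        ([0.5, 0.25, 0.25], 0.45154499349597177),
    ])
    def test_values(self, weights, expected):
        assert shannon_entropy(weights) == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.5, 0.4])


class TestDRMSD:
    def test_identical_zero(self, small_trace):
        assert drmsd(small_trace.coordinates[0],
                     small_trace.coordinates[0]) == 0.0

    def test_rigid_motion_and_reflection_invariance(self, small_trace):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        a = small_trace.coordinates[0]
        b = small_trace.coordinates[1]
        moved = b @ q.T + np.array([1.0, 2.0, 3.0])  # q may be improper
        assert drmsd(a, moved) == pytest.approx(drmsd(a, b), abs=1e-9)
        assert drmsd(b, moved) == pytest.approx(0.0, abs=1e-9)

    def test_three_residue_toy_matches_brute_force(self):
        a = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], float)
        b = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0]], float)
        assert drmsd(a, b) == pytest.approx(brute_force_drmsd(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            drmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_triangle_inequality_on_random_triples(self, small_trace):
        rng = np.random.default_rng(0)
        coords = small_trace.coordinates
        for _ in range(50):
            i, j, k = rng.integers(0, coords.shape[0], 3)
            dij = drmsd(coords[i], coords[j])
            djk = drmsd(coords[j], coords[k])
            dik = drmsd(coords[i], coords[k])
            assert dik <= dij + djk + 1e-9


class TestDistanceMatrix:
    def test_duplicate_conformers_zero(self, small_trace):
        c = small_trace.coordinates[0]
        dm = distance_matrix([CATrace(np.stack([c, c]), [0.5, 0.5])])
        np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_two_singletons_off_diagonal(self, small_trace):
        a, b = small_trace.coordinates[:2]
        dm = distance_matrix([CATrace(a[None], [1.0]),
                              CATrace(b[None], [1.0])])
        assert dm.values[0, 1] == pytest.approx(drmsd(a, b), abs=1e-12)

    def test_matches_naive_double_loop(self, small_trace):
        coords = small_trace.coordinates[:4]
        dm = distance_matrix([CATrace(coords, np.full(4, 0.25))])
        naive = np.array([[brute_force_drmsd(coords[i], coords[j])
                           for j in range(4)] for i in range(4)])
        np.testing.assert_allclose(dm.values, naive, atol=1e-9)
        assert np.allclose(dm.values, dm.values.T, atol=1e-9)

    def test_unequal_length_rejected(self, small_trace):
        short = CATrace(small_trace.coordinates[:1, :-1], [1.0])
        with pytest.raises(ValueError, match="residue count"):
            distance_matrix([small_trace, short])


class TestEnsembleMSD:
    def test_singleton_width_zero(self, small_trace):
        dm = distance_matrix([CATrace(small_trace.coordinates[:1], [1.0])])
        assert ensemble_msd(dm, 0, 0) == 0.0

    def test_two_singletons_squared_drmsd(self, small_trace):
        a, b = small_trace.coordinates[:2]
        dm = distance_matrix([CATrace(a[None], [1.0]),
                              CATrace(b[None], [1.0])])
        assert ensemble_msd(dm, 0, 1) == pytest.approx(drmsd(a, b) ** 2)

    def test_euclidean_decomposition(self, ensemble_pair):
        """Delta_kl = Delta_kk/2 + Delta_ll/2 + |mu_k - mu_l|^2 exactly."""
        e1, e2 = ensemble_pair
        t1, t2 = ca_trace(e1), ca_trace(e2)
        t1.weights = random_weights(t1.n_conformers, 1)
        t2.weights = random_weights(t2.n_conformers, 2)
        dm = distance_matrix([t1, t2])
        d_kl = ensemble_msd(dm, 0, 1)
        d_kk = ensemble_msd(dm, 0, 0)
        d_ll = ensemble_msd(dm, 1, 1)
        mu1 = t1.weights @ internal_distance_vectors(t1.coordinates)
        mu2 = t2.weights @ internal_distance_vectors(t2.coordinates)
        expected = 0.5 * d_kk + 0.5 * d_ll + np.sum((mu1 - mu2) ** 2)
        assert d_kl == pytest.approx(expected, rel=1e-9)

    def test_conformer_permutation_invariance(self, small_trace):
        w = random_weights(small_trace.n_conformers, 3)
        t = CATrace(small_trace.coordinates, w)
        perm = np.random.default_rng(4).permutation(t.n_conformers)
        tp = CATrace(small_trace.coordinates[perm], w[perm])
        dm = distance_matrix([t, t])
        dmp = distance_matrix([tp, tp])
        assert ensemble_msd(dm, 0, 0) == pytest.approx(
            ensemble_msd(dmp, 0, 0), rel=1e-12)


class TestSimilarity:
    def test_distinct_singletons_zero(self, small_trace):
        a, b = small_trace.coordinates[:2]
        dm = distance_matrix([CATrace(a[None], [1.0]),
                              CATrace(b[None], [1.0])])
        assert similarity(dm, 0, 1).s == 0.0

    def test_identical_ensembles_one(self, small_trace):
        dm = distance_matrix([small_trace, small_trace])
        assert similarity(dm, 0, 1).s == pytest.approx(1.0, abs=1e-12)

    def test_bounded_and_matches_decomposition(self, ensemble_pair):
        e1, e2 = ensemble_pair
        t1, t2 = ca_trace(e1), ca_trace(e2)
        dm = distance_matrix([t1, t2])
        r = similarity(dm, 0, 1)
        assert 0.0 <= r.s <= 1.0 + 1e-12
        mu1 = t1.weights @ internal_distance_vectors(t1.coordinates)
        mu2 = t2.weights @ internal_distance_vectors(t2.coordinates)
        d_kl = (0.5 * r.delta_kk + 0.5 * r.delta_ll
                + np.sum((mu1 - mu2) ** 2))
        assert r.s == pytest.approx(
            np.sqrt(r.delta_kk * r.delta_ll) / d_kl, rel=1e-9)


class TestSimilarityMatrix:
    def test_duplicate_list_all_ones(self, small_ensemble):
        s, _ = similarity_matrix([small_ensemble, small_ensemble])
        np.testing.assert_allclose(s, 1.0, atol=1e-12)

    def test_family_structure_orders_similarity(self):
        """Same-library ensembles are more alike than a shifted library."""
        seq = "ASGTPLKQEDGYSNH"
        shifted = RamachandranLibrary({
            "general": [Basin(1.0, -63.0, -43.0, 10.0, 10.0)],  # helix only
            "G": [Basin(1.0, -63.0, -43.0, 15.0, 15.0)],
            "P": [Basin(1.0, -65.0, -35.0, 10.0, 10.0)],
            "T": [Basin(1.0, -63.0, -43.0, 10.0, 10.0)],
        })
        e1 = generate_ensemble(GeneratorConfig(sequence=seq, n_conformers=20,
                                               seed=11))
        e2 = generate_ensemble(GeneratorConfig(sequence=seq, n_conformers=20,
                                               seed=12))
        e3 = generate_ensemble(GeneratorConfig(sequence=seq, n_conformers=20,
                                               seed=13, library=shifted))
        s, _ = similarity_matrix([e1, e2, e3])
        assert s[0, 1] > s[0, 2]
        assert s[0, 1] > s[1, 2]
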