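"""Elastic network construction, Hessian, spectrum, B-factors, calibration."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.linalg import pinv
from scipy.spatial.transform import Rotation

from modewire.enm import (
    build_hessian,
    build_network,
    calc_bfactors,
    calibrate_cutoff,
    compute_modes,
    network_energy,
)
from modewire.exceptions import ModeError, NetworkError
from modewire.structures import StructureModel
from modewire.synthetic import make_chain, _fcc_cluster, _model


def two_nodes(distance):
    return _model(np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
                  ["A", "A"])


class TestBuildNetwork:
    def test_pair_within_cutoff_contacts_with_reference_distance(self):
        network = build_network(two_nodes(5.0), rc=9.0)
        assert network.n_contacts == 1
        assert network.reference_distances[0] == pytest.approx(5.0)

    def test_cutoff_is_strict_upper_bound(self):
        assert build_network(two_nodes(9.5), rc=9.0).n_contacts == 0
        assert build_network(two_nodes(9.0), rc=9.0).n_contacts == 0

    def test_contacts_match_brute_force_all_pairs(self):
        model = make_chain(50, jitter=0.6, seed=9)
        network = build_network(model, rc=9.0)
        got = {tuple(c) for c in network.contacts}
        expected = set()
        for i in range(50):
            for j in range(i + 1, 50):
                if np.linalg.norm(model.coords[i] - model.coords[j]) < 9.0:
                    expected.add((i, j))
        assert got == expected

    def test_coincident_nodes_rejected(self):
        model = _model(np.zeros((2, 3)), ["A", "A"])
        with pytest.raises(NetworkError, match="coincident"):
            build_network(model, rc=9.0)


class TestBuildHessian:
    def test_two_nodes_on_x_axis_closed_form(self):
        h = build_hessian(build_network(two_nodes(5.0), rc=9.0))
        xx = h[np.ix_([0, 3], [0, 3])]
        np.testing.assert_allclose(xx, [[1.0, -1.0], [-1.0, 1.0]])
        mask = np.ones_like(h, dtype=bool)
        mask[np.ix_([0, 3], [0, 3])] = False
        assert np.all(h[mask] == 0.0)

    def test_block_rows_sum_to_zero(self, coil_network):
        h = build_hessian(coil_network)
        n = coil_network.n_nodes
        blocks = h.reshape(n, 3, n, 3)
        np.testing.assert_allclose(blocks.sum(axis=2), 0.0, atol=1e-12)

    def test_matches_finite_difference_of_energy(self, coil_network):
        h = build_hessian(coil_network)
        x0 = coil_network.model.coords
        eps = 1e-4
        n3 = 3 * coil_network.n_nodes
        fd = np.zeros((n3, n3))
        for a in range(n3):
            for b in range(a, n3):
                da = np.zeros(n3)
                db = np.zeros(n3)
                da[a] = eps
                db[b] = eps

                def e(v):
                    return network_energy(coil_network,
                                          x0 + v.reshape(-1, 3))

                fd[a, b] = fd[b, a] = (
                    e(da + db) - e(da - db) - e(db - da) + e(-da - db)
                ) / (4 * eps ** 2)
        np.testing.assert_allclose(h, fd, atol=1e-5)

    def test_energy_zero_at_reference(self, coil_network):
        assert network_energy(coil_network, coil_network.model.coords) == 0.0


class TestComputeModes:
    def test_two_body_stretch_eigenvalue_is_two_gamma(self):
        for gamma in (1.0, 2.5):
            network = build_network(two_nodes(5.0), rc=9.0, gamma=gamma)
            modes = compute_modes(build_hessian(network))
            assert modes.n_zero == 5  # 2 nodes: 3 translations + 2 rotations
            nonzero = modes.eigenvalues[modes.eigenvalues
                                        > 1e-8 * modes.eigenvalues[-1]]
            assert len(nonzero) == 1
            assert nonzero[0] == pytest.approx(2.0 * gamma)

    def test_connected_tetrahedron_has_six_zero_modes(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [1.9, 3.3, 0],
                           [1.9, 1.1, 3.1]], dtype=float)
        modes = compute_modes(build_hessian(
            build_network(_model(coords, ["A"] * 4), rc=9.0)))
        assert modes.n_zero == 6

    def test_disjoint_clusters_give_twelve_zero_modes_and_warning(self):
        rng = np.random.default_rng(1)
        far = np.vstack([_fcc_cluster(8, rng),
                         _fcc_cluster(8, rng) + [50.0, 0, 0]])
        modes = compute_modes(build_hessian(
            build_network(_model(far, ["A"] * 16), rc=9.0)))
        assert modes.n_zero == 12
        assert any("disconnected" in w for w in modes.warnings)

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ModeError, match="symmetric"):
            compute_modes(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_rayleigh_quotients_reproduce_eigenvalues(self, coil_network,
                                                      coil_modes):
        h = build_hessian(coil_network)
        for m in (1, 7, coil_modes.n_modes):
            q = coil_modes.eigenvectors[:, m - 1]
            lam = coil_modes.eigenvalues[m - 1]
            assert q @ h @ q == pytest.approx(
                lam, abs=1e-8 * coil_modes.eigenvalues[-1])

    def test_zero_mode_displacement_costs_no_energy(self, coil_network,
                                                    coil_modes):
        for m in range(coil_modes.n_zero):
            disp = 1e-3 * coil_modes.eigenvectors[:, m].reshape(-1, 3)
            energy = network_energy(coil_network,
                                    coil_network.model.coords + disp)
            assert energy <= 1e-12 * coil_network.gamma

    def test_spectrum_invariant_under_rotation(self, coil):
        rng = np.random.default_rng(11)
        r = Rotation.random(random_state=rng).as_matrix()
        rotated = replace(coil, coords=coil.coords @ r.T)
        lam_a = compute_modes(build_hessian(build_network(coil, rc=9.0))
                              ).eigenvalues
        lam_b = compute_modes(build_hessian(build_network(rotated, rc=9.0))
                              ).eigenvalues
        np.testing.assert_allclose(lam_a, lam_b,
                                   atol=1e-8 * max(lam_a[-1], 1))

    def test_gamma_scaling_scales_eigenvalues_not_vectors(self, coil):
        m1 = compute_modes(build_hessian(build_network(coil, gamma=1.0)))
        m2 = compute_modes(build_hessian(build_network(coil, gamma=2.0)))
        np.testing.assert_allclose(m2.eigenvalues, 2 * m1.eigenvalues,
                                   atol=1e-10 * m2.eigenvalues[-1])
        # deterministic sign fixing makes columns comparable directly
        np.testing.assert_allclose(
            np.abs(m2.eigenvectors[:, m2.n_zero:]),
            np.abs(m1.eigenvectors[:, m1.n_zero:]), atol=1e-6)

    def test_eigenvectors_orthonormal(self, coil_modes):
        v = coil_modes.eigenvectors
        gram = v.T @ v
        assert np.max(np.abs(gram - np.eye(v.shape[1]))) < 1e-8


class TestBFactors:
    def test_two_node_symmetry(self):
        network = build_network(two_nodes(5.0), rc=9.0)
        b = calc_bfactors(compute_modes(build_hessian(network)))
        assert b[0] == pytest.approx(b[1])

    def test_terminal_beads_exceed_central_in_helical_chain(self):
        # a helix is the 3-D analogue of a bead chain with a
        # well-conditioned spectrum (a straight chain has zero-stiffness
        # transverse modes); ends are less constrained, so they fluctuate
        # more than the middle
        t = np.arange(20) * 1.75
        coords = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t),
                                  1.5 * t / 1.75])
        model = _model(coords, ["A"] * 20)
        modes = compute_modes(build_hessian(build_network(model, rc=9.0)))
        assert modes.n_zero == 6
        b = calc_bfactors(modes)
        assert b[0] > b[9] and b[-1] > b[10]

    def test_matches_hessian_pseudoinverse_trace(self, coil_network,
                                                 coil_modes):
        b = calc_bfactors(coil_modes)
        g = pinv(build_hessian(coil_network), rtol=1e-10)
        oracle = np.trace(
            g.reshape(coil_network.n_nodes, 3, coil_network.n_nodes, 3),
            axis1=1, axis2=3).diagonal()
        oracle = oracle / oracle.mean()
        np.testing.assert_allclose(b, oracle, atol=1e-6)


@pytest.fixture(scope="module")
def blob():
    rng = np.random.default_rng(13)
    return _model(_fcc_cluster(60, rng), ["A"] * 60)


class TestCalibrateCutoff:
    def test_self_consistent_bfactors_peak_at_generating_cutoff(self, blob):
        modes = compute_modes(build_hessian(build_network(blob, rc=9.0)))
        b = calc_bfactors(modes)
        table = calibrate_cutoff(replace(blob, bfactors=b), [7, 9, 13])
        row9 = table[table.rc == 9].iloc[0]
        assert row9.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_noisy_bfactors_still_recover_generating_cutoff(self, blob):
        modes = compute_modes(build_hessian(build_network(blob, rc=9.0)))
        b = calc_bfactors(modes)
        rng = np.random.default_rng(21)
        noisy = b * (1.0 + 0.15 * rng.normal(size=b.size))
        table = calibrate_cutoff(replace(blob, bfactors=noisy),
                                 [7, 8, 9, 11, 13])
        best = table.loc[table.pearson_r.idxmax()]
        assert best.rc == 9
        assert best.pearson_r < 1.0

    def test_disconnecting_cutoff_flagged(self, blob):
        b = np.linspace(1, 2, 60)
        table = calibrate_cutoff(replace(blob, bfactors=b), [2.0, 9.0])
        assert bool(table[table.rc == 2.0].iloc[0].disconnected)
        assert not bool(table[table.rc == 9.0].iloc[0].disconnected)

    def test_constant_experimental_bfactors_error(self, blob):
        with pytest.raises(ModeError, match="constant"):
            calibrate_cutoff(replace(blob, bfactors=np.ones(60)), [9.0])
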