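"""Elastic-network construction, Hessian correctness, mode spectra and
rotation-axis extraction, each checked against an independent route
(brute-force thresholding, central-difference derivatives, a second dense
eigensolver, planted-hinge ground truth)."""

import numpy as np
import pytest

from capflex import (
    CaModel,
    ResidueKey,
    axis_angle_between,
    build_hessian,
    build_network,
    extract_rotation_axes,
    generate_two_domain_pair,
    mode_displacements,
    solve_modes,
)
from capflex.enm import (
    DisplacementField,
    ElasticNetwork,
    InsufficientAnchorError,
    NotPositiveSemidefiniteError,
    network_energy,
)
from capflex.synthetic import PlantedMotion

from conftest import random_model, random_rotation


def _model(coords, chain_id="A"):
    coords = np.asarray(coords, dtype=float)
    return CaModel(
        name="m",
        residues=[ResidueKey(chain_id, i + 1) for i in range(len(coords))],
        coords=coords,
    )


def _two_atom_network(dist=5.0, C=1.0):
    model = _model([[0.0, 0.0, 0.0], [dist, 0.0, 0.0]])
    return ElasticNetwork(model=model, cutoff=dist + 1, spring_constant=C,
                          edges=np.array([[0, 1]]), connected=True)


class TestNetwork:
    def test_close_pair_has_edge(self):
        model = _model([[0, 0, 0], [5, 0, 0], [100, 100, 100]])
        net = build_network(model, cutoff=12.0)
        assert [0, 1] in net.edges.tolist()
        assert not net.connected  # third atom is isolated

    def test_far_pair_has_no_edge(self):
        model = _model([[0, 0, 0], [15, 0, 0], [30, 0, 0]])
        net = build_network(model, cutoff=12.0)
        assert len(net.edges) == 0
        assert not net.connected

    def test_edges_match_brute_force(self):
        model = random_model(30, seed=1, spread=12.0)
        net = build_network(model, cutoff=10.0)
        expected = {
            (i, j)
            for i in range(30) for j in range(i + 1, 30)
            if np.linalg.norm(model.coords[i] - model.coords[j]) < 10.0
        }
        assert {tuple(e) for e in net.edges.tolist()} == expected


class TestHessian:
    def test_two_atom_closed_form(self):
        H = build_hessian(_two_atom_network())
        # springs along x: the xx sub-block is [[1,-1],[-1,1]], all else 0
        xx = H[np.ix_([0, 3], [0, 3])]
        np.testing.assert_allclose(xx, [[1, -1], [-1, 1]], atol=1e-12)
        rest = H.copy()
        rest[np.ix_([0, 3], [0, 3])] = 0
        assert np.abs(rest).max() == 0
        evals = np.linalg.eigvalsh(H)
        np.testing.assert_allclose(sorted(evals), [0, 0, 0, 0, 0, 2],
                                   atol=1e-12)

    def test_matches_numerical_second_derivatives(self):
        model = random_model(5, seed=2, spread=6.0)
        net = build_network(model, cutoff=12.0)
        H = build_hessian(net)
        x0 = model.coords.ravel()
        h = 1e-4
        n = x0.size
        H_num = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                xpp = x0.copy(); xpp[i] += h; xpp[j] += h
                xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
                xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
                xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
                val = (network_energy(net, xpp) - network_energy(net, xpm)
                       - network_energy(net, xmp) + network_energy(net, xmm)
                       ) / (4 * h * h)
                H_num[i, j] = H_num[j, i] = val
        np.testing.assert_allclose(H, H_num, atol=1e-5)

    def test_spring_constant_scales_eigenvalues_only(self):
        model = random_model(8, seed=3, spread=6.0)
        H1 = build_hessian(build_network(model, cutoff=12.0,
                                         spring_constant=1.0))
        H10 = build_hessian(build_network(model, cutoff=12.0,
                                          spring_constant=10.0))
        e1, v1 = np.linalg.eigh(H1)
        e10, v10 = np.linalg.eigh(H10)
        np.testing.assert_allclose(e10, 10.0 * e1, atol=1e-9)
        # eigenvectors span the same eigenspaces: columns agree up to sign
        # where eigenvalues are non-degenerate
        np.testing.assert_allclose(np.abs(np.diag(v1.T @ v10))[9:], 1.0,
                                   atol=1e-6)

    def test_coincident_atoms_raise(self):
        model = _model([[0, 0, 0], [0, 0, 0], [5, 0, 0]])
        net = build_network(model, cutoff=12.0)
        with pytest.raises(ValueError, match="coincident"):
            build_hessian(net)


class TestModes:
    def test_triangle_has_six_rigid_three_internal(self):
        model = _model([[0, 0, 0], [5, 0, 0], [2.5, 4.0, 0]])
        modes = solve_modes(build_hessian(build_network(model, cutoff=12.0)))
        assert modes.n_rigid == 6
        assert modes.lowest_internal_index == 6
        assert (modes.eigenvalues[6:] > 1e-8).all()

    def test_two_atom_single_internal_mode(self):
        C = 3.0
        modes = solve_modes(build_hessian(_two_atom_network(C=C)))
        assert modes.n_rigid == 5
        assert modes.eigenvalues[-1] == pytest.approx(2 * C, abs=1e-10)

    def test_spectrum_matches_second_eigensolver(self):
        model = random_model(10, seed=4, spread=7.0)
        H = build_hessian(build_network(model, cutoff=14.0))
        modes = solve_modes(H)
        np.testing.assert_allclose(modes.eigenvalues, np.linalg.eigvalsh(H),
                                   atol=1e-8)

    def test_negative_eigenvalue_raises(self):
        bad = np.diag([-1.0, 1.0, 2.0])
        with pytest.raises(NotPositiveSemidefiniteError):
            solve_modes(bad)

    def test_rigid_generators_in_null_space(self):
        model = random_model(15, seed=5, spread=6.0)
        H = build_hessian(build_network(model, cutoff=14.0))
        lam_max = np.linalg.eigvalsh(H)[-1]
        center = model.coords.mean(axis=0)
        gens = []
        for k in range(3):  # translations
            g = np.zeros((15, 3)); g[:, k] = 1.0
            gens.append(g.ravel())
        for k in range(3):  # infinitesimal rotations about the centroid
            w = np.zeros(3); w[k] = 1.0
            gens.append(np.cross(w, model.coords - center).ravel())
        for g in gens:
            g = g / np.linalg.norm(g)
            assert g @ H @ g < 1e-8 * lam_max


class TestDisplacements:
    def test_unit_eigenvalue_field_is_eigenvector(self):
        model = _model([[0, 0, 0], [5, 0, 0], [2.5, 4.0, 0]])
        modes = solve_modes(build_hessian(build_network(model, cutoff=12.0)))
        k = modes.lowest_internal_index
        field = mode_displacements(modes, k)
        lam = modes.eigenvalues[k]
        np.testing.assert_allclose(
            field.vectors.ravel() * lam, modes.eigenvectors[:, k], atol=1e-12)

    def test_sum_of_squares_is_inverse_eigenvalue_squared(self):
        model = random_model(12, seed=6, spread=6.0)
        modes = solve_modes(build_hessian(build_network(model, cutoff=14.0)))
        for k in (modes.lowest_internal_index,
                  modes.lowest_internal_index + 3):
            field = mode_displacements(modes, k)
            assert field.squared_magnitudes.sum() == pytest.approx(
                1.0 / modes.eigenvalues[k] ** 2, rel=1e-9)

    def test_rigid_mode_rejected(self):
        model = _model([[0, 0, 0], [5, 0, 0], [2.5, 4.0, 0]])
        modes = solve_modes(build_hessian(build_network(model, cutoff=12.0)))
        with pytest.raises(ValueError, match="rigid"):
            mode_displacements(modes, 0)


class TestAxisExtraction:
    def _field(self, model, sq):
        sq = np.asarray(sq, dtype=float)
        vecs = np.zeros((len(model), 3))
        vecs[:, 0] = np.sqrt(sq)
        return DisplacementField(vectors=vecs, squared_magnitudes=sq,
                                 mode_index=6, eigenvalue=1.0)

    def test_no_residues_below_threshold_raises(self):
        model = random_model(10, seed=7)
        field = self._field(model, np.full(10, 5.0))
        with pytest.raises(InsufficientAnchorError):
            extract_rotation_axes(model, field, threshold=2.0)

    def test_collinear_anchors_give_line_axis(self):
        coords = np.zeros((8, 3))
        coords[:, 2] = np.arange(8) * 4.0  # a line along z
        model = _model(coords)
        sq = np.full(8, 0.5)
        res = extract_rotation_axes(model, self._field(model, sq),
                                    threshold=2.0)
        assert len(res.groups) == 1
        g = res.groups[0]
        assert axis_angle_between(g.axis_direction, [0, 0, 1]) < 1e-9
        assert g.variance_explained == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [11, 29])
    def test_planted_hinge_axis_recovered(self, seed):
        model_a, _, motion = generate_two_domain_pair(
            150, 100, PlantedMotion(angle=10.0, seed=seed))
        net = build_network(model_a)
        modes = solve_modes(build_hessian(net))
        assert modes.n_rigid == 6
        field = mode_displacements(modes, modes.lowest_internal_index)
        res = extract_rotation_axes(model_a, field,
                                    threshold_mode="quantile", quantile=0.15)
        largest = res.groups[0]
        # anchors straddle the seam: residues from both chains appear
        assert axis_angle_between(largest.axis_direction,
                                  motion.axis_direction) <= 15.0


class TestEquivariance:
    def test_rotation_of_model_rotates_modes_and_axes(self):
        rng = np.random.default_rng(8)
        model_a, _, _ = generate_two_domain_pair(
            60, 40, PlantedMotion(angle=10.0, seed=9))
        R = random_rotation(rng)
        rotated = CaModel(name="rot", residues=model_a.residues,
                          coords=model_a.coords @ R.T + rng.normal(size=3) * 5)
        m1 = solve_modes(build_hessian(build_network(model_a)))
        m2 = solve_modes(build_hessian(build_network(rotated)))
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)
        f1 = mode_displacements(m1, m1.lowest_internal_index)
        f2 = mode_displacements(m2, m2.lowest_internal_index)
        a1 = extract_rotation_axes(model_a, f1, threshold_mode="quantile")
        a2 = extract_rotation_axes(rotated, f2, threshold_mode="quantile")
        assert axis_angle_between(
            R @ a1.groups[0].axis_direction,
            a2.groups[0].axis_direction) < 1e-4

    def test_axis_directions_independent_of_spring_constant(self):
        model_a, _, _ = generate_two_domain_pair(
            60, 40, PlantedMotion(angle=10.0, seed=10))
        axes = []
        for C in (1.0, 10.0):
            net = build_network(model_a, spring_constant=C)
            modes = solve_modes(build_hessian(net))
            field = mode_displacements(modes, modes.lowest_internal_index)
            res = extract_rotation_axes(model_a, field,
                                        threshold_mode="quantile")
            axes.append(res.groups[0].axis_direction)
        assert axis_angle_between(axes[0], axes[1]) < 1e-6


class TestAxisAngle:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 0, 0], [1, 0, 0], 0.0),
        ([1, 0, 0], [0, 1, 0], 90.0),
        ([1, 0, 0], [-1, 0, 0], 0.0),
    ])
    def test_known_angles(self, a, b, expected):
        assert axis_angle_between(a, b) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            axis_angle_between([0, 0, 0], [1, 0, 0])
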