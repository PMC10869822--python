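"""Boundary-element solver: Calderon identities, sphere oracles, response
properties and the eigenmode fast path."""

import numpy as np
import pytest

from nanoret.bem import (
    BEMSolver,
    assemble_calderon,
    induced_dipole,
    polarizability_spectrum,
    response_charges,
    response_matrix,
)
from nanoret.dielectric import evaluate_epsilon
from nanoret.fixtures import sphere_polarizability_oracle
from nanoret.meshing import SurfaceMesh, build_sphere
from nanoret.units import BOHR_PER_NM


def two_tessera_mesh(distance_nm):
    """Two small triangles facing +z, separated along x (open surface)."""
    tri = np.array([[0, 0, 0], [0.01, 0, 0], [0, 0.01, 0]], float)
    verts = np.vstack([tri, tri + [distance_nm, 0, 0]])
    faces = np.array([[0, 1, 2], [3, 4, 5]])
    return SurfaceMesh(verts, faces)


def test_single_layer_off_diagonal_is_inverse_distance():
    d_nm = 2.0 / BOHR_PER_NM  # two internal (bohr) units apart
    sys_ = assemble_calderon(two_tessera_mesh(d_nm))
    assert sys_.S[0, 1] == pytest.approx(0.5, rel=1e-9)
    assert np.allclose(sys_.S, sys_.S.T)


def test_double_layer_vanishes_for_orthogonal_geometry():
    # both normals are +z, separation is along x -> (s_i - s_j) . n_j = 0
    sys_ = assemble_calderon(two_tessera_mesh(1.0))
    assert sys_.D[0, 1] == pytest.approx(0.0, abs=1e-14)


def test_calderon_sum_rule_on_sphere(sphere_solver):
    sys_ = sphere_solver.system
    rows = (sys_.D * sys_.areas[None, :]).sum(axis=1)
    assert np.max(np.abs(rows + 2 * np.pi)) < 1e-6


def test_vacuum_limit_gives_zero_response(sphere_solver):
    V = sphere_solver.uniform_field_potential([0, 0, 1])
    q = sphere_solver.solve_charges(1.0 + 1e-12j, V)
    assert np.max(np.abs(q.charges)) < 1e-8 * np.max(np.abs(V))


def test_real_epsilon_gives_real_charges(sphere_solver):
    V = sphere_solver.uniform_field_potential([0, 0, 1])
    q = sphere_solver.solve_charges(5.0, V)
    assert np.max(np.abs(q.charges.imag)) == 0.0


def test_response_linearity(sphere_solver):
    rng = np.random.default_rng(3)
    V1 = rng.normal(size=sphere_solver.system.n)
    V2 = rng.normal(size=sphere_solver.system.n)
    eps = -3.0 + 0.4j
    qa = sphere_solver.solve_charges(eps, 2.0 * V1 + 3.0 * V2).charges
    qb = 2.0 * sphere_solver.solve_charges(eps, V1).charges + 3.0 * sphere_solver.solve_charges(
        eps, V2
    ).charges
    assert np.max(np.abs(qa - qb)) < 1e-12 * np.max(np.abs(qb))


def test_response_matrix_matches_solver_application(sphere_solver):
    """The dense Q and the solve-based application agree."""
    eps = -2.0 + 0.5j
    Q = response_matrix(sphere_solver.system, eps)
    V = sphere_solver.uniform_field_potential([0, 0, 1])
    q_direct = response_charges(Q, V)
    q_solve = sphere_solver.solve_charges(eps, V)
    assert np.max(np.abs(q_direct.charges - q_solve.charges)) < 1e-8 * np.max(
        np.abs(q_solve.charges)
    )


def test_modal_path_agrees_with_dense_path(sphere_solver):
    eps = -4.0 + 0.3j
    rng = np.random.default_rng(5)
    V = rng.normal(size=sphere_solver.system.n)
    qd = sphere_solver.solve_charges(eps, V).charges
    qm = sphere_solver.solve_charges_modal(eps, V).charges
    assert np.max(np.abs(qd - qm)) < 1e-9 * np.max(np.abs(qd))


def test_sphere_polarizability_against_analytic(sphere_solver, drude9):
    """Uniform-field BEM response within 2% of a^3 (eps-1)/(eps+2) across a
    10-point frequency window including the dipolar resonance."""
    V = sphere_solver.uniform_field_potential([0, 0, 1])
    for w in np.linspace(4.5, 5.8, 10):
        eps = evaluate_epsilon(drude9, w)
        q = sphere_solver.solve_charges(eps, V)
        mu = induced_dipole(q, sphere_solver)
        exact = sphere_polarizability_oracle(1.0, eps)
        assert abs(mu[2] - exact) / abs(exact) < 0.02


def test_point_charge_image_potential(sphere_solver):
    """Induced potential of a charge outside a dielectric sphere matches the
    classical multipole image series at an exterior probe point."""
    eps = 4.0
    d, p = 1.8, 2.6  # source and probe on the z axis, in nm
    a_au = 1.0 * BOHR_PER_NM
    d_au, p_au = d * BOHR_PER_NM, p * BOHR_PER_NM
    V = 1.0 / np.linalg.norm(
        (sphere_solver.system.centroids) - np.array([0, 0, d_au]), axis=1
    )
    q = sphere_solver.solve_charges(eps, V)
    probe = np.array([0, 0, p_au])
    phi_bem = np.sum(q.charges.real / np.linalg.norm(sphere_solver.system.centroids - probe, axis=1))
    # independent image/multipole series: beta_n = n(1-eps)/(n eps + n + 1)
    phi_series = sum(
        (n * (1 - eps) / (n * eps + n + 1)) * a_au ** (2 * n + 1) / (d_au ** (n + 1) * p_au ** (n + 1))
        for n in range(1, 80)
    )
    assert phi_bem == pytest.approx(phi_series, rel=0.02)


def test_induced_dipole_of_two_point_charges(sphere_solver):
    from nanoret.bem import ResponseCharges

    sys_ = sphere_solver.system
    # find two tesserae symmetric about the equator along z
    top = int(np.argmax(sys_.centroids[:, 2]))
    bot = int(np.argmin(sys_.centroids[:, 2]))
    charges = np.zeros(sys_.n, dtype=complex)
    charges[top], charges[bot] = 1.0, -1.0
    q = ResponseCharges(omega=0.0, charges=charges)
    mu = induced_dipole(q, sphere_solver)
    sep = sys_.centroids[top] - sys_.centroids[bot]
    assert np.allclose(mu.real, sep, atol=1e-9)
    # zero charges -> zero dipole
    q0 = ResponseCharges(omega=0.0, charges=np.zeros(sys_.n))
    assert np.allclose(induced_dipole(q0, sphere_solver), 0.0)


def test_reciprocity_of_response(sphere_solver):
    rng = np.random.default_rng(11)
    # potentials of two random exterior point charges
    src1 = np.array([0.0, 0.0, 2.5 * BOHR_PER_NM])
    src2 = np.array([1.9 * BOHR_PER_NM, 0.7 * BOHR_PER_NM, -0.9 * BOHR_PER_NM])
    s = sphere_solver.system.centroids
    V1 = 1.0 / np.linalg.norm(s - src1, axis=1)
    V2 = 1.0 / np.linalg.norm(s - src2, axis=1)
    eps = -6.0 + 0.8j
    a = V2 @ sphere_solver.solve_charges(eps, V1).charges
    b = V1 @ sphere_solver.solve_charges(eps, V2).charges
    assert abs(a - b) / abs(a) < 0.02


def test_frequency_cache_is_bit_identical(sphere_solver):
    V = sphere_solver.uniform_field_potential([1, 0, 0])
    eps = -7.7 + 0.2j
    q1 = sphere_solver.solve_charges(eps, V).charges
    q2 = sphere_solver.solve_charges(eps, V).charges
    assert np.array_equal(q1, q2)


def test_drude_sphere_spectrum_peak(sphere_solver, drude9):
    om = np.arange(4.9, 5.5, 0.01)
    _, alpha, peak = polarizability_spectrum(sphere_solver, drude9, om)
    assert abs(peak - 9.0 / np.sqrt(3)) <= 0.0100001


def test_spectrum_rejects_unsorted_grid(sphere_solver, drude9):
    with pytest.raises(ValueError):
        polarizability_spectrum(sphere_solver, drude9, [2.0, 1.0, 3.0])


def test_net_charge_neutrality_diagnostic(sphere_solver):
    V = sphere_solver.uniform_field_potential([0, 0, 1])
    q = sphere_solver.solve_charges(-2.0 + 0.5j, V)
    assert q.net_charge_fraction() < 1e-2
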