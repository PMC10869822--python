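"""Transition potentials, Coulomb/metal-mediated couplings, overlap term and
the golden-rule transfer rate."""

import numpy as np
import pytest

from nanoret.dielectric import evaluate_epsilon
from nanoret.emitters import (
    Emitter,
    ProximityError,
    coulomb_coupling,
    eet_rate,
    metal_mediated_coupling,
    overlap_term,
    potential_at,
)
from nanoret.fixtures import gaussian_blob_grid, make_synthetic_emitter
from nanoret.units import BOHR_PER_NM, HARTREE_EV, HBAR_EVS


def point_dipole(label, pos_nm, dipole, omega=2.0):
    return Emitter(label=label, position=np.asarray(pos_nm, float), omega=omega,
                   dipole=np.asarray(dipole, float))


def monopole_pair(sep_nm, q=1.0, center=(0, 0, 0), axis=(0, 0, 1)):
    """Two opposite charges straddling `center`: dipole = q * sep (a.u.)."""
    axis = np.asarray(axis, float)
    h = 0.5 * sep_nm * axis
    pts = np.array([np.asarray(center) + h, np.asarray(center) - h])
    charges = np.array([q, -q])
    dip = charges @ (pts * BOHR_PER_NM)
    return Emitter(label="pair", position=np.asarray(center, float), omega=2.0,
                   dipole=dip, monopole_positions=pts, monopole_charges=charges)


class TestPotential:
    def test_single_charge_coulomb_value(self):
        # +1/-1 pair with the negative charge far away: V ~ 1/r near the + one
        em = monopole_pair(200.0 / BOHR_PER_NM, center=(0, 0, 0))
        probe = em.monopole_positions[0] + np.array([1.0 / BOHR_PER_NM, 0, 0])
        v = potential_at(em, [probe])[0]
        assert v == pytest.approx(1.0, rel=1e-2)

    def test_charge_pair_matches_point_dipole_far_away(self):
        sep = 0.05
        em = monopole_pair(sep)
        dip = point_dipole("d", (0, 0, 0), em.dipole)
        probe = np.array([[0.0, 0.0, 100 * sep]])
        vm = potential_at(em, probe)[0]
        vd = potential_at(dip, probe)[0]
        assert vm == pytest.approx(vd, rel=1e-3)

    def test_gaussian_grid_far_field_matches_point_dipole(self):
        grid = gaussian_blob_grid((0, 0, 0), sigma=0.1, dipole=[0, 0, 2.0],
                                  half_extent=0.45, n=31)
        em = Emitter("g", np.zeros(3), 2.0, grid.dipole_au(), grid=grid)
        dip = point_dipole("d", (0, 0, 0), grid.dipole_au())
        probe = np.array([[0.0, 0.0, 3.0]])
        assert potential_at(em, probe)[0] == pytest.approx(
            potential_at(dip, probe)[0], rel=5e-3
        )

    def test_singular_evaluation_raises(self):
        em = monopole_pair(0.5)
        with pytest.raises(ProximityError):
            potential_at(em, [em.monopole_positions[0]])


class TestCoulombCoupling:
    def test_parallel_perpendicular_dipoles_kappa_one(self):
        R_nm = 1.0
        mu = 1.5
        d1 = point_dipole("d", (0, 0, 0), (0, 0, mu))
        d2 = point_dipole("a", (R_nm, 0, 0), (0, 0, mu))
        v = coulomb_coupling(d1, d2)
        R = R_nm * BOHR_PER_NM
        assert v == pytest.approx(mu * mu / R**3 * HARTREE_EV, rel=1e-12)

    def test_head_to_tail_collinear_dipoles(self):
        R_nm = 1.3
        d1 = point_dipole("d", (0, 0, 0), (2.0, 0, 0))
        d2 = point_dipole("a", (R_nm, 0, 0), (1.0, 0, 0))
        R = R_nm * BOHR_PER_NM
        assert coulomb_coupling(d1, d2) == pytest.approx(-2 * 2.0 / R**3 * HARTREE_EV, rel=1e-12)

    def test_orientation_factor_sweep(self):
        """V R^3/(mu_D mu_A) = sin tD sin tA cos phi - 2 cos tD cos tA."""
        R_nm = 2.0
        R = R_nm * BOHR_PER_NM
        for td in (0.0, 0.4, 1.1, np.pi / 2):
            for ta in (0.2, 0.9, np.pi / 2):
                for phi in (0.0, 0.7, np.pi):
                    # separation along z; azimuth phi between in-plane parts
                    mu_d = np.array([np.sin(td), 0.0, np.cos(td)])
                    mu_a = np.array(
                        [np.sin(ta) * np.cos(phi), np.sin(ta) * np.sin(phi), np.cos(ta)]
                    )
                    d1 = point_dipole("d", (0, 0, 0), mu_d)
                    d2 = point_dipole("a", (0, 0, R_nm), mu_a)
                    kappa = np.sin(td) * np.sin(ta) * np.cos(phi) - 2 * np.cos(td) * np.cos(ta)
                    v_expected = kappa / R**3 * HARTREE_EV
                    assert coulomb_coupling(d1, d2) == pytest.approx(v_expected, abs=1e-15 + 1e-10 * abs(v_expected))

    def test_symmetry_between_representations(self):
        mono = make_synthetic_emitter([1.0, 0.5, 0], 0.3, 16, seed=2, position=(0, 0, 0))
        dip = point_dipole("a", (2.0, 0.3, 0), (0.5, 1.0, 0))
        assert coulomb_coupling(mono, dip) == pytest.approx(coulomb_coupling(dip, mono), rel=1e-12)
        mono2 = make_synthetic_emitter([0, 1.2, 0], 0.3, 16, seed=3, position=(2.0, 0, 0))
        assert coulomb_coupling(mono, mono2) == pytest.approx(
            coulomb_coupling(mono2, mono), rel=1e-12
        )

    def test_monopole_sets_converge_to_dipole_dipole(self):
        """At R = 30 a.u. monopole sets agree with the dipole formula within
        5%, improving as R grows."""
        R30 = 30.0 / BOHR_PER_NM
        errs = []
        for R_nm in (R30, 2 * R30, 4 * R30):
            m1 = make_synthetic_emitter([2.0, 0, 0], 0.15, 20, seed=4)
            m2 = make_synthetic_emitter([2.0, 0, 0], 0.15, 20, seed=5,
                                        position=(R_nm, 0, 0))
            d1 = point_dipole("d", (0, 0, 0), (2.0, 0, 0))
            d2 = point_dipole("a", (R_nm, 0, 0), (2.0, 0, 0))
            vm, vd = coulomb_coupling(m1, m2), coulomb_coupling(d1, d2)
            errs.append(abs(vm - vd) / abs(vd))
        assert errs[0] < 0.05
        assert errs[2] < errs[0]


class TestOverlapTerm:
    def test_disjoint_supports_give_exact_zero(self):
        g1 = gaussian_blob_grid((0, 0, 0), 0.1, [1, 0, 0], 0.3, n=15)
        g2 = gaussian_blob_grid((5, 0, 0), 0.1, [1, 0, 0], 0.3, n=15)
        e1 = Emitter("a", np.zeros(3), 2.0, g1.dipole_au(), grid=g1)
        e2 = Emitter("b", np.array([5.0, 0, 0]), 2.0, g2.dipole_au(), grid=g2)
        assert overlap_term(e1, e2, 2.0) == 0.0

    def test_identical_gaussian_self_overlap_closed_form(self):
        """For rho(r) = C x exp(-r^2/2s^2), INT rho^2 = C^2 s^2 (pi s^2)^{3/2}."""
        sigma = 0.12
        g = gaussian_blob_grid((0, 0, 0), sigma, [2.0, 0, 0], 0.55, n=45)
        e = Emitter("g", np.zeros(3), 2.0, g.dipole_au(), grid=g)
        w0 = 2.0
        got = overlap_term(e, e, w0)
        # closed form with the grid's own normalization constant
        s_au = sigma * BOHR_PER_NM
        # recover C from the dipole: mu = C INT x^2 exp(-r^2/2s^2) = C s^2 (2 pi)^{3/2} s^3
        C = 2.0 / (s_au**2 * (2 * np.pi) ** 1.5 * s_au**3)
        # INT rho^2 = C^2 INT x^2 exp(-r^2/s^2) = C^2 (s^2/2) (pi s^2)^{3/2}
        expected = -w0 * C**2 * (s_au**2 / 2.0) * (np.pi * s_au**2) ** 1.5
        assert got == pytest.approx(expected, rel=5e-3)

    def test_molecule_scale_overlap_negligible_vs_coulomb(self):
        """Dexter-like density-overlap term is orders of magnitude below the
        Coulomb term at >= 1.6 nm centre separation."""
        sigma, sep = 0.4, 1.6
        g1 = gaussian_blob_grid((0, 0, 0), sigma, [2.0, 0, 0], 1.3, n=27)
        g2 = gaussian_blob_grid((sep, 0, 0), sigma, [2.0, 0, 0], 1.3, n=27)
        e1 = Emitter("d", np.zeros(3), 2.11, g1.dipole_au(), grid=g1)
        e2 = Emitter("a", np.array([sep, 0, 0]), 2.02, g2.dipole_au(), grid=g2)
        d1 = point_dipole("d", (0, 0, 0), g1.dipole_au())
        d2 = point_dipole("a", (sep, 0, 0), g2.dipole_au())
        v_c = coulomb_coupling(d1, d2)
        v_o = overlap_term(e1, e2, 2.11)
        assert abs(v_o) / abs(v_c) < 1e-4


class TestMetalMediatedCoupling:
    def test_vacuum_metal_gives_zero(self, sphere_solver):
        d = point_dipole("d", (0, 0, 2.0), (1, 0, 0))
        a = point_dipole("a", (1.5, 0, 2.0), (1, 0, 0))
        v = metal_mediated_coupling(d, a, sphere_solver, 2.0, eps=1.0 + 1e-14j)
        assert abs(v) < 1e-10

    def test_donor_acceptor_exchange_reciprocity(self, sphere_solver):
        eps = -8.0 + 0.6j
        d = point_dipole("d", (0, 0, 1.8), (1, 0, 0))
        a = point_dipole("a", (1.4, 0.3, -1.6), (0, 1, 0))
        v1 = metal_mediated_coupling(d, a, sphere_solver, 2.0, eps=eps)
        v2 = metal_mediated_coupling(a, d, sphere_solver, 2.0, eps=eps)
        assert abs(v1 - v2) / abs(v1) < 0.02

    def test_small_sphere_matches_point_polarizability_model(self):
        """Two dipoles flanking a small sphere: Vmet equals the scattered
        field of the sphere's point polarizability within 5%."""
        from nanoret.bem import BEMSolver
        from nanoret.meshing import build_sphere

        a_nm, eps = 0.35, 6.0
        solver = BEMSolver(build_sphere(a_nm, 3))
        zd, za = 2.2, -2.6  # nm, on the z axis
        mu = 1.0
        d = point_dipole("d", (0, 0, zd), (0, 0, mu))
        a = point_dipole("a", (0, 0, za), (0, 0, mu))
        v = metal_mediated_coupling(d, a, solver, 2.0, eps=eps + 0j)
        # analytic: donor field at the origin E = 2 mu/zd^3 (axial); induced
        # point dipole p = alpha E; interaction with the acceptor dipole is
        # U = -mu_a . E_p(za) = -mu * 2 p/|za|^3 (all three dipoles along +z)
        a_au = a_nm * BOHR_PER_NM
        alpha = a_au**3 * (eps - 1) / (eps + 2)
        zd_au, za_au = zd * BOHR_PER_NM, abs(za) * BOHR_PER_NM
        v_analytic = -(2 * mu / zd_au**3) * alpha * (2 * mu / za_au**3) * HARTREE_EV
        assert v.real == pytest.approx(v_analytic, rel=0.05)


class TestEETRate:
    def test_zero_total_coupling(self):
        assert eet_rate(0.0, 0.0, 1.4) == 0.0

    def test_printed_coupling_arithmetic(self):
        """5 meV coupling, J = 1.4 1/eV: direct arithmetic oracle."""
        v = 5e-3
        expected = 2 * np.pi / HBAR_EVS * v**2 * 1.4
        assert eet_rate(v, 0.0, 1.4) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(3.34e11, rel=0.01)

    def test_quadratic_in_coupling(self):
        assert eet_rate(2e-3, 0.0, 1.4) == pytest.approx(4 * eet_rate(1e-3, 0.0, 1.4), rel=1e-12)

    def test_negative_overlap_rejected(self):
        with pytest.raises(ValueError):
            eet_rate(1e-3, 0.0, -0.1)


class TestFileReaders:
    def test_monopole_file_roundtrip(self, tmp_path):
        from nanoret.emitters import read_monopoles

        p = tmp_path / "mono.txt"
        p.write_text("# units: nm au\n0.1 0.0 1.5 0.25\n-0.1 0.0 1.5 -0.25\n")
        pos, q = read_monopoles(p)
        assert pos.shape == (2, 3) and q.tolist() == [0.25, -0.25]
        # bohr-unit variant converts to nm
        p2 = tmp_path / "mono_bohr.txt"
        p2.write_text("# units: bohr au\n18.897259886 0 0 1.0\n0 0 0 -1.0\n")
        pos2, _ = read_monopoles(p2)
        assert pos2[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_monopole_file_requires_unit_header(self, tmp_path):
        from nanoret.emitters import read_monopoles

        p = tmp_path / "bad.txt"
        p.write_text("0 0 0 1.0\n")
        with pytest.raises(ValueError):
            read_monopoles(p)

    def test_cube_file_reader(self, tmp_path):
        from nanoret.emitters import read_cube

        lines = ["density cube", "synthetic fixture",
                 "0    0.0 0.0 0.0",
                 "2    1.0 0.0 0.0",
                 "2    0.0 1.0 0.0",
                 "2    0.0 0.0 1.0"]
        vals = np.arange(8.0)
        lines += [" ".join(f"{v:.6e}" for v in vals[i:i+4]) for i in (0, 4)]
        p = tmp_path / "rho.cube"
        p.write_text("\n".join(lines) + "\n")
        g = read_cube(p)
        assert g.values.shape == (2, 2, 2)
        assert g.values[1, 0, 1] == 5.0
        assert g.spacing[0] == pytest.approx(1.0 / BOHR_PER_NM)
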