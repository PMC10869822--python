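"""Synthetic emitters and independent analytic oracles.

Everything here is implemented independently of the BEM matrix pipeline, so
agreement between the two is evidence of correctness, not a tautology.

The synthetic transition-monopole generator stands in for ab initio
transition densities (which are not publicly deposited for the studied
phthalocyanines): random charges in a molecular-plane disc are projected onto
the exact constraints sum(q) = 0 and sum(q r) = target dipole.

Analytic oracles: the quasistatic sphere polarizability, the multipole
(Gersten-Nitzan-type) series for decay-rate modification of a dipole near a
sphere, and the closed-form metal-free Forster network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emitters import Emitter
from .units import AU_TIME_S, BOHR_PER_NM, C_AU, HBAR_EVS, ev_to_hartree, hartree_to_ev

__all__ = [
    "OracleResult",
    "make_synthetic_emitter",
    "sphere_polarizability_oracle",
    "dipole_sphere_rates_oracle",
    "forster_network_oracle",
    "phthalocyanine_pair",
    "gaussian_blob_grid",
]


class OracleConvergenceError(RuntimeError):
    pass


@dataclass
class OracleResult:
    quantity: str
    value: complex
    truncation_order: int = 0
    convergence_estimate: float = 0.0


# ---------------------------------------------------------------------------
# synthetic transition monopoles


def make_synthetic_emitter(
    dipole,
    spread: float,
    n_charges: int,
    seed: int,
    label: str = "synthetic",
    position=(0.0, 0.0, 0.0),
    omega: float = 2.0,
    eta0: float = 1.0,
    multipole_noise: float = 0.5,
) -> Emitter:
    """Random transition monopoles with an exactly prescribed dipole.

    Charges are scattered uniformly in a disc of radius `spread` (nm) in the
    molecular (xy) plane around `position`; the minimum-norm charge set
    realizing sum(q) = 0 and sum(q r) = dipole (a.u.) exactly is computed,
    and zero-mean noise in the constraint null space (fraction
    `multipole_noise` of the physical charge scale) roughens the higher
    multipole moments the way a structured molecular density would, without
    letting them swamp the dipole.  The dipole must lie in the molecular
    plane (all charges share one z).
    """
    if n_charges < 2:
        raise ValueError("need at least 2 charges")
    dipole = np.asarray(dipole, float)
    position = np.asarray(position, float)
    if abs(dipole[2]) > 1e-14:
        raise ValueError("in-plane generator cannot realize an out-of-plane dipole")
    rng = np.random.default_rng(seed)
    r = spread * np.sqrt(rng.uniform(0.2, 1.0, n_charges))
    phi = rng.uniform(0, 2 * np.pi, n_charges)
    pts = position + np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(n_charges)])
    # constraints in atomic units, relative coordinates (translation-safe)
    rel = (pts - position) * BOHR_PER_NM
    A = np.vstack([np.ones(n_charges), rel[:, 0], rel[:, 1]])
    b = np.array([0.0, dipole[0], dipole[1]])
    G = A @ A.T
    try:
        q_min = A.T @ np.linalg.solve(G, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("charge positions too degenerate for exact projection") from exc
    # noise projected onto the null space of the constraints
    scale = float(np.max(np.abs(q_min))) if np.any(q_min) else 1.0
    q0 = rng.normal(0.0, multipole_noise * scale, n_charges)
    q = q_min + q0 - A.T @ np.linalg.solve(G, A @ q0)
    return Emitter(
        label=label,
        position=position,
        omega=omega,
        dipole=dipole,
        eta0=eta0,
        monopole_positions=pts,
        monopole_charges=q,
    )


def phthalocyanine_pair(
    separation: float,
    plane_height: float = 1.5,
    dipole_donor: float = 2.4,
    dipole_acceptor: float = 1.7,
    omega_donor: float = 2.11,
    omega_acceptor=(2.02, 2.05),
    eta0_donor: float = 5e-4,
    eta0_acceptor: float = 0.6,
    lobe_angle_deg: float = 30.0,
    representation: str = "monopoles",
    spread: float = 0.4,
    n_charges: int = 24,
    seed: int = 7,
):
    """Synthetic phthalocyanine-like donor/acceptor state sets.

    Two degenerate donor transitions with orthogonal in-plane dipoles (rotated
    by `lobe_angle_deg` from the axes) and two near-degenerate acceptor
    transitions, donor at the origin of the molecular plane (z = plane_height)
    and acceptor displaced by `separation` along +x.

    Default dipole magnitudes follow phthalocyanine Q-band oscillator
    strengths (roughly 0.3 per degenerate metal-Pc component and 0.15 per
    free-base component), giving vacuum radiative lifetimes of tens of ns and
    donor-acceptor couplings of a few meV at the shortest experimental
    separations.

    Returns (donor_states, acceptor_states): two lists of Emitters.
    """
    ang = np.deg2rad(lobe_angle_deg)
    e1 = np.array([np.cos(ang), np.sin(ang), 0.0])
    e2 = np.array([-np.sin(ang), np.cos(ang), 0.0])
    pos_d = np.array([0.0, 0.0, plane_height])
    pos_a = np.array([separation, 0.0, plane_height])

    def make(idx, pos, omega, dip, eta0, tag):
        if representation == "point-dipole":
            return Emitter(label=tag, position=pos, omega=omega, dipole=dip, eta0=eta0)
        return make_synthetic_emitter(
            dip, spread, n_charges, seed + idx, label=tag, position=pos, omega=omega, eta0=eta0
        )

    donors = [
        make(0, pos_d, omega_donor, dipole_donor * e1, eta0_donor, "donor-S1"),
        make(1, pos_d, omega_donor, dipole_donor * e2, eta0_donor, "donor-S2"),
    ]
    acceptors = [
        make(2, pos_a, omega_acceptor[0], dipole_acceptor * e1, eta0_acceptor, "acceptor-S1"),
        make(3, pos_a, omega_acceptor[1], dipole_acceptor * e2, eta0_acceptor, "acceptor-S2"),
    ]
    return donors, acceptors


# ---------------------------------------------------------------------------
# analytic sphere oracles


def sphere_polarizability_oracle(radius: float, eps: complex) -> complex:
    """Quasistatic dipole polarizability a^3 (eps-1)/(eps+2) in a.u.
    (radius in nm)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if eps == -2:
        raise ZeroDivisionError("eps = -2 is the dipolar resonance pole")
    a = radius * BOHR_PER_NM
    return a**3 * (eps - 1.0) / (eps + 2.0)


def _sphere_multipole_polarizability(n: int, radius_au: float, eps: complex) -> complex:
    return radius_au ** (2 * n + 1) * n * (eps - 1.0) / (n * eps + n + 1.0)


def dipole_sphere_rates_oracle(
    radius: float,
    eps: complex,
    distance: float,
    orientation: str,
    omega: float,
    tol: float = 1e-6,
    max_terms: int = 10_000,
):
    """Decay-rate modification of a point dipole near a sphere (multipole
    series), relative to the vacuum radiative rate.

    radius/distance in nm (distance from sphere centre), omega in eV.
    orientation: 'radial' (dipole along the centre-emitter axis) or
    'tangential'.  Returns (gamma_nr_factor, gamma_rad_factor) as
    OracleResults; the nonradiative factor is Gamma_nr_met / Gamma_rad0.
    """
    if distance <= radius:
        raise ValueError("dipole must sit outside the sphere")
    a = radius * BOHR_PER_NM
    d = distance * BOHR_PER_NM
    w = ev_to_hartree(omega)
    if orientation == "radial":
        coeff = lambda n: (n + 1.0) ** 2
    elif orientation == "tangential":
        coeff = lambda n: n * (n + 1.0) / 2.0
    else:
        raise ValueError("orientation must be 'radial' or 'tangential'")
    s = 0.0 + 0.0j
    n = 0
    while True:
        n += 1
        if n > max_terms:
            raise OracleConvergenceError(f"series not converged in {max_terms} terms")
        term = coeff(n) * _sphere_multipole_polarizability(n, a, eps) / d ** (2 * n + 4)
        s += term
        if abs(term) < tol * max(abs(s), 1e-300):
            break
    # Gamma_nr = 2 mu^2 sum c_n Im alpha_n / d^(2n+4); Gamma_rad0 = 4 w^3 mu^2 / (3 c^3)
    gnr = 2.0 * s.imag / (4.0 * w**3 / (3.0 * C_AU**3))
    alpha1 = _sphere_multipole_polarizability(1, a, eps)
    if orientation == "radial":
        grad = abs(1.0 + 2.0 * alpha1 / d**3) ** 2
    else:
        grad = abs(1.0 - alpha1 / d**3) ** 2
    est = abs(term) / max(abs(s), 1e-300)
    if est > tol:
        raise OracleConvergenceError("convergence estimate above requested tolerance")
    return (
        OracleResult("gamma_nr_factor", gnr, n, est),
        OracleResult("gamma_rad_factor", grad, 1, 0.0),
    )


def dipole_sphere_lamb_shift_oracle(
    radius: float, eps: complex, distance: float, orientation: str, tol: float = 1e-6
) -> OracleResult:
    """Re{sum q V} for a unit dipole near a sphere (eV), multipole series."""
    a = radius * BOHR_PER_NM
    d = distance * BOHR_PER_NM
    coeff = (lambda n: (n + 1.0) ** 2) if orientation == "radial" else (lambda n: n * (n + 1.0) / 2.0)
    s = 0.0 + 0.0j
    for n in range(1, 10_000):
        term = coeff(n) * _sphere_multipole_polarizability(n, a, eps) / d ** (2 * n + 4)
        s += term
        if abs(term) < tol * max(abs(s), 1e-300):
            break
    return OracleResult("lamb_shift", hartree_to_ev(-s.real), n, abs(term) / abs(s))


# ---------------------------------------------------------------------------
# metal-free Forster oracle


def forster_network_oracle(
    mu_d: float,
    mu_a: float,
    kappa: float,
    R: float,
    J: float,
    omega_d: float,
    eta0_a: float = 1.0,
):
    """Closed-form RET efficiency for a metal-free dipole-dipole pair.

    mu_d/mu_a in a.u., R in nm, J in 1/eV, omega_d in eV.  Returns a dict with
    the coupling V (eV), the EET rate (s^-1), the donor vacuum radiative rate
    (s^-1), the Forster radius R0 (nm) and RET_eff = 1/(1 + (R/R0)^6).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    Rau = R * BOHR_PER_NM
    V = hartree_to_ev(kappa * mu_d * mu_a / Rau**3)
    geet = 2.0 * np.pi / HBAR_EVS * V**2 * J
    w = ev_to_hartree(omega_d)
    grad_d = 4.0 * w**3 * mu_d**2 / (3.0 * C_AU**3) / AU_TIME_S
    # Geet(R) * eta0_a = grad_d  at  R = R0
    c6 = geet * Rau**6  # rate * bohr^6, distance-independent
    r0_au = (c6 * eta0_a / grad_d) ** (1.0 / 6.0)
    ret = 0.0 if r0_au == 0 else 1.0 / (1.0 + (Rau / r0_au) ** 6)
    return {
        "V_eV": V,
        "gamma_eet": geet,
        "gamma_rad_d": grad_d,
        "R0_nm": r0_au / BOHR_PER_NM,
        "ret_eff": ret,
    }


# ---------------------------------------------------------------------------
# gridded Gaussian densities (for overlap/quadrature tests)


def gaussian_blob_grid(
    center,
    sigma: float,
    dipole,
    half_extent: float,
    n: int = 41,
):
    """A p-orbital-like Gaussian transition density on a regular grid.

    rho(r) ~ (u . (r - c)) exp(-|r - c|^2 / 2 sigma^2), rescaled so the grid
    dipole equals `dipole` (a.u.) exactly.  sigma and half_extent in nm.
    Returns an emitters.DensityGrid.
    """
    from .emitters import DensityGrid

    center = np.asarray(center, float)
    dipole = np.asarray(dipole, float)
    u = dipole / np.linalg.norm(dipole)
    ax = np.linspace(-half_extent, half_extent, n)
    X, Y, Z = np.meshgrid(*(ax,) * 3, indexing="ij")
    rel = np.stack([X, Y, Z], axis=-1)
    r2 = np.sum(rel**2, axis=-1)
    vals = (rel @ u) * np.exp(-r2 / (2.0 * sigma**2))
    grid = DensityGrid(center - half_extent, np.full(3, ax[1] - ax[0]), vals)
    mu = grid.dipole_au()
    grid.values = vals * (np.linalg.norm(dipole) / np.linalg.norm(mu))
    return grid
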