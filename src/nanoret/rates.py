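"""Decay rates of a single emitter state, with and without the metal.

The metal modifies the radiative channel through the dipole it acquires from
the molecular transition density,

    Gamma_rad = (4 w_b^3 / 3 hbar c^3) |mu_mol + mu_ind|^2,

where w_b is ALWAYS the molecular transition energy even when the metal
response was evaluated at a shifted frequency (the shift procedure emulates a
different tip, not a different molecule).  The metal opens a nonradiative
channel given by the imaginary part of the charge-potential self-interaction
on the surface,

    Gamma_nr_met = -2 * Im sum_k q_k V_k,

whose real part is the plasmon-induced Lamb shift of the transition energy.
The purely molecular nonradiative rate follows from the vacuum radiative
quantum efficiency eta0: Gamma_nr0 = Gamma_rad0 * (1 - eta0)/eta0.

Rates are returned in s^-1, energies in eV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bem import ResponseCharges
from .emitters import Emitter
from .units import AU_TIME_S, C_AU, HARTREE_EV, ev_to_hartree, hartree_to_ev

__all__ = [
    "DecayRates",
    "radiative_rate",
    "vacuum_radiative_rate",
    "nonradiative_metal_rate",
    "lamb_shift",
    "intrinsic_nonradiative",
    "decay_rates",
]

log = logging.getLogger(__name__)

# relative threshold below which small negative metal rates (mesh artifacts)
# are clamped to zero after logging
_CLAMP_REL = 1e-6


@dataclass
class DecayRates:
    """All decay channels of one emitter state (rates s^-1, shift eV)."""

    state: str
    omega: float  # molecular transition energy, eV
    gamma_rad0: float  # vacuum radiative
    gamma_rad: float  # radiative with metal
    gamma_nr_met: float  # metal-induced nonradiative
    gamma_nr0: float  # intrinsic nonradiative
    lamb_shift: float = 0.0  # eV; negative = red shift


def vacuum_radiative_rate(emitter: Emitter) -> float:
    """Vacuum spontaneous-emission rate (s^-1) of the transition dipole."""
    return radiative_rate(emitter, np.zeros(3))


def radiative_rate(emitter: Emitter, mu_ind) -> float:
    """Metal-modified radiative rate (s^-1).

    mu_ind is the complex dipole induced in the nanostructure (a.u.); pass
    zeros for the vacuum rate.  The molecular transition dipole is taken as
    the vacuum one (metal polarization of the ground state is negligible for
    these junctions).
    """
    if emitter.omega <= 0:
        raise ValueError("transition energy must be positive")
    w = ev_to_hartree(emitter.omega)
    mu_tot = emitter.dipole.astype(complex) + np.asarray(mu_ind, dtype=complex)
    rate_au = 4.0 * w**3 / (3.0 * C_AU**3) * float(np.sum(np.abs(mu_tot) ** 2))
    return rate_au / AU_TIME_S


def _self_interaction_au(q: ResponseCharges, potential_values) -> complex:
    V = np.asarray(potential_values)
    if V.shape[0] != q.charges.shape[0]:
        raise ValueError("charges and potentials must live on the same tesserae")
    return complex(q.charges @ V)


def nonradiative_metal_rate(q: ResponseCharges, potential_values,
                            gamma_rad0: float | None = None) -> float:
    """Metal-induced nonradiative rate (s^-1): -2 Im{sum_k q_k V_k}.

    q and V must come from the SAME emitter at the same tesserae.  Small
    negative values (discretization artifacts for passive metals) are clamped
    to zero after logging; the threshold is 1e-6 of gamma_rad0 when given.
    """
    rate_au = -2.0 * _self_interaction_au(q, potential_values).imag
    rate = rate_au / AU_TIME_S
    if rate < 0:
        tol = _CLAMP_REL * gamma_rad0 if gamma_rad0 else _CLAMP_REL * abs(rate)
        if abs(rate) > tol:
            log.warning("negative metal nonradiative rate %.3e s^-1 (mesh artifact?)", rate)
        return 0.0
    return rate


def lamb_shift(q: ResponseCharges, potential_values) -> float:
    """Plasmon-induced shift of the transition energy (eV).

    Convention: Re{sum_k q_k V_k} with no extra prefactor; negative values are
    red shifts (image interaction with a polarizable body).  The convention is
    isolated here.
    """
    return hartree_to_ev(_self_interaction_au(q, potential_values).real)


def intrinsic_nonradiative(gamma_rad0: float, eta0: float) -> float:
    """Intrinsic molecular nonradiative rate from the vacuum quantum
    efficiency: Gamma_nr0 = Gamma_rad0 (1 - eta0)/eta0."""
    if not (0.0 < eta0 <= 1.0):
        raise ValueError("eta0 must lie in (0, 1]")
    return gamma_rad0 * (1.0 - eta0) / eta0


def decay_rates(emitter: Emitter, solver, eps: complex, response_omega: float,
                modal: bool = False) -> DecayRates:
    """Evaluate every channel of one emitter state near the metal.

    The metal response (charges, induced dipole) is evaluated at
    response_omega (eV) with permittivity eps; the molecular frequency in the
    radiative prefactor stays emitter.omega.
    """
    from .bem import induced_dipole
    from .emitters import potential_at

    V = potential_at(emitter, solver.mesh.centroids)
    solve = solver.solve_charges_modal if modal else solver.solve_charges
    q = solve(eps, V, omega=response_omega, source=emitter.label)
    mu_ind = induced_dipole(q, solver)
    g_rad0 = vacuum_radiative_rate(emitter)
    return DecayRates(
        state=emitter.label,
        omega=emitter.omega,
        gamma_rad0=g_rad0,
        gamma_rad=radiative_rate(emitter, mu_ind),
        gamma_nr_met=nonradiative_metal_rate(q, V, gamma_rad0=g_rad0),
        gamma_nr0=intrinsic_nonradiative(g_rad0, emitter.eta0),
        lamb_shift=lamb_shift(q, V),
    )
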