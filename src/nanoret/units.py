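"""Physical constants and unit conversions.

All interface quantities are expressed in eV (energies), nm (lengths) and
s^-1 (rates).  Internally the electromagnetic solvers work in Hartree atomic
units (lengths in bohr, energies in hartree, hbar = e = m_e = 1), where the
Coulomb kernel is simply 1/r.
"""

# energy
HARTREE_EV = 27.211386245988  # eV per hartree
HBAR_EVS = 6.582119569e-16  # hbar in eV*s

# length
BOHR_PER_NM = 18.897259886  # bohr per nm
NM_PER_BOHR = 1.0 / BOHR_PER_NM

# time
AU_TIME_S = 2.418884326e-17  # seconds per atomic unit of time

# speed of light in atomic units (1/alpha)
C_AU = 137.035999


def ev_to_hartree(e_ev: float) -> float:
    return e_ev / HARTREE_EV


def hartree_to_ev(e_ha: float) -> float:
    return e_ha * HARTREE_EV


def nm_to_bohr(x_nm):
    return x_nm * BOHR_PER_NM


def bohr_to_nm(x_bohr):
    return x_bohr * NM_PER_BOHR


def au_rate_to_per_second(rate_au: float) -> float:
    """Convert a rate in inverse atomic time units to s^-1."""
    return rate_au / AU_TIME_S
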