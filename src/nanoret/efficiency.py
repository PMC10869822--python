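"""Quantum yields, EET efficiencies and the measurable RET efficiency.

The experiment measures the acceptor's share of the total emitted light upon
donor excitation, RET_eff = I_A / (I_A + I_D).  With degenerate donor states
i (populated with excitation weights Gamma_ex^i) and near-degenerate acceptor
states j, the intensities are

    I_D^i = Gamma_ex^i * Phi_D^i,
    I_A^i = Gamma_ex^i * sum_j eta_EET^(i->j) * Phi_A^j,

with the donor yield, transfer efficiency and acceptor yield

    Phi_D^i      = Grad_D^i / (sum_j Geet^(i->j) + Grad_D^i + Gnrm_D^i + Gnr0_D),
    eta^(i->j)   = Geet^(i->j) / (same denominator),
    Phi_A^j      = Grad_A^j / (Grad_A^j + Gnrm_A^j + Gnr0_A).

The per-donor-state efficiency admits a closed form independent of all donor
nonradiative channels,

    (RET_eff)^i = 1 / (1 + Grad_D^i * [sum_j Geet^(i->j) Phi_A^j-num]^{-1}),

and the total observable sums intensities over i.  Back transfer from the
acceptor to the (higher-energy) donor is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import DecayRates

__all__ = [
    "StateNetwork",
    "DegenerateNetworkError",
    "donor_yield",
    "acceptor_yield",
    "eet_efficiency",
    "ret_eff_state",
    "ret_eff_total",
]


class DegenerateNetworkError(ZeroDivisionError):
    pass


@dataclass
class StateNetwork:
    """Donor/acceptor decay rates plus the EET rate matrix (all s^-1).

    eet_rates[i, j] is the transfer rate from donor state i to acceptor
    state j.  Excitation weights default to equal population of the (quasi-)
    degenerate donor states upon tunneling.
    """

    donor_states: list  # list of DecayRates
    acceptor_states: list  # list of DecayRates
    eet_rates: np.ndarray  # (n_d, n_a)
    excitation_weights: np.ndarray | None = None
    J: float = 1.4  # spectral overlap, 1/eV (bookkeeping; rates already built)

    def __post_init__(self):
        self.eet_rates = np.atleast_2d(np.asarray(self.eet_rates, float))
        nd, na = len(self.donor_states), len(self.acceptor_states)
        if nd == 0 or na == 0:
            raise ValueError("need at least one donor and one acceptor state")
        if self.eet_rates.shape != (nd, na):
            raise ValueError("eet_rates shape must be (n_donor, n_acceptor)")
        if np.any(self.eet_rates < 0):
            raise ValueError("negative EET rate")
        if self.excitation_weights is None:
            self.excitation_weights = np.full(nd, 1.0 / nd)
        else:
            self.excitation_weights = np.asarray(self.excitation_weights, float)
            if np.any(self.excitation_weights < 0):
                raise ValueError("negative excitation weight")


def _donor_denominator(net: StateNetwork, i: int) -> float:
    d: DecayRates = net.donor_states[i]
    tot = net.eet_rates[i].sum() + d.gamma_rad + d.gamma_nr_met + d.gamma_nr0
    if tot <= 0:
        raise DegenerateNetworkError(f"all decay rates of donor state {d.state} vanish")
    return tot


def donor_yield(net: StateNetwork, i: int) -> float:
    """Fluorescence quantum yield Phi_D^i of donor state i."""
    return net.donor_states[i].gamma_rad / _donor_denominator(net, i)


def acceptor_yield(net: StateNetwork, j: int) -> float:
    """Emission quantum yield Phi_A^j of acceptor state j."""
    a: DecayRates = net.acceptor_states[j]
    tot = a.gamma_rad + a.gamma_nr_met + a.gamma_nr0
    if tot <= 0:
        raise DegenerateNetworkError(f"all decay rates of acceptor state {a.state} vanish")
    return a.gamma_rad / tot


def eet_efficiency(net: StateNetwork, i: int, j: int) -> float:
    """Transfer efficiency eta_EET^(i->j) out of donor state i."""
    return net.eet_rates[i, j] / _donor_denominator(net, i)


def ret_eff_state(net: StateNetwork, i: int) -> float:
    """Observable RET efficiency when only donor state i is excited.

    Evaluated in the closed 1/(1+f) form, which is manifestly independent of
    the donor's nonradiative channels; it equals the intensity-ratio route to
    machine precision (a tested identity).
    """
    d: DecayRates = net.donor_states[i]
    bracket = 0.0
    for j, a in enumerate(net.acceptor_states):
        tot_a = a.gamma_rad + a.gamma_nr_met + a.gamma_nr0
        if tot_a <= 0:
            if net.eet_rates[i, j] > 0:
                raise DegenerateNetworkError(
                    f"acceptor state {a.state} has zero total decay but receives EET"
                )
            continue
        bracket += net.eet_rates[i, j] * a.gamma_rad / tot_a
    if bracket == 0.0:
        return 0.0
    f = d.gamma_rad / bracket
    return 1.0 / (1.0 + f)


def ret_eff_state_intensities(net: StateNetwork, i: int) -> float:
    """Intensity-ratio route for one donor state (yields/efficiencies)."""
    ia = sum(
        eet_efficiency(net, i, j) * acceptor_yield(net, j)
        for j in range(len(net.acceptor_states))
    )
    iD = donor_yield(net, i)
    if ia + iD == 0:
        raise DegenerateNetworkError("zero total intensity")
    return ia / (ia + iD)


def ret_eff_total(net: StateNetwork) -> float:
    """Observable RET efficiency with all donor states excited:
    sum_i I_A^i / sum_i (I_A^i + I_D^i)."""
    IA = ID = 0.0
    for i, w in enumerate(net.excitation_weights):
        ia = w * sum(
            eet_efficiency(net, i, j) * acceptor_yield(net, j)
            for j in range(len(net.acceptor_states))
        )
        IA += ia
        ID += w * donor_yield(net, i)
    if IA + ID == 0:
        raise DegenerateNetworkError("zero total emitted intensity")
    return IA / (IA + ID)
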