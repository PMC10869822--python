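"""Frequency-dependent complex dielectric functions for metals.

Implements the Drude / Drude-Lorentz / Brendel-Bormann (BB) family of local
dielectric models,

    eps(w) = eps_inf - f0 * wp^2 / (w^2 + i*g0*w)
             + sum_j f_j * wp^2 / (w_j^2 - a_j^2),     a_j^2 = w^2 + i*g_j*w,

where each Lorentz pole may be broadened by convolving its resonance energy
with a Gaussian of width sigma_j (the BB form), which is evaluated through the
Faddeeva function:

    chi_j(w) = i*sqrt(pi)*f_j*wp^2 / (2*sqrt(2)*a_j*sigma_j)
               * [ w((a_j - w_j)/(sqrt(2)*sigma_j)) + w((a_j + w_j)/(sqrt(2)*sigma_j)) ],

with a_j = sqrt(w^2 + i*g_j*w) taken on the branch with positive real part.
For sigma_j -> 0 this reduces analytically to the plain Lorentz pole above.

Sign convention: time dependence exp(-i*w*t), so a passive medium has
Im eps(w) >= 0 for w > 0, and the analytic continuation to negative
frequencies satisfies eps(-w) = conj(eps(w)).

Energies are in eV at this interface; unit conversion to atomic units happens
only inside the BEM / rates modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import wofz

__all__ = [
    "DielectricModel",
    "evaluate_epsilon",
    "make_silver_bb",
    "make_drude",
    "load_model",
]

_SQRT2 = np.sqrt(2.0)
_SQRTPI = np.sqrt(np.pi)


@dataclass(frozen=True)
class DielectricModel:
    """Parameters of a Drude(-Lorentz/Brendel-Bormann) dielectric model.

    oscillators holds (strength, energy_eV, damping_eV, gaussian_width_eV)
    tuples; gaussian_width = 0 degrades the term to a plain Lorentz pole.
    Oscillator amplitudes are strength * plasma_energy**2; the Drude term is
    scaled by `drude_strength` (f0 of the published fits, 1.0 for a bare
    Drude metal).
    """

    eps_inf: float = 1.0
    plasma_energy: float = 9.0  # eV
    drude_damping: float = 0.05  # eV
    drude_strength: float = 1.0
    oscillators: tuple = ()
    label: str = "drude"

    def __call__(self, omega):
        return evaluate_epsilon(self, omega)


def _bb_term(f: float, wj: float, gj: float, sj: float, omega, wp2: float):
    """One Brendel-Bormann (or Lorentz, if sj == 0) oscillator term."""
    omega = np.asarray(omega, dtype=complex)
    a2 = omega**2 + 1j * gj * omega
    if sj == 0.0:
        return f * wp2 / (wj**2 - a2)
    a = np.sqrt(a2)
    # branch with Re a > 0 (principal sqrt already has Re >= 0 for these args)
    a = np.where(a.real < 0, -a, a)
    z1 = (a - wj) / (_SQRT2 * sj)
    z2 = (a + wj) / (_SQRT2 * sj)
    pref = 1j * _SQRTPI * f * wp2 / (2.0 * _SQRT2 * a * sj)
    return pref * (wofz(z1) + wofz(z2))


def evaluate_epsilon(model: DielectricModel, omega):
    """Complex permittivity eps(omega) for omega in eV (scalar or array).

    Raises ValueError for non-positive frequencies.  Negative frequencies are
    not evaluated directly; the analytic continuation eps(-w) = conj(eps(w))
    is the documented convention.
    """
    om = np.asarray(omega, dtype=float)
    if np.any(om <= 0):
        raise ValueError("omega must be positive (eV)")
    wp2 = model.plasma_energy**2
    eps = np.asarray(
        model.eps_inf
        - model.drude_strength * wp2 / (om**2 + 1j * model.drude_damping * om),
        dtype=complex,
    )
    for f, wj, gj, sj in model.oscillators:
        eps = eps + _bb_term(f, wj, gj, sj, om, wp2)
    if np.isscalar(omega):
        return complex(eps)
    return eps


def make_drude(
    plasma_energy: float, damping: float, eps_inf: float = 1.0
) -> DielectricModel:
    """A bare Drude metal (no interband oscillators)."""
    return DielectricModel(
        eps_inf=eps_inf,
        plasma_energy=plasma_energy,
        drude_damping=damping,
        drude_strength=1.0,
        label=f"drude(wp={plasma_energy}eV,g={damping}eV)",
    )


def load_model(path) -> DielectricModel:
    """Load a dielectric parameter set from a versioned JSON file."""
    data = json.loads(Path(path).read_text())
    return DielectricModel(
        eps_inf=float(data["eps_inf"]),
        plasma_energy=float(data["plasma_energy_eV"]),
        drude_damping=float(data["drude_damping_eV"]),
        drude_strength=float(data.get("drude_strength", 1.0)),
        oscillators=tuple(tuple(map(float, o)) for o in data["oscillators"]),
        label=data.get("name", Path(path).stem),
    )


def make_silver_bb() -> DielectricModel:
    """The Brendel-Bormann parameterization of silver (shipped data file).

    Provenance is documented inside the JSON file; replace the file (or call
    load_model on another file) to swap parameter sets.
    """
    with resources.as_file(
        resources.files("nanoret.data").joinpath("silver_bb_rakic1998.json")
    ) as p:
        return load_model(p)
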