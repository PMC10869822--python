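"""Distance scans, detuning scans and decay-law fits.

A distance scan reproduces the tip-enhanced energy-transfer experiment's
protocol: the donor stays fixed beneath the tip while the acceptor is
translated in the molecular (xy) plane along the donor-acceptor axis.  At
each centre-centre distance R all per-state decay rates, couplings and
transfer rates are assembled into a StateNetwork and the observable RET
efficiency is evaluated.

Detuning ("frequency-shift") scans rigidly shift the frequencies at which
the METAL response is evaluated -- emulating a tip with a shifted plasmonic
spectrum -- while molecular frequencies in the radiative prefactors and
vacuum rates stay put, and the donor-acceptor frequency difference is
preserved.

The resulting efficiency curves are summarized by an exponential fit
RET_eff(R) = A0 exp(-lambda R) (the experiment's parameterization) and can be
contrasted with the dipole-dipole Forster form 1/(1 + (R/R0)^6).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .dielectric import evaluate_epsilon
from .efficiency import StateNetwork, ret_eff_total
from .emitters import Emitter, coulomb_coupling, eet_rate, metal_mediated_coupling, potential_at
from .rates import DecayRates, decay_rates, intrinsic_nonradiative, vacuum_radiative_rate

log = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "FitResult",
    "distance_scan",
    "frequency_shift_scan",
    "fit_exponential",
    "fit_forster",
    "GeometryError",
]


class GeometryError(ValueError):
    pass


@dataclass
class FitResult:
    params: dict
    r_squared: float
    residuals: np.ndarray
    model: str
    identifiable: bool = True


@dataclass
class ScanResult:
    distances: np.ndarray  # nm, centre-centre
    ret_eff: np.ndarray
    networks: list  # per-distance StateNetwork
    response_shift: float  # eV added to metal-response frequencies
    fit: Optional[FitResult] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, float)
        self.ret_eff = np.asarray(self.ret_eff, float)
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any((self.ret_eff < 0) | (self.ret_eff > 1)):
            raise ValueError("RET efficiency outside [0, 1]")

    def rate_table(self):
        """Per-distance rate summary as a pandas DataFrame (units in headers)."""
        import pandas as pd

        rows = []
        for R, net in zip(self.distances, self.networks):
            row = {"distance_nm": R, "ret_eff": ret_eff_total(net)}
            for tag, states in (("D", net.donor_states), ("A", net.acceptor_states)):
                for s in states:
                    p = f"{tag}_{s.state}"
                    row[f"{p}_gamma_rad_per_s"] = s.gamma_rad
                    row[f"{p}_gamma_rad0_per_s"] = s.gamma_rad0
                    row[f"{p}_gamma_nr_met_per_s"] = s.gamma_nr_met
                    row[f"{p}_gamma_nr0_per_s"] = s.gamma_nr0
                    row[f"{p}_lamb_shift_eV"] = s.lamb_shift
            row["gamma_eet_total_per_s"] = float(net.eet_rates.sum())
            rows.append(row)
        return pd.DataFrame(rows)


def _min_metal_distance(emitter: Emitter, mesh) -> float:
    pts = (
        emitter.monopole_positions
        if emitter.monopole_positions is not None
        else emitter.position[None, :]
    )
    from scipy.spatial import cKDTree

    d, _ = cKDTree(mesh.centroids).query(pts)
    return float(np.min(d))


def _vacuum_decay(em: Emitter) -> DecayRates:
    g0 = vacuum_radiative_rate(em)
    return DecayRates(
        state=em.label,
        omega=em.omega,
        gamma_rad0=g0,
        gamma_rad=g0,
        gamma_nr_met=0.0,
        gamma_nr0=intrinsic_nonradiative(g0, em.eta0),
        lamb_shift=0.0,
    )


def distance_scan(
    solver,
    model,
    donor_states: Sequence[Emitter],
    acceptor_states: Sequence[Emitter],
    distances: Sequence[float],
    J: float = 1.4,
    response_shift: float = 0.0,
    include_metal: bool = True,
    modal: bool = False,
    min_clearance: float = 0.05,
) -> ScanResult:
    """Scan the acceptor along the donor-acceptor axis and evaluate RET_eff.

    solver: bem.BEMSolver (ignored when include_metal=False, may be None);
    model: DielectricModel; donor/acceptor_states: Emitter lists (all donor
    states co-centred, likewise acceptors); distances: centre-centre, nm;
    response_shift: rigid shift (eV) of the frequencies at which the metal
    response is evaluated.  J in 1/eV is shared by all state pairs.

    The metal response for each state's decay rates is evaluated at that
    state's (shifted) transition energy; the metal-mediated coupling for the
    pair (i, j) is evaluated at the donor's (shifted) frequency, the emission
    side of the transfer.
    """
    distances = np.asarray(list(distances), float)
    donors = list(donor_states)
    acceptors0 = list(acceptor_states)
    axis = acceptors0[0].position - donors[0].position
    axis[2] = 0.0
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("acceptor template must be laterally displaced from the donor")
    axis = axis / norm

    eps_at = {}

    def eps_for(omega_resp: float) -> complex:
        if omega_resp not in eps_at:
            eps_at[omega_resp] = evaluate_epsilon(model, omega_resp)
        return eps_at[omega_resp]

    # donor-side quantities are distance independent: compute once
    if include_metal:
        donor_rates = [
            decay_rates(d, solver, eps_for(d.omega + response_shift), d.omega + response_shift,
                        modal=modal)
            for d in donors
        ]
        donor_potentials = [potential_at(d, solver.mesh.centroids) for d in donors]
        donor_charges = [
            solver.solve_charges(eps_for(d.omega + response_shift), vd, source=d.label)
            for d, vd in zip(donors, donor_potentials)
        ]
    else:
        donor_rates = [_vacuum_decay(d) for d in donors]
        donor_charges = [None] * len(donors)

    ret = []
    networks = []
    for R in distances:
        shift = donors[0].position + R * axis - acceptors0[0].position
        accs = [a.translated(shift) for a in acceptors0]
        if include_metal:
            for a in accs:
                if _min_metal_distance(a, solver.mesh) < min_clearance:
                    raise GeometryError(
                        f"acceptor {a.label} within {min_clearance} nm of the metal at R={R}"
                    )
            acc_rates = [
                decay_rates(a, solver, eps_for(a.omega + response_shift),
                            a.omega + response_shift, modal=modal)
                for a in accs
            ]
        else:
            acc_rates = [_vacuum_decay(a) for a in accs]
        eet = np.zeros((len(donors), len(accs)))
        for i, d in enumerate(donors):
            for j, a in enumerate(accs):
                v0 = coulomb_coupling(d, a)
                if include_metal:
                    va = potential_at(a, solver.mesh.centroids)
                    from .units import hartree_to_ev

                    vmet = hartree_to_ev(complex(va @ donor_charges[i].charges))
                else:
                    vmet = 0.0
                eet[i, j] = eet_rate(v0, vmet, J)
        net = StateNetwork(
            donor_states=donor_rates,
            acceptor_states=acc_rates,
            eet_rates=eet,
            J=J,
        )
        networks.append(net)
        ret.append(ret_eff_total(net))

    prov = {
        "mesh": getattr(getattr(solver, "mesh", None), "label", "none"),
        "n_tesserae": getattr(getattr(solver, "mesh", None), "n_tesserae", 0),
        "dielectric": getattr(model, "label", str(model)),
        "J_per_eV": J,
        "response_shift_eV": response_shift,
        "include_metal": include_metal,
    }
    prov["config_hash"] = hashlib.sha256(
        json.dumps(prov, sort_keys=True).encode()
    ).hexdigest()[:16]
    return ScanResult(
        distances=distances,
        ret_eff=np.asarray(ret),
        networks=networks,
        response_shift=response_shift,
        provenance=prov,
    )


def frequency_shift_scan(
    solver,
    model,
    donor_states: Sequence[Emitter],
    acceptor_states: Sequence[Emitter],
    distances: Sequence[float],
    shifted_donor_frequencies: Sequence[float],
    J: float = 1.4,
    modal: bool = False,
) -> list[ScanResult]:
    """One distance scan per target donor frequency (eV).

    The shift applied to the metal-response evaluation is
    shifted_donor_frequency - omega_D, identical for all states, so the
    donor-acceptor frequency difference is preserved.
    """
    w_d = donor_states[0].omega
    results = []
    for w_target in shifted_donor_frequencies:
        shift = w_target - w_d
        results.append(
            distance_scan(
                solver, model, donor_states, acceptor_states, distances,
                J=J, response_shift=shift, modal=modal,
            )
        )
    return results


# ---------------------------------------------------------------------------
# decay-law fits


def _r_squared(y, resid):
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)


def fit_exponential(distances, values) -> FitResult:
    """Least-squares fit of A0 * exp(-lambda R) on the linear scale,
    initialized from the log-linear regression."""
    R = np.asarray(distances, float)
    y = np.asarray(values, float)
    if len(R) < 3:
        raise ValueError("need at least 3 points")
    if np.any(y <= 0):
        raise ValueError("values must be positive for an exponential fit")
    slope, intercept = np.polyfit(R, np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    popt, _ = curve_fit(lambda r, a0, lam: a0 * np.exp(-lam * r), R, y, p0=p0, maxfev=20_000)
    resid = y - popt[0] * np.exp(-popt[1] * R)
    return FitResult(
        params={"A0": float(popt[0]), "lambda_per_nm": float(popt[1])},
        r_squared=_r_squared(y, resid),
        residuals=resid,
        model="A0*exp(-lambda*R)",
    )


def fit_forster(distances, values) -> FitResult:
    """Least-squares fit of the Forster efficiency form 1/(1 + (R/R0)^6)."""
    R = np.asarray(distances, float)
    y = np.asarray(values, float)
    if len(R) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        return FitResult(
            params={"R0_nm": float("nan")},
            r_squared=0.0,
            residuals=np.zeros_like(y),
            model="1/(1+(R/R0)^6)",
            identifiable=False,
        )
    yc = np.clip(y, 1e-12, 1.0 - 1e-12)
    r0_guess = float(np.median(R * (1.0 / yc - 1.0) ** (-1.0 / 6.0)))
    popt, _ = curve_fit(
        lambda r, r0: 1.0 / (1.0 + (r / r0) ** 6), R, y, p0=(r0_guess,), maxfev=20_000
    )
    resid = y - 1.0 / (1.0 + (R / popt[0]) ** 6)
    return FitResult(
        params={"R0_nm": float(popt[0])},
        r_squared=_r_squared(y, resid),
        residuals=resid,
        model="1/(1+(R/R0)^6)",
    )
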