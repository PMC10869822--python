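"""Molecular transitions: potentials, couplings and the EET golden rule.

An Emitter is one electronic transition of a chromophore.  Its transition
density can be represented three ways:

* a point dipole at the molecular position;
* a set of transition monopoles (point charges summing to zero whose first
  moment reproduces the transition dipole) -- the workhorse representation,
  standing in for ab initio transition densities;
* a gridded transition density (regular 3D voxel grid).

All charges and dipoles are in atomic units; positions and grid geometry in
nm; energies in eV at the interface.

The donor-acceptor electronic coupling has a direct Coulomb part

    V0 = INT rho_A(r) rho_D(r') / |r - r'| dr dr'

(plus a density-overlap term, -w0 * INT rho_A rho_D dr, relevant only for
overlapping densities) and a metal-mediated part

    Vmet = sum_k [INT rho_A(r)/|r - s_k| dr] q_k(rho_D),

the acceptor potential at the tesserae contracted with the response charges
induced by the donor.  The golden-rule transfer rate is
Gamma_EET = (2*pi/hbar) |V0 + Vmet|^2 J with spectral overlap J in 1/eV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .units import (
    BOHR_PER_NM,
    HARTREE_EV,
    HBAR_EVS,
    ev_to_hartree,
    hartree_to_ev,
    nm_to_bohr,
)

__all__ = [
    "Emitter",
    "DensityGrid",
    "potential_at",
    "coulomb_coupling",
    "overlap_term",
    "metal_mediated_coupling",
    "eet_rate",
    "ProximityError",
]

_MIN_SEPARATION_AU = 1e-6


class ProximityError(ValueError):
    pass


@dataclass
class DensityGrid:
    """Regular voxel grid of a transition density (values in e/bohr^3)."""

    origin: np.ndarray  # (3,) nm, centre of the first voxel
    spacing: np.ndarray  # (3,) nm
    values: np.ndarray  # (nx, ny, nz)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.values = np.asarray(self.values, float)

    @property
    def voxel_volume_au(self) -> float:
        return float(np.prod(self.spacing * BOHR_PER_NM))

    def points_nm(self) -> np.ndarray:
        nx, ny, nz = self.values.shape
        ax = [self.origin[i] + self.spacing[i] * np.arange(n) for i, n in enumerate((nx, ny, nz))]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([x.ravel() for x in g], axis=1)

    def total_charge(self) -> float:
        return float(self.values.sum() * self.voxel_volume_au)

    def dipole_au(self) -> np.ndarray:
        pts = nm_to_bohr(self.points_nm())
        return self.values.ravel() @ pts * self.voxel_volume_au


@dataclass
class Emitter:
    """One molecular transition (position/grid geometry in nm, moments a.u.)."""

    label: str
    position: np.ndarray  # (3,) nm
    omega: float  # transition energy, eV
    dipole: np.ndarray  # (3,) a.u.
    eta0: float = 1.0  # intrinsic (vacuum) quantum efficiency
    monopole_positions: Optional[np.ndarray] = None  # (m, 3) nm
    monopole_charges: Optional[np.ndarray] = None  # (m,) a.u.
    grid: Optional[DensityGrid] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        self.dipole = np.asarray(self.dipole, float)
        if not (0.0 < self.eta0 <= 1.0):
            raise ValueError("eta0 must lie in (0, 1]")
        if (self.monopole_positions is None) != (self.monopole_charges is None):
            raise ValueError("monopole positions and charges must come together")
        if self.monopole_positions is not None:
            self.monopole_positions = np.asarray(self.monopole_positions, float)
            self.monopole_charges = np.asarray(self.monopole_charges, float)
            q, r = self.monopole_charges, nm_to_bohr(self.monopole_positions)
            if abs(q.sum()) > 1e-10:
                raise ValueError(f"monopole charges must sum to zero (got {q.sum():.2e})")
            if np.max(np.abs(q @ r - self.dipole)) > 1e-8:
                raise ValueError("monopole first moment does not reproduce the dipole")
        if self.grid is not None and abs(self.grid.total_charge()) > 1e-6:
            raise ValueError("grid transition density must integrate to zero")

    @property
    def representation(self) -> str:
        if self.monopole_positions is not None:
            return "monopoles"
        if self.grid is not None:
            return "grid"
        return "point-dipole"

    def translated(self, shift_nm) -> "Emitter":
        shift = np.asarray(shift_nm, float)
        new = replace(self, position=self.position + shift)
        if self.monopole_positions is not None:
            new.monopole_positions = self.monopole_positions + shift
        if self.grid is not None:
            new.grid = DensityGrid(self.grid.origin + shift, self.grid.spacing, self.grid.values)
        return new


# ---------------------------------------------------------------------------
# potentials


def _charges_and_points_au(emitter: Emitter):
    """(positions_bohr, charges) of the discrete representation, or None for
    a point dipole."""
    if emitter.representation == "monopoles":
        return nm_to_bohr(emitter.monopole_positions), emitter.monopole_charges
    if emitter.representation == "grid":
        pts = nm_to_bohr(emitter.grid.points_nm())
        return pts, emitter.grid.values.ravel() * emitter.grid.voxel_volume_au
    return None


def potential_at(emitter: Emitter, points_nm) -> np.ndarray:
    """Electrostatic transition potential (a.u.) at a set of points (nm)."""
    pts = np.atleast_2d(nm_to_bohr(np.asarray(points_nm, float)))
    rep = _charges_and_points_au(emitter)
    if rep is None:
        r0 = nm_to_bohr(emitter.position)
        d = pts - r0
        r = np.linalg.norm(d, axis=1)
        if r.min() < _MIN_SEPARATION_AU:
            raise ProximityError(f"evaluation point coincides with dipole of {emitter.label}")
        return (d @ emitter.dipole) / r**3
    src, q = rep
    # chunk over evaluation points to bound memory
    out = np.empty(len(pts))
    chunk = max(1, int(4e6 / max(len(src), 1)))
    for i in range(0, len(pts), chunk):
        d = pts[i : i + chunk, None, :] - src[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=2))
        if r.min() < _MIN_SEPARATION_AU:
            k = np.unravel_index(np.argmin(r), r.shape)
            raise ProximityError(
                f"evaluation point {pts[i + k[0]]} (bohr) touches a source point of {emitter.label}"
            )
        out[i : i + chunk] = (1.0 / r) @ q
    return out


# ---------------------------------------------------------------------------
# couplings


def _dipole_dipole_ev(d1: Emitter, d2: Emitter) -> float:
    r = nm_to_bohr(d2.position - d1.position)
    R = np.linalg.norm(r)
    if R < _MIN_SEPARATION_AU:
        raise ProximityError("coincident point dipoles")
    rh = r / R
    v = (d1.dipole @ d2.dipole - 3.0 * (d1.dipole @ rh) * (d2.dipole @ rh)) / R**3
    return hartree_to_ev(v)


def coulomb_coupling(donor: Emitter, acceptor: Emitter) -> float:
    """Direct Coulomb coupling V0 (eV); exact double sums for discrete
    representations, the dipole-dipole formula when both are point dipoles.

    Mixed representations evaluate the potential of one density at the charges
    of the other (each side in its own representation).
    """
    ra, rd = acceptor.representation, donor.representation
    if ra == "point-dipole" and rd == "point-dipole":
        return _dipole_dipole_ev(donor, acceptor)
    # put the discrete representation on the acceptor side
    if ra == "point-dipole":
        donor, acceptor = acceptor, donor
    pts_a, q_a = _charges_and_points_au(acceptor)
    if donor.representation == "point-dipole":
        va = potential_at(donor, acceptor.monopole_positions
                          if acceptor.representation == "monopoles"
                          else acceptor.grid.points_nm())
        return hartree_to_ev(float(q_a @ va))
    pts_d, q_d = _charges_and_points_au(donor)
    chunk = max(1, int(4e6 / max(len(pts_d), 1)))
    tot = 0.0
    for i in range(0, len(pts_a), chunk):
        d = pts_a[i : i + chunk, None, :] - pts_d[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=2))
        if r.min() < _MIN_SEPARATION_AU:
            raise ProximityError("overlapping singular supports in coulomb_coupling")
        tot += q_a[i : i + chunk] @ (1.0 / r) @ q_d
    return hartree_to_ev(float(tot))


def overlap_term(donor: Emitter, acceptor: Emitter, omega0: float) -> float:
    """Density-overlap contribution -w0 * INT rho_A rho_D dr (eV).

    Both emitters must carry grid representations; the acceptor density is
    resampled onto the donor grid by trilinear interpolation when the grids
    differ.  Disjoint supports give exactly 0.
    """
    if donor.grid is None or acceptor.grid is None:
        raise ValueError("overlap_term requires grid representations on both emitters")
    gd, ga = donor.grid, acceptor.grid
    same = (
        gd.values.shape == ga.values.shape
        and np.allclose(gd.origin, ga.origin)
        and np.allclose(gd.spacing, ga.spacing)
    )
    if same:
        prod = float(np.sum(gd.values * ga.values)) * gd.voxel_volume_au
        return -omega0 * prod
    # overlap of bounding boxes
    lo = np.maximum(gd.origin, ga.origin)
    hi = np.minimum(
        gd.origin + gd.spacing * (np.array(gd.values.shape) - 1),
        ga.origin + ga.spacing * (np.array(ga.values.shape) - 1),
    )
    if np.any(hi < lo):
        return 0.0
    from scipy.interpolate import RegularGridInterpolator

    axes = [ga.origin[i] + ga.spacing[i] * np.arange(ga.values.shape[i]) for i in range(3)]
    interp = RegularGridInterpolator(axes, ga.values, bounds_error=False, fill_value=0.0)
    pts = gd.points_nm()
    vals_a = interp(pts).reshape(gd.values.shape)
    prod = float(np.sum(gd.values * vals_a)) * gd.voxel_volume_au
    return -omega0 * prod


def metal_mediated_coupling(donor: Emitter, acceptor: Emitter, solver, omega: float,
                            eps: complex | None = None, modal: bool = False) -> complex:
    """Metal-mediated coupling Vmet (eV) at evaluation frequency omega (eV).

    Vmet = V_A^T Q(omega) V_D: the response charges induced by the donor
    transition potential, contracted with the acceptor transition potential at
    the tessera centroids.  `solver` is a bem.BEMSolver; eps may be passed
    directly to bypass the dielectric model lookup.
    """
    mesh = solver.mesh
    for em in (donor, acceptor):
        # emitters must be outside the metal: nearest centroid acts as proxy
        dmin = np.min(np.linalg.norm(mesh.centroids - em.position, axis=1))
        if dmin <= 0:
            raise ValueError(f"emitter {em.label} touches the metal surface")
    if eps is None:
        raise ValueError("pass the metal permittivity eps at the evaluation frequency")
    vd = potential_at(donor, mesh.centroids)
    va = potential_at(acceptor, mesh.centroids)
    solve = solver.solve_charges_modal if modal else solver.solve_charges
    q = solve(eps, vd, omega=omega, source=donor.label)
    return hartree_to_ev(complex(va @ q.charges))


def eet_rate(v0: float, vmet: complex, J: float) -> float:
    """Golden-rule EET rate (s^-1) from couplings in eV and J in 1/eV."""
    if J < 0:
        raise ValueError("spectral overlap J must be non-negative")
    return 2.0 * np.pi / HBAR_EVS * abs(v0 + vmet) ** 2 * J


# ---------------------------------------------------------------------------
# file readers


def read_monopoles(path):
    """Read a transition-monopole set from an XYZ-like text file.

    Format: a header line '# units: nm|bohr au' (declaring the position
    units; charges are always a.u.), then one 'x y z q' row per monopole.
    Returns (positions_nm, charges_au).
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines[0].startswith("#") or "units:" not in lines[0]:
        raise ValueError("monopole file must start with '# units: <nm|bohr> au'")
    unit = lines[0].split("units:")[1].split()[0]
    if unit not in ("nm", "bohr"):
        raise ValueError(f"unsupported position unit {unit!r}")
    rows = np.array([[float(x) for x in ln.split()] for ln in lines[1:]])
    pos = rows[:, :3] if unit == "nm" else rows[:, :3] / BOHR_PER_NM
    return pos, rows[:, 3]


def read_cube(path) -> DensityGrid:
    """Read a Gaussian-cube-style volumetric transition density.

    Standard cube conventions: lengths in bohr (positive voxel counts),
    values in e/bohr^3; only axis-aligned (diagonal) voxel vectors are
    supported.
    """
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin_bohr = np.array([float(x) for x in lines[2].split()[1:4]])
    ns, spacing = [], []
    for i in range(3):
        parts = lines[3 + i].split()
        n = int(parts[0])
        vec = np.array([float(x) for x in parts[1:4]])
        if n <= 0:
            raise ValueError("only bohr-unit (positive count) cube files are supported")
        if np.count_nonzero(vec) != 1:
            raise ValueError("only axis-aligned cube grids are supported")
        ns.append(n)
        spacing.append(vec[i])
    data = []
    for ln in lines[6 + natoms :]:
        data.extend(float(x) for x in ln.split())
    values = np.array(data).reshape(ns)
    return DensityGrid(
        origin=origin_bohr / BOHR_PER_NM,
        spacing=np.array(spacing) / BOHR_PER_NM,
        values=values,
    )
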