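# Methods

This note records the model, its numerical choices, and the reasoning behind
every default that is not fixed by first principles.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and assumptions

The metal is a local, frequency-dependent dielectric body in the quasistatic
(non-retarded) limit: valid because the junction (tens of nm) is far smaller
than optical wavelengths.  Nonlocality, electron spill-out and atomistic
structure are outside the model.  Molecules enter only through transition
densities (point dipole, monopole set, or voxel grid); exchange/overlap
contributions to the donor–acceptor coupling are not modelled beyond the
density-overlap term, which the package itself shows to be negligible at
the separations of interest (tested: below 1e-4 of the Coulomb term at
≥ 1.6 nm for molecule-scale densities).

The kinetic model is a steady-state branching network: excitation of a donor
state i, transfer i→j with golden-rule rate `(2π/ħ)|V0+Vmet|²J`, and
radiative/nonradiative decay on both sides.  Back-transfer from the acceptor
to the higher-energy donor is excluded.  Excitation weights of the two
degenerate donor states default to equal (tunneling populates both LUMO
channels symmetrically) but are retained in the data model for
unequal-population scenarios.

## Units

Interfaces use eV, nm and s⁻¹.  All electromagnetic internals run in Hartree
atomic units (1 nm = 18.897259886 bohr, ħ = 1, c = 137.035999,
1 a.u. time = 2.418884326e-17 s).  Conversion happens exactly once, at the
module boundaries.

## Dielectric models

The Brendel–Bormann form is a Drude term plus Gaussian-broadened Lorentz
oscillators, evaluated through the Faddeeva function with the branch
`Re α_j ≥ 0`; σ→0 reduces analytically to a plain Lorentz pole (tested to
1e-12).  Convention: time dependence `exp(-iωt)`, so passivity means
`Im ε ≥ 0`, and the analytic continuation obeys `ε(-ω) = ε(ω)*`.  The
shipped silver parameter file is the published Brendel–Bormann fit of
silver's optical constants (provenance and full table inside
`src/nanoret/data/silver_bb_rakic1998.json`); it is a versioned, swappable
input, not a fitted quantity.  Oscillator strengths are dimensionless and
multiply the square of the file's plasma energy; the Drude term carries its
own strength f₀, matching the published convention.

## Boundary-element discretization

Off-diagonal matrix elements are point-collocated at tessera centroids.
Diagonals follow standard PCM practice: `S_ii = 1.0694·sqrt(4π/A_i)` and
`D_ii` fixed by the Calderón sum rule `Σ_j D_ij A_j = -2π` (exact by
construction, tested to 1e-6 on spheres).  Alternatives were evaluated and
rejected: an exact solid-angle double layer (worse near plasmon resonances —
the sum-rule diagonal compensates surface curvature, the exact flat-panel
integral cannot) and exact flat-triangle self-potentials (helps only off
resonance).

Spheres are discretized as *curved* tesserae: representative points projected
radially onto the true sphere, radial normals, areas scaled to the exact
sphere area.  This is the treatment the 1.0694 self-term constant is
calibrated for and reduces the polarizability error at refinement level 3
from ~3% to ~0.03% near resonance.  File round-trips (MSH 2.2 ASCII, OFF)
persist only vertices and faces, so round-trip tests use flat-faceted
spheres.  Tip and substrate meshes are flat-faceted surfaces of revolution.

Two solution paths share one assembly: cached dense LU factorizations per
dielectric value (exact; preferred for a handful of frequencies), and a
one-time eigendecomposition of `DA` after which any frequency costs O(n²)
(used for dense spectra and scans).  The two paths agree to ~1e-13 in tests,
which also exercises the conditioning of the eigenbasis.

## Junction geometries

STML-style junction (`build_tip_a`): the printed facts are the 0.2 nm apex
curvature, the 2.0 nm tip–substrate gap and the molecular plane 1.5 nm above
the substrate.  Cone half-angle, cone height, substrate radius/thickness and
edge rounding are experimentally unknown; they are explicit parameters.
Defaults (half-angle 45°, height 16 nm, substrate radius 8 nm, thickness
4 nm, edge rounding 1.5 nm) were chosen once so that the junction's
brightest z-polarized mode lies near 3 eV — the reported dipolar resonance
of such silver junctions — and checked to be stable (3.00 eV at 1276, 1436
and 1900 tesserae).  Slimmer cones redshift the mode (a 15° cone puts it at
2.45 eV) and very large substrates contribute a fixed bright disk mode near
3.8 eV; both observations are reproducible with the package itself.  In the
quasistatic limit only shape ratios matter, so the mode position is set by
the cone angle while its brightness grows with tip volume.

TEPL-style junction (`build_tip_b`): spherical-cap protrusion (0.5 nm cap,
0.6 nm base) on a large rounded body, lowest metal point 0.4 nm above the
molecular plane at 1.4 nm.  Body dimensions are likewise free parameters
with documented defaults.

Meshes are graded: target edge length grows linearly with arc distance from
the apex (and from the substrate centre), so the tesserae are smallest where
the molecular near fields are largest.  Azimuthal rings shrink naturally
toward the axis.

## Synthetic emitters

Real transition densities for the studied phthalocyanines are not publicly
deposited, so the fixture generator fabricates transition-monopole sets:
random positions in a molecular-plane disc (default radius 0.4 nm, the
phthalocyanine lobe scale), minimum-norm charges that reproduce the target
dipole exactly (`Σq = 0`, `Σ q r = μ` to machine precision), plus null-space
noise at 0.5 of the physical charge scale to roughen higher multipoles the
way a structured molecular density would.  An early variant with
unconstrained unit-scale random charges produced higher multipoles that
dominated all couplings at 1.6–3.2 nm separations — an instructive artifact,
now prevented by construction.

Default transition-dipole magnitudes follow phthalocyanine Q-band oscillator
strengths: 2.4 a.u. per degenerate donor component (f ≈ 0.3) and 1.7 a.u.
per acceptor component (f ≈ 0.15), giving vacuum radiative lifetimes of tens
of ns.  With these, the total coupling |V0+Vmet| at the shortest
experimental separation under resonant response evaluates to ≈ 5 meV —
consistent with the value reported for the real system, which we treat as an
independent check of the scale, not a fitting target.  Intrinsic quantum
efficiencies default to the solution values η₀ = 0.6 (acceptor) and
5×10⁻⁴ (donor); the spectral overlap J defaults to the experimental
1.4 eV⁻¹ and is shared by both acceptor states unless overridden.

What the generator does *not* emulate: the nodal structure of real
transition densities, exchange contributions, and ground-state polarization
by the metal.  Passing tests therefore validate the electromagnetic and
kinetic machinery under molecule-like sources, not the ab initio accuracy of
any specific chromophore.

## Scans and detuning

The donor stays fixed beneath the tip; the acceptor translates in the
molecular plane along the donor–acceptor axis (centre-to-centre distance,
default 1.6–3.2 nm, 8 points).  Donor-side quantities are computed once per
scan.  Detuning scans rigidly shift the frequencies at which the *metal
response* is evaluated, preserving the donor–acceptor difference; molecular
frequencies in the `ω³` radiative prefactor and the vacuum rates never
shift.  The metal-mediated coupling is evaluated at the donor's (shifted)
frequency — the emission side of the transfer; the 0.09 eV donor–acceptor
difference makes this choice immaterial at the present accuracy.

The plasmon-induced Lamb shift `Re Σ q_k V_k` (negative = red shift; no
extra ½ factor — the convention is isolated in one function) is reported but
not fed back into transition energies by default, as the computed shifts are
meV-scale.

Exponential fits run nonlinear least squares on the linear scale initialized
from the log-linear regression; the Förster comparison fit `1/(1+(R/R₀)⁶)`
flags non-identifiability on flat data.  Small negative metal quenching
rates (discretization artifacts for passive metals) are clamped to zero
after logging, threshold 1e-6 relative to the vacuum radiative rate.

## Problem sizes and tolerances

Default problem sizes: icosphere level 3 (1280 tesserae) for sphere
validations, level 4 (5120) where reciprocity demands a refined mesh, and
~1400–1900 tesserae for the junction.  At these sizes the sphere
polarizability is exact to ~0.03–2%, dipole-near-sphere rates match the
independent multipole series within 5% down to 1.2 sphere radii, and the
junction spectrum peak is mesh-converged to the 0.01 eV grid.  Frequency
grids default to 0.01 eV steps.  All stochastic fixtures take explicit
seeds; scan outputs embed a config hash.

## Known limitations

Quasistatic response only (no retardation or radiative corrections to the
metal's response); local dielectric (no nonlocal screening at the 0.2 nm
apex, where such effects are strongest); flat-faceted junction tesserae;
steady-state branching ratios rather than time-resolved kinetics; the
tunneling excitation rate is never modelled (it cancels in the observable);
absolute RET efficiencies depend on tip dimensions and transition densities
that are not experimentally available, so only trends, orderings and fit
behaviour are meaningful claims of this package.
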