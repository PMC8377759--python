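# Methods

## Continuum model

The package treats a biomolecule as a low-dielectric cavity (ε_in = 2) of
atomic spheres carrying fixed partial charges, immersed in water (ε_out = 80)
with mobile 1:1 salt.  The electrostatic potential solves the
Poisson–Boltzmann equation; the *linearized* form is the default because
every validation oracle (Coulomb, Yukawa, superposition, linear force
scaling) exists only for it, and the analyses built on top — surface
polarity, field-line topology, force directions at ≥20 Å separation — are
insensitive to the nonlinear correction at these charge densities.  The full
`sinh` form is available (`SolverConfig(mode="nonlinear")`) as an
under-relaxed Picard iteration around the linear solver (relaxation 0.5, up
to 40 outer cycles, the argument of `sinh` clipped at ±30 kT/e; only
source-adjacent nodes ever approach the clip).

Units are Å, elementary charges, kT/e for potential and kcal/mol for energy.
The Coulomb prefactor in thermal units is derived at run time from
e²/(4πε₀) = 332.0637 kcal·Å/mol and R·T with R = 1.9872×10⁻³ kcal/(mol·K),
T = 300 K, giving C ≈ 557.0 kT·Å/e².  The bulk screening parameter is
κ² = 8π·C·I/ε_out with the ionic strength I converted to particles/Å³; at
0.15 M this yields a Debye length of 7.95 Å.

## Discretization

* **Grid.** Regular, cubic spacing (default 0.5 Å = 2 grid nodes/Å), odd
  node counts so a center node exists, built from the solute bounding box
  plus ≥5 Å padding (default 10 Å).  A hard per-axis cap (321 nodes) turns
  runaway grids into an explicit resource error.
* **Dielectric map.** Assigned on grid *edges*: an edge midpoint inside any
  probe-inflated atom sphere (radius + 1.4 Å) takes ε_in.  This is the van
  der Waals–union surface, not the reentrant molecular surface a
  rolling-probe construction would give; for the charge architectures
  studied here the difference is a thin shell of mislabeled edges with no
  effect on the qualitative results.  Zero-radius atoms (bare test charges)
  create no cavity.
* **Ion exclusion.** κ² is zeroed at nodes within radius + 2.0 Å of any
  atom — a standard Stern-layer width; the value is a convention, not a
  fitted quantity.
* **Charge spreading.** Cubic B-spline over 4 nodes per axis.  The kernel
  conserves the monopole and dipole moments exactly and smooths the source
  over ~2 spacings, which cuts the worst-case anisotropy error of the
  discrete point-source potential (on-axis nodes at r = 3 Å on a 1 Å grid)
  from 5.4% to 4.0% in the screened case; the classic trilinear (8-node)
  assignment remains available (`spreading="trilinear"`).  Because the grid
  self-energy of a spread charge is spacing-dependent, all accuracy checks
  sample the potential at r ≥ 3 Å from sources.
* **Boundary conditions.** Default `per_atom`: a screened-Coulomb
  (Debye–Hückel) sum over all charges on the six faces.  `dipolar` keeps
  only the solute monopole + dipole expanded about the geometric center —
  the two agree within 5% on face nodes ≥20 Å out for compact solutes —
  and `zero` grounds the faces.
* **Solver.** Successive over-relaxation on the 7-point stencil with
  ω = 2/(1 + sin(π/n_max)); a numba-compiled lexicographic Gauss–Seidel
  sweep when numba is importable, otherwise a vectorized red-black sweep
  (both are consistent orderings with the same asymptotic rate).
  Convergence is declared when the per-sweep maximum change, relative to the
  current potential scale, drops below 10⁻⁵ (10⁻⁶ in the validation runs);
  non-convergence raises an error carrying the residual history.

Measured accuracy for a +1 e charge on a 65³/1.0 Å grid in uniform ε = 80:
worst-case error 2.7% (salt-free, vs C/(80 r)) and 4.0% (0.15 M, vs the
Yukawa form) over all nodes with 3 Å ≤ r ≤ 10 Å; halving the spacing
reduces both.

## Fields and field lines

Potentials are sampled trilinearly; E = −∇φ by central differences of the
interpolated potential with step = grid spacing (exact for globally linear
potentials).  Field lines are fixed-step RK4 streamlines of the normalized
field, traced both ways from each seed and joined, ordered from high to low
potential.  A seed spawns a line only if the local |∇φ| reaches the
threshold (default 3.64 kT/(e·Å)); traces stop on leaving the grid margin,
on |E| < 10⁻⁶ kT/(e·Å), at 10⁴ steps, when the RK4 substeps cancel (a
stagnation point, detected as |Δx| < 0.1·step), or when the arc-length
budget — half the maximum length per direction — is exhausted.  Kept lines
therefore satisfy min ≤ length ≤ max exactly (defaults 4.12 and 35.31,
treated as Å in grid coordinates; the sources of these display conventions
do not state units).  Seeding uses deterministic golden-angle dots on
probe-inflated atom spheres, so results are reproducible without any
rendering tool in the loop.

## Forces

The force on a probe group is the qE sum: solve the PB equation with *only*
source charges — by default the probe's cavity is removed too, leaving the
source in pure solvent (`keep_probe_cavity=True` retains the uncharged
cavity) — then F = Σ qᵢE(rᵢ) over probe atoms.  Dielectric-boundary and
ionic-pressure terms are omitted; at the ≥20 Å separations scanned here the
qE term dominates and the checks confirm Newton's-third-law antisymmetry to
<0.1% and the Coulomb magnitude to <2% on dimer fixtures.  "Distance" in a
scan is displacement *added* to the bound pose along the mass-center axis
(d = 0 is the pose itself), not an absolute center-to-center distance; the
axis is fixed from the bound pose.  The attractive/repulsive label is the
sign of the axial force component with a ±10⁻⁹ dead zone mapped to "none".
Mass centers use atomic masses inferred from the leading element letter of
the atom name (H, C, N, O, P, S; anything else 12.0), with a geometric
alternative — the distinction never changes a label on the fixtures.
Pocket-only calculations extract the pocket residues as an isolated charged
group.

## Titration and folding energy

Site charges follow the standard Henderson–Hasselbalch form: charged
fraction × sign, with y = +1 for bases and −1 for acids, base-10 exponent
y(pKa − pH).  An alternative `as_printed` per-site form with an extra 2.3
inside the base-10 exponent and an always-positive term is retained for
comparison; it titrates ~2.3× too steeply and breaks the sign convention,
so it is never the default.  The relative folding energy is the
Tanford–Wyman integral of Q_f − Q_u, accumulated by the trapezoidal rule on
the pH grid (default 0–14, step 0.5; the grid must start at 0 where the
reference ΔG = 0 is defined; the factor is ln 10 = 2.3026, not the rounded
2.3).  At step 0.5 the trapezoid reproduces the closed-form two-state value
(pKa 4 → 6 gives ΔG(14) ≈ 2.745 kcal/mol) to ≪2%.  The stability range is
the widest contiguous grid interval within `tolerance` (default
0.5 kcal/mol) of the curve minimum, ties broken toward the wider then the
lower-pH interval.  Folded pKas are inputs — computing them is a pKa
engine's job, outside this package's scope; unfolded pKas default to
packaged model-compound values (Asp 3.65, Glu 4.45, His 6.45, Cys 8.3,
Tyr 9.6, Lys 10.4, Arg 12.0, termini 8.0/3.2).

## Synthetic fixtures: what they do and do not show

The generators reproduce the *electrostatic architecture* of an
enzyme–DNA recognition complex and nothing else: a two-strand helix with
−1 e per pseudo-nucleotide and one flipped-out base of net −1 e; a
spherical enzyme with one recessed −1 e pocket site ringed by six +1 e
interface sites and four −1 e back-face sites; their bound complex with a
configurable closest-approach gap (landing within +0.05 Å above the request,
never below); and titratable-site sets whose folded-state pKa shifts
(acids ≤ pH 6 down 1.5, bases ≥ pH 9 up 1.5) produce a folding-energy curve
that falls to a flat mid-pH plateau and rises again — with the default 6+6
sites and 0.5 kcal/mol tolerance the detected stable range is pH 5–10.
All randomness (shell jitter, pKa jitter) comes from NumPy's seeded PCG64
generator, recorded in provenance.  Passing tests on these fixtures
demonstrate that the numerics and the sign conventions are right; they say
nothing about force-field quality, conformational flexibility, hydrogen
bonding or any non-electrostatic contribution to real binding, and the
force magnitudes have no absolute meaning for any particular protein.

## Problem sizes and degenerate inputs

The validation and pipeline runs use 1.0 Å grids (65³ for the point-charge
oracles, ~90³ for complex scans), where a solve takes seconds; the 0.5 Å
default matches production practice and scales the same runs to minutes.
Degenerate inputs are handled explicitly: empty structures give uniform
solvent maps and zero net charge, an empty selection is legal, a zero-charge
probe yields a zero force labelled "none", a boundary node coinciding with
an atom center is guarded by a 10⁻⁶ Å minimum distance, and atoms closer
than two nodes to the grid boundary are rejected rather than silently
truncated.

## Known limitations

Single uniform solute dielectric (no residue-specific or Gaussian-smoothed
models); van der Waals–union surface rather than a reentrant molecular
surface; no multigrid or focusing, so very large grids are slow; qE forces
only; no absolute folding energies and no structure-based pKa prediction;
PDB input takes coordinates only and relies on charge templates for
parameterization.
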