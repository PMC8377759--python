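# pbfield

Continuum electrostatics of protein–DNA recognition: finite-difference
Poisson–Boltzmann (PB) potentials, surface-potential and electric-field-line
analysis, electrostatic binding-force scans along a mass-center separation
axis, and pH-dependent relative folding energy from titratable-site pKas.

The package is aimed at structural bioinformaticians studying how a
base-excision-repair enzyme such as uracil-DNA glycosylase (UDG) finds and
holds a damaged DNA base: the DNA backbone is strongly negative, the enzyme's
binding face carries a ring of positive residues around a single negative
pocket site, and the target base flips out of the helix into that pocket.
Whether the *pocket* or the *whole binding interface* supplies the attractive
force is an electrostatics question this toolkit answers quantitatively on
PQR structures — real or synthetic.

## The model

The electrostatic potential φ (in kT/e) satisfies the Poisson–Boltzmann
equation

    ∇·[ε(r) ∇φ(r)] = −4π ρ(r) + ε(r) κ²(r) sinh φ(r)

with a two-valued dielectric ε (solute interior 2, water 80), atomic partial
charges ρ from a PQR file, and Debye–Hückel screening κ set by the salt
concentration (0.15 M ⇒ Debye length ≈ 7.9 Å).  The linearized form is the
default; the full `sinh` form is available.  The equation is discretized on a
regular grid (7-point stencil, dielectric on edges, charges spread by a cubic
B-spline) and solved by successive over-relaxation with screened-Coulomb
boundary conditions.

On top of the solver:

* **Forces** — the source molecule's field is solved with the probe's charges
  removed, and F = Σᵢ qᵢ E(rᵢ) over the probe atoms gives the net force,
  its projection on the source→probe mass-center axis, and an
  attractive/repulsive label.  A separation scan displaces the probe 20–40 Å
  along that axis in 4 Å steps.
* **Field lines** — RK4 streamlines of E = −∇φ seeded on molecular surfaces,
  filtered by seed gradient magnitude (3.64) and arc length (4.12–35.31 Å).
* **Titration** — Henderson–Hasselbalch site charges q(pH) = y·10^{y(pKa−pH)}
  /(1+10^{y(pKa−pH)}) and the Tanford–Wyman integral
  ΔG(pH) = ln(10)·R·T·∫₀^pH (Q_f − Q_u) d pH′, referenced to 0 kcal/mol at
  pH 0 (R = 1.9872×10⁻³ kcal/(mol·K), T = 300 K).

Synthetic generators (`pbfield.synth`) build desk-scale fixtures with the
charge architecture above — a −1 e/residue double helix with a flipped-out
−1 e base, a polar spherical enzyme with a positively ringed pocket face and
negative back, their bound complex, and titratable-site sets whose folding
energy has a flat mid-pH stable region — so the whole pipeline is testable
against analytic oracles without downloading structures.

## Worked example

```python
import numpy as np
from pbfield import (SolverConfig, Selection, make_complex, separation_scan,
                     enzyme_selection, helix_base_selection)

cpx = make_complex(gap=3.0)          # enzyme (chain E) + DNA (chains A/B)
cfg = SolverConfig()                 # eps 2/80, 0.15 M salt, 300 K

whole = separation_scan(cpx, Selection(chains={"E"}),
                        Selection(chains={"A", "B"}), config=cfg, spacing=1.0)
pocket = separation_scan(cpx, enzyme_selection("pocket"),
                         helix_base_selection(), config=cfg, spacing=1.0)
for r in whole:
    print(f"d={r.separation:4.0f}  |F|={r.magnitude:.3e}  {r.label}")
```

prints (kT/(e·Å)):

```
d=  20  |F|=3.507e-02  attractive
d=  24  |F|=1.894e-02  attractive
d=  28  |F|=1.015e-02  attractive
d=  32  |F|=5.799e-03  attractive
d=  36  |F|=3.187e-03  attractive
d=  40  |F|=1.655e-03  attractive
```

while the `pocket` scan is repulsive at every distance — the whole interface,
not the pocket, pulls the DNA in.  The magnitudes fall off monotonically with
separation, faster than Coulombic because of salt screening.

The same workflow is scriptable from the shell:

```sh
pbfield run --scenario full-synthetic --seed 1 --out out/
pbfield synth --kind titration_set --seed 1 --out sites.csv
pbfield titrate --out out/                 # folding_energy.csv + stable range
```

Every run writes a `manifest.json` (inputs, config hash, versions, seed) that
suffices to reproduce it bit-for-bit.

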