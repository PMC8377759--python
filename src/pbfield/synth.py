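"""Deterministic synthetic fixtures emulating a protein-DNA recognition system.

These generators build desk-scale stand-ins for the biological objects
the pipeline analyzes, with the electrostatic structure that matters
preserved and everything else idealized:

* a net-negative double-helix-like "DNA" (one -1 e pseudo-phosphate per
  residue) with a single flipped-out base carrying net -1 e — the
  extrahelical target base of a base-excision-repair complex;
* a polar globular "enzyme": a neutral spherical shell with a recessed
  -1 e pocket site on one face, ringed by positive (Arg/Lys-like)
  interface sites, and a net-negative back face;
* the bound complex, with the flipped base aimed at the pocket;
* titratable-site tables whose folding-energy curve has a flat stable
  region at mid-range pH.

All generators are pure functions of their parameters and seed (the
only PRNG used is NumPy's default PCG64, seeded explicitly), and all
outputs round-trip through PQR I/O.  Every default-sized structure
fits a 96^3 grid at 1.0 Å spacing with 10 Å padding.
"""

from __future__ import annotations

import math

import numpy as np

from .structures import Atom, ChargeTemplate, Selection, Structure, load_charge_template
from .titration import TitratableSite, load_model_pkas

__all__ = [
    "make_dimer",
    "make_helix",
    "make_polar_enzyme",
    "make_complex",
    "make_titration_set",
    "HELIX_FLIPPED_RESIDUE",
    "enzyme_selection",
    "helix_base_selection",
]

#: Residue name the helix generator gives the flipped-out base.
HELIX_FLIPPED_RESIDUE = "RU"

# Base-ring atom names and charges match the packaged RU template (net -1 e
# together with the neutralized P/C1' backbone of the flipped residue).
_BASE_ATOMS = (
    ("N1", -0.20, 1.55),
    ("C2", 0.30, 1.70),
    ("O2", -0.45, 1.52),
    ("N3", -0.30, 1.55),
    ("C4", 0.40, 1.70),
    ("O4", -0.45, 1.52),
    ("C5", -0.20, 1.70),
    ("C6", -0.10, 1.70),
)


def make_dimer(q1: float, q2: float, distance: float) -> Structure:
    """Two atoms on the x-axis (radius 2.0 Å) — the analytic-oracle fixture."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    atoms = [
        Atom("Q1", "ION", 1, "A", np.array([0.0, 0.0, 0.0]), q1, 2.0),
        Atom("Q2", "ION", 1, "B", np.array([distance, 0.0, 0.0]), q2, 2.0),
    ]
    return Structure(atoms, [f"make_dimer q1={q1} q2={q2} d={distance}"])


def make_helix(
    n_residues: int = 10,
    rise: float = 3.4,
    twist: float = 36.0,
    base_index: int = 5,
    radius: float = 9.0,
    flip_out: float = 6.0,
) -> Structure:
    """Two antiparallel strands of pseudo-nucleotides; one flipped-out base.

    Every residue is a 3-atom DN pseudo-nucleotide (P carrying -1 e,
    neutral C1' and N1) on a helix of the given rise (Å/residue) and
    twist (deg/residue).  Residue ``base_index`` of chain A is instead
    an RU residue: its backbone is neutralized and a base ring of net
    -1 e is displaced ``flip_out`` Å radially outward — the
    extrahelical base.  Total net charge is -2 * n_residues e.
    """
    if n_residues < 4:
        raise ValueError("need n_residues >= 4")
    if not (1 <= base_index <= n_residues):
        raise ValueError("base_index out of range")
    atoms: list[Atom] = []
    for chain, angle0 in (("A", 0.0), ("B", math.pi)):
        for i in range(n_residues):
            theta = angle0 + math.radians(twist) * i
            z = rise * i
            u = np.array([math.cos(theta), math.sin(theta), 0.0])
            p_pos = radius * u + np.array([0.0, 0.0, z])
            flipped = chain == "A" and (i + 1) == base_index
            resname = HELIX_FLIPPED_RESIDUE if flipped else "DN"
            p_charge = 0.0 if flipped else -1.0
            atoms.append(Atom("P", resname, i + 1, chain, p_pos, p_charge, 1.9))
            atoms.append(
                Atom("C1'", resname, i + 1, chain, p_pos - 1.5 * u, 0.0, 1.7)
            )
            if flipped:
                center = (radius + flip_out) * u + np.array([0.0, 0.0, z])
                # hexagon-ish ring in the plane spanned by u and z
                for k, (name, q, r) in enumerate(_BASE_ATOMS):
                    ang = 2 * math.pi * k / len(_BASE_ATOMS)
                    offset = 1.3 * (
                        math.cos(ang) * u + math.sin(ang) * np.array([0.0, 0.0, 1.0])
                    )
                    atoms.append(Atom(name, resname, i + 1, chain, center + offset, q, r))
            else:
                atoms.append(
                    Atom("N1", resname, i + 1, chain, p_pos - 3.0 * u, 0.0, 1.55)
                )
    return Structure(
        atoms,
        [
            f"make_helix n={n_residues} rise={rise} twist={twist} "
            f"base_index={base_index}"
        ],
    )


def make_polar_enzyme(
    n_shell: int = 150,
    radius: float = 10.0,
    n_ring: int = 6,
    n_back: int = 4,
    ring_charge: float = 1.0,
    back_charge: float = -1.0,
    seed: int = 0,
) -> Structure:
    """Spherical pseudo-enzyme with a charged binding face and negative back.

    A neutral shell of ``n_shell`` atoms carries, on the +x face, one
    recessed -1 e pocket site (ASP analog) ringed by ``n_ring``
    positive sites (ARG analogs), and on the -x face ``n_back``
    negative sites (GLU analogs).  Selections for "pocket",
    "interface" and "backside" come from :func:`enzyme_selection`.
    """
    if n_shell < 50:
        raise ValueError("need n_shell >= 50")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    # neutral shell: golden-angle spiral with a small seeded jitter
    i = np.arange(n_shell)
    z = 1.0 - 2.0 * (i + 0.5) / n_shell
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    dots = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    jitter = rng.normal(0.0, 0.15, size=dots.shape)
    for k in range(n_shell):
        pos = radius * dots[k] + jitter[k]
        atoms.append(Atom("CA", "GLY", k + 1, "E", pos, 0.0, 1.7))
    rid = n_shell
    # recessed pocket site on the +x face
    rid += 1
    atoms.append(
        Atom("OD1", "ASP", rid, "E", np.array([radius - 2.0, 0.0, 0.0]), -1.0, 1.5)
    )
    # positive ring around the pocket mouth
    cone = math.radians(30.0)
    for k in range(n_ring):
        rid += 1
        ang = 2 * math.pi * k / n_ring
        d = np.array(
            [math.cos(cone), math.sin(cone) * math.cos(ang), math.sin(cone) * math.sin(ang)]
        )
        atoms.append(Atom("NH1", "ARG", rid, "E", (radius + 0.5) * d, ring_charge, 1.6))
    # negative back face
    back_cone = math.radians(25.0)
    for k in range(n_back):
        rid += 1
        ang = 2 * math.pi * k / n_back + 0.4
        d = np.array(
            [
                -math.cos(back_cone),
                math.sin(back_cone) * math.cos(ang),
                math.sin(back_cone) * math.sin(ang),
            ]
        )
        atoms.append(Atom("OE1", "GLU", rid, "E", (radius + 0.5) * d, back_charge, 1.5))
    return Structure(
        atoms,
        [f"make_polar_enzyme n_shell={n_shell} radius={radius} seed={seed} (PCG64)"],
    )


def enzyme_selection(which: str) -> Selection:
    """Named selections on the polar enzyme: pocket, interface, backside, shell."""
    names = {
        "pocket": {"ASP"},
        "interface": {"ASP", "ARG"},
        "ring": {"ARG"},
        "backside": {"GLU"},
        "shell": {"GLY"},
    }
    if which not in names:
        raise ValueError(f"unknown enzyme selection {which!r}")
    return Selection(residue_names=frozenset(names[which]))


def helix_base_selection() -> Selection:
    """The flipped-out base residue (net -1 e) of a generated helix/complex."""
    return Selection(residue_names=frozenset({HELIX_FLIPPED_RESIDUE}))


def make_complex(
    enzyme: Structure | None = None,
    helix: Structure | None = None,
    gap: float = 3.0,
    seed: int = 0,
) -> Structure:
    """Bound pose: helix beside the enzyme, flipped base aimed at the pocket.

    The helix is rotated about its axis so the extrahelical base points
    toward the enzyme's +x pocket face, then slid along x until the
    closest interatomic approach equals ``gap`` (Å, within 0.05).
    Chains distinguish the molecules (enzyme E, helix A/B).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0 (overlapping placement)")
    if enzyme is None:
        enzyme = make_polar_enzyme(seed=seed)
    if helix is None:
        helix = make_helix()
    helix = helix.copy()
    # locate the flipped base and the helix geometry
    base_atoms = [a for a in helix if a.residue_name == HELIX_FLIPPED_RESIDUE]
    if not base_atoms:
        raise ValueError("helix has no flipped base residue")
    base_center = np.mean([a.position for a in base_atoms], axis=0)
    axis_xy = np.array([base_center[0], base_center[1], 0.0])
    theta = math.atan2(axis_xy[1], axis_xy[0])
    # rotate helix about z so the base points along -x, then place at +x
    rot = -(theta - math.pi)
    c, s = math.cos(rot), math.sin(rot)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    for a in helix.atoms:
        a.position = R @ a.position
    # center the helix z-extent on the pocket plane (z = 0)
    zmid = 0.5 * (helix.positions[:, 2].min() + helix.positions[:, 2].max())
    for a in helix.atoms:
        a.position = a.position + np.array([0.0, 0.0, -zmid])

    enz_pos = enzyme.positions
    enz_rad = enzyme.radii

    def min_gap(shift: float) -> float:
        hp = helix.positions + np.array([shift, 0.0, 0.0])
        d = np.linalg.norm(hp[:, None, :] - enz_pos[None, :, :], axis=2)
        return float(d.min())

    # slide along +x until the closest approach equals the requested gap,
    # landing on the open side of it (never closer than requested)
    shift = 2.0 * (enz_rad.max() + 10.0)
    for _ in range(60):
        err = min_gap(shift) - gap
        if abs(err) < 0.02:
            break
        shift -= err
    while min_gap(shift) < gap:
        shift += 0.01
    for a in helix.atoms:
        a.position = a.position + np.array([shift, 0.0, 0.0])

    merged = Structure(
        [a.copy() for a in enzyme.atoms] + [a.copy() for a in helix.atoms],
        enzyme.provenance + helix.provenance,
    )
    merged.log(f"make_complex gap={gap} shift={shift:.3f}")
    return merged


# ---------------------------------------------------------------------------
# Titration fixtures
# ---------------------------------------------------------------------------

_SHIFT_PROFILES = ("null", "udg_like")


def make_titration_set(
    n_acids: int = 6,
    n_bases: int = 6,
    shift_profile: str = "udg_like",
    seed: int = 0,
    jitter: float = 0.3,
) -> list[TitratableSite]:
    """Titratable sites with model unfolded pKas and profiled folded shifts.

    ``null`` leaves folded = unfolded (flat energy curve).  ``udg_like``
    stabilizes the folded state against both extremes: acidic groups
    with model pKa <= 6 are shifted down by 1.5 units on folding and
    basic groups with model pKa >= 9 up by 1.5, producing a folding
    energy that falls through pH 2-5, stays flat through mid-range pH
    and rises above pH 10 — the signature of a protein most stable
    near neutral pH.
    """
    if n_acids + n_bases < 1:
        raise ValueError("need at least one site")
    if shift_profile not in _SHIFT_PROFILES:
        raise ValueError(f"shift_profile must be one of {_SHIFT_PROFILES}")
    rng = np.random.default_rng(seed)
    model = load_model_pkas()
    acids = [(k, v[1]) for k, v in model.items() if v[0] == -1]
    bases = [(k, v[1]) for k, v in model.items() if v[0] == +1]
    sites: list[TitratableSite] = []
    for n, pool, y in ((n_acids, acids, -1), (n_bases, bases, +1)):
        for i in range(n):
            label, pka0 = pool[i % len(pool)]
            pka_u = pka0 + float(rng.uniform(-jitter, jitter))
            if shift_profile == "null":
                shift = 0.0
            else:
                if y == -1:
                    shift = -1.5 if pka_u <= 6.0 else 0.0
                else:
                    shift = +1.5 if pka_u >= 9.0 else 0.0
            sites.append(
                TitratableSite(
                    label=f"{label}{i + 1}",
                    y=y,
                    pka_unfolded=round(pka_u, 2),
                    pka_folded=round(pka_u + shift, 2),
                )
            )
    return sites


def helix_mutation_template() -> ChargeTemplate:
    """The packaged template holding the RU base and its C replacement."""
    return load_charge_template("nucleotide_charges")
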