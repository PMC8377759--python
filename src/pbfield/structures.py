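"""Atomic structures with partial charges and radii.

The continuum-electrostatics pipeline operates on PQR-style structures:
ordered atom records carrying coordinates (Å), partial charges (e) and
radii (Å), grouped by chain and residue.  This module covers the whole
structure-preparation workflow: PQR/PDB input, charge-template
assignment, residue mutation (charge-template swap on name-matched
atoms), group selection, mass centers, net charges and rigid
translations.

The PQR dialect is the whitespace-delimited one emitted by PDB2PQR:
``ATOM serial name resname [chain] resid x y z charge radius`` with the
chain column optional.  Round trips through :func:`read_pqr` /
:func:`write_pqr` are the identity on every numeric field at the
serialized precision (4 decimals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "ChargeTemplate",
    "Selection",
    "read_pqr",
    "write_pqr",
    "read_pdb",
    "load_charge_template",
    "assign_charges",
    "mutate_residue",
    "select_group",
    "mass_center",
    "net_charge",
    "translate_group",
]

# Masses for the mass-center computation, keyed by the first alphabetic
# character of the atom name.  Unknown elements fall back to 12.0.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}
DEFAULT_MASS = 12.0

WATER_RESIDUES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "H2O"}


class PQRParseError(ValueError):
    """A malformed ATOM/HETATM record; the message names the line number."""


class TemplateLookupError(KeyError):
    """Residue or atom names missing from a charge template."""


class MutationError(ValueError):
    """Mutation impossible: fewer than 3 atom names shared with the template."""


@dataclass
class Atom:
    """One atom record: label, residue, chain, position (Å), charge (e), radius (Å)."""

    name: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    charge: float
    radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.radius < 0:
            raise ValueError(f"radius must be non-negative, got {self.radius}")

    @property
    def mass(self) -> float:
        for ch in self.name:
            if ch.isalpha():
                return ELEMENT_MASSES.get(ch.upper(), DEFAULT_MASS)
        return DEFAULT_MASS

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


class Structure:
    """An ordered collection of atoms plus a provenance trail.

    The (chain, residue_id, atom name) triple is unique within a
    structure; iteration order is the record order of the source file or
    generator.  ``provenance`` is a free-text record of the edits
    (mutations, translations) applied since creation.
    """

    def __init__(self, atoms: Iterable[Atom] = (), provenance: Sequence[str] = ()):
        self.atoms: list[Atom] = list(atoms)
        self.provenance: list[str] = list(provenance)
        self._check_unique()

    def _check_unique(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.residue_id, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom key {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    def copy(self) -> "Structure":
        return Structure((a.copy() for a in self.atoms), self.provenance)

    # -- array views -------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_id, residue_name) triples."""
        out, seen = [], set()
        for a in self.atoms:
            key = (a.chain, a.residue_id, a.residue_name)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def log(self, event: str) -> None:
        self.provenance.append(event)


@dataclass
class Selection:
    """A predicate over (chain, residue_id, residue_name), or an explicit index list.

    Any combination of the keyword filters is ANDed; ``indices`` (atom
    positions in record order) bypasses the predicate entirely.  An
    empty selection is legal and resolves to no atoms.
    """

    chains: frozenset[str] | None = None
    residue_ids: frozenset[int] | None = None
    residue_names: frozenset[str] | None = None
    indices: tuple[int, ...] | None = None
    predicate: Callable[[str, int, str], bool] | None = None

    def __post_init__(self) -> None:
        if self.chains is not None:
            self.chains = frozenset(self.chains)
        if self.residue_ids is not None:
            self.residue_ids = frozenset(self.residue_ids)
        if self.residue_names is not None:
            self.residue_names = frozenset(self.residue_names)
        if self.indices is not None:
            self.indices = tuple(self.indices)

    def resolve(self, structure: Structure) -> list[int]:
        if self.indices is not None:
            return list(self.indices)
        out = []
        for i, a in enumerate(structure.atoms):
            if self.chains is not None and a.chain not in self.chains:
                continue
            if self.residue_ids is not None and a.residue_id not in self.residue_ids:
                continue
            if self.residue_names is not None and a.residue_name not in self.residue_names:
                continue
            if self.predicate is not None and not self.predicate(
                a.chain, a.residue_id, a.residue_name
            ):
                continue
            out.append(i)
        return out

    def complement(self, structure: Structure) -> "Selection":
        inside = set(self.resolve(structure))
        return Selection(indices=tuple(i for i in range(len(structure)) if i not in inside))


class ChargeTemplate:
    """residue_name -> {atom name -> (charge e, radius Å)} lookup table."""

    def __init__(self, entries: dict[str, dict[str, tuple[float, float]]]):
        self.entries = entries

    def residues(self) -> list[str]:
        return list(self.entries)

    def net_charge(self, residue_name: str) -> float:
        return float(sum(q for q, _ in self.entries[residue_name].values()))

    def __contains__(self, residue_name: str) -> bool:
        return residue_name in self.entries

    def lookup(self, residue_name: str, atom_name: str) -> tuple[float, float]:
        return self.entries[residue_name][atom_name]

    @classmethod
    def from_text(cls, text: str) -> "ChargeTemplate":
        entries: dict[str, dict[str, tuple[float, float]]] = {}
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"template line {ln}: expected 4 fields, got {len(parts)}")
            res, atom, q, r = parts
            entries.setdefault(res, {})[atom] = (float(q), float(r))
        return cls(entries)


def load_charge_template(name: str = "nucleotide_charges") -> ChargeTemplate:
    """Load a packaged charge template (plain-text: residue atom charge radius)."""
    text = resources.files("pbfield.data").joinpath(f"{name}.txt").read_text()
    return ChargeTemplate.from_text(text)


# ---------------------------------------------------------------------------
# PQR / PDB I/O
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path, keep_het: bool = False) -> Structure:
    """Parse a whitespace-delimited PQR file.

    Each ATOM/HETATM record needs at least 10 whitespace-separated
    fields; the chain column is optional (10 fields means blank chain).
    Charge and radius are the last two numeric fields.  HETATM records
    and water residues are dropped unless ``keep_het`` is set.
    """
    path = Path(path)
    atoms = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0] not in ("ATOM", "HETATM"):
                continue
            rec = parts[0]
            if len(parts) < 10:
                raise PQRParseError(
                    f"{path.name}:{ln}: ATOM/HETATM record has {len(parts)} fields, need >= 10"
                )
            try:
                name, resname = parts[2], parts[3]
                chain = parts[4] if len(parts) >= 11 else ""
                resid = int(parts[-6])
                x, y, z, q, r = (float(v) for v in parts[-5:])
            except (ValueError, IndexError) as exc:
                raise PQRParseError(f"{path.name}:{ln}: cannot parse record: {exc}") from exc
            if not keep_het and (rec == "HETATM" or resname.upper() in WATER_RESIDUES):
                continue
            atoms.append(Atom(name, resname, resid, chain, np.array([x, y, z]), q, r))
    return Structure(atoms, provenance=[f"read_pqr {path.name}"])


def write_pqr(structure: Structure, path: str | Path) -> None:
    """Serialize to the whitespace PQR dialect, charge then radius last.

    Formatting is deterministic (coordinates, charges and radii at 4
    decimals), so a read/write cycle is a fixed point after the first
    write.
    """
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    with open(path, "w") as fh:
        for i, a in enumerate(structure, start=1):
            chain = f" {a.chain}" if a.chain else ""
            x, y, z = a.position
            fh.write(
                f"ATOM  {i:6d} {a.name:<4s} {a.residue_name:<4s}{chain} "
                f"{a.residue_id:5d} {x:11.4f} {y:11.4f} {z:11.4f} "
                f"{a.charge:9.4f} {a.radius:8.4f}\n"
            )


def read_pdb(path: str | Path, keep_het: bool = False) -> Structure:
    """Read a PDB file (coordinates only) via Bio.PDB.

    Charges and radii are zeroed; use :func:`assign_charges` with a
    template to populate them.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))[0]
    atoms = []
    for chain in model:
        for res in chain:
            hetflag = res.id[0].strip()
            resname = res.get_resname().strip()
            if not keep_het and (hetflag or resname.upper() in WATER_RESIDUES):
                continue
            for at in res:
                atoms.append(
                    Atom(
                        at.get_name(),
                        resname,
                        res.id[1],
                        chain.id.strip(),
                        np.array(at.get_coord(), dtype=float),
                        0.0,
                        0.0,
                    )
                )
    return Structure(atoms, provenance=[f"read_pdb {Path(path).name}"])


# ---------------------------------------------------------------------------
# Editing and queries
# ---------------------------------------------------------------------------

def assign_charges(structure: Structure, template: ChargeTemplate) -> Structure:
    """Overwrite charges and radii from a template by (residue, atom) lookup.

    Every residue and atom name must exist in the template; offenders
    are collected and reported together.  Idempotent.
    """
    missing = []
    out = []
    for a in structure:
        if a.residue_name not in template:
            missing.append(f"residue {a.residue_name}")
            continue
        try:
            q, r = template.lookup(a.residue_name, a.name)
        except KeyError:
            missing.append(f"{a.residue_name}.{a.name}")
            continue
        out.append(replace(a, position=a.position.copy(), charge=q, radius=r))
    if missing:
        raise TemplateLookupError(
            "template lookup failed for: " + ", ".join(sorted(set(missing)))
        )
    result = Structure(out, structure.provenance)
    result.log("assign_charges")
    return result


def mutate_residue(
    structure: Structure,
    chain: str,
    residue_id: int,
    new_residue_name: str,
    template: ChargeTemplate,
) -> Structure:
    """Retype one residue by charge-template swap on name-matched atoms.

    Atoms of the target residue whose names appear in the new template
    keep their coordinates and take the template's charges/radii; atoms
    without a template entry are dropped with a warning, as are template
    atoms with no positional counterpart (no geometry is rebuilt — only
    charges enter the electrostatics).  Fewer than 3 shared atom names
    means there is no common scaffold to graft onto.
    """
    if new_residue_name not in template:
        raise TemplateLookupError(f"residue {new_residue_name} not in template")
    target = [
        i
        for i, a in enumerate(structure)
        if a.chain == chain and a.residue_id == residue_id
    ]
    if not target:
        raise ValueError(f"no residue (chain={chain!r}, id={residue_id})")
    tmpl_atoms = template.entries[new_residue_name]
    target_names = {structure[i].name for i in target}
    matched = target_names & set(tmpl_atoms)
    if len(matched) < 3:
        raise MutationError(
            f"only {len(matched)} atom names shared with template {new_residue_name}; "
            "need >= 3 for a common scaffold"
        )
    dropped = sorted(target_names - matched)
    absent = sorted(set(tmpl_atoms) - target_names)
    if dropped:
        logger.warning("mutation drops atoms without template entry: %s", dropped)
    if absent:
        logger.warning(
            "template atoms with no positional counterpart (not built): %s", absent
        )
    old_name = structure[target[0]].residue_name
    out = []
    for i, a in enumerate(structure):
        if i in target:
            if a.name not in matched:
                continue
            q, r = tmpl_atoms[a.name]
            out.append(
                replace(
                    a,
                    position=a.position.copy(),
                    residue_name=new_residue_name,
                    charge=q,
                    radius=r,
                )
            )
        else:
            out.append(a.copy())
    result = Structure(out, structure.provenance)
    result.log(
        f"mutate chain={chain!r} resid={residue_id} {old_name}->{new_residue_name}"
        + (f" dropped={dropped}" if dropped else "")
    )
    return result


def select_group(structure: Structure, selection: Selection) -> Structure:
    """Order-preserving subset view of a structure (empty result allowed)."""
    idx = selection.resolve(structure)
    return Structure([structure[i] for i in idx], structure.provenance)


def mass_center(group: Structure | Sequence[Atom], geometric: bool = False) -> np.ndarray:
    """Mass-weighted mean position (Å); ``geometric=True`` ignores masses.

    Masses come from the first alphabetic character of the atom name
    (H, C, N, O, P, S), with 12.0 for anything unrecognized.
    """
    atoms = list(group)
    if not atoms:
        raise ValueError("mass center of an empty group is undefined")
    pos = np.array([a.position for a in atoms])
    if geometric:
        return pos.mean(axis=0)
    w = np.array([a.mass for a in atoms])
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def net_charge(group: Structure | Sequence[Atom]) -> float:
    """Sum of partial charges (e); 0 for an empty group."""
    return float(sum(a.charge for a in group))


def translate_group(
    structure: Structure, selection: Selection, vector: np.ndarray
) -> Structure:
    """Rigidly displace the selected atoms by ``vector`` (Å); others untouched."""
    vector = np.asarray(vector, dtype=float)
    idx = set(selection.resolve(structure))
    out = []
    for i, a in enumerate(structure):
        if i in idx:
            out.append(replace(a, position=a.position + vector))
        else:
            out.append(a.copy())
    result = Structure(out, structure.provenance)
    result.log(f"translate {len(idx)} atoms by {np.round(vector, 6).tolist()}")
    return result
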