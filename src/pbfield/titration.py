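"""pH-dependent net charges and relative folding energy from site pKas.

Each titratable site contributes a Henderson-Hasselbalch charge: for a
site of sign y (+1 basic, -1 acidic) and pKa,

    q(pH) = y * 10^(y (pKa - pH)) / (1 + 10^(y (pKa - pH)))   [e]

i.e. the charged fraction times the sign, which is -0.5 e for an acid
at its pKa and approaches +1 e for a base far below its pKa.  The
relative folding energy follows the Tanford-Wyman linkage relation,

    dG(pH) = ln(10) R T * Integral_0^pH [ Q_f - Q_u ] d(pH'),

integrated by the trapezoidal rule on the pH grid (default 0 to 14 in
steps of 0.5) and referenced to 0 kcal/mol at pH 0.  Folded pKas are
inputs (from any pKa engine); unfolded pKas default to packaged model
values.

An alternative ``as_printed`` per-site form — an extra factor 2.3
inside the base-10 exponent and an always-positive term — is kept for
comparison; it double-steepens the titration and contradicts the sign
convention of y, so it is not the default.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .pbe import R_GAS_KCAL

__all__ = [
    "TitratableSite",
    "TitrationCurve",
    "FoldingEnergyCurve",
    "default_ph_grid",
    "site_charge",
    "net_charge_curve",
    "folding_energy_curve",
    "stability_range",
    "load_model_pkas",
    "read_site_table",
    "write_site_table",
    "write_curve_csv",
]

TEMPERATURE_K = 300.0
FORMS = ("standard", "as_printed")


@dataclass(frozen=True)
class TitratableSite:
    """One ionizable group: label, sign y (+1 base / -1 acid), pKas."""

    label: str
    y: int
    pka_unfolded: float
    pka_folded: float

    def __post_init__(self):
        if self.y not in (-1, +1):
            raise ValueError(f"y must be -1 (acid) or +1 (base), got {self.y}")
        if not (math.isfinite(self.pka_unfolded) and math.isfinite(self.pka_folded)):
            raise ValueError("pKas must be finite")

    def pka(self, state: str) -> float:
        if state == "folded":
            return self.pka_folded
        if state == "unfolded":
            return self.pka_unfolded
        raise ValueError(f"state must be 'folded' or 'unfolded', got {state!r}")


@dataclass
class TitrationCurve:
    """Net charge Q(pH) in e for one protonation state of the molecule."""

    ph: np.ndarray
    charge: np.ndarray
    state: str


@dataclass
class FoldingEnergyCurve:
    """Relative folding energy dG(pH) in kcal/mol, dG(0) = 0 by construction."""

    ph: np.ndarray
    energy: np.ndarray
    gas_constant: float = R_GAS_KCAL
    temperature: float = TEMPERATURE_K


def default_ph_grid(start: float = 0.0, stop: float = 14.0, step: float = 0.5) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def site_charge(
    site: TitratableSite, ph: float | np.ndarray, state: str, form: str = "standard"
) -> float | np.ndarray:
    """Charge of one site (e) at the given pH for the chosen pKa state."""
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}, got {form!r}")
    pka = site.pka(state)
    ph_arr = np.asarray(ph, dtype=float)
    if form == "standard":
        x = 10.0 ** (site.y * (pka - ph_arr))
        val = site.y * x / (1.0 + x)
    else:  # literal printed form: extra 2.3 in the exponent, positive term
        x = 10.0 ** (-2.3 * site.y * (ph_arr - pka))
        val = x / (1.0 + x)
    return float(val) if np.isscalar(ph) else val


def net_charge_curve(
    sites: list[TitratableSite],
    state: str,
    grid: np.ndarray | None = None,
    form: str = "standard",
) -> TitrationCurve:
    """Pointwise sum of site charges over the pH grid (e)."""
    if grid is None:
        grid = default_ph_grid()
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("pH grid must be strictly increasing with >= 2 points")
    q = np.zeros_like(grid)
    for s in sites:
        q = q + site_charge(s, grid, state, form)
    return TitrationCurve(ph=grid, charge=q, state=state)


def folding_energy_curve(
    sites: list[TitratableSite],
    grid: np.ndarray | None = None,
    form: str = "standard",
) -> FoldingEnergyCurve:
    """Tanford-Wyman integral of Q_f - Q_u, referenced to 0 at pH 0.

    The grid must start at pH 0 — the reference is defined there — and
    the integral is accumulated with the trapezoidal rule.
    """
    if grid is None:
        grid = default_ph_grid()
    grid = np.asarray(grid, dtype=float)
    if abs(grid[0]) > 1e-12:
        raise ValueError("pH grid must start at 0 (the reference point)")
    qf = net_charge_curve(sites, "folded", grid, form).charge
    qu = net_charge_curve(sites, "unfolded", grid, form).charge
    diff = qf - qu
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (diff[1:] + diff[:-1]) * np.diff(grid))]
    )
    energy = math.log(10.0) * R_GAS_KCAL * TEMPERATURE_K * integral
    return FoldingEnergyCurve(ph=grid, energy=energy)


def stability_range(
    curve: FoldingEnergyCurve, tolerance: float = 0.5
) -> tuple[float, float]:
    """Widest contiguous pH interval with dG <= min(dG) + tolerance.

    Ties are broken toward the wider interval, then toward lower pH.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ok = curve.energy <= curve.energy.min() + tolerance
    best: tuple[float, float] | None = None
    best_width = -1.0
    i = 0
    n = len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            width = curve.ph[j] - curve.ph[i]
            if width > best_width:
                best_width = width
                best = (float(curve.ph[i]), float(curve.ph[j]))
            i = j + 1
        else:
            i += 1
    assert best is not None  # the minimum itself always qualifies
    return best


# ---------------------------------------------------------------------------
# Site-table I/O
# ---------------------------------------------------------------------------

def load_model_pkas() -> dict[str, tuple[int, float]]:
    """Packaged model pKas: label -> (y, pKa) for the common titratable groups."""
    text = resources.files("pbfield.data").joinpath("model_pkas.csv").read_text()
    out: dict[str, tuple[int, float]] = {}
    for row in csv.DictReader(text.splitlines()):
        y = +1 if row["type"].strip() == "base" else -1
        out[row["label"].strip()] = (y, float(row["pka"]))
    return out


def read_site_table(path: str | Path) -> list[TitratableSite]:
    """Read sites from CSV/TSV: label, type(acid|base), pKa_unfolded, pKa_folded.

    A missing or empty ``pka_unfolded`` falls back to the packaged model
    pKa for the residue type named by the label's alphabetic prefix
    (e.g. "ASP12" -> ASP).
    """
    path = Path(path)
    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    model = load_model_pkas()
    sites = []
    for row in csv.DictReader(text.splitlines(), delimiter=delim):
        label = row["label"].strip()
        kind = row["type"].strip().lower()
        if kind not in ("acid", "base"):
            raise ValueError(f"site {label}: type must be acid or base")
        raw_u = (row.get("pka_unfolded") or "").strip()
        if raw_u:
            pka_u = float(raw_u)
        else:
            prefix = "".join(ch for ch in label if ch.isalpha())
            if prefix not in model:
                raise ValueError(
                    f"site {label}: no pKa_unfolded and no model value for {prefix!r}"
                )
            pka_u = model[prefix][1]
        sites.append(
            TitratableSite(
                label=label,
                y=+1 if kind == "base" else -1,
                pka_unfolded=pka_u,
                pka_folded=float(row["pka_folded"]),
            )
        )
    return sites


def write_site_table(sites: list[TitratableSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "type", "pka_unfolded", "pka_folded"])
        for s in sites:
            w.writerow(
                [
                    s.label,
                    "base" if s.y > 0 else "acid",
                    f"{s.pka_unfolded:.2f}",
                    f"{s.pka_folded:.2f}",
                ]
            )


def write_curve_csv(
    ph: np.ndarray, values: np.ndarray, path: str | Path, header: str = "value"
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pH", header])
        for x, v in zip(ph, values):
            w.writerow([f"{x:.2f}", f"{v:.6f}"])
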