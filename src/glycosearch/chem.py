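"""Elemental building blocks: monosaccharide residues, adducts, shared constants.

All masses are monoisotopic and computed from elemental compositions via
pyteomics, never hard-coded, so the printed reference values (HexNAc
203.0794 Da, Hex 162.0528 Da, dHex 146.0579 Da) are reproduced rather than
transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "Monosaccharide",
    "MONOSACCHARIDES",
    "residue_mass",
    "WATER",
    "PROTON",
    "AMMONIA",
    "OXONIUM_MASSES",
]


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a chemical formula string (e.g. ``'C6H10O5'``)."""
    return _pmass.calculate_mass(formula=formula)


@dataclass(frozen=True)
class Monosaccharide:
    """A monosaccharide residue (dehydrated, as incorporated in a glycan)."""

    name: str
    elemental_composition: Mapping[str, int]
    residue_mass: float

    @classmethod
    def from_formula(cls, name: str, formula: str) -> "Monosaccharide":
        comp = _pmass.Composition(formula=formula)
        return cls(name=name, elemental_composition=dict(comp), residue_mass=comp.mass())


# The six residues built in; the table is extensible at run time via
# `register_monosaccharide`.
_BUILTIN = [
    ("Hex", "C6H10O5"),
    ("HexNAc", "C8H13NO5"),
    ("dHex", "C6H10O4"),
    ("NeuAc", "C11H17NO8"),
    ("NeuGc", "C11H17NO9"),
    ("Pent", "C5H8O4"),
]

MONOSACCHARIDES: Dict[str, Monosaccharide] = {
    name: Monosaccharide.from_formula(name, formula) for name, formula in _BUILTIN
}

#: Sialic acids are labile under collisional dissociation and never ride on
#: peptide+Y fragments.
LABILE = frozenset({"NeuAc", "NeuGc"})


def register_monosaccharide(name: str, formula: str) -> Monosaccharide:
    """Add a residue to the global table (no-op if identical already present)."""
    mono = Monosaccharide.from_formula(name, formula)
    existing = MONOSACCHARIDES.get(name)
    if existing is not None and abs(existing.residue_mass - mono.residue_mass) > 1e-9:
        raise ValueError(f"monosaccharide {name!r} already registered with a different mass")
    MONOSACCHARIDES[name] = mono
    return mono


def residue_mass(name: str) -> float:
    """Monoisotopic residue mass in Da for a monosaccharide symbol."""
    try:
        return MONOSACCHARIDES[name].residue_mass
    except KeyError:
        raise KeyError(f"unknown monosaccharide symbol: {name!r}") from None


WATER = formula_mass("H2O")
PROTON = _pmass.nist_mass["H+"][0][0]  # 1.007276
AMMONIA = formula_mass("NH3")  # ammonium adduct neutral mass, +17.02655 Da

# Oxonium (B-type) diagnostic ions for the sialic acids, singly protonated,
# with and without water loss (NeuAc 292.1027 / 274.0921).  Derived from the
# residue compositions.
def _oxonium(name: str):
    m = residue_mass(name)
    return (m + PROTON, m + PROTON - WATER)


OXONIUM_MASSES: Dict[str, tuple] = {
    "NeuAc": _oxonium("NeuAc"),
    "NeuGc": _oxonium("NeuGc"),
}
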