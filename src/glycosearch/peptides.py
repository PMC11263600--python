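"""Protein digestion, modifications, decoy proteins, backbone fragments,
and proton mobility classification.

Digestion follows the trypsin rule (cleave C-terminal to K/R, not before P)
with configurable missed cleavages; other enzymes may be supplied as a
regular expression.  Decoy proteins are full-sequence reversals that retain
the *positions* of the target's N-glycosylation sequons (mirrored into the
reversed coordinate system) even though the local motif is disrupted; no
sequons arising by chance in the reversed sequence are registered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from pyteomics import mass as _pmass

from .chem import PROTON, WATER, formula_mass

__all__ = [
    "Peptide",
    "BackboneFragment",
    "digest",
    "find_sequons",
    "reverse_decoy",
    "backbone_fragments",
    "proton_mobility",
    "read_fasta",
    "write_fasta",
]

# Monoisotopic residue masses for the 20 amino acids, from pyteomics.
AA_MASSES: Dict[str, float] = dict(_pmass.std_aa_mass)

CARBAMIDOMETHYL = formula_mass("C2H3NO")  # +57.0215, fixed on Cys
OXIDATION = formula_mass("O")  # +15.9949, variable on Met

SEQUON = re.compile(r"(?=(N[^P][ST]))")
TRYPSIN = re.compile(r"[KR](?!P)")


def find_sequons(sequence: str) -> List[int]:
    """0-based positions of N in N-X(!=P)-S/T motifs (overlapping allowed)."""
    return [m.start() for m in SEQUON.finditer(sequence)]


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) peptide with its glycosylation sequons.

    ``n_sites`` are 0-based positions *within the peptide*; ``start`` is the
    0-based offset of the peptide in its parent protein.
    """

    sequence: str
    n_sites: Tuple[int, ...] = ()
    fixed_mods: Tuple[Tuple[int, float], ...] = ()
    variable_mods: Tuple[Tuple[int, float], ...] = ()
    start: int = 0
    protein: str = ""
    is_decoy: bool = False
    #: absolute glycosylation-site coordinates in the *target* protein; for
    #: decoy peptides these are the mirrored positions, so site-model lookups
    #: resolve to the same model as the target counterpart
    target_sites: Tuple[int, ...] = ()

    @property
    def mass(self) -> float:
        m = sum(AA_MASSES[aa] for aa in self.sequence) + WATER
        m += sum(delta for _, delta in self.fixed_mods)
        m += sum(delta for _, delta in self.variable_mods)
        return m

    def mod_at(self, i: int) -> float:
        return sum(d for p, d in self.fixed_mods if p == i) + sum(
            d for p, d in self.variable_mods if p == i
        )


def _cleavage_sites(sequence: str, rule: re.Pattern) -> List[int]:
    """Positions *after* which the backbone is cut."""
    return [m.end() for m in rule.finditer(sequence)]


def digest(
    protein: str,
    enzyme: re.Pattern = TRYPSIN,
    max_missed: int = 2,
    require_sequon: bool = True,
    min_length: int = 2,
    protein_name: str = "",
    is_decoy: bool = False,
    decoy_sites: Optional[Sequence[int]] = None,
) -> List[Peptide]:
    """Enzymatic digest retaining (by default) only sequon-bearing peptides.

    ``decoy_sites`` overrides motif detection with a registry of mirrored
    site positions (protein coordinates), used for reversed decoy proteins.
    """
    if not protein:
        return []
    cuts = [0] + _cleavage_sites(protein, enzyme) + [len(protein)]
    cuts = sorted(set(cuts))
    if decoy_sites is not None:
        site_positions = sorted(set(decoy_sites))
    else:
        site_positions = find_sequons(protein)
    peptides: List[Peptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            start, end = cuts[i], cuts[j]
            seq = protein[start:end]
            if len(seq) < min_length:
                continue
            local_sites = tuple(p - start for p in site_positions if start <= p < end)
            if require_sequon and not local_sites:
                continue
            fixed = tuple((k, CARBAMIDOMETHYL) for k, aa in enumerate(seq) if aa == "C")
            peptides.append(
                Peptide(
                    sequence=seq,
                    n_sites=local_sites,
                    fixed_mods=fixed,
                    start=start,
                    protein=protein_name,
                    is_decoy=is_decoy,
                )
            )
    return peptides


def reverse_decoy(protein: str, sites: Optional[Sequence[int]] = None) -> Tuple[str, List[int]]:
    """Reverse a protein, mirroring its sequon registry.

    Returns ``(reversed_sequence, mirrored_site_positions)``.  Applying the
    operation twice recovers the original registry.
    """
    if sites is None:
        sites = find_sequons(protein)
    L = len(protein)
    mirrored = sorted(L - 1 - p for p in sites)
    return protein[::-1], mirrored


@dataclass(frozen=True)
class BackboneFragment:
    series: str  # 'b' or 'y'
    index: int
    mass: float  # neutral fragment mass
    glycosylated: bool


def backbone_fragments(p: Peptide, occupied: Sequence[int] = ()) -> List[BackboneFragment]:
    """Neutral b/y fragment masses for every cleavage position.

    The ``glycosylated`` flag marks fragments spanning an occupied site; the
    masses themselves are bare (stepped collision energy strips the glycan
    from backbone fragments, and training data follow that convention).
    """
    n = len(p.sequence)
    if n < 2:
        return []
    residue = [AA_MASSES[aa] + p.mod_at(i) for i, aa in enumerate(p.sequence)]
    prefix = [0.0]
    for r in residue:
        prefix.append(prefix[-1] + r)
    total = prefix[-1]
    occ = set(occupied)
    frags: List[BackboneFragment] = []
    for i in range(1, n):
        b_glyco = any(site < i for site in occ)
        y_glyco = any(site >= i for site in occ)
        frags.append(BackboneFragment("b", i, prefix[i], b_glyco))
        frags.append(BackboneFragment("y", n - i, total - prefix[i] + WATER, y_glyco))
    return frags


def proton_mobility(p: Peptide | str, charge: int) -> str:
    """'mobile', 'partial', or 'immobile' from basic-residue count vs charge."""
    seq = p.sequence if isinstance(p, Peptide) else p
    basic = sum(seq.count(aa) for aa in "KRH")
    if basic > charge:
        return "immobile"
    if basic == charge:
        return "partial"
    return "mobile"


def read_fasta(path) -> List[Tuple[str, str]]:
    """(header, sequence) pairs from a plain FASTA file."""
    entries: List[Tuple[str, str]] = []
    header = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    entries.append((header, "".join(chunks)))
                header = line[1:].strip()
                chunks = []
            else:
                chunks.append(line)
    if header is not None:
        entries.append((header, "".join(chunks)))
    return entries


def write_fasta(entries: Iterable[Tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
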