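"""Glycan compositions and composition-level peptide+Y fragment ladders.

A glycan is handled purely as a *composition* (a multiset of monosaccharide
residues), never as a topology.  The peptide+Y ladder is generated
semi-structurally: the canonical N-glycan core motif HexNAc2Hex3 is
enumerated explicitly (its rooted sub-structures become *core* fragments,
optionally decorated with one reducing-end dHex or Pent), and every multiset
combination of the remaining non-labile residues is appended to the full
core motif.  Sialic acids (NeuAc/NeuGc) are treated as labile and never
appear on Y fragments.

The expected number of distinct fragment masses is approximated by
``n_g * ln(n_g)`` for core-fucosylated glycans and half that otherwise,
yielding the coverage normalizer ``d_g``; for ``n_g <= 7`` this degrades
gracefully to ``d_g = n_g``.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .chem import LABILE, MONOSACCHARIDES, residue_mass

__all__ = [
    "GlycanComposition",
    "YFragment",
    "DecoyYLadder",
    "parse_composition",
    "approx_size",
    "coverage_normalizer",
    "generate_y_ladder",
    "make_decoy_ladder",
    "glycan_coverage",
    "read_glycan_list",
]


class GlycanParseError(ValueError):
    pass


@dataclass(frozen=True)
class GlycanComposition:
    """A multiset of monosaccharide residues with derived mass and size."""

    counts: Tuple[Tuple[str, int], ...]
    glycan_type: str = "N"

    @classmethod
    def from_dict(cls, counts: Mapping[str, int], glycan_type: str = "N") -> "GlycanComposition":
        clean = []
        for name in sorted(counts):
            n = int(counts[name])
            if name not in MONOSACCHARIDES:
                raise GlycanParseError(f"unknown monosaccharide symbol: {name!r}")
            if n < 0:
                raise GlycanParseError(f"negative count for {name!r}: {n}")
            if n > 0:
                clean.append((name, n))
        return cls(counts=tuple(clean), glycan_type=glycan_type)

    def __getitem__(self, name: str) -> int:
        return dict(self.counts).get(name, 0)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    @property
    def cardinality(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def mass(self) -> float:
        return sum(n * residue_mass(name) for name, n in self.counts)

    def l1_distance(self, other: "GlycanComposition") -> int:
        a, b = self.as_dict(), other.as_dict()
        keys = set(a) | set(b)
        return sum(abs(a.get(k, 0) - b.get(k, 0)) for k in keys)

    def __str__(self) -> str:
        inner = "; ".join(f"{name}:{n}" for name, n in self.counts)
        return "{" + inner + "}"


_BRACED = re.compile(r"^\{(.*)\}$")
_CONCAT = re.compile(r"([A-Za-z]+)\((\d+)\)")


def parse_composition(text: str, glycan_type: str = "N") -> GlycanComposition:
    """Parse ``"{Hex:5; HexNAc:2}"`` or ``"HexNAc(2)Hex(5)"`` dialects."""
    text = text.strip()
    counts: Dict[str, int] = {}
    m = _BRACED.match(text)
    if m:
        body = m.group(1).strip()
        if body:
            for token in body.split(";"):
                token = token.strip()
                if not token:
                    continue
                if ":" not in token:
                    raise GlycanParseError(f"malformed composition token: {token!r}")
                name, _, num = token.partition(":")
                name = name.strip()
                try:
                    n = int(num.strip())
                except ValueError:
                    raise GlycanParseError(f"malformed count in token: {token!r}") from None
                counts[name] = counts.get(name, 0) + n
    else:
        pos = 0
        for m2 in _CONCAT.finditer(text):
            if m2.start() != pos:
                raise GlycanParseError(f"unparseable composition text: {text!r}")
            counts[m2.group(1)] = counts.get(m2.group(1), 0) + int(m2.group(2))
            pos = m2.end()
        if pos != len(text) or not counts:
            raise GlycanParseError(f"unparseable composition text: {text!r}")
    return GlycanComposition.from_dict(counts, glycan_type=glycan_type)


def read_glycan_list(path) -> List[GlycanComposition]:
    """One composition per line; ``#`` comments and blank lines allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(parse_composition(line))
    return out


def approx_size(g: GlycanComposition) -> int:
    """Approximate glycan size n_g: residues minus sialic acids, minus one
    when two or more dHex are present; floored at 0."""
    n = g.cardinality - g["NeuAc"] - g["NeuGc"] - (1 if g["dHex"] > 1 else 0)
    return max(n, 0)


def coverage_normalizer(g: GlycanComposition) -> float:
    """Fragment-count normalizer d_g.

    ``n_g ln n_g`` when core fucosylation is possible (any dHex present),
    otherwise ``(1/2) n_g ln n_g``; never below ``n_g``, and at least 1.
    """
    n = approx_size(g)
    if n < 2:
        return float(max(n, 1))
    scale = 1.0 if g["dHex"] > 0 else 0.5
    return max(scale * n * math.log(n), float(n))


@dataclass(frozen=True)
class YFragment:
    """A peptide+Y fragment: the intact peptide retaining part of the glycan."""

    attached_composition: GlycanComposition
    is_core: bool

    @property
    def mass_delta(self) -> float:
        return self.attached_composition.mass

    @property
    def glycan_size(self) -> int:
        return self.attached_composition.cardinality


# Rooted sub-structures of the canonical core tree
# HexNAc1 -> HexNAc2 -> Hex(central) -> {Hex, Hex}; at the composition level
# only the distinct (HexNAc, Hex) count pairs matter.
_CORE_STEPS = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2), (2, 3)]


def generate_y_ladder(g: GlycanComposition) -> List[YFragment]:
    """Composition-level peptide+Y ladder for ``g`` (see module docstring).

    Fragments with identical mass_delta are merged; a mass that is reachable
    as a core fragment keeps the core flag.  Y0 (bare peptide) is always
    present and counts as a core fragment.
    """
    counts = g.as_dict()
    has_core = counts.get("HexNAc", 0) >= 2 and counts.get("Hex", 0) >= 3
    by_key: Dict[Tuple[Tuple[str, int], ...], YFragment] = {}

    def add(comp_counts: Dict[str, int], is_core: bool) -> None:
        comp = GlycanComposition.from_dict(comp_counts, glycan_type=g.glycan_type)
        prev = by_key.get(comp.counts)
        if prev is None or (is_core and not prev.is_core):
            by_key[comp.counts] = YFragment(attached_composition=comp, is_core=is_core)

    if has_core:
        decorations = [{}]
        if counts.get("dHex", 0) > 0:
            decorations.append({"dHex": 1})
        if counts.get("Pent", 0) > 0:
            decorations.append({"Pent": 1})
        for hexnac, hexose in _CORE_STEPS:
            for deco in decorations:
                frag = {"HexNAc": hexnac, "Hex": hexose}
                if hexnac == 0 and hexose == 0 and deco:
                    continue  # Y0 carries no decoration
                for k, v in deco.items():
                    frag[k] = frag.get(k, 0) + v
                add(frag, is_core=True)
        # non-core: full core motif plus every combination of the remaining
        # non-labile residues
        remaining = {
            name: n - (2 if name == "HexNAc" else 3 if name == "Hex" else 0)
            for name, n in counts.items()
            if name not in LABILE
        }
        remaining = {k: v for k, v in remaining.items() if v > 0}
        names = sorted(remaining)
        for combo in itertools.product(*(range(remaining[n] + 1) for n in names)):
            if sum(combo) == 0:
                continue
            frag = {"HexNAc": 2, "Hex": 3}
            for name, extra in zip(names, combo):
                frag[name] = frag.get(name, 0) + extra
            add(frag, is_core=False)
    else:
        # combination-only mode for compositions not covering the core motif
        # (small O-glycans and truncated N-glycans)
        nonlabile = {k: v for k, v in counts.items() if k not in LABILE}
        names = sorted(nonlabile)
        for combo in itertools.product(*(range(nonlabile[n] + 1) for n in names)):
            add({name: c for name, c in zip(names, combo) if c > 0}, is_core=False)
        add({}, is_core=True)  # Y0

    return sorted(by_key.values(), key=lambda f: f.mass_delta)


@dataclass(frozen=True)
class DecoyYLadder:
    """A Y-ladder with decoy mass shifts.

    Fragments of glycan size 0 or 1 keep their exact target mass; all others
    carry an independent Uniform(1, 30) Da shift, reproducible from the seed.
    """

    fragments: Tuple[YFragment, ...]
    shifts: Tuple[float, ...]
    seed: int

    def shifted_masses(self) -> np.ndarray:
        return np.array([f.mass_delta + s for f, s in zip(self.fragments, self.shifts)])


DECOY_SHIFT_LOW = 1.0
DECOY_SHIFT_HIGH = 30.0


def make_decoy_ladder(g: GlycanComposition, seed: int) -> DecoyYLadder:
    ladder = generate_y_ladder(g)
    rng = np.random.default_rng(seed)
    shifts = tuple(
        0.0 if f.glycan_size <= 1 else float(rng.uniform(DECOY_SHIFT_LOW, DECOY_SHIFT_HIGH))
        for f in ladder
    )
    return DecoyYLadder(fragments=tuple(ladder), shifts=shifts, seed=seed)


def glycan_coverage(
    matched_masses: Iterable[float],
    g: GlycanComposition,
    ladder: Sequence[YFragment] | None = None,
    mass_tol: float = 1e-6,
) -> Tuple[float, float]:
    """(coverage_G, coverage_G_core) for a set of matched Y-fragment masses.

    coverage_G is the number of distinct matched ladder masses divided by
    d_g, clipped to [0, 1]; coverage_G_core is the matched fraction of
    distinct core-fragment masses.
    """
    if ladder is None:
        ladder = generate_y_ladder(g)
    if not ladder:
        return 0.0, 0.0
    matched = sorted(set(float(m) for m in matched_masses))
    ladder_masses = [(f.mass_delta, f.is_core) for f in ladder]
    n_matched = 0
    n_core = 0
    n_core_matched = 0
    for mass, is_core in ladder_masses:
        hit = any(abs(mass - m) <= mass_tol * max(mass, 1.0) for m in matched)
        if is_core:
            n_core += 1
            if hit:
                n_core_matched += 1
        if hit:
            n_matched += 1
    d_g = coverage_normalizer(g)
    cov = min(n_matched / d_g, 1.0) if d_g > 0 else 0.0
    cov_core = n_core_matched / n_core if n_core else 0.0
    return cov, cov_core
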