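"""Brute-force N-glycan topology oracle.

Builds explicit rooted tree topologies (high-mannose, hybrid, complex-type
with a configurable number of LacNAc antennae, with or without core
fucosylation) and enumerates *exactly* the distinct peptide+Y fragment
masses a topology can produce: every subtree that contains the root
(obtained by cutting any set of edges), plus Y0.

Used only as an independent check that the ``n_g ln n_g`` /
``(1/2) n_g ln n_g`` coverage-normalizer envelope encloses the true
fragment counts; the production code never enumerates topologies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import FrozenSet, List, Tuple

from glycosearch.chem import residue_mass
from glycosearch.glycans import GlycanComposition


@dataclass
class Node:
    name: str
    children: List["Node"] = field(default_factory=list)

    def add(self, name: str) -> "Node":
        child = Node(name)
        self.children.append(child)
        return child

    def composition(self) -> Counter:
        total = Counter([self.name])
        for c in self.children:
            total += c.composition()
        return total


MAX_CLEAVAGES = 3  # simultaneous glycosidic cleavage events per Y fragment


def root_subtree_compositions(node: Node, max_cuts: int = MAX_CLEAVAGES):
    """Composition multisets of subtrees rooted at ``node``, mapped to the
    minimum number of edge cuts needed to produce each."""
    child_sets = [root_subtree_compositions(c, max_cuts) for c in node.children]
    results: dict = {}

    def rec(i: int, acc: Counter, cuts: int) -> None:
        if cuts > max_cuts:
            return
        if i == len(child_sets):
            key = tuple(sorted(acc.items()))
            if key not in results or results[key] > cuts:
                results[key] = cuts
            return
        rec(i + 1, acc, cuts + 1)  # cut this child's edge
        for opt, used in child_sets[i].items():
            rec(i + 1, acc + Counter(dict(opt)), cuts + used)

    rec(0, Counter([node.name]), 0)
    return results


def distinct_y_fragment_masses(root: Node, max_cuts: int = MAX_CLEAVAGES) -> int:
    """Distinct glycan-bearing Y-fragment masses (Y0 excluded: the bare
    peptide carries no glycan information and d_g normalizes glycan evidence)."""
    comps = set(root_subtree_compositions(root, max_cuts))
    masses = {round(sum(n * residue_mass(m) for m, n in comp), 4) for comp in comps}
    return len(masses)


def tree_composition(root: Node) -> GlycanComposition:
    return GlycanComposition.from_dict(dict(root.composition()))


# ---------------------------------------------------------------------------
# topology builders


def _core(fucosylated: bool = False) -> Tuple[Node, Node, Node]:
    """Returns (root, branch_a, branch_b): HexNAc2Hex3 core, optional core dHex."""
    root = Node("HexNAc")
    if fucosylated:
        root.add("dHex")
    gn2 = root.add("HexNAc")
    central = gn2.add("Hex")
    a = central.add("Hex")
    b = central.add("Hex")
    return root, a, b


def high_mannose(n_mannose: int) -> Node:
    """Man4..Man9: core plus extra Hex distributed over the two arms."""
    assert 3 <= n_mannose <= 9
    root, a, b = _core()
    extra = n_mannose - 3
    arms = [a, b]
    tip = {0: a, 1: b}
    for i in range(extra):
        arm = i % 2
        tip[arm] = tip[arm].add("Hex")
    return root


def complex_type(n_antennae: int, lacnac_per_arm: int = 1, fucosylated: bool = False) -> Node:
    """Complex-type: each antenna is (HexNAc-Hex) repeated ``lacnac_per_arm``
    times, distributed over the two core branch mannoses."""
    root, a, b = _core(fucosylated)
    anchors = [a, b]
    for i in range(n_antennae):
        tip = anchors[i % 2]
        for _ in range(lacnac_per_arm):
            gn = tip.add("HexNAc")
            tip = gn.add("Hex")
    return root


def hybrid_type(n_mannose_arm: int = 2, fucosylated: bool = False) -> Node:
    """One mannose arm, one LacNAc antenna."""
    root, a, b = _core(fucosylated)
    tip = a
    for _ in range(n_mannose_arm):
        tip = tip.add("Hex")
    gn = b.add("HexNAc")
    gn.add("Hex")
    return root


def fixture_topologies() -> List[Tuple[str, Node]]:
    """Programmatic fixture set spanning 5-14 residues."""
    out: List[Tuple[str, Node]] = []
    for k in range(4, 10):
        out.append((f"high-mannose-Man{k}", high_mannose(k)))
    for ant in (2, 3, 4):
        out.append((f"complex-{ant}ant", complex_type(ant)))
        out.append((f"complex-{ant}ant-fuc", complex_type(ant, fucosylated=True)))
    out.append(("complex-2ant-polylacnac", complex_type(2, lacnac_per_arm=2)))
    out.append(("hybrid", hybrid_type()))
    out.append(("hybrid-fuc", hybrid_type(fucosylated=True)))
    return out
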