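"""Site-specific glycome network smoothing.

A glycome graph connects glycan compositions that differ by exactly one
monosaccharide.  Each glycosylation site with confidently observed glycans
gets a model: biosynthetic-neighborhood central tendencies τ (via a
membership matrix A), and per-glycan priors u_g propagated from observed
scores through the graph Laplacian, controlled by a smoothing parameter λ
chosen by leave-one-observation-out grid search and capped at 0.2.

The objective minimized over (u, τ) is

    Σ_observed (y_g − u_g)²  +  Σ_unobserved u_g²  +  λ·uᵀLu  +  λ·μ·‖u − Aτ‖²

with μ = 1.  Unobserved compositions carry an absence anchor at zero, so
the credit they receive is proportional to λ (capped at 0.2) times the
evidence flowing in from graph neighbors and neighborhood means — without
the anchor a constant u surface would satisfy every term and credit would
propagate without bound.  At λ = 0 the model reproduces observed scores
exactly and assigns zero credit elsewhere.  u is clipped at 0.

Decoy parity is structural: lookups key on (site, glycan composition) only,
so decoy glycans and decoy-peptide mirrored sites retrieve exactly the
value their target counterparts would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .glycans import GlycanComposition, parse_composition

__all__ = [
    "build_graph",
    "NeighborhoodSystem",
    "default_neighborhoods",
    "SiteGlycomeModel",
    "fit_site_model",
    "u_for",
    "LAMBDA_CAP",
    "LAMBDA_GRID",
]

LAMBDA_CAP = 0.2
LAMBDA_GRID = tuple(np.round(np.arange(0.0, 0.2001, 0.025), 4))


def build_graph(glycans: Sequence[GlycanComposition]) -> nx.Graph:
    """Undirected glycome graph: edge iff monosaccharide-count L1 distance 1."""
    graph = nx.Graph()
    nodes = sorted(set(glycans), key=lambda g: (g.cardinality, g.counts))
    for g in nodes:
        graph.add_node(g)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if a.l1_distance(b) == 1:
                graph.add_edge(a, b, weight=1.0)
    return graph


def _trapezoid(x: float, lo: float, hi: float, ramp: float = 1.0) -> float:
    """Membership 1 inside [lo, hi], falling linearly to 0 over ``ramp``."""
    if lo <= x <= hi:
        return 1.0
    d = (lo - x) if x < lo else (x - hi)
    return max(0.0, 1.0 - d / ramp)


@dataclass(frozen=True)
class NeighborhoodRule:
    name: str
    bounds: Tuple[Tuple[str, float, float], ...]  # (monosaccharide, lo, hi)

    def membership(self, g: GlycanComposition) -> float:
        w = 1.0
        for mono, lo, hi in self.bounds:
            w *= _trapezoid(g[mono], lo, hi)
            if w == 0.0:
                return 0.0
        return w


@dataclass
class NeighborhoodSystem:
    rules: List[NeighborhoodRule]

    @property
    def names(self) -> List[str]:
        return [r.name for r in self.rules]

    def membership_matrix(self, glycans: Sequence[GlycanComposition]) -> np.ndarray:
        return np.array([[r.membership(g) for r in self.rules] for g in glycans])

    @classmethod
    def from_file(cls, path) -> "NeighborhoodSystem":
        """Text format: ``name | Mono in [lo, hi]; Mono in [lo, hi]; ...``."""
        rules = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                name, _, spec_txt = line.partition("|")
                bounds = []
                for clause in spec_txt.split(";"):
                    clause = clause.strip()
                    if not clause:
                        continue
                    mono, _, rng = clause.partition(" in ")
                    lo, hi = rng.strip().strip("[]").split(",")
                    bounds.append((mono.strip(), float(lo), float(hi)))
                rules.append(NeighborhoodRule(name.strip(), tuple(bounds)))
        return cls(rules)


def default_neighborhoods() -> NeighborhoodSystem:
    """Nine rule-based N-glycan neighborhoods over monosaccharide counts."""
    inf = float("inf")
    rules = [
        NeighborhoodRule("high-mannose", (("HexNAc", 2, 2), ("Hex", 4, 9), ("NeuAc", 0, 0),
                                          ("dHex", 0, 0))),
        NeighborhoodRule("paucimannose", (("HexNAc", 2, 2), ("Hex", 1, 3), ("NeuAc", 0, 0))),
        NeighborhoodRule("hybrid", (("HexNAc", 3, 3), ("Hex", 4, 7))),
        NeighborhoodRule("bi-antennary", (("HexNAc", 4, 4), ("Hex", 3, 6))),
        NeighborhoodRule("tri-antennary", (("HexNAc", 5, 5), ("Hex", 4, 7))),
        NeighborhoodRule("tetra-antennary", (("HexNAc", 6, 7), ("Hex", 5, 9))),
        NeighborhoodRule("fucosylated", (("dHex", 1, inf), ("HexNAc", 3, inf))),
        NeighborhoodRule("sialylated", (("NeuAc", 1, 2), ("HexNAc", 3, inf))),
        NeighborhoodRule("poly-sialylated", (("NeuAc", 3, inf),)),
    ]
    return NeighborhoodSystem(rules)


@dataclass
class SiteGlycomeModel:
    """Fitted smoothing model for one glycosylation site."""

    protein: str
    position: int
    nodes: List[GlycanComposition]
    tau: np.ndarray
    lam: float
    u: np.ndarray  # per-node prior credit, clipped at 0
    neighborhood_names: List[str] = field(default_factory=list)
    loo_error: float = float("nan")

    def u_map(self) -> Dict[Tuple[Tuple[str, int], ...], float]:
        return {g.counts: float(v) for g, v in zip(self.nodes, self.u)}


def _solve(
    laplacian: np.ndarray,
    A: np.ndarray,
    observed_mask: np.ndarray,
    y: np.ndarray,
    lam: float,
    mu: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> Tuple[np.ndarray, np.ndarray]:
    """Block-coordinate solve of the smoothing objective; returns (u, τ)."""
    n = laplacian.shape[0]
    k = A.shape[1]
    y_full = np.where(observed_mask, y, 0.0)
    if lam == 0.0:
        tau, *_ = np.linalg.lstsq(A, y_full, rcond=None)
        return y_full.copy(), tau
    M = np.eye(n) + lam * laplacian + lam * mu * np.eye(n)
    tau = np.zeros(k)
    u = np.zeros(n)
    AtA = A.T @ A + 1e-10 * np.eye(k)
    for _ in range(max_iter):
        u_new = np.linalg.solve(M, y_full + lam * mu * (A @ tau))
        tau_new = np.linalg.solve(AtA, A.T @ u_new)
        delta = max(
            np.abs(u_new - u).max() / (np.abs(u_new).max() + 1e-12),
            np.abs(tau_new - tau).max() / (np.abs(tau_new).max() + 1e-12),
        )
        u, tau = u_new, tau_new
        if delta < tol:
            break
    return u, tau


def fit_site_model(
    observations: Mapping[GlycanComposition, float],
    graph: nx.Graph,
    neighborhoods: Optional[NeighborhoodSystem] = None,
    lambda_grid: Sequence[float] = LAMBDA_GRID,
    protein: str = "",
    position: int = 0,
) -> Optional[SiteGlycomeModel]:
    """Fit the site model; λ selected by leave-one-observation-out error.

    ``observations`` maps observed glycans to their (positive) scores; the
    caller restricts them to confident identifications.  Returns None when
    there is nothing to fit.
    """
    observations = {g: s for g, s in observations.items() if s > 0}
    if not observations:
        return None
    if neighborhoods is None:
        neighborhoods = default_neighborhoods()
    nodes = sorted(graph.nodes, key=lambda g: (g.cardinality, g.counts))
    index = {g: i for i, g in enumerate(nodes)}
    laplacian = nx.laplacian_matrix(graph, nodelist=nodes, weight="weight").toarray().astype(float)
    A = neighborhoods.membership_matrix(nodes)

    y = np.zeros(len(nodes))
    observed_mask = np.zeros(len(nodes), dtype=bool)
    for g, s in observations.items():
        if g in index:
            y[index[g]] = s  # positive scores, on [0, y_max] by construction
            observed_mask[index[g]] = True
    if not observed_mask.any():
        return None

    lambda_grid = [l for l in lambda_grid if l <= LAMBDA_CAP]
    obs_idx = np.flatnonzero(observed_mask)
    best_lam, best_err = lambda_grid[0], np.inf
    if obs_idx.size >= 2:
        for lam in lambda_grid:
            err = 0.0
            for j in obs_idx:
                mask_j = observed_mask.copy()
                mask_j[j] = False
                u_j, _ = _solve(laplacian, A, mask_j, y, lam)
                err += (y[j] - max(u_j[j], 0.0)) ** 2
            if err < best_err - 1e-12:
                best_err, best_lam = err, lam
    else:
        best_lam, best_err = lambda_grid[0], float("nan")

    u, tau = _solve(laplacian, A, observed_mask, y, best_lam)
    u = np.clip(u, 0.0, None)
    return SiteGlycomeModel(
        protein=protein,
        position=position,
        nodes=nodes,
        tau=tau,
        lam=float(best_lam),
        u=u,
        neighborhood_names=neighborhoods.names,
        loo_error=float(best_err),
    )


def u_for(
    models: Mapping[Tuple[str, int], SiteGlycomeModel] | SiteGlycomeModel | None,
    glycan: GlycanComposition,
    site: Optional[Tuple[str, int]] = None,
    is_decoy_glycan: bool = False,
    is_decoy_peptide: bool = False,
) -> float:
    """Prior credit u_g for a (site, glycan), identical for target and decoy
    variants; 0 when the site or glycan is unmodeled.

    Decoy peptides resolve through the mirrored site registry: callers pass
    the *target* site coordinates recovered from the decoy registry, so the
    decoy flags are accepted and deliberately ignored here.
    """
    if models is None:
        return 0.0
    model: Optional[SiteGlycomeModel]
    if isinstance(models, SiteGlycomeModel):
        model = models
    else:
        if site is None:
            return 0.0
        model = models.get(site)
    if model is None:
        return 0.0
    return model.u_map().get(glycan.counts, 0.0)


def save_site_models(models: Mapping[Tuple[str, int], SiteGlycomeModel], path) -> None:
    payload = []
    for (protein, pos), m in sorted(models.items()):
        payload.append(
            {
                "protein": protein,
                "position": pos,
                "lambda": m.lam,
                "tau": dict(zip(m.neighborhood_names, m.tau.tolist())),
                "u": {str(g): float(v) for g, v in zip(m.nodes, m.u)},
            }
        )
    with open(path, "w") as fh:
        json.dump({"schema_version": 1, "sites": payload}, fh, indent=1)


def load_site_models(path) -> Dict[Tuple[str, int], SiteGlycomeModel]:
    with open(path) as fh:
        payload = json.load(fh)
    out: Dict[Tuple[str, int], SiteGlycomeModel] = {}
    for entry in payload["sites"]:
        nodes = [parse_composition(k) for k in entry["u"]]
        u = np.array(list(entry["u"].values()))
        names = list(entry["tau"])
        out[(entry["protein"], entry["position"])] = SiteGlycomeModel(
            protein=entry["protein"],
            position=entry["position"],
            nodes=nodes,
            tau=np.array(list(entry["tau"].values())),
            lam=entry["lambda"],
            u=u,
            neighborhood_names=names,
        )
    return out
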