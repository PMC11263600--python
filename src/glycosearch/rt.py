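"""Relative retention-time modeling and quasi-isobaric revision.

Glycoforms sharing a peptide backbone elute near each other; the RT offset
of each glycoform from its backbone's reference time is modeled as a linear
function of the signed monosaccharide-count difference from the backbone's
mean composition plus adduct counts.  Coefficients are fit per overlapping
time bin (default 8 bins at 50% overlap) so column behavior may drift over
the gradient; predictions blend adjacent bins.

The model supports an RT score in [0, 1] — the complement of the
probability that a uniformly random time point lands within the observed
residual of the prediction — and a revision step that re-examines
quasi-isobaric composition/adduct assignments (e.g. NeuAc+NH3 vs Hex+dHex,
Δm ≈ 11 mDa) against the predicted elution time, vetoed by diagnostic
oxonium evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .chem import AMMONIA, residue_mass
from .glycans import GlycanComposition

__all__ = [
    "ElutedID",
    "RTModel",
    "RevisionRule",
    "default_revision_rules",
    "parsimony_reassign",
    "fit_rt_model",
    "predict_rt",
    "rt_score",
    "revise",
]

ADDUCT_MASSES = {"NH3": AMMONIA}


@dataclass(frozen=True)
class ElutedID:
    """A glycopeptide identification mapped to an eluting MS1 feature."""

    backbone: str  # peptide backbone key
    glycan: GlycanComposition
    adducts: Tuple[Tuple[str, int], ...] = ()
    apex_rt: float = 0.0  # minutes
    abundance: float = 1.0
    ms2_score: float = 0.0
    feature_id: int = -1
    oxonium_rel: Tuple[Tuple[str, float], ...] = ()  # diagnostic-ion evidence
    provenance: str = ""

    def adduct_count(self, name: str) -> int:
        return dict(self.adducts).get(name, 0)

    @property
    def total_adducts(self) -> int:
        return sum(n for _, n in self.adducts)

    @property
    def neutral_mass(self) -> float:
        return self.glycan.mass + sum(
            n * ADDUCT_MASSES[a] for a, n in self.adducts
        )


@dataclass(frozen=True)
class RevisionRule:
    """A mass-closed composition/adduct substitution."""

    delta_composition: Tuple[Tuple[str, int], ...]
    delta_adducts: Tuple[Tuple[str, int], ...]
    max_net_mass: float = 0.05  # Da; asserted at registration

    @property
    def net_mass(self) -> float:
        dm = sum(n * residue_mass(m) for m, n in self.delta_composition)
        dm += sum(n * ADDUCT_MASSES[a] for a, n in self.delta_adducts)
        return dm

    def __post_init__(self) -> None:
        if abs(self.net_mass) > self.max_net_mass:
            raise ValueError(
                f"revision rule is not mass-closed: net mass {self.net_mass:.4f} Da"
            )

    def apply(self, id_: ElutedID) -> Optional[ElutedID]:
        counts = id_.glycan.as_dict()
        for mono, dn in self.delta_composition:
            counts[mono] = counts.get(mono, 0) + dn
            if counts[mono] < 0:
                return None
        adducts = dict(id_.adducts)
        for a, dn in self.delta_adducts:
            adducts[a] = adducts.get(a, 0) + dn
            if adducts[a] < 0:
                return None
        glycan = GlycanComposition.from_dict(counts, glycan_type=id_.glycan.glycan_type)
        return replace(
            id_,
            glycan=glycan,
            adducts=tuple(sorted((a, n) for a, n in adducts.items() if n > 0)),
        )


def default_revision_rules() -> List[RevisionRule]:
    """NeuAc+NH3 <-> Hex+dHex (both directions), net mass 11.2 mDa."""
    fwd = RevisionRule(
        delta_composition=(("NeuAc", -1), ("Hex", 1), ("dHex", 1)),
        delta_adducts=(("NH3", -1),),
    )
    rev = RevisionRule(
        delta_composition=(("NeuAc", 1), ("Hex", -1), ("dHex", -1)),
        delta_adducts=(("NH3", 1),),
    )
    return [fwd, rev]


# ---------------------------------------------------------------------------
# parsimony over shared MS1 features


def parsimony_reassign(
    feature_groups: Sequence[List[ElutedID]],
    candidate_map: Optional[Callable[[ElutedID], Optional[ElutedID]]] = None,
    rt_overlap: float = 0.5,
) -> List[List[ElutedID]]:
    """Replace mass-shifted assignments with no co-eluting unshifted version.

    ``candidate_map`` maps a shifted id to an unshifted alternative in the
    candidate set (or None); the default strips all adducts when the bare
    glycopeptide explains the same neutral mass family.
    """
    all_unshifted = [i for grp in feature_groups for i in grp if i.total_adducts == 0]

    def has_cover(id_: ElutedID) -> bool:
        return any(
            u.backbone == id_.backbone
            and u.glycan == id_.glycan
            and abs(u.apex_rt - id_.apex_rt) <= rt_overlap
            for u in all_unshifted
        )

    out: List[List[ElutedID]] = []
    for grp in feature_groups:
        new_grp: List[ElutedID] = []
        for id_ in grp:
            if id_.total_adducts == 0 or has_cover(id_):
                new_grp.append(id_)
                continue
            alt = candidate_map(id_) if candidate_map else None
            if alt is not None:
                new_grp.append(replace(alt, provenance="parsimony"))
            else:
                new_grp.append(id_)
        out.append(new_grp)
    return out


# ---------------------------------------------------------------------------
# the relative RT model


@dataclass
class RTBin:
    center: float
    low: float
    high: float
    coef: Dict[str, float]  # monosaccharide / adduct -> minutes per unit
    intercept: float
    residual_scale: float
    n_obs: int


@dataclass
class RTModel:
    """Per-backbone reference times plus time-binned delta coefficients."""

    bins: List[RTBin]
    references: Dict[str, float]  # backbone -> reference RT
    mean_compositions: Dict[str, Dict[str, float]]  # backbone -> mean counts
    run_span: float
    features: List[str]
    coverage: float = 0.0
    covered_backbones: Set[str] = field(default_factory=set)
    # per-backbone accumulators (Σw, Σw·apex, Σw·counts) enabling
    # leave-one-out references during revision
    backbone_stats: Dict[str, Tuple[float, float, Dict[str, float]]] = field(
        default_factory=dict
    )

    def covers(self, backbone: str) -> bool:
        return backbone in self.covered_backbones

    @property
    def residual_scale(self) -> float:
        scales = [b.residual_scale for b in self.bins if b.n_obs > 0]
        return float(np.median(scales)) if scales else 0.0


def _feature_names(ids: Sequence[ElutedID]) -> List[str]:
    monos: Set[str] = set()
    adducts: Set[str] = set()
    for i in ids:
        monos.update(i.glycan.as_dict())
        adducts.update(a for a, _ in i.adducts)
    return sorted(monos) + [f"adduct:{a}" for a in sorted(adducts)]


def _delta_vector(id_: ElutedID, mean_comp: Mapping[str, float], features: Sequence[str]) -> np.ndarray:
    counts = id_.glycan.as_dict()
    x = np.zeros(len(features))
    for k, name in enumerate(features):
        if name.startswith("adduct:"):
            x[k] = id_.adduct_count(name[7:])
        else:
            x[k] = counts.get(name, 0) - mean_comp.get(name, 0.0)
    return x


def fit_rt_model(
    ids: Sequence[ElutedID],
    min_glycoforms: int = 2,
    n_bins: int = 8,
    max_rounds: int = 10,
    similarity_radius: int = 2,
) -> Optional[RTModel]:
    """Fit the relative RT model, iteratively extending coverage.

    Round 1 uses backbones with >= ``min_glycoforms`` distinct glycoforms;
    each later round admits identifications whose glycan composition lies
    within L1 distance ``similarity_radius`` of a composition already
    covered, re-fitting until the covered set stops growing.
    """
    ids = list(ids)
    if not ids:
        return None
    by_backbone: Dict[str, List[ElutedID]] = {}
    for i in ids:
        by_backbone.setdefault(i.backbone, []).append(i)

    eligible = {
        b: grp
        for b, grp in by_backbone.items()
        if len({(g.glycan.counts, g.adducts) for g in grp}) >= min_glycoforms
    }
    if not eligible:
        return None

    rts = [i.apex_rt for i in ids]
    run_low, run_high = min(rts), max(rts)
    run_span = max(run_high - run_low, 1e-6)
    features = _feature_names(ids)

    covered = set(eligible)
    covered_comps = {i.glycan for b in covered for i in by_backbone[b]}
    model: Optional[RTModel] = None
    for _ in range(max_rounds):
        train_ids = [i for b in covered for i in by_backbone[b]]
        model = _fit_once(train_ids, by_backbone, covered, features, run_low, run_span, n_bins)
        # extend to similar glycopeptides
        new_cov = set(covered)
        for b, grp in by_backbone.items():
            if b in new_cov:
                continue
            if any(
                any(i.glycan.l1_distance(c) <= similarity_radius for c in covered_comps)
                for i in grp
            ):
                new_cov.add(b)
        if new_cov == covered:
            break
        covered = new_cov
        covered_comps = {i.glycan for b in covered for i in by_backbone[b]}
    if model is not None:
        model.coverage = sum(len(by_backbone[b]) for b in covered) / len(ids)
        model.covered_backbones = covered
    return model


def _fit_once(
    train_ids: Sequence[ElutedID],
    by_backbone: Mapping[str, List[ElutedID]],
    covered: Set[str],
    features: Sequence[str],
    run_low: float,
    run_span: float,
    n_bins: int,
) -> RTModel:
    references: Dict[str, float] = {}
    mean_comps: Dict[str, Dict[str, float]] = {}
    backbone_stats: Dict[str, Tuple[float, float, Dict[str, float]]] = {}
    for b in covered:
        grp = by_backbone[b]
        raw = np.array([max(i.abundance, 1e-12) for i in grp])
        wts = raw / raw.sum()
        references[b] = float(sum(w * i.apex_rt for w, i in zip(wts, grp)))
        mean: Dict[str, float] = {}
        w_counts: Dict[str, float] = {}
        for rw, w, i in zip(raw, wts, grp):
            for m, n in i.glycan.as_dict().items():
                mean[m] = mean.get(m, 0.0) + w * n
                w_counts[m] = w_counts.get(m, 0.0) + rw * n
        mean_comps[b] = mean
        backbone_stats[b] = (
            float(raw.sum()),
            float(sum(rw * i.apex_rt for rw, i in zip(raw, grp))),
            w_counts,
        )

    # overlapping bins: width = 2 * span / (n_bins + 1) gives 50% overlap
    width = 2.0 * run_span / (n_bins + 1)
    step = width / 2.0
    bins: List[RTBin] = []
    for k in range(n_bins):
        low = run_low + k * step
        high = min(low + width, run_low + run_span)
        center = (low + high) / 2.0
        # membership by the backbone's reference time, not the apex itself:
        # selecting on the apex would truncate on the response and attenuate
        # the composition coefficients
        members = [
            i for i in train_ids
            if i.backbone in references
            and low - 1e-9 <= references[i.backbone] <= high + 1e-9
        ]
        coef, intercept, scale = _fit_bin(members, references, mean_comps, features)
        bins.append(
            RTBin(center=center, low=low, high=high, coef=coef, intercept=intercept,
                  residual_scale=scale, n_obs=len(members))
        )
    # propagate coefficients into empty bins from the nearest populated bin
    populated = [b for b in bins if b.n_obs > 0]
    for b in bins:
        if b.n_obs == 0 and populated:
            src = min(populated, key=lambda p: abs(p.center - b.center))
            b.coef, b.intercept, b.residual_scale = dict(src.coef), src.intercept, src.residual_scale
    return RTModel(
        bins=bins,
        references=references,
        mean_compositions=mean_comps,
        run_span=run_span,
        features=list(features),
        backbone_stats=backbone_stats,
    )


def _fit_bin(
    members: Sequence[ElutedID],
    references: Mapping[str, float],
    mean_comps: Mapping[str, Mapping[str, float]],
    features: Sequence[str],
) -> Tuple[Dict[str, float], float, float]:
    rows, targets, wts = [], [], []
    for i in members:
        if i.backbone not in references:
            continue
        rows.append(_delta_vector(i, mean_comps[i.backbone], features))
        targets.append(i.apex_rt - references[i.backbone])
        wts.append(math.sqrt(max(i.abundance, 1e-12)))
    if len(rows) < len(features) + 1:
        return {f: 0.0 for f in features}, 0.0, 0.0
    X = np.vstack(rows)
    X = np.hstack([X, np.ones((X.shape[0], 1))])
    yv = np.array(targets)
    w = np.array(wts)
    sol, *_ = np.linalg.lstsq(X * w[:, None], yv * w, rcond=None)
    resid = yv - X @ sol
    scale = float(np.median(np.abs(resid)) * 1.4826)
    return dict(zip(features, sol[:-1])), float(sol[-1]), scale


class NotCovered(Exception):
    """Raised when the RT model does not cover a backbone."""


def _bin_weights(model: RTModel, t: float) -> List[Tuple[RTBin, float]]:
    inside = [b for b in model.bins if b.low <= t <= b.high and b.n_obs > 0]
    if inside:
        # overlap-weighted: triangular weight peaking at the bin center
        wts = []
        for b in inside:
            half = (b.high - b.low) / 2.0 or 1.0
            wts.append(max(1.0 - abs(t - b.center) / half, 1e-6))
        total = sum(wts)
        return [(b, w / total) for b, w in zip(inside, wts)]
    populated = [b for b in model.bins if b.n_obs > 0]
    if not populated:
        return [(model.bins[0], 1.0)]
    nearest = min(populated, key=lambda b: abs(b.center - t))
    return [(nearest, 1.0)]


def predict_rt(
    model: RTModel, id_: ElutedID, exclude: Optional[ElutedID] = None
) -> float:
    """Predicted apex time; raises NotCovered for unmodeled backbones.

    ``exclude`` recomputes the backbone reference (and mean composition)
    without that identification's contribution — used during revision so an
    abundant misassignment cannot anchor its own prediction.
    """
    if not model.covers(id_.backbone) or id_.backbone not in model.references:
        raise NotCovered(id_.backbone)
    ref = model.references[id_.backbone]
    mean_comp = model.mean_compositions[id_.backbone]
    if exclude is not None and exclude.backbone in model.backbone_stats:
        W, w_apex, w_counts = model.backbone_stats[exclude.backbone]
        w = max(exclude.abundance, 1e-12)
        if W - w > 1e-9:
            ref = (w_apex - w * exclude.apex_rt) / (W - w)
            counts = exclude.glycan.as_dict()
            mean_comp = {
                m: (tot - w * counts.get(m, 0)) / (W - w) for m, tot in w_counts.items()
            }
    x = _delta_vector(id_, mean_comp, model.features)
    delta = 0.0
    for b, w in _bin_weights(model, ref):
        contrib = sum(b.coef.get(f, 0.0) * x[k] for k, f in enumerate(model.features))
        delta += w * (contrib + b.intercept)
    return ref + delta


def rt_score(model: RTModel, id_: ElutedID) -> float:
    """1 at zero residual, 0.75 when a random time point would land within
    the residual 25% of the time, 0 at half the run span or worse."""
    pred = predict_rt(model, id_)
    return max(0.0, 1.0 - 2.0 * abs(id_.apex_rt - pred) / model.run_span)


def revise(
    model: RTModel,
    id_: ElutedID,
    rules: Optional[Sequence[RevisionRule]] = None,
    search_space: Optional[Set[Tuple[Tuple[str, int], ...]]] = None,
    fdr_guard: Optional[Callable[[ElutedID], bool]] = None,
    oxonium_floor: float = 0.01,
    improvement_factor: float = 2.0,
) -> ElutedID:
    """Pick, among identity and rule-mapped alternatives, the candidate whose
    predicted RT best matches the observed apex.

    A revision must beat the identity residual by ``improvement_factor`` ×
    the model's residual scale, must not contradict diagnostic-ion evidence
    (removing the last NeuAc is vetoed when its oxonium is present above
    ``oxonium_floor`` of the base peak, and adding a first NeuAc is vetoed
    when it is absent), and must pass the FDR guard.
    """
    if rules is None:
        rules = default_revision_rules()
    if not model.covers(id_.backbone):
        return id_
    try:
        base_resid = abs(id_.apex_rt - predict_rt(model, id_, exclude=id_))
    except NotCovered:
        return id_
    oxonium = dict(id_.oxonium_rel)
    best, best_resid = id_, base_resid
    for rule in rules:
        cand = rule.apply(id_)
        if cand is None:
            continue
        if search_space is not None and cand.glycan.counts not in search_space:
            continue
        # diagnostic-ion veto
        d_neuac = cand.glycan["NeuAc"] - id_.glycan["NeuAc"]
        if d_neuac < 0 and cand.glycan["NeuAc"] == 0 and oxonium.get("NeuAc", 0.0) > oxonium_floor:
            continue
        if d_neuac > 0 and id_.glycan["NeuAc"] == 0 and oxonium.get("NeuAc", 0.0) <= oxonium_floor:
            continue
        if fdr_guard is not None and not fdr_guard(cand):
            continue
        try:
            resid = abs(cand.apex_rt - predict_rt(model, cand, exclude=id_))
        except NotCovered:
            continue
        if resid < best_resid:
            best, best_resid = cand, resid
    if best is id_:
        return id_
    threshold = improvement_factor * max(model.residual_scale, 1e-9)
    if base_resid - best_resid > threshold:
        return replace(best, provenance="rt-revision")
    return id_


def iterative_revision(
    ids: Sequence[ElutedID],
    rules: Optional[Sequence[RevisionRule]] = None,
    search_space: Optional[Set[Tuple[Tuple[str, int], ...]]] = None,
    rounds: int = 3,
    fdr_guard: Optional[Callable[[ElutedID], bool]] = None,
    **fit_kwargs,
) -> Tuple[Optional[RTModel], List[ElutedID]]:
    """Alternate model fitting and revision until assignments stabilize.

    Misassigned glycoforms contaminate the coefficients that would expose
    them, so a single fit-revise pass under-corrects; re-fitting on the
    revised assignments sharpens the model each round.
    """
    if rules is None:
        rules = default_revision_rules()
    current = list(ids)
    model: Optional[RTModel] = None
    for _ in range(max(rounds, 1)):
        model = fit_rt_model(current, **fit_kwargs)
        if model is None:
            return None, current
        revised = [
            revise(model, i, rules, search_space=search_space, fdr_guard=fdr_guard)
            if model.covers(i.backbone)
            else i
            for i in current
        ]
        if all(a is b for a, b in zip(revised, current)):
            break
        current = revised
    return model, current
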