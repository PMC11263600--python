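"""Glycan-first glycopeptide search.

Candidate generation inverts the usual peptide-first order: for each
precursor and each allowed mass shift, the sorted glycan mass index proposes
complement peptide masses, which are looked up in the peptide mass table at
the precursor tolerance.  The (peptide, glycan) pairs per shift are ranked
by a cheap pre-score (matched core peptide+Y masses plus matched b/y among
the most intense peaks) and truncated to the top k = 70 before full scoring.

Targets and decoys (reversed-protein peptides; mass-shifted decoy glycan
ladders) flow through byte-identical scoring code; the engine merely labels
the channels for downstream FDR estimation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chem import AMMONIA, PROTON, WATER, residue_mass
from .fdr import glycan_fdr, joint_fdr, peptide_fdr
from .fragmodel import (
    FragmentationModel,
    FragmentRecord,
    TrainingRecord,
    extract_pair_features,
    ladder_direction,
    partition_key,
    predict_intensity,
)
from .glycans import (
    DecoyYLadder,
    GlycanComposition,
    YFragment,
    coverage_normalizer,
    generate_y_ladder,
    make_decoy_ladder,
)
from .peptides import Peptide, backbone_fragments, digest, find_sequons, proton_mobility, reverse_decoy
from .scoring import (
    GPSM,
    MatchedFragment,
    ScoringParams,
    cor_terms,
    score_glycan_base,
    score_glycan_model,
    score_peptide_base,
    score_peptide_model,
    score_total_base,
    score_total_model,
)
from .siteglycome import SiteGlycomeModel, fit_site_model, u_for
from .spectra import Spectrum

__all__ = [
    "SearchConfig",
    "GlycanMassIndex",
    "GlycopeptideDatabase",
    "build_database",
    "candidates_for",
    "match_candidate",
    "search_run",
]


@dataclass
class SearchConfig:
    precursor_tol: float = 5e-6
    fragment_tol: float = 20e-6
    adducts: Tuple[Tuple[str, int], ...] = (("NH3", 2),)  # name -> max count
    k: int = 70
    use_fragmentation_model: bool = False
    use_smoothing: bool = False
    use_rt: bool = False
    fdr_threshold: float = 0.01
    params: ScoringParams = field(default_factory=ScoringParams)
    decoy_seed: int = 0

    def mass_shifts(self) -> List[Tuple[str, float]]:
        """All adduct combinations (currently single adduct species × count)."""
        shifts = [("", 0.0)]
        for name, max_n in self.adducts:
            mass = AMMONIA if name == "NH3" else residue_mass(name)
            for n in range(1, max_n + 1):
                shifts.append((f"{n}x{name}", n * mass))
        return shifts


@dataclass
class GlycanMassIndex:
    """Sorted (mass, glycan) pairs, binary-searchable at tolerance."""

    glycans: List[GlycanComposition]
    masses: np.ndarray

    @classmethod
    def build(cls, glycans: Sequence[GlycanComposition]) -> "GlycanMassIndex":
        uniq = sorted(set(glycans), key=lambda g: (g.mass, g.counts))
        return cls(glycans=uniq, masses=np.array([g.mass for g in uniq]))


@dataclass
class GlycopeptideDatabase:
    peptides: List[Peptide]  # targets and decoys, each with absolute site coords
    glycans: List[GlycanComposition]
    index: GlycanMassIndex = field(init=False)
    peptide_masses: np.ndarray = field(init=False)
    _ladders: Dict[Tuple[Tuple[str, int], ...], List[YFragment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peptides = sorted(self.peptides, key=lambda p: p.mass)
        self.peptide_masses = np.array([p.mass for p in self.peptides])
        self.index = GlycanMassIndex.build(self.glycans)
        self.glycans = self.index.glycans

    def ladder(self, g: GlycanComposition) -> List[YFragment]:
        if g.counts not in self._ladders:
            self._ladders[g.counts] = generate_y_ladder(g)
        return self._ladders[g.counts]

    def decoy_ladder(self, g: GlycanComposition, peptide: Peptide, base_seed: int) -> DecoyYLadder:
        tag = f"{g}|{peptide.sequence}".encode()
        seed = (base_seed + zlib.crc32(tag)) % (2**31)
        return make_decoy_ladder(g, seed)

    def glycan_counts_set(self) -> Set[Tuple[Tuple[str, int], ...]]:
        return {g.counts for g in self.glycans}


def build_database(
    proteins: Sequence[Tuple[str, str]],
    glycans: Sequence[GlycanComposition],
    max_missed: int = 2,
    with_decoys: bool = True,
) -> GlycopeptideDatabase:
    """Digest proteins (trypsin, sequon-bearing peptides only) and attach
    reversed decoys with mirrored site registries."""
    peptides: List[Peptide] = []
    for name, seq in proteins:
        for p in digest(seq, max_missed=max_missed, protein_name=name):
            abs_sites = tuple(p.start + s for s in p.n_sites)
            peptides.append(replace(p, target_sites=abs_sites))
        if with_decoys:
            rev, mirrored = reverse_decoy(seq)
            L = len(seq)
            for p in digest(
                rev,
                max_missed=max_missed,
                protein_name=name,
                is_decoy=True,
                decoy_sites=mirrored,
            ):
                # map mirrored decoy positions back to target-protein coords
                abs_sites = tuple(L - 1 - (p.start + s) for s in p.n_sites)
                peptides.append(replace(p, target_sites=abs_sites))
    return GlycopeptideDatabase(peptides=peptides, glycans=list(glycans))


@dataclass(frozen=True)
class Candidate:
    peptide: Peptide
    glycan: GlycanComposition
    shift_name: str
    shift_mass: float
    decoy_glycan: bool = False


def _match_mass(sorted_masses: np.ndarray, target: float, tol: float) -> int:
    """Index of a peak matching ``target`` within tol (relative), else -1."""
    i = int(np.searchsorted(sorted_masses, target))
    best, best_err = -1, tol * max(target, 1.0)
    for j in (i - 1, i, i + 1):
        if 0 <= j < sorted_masses.size:
            err = abs(sorted_masses[j] - target)
            if err <= best_err:
                best, best_err = j, err
    return best


def candidates_for(
    spectrum: Spectrum,
    db: GlycopeptideDatabase,
    config: SearchConfig,
    include_decoy_glycans: bool = True,
) -> List[Candidate]:
    """Glycan-first complement search with per-shift top-k truncation."""
    out: List[Candidate] = []
    peak_masses = spectrum.masses()
    intensities = spectrum.intensities()
    top_idx = set(np.argsort(-intensities)[:10].tolist()) if intensities.size else set()
    top_masses = np.sort(peak_masses[sorted(top_idx)]) if top_idx else np.array([])
    prec = spectrum.precursor_mass
    window = config.precursor_tol * prec
    for shift_name, shift_mass in config.mass_shifts():
        residual = prec - shift_mass
        pairs: List[Tuple[float, Candidate]] = []
        for g, gmass in zip(db.index.glycans, db.index.masses):
            want = residual - gmass
            if want <= 0:
                continue
            lo = int(np.searchsorted(db.peptide_masses, want - window))
            hi = int(np.searchsorted(db.peptide_masses, want + window, side="right"))
            for pi in range(lo, hi):
                pep = db.peptides[pi]
                pre = _pre_score(peak_masses, top_masses, pep, g, db, config)
                cand = Candidate(pep, g, shift_name, shift_mass)
                pairs.append((pre, cand))
        pairs.sort(key=lambda t: (-t[0], t[1].peptide.sequence, str(t[1].glycan)))
        kept = [c for _, c in pairs[: config.k]]
        out.extend(kept)
        if include_decoy_glycans:
            out.extend(replace(c, decoy_glycan=True) for c in kept)
    return out


def _pre_score(
    peak_masses: np.ndarray,
    top_masses: np.ndarray,
    pep: Peptide,
    g: GlycanComposition,
    db: GlycopeptideDatabase,
    config: SearchConfig,
) -> float:
    score = 0
    for frag in db.ladder(g):
        if frag.is_core and _match_mass(peak_masses, pep.mass + frag.mass_delta, config.fragment_tol) >= 0:
            score += 1
    if top_masses.size:
        for bf in backbone_fragments(pep):
            if _match_mass(top_masses, bf.mass, config.fragment_tol) >= 0:
                score += 1
    return float(score)


OXONIUM_NEUTRAL = {
    "NeuAc": (residue_mass("NeuAc"), residue_mass("NeuAc") - WATER),
    "NeuGc": (residue_mass("NeuGc"), residue_mass("NeuGc") - WATER),
}


def match_candidate(
    spectrum: Spectrum, cand: Candidate, config: SearchConfig, base_seed: int = 0,
    db: Optional[GlycopeptideDatabase] = None,
) -> GPSM:
    """Match fragments and assemble a GPSM (shared by targets and decoys)."""
    pep, g = cand.peptide, cand.glycan
    peak_masses = spectrum.masses()
    intensities = spectrum.intensities()
    base_peak = spectrum.base_peak_intensity or 1.0
    tol = config.fragment_tol

    matched_P: List[MatchedFragment] = []
    covered_bonds: Set[int] = set()
    n = len(pep.sequence)
    for bf in backbone_fragments(pep):
        j = _match_mass(peak_masses, bf.mass, tol)
        if j >= 0:
            ppm = (peak_masses[j] - bf.mass) / bf.mass
            matched_P.append(
                MatchedFragment(
                    target_mass=bf.mass, intensity=float(intensities[j]), ppm=float(ppm),
                    series=bf.series, index=bf.index,
                )
            )
            bond = bf.index if bf.series == "b" else n - bf.index
            covered_bonds.add(bond)
    coverage_p = len(covered_bonds) / max(n - 1, 1)

    if db is not None:
        ladder = db.ladder(g)
    else:
        ladder = generate_y_ladder(g)
    if cand.decoy_glycan:
        if db is not None:
            dl = db.decoy_ladder(g, pep, base_seed)
        else:
            dl = make_decoy_ladder(g, base_seed)
        frag_masses = [f.mass_delta + s for f, s in zip(dl.fragments, dl.shifts)]
        frags = list(dl.fragments)
    else:
        frag_masses = [f.mass_delta for f in ladder]
        frags = list(ladder)

    matched_G: List[MatchedFragment] = []
    n_core = sum(1 for f in frags if f.is_core)
    n_core_matched = 0
    for f, delta in zip(frags, frag_masses):
        target = pep.mass + delta
        j = _match_mass(peak_masses, target, tol)
        if j >= 0:
            ppm = (peak_masses[j] - target) / target
            matched_G.append(
                MatchedFragment(
                    target_mass=target, intensity=float(intensities[j]), ppm=float(ppm),
                    series="Y", glycan_size=f.glycan_size,
                )
            )
            if f.is_core:
                n_core_matched += 1
    d_g = coverage_normalizer(g)
    coverage_g = min(len(matched_G) / d_g, 1.0) if d_g > 0 else 0.0
    coverage_g_core = n_core_matched / n_core if n_core else 0.0

    oxonium_rel: Dict[str, float] = {}
    for mono, targets in OXONIUM_NEUTRAL.items():
        rel = 0.0
        for t in targets:
            j = _match_mass(peak_masses, t, tol)
            if j >= 0:
                rel = max(rel, float(intensities[j]) / base_peak)
        oxonium_rel[mono] = rel

    theo = pep.mass + g.mass + cand.shift_mass
    ppm_pre = (spectrum.precursor_mass - theo) / theo
    return GPSM(
        scan_id=spectrum.scan_id,
        peptide_length=n,
        matched_P=matched_P,
        matched_G=matched_G,
        coverage_P=coverage_p,
        coverage_G=coverage_g,
        coverage_G_core=coverage_g_core,
        ppm_pre=float(ppm_pre),
        sialic_counts={"NeuAc": g["NeuAc"], "NeuGc": g["NeuGc"]},
        oxonium_rel=oxonium_rel,
    )


def _apply_fragmentation_model(
    gpsm: GPSM, cand: Candidate, spectrum: Spectrum, model: FragmentationModel,
    config: SearchConfig,
) -> None:
    """Assign φ and predicted intensities to the matched fragments in place."""
    from .glycans import approx_size

    pep = cand.peptide
    mobility = proton_mobility(pep.sequence, spectrum.precursor_charge)
    key = partition_key(
        len(pep.sequence), approx_size(cand.glycan), spectrum.precursor_charge, mobility,
        cand.glycan.glycan_type,
    )
    pm = model.resolve(key)
    masses = spectrum.masses()
    pep_mass = pep.mass
    frag_records: List[FragmentRecord] = []
    for m in gpsm.matched_P + gpsm.matched_G:
        series = m.series if m.series == "Y" else m.series
        feats = extract_pair_features(masses, m.target_mass, series, pep_mass, config.fragment_tol)
        phi = pm.reliability.predict(feats)
        m_idx = m.index
        frag_records.append(
            FragmentRecord(
                series=m.series, index=m_idx, glycan_size=m.glycan_size,
                intensity=m.intensity, mass=m.target_mass, features=feats, reliability=phi,
            )
        )
    rec = TrainingRecord(
        peptide=pep.sequence, glycan=cand.glycan, charge=spectrum.precursor_charge,
        fragments=frag_records, total_signal=sum(f.intensity for f in frag_records),
    )
    y_frags = [f for f in rec.fragments if f.series == "Y"]
    direction = ladder_direction(y_frags)
    y_model = pm.y_ascending if direction == "ascending" else pm.y_descending
    bb_frags, bb_pred = predict_intensity(pm.backbone, rec)
    yy_frags, yy_pred = predict_intensity(y_model, rec)
    pred_map: Dict[Tuple[str, int, int], float] = {}
    for f, p in zip(bb_frags, bb_pred):
        pred_map[(f.series, f.index, 0)] = float(p)
    for f, p in zip(yy_frags, yy_pred):
        pred_map[("Y", 0, f.glycan_size)] = float(p)
    phi_map = {(f.series, f.index, f.glycan_size): f.reliability for f in frag_records}
    for i, m in enumerate(gpsm.matched_P):
        keyf = (m.series, m.index, 0)
        gpsm.matched_P[i] = replace(
            m, reliability=phi_map.get(keyf, 0.0), predicted=pred_map.get(keyf, 0.0)
        )
    for i, m in enumerate(gpsm.matched_G):
        keyf = ("Y", m.index, m.glycan_size)
        gpsm.matched_G[i] = replace(
            m, reliability=phi_map.get(keyf, 0.0), predicted=pred_map.get(("Y", 0, m.glycan_size), 0.0)
        )


def _score_gpsm(
    gpsm: GPSM, config: SearchConfig, u_g: float = 0.0
) -> Tuple[float, float, float]:
    """(score_P, score_G, score_total) under the configured layer stack."""
    params = config.params
    if config.use_fragmentation_model:
        sp = score_peptide_model(gpsm, params)
        sg = score_glycan_model(gpsm, params, u_g=u_g)
    else:
        sp = score_peptide_base(gpsm, params)
        sg = score_glycan_base(gpsm, params, u_g=u_g)
    if config.use_fragmentation_model:
        total = score_total_model(gpsm, params, u_g=u_g)
    else:
        total = score_total_base(gpsm, params, u_g=u_g)
    return sp, sg, total


def _candidate_site(cand: Candidate) -> Optional[Tuple[str, int]]:
    pep = cand.peptide
    if pep.target_sites:
        return (pep.protein, pep.target_sites[0])
    return None


def search_run(
    spectra: Iterable[Spectrum],
    db: GlycopeptideDatabase,
    config: SearchConfig,
    frag_model: Optional[FragmentationModel] = None,
    site_models: Optional[Mapping[Tuple[str, int], SiteGlycomeModel]] = None,
) -> pd.DataFrame:
    """Score every spectrum against its candidate pool and control FDR.

    Per spectrum the best candidate in each (peptide, glycan) target/decoy
    channel is retained; peptide and glycan q-values come from their
    respective channels; the reported row per spectrum is the best
    target–target assignment.
    """
    if config.use_fragmentation_model and frag_model is None:
        raise ValueError("fragmentation-model layer enabled but no model supplied")

    rows: List[dict] = []
    for spectrum in spectra:
        cands = candidates_for(spectrum, db, config)
        best: Dict[Tuple[bool, bool], dict] = {}
        for cand in cands:
            gpsm = match_candidate(spectrum, cand, config, base_seed=config.decoy_seed, db=db)
            if gpsm.m_p + gpsm.m_g == 0:
                continue
            if config.use_fragmentation_model:
                _apply_fragmentation_model(gpsm, cand, spectrum, frag_model, config)
            site = _candidate_site(cand)
            u_g = 0.0
            if config.use_smoothing and site_models:
                u_g = u_for(site_models, cand.glycan, site=site)
            sp, sg, total = _score_gpsm(gpsm, config, u_g=u_g)
            _, cor_p_prime, _, _ = cor_terms(gpsm)
            # base-scale glycan evidence (log-intensity sum × coverage): the
            # site-glycome observations live on this scale so that u_g stays
            # commensurate with the bracketed evidence it is added to
            sg_base = score_glycan_base(gpsm, config.params)
            channel = (cand.peptide.is_decoy, cand.decoy_glycan)
            row = {
                "scan_id": spectrum.scan_id,
                "peptide": cand.peptide.sequence,
                "protein": cand.peptide.protein,
                "site": site[1] if site else -1,
                "glycan": str(cand.glycan),
                "glycan_size": cand.glycan.cardinality,
                "mass_shift": cand.shift_name,
                "shift_mass": cand.shift_mass,
                "score_peptide": sp,
                "score_glycan": sg,
                "score_glycan_base": sg_base,
                "score_total": total,
                "coverage_P": gpsm.coverage_P,
                "coverage_G": gpsm.coverage_G,
                "coverage_G_core": gpsm.coverage_G_core,
                "cor_p_prime": cor_p_prime,
                "u_g": u_g,
                "rt": spectrum.rt,
                "is_decoy_peptide": cand.peptide.is_decoy,
                "is_decoy_glycan": cand.decoy_glycan,
            }
            prev = best.get(channel)
            if prev is None or row["score_total"] > prev["score_total"]:
                best[channel] = row
        rows.extend(best.values())

    if not rows:
        return pd.DataFrame(
            columns=[
                "scan_id", "peptide", "glycan", "mass_shift", "score_peptide",
                "score_glycan", "score_total", "fdr_peptide", "fdr_glycan", "fdr_joint",
            ]
        )
    df = pd.DataFrame(rows)
    return _assign_fdrs(df, config)


def _assign_fdrs(df: pd.DataFrame, config: SearchConfig) -> pd.DataFrame:
    """Channel-wise FDR assignment; returns the target–target report rows."""
    df = df.copy()
    # peptide channel: per spectrum, best target-peptide row vs best decoy-peptide row
    pep_pop = (
        df.sort_values("score_total", ascending=False)
        .groupby(["scan_id", "is_decoy_peptide"], sort=False)
        .head(1)
        .reset_index(drop=True)
    )
    feats = pep_pop[["score_peptide", "coverage_P", "cor_p_prime"]].to_numpy()
    q_pep = peptide_fdr(feats, pep_pop["is_decoy_peptide"].to_numpy(), seed=config.decoy_seed)
    pep_pop = pep_pop.assign(fdr_peptide=q_pep)
    pep_q_map = {
        (r.scan_id, r.is_decoy_peptide): r.fdr_peptide for r in pep_pop.itertuples()
    }

    gly_pop = (
        df.sort_values("score_glycan", ascending=False)
        .groupby(["scan_id", "is_decoy_glycan"], sort=False)
        .head(1)
        .reset_index(drop=True)
    )
    q_gly, defined = glycan_fdr(
        gly_pop["score_glycan"].to_numpy(),
        gly_pop["is_decoy_glycan"].to_numpy(),
        glycan_sizes=gly_pop["glycan_size"].to_numpy(),
    )
    gly_pop = gly_pop.assign(fdr_glycan=q_gly, glycan_fdr_defined=defined)
    # interpolate glycan q for non-representative rows by score
    rep = gly_pop[~gly_pop["is_decoy_glycan"]].sort_values("score_glycan")
    rep_scores = rep["score_glycan"].to_numpy()
    rep_q = rep["fdr_glycan"].to_numpy()

    def glycan_q_for(score: float) -> float:
        if rep_scores.size == 0:
            return 1.0
        i = int(np.searchsorted(rep_scores, score))
        i = min(max(i, 0), rep_scores.size - 1)
        v = rep_q[i]
        return float(v) if np.isfinite(v) else 1.0

    report = df[(~df["is_decoy_peptide"]) & (~df["is_decoy_glycan"])].copy()
    report["fdr_peptide"] = [
        pep_q_map.get((r.scan_id, False), 1.0) for r in report.itertuples()
    ]
    gly_q_map = {
        (r.scan_id,): (r.fdr_glycan, r.glycan_fdr_defined)
        for r in gly_pop[~gly_pop["is_decoy_glycan"]].itertuples()
    }
    fdr_g, g_def = [], []
    for r in report.itertuples():
        qv, dv = gly_q_map.get((r.scan_id,), (np.nan, False))
        if r.glycan_size <= 3:
            qv, dv = np.nan, False
        fdr_g.append(qv)
        g_def.append(bool(dv))
    report["fdr_glycan"] = fdr_g
    report["glycan_fdr_defined"] = g_def
    report["fdr_joint"] = joint_fdr(
        report["fdr_peptide"].to_numpy(),
        np.nan_to_num(report["fdr_glycan"].to_numpy(), nan=1.0),
        glycan_defined=report["glycan_fdr_defined"].to_numpy(),
    )
    # one row per spectrum: the best target-target assignment
    report = (
        report.sort_values("score_total", ascending=False)
        .groupby("scan_id", sort=False)
        .head(1)
        .reset_index(drop=True)
    )
    return report


def fit_site_models_from_results(
    df: pd.DataFrame,
    glycans: Sequence[GlycanComposition],
    fdr_threshold: float = 0.01,
    neighborhoods=None,
) -> Dict[Tuple[str, int], SiteGlycomeModel]:
    """Fit per-site smoothing models from confident target identifications."""
    from .glycans import parse_composition
    from .siteglycome import build_graph

    graph = build_graph(list(glycans))
    confident = df[(df["fdr_joint"] <= fdr_threshold) & (df["site"] >= 0)]
    score_col = "score_glycan_base" if "score_glycan_base" in df.columns else "score_glycan"
    models: Dict[Tuple[str, int], SiteGlycomeModel] = {}
    for (protein, site), grp in confident.groupby(["protein", "site"]):
        obs: Dict[GlycanComposition, float] = {}
        for r in grp.itertuples():
            g = parse_composition(r.glycan)
            obs[g] = max(obs.get(g, 0.0), float(getattr(r, score_col)))
        model = fit_site_model(obs, graph, neighborhoods=neighborhoods,
                               protein=protein, position=int(site))
        if model is not None:
            models[(protein, int(site))] = model
    return models
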