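"""Partitioned glycopeptide fragmentation learning.

Two learned layers per partition of the training data:

* a *reliability* model φ — a naive-Bayes posterior that a matched peak is a
  genuine fragment, built from inter-peak relationship features (complement
  pairs, amino-acid mass offsets, monosaccharide mass offsets);
* an *intensity* model θ — a multinomial (softmax) model of the relative
  intensity each theoretical fragment receives, fit by iteratively
  re-weighted least squares (Newton steps with step-halving), with spectra
  weighted by their total matched signal and peaks weighted by φ.

Partitions are a grid over peptide-length bin (5) × glycan-size bin (2) ×
precursor-charge bin (5) × proton mobility (3) — 150 cells per
glycosylation type.  Sparse partitions borrow adjacent charge bins for the
reliability layer (never for the intensity layer); a key with no fitted
partition resolves to the nearest fitted one by Manhattan distance on bin
indices, or to a global model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _stats

from .chem import residue_mass
from .glycans import GlycanComposition, approx_size, parse_composition
from .peptides import AA_MASSES, proton_mobility
from .spectra import AnnotatedSpectrum, Spectrum

__all__ = [
    "PartitionKey",
    "partition_key",
    "extract_pair_features",
    "ReliabilityModel",
    "fit_reliability",
    "predict_reliability",
    "ladder_direction",
    "IntensityModel",
    "fit_intensity",
    "predict_intensity",
    "FragmentationModel",
    "TrainingRecord",
    "FragmentRecord",
    "records_from_annotated",
]

MOBILITY_ORDER = ("mobile", "partial", "immobile")

LEN_EDGES = (10, 15, 20, 27)  # {<=10, 11-15, 16-20, 21-27, >=28}
GLYCAN_SIZE_EDGE = 9  # {<=9, >=10}
CHARGE_TOP = 5

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PartitionKey:
    peptide_len_bin: int  # 1..5
    glycan_size_bin: int  # 1..2
    charge_bin: int  # 1..5
    mobility: str
    glyco_type: str = "N"

    def indices(self) -> Tuple[int, int, int, int]:
        return (
            self.peptide_len_bin,
            self.glycan_size_bin,
            self.charge_bin,
            MOBILITY_ORDER.index(self.mobility),
        )

    def manhattan(self, other: "PartitionKey") -> int:
        return sum(abs(a - b) for a, b in zip(self.indices(), other.indices()))


def partition_key(
    peptide_length: int, glycan_size: int, charge: int, mobility: str, glyco_type: str = "N"
) -> PartitionKey:
    len_bin = 1 + sum(peptide_length > e for e in LEN_EDGES)
    gs_bin = 1 if glycan_size <= GLYCAN_SIZE_EDGE else 2
    charge_bin = min(max(charge, 1), CHARGE_TOP)
    return PartitionKey(len_bin, gs_bin, charge_bin, mobility, glyco_type)


# ---------------------------------------------------------------------------
# peak-pair relationship features


def _has_partner(masses: np.ndarray, target: float, tol: float) -> bool:
    if target <= 0:
        return False
    i = np.searchsorted(masses, target)
    window = tol * target
    for j in (i - 1, i, i + 1):
        if 0 <= j < masses.size and abs(masses[j] - target) <= window:
            return True
    return False


def extract_pair_features(
    spectrum_masses: np.ndarray,
    peak_mass: float,
    series: str,
    peptide_mass: float,
    tol: float = 20e-6,
) -> FrozenSet[str]:
    """Binary inter-peak features for one peak under a series hypothesis.

    Backbone series (b/y): complement partner (b_i + y_{n-i} sums to the
    peptide mass), per-amino-acid mass offsets, and a HexNAc offset.
    Y series: HexNAc, Hex, and dHex offsets.
    """
    masses = spectrum_masses
    if masses.size < 2:
        return frozenset()
    feats: List[str] = []
    if series in ("b", "y"):
        if peptide_mass > 0 and _has_partner(masses, peptide_mass - peak_mass, tol):
            feats.append("complement")
        for aa in AA_ALPHABET:
            delta = AA_MASSES[aa]
            if _has_partner(masses, peak_mass + delta, tol) or _has_partner(
                masses, peak_mass - delta, tol
            ):
                feats.append(f"aa:{aa}")
        if _has_partner(masses, peak_mass + residue_mass("HexNAc"), tol) or _has_partner(
            masses, peak_mass - residue_mass("HexNAc"), tol
        ):
            feats.append("offset:HexNAc")
    elif series == "Y":
        for mono in ("HexNAc", "Hex", "dHex"):
            delta = residue_mass(mono)
            if _has_partner(masses, peak_mass + delta, tol) or _has_partner(
                masses, peak_mass - delta, tol
            ):
                feats.append(f"offset:{mono}")
    return frozenset(feats)


# ---------------------------------------------------------------------------
# training-data containers


@dataclass
class FragmentRecord:
    """One (theoretical fragment, observed peak) pairing in a training GPSM."""

    series: str  # 'b' | 'y' | 'Y'
    index: int = 0  # cleavage index for b/y
    glycan_size: int = 0  # residues attached, Y only
    intensity: float = 0.0  # observed intensity (0 => not observed)
    mass: float = 0.0
    features: FrozenSet[str] = frozenset()
    reliability: float = 0.0


@dataclass
class TrainingRecord:
    """A training GPSM reduced to what the fragmentation layers consume."""

    peptide: str
    glycan: GlycanComposition
    charge: int
    fragments: List[FragmentRecord]
    unannotated_features: List[FrozenSet[str]] = field(default_factory=list)
    total_signal: float = 0.0

    @property
    def mobility(self) -> str:
        return proton_mobility(self.peptide, self.charge)

    @property
    def key(self) -> PartitionKey:
        return partition_key(
            len(self.peptide), approx_size(self.glycan), self.charge, self.mobility,
            self.glycan.glycan_type,
        )


def records_from_annotated(
    spectra: Iterable[AnnotatedSpectrum],
    tol: float = 20e-6,
    noise_floor: float = 1e-3,
) -> List[TrainingRecord]:
    """Convert annotated spectra into training records.

    Annotated peaks become fragment records with their labeled series;
    unannotated peaks at or above ``noise_floor`` of the base peak supply
    the negative class for the reliability model.
    """
    out: List[TrainingRecord] = []
    for spec in spectra:
        if not spec.peptide or not spec.glycan:
            continue
        glycan = parse_composition(spec.glycan)
        masses = spec.masses()
        base = spec.base_peak_intensity or 1.0
        pep_mass = _peptide_backbone_mass(spec.peptide)
        frags: List[FragmentRecord] = []
        negatives: List[FrozenSet[str]] = []
        annotated_idx = set(spec.annotations)
        for i, peak in enumerate(spec.peaks):
            label = spec.annotations.get(i)
            if label is None:
                if peak.intensity >= noise_floor * base:
                    negatives.append(
                        extract_pair_features(masses, peak.neutral_mass, "b", pep_mass, tol)
                    )
                continue
            rec = _record_from_label(label, peak.neutral_mass, peak.intensity)
            if rec is None:
                continue
            rec.features = extract_pair_features(
                masses, peak.neutral_mass, rec.series if rec.series != "Y" else "Y", pep_mass, tol
            )
            frags.append(rec)
        total = sum(f.intensity for f in frags)
        out.append(
            TrainingRecord(
                peptide=spec.peptide,
                glycan=glycan,
                charge=spec.precursor_charge,
                fragments=frags,
                unannotated_features=negatives,
                total_signal=total,
            )
        )
    return out


def _peptide_backbone_mass(seq: str) -> float:
    from .chem import WATER

    return sum(AA_MASSES[aa] for aa in seq) + WATER


def _record_from_label(label: str, mass: float, intensity: float) -> Optional[FragmentRecord]:
    if label.startswith("oxonium:"):
        return None
    if label.startswith("Y:"):
        body = label[2:]
        size = 0 if body == "0" else parse_composition(body).cardinality
        return FragmentRecord(series="Y", glycan_size=size, intensity=intensity, mass=mass)
    if label[0] in "by" and label[1:].isdigit():
        return FragmentRecord(series=label[0], index=int(label[1:]), intensity=intensity, mass=mass)
    return None


# ---------------------------------------------------------------------------
# reliability model


@dataclass
class ReliabilityModel:
    """Naive-Bayes reliability: per-feature likelihood ratios and a prior."""

    likelihood_ratios: Dict[str, float]
    prior: float

    def predict(self, features: Iterable[str]) -> float:
        odds = self.prior / (1.0 - self.prior)
        for f in features:
            odds *= self.likelihood_ratios.get(f, 1.0)
        return odds / (1.0 + odds)


def fit_reliability(
    records: Sequence[TrainingRecord],
) -> ReliabilityModel:
    """Fit LR_f = P(f | annotated) / P(f | unannotated) with add-one smoothing."""
    pos: List[FrozenSet[str]] = []
    neg: List[FrozenSet[str]] = []
    for rec in records:
        pos.extend(f.features for f in rec.fragments if f.intensity > 0)
        neg.extend(rec.unannotated_features)
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0:
        return ReliabilityModel(likelihood_ratios={}, prior=0.5)
    all_feats = set().union(*pos) | (set().union(*neg) if neg else set())
    lrs: Dict[str, float] = {}
    for f in all_feats:
        p1 = (sum(f in s for s in pos) + 1) / (n_pos + 2)
        p0 = (sum(f in s for s in neg) + 1) / (n_neg + 2)
        lrs[f] = p1 / p0
    prior = n_pos / max(n_pos + n_neg, 1)
    prior = min(max(prior, 1e-3), 1 - 1e-3)
    return ReliabilityModel(likelihood_ratios=lrs, prior=prior)


def predict_reliability(model: ReliabilityModel, features: Iterable[str]) -> float:
    return model.predict(features)


# ---------------------------------------------------------------------------
# ladder direction


def ladder_direction(y_fragments: Sequence[FragmentRecord]) -> str:
    """'ascending' or 'descending' intensity trend of the Y ladder with
    glycan size; fewer than two distinct sizes, or a tie, gives 'descending'."""
    pts = [(f.glycan_size, f.intensity) for f in y_fragments if f.intensity > 0]
    sizes = {s for s, _ in pts}
    if len(sizes) < 2 or len({i for _, i in pts}) < 2:
        return "descending"
    rho = _stats.spearmanr([s for s, _ in pts], [i for _, i in pts]).statistic
    if not np.isfinite(rho) or rho <= 0:
        return "descending"
    return "ascending"


# ---------------------------------------------------------------------------
# intensity model


def backbone_fragment_features(frag: FragmentRecord, peptide: str, mobility: str) -> np.ndarray:
    """Feature vector for a backbone fragment: amino-acid composition of the
    fragment, flanking residues at the cleavage site, series, relative
    position, and mobility interactions."""
    n = len(peptide)
    if frag.series == "b":
        segment = peptide[: frag.index]
        cleave = frag.index
    else:
        segment = peptide[n - frag.index :]
        cleave = n - frag.index
    x = np.zeros(backbone_feature_dim())
    for aa in segment:
        x[AA_ALPHABET.index(aa)] += 1.0
    off = len(AA_ALPHABET)
    nterm = peptide[cleave - 1]
    cterm = peptide[cleave] if cleave < n else peptide[-1]
    x[off + AA_ALPHABET.index(nterm)] = 1.0
    x[off + 20 + AA_ALPHABET.index(cterm)] = 1.0
    x[off + 40] = 1.0 if frag.series == "b" else 0.0
    relpos = cleave / max(n - 1, 1)
    x[off + 41] = relpos
    mob = MOBILITY_ORDER.index(mobility)
    x[off + 42] = 1.0 if mob == 1 else 0.0
    x[off + 43] = 1.0 if mob == 2 else 0.0
    x[off + 44] = relpos * (1.0 if mob == 2 else 0.0)
    return x


def backbone_feature_dim() -> int:
    return len(AA_ALPHABET) + 45


def y_fragment_features(frag: FragmentRecord, peptide: str, mobility: str) -> np.ndarray:
    """Feature vector for a peptide+Y fragment: glycan size terms, basic
    residue content of the backbone, and mobility."""
    x = np.zeros(y_feature_dim())
    size = float(frag.glycan_size)
    x[0] = size
    x[1] = size * size / 10.0
    x[2] = 1.0 if size <= 1 else 0.0
    x[3] = sum(peptide.count(a) for a in "KRH") / 5.0
    x[4] = len(peptide) / 20.0
    mob = MOBILITY_ORDER.index(mobility)
    x[5] = 1.0 if mob == 1 else 0.0
    x[6] = 1.0 if mob == 2 else 0.0
    x[7] = size * (1.0 if mob == 2 else 0.0) / 5.0
    return x


def y_feature_dim() -> int:
    return 8


@dataclass
class IntensityModel:
    """Per-series-group multinomial coefficients θ."""

    theta: np.ndarray
    series_group: str  # 'backbone' | 'Y-ascending' | 'Y-descending'
    converged: bool = True
    loglik_trace: Tuple[float, ...] = ()

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.theta
        z = z - z.max()
        p = np.exp(z)
        return p / p.sum()


def _design_for(rec: TrainingRecord, series_group: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, v): features, observed proportions, peak weights (φ)."""
    mobility = rec.mobility
    if series_group == "backbone":
        frags = [f for f in rec.fragments if f.series in ("b", "y")]
        feats = [backbone_fragment_features(f, rec.peptide, mobility) for f in frags]
    else:
        frags = [f for f in rec.fragments if f.series == "Y"]
        feats = [y_fragment_features(f, rec.peptide, mobility) for f in frags]
    if not frags:
        dim = backbone_feature_dim() if series_group == "backbone" else y_feature_dim()
        return np.zeros((0, dim)), np.zeros(0), np.zeros(0)
    X = np.vstack(feats)
    inten = np.array([f.intensity for f in frags], dtype=float)
    total = inten.sum()
    y = inten / total if total > 0 else np.zeros_like(inten)
    v = np.array([f.reliability if f.reliability > 0 else 1.0 for f in frags])
    return X, y, v


def fit_intensity(
    records: Sequence[TrainingRecord],
    series_group: str,
    use_reliability_weights: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
    ridge: float = 0.0,
) -> IntensityModel:
    """Maximize the weighted multinomial log-likelihood by Newton steps.

    Spectrum weight ∝ total matched signal; peak weight ∝ φ (or 1).  A
    singular Hessian triggers a 1e-4 ridge retry; an unstable solution
    (non-convergence or condition number > 1e8) falls back to φ ≡ 1
    weights, and ultimately to uniform θ = 0.
    """
    designs = []
    for rec in records:
        X, y, v = _design_for(rec, series_group)
        if X.shape[0] < 2 or y.sum() <= 0:
            continue
        if not use_reliability_weights:
            v = np.ones_like(v)
        w_s = rec.total_signal if rec.total_signal > 0 else 1.0
        designs.append((X, y, v, math.log1p(w_s)))
    dim = backbone_feature_dim() if series_group == "backbone" else y_feature_dim()
    if not designs:
        return IntensityModel(theta=np.zeros(dim), series_group=series_group, converged=False)

    def loglik_grad_hess(theta: np.ndarray):
        ll = 0.0
        grad = np.zeros(dim)
        hess = np.zeros((dim, dim))
        for X, y, v, w in designs:
            z = X @ theta
            z = z - z.max()
            expz = np.exp(z)
            Z = expz.sum()
            p = expz / Z
            c = v * y
            C = c.sum()
            ll += w * float(c @ (z - math.log(Z)))
            xbar = p @ X
            grad += w * ((c @ X) - C * xbar)
            hess -= w * C * ((X.T * p) @ X - np.outer(xbar, xbar))
        if ridge > 0:
            ll -= 0.5 * ridge * float(theta @ theta)
            grad -= ridge * theta
            hess -= ridge * np.eye(dim)
        return ll, grad, hess

    theta = np.zeros(dim)
    ll, grad, hess = loglik_grad_hess(theta)
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        try:
            cond = np.linalg.cond(-hess)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            if ridge == 0.0:
                return fit_intensity(
                    records, series_group, use_reliability_weights, max_iter, tol, ridge=1e-4
                )
            return IntensityModel(theta=np.zeros(dim), series_group=series_group, converged=False)
        # step-halving to keep the objective non-decreasing
        scale = 1.0
        for _half in range(30):
            cand = theta + scale * step
            new_ll, new_grad, new_hess = loglik_grad_hess(cand)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        delta = new_ll - ll
        theta, ll, grad, hess = cand, new_ll, new_grad, new_hess
        trace.append(ll)
        if abs(delta) < tol:
            converged = True
            break
    if not converged and use_reliability_weights:
        # unstable with φ weights: retry with unit peak weights
        alt = fit_intensity(records, series_group, use_reliability_weights=False,
                            max_iter=max_iter, tol=tol, ridge=ridge)
        if alt.converged:
            return alt
    return IntensityModel(
        theta=theta, series_group=series_group, converged=converged,
        loglik_trace=tuple(trace),
    )


def predict_intensity(
    model: IntensityModel, rec: TrainingRecord
) -> Tuple[List[FragmentRecord], np.ndarray]:
    """Softmax predictions over the record's fragments for the model's group."""
    X, _, _ = _design_for(rec, model.series_group)
    if model.series_group == "backbone":
        frags = [f for f in rec.fragments if f.series in ("b", "y")]
    else:
        frags = [f for f in rec.fragments if f.series == "Y"]
    if not frags:
        return [], np.zeros(0)
    return frags, model.predict(X)


# ---------------------------------------------------------------------------
# the assembled per-partition model


@dataclass
class PartitionModels:
    reliability: ReliabilityModel
    backbone: IntensityModel
    y_ascending: IntensityModel
    y_descending: IntensityModel
    n_spectra: int = 0


@dataclass
class FragmentationModel:
    """All fitted partitions plus a global fallback.

    ``fit`` is the entry point; lookups resolve missing partitions to the
    nearest fitted one (Manhattan distance on bin indices), falling back to
    the global model.
    """

    partitions: Dict[PartitionKey, PartitionModels]
    global_model: PartitionModels
    min_spectra: int = 50

    @classmethod
    def fit(
        cls, records: Sequence[TrainingRecord], min_spectra: int = 50
    ) -> "FragmentationModel":
        groups: Dict[PartitionKey, List[TrainingRecord]] = {}
        for rec in records:
            groups.setdefault(rec.key, []).append(rec)

        def reliability_pool(key: PartitionKey) -> List[TrainingRecord]:
            pool = list(groups.get(key, []))
            # borrow adjacent charge bins for sparse partitions
            offset = 1
            while len(pool) < min_spectra and offset <= CHARGE_TOP:
                for dc in (-offset, offset):
                    adj = PartitionKey(
                        key.peptide_len_bin, key.glycan_size_bin,
                        key.charge_bin + dc, key.mobility, key.glyco_type,
                    )
                    pool.extend(groups.get(adj, []))
                offset += 1
            return pool

        partitions: Dict[PartitionKey, PartitionModels] = {}
        for key, recs in groups.items():
            rel = fit_reliability(reliability_pool(key))
            _assign_reliabilities(recs, rel)
            asc, desc = _split_by_direction(recs)
            partitions[key] = PartitionModels(
                reliability=rel,
                backbone=fit_intensity(recs, "backbone"),
                y_ascending=fit_intensity(asc or recs, "Y-ascending"),
                y_descending=fit_intensity(desc or recs, "Y-descending"),
                n_spectra=len(recs),
            )
        all_recs = list(records)
        rel_global = fit_reliability(all_recs)
        _assign_reliabilities(all_recs, rel_global)
        asc, desc = _split_by_direction(all_recs)
        global_model = PartitionModels(
            reliability=rel_global,
            backbone=fit_intensity(all_recs, "backbone"),
            y_ascending=fit_intensity(asc or all_recs, "Y-ascending"),
            y_descending=fit_intensity(desc or all_recs, "Y-descending"),
            n_spectra=len(all_recs),
        )
        return cls(partitions=partitions, global_model=global_model, min_spectra=min_spectra)

    def resolve(self, key: PartitionKey) -> PartitionModels:
        if key in self.partitions:
            return self.partitions[key]
        candidates = [k for k in self.partitions if k.glyco_type == key.glyco_type]
        if not candidates:
            return self.global_model
        best = min(candidates, key=lambda k: (key.manhattan(k), k.indices()))
        return self.partitions[best]

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        def enc_partition(pm: PartitionModels) -> dict:
            return {
                "reliability": {
                    "prior": pm.reliability.prior,
                    "lrs": pm.reliability.likelihood_ratios,
                },
                "backbone": pm.backbone.theta.tolist(),
                "y_ascending": pm.y_ascending.theta.tolist(),
                "y_descending": pm.y_descending.theta.tolist(),
                "n_spectra": pm.n_spectra,
            }

        payload = {
            "schema_version": 1,
            "min_spectra": self.min_spectra,
            "global": enc_partition(self.global_model),
            "partitions": [
                {
                    "key": [k.peptide_len_bin, k.glycan_size_bin, k.charge_bin, k.mobility,
                            k.glyco_type],
                    **enc_partition(pm),
                }
                for k, pm in sorted(self.partitions.items(), key=lambda kv: kv[0].indices())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FragmentationModel":
        with open(path) as fh:
            payload = json.load(fh)

        def dec_partition(d: dict) -> PartitionModels:
            return PartitionModels(
                reliability=ReliabilityModel(
                    likelihood_ratios=d["reliability"]["lrs"], prior=d["reliability"]["prior"]
                ),
                backbone=IntensityModel(np.array(d["backbone"]), "backbone"),
                y_ascending=IntensityModel(np.array(d["y_ascending"]), "Y-ascending"),
                y_descending=IntensityModel(np.array(d["y_descending"]), "Y-descending"),
                n_spectra=d.get("n_spectra", 0),
            )

        partitions = {}
        for entry in payload["partitions"]:
            lb, gb, cb, mob, gt = entry["key"]
            partitions[PartitionKey(lb, gb, cb, mob, gt)] = dec_partition(entry)
        return cls(
            partitions=partitions,
            global_model=dec_partition(payload["global"]),
            min_spectra=payload.get("min_spectra", 50),
        )


def _assign_reliabilities(records: Sequence[TrainingRecord], rel: ReliabilityModel) -> None:
    for rec in records:
        for frag in rec.fragments:
            frag.reliability = rel.predict(frag.features)


def _split_by_direction(
    records: Sequence[TrainingRecord],
) -> Tuple[List[TrainingRecord], List[TrainingRecord]]:
    asc, desc = [], []
    for rec in records:
        ys = [f for f in rec.fragments if f.series == "Y"]
        (asc if ladder_direction(ys) == "ascending" else desc).append(rec)
    return asc, desc
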