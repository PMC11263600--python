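"""Closed-form glycopeptide–spectrum match (GPSM) scores.

Three layers share one code path for targets and decoys:

* the base model — mass-accuracy-weighted log-intensity sums over matched
  peptide (b/y) and glycan (peptide+Y) fragments, scaled by coverage terms,
  mixed linearly with precursor-accuracy and signature-ion biases;
* the fragmentation-model-enhanced scores, which reweight peaks by their
  reliability φ and add intensity-correlation terms against a learned
  multinomial predictor;
* network-smoothed glycan scores, which add the site-specific glycome prior
  u_g inside the bracket before the coverage scaling, so unsupported
  glycans (zero coverage) gain nothing.

All logs are base 10, so the enhanced scores reduce exactly to the base
scores when φ ≡ 0 and the correlation terms vanish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MatchedFragment",
    "ScoringParams",
    "GPSM",
    "score_peptide_base",
    "score_glycan_base",
    "mass_accuracy_bias",
    "signature_ion_term",
    "score_total_base",
    "cor_terms",
    "score_peptide_model",
    "score_glycan_model",
    "score_total_model",
    "apply_smoothing",
    "shifted_pearson",
    "sigfrag",
    "peptide_coverage_gate",
]


@dataclass(frozen=True)
class MatchedFragment:
    target_mass: float
    intensity: float
    ppm: float  # fractional relative error, e.g. 3e-6
    series: str  # 'b' | 'y' | 'Y' | 'oxonium'
    reliability: float = 0.0  # φ ∈ [0, 1]; 0 when no model
    glycan_size: int = 0  # Y fragments only
    index: int = 0  # cleavage index (b/y) for coverage bookkeeping
    predicted: float = 0.0  # model-predicted relative intensity


@dataclass
class ScoringParams:
    alpha: float = 0.5
    beta: float = 0.4
    gamma: float = 1.0
    w: float = 0.65
    tol: float = 20e-6  # fragment tolerance (fractional)
    precursor_tol: float = 5e-6
    mu_pre: float = 0.0
    sigma_pre: float = 5e-6
    mass_acc_cap: float = 30.0
    mass_acc_floor: float = 1e-3


@dataclass
class GPSM:
    """A candidate glycopeptide paired with a spectrum, with matched evidence."""

    scan_id: str = ""
    peptide_length: int = 0
    matched_P: List[MatchedFragment] = field(default_factory=list)
    matched_G: List[MatchedFragment] = field(default_factory=list)
    coverage_P: float = 0.0
    coverage_G: float = 0.0
    coverage_G_core: float = 0.0
    ppm_pre: float = 0.0
    # counts of expected sialic acids and their observed oxonium relative
    # intensities (fraction of base peak)
    sialic_counts: Dict[str, int] = field(default_factory=dict)
    oxonium_rel: Dict[str, float] = field(default_factory=dict)

    @property
    def m_p(self) -> int:
        return len(self.matched_P)

    @property
    def m_g(self) -> int:
        return len(self.matched_G)


def _weighted_log_sum(matches: Sequence[MatchedFragment], tol: float, use_phi: bool) -> float:
    total = 0.0
    for m in matches:
        if m.intensity <= 0:
            continue  # contribution undefined; skipped
        weight = 1.0 - abs(m.ppm / tol) ** 4
        term = math.log10(m.intensity) * weight
        if use_phi:
            term = term * (m.reliability + 1.0) + m.reliability
        total += term
    return total


def score_peptide_base(gpsm: GPSM, params: ScoringParams) -> float:
    return _weighted_log_sum(gpsm.matched_P, params.tol, use_phi=False) * (
        gpsm.coverage_P ** params.gamma
    )


def score_glycan_base(gpsm: GPSM, params: ScoringParams, u_g: float = 0.0) -> float:
    inner = _weighted_log_sum(gpsm.matched_G, params.tol, use_phi=False) + u_g
    return inner * (gpsm.coverage_G ** params.alpha) * (gpsm.coverage_G_core ** params.beta)


def mass_accuracy_bias(
    ppm_pre: float,
    mu_pre: float = 0.0,
    sigma_pre: float = 5e-6,
    floor: float = 1e-3,
    cap: float = 30.0,
) -> float:
    """Precursor mass-accuracy bias: a bonus for near-exact precursor matches.

    Gaussian 2σ² convention, argument floored so a perfect match yields the
    cap (+30 at the defaults) rather than +∞; tends to 0 far off-peak.
    """
    arg = 1.0 - math.exp(-((ppm_pre - mu_pre) ** 2) / (2.0 * sigma_pre**2))
    return min(-10.0 * math.log10(max(arg, floor)), cap)


def signature_ion_term(gpsm: GPSM) -> float:
    """Signature (oxonium) ion penalties for NeuAc/NeuGc.

    An observed oxonium for an absent monosaccharide is penalized by its
    relative intensity; an expected oxonium that is missing (≤ 1% of base
    peak) is penalized by the expected count.
    """
    total = 0.0
    for mono in ("NeuAc", "NeuGc"):
        o = gpsm.sialic_counts.get(mono, 0)
        rel = gpsm.oxonium_rel.get(mono, 0.0)
        if o == 0:
            rel = min(rel, 0.999)
            if rel > 0:
                total += 10.0 * math.log10(1.0 - rel)
        elif rel <= 0.01:
            total += 10.0 * math.log10(1.0 - min(o / 2.0, 0.99))
    return total


def score_total_base(gpsm: GPSM, params: ScoringParams, u_g: float = 0.0) -> float:
    return (
        params.w * score_peptide_base(gpsm, params)
        + (1.0 - params.w) * score_glycan_base(gpsm, params, u_g=u_g)
        + signature_ion_term(gpsm)
        + mass_accuracy_bias(
            gpsm.ppm_pre, params.mu_pre, params.sigma_pre, params.mass_acc_floor, params.mass_acc_cap
        )
    )


def shifted_pearson(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson ρ with degenerate cases (n < 3 or zero variance) pinned to 0."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size < 3 or y.size != x.size:
        return 0.0
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def pad(x: float) -> float:
    return 0.5 * x + 0.5


def sigfrag(gpsm: GPSM) -> int:
    """Number of matched glycan fragments with more than one residue attached."""
    return sum(1 for m in gpsm.matched_G if m.glycan_size > 1)


def peptide_coverage_gate(coverage_p: float) -> float:
    """s(x) = min(exp(3x − 1), 1): gates the glycan model terms by peptide
    coverage so the model cannot favor a wrong backbone."""
    return min(math.exp(3.0 * coverage_p - 1.0), 1.0)


def cor_terms(gpsm: GPSM) -> Tuple[float, float, float, float]:
    """(Cor_P, Cor'_P, Cor_G, Rel_G) from matched fragments and predictions."""
    if gpsm.m_p == 0:
        # no peptide evidence: the correlation machinery is undefined
        return 0.0, 0.0, 0.0, 0.0
    else:
        rho_p = shifted_pearson(
            [m.intensity for m in gpsm.matched_P], [m.predicted for m in gpsm.matched_P]
        )
        cor_p = (rho_p + 1.0) * math.log10(gpsm.m_p) if gpsm.m_p >= 1 else 0.0
        cor_p_prime = (rho_p + 1.0) * gpsm.m_p * gpsm.coverage_P
    if gpsm.m_g == 0:
        cor_g = rel_g = 0.0
    else:
        rho_g = shifted_pearson(
            [m.intensity for m in gpsm.matched_G], [m.predicted for m in gpsm.matched_G]
        )
        cor_g = (rho_g + 1.0) / 2.0
        rel_g = sum(pad(m.reliability) for m in gpsm.matched_G) * max(rho_g, 0.25)
    return cor_p, cor_p_prime, cor_g, rel_g


def score_peptide_model(gpsm: GPSM, params: ScoringParams) -> float:
    cor_p, _, _, _ = cor_terms(gpsm)
    inner = _weighted_log_sum(gpsm.matched_P, params.tol, use_phi=True) + cor_p
    return inner * (gpsm.coverage_P ** params.gamma)


def score_glycan_model(gpsm: GPSM, params: ScoringParams, u_g: float = 0.0) -> float:
    _, _, cor_g, rel_g = cor_terms(gpsm)
    inner = (
        _weighted_log_sum(gpsm.matched_G, params.tol, use_phi=False)
        + (rel_g + cor_g) * sigfrag(gpsm) * peptide_coverage_gate(gpsm.coverage_P)
        + u_g
    )
    return inner * (gpsm.coverage_G ** params.alpha) * (gpsm.coverage_G_core ** params.beta)


def score_total_model(gpsm: GPSM, params: ScoringParams, u_g: float = 0.0) -> float:
    return (
        params.w * score_peptide_model(gpsm, params)
        + (1.0 - params.w) * score_glycan_model(gpsm, params, u_g=u_g)
        + signature_ion_term(gpsm)
        + mass_accuracy_bias(
            gpsm.ppm_pre, params.mu_pre, params.sigma_pre, params.mass_acc_floor, params.mass_acc_cap
        )
    )


def apply_smoothing(
    gpsm: GPSM, params: ScoringParams, u_g: float, model_enhanced: bool = False
) -> float:
    """Smoothed glycan score: u_g enters inside the bracket, gated by coverage."""
    if model_enhanced:
        return score_glycan_model(gpsm, params, u_g=u_g)
    return score_glycan_base(gpsm, params, u_g=u_g)
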