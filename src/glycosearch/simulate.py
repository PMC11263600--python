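"""Synthetic glycoproteomics fixtures.

Emulates the structure of stepped-collision-energy glycopeptide MS/MS and
LC elution data well enough to exercise every layer of the engine:

* deconvoluted GPSM spectra — b/y backbone ions with multinomial relative
  intensities drawn from a ground-truth θ over the same feature space the
  intensity model fits, a peptide+Y ladder with an ascending or descending
  intensity profile, oxonium ions for sialylated compositions,
  multiplicative log-normal intensity noise, and Poisson-count random noise
  peaks;
* LC runs — apex times from a linear composition model (per-monosaccharide
  minutes-per-residue, optional drift across the gradient) with Gaussian
  noise, and a configured fraction of identifications recorded under the
  quasi-isobaric NeuAc+NH3 <-> Hex+dHex swap, with truth labels;
* target/decoy score populations with a known null fraction, for FDR
  calibration checks.

Everything is seeded; identical configs give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import AMMONIA, WATER, residue_mass
from .fragmodel import (
    FragmentRecord,
    backbone_feature_dim,
    backbone_fragment_features,
    y_feature_dim,
    y_fragment_features,
)
from .glycans import GlycanComposition, generate_y_ladder
from .peptides import Peptide, backbone_fragments, proton_mobility
from .rt import ADDUCT_MASSES, ElutedID
from .spectra import AnnotatedSpectrum, DeconvolutedPeak

__all__ = [
    "SimulationConfig",
    "default_theta_backbone",
    "default_theta_y",
    "simulate_spectrum",
    "simulate_spectra",
    "simulate_run",
    "simulate_score_populations",
    "example_proteins",
    "example_glycans",
]


@dataclass
class SimulationConfig:
    n_backbones: int = 10
    glycoforms_per_backbone: int = 5
    noise_sigma: float = 0.3  # log-normal multiplicative intensity noise
    n_noise_peaks: float = 20.0  # Poisson mean
    ppm_jitter: float = 2e-6  # fragment/precursor mass error scale
    swap_rate: float = 0.0  # planted quasi-isobaric misassignment rate
    ascending_fraction: float = 0.3  # share of spectra with ascending Y ladders
    rt_coefficients: Dict[str, float] = field(
        default_factory=lambda: {"Hex": 0.5, "HexNAc": 0.8, "NeuAc": 2.0, "dHex": -0.3,
                                 "adduct:NH3": -0.5}
    )
    rt_noise: float = 0.1  # minutes
    rt_drift: float = 0.0  # linear change of each coefficient across the run
    run_span: float = 90.0  # minutes
    seed: int = 0


def default_theta_backbone() -> np.ndarray:
    """A plausible ground-truth backbone θ: enhanced cleavage N-terminal to
    proline, suppressed after proline, y-series preference, mobility effects."""
    theta = np.zeros(backbone_feature_dim())
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    off = len(alphabet)
    theta[alphabet.index("P")] = 0.15  # P content in fragment
    theta[off + alphabet.index("D")] = 0.8  # cleavage C-terminal to D
    theta[off + alphabet.index("E")] = 0.4
    theta[off + 20 + alphabet.index("P")] = 1.2  # cleavage N-terminal to P
    theta[off + 40] = -0.6  # b ions weaker than y under SCE
    theta[off + 41] = 0.5  # later cleavages slightly favored
    theta[off + 43] = -0.3  # immobile precursors fragment less selectively
    return theta


def default_theta_y(direction: str = "descending") -> np.ndarray:
    theta = np.zeros(y_feature_dim())
    theta[0] = 0.5 if direction == "ascending" else -0.5
    theta[2] = 0.8  # Y0/Y1 prominent
    return theta


def simulate_spectrum(
    peptide: Peptide,
    glycan: GlycanComposition,
    rng: np.random.Generator,
    config: SimulationConfig,
    theta_backbone: Optional[np.ndarray] = None,
    theta_y: Optional[np.ndarray] = None,
    charge: int = 3,
    scan_id: str = "sim",
    shift_mass: float = 0.0,
    rt: float = 0.0,
    direction: Optional[str] = None,
) -> AnnotatedSpectrum:
    """One annotated GPSM spectrum; peak origins are stored as annotations."""
    if theta_backbone is None:
        theta_backbone = default_theta_backbone()
    if direction is None:
        direction = "ascending" if rng.random() < config.ascending_fraction else "descending"
    if theta_y is None:
        theta_y = default_theta_y(direction)
    mobility = proton_mobility(peptide.sequence, charge)
    peaks: List[Tuple[float, float, str]] = []  # (mass, intensity, label)

    bb = backbone_fragments(peptide)
    X = np.vstack(
        [
            backbone_fragment_features(
                FragmentRecord(series=f.series, index=f.index), peptide.sequence, mobility
            )
            for f in bb
        ]
    )
    z = X @ theta_backbone
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    total_bb = 1e5
    for f, prob in zip(bb, p):
        inten = total_bb * prob * rng.lognormal(0.0, config.noise_sigma)
        mass = f.mass * (1.0 + rng.normal(0.0, config.ppm_jitter))
        peaks.append((mass, inten, f"{f.series}{f.index}"))

    ladder = generate_y_ladder(glycan)
    Xy = np.vstack(
        [
            y_fragment_features(
                FragmentRecord(series="Y", glycan_size=f.glycan_size), peptide.sequence, mobility
            )
            for f in ladder
        ]
    )
    zy = Xy @ theta_y
    zy -= zy.max()
    py = np.exp(zy)
    py /= py.sum()
    total_y = 5e4
    for f, prob in zip(ladder, py):
        inten = total_y * prob * rng.lognormal(0.0, config.noise_sigma)
        mass = (peptide.mass + f.mass_delta) * (1.0 + rng.normal(0.0, config.ppm_jitter))
        label = "Y:0" if f.glycan_size == 0 else f"Y:{str(f.attached_composition)}"
        peaks.append((mass, inten, label))

    if glycan["NeuAc"] > 0:
        for m in (residue_mass("NeuAc"), residue_mass("NeuAc") - WATER):
            peaks.append(
                (m * (1.0 + rng.normal(0.0, config.ppm_jitter)),
                 2e4 * rng.lognormal(0.0, config.noise_sigma), "oxonium:NeuAc")
            )

    n_noise = rng.poisson(config.n_noise_peaks)
    precursor = peptide.mass + glycan.mass + shift_mass
    for _ in range(n_noise):
        peaks.append(
            (float(rng.uniform(150.0, precursor)), float(rng.lognormal(4.0, 1.0)), "")
        )

    dec_peaks = [
        DeconvolutedPeak(neutral_mass=m, intensity=i, charge=1) for m, i, _ in peaks
    ]
    spec = AnnotatedSpectrum(
        scan_id=scan_id,
        precursor_mass=precursor * (1.0 + rng.normal(0.0, config.ppm_jitter / 2.0)),
        precursor_charge=charge,
        rt=rt,
        peaks=dec_peaks,
        peptide=peptide.sequence,
        glycan=str(glycan),
    )
    # map labels to the mass-sorted peak order
    order = sorted(range(len(peaks)), key=lambda i: peaks[i][0])
    annotations = {}
    for new_idx, old_idx in enumerate(order):
        label = peaks[old_idx][2]
        if label:
            annotations[new_idx] = label
    spec.annotations = annotations
    return spec


def simulate_spectra(
    glycopeptides: Sequence[Tuple[Peptide, GlycanComposition]],
    config: SimulationConfig,
    theta_backbone: Optional[np.ndarray] = None,
    theta_y_asc: Optional[np.ndarray] = None,
    theta_y_desc: Optional[np.ndarray] = None,
    shifts: Optional[Sequence[float]] = None,
) -> Tuple[List[AnnotatedSpectrum], pd.DataFrame]:
    """Annotated spectra plus a truth table (one row per spectrum)."""
    rng = np.random.default_rng(config.seed)
    spectra: List[AnnotatedSpectrum] = []
    truth_rows = []
    for i, (pep, gly) in enumerate(glycopeptides):
        charge = int(rng.integers(2, 5))
        direction = "ascending" if rng.random() < config.ascending_fraction else "descending"
        theta_y = theta_y_asc if direction == "ascending" else theta_y_desc
        shift = float(shifts[i]) if shifts is not None else 0.0
        rt = float(rng.uniform(5.0, config.run_span - 5.0))
        spec = simulate_spectrum(
            pep, gly, rng, config,
            theta_backbone=theta_backbone, theta_y=theta_y,
            charge=charge, scan_id=f"sim_{i}", shift_mass=shift, rt=rt,
            direction=direction,
        )
        spectra.append(spec)
        truth_rows.append(
            {
                "scan_id": spec.scan_id,
                "peptide": pep.sequence,
                "glycan": str(gly),
                "charge": charge,
                "direction": direction,
                "shift_mass": shift,
                "rt": rt,
            }
        )
    return spectra, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# LC run simulation


def _rt_for(
    glycan: GlycanComposition,
    adducts: Tuple[Tuple[str, int], ...],
    backbone_rt: float,
    mean_comp: Dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> float:
    t = backbone_rt
    drift_factor = 1.0 + config.rt_drift * (backbone_rt / config.run_span - 0.5)
    counts = glycan.as_dict()
    for mono, coef in config.rt_coefficients.items():
        if mono.startswith("adduct:"):
            continue
        t += coef * drift_factor * (counts.get(mono, 0) - mean_comp.get(mono, 0.0))
    for name, count in adducts:
        t += config.rt_coefficients.get(f"adduct:{name}", 0.0) * drift_factor * count
    return t + float(rng.normal(0.0, config.rt_noise))


def simulate_run(
    config: SimulationConfig,
    backbones: Optional[Sequence[str]] = None,
    glycans: Optional[Sequence[GlycanComposition]] = None,
) -> pd.DataFrame:
    """An ElutedID table with planted quasi-isobaric swaps.

    Each backbone elutes near a base time; its glycoforms shift by the
    composition model.  A ``swap_rate`` fraction of sialylated+ammoniated
    identifications are *recorded* with the NeuAc+NH3 -> Hex+dHex
    substitution while their apex time reflects the true composition.
    Columns carry both the recorded and the true assignment.
    """
    rng = np.random.default_rng(config.seed)
    if glycans is None:
        glycans = example_glycans()
    if backbones is None:
        backbones = [f"BB{i}" for i in range(config.n_backbones)]
    rows = []
    for b in backbones:
        base_rt = float(rng.uniform(15.0, config.run_span - 15.0))
        chosen = rng.choice(len(glycans), size=min(config.glycoforms_per_backbone, len(glycans)),
                            replace=False)
        comps = [glycans[int(i)] for i in chosen]
        mean_comp: Dict[str, float] = {}
        for g in comps:
            for m, n in g.as_dict().items():
                mean_comp[m] = mean_comp.get(m, 0.0) + n / len(comps)
        for g in comps:
            has_adduct = rng.random() < 0.35
            adducts = (("NH3", 1),) if has_adduct else ()
            apex = _rt_for(g, adducts, base_rt, mean_comp, config, rng)
            true_g, true_adducts = g, adducts
            rec_g, rec_adducts = g, adducts
            swapped = False
            if (
                g["NeuAc"] >= 1
                and has_adduct
                and rng.random() < config.swap_rate
            ):
                counts = g.as_dict()
                counts["NeuAc"] -= 1
                counts["Hex"] = counts.get("Hex", 0) + 1
                counts["dHex"] = counts.get("dHex", 0) + 1
                rec_g = GlycanComposition.from_dict(counts)
                rec_adducts = ()
                swapped = True
            oxon = (("NeuAc", 0.2),) if true_g["NeuAc"] > 0 else (("NeuAc", 0.0),)
            rows.append(
                {
                    "backbone": b,
                    "glycan": str(rec_g),
                    "true_glycan": str(true_g),
                    "adducts": ";".join(f"{a}:{n}" for a, n in rec_adducts),
                    "true_adducts": ";".join(f"{a}:{n}" for a, n in true_adducts),
                    "apex_rt": apex,
                    "abundance": float(rng.lognormal(10.0, 1.0)),
                    "swapped": swapped,
                    "oxonium_neuac": dict(oxon)["NeuAc"],
                }
            )
    return pd.DataFrame(rows)


def eluted_ids_from_table(df: pd.DataFrame) -> List[ElutedID]:
    from .glycans import parse_composition

    out = []
    for r in df.itertuples():
        adducts = tuple(
            (a.split(":")[0], int(a.split(":")[1]))
            for a in str(r.adducts).split(";")
            if a and a != "nan"
        )
        out.append(
            ElutedID(
                backbone=r.backbone,
                glycan=parse_composition(r.glycan),
                adducts=adducts,
                apex_rt=float(r.apex_rt),
                abundance=float(r.abundance),
                oxonium_rel=(("NeuAc", float(getattr(r, "oxonium_neuac", 0.0))),),
            )
        )
    return out


# ---------------------------------------------------------------------------
# score-population simulation for FDR calibration


def simulate_score_populations(
    seed: int,
    n_true: int = 400,
    n_null_target: int = 400,
    n_decoy: int = 400,
    true_mu: float = 18.0,
    null_mu: float = 6.0,
    sigma: float = 3.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(scores, is_decoy, is_true) with decoys drawn from the null law.

    Targets are a mixture of genuine matches (shifted high) and random
    matches distributed exactly like decoys, so realized false-discovery
    proportions can be measured against estimated q-values.
    """
    rng = np.random.default_rng(seed)
    true_scores = rng.normal(true_mu, sigma, n_true)
    null_scores = rng.normal(null_mu, sigma, n_null_target)
    decoy_scores = rng.normal(null_mu, sigma, n_decoy)
    scores = np.concatenate([true_scores, null_scores, decoy_scores])
    is_decoy = np.concatenate(
        [np.zeros(n_true + n_null_target, bool), np.ones(n_decoy, bool)]
    )
    is_true = np.concatenate(
        [np.ones(n_true, bool), np.zeros(n_null_target + n_decoy, bool)]
    )
    return scores, is_decoy, is_true


# ---------------------------------------------------------------------------
# small built-in example search space


def example_proteins(n: int = 6, seed: int = 7) -> List[Tuple[str, str]]:
    """Random tryptic proteins guaranteed to contain N-X-S/T sequons."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHILMPQSVWY")  # K/R/N/T added deliberately
    proteins = []
    for i in range(n):
        parts = []
        for _ in range(rng.integers(3, 6)):
            length = int(rng.integers(6, 14))
            body = "".join(rng.choice(alphabet, size=length))
            # plant a sequon mid-peptide
            pos = int(rng.integers(1, max(length - 2, 2)))
            body = body[:pos] + "N" + body[pos + 1 : pos + 2] + "T" + body[pos + 3 :]
            body = body.replace("NP", "NA")  # keep the sequon valid
            parts.append(body + ("K" if rng.random() < 0.5 else "R"))
        proteins.append((f"PROT{i}", "".join(parts)))
    return proteins


def example_glycans() -> List[GlycanComposition]:
    specs = [
        {"HexNAc": 2, "Hex": 5},
        {"HexNAc": 2, "Hex": 6},
        {"HexNAc": 2, "Hex": 7},
        {"HexNAc": 2, "Hex": 8},
        {"HexNAc": 2, "Hex": 9},
        {"HexNAc": 4, "Hex": 5},
        {"HexNAc": 4, "Hex": 5, "NeuAc": 1},
        {"HexNAc": 4, "Hex": 5, "NeuAc": 2},
        {"HexNAc": 4, "Hex": 5, "dHex": 1},
        {"HexNAc": 4, "Hex": 5, "dHex": 1, "NeuAc": 1},
        {"HexNAc": 4, "Hex": 6, "dHex": 1},
        {"HexNAc": 5, "Hex": 6},
        {"HexNAc": 5, "Hex": 6, "NeuAc": 1},
        {"HexNAc": 5, "Hex": 6, "dHex": 1, "NeuAc": 1},
        {"HexNAc": 3, "Hex": 6},
        {"HexNAc": 3, "Hex": 5, "NeuAc": 1},
    ]
    return [GlycanComposition.from_dict(s) for s in specs]
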