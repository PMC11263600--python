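"""Deconvoluted spectrum model and the file formats around it.

The search input is an MGF dialect holding *neutral-mass*, charge-deconvoluted
peak lists: a ``CHARGE=0`` sentinel in a block marks PEPMASS as a neutral
precursor mass (otherwise PEPMASS is interpreted as m/z and converted with
the given charge).  Annotated MGF adds a third token on peak lines carrying
a fragment label (``b4``, ``y7``, ``Y:HexNAc2Hex3``, ``Y:0``,
``oxonium:NeuAc``), used for fragmentation-model training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import PROTON

__all__ = [
    "DeconvolutedPeak",
    "Spectrum",
    "AnnotatedSpectrum",
    "read_mgf",
    "write_mgf",
    "write_annotated_mgf",
    "read_annotated_mgf",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class DeconvolutedPeak:
    neutral_mass: float
    intensity: float
    charge: int = 1
    rank: int = 0  # 1 = most intense; assigned at load


@dataclass
class Spectrum:
    scan_id: str
    precursor_mass: float  # neutral, corrected
    precursor_charge: int
    rt: float  # minutes
    peaks: List[DeconvolutedPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = assign_ranks(sorted(self.peaks, key=lambda p: p.neutral_mass))

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def masses(self) -> np.ndarray:
        return np.array([p.neutral_mass for p in self.peaks])

    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


@dataclass
class AnnotatedSpectrum(Spectrum):
    """A spectrum with a resolved glycopeptide assignment and peak labels."""

    peptide: str = ""
    glycan: str = ""
    annotations: Dict[int, str] = field(default_factory=dict)  # peak index -> label


def assign_ranks(peaks: Sequence[DeconvolutedPeak]) -> List[DeconvolutedPeak]:
    order = np.argsort([-p.intensity for p in peaks], kind="stable")
    ranks = np.empty(len(peaks), dtype=int)
    ranks[order] = np.arange(1, len(peaks) + 1)
    return [replace(p, rank=int(r)) for p, r in zip(peaks, ranks)]


class MGFFormatError(ValueError):
    pass


def _parse_block(lines: List[str], scan_default: str, annotated: bool):
    headers: Dict[str, str] = {}
    peaks: List[DeconvolutedPeak] = []
    annotations: Dict[int, str] = {}
    skipped = 0
    for line in lines:
        if "=" in line and not line[0].isdigit():
            key, _, val = line.partition("=")
            headers[key.strip().upper()] = val.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            skipped += 1
            continue
        try:
            mass, inten = float(parts[0]), float(parts[1])
        except ValueError:
            skipped += 1
            continue
        charge = 1
        label = None
        for tok in parts[2:]:
            try:
                charge = int(tok)
            except ValueError:
                label = tok
        if label is not None and annotated:
            annotations[len(peaks)] = label
        peaks.append(DeconvolutedPeak(neutral_mass=mass, intensity=inten, charge=charge))

    scan_id = headers.get("TITLE", scan_default)
    charge_str = headers.get("CHARGE", "1").rstrip("+")
    try:
        precursor_charge = int(charge_str)
    except ValueError:
        raise MGFFormatError(f"malformed CHARGE in scan {scan_id!r}")
    pepmass_str = headers.get("PEPMASS")
    if pepmass_str is None:
        raise MGFFormatError(f"missing PEPMASS in scan {scan_id!r}")
    pepmass = float(pepmass_str.split()[0])
    if precursor_charge == 0:
        # sentinel dialect: PEPMASS is already the neutral precursor mass
        precursor_mass = pepmass
        precursor_charge = int(headers.get("PRECURSORCHARGE", "1"))
    else:
        precursor_mass = pepmass * precursor_charge - precursor_charge * PROTON
    rt = float(headers.get("RTINSECONDS", "0")) / 60.0

    # the annotation indices refer to input order; remap to mass-sorted order
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].neutral_mass)
    remap = {old: new for new, old in enumerate(order)}
    annotations = {remap[i]: lab for i, lab in annotations.items()}

    if annotated:
        spec = AnnotatedSpectrum(
            scan_id=scan_id,
            precursor_mass=precursor_mass,
            precursor_charge=precursor_charge,
            rt=rt,
            peaks=peaks,
            peptide=headers.get("PEPTIDE", ""),
            glycan=headers.get("GLYCAN", ""),
            annotations=annotations,
        )
    else:
        spec = Spectrum(
            scan_id=scan_id,
            precursor_mass=precursor_mass,
            precursor_charge=precursor_charge,
            rt=rt,
            peaks=peaks,
        )
    return spec, skipped


def _iter_blocks(path) -> Iterator[Tuple[int, List[str]]]:
    block: Optional[List[str]] = None
    idx = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                block = []
            elif line == "END IONS":
                if block is None:
                    raise MGFFormatError("END IONS without BEGIN IONS")
                yield idx, block
                idx += 1
                block = None
            elif block is not None:
                block.append(line)
    if block is not None:
        raise MGFFormatError("unterminated BEGIN IONS block at end of file")


def read_mgf(path, annotated: bool = False) -> Iterator[Spectrum]:
    """Stream spectra from the MGF dialect; memory is O(one spectrum)."""
    total_skipped = 0
    for idx, block in _iter_blocks(path):
        spec, skipped = _parse_block(block, scan_default=f"scan={idx}", annotated=annotated)
        total_skipped += skipped
        if skipped:
            warnings.warn(f"skipped {skipped} non-numeric peak line(s) in {spec.scan_id}")
        yield spec


def read_annotated_mgf(path) -> Iterator[AnnotatedSpectrum]:
    return read_mgf(path, annotated=True)  # type: ignore[return-value]


def _write_block(fh, spec: Spectrum, annotations: Optional[Dict[int, str]] = None) -> None:
    fh.write("BEGIN IONS\n")
    fh.write(f"TITLE={spec.scan_id}\n")
    fh.write(f"PEPMASS={spec.precursor_mass:.6f}\n")
    fh.write("CHARGE=0\n")  # neutral-mass sentinel
    fh.write(f"PRECURSORCHARGE={spec.precursor_charge}\n")
    fh.write(f"RTINSECONDS={spec.rt * 60.0:.4f}\n")
    if isinstance(spec, AnnotatedSpectrum):
        if spec.peptide:
            fh.write(f"PEPTIDE={spec.peptide}\n")
        if spec.glycan:
            fh.write(f"GLYCAN={spec.glycan}\n")
    for i, p in enumerate(spec.peaks):
        label = (annotations or {}).get(i)
        if label is not None:
            fh.write(f"{p.neutral_mass:.6f} {p.intensity:.6f} {p.charge} {label}\n")
        else:
            fh.write(f"{p.neutral_mass:.6f} {p.intensity:.6f} {p.charge}\n")
    fh.write("END IONS\n")


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    with open(path, "w") as fh:
        for spec in spectra:
            _write_block(fh, spec)


def write_annotated_mgf(spectra: Sequence[AnnotatedSpectrum], path) -> None:
    with open(path, "w") as fh:
        for spec in spectra:
            for i in spec.annotations:
                if i < 0 or i >= len(spec.peaks):
                    raise ValueError(
                        f"annotation index {i} out of range in scan {spec.scan_id!r}"
                    )
            _write_block(fh, spec, annotations=spec.annotations)


RESULT_COLUMNS = [
    "scan_id",
    "peptide",
    "glycan",
    "mass_shift",
    "score_peptide",
    "score_glycan",
    "score_total",
    "coverage_P",
    "coverage_G",
    "coverage_G_core",
    "fdr_peptide",
    "fdr_glycan",
    "fdr_joint",
    "rt",
    "rt_score",
    "u_g",
    "is_decoy_peptide",
    "is_decoy_glycan",
]


def write_results(gpsms: pd.DataFrame | Sequence[dict], path) -> None:
    """Write the delimited results table (TSV, scores at 4 decimals)."""
    df = pd.DataFrame(gpsms) if not isinstance(gpsms, pd.DataFrame) else gpsms.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    df = df[RESULT_COLUMNS + extra]
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
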