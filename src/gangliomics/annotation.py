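"""Exact-mass annotation of observed ions and ceramide LCB/FA decomposition.

The high-resolution workflow identifies each molecular species from its exact
mass; the long-chain base is identified from MS/MS and the fatty acyl deduced
by difference.  The triple-quadrupole workflow contributes signal-to-noise
gates: species are detected above S/N 3 and quantifiable above S/N 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from . import core
from .core import (CeramideSpecies, CeramideStructure, FattyAcyl,
                   GangliosideSpecies, IonSpecies, LongChainBase)

logger = logging.getLogger(__name__)

__all__ = [
    "ObservedIon",
    "Annotation",
    "DecompositionResult",
    "enumerate_candidates",
    "match_ion",
    "decompose_ceramide",
    "flag_detection",
    "DETECTION_SN", "QUANTIFICATION_SN",
]

#: S/N gates: detection above 3, quantification at or above 10.
DETECTION_SN = 3.0
QUANTIFICATION_SN = 10.0


@dataclass(frozen=True)
class ObservedIon:
    mz: float
    polarity: str = "negative"
    charge: int = 0            # 0 = unknown
    intensity: float = 0.0
    source: str = "full_scan"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("observed m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class Annotation:
    ion: ObservedIon
    candidate: IonSpecies
    mass_error_ppm: float
    rank: int


@dataclass(frozen=True)
class DecompositionResult:
    species: CeramideSpecies
    structures: Tuple[CeramideStructure, ...]
    major: Optional[CeramideStructure]


def enumerate_candidates(
    classes: Iterable[str],
    ceramides: Iterable[CeramideSpecies | str],
    charges: Iterable[int] = (1, 2, 3, 4),
    polarity: str = "negative",
    mz_window: Tuple[float, float] | None = (200.0, 2600.0),
) -> List[IonSpecies]:
    """Cross-product candidate space (class x ceramide x permitted charge).

    Negative-mode charges above the class's sialic-acid count are excluded;
    candidates outside ``mz_window`` are dropped.  Sorted by m/z.
    """
    classes = list(classes)
    ceramides = [
        c if isinstance(c, CeramideSpecies) else CeramideSpecies.parse(c)
        for c in ceramides
    ]
    charges = sorted(set(charges))
    if not classes or not ceramides:
        raise ValueError("class and ceramide sets must be non-empty")
    out: List[IonSpecies] = []
    for name in classes:
        gclass = core.parse_class_name(name)
        for cer in ceramides:
            species = GangliosideSpecies(gclass=gclass, ceramide=cer)
            for x in charges:
                if polarity == "negative" and x > core.max_negative_charge(gclass):
                    continue
                ion = core.ion_mz(species, polarity, x)
                if mz_window is not None and not (mz_window[0] <= ion.mz <= mz_window[1]):
                    continue
                out.append(ion)
    if not out:
        logger.warning("candidate enumeration produced an empty list after filtering")
    out.sort(key=lambda i: i.mz)
    return out


def _complexity(ion: IonSpecies) -> Tuple[int, int]:
    cer = ion.parent.ceramide
    return (cer.total_double_bonds, ion.parent.gclass.residue_count)


def match_ion(
    obs: ObservedIon,
    candidates: Sequence[IonSpecies],
    tol_ppm: float = 5.0,
) -> List[Annotation]:
    """Rank candidates within a ppm tolerance of an observed ion.

    Ranked by absolute mass error; ties broken by fewer ceramide double bonds,
    then fewer glycan residues.  If the ion's charge is known, only candidates
    of that charge (and polarity) are considered.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    hits = []
    for cand in candidates:
        if cand.polarity != obs.polarity:
            continue
        if obs.charge and cand.charge != obs.charge:
            continue
        err_ppm = (obs.mz - cand.mz) / cand.mz * 1e6
        if abs(err_ppm) <= tol_ppm:
            hits.append((abs(err_ppm), _complexity(cand), err_ppm, cand))
    hits.sort(key=lambda h: (h[0], h[1], h[3].parent.label))
    return [
        Annotation(ion=obs, candidate=cand, mass_error_ppm=err, rank=i + 1)
        for i, (_, _, err, cand) in enumerate(hits)
    ]


def decompose_ceramide(
    species: CeramideSpecies | str,
    lcb_set: Iterable[LongChainBase | str] = core.DEFAULT_LCB_SET,
    fa_carbons: Tuple[int, int] = (14, 26),
    fa_double_bonds: Tuple[int, int] = (0, 2),
) -> DecompositionResult:
    """All LCB/FA splits of a ceramide C:D total consistent with the registry.

    For each candidate base the fatty acyl is deduced by difference
    (total C - LCB C : total DB - LCB DB) and kept if it falls inside the FA
    constraints.  Ordered by LCB carbons then LCB double bonds.  The major
    structure is the d18:1 (sphingosine) combination when present, reflecting
    its dominance among mammalian sphingolipids.
    """
    if isinstance(species, str):
        species = CeramideSpecies.parse(species)
    bases = sorted(
        b if isinstance(b, LongChainBase) else LongChainBase.parse(b)
        for b in lcb_set
    )
    if not bases:
        raise ValueError("lcb_set must be non-empty")
    structures: List[CeramideStructure] = []
    seen = set()
    for lcb in bases:
        fc = species.total_carbons - lcb.carbons
        fd = species.total_double_bonds - lcb.double_bonds
        if not (fa_carbons[0] <= fc <= fa_carbons[1]):
            continue
        if not (fa_double_bonds[0] <= fd <= fa_double_bonds[1]):
            continue
        structure = CeramideStructure(lcb=lcb, fa=FattyAcyl(fc, fd))
        if structure.label in seen:
            continue
        seen.add(structure.label)
        structures.append(structure)
    major = next((s for s in structures if s.lcb.label == "d18:1"), None)
    return DecompositionResult(species=species, structures=tuple(structures),
                               major=major)


def flag_detection(records: pd.DataFrame, snr_column: str = "snr") -> pd.DataFrame:
    """Partition peak records by the S/N gates into a ``status`` column.

    ``non_detected`` (S/N <= 3), ``detected_below_LOQ`` (3 < S/N < 10),
    ``quantified`` (S/N >= 10).  Records with missing S/N are dropped and
    logged by their identifying columns.
    """
    df = records.copy()
    if snr_column not in df.columns:
        raise KeyError(f"records lack an {snr_column!r} column")
    missing = df[snr_column].isna()
    if missing.any():
        for _, row in df.loc[missing].iterrows():
            logger.warning("record rejected, missing S/N: %s",
                           row.drop(snr_column).to_dict())
        df = df.loc[~missing].copy()
    snr = df[snr_column]
    status = pd.Series("detected_below_LOQ", index=df.index, dtype="object")
    status[snr <= DETECTION_SN] = "non_detected"
    status[snr >= QUANTIFICATION_SN] = "quantified"
    df["status"] = status
    return df


def annotation_table(annotations: Iterable[Annotation]) -> pd.DataFrame:
    """Flatten annotations for TSV export."""
    rows = []
    for a in annotations:
        sp = a.candidate.parent
        rows.append({
            "observed_mz": a.ion.mz,
            "class": sp.gclass.name,
            "ceramide": sp.ceramide.label,
            "charge": a.candidate.charge,
            "polarity": a.candidate.polarity,
            "theoretical_mz": a.candidate.mz,
            "mass_error_ppm": a.mass_error_ppm,
            "rank": a.rank,
        })
    return pd.DataFrame(rows)
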