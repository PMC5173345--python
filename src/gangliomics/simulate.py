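"""Synthetic SRM peak tables and HPTLC plates with the study's structure.

The generator emulates the measurement design the analysis assumes: six
tissue groups (retina, brain, RPE/choroid, optic nerve, ciliary body,
plasma) with 7/7/7/6/4/4 subjects, three injection replicates per sample, a
14-class ganglioside panel and a 19-species ceramide panel.  Subject-level
species compositions are Dirichlet draws around tissue-specific mean
profiles; injection peak areas get multiplicative lognormal noise; S/N is
area over a noisy noise floor, so minor species fall below the
quantification (S/N 10) or detection (S/N 3) gates, reproducing the high
frequency of below-detection values in this kind of panel.

The built-in profiles encode the study's qualitative tissue pattern, not
its measured numbers: nervous tissues dominated by 36:1/38:1 ceramides
(about 60% in the hematosides GM3/GD3/AcGD3, 85-100% in tetraosyl classes),
plasma and ciliary body rich in 34:1, optic nerve carrying 43:1/44:2,
GT3/AcGT3 expressed only in retina and brain with the retinal forms shifted
toward 40:1/42:2/42:1, and ceramide 42:3 absent from retina and brain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import SRM_CLASS_PANEL, DEFAULT_CERAMIDE_PANEL, parse_class_name

__all__ = [
    "TissueProfile",
    "GeneratorConfig",
    "DEFAULT_SUBJECTS",
    "paper_pattern_profiles",
    "generate_peak_table",
    "generate_calibration_plate",
]

SPECIES_PANEL: Tuple[str, ...] = tuple(c.label for c in DEFAULT_CERAMIDE_PANEL)

#: Group sizes of the study design.
DEFAULT_SUBJECTS: Dict[str, int] = {
    "retina": 7,
    "brain": 7,
    "rpe_choroid": 7,
    "optic_nerve": 6,
    "ciliary_body": 4,
    "plasma": 4,
}


@dataclass(frozen=True)
class TissueProfile:
    """Generating truth for one tissue: per-class closed mean-proportion
    vectors over the species panel (absent classes simply missing) and the
    Dirichlet precision controlling between-subject spread."""

    tissue: str
    class_profiles: Mapping[str, Mapping[str, float]]
    precision: float = 200.0

    def __post_init__(self) -> None:
        for cname, vec in self.class_profiles.items():
            total = sum(vec.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"{self.tissue}/{cname} profile sums to {total}, not 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Measurement-design knobs; the seed fully determines all outputs."""

    seed: int = 0
    subjects: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBJECTS))
    injections: int = 3
    sigma_injection: float = 0.15   # lognormal sigma of injection noise
    area_scale: float = 1.0e6       # typical summed class area
    class_scale_sigma: float = 0.30  # lognormal sigma of per-injection class total
    noise_floor: float = 300.0      # area units at S/N = 1
    noise_floor_sigma: float = 0.30


def _closed(vec: Mapping[str, float]) -> Dict[str, float]:
    total = sum(vec.values())
    return {k: v / total for k, v in vec.items()}


def _nervous_tetraosyl() -> Dict[str, float]:
    # 36:1+38:1 ~ 0.90; no 42:3
    return _closed({
        "36:1": 0.565, "38:1": 0.335, "34:1": 0.030, "40:1": 0.020,
        "42:2": 0.005, "42:1": 0.005, "36:2": 0.012, "38:2": 0.008,
        "37:1": 0.005, "39:1": 0.004, "40:2": 0.004, "41:1": 0.002,
        "32:1": 0.002, "33:1": 0.001, "34:2": 0.001, "35:1": 0.001,
    })


def _nervous_hematoside() -> Dict[str, float]:
    # GM3/GD3/AcGD3 in retina/brain: 36:1+38:1 ~ 0.61, 40:1+42:2+42:1 ~ 0.2
    return _closed({
        "36:1": 0.40, "38:1": 0.21, "34:1": 0.050, "40:1": 0.095,
        "42:2": 0.055, "42:1": 0.050, "36:2": 0.040, "38:2": 0.030,
        "40:2": 0.015, "37:1": 0.005, "39:1": 0.004, "41:1": 0.002,
        "32:1": 0.002, "33:1": 0.001, "34:2": 0.002, "35:1": 0.001,
        "43:1": 0.002, "44:2": 0.001,
    })


def _retina_gt3() -> Dict[str, float]:
    # retinal GT3/AcGT3: 36:1+38:1 ~ 0.35, 40:1+42:2+42:1 ~ 0.54,
    # 2-unsaturated ~ 0.19, >=42 C ~ 0.31
    return _closed({
        "36:1": 0.215, "38:1": 0.130, "40:1": 0.215, "42:2": 0.165,
        "42:1": 0.145, "34:1": 0.030, "36:2": 0.010, "38:2": 0.010,
        "40:2": 0.010, "37:1": 0.005, "39:1": 0.005, "41:1": 0.005,
        "32:1": 0.002, "33:1": 0.001, "34:2": 0.001, "35:1": 0.001,
        "43:1": 0.003, "44:2": 0.002,
    })


def _brain_gt3() -> Dict[str, float]:
    # brain GT3/AcGT3: almost pure 36:1/38:1, ~2% 2-unsaturated
    return _closed({
        "36:1": 0.695, "38:1": 0.280, "36:2": 0.015, "38:2": 0.005,
        "37:1": 0.003, "40:1": 0.002,
    })


def _plasma_like() -> Dict[str, float]:
    # 34:1-rich, short chains abundant, 42:3 present
    return _closed({
        "32:1": 0.050, "33:1": 0.005, "34:2": 0.015, "34:1": 0.355,
        "35:1": 0.005, "36:2": 0.055, "36:1": 0.095, "37:1": 0.005,
        "38:2": 0.045, "38:1": 0.040, "39:1": 0.005, "40:2": 0.045,
        "40:1": 0.070, "41:1": 0.005, "42:3": 0.010, "42:2": 0.095,
        "42:1": 0.090, "43:1": 0.005, "44:2": 0.005,
    })


def _ciliary_like() -> Dict[str, float]:
    return _closed({
        "32:1": 0.020, "33:1": 0.003, "34:2": 0.012, "34:1": 0.170,
        "35:1": 0.005, "36:2": 0.060, "36:1": 0.120, "37:1": 0.005,
        "38:2": 0.050, "38:1": 0.060, "39:1": 0.005, "40:2": 0.055,
        "40:1": 0.130, "41:1": 0.005, "42:3": 0.015, "42:2": 0.150,
        "42:1": 0.110, "43:1": 0.015, "44:2": 0.010,
    })


def _rpe_like() -> Dict[str, float]:
    return _closed({
        "32:1": 0.020, "33:1": 0.002, "34:2": 0.010, "34:1": 0.190,
        "35:1": 0.003, "36:2": 0.055, "36:1": 0.170, "37:1": 0.005,
        "38:2": 0.045, "38:1": 0.090, "39:1": 0.004, "40:2": 0.050,
        "40:1": 0.130, "41:1": 0.004, "42:3": 0.012, "42:2": 0.130,
        "42:1": 0.070, "43:1": 0.006, "44:2": 0.004,
    })


def _optic_nerve_like() -> Dict[str, float]:
    # 43:1/44:2 signal is an optic-nerve marker
    return _closed({
        "32:1": 0.005, "33:1": 0.002, "34:2": 0.008, "34:1": 0.070,
        "35:1": 0.003, "36:2": 0.055, "36:1": 0.110, "37:1": 0.005,
        "38:2": 0.060, "38:1": 0.060, "39:1": 0.005, "40:2": 0.070,
        "40:1": 0.160, "41:1": 0.010, "42:3": 0.010, "42:2": 0.180,
        "42:1": 0.110, "43:1": 0.045, "44:2": 0.032,
    })


#: Which classes each tissue expresses (the study's qualitative pattern).
_PRESENCE: Dict[str, Tuple[str, ...]] = {
    "retina": SRM_CLASS_PANEL,
    "brain": SRM_CLASS_PANEL,
    "rpe_choroid": ("GM3", "GD3", "GD1a", "GD1b", "GT1b", "AcGT1b", "GQ1b"),
    "ciliary_body": ("GM3", "GM2", "GD3", "AcGD3", "GD2", "GD1a", "GD1b",
                     "GT1b", "AcGT1b", "GQ1b"),
    "optic_nerve": ("GM3", "GM2", "GD3", "AcGD3", "GD2", "GD1a", "GD1b",
                    "AcGD1b", "GT1b", "AcGT1b", "GQ1b", "AcGQ1b"),
    "plasma": ("GM3", "GM2", "GD3", "GD1a", "GD1b", "GT1b"),
}

_HEMATOSIDES = ("GM3", "GM2", "GD3", "AcGD3")


def paper_pattern_profiles(precision: float = 200.0) -> Dict[str, TissueProfile]:
    """Built-in tissue profiles encoding the study's qualitative pattern.

    GT3/AcGT3 appear only in retina and brain; retinal GT3/AcGT3 are shifted
    toward 40:1/42:2/42:1; ceramide 42:3 never appears in retina or brain.
    """
    base: Dict[str, Dict[str, Dict[str, float]]] = {}
    for tissue in ("retina", "brain"):
        profiles = {}
        for cname in _PRESENCE[tissue]:
            if cname in ("GT3", "AcGT3"):
                profiles[cname] = _retina_gt3() if tissue == "retina" else _brain_gt3()
            elif cname in _HEMATOSIDES:
                profiles[cname] = _nervous_hematoside()
            else:
                profiles[cname] = _nervous_tetraosyl()
        base[tissue] = profiles
    archetypes = {
        "rpe_choroid": _rpe_like,
        "ciliary_body": _ciliary_like,
        "plasma": _plasma_like,
        "optic_nerve": _optic_nerve_like,
    }
    for tissue, make in archetypes.items():
        base[tissue] = {cname: make() for cname in _PRESENCE[tissue]}
    return {
        tissue: TissueProfile(tissue=tissue, class_profiles=profiles,
                              precision=precision)
        for tissue, profiles in base.items()
    }


def generate_peak_table(
    config: GeneratorConfig,
    profiles: Optional[Mapping[str, TissueProfile]] = None,
    return_truth: bool = False,
):
    """Simulate an SRM peak table (one row per monitored transition).

    Columns: tissue, subject, injection, gclass, species, area, snr.  Every
    panel species of every expressed class gets a row; species absent from
    the tissue profile get zero area (their SRM channel records noise only).
    Deterministic under ``config.seed``.

    With ``return_truth`` also returns the realised subject-level
    compositions (tissue, subject, gclass, species, proportion) — the
    generating truth that a perfect measurement pipeline would recover.
    """
    if profiles is None:
        profiles = paper_pattern_profiles()
    for tissue in config.subjects:
        if tissue not in profiles:
            raise ValueError(f"no profile for configured tissue {tissue!r}")
    rng = np.random.default_rng(config.seed)
    rows: List[dict] = []
    truth_rows: List[dict] = []
    for tissue, n_subj in config.subjects.items():
        profile = profiles[tissue]
        for subj_idx in range(1, n_subj + 1):
            subject = f"D{subj_idx}"
            for cname, mean_vec in profile.class_profiles.items():
                species = [s for s in SPECIES_PANEL if mean_vec.get(s, 0.0) > 0]
                means = np.array([mean_vec[s] for s in species])
                if math.isinf(profile.precision):
                    comp = means
                else:
                    comp = rng.dirichlet(profile.precision * means)
                comp_map = dict(zip(species, comp))
                if return_truth:
                    for s, p in comp_map.items():
                        truth_rows.append({
                            "tissue": tissue, "subject": subject,
                            "gclass": cname, "species": s,
                            "proportion": float(p),
                        })
                for injection in range(1, config.injections + 1):
                    class_total = config.area_scale * _lognormal(
                        rng, config.class_scale_sigma)
                    for s in SPECIES_PANEL:
                        p = comp_map.get(s, 0.0)
                        area = p * class_total * _lognormal(
                            rng, config.sigma_injection)
                        noise = config.noise_floor * _lognormal(
                            rng, config.noise_floor_sigma)
                        rows.append({
                            "tissue": tissue, "subject": subject,
                            "injection": injection, "gclass": cname,
                            "species": s, "area": area,
                            "snr": area / noise,
                        })
    table = pd.DataFrame(rows)
    if return_truth:
        return table, pd.DataFrame(truth_rows)
    return table


def _lognormal(rng: np.random.Generator, sigma: float) -> float:
    if sigma <= 0:
        return 1.0
    return float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))


def generate_calibration_plate(
    seed: int = 0,
    classes: Sequence[str] = ("GM3", "GM1", "GD3", "GD1a", "GD1b", "GT1b", "GQ1b"),
    amounts: Sequence[float] = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    loadings_gg_nmol: Optional[Mapping[str, float]] = None,
    protein_mg: float = 2.0,
    density_sigma: float = 0.0,
) -> Tuple[pd.DataFrame, Dict[str, float], Dict[str, object]]:
    """Simulate an HPTLC plate: calibration lanes plus one tissue lane.

    Calibration points follow density = slope_class * nmol(sialic) + noise;
    the tissue band for a class loaded with g nmol of ganglioside emits a
    sialic-acid equivalent of g * (sialic residues of the class) nmol before
    densitometry.  Returns (calibration table, band densities, truth).
    """
    amounts = list(amounts)
    if not all(b > a for a, b in zip(amounts, amounts[1:])):
        raise ValueError("calibration amounts must be strictly increasing")
    rng = np.random.default_rng(seed)
    if loadings_gg_nmol is None:
        loadings_gg_nmol = {c: float(1.0 + i) for i, c in enumerate(classes)}
    slopes = {c: float(rng.uniform(1.5, 3.0)) for c in classes}
    intercepts = {c: float(rng.uniform(0.0, 0.5)) for c in classes}
    cal_rows = []
    for c in classes:
        for nmol in amounts:
            density = slopes[c] * nmol + intercepts[c]
            if density_sigma > 0:
                density += rng.normal(0.0, density_sigma)
            cal_rows.append({"gclass": c, "nmol": nmol, "density": density})
    bands: Dict[str, float] = {}
    for c, gg in loadings_gg_nmol.items():
        sialic = gg * parse_class_name(c).neuac
        density = slopes[c] * sialic + intercepts[c]
        if density_sigma > 0:
            density += rng.normal(0.0, density_sigma)
        bands[c] = density
    truth = {
        "loadings_gg_nmol": dict(loadings_gg_nmol),
        "protein_mg": protein_mg,
        "slopes": slopes,
        "intercepts": intercepts,
    }
    return pd.DataFrame(cal_rows), bands, truth
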