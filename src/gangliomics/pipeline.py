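"""End-to-end assembly: enumeration, annotation, quantification, statistics
and the shaped tabular outputs (species/mass list, per-class proportion
table with detection markers, colorscale matrix, compact-letter report,
ternary coordinates)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import annotation, compstats, core, quantify
from .compstats import AnovaResult

logger = logging.getLogger(__name__)

__all__ = [
    "enumerate_species_table",
    "ClassComparison",
    "profile_pipeline",
    "ProfileResult",
    "table1_report",
    "proportion_report",
    "colorscale_matrix",
    "ternary_records",
]


def enumerate_species_table(
    classes: Sequence[str] = core.SRM_CLASS_PANEL,
    ceramides: Sequence[core.CeramideSpecies] = core.DEFAULT_CERAMIDE_PANEL,
    charges: Sequence[int] = (1, 2, 3, 4),
    polarity: str = "negative",
    mz_window: Tuple[float, float] | None = (200.0, 2600.0),
) -> pd.DataFrame:
    """Species/mass list: one row per (class, ceramide, charge) ion with
    formula, neutral monoisotopic mass and m/z.  Stable row order: class
    (panel order), ceramide carbons, double bonds, charge."""
    ions = annotation.enumerate_candidates(classes, ceramides, charges,
                                           polarity, mz_window)
    rows = []
    for ion in ions:
        sp = ion.parent
        comp = core.elemental_composition(sp)
        rows.append({
            "class": sp.gclass.name,
            "ceramide": sp.ceramide.label,
            "formula": core.chem.formula_string(comp),
            "neutral_mass": core.chem.monoisotopic_mass(comp),
            "charge": ion.charge,
            "polarity": ion.polarity,
            "mz": ion.mz,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    class_order = {name: i for i, name in enumerate(classes)}
    df["_c"] = df["class"].map(class_order)
    df["_tc"] = df["ceramide"].str.split(":").str[0].astype(int)
    df["_db"] = df["ceramide"].str.split(":").str[1].astype(int)
    df = df.sort_values(["_c", "_tc", "_db", "charge"]).drop(
        columns=["_c", "_tc", "_db"]).reset_index(drop=True)
    return df


@dataclass
class ClassComparison:
    """ANOVA + Newman-Keuls outcome for one (class, derived variable)."""

    gclass: str
    variable: str
    anova: AnovaResult
    letters: Optional[Dict[str, str]]
    tissue_means_raw: Dict[str, float]   # means of the untransformed variable


@dataclass
class ProfileResult:
    proportions: pd.DataFrame        # long, per injection
    subject_table: pd.DataFrame      # wide, per (tissue, subject, class)
    group_means: pd.DataFrame        # wide, per (tissue, class)
    grouped_means: pd.DataFrame      # minor species pooled into "others"
    derived: pd.DataFrame            # 7 variables per (tissue, subject, class)
    comparisons: List[ClassComparison]
    gate_counts: Dict[str, int]


def profile_pipeline(records: pd.DataFrame, alpha: float = 0.05,
                     minor_threshold: float = 0.01) -> ProfileResult:
    """Run detection gating -> proportions -> aggregation -> derived
    variables -> clr -> additive ANOVA -> Newman-Keuls letters."""
    flagged = annotation.flag_detection(records)
    gate_counts = flagged["status"].value_counts().to_dict()
    props = quantify.species_proportions(flagged)
    subject_table, group_means = quantify.average_replicates(props)
    grouped = quantify.group_minor_species(group_means, threshold=minor_threshold)
    derived = compstats.derive_variable_table(subject_table)

    comparisons: List[ClassComparison] = []
    meta = derived.reset_index()
    for gclass, sub in meta.groupby("gclass"):
        if sub["tissue"].nunique() < 2:
            logger.info("class %s present in a single tissue; no comparison", gclass)
            continue
        for variable in compstats.DERIVED_VARIABLES:
            values = sub[variable].to_numpy(dtype=float)
            response = compstats.clr_response(values)
            frame = pd.DataFrame({
                "response": response,
                "tissue": sub["tissue"].to_numpy(),
                "subject": sub["subject"].to_numpy(),
            })
            result = compstats.anova_additive(frame)
            raw_means = sub.groupby("tissue")[variable].mean().to_dict()
            if result.degenerate:
                letters = {t: "a" for t in result.tissue_means}
            else:
                letters = compstats.newman_keuls(
                    result.tissue_means, result.residual_ms,
                    result.residual_df, result.group_sizes, alpha=alpha)
            comparisons.append(ClassComparison(
                gclass=gclass, variable=variable, anova=result,
                letters=letters, tissue_means_raw=raw_means))
    return ProfileResult(
        proportions=props, subject_table=subject_table,
        group_means=group_means, grouped_means=grouped,
        derived=derived, comparisons=comparisons, gate_counts=gate_counts)


def proportion_report(flagged: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per (tissue, class, species) with N.D. and <LOQ markers.

    A species is marked N.D. in a tissue when never detected, <LOQ when
    detected but never quantified; otherwise its subject-level mean and SD
    (as percentages) are shown.
    """
    props = quantify.species_proportions(flagged)
    subject_table, _ = quantify.average_replicates(props)
    stacked = subject_table.stack()
    stacked.name = "proportion"
    stats_df = stacked.groupby(["tissue", "gclass", "species"]).agg(
        ["mean", "std"])
    best_snr = flagged.groupby(["tissue", "gclass", "species"])["snr"].max()

    rows = []
    for (tissue, gclass, species), snr in best_snr.items():
        key = (tissue, gclass, species)
        if snr >= annotation.QUANTIFICATION_SN and key in stats_df.index:
            mean, sd = stats_df.loc[key, "mean"], stats_df.loc[key, "std"]
            display = f"{100 * mean:.2f} ± {0.0 if np.isnan(sd) else 100 * sd:.2f}"
            rows.append({"tissue": tissue, "gclass": gclass, "species": species,
                         "mean": mean, "sd": sd, "display": display})
        elif snr > annotation.DETECTION_SN:
            rows.append({"tissue": tissue, "gclass": gclass, "species": species,
                         "mean": np.nan, "sd": np.nan, "display": "<LOQ"})
        else:
            rows.append({"tissue": tissue, "gclass": gclass, "species": species,
                         "mean": np.nan, "sd": np.nan, "display": "N.D."})
    return pd.DataFrame(rows)


def colorscale_matrix(grouped_means: pd.DataFrame) -> pd.DataFrame:
    """Colorscale export: mean percentages, rows (tissue, class), species in
    columns, values in percent — intensity proportional to the mean."""
    return (grouped_means * 100.0).round(2)


def table1_report(comparisons: Iterable[ClassComparison]) -> pd.DataFrame:
    """Compact-letter report: one row per (variable, class, tissue) with the
    untransformed tissue mean and its letters."""
    rows = []
    for comp in comparisons:
        for tissue, mean in sorted(comp.tissue_means_raw.items()):
            rows.append({
                "variable": comp.variable,
                "gclass": comp.gclass,
                "tissue": tissue,
                "mean": round(mean, 4),
                "letters": comp.letters.get(tissue, "") if comp.letters else "",
            })
    return pd.DataFrame(rows)


def ternary_records(subject_table: pd.DataFrame,
                    schemes: Sequence[str] = ("chain_groups", "unsaturation",
                                              "chain_length"),
                    level: float = 0.95) -> List[dict]:
    """Ternary points and confidence ellipses per (scheme, tissue, class),
    serialisable as JSONL.  Vertex order is (variable 1, variable 2,
    remainder) as named in each record's ``parts`` field."""
    out: List[dict] = []
    meta = subject_table.reset_index()
    for scheme in schemes:
        part_names = compstats._TERNARY_SCHEMES[scheme]
        for (tissue, gclass), sub in meta.groupby(["tissue", "gclass"]):
            comps = []
            for _, row in sub.iterrows():
                comp = row.drop(["tissue", "subject", "gclass"]).to_dict()
                comps.append(compstats.ternary_parts(comp, scheme))
            points = [compstats.ternary_coordinates(c).xy for c in comps]
            record = {
                "scheme": scheme,
                "parts": list(part_names),
                "tissue": tissue,
                "gclass": gclass,
                "points": [[float(x), float(y)] for x, y in points],
            }
            if len(comps) >= 3:
                ell = compstats.confidence_ellipse(comps, level=level)
                record["ellipse"] = np.asarray(ell.polyline).round(6).tolist()
                record["degenerate"] = ell.degenerate
            out.append(record)
    return out
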