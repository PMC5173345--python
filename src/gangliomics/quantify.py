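"""Peak-area to proportion quantification and HPTLC standard-curve fitting.

SRM peak areas are turned into molecular-species proportions per ganglioside
class: the proportion of a species is its peak area divided by the summed
areas of all detected species of the same class within the same injection,
each class closed independently.  Averages are taken first over the three
injection replicates, then over subjects.  HPTLC band densities are converted
to amounts by inverse prediction from per-class linear standard curves; the
curves measure ganglioside-bound sialic acid, so the ganglioside amount is
the sialic amount divided by the class's sialic-residue count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import core
from .annotation import flag_detection

logger = logging.getLogger(__name__)

__all__ = [
    "species_proportions",
    "average_injections",
    "tissue_means",
    "average_replicates",
    "group_minor_species",
    "StandardCurve",
    "fit_standard_curve",
    "quantify_tissue",
    "TissueQuantification",
    "CalibrationError",
]

SAMPLE_KEYS = ["tissue", "subject", "injection", "gclass"]


class CalibrationError(ValueError):
    """A standard curve cannot be fitted."""


def species_proportions(records: pd.DataFrame,
                        denominator: str = "detected") -> pd.DataFrame:
    """Per-class molecular-species proportions from peak areas.

    ``records`` needs columns tissue, subject, injection, gclass, species,
    area and either a status column from
    :func:`~gangliomics.annotation.flag_detection` or a snr column (gated
    here).  Within each (tissue, subject, injection, gclass) the proportion
    of a species is its area divided by the summed areas of all detected
    species of the class — every class closed independently.  With
    ``denominator="quantified"`` only quantified (S/N >= 10) species enter,
    both numerator and denominator.  Classes whose retained areas sum to
    zero are dropped for that sample and logged.
    """
    if denominator not in ("detected", "quantified"):
        raise ValueError("denominator must be 'detected' or 'quantified'")
    df = records.copy()
    if "status" not in df.columns:
        if "snr" not in df.columns:
            raise KeyError("records need a 'status' or 'snr' column")
        df = flag_detection(df)
    keep = (("detected_below_LOQ", "quantified") if denominator == "detected"
            else ("quantified",))
    quant = df[df["status"].isin(keep)].copy()
    if quant.empty:
        return quant.assign(proportion=pd.Series(dtype=float))
    totals = quant.groupby(SAMPLE_KEYS)["area"].transform("sum")
    zero = totals <= 0
    if zero.any():
        for key, _ in quant.loc[zero].groupby(SAMPLE_KEYS):
            logger.warning("class dropped (all-zero quantified areas): %s", key)
        quant = quant.loc[~zero]
        totals = totals.loc[~zero]
    quant["proportion"] = quant["area"] / totals
    return quant.reset_index(drop=True)


def _closed_pivot(df: pd.DataFrame, index_keys: List[str]) -> pd.DataFrame:
    """Long -> per-sample species columns, absent species as 0 within a
    (sample, class) cell so that closure survives averaging."""
    wide = df.pivot_table(index=index_keys, columns="species",
                          values="proportion", fill_value=0.0, aggfunc="sum")
    return wide


def average_injections(proportions: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over injection replicates -> per-subject proportions.

    Species falling below the gates in some injections of a sample
    contribute zero to those injections, so per-subject vectors stay closed
    to 1.  Missing replicates are averaged over what is present, with a log
    entry.
    """
    wide = _closed_pivot(proportions, SAMPLE_KEYS)
    counts = wide.groupby(["tissue", "subject", "gclass"]).size()
    expected = counts.max()
    short = counts[counts < expected]
    for key, n in short.items():
        logger.info("sample %s has %d of %d injections; mean over available",
                    key, n, expected)
    subj = wide.groupby(["tissue", "subject", "gclass"]).mean()
    return subj


def tissue_means(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Mean over subjects -> per-tissue group means (n recorded)."""
    means = subject_table.groupby(["tissue", "gclass"]).mean()
    n = subject_table.groupby(["tissue", "gclass"]).size()
    means.attrs["n"] = n.to_dict()
    return means


def average_replicates(proportions: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential aggregation: injections first, then subjects.

    Returns ``(subject_table, group_means)``.  The order matters on
    unbalanced designs; pooled averaging over all injections of a tissue is
    deliberately not used.
    """
    subj = average_injections(proportions)
    return subj, tissue_means(subj)


def group_minor_species(means: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Pool species whose mean proportion is below ``threshold`` (default 1%)
    into an ``others`` column, row by row; closure is preserved exactly.

    A species column is dropped entirely only if it is minor in every row;
    otherwise its minor cells are moved into ``others`` and zeroed.
    """
    out = means.copy()
    minor_mask = out.lt(threshold) & out.gt(0.0)
    pooled = out.where(minor_mask, 0.0).sum(axis=1)
    out = out.where(~minor_mask, 0.0)
    out = out.loc[:, (out != 0).any(axis=0) | ~minor_mask.any(axis=0)]
    if (pooled > 0).any():
        out = out.assign(others=pooled)
    return out


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration line density = slope * amount + intercept."""

    gclass: str
    amounts: Tuple[float, ...]
    densities: Tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept

    def inverse_predict(self, density: float) -> float:
        return (density - self.intercept) / self.slope

    def in_range(self, density: float) -> bool:
        lo, hi = self.predict(min(self.amounts)), self.predict(max(self.amounts))
        return min(lo, hi) <= density <= max(lo, hi)


def fit_standard_curve(gclass: str, amounts: Sequence[float],
                       densities: Sequence[float]) -> StandardCurve:
    """Fit a linear standard curve through >= 3 calibration points."""
    amounts = np.asarray(amounts, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if amounts.size < 3:
        raise CalibrationError("need at least 3 calibration points")
    if not np.all(np.diff(amounts) > 0):
        raise CalibrationError("calibration amounts must be strictly increasing")
    fit = stats.linregress(amounts, densities)
    if not np.isfinite(fit.slope) or fit.slope == 0:
        raise CalibrationError("singular calibration fit")
    return StandardCurve(
        gclass=gclass,
        amounts=tuple(amounts),
        densities=tuple(densities),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        slope_stderr=float(fit.stderr),
    )


@dataclass(frozen=True)
class TissueQuantification:
    gclass: str
    sialic_nmol: float
    gg_nmol: float
    normalizer: float
    unit: str                  # "nmol/mg protein" or "nmol/mL plasma"
    value: float
    extrapolated: bool = False


def quantify_tissue(
    band_densities: Mapping[str, float],
    curves: Mapping[str, StandardCurve],
    normalizer: float,
    unit: str = "nmol/mg protein",
) -> List[TissueQuantification]:
    """HPTLC quantification of ganglioside classes from band densities.

    For each class band: sialic-acid nmol by inverse prediction from the
    class's standard curve; ganglioside nmol = sialic nmol / sialic-residue
    count of the class; normalised per mg protein (tissues) or per mL
    (plasma).  Densities outside the calibrated range carry an extrapolation
    flag.
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    out = []
    for name, density in band_densities.items():
        if name not in curves:
            raise CalibrationError(f"no standard curve for class {name!r}")
        curve = curves[name]
        sialic = curve.inverse_predict(density)
        neuac = core.parse_class_name(name).neuac
        if neuac == 0:
            raise ValueError(f"{name} carries no sialic acid; not quantifiable "
                             "by sialic-acid densitometry")
        gg = sialic / neuac
        extrapolated = not curve.in_range(density)
        if extrapolated:
            logger.warning("band density for %s outside calibrated range", name)
        out.append(TissueQuantification(
            gclass=name, sialic_nmol=sialic, gg_nmol=gg,
            normalizer=normalizer, unit=unit, value=gg / normalizer,
            extrapolated=extrapolated))
    return out
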