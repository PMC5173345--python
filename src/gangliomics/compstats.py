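"""Compositional statistics on ceramide-species proportions.

Per ganglioside class the analysis derives seven biologically motivated
variables from the closed species composition (sums on the real
compositional scale, zeros kept), maps each to a univariate response by a
centred log-ratio transform of the two-part composition (v, 1-v), fits an
additive two-factor ANOVA (tissue + subject, no interaction, Type II sums of
squares for the unbalanced design), and compares tissues with the
Newman-Keuls stepwise studentized-range procedure rendered as compact
letters, "a" marking the highest mean.  Three-part amalgamations are drawn
as ternary coordinates with confidence ellipses for the group means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .core import CeramideSpecies, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "DERIVED_VARIABLES",
    "derive_variables",
    "derive_variable_table",
    "ClrValue",
    "clr_transform",
    "clr_response",
    "AnovaResult",
    "anova_additive",
    "newman_keuls",
    "TernaryPoint",
    "ternary_coordinates",
    "ternary_parts",
    "TernaryEllipse",
    "confidence_ellipse",
]

#: The seven derived ceramide variables, in reporting order.
DERIVED_VARIABLES: Tuple[str, ...] = (
    "36:1+38:1",
    "34:1",
    "40:1+42:2+42:1",
    "1-unsaturation",
    "2-unsaturations",
    "<=34C",
    ">=42C",
)

_TERNARY_SCHEMES = {
    # (name, part labels) — the three Fig-5-style amalgamations
    "chain_groups": ("36:1+38:1", "40:1+42:2+42:1", "others"),
    "unsaturation": ("1-unsaturation", "2-unsaturations", "3-unsaturations"),
    "chain_length": ("<=34C", ">=42C", "others"),
}


def _parse_labels(labels: Iterable[str]) -> Dict[str, CeramideSpecies]:
    out = {}
    for label in labels:
        try:
            out[label] = CeramideSpecies.parse(label)
        except StructureError as exc:
            raise StructureError(f"unparseable species label {label!r}") from exc
    return out


def derive_variables(composition: Mapping[str, float]) -> Dict[str, float]:
    """The seven derived variables of a closed per-class composition.

    Amalgamation is plain summation on the real compositional scale; species
    absent from the mapping (non-detected) contribute zero.
    """
    species = _parse_labels(composition.keys())
    v = dict.fromkeys(DERIVED_VARIABLES, 0.0)
    for label, sp in species.items():
        p = float(composition[label])
        if label in ("36:1", "38:1"):
            v["36:1+38:1"] += p
        if label == "34:1":
            v["34:1"] += p
        if label in ("40:1", "42:2", "42:1"):
            v["40:1+42:2+42:1"] += p
        if sp.total_double_bonds == 1:
            v["1-unsaturation"] += p
        if sp.total_double_bonds == 2:
            v["2-unsaturations"] += p
        if sp.total_carbons <= 34:
            v["<=34C"] += p
        if sp.total_carbons >= 42:
            v[">=42C"] += p
    return v


def derive_variable_table(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`derive_variables` to every row of a wide proportion table
    (species in columns, e.g. the per-subject output of
    :func:`~gangliomics.quantify.average_injections`)."""
    rows = [derive_variables(row.to_dict()) for _, row in subject_table.iterrows()]
    return pd.DataFrame(rows, index=subject_table.index, columns=list(DERIVED_VARIABLES))


def ternary_parts(composition: Mapping[str, float], scheme: str) -> Tuple[float, float, float]:
    """Three-part amalgamation of a per-class composition for ternary plots.

    Schemes: ``chain_groups`` (36:1+38:1 / 40:1+42:2+42:1 / others),
    ``unsaturation`` (1 / 2 / 3 double bonds), ``chain_length``
    (<=34 C / >=42 C / others).
    """
    if scheme not in _TERNARY_SCHEMES:
        raise ValueError(f"unknown ternary scheme {scheme!r}")
    v = derive_variables(composition)
    total = sum(composition.values())
    if scheme == "chain_groups":
        a, b = v["36:1+38:1"], v["40:1+42:2+42:1"]
        return (a, b, max(total - a - b, 0.0))
    if scheme == "unsaturation":
        a, b = v["1-unsaturation"], v["2-unsaturations"]
        return (a, b, max(total - a - b, 0.0))
    a, b = v["<=34C"], v[">=42C"]
    return (a, b, max(total - a - b, 0.0))


# ---------------------------------------------------------------------------
# Centred log-ratio transform of a two-part composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClrValue:
    parts: Tuple[float, float]
    coords: Tuple[float, float]
    zero_replaced: bool = False

    @property
    def response(self) -> float:
        """First clr coordinate — the univariate ANOVA response."""
        return self.coords[0]


def clr_transform(v: float, delta: Optional[float] = None) -> ClrValue:
    """clr of the two-part composition (v, 1-v).

    Coordinates are (log v - m, log(1-v) - m) with m the mean of the two
    logs; the first coordinate equals log(v/(1-v))/2.  A boundary value
    (v = 0 or 1) is routed through multiplicative zero replacement with
    ``delta`` and flagged.
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {v}")
    replaced = False
    if v == 0.0 or v == 1.0:
        if delta is None:
            raise ValueError(
                "boundary proportion requires a zero-replacement delta")
        replaced = True
        v = delta if v == 0.0 else 1.0 - delta
        logger.debug("boundary proportion replaced with delta=%g", delta)
    m = 0.5 * (math.log(v) + math.log1p(-v))
    coords = (math.log(v) - m, math.log1p(-v) - m)
    return ClrValue(parts=(v, 1.0 - v), coords=coords, zero_replaced=replaced)


def default_delta(values: Sequence[float], fallback: float = 1e-3) -> float:
    """Zero-replacement delta: half the smallest nonzero part observed for
    the variable across the dataset (parts are both v and 1-v)."""
    arr = np.asarray(list(values), dtype=float)
    parts = np.concatenate([arr, 1.0 - arr])
    nonzero = parts[parts > 0]
    if nonzero.size == 0:
        logger.warning("no nonzero parts; using fallback delta %g", fallback)
        return fallback
    # capped so replacement stays a small perturbation even when the
    # smallest observed part is itself large (degenerate variables)
    return min(0.5 * float(nonzero.min()), 0.01)


def clr_response(values: Sequence[float], delta: Optional[float] = None) -> np.ndarray:
    """Vector of first clr coordinates for a variable across a dataset,
    computing the default delta from the data when not supplied."""
    if delta is None:
        delta = default_delta(values)
    return np.array([clr_transform(v, delta=delta).response for v in values])


# ---------------------------------------------------------------------------
# Additive two-factor ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    table: pd.DataFrame          # rows: tissue, subject, Residual
    residual_ms: float
    residual_df: float
    tissue_means: Dict[str, float]
    group_sizes: Dict[str, int]
    degenerate: bool = False


def anova_additive(data: pd.DataFrame, response: str = "response",
                   tissue: str = "tissue", subject: str = "subject") -> AnovaResult:
    """Two-way additive fixed-effects ANOVA (tissue + subject, no
    interaction) with Type II sums of squares for unbalanced designs.

    Exposes the residual mean square and degrees of freedom for the
    multiple-comparison step, plus tissue group means and sizes.
    """
    df = data[[response, tissue, subject]].dropna().copy()
    df[tissue] = df[tissue].astype(str)
    df[subject] = df[subject].astype(str)
    sizes = df.groupby(tissue).size()
    if (sizes < 2).any():
        for t in sizes[sizes < 2].index:
            logger.warning("tissue %r has a single observation", t)
    if len(sizes) < 2:
        raise ValueError("need at least 2 tissues")

    y = df[response].to_numpy(dtype=float)
    n_obs = y.size
    intercept = np.ones((n_obs, 1))
    d_tissue = pd.get_dummies(df[tissue], drop_first=True, dtype=float).to_numpy()
    d_subject = pd.get_dummies(df[subject], drop_first=True, dtype=float).to_numpy()
    x_full = np.hstack([intercept, d_tissue, d_subject])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError(
            "rank-deficient additive design: tissue and subject levels are "
            "aliased (some subject's tissue membership pattern is confounded "
            "with the tissue factor)")

    fit_full = sm.OLS(y, x_full).fit()
    # Type II: each factor adjusted for the other (no interaction term)
    fit_no_tissue = sm.OLS(y, np.hstack([intercept, d_subject])).fit()
    fit_no_subject = sm.OLS(y, np.hstack([intercept, d_tissue])).fit()
    resid_ss = float(fit_full.ssr)
    resid_df = float(fit_full.df_resid)
    df_t = float(d_tissue.shape[1])
    df_s = float(d_subject.shape[1])
    ss_t = max(float(fit_no_tissue.ssr) - resid_ss, 0.0)
    ss_s = max(float(fit_no_subject.ssr) - resid_ss, 0.0)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    degenerate = (resid_df <= 0 or total_ss <= 1e-300
                  or resid_ss <= 1e-12 * total_ss)
    if degenerate:
        logger.warning("degenerate ANOVA: residual SS ~ 0 or no residual df")
        f_t = f_s = p_t = p_s = np.nan
    else:
        ms_resid = resid_ss / resid_df
        f_t = (ss_t / df_t) / ms_resid
        f_s = (ss_s / df_s) / ms_resid
        p_t = float(stats.f.sf(f_t, df_t, resid_df))
        p_s = float(stats.f.sf(f_s, df_s, resid_df))
    table = pd.DataFrame(
        {"sum_sq": [ss_t, ss_s, resid_ss],
         "df": [df_t, df_s, resid_df],
         "F": [f_t, f_s, np.nan],
         "PR(>F)": [p_t, p_s, np.nan]},
        index=["tissue", "subject", "Residual"])
    table["mean_sq"] = table["sum_sq"] / table["df"]
    return AnovaResult(
        table=table,
        residual_ms=float(table.loc["Residual", "mean_sq"]) if resid_df > 0 else float("nan"),
        residual_df=resid_df,
        tissue_means=df.groupby(tissue)[response].mean().to_dict(),
        group_sizes=sizes.to_dict(),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Newman-Keuls multiple comparisons with compact letters
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _q_critical(alpha: float, r: int, df: float) -> float:
    # studentized-range ppf is expensive (numerical integration); cache it
    return float(stats.studentized_range.ppf(1.0 - alpha, r, df))


def newman_keuls(
    tissue_means: Mapping[str, float],
    residual_ms: float,
    residual_df: float,
    group_sizes: Mapping[str, int],
    alpha: float = 0.05,
) -> Dict[str, str]:
    """Stepwise studentized-range comparisons rendered as compact letters.

    Means are sorted descending; a pair spanning ``r`` ordered means is
    tested against the studentized-range critical value for ``r`` means, with
    the harmonic mean of the pair's group sizes standing in for unequal n.
    Pairs inside a non-significant stretch are not tested (stepwise
    protection), so non-significance is interval-structured and the maximal
    non-significant stretches are the letter groups; "a" labels the stretch
    containing the highest mean.
    """
    if residual_df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    names = sorted(tissue_means, key=lambda t: -tissue_means[t])
    k = len(names)
    if k == 1:
        return {names[0]: "a"}
    means = np.array([tissue_means[t] for t in names])
    ns_intervals: List[Tuple[int, int]] = []

    def contained(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in ns_intervals)

    for r in range(k, 1, -1):
        qcrit = _q_critical(alpha, r, round(float(residual_df), 6))
        for i in range(0, k - r + 1):
            j = i + r - 1
            if contained(i, j):
                continue
            ni, nj = group_sizes[names[i]], group_sizes[names[j]]
            nh = 2.0 / (1.0 / ni + 1.0 / nj)
            se = math.sqrt(residual_ms / nh)
            q = (means[i] - means[j]) / se if se > 0 else math.inf
            if not (q > qcrit):
                ns_intervals.append((i, j))

    # maximal non-significant stretches -> letters
    letters: Dict[str, List[str]] = {t: [] for t in names}
    intervals = sorted(set(ns_intervals))
    maximal = [iv for iv in intervals
               if not any(a <= iv[0] and iv[1] <= b and iv != (a, b)
                          for a, b in intervals)]
    covered = set()
    for a, b in maximal:
        covered.update(range(a, b + 1))
    for i in range(k):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()
    for letter_idx, (a, b) in enumerate(maximal):
        letter = chr(ord("a") + letter_idx)
        for i in range(a, b + 1):
            letters[names[i]].append(letter)
    return {t: "".join(ls) for t, ls in letters.items()}


# ---------------------------------------------------------------------------
# Ternary coordinates and confidence ellipses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TernaryPoint:
    parts: Tuple[float, float, float]   # closed to 1
    xy: Tuple[float, float]
    group: Optional[str] = None


def ternary_coordinates(parts: Sequence[float], group: Optional[str] = None) -> TernaryPoint:
    """Planar coordinates of a 3-part composition inside the unit triangle.

    Parts (a, b, c) are closed to 1 and mapped to x = b + c/2,
    y = (sqrt(3)/2) c; the vertices map to (0,0), (1,0) and (1/2, sqrt3/2).
    """
    arr = np.asarray(parts, dtype=float)
    if arr.shape != (3,) or (arr < 0).any():
        raise ValueError("parts must be 3 non-negative numbers")
    total = arr.sum()
    if total <= 0:
        raise ValueError("at least one part must be positive")
    a, b, c = arr / total
    return TernaryPoint(parts=(a, b, c),
                        xy=(b + c / 2.0, math.sqrt(3.0) / 2.0 * c),
                        group=group)


def _replace_zeros(arr: np.ndarray, delta: Optional[float]) -> np.ndarray:
    """Multiplicative simple replacement of zero parts in closed rows."""
    if delta is None:
        nonzero = arr[arr > 0]
        delta = min(0.5 * float(nonzero.min()), 0.01) if nonzero.size else 1e-3
    zeros = arr == 0.0
    if not zeros.any():
        return arr
    arr = arr.copy()
    for row in range(arr.shape[0]):
        z = zeros[row]
        if z.any():
            arr[row, z] = delta
            arr[row, ~z] *= (1.0 - z.sum() * delta) / arr[row, ~z].sum()
    return arr


_ILR_BASIS = np.array([
    [1.0 / math.sqrt(2.0), -1.0 / math.sqrt(2.0), 0.0],
    [1.0 / math.sqrt(6.0), 1.0 / math.sqrt(6.0), -2.0 / math.sqrt(6.0)],
])


def _ilr(comps: np.ndarray) -> np.ndarray:
    logs = np.log(comps)
    return logs @ _ILR_BASIS.T


def _ilr_inverse(z: np.ndarray) -> np.ndarray:
    logs = z @ _ILR_BASIS
    comps = np.exp(logs)
    return comps / comps.sum(axis=-1, keepdims=True)


@dataclass
class TernaryEllipse:
    center: TernaryPoint
    polyline: np.ndarray          # (m, 2) ternary xy coordinates
    level: float
    degenerate: bool = False


def confidence_ellipse(points: Sequence[Sequence[float]], level: float = 0.95,
                       n_arc: int = 120,
                       delta: Optional[float] = None) -> TernaryEllipse:
    """Confidence ellipse for the mean of a group of 3-part compositions.

    Compositions are closed, zeros replaced multiplicatively (delta defaults
    to half the smallest nonzero part in the group), mapped to 2-D isometric
    log-ratio coordinates, and the mean's chi-square confidence region
    (covariance / n scaling) is traced and back-transformed point-wise to
    ternary coordinates.  A singular covariance (e.g. identical points)
    collapses the ellipse to the mean and flags it degenerate.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 3:
        raise ValueError("need >= 3 compositions of 3 parts")
    arr = arr / arr.sum(axis=1, keepdims=True)
    arr = _replace_zeros(arr, delta)
    z = _ilr(arr)
    n = z.shape[0]
    mean = z.mean(axis=0)
    cov = np.cov(z, rowvar=False)
    center = ternary_coordinates(_ilr_inverse(mean[None, :])[0])
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) <= 1e-15:
        logger.warning("singular covariance; ellipse collapsed to the mean")
        poly = np.repeat([center.xy], n_arc, axis=0)
        return TernaryEllipse(center=center, polyline=poly, level=level,
                              degenerate=True)
    radius2 = stats.chi2.ppf(level, df=2) / n
    theta = np.linspace(0.0, 2.0 * np.pi, n_arc)
    circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    contour = mean + (circle * np.sqrt(evals * radius2)) @ evecs.T
    comps = _ilr_inverse(contour)
    poly = np.array([ternary_coordinates(c).xy for c in comps])
    return TernaryEllipse(center=center, polyline=poly, level=level,
                          degenerate=False)


def mean_in_ellipse(points: Sequence[Sequence[float]], target: Sequence[float],
                    level: float = 0.95, delta: Optional[float] = None) -> bool:
    """Whether ``target`` (a 3-part composition) lies inside the group-mean
    confidence region of ``points`` — the coverage check for the ellipse."""
    arr = np.asarray(points, dtype=float)
    arr = arr / arr.sum(axis=1, keepdims=True)
    arr = _replace_zeros(arr, delta)
    z = _ilr(arr)
    n = z.shape[0]
    mean = z.mean(axis=0)
    cov = np.cov(z, rowvar=False)
    t = np.asarray(target, dtype=float)
    t = t / t.sum()
    zt = _ilr(np.maximum(t, 1e-12)[None, :])[0]
    d = zt - mean
    md2 = float(d @ np.linalg.solve(cov / n, d))
    return md2 <= stats.chi2.ppf(level, df=2)
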