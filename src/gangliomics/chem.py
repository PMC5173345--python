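"""Elemental composition arithmetic and monoisotopic masses.

Compositions are plain ``{element: count}`` dicts restricted to the elements
occurring in gangliosides (C, H, N, O) plus Na for sodiated adducts.  Masses
are monoisotopic (lightest stable isotope), which is what high-resolution
mass spectrometry measures for the monoisotopic peak.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Mapping

Composition = Dict[str, int]

#: CODATA/IUPAC monoisotopic atomic masses, Da.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.9897692820,
}

#: Mass of the proton (not the H atom), Da — used for charge arithmetic.
PROTON_MASS = 1.00727646688

#: Electron mass, Da — for adduct cations formed by cation attachment.
ELECTRON_MASS = 0.00054857991

# Glycan residue compositions, i.e. the monosaccharide minus the water lost
# on glycosidic bond formation.
HEXOSE_RESIDUE: Composition = {"C": 6, "H": 10, "O": 5}
HEXNAC_RESIDUE: Composition = {"C": 8, "H": 13, "N": 1, "O": 5}
NEUAC_RESIDUE: Composition = {"C": 11, "H": 17, "N": 1, "O": 8}
OACETYL_RESIDUE: Composition = {"C": 2, "H": 2, "O": 1}
WATER: Composition = {"H": 2, "O": 1}


class CompositionError(ValueError):
    """An elemental composition is chemically impossible."""


def combine(*parts: Mapping[str, int], subtract: Mapping[str, int] | None = None) -> Composition:
    """Sum compositions (optionally subtracting one), dropping zero counts.

    Raises :class:`CompositionError` if any element count goes negative.
    """
    total: Counter = Counter()
    for part in parts:
        total.update(part)
    if subtract is not None:
        total.subtract(subtract)
    result = {el: n for el, n in total.items() if n != 0}
    negatives = [el for el, n in result.items() if n < 0]
    if negatives:
        raise CompositionError(f"negative element count for {negatives}")
    return result


def scaled(part: Mapping[str, int], k: int) -> Composition:
    return {el: n * k for el, n in part.items() if n * k != 0}


def monoisotopic_mass(composition: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of an elemental composition.

    Only C, H, N, O, Na are recognised; an unknown element raises ``KeyError``
    wrapped in a :class:`CompositionError` naming it.
    """
    mass = 0.0
    for el, n in composition.items():
        try:
            mass += n * MONOISOTOPIC_MASS[el]
        except KeyError:
            raise CompositionError(f"unknown element {el!r}") from None
    return mass


def formula_string(composition: Mapping[str, int]) -> str:
    """Hill-order formula string, e.g. ``C36H71NO3``."""
    order = ["C", "H"] + sorted(el for el in composition if el not in ("C", "H"))
    out = []
    for el in order:
        n = composition.get(el, 0)
        if n == 0:
            continue
        out.append(el if n == 1 else f"{el}{n}")
    return "".join(out)
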