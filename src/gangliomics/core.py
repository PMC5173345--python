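"""Structural model of gangliosides: ceramides, Svennerholm classes,
biosynthesis graph and ion m/z computation.

A ganglioside is a ceramide (long-chain base amide-linked to a fatty acyl)
carrying an oligosaccharide head group.  Classes are named after Svennerholm
(G + M/D/T/Q for 1-4 sialic acids + migration digit + a/b/c series letter);
molecular species within a class are labelled by the ceramide's total
carbons:double bonds (e.g. 36:1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import networkx as nx

from . import chem
from .chem import Composition

__all__ = [
    "LongChainBase",
    "FattyAcyl",
    "CeramideSpecies",
    "CeramideStructure",
    "GangliosideClass",
    "GangliosideSpecies",
    "IonSpecies",
    "NomenclatureError",
    "StructureError",
    "IonizationError",
    "parse_class_name",
    "format_class_name",
    "class_registry",
    "registry_to_yaml",
    "registry_from_yaml",
    "biosynthesis_graph",
    "series_of",
    "elemental_composition",
    "ceramide_composition",
    "ion_mz",
    "sialic_fragment_mz",
    "DEFAULT_LCB_SET",
    "DEFAULT_CERAMIDE_PANEL",
    "SRM_CLASS_PANEL",
]


class NomenclatureError(ValueError):
    """A ganglioside class name cannot be interpreted."""


class StructureError(ValueError):
    """A lipid structure violates its own invariants."""


class IonizationError(ValueError):
    """An ion cannot be formed (e.g. charge exceeds acidic sites)."""


# ---------------------------------------------------------------------------
# Ceramide building blocks
# ---------------------------------------------------------------------------

_LCB_RE = re.compile(r"^d(\d+):(\d+)$")
_FA_RE = re.compile(r"^(h?)(\d+):(\d+)$")
_CER_RE = re.compile(r"^(\d+):(\d+)$")


@dataclass(frozen=True, order=True)
class LongChainBase:
    """Dihydroxy sphingoid base, label ``d{C}:{D}`` (d18:1 = sphingosine)."""

    carbons: int
    double_bonds: int
    hydroxyls: int = 2

    def __post_init__(self) -> None:
        if self.double_bonds not in (0, 1, 2):
            raise StructureError(f"LCB double bonds must be 0-2, got {self.double_bonds}")
        if self.hydroxyls != 2:
            raise StructureError("only dihydroxy ('d') bases are modelled")

    @property
    def label(self) -> str:
        return f"d{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, label: str) -> "LongChainBase":
        m = _LCB_RE.match(label)
        if not m:
            raise StructureError(f"cannot parse LCB label {label!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def composition(self) -> Composition:
        # d-base C_c H_{2c+3-2d} N O2 (sphingosine d18:1 = C18H37NO2)
        h = 2 * self.carbons + 3 - 2 * self.double_bonds
        if h <= 0:
            raise chem.CompositionError("impossible LCB double-bond count")
        return {"C": self.carbons, "H": h, "N": 1, "O": 2}


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """Fatty acid, label ``{C}:{D}`` with ``h`` prefix when 2-hydroxylated."""

    carbons: int
    double_bonds: int
    hydroxylated: bool = False

    def __post_init__(self) -> None:
        if not 14 <= self.carbons <= 26:
            raise StructureError(f"FA carbons must be 14-26, got {self.carbons}")
        if self.double_bonds not in (0, 1, 2):
            raise StructureError(f"FA double bonds must be 0-2, got {self.double_bonds}")

    @property
    def label(self) -> str:
        return ("h" if self.hydroxylated else "") + f"{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, label: str) -> "FattyAcyl":
        m = _FA_RE.match(label)
        if not m:
            raise StructureError(f"cannot parse FA label {label!r}")
        return cls(int(m.group(2)), int(m.group(3)), hydroxylated=bool(m.group(1)))

    def composition(self) -> Composition:
        # free acid C_c H_{2c-2d} O2 (stearic 18:0 = C18H36O2); hFA adds one O
        h = 2 * self.carbons - 2 * self.double_bonds
        comp = {"C": self.carbons, "H": h, "O": 3 if self.hydroxylated else 2}
        return comp


@dataclass(frozen=True, order=True)
class CeramideSpecies:
    """Ceramide summed over its parts: total carbons : total double bonds."""

    total_carbons: int
    total_double_bonds: int

    def __post_init__(self) -> None:
        if not 32 <= self.total_carbons <= 44:
            raise StructureError(
                f"ceramide carbons must be 32-44, got {self.total_carbons}")
        if self.total_double_bonds not in (1, 2, 3):
            raise StructureError(
                f"ceramide double bonds must be 1-3, got {self.total_double_bonds}")

    @property
    def label(self) -> str:
        return f"{self.total_carbons}:{self.total_double_bonds}"

    @classmethod
    def parse(cls, label: str) -> "CeramideSpecies":
        m = _CER_RE.match(label.strip())
        if not m:
            raise StructureError(f"cannot parse ceramide label {label!r}")
        return cls(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class CeramideStructure:
    """A resolved LCB/FA combination for a ceramide species."""

    lcb: LongChainBase
    fa: FattyAcyl

    @property
    def species(self) -> CeramideSpecies:
        return CeramideSpecies(
            self.lcb.carbons + self.fa.carbons,
            self.lcb.double_bonds + self.fa.double_bonds,
        )

    @property
    def label(self) -> str:
        return f"{self.lcb.label}/{self.fa.label}"

    def composition(self) -> Composition:
        return chem.combine(
            self.lcb.composition(), self.fa.composition(), subtract=chem.WATER)


def ceramide_composition(species: CeramideSpecies, hydroxylated: bool = False) -> Composition:
    """Elemental composition of a ceramide from its C:D totals alone.

    Any LCB/FA split with the same totals gives the same formula:
    C_T H_{2T+1-2D} N O3 (one extra O for a hydroxylated FA).
    """
    t, d = species.total_carbons, species.total_double_bonds
    return {"C": t, "H": 2 * t + 1 - 2 * d, "N": 1, "O": 4 if hydroxylated else 3}


# ---------------------------------------------------------------------------
# Svennerholm nomenclature
# ---------------------------------------------------------------------------

_SERIES_LABEL = {0: "0", 1: "a", 2: "b", 3: "c"}
_LETTER_NEUAC = {"M": 1, "D": 2, "T": 3, "Q": 4}
_NEUAC_LETTER = {v: k for k, v in _LETTER_NEUAC.items()}
_CLASS_RE = re.compile(r"^(Ac)?G([MDTQ])([1-4])([abc])?$")


@dataclass(frozen=True)
class GangliosideClass:
    """A glycan head group identified by its Svennerholm name."""

    name: str
    hex: int
    hexnac: int
    neuac: int
    oacetyl: int = 0
    series: str = "a"

    def glycan_composition(self) -> Composition:
        return chem.combine(
            chem.scaled(chem.HEXOSE_RESIDUE, self.hex),
            chem.scaled(chem.HEXNAC_RESIDUE, self.hexnac),
            chem.scaled(chem.NEUAC_RESIDUE, self.neuac),
            chem.scaled(chem.OACETYL_RESIDUE, self.oacetyl),
        )

    @property
    def residue_count(self) -> int:
        return self.hex + self.hexnac + self.neuac + self.oacetyl


def _special_classes() -> Dict[str, GangliosideClass]:
    return {
        "GalCer": GangliosideClass("GalCer", hex=1, hexnac=0, neuac=0, series="gala"),
        "LacCer": GangliosideClass("LacCer", hex=2, hexnac=0, neuac=0, series="0"),
        "GA2": GangliosideClass("GA2", hex=2, hexnac=1, neuac=0, series="0"),
        "GA1": GangliosideClass("GA1", hex=3, hexnac=1, neuac=0, series="0"),
    }


def parse_class_name(name: str) -> GangliosideClass:
    """Parse a Svennerholm class name into its glycan composition and series.

    Supports the ganglio-series grid (0/a/b/c columns through the
    quadrisialylated row), the gala-series GM4, LacCer and the asialo GA1/GA2
    precursors, with an optional case-sensitive ``Ac`` prefix for one O-acetyl
    group.
    """
    if not isinstance(name, str):
        raise NomenclatureError(f"class name must be a string, got {name!r}")
    specials = _special_classes()
    if name in specials:
        return specials[name]
    m = _CLASS_RE.match(name)
    if not m:
        raise NomenclatureError(f"unrecognised ganglioside class name {name!r}")
    ac, letter, digit_s, suffix = m.groups()
    neuac = _LETTER_NEUAC[letter]
    digit = int(digit_s)
    oacetyl = 1 if ac else 0

    if digit == 4:
        # gala-series: NeuAc-Gal-Cer, only GM4 exists
        if letter != "M" or suffix:
            raise NomenclatureError(f"{name!r}: only GM4 exists in the gala-series")
        return GangliosideClass(name, hex=1, hexnac=0, neuac=1,
                                oacetyl=oacetyl, series="gala")
    if digit == 3:
        if suffix:
            raise NomenclatureError(f"{name!r}: '3' names take no series suffix")
        if neuac > 3:
            raise NomenclatureError(f"{name!r}: at most 3 sialic acids on the inner Gal")
        hex_, hexnac, inner = 2, 0, neuac
    elif digit == 2:
        if suffix:
            raise NomenclatureError(f"{name!r}: '2' names take no series suffix")
        if neuac > 3:
            raise NomenclatureError(f"{name!r}: at most 3 sialic acids on the inner Gal")
        hex_, hexnac, inner = 2, 1, neuac
    else:  # digit == 1: full Gal-GalNAc-Gal-Glc backbone
        hex_, hexnac = 3, 1
        if suffix is None:
            if letter == "M":
                inner = 1  # the paper's "GM1" is GM1a
            else:
                raise NomenclatureError(
                    f"{name!r}: ambiguous — specify the series letter (a/b/c)")
        else:
            inner = {"a": 1, "b": 2, "c": 3}[suffix]
            if inner > neuac:
                # GM1b / GD1c: all sialic acids sit on the terminal Gal
                inner = 0
        terminal = neuac - inner
        if not 0 <= terminal <= 2:
            raise NomenclatureError(
                f"{name!r}: {terminal} sialic acids on the terminal Gal is not modelled")
        return GangliosideClass(name, hex=hex_, hexnac=hexnac, neuac=neuac,
                                oacetyl=oacetyl, series=_SERIES_LABEL[inner])
    return GangliosideClass(name, hex=hex_, hexnac=hexnac, neuac=neuac,
                            oacetyl=oacetyl, series=_SERIES_LABEL[inner])


def format_class_name(gclass: GangliosideClass) -> str:
    """Canonical Svennerholm name; inverse of :func:`parse_class_name`."""
    return gclass.name


#: The 14 classes quantified in the SRM comparison (Table-1 panel).
SRM_CLASS_PANEL: Tuple[str, ...] = (
    "GM3", "GM2", "GD3", "AcGD3", "GD2", "GD1a", "GD1b", "AcGD1b",
    "GT3", "AcGT3", "GT1b", "AcGT1b", "GQ1b", "AcGQ1b",
)

_REGISTRY_NAMES: Tuple[str, ...] = (
    # 0-series column rooted at LacCer
    "LacCer", "GA2", "GA1", "GM1b", "GD1c",
    # a-series rooted at GM3
    "GM3", "GM2", "GM1a", "GD1a", "GT1a",
    # b-series rooted at GD3
    "GD3", "GD2", "GD1b", "GT1b", "GQ1b",
    # c-series rooted at GT3 (through the quadrisialylated row)
    "GT3", "GT2", "GT1c", "GQ1c",
    # gala-series
    "GalCer", "GM4",
    # O-acetylated variants observed in tissue
    "AcGD3", "AcGD1b", "AcGT3", "AcGT1b", "AcGQ1b",
)


def class_registry() -> Dict[str, GangliosideClass]:
    """Built-in class registry (name -> parsed class)."""
    reg = {}
    for name in _REGISTRY_NAMES:
        reg[name] = parse_class_name(name)
    # the paper's shorthand for GM1a
    reg["GM1"] = parse_class_name("GM1")
    return reg


def registry_to_yaml(path) -> None:
    """Write the class registry as a versioned YAML config."""
    import yaml

    reg = class_registry()
    doc = {
        "version": 1,
        "classes": {
            name: {"hex": c.hex, "hexnac": c.hexnac, "neuac": c.neuac,
                   "oacetyl": c.oacetyl, "series": c.series}
            for name, c in sorted(reg.items())
        },
        "lcb_set": [b.label for b in DEFAULT_LCB_SET],
        "fa_carbons": [14, 26],
        "fa_double_bonds": [0, 2],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def registry_from_yaml(path) -> Dict[str, GangliosideClass]:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {
        name: GangliosideClass(name=name, **fields)
        for name, fields in doc["classes"].items()
    }


# ---------------------------------------------------------------------------
# Biosynthesis graph
# ---------------------------------------------------------------------------

def biosynthesis_graph(include_acetylated: bool = False) -> "nx.DiGraph":
    """Directed biosynthesis graph over ganglioside classes.

    Nodes are class names; edges carry an ``enzyme`` attribute.  The 0/a/b/c
    series form four columns rooted at LacCer, GM3, GD3 and GT3; rows are the
    successive glycosyltransferase steps.  GM4 hangs off the GalCer precursor
    (gala-series).  With ``include_acetylated`` the observed O-acetylated
    variants are attached to their parents.
    """
    g = nx.DiGraph()
    columns = {
        "0": ["LacCer", "GA2", "GA1", "GM1b", "GD1c"],
        "a": ["GM3", "GM2", "GM1a", "GD1a", "GT1a"],
        "b": ["GD3", "GD2", "GD1b", "GT1b", "GQ1b"],
        "c": ["GT3", "GT2", "GT1c", "GQ1c"],
    }
    row_enzymes = [
        "GM2/GD2 synthase",       # GalNAc transferase
        "GM1/GD1b synthase",      # galactosyltransferase II
        "GD1a/GT1b synthase",     # sialyltransferase IV
        "GT1a/GQ1b synthase",     # sialyltransferase V
    ]
    for names in columns.values():
        for node in names:
            g.add_node(node, gclass=parse_class_name(node))
        for parent, child, enzyme in zip(names, names[1:], row_enzymes):
            g.add_edge(parent, child, enzyme=enzyme)
    # root sialylations across columns
    g.add_edge("LacCer", "GM3", enzyme="GM3 synthase")
    g.add_edge("GM3", "GD3", enzyme="GD3 synthase")
    g.add_edge("GD3", "GT3", enzyme="GT3 synthase")
    # gala-series
    g.add_node("GalCer", gclass=parse_class_name("GalCer"))
    g.add_node("GM4", gclass=parse_class_name("GM4"))
    g.add_edge("GalCer", "GM4", enzyme="GM4 synthase")
    if include_acetylated:
        for name in ("AcGD3", "AcGD1b", "AcGT3", "AcGT1b", "AcGQ1b"):
            parent = name[2:]
            g.add_node(name, gclass=parse_class_name(name))
            g.add_edge(parent, name, enzyme="sialate O-acetyltransferase")
    return g


def series_of(name: str) -> str:
    """Series membership (0/a/b/c/gala) of a class name."""
    return parse_class_name(name).series


# ---------------------------------------------------------------------------
# Species, composition, mass and m/z
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GangliosideSpecies:
    """A (class, ceramide) molecular species, optionally with a resolved
    LCB/FA structure."""

    gclass: GangliosideClass
    ceramide: CeramideSpecies
    structure: Optional[CeramideStructure] = None
    hydroxylated_fa: bool = False

    def __post_init__(self) -> None:
        if self.structure is not None and self.structure.species != self.ceramide:
            raise StructureError(
                f"structure {self.structure.label} does not match species "
                f"{self.ceramide.label}")

    @property
    def label(self) -> str:
        return f"{self.gclass.name} {self.ceramide.label}"


def elemental_composition(species: GangliosideSpecies) -> Composition:
    """Elemental composition: ceramide + glycan residues.

    The glycan contributes hex*C6H10O5 + hexnac*C8H13NO5 + neuac*C11H17NO8 +
    oacetyl*C2H2O; a hydroxylated fatty acyl adds one oxygen.
    """
    hfa = species.hydroxylated_fa or (
        species.structure is not None and species.structure.fa.hydroxylated)
    return chem.combine(
        ceramide_composition(species.ceramide, hydroxylated=hfa),
        species.gclass.glycan_composition(),
    )


def neutral_mass(species: GangliosideSpecies) -> float:
    return chem.monoisotopic_mass(elemental_composition(species))


@dataclass(frozen=True)
class IonSpecies:
    """An ionized ganglioside species with its m/z."""

    parent: GangliosideSpecies
    polarity: str           # "negative" | "positive"
    charge: int             # x >= 1
    adduct: str             # "deprotonation" | "protonation" | "sodiation"
    mz: float


def max_negative_charge(gclass: GangliosideClass) -> int:
    """Deprotonation sites: one acidic carboxyl per sialic residue."""
    return gclass.neuac


def ion_mz(species: GangliosideSpecies, polarity: str, charge: int,
           adduct: str = None) -> IonSpecies:
    """Compute the m/z of ``[M-xH]x-``, ``[M+xH]x+`` or ``[M+xNa]x+``.

    Negative-mode charge is capped at the sialic-acid count (each NeuAc
    carboxyl is one acidic site).
    """
    if charge < 1:
        raise IonizationError("charge must be >= 1")
    m = neutral_mass(species)
    if polarity == "negative":
        adduct = adduct or "deprotonation"
        if adduct != "deprotonation":
            raise IonizationError(f"negative-mode adduct {adduct!r} not modelled")
        cap = max_negative_charge(species.gclass)
        if charge > cap:
            raise IonizationError(
                f"{species.gclass.name} has {cap} acidic sites; cannot form "
                f"[M-{charge}H]{charge}-")
        mz = (m - charge * chem.PROTON_MASS) / charge
    elif polarity == "positive":
        adduct = adduct or "protonation"
        if adduct == "protonation":
            mz = (m + charge * chem.PROTON_MASS) / charge
        elif adduct == "sodiation":
            na_cation = chem.MONOISOTOPIC_MASS["Na"] - chem.ELECTRON_MASS
            mz = (m + charge * na_cation) / charge
        else:
            raise IonizationError(f"unknown adduct {adduct!r}")
    else:
        raise IonizationError(f"unknown polarity {polarity!r}")
    return IonSpecies(parent=species, polarity=polarity, charge=charge,
                      adduct=adduct, mz=mz)


def sialic_fragment_mz() -> float:
    """m/z of the diagnostic sialic-acid fragment anion (nominal 290).

    The B-type fragment is dehydrated NeuAc (C11H17NO8) deprotonated:
    ~290.088 Da/e.  This is the reporter ion for ganglioside precursor-ion
    scanning in negative mode.
    """
    return chem.monoisotopic_mass(chem.NEUAC_RESIDUE) - chem.PROTON_MASS


#: LCBs observed in the study (d18:0/d20:0 were specifically not detected).
DEFAULT_LCB_SET: Tuple[LongChainBase, ...] = tuple(
    LongChainBase.parse(s) for s in
    ("d16:1", "d17:0", "d17:1", "d18:1", "d18:2", "d20:1")
)

#: 19-species ceramide panel covering the observed 32-44 C / 1-3 DB envelope.
DEFAULT_CERAMIDE_PANEL: Tuple[CeramideSpecies, ...] = tuple(
    CeramideSpecies.parse(s) for s in
    ("32:1", "33:1", "34:2", "34:1", "35:1", "36:2", "36:1", "37:1",
     "38:2", "38:1", "39:1", "40:2", "40:1", "41:1", "42:3", "42:2",
     "42:1", "43:1", "44:2")
)
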