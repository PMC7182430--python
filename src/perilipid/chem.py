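"""Molecular formulas, monoisotopic masses, and the theoretical lipid library.

Lipid species are described at the class + ``X:Y`` level (total acyl carbons
``X`` : total double bonds ``Y``, summed over both chains), which is the
resolution a single-stage accurate-mass experiment can support.  Each class
has a deterministic construction rule that maps ``(class, X, Y)`` to a
molecular formula; the phosphoglycerolipid rules are all expressed as a head
group added to the phosphatidic-acid (PA) backbone.

The monoisotopic masses of the supported elements are pinned to the NIST/CODATA
values below so that every theoretical m/z in the library is a pure function
of the configuration, independent of any runtime lookup.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ELEMENT_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_C12_DELTA",
    "CH2_MASS",
    "H2_MASS",
    "FORMIC_ACID_MASS",
    "SODIUM_FORMATE_MASS",
    "LipidClass",
    "Adduct",
    "ADDUCTS",
    "LipidSpecies",
    "LibraryConfig",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "species_formula",
    "ionize",
    "ppm_error",
    "default_adduct",
    "build_library",
    "write_library",
    "read_library",
]

# Monoisotopic (most abundant isotope) masses in Da, NIST atomic weights.
ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "Cl": 34.96885268,
}

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857991
#: mass difference between 13C and 12C; the spacing of the M+1 isotope peak
C13_C12_DELTA = 1.0033548378
CH2_MASS = ELEMENT_MASS["C"] + 2 * ELEMENT_MASS["H"]  # 14.015650
H2_MASS = 2 * ELEMENT_MASS["H"]  # 2.015650
#: neutral HCOOH; the spacing between [M-H]- and [M+HCOO]- of one molecule
FORMIC_ACID_MASS = ELEMENT_MASS["C"] + 2 * ELEMENT_MASS["H"] + 2 * ELEMENT_MASS["O"]
#: NaHCOO cluster unit, the spacing of salt-cluster ladders in ESI
SODIUM_FORMATE_MASS = (
    ELEMENT_MASS["Na"] + ELEMENT_MASS["H"] + ELEMENT_MASS["C"] + 2 * ELEMENT_MASS["O"]
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string into an element → count map.

    Only the elements in :data:`ELEMENT_MASS` are accepted.

    >>> parse_formula("C28H44O")
    {'C': 28, 'H': 44, 'O': 1}
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        pos = match.end()
        symbol, digits = match.groups()
        if symbol not in ELEMENT_MASS:
            raise ValueError(f"unsupported element {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return counts


def formula_to_string(counts: Mapping[str, int]) -> str:
    """Render an element-count map in Hill order (C, H, then alphabetical)."""
    symbols = sorted(counts, key=lambda s: (s != "C", s != "H", s))
    parts = []
    for sym in symbols:
        n = counts[sym]
        if n < 0:
            raise ValueError(f"negative count for {sym}")
        if n == 0:
            continue
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of an element-count map (empty map → 0)."""
    total = 0.0
    for sym, n in counts.items():
        if sym not in ELEMENT_MASS:
            raise ValueError(f"unsupported element {sym!r}")
        if n < 0:
            raise ValueError(f"negative count for {sym}")
        total += ELEMENT_MASS[sym] * n
    return total


class LipidClass(str, Enum):
    """Lipid classes of the yeast plasma membrane covered by the library."""

    PC = "PC"
    PE = "PE"
    PS = "PS"
    PI = "PI"
    PG = "PG"
    PA = "PA"
    CL = "CL"
    DAG = "DAG"
    IPC = "IPC"
    MIPC = "MIPC"
    ERG = "ERG"


#: glycerophospholipid classes built from the diacyl-PA backbone
GLYCEROPHOSPHOLIPIDS = (
    LipidClass.PC,
    LipidClass.PE,
    LipidClass.PS,
    LipidClass.PI,
    LipidClass.PG,
    LipidClass.PA,
    LipidClass.CL,
    LipidClass.DAG,
)
SPHINGOLIPIDS = (LipidClass.IPC, LipidClass.MIPC)

# Head-group increments relative to the PA(c, d) backbone C(c+3)H(2c-2d+5)O8P.
_HEADGROUP_DELTA: dict[LipidClass, dict[str, int]] = {
    LipidClass.PA: {},
    LipidClass.PC: {"C": 5, "H": 11, "N": 1},
    LipidClass.PE: {"C": 2, "H": 5, "N": 1},
    LipidClass.PS: {"C": 3, "H": 5, "N": 1, "O": 2},
    LipidClass.PG: {"C": 3, "H": 6, "O": 2},
    LipidClass.PI: {"C": 6, "H": 10, "O": 5},
}

ERGOSTEROL_FORMULA = {"C": 28, "H": 44, "O": 1}


def species_formula(
    cls: LipidClass, carbons: int = 0, double_bonds: int = 0, hydroxyls: int = 4
) -> dict[str, int]:
    """Molecular formula for a lipid species from its class construction rule.

    Glycerophospholipids are diacyl species built from the PA backbone
    ``C(c+3)H(2c-2d+5)O8P`` plus a head-group increment.  DAG is the
    dephosphorylated backbone ``C(c+3)H(2c-2d+4)O5`` and cardiolipin the
    tetra-acyl ``C(c+9)H(2c-2d+14)O17P2``.  IPC is modeled on a
    tetra-hydroxylated ceramide backbone ``C(c+6)H(2c+12)NO13P`` (``hydroxyls``
    counts backbone OH groups; only the default 4 is supported), MIPC adds one
    hexose, and ergosterol is the fixed ``C28H44O``.

    Parameters
    ----------
    cls:
        Lipid class.
    carbons, double_bonds:
        Total acyl carbons ``X`` and double bonds ``Y`` (ignored for ERG).
    hydroxyls:
        Sphingolipid backbone hydroxylation state; only 4 is supported.
    """
    cls = LipidClass(cls)
    if cls is LipidClass.ERG:
        return dict(ERGOSTEROL_FORMULA)
    if carbons < 0 or double_bonds < 0:
        raise ValueError("carbons and double_bonds must be non-negative")
    c, d = carbons, double_bonds
    if cls in _HEADGROUP_DELTA:
        counts = {"C": c + 3, "H": 2 * c - 2 * d + 5, "O": 8, "P": 1}
        for sym, n in _HEADGROUP_DELTA[cls].items():
            counts[sym] = counts.get(sym, 0) + n
    elif cls is LipidClass.DAG:
        counts = {"C": c + 3, "H": 2 * c - 2 * d + 4, "O": 5}
    elif cls is LipidClass.CL:
        counts = {"C": c + 9, "H": 2 * c - 2 * d + 14, "O": 17, "P": 2}
    elif cls in SPHINGOLIPIDS:
        if hydroxyls != 4:
            raise ValueError("only the tetra-hydroxylated backbone is supported")
        if d != 0:
            raise ValueError("unsaturated sphingolipid backbones not supported")
        counts = {"C": c + 6, "H": 2 * c + 12, "N": 1, "O": 13, "P": 1}
        if cls is LipidClass.MIPC:
            counts["C"] += 6
            counts["H"] += 10
            counts["O"] += 5
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unsupported class {cls}")
    if counts["H"] < 0:
        raise ValueError(f"negative hydrogen count for {cls} {c}:{d}")
    return counts


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at class + ``X:Y`` resolution."""

    lipid_class: LipidClass
    carbons: int = 0
    double_bonds: int = 0
    hydroxyls: int = 4

    @property
    def formula(self) -> dict[str, int]:
        return species_formula(
            self.lipid_class, self.carbons, self.double_bonds, self.hydroxyls
        )

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def name(self) -> str:
        if self.lipid_class is LipidClass.ERG:
            return "ERG"
        return f"{self.lipid_class.value} {self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: m/z = multiplicity × M + mass_shift."""

    name: str
    mass_shift: float
    charge_sign: int
    multiplicity: int = 1


ADDUCTS: dict[str, Adduct] = {
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, -1, 1),
    "[M+H]+": Adduct("[M+H]+", +PROTON_MASS, +1, 1),
    "[M+HCOO]-": Adduct(
        "[M+HCOO]-", FORMIC_ACID_MASS - PROTON_MASS, -1, 1
    ),  # +44.998203
    "[2M-H]-": Adduct("[2M-H]-", -PROTON_MASS, -1, 2),
}


def ionize(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of a singly charged ion from the neutral monoisotopic mass."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return adduct.multiplicity * neutral_mass + adduct.mass_shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error of ``observed`` relative to ``theoretical`` in ppm."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def default_adduct(cls: LipidClass) -> Adduct:
    """The adduct under which a class is detected in this chromatography.

    With an ammonium-formate mobile phase the zwitterionic/neutral classes PC
    and DAG are seen as formate adducts in negative mode, ergosterol only as
    the protonated ion in positive mode, and every other (anionic) class as
    the deprotonated ion.
    """
    cls = LipidClass(cls)
    if cls in (LipidClass.PC, LipidClass.DAG):
        return ADDUCTS["[M+HCOO]-"]
    if cls is LipidClass.ERG:
        return ADDUCTS["[M+H]+"]
    return ADDUCTS["[M-H]-"]


@dataclass(frozen=True)
class LibraryConfig:
    """Enumeration ranges for the theoretical library.

    Defaults cover the acyl-chain space observed for yeast plasma-membrane
    glycerophospholipids (26–44 carbons, 0–6 double bonds; cardiolipin spans
    twice that carbon range) and the saturated very-long-chain ceramide
    backbones of IPC/MIPC (40–46 carbons).
    """

    classes: tuple[LipidClass, ...] = tuple(LipidClass)
    carbon_range: tuple[int, int] = (26, 44)
    double_bond_range: tuple[int, int] = (0, 6)
    cl_carbon_range: tuple[int, int] = (52, 88)
    sphingo_carbon_range: tuple[int, int] = (40, 46)
    adducts_per_class: Mapping[LipidClass, tuple[str, ...]] | None = None

    def adducts_for(self, cls: LipidClass) -> tuple[str, ...]:
        if self.adducts_per_class and cls in self.adducts_per_class:
            return tuple(self.adducts_per_class[cls])
        # classes whose primary ion is the formate adduct are also listed as
        # [M-H]-, the canonical representative after adduct collapse
        if cls in (LipidClass.PC, LipidClass.DAG):
            return ("[M+HCOO]-", "[M-H]-")
        return (default_adduct(cls).name,)


def build_library(config: LibraryConfig | None = None) -> pd.DataFrame:
    """Enumerate the theoretical (species, adduct, m/z) library.

    Returns a DataFrame with columns ``class, carbons, double_bonds, formula,
    adduct, mz`` sorted deterministically by (class, carbons, double_bonds,
    adduct), a pure function of the configuration.
    """
    config = config or LibraryConfig()
    if not config.classes:
        raise ValueError("empty class set")
    rows = []
    for cls in config.classes:
        cls = LipidClass(cls)
        if cls is LipidClass.ERG:
            grid: Iterable[tuple[int, int]] = [(0, 0)]
        elif cls in SPHINGOLIPIDS:
            lo, hi = config.sphingo_carbon_range
            grid = [(c, 0) for c in range(lo, hi + 1)]
        elif cls is LipidClass.CL:
            lo, hi = config.cl_carbon_range
            dlo, dhi = config.double_bond_range
            grid = itertools.product(range(lo, hi + 1), range(dlo, dhi + 1))
        else:
            lo, hi = config.carbon_range
            dlo, dhi = config.double_bond_range
            grid = itertools.product(range(lo, hi + 1), range(dlo, dhi + 1))
        for c, d in grid:
            formula = species_formula(cls, c, d)
            mass = monoisotopic_mass(formula)
            for adduct_name in config.adducts_for(cls):
                rows.append(
                    {
                        "class": cls.value,
                        "carbons": c,
                        "double_bonds": d,
                        "formula": formula_to_string(formula),
                        "adduct": adduct_name,
                        "mz": ionize(mass, adduct_name),
                    }
                )
    lib = pd.DataFrame(rows)
    order = {cls.value: i for i, cls in enumerate(LipidClass)}
    lib = lib.sort_values(
        by=["class", "carbons", "double_bonds", "adduct"],
        key=lambda col: col.map(order) if col.name == "class" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return lib


def write_library(library: pd.DataFrame, path: str | Path) -> None:
    """Write the library as CSV with m/z at 6 decimal places."""
    out = library.copy()
    out["mz"] = out["mz"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def read_library(path: str | Path) -> pd.DataFrame:
    lib = pd.read_csv(path)
    expected = {"class", "carbons", "double_bonds", "formula", "adduct", "mz"}
    missing = expected - set(lib.columns)
    if missing:
        raise ValueError(f"library file missing columns: {sorted(missing)}")
    lib["mz"] = lib["mz"].astype(float)
    return lib
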