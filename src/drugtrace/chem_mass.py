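"""Molecular-formula arithmetic for mass offsets, adduct spacings and precursor m/z.

Monoisotopic masses of the most abundant isotope of each supported element
are hard-coded (NIST, 6 decimal places).  All ion m/z arithmetic uses the
proton mass 1.007276 Da; electron mass is accounted for inside the per-adduct
deltas so that adduct-to-adduct spacings come out exact.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "Formula",
    "FormulaError",
    "MassOffsetEntry",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "SUPPORTED_ADDUCTS",
    "monoisotopic_mass",
    "ion_mz",
    "adduct_offset",
    "load_mass_offsets",
]

#: Monoisotopic mass of the most abundant isotope, Da (NIST).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "F": 18.998403,
    "Na": 22.989770,
    "Mg": 23.985042,
    "Si": 27.976927,
    "P": 30.973762,
    "S": 31.972071,
    "Cl": 34.968853,
    "K": 38.963707,
    "Ca": 39.962591,
    "Fe": 55.934942,
    "Se": 79.916522,
    "Br": 78.918338,
    "I": 126.904468,
}

PROTON_MASS = 1.007276
ELECTRON_MASS = 0.000549

#: Spacing of the M+1 isotopologue peak (13C - 12C), Da.
ISOTOPE_SPACING = 1.003355

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unknown element symbols or empty/invalid formulas."""


@dataclass(frozen=True)
class Formula:
    """Elemental composition as element symbol -> count (non-negative ints)."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for element, count in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaError(f"count for {element} must be a non-negative int")
            if count:
                cleaned[element] = count
        if not cleaned:
            raise FormulaError("formula has no atoms")
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``C17H19N3O3S``."""
        text = text.strip()
        if not text:
            raise FormulaError("empty formula string")
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"unparsable formula: {text!r}")
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"unparsable formula: {text!r}")
        return cls(counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return Formula(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        ordered = sorted(
            self.counts,
            key=lambda e: (0, "") if e == "C" else (1, "") if e == "H" else (2, e),
        )
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] > 1 else e for e in ordered
        )


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts.items())


def _adduct_delta(added: Iterable[str], removed: Iterable[str], charge: int) -> float:
    delta = sum(MONOISOTOPIC_MASS[e] for e in added)
    delta -= sum(MONOISOTOPIC_MASS[e] for e in removed)
    return delta - charge * ELECTRON_MASS


#: adduct spec -> (mass delta relative to the neutral, charge)
SUPPORTED_ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+Na]+": (_adduct_delta(["Na"], [], 1), 1),
    "[M+K]+": (_adduct_delta(["K"], [], 1), 1),
    "[M+Ca-H]+": (_adduct_delta(["Ca"], ["H"], 1), 1),
    "[M+NH4]+": (_adduct_delta(["N", "H", "H", "H", "H"], [], 1), 1),
    "[M-H]-": (-PROTON_MASS, 1),
}


def ion_mz(formula: Formula | str, adduct_spec: str) -> float:
    """m/z of the named ion form of a neutral formula.

    Supported forms: ``[M+H]+``, ``[M+Na]+``, ``[M+K]+``, ``[M+Ca-H]+``,
    ``[M+NH4]+``, ``[M-H]-``.
    """
    if adduct_spec not in SUPPORTED_ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct_spec!r}; supported: "
            f"{sorted(SUPPORTED_ADDUCTS)}"
        )
    delta, charge = SUPPORTED_ADDUCTS[adduct_spec]
    return (monoisotopic_mass(formula) + delta) / charge


def adduct_offset(adduct_a: str, adduct_b: str) -> float:
    """Signed precursor-m/z spacing between two charge-1 ion forms of one neutral.

    E.g. ``adduct_offset("[M+Na]+", "[M+H]+")`` is +21.98 Da, the spacing a
    sodiated ion sits above the protonated ion of the same compound.
    """
    for spec in (adduct_a, adduct_b):
        if spec not in SUPPORTED_ADDUCTS:
            raise ValueError(f"unsupported adduct {spec!r}")
    (da, za), (db, zb) = SUPPORTED_ADDUCTS[adduct_a], SUPPORTED_ADDUCTS[adduct_b]
    if za != 1 or zb != 1:
        raise ValueError("adduct_offset is defined for charge-1 forms only")
    return da - db


@dataclass(frozen=True)
class MassOffsetEntry:
    """One curated precursor mass offset (metabolic transformation or ion-form
    spacing) against which analog mass offsets are matched."""

    delta_mass: float
    label: str
    category: str  # {metabolism, adduct, isotope}
    composition: Formula | None = None

    _CATEGORIES = frozenset({"metabolism", "adduct", "isotope"})

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("offset label must be non-empty")
        if self.category not in self._CATEGORIES:
            raise ValueError(f"category must be one of {sorted(self._CATEGORIES)}")
        if abs(self.delta_mass) > 200:
            raise ValueError(
                "offset magnitude exceeds the 200 Da analog search window"
            )


def load_mass_offsets(path: str | None = None) -> list[MassOffsetEntry]:
    """Load a mass-offset table (CSV: delta_mass,label,category,composition).

    With no ``path`` the packaged curated list is returned.  Compositions are
    optional; signed entries are distinct (a gain and a loss of the same group
    are two rows).
    """
    if path is None:
        source = resources.files("drugtrace.data").joinpath("mass_offsets.csv")
        text = source.read_text()
    else:
        with open(path) as handle:
            text = handle.read()
    entries = []
    for row in csv.DictReader(text.splitlines()):
        composition = row.get("composition") or None
        entries.append(
            MassOffsetEntry(
                delta_mass=float(row["delta_mass"]),
                label=row["label"],
                category=row["category"],
                composition=Formula.parse(composition) if composition else None,
            )
        )
    if not entries:
        raise ValueError("mass-offset table is empty")
    return entries
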