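"""Monoisotopic mass and adduct m/z arithmetic.

Supports the mass-spectrometric verification of the first two steps of
bile-acid 7alpha-dehydroxylation: CoA ligation of cholic acid by BaiB
(cholyl-CoA) and 3-dehydrogenation by BaiA (3-oxo-cholyl-CoA).  Isotope
masses come from the NIST table shipped with pyteomics; the proton-mass
convention is used for adducts (electron mass neglected).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from pyteomics.mass import nist_mass

PROTON_MASS = 1.007276466  # Da
_SODIUM_ION = nist_mass["Na"][0][0] - 0.000548580  # Na+ (electron removed)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral (or charged) molecule.

    Supports addition/subtraction for condensation and redox arithmetic.
    """

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        if not clean:
            raise ValueError("formula must contain at least one atom")
        for el, n in clean.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if el not in nist_mass:
                raise ValueError(f"unknown element {el!r}")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_string(cls, formula: str, charge: int = 0) -> "MolecularFormula":
        """Parse Hill-notation strings such as ``C24H40O5``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {pos}")
            if not m.group(0):
                break
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
            pos = m.end()
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts, charge)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts, self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) - n
        return MolecularFormula(counts, self.charge - other.charge)

    def to_string(self) -> str:
        """Hill notation: C first, H second, the rest alphabetical."""
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        return "".join(
            f"{el}{self.counts[el]}" if self.counts[el] > 1 else el for el in order
        )


WATER = MolecularFormula({"H": 2, "O": 1})
H2 = MolecularFormula({"H": 2})
CHOLIC_ACID = MolecularFormula.from_string("C24H40O5")
COENZYME_A = MolecularFormula.from_string("C21H36N7O16P3S")


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of most-abundant-isotope masses, in Da."""
    return sum(nist_mass[el][0][0] * n for el, n in f.counts.items())


def condense_thioester(acid: MolecularFormula, coa: MolecularFormula = COENZYME_A) -> MolecularFormula:
    """Condense a carboxylic acid with coenzyme A, releasing one water.

    Models the BaiB (bile acid-CoA ligase) reaction: cholic acid + CoA ->
    cholyl-CoA + H2O.
    """
    if acid.counts.get("O", 0) < 1 or acid.counts.get("H", 0) < 2:
        raise ValueError("acid lacks a carboxyl group (needs >=1 O and >=2 H)")
    if coa.counts.get("S", 0) < 1:
        raise ValueError("CoA moiety must contain a thiol sulfur")
    return acid + coa - WATER


def dehydrogenate(f: MolecularFormula) -> MolecularFormula:
    """Remove H2, e.g. BaiA oxidation of the 3-OH to a 3-oxo group."""
    return f - H2


ADDUCTS = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M+Na]+": _SODIUM_ION,
}


def adduct_mz(f: MolecularFormula, adduct: str) -> float:
    """m/z of a singly charged adduct ion of the neutral molecule ``f``."""
    key = adduct.replace("−", "-")  # accept the typographic minus
    if key not in ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}"
        )
    return monoisotopic_mass(f) + ADDUCTS[key]


def cholyl_coa() -> MolecularFormula:
    """C45H74N7O20P3S, the BaiB product."""
    return condense_thioester(CHOLIC_ACID, COENZYME_A)


def oxo_cholyl_coa() -> MolecularFormula:
    """C45H72N7O20P3S, the BaiA product (3-oxo-cholyl-CoA)."""
    return dehydrogenate(cholyl_coa())
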