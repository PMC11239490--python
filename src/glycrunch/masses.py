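"""Monoisotopic mass arithmetic for glycans and their ions.

Residue masses are dehydrated (as incorporated in a chain); an intact glycan is
the sum of its residue masses plus one water, plus two hydrogens if the
reducing end is an alditol. Ion m/z values follow the usual electrospray
conventions: deprotonation in negative mode, protonation in positive mode, with
acetate and sodium adducts on a documented whitelist.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .glycans import Composition, GlycanGraph, to_composition

__all__ = [
    "ELEMENTS",
    "RESIDUE_FORMULAS",
    "IonSpec",
    "formula_mass",
    "residue_mass",
    "glycan_mass",
    "ion_mz",
    "composition_match",
    "infer_composition",
    "WATER",
    "PROTON",
    "REDUCTION",
]

# CODATA/IUPAC monoisotopic element masses (Da)
ELEMENTS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "O": 15.994914620,
    "N": 14.003074005,
    "S": 31.972071174,
    "P": 30.973761998,
    "Na": 22.989769282,
}

PROTON = 1.007276467  # H+ (hydrogen atom minus electron)
ELECTRON = 0.000548580

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula such as ``"C6H10O5"``."""
    mass = 0.0
    consumed = 0
    for el, count in _FORMULA_RE.findall(formula):
        if not el:
            continue
        if el not in ELEMENTS:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        mass += ELEMENTS[el] * (int(count) if count else 1)
        consumed += len(el) + len(count)
    if consumed != len(formula):
        raise ValueError(f"could not parse formula {formula!r}")
    return mass


# Dehydrated residue formulas per composition class
RESIDUE_FORMULAS: dict[str, str] = {
    "Hex": "C6H10O5",
    "HexNAc": "C8H13NO5",
    "dHex": "C6H10O4",
    "Neu5Ac": "C11H17NO8",
    "Neu5Gc": "C11H17NO9",
    "Pen": "C5H8O4",
    "Kdn": "C9H14O8",
    "S": "SO3",  # sulfation: +SO3 on a hydroxyl
    "P": "HPO3",  # phosphorylation: +HPO3
}

RESIDUE_MASSES: dict[str, float] = {k: formula_mass(v) for k, v in RESIDUE_FORMULAS.items()}

WATER = formula_mass("H2O")
REDUCTION = formula_mass("H2")  # open-ring alditol at the reducing end
METHYL = formula_mass("CH2")  # net increment per permethylation site
ACETIC_ACID = formula_mass("C2H4O2")
SODIUM_MINUS_H = ELEMENTS["Na"] - ELEMENTS["H"]

# Free hydroxyl/amide sites gaining a methyl on permethylation, per chain
# residue with a single glycosidic bond (bookkeeping table; additional linkages
# each remove one site, which we do not track per-topology).
PERMETHYL_SITES: dict[str, int] = {
    "Hex": 3,
    "HexNAc": 3,  # 3 OH sites replaced by linkage/N-acetyl bookkeeping, N-CH3 included
    "dHex": 2,
    "Neu5Ac": 4,
    "Neu5Gc": 5,
    "Pen": 2,
    "Kdn": 5,
    "S": 0,
    "P": 0,
}


def residue_mass(label: str, derivatization: str = "none") -> float:
    """Dehydrated monoisotopic residue mass for a composition class.

    ``derivatization='permethylated'`` adds one methyl increment per free
    hydroxyl/amide site from :data:`PERMETHYL_SITES`.
    """
    if label not in RESIDUE_MASSES:
        raise ValueError(f"unknown residue class {label!r}")
    mass = RESIDUE_MASSES[label]
    if derivatization == "permethylated":
        mass += METHYL * PERMETHYL_SITES[label]
    elif derivatization != "none":
        raise ValueError(f"unknown derivatization {derivatization!r}")
    return mass


def glycan_mass(
    g: GlycanGraph | Composition,
    reduced: bool | None = None,
    derivatization: str = "none",
) -> float:
    """Neutral monoisotopic mass of an intact glycan.

    Composition-determined: two glycans with the same composition have the same
    mass regardless of topology. ``reduced=None`` takes the flag from the
    GlycanGraph (False for a bare Composition).
    """
    if isinstance(g, GlycanGraph):
        comp = to_composition(g)
        if reduced is None:
            reduced = g.reduced
    else:
        comp = g
        if reduced is None:
            reduced = False
    if not comp.counts:
        raise ValueError("empty composition has no mass")
    mass = sum(residue_mass(cls, derivatization) * n for cls, n in comp)
    mass += WATER
    if derivatization == "permethylated":
        mass += 2 * METHYL  # free reducing-end and terminal sites
    if reduced:
        mass += REDUCTION
    return mass


# ---------------------------------------------------------------------------
# ions
# ---------------------------------------------------------------------------

_ADDUCTS = (None, "none", "acetate", "sodium")


@dataclass(frozen=True)
class IonSpec:
    """Ionization state: mode, optional adduct and charge.

    Whitelist: negative mode supports plain deprotonation at any charge,
    acetate ([M+OAc]-) and sodium ([M-2H+Na]-) at charge 1; positive mode
    supports protonation at any charge and sodium ([M+Na]+) at charge 1.
    """

    mode: str = "negative"
    adduct: str | None = None
    charge: int = 1

    def __post_init__(self):
        if self.mode not in ("negative", "positive"):
            raise ValueError(f"unknown ion mode {self.mode!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        adduct = None if self.adduct in (None, "none") else self.adduct
        object.__setattr__(self, "adduct", adduct)
        if adduct not in (None, "acetate", "sodium"):
            raise ValueError(f"unknown adduct {self.adduct!r}")
        if adduct is not None and self.charge != 1:
            raise ValueError("adduct ions are whitelisted at charge 1 only")
        if adduct == "acetate" and self.mode != "negative":
            raise ValueError("acetate adduct is negative-mode only")

    @property
    def label(self) -> str:
        z = self.charge
        if self.mode == "negative":
            if self.adduct == "acetate":
                return "[M+OAc]−"
            if self.adduct == "sodium":
                return "[M−2H+Na]−"
            return "[M−H]−" if z == 1 else f"[M−{z}H]{z}−"
        if self.adduct == "sodium":
            return "[M+Na]+"
        return "[M+H]+" if z == 1 else f"[M+{z}H]{z}+"


def ion_mz(neutral: float, ion: IonSpec) -> float:
    """m/z of a neutral mass under an :class:`IonSpec`."""
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    z = ion.charge
    if ion.mode == "negative":
        if ion.adduct == "acetate":
            # neutral acetic acid attaches, then deprotonation
            return neutral + ACETIC_ACID - PROTON
        if ion.adduct == "sodium":
            return neutral + SODIUM_MINUS_H - PROTON
        return (neutral - z * PROTON) / z
    if ion.adduct == "sodium":
        return neutral + ELEMENTS["Na"] - ELECTRON
    return (neutral + z * PROTON) / z


def composition_match(
    observed_mz: float,
    candidates: Iterable[Composition],
    tolerance: float = 0.5,
    max_charge: int = 2,
    mode: str = "negative",
    reduced: bool = True,
    derivatization: str = "none",
    adducts: Sequence[str] = (),
) -> list[tuple[Composition, IonSpec, float]]:
    """All (composition, ion, mass error) pairs matching an observed m/z.

    Sorted by absolute mass error. Charges 1..max_charge are scanned; adduct
    forms are added for charge 1 when requested.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    ions = [IonSpec(mode, None, z) for z in range(1, max_charge + 1)]
    ions += [IonSpec(mode, a, 1) for a in adducts]
    out = []
    for comp in candidates:
        neutral = glycan_mass(comp, reduced=reduced, derivatization=derivatization)
        for ion in ions:
            err = ion_mz(neutral, ion) - observed_mz
            if abs(err) <= tolerance:
                out.append((comp, ion, err))
    # parsimony tie-break for isobaric compositions (e.g. Hex+Neu5Ac has the
    # same elemental formula as dHex+Neu5Gc): prefer fewer residue classes and
    # fewer rare residues at equal mass error
    rare = ("Neu5Gc", "Kdn", "Pen", "S", "P")

    def key(t):
        comp, ion, err = t
        return (
            round(abs(err), 9),
            len(comp.counts),
            sum(comp[r] for r in rare),
            str(comp),
            ion.charge,
        )

    out.sort(key=key)
    return out


_DEFAULT_BOUNDS: Mapping[str, int] = {
    "Hex": 9,
    "HexNAc": 7,
    "dHex": 4,
    "Neu5Ac": 4,
    "Neu5Gc": 2,
    "S": 2,
}


def infer_composition(
    observed_mz: float,
    tolerance: float = 0.5,
    max_charge: int = 2,
    mode: str = "negative",
    reduced: bool = True,
    bounds: Mapping[str, int] | None = None,
) -> tuple[Composition, IonSpec, float] | None:
    """Best composition explaining an observed precursor m/z, if any.

    Enumerates compositions within per-class count bounds and returns the match
    with the smallest absolute error, preferring lower charge on ties.
    """
    bounds = dict(_DEFAULT_BOUNDS if bounds is None else bounds)
    classes = list(bounds)
    candidates = []
    for counts in itertools.product(*(range(bounds[c] + 1) for c in classes)):
        d = {c: n for c, n in zip(classes, counts) if n}
        if not d or not any(k not in ("S", "P") for k in d):
            continue
        if d.get("S", 0) > sum(v for k, v in d.items() if k not in ("S", "P")):
            continue
        candidates.append(Composition.from_dict(d))
    matches = composition_match(
        observed_mz, candidates, tolerance, max_charge, mode, reduced=reduced
    )
    return matches[0] if matches else None


# ---------------------------------------------------------------------------
# cross-ring cleavage bookkeeping
# ---------------------------------------------------------------------------

# Ring cleavage at bonds {i,j} splits a residue into two arcs. For each residue
# class and bond pair we store (formula of the arc containing the anomeric
# carbon C1, attachment positions on that arc, formula of the other arc,
# attachment positions on the other arc). Formulas of the two arcs sum exactly
# to the residue formula (atom-partition convention, no hydrogen transfer).
# Positions are glycosylation sites a child linkage can occupy.
RING_ARCS: dict[str, dict[tuple[int, int], tuple[str, frozenset, str, frozenset]]] = {
    "Hex": {
        (0, 2): ("C2H4O2", frozenset({2}), "C4H6O3", frozenset({3, 4, 6})),
        (2, 4): ("C4H6O3", frozenset({2, 6}), "C2H4O2", frozenset({3, 4})),
        (0, 3): ("C3H6O3", frozenset({2, 3}), "C3H4O2", frozenset({4, 6})),
        (1, 5): ("CH2O", frozenset(), "C5H8O4", frozenset({2, 3, 4, 6})),
    },
    "HexNAc": {
        (0, 2): ("C4H7NO2", frozenset(), "C4H6O3", frozenset({3, 4, 6})),
        (2, 4): ("C6H9NO3", frozenset({6}), "C2H4O2", frozenset({3, 4})),
        (0, 3): ("C5H9NO3", frozenset({3}), "C3H4O2", frozenset({4, 6})),
        (1, 5): ("CH2O", frozenset(), "C7H11NO4", frozenset({3, 4, 6})),
    },
    "dHex": {
        (0, 2): ("C2H4O2", frozenset({2}), "C4H6O2", frozenset({3, 4})),
        (2, 4): ("C4H6O2", frozenset({2}), "C2H4O2", frozenset({3, 4})),
        (0, 3): ("C3H6O3", frozenset({2, 3}), "C3H4O", frozenset({4})),
        (1, 5): ("CH2O", frozenset(), "C5H8O3", frozenset({2, 3, 4})),
    },
    "Pen": {
        (0, 2): ("C2H4O2", frozenset({2}), "C3H4O2", frozenset({3, 4})),
    },
    "Neu5Ac": {
        (0, 2): ("C2H2O3", frozenset(), "C9H15NO5", frozenset({4, 8, 9})),
    },
    "Neu5Gc": {
        (0, 2): ("C2H2O3", frozenset(), "C9H15NO6", frozenset({4, 8, 9})),
    },
    "Kdn": {
        (0, 2): ("C2H2O3", frozenset(), "C7H12O5", frozenset({4, 8, 9})),
    },
}


def ring_arc_masses(residue_class: str, pair: tuple[int, int]) -> tuple[float, float]:
    """(mass of C1-side arc, mass of the other arc) for a ring cleavage."""
    try:
        f_c1, _, f_other, _ = RING_ARCS[residue_class][pair]
    except KeyError:
        raise ValueError(f"no ring cleavage {pair} for residue class {residue_class!r}") from None
    return formula_mass(f_c1), formula_mass(f_other)
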