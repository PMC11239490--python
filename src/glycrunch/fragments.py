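"""Exhaustive theoretical fragmentation and MS/MS peak annotation.

Collision-induced dissociation of a glycan breaks glycosidic bonds (B/C ions
retain the non-reducing side, Y/Z the reducing side) or cuts through two bonds
of a sugar ring (A/X cross-ring ions). Every fragment of a tree-shaped glycan
is an induced connected subgraph plus a record of how its boundary was cleaved,
so enumeration proceeds in two steps: list all induced connected subtrees, then
decorate each boundary with admissible cleavage types, global neutral losses
and charge states. Fragments are named in Domon-Costello nomenclature (B2,
Y1α, 0,2A3, ...) and in IUPAC-condensed form.

Mass bookkeeping (neutral fragments): a fragment's mass is the sum of its
retained residue (or ring-arc) masses plus one water, minus one water for each
B, Z or A cleavage, plus two hydrogens when an intact reduced (alditol)
reducing end is retained. Under this convention B_i and its complementary
Y_(n-i) sum exactly to the intact neutral mass, as do C/Z pairs.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .glycans import GREEK, GlycanGraph, RESIDUE_CLASSES, split_label
from .masses import (
    WATER,
    REDUCTION,
    IonSpec,
    RING_ARCS,
    formula_mass,
    ion_mz,
    residue_mass,
    ring_arc_masses,
)

__all__ = [
    "Cleavage",
    "FragmentIon",
    "PeakAnnotation",
    "enumerate_connected_subgraphs",
    "enumerate_fragments",
    "domon_costello_name",
    "parse_dc_name",
    "match_peaks",
    "prioritize",
    "annotate_spectrum",
    "node_mass",
    "fragment_neutral_mass",
    "DEFAULT_GLOBAL_MODS",
]

CO2 = formula_mass("CO2")

_KIND_DELTA = {"B": -WATER, "C": 0.0, "Y": 0.0, "Z": -WATER, "A": -WATER, "X": 0.0}
_KIND_ORDER = {"B": 0, "C": 1, "A": 2, "Y": 3, "Z": 4, "X": 5}

MOD_GROUP_MASS = {"S": formula_mass("SO3"), "P": formula_mass("HPO3")}

# name -> (mass delta, requires sialic acid). Applied one at a time.
DEFAULT_GLOBAL_MODS: dict[str, tuple[float, bool]] = {
    "-H2O": (-WATER, False),
    "-2H2O": (-2 * WATER, False),
    "-CO2": (-CO2, True),
}

_SIALIC = {"Neu5Ac", "Neu5Gc", "Kdn"}


def node_mass(label: str, derivatization: str = "none") -> float:
    """Dehydrated mass of a labeled node including site modifications."""
    base, mods = split_label(label)
    mass = residue_mass(RESIDUE_CLASSES[base], derivatization)
    for mod in mods:
        mass += MOD_GROUP_MASS[mod[-1]]
    return mass


@dataclass(frozen=True)
class Cleavage:
    """One cleavage event in Domon-Costello terms.

    ``kind`` is one of B/C/Y/Z (glycosidic) or A/X (cross-ring, with the pair
    of cleaved ring bonds); ``index`` counts residues from the non-reducing
    terminus for B/C/A and from the reducing end for Y/Z/X; ``branch`` is the
    Greek-letter branch designator ("" on an unbranched path).
    """

    kind: str
    index: int
    branch: str = ""
    ring_bonds: tuple[int, int] | None = None

    def __post_init__(self):
        if self.kind in ("A", "X"):
            if self.ring_bonds is None:
                raise ValueError("A/X cleavages need ring_bonds")
        elif self.ring_bonds is not None:
            raise ValueError("glycosidic cleavages carry no ring_bonds")
        if self.index < 1:
            raise ValueError("cleavage index must be >= 1")

    def render(self) -> str:
        prefix = f"{self.ring_bonds[0]},{self.ring_bonds[1]}" if self.ring_bonds else ""
        return f"{prefix}{self.kind}{self.index}{self.branch}"


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical fragment: retained subgraph, cleavages, mods and charge."""

    parent: GlycanGraph = field(repr=False, compare=False)
    nodes: frozenset[int]
    cleavages: tuple[Cleavage, ...]
    ring_cuts: tuple[tuple[int, tuple[int, int], str], ...]  # (node, pair, side A|X)
    global_mods: tuple[str, ...]
    ion: IonSpec
    neutral_mass: float
    theo_mz: float
    dc_name: str
    iupac_name: str

    @property
    def n_cross_ring(self) -> int:
        return sum(1 for c in self.cleavages if c.kind in ("A", "X"))

    @property
    def subgraph(self) -> GlycanGraph:
        return self.parent.induced(self.nodes)


# ---------------------------------------------------------------------------
# subgraph enumeration
# ---------------------------------------------------------------------------

def enumerate_connected_subgraphs(g: GlycanGraph) -> list[frozenset[int]]:
    """Every induced connected subgraph of the glycan tree, exactly once.

    A connected induced subgraph of a rooted tree is determined by its top node
    v plus, independently per child of any included node, an included subtree;
    enumeration is the corresponding product, memoized per node.
    """
    if g.n_nodes > 25:
        raise ValueError("glycan too large for exhaustive subgraph enumeration")

    memo: dict[int, list[frozenset[int]]] = {}

    def at(v: int) -> list[frozenset[int]]:
        if v in memo:
            return memo[v]
        options = []
        for c in g.children(v):
            options.append([None] + at(c))
        combos = [frozenset({v})]
        for opts in options:
            combos = [
                s | extra if extra else s
                for s in combos
                for extra in opts
            ]
        memo[v] = combos
        return combos

    out: list[frozenset[int]] = []
    for v in range(g.n_nodes):
        out.extend(at(v))
    return out


# ---------------------------------------------------------------------------
# Domon-Costello branch designators
# ---------------------------------------------------------------------------

def _branch_suffixes(g: GlycanGraph) -> list[str]:
    """Greek-letter branch designator per node (ordered by branch mass)."""

    def subtree_mass(i: int) -> float:
        return sum(node_mass(g.labels[j]) for j in g.subtree_nodes(i))

    suffix = [""] * g.n_nodes

    def walk(i: int, acc: str) -> None:
        suffix[i] = acc
        kids = g.children(i)
        if len(kids) <= 1:
            for c in kids:
                walk(c, acc)
            return
        ranked = sorted(kids, key=lambda c: (-subtree_mass(c), g._canon(c)))
        for rank, c in enumerate(ranked):
            walk(c, acc + GREEK[rank])

    walk(g.root, "")
    return suffix


def domon_costello_name(fragment: FragmentIon, parent: GlycanGraph | None = None) -> str:
    """Domon-Costello name of a fragment; the intact species is named "M"."""
    if parent is not None and fragment.parent.canonical != parent.canonical:
        raise ValueError("fragment was not derived from this parent glycan")
    return fragment.dc_name


_DC_COMPONENT_RE = re.compile(r"^(?:(\d),(\d))?([ABCXYZ])(\d+)([α-κ]*)$")


def parse_dc_name(name: str) -> list[Cleavage]:
    """Parse a Domon-Costello name back into its cleavage records."""
    if name == "M":
        return []
    out = []
    for part in name.split("/"):
        m = _DC_COMPONENT_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse Domon-Costello component {part!r}")
        i, j, kind, index, branch = m.groups()
        ring = (int(i), int(j)) if i is not None else None
        out.append(Cleavage(kind, int(index), branch, ring))
    return out


def _render_name(cleavages: Sequence[Cleavage]) -> str:
    if not cleavages:
        return "M"
    ordered = sorted(cleavages, key=lambda c: (_KIND_ORDER[c.kind], c.index, c.branch))
    return "/".join(c.render() for c in ordered)


# ---------------------------------------------------------------------------
# fragment enumeration
# ---------------------------------------------------------------------------

def _child_position(g: GlycanGraph, child: int) -> int | None:
    pos = g.linkages[child][-1]
    return int(pos) if pos.isdigit() else None


def _ring_options(
    g: GlycanGraph, q: int, kept: frozenset[int], is_sub_root: bool
) -> list[tuple[tuple[int, int], str]]:
    """Admissible ring cleavages at node q given the retained node set.

    A-cuts (at the subgraph root) keep the arc without the anomeric carbon; the
    retained children must attach there and the lost children on the anomeric
    arc. X-cuts (elsewhere) keep the anomeric arc, with the symmetric
    constraint. Children at unknown ('?') positions block ring cuts.
    """
    if g.reduced and q == g.root:
        return []  # alditol: no ring at the reduced reducing end
    base, _ = split_label(g.labels[q])
    arcs = RING_ARCS.get(RESIDUE_CLASSES[base])
    if not arcs:
        return []
    kept_pos, lost_pos = [], []
    for c in g.children(q):
        pos = _child_position(g, c)
        (kept_pos if c in kept else lost_pos).append(pos)
    side = "A" if is_sub_root else "X"
    out = []
    for pair, (_, c1_positions, _, other_positions) in arcs.items():
        keep_arc, lose_arc = (
            (other_positions, c1_positions) if side == "A" else (c1_positions, other_positions)
        )
        if any(p is None or p not in keep_arc for p in kept_pos):
            continue
        if any(p is None or p not in lose_arc for p in lost_pos):
            continue
        out.append((pair, side))
    return out


def fragment_neutral_mass(
    parent: GlycanGraph,
    nodes: frozenset[int],
    cleavages: Sequence[Cleavage],
    ring_cuts: Sequence[tuple[int, tuple[int, int], str]],
    global_mods: Sequence[str] = (),
    derivatization: str = "none",
    global_mod_table: dict[str, tuple[float, bool]] | None = None,
) -> float:
    """Recompute a fragment's neutral mass from its structural records."""
    table = DEFAULT_GLOBAL_MODS if global_mod_table is None else global_mod_table
    cut_nodes = {q: (pair, side) for q, pair, side in ring_cuts}
    mass = WATER
    for q in nodes:
        if q in cut_nodes:
            pair, side = cut_nodes[q]
            base, mods = split_label(parent.labels[q])
            c1_mass, other_mass = ring_arc_masses(RESIDUE_CLASSES[base], pair)
            mass += other_mass if side == "A" else c1_mass
            # site modifications follow the arc holding their position
            _, c1_pos, _, other_pos = RING_ARCS[RESIDUE_CLASSES[base]][pair]
            for mod in mods:
                pos = int(mod[0]) if mod[0].isdigit() else None
                on_other = pos is not None and pos in other_pos
                kept = on_other if side == "A" else not on_other
                if kept:
                    mass += MOD_GROUP_MASS[mod[-1]]
        else:
            mass += node_mass(parent.labels[q], derivatization)
    for c in cleavages:
        mass += _KIND_DELTA[c.kind]
    root_cut = any(q == parent.root for q in cut_nodes)
    if parent.reduced and parent.root in nodes and not root_cut:
        mass += REDUCTION
    for mod in global_mods:
        mass += table[mod][0]
    return mass


def enumerate_fragments(
    g: GlycanGraph,
    ions: Sequence[IonSpec] | None = None,
    max_cleavages: int = 2,
    allow_cross_ring: bool = True,
    global_mods: dict[str, tuple[float, bool]] | None = None,
    scan_range: tuple[float, float] | None = None,
    derivatization: str = "none",
) -> list[FragmentIon]:
    """All theoretical fragment ions of a glycan.

    Every induced connected subgraph is decorated with each admissible
    combination of boundary cleavages (B/C where the reducing side is lost, Y/Z
    where a non-reducing branch is lost, A/X ring cuts at terminal residues
    when ``allow_cross_ring``), capped at ``max_cleavages`` cleavage events,
    then combined with each applicable global modification and each requested
    ion species. The intact species (no cleavage) is included as "M".
    """
    if ions is None:
        ions = [IonSpec("negative", None, 1), IonSpec("negative", None, 2)]
    mod_table = DEFAULT_GLOBAL_MODS if global_mods is None else global_mods
    suffix = _branch_suffixes(g)
    all_nodes = frozenset(range(g.n_nodes))
    results: list[FragmentIon] = []

    for sub in enumerate_connected_subgraphs(g):
        sub_root = next(i for i in sub if g.parents[i] not in sub)
        lost_edges = {
            q: [c for c in g.children(q) if c not in sub]
            for q in sub
            if any(c not in sub for c in g.children(q))
        }
        # candidate nodes for ring cuts: the subgraph root and any node whose
        # kept/lost children are compatible with an arc split
        ring_nodes = []
        if allow_cross_ring:
            for q in sorted(sub):
                opts = _ring_options(g, q, sub, is_sub_root=(q == sub_root))
                if opts:
                    ring_nodes.append((q, opts))

        ring_assignments: list[dict[int, tuple[tuple[int, int], str]]] = [{}]
        for q, opts in ring_nodes:
            ring_assignments = [
                {**a, **({q: o} if o else {})}
                for a in ring_assignments
                for o in [None, *opts]
            ]

        for assignment in ring_assignments:
            n_ring = len(assignment)
            has_parent_cut = sub_root != g.root and sub_root not in assignment
            open_edges = [
                (q, c)
                for q, cs in lost_edges.items()
                if q not in assignment
                for c in cs
            ]
            n_cleav = n_ring + (1 if has_parent_cut else 0) + len(open_edges)
            if n_cleav > max_cleavages:
                continue

            fixed: list[Cleavage] = []
            for q, (pair, side) in assignment.items():
                if side == "A":
                    fixed.append(Cleavage("A", g.height(q), suffix[q], pair))
                else:
                    fixed.append(Cleavage("X", g.depth(q), suffix[q], pair))

            parent_kinds = ["B", "C"] if has_parent_cut else [None]
            edge_kind_sets = [["Y", "Z"] for _ in open_edges]
            for pkind in parent_kinds:
                for ekinds in itertools.product(*edge_kind_sets):
                    cleavages = list(fixed)
                    if pkind is not None:
                        cleavages.append(
                            Cleavage(pkind, g.height(sub_root), suffix[sub_root])
                        )
                    for (q, c), kind in zip(open_edges, ekinds):
                        cleavages.append(Cleavage(kind, g.depth(q), suffix[c]))
                    ring_cuts = tuple(
                        (q, pair, side) for q, (pair, side) in sorted(assignment.items())
                    )
                    base_mass = fragment_neutral_mass(
                        g, sub, cleavages, ring_cuts, (), derivatization, mod_table
                    )
                    name = _render_name(cleavages)
                    iupac = _iupac_fragment_name(g, sub, ring_cuts)
                    mod_options: list[tuple[str, ...]] = [()]
                    has_sialic = any(
                        split_label(g.labels[q])[0] in _SIALIC
                        for q in sub
                        if q not in assignment
                    )
                    for mod, (_, needs_sialic) in mod_table.items():
                        if needs_sialic and not has_sialic:
                            continue
                        mod_options.append((mod,))
                    for mods in mod_options:
                        neutral = base_mass + sum(mod_table[m][0] for m in mods)
                        if neutral <= 0:
                            continue
                        for ion in ions:
                            mz = ion_mz(neutral, ion)
                            if mz <= 0:
                                continue
                            if scan_range and not (scan_range[0] <= mz < scan_range[1]):
                                continue
                            results.append(
                                FragmentIon(
                                    parent=g,
                                    nodes=sub,
                                    cleavages=tuple(cleavages),
                                    ring_cuts=ring_cuts,
                                    global_mods=mods,
                                    ion=ion,
                                    neutral_mass=neutral,
                                    theo_mz=mz,
                                    dc_name=name,
                                    iupac_name=iupac,
                                )
                            )
    return results


def _iupac_fragment_name(
    g: GlycanGraph,
    nodes: frozenset[int],
    ring_cuts: tuple[tuple[int, tuple[int, int], str], ...],
) -> str:
    sub = g.induced(nodes)
    name = sub.canonical
    if sub.reduced and not any(q == g.root for q, _, _ in ring_cuts):
        name += "-ol"
    for q, pair, side in ring_cuts:
        name += f" ({pair[0]},{pair[1]}{side} at {g.labels[q]})"
    return name


# ---------------------------------------------------------------------------
# peak matching and prioritization
# ---------------------------------------------------------------------------

@dataclass
class PeakAnnotation:
    """One observed peak with its ranked candidate fragments."""

    observed_mz: float
    intensity: float
    candidates: list[FragmentIon]
    mass_errors: list[float]

    @property
    def best(self) -> FragmentIon | None:
        return self.candidates[0] if self.candidates else None


def match_peaks(
    fragments: Sequence[FragmentIon],
    peaks: Sequence[tuple[float, float]],
    tolerance: float = 0.5,
) -> list[PeakAnnotation]:
    """Annotate each peak with every fragment within the m/z tolerance.

    Candidates are initially ordered by absolute mass error; peaks without any
    candidate get an empty list.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    frs = sorted(fragments, key=lambda f: f.theo_mz)
    mzs = np.array([f.theo_mz for f in frs])
    out = []
    for mz, inten in peaks:
        lo = int(np.searchsorted(mzs, mz - tolerance, side="left"))
        hi = int(np.searchsorted(mzs, mz + tolerance, side="right"))
        cands = sorted(frs[lo:hi], key=lambda f: (abs(f.theo_mz - mz), f.dc_name))
        out.append(
            PeakAnnotation(
                observed_mz=mz,
                intensity=inten,
                candidates=cands,
                mass_errors=[f.theo_mz - mz for f in cands],
            )
        )
    return out


def _same_series(f: FragmentIon, other: FragmentIon) -> bool:
    f_has_root = f.parent.root in f.nodes
    o_has_root = other.parent.root in other.nodes
    return f_has_root == o_has_root


def _corroboration(f: FragmentIon, context: Sequence[PeakAnnotation]) -> int:
    """Number of other peaks carrying complementary or same-series sub/super
    fragments of ``f``."""
    all_nodes = frozenset(range(f.parent.n_nodes))
    score = 0
    for ann in context:
        if abs(ann.observed_mz - f.theo_mz) < 1e-9:
            continue
        for other in ann.candidates:
            if other.nodes == f.nodes and other.dc_name == f.dc_name:
                continue
            complementary = (
                not (f.nodes & other.nodes)
                and (f.nodes | other.nodes) == all_nodes
                and len(f.cleavages) == 1
                and len(other.cleavages) == 1
            )
            nested = (
                (other.nodes < f.nodes or f.nodes < other.nodes)
                and _same_series(f, other)
            )
            if complementary or nested:
                score += 1
                break
    return score


def prioritize(
    candidates: Sequence[FragmentIon],
    spectrum_context: Sequence[PeakAnnotation] = (),
    mass_errors: Sequence[float] | None = None,
) -> list[FragmentIon]:
    """Rank ambiguous fragment assignments.

    Stable tiers: fewer cleavages; glycosidic before cross-ring; fewer global
    modifications; more corroborating complementary/series fragments elsewhere
    in the spectrum; smaller absolute mass error; name as final tie-break.
    """
    if not candidates:
        raise ValueError("prioritize requires at least one candidate")
    errors = dict(zip(candidates, mass_errors)) if mass_errors is not None else {}

    def key(f: FragmentIon):
        return (
            len(f.cleavages),
            f.n_cross_ring,
            len(f.global_mods),
            -_corroboration(f, spectrum_context),
            abs(errors.get(f, 0.0)),
            f.dc_name,
            f.ion.charge,
        )

    return sorted(candidates, key=key)


def annotate_spectrum(
    glycan: GlycanGraph,
    peaks: Sequence[tuple[float, float]],
    tolerance: float = 0.5,
    ions: Sequence[IonSpec] | None = None,
    max_cleavages: int = 2,
    allow_cross_ring: bool = True,
    global_mods: dict[str, tuple[float, bool]] | None = None,
) -> list[PeakAnnotation]:
    """Annotate an observed MS/MS spectrum against one candidate glycan.

    Runs the full enumeration, matches peaks within ``tolerance`` and ranks
    ambiguous assignments with the prioritization scheme, using the whole
    spectrum as corroborating context.
    """
    fragments = enumerate_fragments(
        glycan,
        ions=ions,
        max_cleavages=max_cleavages,
        allow_cross_ring=allow_cross_ring,
        global_mods=global_mods,
    )
    annotations = match_peaks(fragments, peaks, tolerance)
    for ann in annotations:
        if len(ann.candidates) > 1:
            ranked = prioritize(ann.candidates, annotations, ann.mass_errors)
            errs = {f: e for f, e in zip(ann.candidates, ann.mass_errors)}
            ann.candidates = ranked
            ann.mass_errors = [errs[f] for f in ranked]
    return annotations
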