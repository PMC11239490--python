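"""Glycan structures as rooted labeled trees.

Glycans are branched polymers of monosaccharides joined by glycosidic linkages.
We model a glycan as a rooted tree whose root is the reducing-end residue (the
residue with the free anomeric carbon, optionally reduced to an alditol by
sample preparation) and whose edges point from parent (reducing side) to child
(non-reducing side). Each node carries a monosaccharide label, optionally with
site modifications such as sulfation ("GlcNAc6S"); each edge carries a linkage
label such as "β1-3" or "α2-6", with "?" allowed as a wildcard for unknown
anomeric configuration or attachment position.

Structures are read and written in IUPAC-condensed nomenclature, e.g.
``GlcNAcβ1-3(Neu5Acα2-6)GalNAc``: the rightmost residue is the reducing end and
parenthesized groups are branches attached to the residue that follows them.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GlycanGraph",
    "Composition",
    "MotifVocabulary",
    "GlycanParseError",
    "parse_iupac",
    "serialize",
    "to_composition",
    "fingerprint",
    "structure_distance",
    "subgraph_of",
    "biosynthetic_precursors",
    "read_library",
    "write_library",
    "RESIDUE_CLASSES",
]

# Residue base names -> composition class. The class set mirrors what negative-
# mode glycomics can distinguish by mass alone.
RESIDUE_CLASSES: dict[str, str] = {
    "Glc": "Hex",
    "Gal": "Hex",
    "Man": "Hex",
    "Hex": "Hex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "ManNAc": "HexNAc",
    "HexNAc": "HexNAc",
    "Fuc": "dHex",
    "Rha": "dHex",
    "dHex": "dHex",
    "Neu5Ac": "Neu5Ac",
    "Neu5Gc": "Neu5Gc",
    "Kdn": "Kdn",
    "Xyl": "Pen",
    "Ara": "Pen",
    "Rib": "Pen",
    "Pen": "Pen",
}

COMPOSITION_CLASSES = ("Hex", "HexNAc", "dHex", "Neu5Ac", "Neu5Gc", "Pen", "Kdn", "S", "P")

_MOD_RE = re.compile(r"(?:[1-9]?[SP])")
_LINKAGE_RE = re.compile(r"[αβab?][12]-[1-9?]")

GREEK = "αβγδεζηθικ"


class GlycanParseError(ValueError):
    """Raised for malformed IUPAC-condensed strings; carries the position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


def split_label(label: str) -> tuple[str, tuple[str, ...]]:
    """Split a node label into (base residue, modifications).

    ``"GlcNAc6S" -> ("GlcNAc", ("6S",))``. Raises ``GlycanParseError`` when the
    base residue is unknown.
    """
    mods: list[str] = []
    base = label
    while True:
        m = _MOD_RE.search(base)
        if m and m.end() == len(base) and base[: m.start()] and base[: m.start()][-1].isalpha():
            mods.insert(0, m.group())
            base = base[: m.start()]
        else:
            break
    if base not in RESIDUE_CLASSES:
        raise GlycanParseError(f"unknown residue label {label!r}")
    return base, tuple(mods)


def _valid_label(label: str) -> bool:
    try:
        split_label(label)
        return True
    except GlycanParseError:
        return False


def _normalize_linkage(link: str) -> str:
    return link.replace("a", "α").replace("b", "β")


class GlycanGraph:
    """Rooted labeled tree of monosaccharides.

    Node ids are dense integers ``0..n-1``; ``parents[i]`` is the parent node id
    (``-1`` for the root) and ``linkages[i]`` is the linkage joining node ``i``
    to its parent (``""`` for the root). ``reduced`` marks an alditol reducing
    end.
    """

    __slots__ = ("labels", "parents", "linkages", "reduced", "_children", "_canonical")

    def __init__(
        self,
        labels: Sequence[str],
        parents: Sequence[int],
        linkages: Sequence[str],
        reduced: bool = False,
    ):
        self.labels = tuple(labels)
        self.parents = tuple(parents)
        self.linkages = tuple(_normalize_linkage(l) for l in linkages)
        self.reduced = bool(reduced)
        self._children: tuple[tuple[int, ...], ...] | None = None
        self._canonical: str | None = None
        self._validate()

    # -- basic structure ---------------------------------------------------
    def _validate(self) -> None:
        n = len(self.labels)
        if n == 0:
            raise GlycanParseError("empty glycan")
        roots = [i for i, p in enumerate(self.parents) if p == -1]
        if len(roots) != 1:
            raise GlycanParseError(f"glycan must have exactly one root, found {len(roots)}")
        for i, p in enumerate(self.parents):
            if p != -1 and not (0 <= p < n):
                raise GlycanParseError(f"node {i} has invalid parent {p}")
            if p != -1 and not _LINKAGE_RE.fullmatch(self.linkages[i].replace("α", "a").replace("β", "b")):
                raise GlycanParseError(f"invalid linkage label {self.linkages[i]!r}")
        for label in self.labels:
            split_label(label)
        # acyclicity / connectivity: walk to root from every node
        for i in range(n):
            seen = set()
            j = i
            while j != -1:
                if j in seen:
                    raise GlycanParseError("cycle detected in glycan graph")
                seen.add(j)
                j = self.parents[j]

    @property
    def root(self) -> int:
        return self.parents.index(-1)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def children(self, i: int) -> tuple[int, ...]:
        if self._children is None:
            kids: list[list[int]] = [[] for _ in self.labels]
            for j, p in enumerate(self.parents):
                if p != -1:
                    kids[p].append(j)
            self._children = tuple(tuple(k) for k in kids)
        return self._children[i]

    def leaves(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_nodes) if not self.children(i))

    def depth(self, i: int) -> int:
        """Residue count from the reducing end to node ``i``, root = 1."""
        d = 1
        while self.parents[i] != -1:
            i = self.parents[i]
            d += 1
        return d

    def height(self, i: int) -> int:
        """Residue count of the longest path from ``i`` to a leaf, leaf = 1."""
        kids = self.children(i)
        return 1 if not kids else 1 + max(self.height(c) for c in kids)

    def subtree_nodes(self, i: int) -> frozenset[int]:
        acc = {i}
        stack = [i]
        while stack:
            for c in self.children(stack.pop()):
                acc.add(c)
                stack.append(c)
        return frozenset(acc)

    # -- canonical form ----------------------------------------------------
    def _canon(self, i: int) -> str:
        kids = sorted(
            self.children(i), key=lambda c: (self.linkages[c], self._canon(c))
        )
        if not kids:
            return self.labels[i]
        parts = [self._canon(kids[0]) + self.linkages[kids[0]]]
        for c in kids[1:]:
            parts.append("(" + self._canon(c) + self.linkages[c] + ")")
        return "".join(parts) + self.labels[i]

    @property
    def canonical(self) -> str:
        if self._canonical is None:
            self._canonical = self._canon(self.root)
        return self._canonical

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanGraph):
            return NotImplemented
        return self.canonical == other.canonical and self.reduced == other.reduced

    def __hash__(self) -> int:
        return hash((self.canonical, self.reduced))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        suffix = "-ol" if self.reduced else ""
        return f"GlycanGraph({self.canonical!r}{suffix})"

    # -- interop -----------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i, label in enumerate(self.labels):
            g.add_node(i, label=label)
        for i, p in enumerate(self.parents):
            if p != -1:
                g.add_edge(p, i, linkage=self.linkages[i])
        return g

    def induced(self, nodes: Iterable[int], reduced: bool | None = None) -> "GlycanGraph":
        """Induced connected subgraph on ``nodes`` as a new GlycanGraph.

        The new root is the unique node whose parent lies outside the set. The
        ``reduced`` flag defaults to "reduced iff the original root is kept".
        """
        keep = sorted(set(nodes))
        index = {old: new for new, old in enumerate(keep)}
        roots = [i for i in keep if self.parents[i] not in index]
        if len(roots) != 1:
            raise ValueError("node set does not induce a connected subtree")
        labels = [self.labels[i] for i in keep]
        parents = [index.get(self.parents[i], -1) for i in keep]
        linkages = [self.linkages[i] if self.parents[i] in index else "" for i in keep]
        if reduced is None:
            reduced = self.reduced and self.root in index
        return GlycanGraph(labels, parents, linkages, reduced=reduced)


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

def _tokenize(s: str) -> list[tuple[str, str, int]]:
    """Tokenize into (kind, text, position); kinds: residue, linkage, (, )."""
    tokens: list[tuple[str, str, int]] = []
    buf = ""
    buf_start = 0
    i = 0
    while i < len(s):
        ch = s[i]
        if ch in "()":
            if buf:
                tokens.append(("residue", buf, buf_start))
                buf = ""
            tokens.append((ch, ch, i))
            i += 1
            continue
        m = _LINKAGE_RE.match(s, i)
        # only split off a linkage when the residue buffer so far is valid;
        # otherwise the match is part of a residue name (e.g. the "a" in "Ara")
        if m and buf and _valid_label(buf):
            tokens.append(("residue", buf, buf_start))
            buf = ""
            tokens.append(("linkage", m.group(), i))
            i = m.end()
            continue
        if not buf:
            buf_start = i
        buf += ch
        i += 1
    if buf:
        tokens.append(("residue", buf, buf_start))
    return tokens


def parse_iupac(s: str, reduced: bool = False) -> GlycanGraph:
    """Parse an IUPAC-condensed glycan string into a :class:`GlycanGraph`.

    The last residue of the string becomes the root (reducing end); branches in
    parentheses attach to the residue that follows the closing parenthesis.
    A trailing ``-ol`` marks a reduced (alditol) reducing end.
    """
    s = s.strip()
    if not s:
        raise GlycanParseError("empty glycan string", 0)
    if s.endswith("-ol"):
        reduced = True
        s = s[:-3]
    if s.count("(") != s.count(")"):
        raise GlycanParseError("unbalanced parentheses", len(s))

    labels: list[str] = []
    parents: list[int] = []
    linkages: list[str] = []

    def new_node(label: str, pos: int) -> int:
        try:
            split_label(label)
        except GlycanParseError:
            raise GlycanParseError(f"malformed token {label!r}", pos) from None
        labels.append(label)
        parents.append(-1)
        linkages.append("")
        return len(labels) - 1

    tokens = _tokenize(s)

    def parse_chain(pos: int, depth: int) -> tuple[int, str | None, int]:
        """Parse a chain starting at token index ``pos``.

        Returns (root node id of the chain, trailing linkage or None, next
        token index). A trailing linkage is only legal inside parentheses.
        """
        pending: list[tuple[int, str]] = []  # (child node, linkage to next residue)
        last_node: int | None = None
        last_link: str | None = None
        while pos < len(tokens):
            kind, text, at = tokens[pos]
            if kind == ")":
                break
            if kind == "(":
                if last_node is not None and last_link is None:
                    raise GlycanParseError("branch must follow a linkage", at)
                sub_root, sub_link, pos = parse_chain(pos + 1, depth + 1)
                if pos >= len(tokens) or tokens[pos][0] != ")":
                    raise GlycanParseError("unbalanced parentheses", at)
                pos += 1
                if sub_link is None:
                    raise GlycanParseError("branch missing trailing linkage", at)
                pending.append((sub_root, sub_link))
                continue
            if kind == "residue":
                if last_node is not None and last_link is None:
                    raise GlycanParseError(f"expected linkage before {text!r}", at)
                node = new_node(text, at)
                if last_node is not None:
                    pending.append((last_node, last_link))  # type: ignore[arg-type]
                for child, link in pending:
                    parents[child] = node
                    linkages[child] = link
                pending = []
                last_node, last_link = node, None
                pos += 1
                continue
            if kind == "linkage":
                if last_node is None or last_link is not None:
                    raise GlycanParseError(f"unexpected linkage {text!r}", at)
                last_link = text
                pos += 1
                continue
            raise GlycanParseError(f"unexpected token {text!r}", at)
        if last_node is None:
            raise GlycanParseError("empty chain", tokens[pos][2] if pos < len(tokens) else len(s))
        if pending:
            raise GlycanParseError("dangling branch", len(s))
        if last_link is not None and depth == 0:
            raise GlycanParseError("trailing linkage without residue", len(s))
        return last_node, last_link, pos

    root, _, pos = parse_chain(0, 0)
    if pos != len(tokens):
        raise GlycanParseError("unbalanced parentheses", tokens[pos][2])
    return GlycanGraph(labels, parents, linkages, reduced=reduced)


def serialize(g: GlycanGraph) -> str:
    """Canonical IUPAC-condensed string (children sorted by linkage, subtree);
    a reduced (alditol) reducing end is written with a trailing ``-ol``."""
    return g.canonical + ("-ol" if g.reduced else "")


def read_library(path) -> list[GlycanGraph]:
    """Read a reference library: one IUPAC-condensed string per line, '#' comments."""
    glycans: list[GlycanGraph] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                glycans.append(parse_iupac(line))
    return glycans


def write_library(glycans: Iterable[GlycanGraph], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in glycans:
            fh.write(serialize(g) + "\n")


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """Counts of residue classes (plus sulfate/phosphate groups)."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "Composition":
        for k in d:
            if k not in COMPOSITION_CLASSES:
                raise ValueError(f"unknown composition class {k!r}")
        items = tuple(sorted((k, int(v)) for k, v in d.items() if v))
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, key: str) -> int:
        return dict(self.counts).get(key, 0)

    def total_residues(self) -> int:
        return sum(v for k, v in self.counts if k not in ("S", "P"))

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def vector(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d.get(c, 0) for c in COMPOSITION_CLASSES], dtype=float)

    def __str__(self) -> str:
        return "".join(f"{k}{v}" for k, v in self.counts)


def to_composition(g: GlycanGraph) -> Composition:
    """Residue-class composition of a glycan; site modifications feed S/P counts."""
    counts: dict[str, int] = {}
    for label in g.labels:
        base, mods = split_label(label)
        cls = RESIDUE_CLASSES[base]
        counts[cls] = counts.get(cls, 0) + 1
        for mod in mods:
            grp = mod[-1]  # S or P
            counts[grp] = counts.get(grp, 0) + 1
    return Composition.from_dict(counts)


def composition_distance(c1: Composition, c2: Composition) -> float:
    """Cosine distance between composition count vectors."""
    v1, v2 = c1.vector(), c2.vector()
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0 if c1 == c2 else 1.0
    return float(1.0 - np.dot(v1, v2) / (n1 * n2))


# ---------------------------------------------------------------------------
# motif fingerprints and structure distance
# ---------------------------------------------------------------------------

def _motifs(g: GlycanGraph) -> list[str]:
    out = list(g.labels)
    for i, p in enumerate(g.parents):
        if p != -1:
            out.append(f"{g.labels[i]}{g.linkages[i]}{g.labels[p]}")
    return out


class MotifVocabulary:
    """Fixed vocabulary of monosaccharide and linkage-typed disaccharide motifs.

    Built once from the reference library and then frozen so that fingerprint
    geometry is stable; out-of-vocabulary motifs seen at inference are ignored.
    """

    def __init__(self, motifs: Iterable[str] = ()):
        self._index: dict[str, int] = {}
        for m in motifs:
            self._index.setdefault(m, len(self._index))

    @classmethod
    def from_glycans(cls, glycans: Iterable[GlycanGraph]) -> "MotifVocabulary":
        vocab = cls()
        for g in glycans:
            for m in _motifs(g):
                vocab._index.setdefault(m, len(vocab._index))
        return vocab

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, motif: str) -> bool:
        return motif in self._index

    def transform(self, g: GlycanGraph, frozen: bool = True) -> np.ndarray:
        if not frozen:
            for m in _motifs(g):
                self._index.setdefault(m, len(self._index))
        vec = np.zeros(len(self._index), dtype=float)
        for m in _motifs(g):
            idx = self._index.get(m)
            if idx is not None:
                vec[idx] += 1
        return vec


def fingerprint(g: GlycanGraph, vocab: MotifVocabulary | None = None) -> np.ndarray:
    """Counts of mono- and disaccharide motifs against ``vocab``.

    With ``vocab=None`` an ad-hoc vocabulary from the glycan itself is used.
    """
    if vocab is None:
        vocab = MotifVocabulary.from_glycans([g])
    return vocab.transform(g)


def structure_distance(
    g1: GlycanGraph, g2: GlycanGraph, vocab: MotifVocabulary | None = None
) -> float:
    """Cosine distance of motif fingerprints, in [0, 1].

    Convention for degenerate inputs: a zero-vector fingerprint (fully
    out-of-vocabulary glycan) has distance 0 to an identical glycan and 1 to
    anything else.
    """
    if vocab is None:
        vocab = MotifVocabulary.from_glycans([g1, g2])
    v1, v2 = vocab.transform(g1), vocab.transform(g2)
    if g1 == g2:
        return 0.0
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 1.0
    cos = float(np.dot(v1, v2) / (n1 * n2))
    return float(min(1.0, max(0.0, 1.0 - cos)))


# ---------------------------------------------------------------------------
# subgraph isomorphism and biosynthesis
# ---------------------------------------------------------------------------

def _linkage_compatible(sub_link: str, sup_link: str, wildcards: bool) -> bool:
    if sub_link == sup_link:
        return True
    if not wildcards:
        return False
    if len(sub_link) != len(sup_link):
        return False
    return all(a == b or a == "?" or b == "?" for a, b in zip(sub_link, sup_link))


def subgraph_of(sub: GlycanGraph, sup: GlycanGraph, wildcards: bool = True) -> bool:
    """True iff ``sub`` embeds into ``sup`` preserving labels, linkages and
    parent->child orientation. With ``wildcards``, '?' in a linkage matches any
    character at that slot.
    """

    def match(si: int, ti: int) -> bool:
        if sub.labels[si] != sup.labels[ti]:
            return False
        skids = sub.children(si)
        tkids = sup.children(ti)
        if len(skids) > len(tkids):
            return False
        if not skids:
            return True
        for perm in itertools.permutations(tkids, len(skids)):
            ok = True
            for sc, tc in zip(skids, perm):
                if not _linkage_compatible(sub.linkages[sc], sup.linkages[tc], wildcards):
                    ok = False
                    break
                if not match(sc, tc):
                    ok = False
                    break
            if ok:
                return True
        return False

    return any(match(sub.root, t) for t in range(sup.n_nodes))


def biosynthetic_precursors(g: GlycanGraph) -> set[GlycanGraph]:
    """All glycans obtained by deleting one terminal (non-root) monosaccharide.

    Biosynthesis extends glycans one monosaccharide at a time, so the direct
    precursors of a structure are exactly its single-leaf deletions,
    deduplicated by canonical form. A single-residue glycan has no precursors.
    """
    if g.n_nodes < 2:
        return set()
    out: set[GlycanGraph] = set()
    for leaf in g.leaves():
        if leaf == g.root:
            continue
        keep = [i for i in range(g.n_nodes) if i != leaf]
        out.add(g.induced(keep))
    return out


def biosynthetic_network_nodes(roots: Iterable[GlycanGraph]) -> set[GlycanGraph]:
    """Transitive closure of biosynthetic precursors of ``roots`` (inclusive).

    This is the node set of the biosynthetic network implied by a set of
    observed structures: every intermediate on a path of single-residue
    deletions down to the core.
    """
    seen: set[GlycanGraph] = set()
    stack = list(roots)
    while stack:
        g = stack.pop()
        if g in seen:
            continue
        seen.add(g)
        stack.extend(biosynthetic_precursors(g))
    return seen
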