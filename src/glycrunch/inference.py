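"""Raw file to ranked structure table: the full inference pipeline.

Spectra are grouped by precursor m/z (a new group starts at every discontinuity
greater than 0.5 Da in the sorted precursor values), then into retention-time
chunks of 0.5 min to separate structural isomers. Each (mass, retention) entity
is represented by a robust averaged spectrum (model input) and a median
spectrum (evidence checks). Predictions are filtered with domain knowledge
(score floor, glycan class, precursor mass at any charge, diagnostic ions),
deduplicated, rescored with biosynthetic context (a confidence bonus per unique
lower-mass top-1 prediction that is a biosynthetic precursor), optionally
extended with zero-shot candidates, and annotated with relative abundances from
precursor ion intensities.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace as dc_replace
from importlib import resources

import numpy as np
import pandas as pd

from .glycans import (
    Composition,
    GlycanGraph,
    biosynthetic_network_nodes,
    parse_iupac,
    serialize,
    split_label,
    subgraph_of,
    to_composition,
    RESIDUE_CLASSES,
)
from .masses import IonSpec, composition_match, glycan_mass, infer_composition
from .predictors import Predictor
from .spectra import (
    Spectrum,
    average_spectra,
    bin_spectrum,
    load_spectra,
    normalize_intensities,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "PredictionRow",
    "group_precursors",
    "group_rt",
    "apply_domain_filters",
    "canonicalize_biosynthesis",
    "zero_shot_extend",
    "estimate_abundance",
    "wrap_inference",
    "rows_to_table",
    "load_diagnostic_ions",
    "infer_glycan_class",
]


@dataclass(frozen=True)
class InferenceConfig:
    topk_initial: int = 25
    score_floor: float = 0.01
    cross_class_override: float = 0.2
    precursor_gap: float = 0.5  # Da
    rt_chunk: float = 0.5  # minutes
    platt_factor: float = 1.15
    tta_rounds: int = 5
    precursor_bonus: float = 0.1
    topk_final: int = 5
    mass_tolerance: float = 0.5  # Da
    max_charge: int = 2

    def __post_init__(self):
        if min(
            self.topk_initial, self.score_floor, self.cross_class_override,
            self.precursor_gap, self.rt_chunk, self.platt_factor, self.tta_rounds,
            self.precursor_bonus, self.topk_final, self.mass_tolerance, self.max_charge,
        ) <= 0:
            raise ValueError("all inference parameters must be positive")
        if self.topk_final > self.topk_initial:
            raise ValueError("topk_final must not exceed topk_initial")


@dataclass
class PredictionRow:
    """One (precursor mass, retention window) entity with ranked candidates."""

    precursor_mz: float
    rt_window: tuple[float, float]
    candidates: list[tuple[GlycanGraph, float]]
    evidence: str = "strong"  # strong | medium | weak
    composition: Composition | None = None
    charge: int | None = None
    abundance: float | None = None
    median_spectrum: Spectrum | None = field(default=None, repr=False)
    members: list[Spectrum] = field(default_factory=list, repr=False)

    @property
    def top1(self) -> GlycanGraph | None:
        return self.candidates[0][0] if self.candidates else None


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_precursors(spectra: list[Spectrum], gap: float = 0.5) -> list[list[Spectrum]]:
    """Group spectra by precursor m/z; a discontinuity strictly greater than
    ``gap`` between consecutive sorted precursor values starts a new group."""
    if not spectra:
        return []
    ordered = sorted(spectra, key=lambda s: s.precursor_mz)
    groups = [[ordered[0]]]
    for s in ordered[1:]:
        if s.precursor_mz - groups[-1][-1].precursor_mz > gap:
            groups.append([s])
        else:
            groups[-1].append(s)
    return groups


def group_rt(group: list[Spectrum], chunk: float = 0.5) -> list[list[Spectrum]]:
    """Partition one precursor group into retention-time chunks of ``chunk``
    minutes (floor rule; missing retention times land in chunk 0)."""
    chunks: dict[int, list[Spectrum]] = {}
    for s in group:
        rt = s.rt if s.rt is not None else 0.0
        chunks.setdefault(int(rt // chunk), []).append(s)
    return [chunks[k] for k in sorted(chunks)]


# ---------------------------------------------------------------------------
# domain filters
# ---------------------------------------------------------------------------

def infer_glycan_class(g: GlycanGraph) -> str:
    """Crude class call from the reducing-end residue: GalNAc roots are
    O-glycans, GlcNAc roots N-glycans, anything else a free oligosaccharide."""
    base, _ = split_label(g.labels[g.root])
    if base == "GalNAc":
        return "O"
    if base == "GlcNAc":
        return "N"
    return "free"


def load_diagnostic_ions() -> dict[str, list[float]]:
    """Shipped table of required diagnostic fragment m/z per residue class."""
    table: dict[str, list[float]] = {}
    path = resources.files("glycrunch").joinpath("data/diagnostic_ions.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["residue_class"], []).append(float(row["mz"]))
    return table


def _has_peak(spectrum: Spectrum | None, mz: float, tol: float) -> bool:
    if spectrum is None or not len(spectrum.peaks):
        return True  # no evidence available -> do not reject
    return bool(np.any(np.abs(spectrum.peaks[:, 0] - mz) <= tol))


def _diagnostics_ok(
    g: GlycanGraph, spectrum: Spectrum | None, table: dict[str, list[float]], tol: float
) -> bool:
    comp = to_composition(g)
    for cls, count in comp:
        if count and cls in table:
            if not any(_has_peak(spectrum, mz, tol) for mz in table[cls]):
                return False
    return True


def _mass_ok(g: GlycanGraph, precursor_mz: float, cfg: InferenceConfig) -> bool:
    return bool(
        composition_match(
            precursor_mz,
            [to_composition(g)],
            tolerance=cfg.mass_tolerance,
            max_charge=cfg.max_charge,
            reduced=g.reduced,
        )
    )


def apply_domain_filters(
    rows: list[PredictionRow],
    cfg: InferenceConfig,
    expected_class: str = "O",
    diagnostics: dict[str, list[float]] | None = None,
) -> list[PredictionRow]:
    """Remove candidates that fail domain-knowledge checks.

    Filters: (1) score below the floor; (2) wrong glycan class, unless the
    score exceeds the cross-class override (O-glycan samples often carry
    remnant N-glycans); (3) precursor mass mismatch at every charge state up to
    ``max_charge``; (4) missing diagnostic ions in the median spectrum for
    residues with a shipped diagnostic table entry. Filters only ever remove
    candidates; rows are kept (possibly with no candidates) for zero-shot use.
    """
    if diagnostics is None:
        diagnostics = load_diagnostic_ions()
    out = []
    for row in rows:
        kept = []
        for g, score in row.candidates:
            if score < cfg.score_floor:
                continue
            if infer_glycan_class(g) != expected_class and score <= cfg.cross_class_override:
                continue
            if not _mass_ok(g, row.precursor_mz, cfg):
                continue
            if not _diagnostics_ok(g, row.median_spectrum, diagnostics, cfg.mass_tolerance):
                continue
            kept.append((g, score))
        out.append(dc_replace(row, candidates=kept))
    return out


# ---------------------------------------------------------------------------
# deduplication and biosynthetic rescoring
# ---------------------------------------------------------------------------

def _row_key(row: PredictionRow) -> tuple[str, ...]:
    return tuple(serialize(g) for g, _ in row.candidates)


def dedup_rows(rows: list[PredictionRow], gap: float = 0.5) -> list[PredictionRow]:
    """Merge mass/retention windows with identical ordered predictions whose
    precursor values lie within one gap width."""
    ordered = sorted(rows, key=lambda r: (r.precursor_mz, r.rt_window[0]))
    merged: list[PredictionRow] = []
    for row in ordered:
        if (
            merged
            and row.candidates
            and _row_key(row) == _row_key(merged[-1])
            and abs(row.precursor_mz - merged[-1].precursor_mz) <= gap
        ):
            prev = merged[-1]
            members = prev.members + row.members
            scores = [
                (g, (s1 + s2) / 2)
                for (g, s1), (_, s2) in zip(prev.candidates, row.candidates)
            ]
            merged[-1] = dc_replace(
                prev,
                rt_window=(
                    min(prev.rt_window[0], row.rt_window[0]),
                    max(prev.rt_window[1], row.rt_window[1]),
                ),
                candidates=scores,
                members=members,
            )
        else:
            merged.append(row)
    return merged


def _renormalize(cands: list[tuple[GlycanGraph, float]], topk: int) -> list[tuple[GlycanGraph, float]]:
    cands = sorted(cands, key=lambda t: -t[1])
    total = sum(s for _, s in cands)
    if total > 0:
        cands = [(g, s / total) for g, s in cands]
    return cands[:topk]


def canonicalize_biosynthesis(
    rows: list[PredictionRow],
    bonus: float = 0.1,
    topk: int = 5,
    strong_only: bool = False,
) -> list[PredictionRow]:
    """Biosynthetic rescoring of candidate lists.

    Starting from the largest glycan (by neutral mass, ties by node count),
    every candidate's score gains ``bonus`` for each unique lower-mass top-1
    prediction elsewhere in the table that is a biosynthetic precursor
    (wildcard-linkage subgraph) of it. Candidates are then re-sorted, scores
    renormalized to 1 and the up-to-top-``topk`` predictions retained.
    """
    top1s: list[tuple[float, GlycanGraph]] = []
    for row in rows:
        if row.candidates and (not strong_only or row.evidence == "strong"):
            g = row.candidates[0][0]
            top1s.append((glycan_mass(g), g))

    def boosted(row: PredictionRow) -> list[tuple[GlycanGraph, float]]:
        out = []
        for g, score in row.candidates:
            mass = glycan_mass(g)
            hits = {
                serialize(t)
                for t_mass, t in top1s
                if t_mass < mass - 0.5 and subgraph_of(t, g, wildcards=True)
            }
            out.append((g, score + bonus * len(hits)))
        return out

    order = sorted(
        range(len(rows)),
        key=lambda i: (
            -(glycan_mass(rows[i].top1) if rows[i].top1 else rows[i].precursor_mz),
            -(rows[i].top1.n_nodes if rows[i].top1 else 0),
        ),
    )
    new_rows = list(rows)
    for i in order:
        row = rows[i]
        if not row.candidates:
            continue
        new_rows[i] = dc_replace(row, candidates=_renormalize(boosted(row), topk))
    return new_rows


# ---------------------------------------------------------------------------
# zero-shot extension
# ---------------------------------------------------------------------------

def _swap_variants(g: GlycanGraph, glycan_class: str) -> list[GlycanGraph]:
    """Single Neu5Ac<->Neu5Gc substitutions, plus GlcNAc<->GlcNAc6S swaps on
    residues attached to the reducing-end GalNAc for O-glycans."""
    variants = []
    for i, label in enumerate(g.labels):
        new_label = None
        if label == "Neu5Ac":
            new_label = "Neu5Gc"
        elif label == "Neu5Gc":
            new_label = "Neu5Ac"
        elif glycan_class == "O" and g.parents[i] == g.root:
            if label == "GlcNAc":
                new_label = "GlcNAc6S"
            elif label == "GlcNAc6S":
                new_label = "GlcNAc"
        if new_label is not None:
            labels = list(g.labels)
            labels[i] = new_label
            variants.append(GlycanGraph(labels, g.parents, g.linkages, reduced=g.reduced))
    return variants


def zero_shot_extend(
    rows: list[PredictionRow],
    reference: list[GlycanGraph],
    cfg: InferenceConfig,
    glycan_class: str = "O",
    mode: str = "negative",
    diagnostics: dict[str, list[float]] | None = None,
) -> list[PredictionRow]:
    """Propose structures for spectra without a valid prediction.

    (a) Biosynthetic-network intermediates implied by the strong top-1
    predictions that explain an unexplained precursor mass within the tolerance
    at any charge are added with evidence 'medium'. (b) Neu5Ac<->Neu5Gc (and,
    for O-glycans, GlcNAc<->GlcNAc6S) variants of strong predictions, and (c)
    reference-library mass matches, are added with evidence 'weak'. All
    additions pass the domain filters (which checks the diagnostic ions for the
    swaps); biosynthetic bonuses count strong-evidence rows only.
    """
    if diagnostics is None:
        diagnostics = load_diagnostic_ions()
    strong_top1 = [r.candidates[0][0] for r in rows if r.evidence == "strong" and r.candidates]
    predicted = {serialize(g) for g in strong_top1}

    intermediates = [
        g
        for g in biosynthetic_network_nodes(strong_top1)
        if serialize(g) not in predicted
    ]
    swaps = [
        v
        for g in strong_top1
        for v in _swap_variants(g, glycan_class)
        if serialize(v) not in predicted
    ]

    def matches(pool: list[GlycanGraph], mz: float) -> list[GlycanGraph]:
        out, seen = [], set()
        for g in pool:
            if serialize(g) in seen:
                continue
            if composition_match(
                mz, [to_composition(g)], cfg.mass_tolerance, cfg.max_charge,
                mode, reduced=g.reduced,
            ):
                seen.add(serialize(g))
                out.append(g)
        return out

    new_rows = list(rows)
    for i, row in enumerate(rows):
        if row.candidates:
            continue
        for pool, evidence in (
            (intermediates, "medium"),
            (swaps, "weak"),
            (list(reference), "weak"),
        ):
            if evidence == "medium" and not strong_top1:
                continue
            hits = matches(pool, row.precursor_mz)
            if hits:
                cands = [(g, 1.0 / len(hits)) for g in hits]
                new_rows[i] = dc_replace(row, candidates=cands, evidence=evidence)
                break
    # re-filter only the newly added rows; strong rows already passed
    added_idx = [i for i, (old, new) in enumerate(zip(rows, new_rows)) if new is not old]
    if added_idx:
        filtered = apply_domain_filters(
            [new_rows[i] for i in added_idx], cfg, glycan_class, diagnostics
        )
        for i, row in zip(added_idx, filtered):
            new_rows[i] = row if row.candidates else rows[i]
    return canonicalize_biosynthesis(
        new_rows, cfg.precursor_bonus, cfg.topk_final, strong_only=True
    )


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

def estimate_abundance(rows: list[PredictionRow]) -> list[PredictionRow]:
    """Relative abundances from summed precursor ion intensities per row,
    normalized to fractions over the sample; missing when no MS1-derived
    precursor intensities are available."""
    sums = []
    for row in rows:
        vals = [s.precursor_intensity for s in row.members if s.precursor_intensity is not None]
        sums.append(float(np.sum(vals)) if vals else None)
    total = sum(v for v in sums if v is not None)
    if total <= 0:
        if any(s is not None for s in sums):
            logger.info("all precursor intensities zero; abundances left missing")
        return [dc_replace(r, abundance=None) for r in rows]
    return [
        dc_replace(r, abundance=(v / total if v is not None else None))
        for r, v in zip(rows, sums)
    ]


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def wrap_inference(
    source,
    predictor: Predictor,
    reference_library: list[GlycanGraph] | None = None,
    cfg: InferenceConfig | None = None,
    glycan_class: str = "O",
    mode: str = "negative",
    zero_shot: bool = False,
    seed: int = 0,
    diagnostics: dict[str, list[float]] | None = None,
) -> list[PredictionRow]:
    """Raw file (or spectra list) to the final ranked prediction rows.

    Deterministic for a fixed seed: load -> precursor grouping -> retention
    chunking -> robust averaging -> top-k prediction -> domain filters ->
    deduplication -> biosynthetic rescoring -> optional zero-shot extension ->
    abundance estimation.
    """
    cfg = InferenceConfig() if cfg is None else cfg
    rng = np.random.default_rng(seed)
    spectra = load_spectra(source) if isinstance(source, (str,)) or hasattr(source, "__fspath__") else list(source)
    if not spectra:
        return []
    max_rt = max((s.rt for s in spectra if s.rt is not None), default=0.0)

    rows: list[PredictionRow] = []
    for pgroup in group_precursors(spectra, cfg.precursor_gap):
        for rgroup in group_rt(pgroup, cfg.rt_chunk):
            averaged, median = average_spectra(rgroup)
            binned = bin_spectrum(normalize_intensities(averaged), max_rt=max_rt)
            preds = predictor.predict(binned, cfg.topk_initial, rng)
            candidates = [(parse_iupac(s), p) for s, p in preds]
            rts = [s.rt for s in rgroup if s.rt is not None]
            chunk0 = (min(rts) // cfg.rt_chunk) * cfg.rt_chunk if rts else 0.0
            comp, charge = None, None
            if candidates:
                m = composition_match(
                    averaged.precursor_mz,
                    [to_composition(candidates[0][0])],
                    cfg.mass_tolerance, cfg.max_charge, mode,
                    reduced=candidates[0][0].reduced,
                )
                if m:
                    comp, charge = m[0][0], m[0][1].charge
            if comp is None:
                hit = infer_composition(
                    averaged.precursor_mz, cfg.mass_tolerance, cfg.max_charge, mode
                )
                if hit:
                    comp, charge = hit[0], hit[1].charge
            rows.append(
                PredictionRow(
                    precursor_mz=averaged.precursor_mz,
                    rt_window=(float(chunk0), float(chunk0 + cfg.rt_chunk)),
                    candidates=candidates,
                    evidence="strong",
                    composition=comp,
                    charge=charge,
                    median_spectrum=median,
                    members=list(rgroup),
                )
            )

    rows = apply_domain_filters(rows, cfg, glycan_class, diagnostics)
    rows = dedup_rows(rows, cfg.precursor_gap)
    rows = canonicalize_biosynthesis(rows, cfg.precursor_bonus, cfg.topk_final)
    if zero_shot:
        rows = zero_shot_extend(
            rows, reference_library or [], cfg, glycan_class, mode, diagnostics
        )
    rows = estimate_abundance(rows)
    rows.sort(key=lambda r: (r.precursor_mz, r.rt_window[0]))
    return rows


def rows_to_table(rows: list[PredictionRow], topk: int = 5) -> pd.DataFrame:
    """Flat output table: one row per (mass, retention window) entity."""
    records = []
    for row in rows:
        rec = {
            "precursor_mz": round(row.precursor_mz, 4),
            "rt_start": round(row.rt_window[0], 3),
            "rt_end": round(row.rt_window[1], 3),
            "charge": row.charge,
            "composition": str(row.composition) if row.composition else "",
            "evidence": row.evidence,
            "abundance": row.abundance,
        }
        for i in range(topk):
            if i < len(row.candidates):
                g, s = row.candidates[i]
                rec[f"top{i + 1}"] = serialize(g)
                rec[f"top{i + 1}_score"] = round(s, 4)
            else:
                rec[f"top{i + 1}"] = ""
                rec[f"top{i + 1}_score"] = np.nan
        records.append(rec)
    return pd.DataFrame(records)
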