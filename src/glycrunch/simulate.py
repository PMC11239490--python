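"""In-silico glycan libraries and LC-MS/MS spectra.

The generator grows glycan libraries by biosynthetically plausible
single-monosaccharide additions from class-specific cores (a reduced GalNAc for
O-glycans, the chitobiose-mannose core for N-glycans, glucose for free
oligosaccharides) and simulates MS2 spectra whose peaks are the theoretical
fragment m/z values of the generating glycan — intensities decaying
exponentially with cleavage count, optional m/z jitter, random fragment
drop-out and uniform decoy noise peaks. Precursor m/z is the exact ion m/z of
the intact glycan (before jitter) and retention times follow a per-glycan
Gaussian, so grouping, annotation and training are all testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentIon, enumerate_fragments
from .glycans import GlycanGraph, serialize
from .masses import IonSpec, glycan_mass, ion_mz
from .model.training import featurize, stack_features
from .spectra import (
    MZ_MIN,
    MZ_MAX,
    Spectrum,
    bin_spectrum,
    default_meta,
    normalize_intensities,
)

__all__ = [
    "SimParams",
    "generate_library",
    "simulate_spectrum",
    "simulate_run",
    "make_dataset",
    "EXTENSION_RULES",
    "CORES",
]

# parent residue -> possible (child residue, linkage) additions, per glycan class
EXTENSION_RULES: dict[str, dict[str, list[tuple[str, str]]]] = {
    "O": {
        "GalNAc": [("Gal", "β1-3"), ("GlcNAc", "β1-6"), ("GlcNAc", "β1-3"), ("Neu5Ac", "α2-6")],
        "Gal": [("GlcNAc", "β1-3"), ("Neu5Ac", "α2-3"), ("Neu5Gc", "α2-3"), ("Fuc", "α1-2")],
        "GlcNAc": [("Gal", "β1-4"), ("Gal", "β1-3"), ("Fuc", "α1-3")],
    },
    "N": {
        "GlcNAc": [("Gal", "β1-4"), ("Fuc", "α1-6"), ("Fuc", "α1-3")],
        "Man": [("Man", "α1-3"), ("Man", "α1-6"), ("GlcNAc", "β1-2")],
        "Gal": [("Neu5Ac", "α2-6"), ("Neu5Ac", "α2-3")],
    },
    "free": {
        "Glc": [("Gal", "β1-4")],
        "Gal": [("GlcNAc", "β1-3"), ("Fuc", "α1-2"), ("Neu5Ac", "α2-3"), ("Neu5Ac", "α2-6")],
        "GlcNAc": [("Gal", "β1-4"), ("Gal", "β1-3"), ("Fuc", "α1-3"), ("Fuc", "α1-4")],
    },
}

CORES: dict[str, tuple[str, bool]] = {
    "O": ("GalNAc", True),  # reductive beta-elimination leaves an alditol
    "N": ("Manβ1-4GlcNAcβ1-4GlcNAc", False),
    "free": ("Glc", True),
}


def _add_child(g: GlycanGraph, node: int, child_label: str, linkage: str) -> GlycanGraph:
    return GlycanGraph(
        list(g.labels) + [child_label],
        list(g.parents) + [node],
        list(g.linkages) + [linkage],
        reduced=g.reduced,
    )


def generate_library(
    n: int, glycan_class: str = "O", rng: np.random.Generator | int | None = None,
    max_nodes: int = 8,
) -> list[GlycanGraph]:
    """Grow ``n`` distinct structures from the class core by random
    biosynthetically plausible single-residue additions (deterministic per
    seed). Two children never share an attachment position on one residue."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rules = EXTENSION_RULES[glycan_class]
    core_str, reduced = CORES[glycan_class]
    from .glycans import parse_iupac

    core = parse_iupac(core_str, reduced=reduced)
    library: list[GlycanGraph] = [core]
    seen = {core.canonical}
    attempts = 0
    while len(library) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError("library generation failed to find enough structures")
        g = library[rng.integers(len(library))]
        if g.n_nodes >= max_nodes:
            continue
        node = int(rng.integers(g.n_nodes))
        base = g.labels[node].rstrip("123456789SP")
        options = rules.get(base, [])
        if not options:
            continue
        child, linkage = options[rng.integers(len(options))]
        taken = {g.linkages[c][-1] for c in g.children(node)}
        if linkage[-1] in taken:
            continue
        new = _add_child(g, node, child, linkage)
        if new.canonical not in seen:
            seen.add(new.canonical)
            library.append(new)
    return library[:n]


# ---------------------------------------------------------------------------
# spectrum simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """Noise and intensity model for simulated MS2 spectra."""

    n_noise_peaks: int = 15
    noise_intensity_frac: float = 0.2
    mz_jitter_sd: float = 0.02  # Da
    fragment_keep_prob: float = 0.8
    intensity_model: str = "exponential"  # or "uniform"
    decay_rate: float = 1.2  # per cleavage event, exponential model
    rt_sd: float = 0.05  # minutes
    max_charge: int = 1
    precursor_charge: int = 1
    max_cleavages: int = 2
    allow_cross_ring: bool = False

    def __post_init__(self):
        if not 0 <= self.fragment_keep_prob <= 1:
            raise ValueError("fragment_keep_prob must lie in [0, 1]")
        if self.mz_jitter_sd < 0 or self.rt_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def theoretical_fragments(g: GlycanGraph, p: SimParams, mode: str = "negative") -> list[FragmentIon]:
    ions = [IonSpec(mode, None, z) for z in range(1, p.max_charge + 1)]
    return enumerate_fragments(
        g, ions=ions, max_cleavages=p.max_cleavages, allow_cross_ring=p.allow_cross_ring
    )


def simulate_spectrum(
    g: GlycanGraph,
    p: SimParams,
    rng: np.random.Generator | int | None = None,
    mode: str = "negative",
    rt_mean: float | None = None,
    scan_id: str = "",
    return_provenance: bool = False,
):
    """Simulate one MS2 spectrum of a glycan.

    Peaks are theoretical fragment m/z values (kept with
    ``fragment_keep_prob``, jittered by ``mz_jitter_sd``) plus uniform decoy
    peaks; intensities decay exponentially with the number of cleavage events
    (plus a half-event per global modification). With
    ``return_provenance=True`` also returns, per peak, the set of generating
    fragments (None for decoys) — fragments of identical m/z merge into one
    peak and are all recorded as its generators.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fragments = theoretical_fragments(g, p, mode)
    # merge fragments of (numerically) identical m/z into single peaks
    by_mz: dict[float, list[FragmentIon]] = {}
    for f in fragments:
        by_mz.setdefault(round(f.theo_mz, 9), []).append(f)

    mzs, intens, provenance = [], [], []
    for mz, gens in sorted(by_mz.items()):
        if rng.random() > p.fragment_keep_prob:
            continue
        if p.intensity_model == "exponential":
            events = min(len(f.cleavages) + 0.5 * len(f.global_mods) for f in gens)
            inten = float(np.exp(-p.decay_rate * events) * rng.uniform(0.5, 1.0))
        else:
            inten = float(rng.uniform(0.1, 1.0))
        mzs.append(mz + (rng.normal(0, p.mz_jitter_sd) if p.mz_jitter_sd > 0 else 0.0))
        intens.append(inten)
        provenance.append(gens)

    precursor = ion_mz(glycan_mass(g), IonSpec(mode, None, p.precursor_charge))
    if p.n_noise_peaks > 0:
        base = float(np.mean(intens)) if intens else 1.0
        hi = min(max(precursor * 1.05, MZ_MIN + 10), MZ_MAX)
        for _ in range(p.n_noise_peaks):
            mzs.append(float(rng.uniform(MZ_MIN, hi)))
            intens.append(base * p.noise_intensity_frac * float(rng.uniform(0.1, 1.0)))
            provenance.append(None)

    order = np.argsort(mzs, kind="stable")
    peaks = np.column_stack([np.asarray(mzs)[order], np.asarray(intens)[order]])
    provenance = [provenance[i] for i in order]
    if rt_mean is None:
        rt_mean = float(rng.uniform(3.0, 25.0))
    rt = max(2.0, float(rng.normal(rt_mean, p.rt_sd)))
    meta = default_meta(ion_mode=mode, modification="reduced" if g.reduced else "native")
    spectrum = Spectrum(
        peaks=peaks,
        precursor_mz=precursor,
        rt=rt,
        precursor_intensity=float(rng.uniform(1e5, 1e7)),
        scan_id=scan_id,
        meta=meta,
    )
    if return_provenance:
        return spectrum, provenance
    return spectrum


def simulate_run(
    library: list[GlycanGraph],
    p: SimParams,
    rng: np.random.Generator | int | None = None,
    replicates: int = 3,
    mode: str = "negative",
) -> tuple[list[Spectrum], list[str]]:
    """One simulated LC-MS/MS run: ``replicates`` spectra per library glycan on
    a shared retention-time axis. Returns (spectra, generating canonical
    strings aligned with spectra)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rt_means = {serialize(g): float(rng.uniform(3.0, 25.0)) for g in library}
    spectra, truths = [], []
    i = 0
    for g in library:
        key = serialize(g)
        for _ in range(replicates):
            spectra.append(
                simulate_spectrum(g, p, rng, mode=mode, rt_mean=rt_means[key], scan_id=f"scan{i}")
            )
            truths.append(key)
            i += 1
    return spectra, truths


# ---------------------------------------------------------------------------
# datasets for training
# ---------------------------------------------------------------------------

def make_dataset(
    library: list[GlycanGraph],
    spectra_per_glycan: int,
    p: SimParams,
    rng: np.random.Generator | int | None = None,
    test_frac: float = 0.2,
    mode: str = "negative",
) -> dict:
    """Simulated training corpus with a sample-level train/test split.

    Each replicate index forms one pseudo-sample (a simulated run containing
    one spectrum per glycan on a shared retention-time axis); whole
    pseudo-samples are assigned to train or test so that no sample spans the
    split. Returns feature arrays, integer labels, the class library, index
    arrays and a per-class balance report."""
    if not library:
        raise ValueError("library must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = [serialize(g) for g in library]
    rt_means = {lbl: float(rng.uniform(3.0, 25.0)) for lbl in labels}
    feats, y, sample_ids = [], [], []
    for sample in range(spectra_per_glycan):
        for ci, g in enumerate(library):
            s = simulate_spectrum(g, p, rng, mode=mode, rt_mean=rt_means[labels[ci]],
                                  scan_id=f"s{sample}g{ci}")
            feats.append(featurize(bin_spectrum(normalize_intensities(s))))
            y.append(ci)
            sample_ids.append(sample)
    data = stack_features(feats)
    data["y"] = np.asarray(y, dtype=np.int64)
    data["sample_id"] = np.asarray(sample_ids)
    n_test = max(1, int(round(test_frac * spectra_per_glycan)))
    test_samples = set(rng.choice(spectra_per_glycan, size=n_test, replace=False).tolist())
    mask = np.array([sid in test_samples for sid in sample_ids])
    data["test_idx"] = np.nonzero(mask)[0]
    data["train_idx"] = np.nonzero(~mask)[0]
    data["labels"] = labels
    report = pd.DataFrame(
        {
            "glycan": labels,
            "train": [int(((data["y"] == i) & ~mask).sum()) for i in range(len(labels))],
            "test": [int(((data["y"] == i) & mask).sum()) for i in range(len(labels))],
        }
    )
    data["report"] = report
    return data
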