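"""LC-MS/MS spectrum ingestion, normalization and binning.

MS2 spectra are reduced to a fixed-length representation for the classifier:
total-intensity-normalized peak intensities summed into 2,048 equal m/z windows
spanning [39.714, 3000), plus one m/z "remainder" per bin (the offset of the
bin's highest-intensity peak from the left bin edge), which preserves exact
peak location despite the ~1.45 Da nominal bin width. Retention times are
normalized by the sample's maximum retention time, floored at 30 minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "BinnedSpectrum",
    "MZ_MIN",
    "MZ_MAX",
    "N_BINS",
    "BIN_WIDTH",
    "GLYCAN_CLASSES",
    "ION_MODES",
    "TRAPS",
    "LC_TYPES",
    "MODIFICATIONS",
    "default_meta",
    "load_spectra",
    "normalize_intensities",
    "bin_spectrum",
    "normalize_rt",
    "average_spectra",
    "write_tsv",
]

MZ_MIN = 39.714
MZ_MAX = 3000.0
N_BINS = 2048
BIN_WIDTH = (MZ_MAX - MZ_MIN) / N_BINS

RT_NOISE_CUTOFF_MIN = 2.0
MAX_PEAKS = 1000
RT_NORM_FLOOR_MIN = 30.0

# categorical codebooks for the embedded metadata inputs
GLYCAN_CLASSES = {"O": 0, "N": 1, "free": 2, "lipid": 3, "other": 4}
ION_MODES = {"negative": 0, "positive": 1}
TRAPS = {"linear": 0, "orbitrap": 1, "amazon": 2, "qtof": 3, "other": 4}
LC_TYPES = {"PGC": 0, "C18": 1, "HILIC": 2, "other": 3}
MODIFICATIONS = {"reduced": 0, "native": 1, "permethylated": 2, "2AB": 3, "other": 4}

META_FIELDS = ("glycan_class", "ion_mode", "trap", "lc_type", "modification")


def default_meta(
    glycan_class: str = "O",
    ion_mode: str = "negative",
    trap: str = "linear",
    lc_type: str = "PGC",
    modification: str = "reduced",
) -> dict[str, int]:
    return {
        "glycan_class": GLYCAN_CLASSES[glycan_class],
        "ion_mode": ION_MODES[ion_mode],
        "trap": TRAPS[trap],
        "lc_type": LC_TYPES[lc_type],
        "modification": MODIFICATIONS[modification],
    }


@dataclass
class Spectrum:
    """One MS2 scan: peak list plus precursor metadata."""

    peaks: np.ndarray  # (n, 2) array of (m/z, intensity), sorted by m/z
    precursor_mz: float
    rt: float | None = None  # minutes
    precursor_intensity: float | None = None
    scan_id: str = ""
    meta: dict[str, int] = field(default_factory=default_meta)

    def __post_init__(self):
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if np.any(peaks[:, 1] < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]
        if len(self.peaks) > MAX_PEAKS:
            keep = np.argsort(self.peaks[:, 1], kind="stable")[-MAX_PEAKS:]
            self.peaks = self.peaks[np.sort(keep)]

    @property
    def total_intensity(self) -> float:
        return float(self.peaks[:, 1].sum()) if len(self.peaks) else 0.0


@dataclass
class BinnedSpectrum:
    """Fixed-length model input: binned intensities + per-bin m/z remainders."""

    intensities: np.ndarray  # (N_BINS,)
    remainders: np.ndarray  # (N_BINS,), Da offsets into each bin
    rt_norm: float
    precursor_mz: float
    meta: dict[str, int] = field(default_factory=default_meta)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("scan_id", "precursor_mz", "rt_min", "mz", "intensity")


def _load_tsv(path: Path, meta: dict[str, int]) -> list[Spectrum]:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak-list TSV {path} is missing columns {missing}")
    out = []
    for scan_id, grp in df.groupby("scan_id", sort=True):
        rt = grp["rt_min"].iloc[0]
        rt = None if pd.isna(rt) else float(rt)
        prec_int = None
        if "precursor_intensity" in grp.columns and not pd.isna(grp["precursor_intensity"].iloc[0]):
            prec_int = float(grp["precursor_intensity"].iloc[0])
        out.append(
            Spectrum(
                peaks=grp[["mz", "intensity"]].to_numpy(float),
                precursor_mz=float(grp["precursor_mz"].iloc[0]),
                rt=rt,
                precursor_intensity=prec_int,
                scan_id=str(scan_id),
                meta=dict(meta),
            )
        )
    return out


_MS_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(array_el) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (base64, optional zlib, 32/64-bit)."""
    import base64
    import zlib

    dtype = np.float64
    compressed = False
    for cv in array_el.iter(f"{_MS_NS}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = np.float32
        elif acc == "MS:1000523":
            dtype = np.float64
        elif acc == "MS:1000574":
            compressed = True
    binary = array_el.findtext(f"{_MS_NS}binary") or ""
    raw = base64.b64decode(binary)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)


def _load_mzml_file(path: Path, meta: dict[str, int]) -> list[Spectrum]:
    """Minimal namespace-aware mzML reader for centroided MS2 spectra.

    Covers the subset written by msconvert that the pipeline needs: ms level,
    scan start time (minute/second units), selected ion m/z and intensity, and
    base64/zlib-encoded 32- or 64-bit peak arrays.
    """
    from lxml import etree

    out = []
    for _, spec in etree.iterparse(str(path), tag=f"{_MS_NS}spectrum"):
        params = {
            cv.get("accession"): cv
            for cv in spec.iter(f"{_MS_NS}cvParam")
        }
        level = params.get("MS:1000511")
        if level is None or int(level.get("value", 0)) != 2:
            spec.clear()
            continue
        prec_el = params.get("MS:1000744")
        if prec_el is None:
            spec.clear()
            continue
        rt = None
        rt_el = params.get("MS:1000016")
        if rt_el is not None:
            rt = float(rt_el.get("value"))
            unit = (rt_el.get("unitName") or "minute").lower()
            if "second" in unit:
                rt /= 60.0
        prec_int_el = params.get("MS:1000042")
        mz = inten = None
        for arr in spec.iter(f"{_MS_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in arr.iter(f"{_MS_NS}cvParam")}
            if "MS:1000514" in accs:
                mz = _decode_binary_array(arr)
            elif "MS:1000515" in accs:
                inten = _decode_binary_array(arr)
        if mz is None or inten is None or len(mz) != len(inten):
            spec.clear()
            continue
        out.append(
            Spectrum(
                peaks=np.column_stack([mz, inten]),
                precursor_mz=float(prec_el.get("value")),
                rt=rt,
                precursor_intensity=(
                    float(prec_int_el.get("value")) if prec_int_el is not None else None
                ),
                scan_id=str(spec.get("id", "")),
                meta=dict(meta),
            )
        )
        spec.clear()
    return out


def _load_mzxml_file(path: Path, meta: dict[str, int]) -> list[Spectrum]:
    from pyteomics import mzxml

    out = []
    with mzxml.read(str(path)) as reader:
        for scan in reader:
            if int(scan.get("msLevel", 0)) != 2:
                continue
            rt = scan.get("retentionTime")
            prec = scan["precursorMz"][0]
            out.append(
                Spectrum(
                    peaks=np.column_stack([scan["m/z array"], scan["intensity array"]]),
                    precursor_mz=float(prec["precursorMz"]),
                    rt=None if rt is None else float(rt),
                    precursor_intensity=prec.get("precursorIntensity"),
                    scan_id=str(scan.get("num", "")),
                    meta=dict(meta),
                )
            )
    return out


def load_spectra(
    path,
    meta: dict[str, int] | None = None,
    rt_cutoff: float = RT_NOISE_CUTOFF_MIN,
) -> list[Spectrum]:
    """Load MS2 spectra from mzML, mzXML or the fixture peak-list TSV.

    Per spectrum only the 1,000 highest-intensity peaks are retained; spectra
    eluting before ``rt_cutoff`` minutes are dropped as noise (spectra without
    a retention time are kept).
    """
    path = Path(path)
    meta = default_meta() if meta is None else meta
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt", ".csv"):
        spectra = _load_tsv(path, meta)
    elif suffix == ".mzml":
        spectra = _load_mzml_file(path, meta)
    elif suffix == ".mzxml":
        spectra = _load_mzxml_file(path, meta)
    else:
        raise ValueError(f"unsupported spectrum file format {path.suffix!r} for {path}")
    if not spectra:
        logger.warning("no MS2 spectra found in %s", path)
        return []
    kept = [s for s in spectra if s.rt is None or s.rt >= rt_cutoff]
    if len(kept) < len(spectra):
        logger.info("dropped %d early-eluting spectra (< %.1f min)", len(spectra) - len(kept), rt_cutoff)
    return kept


def write_tsv(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra in the fixture peak-list dialect (one row per peak)."""
    rows = []
    for i, s in enumerate(spectra):
        for mz, inten in s.peaks:
            rows.append(
                {
                    "scan_id": s.scan_id or f"scan{i}",
                    "precursor_mz": s.precursor_mz,
                    "rt_min": np.nan if s.rt is None else s.rt,
                    "mz": mz,
                    "intensity": inten,
                    "precursor_intensity": np.nan
                    if s.precursor_intensity is None
                    else s.precursor_intensity,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization and binning
# ---------------------------------------------------------------------------

def normalize_intensities(s: Spectrum) -> Spectrum:
    """Divide every peak intensity by the spectrum's total intensity."""
    total = s.total_intensity
    if total == 0:
        if len(s.peaks):
            logger.warning("spectrum %s has all-zero intensities", s.scan_id)
        return replace(s, peaks=s.peaks.copy())
    peaks = s.peaks.copy()
    peaks[:, 1] /= total
    return replace(s, peaks=peaks)


def normalize_rt(rt: float | None, max_rt: float) -> float:
    """rt / max(max_rt, 30); missing retention times map to zero."""
    if max_rt < 0:
        raise ValueError("max_rt must be non-negative")
    if rt is None:
        return 0.0
    if rt < 0:
        raise ValueError("negative retention time")
    return rt / max(max_rt, RT_NORM_FLOOR_MIN)


def bin_spectrum(s: Spectrum, max_rt: float = RT_NORM_FLOOR_MIN) -> BinnedSpectrum:
    """Bin a normalized spectrum into the fixed 2,048-window representation.

    Intensities are summed per half-open window [left, right); the remainder of
    a bin is the offset of its highest-intensity peak from the left edge.
    Peaks outside [39.714, 3000) are discarded (and counted in the log).
    """
    intensities = np.zeros(N_BINS)
    remainders = np.zeros(N_BINS)
    mz = s.peaks[:, 0]
    inten = s.peaks[:, 1]
    in_range = (mz >= MZ_MIN) & (mz < MZ_MAX)
    n_out = int((~in_range).sum())
    if n_out:
        logger.info("discarded %d out-of-range peaks in %s", n_out, s.scan_id)
    mz, inten = mz[in_range], inten[in_range]
    if len(mz):
        bins = np.floor((mz - MZ_MIN) / BIN_WIDTH).astype(int)
        np.add.at(intensities, bins, inten)
        # remainder from the highest-intensity peak of each bin
        order = np.lexsort((inten, bins))
        top = order[np.append(np.diff(bins[order]) != 0, True)]
        remainders[bins[top]] = mz[top] - (MZ_MIN + bins[top] * BIN_WIDTH)
    return BinnedSpectrum(
        intensities=intensities,
        remainders=remainders,
        rt_norm=normalize_rt(s.rt, max_rt),
        precursor_mz=s.precursor_mz,
        meta=dict(s.meta),
    )


def average_spectra(group: Sequence[Spectrum]) -> tuple[Spectrum, Spectrum]:
    """Robust (averaged, median) representative spectra of an isomer group.

    Operates on the 2,048-bin grid: member spectra are intensity-normalized and
    binned, then combined bin-wise (mean / element-wise median). Peak m/z in
    the output is reconstructed as left bin edge plus the mean (median) of the
    members' remainders. The precursor m/z is the median over members and the
    precursor intensity is summed for downstream abundance estimation.
    """
    if not group:
        raise ValueError("cannot average an empty spectrum group")
    binned = [bin_spectrum(normalize_intensities(s)) for s in group]
    inten = np.stack([b.intensities for b in binned])
    rem = np.stack([b.remainders for b in binned])
    present = inten > 0
    with np.errstate(invalid="ignore"):
        mean_rem = np.where(
            present.any(0), rem.sum(0, where=present) / np.maximum(present.sum(0), 1), 0.0
        )
    mean_int = inten.mean(0)
    med_int = np.median(inten, axis=0)

    def rebuild(intvec: np.ndarray, remvec: np.ndarray, rt, prec_int) -> Spectrum:
        nz = np.nonzero(intvec)[0]
        peaks = np.column_stack([MZ_MIN + nz * BIN_WIDTH + remvec[nz], intvec[nz]])
        return Spectrum(
            peaks=peaks,
            precursor_mz=float(np.median([s.precursor_mz for s in group])),
            rt=rt,
            precursor_intensity=prec_int,
            scan_id=group[0].scan_id,
            meta=dict(group[0].meta),
        )

    rts = [s.rt for s in group if s.rt is not None]
    rt = float(np.median(rts)) if rts else None
    prec_ints = [s.precursor_intensity for s in group if s.precursor_intensity is not None]
    total_prec = float(np.sum(prec_ints)) if prec_ints else None
    averaged = rebuild(mean_int, mean_rem, rt, total_prec)
    median = rebuild(med_int, mean_rem, rt, total_prec)
    return averaged, median
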