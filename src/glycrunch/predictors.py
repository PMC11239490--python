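"""Predictor interface: score a binned spectrum against a glycan library.

Two implementations are provided. :class:`CosineBaselinePredictor` compares the
binned spectrum against deterministic in-silico reference spectra of each
library glycan (cosine similarity, normalized to a probability vector) — a
training-free baseline that makes the whole inference pipeline testable.
:class:`NeuralPredictor` wraps the trained dilated residual classifier with
Platt-scaled calibration and test-time augmentation.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np

from .glycans import GlycanGraph, serialize
from .model.network import SpectrumClassifier
from .model.training import AugmentConfig, calibrate_and_predict
from .spectra import BinnedSpectrum, Spectrum, bin_spectrum, normalize_intensities

__all__ = ["Predictor", "CosineBaselinePredictor", "NeuralPredictor", "reference_vector"]


class Predictor(Protocol):
    """Anything that ranks library glycans for one binned spectrum."""

    labels: list[str]

    def predict(
        self, binned: BinnedSpectrum, k: int, rng: np.random.Generator
    ) -> list[tuple[str, float]]:
        """Top-k (canonical glycan string, score) pairs, scores summing <= 1."""
        ...


def reference_vector(
    g: GlycanGraph,
    mode: str = "negative",
    max_charge: int = 1,
    decay_rate: float = 1.2,
    allow_cross_ring: bool = False,
) -> np.ndarray:
    """Deterministic noiseless binned intensity vector of a glycan's
    theoretical fragment spectrum (intensity = exp(-decay * cleavage events))."""
    from .fragments import enumerate_fragments
    from .masses import IonSpec

    ions = [IonSpec(mode, None, z) for z in range(1, max_charge + 1)]
    frs = enumerate_fragments(g, ions=ions, allow_cross_ring=allow_cross_ring)
    by_mz: dict[float, float] = {}
    for f in frs:
        events = len(f.cleavages) + 0.5 * len(f.global_mods)
        inten = float(np.exp(-decay_rate * events))
        key = round(f.theo_mz, 9)
        by_mz[key] = max(by_mz.get(key, 0.0), inten)
    peaks = np.array(sorted(by_mz.items())) if by_mz else np.zeros((0, 2))
    s = Spectrum(peaks=peaks, precursor_mz=0.0, rt=None)
    return bin_spectrum(normalize_intensities(s)).intensities


class CosineBaselinePredictor:
    """Cosine similarity against simulated reference spectra of the library."""

    def __init__(
        self,
        library: list[GlycanGraph],
        mode: str = "negative",
        max_charge: int = 1,
        decay_rate: float = 1.2,
    ):
        if not library:
            raise ValueError("empty reference library")
        self.library = list(library)
        self.labels = [serialize(g) for g in library]
        refs = np.stack(
            [reference_vector(g, mode, max_charge, decay_rate) for g in library]
        )
        norms = np.linalg.norm(refs, axis=1, keepdims=True)
        self._refs = np.divide(refs, norms, out=np.zeros_like(refs), where=norms > 0)

    def predict(
        self, binned: BinnedSpectrum, k: int, rng: np.random.Generator | None = None
    ) -> list[tuple[str, float]]:
        v = binned.intensities
        norm = np.linalg.norm(v)
        if norm == 0:
            sims = np.full(len(self.labels), 1.0 / len(self.labels))
        else:
            sims = np.clip(self._refs @ (v / norm), 0.0, None)
        total = sims.sum()
        scores = sims / total if total > 0 else np.full_like(sims, 1.0 / len(sims))
        k = min(k, len(self.labels))
        top = np.argsort(-scores, kind="stable")[:k]
        return [(self.labels[i], float(scores[i])) for i in top]


class NeuralPredictor:
    """Trained classifier with calibration and test-time augmentation."""

    def __init__(
        self,
        model: SpectrumClassifier,
        labels: list[str],
        platt_factor: float = 1.15,
        tta_rounds: int = 5,
        acfg: AugmentConfig | None = None,
    ):
        if model.cfg.n_classes != len(labels):
            raise ValueError("label list does not match the model's class count")
        self.model = model
        self.labels = list(labels)
        self.platt_factor = platt_factor
        self.tta_rounds = tta_rounds
        self.acfg = acfg if acfg is not None else AugmentConfig()

    def predict(
        self, binned: BinnedSpectrum, k: int, rng: np.random.Generator | None = None
    ) -> list[tuple[str, float]]:
        return calibrate_and_predict(
            self.model,
            binned,
            self.labels,
            platt_factor=self.platt_factor,
            tta_rounds=self.tta_rounds,
            k=k,
            rng=rng,
            acfg=self.acfg,
        )
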