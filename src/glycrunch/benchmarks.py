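"""Desk-scale benchmark experiments used by tests and the acceptance script.

These bundle the package's own end-to-end checks: pairwise distance matrices
over a library, and the toy classification experiment (simulated corpus,
sample-level split, full architecture trained with and without the
glycan-distance losses, errors scored by structural distance to the truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glycans import (
    GlycanGraph,
    MotifVocabulary,
    composition_distance,
    structure_distance,
    to_composition,
)
from .model import ModelConfig, TrainConfig, build_model, train
from .model.training import _take
from .simulate import SimParams, generate_library, make_dataset

__all__ = ["distance_matrices", "ToyResult", "toy_classification_experiment"]


def distance_matrices(
    library: list[GlycanGraph], vocab: MotifVocabulary | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(structure, composition) cosine-distance matrices over a library."""
    if vocab is None:
        vocab = MotifVocabulary.from_glycans(library)
    n = len(library)
    comps = [to_composition(g) for g in library]
    d_struct = np.zeros((n, n))
    d_comp = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d_struct[i, j] = d_struct[j, i] = structure_distance(
                library[i], library[j], vocab
            )
            d_comp[i, j] = d_comp[j, i] = composition_distance(comps[i], comps[j])
    return d_struct, d_comp


@dataclass(frozen=True)
class ToyResult:
    accuracy: float
    n_errors: int
    mean_error_structure_distance: float
    n_test: int
    epochs_run: int
    baseline_accuracy: float


# Toy study conditions: 20 classes x 50 spectra with the default noise model.
# The corpus-scale training defaults (learning rate 1e-4, batch 256) are tuned
# to hundreds of thousands of spectra; at one thousand spectra they yield very
# few optimizer steps per epoch, so the toy runs use a higher learning rate and
# a smaller batch, chosen once for this problem size.
TOY_TRAIN = dict(lr=2e-3, batch_size=64, epochs=30, early_stop=25, lr_patience=10)


def _baseline_accuracy(library, data, test_idx) -> float:
    """Held-out accuracy of the training-free cosine baseline predictor."""
    from .predictors import CosineBaselinePredictor
    from .spectra import BIN_WIDTH, BinnedSpectrum, default_meta

    base = CosineBaselinePredictor(library)
    correct = 0
    for i in test_idx:
        binned = BinnedSpectrum(
            intensities=data["intensity"][i].astype(float),
            remainders=data["remainder"][i] * BIN_WIDTH,
            rt_norm=float(data["rt"][i]),
            precursor_mz=float(data["precursor"][i]),
            meta=default_meta(),
        )
        correct += base.predict(binned, 1)[0][0] == data["labels"][data["y"][i]]
    return correct / len(test_idx)


def toy_classification_experiment(
    seed: int = 1,
    n_classes: int = 20,
    spectra_per_class: int = 50,
    use_distance_losses: bool = True,
    params: SimParams | None = None,
    augment: bool = True,
) -> ToyResult:
    """Train the full classifier on a simulated corpus and score its errors.

    Trains with the standard spectrum augmentation by default and returns held-out
    top-1 accuracy, the mean structural distance between mispredicted and true
    glycans (0 when there are no errors) and the cosine-baseline accuracy on
    the same split.
    """
    from .model.training import AugmentConfig

    rng = np.random.default_rng(seed)
    library = generate_library(n_classes, "O", rng)
    data = make_dataset(library, spectra_per_class, params or SimParams(), rng)
    d_struct, d_comp = distance_matrices(library)
    model = build_model(ModelConfig(n_classes=n_classes), np.random.default_rng(seed))
    tcfg = TrainConfig(seed=seed, use_distance_losses=use_distance_losses, **TOY_TRAIN)
    acfg = AugmentConfig() if augment else None
    history = train(model, data, tcfg, acfg, d_struct, d_comp)
    logits = model.forward(_take(data, data["test_idx"]), train=False)
    pred = logits.argmax(1)
    truth = data["y"][data["test_idx"]]
    errors = [(int(t), int(p)) for t, p in zip(truth, pred) if t != p]
    mean_dist = (
        float(np.mean([d_struct[t, p] for t, p in errors])) if errors else 0.0
    )
    return ToyResult(
        accuracy=float((pred == truth).mean()),
        n_errors=len(errors),
        mean_error_structure_distance=mean_dist,
        n_test=len(truth),
        epochs_run=len(history["val_acc"]),
        baseline_accuracy=_baseline_accuracy(library, data, data["test_idx"]),
    )
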