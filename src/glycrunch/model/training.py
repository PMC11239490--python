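"""Training loop, data augmentation, calibration and top-k inference."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from ..spectra import BIN_WIDTH, MZ_MIN, MZ_MAX, BinnedSpectrum, META_FIELDS, Spectrum
from .losses import classification_loss, softmax
from .network import SpectrumClassifier
from .optim import AdamW, PlateauScheduler

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "augment",
    "augment_batch",
    "featurize",
    "stack_features",
    "train",
    "calibrate_and_predict",
]

ACETATE_SHIFT = 60.021130  # [M+OAc]- vs [M-H]-
SODIUM_SHIFT = 21.981944  # [M-2H+Na]- vs [M-H]-
_ADDUCT_SHIFTS = {"acetate": ACETATE_SHIFT, "sodium": SODIUM_SHIFT}


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    lr_patience: int = 4
    lr_factor: float = 0.2
    weight_decay: float = 2e-5
    batch_size: int = 256
    epochs: int = 200
    early_stop: int = 12
    label_smoothing: float = 0.1
    poly_epsilon: float = 1.0
    sharpness_aware: bool = False
    use_distance_losses: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.weight_decay, self.batch_size, self.epochs) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if not self.lr_patience < self.early_stop:
            raise ValueError("lr_patience must be smaller than early_stop")


@dataclass(frozen=True)
class AugmentConfig:
    """Spectrum-level augmentation rates (all probabilities in [0, 1])."""

    peak_drop_frac: float = 0.2
    intensity_jitter_sd: float = 0.1
    new_peak_rate: float = 3.0
    adducts: tuple[str, ...] = ("acetate", "sodium")
    adduct_prob: float = 0.1
    precursor_jitter: float = 0.5  # Da, uniform +-
    rt_jitter: float = 0.1  # relative, uniform +-

    def __post_init__(self):
        for p in (self.peak_drop_frac, self.adduct_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def featurize(binned: BinnedSpectrum) -> dict[str, np.ndarray]:
    """Model inputs for one binned spectrum (remainders scaled to bin units)."""
    return {
        "intensity": binned.intensities.astype(np.float32),
        "remainder": (binned.remainders / BIN_WIDTH).astype(np.float32),
        "precursor": np.float32(binned.precursor_mz),
        "rt": np.float32(binned.rt_norm),
        "cats": np.array([binned.meta[f] for f in META_FIELDS], dtype=np.int64),
    }


def stack_features(features: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    return {
        "intensity": np.stack([f["intensity"] for f in features]),
        "remainder": np.stack([f["remainder"] for f in features]),
        "precursor": np.array([f["precursor"] for f in features], dtype=np.float32),
        "rt": np.array([f["rt"] for f in features], dtype=np.float32),
        "cats": np.stack([f["cats"] for f in features]),
    }


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(s: Spectrum, acfg: AugmentConfig, rng: np.random.Generator) -> Spectrum:
    """Randomly perturb a raw spectrum: low-intensity peak removal, intensity
    jitter, new peak addition, precursor adduct/jitter and retention-time
    jitter. With all rates zero this is the identity; reproducible per seed."""
    peaks = s.peaks.copy()
    if len(peaks):
        if acfg.peak_drop_frac > 0:
            low = peaks[:, 1] < np.median(peaks[:, 1])
            drop = low & (rng.random(len(peaks)) < acfg.peak_drop_frac)
            peaks = peaks[~drop]
        if acfg.intensity_jitter_sd > 0 and len(peaks):
            peaks[:, 1] = np.clip(
                peaks[:, 1] * (1 + rng.normal(0, acfg.intensity_jitter_sd, len(peaks))), 0, None
            )
    if acfg.new_peak_rate > 0:
        n_new = rng.poisson(acfg.new_peak_rate)
        if n_new:
            hi = min(max(s.precursor_mz, MZ_MIN + 1), MZ_MAX)
            base = float(np.median(peaks[:, 1])) if len(peaks) else 1.0
            new = np.column_stack(
                [rng.uniform(MZ_MIN, hi, n_new), base * rng.uniform(0.1, 0.5, n_new)]
            )
            peaks = np.vstack([peaks, new]) if len(peaks) else new
    precursor = s.precursor_mz
    if acfg.precursor_jitter > 0:
        precursor += rng.uniform(-acfg.precursor_jitter, acfg.precursor_jitter)
    if acfg.adduct_prob > 0 and acfg.adducts and rng.random() < acfg.adduct_prob:
        precursor += _ADDUCT_SHIFTS[acfg.adducts[rng.integers(len(acfg.adducts))]]
    rt = s.rt
    if rt is not None and acfg.rt_jitter > 0:
        rt = max(0.0, rt * (1 + rng.uniform(-acfg.rt_jitter, acfg.rt_jitter)))
    return dc_replace(s, peaks=peaks, precursor_mz=precursor, rt=rt)


def augment_batch(
    batch: dict[str, np.ndarray], acfg: AugmentConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Binned-grid version of :func:`augment`, used for training batches and
    test-time augmentation."""
    inten = batch["intensity"].copy()
    b, n = inten.shape
    nz = inten > 0
    if acfg.peak_drop_frac > 0:
        mean_nz = np.where(nz.any(1), inten.sum(1) / np.maximum(nz.sum(1), 1), 0.0)
        low = nz & (inten < mean_nz[:, None])
        inten[low & (rng.random(inten.shape) < acfg.peak_drop_frac)] = 0.0
    if acfg.intensity_jitter_sd > 0:
        inten = np.clip(inten * (1 + rng.normal(0, acfg.intensity_jitter_sd, inten.shape)), 0, None)
    if acfg.new_peak_rate > 0:
        add = rng.random(inten.shape) < acfg.new_peak_rate / n
        base = np.where(nz.any(1), inten.max(1), 1.0)
        inten = inten + add * (0.1 * base[:, None] * rng.random(inten.shape))
    totals = inten.sum(1, keepdims=True)
    inten = np.divide(inten, totals, out=np.zeros_like(inten), where=totals > 0)

    precursor = batch["precursor"].copy()
    if acfg.precursor_jitter > 0:
        precursor = precursor + rng.uniform(-acfg.precursor_jitter, acfg.precursor_jitter, b)
    if acfg.adduct_prob > 0 and acfg.adducts:
        hit = rng.random(b) < acfg.adduct_prob
        shifts = np.array([_ADDUCT_SHIFTS[a] for a in acfg.adducts])
        precursor = precursor + hit * shifts[rng.integers(len(shifts), size=b)]
    rt = batch["rt"].copy()
    if acfg.rt_jitter > 0:
        rt = np.clip(rt * (1 + rng.uniform(-acfg.rt_jitter, acfg.rt_jitter, b)), 0, 1)
    return {
        "intensity": inten.astype(np.float32),
        "remainder": batch["remainder"],
        "precursor": precursor.astype(np.float32),
        "rt": rt.astype(np.float32),
        "cats": batch["cats"],
    }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _take(data: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {k: data[k][idx] for k in ("intensity", "remainder", "precursor", "rt", "cats")}


def _evaluate(
    model: SpectrumClassifier,
    data: dict[str, np.ndarray],
    idx: np.ndarray,
    tcfg: TrainConfig,
    d_struct,
    d_comp,
) -> tuple[float, float]:
    losses, correct = [], 0
    for start in range(0, len(idx), tcfg.batch_size):
        sl = idx[start : start + tcfg.batch_size]
        logits = model.forward(_take(data, sl), train=False)
        comps, _ = classification_loss(
            logits, data["y"][sl], d_struct, d_comp, tcfg.label_smoothing, tcfg.poly_epsilon
        )
        losses.append(comps["total"] * len(sl))
        correct += int((logits.argmax(1) == data["y"][sl]).sum())
    return float(np.sum(losses) / len(idx)), correct / len(idx)


def train(
    model: SpectrumClassifier,
    dataset: dict[str, np.ndarray],
    tcfg: TrainConfig,
    acfg: AugmentConfig | None = None,
    d_struct: np.ndarray | None = None,
    d_comp: np.ndarray | None = None,
) -> dict[str, list]:
    """Train the classifier; returns the per-epoch history.

    ``dataset`` carries feature arrays ('intensity', 'remainder', 'precursor',
    'rt', 'cats'), integer labels 'y' and index arrays 'train_idx'/'test_idx'
    from a sample-level split. The loss is PolyLoss (label smoothing 0.1,
    epsilon 1) plus, when enabled, the structure- and composition-distance
    terms. The learning rate drops to a fifth after ``lr_patience`` epochs
    without test-loss improvement; training stops after ``early_stop`` stale
    epochs and the best weights are restored.
    """
    train_idx = np.asarray(dataset["train_idx"])
    test_idx = np.asarray(dataset["test_idx"])
    if len(train_idx) == 0 or len(dataset["y"]) == 0:
        raise ValueError("empty training dataset")
    if len(np.unique(dataset["y"][train_idx])) < 2:
        raise ValueError("training data must contain at least two classes")
    if not tcfg.use_distance_losses:
        d_struct = d_comp = None

    rng = np.random.default_rng(tcfg.seed)
    model.set_dropout_rng(rng)
    opt = AdamW(model.params(), lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    sched = PlateauScheduler(
        opt, factor=tcfg.lr_factor, patience=tcfg.lr_patience, early_stop=tcfg.early_stop
    )
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "val_acc": [], "lr": []}
    best_state = model.state()
    best_loss = np.inf

    for epoch in range(tcfg.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), tcfg.batch_size):
            sl = order[start : start + tcfg.batch_size]
            batch = _take(dataset, sl)
            if acfg is not None:
                batch = augment_batch(batch, acfg, rng)
            model.zero_grad()
            logits = model.forward(batch, train=True)
            comps, dlogits = classification_loss(
                logits, dataset["y"][sl], d_struct, d_comp,
                tcfg.label_smoothing, tcfg.poly_epsilon,
            )
            model.backward(dlogits)
            opt.step()
            epoch_loss += comps["total"] * len(sl)
        val_loss, val_acc = _evaluate(model, dataset, test_idx, tcfg, d_struct, d_comp)
        history["train_loss"].append(epoch_loss / len(order))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        logger.info(
            "epoch %d train %.4f val %.4f acc %.3f", epoch, epoch_loss / len(order), val_loss, val_acc
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state()
        if sched.step(val_loss):
            break
    model.load_state(best_state)
    return history


# ---------------------------------------------------------------------------
# calibrated inference
# ---------------------------------------------------------------------------

def calibrate_and_predict(
    model: SpectrumClassifier,
    binned: BinnedSpectrum,
    labels: list[str],
    platt_factor: float = 1.15,
    tta_rounds: int = 5,
    k: int = 25,
    rng: np.random.Generator | None = None,
    acfg: AugmentConfig | None = None,
) -> list[tuple[str, float]]:
    """Calibrated top-k prediction with test-time augmentation.

    Logits are divided by the Platt scaling factor before the softmax (a
    monotone transform that never changes the arg-max of a single inference);
    probabilities are averaged over ``tta_rounds`` independently augmented
    passes.
    """
    if k > len(labels):
        logger.warning("requested top-%d of only %d classes; clipping", k, len(labels))
        k = len(labels)
    rng = np.random.default_rng() if rng is None else rng
    feats = stack_features([featurize(binned)] * max(1, tta_rounds))
    if acfg is not None and tta_rounds > 1:
        feats = augment_batch(feats, acfg, rng)
    logits = model.forward(feats, train=False)
    probs = softmax(logits / platt_factor).mean(axis=0)
    top = np.argsort(-probs, kind="stable")[:k]
    return [(labels[i], float(probs[i])) for i in top]
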