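"""Training losses: PolyLoss with label smoothing plus glycan-distance terms.

PolyLoss is cross-entropy plus epsilon times the complement of the target-class
probability (the leading polynomial correction term); label smoothing is
applied to the targets first. The two distance losses are the expected
structure / composition distance to the target glycan under the predicted class
distribution — an unsupervised penalty that makes confident but structurally
remote predictions expensive, so that residual errors stay close to the truth.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "distance_loss", "classification_loss"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def distance_loss(class_probs: np.ndarray, distance_vector: np.ndarray) -> float:
    """Expected distance under the predicted distribution, batch-averaged.

    ``class_probs`` are post-softmax probabilities, shape (C,) or (B, C);
    ``distance_vector`` holds per-class distances to the target(s) in [0, 1]
    with matching shape. Bounded by the distance bounds themselves.
    """
    p = np.atleast_2d(np.asarray(class_probs, dtype=float))
    d = np.atleast_2d(np.asarray(distance_vector, dtype=float))
    if p.shape != d.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {d.shape}")
    return float((p * d).sum(axis=-1).mean())


def classification_loss(
    logits: np.ndarray,
    targets: np.ndarray,
    d_struct: np.ndarray | None = None,
    d_comp: np.ndarray | None = None,
    label_smoothing: float = 0.1,
    poly_epsilon: float = 1.0,
) -> tuple[dict[str, float], np.ndarray]:
    """Total training loss and its gradient w.r.t. the logits.

    ``d_struct``/``d_comp`` are (C, C) distance matrices indexed
    [target, predicted]; pass ``None`` to drop a term (with all-zero distances
    the total reduces exactly to PolyLoss).

    Returns ``(components, dlogits)`` where components holds 'poly', 'struct',
    'comp' and 'total' (batch means).
    """
    b, c = logits.shape
    p = softmax(logits)
    q = np.full((b, c), label_smoothing / c)
    q[np.arange(b), targets] += 1.0 - label_smoothing

    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    ce = -(q * logp).sum(axis=1)
    s = (q * p).sum(axis=1)
    poly = ce + poly_epsilon * (1.0 - s)

    dlogits = (p - q) - poly_epsilon * p * (q - s[:, None])

    comps = {"poly": float(poly.mean())}
    for name, dmat in (("struct", d_struct), ("comp", d_comp)):
        if dmat is None:
            comps[name] = 0.0
            continue
        dvec = dmat[targets]  # (B, C) distances to each sample's target
        expected = (p * dvec).sum(axis=1)
        comps[name] = float(expected.mean())
        dlogits = dlogits + p * (dvec - expected[:, None])

    comps["total"] = comps["poly"] + comps["struct"] + comps["comp"]
    return comps, (dlogits / b).astype(logits.dtype)
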