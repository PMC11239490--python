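"""The dilated residual spectrum classifier.

Architecture: binned intensities and m/z remainders enter as a two-channel
signal through an initial convolution and six residual dilated convolutions
(dilations 1, 2, 4, 8, 16, 32), followed by max-pooling (kernel 20) and a fully
connected projection to a 1,024-dimensional trunk. Precursor m/z and normalized
retention time each pass through a linear layer, layer normalization and a
leaky ReLU into 24 dimensions; the five experimental-metadata categories
(glycan class, ion mode, trap, LC type, derivatization) are embedded into 24
dimensions each. All branches are concatenated and passed through two
fully-connected blocks (layer norm, leaky ReLU, dropout 0.2) and a final linear
layer producing one score per library glycan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (
    DTYPE,
    Conv1d,
    Dropout,
    Embedding,
    LayerNorm,
    LeakyReLU,
    Linear,
    MaxPool1d,
    Param,
)

__all__ = ["ModelConfig", "SpectrumClassifier", "build_model", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int
    n_bins: int = 2048
    conv_channels: int = 8
    kernel_size: int = 9
    dilations: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    pool_kernel: int = 20
    trunk_dim: int = 1024
    embed_dim: int = 24
    hidden_dims: tuple[int, ...] = (512, 256)
    dropout: float = 0.2
    cat_sizes: tuple[int, ...] = (5, 2, 5, 4, 5)
    precursor_scale: float = 3000.0
    # fixed input gain: total-intensity-normalized spectra have per-bin values
    # of order 1/n_peaks; the gain brings occupied bins to order one so the
    # convolution stack starts in a well-conditioned regime
    intensity_gain: float = 100.0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if min(
            self.n_bins, self.conv_channels, self.kernel_size, self.pool_kernel,
            self.trunk_dim, self.embed_dim, *self.hidden_dims, *self.dilations,
        ) <= 0:
            raise ValueError("all model dimensions must be positive")


class _ResBlock:
    """x + LeakyReLU(Conv(x)) with a fixed dilation."""

    def __init__(self, channels: int, kernel: int, dilation: int, rng):
        self.conv = Conv1d(channels, channels, kernel, dilation, rng)
        self.act = LeakyReLU()

    def forward(self, x, train=False):
        return x + self.act.forward(self.conv.forward(x, train), train)

    def backward(self, dy):
        return dy + self.conv.backward(self.act.backward(dy))

    def params(self):
        return self.conv.params()


class _ScalarBranch:
    """Linear -> LayerNorm -> LeakyReLU embedding of one scalar input.

    Biases are initialized to -w*u with u ~ U(0, 1): each feature w*(x - u)
    then changes sign inside the unit interval the scalar inputs live in,
    giving the branch a spread of piecewise-linear kinks over the data range
    from the start. (With zero biases every feature of w*x is proportional to
    x and the layer normalization would collapse the branch to sign(x).)
    """

    def __init__(self, dim: int, rng):
        self.lin = Linear(1, dim, rng)
        self.lin.b.value[...] = -self.lin.w.value[0] * rng.random(dim).astype(
            self.lin.b.value.dtype
        )
        self.ln = LayerNorm(dim)
        self.act = LeakyReLU()

    def forward(self, x, train=False):
        return self.act.forward(self.ln.forward(self.lin.forward(x[:, None], train), train), train)

    def backward(self, dy):
        self.lin.backward(self.ln.backward(self.act.backward(dy)))

    def params(self):
        return self.lin.params() + self.ln.params()


class SpectrumClassifier:
    """Forward/backward network over batches of featurized binned spectra.

    Batches are dicts with float32 arrays ``intensity`` and ``remainder`` of
    shape (B, n_bins), ``precursor`` and ``rt`` of shape (B,), and an int array
    ``cats`` of shape (B, 5).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        k = cfg.kernel_size
        self.conv0 = Conv1d(2, cfg.conv_channels, k, 1, rng)
        self.act0 = LeakyReLU()
        self.blocks = [_ResBlock(cfg.conv_channels, k, d, rng) for d in cfg.dilations]
        self.pool = MaxPool1d(cfg.pool_kernel)
        pooled = cfg.n_bins // cfg.pool_kernel
        self.trunk = Linear(cfg.conv_channels * pooled, cfg.trunk_dim, rng)
        # normalize the spectral trunk to the same per-feature scale as the
        # scalar/categorical branches, so the concatenation is balanced and
        # retention time / precursor inputs are not drowned out at init
        self.trunk_ln = LayerNorm(cfg.trunk_dim)
        self.trunk_act = LeakyReLU()
        self.prec_branch = _ScalarBranch(cfg.embed_dim, rng)
        self.rt_branch = _ScalarBranch(cfg.embed_dim, rng)
        self.embeddings = [Embedding(n, cfg.embed_dim, rng) for n in cfg.cat_sizes]
        concat_dim = cfg.trunk_dim + (2 + len(cfg.cat_sizes)) * cfg.embed_dim
        self.fcs, self.lns, self.acts, self.drops = [], [], [], []
        d_in = concat_dim
        for h in cfg.hidden_dims:
            self.fcs.append(Linear(d_in, h, rng))
            self.lns.append(LayerNorm(h))
            self.acts.append(LeakyReLU())
            self.drops.append(Dropout(cfg.dropout))
            d_in = h
        self.head = Linear(d_in, cfg.n_classes, rng)
        self._pooled = pooled

    # ------------------------------------------------------------------
    def set_dropout_rng(self, rng: np.random.Generator | None) -> None:
        for d in self.drops:
            d.rng = rng

    def forward(self, batch: dict, train: bool = False) -> np.ndarray:
        # channels-last layout: (batch, bins, 2)
        x = np.stack(
            [batch["intensity"] * self.cfg.intensity_gain, batch["remainder"]], axis=-1
        ).astype(DTYPE)
        h = self.act0.forward(self.conv0.forward(x, train), train)
        for blk in self.blocks:
            h = blk.forward(h, train)
        h = self.pool.forward(h, train)
        b = h.shape[0]
        h = h.reshape(b, -1)
        trunk = self.trunk_act.forward(
            self.trunk_ln.forward(self.trunk.forward(h, train), train), train
        )
        prec = self.prec_branch.forward(
            (batch["precursor"] / self.cfg.precursor_scale).astype(DTYPE), train
        )
        rt = self.rt_branch.forward(batch["rt"].astype(DTYPE), train)
        cats = [emb.forward(batch["cats"][:, i], train) for i, emb in enumerate(self.embeddings)]
        z = np.concatenate([trunk, prec, rt, *cats], axis=1).astype(DTYPE)
        self._split = [trunk.shape[1], prec.shape[1], rt.shape[1]] + [c.shape[1] for c in cats]
        for fc, ln, act, drop in zip(self.fcs, self.lns, self.acts, self.drops):
            z = drop.forward(act.forward(ln.forward(fc.forward(z, train), train), train), train)
        return self.head.forward(z, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits.astype(DTYPE))
        for fc, ln, act, drop in zip(
            reversed(self.fcs), reversed(self.lns), reversed(self.acts), reversed(self.drops)
        ):
            dz = fc.backward(ln.backward(act.backward(drop.backward(dz))))
        bounds = np.cumsum(self._split)
        dtrunk = dz[:, : bounds[0]]
        self.prec_branch.backward(dz[:, bounds[0] : bounds[1]])
        self.rt_branch.backward(dz[:, bounds[1] : bounds[2]])
        for i, emb in enumerate(self.embeddings):
            emb.backward(dz[:, bounds[2 + i] : bounds[3 + i]])
        dh = self.trunk.backward(self.trunk_ln.backward(self.trunk_act.backward(dtrunk)))
        b = dh.shape[0]
        dh = dh.reshape(b, self._pooled, self.cfg.conv_channels)
        dh = self.pool.backward(dh)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        self.conv0.backward(self.act0.backward(dh))

    def params(self) -> list[Param]:
        out = self.conv0.params()
        for blk in self.blocks:
            out += blk.params()
        out += self.trunk.params() + self.trunk_ln.params()
        out += self.prec_branch.params() + self.rt_branch.params()
        for emb in self.embeddings:
            out += emb.params()
        for fc, ln in zip(self.fcs, self.lns):
            out += fc.params() + ln.params()
        out += self.head.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


def build_model(cfg: ModelConfig, rng: np.random.Generator | int | None = None) -> SpectrumClassifier:
    """Construct a :class:`SpectrumClassifier` with He-initialized weights."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return SpectrumClassifier(cfg, rng)


def save_model(model: SpectrumClassifier, path, library: list[str] | None = None) -> None:
    """Portable checkpoint: weights + config (+ the class library strings)."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    meta = {"config": asdict(model.cfg), "library": library}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path) -> tuple[SpectrumClassifier, list[str] | None]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg_d = meta["config"]
    for key in ("dilations", "hidden_dims", "cat_sizes"):
        cfg_d[key] = tuple(cfg_d[key])
    model = build_model(ModelConfig(**cfg_d), rng=0)
    model.load_state([data[f"p{i}"] for i in range(len(model.params()))])
    return model, meta.get("library")
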