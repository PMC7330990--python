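"""Recurrent sequence models: peptide language model and affinity regressor.

Both models share one backbone — a learned token embedding feeding a single
weight-dropped LSTM layer (AWD-LSTM regularization: one dropout mask applied
to the recurrent weight matrix for an entire sequence, plus variational
embedding/input/output dropouts).  The language model adds a linear decoder
producing a next-token distribution at every position; the regressor replaces
it with a concat-pooling layer (last hidden state ++ max-over-time ++
mean-over-time, masked to the true sequence length) and two fully connected
layers ending in one unconstrained real output, interpreted in transformed
affinity (y) space.

The implementation is plain numpy with hand-written backpropagation; the
default model is small (1 layer, 64 hidden units, 50-dim embedding) and all
gradients are validated against finite differences in the test suite.
Dropout masks are drawn from an explicit ``numpy.random.Generator``, so every
forward/backward pass is reproducible given a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .peptide_data import PaddedBatch

__all__ = [
    "DropoutSpec",
    "ModelConfig",
    "PeptideLanguageModel",
    "AffinityRegressor",
    "concat_pool",
    "save_checkpoint",
    "load_checkpoint",
    "LAYER_GROUPS",
]


@dataclass(frozen=True)
class DropoutSpec:
    """Dropout rates of the AWD-LSTM backbone (all in [0, 1))."""

    embedding: float = 0.1    # drops whole vocabulary rows of the embedding
    input: float = 0.25       # variational dropout on embedded inputs
    weight_drop: float = 0.3  # on the hidden-to-hidden weight matrix
    output: float = 0.1       # variational dropout on LSTM outputs

    def validate(self) -> None:
        for name, rate in asdict(self).items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"dropout rate {name}={rate} outside [0, 1)")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the downsized peptide-scale configuration: one LSTM layer,
    64 hidden units, embedding dimension 50, vocabulary 22 (20 amino acids
    plus PAD and BOS).  The regression head is two fully connected layers
    3*hidden -> head_hidden -> 1.
    """

    vocab_size: int = 22
    embedding_dim: int = 50
    hidden_units: int = 64
    num_layers: int = 1
    dropout: DropoutSpec = field(default_factory=DropoutSpec)
    head_hidden: int = 64
    head_dropout: float = 0.1

    def validate(self) -> None:
        if self.num_layers != 1:
            raise ValueError(
                "only the single-layer peptide-scale variant is supported "
                f"(num_layers={self.num_layers})"
            )
        for name in ("vocab_size", "embedding_dim", "hidden_units", "head_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        self.dropout.validate()
        if not (0.0 <= self.head_dropout < 1.0):
            raise ValueError("head_dropout outside [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["dropout"] = DropoutSpec(**d["dropout"])
        return cls(**d)


#: Backbone parameter names shared between the LM and the regressor.
BACKBONE_PARAMS = ("emb", "lstm_Wx", "lstm_Wh", "lstm_b")

#: Layer groups, head first, for discriminative learning rates.
LAYER_GROUPS = {
    "head": None,  # filled per model: decoder or FC head
    "rnn": ("lstm_Wx", "lstm_Wh", "lstm_b"),
    "emb": ("emb",),
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def concat_pool(hidden_states: np.ndarray, length: int) -> np.ndarray:
    """Concat-pool a (T, H) state block over its first ``length`` positions.

    Returns ``concat(h_last, max-over-time, mean-over-time)`` of size 3H.
    PAD positions (beyond ``length``) never contribute.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if hidden_states.shape[0] < length:
        raise ValueError("fewer positions than length")
    valid = hidden_states[:length]
    return np.concatenate([valid[-1], valid.max(axis=0), valid.mean(axis=0)])


class _Backbone:
    """Embedding + single weight-dropped LSTM layer with manual backprop."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        E, H, V = cfg.embedding_dim, cfg.hidden_units, cfg.vocab_size
        k = 1.0 / np.sqrt(H)
        self.params = {
            "emb": rng.uniform(-0.1, 0.1, size=(V, E)),
            "lstm_Wx": rng.uniform(-k, k, size=(E, 4 * H)),
            "lstm_Wh": rng.uniform(-k, k, size=(H, 4 * H)),
            "lstm_b": np.zeros(4 * H),
        }
        # positive forget-gate bias stabilizes early training
        self.params["lstm_b"][H : 2 * H] = 1.0

    def forward(self, batch: PaddedBatch, train: bool, rng: np.random.Generator | None):
        cfg, p = self.cfg, self.params
        drop = cfg.dropout
        B, T = batch.indices.shape
        E, H = cfg.embedding_dim, cfg.hidden_units

        cache: dict = {"batch": batch, "train": train}
        if train and rng is None:
            raise ValueError("training-mode forward requires an rng")

        emb = p["emb"]
        if train and drop.embedding > 0:
            emb_mask = (rng.random((cfg.vocab_size, 1)) >= drop.embedding) / (
                1 - drop.embedding
            )
            emb = emb * emb_mask
            cache["emb_mask"] = emb_mask
        x = emb[batch.indices]  # (B, T, E)

        if train and drop.input > 0:
            in_mask = (rng.random((B, 1, E)) >= drop.input) / (1 - drop.input)
            x = x * in_mask
            cache["in_mask"] = in_mask
        cache["x"] = x

        Wh = p["lstm_Wh"]
        if train and drop.weight_drop > 0:
            wd_mask = (rng.random(Wh.shape) >= drop.weight_drop) / (
                1 - drop.weight_drop
            )
            Wh = Wh * wd_mask
            cache["wd_mask"] = wd_mask
        cache["Wh_used"] = Wh

        # gate layout: [input, forget, output | cell-candidate]; the three
        # sigmoid gates occupy one contiguous block
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates, cells, tanhs, hs, h_prevs, c_prevs = [], [], [], [], [], []
        xW = x.reshape(B * T, E) @ p["lstm_Wx"]
        xW = xW.reshape(B, T, 4 * H) + p["lstm_b"]
        for t in range(T):
            z = xW[:, t] + h @ Wh
            z[:, : 3 * H] = _sigmoid(z[:, : 3 * H])
            z[:, 3 * H :] = np.tanh(z[:, 3 * H :])
            i, f, o = z[:, :H], z[:, H : 2 * H], z[:, 2 * H : 3 * H]
            g = z[:, 3 * H :]
            h_prevs.append(h)
            c_prevs.append(c)
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates.append(z)
            cells.append(c)
            tanhs.append(tc)
            hs.append(h)
        h_seq = np.stack(hs, axis=1)  # (B, T, H)

        if train and drop.output > 0:
            out_mask = (rng.random((B, 1, H)) >= drop.output) / (1 - drop.output)
            h_drop = h_seq * out_mask
            cache["out_mask"] = out_mask
        else:
            h_drop = h_seq
        cache.update(
            gates=gates, cells=cells, tanhs=tanhs,
            h_prevs=h_prevs, c_prevs=c_prevs, h_seq=h_seq, h_drop=h_drop,
        )
        return cache

    def backward(self, cache: dict, dh_drop: np.ndarray) -> dict:
        """Backprop from gradients on the (dropped-out) LSTM output sequence."""
        cfg, p = self.cfg, self.params
        H = cfg.hidden_units
        batch: PaddedBatch = cache["batch"]
        B, T = batch.indices.shape

        if "out_mask" in cache:
            dh_seq = dh_drop * cache["out_mask"]
        else:
            dh_seq = dh_drop

        Wh_used = cache["Wh_used"]
        x = cache["x"]
        dWx = np.zeros_like(p["lstm_Wx"])
        dWh_used = np.zeros_like(p["lstm_Wh"])
        db = np.zeros_like(p["lstm_b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dz = np.empty((B, 4 * H))
        for t in range(T - 1, -1, -1):
            z = cache["gates"][t]
            i, f, o = z[:, :H], z[:, H : 2 * H], z[:, 2 * H : 3 * H]
            g = z[:, 3 * H :]
            tc = cache["tanhs"][t]
            c_prev = cache["c_prevs"][t]
            h_prev = cache["h_prevs"][t]
            dh = dh_seq[:, t] + dh_next
            dc = dc_next + dh * o * (1 - tc * tc)
            dz[:, :H] = dc * g          # d input gate
            dz[:, H : 2 * H] = dc * c_prev   # d forget gate
            dz[:, 2 * H : 3 * H] = dh * tc   # d output gate
            sig = z[:, : 3 * H]
            dz[:, : 3 * H] *= sig * (1 - sig)
            dz[:, 3 * H :] = dc * i * (1 - g * g)
            dc_next = dc * f
            dWx += x[:, t].T @ dz
            dWh_used += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ p["lstm_Wx"].T
            dh_next = dz @ Wh_used.T

        if "wd_mask" in cache:
            dWh = dWh_used * cache["wd_mask"]
        else:
            dWh = dWh_used

        if "in_mask" in cache:
            dx = dx * cache["in_mask"]
        demb = np.zeros_like(p["emb"])
        np.add.at(demb, batch.indices.ravel(), dx.reshape(-1, dx.shape[-1]))
        if "emb_mask" in cache:
            demb = demb * cache["emb_mask"]

        return {"emb": demb, "lstm_Wx": dWx, "lstm_Wh": dWh, "lstm_b": db}


class PeptideLanguageModel:
    """Next-token predictor over peptide sequences.

    At each position t the model emits a probability distribution over the
    vocabulary for the token at position t+1; positions past a sequence's
    true length carry no loss.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = _Backbone(cfg, rng)
        H, V = cfg.hidden_units, cfg.vocab_size
        k = 1.0 / np.sqrt(H)
        self.params = self.backbone.params
        self.params["dec_W"] = rng.uniform(-k, k, size=(H, V))
        self.params["dec_b"] = np.zeros(V)

    @property
    def layer_groups(self) -> dict[str, tuple[str, ...]]:
        return {"head": ("dec_W", "dec_b"), "rnn": LAYER_GROUPS["rnn"],
                "emb": LAYER_GROUPS["emb"]}

    def forward(self, batch: PaddedBatch, train: bool = False,
                rng: np.random.Generator | None = None):
        cache = self.backbone.forward(batch, train, rng)
        logits = cache["h_drop"] @ self.params["dec_W"] + self.params["dec_b"]
        cache["logits"] = logits
        return cache

    def predict_proba(self, batch: PaddedBatch) -> np.ndarray:
        """(B, T, V) next-token distributions (deterministic, no dropout)."""
        return _softmax(self.forward(batch)["logits"])

    @staticmethod
    def _target_mask(batch: PaddedBatch):
        """Positions t with a next token: t + 1 < length."""
        B, T = batch.indices.shape
        pos = np.arange(T)[None, :]
        mask = pos + 1 < batch.lengths[:, None]
        targets = np.zeros((B, T), dtype=np.int64)
        targets[:, :-1] = batch.indices[:, 1:]
        return mask, targets

    def loss_and_metrics(self, batch: PaddedBatch):
        """Mean next-token cross-entropy and argmax accuracy (eval mode)."""
        cache = self.forward(batch)
        probs = _softmax(cache["logits"])
        mask, targets = self._target_mask(batch)
        n = int(mask.sum())
        picked = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        ce = -np.log(np.maximum(picked, 1e-300))[mask].sum() / n
        acc = float((probs.argmax(axis=-1) == targets)[mask].sum() / n)
        return float(ce), acc

    def loss_and_grads(self, batch: PaddedBatch, train: bool = True,
                       rng: np.random.Generator | None = None):
        cache = self.forward(batch, train=train, rng=rng)
        probs = _softmax(cache["logits"])
        mask, targets = self._target_mask(batch)
        n = int(mask.sum())
        picked = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        loss = float(-np.log(np.maximum(picked, 1e-300))[mask].sum() / n)

        dlogits = probs.copy()
        B, T = batch.indices.shape
        rows = np.repeat(np.arange(B), T).reshape(B, T)
        cols = np.tile(np.arange(T), B).reshape(B, T)
        dlogits[rows, cols, targets] -= 1.0
        dlogits *= mask[..., None] / n

        grads = {
            "dec_W": np.einsum("bth,btv->hv", cache["h_drop"], dlogits),
            "dec_b": dlogits.sum(axis=(0, 1)),
        }
        dh_drop = dlogits @ self.params["dec_W"].T
        grads.update(self.backbone.backward(cache, dh_drop))
        return loss, grads


class AffinityRegressor:
    """Regression model: backbone + masked concat pooling + two FC layers.

    Output is one unconstrained real per peptide, interpreted in transformed
    affinity (y) space; clipping to [0, 1] happens only at reporting time.
    When ``pretrained`` backbone weights are given (from a language model),
    the embedding and recurrent layers start from them and the head is
    freshly initialized.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0,
                 pretrained: dict[str, np.ndarray] | None = None):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = _Backbone(cfg, rng)
        self.params = self.backbone.params
        H, Hd = cfg.hidden_units, cfg.head_hidden
        k1 = 1.0 / np.sqrt(3 * H)
        k2 = 1.0 / np.sqrt(Hd)
        self.params["fc1_W"] = rng.uniform(-k1, k1, size=(3 * H, Hd))
        self.params["fc1_b"] = np.zeros(Hd)
        self.params["fc2_W"] = rng.uniform(-k2, k2, size=(Hd, 1))
        self.params["fc2_b"] = np.zeros(1)
        if pretrained is not None:
            self.load_backbone(pretrained)

    def load_backbone(self, weights: dict[str, np.ndarray]) -> None:
        for name in BACKBONE_PARAMS:
            if name not in weights:
                raise ValueError(f"pretrained weights missing layer {name!r}")
            if weights[name].shape != self.params[name].shape:
                raise ValueError(
                    f"shape mismatch for layer {name!r}: pretrained "
                    f"{weights[name].shape} vs configured {self.params[name].shape}"
                )
            self.params[name] = weights[name].copy()

    def backbone_weights(self) -> dict[str, np.ndarray]:
        return {name: self.params[name].copy() for name in BACKBONE_PARAMS}

    @property
    def layer_groups(self) -> dict[str, tuple[str, ...]]:
        return {"head": ("fc1_W", "fc1_b", "fc2_W", "fc2_b"),
                "rnn": LAYER_GROUPS["rnn"], "emb": LAYER_GROUPS["emb"]}

    def _pool(self, cache: dict):
        """Masked concat pooling over the (dropped-out) output sequence."""
        batch: PaddedBatch = cache["batch"]
        h = cache["h_drop"]
        B, T, H = h.shape
        lengths = batch.lengths
        valid = np.arange(T)[None, :] < lengths[:, None]  # (B, T)
        h_last = h[np.arange(B), lengths - 1]
        h_neg = np.where(valid[..., None], h, -np.inf)
        argmax_t = h_neg.argmax(axis=1)  # (B, H)
        h_max = np.take_along_axis(h, argmax_t[:, None, :], axis=1)[:, 0, :]
        h_mean = (h * valid[..., None]).sum(axis=1) / lengths[:, None]
        cache["pool_valid"] = valid
        cache["pool_argmax"] = argmax_t
        return np.concatenate([h_last, h_max, h_mean], axis=1)  # (B, 3H)

    def forward(self, batch: PaddedBatch, train: bool = False,
                rng: np.random.Generator | None = None):
        p = self.params
        cache = self.backbone.forward(batch, train, rng)
        pooled = self._pool(cache)
        a1 = pooled @ p["fc1_W"] + p["fc1_b"]
        r1 = np.maximum(a1, 0.0)
        if train and self.cfg.head_dropout > 0:
            hd_mask = (rng.random(r1.shape) >= self.cfg.head_dropout) / (
                1 - self.cfg.head_dropout
            )
            r1d = r1 * hd_mask
            cache["hd_mask"] = hd_mask
        else:
            r1d = r1
        y = (r1d @ p["fc2_W"] + p["fc2_b"])[:, 0]
        cache.update(pooled=pooled, a1=a1, r1=r1, r1d=r1d, y=y)
        return cache

    def predict(self, batch: PaddedBatch) -> np.ndarray:
        """Deterministic per-peptide outputs in y-space (no dropout)."""
        return self.forward(batch)["y"]

    def loss_and_grads(self, batch: PaddedBatch, y_true: np.ndarray,
                       direction: np.ndarray, train: bool = True,
                       rng: np.random.Generator | None = None):
        from .affinity_targets import censored_residual

        p = self.params
        cache = self.forward(batch, train=train, rng=rng)
        r = censored_residual(cache["y"], y_true, direction)
        n = len(r)
        loss = float(np.mean(r * r))
        dy = (2.0 * r / n)[:, None]  # (B, 1)

        grads = {
            "fc2_W": cache["r1d"].T @ dy,
            "fc2_b": dy.sum(axis=0),
        }
        dr1d = dy @ p["fc2_W"].T
        if "hd_mask" in cache:
            dr1 = dr1d * cache["hd_mask"]
        else:
            dr1 = dr1d
        da1 = dr1 * (cache["a1"] > 0)
        grads["fc1_W"] = cache["pooled"].T @ da1
        grads["fc1_b"] = da1.sum(axis=0)
        dpooled = da1 @ p["fc1_W"].T

        batch_ = cache["batch"]
        B, T, H = cache["h_drop"].shape
        dlast = dpooled[:, :H]
        dmax = dpooled[:, H : 2 * H]
        dmean = dpooled[:, 2 * H :]
        dh = np.zeros((B, T, H))
        dh[np.arange(B), batch_.lengths - 1] += dlast
        np.add.at(
            dh,
            (np.arange(B)[:, None], cache["pool_argmax"], np.arange(H)[None, :]),
            dmax,
        )
        dh += (cache["pool_valid"][..., None] / batch_.lengths[:, None, None]) \
            * dmean[:, None, :]
        grads.update(self.backbone.backward(cache, dh))
        return loss, grads


def parameter_count(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


def save_checkpoint(path: str | Path, cfg: ModelConfig,
                    params: dict[str, np.ndarray]) -> None:
    """Write a self-describing archive: config JSON + named weight blocks."""
    meta = np.array(json.dumps(cfg.to_dict()))
    np.savez(path, __config__=meta, **params)


def load_checkpoint(path: str | Path):
    """Load a checkpoint, validating stored weight shapes against its config."""
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        params = {k: data[k].copy() for k in data.files if k != "__config__"}
    E, H, V = cfg.embedding_dim, cfg.hidden_units, cfg.vocab_size
    expected = {"emb": (V, E), "lstm_Wx": (E, 4 * H), "lstm_Wh": (H, 4 * H),
                "lstm_b": (4 * H,)}
    for name, shape in expected.items():
        if name in params and params[name].shape != shape:
            raise ValueError(
                f"checkpoint layer {name!r} has shape {params[name].shape}, "
                f"config implies {shape}"
            )
    return cfg, params
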