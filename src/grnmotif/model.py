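"""Transformer pair-classifier, implemented directly in NumPy.

Architecture (one pass over a GEM sequence of shape L x d_model, d_model = 2s):

1. sinusoidal positional encoding added to the input sub-vectors;
2. one transformer encoder layer: multi-head (default 2) scaled dot-product
   self-attention, residual + layer normalization, then a two-layer ReLU
   feed-forward network with residual + layer normalization;
3. average pooling over the L positions;
4. a two-layer ReLU classification head with sigmoid output.

Training minimizes binary cross-entropy with Adam.  Forward, backward and the
optimizer are written out explicitly; the analytic gradients are covered by a
finite-difference check in the test suite.

Two details of the architecture exist in both a standard and a "literal"
variant, selectable in :class:`ModelConfig`:

* attention logits are scaled by sqrt(d_head) by default, or by the window
  size s in literal mode;
* the positional-encoding exponent divisor is d_model by default, or s in
  literal mode;
* the second residual + layer-norm after the feed-forward network is applied
  by default and omitted in literal mode.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .gem import GEMTensor

LN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Hyperparameters; ``d_model`` is always ``2 * window``."""

    window: int = 100
    n_heads: int = 2
    d_ff: int | None = None  # defaults to 2 * d_model
    d_hidden: int | None = None  # classification-head width, defaults to d_model // 2
    dropout: float = 0.1
    n_encoder_layers: int = 1
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    use_positional: bool = True
    literal_scale: bool = False  # divide attention logits by s instead of sqrt(d_head)
    literal_pe: bool = False  # positional exponent divisor s instead of d_model
    literal_no_post_ln: bool = False  # omit residual+LN after the FFN

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_encoder_layers != 1:
            raise ValueError("only a single encoder layer is supported")
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model
        if self.d_hidden is None:
            self.d_hidden = max(self.d_model // 2, 8)

    @property
    def d_model(self) -> int:
        return 2 * self.window

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class ForwardTrace:
    """Intermediate activations of one sample's forward pass (eval mode)."""

    x_posi: np.ndarray  # (L, d_model)
    attn_weights: np.ndarray  # (n_heads, L, L)
    x_attention: np.ndarray  # (L, d_model), post attention + LN
    x_encoder: np.ndarray  # (L, d_model), encoder output
    x_average: np.ndarray  # (d_model,)
    prob: float


def positional_encoding(L: int, d: int, d_pe: int | None = None) -> np.ndarray:
    """Sinusoidal position matrix: sin on even channels, cos on odd.

    Entry (m, 2n) = sin(m / 10000**(2n / d_pe)) and entry (m, 2n+1) =
    cos(m / 10000**((2n+1) / d_pe)); ``d_pe`` defaults to ``d``.
    """
    if L < 1 or d < 2 or d % 2:
        raise ValueError("require L >= 1 and even d >= 2")
    d_pe = d if d_pe is None else d_pe
    pos = np.arange(L, dtype=np.float64)[:, None]
    chan = np.arange(d, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, chan / d_pe)
    pe = np.empty((L, d), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, scale: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """softmax(Q K^T / scale) V; returns (output, attention weights)."""
    if scale is None:
        scale = np.sqrt(Q.shape[-1])
    A = softmax(Q @ np.swapaxes(K, -1, -2) / scale)
    return A @ V, A


def sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
                    np.exp(np.clip(z, -500, 500)) / (1.0 + np.exp(np.clip(z, -500, 500))))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy, g, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


class MotifTransformer:
    """The pair classifier: parameters, forward pass, gradients, Adam state."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, H, dh = config.d_model, config.n_heads, config.d_head
        dff, dcls = config.d_ff, config.d_hidden
        p: dict[str, np.ndarray] = {
            "Wq": _glorot(rng, D, dh, (H, D, dh)),
            "Wk": _glorot(rng, D, dh, (H, D, dh)),
            "Wv": _glorot(rng, D, dh, (H, D, dh)),
            "ln1_g": np.ones(D),
            "ln1_b": np.zeros(D),
            "W1": _glorot(rng, D, dff, (D, dff)),
            "b1": np.zeros(dff),
            "W2": _glorot(rng, dff, D, (dff, D)),
            "b2": np.zeros(D),
            "ln2_g": np.ones(D),
            "ln2_b": np.zeros(D),
            "Wc1": _glorot(rng, D, dcls, (D, dcls)),
            "bc1": np.zeros(dcls),
            "Wc2": _glorot(rng, dcls, 1, (dcls, 1)),
            "bc2": np.zeros(1),
        }
        self.params = p
        self._pe_cache: dict[int, np.ndarray] = {}
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7919])
        )

    # ---------------------------------------------------------------- forward

    def _pe(self, L: int) -> np.ndarray:
        if L not in self._pe_cache:
            c = self.config
            d_pe = c.window if c.literal_pe else c.d_model
            self._pe_cache[L] = positional_encoding(L, c.d_model, d_pe)
        return self._pe_cache[L]

    def add_positional(self, seq: np.ndarray) -> np.ndarray:
        """x_posi = x + PE (elementwise; PE depends only on the shape)."""
        seq = np.asarray(seq, dtype=np.float64)
        if seq.shape[-1] != self.config.d_model:
            raise ValueError(
                f"sequence width {seq.shape[-1]} != d_model {self.config.d_model}"
            )
        if not self.config.use_positional:
            return seq
        return seq + self._pe(seq.shape[-2])

    def _attention_scale(self) -> float:
        c = self.config
        return float(c.window) if c.literal_scale else float(np.sqrt(c.d_head))

    def _forward(self, X: np.ndarray, training: bool):
        """Full forward on a batch (B, L, D); returns probs and a cache."""
        c, p = self.config, self.params
        Xp = self.add_positional(X)
        # multi-head self-attention, heads concatenated (no output projection)
        Q = np.einsum("bld,hde->hble", Xp, p["Wq"])
        K = np.einsum("bld,hde->hble", Xp, p["Wk"])
        V = np.einsum("bld,hde->hble", Xp, p["Wv"])
        O_h, A = scaled_dot_attention(Q, K, V, self._attention_scale())
        B, L = X.shape[0], X.shape[1]
        O = O_h.transpose(1, 2, 0, 3).reshape(B, L, c.d_model)
        if training and c.dropout > 0:
            mask1 = (
                self._dropout_rng.random(O.shape) >= c.dropout
            ) / (1.0 - c.dropout)
            O = O * mask1
        else:
            mask1 = None
        S1 = Xp + O
        X1, ln1_cache = _layer_norm(S1, p["ln1_g"], p["ln1_b"])
        Z = X1 @ p["W1"] + p["b1"]
        R = np.maximum(Z, 0.0)
        F = R @ p["W2"] + p["b2"]
        if training and c.dropout > 0:
            mask2 = (
                self._dropout_rng.random(F.shape) >= c.dropout
            ) / (1.0 - c.dropout)
            F = F * mask2
        else:
            mask2 = None
        if c.literal_no_post_ln:
            X2, ln2_cache = F, None
        else:
            X2, ln2_cache = _layer_norm(X1 + F, p["ln2_g"], p["ln2_b"])
        pooled = X2.mean(axis=1)
        Hc = np.maximum(pooled @ p["Wc1"] + p["bc1"], 0.0)
        logit = (Hc @ p["Wc2"] + p["bc2"])[:, 0]
        prob = sigmoid(logit)
        cache = dict(
            Xp=Xp, Q=Q, K=K, V=V, A=A, O_h=O_h, mask1=mask1,
            ln1_cache=ln1_cache, X1=X1, Z=Z, R=R, mask2=mask2,
            ln2_cache=ln2_cache, X2=X2, pooled=pooled, Hc=Hc, prob=prob,
        )
        return prob, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Classification probabilities for a batch (B, L, d_model)."""
        prob, _ = self._forward(np.asarray(X, dtype=np.float64), training=False)
        return prob

    def forward(self, pair: GEMTensor, trace: bool = False):
        """Probability for one encoded pair; optionally the full trace."""
        if pair.window != self.config.window:
            raise ValueError(
                f"model window {self.config.window} != tensor window {pair.window}"
            )
        prob, cache = self._forward(pair.seq[None], training=False)
        if not trace:
            return float(prob[0])
        return float(prob[0]), ForwardTrace(
            x_posi=cache["Xp"][0],
            attn_weights=cache["A"][:, 0],
            x_attention=cache["X1"][0],
            x_encoder=cache["X2"][0],
            x_average=cache["pooled"][0],
            prob=float(prob[0]),
        )

    def encoder_outputs(self, X: np.ndarray) -> np.ndarray:
        """Position-wise encoder outputs (B, L, d_model), eval mode."""
        _, cache = self._forward(np.asarray(X, dtype=np.float64), training=False)
        return cache["X2"]

    def head_probs(self, vecs: np.ndarray) -> np.ndarray:
        """Apply the trained classification head to arbitrary d_model vectors."""
        p = self.params
        Hc = np.maximum(vecs @ p["Wc1"] + p["bc1"], 0.0)
        return sigmoid((Hc @ p["Wc2"] + p["bc2"])[..., 0])

    # --------------------------------------------------------------- backward

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, training: bool = True):
        """Mean binary cross-entropy and gradients for every parameter."""
        c, p = self.config, self.params
        B, L, D = X.shape
        prob, cc = self._forward(X, training=training)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        g = {k: np.zeros_like(v) for k, v in p.items()}

        dlogit = (prob - y) / B  # (B,)
        g["Wc2"] = cc["Hc"].T @ dlogit[:, None]
        g["bc2"] = np.array([dlogit.sum()])
        dHc = dlogit[:, None] @ p["Wc2"].T
        dHc *= cc["Hc"] > 0
        g["Wc1"] = cc["pooled"].T @ dHc
        g["bc1"] = dHc.sum(axis=0)
        dpooled = dHc @ p["Wc1"].T
        dX2 = np.repeat(dpooled[:, None, :], L, axis=1) / L

        if c.literal_no_post_ln:
            dF = dX2
            dX1 = np.zeros_like(dX2)
        else:
            dS2, g["ln2_g"], g["ln2_b"] = _layer_norm_backward(
                dX2, p["ln2_g"], cc["ln2_cache"]
            )
            dF = dS2.copy()
            dX1 = dS2.copy()
        if cc["mask2"] is not None:
            dF = dF * cc["mask2"]
        g["W2"] = np.einsum("blf,bld->fd", cc["R"], dF)
        g["b2"] = dF.sum(axis=(0, 1))
        dR = dF @ p["W2"].T
        dZ = dR * (cc["Z"] > 0)
        g["W1"] = np.einsum("bld,blf->df", cc["X1"], dZ)
        g["b1"] = dZ.sum(axis=(0, 1))
        dX1 += dZ @ p["W1"].T

        dS1, g["ln1_g"], g["ln1_b"] = _layer_norm_backward(
            dX1, p["ln1_g"], cc["ln1_cache"]
        )
        dXp = dS1.copy()
        dO = dS1.copy()
        if cc["mask1"] is not None:
            dO = dO * cc["mask1"]
        dO_h = dO.reshape(B, L, c.n_heads, c.d_head).transpose(2, 0, 1, 3)

        A, Q, K, V = cc["A"], cc["Q"], cc["K"], cc["V"]
        dA = dO_h @ np.swapaxes(V, -1, -2)
        dV = np.swapaxes(A, -1, -2) @ dO_h
        dlogits = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        scale = self._attention_scale()
        dQ = dlogits @ K / scale
        dK = np.swapaxes(dlogits, -1, -2) @ Q / scale
        Xp = cc["Xp"]
        g["Wq"] = np.einsum("bld,hble->hde", Xp, dQ)
        g["Wk"] = np.einsum("bld,hble->hde", Xp, dK)
        g["Wv"] = np.einsum("bld,hble->hde", Xp, dV)
        dXp += np.einsum("hble,hde->bld", dQ, p["Wq"])
        dXp += np.einsum("hble,hde->bld", dK, p["Wk"])
        dXp += np.einsum("hble,hde->bld", dV, p["Wv"])
        return loss, g, dXp

    def adam_step(self, grads: dict, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        self._adam_t += 1
        t, lr = self._adam_t, self.config.lr
        for k, gk in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------ persistence

    def state_dict(self) -> dict:
        return copy.deepcopy(self.params)

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path, fingerprint: str = "") -> None:
        """Single-file checkpoint: weights + config + dataset fingerprint."""
        meta = json.dumps({"config": asdict(self.config), "fingerprint": fingerprint})
        np.savez(path, __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path, expect_window: int | None = None) -> "MotifTransformer":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            config = ModelConfig(**meta["config"])
            if expect_window is not None and config.window != expect_window:
                raise ValueError(
                    f"checkpoint window {config.window} != expected {expect_window}"
                )
            model = cls(config)
            model.load_state_dict({k: data[k] for k in model.params})
        return model
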