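"""Transformer encoder for per-timestep activity classification.

The network maps a ``T x C`` inertial window to ``T x K`` class logits
(sequence-to-sequence): built-in channel standardization with calibration
stored from the training data, a per-timestep linear projection C -> d_model,
an added learned position embedding ``P`` (T x d_model), ``L`` pre-norm
encoder blocks (multi-head self-attention and a position-wise feed-forward
network, each wrapped as ``x + Dropout(Sublayer(LayerNorm(x)))``), a final
layer norm, and a shared linear head applied at every timestep. The output
is raw logits; softmax only enters the training loss.

Attention per head follows ``softmax(Q K^T / sqrt(d_k)) V`` with learned
projections per head and a combining output projection. Projections carry
no bias terms. All dense weights are initialized from a truncated normal
(sd 0.02, truncated at +/-2 sd); biases start at zero, layer-norm gains at
one.

Everything is plain NumPy; gradients for training are computed by the
hand-written reverse pass in :mod:`harformer.training`, which consumes the
caches produced by :func:`forward_with_cache`.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.special import erf
from scipy.stats import truncnorm

from .datasets import SignalWindow, WindowDataset

__all__ = [
    "ModelConfig",
    "NormalizerState",
    "AttentionParams",
    "FFNParams",
    "EncoderBlockParams",
    "HARTransformerParams",
    "AttentionRecord",
    "fit_normalizer",
    "apply_normalizer",
    "scaled_dot_product_attention",
    "multi_head_attention",
    "position_wise_ffn",
    "encoder_block",
    "init_params",
    "forward",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_LN_EPS = 1e-6
_INIT_SD = 0.02
_INIT_TRUNC = 2.0  # truncation in units of sd


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the optimized full-scale settings: 300-step windows of 6
    channels, 18 classes, embedding size 128, feed-forward size 256,
    6 heads, 3 encoder blocks, dropout 0.1 throughout.
    """

    n_steps: int = 300
    n_channels: int = 6
    n_classes: int = 18
    d_model: int = 128
    d_ff: int = 256
    n_heads: int = 6
    n_layers: int = 3
    dropout_rate: float = 0.1
    attention_dropout_rate: float = 0.1
    activation: str = "gelu"

    def __post_init__(self) -> None:
        for name in ("n_steps", "n_channels", "n_classes", "d_model", "d_ff",
                     "n_heads", "n_layers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_model < self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} smaller than n_heads={self.n_heads}"
            )
        if self.activation not in ("gelu", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        for name in ("dropout_rate", "attention_dropout_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        """Per-head width ``d_k = floor(d_model / n_heads)``.

        Floor division keeps configurations like embedding 128 with 6 heads
        valid (d_k = 21, inner width 126), matching the convention of the
        usual framework attention layers; when d_model is divisible by
        n_heads this is exactly d_model / h.
        """
        return self.d_model // self.n_heads

    @property
    def attention_inner_dim(self) -> int:
        return self.head_dim * self.n_heads

    def to_dict(self) -> dict:
        return {
            "n_steps": self.n_steps, "n_channels": self.n_channels,
            "n_classes": self.n_classes, "d_model": self.d_model,
            "d_ff": self.d_ff, "n_heads": self.n_heads,
            "n_layers": self.n_layers, "dropout_rate": self.dropout_rate,
            "attention_dropout_rate": self.attention_dropout_rate,
            "activation": self.activation,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelConfig":
        return cls(**payload)


@dataclass
class NormalizerState:
    """Per-channel calibration: mean and sd pooled over training windows.

    The same stored state is applied at inference, so deployed inputs only
    need to be in base physical units (m/s^2, rad/s)."""

    mean: np.ndarray
    std: np.ndarray
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std < 0):
            raise ValueError("std entries must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def identity(cls, n_channels: int) -> "NormalizerState":
        return cls(np.zeros(n_channels), np.ones(n_channels))


def fit_normalizer(
    train: WindowDataset | np.ndarray, epsilon: float = 1e-6
) -> NormalizerState:
    """Per-channel mean/sd pooled over all training windows and timesteps."""
    if isinstance(train, WindowDataset):
        if len(train) == 0:
            raise ValueError("cannot fit a normalizer on an empty dataset")
        pooled = np.concatenate([w.values for w in train.windows], axis=0)
    else:
        pooled = np.asarray(train, dtype=float)
        if pooled.ndim == 3:
            pooled = pooled.reshape(-1, pooled.shape[-1])
        if pooled.size == 0:
            raise ValueError("cannot fit a normalizer on empty data")
    return NormalizerState(
        pooled.mean(axis=0), pooled.std(axis=0), epsilon=epsilon
    )


def apply_normalizer(
    state: NormalizerState, window: SignalWindow | np.ndarray
) -> np.ndarray:
    """``(x - mean_c) / (std_c + epsilon)`` elementwise; constant channels
    map to zero (the epsilon guard avoids division blow-up)."""
    x = window.values if isinstance(window, SignalWindow) else np.asarray(window, float)
    if x.shape[-1] != self_channels(state):
        raise ValueError(
            f"window has {x.shape[-1]} channels, normalizer has "
            f"{self_channels(state)}"
        )
    return (x - state.mean) / (state.std + state.epsilon)


def self_channels(state: NormalizerState) -> int:
    return state.mean.shape[0]


@dataclass
class AttentionParams:
    """Multi-head projection weights, stored stacked.

    ``w_query[:, i*d_k:(i+1)*d_k]`` is head ``i``'s query projection
    ``W_i^Q`` (likewise key/value); ``w_output`` combines the concatenated
    heads (``W^O``). No bias terms.
    """

    w_query: np.ndarray  # (d_model, n_heads * d_k)
    w_key: np.ndarray
    w_value: np.ndarray
    w_output: np.ndarray  # (n_heads * d_k, d_model)
    n_heads: int

    def head_slice(self, i: int) -> slice:
        d_k = self.w_query.shape[1] // self.n_heads
        return slice(i * d_k, (i + 1) * d_k)


@dataclass
class FFNParams:
    """Position-wise feed-forward weights: act(x W1 + b1) W2 + b2."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray


@dataclass
class EncoderBlockParams:
    ln1_gain: np.ndarray
    ln1_bias: np.ndarray
    attn: AttentionParams
    ln2_gain: np.ndarray
    ln2_bias: np.ndarray
    ffn: FFNParams


@dataclass
class HARTransformerParams:
    """All learnable tensors plus the (non-learnable) normalizer state."""

    config: ModelConfig
    normalizer: NormalizerState
    input_weight: np.ndarray  # (C, d_model)
    input_bias: np.ndarray  # (d_model,)
    position_embedding: np.ndarray  # (T, d_model)
    blocks: list[EncoderBlockParams]
    final_gain: np.ndarray
    final_bias: np.ndarray
    head_weight: np.ndarray  # (d_model, K)
    head_bias: np.ndarray  # (K,)

    def named_tensors(self) -> Iterator[tuple[str, np.ndarray]]:
        """Deterministic iteration over every trainable tensor."""
        yield "input.weight", self.input_weight
        yield "input.bias", self.input_bias
        yield "position_embedding", self.position_embedding
        for i, blk in enumerate(self.blocks):
            p = f"blocks.{i}."
            yield p + "ln1.gain", blk.ln1_gain
            yield p + "ln1.bias", blk.ln1_bias
            yield p + "attn.w_query", blk.attn.w_query
            yield p + "attn.w_key", blk.attn.w_key
            yield p + "attn.w_value", blk.attn.w_value
            yield p + "attn.w_output", blk.attn.w_output
            yield p + "ln2.gain", blk.ln2_gain
            yield p + "ln2.bias", blk.ln2_bias
            yield p + "ffn.w1", blk.ffn.w1
            yield p + "ffn.b1", blk.ffn.b1
            yield p + "ffn.w2", blk.ffn.w2
            yield p + "ffn.b2", blk.ffn.b2
        yield "final.gain", self.final_gain
        yield "final.bias", self.final_bias
        yield "head.weight", self.head_weight
        yield "head.bias", self.head_bias

    def copy(self) -> "HARTransformerParams":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class AttentionRecord:
    """One head's T x T softmax attention matrix from a forward pass."""

    layer: int
    head: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("attention matrix must be square")
        if np.any(m < -1e-9) or np.any(m > 1 + 1e-9):
            raise ValueError("attention weights must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-5):
            raise ValueError("attention rows must sum to 1")
        object.__setattr__(self, "matrix", m)


def count_parameters(params: HARTransformerParams) -> int:
    """Exact number of scalar learnables (normalizer excluded)."""
    return sum(int(a.size) for _, a in params.named_tensors())


# ---------------------------------------------------------------------------
# initialization


def _trunc_normal(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    return truncnorm.rvs(
        -_INIT_TRUNC, _INIT_TRUNC, loc=0.0, scale=_INIT_SD, size=shape,
        random_state=rng,
    )


def init_params(config: ModelConfig, seed: int) -> HARTransformerParams:
    """Fresh parameters: truncated-normal dense weights (sd 0.02, cut at
    +/-2 sd), zero biases, unit layer-norm gains, identity normalizer."""
    rng = np.random.default_rng(seed)
    d, t, c, k = config.d_model, config.n_steps, config.n_channels, config.n_classes
    blocks = []
    for _ in range(config.n_layers):
        blocks.append(
            EncoderBlockParams(
                ln1_gain=np.ones(d), ln1_bias=np.zeros(d),
                attn=AttentionParams(
                    w_query=_trunc_normal(rng, (d, config.attention_inner_dim)),
                    w_key=_trunc_normal(rng, (d, config.attention_inner_dim)),
                    w_value=_trunc_normal(rng, (d, config.attention_inner_dim)),
                    w_output=_trunc_normal(rng, (config.attention_inner_dim, d)),
                    n_heads=config.n_heads,
                ),
                ln2_gain=np.ones(d), ln2_bias=np.zeros(d),
                ffn=FFNParams(
                    w1=_trunc_normal(rng, (d, config.d_ff)),
                    b1=np.zeros(config.d_ff),
                    w2=_trunc_normal(rng, (config.d_ff, d)),
                    b2=np.zeros(d),
                ),
            )
        )
    return HARTransformerParams(
        config=config,
        normalizer=NormalizerState.identity(c),
        input_weight=_trunc_normal(rng, (c, d)),
        input_bias=np.zeros(d),
        position_embedding=_trunc_normal(rng, (t, d)),
        blocks=blocks,
        final_gain=np.ones(d), final_bias=np.zeros(d),
        head_weight=_trunc_normal(rng, (d, k)),
        head_bias=np.zeros(k),
    )


# ---------------------------------------------------------------------------
# functional pieces (batched over arbitrary leading axes)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / np.sqrt(
        2.0 * np.pi
    )


def _activation(x: np.ndarray, kind: str) -> np.ndarray:
    return _gelu(x) if kind == "gelu" else np.maximum(x, 0.0)


def _activation_grad(x: np.ndarray, kind: str) -> np.ndarray:
    return _gelu_grad(x) if kind == "gelu" else (x > 0).astype(float)


def _layer_norm(x: np.ndarray, gain: np.ndarray, bias: np.ndarray):
    mean = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mean) * inv
    return xhat * gain + bias, (xhat, inv)


def _layer_norm_backward(dy, cache, gain):
    xhat, inv = cache
    d = xhat.shape[-1]
    dgain = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbias = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gain
    dx = inv / d * (
        d * dxhat
        - dxhat.sum(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
    )
    return dx, dgain, dbias


def _dropout_mask(
    rng: np.random.Generator | None, rate: float, shape, training: bool
):
    if not training or rate <= 0.0:
        return None
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    return (rng.random(shape) >= rate) / (1.0 - rate)


def scaled_dot_product_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """``softmax(q k^T / sqrt(d_k)) v``; also returns the weight matrix.

    Accepts arbitrary leading batch axes; the last two axes are
    (sequence, feature).
    """
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("query and key feature sizes differ")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("key and value sequence lengths differ")
    scale = 1.0 / np.sqrt(q.shape[-1])
    weights = _softmax(q @ np.swapaxes(k, -1, -2) * scale)
    return weights @ v, weights


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    *lead, t, d = x.shape
    return x.reshape(*lead, t, n_heads, d // n_heads).swapaxes(-2, -3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    x = x.swapaxes(-2, -3)
    *lead, t, h, dk = x.shape
    return x.reshape(*lead, t, h * dk)


def multi_head_attention(
    x: np.ndarray,
    params: AttentionParams,
    attention_dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[AttentionRecord]]:
    """Self-attention: per-head projections of the same ``x`` as query, key
    and value; heads concatenated and mixed by ``w_output``.

    Returns the output and one :class:`AttentionRecord` per head (pre-dropout
    weights). Dropout acts on the attention weights only when ``training``.
    """
    x = np.asarray(x, dtype=float)
    d = params.w_query.shape[0]
    if x.shape[-1] != d:
        raise ValueError(f"input feature size {x.shape[-1]} != d_model {d}")
    if params.w_query.shape[1] % params.n_heads:
        raise ValueError(
            f"projection width {params.w_query.shape[1]} not divisible by "
            f"{params.n_heads} heads"
        )
    q = _split_heads(x @ params.w_query, params.n_heads)
    k = _split_heads(x @ params.w_key, params.n_heads)
    v = _split_heads(x @ params.w_value, params.n_heads)
    scale = 1.0 / np.sqrt(q.shape[-1])
    weights = _softmax(q @ np.swapaxes(k, -1, -2) * scale)
    mask = _dropout_mask(rng, attention_dropout, weights.shape, training)
    applied = weights if mask is None else weights * mask
    y = _merge_heads(applied @ v) @ params.w_output
    records = []
    if x.ndim == 2:
        records = [
            AttentionRecord(layer=-1, head=h, matrix=weights[h])
            for h in range(params.n_heads)
        ]
    return y, records


def position_wise_ffn(
    x: np.ndarray, params: FFNParams, activation: str = "gelu"
) -> np.ndarray:
    """Two dense layers applied independently at each timestep."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.w1.shape[0]:
        raise ValueError("input feature size does not match W1")
    return _activation(x @ params.w1 + params.b1, activation) @ params.w2 + params.b2


def encoder_block(
    x: np.ndarray,
    block: EncoderBlockParams,
    dropout_rate: float = 0.0,
    attention_dropout_rate: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
    activation: str = "gelu",
) -> tuple[np.ndarray, list[AttentionRecord]]:
    """Pre-norm block: ``u = x + Drop(MHA(LN(x)))``, ``y = u + Drop(FFN(LN(u)))``."""
    x = np.asarray(x, dtype=float)
    ln1, _ = _layer_norm(x, block.ln1_gain, block.ln1_bias)
    attn_out, records = multi_head_attention(
        ln1, block.attn, attention_dropout_rate, training, rng
    )
    mask1 = _dropout_mask(rng, dropout_rate, attn_out.shape, training)
    u = x + (attn_out if mask1 is None else attn_out * mask1)
    ln2, _ = _layer_norm(u, block.ln2_gain, block.ln2_bias)
    ffn_out = position_wise_ffn(ln2, block.ffn, activation)
    mask2 = _dropout_mask(rng, dropout_rate, ffn_out.shape, training)
    y = u + (ffn_out if mask2 is None else ffn_out * mask2)
    return y, records


# ---------------------------------------------------------------------------
# full forward pass


def _coerce_batch(window, config: ModelConfig) -> tuple[np.ndarray, bool]:
    if isinstance(window, SignalWindow):
        x = window.values[None]
        single = True
    else:
        x = np.asarray(window, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
    if x.shape[1:] != (config.n_steps, config.n_channels):
        raise ValueError(
            f"input shape {x.shape[1:]} does not match configured "
            f"({config.n_steps}, {config.n_channels})"
        )
    return x, single


def forward(
    window,
    params: HARTransformerParams,
    config: ModelConfig | None = None,
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_attention: bool = False,
):
    """Full pipeline: normalize -> project -> +P -> dropout -> L blocks ->
    final LayerNorm -> per-timestep linear head.

    ``window`` may be a :class:`SignalWindow`, a ``(T, C)`` array or a
    batch ``(B, T, C)``. Returns ``logits`` with matching leading shape
    and, when ``return_attention``, the per-layer/per-head attention
    weights (a list of :class:`AttentionRecord` for single inputs, raw
    ``(L, B, H, T, T)`` arrays for batches). With ``training=False`` the
    map is deterministic.
    """
    cfg = config or params.config
    x, single = _coerce_batch(window, cfg)
    logits, _, attn = _forward_batch(
        x, params, cfg, training=training, rng=rng,
        capture_attention=return_attention, need_cache=False,
    )
    if single:
        logits = logits[0]
    if not return_attention:
        return logits
    if single:
        records = [
            AttentionRecord(layer=li, head=h, matrix=attn[li][0, h])
            for li in range(len(attn))
            for h in range(cfg.n_heads)
        ]
        return logits, records
    return logits, attn


def forward_with_cache(
    x: np.ndarray,
    params: HARTransformerParams,
    training: bool,
    rng: np.random.Generator | None,
):
    """Batched forward returning the caches the reverse pass needs."""
    cfg = params.config
    return _forward_batch(
        x, params, cfg, training=training, rng=rng,
        capture_attention=False, need_cache=True,
    )


def _forward_batch(
    x: np.ndarray,
    params: HARTransformerParams,
    cfg: ModelConfig,
    training: bool,
    rng: np.random.Generator | None,
    capture_attention: bool,
    need_cache: bool,
):
    cache: dict = {}
    xn = (x - params.normalizer.mean) / (
        params.normalizer.std + params.normalizer.epsilon
    )
    h = xn @ params.input_weight + params.input_bias + params.position_embedding
    mask0 = _dropout_mask(rng, cfg.dropout_rate, h.shape, training)
    if mask0 is not None:
        h = h * mask0
    if need_cache:
        cache["xn"] = xn
        cache["mask0"] = mask0
        cache["blocks"] = []
    attn_stack: list[np.ndarray] = []

    scale = 1.0 / np.sqrt(cfg.head_dim)
    for blk in params.blocks:
        blk_cache: dict = {"x_in": h}
        ln1, ln1_c = _layer_norm(h, blk.ln1_gain, blk.ln1_bias)
        q = _split_heads(ln1 @ blk.attn.w_query, cfg.n_heads)
        k = _split_heads(ln1 @ blk.attn.w_key, cfg.n_heads)
        v = _split_heads(ln1 @ blk.attn.w_value, cfg.n_heads)
        weights = _softmax(q @ np.swapaxes(k, -1, -2) * scale)
        amask = _dropout_mask(
            rng, cfg.attention_dropout_rate, weights.shape, training
        )
        applied = weights if amask is None else weights * amask
        concat = _merge_heads(applied @ v)
        attn_out = concat @ blk.attn.w_output
        mask1 = _dropout_mask(rng, cfg.dropout_rate, attn_out.shape, training)
        u = h + (attn_out if mask1 is None else attn_out * mask1)

        ln2, ln2_c = _layer_norm(u, blk.ln2_gain, blk.ln2_bias)
        pre = ln2 @ blk.ffn.w1 + blk.ffn.b1
        act = _activation(pre, cfg.activation)
        ffn_out = act @ blk.ffn.w2 + blk.ffn.b2
        mask2 = _dropout_mask(rng, cfg.dropout_rate, ffn_out.shape, training)
        h = u + (ffn_out if mask2 is None else ffn_out * mask2)

        if capture_attention:
            attn_stack.append(weights)
        if need_cache:
            blk_cache.update(
                ln1=ln1, ln1_c=ln1_c, q=q, k=k, v=v, weights=weights,
                amask=amask, applied=applied, concat=concat, mask1=mask1,
                u=u, ln2=ln2, ln2_c=ln2_c, pre=pre, act=act, mask2=mask2,
            )
            cache["blocks"].append(blk_cache)

    hf, final_c = _layer_norm(h, params.final_gain, params.final_bias)
    logits = hf @ params.head_weight + params.head_bias
    if need_cache:
        cache["h_last"] = h
        cache["final_c"] = final_c
        cache["hf"] = hf
    return logits, cache, attn_stack


def backward(
    dlogits: np.ndarray,
    params: HARTransformerParams,
    cache: dict,
) -> dict[str, np.ndarray]:
    """Reverse pass matching :func:`forward_with_cache`.

    Returns gradients keyed like :meth:`HARTransformerParams.named_tensors`.
    """
    cfg = params.config
    grads: dict[str, np.ndarray] = {}
    sum_bt = lambda a: a.sum(axis=(0, 1))
    scale = 1.0 / np.sqrt(cfg.head_dim)

    hf = cache["hf"]
    grads["head.weight"] = np.einsum("btd,btk->dk", hf, dlogits)
    grads["head.bias"] = sum_bt(dlogits)
    dhf = dlogits @ params.head_weight.T
    dh, dg, db = _layer_norm_backward(dhf, cache["final_c"], params.final_gain)
    grads["final.gain"], grads["final.bias"] = dg, db

    for i in range(cfg.n_layers - 1, -1, -1):
        blk = params.blocks[i]
        c = cache["blocks"][i]
        p = f"blocks.{i}."

        dffn_out = dh if c["mask2"] is None else dh * c["mask2"]
        du = dh
        grads[p + "ffn.w2"] = np.einsum("btf,btd->fd", c["act"], dffn_out)
        grads[p + "ffn.b2"] = sum_bt(dffn_out)
        dact = dffn_out @ blk.ffn.w2.T
        dpre = dact * _activation_grad(c["pre"], cfg.activation)
        grads[p + "ffn.w1"] = np.einsum("btd,btf->df", c["ln2"], dpre)
        grads[p + "ffn.b1"] = sum_bt(dpre)
        dln2 = dpre @ blk.ffn.w1.T
        dx2, dg2, db2 = _layer_norm_backward(dln2, c["ln2_c"], blk.ln2_gain)
        grads[p + "ln2.gain"], grads[p + "ln2.bias"] = dg2, db2
        du = du + dx2

        dattn_out = du if c["mask1"] is None else du * c["mask1"]
        dh_in = du
        grads[p + "attn.w_output"] = np.einsum(
            "btd,bte->de", c["concat"], dattn_out
        )
        dconcat = dattn_out @ blk.attn.w_output.T
        dheads = _split_heads(dconcat, cfg.n_heads)
        dapplied = dheads @ np.swapaxes(c["v"], -1, -2)
        dv = np.swapaxes(c["applied"], -1, -2) @ dheads
        dw = dapplied if c["amask"] is None else dapplied * c["amask"]
        w = c["weights"]
        ds = w * (dw - (dw * w).sum(axis=-1, keepdims=True))
        dq = ds @ c["k"] * scale
        dk = np.swapaxes(ds, -1, -2) @ c["q"] * scale
        dqf, dkf, dvf = (_merge_heads(a) for a in (dq, dk, dv))
        ln1 = c["ln1"]
        grads[p + "attn.w_query"] = np.einsum("btd,bte->de", ln1, dqf)
        grads[p + "attn.w_key"] = np.einsum("btd,bte->de", ln1, dkf)
        grads[p + "attn.w_value"] = np.einsum("btd,bte->de", ln1, dvf)
        dln1 = (
            dqf @ blk.attn.w_query.T
            + dkf @ blk.attn.w_key.T
            + dvf @ blk.attn.w_value.T
        )
        dx1, dg1, db1 = _layer_norm_backward(dln1, c["ln1_c"], blk.ln1_gain)
        grads[p + "ln1.gain"], grads[p + "ln1.bias"] = dg1, db1
        dh = dh_in + dx1

    if cache["mask0"] is not None:
        dh = dh * cache["mask0"]
    grads["position_embedding"] = dh.sum(axis=0)
    grads["input.weight"] = np.einsum("btc,btd->cd", cache["xn"], dh)
    grads["input.bias"] = sum_bt(dh)
    return grads


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(params: HARTransformerParams, path) -> None:
    """Portable array-container checkpoint (.npz) + JSON config sidecar."""
    path = Path(path)
    tensors = dict(params.named_tensors())
    tensors["normalizer.mean"] = params.normalizer.mean
    tensors["normalizer.std"] = params.normalizer.std
    np.savez(path, **tensors)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "model": params.config.to_dict(),
                "normalizer_epsilon": params.normalizer.epsilon,
            },
            indent=2,
        )
    )


def load_checkpoint(path) -> HARTransformerParams:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig.from_dict(sidecar["model"])
    with np.load(path) as data:
        tensors = {k: data[k] for k in data.files}
    params = init_params(config, seed=0)
    params.normalizer = NormalizerState(
        tensors.pop("normalizer.mean"),
        tensors.pop("normalizer.std"),
        epsilon=sidecar["normalizer_epsilon"],
    )
    for name, arr in params.named_tensors():
        arr[...] = tensors[name]
    return params
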