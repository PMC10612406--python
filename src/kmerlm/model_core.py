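"""BERT-style masked language model with an explicit module partition.

Every trainable parameter belongs to exactly one of three named groups:

- ``embedding`` — token / position / token-type tables plus their layer
  norm (the *embedding module*);
- ``encoding``  — the stack of post-norm transformer layers, multi-head
  attention + feed-forward (the *encoding module*);
- ``head``      — the MLM output projection.

The partition is the unit of "knockout" re-initialization: either
module can be freshly re-initialized while the other is retained
bit-for-bit. The model runs on the NumPy primitives in :mod:`._nn`
with hand-written gradients (no framework dependency); correctness is
established by finite-difference checks in the test suite.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import _nn
from .embeddings import EmbeddingTable
from .kmer_tokens import (
    KmerVocabulary, TokenSequence, MaskingPlan, build_vocabulary,
    apply_mask,
)


class ConfigValidationError(ValueError):
    """Inconsistent model configuration; message lists all violations."""


class CheckpointError(ValueError):
    """Version or shape mismatch while loading a checkpoint."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``vocab_size`` is derived as ``4**k + 5`` when left at None. The
    full-scale 5-mer configuration is ``ModelConfig(k=5, hidden=768,
    layers=12, heads=12, ffn=3072, max_positions=512)``; the default is
    a desk-scale mini model.
    """

    k: int = 3
    hidden: int = 64
    layers: int = 2
    heads: int = 4
    ffn: int = 256
    max_positions: int = 128
    type_vocab: int = 2
    dropout: float = 0.0
    seed: int = 0
    vocab_size: int | None = None
    tie_weights: bool = False
    dtype: str = "float64"  # float32 roughly halves desk-scale step time

    def __post_init__(self):
        if self.vocab_size is None:
            self.vocab_size = 4 ** self.k + 5
        self.validate()

    def validate(self) -> None:
        problems = []
        if not 1 <= self.k <= 8:
            problems.append(f"k={self.k} outside [1, 8]")
        if self.hidden % self.heads != 0:
            problems.append(
                f"hidden={self.hidden} not divisible by heads={self.heads}")
        if self.vocab_size != 4 ** self.k + 5:
            problems.append(
                f"vocab_size={self.vocab_size} != 4**{self.k} + 5")
        if self.layers < 1:
            problems.append("layers must be >= 1")
        if self.max_positions < self.k + 2:
            problems.append("max_positions too small")
        if not 0.0 <= self.dropout < 1.0:
            problems.append(f"dropout={self.dropout} outside [0, 1)")
        if self.dtype not in ("float32", "float64"):
            problems.append(f"dtype={self.dtype!r} unsupported")
        if problems:
            raise ConfigValidationError("; ".join(problems))


@dataclass
class ParameterCount:
    embedding_params: int
    encoding_params: int
    head_params: int

    @property
    def fraction_encoding(self) -> float:
        """Encoding share of embedding+encoding (head excluded)."""
        return self.encoding_params / (self.embedding_params
                                       + self.encoding_params)

    @property
    def total(self) -> int:
        return self.embedding_params + self.encoding_params + self.head_params


@dataclass
class ModelState:
    """Configuration plus a flat name -> array parameter dictionary."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    @property
    def vocab(self) -> KmerVocabulary:
        return build_vocabulary(self.config.k)

    def copy(self) -> "ModelState":
        return ModelState(config=copy.deepcopy(self.config),
                          params={k: v.copy()
                                  for k, v in self.params.items()},
                          provenance=dict(self.provenance))


def param_group(name: str) -> str:
    """Map a parameter name to its module group."""
    group = name.split(".", 1)[0]
    if group not in ("embedding", "encoding", "head"):
        raise ValueError(f"unknown parameter group for {name!r}")
    return group


def _param_shapes(cfg: ModelConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Ordered parameter name/shape list; order fixes the init stream."""
    H, F, V = cfg.hidden, cfg.ffn, cfg.vocab_size
    shapes: list[tuple[str, tuple[int, ...]]] = [
        ("embedding.token", (V, H)),
        ("embedding.position", (cfg.max_positions, H)),
        ("embedding.type", (cfg.type_vocab, H)),
        ("embedding.ln_g", (H,)),
        ("embedding.ln_b", (H,)),
    ]
    for layer in range(cfg.layers):
        p = f"encoding.{layer}"
        shapes += [
            (f"{p}.attn.wq", (H, H)), (f"{p}.attn.bq", (H,)),
            (f"{p}.attn.wk", (H, H)), (f"{p}.attn.bk", (H,)),
            (f"{p}.attn.wv", (H, H)), (f"{p}.attn.bv", (H,)),
            (f"{p}.attn.wo", (H, H)), (f"{p}.attn.bo", (H,)),
            (f"{p}.ln1_g", (H,)), (f"{p}.ln1_b", (H,)),
            (f"{p}.ffn.w1", (H, F)), (f"{p}.ffn.b1", (F,)),
            (f"{p}.ffn.w2", (F, H)), (f"{p}.ffn.b2", (H,)),
            (f"{p}.ln2_g", (H,)), (f"{p}.ln2_b", (H,)),
        ]
    if not cfg.tie_weights:
        shapes.append(("head.w", (V, H)))
    shapes.append(("head.b", (V,)))
    return shapes


def _init_params(cfg: ModelConfig, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    dtype = np.dtype(cfg.dtype)
    params: dict[str, np.ndarray] = {}
    for name, shape in _param_shapes(cfg):
        if name.endswith(("_g",)):
            params[name] = np.ones(shape, dtype=dtype)
        elif name.endswith(("_b", ".bq", ".bk", ".bv", ".bo",
                            ".b1", ".b2", ".b")):
            params[name] = np.zeros(shape, dtype=dtype)
        else:
            params[name] = _nn.truncated_normal(rng, shape,
                                                std=0.02).astype(dtype)
    return params


def build_model(cfg: ModelConfig) -> ModelState:
    """Initialize a model deterministically from ``cfg.seed``.

    Weight matrices are truncated-normal (std 0.02, clipped at 2 sd by
    resampling); biases zero; layer-norm scales one.
    """
    cfg.validate()
    return ModelState(config=cfg, params=_init_params(cfg, cfg.seed),
                      provenance={"built_with_seed": cfg.seed})


def count_parameters(cfg: ModelConfig) -> ParameterCount:
    """Closed-form per-module parameter counts.

    embedding = V*H + P*H + T*H + 2H
    encoding  = layers * [4*(H^2 + H) + (H*F + F) + (F*H + H) + 2*2H]
    head      = V*H + V  (V only when weights are tied)
    """
    H, F, V = cfg.hidden, cfg.ffn, cfg.vocab_size
    emb = V * H + cfg.max_positions * H + cfg.type_vocab * H + 2 * H
    per_layer = 4 * (H * H + H) + (H * F + F) + (F * H + H) + 2 * 2 * H
    enc = cfg.layers * per_layer
    head = V if cfg.tie_weights else V * H + V
    return ParameterCount(embedding_params=emb, encoding_params=enc,
                          head_params=head)


def count_parameters_by_walk(state: ModelState) -> ParameterCount:
    """Independent count by walking the built model's actual shapes."""
    totals = {"embedding": 0, "encoding": 0, "head": 0}
    for name, arr in state.params.items():
        totals[param_group(name)] += arr.size
    return ParameterCount(embedding_params=totals["embedding"],
                          encoding_params=totals["encoding"],
                          head_params=totals["head"])


def reinitialize_module(state: ModelState, scope: str,
                        seed: int) -> ModelState:
    """Freshly initialize one module; everything else stays bit-identical.

    ``scope='encoding'`` is the encoding-knockout construction: the
    transformer stack is re-drawn while the learned embeddings are
    retained. ``scope='all'`` reproduces :func:`build_model` with the
    given seed.
    """
    if scope not in ("encoding", "embedding", "all"):
        raise ValueError(
            f"scope must be one of encoding/embedding/all, got {scope!r}")
    fresh_cfg = copy.deepcopy(state.config)
    fresh_cfg.seed = seed
    fresh = _init_params(fresh_cfg, seed)
    out = state.copy()
    for name in out.params:
        group = param_group(name)
        if scope == "all" or group == scope:
            out.params[name] = fresh[name]
    if scope == "all":
        out.config.seed = seed
    out.provenance = {**state.provenance,
                      "reinitialized": scope, "reinit_seed": seed}
    return out


def extract_token_embeddings(state: ModelState,
                             include_specials: bool = True) -> EmbeddingTable:
    """Token-embedding rows labelled by vocabulary strings.

    Position and type embeddings are deliberately excluded: the
    analysis concerns k-mer token representations only.
    """
    vocab = state.vocab
    mat = state.params["embedding.token"]
    if include_specials:
        labels = list(vocab.tokens)
    else:
        labels = list(vocab.kmer_tokens)
        mat = mat[vocab.n_special:]
    return EmbeddingTable(row_labels=labels, matrix=mat.copy(),
                          source="model",
                          includes_specials=include_specials)


# --------------------------------------------------------------------------
# Forward / backward
# --------------------------------------------------------------------------

def forward_hidden(state: ModelState, input_ids: np.ndarray,
                   train: bool = False,
                   rng: np.random.Generator | None = None):
    """Run the embedding + encoding modules.

    Parameters
    ----------
    input_ids : int array (batch, seq)
    train : bool
        Enables dropout (when ``config.dropout > 0``).

    Returns
    -------
    (hidden, cache)
        ``hidden`` is (batch, seq, H); ``cache`` feeds
        :func:`backward_hidden`.
    """
    cfg, p = state.config, state.params
    ids = np.asarray(input_ids)
    if ids.ndim == 1:
        ids = ids[None, :]
    B, T = ids.shape
    if T > cfg.max_positions:
        raise ValueError(
            f"sequence length {T} exceeds max_positions={cfg.max_positions}")
    H, A = cfg.hidden, cfg.heads
    dh = H // A
    scale = 1.0 / np.sqrt(dh)
    use_drop = train and cfg.dropout > 0
    if use_drop and rng is None:
        rng = np.random.default_rng(0)

    def dropout(x):
        if not use_drop:
            return x, None
        keep = (rng.random(x.shape) >= cfg.dropout) / (1 - cfg.dropout)
        return x * keep, keep

    x0 = (p["embedding.token"][ids] + p["embedding.position"][:T]
          + p["embedding.type"][0])
    x, emb_ln = _nn.layernorm_forward(x0, p["embedding.ln_g"],
                                      p["embedding.ln_b"])
    x, emb_drop = dropout(x)

    layer_caches = []
    for layer in range(cfg.layers):
        pre = f"encoding.{layer}"
        xin = x
        q = x @ p[f"{pre}.attn.wq"] + p[f"{pre}.attn.bq"]
        k = x @ p[f"{pre}.attn.wk"] + p[f"{pre}.attn.bk"]
        v = x @ p[f"{pre}.attn.wv"] + p[f"{pre}.attn.bv"]
        qh = q.reshape(B, T, A, dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, T, A, dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, T, A, dh).transpose(0, 2, 1, 3)
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale
        attn = _nn.softmax(scores, axis=-1)
        ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, H)
        attn_out = ctx @ p[f"{pre}.attn.wo"] + p[f"{pre}.attn.bo"]
        attn_out, drop1 = dropout(attn_out)
        y1, ln1 = _nn.layernorm_forward(xin + attn_out,
                                        p[f"{pre}.ln1_g"], p[f"{pre}.ln1_b"])
        h_pre = y1 @ p[f"{pre}.ffn.w1"] + p[f"{pre}.ffn.b1"]
        h = _nn.gelu(h_pre)
        ffn_out = h @ p[f"{pre}.ffn.w2"] + p[f"{pre}.ffn.b2"]
        ffn_out, drop2 = dropout(ffn_out)
        y2, ln2 = _nn.layernorm_forward(y1 + ffn_out,
                                        p[f"{pre}.ln2_g"], p[f"{pre}.ln2_b"])
        layer_caches.append(dict(xin=xin, qh=qh, kh=kh, vh=vh, attn=attn,
                                 ctx=ctx, ln1=ln1, y1=y1, h_pre=h_pre, h=h,
                                 ln2=ln2, drop1=drop1, drop2=drop2))
        x = y2

    cache = dict(ids=ids, emb_ln=emb_ln, emb_drop=emb_drop,
                 layers=layer_caches, state=state, scale=scale,
                 shape=(B, T, H, A, dh))
    return x, cache


def backward_hidden(cache, dhidden: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all embedding/encoding
    parameters, given its gradient w.r.t. the final hidden states."""
    state: ModelState = cache["state"]
    cfg, p = state.config, state.params
    B, T, H, A, dh = cache["shape"]
    scale = cache["scale"]
    grads: dict[str, np.ndarray] = {}
    dx = dhidden

    def flat(a):
        return a.reshape(-1, a.shape[-1])

    for layer in reversed(range(cfg.layers)):
        c = cache["layers"][layer]
        pre = f"encoding.{layer}"
        dsum2, dg2, db2 = _nn.layernorm_backward(dx, c["ln2"])
        grads[f"{pre}.ln2_g"] = dg2
        grads[f"{pre}.ln2_b"] = db2
        dffn_out = dsum2 if c["drop2"] is None else dsum2 * c["drop2"]
        dy1 = dsum2.copy()
        grads[f"{pre}.ffn.w2"] = flat(c["h"]).T @ flat(dffn_out)
        grads[f"{pre}.ffn.b2"] = flat(dffn_out).sum(axis=0)
        dh_act = dffn_out @ p[f"{pre}.ffn.w2"].T
        dh_pre = dh_act * _nn.gelu_grad(c["h_pre"])
        grads[f"{pre}.ffn.w1"] = flat(c["y1"]).T @ flat(dh_pre)
        grads[f"{pre}.ffn.b1"] = flat(dh_pre).sum(axis=0)
        dy1 += dh_pre @ p[f"{pre}.ffn.w1"].T

        dsum1, dg1, db1 = _nn.layernorm_backward(dy1, c["ln1"])
        grads[f"{pre}.ln1_g"] = dg1
        grads[f"{pre}.ln1_b"] = db1
        dattn_out = dsum1 if c["drop1"] is None else dsum1 * c["drop1"]
        dx = dsum1.copy()
        grads[f"{pre}.attn.wo"] = flat(c["ctx"]).T @ flat(dattn_out)
        grads[f"{pre}.attn.bo"] = flat(dattn_out).sum(axis=0)
        dctx = (dattn_out @ p[f"{pre}.attn.wo"].T) \
            .reshape(B, T, A, dh).transpose(0, 2, 1, 3)
        dattn = dctx @ c["vh"].transpose(0, 1, 3, 2)
        dvh = c["attn"].transpose(0, 1, 3, 2) @ dctx
        a = c["attn"]
        dscores = a * (dattn - (dattn * a).sum(axis=-1, keepdims=True))
        dqh = (dscores @ c["kh"]) * scale
        dkh = (dscores.transpose(0, 1, 3, 2) @ c["qh"]) * scale
        dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, H)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, H)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, H)
        xin = c["xin"]
        grads[f"{pre}.attn.wq"] = flat(xin).T @ flat(dq)
        grads[f"{pre}.attn.bq"] = flat(dq).sum(axis=0)
        grads[f"{pre}.attn.wk"] = flat(xin).T @ flat(dk)
        grads[f"{pre}.attn.bk"] = flat(dk).sum(axis=0)
        grads[f"{pre}.attn.wv"] = flat(xin).T @ flat(dv)
        grads[f"{pre}.attn.bv"] = flat(dv).sum(axis=0)
        dx += (dq @ p[f"{pre}.attn.wq"].T + dk @ p[f"{pre}.attn.wk"].T
               + dv @ p[f"{pre}.attn.wv"].T)

    if cache["emb_drop"] is not None:
        dx = dx * cache["emb_drop"]
    dx0, dg, db = _nn.layernorm_backward(dx, cache["emb_ln"])
    grads["embedding.ln_g"] = dg
    grads["embedding.ln_b"] = db
    dtok = np.zeros_like(p["embedding.token"])
    np.add.at(dtok, cache["ids"].ravel(), dx0.reshape(-1, H))
    grads["embedding.token"] = dtok
    dpos = np.zeros_like(p["embedding.position"])
    dpos[:T] = dx0.sum(axis=0)
    grads["embedding.position"] = dpos
    dtype = np.zeros_like(p["embedding.type"])
    dtype[0] = dx0.sum(axis=(0, 1))
    grads["embedding.type"] = dtype
    return grads


def _head_matrix(state: ModelState) -> np.ndarray:
    if state.config.tie_weights:
        return state.params["embedding.token"]
    return state.params["head.w"]


def mlm_logits(state: ModelState, hidden: np.ndarray) -> np.ndarray:
    """Vocabulary logits from hidden states (any leading shape)."""
    return hidden @ _head_matrix(state).T + state.params["head.b"]


def mlm_loss_batch(state: ModelState, input_ids: np.ndarray,
                   labels: np.ndarray, mask: np.ndarray,
                   with_grads: bool = False, train: bool = False,
                   rng: np.random.Generator | None = None):
    """Masked cross-entropy over a batch.

    Parameters
    ----------
    input_ids : (B, T) ids after mask application
    labels : (B, T) original token ids
    mask : (B, T) bool, True at predicted positions

    Returns
    -------
    (loss, predictions) or (loss, predictions, grads)
        ``loss`` in nats per masked token; ``predictions`` is the
        argmax token id at each masked position (row-major order).
    """
    if not mask.any():
        raise ValueError("plan contains zero masked positions")
    hidden, cache = forward_hidden(state, input_ids, train=train, rng=rng)
    hm = hidden[mask]
    logits = mlm_logits(state, hm)
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    y = labels[mask]
    n = y.size
    loss = float(-logp[np.arange(n), y].mean())
    preds = logits.argmax(axis=1)
    if not with_grads:
        return loss, preds
    probs = np.exp(logp)
    dlogits = probs
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    w = _head_matrix(state)
    dw = dlogits.T @ hm
    db = dlogits.sum(axis=0)
    dhm = dlogits @ w
    dhidden = np.zeros_like(hidden)
    dhidden[mask] = dhm
    grads = backward_hidden(cache, dhidden)
    if state.config.tie_weights:
        grads["embedding.token"] = grads["embedding.token"] + dw
    else:
        grads["head.w"] = dw
    grads["head.b"] = db
    return loss, preds, grads


def mlm_loss(state: ModelState, ts: TokenSequence, plan: MaskingPlan):
    """Spec-level single-sequence MLM loss.

    Applies the plan's replacement actions, runs the model, and returns
    (mean cross-entropy in nats over masked positions, argmax token ids
    at those positions in order).
    """
    masked = plan.masked_positions
    if not masked:
        raise ValueError("plan contains zero masked positions")
    input_ids = np.array([apply_mask(ts, plan)])
    labels = np.array([ts.ids])
    mask = np.zeros_like(labels, dtype=bool)
    mask[0, masked] = True
    loss, preds = mlm_loss_batch(state, input_ids, labels, mask)
    return loss, list(preds)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(state: ModelState, path) -> None:
    """Single-file ``.npz`` container with embedded JSON config."""
    meta = json.dumps({
        "format_version": _FORMAT_VERSION,
        "config": asdict(state.config),
        "provenance": state.provenance,
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state.params)


def load_model(path) -> ModelState:
    with np.load(path) as data:
        if "__meta__" not in data:
            raise CheckpointError("missing metadata block")
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise CheckpointError(
                f"unsupported checkpoint version {meta.get('format_version')}")
        cfg = ModelConfig(**meta["config"])
        params = {k: data[k] for k in data.files if k != "__meta__"}
    expected = dict(_param_shapes(cfg))
    if set(params) != set(expected):
        missing = set(expected) - set(params)
        extra = set(params) - set(expected)
        raise CheckpointError(
            f"parameter set mismatch (missing={sorted(missing)}, "
            f"extra={sorted(extra)})")
    for name, shape in expected.items():
        if params[name].shape != shape:
            raise CheckpointError(
                f"shape mismatch for {name}: file has "
                f"{params[name].shape}, config implies {shape}")
    return ModelState(config=cfg, params=params,
                      provenance=meta.get("provenance", {}))
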