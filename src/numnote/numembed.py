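"""Magnitude-aware numeric embeddings: lookup, ScaleNum and AttnToNum.

Standard tokenization treats ``1.7`` and ``1.8`` as unrelated tokens, which
starves small-corpus models of numerical signal.  ScaleNum instead maps a
strictly positive value x through a learned sigmoid-linear-log scaling

    g_k(x) = sigmoid(a_k * log(clamp(x, 1, 1000)) + b_k),   k = 1..K

(all operations elementwise on embed-dimension vectors) and embeds x as the
sum of the K transformations, ghat(x) = sum_k g_k(x).  AttnToNum refines
ghat(x) with multi-head attention over the token embeddings in the number's
keyword context window (query = ghat(x); keys/values = the window's
embeddings, the number's own slot holding its ScaleNum embedding), so the
final number embedding also reflects whether the value is e.g. a BUN or a
creatinine and whether the clinician flagged it (H) or (L).

Forward functions return caches; the matching ``*_backward`` functions
implement the analytic gradients used by the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .textprep import NumericMention, Vocabulary, EmbeddingMode

__all__ = [
    "ScaleNumParams",
    "AttnParams",
    "EmbeddedNote",
    "g_single",
    "scalenum_forward",
    "scalenum_embed",
    "scalenum_backward",
    "attention_forward",
    "attention_backward",
    "attn_to_num",
    "embed_sequence",
]


@dataclass
class ScaleNumParams:
    """The K learned (a_k, b_k) pairs and the clamp bounds of g(x)."""

    a: np.ndarray  # (K, embed_dim)
    b: np.ndarray  # (K, embed_dim)
    lo: float = 1.0
    hi: float = 1000.0

    @property
    def n_transforms(self) -> int:
        return self.a.shape[0]

    @property
    def embed_dim(self) -> int:
        return self.a.shape[1]

    @property
    def n_params(self) -> int:
        return self.a.size + self.b.size

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        n_transforms: int = 5,
        embed_dim: int = 50,
        scale: float = 0.1,
        dtype=np.float64,
    ) -> "ScaleNumParams":
        return cls(
            a=rng.normal(0.0, scale, (n_transforms, embed_dim)).astype(dtype),
            b=rng.normal(0.0, scale, (n_transforms, embed_dim)).astype(dtype),
        )


@dataclass
class AttnParams:
    """Multi-head attention projections for the AttnToNum refinement.

    H heads of dimension d_h with H * d_h = embed_dim; four square
    projections (query, key, value, output) plus offsets: 4*(d^2 + d)
    learned scalars (10,200 at d = 50).
    """

    w_q: np.ndarray
    b_q: np.ndarray
    w_k: np.ndarray
    b_k: np.ndarray
    w_v: np.ndarray
    b_v: np.ndarray
    w_o: np.ndarray
    b_o: np.ndarray
    n_heads: int = 5

    @property
    def embed_dim(self) -> int:
        return self.w_q.shape[0]

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def n_params(self) -> int:
        return sum(
            m.size
            for m in (self.w_q, self.b_q, self.w_k, self.b_k,
                      self.w_v, self.b_v, self.w_o, self.b_o)
        )

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        embed_dim: int = 50,
        n_heads: int = 5,
        dtype=np.float64,
    ) -> "AttnParams":
        if embed_dim % n_heads:
            raise ValueError("n_heads must divide embed_dim")
        lim = 1.0 / np.sqrt(embed_dim)
        def mat() -> np.ndarray:
            return rng.uniform(-lim, lim, (embed_dim, embed_dim)).astype(dtype)
        zeros = lambda: np.zeros(embed_dim, dtype=dtype)
        return cls(mat(), zeros(), mat(), zeros(), mat(), zeros(), mat(), zeros(),
                   n_heads=n_heads)


@dataclass
class EmbeddedNote:
    """A note as a (max_len x embed_dim) matrix; padded rows are all-zero."""

    matrix: np.ndarray
    mask: np.ndarray  # bool, True at real-token rows


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def g_single(x: float, a: np.ndarray, b: np.ndarray,
             lo: float = 1.0, hi: float = 1000.0) -> np.ndarray:
    """One sigmoid-linear-log transform g(x) = sigmoid(a log(clamp(x)) + b).

    Equivalent closed form: x_c^a e^b / (x_c^a e^b + 1) with x_c the clamped
    value; every component lies strictly in (0, 1).
    """
    if x <= 0:
        raise ValueError("g(x) is defined for strictly positive x")
    logx = np.log(np.clip(x, lo, hi))
    return _sigmoid(a * logx + b)


def scalenum_forward(x: float, params: ScaleNumParams):
    """ghat(x) = sum_k g_k(x) plus the cache needed for the backward pass."""
    if x <= 0:
        raise ValueError("ScaleNum embeds strictly positive values only")
    logx = np.log(np.clip(x, params.lo, params.hi))
    y = _sigmoid(params.a * logx + params.b)  # (K, d)
    return y.sum(axis=0), {"y": y, "logx": logx}


def scalenum_embed(x: float, params: ScaleNumParams) -> np.ndarray:
    """The ScaleNum embedding of x: componentwise in (0, K)."""
    out, _ = scalenum_forward(x, params)
    return out


def scalenum_backward(dout: np.ndarray, cache: dict,
                      da: np.ndarray, db: np.ndarray) -> None:
    """Accumulate d loss/d a_k and d loss/d b_k given d loss/d ghat."""
    y = cache["y"]
    dz = dout[None, :] * y * (1.0 - y)  # (K, d)
    da += dz * cache["logx"]
    db += dz


def attention_forward(query: np.ndarray, context: np.ndarray, params: AttnParams):
    """Scaled dot-product multi-head attention of one number over its window.

    query: (d,) — the number's ScaleNum embedding; context: (w, d) — the
    window token embeddings (keys and values).  Returns the refined (d,)
    embedding, the (H, w) row-stochastic weight matrix, and a cache.
    """
    H, dh = params.n_heads, params.head_dim
    q = query @ params.w_q + params.b_q            # (d,)
    k = context @ params.w_k + params.b_k          # (w, d)
    v = context @ params.w_v + params.b_v          # (w, d)
    qh = q.reshape(H, dh)
    kh = k.reshape(-1, H, dh)
    vh = v.reshape(-1, H, dh)
    scores = (kh * qh).sum(axis=2).T / np.sqrt(dh)           # (H, w)
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=1, keepdims=True)               # (H, w)
    oh = (weights.T[:, :, None] * vh).sum(axis=0)            # (H, dh)
    o = oh.reshape(-1)
    out = o @ params.w_o + params.b_o
    cache = {"query": query, "context": context, "qh": qh, "kh": kh,
             "vh": vh, "weights": weights, "o": o}
    return out, weights, cache


def attention_backward(dout: np.ndarray, cache: dict, params: AttnParams,
                       grads: dict) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of the attention output w.r.t. inputs and projections.

    Returns (dquery, dcontext); accumulates projection gradients into
    ``grads`` under keys matching the AttnParams field names.
    """
    H, dh = params.n_heads, params.head_dim
    qh, kh, vh = cache["qh"], cache["kh"], cache["vh"]
    weights = cache["weights"]

    grads["w_o"] += np.outer(cache["o"], dout)
    grads["b_o"] += dout
    do = params.w_o @ dout                 # (d,)
    doh = do.reshape(H, dh)

    dweights = (vh * doh).sum(axis=2).T                      # (H, w)
    dvh = weights.T[:, :, None] * doh[None, :, :]            # (w, H, dh)
    # softmax jacobian, rowwise
    dscores = weights * (dweights - (weights * dweights).sum(axis=1, keepdims=True))
    dscores = dscores / np.sqrt(dh)
    dqh = (dscores.T[:, :, None] * kh).sum(axis=0)           # (H, dh)
    dkh = dscores.T[:, :, None] * qh[None, :, :]             # (w, H, dh)

    dq = dqh.reshape(-1)
    dk = dkh.reshape(-1, H * dh)
    dv = dvh.reshape(-1, H * dh)

    grads["w_q"] += np.outer(cache["query"], dq)
    grads["b_q"] += dq
    grads["w_k"] += cache["context"].T @ dk
    grads["b_k"] += dk.sum(axis=0)
    grads["w_v"] += cache["context"].T @ dv
    grads["b_v"] += dv.sum(axis=0)

    dquery = params.w_q @ dq
    dcontext = dk @ params.w_k.T + dv @ params.w_v.T
    return dquery, dcontext


def attn_to_num(
    x: float,
    context_embeds: np.ndarray | Sequence[np.ndarray],
    scalenum: ScaleNumParams,
    attn: AttnParams,
) -> np.ndarray:
    """AttnToNum embedding of value x given its context-window embeddings.

    The window follows the context definition (keyword - 1 .. keyword + 2,
    the number's own slot occupied by its ScaleNum embedding).  An empty
    window returns the ScaleNum embedding unchanged.
    """
    ghat = scalenum_embed(x, scalenum)
    context = np.asarray(context_embeds, dtype=ghat.dtype)
    if context.size == 0:
        return ghat
    out, _, _ = attention_forward(ghat, context, attn)
    return out


def context_window(mention: NumericMention, seq_len: int,
                   left: int = 1, right: int = 2) -> list[int]:
    """Positions of the mention's attention window within the sequence."""
    anchor = mention.keyword_position
    if anchor is None:
        anchor = mention.position
    return [p for p in range(anchor - left, anchor + right + 1) if 0 <= p < seq_len]


def embed_sequence(
    ids: Sequence[int],
    mentions: Sequence[NumericMention],
    mode: str,
    table: np.ndarray,
    scalenum: ScaleNumParams | None = None,
    attn: AttnParams | None = None,
) -> EmbeddedNote:
    """Embed an encoded note under one of the four modes.

    Basic/ROOC rows are pure table lookups; ScaleNum replaces in-context
    number rows with ghat(x); AttnToNum further refines them by window
    attention.  Mention positions beyond the encoded length are ignored;
    padded rows are all-zero in every mode.
    """
    ids = np.asarray(ids, dtype=np.int64)
    mask = ids != Vocabulary.PAD_ID
    X = table[ids].copy()
    L = len(ids)
    if mode in EmbeddingMode.NUMERIC_PATH:
        if scalenum is None:
            raise ValueError("ScaleNum parameters required for numeric modes")
        active = [m for m in mentions if m.in_context and m.position < L]
        for m in active:
            X[m.position] = scalenum_embed(m.value, scalenum)
        if mode == EmbeddingMode.ATTNTONUM:
            if attn is None:
                raise ValueError("attention parameters required for AttnToNum")
            snapshot = X.copy()
            for m in active:
                window = context_window(m, L)
                X[m.position] = attn_to_num(
                    m.value, snapshot[window], scalenum, attn
                )
    X[~mask] = 0.0
    return EmbeddedNote(matrix=X, mask=mask)
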