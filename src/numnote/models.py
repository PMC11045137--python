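"""TextCNN and TextLSTM classifier heads over numerically embedded notes.

Both models share the embedding front end (token lookup table plus, for the
ScaleNum / AttnToNum modes, the learned numeric path from ``numembed``).
TextCNN applies parallel banks of 1-d convolutions (filter sizes 1, 2, 3, 5;
44 kernels each => 176 filters), a note-wide max pool per filter, dropout on
the pooled vector and a single linear layer, so the logit decomposes as

    logit_s = w0 + sum_f w_f * a_{s,f}

with exactly one max-pooled activation a_{s,f} per filter — the additive
structure SHAP-N attribution relies on.  TextLSTM replaces the convolutions
with a bi-directional LSTM (hidden 88 per direction, 176-wide output states)
followed by the same temporal max pool and linear head.

Everything is plain numpy with hand-written backward passes (verified by
finite differences in the test suite) so the package trains on one CPU with
no deep-learning framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .textprep import EmbeddingMode, NumericMention, Vocabulary
from .numembed import (
    AttnParams,
    ScaleNumParams,
    attention_backward,
    attention_forward,
    context_window,
    scalenum_backward,
    scalenum_forward,
)

__all__ = [
    "TextCNNConfig",
    "TextLSTMConfig",
    "ForwardRecord",
    "ParameterBreakdown",
    "TextCNN",
    "TextLSTM",
    "build_model",
    "count_parameters",
    "Adam",
    "bce_with_logits",
]


@dataclass
class TextCNNConfig:
    embed_dim: int = 50
    filter_sizes: tuple[int, ...] = (1, 2, 3, 5)
    n_kernels: int = 44
    dropout: float = 0.5
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 3.5e-4
    max_len: int = 3000
    n_scalenum: int = 5
    n_heads: int = 5

    @property
    def n_filters(self) -> int:
        return self.n_kernels * len(self.filter_sizes)


@dataclass
class TextLSTMConfig:
    embed_dim: int = 50
    hidden_dim: int = 88
    dropout: float = 0.0
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 3.5e-4
    max_len: int = 3000
    n_scalenum: int = 5
    n_heads: int = 5

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden_dim


@dataclass
class ForwardRecord:
    """One TextCNN inference: logit, per-filter max activations and spans."""

    logit: float
    activations: np.ndarray      # (F,)
    argmax_positions: np.ndarray  # (F,) window start index per filter
    filter_sizes: np.ndarray      # (F,) window length per filter


@dataclass
class ParameterBreakdown:
    """Itemized learnable-scalar counts, Table-of-parameters style."""

    embed: int
    number_embedding: int
    attention: int
    post_embed: int

    @property
    def total(self) -> int:
        return self.embed + self.number_embedding + self.attention + self.post_embed


def count_parameters(config, vocab_size: int, mode: str) -> ParameterBreakdown:
    """Closed-form parameter accounting for either architecture.

    CNN post-embed: sum_k kernels*k*d convolution weights + one offset per
    kernel + the (F+1)-parameter classification layer.  Bi-LSTM post-embed:
    per direction 4H(d+H) gate weights and two 4H offset vectors, plus the
    (2H+1)-parameter classification layer.
    """
    d = config.embed_dim
    embed = vocab_size * d
    number = 2 * config.n_scalenum * d if mode in EmbeddingMode.NUMERIC_PATH else 0
    attention = 4 * (d * d + d) if mode == EmbeddingMode.ATTNTONUM else 0
    if isinstance(config, TextCNNConfig):
        conv = sum(config.n_kernels * k * d for k in config.filter_sizes)
        conv += len(config.filter_sizes) * config.n_kernels
        post = conv + config.n_filters + 1
    elif isinstance(config, TextLSTMConfig):
        H = config.hidden_dim
        per_dir = 4 * H * (d + H) + 2 * 4 * H
        post = 2 * per_dir + config.output_dim + 1
    else:  # pragma: no cover - defensive
        raise TypeError(f"unknown config type {type(config)!r}")
    return ParameterBreakdown(embed, number, attention, post)


def bce_with_logits(logits: np.ndarray, labels: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / len(z)).astype(logits.dtype)


class Adam:
    """Adam with the usual bias-corrected moments."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


class _NumericTextModel:
    """Shared embedding front end: lookup table + ScaleNum / AttnToNum path."""

    #: params-dict key prefixes per reporting group
    GROUPS = {
        "embed": ("embed",),
        "number_embedding": ("sn_a", "sn_b"),
        "attention": ("attn_",),
    }

    def __init__(self, config, vocab_size: int, mode: str,
                 rng: np.random.Generator, dtype=np.float32):
        if mode not in EmbeddingMode.ALL:
            raise ValueError(f"unknown mode {mode!r}")
        self.config = config
        self.mode = mode
        self.vocab_size = vocab_size
        self.dtype = dtype
        self.rng = rng
        d = config.embed_dim
        self.params: dict[str, np.ndarray] = {}
        table = rng.normal(0.0, 0.1, (vocab_size, d)).astype(dtype)
        table[Vocabulary.PAD_ID] = 0.0
        self.params["embed"] = table
        if mode in EmbeddingMode.NUMERIC_PATH:
            sn = ScaleNumParams.init(rng, config.n_scalenum, d, dtype=dtype)
            self.params["sn_a"] = sn.a
            self.params["sn_b"] = sn.b
        if mode == EmbeddingMode.ATTNTONUM:
            at = AttnParams.init(rng, d, config.n_heads, dtype=dtype)
            for name in ("w_q", "b_q", "w_k", "b_k", "w_v", "b_v", "w_o", "b_o"):
                self.params["attn_" + name] = getattr(at, name)

    # --- parameter views -------------------------------------------------
    @property
    def scalenum_params(self) -> ScaleNumParams | None:
        if "sn_a" not in self.params:
            return None
        return ScaleNumParams(a=self.params["sn_a"], b=self.params["sn_b"])

    @property
    def attn_params(self) -> AttnParams | None:
        if "attn_w_q" not in self.params:
            return None
        return AttnParams(
            *(self.params["attn_" + n]
              for n in ("w_q", "b_q", "w_k", "b_k", "w_v", "b_v", "w_o", "b_o")),
            n_heads=self.config.n_heads,
        )

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def parameter_group_sizes(self) -> dict[str, int]:
        """Actual learnable-scalar counts per reporting group."""
        sizes = {g: 0 for g in ("embed", "number_embedding", "attention", "post_embed")}
        for name, arr in self.params.items():
            for group, prefixes in self.GROUPS.items():
                if any(name.startswith(p) for p in prefixes):
                    sizes[group] += arr.size
                    break
            else:
                sizes["post_embed"] += arr.size
        return sizes

    # --- embedding forward / backward ------------------------------------
    def _embed_forward(self, ids: np.ndarray,
                       mentions: Sequence[Sequence[NumericMention]]):
        B, L = ids.shape
        X = self.params["embed"][ids].copy()
        mask = ids != Vocabulary.PAD_ID
        sn_items: list[tuple[int, NumericMention, dict]] = []
        attn_items: list[tuple[int, NumericMention, list[int], dict]] = []
        if self.mode in EmbeddingMode.NUMERIC_PATH:
            sn = self.scalenum_params
            for b, ms in enumerate(mentions):
                for m in ms:
                    if not m.in_context or m.position >= L:
                        continue
                    g, c = scalenum_forward(m.value, sn)
                    X[b, m.position] = g
                    sn_items.append((b, m, c))
            if self.mode == EmbeddingMode.ATTNTONUM and sn_items:
                at = self.attn_params
                snapshot = X.copy()
                for b, m, _ in sn_items:
                    window = context_window(m, L)
                    out, _, ac = attention_forward(
                        snapshot[b, m.position], snapshot[b, window], at
                    )
                    X[b, m.position] = out
                    attn_items.append((b, m, window, ac))
        X[~mask] = 0.0
        cache = {"ids": ids, "mask": mask, "sn": sn_items, "attn": attn_items}
        return X.astype(self.dtype, copy=False), cache

    def _embed_backward(self, dX: np.ndarray, cache: dict,
                        grads: dict[str, np.ndarray]) -> None:
        mask = cache["mask"]
        dPre = np.where(mask[:, :, None], dX, 0.0).astype(np.float64)
        # attention slots consume their position's pre-attention value
        for b, m, _, _ in cache["attn"]:
            dPre[b, m.position] = 0.0
        if cache["attn"]:
            at = self.attn_params
            attn_grads = {n: grads["attn_" + n]
                          for n in ("w_q", "b_q", "w_k", "b_k", "w_v", "b_v",
                                    "w_o", "b_o")}
            for b, m, window, ac in cache["attn"]:
                dout = dX[b, m.position].astype(np.float64)
                dquery, dcontext = attention_backward(dout, ac, at, attn_grads)
                dPre[b, window] += dcontext
                dPre[b, m.position] += dquery
        if cache["sn"]:
            for b, m, c in cache["sn"]:
                scalenum_backward(dPre[b, m.position], c,
                                  grads["sn_a"], grads["sn_b"])
                dPre[b, m.position] = 0.0
        ids, msk = cache["ids"], mask
        np.add.at(grads["embed"], ids[msk], dPre[msk])


class TextCNN(_NumericTextModel):
    """Convolutional note classifier with note-wide max pooling."""

    def __init__(self, config: TextCNNConfig, vocab_size: int, mode: str,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__(config, vocab_size, mode, rng, dtype)
        d = config.embed_dim
        for k in config.filter_sizes:
            lim = 1.0 / np.sqrt(k * d)
            self.params[f"conv_w{k}"] = rng.uniform(
                -lim, lim, (config.n_kernels, k * d)).astype(dtype)
            self.params[f"conv_b{k}"] = np.zeros(config.n_kernels, dtype=dtype)
        lim = 1.0 / np.sqrt(config.n_filters)
        self.params["fc_w"] = rng.uniform(-lim, lim, config.n_filters).astype(dtype)
        self.params["fc_b"] = np.zeros(1, dtype=dtype)

    @property
    def filter_size_per_filter(self) -> np.ndarray:
        return np.repeat(self.config.filter_sizes, self.config.n_kernels)

    def _pad_ids(self, ids: np.ndarray) -> np.ndarray:
        need = max(self.config.filter_sizes) - ids.shape[1]
        if need > 0:
            ids = np.pad(ids, ((0, 0), (0, need)))
        return ids

    def forward(self, ids: np.ndarray,
                mentions: Sequence[Sequence[NumericMention]],
                train: bool = False):
        """Batch logits plus the cache for ``backward``.

        Max pooling runs over windows starting inside the note (plus one
        guard window for empty notes), so logits do not depend on how much
        batch padding follows a note.
        """
        ids = self._pad_ids(np.asarray(ids))
        B, L = ids.shape
        X, ecache = self._embed_forward(ids, mentions)
        lengths = ecache["mask"].sum(axis=1)
        cache = {"embed": ecache, "X": X, "conv": {}, "B": B, "L": L}
        pooled = []
        argmaxes = []
        for k in self.config.filter_sizes:
            P = L - k + 1
            W, bias = self.params[f"conv_w{k}"], self.params[f"conv_b{k}"]
            Xw = sliding_window_view(X, k, axis=1).transpose(0, 1, 3, 2)
            Xw = np.ascontiguousarray(Xw).reshape(B, P, k * self.config.embed_dim)
            Z = Xw @ W.T + bias
            A = np.maximum(Z, 0.0)
            n_valid = np.maximum(1, np.minimum(P, lengths - k + 1))
            valid = np.arange(P)[None, :] < n_valid[:, None]
            Am = np.where(valid[:, :, None], A, np.asarray(-1.0, dtype=A.dtype))
            am = Am.argmax(axis=1)                      # (B, kernels)
            a = np.take_along_axis(Am, am[:, None, :], axis=1)[:, 0, :]
            pooled.append(a)
            argmaxes.append(am)
            cache["conv"][k] = {"Xw": Xw, "Z": Z, "argmax": am}
        h = np.concatenate(pooled, axis=1)               # (B, F)
        cache["h"] = h
        cache["argmax"] = np.concatenate(argmaxes, axis=1)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            dm = (self.rng.random(h.shape) < keep).astype(h.dtype) / keep
        else:
            dm = np.ones_like(h)
        cache["dropmask"] = dm
        hd = h * dm
        cache["hd"] = hd
        logits = hd @ self.params["fc_w"] + self.params["fc_b"][0]
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        grads = self.zero_grads()
        grads["fc_w"] += cache["hd"].T @ dlogits
        grads["fc_b"][0] += dlogits.sum()
        dh = (np.outer(dlogits, self.params["fc_w"]) * cache["dropmask"]).astype(self.dtype)
        B, L = cache["B"], cache["L"]
        dX = np.zeros_like(cache["X"])
        col = 0
        nk = self.config.n_kernels
        for k in self.config.filter_sizes:
            c = cache["conv"][k]
            P = L - k + 1
            dA = np.zeros((B, P, nk), dtype=self.dtype)
            rows = np.arange(B)[:, None]
            cols = np.arange(nk)[None, :]
            dA[rows, c["argmax"], cols] = dh[:, col:col + nk]
            dZ = dA * (c["Z"] > 0)
            W = self.params[f"conv_w{k}"]
            I = k * self.config.embed_dim
            grads[f"conv_w{k}"] += dZ.reshape(B * P, nk).T @ c["Xw"].reshape(B * P, I)
            grads[f"conv_b{k}"] += dZ.sum(axis=(0, 1))
            dXw = (dZ @ W).reshape(B, P, k, self.config.embed_dim)
            for j in range(k):
                dX[:, j:j + P, :] += dXw[:, :, j, :]
            col += nk
        self._embed_backward(dX, cache["embed"], grads)
        return grads

    def forward_record(self, ids: Sequence[int],
                       mentions: Sequence[NumericMention]) -> ForwardRecord:
        """Single-note inference with per-filter activations and argmax spans."""
        logits, cache = self.forward(np.asarray(ids)[None, :], [list(mentions)],
                                     train=False)
        return ForwardRecord(
            logit=float(logits[0]),
            activations=cache["h"][0].copy(),
            argmax_positions=cache["argmax"][0].copy(),
            filter_sizes=self.filter_size_per_filter,
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class TextLSTM(_NumericTextModel):
    """Bi-directional LSTM note classifier with temporal max pooling.

    Each direction runs over the note's real tokens only (state updates are
    gated off past the note's length), the 2H-wide output states are
    max-pooled over time and fed to a single linear layer.
    """

    DIRECTIONS = ("fw", "bw")

    def __init__(self, config: TextLSTMConfig, vocab_size: int, mode: str,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__(config, vocab_size, mode, rng, dtype)
        d, H = config.embed_dim, config.hidden_dim
        lim = 1.0 / np.sqrt(H)
        for direc in self.DIRECTIONS:
            self.params[f"lstm_{direc}_wih"] = rng.uniform(
                -lim, lim, (4 * H, d)).astype(dtype)
            self.params[f"lstm_{direc}_whh"] = rng.uniform(
                -lim, lim, (4 * H, H)).astype(dtype)
            self.params[f"lstm_{direc}_bih"] = np.zeros(4 * H, dtype=dtype)
            self.params[f"lstm_{direc}_bhh"] = np.zeros(4 * H, dtype=dtype)
        lim = 1.0 / np.sqrt(config.output_dim)
        self.params["fc_w"] = rng.uniform(-lim, lim, config.output_dim).astype(dtype)
        self.params["fc_b"] = np.zeros(1, dtype=dtype)

    def _run_direction(self, X: np.ndarray, lengths: np.ndarray, direc: str):
        B, L, d = X.shape
        H = self.config.hidden_dim
        Wih = self.params[f"lstm_{direc}_wih"]
        Whh = self.params[f"lstm_{direc}_whh"]
        bias = self.params[f"lstm_{direc}_bih"] + self.params[f"lstm_{direc}_bhh"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.zeros((B, L, H))
        steps = []
        pre = X.astype(np.float64) @ Wih.T.astype(np.float64) + bias  # (B, L, 4H)
        for t in range(L):
            active = (t < lengths)[:, None]
            gates = pre[:, t] + h @ Whh.T
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H:2 * H])
            g = np.tanh(gates[:, 2 * H:3 * H])
            o = _sigmoid(gates[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append({"i": i, "f": f, "g": g, "o": o, "tc": tc,
                          "h_prev": h, "c_prev": c, "active": active})
            h = np.where(active, h_new, h)
            c = np.where(active, c_new, c)
            Hs[:, t] = np.where(active, h_new, -np.inf)
        return Hs, steps

    def _backward_direction(self, dHs: np.ndarray, steps: list, X: np.ndarray,
                            direc: str, grads: dict) -> np.ndarray:
        B, L, d = X.shape
        H = self.config.hidden_dim
        Whh = self.params[f"lstm_{direc}_whh"].astype(np.float64)
        Wih = self.params[f"lstm_{direc}_wih"].astype(np.float64)
        dWih = grads[f"lstm_{direc}_wih"]
        dWhh = grads[f"lstm_{direc}_whh"]
        dX = np.zeros((B, L, d))
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in reversed(range(L)):
            s = steps[t]
            act = s["active"]
            dh_t = np.where(act, dHs[:, t] + dh, 0.0)
            dc_t = np.where(act, dc, 0.0)
            do = dh_t * s["tc"]
            dtc = dh_t * s["o"]
            dc_new = dc_t + dtc * (1.0 - s["tc"] ** 2)
            di = dc_new * s["g"]
            df = dc_new * s["c_prev"]
            dg = dc_new * s["i"]
            dgates = np.concatenate([
                di * s["i"] * (1 - s["i"]),
                df * s["f"] * (1 - s["f"]),
                dg * (1 - s["g"] ** 2),
                do * s["o"] * (1 - s["o"]),
            ], axis=1)                                    # (B, 4H)
            dWih += dgates.T @ X[:, t].astype(np.float64)
            dWhh += dgates.T @ s["h_prev"]
            db = dgates.sum(axis=0)
            grads[f"lstm_{direc}_bih"] += db
            grads[f"lstm_{direc}_bhh"] += db
            dX[:, t] = dgates @ Wih
            # inactive (padded) steps pass state through, so their carried
            # gradients flow back unchanged
            dh = dgates @ Whh + np.where(act, 0.0, dh)
            dc = dc_new * s["f"] + np.where(act, 0.0, dc)
        return dX

    @staticmethod
    def _reverse_within_length(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        out = np.zeros_like(X)
        for b, n in enumerate(lengths):
            n = int(n)
            out[b, :n] = X[b, :n][::-1]
        return out

    def forward(self, ids: np.ndarray,
                mentions: Sequence[Sequence[NumericMention]],
                train: bool = False):
        ids = np.asarray(ids)
        B, L = ids.shape
        X, ecache = self._embed_forward(ids, mentions)
        lengths = np.maximum(ecache["mask"].sum(axis=1), 1)
        Xr = self._reverse_within_length(X, lengths)
        Hf, steps_f = self._run_direction(X, lengths, "fw")
        Hb, steps_b = self._run_direction(Xr, lengths, "bw")
        Hall = np.concatenate([Hf, Hb], axis=2)          # (B, L, 2H)
        pooled = Hall.max(axis=1)
        argmax = Hall.argmax(axis=1)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            dm = (self.rng.random(pooled.shape) < keep).astype(pooled.dtype) / keep
        else:
            dm = np.ones_like(pooled)
        hd = pooled * dm
        logits = hd @ self.params["fc_w"].astype(np.float64) + self.params["fc_b"][0]
        cache = {"embed": ecache, "X": X, "Xr": Xr, "lengths": lengths,
                 "steps_f": steps_f, "steps_b": steps_b, "argmax": argmax,
                 "dropmask": dm, "hd": hd, "B": B, "L": L}
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        grads = self.zero_grads()
        grads["fc_w"] += cache["hd"].T @ dlogits
        grads["fc_b"][0] += dlogits.sum()
        dpool = np.outer(dlogits, self.params["fc_w"]) * cache["dropmask"]
        B, L = cache["B"], cache["L"]
        H = self.config.hidden_dim
        dHall = np.zeros((B, L, 2 * H))
        rows = np.arange(B)[:, None]
        cols = np.arange(2 * H)[None, :]
        dHall[rows, cache["argmax"], cols] = dpool
        dXf = self._backward_direction(dHall[:, :, :H], cache["steps_f"],
                                       cache["X"], "fw", grads)
        dXb = self._backward_direction(dHall[:, :, H:], cache["steps_b"],
                                       cache["Xr"], "bw", grads)
        dX = dXf + self._reverse_within_length(dXb, cache["lengths"])
        self._embed_backward(dX, cache["embed"], grads)
        return grads


def build_model(config, vocab_size: int, mode: str, rng: np.random.Generator,
                dtype=np.float32):
    """Instantiate the architecture matching the config type."""
    if isinstance(config, TextCNNConfig):
        return TextCNN(config, vocab_size, mode, rng, dtype)
    if isinstance(config, TextLSTMConfig):
        return TextLSTM(config, vocab_size, mode, rng, dtype)
    raise TypeError(f"unknown config type {type(config)!r}")
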