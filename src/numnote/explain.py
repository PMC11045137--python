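"""SHAP-N ngram attribution, embedding-correlation and attention probes.

Because TextCNN's note-wide max pool leaves exactly one activation per
filter and the head is linear, the logit decomposes exactly:

    logit_s = phi0 + sum_f phi_{f,s},
    phi_{f,s} = w_f (a_{s,f} - mu_f),    phi0 = w0 + sum_f w_f mu_f,

with mu_f the dataset mean of filter f's activation.  Each filter's
attribution belongs to the ngram at its argmax window; filters whose span is
contained in a longer passing span (sub-ngrams pass shorter filters too) are
pooled into that span's ngram, keeping the decomposition conservative.  The
final SHAP-N value of an ngram is its mean attribution across all samples of
the evaluated split.

Also here: Pearson correlations between number embeddings at each pipeline
stage (lookup / ScaleNum / AttnToNum) for probe phrases like
``"BUN 25.0 (H)"``, and per-head attention-weight extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .textprep import (
    DEFAULT_KEYWORDS,
    EmbeddingMode,
    Vocabulary,
    encode,
    prepare_tokens,
    tokenize,
    parse_number,
)
from .numembed import attention_forward, context_window, embed_sequence, scalenum_embed
from .models import ForwardRecord, TextCNN

__all__ = [
    "ShapDecomposition",
    "ShapNRecord",
    "collect_forward_records",
    "shap_filters",
    "aggregate_ngrams",
    "mean_shapn",
    "embedding_correlation",
    "attention_weights",
    "trigram_value_table",
]


@dataclass
class ShapDecomposition:
    """Per-filter SHAP values for one sample, plus the shared mu/w/phi0."""

    phi0: float
    phi: np.ndarray            # (F,) per-filter phi_{f,s}
    mu: np.ndarray             # (F,) dataset means
    weights: np.ndarray        # (F,) head coefficients w_f
    activations: np.ndarray    # (F,) a_{s,f}
    spans: list[tuple[int, int]]  # (start, length) argmax window per filter
    logit: float


@dataclass
class ShapNRecord:
    """An ngram with its dataset-mean SHAP-N value and support count."""

    ngram: tuple[str, ...]
    phi: float
    support: int


def collect_forward_records(model: TextCNN, vocab: Vocabulary, notes,
                            mode: str, max_len: int = 512,
                            keywords=DEFAULT_KEYWORDS):
    """Per-note ForwardRecords plus the prepped token lists they refer to."""
    records, token_lists = [], []
    for rec in notes:
        seq, mentions = prepare_tokens(tokenize(rec.text, rec.note_id),
                                       mode, keywords)
        ids = encode(seq, vocab, max_len)
        records.append(model.forward_record(
            ids, [m for m in mentions if m.in_context]))
        token_lists.append(seq.tokens[:max_len])
    return records, token_lists


def shap_filters(model: TextCNN, records: Sequence[ForwardRecord]
                 ) -> list[ShapDecomposition]:
    """Exact per-filter SHAP decomposition for every sample of a dataset.

    Only valid for TextCNN (the additive max-pool structure); mu_f is the
    mean activation over the supplied records (the split being explained).
    """
    if not isinstance(model, TextCNN):
        raise TypeError("SHAP-N requires the additive TextCNN head")
    acts = np.stack([r.activations for r in records])     # (S, F)
    mu = acts.mean(axis=0)
    w = np.asarray(model.params["fc_w"], dtype=np.float64)
    w0 = float(model.params["fc_b"][0])
    phi0 = w0 + float(w @ mu)
    out = []
    for r in records:
        phi = w * (r.activations - mu)
        spans = [(int(p), int(k))
                 for p, k in zip(r.argmax_positions, r.filter_sizes)]
        out.append(ShapDecomposition(
            phi0=phi0, phi=phi, mu=mu, weights=w,
            activations=np.asarray(r.activations, dtype=np.float64),
            spans=spans, logit=r.logit))
    return out


def _maximal_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    uniq = sorted(set(spans), key=lambda s: (s[0], -s[1]))
    out = []
    for s in uniq:
        contained = any(o != s and o[0] <= s[0] and s[0] + s[1] <= o[0] + o[1]
                        for o in uniq)
        if not contained:
            out.append(s)
    return out


def _merge_overlaps(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    merged = [spans[0]]
    for s, k in spans[1:]:
        ps, pk = merged[-1]
        if s <= ps + pk:
            merged[-1] = (ps, max(ps + pk, s + k) - ps)
        else:
            merged.append((s, k))
    return merged


def _ngram_of(span: tuple[int, int], tokens: Sequence[str]) -> tuple[str, ...]:
    start, length = span
    return tuple(
        tokens[p] if p < len(tokens) else Vocabulary.RESERVED[Vocabulary.PAD_ID]
        for p in range(start, start + length)
    )


def aggregate_ngrams(decomp: ShapDecomposition, tokens: Sequence[str],
                     merge_overlapping: bool = False
                     ) -> dict[tuple[str, ...], float]:
    """Pool per-filter SHAP values into ngram-level phi_{n,s}.

    Each filter is assigned to exactly one maximal passing span: the longest
    span containing its argmax window (ties: leftmost), so sub-ngrams of a
    passing ngram fold into it and conservation is preserved.  The optional
    ``merge_overlapping`` variant further unions overlapping maximal spans
    before assignment; it is off by default because it smears attribution
    over long hard-to-read overlaps.
    """
    targets = _maximal_spans(decomp.spans)
    if merge_overlapping:
        targets = _merge_overlaps(targets)
    phi_by_ngram: dict[tuple[str, ...], float] = {}
    for span, phi in zip(decomp.spans, decomp.phi):
        candidates = [t for t in targets
                      if t[0] <= span[0] and span[0] + span[1] <= t[0] + t[1]]
        # longest containing span, leftmost on ties
        best = max(candidates, key=lambda t: (t[1], -t[0]))
        ng = _ngram_of(best, tokens)
        phi_by_ngram[ng] = phi_by_ngram.get(ng, 0.0) + float(phi)
    return phi_by_ngram


def mean_shapn(per_sample: Sequence[dict[tuple[str, ...], float]]
               ) -> list[ShapNRecord]:
    """Dataset-mean SHAP-N table, descending.

    The mean runs over all samples (samples where the ngram never passed a
    max pool contribute 0); the support count reports in how many samples it
    did pass.
    """
    totals: dict[tuple[str, ...], float] = {}
    support: dict[tuple[str, ...], int] = {}
    for sample in per_sample:
        for ng, phi in sample.items():
            totals[ng] = totals.get(ng, 0.0) + phi
            support[ng] = support.get(ng, 0) + 1
    S = max(len(per_sample), 1)
    records = [ShapNRecord(ngram=ng, phi=t / S, support=support[ng])
               for ng, t in totals.items()]
    records.sort(key=lambda r: -r.phi)
    return records


def trigram_value_table(records: Sequence[ShapNRecord], keyword: str
                        ) -> list[tuple[float, float]]:
    """(value, phi) pairs for trigrams ``keyword value (H|L)``, sorted by value."""
    out = []
    for r in records:
        if len(r.ngram) != 3:
            continue
        kw, val, flag = r.ngram
        if kw.lower() != keyword.lower() or flag not in ("(H)", "(L)"):
            continue
        v = parse_number(val)
        if v is not None:
            out.append((v, r.phi))
    return sorted(out)


# --------------------------------------------------------------------------
# embedding probes
# --------------------------------------------------------------------------

def _number_embedding(phrase: str, model, vocab: Vocabulary, stage: str,
                      keywords=DEFAULT_KEYWORDS) -> np.ndarray:
    seq, mentions = prepare_tokens(tokenize(phrase), EmbeddingMode.ROOC, keywords)
    in_ctx = [m for m in mentions if m.in_context]
    if not in_ctx:
        raise ValueError(f"phrase {phrase!r} has no in-context number")
    m = in_ctx[0]
    ids = encode(seq, vocab, max_len=len(seq.tokens))
    if stage == EmbeddingMode.ROOC:
        return np.asarray(model.params["embed"][ids[m.position]], dtype=np.float64)
    note = embed_sequence(ids, in_ctx, stage, model.params["embed"],
                          model.scalenum_params, model.attn_params)
    return np.asarray(note.matrix[m.position], dtype=np.float64)


def embedding_correlation(phrase1: str, phrase2: str, model, vocab: Vocabulary,
                          stage: str, keywords=DEFAULT_KEYWORDS) -> float:
    """Pearson correlation of two phrases' number embeddings at a stage.

    Phrases follow the note format ``[BUN|creatinine] [value] ([L|H])``;
    stage is one of rooc / scalenum / attntonum.
    """
    v1 = _number_embedding(phrase1, model, vocab, stage, keywords)
    v2 = _number_embedding(phrase2, model, vocab, stage, keywords)
    return float(np.corrcoef(v1, v2)[0, 1])


def attention_weights(phrase: str, model, vocab: Vocabulary,
                      keywords=DEFAULT_KEYWORDS):
    """Per-head attention weights of a phrase's number over its window.

    Returns (weights, window_tokens): weights is (heads x window) and each
    row sums to 1.
    """
    seq, mentions = prepare_tokens(tokenize(phrase), EmbeddingMode.ROOC, keywords)
    in_ctx = [m for m in mentions if m.in_context]
    if not in_ctx:
        raise ValueError(f"phrase {phrase!r} has no in-context number")
    m = in_ctx[0]
    ids = encode(seq, vocab, max_len=len(seq.tokens))
    table = model.params["embed"]
    X = np.asarray(table[ids], dtype=np.float64).copy()
    sn = model.scalenum_params
    for mm in in_ctx:
        X[mm.position] = scalenum_embed(mm.value, sn)
    window = context_window(m, len(ids))
    _, weights, _ = attention_forward(X[m.position], X[window],
                                      model.attn_params)
    return weights, [seq.tokens[p] for p in window]
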