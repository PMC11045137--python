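"""Tokenization and numeric-context preprocessing for clinical notes.

Preoperative consult notes mix free text with lab mentions such as
``BUN 24.0 (H)`` or ``creatinine .7 (L)``, date strings, and out-of-context
numbers from other labs and vitals.  This module turns raw note text into
token sequences, tags dates, locates numeric tokens and decides whether each
sits inside the context window of a renal-function keyword, substitutes
out-of-context numbers with the ``_INUM_`` / ``_lgnum_`` tags (ROOC), and
builds the vocabulary / fixed-length id encodings the classifiers consume.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TokenSequence",
    "NumericMention",
    "Vocabulary",
    "EmbeddingMode",
    "DEFAULT_KEYWORDS",
    "tokenize",
    "tag_dates",
    "find_numeric_mentions",
    "rooc_transform",
    "prepare_tokens",
    "build_vocab",
    "encode",
]

DEFAULT_KEYWORDS = ("bun", "creatinine")

DATE_TAG = "_date_"
INUM_TAG = "_INUM_"
LGNUM_TAG = "_lgnum_"

#: numbers replaced by _lgnum_ when strictly greater than this (ties -> _INUM_)
LARGE_NUMBER_CUTOFF = 1000.0

_DATE_RE = re.compile(r"\d{1,2}/\d{1,2}/\d{2,4}")
_NUMBER_RE = re.compile(r"\.\d+|\d+(?:\.\d+)?")
_FLAG_RE = re.compile(r"\([A-Za-z]+\)")
_WORD_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_/'-]*")
_EDGE_PUNCT = ".,;:!?\"'()*"


@dataclass
class TokenSequence:
    """An ordered token stream from one note (no empty tokens)."""

    tokens: list[str]
    source_note_id: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass(frozen=True)
class NumericMention:
    """A number token: position, parsed value, governing keyword and context flag.

    ``in_context`` is true iff some keyword occurrence ``k`` satisfies
    ``k - left <= position <= k + right`` with ``position != k``; ``keyword``
    and ``keyword_position`` then record the governing occurrence (the nearest
    one, ties broken leftward).
    """

    position: int
    value: float
    keyword: str | None = None
    keyword_position: int | None = None
    in_context: bool = False


class EmbeddingMode:
    """The four numeric-embedding strategies."""

    BASIC = "basic"
    ROOC = "rooc"
    SCALENUM = "scalenum"
    ATTNTONUM = "attntonum"

    ALL = (BASIC, ROOC, SCALENUM, ATTNTONUM)
    #: modes whose in-context numbers bypass the lookup table
    NUMERIC_PATH = (SCALENUM, ATTNTONUM)


def _fullmatch_special(tok: str) -> bool:
    return bool(
        _DATE_RE.fullmatch(tok)
        or _NUMBER_RE.fullmatch(tok)
        or _FLAG_RE.fullmatch(tok)
    )


def _split_chunk(chunk: str) -> list[str]:
    # peel punctuation off the edges unless the chunk is a number, a date or
    # a parenthesized flag like "(H)"; interior punctuation (hyphens, slashes)
    # stays fused so forms like "_date_-bun" survive as single tokens
    if not chunk:
        return []
    if _fullmatch_special(chunk) or _WORD_RE.fullmatch(chunk):
        return [chunk]
    if len(chunk) > 1 and chunk[0] in _EDGE_PUNCT:
        return [chunk[0]] + _split_chunk(chunk[1:])
    if len(chunk) > 1 and chunk[-1] in _EDGE_PUNCT:
        return _split_chunk(chunk[:-1]) + [chunk[-1]]
    return [chunk]


def tokenize(text: str, note_id: str = "") -> TokenSequence:
    """Whitespace tokenization that keeps numbers, dates and ``(H)``-style
    flags as single tokens and pads other edge punctuation off words.

    ``"BUN 24.0 (H)"`` -> ``["BUN", "24.0", "(H)"]``;
    ``"creatinine .7 (L)"`` keeps the leading-dot decimal intact.
    """
    tokens: list[str] = []
    for chunk in text.split():
        tokens.extend(_split_chunk(chunk))
    return TokenSequence(tokens=[t for t in tokens if t], source_note_id=note_id)


def tag_dates(seq: TokenSequence) -> TokenSequence:
    """Replace date substrings (``dd/dd/dd``, ``dd/dd/dddd``) with ``_date_``.

    Sequence length is preserved; hyphen-fused forms such as ``03/04/18-BUN``
    become ``_date_-BUN``.
    """
    out = [_DATE_RE.sub(DATE_TAG, tok) for tok in seq.tokens]
    return TokenSequence(tokens=out, source_note_id=seq.source_note_id)


def parse_number(token: str) -> float | None:
    """Parsed value of a number token, or None for pseudo-numbers ('1.2.3')."""
    if _NUMBER_RE.fullmatch(token):
        return float(token)
    return None


def _is_keyword(token: str, keywords: Sequence[str]) -> str | None:
    norm = token.lower()
    for kw in keywords:
        k = kw.lower()
        if norm == k or norm.endswith("-" + k):
            return k
    return None


def find_numeric_mentions(
    seq: TokenSequence,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    left: int = 1,
    right: int = 2,
) -> list[NumericMention]:
    """Locate every strictly positive number token and classify its context.

    A number at position ``p`` is in context iff a keyword occurrence ``k``
    (case-insensitive; hyphen-fused forms like ``_date_-bun`` count) satisfies
    ``k - left <= p <= k + right``, ``p != k``.  Default window: 1 token left,
    2 tokens right of ``BUN`` / ``creatinine``.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    if left < 0 or right < 0:
        raise ValueError("window sizes must be non-negative")
    kw_positions = [
        (i, kw)
        for i, tok in enumerate(seq.tokens)
        if (kw := _is_keyword(tok, keywords)) is not None
    ]
    mentions: list[NumericMention] = []
    for p, tok in enumerate(seq.tokens):
        value = parse_number(tok)
        if value is None or value <= 0:
            continue
        governing: tuple[int, str] | None = None
        for k, kw in kw_positions:
            if p != k and k - left <= p <= k + right:
                if governing is None or abs(k - p) < abs(governing[0] - p):
                    governing = (k, kw)
        if governing is not None:
            mentions.append(
                NumericMention(
                    position=p,
                    value=value,
                    keyword=governing[1],
                    keyword_position=governing[0],
                    in_context=True,
                )
            )
        else:
            mentions.append(NumericMention(position=p, value=value))
    return mentions


def rooc_transform(
    seq: TokenSequence, mentions: Iterable[NumericMention]
) -> TokenSequence:
    """Replace Out-Of-Context numbers with ``_INUM_`` (value <= 1000) or
    ``_lgnum_`` (value > 1000); in-context numbers and non-numbers untouched.
    """
    out = list(seq.tokens)
    for m in mentions:
        if not m.in_context:
            out[m.position] = LGNUM_TAG if m.value > LARGE_NUMBER_CUTOFF else INUM_TAG
    return TokenSequence(tokens=out, source_note_id=seq.source_note_id)


def prepare_tokens(
    seq: TokenSequence,
    mode: str,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    left: int = 1,
    right: int = 2,
) -> tuple[TokenSequence, list[NumericMention]]:
    """Full mode-dependent preprocessing: date tagging, mention detection and
    (for every mode except Basic) ROOC substitution.

    Returns the transformed sequence plus the mentions of the *transformed*
    sequence (in-context numbers keep their surface forms in every mode).
    """
    if mode not in EmbeddingMode.ALL:
        raise ValueError(f"unknown embedding mode: {mode!r}")
    seq = tag_dates(seq)
    mentions = find_numeric_mentions(seq, keywords, left, right)
    if mode != EmbeddingMode.BASIC:
        seq = rooc_transform(seq, mentions)
        mentions = [m for m in mentions if m.in_context]
    return seq, mentions


@dataclass
class Vocabulary:
    """Token -> id map with reserved ids.

    id 0 is padding and is never assigned to a real token; ids 1-4 are the
    unknown token and the ``_date_`` / ``_INUM_`` / ``_lgnum_`` tags.
    """

    PAD_ID = 0
    UNK_ID = 1

    token_to_id: dict[str, int] = field(default_factory=dict)

    RESERVED = ("<pad>", "<unk>", DATE_TAG, INUM_TAG, LGNUM_TAG)

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.RESERVED):
            self.token_to_id.setdefault(tok, i)

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.UNK_ID)

    def add(self, token: str) -> int:
        if token not in self.token_to_id:
            self.token_to_id[token] = len(self.token_to_id)
        return self.token_to_id[token]


def build_vocab(
    corpus: Iterable[TokenSequence],
    mode: str,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    left: int = 1,
    right: int = 2,
    min_count: int = 1,
) -> Vocabulary:
    """Vocabulary from a (training) corpus under an embedding mode.

    Basic keeps number tokens as ordinary entries; ROOC keeps only in-context
    numbers (OOC ones were replaced by tags); ScaleNum / AttnToNum exclude all
    number surface forms, since those route through the numeric embedding path.
    Entries get ids by descending frequency, ties alphabetical.
    """
    counts: Counter[str] = Counter()
    n_seqs = 0
    for seq in corpus:
        n_seqs += 1
        prepped, _ = prepare_tokens(seq, mode, keywords, left, right)
        counts.update(prepped.tokens)
    if n_seqs == 0:
        raise ValueError("empty corpus")
    vocab = Vocabulary()
    drop_numbers = mode in EmbeddingMode.NUMERIC_PATH
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for tok, c in ordered:
        if c < min_count or tok in vocab:
            continue
        if drop_numbers and parse_number(tok) is not None:
            continue
        vocab.add(tok)
    return vocab


def encode(seq: TokenSequence, vocab: Vocabulary, max_len: int = 3000) -> list[int]:
    """Fixed-length id encoding: unknown -> unk id, truncate at ``max_len``,
    right-pad with 0."""
    ids = [vocab.id_of(t) for t in seq.tokens[:max_len]]
    ids.extend([Vocabulary.PAD_ID] * (max_len - len(ids)))
    return ids
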