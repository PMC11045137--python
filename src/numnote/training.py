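"""Experiment harness: stratified splits, model fitting, calibration, AUC.

The evaluation protocol is 10 random-split experiments.  Each experiment
holds out a random stratified 15% of the notes, splits the remainder
85%/15% into training and validation, fits the classifier on the training
notes (vocabulary built from the training split only), fits a binned linear
calibration of predicted probability against observed outcome rate on the
validation set, and reports AUC on the holdout set.  The same split seeds
are shared across embedding modes and architectures so per-split AUC vectors
are directly comparable (the input to the sign-flip permutation test in
``numnote.stats``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .io import NoteRecord
from .textprep import (
    DEFAULT_KEYWORDS,
    EmbeddingMode,
    NumericMention,
    TokenSequence,
    Vocabulary,
    build_vocab,
    encode,
    prepare_tokens,
    tokenize,
)
from .models import (
    Adam,
    TextCNNConfig,
    TextLSTMConfig,
    bce_with_logits,
    build_model,
)

__all__ = [
    "SplitIndices",
    "CalibrationFit",
    "ExperimentResult",
    "Summary",
    "stratified_split",
    "fit",
    "FitResult",
    "calibrate",
    "auc",
    "run_experiments",
    "summarize",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitIndices:
    """Disjoint, covering train/validation/holdout index sets."""

    train: np.ndarray
    validation: np.ndarray
    holdout: np.ndarray
    seed: int


def _allocate_per_class(class_counts: dict, total: int) -> dict:
    """Largest-remainder allocation of ``total`` slots across classes."""
    n = sum(class_counts.values())
    ideal = {c: total * cnt / n for c, cnt in class_counts.items()}
    base = {c: int(math.floor(v)) for c, v in ideal.items()}
    short = total - sum(base.values())
    order = sorted(class_counts, key=lambda c: (ideal[c] - base[c], c), reverse=True)
    for c in order[:short]:
        base[c] += 1
    return base


def _stratified_take(indices_by_class: dict, labels: np.ndarray, total: int,
                     rng: np.random.Generator):
    counts = {c: len(ix) for c, ix in indices_by_class.items()}
    alloc = _allocate_per_class(counts, total)
    taken, rest = [], []
    for c, ix in indices_by_class.items():
        ix = np.array(ix)
        perm = rng.permutation(len(ix))
        taken.append(ix[perm[: alloc[c]]])
        rest.append(ix[perm[alloc[c]:]])
    return np.sort(np.concatenate(taken)), np.concatenate(rest)


def stratified_split(labels: Sequence[int], holdout_frac: float = 0.15,
                     val_frac: float = 0.15, seed: int = 0) -> SplitIndices:
    """Stratified holdout / validation / train split.

    The holdout takes ``round(holdout_frac * n)`` samples (round half away
    from zero), then the validation takes ``round(val_frac * remaining)``;
    within each stage, class slots are assigned by largest-remainder
    allocation so each part's outcome prevalence tracks the global rate.
    Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least two samples of each class")
    rng = np.random.default_rng(seed)
    by_class = {int(c): np.flatnonzero(labels == c) for c in classes}

    n = len(labels)
    holdout, pool = _stratified_take(by_class, labels, _round_half_away(holdout_frac * n), rng)
    pool_by_class = {int(c): pool[labels[pool] == c] for c in classes}
    n_val = _round_half_away(val_frac * len(pool))
    validation, train = _stratified_take(pool_by_class, labels, n_val, rng)
    return SplitIndices(train=np.sort(train), validation=validation,
                        holdout=holdout, seed=seed)


@dataclass
class CalibrationFit:
    """Linear fit of observed outcome rate on binned mean prediction."""

    slope: float
    intercept: float
    bin_width: float = 0.1
    bins: list = field(default_factory=list)  # (mean_pred, observed_rate, count)

    def apply(self, preds: np.ndarray) -> np.ndarray:
        return np.clip(self.slope * np.asarray(preds) + self.intercept, 0.0, 1.0)


def calibrate(val_preds: Sequence[float], val_labels: Sequence[int],
              bin_width: float = 0.1) -> CalibrationFit:
    """Binned linear calibration.

    Predictions are grouped in bins [0, 0.1), ..., [0.9, 1.0] (upper bin
    closed); empty bins are dropped; ordinary least squares regresses each
    bin's observed outcome rate on its mean prediction.  Fewer than two
    non-empty bins yields the identity fit with a warning.
    """
    p = np.asarray(val_preds, dtype=float)
    y = np.asarray(val_labels, dtype=float)
    if p.size != y.size:
        raise ValueError("predictions and labels differ in length")
    n_bins = int(round(1.0 / bin_width))
    idx = np.minimum((p / bin_width).astype(int), n_bins - 1)
    bins = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            bins.append((float(p[mask].mean()), float(y[mask].mean()),
                         int(mask.sum())))
    if len(bins) < 2:
        warnings.warn("fewer than 2 non-empty calibration bins; identity fit")
        return CalibrationFit(slope=1.0, intercept=0.0, bin_width=bin_width,
                              bins=bins)
    x = np.array([b[0] for b in bins])
    r = np.array([b[1] for b in bins])
    A = np.stack([x, np.ones_like(x)], axis=1)
    (slope, intercept), *_ = np.linalg.lstsq(A, r, rcond=None)
    return CalibrationFit(slope=float(slope), intercept=float(intercept),
                          bin_width=bin_width, bins=bins)


def auc(preds: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(preds, dtype=float)))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class PreparedNote:
    ids: list[int]
    mentions: list[NumericMention]


@dataclass
class FitResult:
    model: object
    vocab: Vocabulary
    val_probs: np.ndarray
    holdout_probs: np.ndarray
    holdout_probs_calibrated: np.ndarray
    calibration: CalibrationFit
    epoch_losses: list[float]


def _prepare_corpus(notes: Sequence[NoteRecord], mode: str,
                    keywords: Sequence[str]) -> list[tuple[TokenSequence, list]]:
    out = []
    for rec in notes:
        seq = tokenize(rec.text, rec.note_id)
        out.append(prepare_tokens(seq, mode, keywords))
    return out


def _encode_corpus(prepped, vocab: Vocabulary, max_len: int) -> list[PreparedNote]:
    out = []
    for seq, mentions in prepped:
        ids = encode(seq, vocab, max_len)
        out.append(PreparedNote(ids=ids, mentions=[m for m in mentions
                                                   if m.in_context]))
    return out


def _collate(notes: list[PreparedNote], min_len: int = 5):
    lengths = [sum(1 for i in n.ids if i != Vocabulary.PAD_ID) for n in notes]
    L = max(max(lengths), min_len)
    ids = np.array([n.ids[:L] for n in notes], dtype=np.int64)
    mentions = [n.mentions for n in notes]
    return ids, mentions


def predict_proba(model, notes: list[PreparedNote], batch_size: int = 128) -> np.ndarray:
    probs = []
    for i in range(0, len(notes), batch_size):
        ids, mentions = _collate(notes[i:i + batch_size])
        logits, _ = model.forward(ids, mentions, train=False)
        probs.append(1.0 / (1.0 + np.exp(-np.asarray(logits, dtype=np.float64))))
    return np.concatenate(probs)


def fit(config, mode: str, notes: Sequence[NoteRecord], labels: Sequence[int],
        split: SplitIndices, seed: int = 0,
        keywords: Sequence[str] = DEFAULT_KEYWORDS) -> FitResult:
    """Train one model on a split and return validation/holdout predictions.

    The vocabulary is built from the training split only; training runs the
    configured number of epochs of Adam on mean binary cross-entropy, with
    per-epoch reshuffling; validation predictions feed the calibration fit,
    which is then applied to the holdout predictions.
    """
    labels = np.asarray(labels)
    if min(len(split.train), len(split.validation), len(split.holdout)) == 0:
        raise ValueError("empty split")
    prepped = _prepare_corpus(notes, mode, keywords)
    vocab = build_vocab((prepped[i][0] for i in split.train), mode, keywords)
    enc = _encode_corpus(prepped, vocab, config.max_len)

    rng = np.random.default_rng(seed)
    model = build_model(config, len(vocab), mode, rng)
    opt = Adam(model.params, lr=config.learning_rate)
    train_ix = np.array(split.train)
    y = labels.astype(np.float64)
    losses = []
    for _ in range(config.epochs):
        order = rng.permutation(len(train_ix))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = train_ix[order[start:start + config.batch_size]]
            ids, mentions = _collate([enc[i] for i in batch])
            logits, cache = model.forward(ids, mentions, train=True)
            loss, dlogits = bce_with_logits(logits, y[batch])
            grads = model.backward(dlogits, cache)
            opt.step(grads)
            epoch_loss += loss * len(batch)
        losses.append(epoch_loss / len(train_ix))

    val_probs = predict_proba(model, [enc[i] for i in split.validation])
    holdout_probs = predict_proba(model, [enc[i] for i in split.holdout])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cal = calibrate(val_probs, labels[split.validation])
    return FitResult(
        model=model,
        vocab=vocab,
        val_probs=val_probs,
        holdout_probs=holdout_probs,
        holdout_probs_calibrated=cal.apply(holdout_probs),
        calibration=cal,
        epoch_losses=losses,
    )


# --------------------------------------------------------------------------
# multi-experiment harness
# --------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    architecture: str
    mode: str
    holdout_aucs: list[float]
    calibrations: list[CalibrationFit]
    seeds: list[int]


@dataclass
class Summary:
    mean: float
    variance: float  # sample variance (ddof=1)
    ci_low: float
    ci_high: float


def summarize(aucs: Sequence[float], n_boot: int = 10000,
              seed: int = 0) -> Summary:
    """Mean, sample variance and 95% percentile-bootstrap CI of an AUC vector."""
    a = np.asarray(aucs, dtype=float)
    rng = np.random.default_rng(seed)
    means = rng.choice(a, size=(n_boot, len(a)), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return Summary(mean=float(a.mean()), variance=float(a.var(ddof=1)),
                   ci_low=float(lo), ci_high=float(hi))


def run_experiments(
    notes: Sequence[NoteRecord],
    labels: Sequence[int],
    modes: Sequence[str],
    configs: dict,
    n_experiments: int = 10,
    base_seed: int = 0,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> dict[tuple[str, str], ExperimentResult]:
    """Run the split-sharing experiment grid.

    ``configs`` maps architecture name to its config.  Every (architecture,
    mode) cell reuses the identical per-experiment splits, so AUC vectors are
    aligned by split for the paired permutation test.
    """
    labels = np.asarray(labels)
    splits = [stratified_split(labels, seed=base_seed + i)
              for i in range(n_experiments)]
    results: dict[tuple[str, str], ExperimentResult] = {}
    for arch, config in configs.items():
        for mode in modes:
            aucs, cals, seeds = [], [], []
            for i, split in enumerate(splits):
                fit_seed = base_seed + i
                res = fit(config, mode, notes, labels, split, seed=fit_seed,
                          keywords=keywords)
                aucs.append(auc(res.holdout_probs, labels[split.holdout]))
                cals.append(res.calibration)
                seeds.append(fit_seed)
            results[(arch, mode)] = ExperimentResult(
                architecture=arch, mode=mode, holdout_aucs=aucs,
                calibrations=cals, seeds=seeds)
    return results
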