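"""Seeded generator of surgical-consult-style notes with labeled outcomes.

The real corpus this package's methods were developed for is protected
health information, so every pipeline stage is exercised on synthetic notes
that emulate its statistical structure: free text with occasional bulleted
symptom lists, date strings, out-of-context numbers from other labs and
vitals (both below and above 1000, so the ``_INUM_`` and ``_lgnum_`` tags
each occur), and exactly one BUN and one creatinine mention per note in the
transcription format ``BUN 24.0 (H)`` / ``creatinine .7 (L)``.  Flags follow
the charting cutoffs: BUN is (H) above 20, creatinine above 1.0.

Outcomes are drawn from a logistic ground truth on the log lab values,

    P(outcome) = sigmoid(beta0 + bB*(log BUN - mB) + bC*(log Cr - mC)),

with beta0 bisected so the mean probability matches the target prevalence
(default 32.6%).  A ``flag_only`` switch makes the outcome depend on the
(H)/(L) indicators instead, removing any within-flag magnitude signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import NoteRecord, write_labels, write_notes
from .textprep import parse_number

__all__ = ["SynthConfig", "SynthCorpus", "generate_note", "generate_corpus",
           "make_separable_corpus", "write_corpus"]


_FILLER_WORDS = (
    "patient presents with history of and was seen in clinic for "
    "evaluation of coronary artery disease referred by cardiology team "
    "denies reports states notes exam unremarkable stable improved "
    "discussed plan continue follow up surgical consult obtained prior "
    "echo showed mild moderate severe stenosis lesion vessel disease "
    "tobacco use former smoker hypertension diabetes hyperlipidemia on "
    "medications including aspirin statin beta blocker currently "
    "ambulates without assistance lives at home with family tolerating "
    "diet well no acute distress alert oriented heart regular rate rhythm "
    "lungs clear bilaterally extremities warm well perfused incision "
    "planned risks benefits reviewed consent signed will proceed with "
    "operative intervention pending optimization renal function monitored "
    "closely overnight telemetry"
).split()

_SYMPTOMS = (
    "chest pain", "shortness of breath", "fatigue", "dizziness",
    "palpitations", "orthopnea", "leg swelling", "nausea", "diaphoresis",
    "exertional dyspnea",
)

#: out-of-context labs/vitals: (name, low, high, decimals)
_OOC_LABS = (
    ("Cl", 88.0, 112.0, 1),
    ("Na", 130.0, 146.0, 1),
    ("K", 3.2, 5.8, 1),
    ("glucose", 78.0, 320.0, 1),
    ("WBC", 3.5, 14.0, 1),
    ("HR", 55.0, 115.0, 1),
    ("platelets", 140000.0, 420000.0, 0),
)

BUN_FLAG_CUTOFF = 20.0
CREATININE_FLAG_CUTOFF = 1.0


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the target corpus conditions."""

    n_notes: int = 1000
    prevalence: float = 0.326
    bun_log_mean: float = float(np.log(18.0))
    bun_log_sd: float = 0.5
    creatinine_log_mean: float = 0.0  # median 1.0
    creatinine_log_sd: float = 0.4
    beta_bun: float = 1.5
    beta_creatinine: float = 2.0
    flag_only: bool = False
    note_len_range: tuple[int, int] = (60, 160)
    bullet_fraction: float = 0.35
    max_dates: int = 3
    ooc_labs_range: tuple[int, int] = (2, 5)
    fused_date_fraction: float = 0.15
    seed: int = 0


@dataclass
class SynthCorpus:
    """Generated notes plus the ground truth behind their labels."""

    records: list[NoteRecord]
    bun: np.ndarray
    creatinine: np.ndarray
    probability: np.ndarray
    config: SynthConfig


def _format_value(v: float, decimals: int) -> str:
    if decimals == 0:
        return f"{v:.0f}"
    s = f"{v:.{decimals}f}"
    if s.startswith("0."):
        s = s[1:]  # charting style: "creatinine .7 (L)"
    return s


def _random_date(rng: np.random.Generator) -> str:
    month = rng.integers(1, 13)
    day = rng.integers(1, 29)
    year = rng.integers(14, 23)
    return f"{month:02d}/{day:02d}/{year:02d}"


def _lab_unit(name: str, value_str: str, flag: str | None) -> list[str]:
    toks = [name, value_str]
    if flag is not None:
        toks.append(f"({flag})")
    return toks


def generate_note(config: SynthConfig, rng: np.random.Generator,
                  note_id: str, bun: float, creatinine: float) -> NoteRecord:
    """One synthetic consult note containing the given BUN/creatinine values.

    The note mixes filler prose, an optional bulleted symptom list, dates,
    nuisance lab mentions and exactly one BUN and one creatinine unit whose
    (H)/(L) flags follow the charting cutoffs.
    """
    n_target = int(rng.integers(*config.note_len_range))
    parts: list[str] = []

    parts.extend(rng.choice(_FILLER_WORDS, size=max(8, n_target // 4)))

    if rng.random() < config.bullet_fraction:
        for s in rng.choice(len(_SYMPTOMS), size=int(rng.integers(2, 5)),
                            replace=False):
            parts.extend(["-", *_SYMPTOMS[s].split()])

    for _ in range(int(rng.integers(0, config.max_dates + 1))):
        parts.append(_random_date(rng))

    # labs line: nuisance labs + the two renal values, each unit separated
    # by a non-numeric token so windows never capture a neighbour's number
    lab_tokens: list[str] = ["labs", "reviewed", ":"]
    n_ooc = int(rng.integers(config.ooc_labs_range[0],
                             config.ooc_labs_range[1] + 1))
    picks = rng.choice(len(_OOC_LABS), size=n_ooc, replace=False)
    units: list[list[str]] = []
    for j in picks:
        name, lo, hi, dec = _OOC_LABS[int(j)]
        v = float(rng.uniform(lo, hi))
        flag = None
        if rng.random() < 0.3:
            flag = "H" if rng.random() < 0.5 else "L"
        units.append(_lab_unit(name, _format_value(v, dec), flag))

    bun_name = "BUN"
    if rng.random() < config.fused_date_fraction:
        bun_name = f"{_random_date(rng)}-BUN"
    units.append(_lab_unit(
        bun_name, _format_value(bun, 1),
        "H" if bun > BUN_FLAG_CUTOFF else "L"))
    cr_name = "creatinine" if rng.random() < 0.7 else "Creatinine"
    units.append(_lab_unit(
        cr_name, _format_value(creatinine, 1),
        "H" if creatinine > CREATININE_FLAG_CUTOFF else "L"))

    rng.shuffle(units)
    for u in units:
        lab_tokens.extend(u)
        sep = rng.choice(_FILLER_WORDS, size=int(rng.integers(1, 3)))
        lab_tokens.extend(sep)
        if rng.random() < 0.25:
            lab_tokens.append(_random_date(rng))

    insert_at = int(rng.integers(0, len(parts) + 1))
    tokens = parts[:insert_at] + lab_tokens + parts[insert_at:]
    while len(tokens) < n_target:
        tokens.append(str(rng.choice(_FILLER_WORDS)))
    return NoteRecord(note_id=note_id, text=" ".join(tokens))


def _tune_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Bisect beta0 so mean sigmoid(beta0 + eta) hits the target prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate the full corpus; byte-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_notes
    bun_raw = np.exp(rng.normal(config.bun_log_mean, config.bun_log_sd, n))
    cr_raw = np.exp(rng.normal(config.creatinine_log_mean,
                               config.creatinine_log_sd, n))
    # the model only ever sees the charted (rounded, >= 0.1) values, so the
    # ground truth uses them too
    bun = np.maximum(np.round(bun_raw, 1), 0.1)
    cr = np.maximum(np.round(cr_raw, 1), 0.1)

    if config.flag_only:
        eta = (config.beta_bun * (bun > BUN_FLAG_CUTOFF)
               + config.beta_creatinine * (cr > CREATININE_FLAG_CUTOFF))
    else:
        eta = (config.beta_bun * (np.log(bun) - config.bun_log_mean)
               + config.beta_creatinine * (np.log(cr) - config.creatinine_log_mean))
    beta0 = _tune_intercept(eta, config.prevalence)
    prob = 1.0 / (1.0 + np.exp(-(beta0 + eta)))
    labels = (rng.random(n) < prob).astype(int)

    records = []
    for i in range(n):
        rec = generate_note(config, rng, note_id=f"note{i:05d}",
                            bun=float(bun[i]), creatinine=float(cr[i]))
        rec.label = int(labels[i])
        records.append(rec)
    return SynthCorpus(records=records, bun=bun, creatinine=cr,
                       probability=prob, config=config)


def make_separable_corpus(n: int = 200, seed: int = 0,
                          prevalence: float = 0.4) -> list[NoteRecord]:
    """Trivially separable control corpus: the token SICK appears iff label 1."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        label = int(rng.random() < prevalence)
        words = list(rng.choice(_FILLER_WORDS, size=int(rng.integers(20, 40))))
        if label:
            words.insert(int(rng.integers(0, len(words))), "SICK")
        records.append(NoteRecord(note_id=f"sep{i:04d}", text=" ".join(words),
                                  label=label))
    return records


def write_corpus(corpus: SynthCorpus, out_dir) -> None:
    """notes CSV + labels CSV + ground-truth JSON-lines (synthetic data)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_notes(corpus.records, out / "notes.csv")
    write_labels(corpus.records, out / "labels.csv")
    with (out / "truth.jsonl").open("w") as fh:
        for i, rec in enumerate(corpus.records):
            fh.write(json.dumps({
                "note_id": rec.note_id,
                "bun": float(corpus.bun[i]),
                "creatinine": float(corpus.creatinine[i]),
                "probability": float(corpus.probability[i]),
                "label": rec.label,
                "synthetic": True,
            }) + "\n")
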