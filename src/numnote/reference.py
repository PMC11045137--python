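"""Published per-split holdout AUCs for the four numeric-embedding modes.

The original clinical evaluation of these embedding techniques ran 10
shared-split experiments on a single-center corpus of 1,738 preoperative
CABG consult notes (PHI, not distributable).  Its reported per-split holdout
AUC vectors are reproduced here as inputs: they are what the sign-flip
permutation comparisons and the summary arithmetic operate on, and the only
part of that evaluation that can be recomputed without the protected corpus.
"""

from __future__ import annotations

__all__ = ["TEXTCNN_HOLDOUT_AUCS", "TEXTLSTM_HOLDOUT_AUCS"]

#: TextCNN holdout AUCs, 10 shared splits per embedding mode
TEXTCNN_HOLDOUT_AUCS: dict[str, list[float]] = {
    "Basic":     [0.766, 0.767, 0.742, 0.738, 0.798, 0.800, 0.799, 0.815, 0.797, 0.854],
    "ROOC":      [0.813, 0.796, 0.782, 0.758, 0.832, 0.813, 0.802, 0.805, 0.778, 0.834],
    "ScaleNum":  [0.825, 0.798, 0.799, 0.741, 0.813, 0.815, 0.826, 0.828, 0.789, 0.845],
    "AttnToNum": [0.804, 0.843, 0.800, 0.782, 0.829, 0.816, 0.843, 0.833, 0.795, 0.860],
}

#: TextLSTM holdout AUCs on the same 10 splits
TEXTLSTM_HOLDOUT_AUCS: dict[str, list[float]] = {
    "Basic":     [0.789, 0.748, 0.770, 0.760, 0.804, 0.778, 0.789, 0.787, 0.785, 0.805],
    "ROOC":      [0.797, 0.773, 0.789, 0.761, 0.827, 0.827, 0.821, 0.784, 0.781, 0.815],
    "ScaleNum":  [0.830, 0.808, 0.816, 0.765, 0.813, 0.842, 0.830, 0.840, 0.790, 0.838],
    "AttnToNum": [0.846, 0.834, 0.802, 0.774, 0.827, 0.836, 0.826, 0.816, 0.807, 0.881],
}
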