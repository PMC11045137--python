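import numpy as np
import pytest

from numnote.models import TextCNNConfig
from numnote.synthdata import SynthConfig, generate_corpus
from numnote.training import auc, fit, stratified_split

END_TO_END_MODES = ("basic", "scalenum", "attntonum")


@pytest.fixture(scope="session")
def small_corpus():
    """300 synthetic consult notes with log-lab-driven outcomes."""
    return generate_corpus(SynthConfig(n_notes=300, seed=11))


@pytest.fixture(scope="session")
def trained_attn(small_corpus):
    """A TextCNN/AttnToNum model trained on the small synthetic corpus."""
    labels = np.array([r.label for r in small_corpus.records])
    cfg = TextCNNConfig(epochs=12, max_len=256)
    split = stratified_split(labels, seed=3)
    res = fit(cfg, "attntonum", small_corpus.records, labels, split, seed=3)
    return {"corpus": small_corpus, "labels": labels, "cfg": cfg,
            "split": split, "res": res}


@pytest.fixture(scope="session")
def endtoend_grid():
    """The reduced-scale embedding-comparison grid on synthetic notes.

    1,000 notes, max_len 512, 15 epochs; Basic vs ScaleNum vs AttnToNum on
    5 shared splits (seeds 0-4); keeps the best AttnToNum fit for
    attribution checks.
    """
    corpus = generate_corpus(SynthConfig(n_notes=1000, seed=7))
    labels = np.array([r.label for r in corpus.records])
    cfg = TextCNNConfig(epochs=15, max_len=512)
    aucs = {m: [] for m in END_TO_END_MODES}
    best = None
    for i in range(5):
        split = stratified_split(labels, seed=i)
        for mode in END_TO_END_MODES:
            res = fit(cfg, mode, corpus.records, labels, split, seed=i)
            a = auc(res.holdout_probs, labels[split.holdout])
            aucs[mode].append(a)
            if mode == "attntonum" and (best is None or a > best["auc"]):
                best = {"res": res, "split": split, "auc": a}
    return {"corpus": corpus, "labels": labels, "cfg": cfg,
            "aucs": aucs, "best": best}
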