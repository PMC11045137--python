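"""Generate a synthetic surgical-consult corpus and inspect one note.

Outcomes follow a logistic model on log BUN and log creatinine, with the
intercept bisected to a 32.6% prevalence.  Every note carries exactly one
BUN and one creatinine mention with (H)/(L) flags at the charting cutoffs
(BUN > 20, creatinine > 1.0).
"""

import numpy as np

from numnote.synthdata import SynthConfig, generate_corpus

corpus = generate_corpus(SynthConfig(n_notes=500, seed=42))
labels = np.array([r.label for r in corpus.records])

print(f"{len(corpus.records)} notes, outcome prevalence {labels.mean():.3f}")
print(f"BUN median {np.median(corpus.bun):.1f}, "
      f"creatinine median {np.median(corpus.creatinine):.2f}")
print()
print("--- first note ---")
print(corpus.records[0].text[:400], "...")
print(f"label={corpus.records[0].label}  "
      f"true P(outcome)={corpus.probability[0]:.3f}  "
      f"BUN={corpus.bun[0]}  creatinine={corpus.creatinine[0]}")
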