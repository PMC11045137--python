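"""Preprocess a note snippet: tokenize, tag dates, find and replace numbers.

Numbers inside the context window of BUN / creatinine (1 token left, 2
right) are kept for the numeric embedding path; all other numbers collapse
to the _INUM_ / _lgnum_ tags so they stop inflating the vocabulary.
"""

from numnote import textprep as tp

text = "Cl 93.0 (L) 03/04/18 creatinine 5.2 (H) 03/05/18 platelets 250000"

seq = tp.tag_dates(tp.tokenize(text))
print("tokens:        ", seq.tokens)

mentions = tp.find_numeric_mentions(seq)
for m in mentions:
    where = f"in context of '{m.keyword}'" if m.in_context else "out of context"
    print(f"number {m.value:>9} at position {m.position}: {where}")

print("after ROOC:    ", tp.rooc_transform(seq, mentions).tokens)
# the creatinine value survives as a number; 93.0 becomes _INUM_ and the
# platelet count (over 1000) becomes _lgnum_
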