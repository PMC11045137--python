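"""ScaleNum in action: similar magnitudes get similar embeddings.

ScaleNum maps a positive value through K=5 learned sigmoid-linear-log
transforms and sums them, so 1.7 and 1.8 land near each other in embedding
space even if neither value ever occurred in training.  Here the parameters
are randomly initialized; training moves them, but the smoothness in x is
structural.
"""

import numpy as np

from numnote.numembed import ScaleNumParams, scalenum_embed

rng = np.random.default_rng(0)
params = ScaleNumParams.init(rng, n_transforms=5, embed_dim=50, scale=1.0)

for pair in [(1.7, 1.8), (1.7, 24.0), (24.0, 25.0), (24.0, 900.0)]:
    v1 = scalenum_embed(pair[0], params)
    v2 = scalenum_embed(pair[1], params)
    rho = np.corrcoef(v1, v2)[0, 1]
    print(f"corr(embed({pair[0]:>6}), embed({pair[1]:>6})) = {rho:+.3f}")
# close values correlate near +1; the correlation decays with the
# magnitude gap on the log scale
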