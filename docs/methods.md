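# Methods

## Preprocessing and the context window

Notes are whitespace-tokenized with three exceptions chosen to match how
clinicians chart labs: parenthesized flags (`(H)`, `(L)`) stay single
tokens, numbers (including leading-dot decimals like `.7`) stay single
tokens, and other edge punctuation is split off. Date substrings matching
`dd/dd/dd(dd)` become `_date_`, including inside hyphen-fused tokens
(`03/04/18-BUN` → `_date_-BUN`), which preserves keyword fusions seen in
real charting. A numeric token at position p is *in context* iff a keyword
occurrence k (default keywords `bun`, `creatinine`, case-insensitive,
hyphen-fused forms included) satisfies k−1 ≤ p ≤ k+2, p ≠ k; when several
keywords qualify, the nearest (ties leftward) governs. Out-of-context
numbers become `_INUM_` (value ≤ 1000; the tie at exactly 1000 maps small,
since the charting rule only distinguishes strictly less/greater) or
`_lgnum_`. Keyword fusions are matched but never split apart.

Vocabularies are built from the training split only, ordered by frequency
(ties alphabetical), with reserved ids: 0 padding (never a real token),
1 unknown, then the three tags. Under ScaleNum/AttnToNum all numeric
surface forms are excluded from the vocabulary — in-context numbers route
through the numeric path, so the embedding table carries no per-number
rows and the numeric parameter count is input-independent.

## Numeric embeddings

ScaleNum: ĝ(x) = Σₖ₌₁⁵ σ(aₖ·log(clamp(x,1,1000)) + bₖ) with aₖ, bₖ ∈ ℝ⁵⁰,
i.e. 500 learned scalars. Each component is a sigmoid of a linear-log, so
each of the 250 (k, dimension) cells can specialize to a different value
scale; the clamp keeps the log finite and saturates outside the clinically
occupied range. Zero or negative quantities are outside the model (the log
excludes them); the tokenizer's number pattern admits no negatives.

AttnToNum: the number's ĝ(x) is the query; keys and values are the
embeddings of the tokens in its context window (the 4-token layout
window = keyword−1 … keyword+2, with the number's own slot holding its
ScaleNum embedding). Five heads of dimension 10, scaled dot-product scores
(÷√10 — standard, since unscaled scores at this dimension saturate the
softmax), four 50×50 projections with offsets (10,200 parameters). The
attention output *replaces* the ScaleNum embedding at the number's
position (no residual add: the pipeline is sequential and a residual would
let the model bypass the context refinement). When two mentions share a
window, keys/values come from the post-ScaleNum, pre-attention snapshot,
so attention outputs never feed each other.

Initialization: embedding table N(0, 0.1); aₖ, bₖ N(0, 0.1); projections
uniform ±1/√50; conv/linear layers uniform fan-in; all seeds flow from a
single per-run generator, making runs bit-reproducible.

## Classifiers

TextCNN: valid (no temporal padding) 1-d convolutions of sizes 1/2/3/5,
44 kernels each, ReLU, then a note-wide max pool per filter restricted to
windows lying fully inside the note (one guard window for notes shorter
than the filter), which makes logits independent of batch padding length.
Dropout 0.5 is applied to the pooled 176-vector feeding the single linear
head — the head is where the parameter bottleneck is, and the pooled
vector is its input. The logit is therefore exactly
w₀ + Σ_f w_f a_{s,f}, the identity SHAP-N relies on.

TextLSTM: same front end; a bi-directional LSTM (hidden 88 per direction,
so the pooled output width matches TextCNN's 176) replaces the
convolutions. Each direction runs over the note's real tokens only (state
updates gated off past the note length — equivalent to packed sequences),
the backward direction on the reversed real prefix; the temporal max pool
runs over real steps. Gates use two offset vectors per bank (the
convention under which the post-embedding parameter count is 98,737).
Dropout 0 and 50 epochs by default: the recurrent model overfits earlier
and dropout did not regularize it.

Training: Adam (β 0.9/0.999), learning rate 3.5×10⁻⁴, batch 64, mean
binary cross-entropy on the logit, fixed epoch budget (100 CNN / 50 LSTM
at full scale), final-epoch weights; no early stopping. Batches are
trimmed to the longest note in the batch (padding beyond that cannot
affect any logit, see above), which is what makes CPU training practical.
All forward/backward passes are hand-written numpy, verified against
central finite differences to ~1e-11 in float64; training uses float32.

## Evaluation harness

Each experiment: stratified 15% holdout, then 15% of the remainder for
validation. Totals use round-half-away rounding and per-class
largest-remainder allocation, so each part's prevalence tracks the global
rate; splits are deterministic per seed and shared across embedding modes
and architectures. (At n = 1,738 this gives 261 / 222 / 1,255 — the three
parts necessarily sum to n.) Calibration: validation predictions binned at
width 0.1 (upper bin closed), empty bins dropped, OLS of observed outcome
rate on mean bin prediction; fewer than two occupied bins falls back to
the identity with a warning; applied outputs are clipped to [0, 1].
Calibration rescales probabilities but cannot change AUC (it is a monotone
affine map); it is fitted and stored per experiment regardless. AUC is the
Mann–Whitney statistic with ties counted ½ (via scikit-learn), checked in
the tests against exhaustive pair enumeration. Summaries report the mean,
the *sample variance* (n−1; this is what the ± figures attached to the
reference AUC rows turn out to be), and a 95% percentile bootstrap CI —
the reference intervals match no standard closed form, so the bootstrap is
used as the package's own choice.

## Permutation comparison

For paired AUC vectors A, T on shared splits: gv = A − T, t = Σ gv. Mock
gaps m = sn·gv over sign vectors sn ∈ {−1,+1}ⁿ; p1 counts t ≤ m, p2
counts t ≤ |m|, both non-strict so ties count against significance. The
Monte Carlo sampler (default 35,000 draws) uses the add-one estimator
(count+1)/(N+1); the exact enumeration (n ≤ 20) reports count/2ⁿ — the
full null distribution needs no smoothing, and with the identity pattern
always counted the p-value is strictly positive. Note the reference
two-sided value 0.067 for AttnToNum-vs-ScaleNum was computed on unrounded
AUCs; from the 3-decimal published rows (whose gap vector contains two
0.001 near-ties) the exact value is 60/1024 ≈ 0.0586, and that is what
this package reproduces.

## SHAP-N

μ_f is the mean of filter f's activation over the split being explained
(holdout by default, selectable); φ_{f,s} = w_f(a_{s,f} − μ_f);
φ₀ = w₀ + Σ w_f μ_f. Conservation φ₀ + Σφ = logit is exact and asserted at
1e−5 on trained models. Each filter's argmax window is assigned to exactly
one *maximal* passing span — the longest span containing it, leftmost on
ties — so sub-ngrams fold into their containing ngram and no filter is
double-counted. The set-union variant that additionally merges overlapping
maximal spans is implemented behind an off-by-default flag; it smears
attribution over long overlaps and is not recommended. The dataset-level
SHAP-N of an ngram is its mean φ_{n,s} over *all* samples (absent samples
contribute 0), with the support count reported alongside, since "mean over
supporting samples" would favour rare ngrams. LSTM models are refused: the
decomposition needs the additive max-pool structure.

## Synthetic corpus

The generator is the package's study bed, not a model of clinical
language. Defaults: BUN ~ lognormal(median 18, σ_log 0.5), creatinine ~
lognormal(median 1.0, σ_log 0.4) — strictly positive, right-skewed like
real labs, medians straddling the charting cutoffs (20, 1.0) so both
flags are frequent; values are rounded to one decimal as charted (and the
ground truth uses the charted values, which are all the model can see).
Outcome: P = σ(β₀ + 1.5·(log BUN − μ_B) + 2.0·(log Cr − μ_C)), β₀
bisected so the mean probability is 0.326; the log-scale dependence is
deliberate — it is the regime the sigmoid-linear-log embedding is built
for, and the creatinine coefficient is larger so attribution sign checks
have a clear target. A `flag_only` switch moves all signal into the
(H)/(L) indicators to stress the context-attention path; setting both β
to 0 yields the null-signal control. Notes are 60–160 tokens of shuffled
filler vocabulary with ~35% bulleted symptom lists, 0–3 dates, 2–5
out-of-context labs/vitals spanning both tag ranges, ~15% hyphen-fused
`date-BUN` forms, and exactly one BUN and one creatinine unit separated
from other numbers by non-numeric tokens (so context windows never capture
a neighbour's value). What passing tests on this corpus show is that the
pipeline recovers planted magnitude signal and orders the embedding modes
as expected; they cannot show robustness to real clinical language —
misspellings, negation, section structure, unit variation are all absent.

## Scale choices

The end-to-end comparison in the test suite runs at reduced scale — 1,000
notes, 512-token cap, 15 epochs, 5 shared splits — chosen so the full
grid (3 modes × 5 splits) trains in a few minutes on one CPU while still
separating the modes by several AUC points. The default configs keep the
full-scale settings (3,000 tokens, 100 epochs).

## Known limitations

- Strictly positive values only; zero/negative quantities would need an
  offset or a different scaling function.
- The context window is a fixed hyperparameter — injected domain
  knowledge, not learned.
- The reference per-split AUC tables are rounded to 3 decimals, which
  bounds how exactly sampled permutation p-values computed from them can
  match values computed on the unrounded originals (see above).
- The LSTM path supports training and evaluation but not SHAP-N.
- No transformer baselines; no fusion with structured records.
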