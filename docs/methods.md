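# Methods

## The task and the model

`capsicd` predicts the set of 3-digit ICD-9 category codes attached to a
free-text clinical note — a multi-label document classification problem with
a large, highly skewed label space and long documents. The classifier
combines three ideas:

1. **Bidirectional LSTM encoding.** Tokens are embedded with pretrained word
   vectors and encoded by a single Bi-LSTM layer (standard gate equations,
   zero initial states), so each position carries context from both
   directions. Long notes are the regime this component targets: n-gram
   filters alone cannot see past their window.
2. **Label-embedding fusion.** Each label is embedded as the mean of the
   word vectors of its ICD code description, placing codes and words in one
   vector space. Label information enters twice: (a) before encoding, the
   cosine similarity between every token vector and every label vector is
   concatenated onto the token embedding (an L-dimensional similarity
   column per token); (b) after encoding, the cosine similarity between a
   projected mean-pooled text representation and every label vector is
   concatenated onto the features entering the classification head.
3. **Capsule network with dynamic routing.** A valid n-gram convolution
   (window K1, ReLU) produces window features; a shared linear map turns
   each window into one or more capsule pose vectors, squashed by
   v = (|s|²/(1+|s|²))·(s/|s|). Class capsules are formed by
   routing-by-agreement: coupling coefficients are the class-wise softmax of
   logits initialised at zero and updated by the scalar product between
   prediction vectors and class capsules; three iterations by default, with
   the logit update skipped after the final iteration. The class score is
   the class capsule's norm, in [0, 1). The final couplings are retained:
   summed over capsule channels at a position they measure how strongly an
   n-gram supported a code, which is what the attribution module exports.

The head concatenates the flattened class capsules with the text-label
similarity vector and applies a dense layer. Two output modes exist:
`sigmoid-bce` (the default: independent per-label probabilities, so a 0.5
threshold is a well-posed decision rule) and `softmax-ce` (normalised
multi-hot targets under categorical cross-entropy; scores then sum to one
across labels and a threshold rule is ill-posed, so this mode is kept for
fidelity comparisons rather than as the default).

All of the network — forward passes, backpropagation through time, the
unrolled routing gradient, and Adam — is implemented directly in numpy. The
routing gradient is exact through all unrolled iterations, and the package's
tests check every layer's gradient against central finite differences. Word
and label embeddings are frozen inputs: the similarity features then remain
an honest function of the description-derived label space. Fine-tuning the
label embeddings end-to-end is not implemented (see Known limitations).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| embedding dim e | 200 | word/label vector dimension (shared space) |
| hidden units u | 300 | per-direction LSTM state size (encoder output 2u) |
| capsule dim d | 50 | pose vector length |
| routing iterations | 3 | agreement refinement steps |
| kernel size K1 | 3 | n-gram window of the convolution |
| n_filters / n_channels | 64 / 32 | conv feature maps / capsules per window |
| batch size | 16 | Adam minibatch |
| learning rate | 0.01 | Adam step size |
| threshold τ | 0.5 | decision rule in sigmoid mode (top-k optional) |
| max_len | 2500 | token truncation (notes average ~1500 words) |

Defaults follow the reference configuration for this architecture family;
`n_filters`/`n_channels` are not pinned by that configuration and are
package choices. Early stopping monitors validation loss with patience 3
(configurable) and restores the best epoch.

## Preprocessing and label space

Codes are normalised (dots/whitespace stripped, uppercased) and rolled up to
3-digit category roots. The rollup follows the ICD-9-CM category
convention: numeric and V-codes keep three characters, E-codes four
(E934 ≠ E93x merging is thereby avoided); a literal first-three-characters
scheme is available as a config switch. Text is lowercased, punctuation is
discarded, stopwords (sklearn's English list by default) are removed, and
tokens below a corpus frequency cut (default 3) become the unknown token —
replaced in place, so positions are preserved. The label space is the k
most frequent roots (ties broken lexicographically); frequency ranking is
an assumption where the selection criterion is not otherwise specified, and
the resulting order is the canonical label index everywhere. Notes whose
gold set becomes empty after label-space filtering are dropped with a
logged count. Splits are 0.7/0.1/0.2 by note, deterministic per seed.
Multiple note rows for one admission are concatenated in file order.

Two documented metric quirks: published frequency groupings of the form
[51,100] and [100, ∞) overlap at 100; the package uses [51,100] and
[101, ∞). Error analyses in this literature sometimes label false negatives
"true-negative errors"; the error breakdown reports false negatives.

## The synthetic corpus

The generator plants an identifiable label-keyword structure: each label
owns disjoint signature tokens, its description consists of exactly those
tokens, notes draw a label multiset from a power-law popularity
distribution, and each chosen label's signature tokens are inserted at a
configurable rate among Zipf-distributed background tokens. Generator
defaults emulate the broad shape of a rolled-up hospital coding corpus
(skewed labels, ~8 codes per admission, configurable note length toward
~1500 words). What it does **not** emulate: clinical syntax, abbreviations,
misspellings, correlated labels, or signatures that overlap between codes —
so passing the learning checks demonstrates that the architecture and
training machinery work, not that the model reaches any particular accuracy
on real clinical text.

The benchmark condition used by the learning checks is scaled for a single
CPU: 20 labels, 3000 notes of ~120 tokens over a 400-token vocabulary, and
a tiny model (e = 32, u = 32, d = 8, K1 = 3, 16 filters × 2 channels,
batch 64, ≤ 10 epochs). Three of its settings are deliberate:

- **~3 codes per note, popularity exponent 0.5.** With 20 labels, these
  keep every label's presence rate below one half. A model trained on
  shuffled targets can then learn only label marginals, predicts nothing at
  the 0.5 threshold, and scores ≈ 0 micro F1 — which is exactly what the
  permutation control must measure. A more skewed 20-label corpus would let
  the control score substantially above zero through base rates alone and
  the control would stop being informative.
- **Insertion rate 1.** Every signature token of every gold label is
  present, so a keyword-matching classifier reaches micro F1 = 1.0 exactly:
  the identifiability ceiling the trained model is judged against.
- **Batch 64** rather than the full-scale default 16, purely a
  throughput choice at this corpus size.

## Numerical choices

- Cosine similarity of any zero-norm vector is defined as 0 (padding
  neutrality); the squash denominator carries a 1e-12 guard; softmaxes are
  max-subtracted.
- Padded positions carry LSTM state through unchanged and emit zeros;
  convolution windows that would overlap padding are masked to zero and
  their capsules contribute nothing to routing.
- Per-label F1 is 0 when precision + recall is 0; per-label AUC skips
  labels whose test gold column is constant (with a warning); empty
  frequency groups are absent from reports rather than zero.
- Ties in top-k decisions and ranked recall are broken by label order
  (stable argsort), making every metric deterministic.
- Notes shorter than K1 are padded up to one full window; empty notes are
  scored (flagged with a warning) rather than dropped at prediction time.
- Training aborts with a diagnostic if the loss becomes non-finite.
- `dtype="float32"` halves memory and speeds up the long benchmark runs;
  float64 is the default and is what the oracle-comparison tests use.

## Open design points resolved here

- The similarity column of the pre-encoder fusion is taken per token (the
  full L-vector), not pooled; width at large L can be reduced via the
  top-m/max config switch.
- The pooled text representation feeding the post-encoder similarity is the
  masked mean of the Bi-LSTM output, linearly projected to the embedding
  dimension (a flattened-capsule alternative exists as a config switch).
- The post-encoder similarity enters the head by concatenation; an additive
  score adjustment is a config flag.
- The score→code-set decision rule (never pinned down in this literature's
  reports): threshold 0.5 by default, top-k optional; every metrics report
  records which policy produced it.
- Attribution aggregates channel couplings at a position by sum, which
  preserves the softmax normalisation property; max is a config switch.
  Duplicate n-grams aggregate by max strength (font-size semantics).
  Per-note and corpus-aggregated word-cloud exports are both available.

## Known limitations

- No GPU path; full-scale training (344 labels, 50k notes, e = 200,
  u = 300) is out of reach of this implementation's numpy loops and is not
  attempted — headline accuracies on restricted clinical corpora are
  therefore not reproduced here.
- The W_ij routing transforms are shared across positions per
  (channel, class) pair to keep the parameter count tractable at large
  label counts; a full per-capsule option exists but is memory-hungry.
- Dropout is not applied inside the LSTM.
- Label embeddings are description-derived and frozen; an end-to-end
  trainable label-embedding variant (gradients through every similarity
  path) is not implemented.
- The synthetic generator's identifiability makes the learning checks
  necessary-but-not-sufficient evidence for real-data performance.
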