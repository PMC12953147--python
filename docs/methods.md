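# Methods

## Conditioning mechanism

The generative model is a decoder-only pre-norm transformer trained with the
usual next-token cross-entropy, except that every sequence carries a trait
profile ψ ∈ ℝᵗ (standardized units) and the objective is the conditional
likelihood p(s | ψ) = ∏ⱼ p(wⱼ | w₁..wⱼ₋₁, ψ). Conditioning is injected at
every layer: the bias-augmented profile p̃ = [ψ, 1] is mapped by two learned
matrices per layer into that layer's key/value width and supplied as the
key/value states of a *dummy position* at attention index 0. All real tokens
may attend to the dummy slot; it has no query, no residual-stream state, no
positional embedding, emits no prediction and receives no loss. The bias
component lets the dummy states carry a profile-independent intercept, so a
zero profile is a learned "average author" rather than an absent one.

Two conventions were genuinely open and were fixed as follows:

- **Which layers are injected, and the parameter count.** Key and value
  projections are learned for *all* L layers with input width t + 1. This
  convention uniquely reproduces all three published adapter sizes
  (2·L·(t+1)·kv_width = 55,296 / 552,960 / 393,216 for the 2B / 774M / 8B
  base geometries); an (L − 1)-layer count without the bias column divides
  none of them. `AdapterConfig.inject_layers` still accepts an explicit
  subset for experimentation.
- **Key/value injection, not residual-stream replacement.** The trait state
  participates in attention only. This is the reading consistent with one
  key and one value matrix per layer, and it keeps the mechanism exactly
  prefix-shaped: removable, and additive in parameter count.

Positions: the dummy occupies index 0 and real tokens 1..n+2, so positional
embeddings apply to real tokens only. Sequences are evaluated as
`[SOS] w₁..wₙ [EOS]` with n + 1 prediction steps (body plus `[EOS]`).

## Tiny reference model and training

The environment-independent reference implementation is pure numpy with a
hand-derived backward pass (verified against central finite differences to
~1e−6 relative error). Default architecture: 2 layers, hidden 64, 4 query
heads, 2 key/value heads of dimension 16 (exercising grouped-query
attention), ReLU MLP at ratio 4, learned positional embeddings, untied
output head, float64 throughout. Training is plain Adam at a constant
learning rate 5e−4, batch 32. Low-rank factorization is deliberately absent:
it is an efficiency device for billion-parameter models and changes nothing
at this scale; `freeze_base=True` marks where an adapter would attach to a
frozen pretrained model and is tested to leave base weights bit-identical.

Default epochs = 10, chosen by a pilot on the reference fixture: held-out
NLL is near-optimal between 6 and 15 epochs, while by 30 both the
conditioned and the matched unconditioned model overfit (the conditional
held-out advantage was +0.17 nats at 10 epochs and gone at 30). Training is
deterministic for a fixed seed; a non-finite loss aborts with diagnostics
rather than continuing silently.

Sampling defaults to temperature 1.0 with top-k 40 (a seed is mandatory);
greedy, plain-temperature and nucleus policies are available. The sampler
masks `[PAD]`/`[SOS]` and stops at `[EOS]` or the token budget.

## Message-level score estimation

Trait measurements live at the author level, so the "teacher" is fit there:
per dimension *i*, a no-intercept ridge regression Wᵢ from an author's
pooled relative word frequencies (pooled over all their messages, not a
mean of per-message vectors) to their score, then transferred to single
messages as ψ̂ₘ = W·Xₘ. Estimated scores are standardized (mean 0, SD 1)
over the *training* corpus and the constants are frozen into the
estimator/checkpoint, so generation-time inputs such as (0, 0, +3, 0, 0)
refer to the same scale the adapter was trained on. Default λ = 1e−3;
λ = 0 falls back to the minimum-norm least-squares solution and warns on
rank-deficient designs. Messages whose tokens are entirely out of
vocabulary have no defined feature vector; they receive the corpus-mean raw
score and are flagged. A topic-loading feature mode (mean of per-token
loading vectors) stands in for topic-model features.

## Synthetic corpus

The simulator emulates short trait-labeled social-media messages. Authors
draw ψ i.i.d. standard normal per dimension; message tokens are i.i.d. from
the log-linear vocabulary distribution softmax(b_w + Σᵢ ψᵢ·β_{i,w}), where
each dimension owns `markers_per_trait` high markers (β = +beta) and as many
low markers (β = −beta), and filler words are uncoupled. Defaults: t = 5,
vocabulary 60, four markers per pole, beta = 1.0 (log-odds per SD), message
length uniform on 12–24 words (between the study domains' typical tweet and
truncated-blog lengths), 200 authors × 10 messages, 20% of each author's
messages held out. Marker words share a common base logit while fillers
carry a mildly skewed background (logits linear from +1 to −1), so signal
strength is identical across dimensions — an intentional symmetry that
makes per-dimension comparisons fair and keeps expected marker frequencies
available in closed form (`token_distribution`) for oracle tests. The
message-level true score equals the author's ψ, mirroring how
participant-level estimators are transferred to messages.

What passing tests on this corpus do **not** show: natural-language
fluency, long-range syntax, topic structure, or the behaviour of
billion-parameter pretrained models. The simulator is a bag-of-words
process; it validates the conditioning mechanism, the estimation transfer
and the evaluation protocol, not linguistic quality.

## Evaluation protocol

For one trait, the generator produces a group of samples at each input
level (default k ∈ {−3, 0, +3}: Low/Neutral/High; the five-level variant
uses {−3, −1.5, 0, +1.5, +3}), groups are shuffled per trial, and a blinded
rater must produce a bijection from presented groups to levels. A trial
scores the fixed-point fraction of that permutation — on three levels
exactly 0, 1/3 or 1 — and a uniformly random bijection scores 1/m in
expectation (33.33% for three levels; verified by exhaustive enumeration up
to m = 6). Ten trials per dimension with independent generation seeds is
the default. Human raters are replaced by a deterministic *oracle rater*
that ranks groups by net marker frequency (high-pole minus low-pole, for
the trial's trait) and assigns levels in rank order, ties broken by
presented order. Rater agreement is summarized by weighted Cohen's kappa
(linear weights by default, quadratic available), computed via
scikit-learn and guarded against the degenerate single-category case.

## Numerical and design notes

- Trait profiles are clamped to [−5, +5] at construction; the operating
  range of the trained adapter is [−3, +3] (akin to a 7-point Likert
  scale), and far-out scores are out-of-distribution by construction.
- The circumplex rotation uses degrees in interfaces (α = 22.5° default)
  and is exactly orthonormal; the inverse rotation is provided and
  round-trips to ~1e−16.
- Trait indices are 0-based everywhere and ordered by `TraitSpec.names`,
  preventing silent dimension permutations.
- Corpus I/O is line-delimited JSON with strict and lenient modes;
  preprocessing drops messages under five words or containing links,
  strips hashtags and emoji codes, and in blog mode truncates to the
  shortest sentence prefix reaching 30 words (sentences split on `.!?` +
  whitespace). Link/hashtag/emoji patterns are configurable since no
  canonical pattern set exists.
- Attention masking guarantees causality (position j sees only the dummy
  slot and positions ≤ j); padded positions attend only to the dummy slot
  and receive zero gradient through the loss mask.
- Problem sizes throughout (200 × 10 corpus, 2-layer model, 10 epochs,
  50 generations per level, 10 trials per dimension) are the package's
  reference desk-scale conditions; they complete in about a minute of CPU
  for the full training-plus-evaluation chain.

## Known limitations

- The reference model cannot attach to real pretrained checkpoints (no
  tensor-framework interop); `freeze_base` plus `AdapterProjectionSet`
  define the attachment surface only.
- The estimator is linear in word frequencies by design; nonlinear or
  contextual teachers are out of scope.
- Published rater-accuracy figures for billion-parameter models with human
  or LLM judges are not reproducible at this scale and are replaced by the
  property suite above (likelihood gain, marker monotonicity, oracle
  matching).
- The oracle rater presumes the synthetic marker vocabulary; it is not a
  general text-quality judge.
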