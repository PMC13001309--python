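# Methods

This note documents the models and procedures implemented in `odieu`, the
assumptions behind them, the parameters that matter, and what the synthetic
test bed does and does not establish about real data.

## 1. Catalogue model and pair enumeration

A catalogue is a set of molecules (caller-supplied stable keys plus SMILES)
and description records, each typed by provenance kind: raw human
descriptions (HD), human descriptions completed into full sentences (CHD),
human semantic labels (HL), labels completed into sentences (CHL),
sentences completed from machine-predicted labels (CDL), SMILES-prompted
generations (S_ZS / S_HD / S_CHD / S_CHL), neural-data-derived descriptions
(MD), and a catch-all GEN.  Uniqueness is enforced on
`(molecule, source, kind)`.

Molecule identity is deliberately the caller's key: canonicalizing SMILES
for identity would silently merge stereoisomers that sources may describe
differently.  A canonical-SMILES merge utility exists
(`catalog.canonical_smiles_merge`, requires rdkit) but is off by default.

Cross-source same-molecule pairs of one kind are the unit of the
consensus analysis.  A molecule held by *m* sources contributes C(*m*, 2)
unordered pairs, oriented lexicographically by source so the index is
deterministic.  The canonical overlap structure — 1,762 molecules in
exactly two of three sources and 854 in all three — yields
1762 + 3·854 = 4,324 pairs, which the test suite and acceptance script
reproduce by construction.

Text is Unicode-NFC-normalized with whitespace collapsed at load time
(the raw string is retained), so that tokenization is stable across
platforms.

## 2. Synthetic data generator

The generator emulates the structure the benchmark needs without any
chemical realism:

- each molecule belongs to one of `n_families` perceptual families
  (built-in vocabularies themed on classical odor descriptor families:
  fruity, floral, sulfurous, woody, minty, citrus, nutty, smoky);
- each present source draws `tokens_per_description` = 3 tokens, each from
  the molecule's true family with probability α (the inter-observer
  agreement) and from a random family otherwise, and wraps them in the
  sentence frame "This molecule has a …, … odor." (HL records carry the
  raw tokens as labels);
- a per-molecule Gaussian latent (dimension 8 by default) carries the
  family identity in its leading coordinates; descriptor vectors and
  30-dimensional neural response vectors are independent full-rank random
  linear images of that latent plus isotropic Gaussian noise
  (`noise_sigma`, default 0.1);
- the source-presence pattern is configurable (`multiplicity_counts`) to
  reproduce any 1/2/3-source overlap census.

Defaults (200 molecules, 3 sources, 4 families, α = 1.0 unless a scenario
specifies otherwise, σ = 0.1) are chosen so that same-molecule agreement is
strong but not degenerate, and so that cross-modal recovery (CCA,
Procrustes) is analytically predictable from the shared-latent
construction.  All draws derive from a single integer seed; identical
configs produce byte-identical catalogues.

What the generator does **not** emulate: realistic vocabulary size and
Zipfian token frequencies, variable description length and syntax,
chemically structured descriptor covariance, correlated noise across
neural dimensions, or source-specific style.  Tests passing on this bed
therefore establish the *correctness and calibration of the machinery*
(pair logic, metric oracles, null construction, recovery of planted
structure), not performance claims about real perfumery datasets — which
additionally require licensed texts and pretrained embedding checkpoints.

The retained `SyntheticTruth` (latents, family ids, mixing maps) is used
only by recovery tests; no method under test reads it.

## 3. Lexical metrics

All metrics share one tokenizer — lowercase, Unicode NFC, split on
non-alphanumeric runs — and report on the ×100 scale.

- **BLEU**: modified n-gram precision with clipping against the maximum
  reference count, geometric mean over orders 1..N (N = 1 or 4), brevity
  penalty against the closest reference length.  Unsmoothed by default, so
  any zero higher-order precision gives 0; an add-one smoothing flag
  exists for very short texts.
- **ROUGE-L**: LCS-based F-measure (β = 1 by default).
- **METEOR**: greedy left-to-right unigram alignment in two stages (exact
  match, then a small rule-based suffix-stripping stemmer), recall-weighted
  harmonic mean F = 10PR/(R+9P), fragmentation penalty
  0.5·(chunks/matches)³.  Note the penalty implies an identical pair
  scores 100·(1 − 0.5/m³), not exactly 100; tests assert the closed form.
- **BERTScore**: greedy max-cosine matching F1 over per-token vectors from
  a pluggable token embedder (a hashed one-hot embedder serves tests);
  baseline rescaling is not applied.

The consensus gap symmetrizes human-human pairs (mean of both directions,
each partner serving once as sole reference) because the pair is unordered;
machine-human pairs score the machine text against the human reference.

## 4. Embedders and contrastive fine-tuning

An embedder is any object mapping texts to fixed-dimension vectors;
`embed_texts` unit-normalizes rows.  Two reference embedders ship:

- `HashingEmbedder` — deterministic hashed bag of content words
  (stopwords dropped), dimension 256 by default; the training-free "toy"
  embedder used in tests and baselines.
- `TrainableBowEmbedder` — a linear map over the same hashed features,
  initialized at identity (so it starts exactly equal to the hashing
  embedder) and trained by gradient descent.

Fine-tuning builds positives from all cross-source same-molecule pairs and
negatives by seeded uniform sampling of different-molecule record pairs
(1:1 by default).  Cross-validation folds partition **molecules**, not
descriptions, to prevent leakage through same-molecule texts; each fold's
model trains only on pairs whose molecules lie outside the held-out fold,
and every reported held-out similarity uses the fold model that never saw
that molecule.

The default objective is an AnglE-style compound loss: a CoSENT-type
ranking term log(1 + Σ exp(τ(s⁻ − s⁺))) on cosine similarities plus the
same ranking on a complex-angle similarity (embedding split into
real/imaginary halves; similarity |Σ re| + |Σ im| of the normalized
complex product), τ = 20, equal weights.  A plain cosine-margin
contrastive loss (margin 0.5) is the documented fallback; both are
config-exposed since the reference formulation's hyperparameters are not
fixed by the benchmark definition.  Optimization is Adam on the in-repo
autodiff engine (`odieu.nn`), whose gradients are verified against
central finite differences in the test suite.

## 5. Benchmark statistics

- **Shuffled null**: a seeded derangement (permutation with no fixed
  points) of one side of the pairing, so no "shuffled" pair is accidentally
  a true pair.
- **EMD**: the 1-Wasserstein distance between the paired and null CS
  samples (equal sizes: mean |sorted difference|), computed on the raw CS
  samples; tests pin it to an exhaustive optimal-transport LP on small
  instances.
- **Top-k retrieval**: queries are one kind's embeddings, the gallery
  holds cross-source description embeddings, self-records excluded; ties
  broken by stable gallery order.  Orthogonal embeddings retrieve
  perfectly; i.i.d. random embeddings calibrate to k/N.
- **Consensus verdict**: Welch (unequal-variance) two-sample t-test on the
  per-pair CS samples.
- **Averaged embeddings**: the crowd embedding per molecule is the
  renormalized mean over sources; the leave-source-out variant excludes
  the source being evaluated, removing the self-inflation that otherwise
  makes the crowd look artificially close to each member.

## 6. Odor-space geometry

- **MDS**: metric MDS on Euclidean distances, initialized by classical
  (Torgerson) scaling and refined by SMACOF; the reported stress is
  normalized, √(Σ(d−d̂)²/Σd²), so data whose intrinsic dimension fits the
  target reduce with stress ≈ 0.
- **CCA**: each space is centered and projected onto its top
  min(d, n−1) principal components with a small ridge (1e-8) on the
  covariance blocks before the SVD-based canonical analysis — the minimal
  regularization that makes high-dimensional or rank-deficient inputs
  well-posed while leaving full-rank results unchanged (the self-comparison
  sum equals d to 1e-6 and the sum is invariant under invertible linear
  transforms).  The headline quantity is Σρ²ᵢ, the effective number of
  shared dimensions.
- **Predictive maps**: seeded 80/20 molecule split; both spaces centered
  with training means only (shifting held-out molecules must not change
  the fitted map); least-squares (pseudoinverse) fit; accuracy is the
  unweighted mean per-coordinate Pearson r on held-out molecules.  Under
  target = base + equal-variance noise this attenuates to 1/√2, which the
  tests verify over 50 seeded replicates.

## 7. CIRANO: prefix tuning a frozen causal LM

A 4-layer MLP encoder (tanh hidden activations, hidden width 32 by
default) maps a z-scored molecular descriptor vector to k = 10 prefix
slots in the language model's token-embedding space.  Training minimizes
teacher-forced next-token NLL of the target text (prefix positions carry
no loss) over **encoder parameters only**; the language model's parameters
are write-protected at the buffer level and fingerprinted (SHA-256 over
all parameter bytes) before and after training — any mutation is a hard
failure.

The LM backend is a contract.  The default backend is a tiny frozen
randomly-initialized causal network over a word-level vocabulary:

    h_t      = tanh(W1·[e_t ; mean(e_0..e_t) ; p̄] + b1)
    logits_t = W2·h_t + b2 + β·p̄·Eᵀ

with token+position embeddings e, prefix mean p̄ and tied-embedding readout
weight β = 1.  Two design points matter.  The persistent p̄ channel keeps
the learned prefix visible at every decoding step instead of being diluted
by the growing context — the role attention plays for the prefix in a
transformer backbone — and the tied readout gives the encoder a
well-conditioned, near-convex path from prefix to next-token scores.
Without these the optimization through a frozen random network is
unstable.  Gradient-norm clipping (1.0) and Adam (lr 5e-3) are the
training defaults; a plain-SGD option exists, under which the loss on a
single memorizable pair decreases strictly — the contract the tests pin.

Decoding is greedy by default with a repetition penalty (2.0 subtracted
from logits of already-emitted tokens; tiny LMs are otherwise prone to
degenerate repetition loops) and a minimum length of 4 tokens before
end-of-sequence is allowed; seeded temperature sampling is available.
An immediate end-of-sequence yields an empty string, flagged by callers
rather than fatal.

The synthetic evaluation ties two descriptor clusters to disjoint odor
vocabularies and asks whether held-out generations are closer (toy-embedder
CS) to their own cluster's ground-truth texts than to the other's; with the
defaults this holds for well over 80% of held-out molecules across seeds.
A full-scale pretrained backbone can be plugged in through the same
`FrozenLM` interface (differentiable per-position logits given prefix rows).

## 8. N2T: Procrustes alignment and decoding

The alignment is the similarity-transform Procrustes fit: translation,
isotropic scale and orthogonal matrix minimizing ‖s(Q−c_q)Ω − (E−c_e)‖_F,
solved in closed form by SVD of the centered cross-covariance.  Orthogonal
includes reflections (det ±1); the fitted matrix satisfies ‖ΩᵀΩ−I‖ < 1e-8.

When the embedding dimension exceeds the neural dimension (the usual
case: d_q = 30 vs hundreds of embedding dimensions), embeddings are
reduced to d_q principal components fitted on the training odorants only,
alignment happens in that space, and predictions are mapped back through
the transposed loadings before decoding.  PCA reduction is the
minimal-information choice; zero-padding Q is the documented alternative.

Evaluation is leave-one-out: fit on n−1 odorants, predict the left-out
embedding, record CS(predicted, true); the null repeats the identical
protocol with embedding rows deranged, so the comparison isolates the
odorant correspondence.  Per-animal fits stay separate by default.

Decoding goes through an invertible-embedder contract (`embed` +
`invert`).  The shipped toy backend embeds a text as its exact token-count
vector and inverts by rounding, so under a noiseless similarity link the
end-to-end pipeline reproduces the target token multiset exactly — the
strongest property a round-trip test can pin without a learned inverse
model.

## 9. Augmentation

Sentence completion (HD→CHD, HL→CHL, machine labels→CDL) is backend-
pluggable; the shipped deterministic backend wraps the record's content
words into the canonical sentence frame, and a validator warns if any
input label token is missing from the output.  Prompt templates are
plain-text reconstructions with sensible defaults, not verbatim copies of
any external prompt.  Few-shot SMILES prompts select example blocks by
seeded sampling without replacement and refuse a query that appears in the
example pool (leakage guard).  Augmented records never overwrite
originals; both kinds coexist in the catalogue.

## 10. Numerical choices and degenerate inputs

- Zero-vector embeddings (texts with no content words) stay zero after
  normalization; cosine similarity against them is an error.
- Constant similarity samples make the Welch test undefined and raise.
- Derangement sampling is rejection-based (expected < 2 draws).
- `emd_1d` rejects empty samples; retrieval rejects k beyond the gallery.
- CCA requires ≥ 3 overlapping molecules; predictive maps ≥ 5 with ≥ 2
  held out; Procrustes ≥ 3 matched rows and non-constant inputs; LOOCV ≥ 4.
- Seeds: every stochastic operation takes an explicit seed; sub-streams
  are derived via `numpy.random.SeedSequence` so stages are independently
  reproducible.

## 11. Problem sizes

The test suite and the acceptance script run the pipeline at deliberately
modest sizes — 59–200 molecules, 64–512-dimensional embedders, a
few-thousand-parameter language model, 10–15 training epochs — chosen so
the planted structure is recovered with comfortable statistical margins
while every stage (including both gradient-training loops) executes in
seconds.  The same code paths scale to real catalogues; only the backends
(pretrained sentence embedders, a full causal LM) change through their
respective contracts.
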