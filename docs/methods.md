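# Methods

This note records the models, defaults, and design decisions behind each
component, what the synthetic data does and does not emulate, and the
numerical choices that affect results.

## Sequence handling

Sequences live internally in the DNA alphabet: input is uppercased and U is
replaced by T, while all IUPAC ambiguity codes (R, Y, S, W, K, M, B, D, H,
V, N) are preserved. An RNA rendering toggle (T→U) applies only when
writing FASTA. All indices are 0-based, half-open. FASTA I/O goes through
Biopython, wrapped at 60 columns.

Deduplication is greedy representative clustering: records are scanned in
order, each compared against retained representatives by Smith-Waterman
local alignment, and discarded when the best alignment reaches the identity
threshold (default 80%, matches / alignment columns) **and** covers at
least 80% of the shorter sequence. The coverage requirement is essential:
without it, any two random sequences sharing a chance 7-mer would count as
"100% identical" over that 7-column alignment and every corpus would
collapse to one cluster. A shared-7-mer prefilter skips pairs that cannot
align at all. This stand-in reproduces threshold semantics at desk scale,
not the behavior of any specific production clusterer.

Corpus splits permute records with a seeded generator and apportion sizes
by largest remainder, so round corpora hit fraction targets exactly
(10,000 at 99/1 → 9,900/100; 1,000 at 60/30/10 → 600/300/100).

## Tokenizer

Byte-pair encoding over the nucleotide alphabet: training repeatedly merges
the most frequent adjacent token pair within sequences (never across the
EOS boundary), stopping at the requested vocabulary size or when no pair
occurs at least twice (the model is then flagged undersized). Ties are
broken by the lexicographically smallest concatenated string, making
training deterministic with no seed dependence. Ambiguity codes are
ordinary symbols that simply merge rarely. EOS has id 0; there is no BOS.
Encoding applies merges in rank order, leftmost first, via a
linked-list/heap scan; decode concatenates token strings and skips EOS.
The default vocabulary for full runs is 1024 (about 4.2 nt/token on a
uniform background corpus); tests use 5–64-token vocabularies.

## Language model

A pre-normalization causal transformer (GPT-2 lineage): learned absolute
positional embeddings, multi-head self-attention with causal masking, GELU
feed-forward blocks of width 4d, a final layer norm, and an output
projection tied to the token embedding. The full-scale preset (24 layers,
width 1280, context 1024) is recorded but never instantiated; the desk
preset is 4 layers, width 128, 4 heads, context 256, and most experiments
use even smaller 1–2-layer configurations. The method, not the scale, is
the artifact.

Initialization: matmul weights are Kaiming normal (std = √(2/fan_in));
embeddings are Gaussian with std 0.02; layer-norm gains start at 1, all
biases at 0. Forward and backward passes are handwritten numpy (float64);
the analytic gradients are checked against central differences to ~1e-6
relative error in the test suite. All probabilities are natural-log.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with gradient clipping at global
norm 1.0 (switchable). Pre-training uses a linear warmup from 0 to the
peak rate (default 1e-3) over 0.67 epoch, then linear decay to the final
rate (default 1e-4) at the last step; decay is per-step, not per-epoch.
Fine-tuning uses a constant rate, default 1e-4, with no warmup or
scheduler. Desk defaults where the choice was open: batch size 8–32, no
weight decay.

Two stream layouts feed the model:

- **concat** (pre-training default): sequences are concatenated with EOS
  separators in a seeded per-epoch order and chunked into context-length
  blocks; every token appears exactly once per epoch, and the trailing
  partial block is EOS-filled with the filler masked out of the loss.
- **padded** (fine-tuning default): one sequence per block, laid out as
  [EOS, tokens…, EOS, pad]. This matches the conditioning at generation
  time, where decoding always starts from EOS at position 0. With absolute
  positional embeddings the distinction matters: a model fine-tuned on
  concatenated chunks sees sequences at arbitrary offsets and cannot
  reproduce them from the position-0 prompt it is actually given.

Validation NLL is computed per sequence as [EOS] + tokens + [EOS];
perplexity is exactly exp(per-token NLL). Early stopping (optional
patience on validation loss) returns the best-validation checkpoint;
divergence (non-finite loss) aborts with a diagnostic.

## Generation

Decoding starts from [EOS] + encode(prefix) and proceeds token by token to
EOS or the new-token budget (default: the context length; capped sequences
are flagged truncated). Temperature divides logits before the softmax.
Top-k renormalizes over the k largest-probability tokens. Beam search
scores hypotheses by raw summed log-probability without length
normalization; hypotheses that emit EOS are frozen and compete at the end,
with ties broken toward the lexicographically smaller token-id sequence,
so beam width 1 reproduces greedy exactly. Deterministic strategies are
batched by enumerating all nucleotide prefixes of a fixed length (4⁵ =
1024 at the default length 5); prefixes are encoded greedily and decoding
continues at token granularity. Top-k batches are independent seeded draws
from the empty prefix.

## Evaluation statistics

**k-mer distributions** use a 1-nt sliding window over the 4^k k-mers in
lexicographic order; windows containing ambiguity codes are skipped. KL
divergence is Σ P ln(P/Q) in nats after adding a pseudocount (default 1)
to both count vectors and renormalizing; terms with P(i) = 0 contribute 0,
and with pseudocount 0 a Q-zero under P-support returns infinity with a
warning. Reported KL magnitudes are therefore comparable only under the
same smoothing and log-base conventions.

**k-let shuffle** is the exact construction: vertices are (k−1)-mers,
edges the sequence's k-mers; a uniform in-tree toward the terminal vertex
is sampled with Wilson's loop-erased random walk, each vertex's remaining
out-edges are ordered uniformly at random with its tree edge last, and the
Eulerian walk from the start vertex is read off. The output preserves the
exact k-mer multiset (hence composition and (k−1)-mer content), the first
and last (k−1)-mer, and the length. Sequences of length ≤ k are returned
unchanged. A rejection-sampling permutation oracle backs this in the
tests.

**Folding** scores come from a Nussinov-style dynamic program maximizing
total pair weight (GC 3, AU 2, GU 1) with a minimum loop of 3 unpaired
nucleotides, O(n³) with traceback to dot-bracket (numba-compiled fill).
The reported score is the negated pair weight, so lower = more stably
paired, mirroring the sign convention of free energies — but these are
arbitrary units from a base-pairing model, not a thermodynamic
nearest-neighbor energy, and are comparable only within one backend.
Ambiguity codes are forced unpaired. An adapter calls the RNAfold program
(kcal/mol) when present; no test or result depends on it. The DP is
verified against exhaustive structure enumeration for n ≤ 12.

**Group experiment**: the generated set is compared against (a) a natural
sample drawn from a pool to match the generated length histogram (bin
width 50 nt), (b) per-sequence uniform-random controls of identical
length, and (c) the 3-let shuffle of each generated sequence.
Mann-Whitney U tests: two-sided for generated vs natural, one-sided
(generated lower) against shuffled and random, using the normal
approximation as implemented in scipy. The length-binned variant reports,
per 50-nt bin, the fraction of sequences scoring strictly below their own
shuffle; ties count as not-lower (conservative), and empty bins are
reported missing rather than 0. A token-level shuffle control (permute the
generated token list, then decode) isolates what the tokenizer's
vocabulary alone contributes to structure.

**Alignment and novelty**: local alignments use Biopython's
PairwiseAligner (match +1, mismatch −1, gap open −2, extend −1; ambiguity
codes always score as mismatches and never count as identities). Identity
is 100 · n_identical / n_align over all columns of the best local
alignment, gaps included. Novelty search aligns each query only against
database entries sharing a 7-mer seed word (verified against unseeded
full DP on small instances); significance is empirical — the e-value of a
hit is the number of targets in a dinucleotide-shuffled decoy database
reaching its score for that query — and a hit is significant at e ≤ 0.1,
i.e. when no decoy matches it. Significant hits at exactly 100% identity
are "identical" (the aligned subsequence matches perfectly; it need not
span the whole query), other significant hits "partial", the rest
"no-hit".

## Protein-binding workflow

Curation deduplicates positives and negatives separately (80% identity, as
above), splits positives 60/30/10 into generator-fine-tuning, scorer
training, and test partitions, and samples negatives without replacement
to match the scorer-training and test counts.

The affinity scorer is a deliberately simple, pluggable stand-in for a
trained protein-binding network — the pipeline only requires the contract
sequence → [0, 1]. It estimates a PWM from the most enriched width-w word
(default w = 8) in positives relative to negatives, collecting each
positive's closest window (pseudocount 1), converts to log-odds against a
uniform background, and calibrates the best-sliding-window score with a
two-parameter logistic fitted by penalized maximum likelihood (a small
ridge term keeps the slope finite on perfectly separable fixtures). On
motif-implanted fixtures it separates held-out classes with >90% accuracy;
on real CLIP data a learned scorer should be substituted.

The binder experiment fine-tunes the pre-trained model on the
generator-fine-tuning positives (padded stream), generates as many
sequences as the positive test set (resampling sequences shorter than the
motif width, with a capped retry budget), scores the generated, positive
test, and negative test sets, and runs novelty search of the generated
sequences against all positives.

The ablation trains the same architecture from random weights on the same
fine-tuning split and compares its generated-sequence novelty against the
fine-tuned model's. Two scale-driven choices:

- The scratch model's validation is a sample of its own training split.
  The synthetic positives are mutually independent background sequences,
  so a disjoint validation split measures nothing a scratch model can
  learn; real binding data shares motif and family structure across
  splits, which is what held-out validation tracks at full scale.
- The scratch model trains to its epoch budget rather than stopping early.
  At desk scale an epoch is 2–5 optimizer steps, and epoch-granularity
  patience fires during the long initial loss plateau, before the
  memorization phase it is meant to bound. Early stopping remains
  implemented and selectable (`--scratch-patience`); the demonstration
  disables it.

Under the default demonstration conditions (30 curated positives of 30 nt;
scratch: 200 epochs at 2e-3; fine-tuned: 5 epochs at 1e-3; top-k 2
sampling), the scratch model reaches its memorization floor (per-token NLL
≈ ln 30 / 31) and replicates training data — 80–100% identical hits —
while the fine-tuned model produces mostly novel sequences (0% identical),
reproducing the qualitative pre-training advantage. These are properties
of the constructed fixture, demonstrated by the acceptance script, not
estimates of any real dataset's values.

## Synthetic data: what it does and does not emulate

The generators provide Markov background corpora (order 0–3, complete
per-context transition tables, constant or uniform length families),
designed hairpins (stem + loop + reverse-complement stem, so a perfect
helix exists by construction), and motif-implanted binding sets (one
PWM-sampled instance overwritten at a uniform position in each positive at
the implant rate, preserving length; negatives are pure background). All
randomness flows through one seeded generator per call.

They deliberately do not emulate: RNA family/phylogenetic structure,
real k-mer and GC biases of curated databases, CLIP crosslink and coverage
biases, multiple or positionally biased motif occurrences, or secondary
structure beyond the designed hairpins. Passing tests therefore show the
pipeline's statistics behave correctly under controlled conditions
(composition-matched shuffles score worse than designed structure,
implanted motifs are recoverable, memorization is detectable) — they do
not certify performance on natural RNA.

## Default demonstration conditions and problem sizes

- Binding demo: 300 positives + 300 negatives of 50 nt, width-8 consensus
  PWM at 0.97 per-position probability, implant rate 1.0; fine-tuning 30
  epochs at 1e-3; top-k 4 generation. Generated mean affinity exceeds the
  negative-test mean across seeds, with the positive test set highest.
- Ablation demo: 50 positives + 50 negatives of 30 nt (conditions above).
- Memorization check: 500 copies of one 20-nt sequence, 4-layer/width-128
  model, ≥300 steps at 1e-3 → per-token validation NLL < 0.1 nats.
- Tokenizer-at-scale check: vocabulary 1024 trained on 1,500 × 300-nt
  background sequences.
- Oracle suites: folding DP vs enumeration at n ≤ 12 (200 cases), seeded
  vs unseeded alignment (50 pairs), k-let shuffle k-mer preservation
  (10⁴ randomized cases), KL identity/non-negativity sweeps (10³ pairs).

## Known limitations

- The folding stand-in ranks structures by weighted pair count only; no
  stacking, dangles, or loop penalties. Conclusions about "stability" are
  relative statements within one scoring scheme.
- The affinity scorer is a single-PWM model; it cannot represent composite
  or structure-dependent binding preferences.
- Novelty significance is calibrated on shuffled decoys of the given
  database; it is an empirical, database-relative quantity, not a
  profile-HMM e-value, and the search's sensitivity is word-seeded
  (default 7-mer), so hits with no exact shared word are missed.
- The numpy model is single-threaded and unbatched at generation time;
  it is built for correctness and desk-scale experiments, not throughput.
- Deduplication is O(n²) in retained representatives and intended for
  corpora of up to a few thousand sequences.
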