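# rnalm

Desk-scale autoregressive language modeling for RNA sequences: train a
byte-pair-encoding (BPE) tokenizer and a causal transformer decoder on
nucleotide corpora, generate new sequences by greedy, beam, or top-k
decoding, and evaluate what came out with the statistics this field actually
uses — k-mer frequency divergence, secondary-structure controls against
exact k-let-preserving shuffles, and local-alignment novelty search. A
fine-tuning workflow turns the pre-trained model into a generator of
protein-binding RNAs and quantifies what pre-training buys over training
from scratch.

The package is aimed at people studying generative sequence models for RNA
design who want the full pipeline — corpus preparation, tokenization,
training, decoding, and evaluation — runnable end-to-end on one CPU with
synthetic data, rather than a frozen large-scale checkpoint.

## The model

A sequence is a string of tokens $x_1 \dots x_L$, where each token covers
one or more nucleotides as decided by a learned BPE vocabulary and a special
EOS token delimits sequences. The model is an autoregressive decoder:

$$p(X) = \prod_{i=1}^{L} p_\theta(x_i \mid x_{<i})$$

trained by minimizing the negative log-likelihood
$\mathrm{NLL} = -\sum_i \log p_\theta(x_i \mid x_{<i})$ with Adam
($\beta_1 = 0.9$, $\beta_2 = 0.999$), a linear warmup to the peak learning
rate over the first 0.67 epoch and linear decay thereafter. Perplexity is
$\exp$ of the per-token NLL. The architecture is a pre-normalization
transformer in the GPT-2 lineage (learned absolute positions, causal
multi-head self-attention, GELU feed-forward, tied input/output embedding),
implemented here directly in numpy with handwritten backpropagation and
verified against numerical gradients.

Evaluation statistics:

- **k-mer KL divergence** between generated and reference sequence sets:
  $\mathrm{KLD} = \sum_i P(i)\,\ln\!\big(P(i)/Q(i)\big)$ over all $4^k$
  k-mers counted with a 1-nt sliding window (natural log; pseudocount 1 by
  default).
- **Folding controls**: each generated sequence is compared against a
  length-matched natural sample, a per-sequence uniform-random control, and
  an exact 3-let-preserving shuffle of itself (random Eulerian walk on the
  de Bruijn multigraph). Structure scores come from a built-in
  base-pair-weight maximization DP (GC −3, AU −2, GU −1, minimum loop 3);
  an adapter uses RNAfold when it is installed. Group differences are
  assessed with Mann-Whitney U tests.
- **Novelty**: seeded Smith-Waterman local alignment of generated sequences
  against a database, with identity $= 100 \cdot n_{\text{identical}} /
  n_{\text{align}}$ and an empirical e-value calibrated on a shuffled decoy
  database; queries are classed identical-hit / partial-hit / no-hit.

See `docs/methods.md` for assumptions, parameter defaults, and the design
choices behind each component.

## Worked example

```python
import rnalm as R
from rnalm.training import TrainConfig, ConstantLR, make_training_stream, train

# 1. synthesize a background corpus and train a BPE tokenizer
corpus = R.generate_markov_corpus(R.uniform_markov_spec(400, 80, seed=0))
tok = R.train_bpe(corpus, vocab_size=64)

# 2. pre-train a small causal LM
model = R.build_model(R.ModelConfig(n_layers=2, d_model=64, n_heads=4,
                                    context_len=64, vocab_size=tok.vocab_size, seed=0))
stream = make_training_stream(corpus[:360], tok, 64, seed=0)
model, history = train(model, stream, corpus[360:],
                       TrainConfig(schedule=ConstantLR(1e-3), batch_size=8, epochs=3, seed=0),
                       tokenizer=tok)

# 3. generate with top-k sampling and evaluate the k-mer match to the corpus
batch = R.generate_batch(model, tok, R.SamplingSpec(strategy="topk", top_k=40, seed=0,
                                                    max_new_tokens=40), n=200)
generated = [r.sequence for r in batch if len(r.sequence) >= 3]
kld = R.kl_divergence(R.kmer_counts(generated, 3), R.kmer_counts(corpus, 3))

# 4. folding control: designed hairpins vs their 3-let shuffles
hairpins = R.generate_hairpin_corpus(50, stem_len=12, loop_len=5, seed=1)
res = R.mfe_group_experiment(hairpins, R.generate_hairpin_corpus(200, 12, 5, seed=2),
                             k_shuffle=3, seed=0)
```

Output:

```
tokenizer: vocab=64, 2.52 nt/token
pretraining: val NLL 3.858 -> 3.846 nats/token (perplexity 46.8)
3-mer KL divergence, generated vs corpus: 0.0201 nats
mean fold score: generated -31.2 | shuffled -25.6 | random -21.3 (generated-vs-shuffled one-sided p = 7.63e-16)
```

Reading it: the 64-token vocabulary compresses 2.5 nucleotides into each
token; a uniform random corpus has nothing to learn beyond base frequencies,
so validation NLL stays near the tokenizer's entropy, while the generated
sequences already match the corpus 3-mer composition closely (KLD 0.02
nats). The designed hairpins score far below both their own k-let shuffles
and random controls — the composition-controlled signature of real secondary
structure, which is the comparison the folding experiment is built to make.

The same stages are exposed as a CLI:

```bash
rnalm synth --kind markov --n 400 --length 80 --out runs/corpus
rnalm train-tokenizer runs/corpus/corpus.fasta --vocab-size 64 --out runs/tok
rnalm pretrain runs/corpus/corpus.fasta --tokenizer runs/tok/tokenizer.json --out runs/lm
rnalm generate --checkpoint runs/lm/model.npz --tokenizer runs/tok/tokenizer.json \
      --strategy topk --n 200 --out runs/gen
rnalm evaluate kld runs/gen/generated.fasta runs/corpus/corpus.fasta --k 3 --out runs/eval
```

plus `prep`, `finetune`, `evaluate mfe`, `evaluate novelty`, `binder`, and
`ablate` for the remaining stages.

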