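# kmerlm

What does a BERT-style masked language model learn from overlapping
k-mer nucleotide tokens? This package implements the full analysis at
desk scale on a single CPU:

- **Overlapping k-mer tokenization** with DNABERT-style contiguous-k
  masking and a nucleotide-level *inferability* analysis: a single
  masked k-mer is trivially recoverable from its neighbours, and an
  isolated run of k masked tokens leaves exactly one free nucleotide,
  shrinking the non-trivial label space from `4^k + 5` to `4 + 5`.
- **A NumPy BERT** (no deep-learning framework; hand-written,
  gradient-checked backprop) decomposed into an *embedding module*
  (token/position/type tables) and an *encoding module* (transformer
  stack). For the full-scale 5-mer configuration the encoding module
  holds ~98.6% of the embedding+encoding parameters (~85M). Either
  module can be knocked out (re-initialized) independently.
- **Pre-training on synthetic corpora** — uniform random text and
  Markov-structured text — with dev-loss tracking, convergence
  detection, masked-token accuracy, and *prediction overlap
  consistency* (do predictions agree with the characters forced by
  flanking unmasked tokens?). On uniform random data a 1-mer model is
  pinned at the ln 4 entropy floor, while a k-mer model still learns
  the data-independent overlap subtask.
- **Embedding geometry analysis**: nearest-neighbour prefix/suffix
  similarity against a label-permutation null, central-nucleotide
  silhouette, and t-SNE projection.
- **Synthetic benchmarks**: PWM-implanted motif-discovery sets with
  dinucleotide-preserving (Altschul–Erikson) shuffled negatives,
  GC/motif-strength-matched occupancy sets, and TATA/non-TATA promoter
  sets.
- **Frozen-embedding CNN** downstream evaluation (accuracy, F1, MCC,
  AUROC via midranks, AUPRC via step integration), comparing one-hot,
  external word2vec-format, and model-extracted k-mer embeddings.
- **Warm-start pre-training**: initializing from a model pre-trained on
  random sequences accelerates convergence on structured corpora.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` contains the acceptance criteria, including
the training-based ones (a few minutes each on one CPU); the rest of
the suite runs in well under a minute.

## CLI

```bash
kmerlm count-params                       # parameter accounting
kmerlm gen-data --task motif-discovery --n 2000 --outdir out/
kmerlm gen-data --task corpus-random -L 1000000 --outdir out/
kmerlm pretrain --corpus out/corpus-random.fasta --steps 2500 --outdir out/
kmerlm extract-embeddings --model out/model.npz --outdir out/
kmerlm analyze-embeddings --table out/embeddings.w2v.txt --outdir out/
kmerlm train-downstream --dataset out/motif-discovery.tsv --k 3 --outdir out/
kmerlm run-experiment --experiment warm_start --seeds 0,1,2 --outdir out/
```

`run-experiment` covers the four packaged comparative experiments:
`pretrain_contrast` (embedding geometry: random-trained vs
Markov-trained vs untrained), `downstream_ablation` (fine-tuning under
structured / data-randomized / encoding-reinitialized / fully
reinitialized arms), `embedding_comparison` (frozen-embedding CNN
across embedding sources), and `warm_start`. Each accepts `--config`
(YAML/JSON) for model/optimizer overrides and writes JSON + TSV reports
with per-seed rows and mean±sd aggregates.

## Layout

```
src/kmerlm/
  kmer_tokens.py        vocabulary, tokenization, masking, inferability
  synthetic_data.py     corpora, PWMs, dinucleotide shuffle, datasets
  model_core.py         NumPy BERT, module partition, (de)serialization
  pretraining.py        MLM loop, convergence, accuracy, consistency
  embeddings.py         embedding tables, word2vec text I/O
  embedding_analysis.py neighbour statistic, silhouette, t-SNE
  downstream_eval.py    frozen-embedding CNN + metric suite
  experiments.py        comparative experiment recipes
  cli.py                command-line interface
```
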