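# Methods

## The distributed-memory context representation

The core primitive is a paragraph-vector distributed-memory (PV-DM)
network trained on overlapping n-gram biological words (n = 3 by default;
the machinery is generic in n).  It is implemented in-package with
numba-compiled kernels rather than delegated to an external embedding
library, because every downstream quantity depends on its exact semantics:

* **Architecture.** Each word and each document (protein) owns a
  d-dimensional input vector; a shared output matrix scores candidate
  words.  At each position the hidden state is the *mean* of the document
  vector and the word vectors inside a reduced co-occurrence window
  (word2vec-style: the effective window is drawn uniformly from 1..window
  per position).  The centre word is the positive target; `negative`
  additional targets are drawn from the unigram^0.75 distribution.
  Gradients use the exact mean-combine scaling (each contributor receives
  grad/(n_ctx+1)).
* **Schedule.** The learning rate decays linearly from `initial_lr` to
  `min_lr` (1e-4) over all epochs x documents steps.
* **Defaults** (dim 100, window 25, lr 0.25, negative 5, epochs 400) are
  the published training configuration.  At desk scale (hundreds of
  proteins instead of half a million) the corpus is tiny, so tests and the
  acceptance study reduce the pass count to 50; with 50 passes over ~200
  proteins the embedding already separates planted composition classes.
* **Determinism.** All stochastic choices inside the kernels flow from a
  single xorshift64* stream seeded by the caller; training is
  single-threaded.  Two runs with the same corpus and seed are bitwise
  identical, which the serialization round-trip tests rely on.
* **Inference strategy.** `vec_infer` freezes word vectors and output
  weights and runs the same SGD on a fresh document vector.  Inference
  epochs/learning rate default to the training values because no
  inference-time setting is published; both are overridable.  Word order
  affects the result only through window co-occurrence, which is exactly
  the property that distinguishes the inference strategy from the additive
  one.
* **Out-of-vocabulary policy.** Under the additive strategy unseen words
  contribute zero and are counted; at desk scale OOV words are common and
  raising would make boundary windows (padded with `X`) unusable.  The sum
  is not length-normalised by default (an option exists) — the additive
  representation follows the original summed construction.

## Context windows

Windows always have exactly 2m+1 residues; positions beyond the termini
are filled with the pad letter `X`.  Pad-containing 3-grams are usually
OOV and therefore contribute zero under the additive strategy — a
documented, intentional consequence rather than an error.  Exposed window
sizes mirror the published options (7, 11, 15, 19 total residues).

## Residue-level features and the 126-d layout

The published total of 126 components with only the OP width (10) printed
forces the decomposition 1 (Shannon) + 1 (relative entropy) + 1 (disorder)
+ 3 (secondary structure) + 10 (OP) + 10 (ACH) + 100 (context).  Choices
where the source is silent:

* Entropies are computed in bits (configurable base); Shannon entropy of
  the normalised 20-way profile row, KL divergence against the BLOSUM62
  marginal frequencies (hard-coded to 4 decimals).
* Disorder enters as the predicted probability of the target residue;
  secondary structure as its 3-probability row.
* ACH uses the Sweet–Eisenberg optimal-matching hydrophobicity index over
  centred windows of sizes 3, 5, ..., 21 with *truncated-mean* boundary
  handling (only in-bounds residues averaged); zero-padding is available
  via an option.  Ambiguity letters contribute zero.
* Taylor's overlapping properties use a fixed 10-class membership table
  (hydrophobic, polar, small, tiny, aliphatic, aromatic, positive,
  negative, charged, proline) transcribed from the classical Venn-diagram
  classification; non-standard letters encode as zeros with a warning.
* Profile readers parse the weighted-observed-percentage block of
  PSI-BLAST ASCII profile output (columns 23–42), renormalise rows to sum
  1, and replace all-zero rows with the background.

## Dataset curation

Merging drops by-similarity records, renames accessions, normalises kinase
labels, collapses exact duplicate triples, and removes kinases with fewer
than 20 records; benchmark selection keeps labels with strictly more than
500.  Splits operate on triple records (k = 5; four parts train, one
test), which can place different sites of one protein on both sides; a
by-protein split was considered and not made the default because the
record-level split is the stated protocol — leakage-controlled experiments
can partition annotations by accession before calling `make_splits`.
Negative exclusion uses *all* known positives of any kinase (the stricter
reading of "not annotated as phosphosites"), configurable through the
`known_positives` argument.  Training negatives are an exact-ratio seeded
uniform sample (1:1 by default); test negatives are every unannotated site
of the residue class(es) the task targets — S+T for S/T kinase families, Y
for TK/SRC and general-Y.

## Classifier and evaluation

Features are standardised (mean/variance fit on the training portion of
each fold only, via a pipeline) because rbf-kernel SVMs need a stated
scaling convention.  Model selection is by mean AUC under stratified
k-fold CV, ties broken toward lower C and linear before rbf.  MCC uses the
standard form (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) and is
defined as 0 when a marginal is empty.  FPR-anchored cutoffs are empirical
quantiles of the negative score distribution: the smallest observed score
such that the fraction of negatives strictly above it does not exceed the
level; no interpolation, so the realized FPR is always <= the requested
level and the next-lower candidate would violate it.

## The synthetic data generator

Sequences are i.i.d. draws from the BLOSUM62 marginal amino-acid
frequencies; annotations come from a planted local motif.  The default
motif, R at offsets −3 and −2 from an S/T acceptor, emulates the
basophilic PKA consensus.  The study conditions used by the tests and the
acceptance script are 200 proteins of 80–160 residues with the motif at
30% of eligible acceptor sites.  The synthetic profile provider returns
mix·one-hot + (1−mix)·background profile rows (mix = 0.7), Beta(2, 5)
disorder and Dirichlet(1, 1, 1) secondary structure, keyed on
(seed, accession) so profiles are call-order independent.

What the generator does *not* emulate: residue autocorrelation and domain
structure of real proteins, realistic evolutionary profiles (real WOP rows
correlate with structure and conservation, so the entropy features carry
far more signal on real data than here), degenerate/partial motifs, and
the hundreds-fold class imbalance of real proteomes (the test split is
imbalanced only ~6:1).  Passing the signal-recovery tests therefore shows
the pipeline can recover a planted contextual signal end to end — not that
real-data AUCs are reproduced.  Conversely, the null-calibration test
shows the pipeline does not manufacture signal from label-independent
features.

## Numerical and degenerate-input choices

All-zero profile rows are an error in the entropy functions and are
replaced by the background at the reader level; empty word lists error in
`vec_infer` and warn (returning zeros) in `vec_add`; zero denominators in
sensitivity/specificity yield NaN flags rather than exceptions; the n-gram
splitter warns and returns an empty list for sequences shorter than n.
Non-overlapping splitting drops the trailing partial word.  Ambiguity
letters (X, B, Z, U, O) are kept in biological words — they form rare
vocabulary items — preserving the L − n + 1 word-count identity.

## Problem sizes

Unit tests train dim-32 embeddings on 40-protein corpora (seconds); the
signal-recovery study uses 200 proteins, a dim-100/window-25 embedding at
50 passes, ~1,400 training sites and 10-fold CV, completing in well under
a minute single-threaded.  Full-scale published settings (400 epochs,
half-a-million-protein corpus) are supported by the same code paths but
are not exercised by the test suite.
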