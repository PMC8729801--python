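# Methods

## Model and score

The scorer is a character-level autoregressive language model over
SMILES. A string S of N characters is framed as (s₀, s₁, …, s_{N+1})
with s₀ = SOS and s_{N+1} = EOS; an embedding layer feeds a stack of GRU
layers whose final hidden state passes through a linear layer and a
softmax to give p(s_{t+1} | s₀…s_t) over the character vocabulary. The
joint probability factorizes by the chain rule, with p(s₀) = 1 since
every sequence begins with SOS, and the drug-likeness score is

    score(S) = 100 + log p(S),

natural log by default (`log_base` rescales it; all shipped numbers use
ln). The score is bounded above by 100, attained only when every
conditional along the sequence equals 1. Log-probabilities are
accumulated in log space throughout; raw probabilities are never
multiplied.

Training is teacher forcing with summed next-token cross-entropy, Adam
(pretraining rate 1e-3, fine-tuning rate 1e-4), and global-norm gradient
clipping at 5. Batches are right-padded with an internal PAD token that
has an embedding row but no softmax column and is masked out of the
loss, so padding cannot leak into probabilities. Sequences are bucketed
by length before batching to keep padding small; batch order is
reshuffled each epoch from the run seed.

Because the conditional structure depends on the SMILES dialect, both
training and scoring use RDKit canonical isomeric SMILES. Unassigned
stereocenters are handled asymmetrically, matching their different roles:
during training each molecule contributes one stereoisomer per epoch,
sampled uniformly at random (cheap, and over many epochs covers the
isomer set); at inference the score is the maximum over all enumerated
stereoisomers (cap 32, deterministic lexicographic enumeration order;
ties break toward the first). Stereoisomer enumeration delegates to
RDKit with a fixed internal seed and post-sorting, so results are
reproducible even when the cap truncates.

Two-letter element symbols (Cl, Br) are two tokens each: the vocabulary
is strictly per character. This affects absolute probabilities (a
chlorine costs two prediction steps) but is applied identically in
training and scoring. The vocabulary is the sorted set of characters
observed in the training pool (including all stereoisomer variants that
sampling may emit) plus SOS and EOS, serialized with every checkpoint;
scoring a molecule containing characters outside it raises an error
rather than silently renormalizing, and fine-tuning must reuse the
pretraining vocabulary.

## Reference architecture and desk-scale variants

The reference configuration is four GRU layers with hidden size 1024 and
embedding 256 — appropriate for corpora of millions of molecules and
kept as the constructor default. Nothing in the mathematics depends on
width, so the shipped experiments use scaled-down variants chosen to
converge in minutes on one CPU: 2×128 (embedding 32) for the Markov
source-recovery study and 2×96 for the toy-family study. Optimizer
settings, the 0.3 dropout rate of the classifier and both models' epoch
counts are this package's own defaults; they are exposed in the
estimator constructors.

## The two-class baseline

The classifier receives G(H⁰, A): per-atom features are one-hot atom
symbol over {C, N, O, S, F, P, Cl, Br, I, else}, one-hot hydrogen count
{0–5, else}, one-hot heavy-atom degree {0–5, else}, one-hot implicit
valence {0–4, else} and an aromaticity flag — 31 dimensions; hydrogens
are implicit and bond orders are ignored in the binary adjacency.
Stereochemistry is absent from the representation by construction.

A linear lift takes the 31 features to width 64 (the layer widths inside
the convolution stack are not pinned down by the architecture sketch we
follow; 64 is this package's choice, configurable). Each of the four
convolution layers runs four scaled dot-product self-attention heads
restricted to bonded neighbors plus self (per-head linear projections;
self-loops ensure isolated atoms still update), merges heads by a linear
map with ReLU, and applies a gated residual H' = z ⊙ H_att + (1−z) ⊙ H_in
with z = σ([H_in ‖ H_att] W_z + b_z). The readout sums node features and
maps them to a 256-dimensional graph vector; a 256→256→1 MLP and sigmoid
give the drug probability. Dropout (default 0.3) is applied immediately
before each fully connected layer during training only. Training is
binary cross-entropy with Adam under stratified 5-fold cross-validation,
optionally downsampling the larger class to the smaller first; at
inference the five fold models' sigmoid outputs are averaged (the
ensemble rule is this package's choice) and clipped away from exact 0/1.

Layer equivariance to atom permutations and readout invariance hold by
construction and are asserted numerically in the tests.

## Synthetic data: what it emulates and what it does not

**Markov source.** A first-order chain over five genuine SMILES
characters {C, c, 1, O, N} with an absorbing EOS (per-row hazard ≈ 0.12,
mean string length ≈ 8; non-uniform rows so the model must learn real
conditional structure). Every sampled string has an exactly computable
log-probability, giving an analytic oracle for the likelihood pipeline:
a model trained on 5,000 samples should reproduce held-out string
log-probabilities. The shipped run recovers them to a mean absolute
error well under 1 nat with Spearman ρ > 0.99. These strings exercise
the tokenizer/training/scoring path but are not valid molecules; chem
filters and stereochemistry are bypassed (`canonicalize=False`).

**Toy families.** Three template-enumerated, structurally disjoint
SMILES families: *drug_like* (nitrogen-bearing decorated rings),
*zinc_like* (acyclic oxygen-rich ethers/esters, no nitrogen, no rings)
and *nondrug_like* (pure hydrocarbons, many of them rings). Acyclic
alkenes in the hydrocarbon family are terminal only, so no E/Z geometry
arises and every stereoisomer stays encodable under a vocabulary learned
from the ring families. The design makes the in-distribution task
(drug_like vs. zinc_like) linearly separable for the classifier while
the hydrocarbons share ring/aromatic features with the positive class —
so a classifier that learned "ring ⇒ drug" shortcuts is confidently
wrong on them, reproducing the known overconfidence failure of two-class
drug-likeness models on hydrocarbons. The families are auditable by
construction (membership rules are atom-content predicates) but are far
smaller, shorter and cleaner than real drug/screening libraries: passing
these tests demonstrates correct mechanics and the qualitative
data-dependency contrast, not real-world screening performance, which
requires real corpora and large-scale pretraining.

## Evaluation

AUROC uses the Mann–Whitney convention (ties credited ½; delegated to
scikit-learn, cross-checked in tests against brute-force pair counting)
— the tie handling matters because the classifier's outputs polarize.
The resampled protocol draws n negative samples from a large pool with
seeds seed+i and reports mean ± sd of AUROC. Distribution summaries
report mean, median, 5/25/75/95% quantiles, skewness and the
polarization audit (fractions above 0.9 / below 0.1). QED is included as
the traditional comparator, delegated to RDKit.

## Numerical choices and degenerate inputs

- Softmax and sigmoid computations are max-shifted / clipped for
  stability; next-token distributions sum to 1 within 1e-6 by
  construction.
- An empty string scores as the probability of emitting EOS immediately;
  empty corpora, empty score sets and empty graphs raise errors.
- Unparseable SMILES in input files become records with `parse_ok=False`
  (data, not exceptions); operations that require a parsed molecule
  raise with the offending string.
- The length filter counts characters of the raw input string with an
  exclusive bound (< 100) and is applied before canonicalization;
  multi-fragment detection is the presence of '.' in the raw string.
- Tanimoto deduplication uses Morgan fingerprints (radius 2, 2048 bits),
  the field-standard choice.
- All randomness (weight init, batch order, stereo sampling, fold
  splits, dropout, resampling) flows from explicit integer seeds through
  NumPy generators; identical seeds reproduce scores and CSVs
  bit-for-bit on the same platform.

## Known limitations

- Likelihood-based scores favor short SMILES: each additional character
  multiplies in another conditional ≤ 1, so small molecules (methane at
  the extreme) can outscore genuine drugs. This is a property of the
  score itself, visible in the toy experiment (hydrocarbon mean sits
  above the zinc-like mean partly because hydrocarbons are shorter).
- The NumPy training loop is single-threaded and desk-scale;
  multi-million-molecule pretraining is supported by the API but not a
  tested path.
- The transformer alternative and positive-unlabeled learning variants
  are out of scope.
- Scores are comparable within one trained model only; they are not
  calibrated probabilities of clinical approval.
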