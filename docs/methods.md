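# Methods

## Model

An input sequence (a canonical SMILES string or a protein amino-acid
sequence) is segmented by several tokenizers at once.  For SMILES the
tokenizers are learned BPE over SMILES-aware base symbols and per-atom
circular-environment (ECFP) identifiers at radii 1 and 2; for proteins,
overlapping k-mers (k = 3 by default) and BPE.  Each token stream is
embedded (tables pretrained with skip-gram word2vec, then fine-tuned),
summed with sinusoidal positional encodings, and passed through its own
stack of pre-norm transformer layers (multi-head self-attention plus a
feed-forward block of width 4d, dropout 0.1, final layer norm).  Token
positions are mean-pooled into one vector h_T per tokenization.

A tokenization-level self-attention then scores each h_T with a one-hidden-
layer MLP (width d, tanh, scalar output), softmaxes the scores into weights
a_T, and returns the convex combination h = Σ a_T h_T together with the
weights, which serve as a per-input report of how much each tokenization
contributed.

Two classifiers are trained end to end with cross-entropy: the activity
model (one encoder, MLP head d → d/2 → 2) and the interaction model (two
encoders — compound and protein, with separate fusion scorers — whose fused
vectors are concatenated into a 2d feature before the same kind of head).

## Parameters

| parameter | default | notes |
|---|---|---|
| feature dimension d | 128 | reference setting; desk-scale runs use 32 |
| transformer layers | 5 | per tokenization |
| attention heads | 6 (activity), 4 (interaction) | see "heads vs d" below |
| dropout | 0.1 | attention weights and both residual branches |
| learning rate | 0.01 (activity), 0.001 (interaction) | Adam |
| batch size | 32 | |
| epochs | ≤ 100, early stopping on validation AUC, patience 10 | |
| word2vec | skip-gram, window 5, 5 negatives, min_count 1, 10 epochs | |
| ECFP radii | 1 and 2 | one token per heavy atom |
| k-mer k | 3 | overlapping, stride 1 |
| token cap | 512 | longer streams truncated with a log message |
| activity threshold | 50 µM, strict on both sides | value = 50 dropped |

**Heads vs d.**  The reference setting pairs d = 128 with 6 heads, which no
equal-split multi-head attention can satisfy.  Attention here therefore
projects queries/keys/values to an inner width of `heads × ceil(d/heads)`
and projects the concatenated head outputs back to d, so any (d, heads)
combination is valid.

**Optimizer.**  Adam with the task learning rates above.  The training loss
typically plateaus near ln 2 for roughly ten epochs before the encoders
break through, so early-stopping patience should not be set below ~10.

## Tokenization details

* BPE base symbols are single characters except the two-character halogens
  (Cl, Br) and bracket atoms `[...]`, which are atomic; merges are learned
  greedily by pair frequency with lexicographic tie-breaking, so the
  vocabulary is a pure function of the corpus.  Learning stops early when
  no pair repeats.  Applying merges in learned order guarantees the token
  concatenation reproduces the input exactly.
* ECFP tokens are the 32-bit Morgan identifiers of each heavy atom's
  environment at the requested radius (redundant environments included so
  every atom has an identifier at every radius), rendered as decimal
  strings and ordered by the molecule's canonical atom ranking, which makes
  the stream independent of how the input SMILES was written.  Duplicate
  identifiers are retained: exactly one token per heavy atom.
* SMILES are canonicalized before any tokenization.  Unknown tokens at
  inference map to a reserved UNK embedding.

## Evaluation protocol

10-fold cross-validation with rotating roles: fold i is the test set, fold
(i+1) mod k the validation set used for early stopping, the remaining eight
folds the training set; every record is tested exactly once.  Folds are
stratified by label for both tasks.  AUC (trapezoidal ROC area, ties at
half credit) is the headline metric; the suite cross-checks it against a
brute-force Mann–Whitney concordance count.

## Synthetic data

The generator assembles valid molecules by concatenating 2–5 fragments from
a curated pool (chains, functional groups, aromatic and fused ring systems
echoing flavonoid/terpenoid chemotypes) and validating each assembly with
the toolkit parser; proteins are uniform over the 20-letter alphabet.  A
signal fragment (furan by default, absent from the base pool) is planted in
half the compounds, and for pairs a protein motif in half the proteins.
With signal strength s and label noise η, a signal-carrying compound is
labeled active with probability s, a plain one with probability 1 − s, and
labels flip independently with probability η; pair labels follow the AND of
the fragment and motif indicators.  Defaults are s = 1, η = 0 (labels fully
determined by structure), which is the regime the recovery experiments use;
s = 0.95, η = 0.05 is exercised as an explicitly noisy condition.

What this emulates — and does not: datasets of valid, moderately diverse
small molecules with a recoverable substructure-based activity rule and a
configurable class imbalance.  It does not emulate real assay noise
structure, activity cliffs, correlated scaffolds between train and test, or
the label sparsity of literature-derived data, so passing recovery tests
demonstrates that the architecture and training loop work, not that the
model generalizes on real bioactivity data.

## Desk-scale problem sizes

The shipped experiments use n = 400 labeled compounds (d = 32, 2 layers,
2 heads, ECFP1 + BPE) for the activity task, n = 240 pairs (60 compounds ×
30 proteins, protein lengths 60–120) for the interaction task, and n = 200
for the 10-fold cross-validation, with word2vec at 5 epochs.  These sizes
keep a full run to a few CPU-minutes while leaving the planted signal
comfortably learnable; the full-scale configurations in `configs/` carry
the reference hyperparameters for users with a curated dataset.

## Numerical choices and degenerate inputs

* The autodiff core accumulates gradients in float64; softmax and
  log-softmax subtract the row maximum before exponentiation.
* Padded batch positions are masked out of attention (additive −1e9 bias)
  and of the mean pool, so a sequence encodes identically alone or inside
  a padded batch (tested).
* Fusing a single tokenization reduces to the identity; fused vectors lie
  coordinate-wise in the convex hull of the per-tokenization vectors.
* An assay value exactly at 50 µM is dropped rather than labeled, because
  the activity definition is strict on both sides.  Conflicting assay
  values for one compound resolve to the minimum (most potent) before
  labeling, and the conflict is logged.
* Acyclic molecules have an empty Bemis–Murcko scaffold; disconnected
  frameworks keep the largest fragment.  Constant descriptor columns are
  dropped (with a warning) before PCA standardization.
* BPE sequences containing symbols never seen in training keep them as
  singleton tokens and log a warning.

## Design choices where the design was open

* **Pooling** of token positions into h_T is a masked mean — the simplest
  reduction consistent with variable lengths; it is isolated in one place
  so max- or CLS-pooling can be swapped in.
* **Validation fold** in cross-validation is the next fold cyclically.
* **word2vec variant** is skip-gram with negative sampling; embeddings are
  fine-tuned downstream rather than frozen.
* **Compound/protein encoders** in the interaction model are fully
  separate, including their fusion scorers.
* **PCA reference set** is a packaged table of well-known approved drugs
  (descriptors computed at run time from their SMILES); it affects only
  chemical-space plots, never a model.
* **Class imbalance** in pair data is left unweighted by default; the
  generator can realize a requested positive:negative ratio for imbalance
  experiments.

## Known limitations

* The NumPy core is single-threaded and CPU-bound; it is sized for
  desk-scale studies (hundreds to low thousands of sequences), not for
  corpus-scale pretraining over millions of SMILES.
* Protein BPE operates on raw residue characters; no residue-class
  compression is applied first.
* Checkpoints store weights as JSON text, which is robust and portable but
  large for big models.
* The fusion weights are tokenization-level only; the package does not
  produce token-level attribution maps.
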