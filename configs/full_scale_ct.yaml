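# Full-scale compound-target interaction run: reference hyperparameters
# (dimension 128, 5 layers, 4 heads, lr 0.001, 10-fold CV).  Point the data
# paths at a compound table and a pair table with protein sequences.
task: ct
mode: cv
k_folds: 10
seed: 0
encoder:
  dimension: 128
  heads: 4
  layers: 5
  dropout: 0.1
  max_len: 512
training:
  lr: 0.001
  batch_size: 32
  max_epochs: 100
  patience: 10
embedding:
  window: 5
  epochs: 10
  negatives: 5
compound_tokenizers:
  - {kind: ecfp, radius: 1}
  - {kind: ecfp, radius: 2}
  - {kind: bpe, num_merges: 1000}
protein_tokenizers:
  - {kind: kmer, k: 3}
  - {kind: bpe, num_merges: 1000}
data:
  compounds: data/compounds.csv
  pairs: data/pairs.csv
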