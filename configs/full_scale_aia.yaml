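# Full-scale anti-inflammatory-activity run: reference hyperparameters
# (dimension 128, 5 layers, 6 heads, lr 0.01, 10-fold CV).  Point the data
# paths at a curated compound table and activity table to reproduce a full
# training run; see README for the expected CSV columns.
task: aia
mode: cv
k_folds: 10
seed: 0
encoder:
  dimension: 128
  heads: 6
  layers: 5
  dropout: 0.1
  max_len: 512
training:
  lr: 0.01
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
data:
  compounds: data/compounds.csv
  activities: data/activities.csv
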