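# multitok

Multi-tokenization transformer (MTT) models for natural-product bioactivity
and compound–target interaction prediction.

## The problem

Sequence models for molecules and proteins have to commit to a tokenization
before they see any data, and there is no canonical one: a SMILES string can
be segmented into learned byte-pair-encoding (BPE) substrings, or into one
token per heavy atom carrying that atom's circular-environment (ECFP)
identifier; a protein sequence into overlapping k-mers or BPE pieces.  Each
segmentation carries different chemistry.  `multitok` encodes *all* of them:
each tokenization gets its own transformer encoder, and a tokenization-level
self-attention fuses the per-view vectors

```
a_T = exp(MLP(h_T)) / Σ_T' exp(MLP(h_T'))        (attention over tokenizations)
h   = Σ_T a_T · h_T                               (final representation)
```

where `h_T` is the mean-pooled output of the transformer reading
tokenization `T`.  The weights `a_T` are returned with every encoding and
show which view of the molecule the model leaned on.

On top of the encoder sit two end-to-end classifiers for anti-inflammatory
natural-product research:

* **AI-A** — probability that a compound inhibits NO production in
  macrophages with IC50 < 50 µM (single-compound binary classifier);
* **C–T** — probability that a compound interacts with a protein target
  (compound and protein encodings concatenated, MLP classifier).

Token embeddings are pretrained per tokenization with skip-gram word2vec
over a sequence corpus and fine-tuned during supervised training.  The
package also ships the surrounding workflow: dataset curation with the
strict 50 µM activity rule and macrophage/NO assay filtering, six-descriptor
drug-likeness profiling (MW, LogP, TPSA, #HBD, #HBA, #RotB), Bemis–Murcko
scaffolds, chemical-space PCA against a packaged approved-drug reference
set, 10-fold cross-validation with a rotating validation fold, and a
synthetic-data generator that plants a recoverable structure–activity
signal for controlled experiments.

The neural core (transformers, fusion, training) runs on a small NumPy
reverse-mode autodiff engine included in the package; gradients are
verified against finite differences in the test suite.

## Worked example

Train the activity model on a synthetic dataset in which activity is tied
to a planted furan substructure:

```python
from multitok import (SyntheticSpec, generate_activity_dataset,
                      EncoderConfig, TrainingConfig, train_activity_model,
                      predict_activity)
from multitok.config import (TokenizerEntry, EmbeddingTrainConfig,
                             build_specs, pretrain_tables)

data = generate_activity_dataset(SyntheticSpec(n_compounds=200, seed=0))
corpus = sorted({r.smiles for r in data})
specs = build_specs([TokenizerEntry(kind="ecfp", radius=1),
                     TokenizerEntry(kind="bpe", num_merges=100)],
                    corpus, 256)
tables = pretrain_tables(corpus, specs, EmbeddingTrainConfig(epochs=5),
                         dimension=32, seed=1)
model, log = train_activity_model(
    data, specs, tables,
    EncoderConfig(dimension=32, heads=2, layers=2),
    TrainingConfig(lr=0.01, max_epochs=25, patience=25), seed=0)

print(f"best validation AUC: {log.best_val_auc:.3f} (epoch {log.best_epoch})")
active = next(r for r in data if r.label == 1)
inactive = next(r for r in data if r.label == 0)
print(f"P(active | signal compound)    = {predict_activity(model, active.smiles):.3f}")
print(f"P(active | no-signal compound) = {predict_activity(model, inactive.smiles):.3f}")
print("tokenization attention weights:",
      {k: round(v, 3) for k, v in model.encoder.encode(active.smiles).weights.items()})
```

Output:

```
best validation AUC: 1.000 (epoch 15)
P(active | signal compound)    = 0.999
P(active | no-signal compound) = 0.000
tokenization attention weights: {'ecfp1': 0.982, 'bpe': 0.018}
```

The model separates signal from no-signal compounds cleanly, and the fusion
weights show it relying mostly on the atom-environment (ECFP) view — the
planted rule is a substructure, which ECFP tokens expose directly.

A `multitok` console script wraps the same functionality
(`multitok tokenize`, `learn-bpe`, `train-aia`, `train-ct`, `cv`,
`predict-aia`, `predict-ct`, `curate`, `synth`); run
`multitok --help` for details.  Full-scale training configurations with the
reference hyperparameters (dimension 128, 5 layers, 6 heads / lr 0.01 for
AI-A, 4 heads / lr 0.001 for C–T, 10-fold CV) are in `configs/`.

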