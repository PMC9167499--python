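"""Prediction models on top of the MTT encoder.

Two binary classifiers, trained end to end with cross-entropy:

* :class:`ActivityModel` — anti-inflammatory activity (AI-A): probability
  that a compound inhibits NO production in macrophages with IC50 < 50 µM.
  Single MTT encoder over the compound SMILES, MLP head, Adam at lr 0.01.
* :class:`InteractionModel` — compound–target interaction (C–T): separate
  MTT encoders for the compound SMILES and the protein sequence; the two
  fused vectors are concatenated (length 2d) and fed to an MLP classifier.
  Adam at lr 0.001.

Training uses minibatches of 32, a stratified validation split, and early
stopping on validation AUC (max 100 epochs, patience 10 by default).  All
randomness flows from the seed passed in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .autodiff import Tensor, concat, gather_rows
from .curate import ActivityRecord, PairRecord
from .embed import EmbeddingTable
from .encoder import EncoderConfig, MTTEncoder
from .nn import Adam, Linear
from .tokenize import BpeVocabulary, TokenizerSpec, canonical_smiles

logger = logging.getLogger(__name__)

CHECKPOINT_SCHEMA = 1


@dataclass
class TrainingConfig:
    """Optimization settings for either head."""

    lr: float = 0.01
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainingLog:
    """Per-epoch loss / validation-AUC trace of one fit."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")

    @property
    def initial_loss(self) -> float:
        return self.epochs[0]["train_loss"]

    @property
    def final_loss(self) -> float:
        return self.epochs[-1]["train_loss"]


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean two-class cross-entropy from raw logits."""
    n = logits.shape[0]
    logp = logits.log_softmax(axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(n), labels] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


class _Classifier:
    """MLP head d_in -> d_in/2 -> 2 with ReLU."""

    def __init__(self, rng: np.random.Generator, d_in: int):
        self.fc1 = Linear(rng, d_in, max(2, d_in // 2))
        self.fc2 = Linear(rng, max(2, d_in // 2), 2)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


# ---------------------------------------------------------------------------
# AI-A
# ---------------------------------------------------------------------------

class ActivityModel:
    """Anti-inflammatory-activity classifier (MTT encoder + MLP head)."""

    def __init__(self, specs: list[TokenizerSpec],
                 tables: dict[str, EmbeddingTable],
                 encoder_config: EncoderConfig,
                 training: TrainingConfig | None = None,
                 seed: int = 0):
        self.encoder_config = encoder_config
        self.training = training or TrainingConfig(lr=0.01)
        self.seed = seed
        self.encoder = MTTEncoder(specs, tables, encoder_config, seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        self.classifier = _Classifier(rng, encoder_config.dimension)
        self._predict_cache: dict[str, float] = {}

    def parameters(self):
        return self.encoder.parameters() + self.classifier.parameters()

    def _forward(self, smiles: list[str], rng=None, train=False) -> Tensor:
        fused, _ = self.encoder.encode_batch(smiles, rng=rng, train=train)
        return self.classifier(fused)

    def predict_proba(self, smiles: str) -> float:
        """P(active) for one compound; canonicalizes and caches."""
        smi = canonical_smiles(smiles)
        if smi not in self._predict_cache:
            logits = self._forward([smi]).data[0]
            z = logits - logits.max()
            p = np.exp(z) / np.exp(z).sum()
            self._predict_cache[smi] = float(p[1])
        return self._predict_cache[smi]

    def predict_scores(self, records: list[ActivityRecord],
                       batch_size: int = 64) -> np.ndarray:
        smiles = [canonical_smiles(r.smiles) for r in records]
        out = np.empty(len(smiles))
        for start in range(0, len(smiles), batch_size):
            chunk = smiles[start:start + batch_size]
            out[start:start + len(chunk)] = _softmax_pos(self._forward(chunk).data)
        return out


def predict_activity(model: ActivityModel, smiles: str) -> float:
    return model.predict_proba(smiles)


def train_activity_model(dataset: list[ActivityRecord],
                         specs: list[TokenizerSpec],
                         tables: dict[str, EmbeddingTable],
                         encoder_config: EncoderConfig | None = None,
                         training: TrainingConfig | None = None,
                         seed: int = 0,
                         val_records: list[ActivityRecord] | None = None,
                         ) -> tuple[ActivityModel, TrainingLog]:
    """Fit the AI-A model end to end with cross-entropy and early stopping."""
    encoder_config = encoder_config or EncoderConfig()
    training = training or TrainingConfig(lr=0.01)
    labels = np.array([r.label for r in dataset])
    if len(set(labels.tolist())) < 2:
        raise ValueError("activity dataset must contain both classes")

    if val_records is None:
        train_recs, val_recs = train_test_split(
            dataset, test_size=training.val_fraction, random_state=seed,
            stratify=labels)
    else:
        train_recs, val_recs = list(dataset), list(val_records)

    model = ActivityModel(specs, tables, encoder_config, training, seed=seed)
    log = _fit(model, train_recs, val_recs, training, seed,
               inputs=lambda rs: [r.smiles for r in rs],
               forward=model._forward)
    return model, log


# ---------------------------------------------------------------------------
# C–T
# ---------------------------------------------------------------------------

class InteractionModel:
    """Compound–target interaction classifier.

    Two MTT encoders (compound, protein); fused vectors concatenated into a
    2d feature and classified by an MLP.  The fusion scorers of the two
    modalities are separate.
    """

    def __init__(self, compound_specs: list[TokenizerSpec],
                 protein_specs: list[TokenizerSpec],
                 tables: dict[str, EmbeddingTable],
                 encoder_config: EncoderConfig,
                 training: TrainingConfig | None = None,
                 seed: int = 0):
        self.encoder_config = encoder_config
        self.training = training or TrainingConfig(lr=0.001)
        self.seed = seed
        self.compound_encoder = MTTEncoder(compound_specs, tables,
                                           encoder_config, seed=seed)
        self.protein_encoder = MTTEncoder(protein_specs, tables,
                                          encoder_config, seed=seed + 500)
        rng = np.random.default_rng(seed + 10_000)
        self.classifier = _Classifier(rng, 2 * encoder_config.dimension)
        self._compound_cache: dict[str, np.ndarray] = {}
        self._protein_cache: dict[str, np.ndarray] = {}

    def parameters(self):
        return (self.compound_encoder.parameters()
                + self.protein_encoder.parameters()
                + self.classifier.parameters())

    def _encode_side(self, encoder: MTTEncoder, seqs: list[str],
                     rng, train) -> Tensor:
        """Encode with within-batch deduplication of repeated sequences."""
        uniq = sorted(set(seqs))
        pos = {s: i for i, s in enumerate(uniq)}
        fused, _ = encoder.encode_batch(uniq, rng=rng, train=train)
        idx = np.array([pos[s] for s in seqs], dtype=np.int64)
        return gather_rows(fused, idx)

    def _forward(self, pairs: list[tuple[str, str]], rng=None,
                 train=False) -> Tensor:
        comp = self._encode_side(self.compound_encoder,
                                 [c for c, _ in pairs], rng, train)
        prot = self._encode_side(self.protein_encoder,
                                 [p for _, p in pairs], rng, train)
        return self.classifier(concat([comp, prot], axis=-1))

    def compound_embedding(self, smiles: str) -> np.ndarray:
        """Inference-mode fused compound vector, cached by canonical SMILES."""
        smi = canonical_smiles(smiles)
        if smi not in self._compound_cache:
            self._compound_cache[smi] = self.compound_encoder.encode(smi).h
        return self._compound_cache[smi]

    def predict_proba(self, smiles: str, protein_seq: str) -> float:
        if not protein_seq:
            raise ValueError("protein sequence must be non-empty")
        smi = canonical_smiles(smiles)
        logits = self._forward([(smi, protein_seq)]).data[0]
        z = logits - logits.max()
        p = np.exp(z) / np.exp(z).sum()
        return float(p[1])

    def predict_scores(self, records: list[PairRecord],
                       batch_size: int = 32) -> np.ndarray:
        pairs = [(canonical_smiles(r.smiles), r.protein_sequence)
                 for r in records]
        out = np.empty(len(pairs))
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start:start + batch_size]
            out[start:start + len(chunk)] = _softmax_pos(self._forward(chunk).data)
        return out


def predict_interaction(model: InteractionModel, smiles: str,
                        protein_seq: str) -> float:
    return model.predict_proba(smiles, protein_seq)


def train_interaction_model(pairs: list[PairRecord],
                            compound_specs: list[TokenizerSpec],
                            protein_specs: list[TokenizerSpec],
                            tables: dict[str, EmbeddingTable],
                            encoder_config: EncoderConfig | None = None,
                            training: TrainingConfig | None = None,
                            seed: int = 0,
                            val_records: list[PairRecord] | None = None,
                            ) -> tuple[InteractionModel, TrainingLog]:
    """Fit the C–T model; pairs must resolve to SMILES + protein sequences."""
    encoder_config = encoder_config or EncoderConfig(heads=4)
    training = training or TrainingConfig(lr=0.001)
    dangling = [p for p in pairs if not p.smiles or not p.protein_sequence]
    if dangling:
        ids = [(p.compound_id, p.protein_id) for p in dangling[:10]]
        raise ValueError(f"pairs with unresolved sequences: {ids}")
    labels = np.array([p.label for p in pairs])
    if len(set(labels.tolist())) < 2:
        raise ValueError("pair dataset must contain both classes")

    if val_records is None:
        train_recs, val_recs = train_test_split(
            pairs, test_size=training.val_fraction, random_state=seed,
            stratify=labels)
    else:
        train_recs, val_recs = list(pairs), list(val_records)

    model = InteractionModel(compound_specs, protein_specs, tables,
                             encoder_config, training, seed=seed)
    log = _fit(model, train_recs, val_recs, training, seed,
               inputs=lambda rs: [(r.smiles, r.protein_sequence) for r in rs],
               forward=model._forward)
    return model, log


# ---------------------------------------------------------------------------
# shared training loop
# ---------------------------------------------------------------------------

def _fit(model, train_recs, val_recs, training: TrainingConfig, seed: int,
         inputs, forward) -> TrainingLog:
    params = model.parameters()
    opt = Adam(params, lr=training.lr)
    rng = np.random.default_rng(seed + 1)
    drop_rng = np.random.default_rng(seed + 2)
    y_train = np.array([r.label for r in train_recs])
    y_val = np.array([r.label for r in val_recs])
    log = TrainingLog()
    best = {"auc": -np.inf, "state": None, "epoch": -1}
    n = len(train_recs)

    for epoch in range(training.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, training.batch_size):
            sel = order[start:start + training.batch_size]
            batch = [train_recs[i] for i in sel]
            opt.zero_grad()
            logits = forward(inputs(batch), rng=drop_rng, train=True)
            loss = cross_entropy(logits, y_train[sel])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_logits = forward(inputs(val_recs)).data
        val_scores = _softmax_pos(val_logits)
        val_auc = (roc_auc_score(y_val, val_scores)
                   if len(set(y_val.tolist())) > 1 else float("nan"))
        log.epochs.append({"epoch": epoch,
                           "train_loss": float(np.mean(losses)),
                           "val_auc": float(val_auc)})
        if np.isfinite(val_auc) and val_auc > best["auc"]:
            best = {"auc": val_auc,
                    "state": [p.data.copy() for p in params],
                    "epoch": epoch}
        elif epoch - best["epoch"] >= training.patience and best["state"] is not None:
            logger.info("early stop at epoch %d (best %d)", epoch, best["epoch"])
            break

    if best["state"] is not None:
        for p, saved in zip(params, best["state"]):
            p.data = saved
    log.best_epoch = best["epoch"]
    log.best_val_auc = float(best["auc"]) if np.isfinite(best["auc"]) else float("nan")
    _clear_caches(model)
    return log


def _clear_caches(model) -> None:
    for attr in ("_predict_cache", "_compound_cache", "_protein_cache"):
        if hasattr(model, attr):
            getattr(model, attr).clear()


def _softmax_pos(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    return p[:, 1]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: TokenizerSpec) -> dict:
    d = {"kind": spec.kind, "radius": spec.radius, "k": spec.k,
         "max_tokens": spec.max_tokens, "name": spec.name}
    if spec.vocabulary is not None:
        d["merges"] = [list(m) for m in spec.vocabulary.merges]
        d["corpus_tag"] = spec.vocabulary.corpus_tag
    return d


def _spec_from_dict(d: dict) -> TokenizerSpec:
    vocab = None
    if "merges" in d:
        merges = [tuple(m) for m in d["merges"]]
        token_set = {a + b for a, b in merges}
        token_set.update(s for pair in merges for s in pair)
        vocab = BpeVocabulary(merges=merges, token_set=token_set,
                              corpus_tag=d.get("corpus_tag", ""))
    return TokenizerSpec(kind=d["kind"], radius=d["radius"], k=d["k"],
                         vocabulary=vocab, max_tokens=d["max_tokens"],
                         name=d.get("name"))


def _encoder_vocab_tables(mtt: MTTEncoder) -> dict:
    out = {}
    for tid, enc in mtt.encoders.items():
        tokens = [None] * len(enc.token_index)
        for tok, i in enc.token_index.items():
            tokens[i] = tok
        out[tid] = tokens
    return out


def _stub_tables(vocabs: dict[str, list[str]], d: int) -> dict[str, EmbeddingTable]:
    """Zero-vector tables used only to rebuild encoder shapes before loading."""
    from .embed import UNK
    tables = {}
    for tid, tokens in vocabs.items():
        vecs = {t: np.zeros(d) for t in tokens}
        vecs[UNK] = np.zeros(d)
        tables[tid] = EmbeddingTable(vectors=vecs, dimension=d, tokenizer_id=tid)
    return tables


def save_model(model, path: str) -> None:
    """Single-file JSON checkpoint: schema, config, vocabularies, weights."""
    cfg = model.encoder_config
    state: dict = {
        "schema_version": CHECKPOINT_SCHEMA,
        "kind": "ct" if isinstance(model, InteractionModel) else "aia",
        "encoder_config": {"dimension": cfg.dimension, "heads": cfg.heads,
                           "layers": cfg.layers, "dropout": cfg.dropout,
                           "max_len": cfg.max_len, "ff_mult": cfg.ff_mult},
        "training": vars(model.training),
        "seed": model.seed,
        "weights": [p.data.tolist() for p in model.parameters()],
    }
    if isinstance(model, InteractionModel):
        state["compound_specs"] = [_spec_to_dict(s)
                                   for s in model.compound_encoder.specs]
        state["protein_specs"] = [_spec_to_dict(s)
                                  for s in model.protein_encoder.specs]
        state["vocabs"] = {**_encoder_vocab_tables(model.compound_encoder),
                           **_encoder_vocab_tables(model.protein_encoder)}
    else:
        state["specs"] = [_spec_to_dict(s) for s in model.encoder.specs]
        state["vocabs"] = _encoder_vocab_tables(model.encoder)
    with open(path, "w") as fh:
        json.dump(state, fh)


def load_model(path: str):
    """Rebuild a saved ActivityModel or InteractionModel."""
    with open(path) as fh:
        state = json.load(fh)
    if state.get("schema_version") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema: "
                         f"{state.get('schema_version')}")
    cfg = EncoderConfig(**state["encoder_config"])
    training = TrainingConfig(**state["training"])
    tables = _stub_tables(state["vocabs"], cfg.dimension)
    if state["kind"] == "aia":
        specs = [_spec_from_dict(d) for d in state["specs"]]
        model = ActivityModel(specs, tables, cfg, training, seed=state["seed"])
    else:
        cspecs = [_spec_from_dict(d) for d in state["compound_specs"]]
        pspecs = [_spec_from_dict(d) for d in state["protein_specs"]]
        model = InteractionModel(cspecs, pspecs, tables, cfg, training,
                                 seed=state["seed"])
    params = model.parameters()
    if len(params) != len(state["weights"]):
        raise ValueError("checkpoint weight count mismatch")
    for p, w in zip(params, state["weights"]):
        arr = np.asarray(w, dtype=np.float64)
        if arr.shape != p.data.shape:
            raise ValueError("checkpoint weight shape mismatch")
        p.data = arr
    return model
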