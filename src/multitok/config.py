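"""Run configuration, validation and the end-to-end pipeline driver.

A run is described by one YAML document with an explicit master seed; every
stochastic stage (corpus generation, embedding pretraining, weight init,
batching, fold assignment) derives its own seed from it, so any reported
metric is reproducible from the logged config + seed alone.  Unknown keys
are rejected rather than ignored.

Defaults mirror the reference training setting: feature dimension 128,
5 transformer layers, 6 attention heads and learning rate 0.01 for the
activity task; 4 heads and learning rate 0.001 for the interaction task.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .embed import EmbeddingTable, train_token_embeddings
from .encoder import EncoderConfig
from .heads import (TrainingConfig, save_model, train_activity_model,
                    train_interaction_model)
from .tokenize import TokenizerSpec, learn_bpe_vocabulary, tokenize_one

logger = logging.getLogger(__name__)

_TASK_DEFAULTS = {
    "aia": {"heads": 6, "lr": 0.01},
    "ct": {"heads": 4, "lr": 0.001},
}


@dataclass
class EmbeddingTrainConfig:
    dimension: int | None = None  # defaults to encoder dimension
    window: int = 5
    epochs: int = 10
    negatives: int = 5
    min_count: int = 1


@dataclass
class TokenizerEntry:
    kind: str
    radius: int = 1
    k: int = 3
    num_merges: int = 200


@dataclass
class SyntheticDataConfig:
    n_compounds: int = 400
    n_proteins: int = 50
    signal_strength: float = 1.0
    label_noise: float = 0.0
    n_pairs: int | None = None
    target_ratio: float | None = None


@dataclass
class DataConfig:
    synthetic: SyntheticDataConfig | None = None
    compounds: str | None = None
    activities: str | None = None
    pairs: str | None = None


@dataclass
class RunConfig:
    task: str = "aia"
    seed: int = 0
    mode: str = "cv"                     # "cv" or "train"
    k_folds: int = 10
    out_dir: str = "runs"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    embedding: EmbeddingTrainConfig = field(default_factory=EmbeddingTrainConfig)
    compound_tokenizers: list[TokenizerEntry] = field(default_factory=lambda: [
        TokenizerEntry(kind="ecfp", radius=1),
        TokenizerEntry(kind="ecfp", radius=2),
        TokenizerEntry(kind="bpe")])
    protein_tokenizers: list[TokenizerEntry] = field(default_factory=lambda: [
        TokenizerEntry(kind="kmer", k=3),
        TokenizerEntry(kind="bpe")])
    data: DataConfig = field(default_factory=DataConfig)

    def __post_init__(self):
        if self.task not in _TASK_DEFAULTS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.mode not in ("cv", "train"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, raw: dict, path: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    return cls(**raw)


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    task = raw.get("task", "aia")
    defaults = _TASK_DEFAULTS.get(task, _TASK_DEFAULTS["aia"])

    enc_raw = dict(raw.pop("encoder", {}))
    enc_raw.setdefault("heads", defaults["heads"])
    encoder = _build(EncoderConfig, enc_raw, "encoder")

    tr_raw = dict(raw.pop("training", {}))
    tr_raw.setdefault("lr", defaults["lr"])
    training = _build(TrainingConfig, tr_raw, "training")

    emb = _build(EmbeddingTrainConfig, dict(raw.pop("embedding", {})), "embedding")

    ct = [_build(TokenizerEntry, dict(e), "compound_tokenizers")
          for e in raw.pop("compound_tokenizers", [])] or None
    pt = [_build(TokenizerEntry, dict(e), "protein_tokenizers")
          for e in raw.pop("protein_tokenizers", [])] or None

    data_raw = dict(raw.pop("data", {}))
    syn = data_raw.pop("synthetic", None)
    data = _build(DataConfig, data_raw, "data")
    if syn is not None:
        data.synthetic = _build(SyntheticDataConfig, dict(syn), "data.synthetic")

    cfg = _build(RunConfig, raw, "<root>")
    cfg.encoder = encoder
    cfg.training = training
    cfg.embedding = emb
    if ct is not None:
        cfg.compound_tokenizers = ct
    if pt is not None:
        cfg.protein_tokenizers = pt
    cfg.data = data
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# pipeline helpers
# ---------------------------------------------------------------------------

def build_specs(entries: list[TokenizerEntry], corpus: list[str],
                max_tokens: int, corpus_tag: str = "") -> list[TokenizerSpec]:
    """Turn tokenizer entries into specs, learning BPE vocabularies on the
    corpus where needed."""
    specs = []
    for e in entries:
        if e.kind == "bpe":
            vocab = learn_bpe_vocabulary(corpus, e.num_merges,
                                         corpus_tag=corpus_tag)
            specs.append(TokenizerSpec(kind="bpe", vocabulary=vocab,
                                       max_tokens=max_tokens,
                                       name=f"bpe_{corpus_tag}" if corpus_tag
                                       else None))
        elif e.kind == "ecfp":
            specs.append(TokenizerSpec(kind="ecfp", radius=e.radius,
                                       max_tokens=max_tokens))
        else:
            specs.append(TokenizerSpec(kind="kmer", k=e.k,
                                       max_tokens=max_tokens))
    return specs


def pretrain_tables(corpus: list[str], specs: list[TokenizerSpec],
                    emb: EmbeddingTrainConfig, dimension: int,
                    seed: int) -> dict[str, EmbeddingTable]:
    """Skip-gram pretraining of one embedding table per tokenization."""
    dim = emb.dimension or dimension
    tables = {}
    for i, spec in enumerate(specs):
        tokenized = [tokenize_one(s, spec) for s in corpus]
        tables[spec.tokenizer_id] = train_token_embeddings(
            tokenized, dimension=dim, window=emb.window, epochs=emb.epochs,
            seed=seed + i, negatives=emb.negatives, min_count=emb.min_count)
    return tables


def _load_dataset(cfg: RunConfig):
    from . import curate, synthetic
    if cfg.data.synthetic is not None:
        s = cfg.data.synthetic
        spec = synthetic.SyntheticSpec(
            n_compounds=s.n_compounds, n_proteins=s.n_proteins,
            signal_strength=s.signal_strength, label_noise=s.label_noise,
            seed=cfg.seed)
        if cfg.task == "aia":
            return synthetic.generate_activity_dataset(spec)
        records, _ = synthetic.generate_pair_dataset(
            spec, target_ratio=s.target_ratio, n_pairs=s.n_pairs)
        return records
    if cfg.task == "aia":
        if not (cfg.data.compounds and cfg.data.activities):
            raise ValueError("aia task needs data.compounds and data.activities "
                             "(or data.synthetic)")
        compounds = curate.read_compounds(cfg.data.compounds)
        measurements = curate.read_measurements(cfg.data.activities)
        return curate.assemble_activity_dataset(compounds, measurements)
    if not (cfg.data.compounds and cfg.data.pairs):
        raise ValueError("ct task needs data.compounds and data.pairs "
                         "(or data.synthetic)")
    import pandas as pd
    compounds = curate.read_compounds(cfg.data.compounds)
    return curate.assemble_pair_dataset(compounds, pd.read_csv(cfg.data.pairs))


def run(cfg: RunConfig) -> dict:
    """Execute a full run: data -> BPE -> pretraining -> train or CV.

    Writes ``report.json`` (and a model checkpoint in ``train`` mode) under
    ``out_dir`` and returns the report dict.
    """
    from .evaluate import cross_validate

    t0 = time.time()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    dataset = _load_dataset(cfg)
    stages["data"] = time.time() - t0
    logger.info("dataset: %d records", len(dataset))

    smiles_corpus = sorted({r.smiles for r in dataset})
    c_specs = build_specs(cfg.compound_tokenizers, smiles_corpus,
                          cfg.encoder.max_len, corpus_tag="compound")
    tables = pretrain_tables(smiles_corpus, c_specs, cfg.embedding,
                             cfg.encoder.dimension, cfg.seed + 100)
    p_specs = None
    if cfg.task == "ct":
        protein_corpus = sorted({r.protein_sequence for r in dataset})
        p_specs = build_specs(cfg.protein_tokenizers, protein_corpus,
                              cfg.encoder.max_len, corpus_tag="protein")
        tables.update(pretrain_tables(protein_corpus, p_specs, cfg.embedding,
                                      cfg.encoder.dimension, cfg.seed + 200))
    stages["pretrain"] = time.time() - t0 - stages["data"]

    report: dict = {"task": cfg.task, "mode": cfg.mode, "seed": cfg.seed,
                    "config_hash": cfg.config_hash(), "n_records": len(dataset),
                    "config": cfg.to_dict()}

    if cfg.task == "aia":
        def builder(train, val, fold_seed):
            model, _ = train_activity_model(
                train, c_specs, tables, cfg.encoder, cfg.training,
                seed=fold_seed, val_records=val)
            return model
    else:
        def builder(train, val, fold_seed):
            model, _ = train_interaction_model(
                train, c_specs, p_specs, tables, cfg.encoder, cfg.training,
                seed=fold_seed, val_records=val)
            return model

    if cfg.mode == "cv":
        result = cross_validate(dataset, builder, k=cfg.k_folds, seed=cfg.seed)
        report["fold_aucs"] = result.fold_aucs
        report["mean_auc"] = result.mean_auc
    else:
        if cfg.task == "aia":
            model, log = train_activity_model(
                dataset, c_specs, tables, cfg.encoder, cfg.training,
                seed=cfg.seed)
        else:
            model, log = train_interaction_model(
                dataset, c_specs, p_specs, tables, cfg.encoder, cfg.training,
                seed=cfg.seed)
        ckpt = out_dir / f"model_{cfg.task}_{cfg.config_hash()}.json"
        save_model(model, str(ckpt))
        report["checkpoint"] = str(ckpt)
        report["best_val_auc"] = log.best_val_auc
        report["final_train_loss"] = log.final_loss

    stages["fit"] = time.time() - t0 - stages["data"] - stages["pretrain"]
    report["timing_s"] = {k: round(v, 2) for k, v in stages.items()}
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
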