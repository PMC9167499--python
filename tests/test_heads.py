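"""Prediction-head tests: loss closed form, optimizer sanity, determinism,
permutation null, checkpoint round-trip."""

import numpy as np
import pytest

from multitok.autodiff import Tensor
from multitok.heads import (TrainingConfig, cross_entropy, load_model,
                            predict_activity, predict_interaction, save_model,
                            train_activity_model, train_interaction_model)
from multitok.synthetic import (SyntheticSpec, generate_activity_dataset,
                                generate_pair_dataset, shuffle_labels)
from multitok.tokenize import SmilesParseError


@pytest.fixture(scope="module")
def activity_data():
    return generate_activity_dataset(SyntheticSpec(n_compounds=80, seed=21))


@pytest.fixture(scope="module")
def quick_training():
    return TrainingConfig(lr=0.01, batch_size=32, max_epochs=4, patience=10)


@pytest.fixture(scope="module")
def trained_aia(activity_data, compound_specs, tables, small_config,
                quick_training):
    model, log = train_activity_model(
        activity_data, compound_specs, tables, small_config, quick_training,
        seed=0)
    return model, log


def test_cross_entropy_closed_form():
    """Uniform two-class prediction on one example costs ln 2."""
    logits = Tensor(np.zeros((1, 2)), requires_grad=True)
    loss = cross_entropy(logits, np.array([1]))
    assert float(loss.data) == pytest.approx(np.log(2.0), abs=1e-12)

    # perfect prediction costs ~0; a (0.9, 0.1)-style prediction matches -ln p
    logits = Tensor(np.array([[np.log(9.0), 0.0]]))
    loss = cross_entropy(logits, np.array([0]))
    assert float(loss.data) == pytest.approx(-np.log(0.9), abs=1e-12)


def test_training_reduces_loss(trained_aia):
    _, log = trained_aia
    assert log.final_loss < log.initial_loss


def test_training_is_deterministic(activity_data, compound_specs, tables,
                                   small_config):
    tc = TrainingConfig(lr=0.01, max_epochs=2, patience=10)
    _, log1 = train_activity_model(activity_data, compound_specs, tables,
                                   small_config, tc, seed=4)
    _, log2 = train_activity_model(activity_data, compound_specs, tables,
                                   small_config, tc, seed=4)
    assert log1.epochs == log2.epochs


def test_single_class_dataset_rejected(activity_data, compound_specs, tables,
                                       small_config):
    ones = [r for r in activity_data if r.label == 1]
    with pytest.raises(ValueError):
        train_activity_model(ones, compound_specs, tables, small_config)


def test_probability_range_and_determinism(trained_aia, activity_data):
    model, _ = trained_aia
    smi = activity_data[0].smiles
    p = predict_activity(model, smi)
    assert 0.0 <= p <= 1.0
    assert predict_activity(model, smi) == p


def test_predict_rejects_bad_smiles(trained_aia):
    model, _ = trained_aia
    with pytest.raises(SmilesParseError):
        predict_activity(model, "][")


def test_class_probabilities_sum_to_one(trained_aia, activity_data):
    model, _ = trained_aia
    logits = model._forward([activity_data[0].smiles]).data
    z = np.exp(logits - logits.max())
    assert (z / z.sum()).sum() == pytest.approx(1.0)


def test_label_shuffled_control_near_chance(compound_specs, tables,
                                            small_config):
    """Training on permuted labels yields held-out AUC ~ 0.5 (5 seeds)."""
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split

    data = generate_activity_dataset(SyntheticSpec(n_compounds=120, seed=33))
    tc = TrainingConfig(lr=0.01, max_epochs=4, patience=10)
    aucs = []
    for seed in range(5):
        shuffled = shuffle_labels(data, seed=seed)
        labels = [r.label for r in shuffled]
        tr, te = train_test_split(shuffled, test_size=0.3, random_state=seed,
                                  stratify=labels)
        model, _ = train_activity_model(tr, compound_specs, tables,
                                        small_config, tc, seed=seed)
        aucs.append(roc_auc_score([r.label for r in te],
                                  model.predict_scores(te)))
    assert 0.4 <= float(np.mean(aucs)) <= 0.6


@pytest.fixture(scope="module")
def pair_setup():
    from multitok.config import (EmbeddingTrainConfig, TokenizerEntry,
                                 build_specs, pretrain_tables)
    spec = SyntheticSpec(n_compounds=40, n_proteins=16, seed=9,
                         protein_length_range=(40, 80))
    pairs, _ = generate_pair_dataset(spec, n_pairs=120)
    smiles = sorted({p.smiles for p in pairs})
    prots = sorted({p.protein_sequence for p in pairs})
    cspecs = build_specs([TokenizerEntry(kind="ecfp", radius=1),
                          TokenizerEntry(kind="bpe", num_merges=40)],
                         smiles, 128, corpus_tag="c")
    pspecs = build_specs([TokenizerEntry(kind="kmer", k=3),
                          TokenizerEntry(kind="bpe", num_merges=40)],
                         prots, 128, corpus_tag="p")
    emb = EmbeddingTrainConfig(epochs=2)
    tabs = pretrain_tables(smiles, cspecs, emb, 16, seed=1)
    tabs.update(pretrain_tables(prots, pspecs, emb, 16, seed=2))
    return pairs, cspecs, pspecs, tabs


@pytest.fixture(scope="module")
def trained_ct(pair_setup, small_config):
    pairs, cspecs, pspecs, tabs = pair_setup
    tc = TrainingConfig(lr=0.001, max_epochs=3, patience=10)
    model, log = train_interaction_model(pairs, cspecs, pspecs, tabs,
                                         small_config, tc, seed=0)
    return model, log


class TestInteraction:
    def test_loss_decreases(self, trained_ct):
        _, log = trained_ct
        assert log.final_loss < log.initial_loss

    def test_compound_embedding_cached_and_reused(self, trained_ct, pair_setup):
        model, _ = trained_ct
        pairs = pair_setup[0]
        smi = pairs[0].smiles
        e1 = model.compound_embedding(smi)
        e2 = model.compound_embedding(smi)
        assert e1 is e2  # same object: cache hit, not recomputation

    def test_prediction_contract(self, trained_ct, pair_setup):
        model, _ = trained_ct
        pairs = pair_setup[0]
        p = predict_interaction(model, pairs[0].smiles,
                                pairs[0].protein_sequence)
        assert 0.0 <= p <= 1.0
        assert predict_interaction(model, pairs[0].smiles,
                                   pairs[0].protein_sequence) == p

    def test_protein_ranking_stable(self, trained_ct, pair_setup):
        model, _ = trained_ct
        pairs = pair_setup[0]
        prots = sorted({p.protein_sequence for p in pairs})[:5]
        smi = pairs[0].smiles
        r1 = sorted(prots, key=lambda s: model.predict_proba(smi, s))
        r2 = sorted(prots, key=lambda s: model.predict_proba(smi, s))
        assert r1 == r2

    def test_dangling_pairs_rejected(self, pair_setup, small_config):
        pairs, cspecs, pspecs, tabs = pair_setup
        from multitok.curate import PairRecord
        broken = pairs[:20] + [PairRecord(compound_id="X", protein_id="Y",
                                          protein_sequence="", label=1,
                                          smiles="CCO")]
        with pytest.raises(ValueError, match="unresolved"):
            train_interaction_model(broken, cspecs, pspecs, tabs, small_config)


def test_checkpoint_roundtrip(trained_aia, activity_data, tmp_path):
    """Saved model reloads with identical predictions."""
    model, _ = trained_aia
    path = tmp_path / "model.json"
    save_model(model, str(path))
    loaded = load_model(str(path))
    for rec in activity_data[:5]:
        assert loaded.predict_proba(rec.smiles) == \
            pytest.approx(model.predict_proba(rec.smiles), abs=1e-12)
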