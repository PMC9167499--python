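"""Encoder and fusion tests: softmax contracts, closed forms, gradient flow."""

import numpy as np
import pytest

from multitok.autodiff import Tensor
from multitok.embed import UNK, EmbeddingTable
from multitok.encoder import (EncoderConfig, FusionScorer, MTTEncoder,
                              TokenizationEncoding, encode,
                              encode_one_tokenization, fuse)
from multitok.heads import cross_entropy
from multitok.tokenize import TokenSequence


class _StubScorer:
    """Scorer returning preset logits, for closed-form fusion checks."""

    def __init__(self, logits):
        self._logits = list(logits)

    def scores(self, h):
        return Tensor(np.asarray(self._logits)[: h.shape[0], None])


def _enc(vec, tid):
    return TokenizationEncoding(h=np.asarray(vec, dtype=float), tokenizer_id=tid)


class TestFusionClosedForms:
    def test_singleton_is_identity(self):
        e = _enc([1.0, -2.0, 3.0], "bpe")
        out = fuse([e], _StubScorer([0.7]))
        assert out.weights == {"bpe": 1.0}
        np.testing.assert_allclose(out.h, e.h)

    def test_equal_logits_average(self):
        out = fuse([_enc([2.0, 0.0], "a"), _enc([0.0, 2.0], "b")],
                   _StubScorer([1.3, 1.3]))
        assert out.weights["a"] == pytest.approx(0.5)
        np.testing.assert_allclose(out.h, [1.0, 1.0])

    def test_logits_zero_and_ln3(self):
        # softmax(0, ln 3) = (1/(1+3), 3/(1+3)) = (0.25, 0.75)
        out = fuse([_enc([4.0, 0.0], "a"), _enc([0.0, 4.0], "b")],
                   _StubScorer([0.0, np.log(3.0)]))
        assert out.weights["a"] == pytest.approx(0.25)
        assert out.weights["b"] == pytest.approx(0.75)
        np.testing.assert_allclose(out.h, [1.0, 3.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse([_enc([1.0], "a"), _enc([1.0, 2.0], "b")], _StubScorer([0, 0]))


class TestFusionProperties:
    def test_weights_sum_to_one_and_convex_hull(self, rng):
        """Softmax contract and per-coordinate convex-hull containment."""
        scorer = FusionScorer(8, seed=1)
        for _ in range(20):
            encs = [_enc(rng.standard_normal(8), f"t{j}") for j in range(3)]
            out = fuse(encs, scorer)
            w = np.array(list(out.weights.values()))
            assert w.sum() == pytest.approx(1.0, abs=1e-6)
            assert (w >= 0).all()
            H = np.stack([e.h for e in encs])
            assert (out.h >= H.min(axis=0) - 1e-9).all()
            assert (out.h <= H.max(axis=0) + 1e-9).all()

    def test_batch_fusion_matches_single(self, compound_specs, tables,
                                         small_config):
        enc = MTTEncoder(compound_specs, tables, small_config, seed=0)
        fr = enc.encode("CCOc1ccccc1")
        fused, weights = enc.encode_batch(["CCOc1ccccc1"])
        np.testing.assert_allclose(fused.data[0], fr.h)
        np.testing.assert_allclose(weights[0].sum(), 1.0)


class TestEncodeOneTokenization:
    def _table(self, rng, d=16):
        toks = {f"t{i}": rng.standard_normal(d) for i in range(6)}
        toks[UNK] = rng.standard_normal(d)
        return EmbeddingTable(vectors=toks, dimension=d, tokenizer_id="stub")

    def test_inference_deterministic(self, rng, small_config):
        table = self._table(rng)
        seq = TokenSequence(tokens=("t0", "t1", "t2"), tokenizer_id="stub",
                            source_length=3)
        h1 = encode_one_tokenization(seq, table, small_config, seed=5)
        h2 = encode_one_tokenization(seq, table, small_config, seed=5)
        np.testing.assert_array_equal(h1.h, h2.h)

    def test_order_sensitivity(self, rng, small_config):
        """Positional encoding makes token order matter."""
        table = self._table(rng)
        a = TokenSequence(tokens=("t0", "t1", "t2"), tokenizer_id="stub",
                          source_length=3)
        b = TokenSequence(tokens=("t2", "t1", "t0"), tokenizer_id="stub",
                          source_length=3)
        ha = encode_one_tokenization(a, table, small_config, seed=5)
        hb = encode_one_tokenization(b, table, small_config, seed=5)
        assert not np.allclose(ha.h, hb.h)

    def test_single_token_input(self, rng, small_config):
        table = self._table(rng)
        seq = TokenSequence(tokens=("t3",), tokenizer_id="stub",
                            source_length=1)
        out = encode_one_tokenization(seq, table, small_config, seed=5)
        assert out.h.shape == (small_config.dimension,)
        assert np.isfinite(out.h).all()

    def test_empty_rejected(self, rng, small_config):
        table = self._table(rng)
        seq = TokenSequence(tokens=(), tokenizer_id="stub", source_length=0)
        with pytest.raises(ValueError):
            encode_one_tokenization(seq, table, small_config)


class TestEndToEndEncode:
    def test_weights_per_spec_sum_to_one(self, compound_specs, tables,
                                         small_config):
        out = encode("CC(=O)Oc1ccccc1", compound_specs, tables, small_config)
        assert set(out.weights) == {s.tokenizer_id for s in compound_specs}
        assert sum(out.weights.values()) == pytest.approx(1.0, abs=1e-6)

    def test_repeat_encoding_identical(self, compound_specs, tables,
                                       small_config):
        enc = MTTEncoder(compound_specs, tables, small_config, seed=3)
        h1 = enc.encode("CCN(CC)CC").h
        h2 = enc.encode("CCN(CC)CC").h
        np.testing.assert_array_equal(h1, h2)

    def test_padding_does_not_leak(self, compound_specs, tables, small_config):
        """A sequence's encoding is identical alone or in a padded batch."""
        enc = MTTEncoder(compound_specs, tables, small_config, seed=3)
        short = "CCO"
        long = "CCOc1ccc(OC)cc1CCNC(=O)C"
        solo, _ = enc.encode_batch([short])
        batched, _ = enc.encode_batch([short, long])
        np.testing.assert_allclose(batched.data[0], solo.data[0], atol=1e-10)

    def test_heads_not_dividing_dimension_supported(self, rng):
        """The reference setting pairs d=128 with 6 heads; attention must
        handle heads that do not divide the feature dimension."""
        cfg = EncoderConfig(dimension=16, heads=6, layers=1, dropout=0.0)
        from multitok.encoder import TransformerLayer
        layer = TransformerLayer(rng, cfg)
        x = Tensor(rng.standard_normal((2, 5, 16)))
        out = layer(x, Tensor(np.zeros((2, 1, 1, 5))), None, False)
        assert out.shape == (2, 5, 16)
        assert np.isfinite(out.data).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(dimension=16, heads=0)
        with pytest.raises(ValueError):
            EncoderConfig(dimension=16, heads=2, dropout=1.0)


def test_gradient_flow_through_all_parameters(compound_specs, tables,
                                              small_config):
    """End-to-end training signal reaches every trainable tensor.

    Embeddings, every transformer layer, the fusion MLP and the loss path
    must all receive a nonzero gradient on a nontrivial batch.
    """
    enc = MTTEncoder(compound_specs, tables, small_config, seed=0)
    fused, _ = enc.encode_batch(["CCOc1ccccc1", "CCN(CC)CC", "CC(=O)O"],
                                train=False)
    logits = fused @ Tensor(np.random.default_rng(1).standard_normal(
        (small_config.dimension, 2)), requires_grad=True)
    loss = cross_entropy(logits, np.array([0, 1, 0]))
    loss.backward()
    dead = [i for i, p in enumerate(enc.parameters())
            if p.grad is None or not np.any(p.grad)]
    assert dead == []
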