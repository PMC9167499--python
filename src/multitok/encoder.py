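"""Multi-tokenization transformer (MTT) sequence encoder.

One transformer encoder per tokenization turns each token stream into a
contextualized vector h_T (mean-pooled over positions), and a
tokenization-level self-attention then weighs the views:

    a_T = softmax_T( MLP(h_T) )        (attention over tokenizations)
    h   = sum_T a_T * h_T              (convex combination)

The weights a_T are returned alongside h: they indicate how much each
tokenization contributed to the final representation of a given input,
which is the model's built-in interpretability handle.

Transformer internals: learned token embeddings (initialized from the
pretrained tables, fine-tuned downstream), sinusoidal positional encoding,
pre-norm layers with multi-head self-attention and a 4d feed-forward, a
final layer norm, and masked mean pooling over positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .embed import UNK, EmbeddingTable
from .nn import LayerNorm, Linear, dropout
from .tokenize import TokenSequence, TokenizerSpec, tokenize_all

PAD = "<pad>"


@dataclass
class EncoderConfig:
    """Architecture hyperparameters shared by all tokenization encoders.

    Defaults follow the activity-prediction setting: feature dimension 128,
    5 transformer layers, 6 attention heads; the interaction model uses 4
    heads instead.  ``heads`` need not divide ``dimension``: attention
    projects to an inner width of ``heads * ceil(dimension / heads)`` and
    the output projection maps back to ``dimension``.
    """

    dimension: int = 128
    heads: int = 6
    layers: int = 5
    dropout: float = 0.1
    max_len: int = 512
    ff_mult: int = 4

    def __post_init__(self):
        if self.dimension < 2 or self.heads < 1 or self.layers < 1:
            raise ValueError("dimension >= 2, heads >= 1, layers >= 1 required")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TokenizationEncoding:
    """Contextualized d-vector h_T from one tokenization-specific encoder."""

    h: np.ndarray
    tokenizer_id: str


@dataclass(frozen=True)
class FusedRepresentation:
    """Final representation h plus the per-tokenization attention weights."""

    h: np.ndarray
    weights: dict[str, float] = field(default_factory=dict)


def sinusoidal_positions(length: int, d: int) -> np.ndarray:
    """Standard sine/cosine positional encoding, shape (length, d)."""
    pos = np.arange(length)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d)
    enc = np.zeros((length, d))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles[:, : d - d // 2])
    return enc


class TransformerLayer:
    """Pre-norm block: x + MHA(LN(x)); then x + FFN(LN(x))."""

    def __init__(self, rng: np.random.Generator, config: EncoderConfig):
        d, self.heads = config.dimension, config.heads
        self.d_head = -(-d // config.heads)  # ceil: heads need not divide d
        inner = self.heads * self.d_head
        self.ln1 = LayerNorm(d)
        self.q = Linear(rng, d, inner)
        self.k = Linear(rng, d, inner)
        self.v = Linear(rng, d, inner)
        self.o = Linear(rng, inner, d)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(rng, d, config.ff_mult * d)
        self.ff2 = Linear(rng, config.ff_mult * d, d)
        self.p_drop = config.dropout

    def __call__(self, x: Tensor, mask_bias: Tensor,
                 rng: np.random.Generator | None, train: bool) -> Tensor:
        B, L, d = x.shape
        h = self.ln1(x)

        def split(t: Tensor) -> Tensor:  # (B,L,d) -> (B,H,L,dh)
            return t.reshape(B, L, self.heads, self.d_head).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(h)), split(self.k(h)), split(self.v(h))
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(self.d_head))
        att = (scores + mask_bias).softmax(axis=-1)
        att = dropout(att, self.p_drop, rng, train)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, L,
                                                      self.heads * self.d_head)
        x = x + dropout(self.o(ctx), self.p_drop, rng, train)

        h = self.ln2(x)
        h = self.ff2(self.ff1(h).relu())
        return x + dropout(h, self.p_drop, rng, train)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for mod in (self.ln1, self.q, self.k, self.v, self.o,
                    self.ln2, self.ff1, self.ff2):
            out.extend(mod.parameters())
        return out


class TokenizationEncoder:
    """Transformer encoder for one tokenization.

    The embedding matrix is initialized from the pretrained table (one row
    per token seen in pretraining, plus UNK and PAD) and is trainable.
    """

    def __init__(self, table: EmbeddingTable, config: EncoderConfig,
                 seed: int = 0):
        self.tokenizer_id = table.tokenizer_id
        self.config = config
        rng = np.random.default_rng(seed)
        vocab = sorted(t for t in table.vectors if t not in (UNK, PAD))
        self.token_index = {t: i for i, t in enumerate(vocab)}
        self.unk_index = len(vocab)
        self.pad_index = len(vocab) + 1

        d = config.dimension
        emb = np.zeros((len(vocab) + 2, d))
        for tok, i in self.token_index.items():
            vec = table.vectors[tok]
            emb[i] = _fit_dim(vec, d)
        emb[self.unk_index] = _fit_dim(table.vectors[UNK], d)
        self.embedding = Tensor(emb, requires_grad=True)
        self.positions = sinusoidal_positions(config.max_len, d)
        self.layers = [TransformerLayer(rng, config) for _ in range(config.layers)]
        self.final_ln = LayerNorm(d)

    # -- encoding ---------------------------------------------------------

    def indices(self, seq: TokenSequence) -> np.ndarray:
        return np.array([self.token_index.get(t, self.unk_index)
                         for t in seq.tokens], dtype=np.int64)

    def encode_batch(self, seqs: list[TokenSequence],
                     rng: np.random.Generator | None = None,
                     train: bool = False) -> Tensor:
        """Encode a batch of token streams into pooled vectors, shape (B, d)."""
        if any(len(s) == 0 for s in seqs):
            raise ValueError("cannot encode an empty token sequence")
        from .autodiff import gather_rows

        B = len(seqs)
        L = max(len(s) for s in seqs)
        idx = np.full((B, L), self.pad_index, dtype=np.int64)
        mask = np.zeros((B, L))
        for b, s in enumerate(seqs):
            idx[b, : len(s)] = self.indices(s)
            mask[b, : len(s)] = 1.0

        x = gather_rows(self.embedding, idx) + Tensor(self.positions[None, :L, :])
        bias = Tensor(((mask - 1.0) * 1e9)[:, None, None, :])  # (B,1,1,L)
        for layer in self.layers:
            x = layer(x, bias, rng, train)
        x = self.final_ln(x)
        # masked mean pool over valid positions
        m = Tensor(mask[:, :, None])
        counts = Tensor(1.0 / mask.sum(axis=1)[:, None])
        return (x * m).sum(axis=1) * counts

    def parameters(self) -> list[Tensor]:
        out = [self.embedding]
        for layer in self.layers:
            out.extend(layer.parameters())
        out.extend(self.final_ln.parameters())
        return out


class FusionScorer:
    """Tokenization-level self-attention: MLP score -> softmax weights."""

    def __init__(self, dimension: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden = Linear(rng, dimension, dimension)
        self.out = Linear(rng, dimension, 1)

    def scores(self, h: Tensor) -> Tensor:
        """Scalar attention logit per row of ``h``; h is (..., d)."""
        return self.out(self.hidden(h).tanh())

    def fuse_batch(self, encodings: list[Tensor],
                   ids: list[str]) -> tuple[Tensor, np.ndarray]:
        """Fuse per-tokenization (B, d) tensors into (B, d) plus weights (B, T)."""
        from .autodiff import concat

        if not encodings:
            raise ValueError("need at least one tokenization encoding")
        dims = {e.shape[-1] for e in encodings}
        if len(dims) != 1:
            raise ValueError(f"dimension mismatch across tokenizations: {dims}")
        logits = concat([self.scores(e) for e in encodings], axis=-1)  # (B, T)
        weights = logits.softmax(axis=-1)
        B, T = weights.shape
        fused = None
        for t, enc in enumerate(encodings):
            sel = np.zeros((T, 1))
            sel[t, 0] = 1.0
            w_t = weights @ Tensor(sel)          # (B, 1)
            term = enc * w_t
            fused = term if fused is None else fused + term
        return fused, weights.data.copy()

    def parameters(self) -> list[Tensor]:
        return self.hidden.parameters() + self.out.parameters()


def _fit_dim(vec: np.ndarray, d: int) -> np.ndarray:
    """Pad with zeros / truncate a pretrained vector to the encoder width."""
    if len(vec) == d:
        return vec
    out = np.zeros(d)
    out[: min(d, len(vec))] = vec[:d]
    return out


class MTTEncoder:
    """The full multi-tokenization encoder for one modality.

    Holds one :class:`TokenizationEncoder` per tokenizer spec plus the
    fusion scorer; tokenization of raw sequences is cached so repeated
    encodings of the same input never re-tokenize.
    """

    def __init__(self, specs: list[TokenizerSpec],
                 tables: dict[str, EmbeddingTable],
                 config: EncoderConfig, seed: int = 0):
        if not specs:
            raise ValueError("at least one tokenizer spec is required")
        missing = [s.tokenizer_id for s in specs if s.tokenizer_id not in tables]
        if missing:
            raise ValueError(f"no embedding table for tokenizers: {missing}")
        self.specs = specs
        self.config = config
        self.encoders = {
            s.tokenizer_id: TokenizationEncoder(tables[s.tokenizer_id], config,
                                                seed=seed + i)
            for i, s in enumerate(specs)
        }
        self.fusion = FusionScorer(config.dimension, seed=seed + len(specs))
        self._token_cache: dict[str, list[TokenSequence]] = {}

    def tokenize(self, sequence: str) -> list[TokenSequence]:
        cached = self._token_cache.get(sequence)
        if cached is None:
            cached = tokenize_all(sequence, self.specs)
            self._token_cache[sequence] = cached
        return cached

    def encode_batch(self, sequences: list[str],
                     rng: np.random.Generator | None = None,
                     train: bool = False) -> tuple[Tensor, np.ndarray]:
        """Encode raw sequences; returns fused (B, d) and weights (B, T)."""
        per_tok = [self.tokenize(s) for s in sequences]
        encodings = []
        for t, spec in enumerate(self.specs):
            seqs = [views[t] for views in per_tok]
            encodings.append(
                self.encoders[spec.tokenizer_id].encode_batch(seqs, rng, train))
        return self.fusion.fuse_batch(
            encodings, [s.tokenizer_id for s in self.specs])

    def encode(self, sequence: str) -> FusedRepresentation:
        """Inference-mode encoding of a single sequence."""
        fused, weights = self.encode_batch([sequence], rng=None, train=False)
        ids = [s.tokenizer_id for s in self.specs]
        return FusedRepresentation(
            h=fused.data[0].copy(),
            weights={tid: float(w) for tid, w in zip(ids, weights[0])})

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for spec in self.specs:
            out.extend(self.encoders[spec.tokenizer_id].parameters())
        out.extend(self.fusion.parameters())
        return out


# ---------------------------------------------------------------------------
# functional API
# ---------------------------------------------------------------------------

def encode_one_tokenization(tokens: TokenSequence, table: EmbeddingTable,
                            config: EncoderConfig,
                            seed: int = 0) -> TokenizationEncoding:
    """Encode one token stream with a freshly seeded tokenization encoder."""
    if len(tokens) == 0:
        raise ValueError("cannot encode an empty token sequence")
    enc = TokenizationEncoder(table, config, seed=seed)
    pooled = enc.encode_batch([tokens], rng=None, train=False)
    return TokenizationEncoding(h=pooled.data[0].copy(),
                                tokenizer_id=tokens.tokenizer_id)


def fuse(encodings: list[TokenizationEncoding],
         scorer: FusionScorer) -> FusedRepresentation:
    """Softmax-attention fusion of per-tokenization encodings."""
    if not encodings:
        raise ValueError("need at least one encoding")
    dims = {len(e.h) for e in encodings}
    if len(dims) != 1:
        raise ValueError(f"dimension mismatch: {dims}")
    H = Tensor(np.stack([e.h for e in encodings]))       # (T, d)
    logits = scorer.scores(H).data.ravel()               # (T,)
    z = logits - logits.max()
    w = np.exp(z) / np.exp(z).sum()
    h = (w[:, None] * H.data).sum(axis=0)
    return FusedRepresentation(
        h=h, weights={e.tokenizer_id: float(wi) for e, wi in zip(encodings, w)})


def encode(sequence: str, specs: list[TokenizerSpec],
           tables: dict[str, EmbeddingTable], config: EncoderConfig,
           seed: int = 0) -> FusedRepresentation:
    """Tokenize -> per-tokenization encode -> fuse, with fresh seeded weights."""
    return MTTEncoder(specs, tables, config, seed=seed).encode(sequence)
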