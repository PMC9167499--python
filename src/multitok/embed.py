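"""Self-supervised token-embedding pretraining (skip-gram word2vec).

Each tokenization of the corpus is treated as its own language: token
streams are sentences, tokens are words, and a skip-gram model with
negative sampling is trained per tokenization to place co-occurring tokens
near each other in embedding space.  The resulting tables initialize the
encoder's embedding layers and are fine-tuned end to end downstream.

The trainer is a vectorized NumPy implementation: all (center, context)
pairs are materialized once, shuffled per epoch, and updated in minibatches
with a linearly decaying learning rate.  Training is single-threaded and
fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tokenize import TokenSequence

UNK = "<unk>"


@dataclass
class EmbeddingTable:
    """token -> d-vector mapping from skip-gram pretraining."""

    vectors: dict[str, np.ndarray]
    dimension: int
    tokenizer_id: str
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if UNK not in self.vectors:
            raise ValueError("embedding table must contain the UNK token")
        for tok, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(f"vector for {tok!r} has wrong dimension")

    def get(self, token: str) -> np.ndarray:
        return self.vectors.get(token, self.vectors[UNK])

    def save(self, path: str) -> None:
        """Persist in the standard word2vec text format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for tok, vec in self.vectors.items():
                fh.write(tok + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load(cls, path: str, tokenizer_id: str = "") -> "EmbeddingTable":
        with open(path) as fh:
            count, dim = map(int, fh.readline().split())
            vectors: dict[str, np.ndarray] = {}
            for _ in range(count):
                parts = fh.readline().rstrip("\n").split(" ")
                vectors[parts[0]] = np.array(parts[1:], dtype=np.float64)
        return cls(vectors=vectors, dimension=dim, tokenizer_id=tokenizer_id)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_token_embeddings(tokenized_corpus: list[TokenSequence],
                           dimension: int = 128,
                           window: int = 5,
                           epochs: int = 10,
                           seed: int = 0,
                           negatives: int = 5,
                           min_count: int = 1,
                           batch_size: int = 1024,
                           lr: float = 0.025) -> EmbeddingTable:
    """Train skip-gram embeddings with negative sampling over one tokenization.

    Parameters follow the usual word2vec conventions: symmetric context
    ``window``, ``negatives`` noise words per positive pair drawn from the
    unigram distribution raised to 3/4, tokens below ``min_count`` dropped
    (they fall back to UNK at lookup time).  The learning rate decays
    linearly from ``lr`` to ``lr/100`` over all updates.
    """
    if not tokenized_corpus:
        raise ValueError("corpus must be non-empty")
    if dimension < 2:
        raise ValueError("dimension must be >= 2")

    tokenizer_id = tokenized_corpus[0].tokenizer_id
    counts: dict[str, int] = {}
    for seq in tokenized_corpus:
        for tok in seq.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(tok for tok, c in counts.items() if c >= min_count)
    if len(vocab) < 2:
        raise ValueError("corpus must contain at least 2 distinct tokens")
    index = {tok: i for i, tok in enumerate(vocab)}

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W_in = (rng.random((V, dimension)) - 0.5) / dimension
    W_out = np.zeros((V, dimension))

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise_p = freq / freq.sum()

    # materialize all (center, context) pairs once
    centers_l: list[int] = []
    contexts_l: list[int] = []
    for seq in tokenized_corpus:
        ids = [index[t] for t in seq.tokens if t in index]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers_l.append(c)
                    contexts_l.append(ids[j])
    centers = np.array(centers_l, dtype=np.int64)
    contexts = np.array(contexts_l, dtype=np.int64)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("corpus yields no skip-gram pairs")

    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            cur_lr = lr * max(1e-2, 1.0 - step / total_batches)
            step += 1
            sel = order[start:start + batch_size]
            c_idx, o_idx = centers[sel], contexts[sel]
            B = len(sel)
            neg_idx = rng.choice(V, size=(B, negatives), p=noise_p)

            v = W_in[c_idx]                     # (B, d)
            u_pos = W_out[o_idx]                # (B, d)
            u_neg = W_out[neg_idx]              # (B, neg, d)

            g_pos = _sigmoid((v * u_pos).sum(1)) - 1.0          # (B,)
            g_neg = _sigmoid(np.einsum("bd,bnd->bn", v, u_neg))  # (B, neg)

            grad_v = g_pos[:, None] * u_pos + np.einsum("bn,bnd->bd", g_neg, u_neg)
            np.add.at(W_in, c_idx, -cur_lr * grad_v)
            np.add.at(W_out, o_idx, -cur_lr * g_pos[:, None] * v)
            np.add.at(W_out, neg_idx.ravel(),
                      (-cur_lr * g_neg[..., None] * v[:, None, :]).reshape(-1, dimension))

    vectors = {tok: W_in[i].copy() for tok, i in index.items()}
    # UNK gets its own (untrained) embedding drawn from the same init scheme
    vectors[UNK] = (rng.random(dimension) - 0.5) / dimension
    return EmbeddingTable(
        vectors=vectors, dimension=dimension, tokenizer_id=tokenizer_id,
        train_meta={"window": window, "epochs": epochs, "seed": seed,
                    "negatives": negatives, "min_count": min_count})


def lookup(table: EmbeddingTable, tokens: TokenSequence) -> np.ndarray:
    """Stack per-token vectors into a (len(tokens), d) matrix (UNK fallback)."""
    if not tokens.tokens:
        return np.zeros((0, table.dimension))
    return np.stack([table.get(t) for t in tokens.tokens])
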