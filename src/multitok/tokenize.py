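"""Multiple alternative tokenizations of SMILES and protein sequences.

A molecule or protein has no single natural segmentation, and different
segmentations carry different semantics: byte-pair encoding (BPE) finds
high-frequency substrings of the text, circular-fingerprint (ECFP) tokens
describe each heavy atom's bonded neighborhood out to a radius, and k-mers
are the standard windows over amino-acid sequences.  Each tokenizer here
turns one input sequence into one :class:`TokenSequence`; downstream, one
transformer encoder per tokenization consumes these streams in parallel.

SMILES are canonicalized (RDKit) before any tokenization so that equivalent
input strings produce identical token streams.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: Hard cap on token-stream length; longer streams are truncated (and logged).
DEFAULT_MAX_TOKENS = 512

#: Two-character organic-subset halogens kept atomic during BPE base splitting.
_TWO_CHAR_ATOMS = ("Cl", "Br")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class TokenSequence:
    """Ordered token stream produced by one tokenizer from one sequence."""

    tokens: tuple[str, ...]
    tokenizer_id: str
    source_length: int

    def __post_init__(self):
        if self.source_length < 0:
            raise ValueError("source_length must be non-negative")

    def __len__(self) -> int:
        return len(self.tokens)

    def joined(self, sep: str = "|") -> str:
        """Render the stream with tokens separated by ``sep`` (display form)."""
        return sep.join(self.tokens)


@dataclass
class BpeVocabulary:
    """Learned BPE merge list plus the token set it induces."""

    merges: list[tuple[str, str]]
    token_set: set[str]
    corpus_tag: str = ""

    def save(self, path: str) -> None:
        """Write merges as ordered two-column plain text."""
        with open(path, "w") as fh:
            fh.write(f"# bpe merges\t{self.corpus_tag}\n")
            for a, b in self.merges:
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def load(cls, path: str) -> "BpeVocabulary":
        merges: list[tuple[str, str]] = []
        tag = ""
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    parts = line.split("\t")
                    tag = parts[1] if len(parts) > 1 else ""
                    continue
                if not line:
                    continue
                a, b = line.split("\t")
                merges.append((a, b))
        token_set = {a + b for a, b in merges}
        token_set.update(s for pair in merges for s in pair)
        return cls(merges=merges, token_set=token_set, corpus_tag=tag)


@dataclass
class TokenizerSpec:
    """Declarative description of one tokenizer.

    ``kind`` is one of ``bpe``, ``ecfp``, ``kmer``.  ``radius`` applies to
    ecfp (1 or 2 in practice), ``k`` to kmer, and ``vocabulary`` to bpe.
    """

    kind: str
    radius: int = 1
    k: int = 3
    vocabulary: BpeVocabulary | None = None
    max_tokens: int = DEFAULT_MAX_TOKENS
    name: str | None = field(default=None)

    def __post_init__(self):
        if self.kind not in ("bpe", "ecfp", "kmer"):
            raise ValueError(f"unknown tokenizer kind {self.kind!r}")
        if self.kind == "ecfp" and self.radius < 0:
            raise ValueError("ecfp radius must be non-negative")
        if self.kind == "kmer" and self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def tokenizer_id(self) -> str:
        if self.name:
            return self.name
        if self.kind == "ecfp":
            return f"ecfp{self.radius}"
        if self.kind == "kmer":
            return f"kmer{self.k}"
        return "bpe"


# ---------------------------------------------------------------------------
# SMILES handling
# ---------------------------------------------------------------------------

def canonical_smiles(smiles: str) -> str:
    """Return the RDKit canonical SMILES, raising on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def split_base_symbols(sequence: str) -> list[str]:
    """Split text into BPE base symbols.

    Single characters, except that the two-character halogens Cl/Br and
    bracketed atom expressions ``[...]`` are kept atomic — splitting inside
    them would produce chemically meaningless units.
    """
    symbols: list[str] = []
    i = 0
    n = len(sequence)
    while i < n:
        ch = sequence[i]
        if ch == "[":
            j = sequence.find("]", i)
            if j == -1:  # unbalanced bracket: fall back to char-level
                symbols.append(ch)
                i += 1
                continue
            symbols.append(sequence[i:j + 1])
            i = j + 1
        elif sequence[i:i + 2] in _TWO_CHAR_ATOMS:
            symbols.append(sequence[i:i + 2])
            i += 2
        else:
            symbols.append(ch)
            i += 1
    return symbols


# ---------------------------------------------------------------------------
# BPE
# ---------------------------------------------------------------------------

def learn_bpe_vocabulary(corpus: list[str], num_merges: int,
                         corpus_tag: str = "") -> BpeVocabulary:
    """Learn a BPE merge list from a sequence corpus.

    Iteratively merges the most frequent adjacent symbol pair; ties are
    broken by the lexicographically smallest pair so the result is a pure
    function of the corpus.  Stops early when no pair occurs at least twice.
    """
    if not corpus:
        raise ValueError("BPE corpus must be non-empty")
    if num_merges < 0:
        raise ValueError("num_merges must be >= 0")

    sequences = [split_base_symbols(s) for s in corpus]
    token_set: set[str] = {sym for seq in sequences for sym in seq}
    merges: list[tuple[str, str]] = []

    for _ in range(num_merges):
        counts: Counter[tuple[str, str]] = Counter()
        for seq in sequences:
            for a, b in zip(seq, seq[1:]):
                counts[(a, b)] += 1
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break
        pair = min(p for p, c in counts.items() if c == best_count)
        merges.append(pair)
        token_set.add(pair[0] + pair[1])
        sequences = [_merge_pair(seq, pair) for seq in sequences]

    return BpeVocabulary(merges=merges, token_set=token_set, corpus_tag=corpus_tag)


def _merge_pair(symbols: list[str], pair: tuple[str, str]) -> list[str]:
    """Merge every non-overlapping occurrence of ``pair``, left to right."""
    a, b = pair
    out: list[str] = []
    i = 0
    while i < len(symbols):
        if i + 1 < len(symbols) and symbols[i] == a and symbols[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(symbols[i])
            i += 1
    return out


def apply_bpe(sequence: str, vocab: BpeVocabulary,
              tokenizer_id: str = "bpe",
              max_tokens: int = DEFAULT_MAX_TOKENS) -> TokenSequence:
    """Tokenize ``sequence`` by replaying the learned merges in order.

    The concatenation of the returned tokens always reproduces the input
    exactly.  Symbols never seen during learning stay as singleton tokens.
    """
    if not sequence:
        raise ValueError("cannot tokenize an empty sequence")
    symbols = split_base_symbols(sequence)
    unseen = {s for s in symbols if s not in vocab.token_set and vocab.token_set}
    if unseen:
        logger.warning("symbols outside the BPE base alphabet kept as "
                       "singletons: %s", sorted(unseen))
    for pair in vocab.merges:
        symbols = _merge_pair(symbols, pair)
    symbols = _truncate(symbols, max_tokens, tokenizer_id)
    return TokenSequence(tokens=tuple(symbols), tokenizer_id=tokenizer_id,
                         source_length=len(sequence))


# ---------------------------------------------------------------------------
# ECFP atom-environment tokens
# ---------------------------------------------------------------------------

def tokenize_ecfp(smiles: str, radius: int,
                  max_tokens: int = DEFAULT_MAX_TOKENS) -> TokenSequence:
    """One token per heavy atom: the circular-environment identifier.

    Each heavy atom gets the 32-bit Morgan identifier of its bonded
    neighborhood at the requested radius (the identifier of the largest
    available radius if the atom's environment stops growing earlier, e.g.
    in small fragments), rendered as a decimal string.  Tokens are ordered
    by the canonical atom ranking of the parsed molecule so the stream is
    independent of the input SMILES writing.  Duplicate identifiers are
    retained — the stream has exactly one token per heavy atom.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")

    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, includeRedundantEnvironments=True)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    bit_info = ao.GetBitInfoMap()

    # invert: atom index -> identifier at the largest radius <= requested
    best: dict[int, tuple[int, int]] = {}  # atom -> (radius, identifier)
    for identifier, occurrences in bit_info.items():
        for atom_idx, r in occurrences:
            if atom_idx not in best or r > best[atom_idx][0]:
                best[atom_idx] = (r, identifier)

    ranks = list(Chem.CanonicalRankAtoms(mol))
    order = sorted(range(mol.GetNumAtoms()), key=lambda i: (ranks[i], i))
    tokens = [str(best[i][1]) for i in order]
    tokens = _truncate(tokens, max_tokens, f"ecfp{radius}")
    return TokenSequence(tokens=tuple(tokens), tokenizer_id=f"ecfp{radius}",
                         source_length=mol.GetNumAtoms())


# ---------------------------------------------------------------------------
# k-mers
# ---------------------------------------------------------------------------

def tokenize_kmer(sequence: str, k: int,
                  max_tokens: int = DEFAULT_MAX_TOKENS) -> TokenSequence:
    """Overlapping windows of length ``k`` at stride 1.

    Sequences shorter than ``k`` yield the whole sequence as a single token,
    so the token count is ``max(len - k + 1, 1)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not sequence:
        raise ValueError("cannot tokenize an empty sequence")
    if len(sequence) < k:
        tokens = [sequence]
    else:
        tokens = [sequence[i:i + k] for i in range(len(sequence) - k + 1)]
    tokens = _truncate(tokens, max_tokens, f"kmer{k}")
    return TokenSequence(tokens=tuple(tokens), tokenizer_id=f"kmer{k}",
                         source_length=len(sequence))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def tokenize_one(sequence: str, spec: TokenizerSpec) -> TokenSequence:
    """Apply a single tokenizer spec to one sequence."""
    try:
        if spec.kind == "bpe":
            if spec.vocabulary is None:
                raise ValueError("bpe spec requires a learned vocabulary")
            return apply_bpe(sequence, spec.vocabulary,
                             tokenizer_id=spec.tokenizer_id,
                             max_tokens=spec.max_tokens)
        if spec.kind == "ecfp":
            return tokenize_ecfp(sequence, spec.radius, max_tokens=spec.max_tokens)
        return tokenize_kmer(sequence, spec.k, max_tokens=spec.max_tokens)
    except Exception as exc:
        exc.args = (f"[{spec.tokenizer_id}] {exc.args[0] if exc.args else exc}",)
        raise


def tokenize_all(sequence: str, specs: list[TokenizerSpec]) -> list[TokenSequence]:
    """Produce the multi-view input: one TokenSequence per spec, in order."""
    if not specs:
        raise ValueError("at least one TokenizerSpec is required")
    return [tokenize_one(sequence, spec) for spec in specs]


def _truncate(tokens: list[str], max_tokens: int, tokenizer_id: str) -> list[str]:
    if len(tokens) > max_tokens:
        logger.warning("[%s] truncating token stream from %d to %d tokens",
                       tokenizer_id, len(tokens), max_tokens)
        return tokens[:max_tokens]
    return tokens
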