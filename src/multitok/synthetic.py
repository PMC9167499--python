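"""Synthetic corpora and labeled datasets with a plantable signal.

Generates valid SMILES by joining fragments from a curated pool (ring
systems, chains, functional groups — including flavonoid- and
terpenoid-like scaffolds so the corpus loosely resembles a natural-product
collection), random protein sequences over the 20-letter alphabet, and
labeled activity / compound–protein pair datasets in which the positive
class is tied to the presence of a planted substructure (and, for pairs, a
planted protein motif).  Everything is deterministic under its seed.

Label model: with signal strength s and noise rate eta, a compound carrying
the signal fragment is labeled 1 with probability s, one without it with
probability 1 - s; each label is then flipped independently with
probability eta.  Defaults (s = 1, eta = 0) give labels fully determined by
structure — the regime used for signal-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .curate import ActivityRecord, PairRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Appendable SMILES pieces: any prefix-concatenation of these parses for
#: the vast majority of draws; invalid assemblies are rejected and redrawn.
DEFAULT_FRAGMENT_POOL = (
    "C", "CC", "CCC", "CCO", "CCN", "CO", "CN",
    "C(C)C", "CC(C)C", "C(=O)O", "C(=O)N", "C(=O)C",
    "c1ccccc1", "c1ccc(O)cc1", "c1ccncc1", "c1ccc(OC)cc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOC1",
    # fused polycyclics echoing flavonoid / terpenoid chemotypes
    "c1ccc2ccccc2c1", "C1CCC2CCCCC2C1", "c1ccc2occc2c1",
    "C1CC2CCC1C2",
)

#: Default planted bioactivity substructure (furan ring), absent from the
#: base pool so the signal is carried only where it is planted.
DEFAULT_SIGNAL_FRAGMENT = "c1ccoc1"
DEFAULT_PROTEIN_MOTIF = "HKDES"


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for a labeled synthetic dataset."""

    n_compounds: int = 400
    n_proteins: int = 50
    signal_fragment: str = DEFAULT_SIGNAL_FRAGMENT
    protein_motif: str = DEFAULT_PROTEIN_MOTIF
    signal_strength: float = 1.0
    label_noise: float = 0.0
    seed: int = 0
    fragment_pool: tuple[str, ...] = DEFAULT_FRAGMENT_POOL
    protein_length_range: tuple[int, int] = (100, 300)

    def __post_init__(self):
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        if Chem.MolFromSmiles(self.signal_fragment) is None:
            raise ValueError(f"signal fragment does not parse: "
                             f"{self.signal_fragment!r}")


def _assemble(rng: np.random.Generator, pool: tuple[str, ...],
              insert: str | None, exclude_query=None,
              max_attempts: int = 200) -> str:
    """Join 2–5 random fragments into one valid canonical SMILES."""
    for _ in range(max_attempts):
        n_frag = int(rng.integers(2, 6))
        parts = [pool[int(i)] for i in rng.integers(0, len(pool), n_frag)]
        if insert is not None:
            parts.insert(int(rng.integers(0, len(parts) + 1)), insert)
        mol = Chem.MolFromSmiles("".join(parts))
        if mol is None:
            continue
        if exclude_query is not None and mol.HasSubstructMatch(exclude_query):
            continue
        return Chem.MolToSmiles(mol)
    raise RuntimeError("fragment pool failed to assemble a valid molecule")


def generate_smiles(n: int, seed: int = 0,
                    fragment_pool: tuple[str, ...] = DEFAULT_FRAGMENT_POOL,
                    ) -> list[str]:
    """``n`` valid canonical SMILES assembled from the fragment pool."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [_assemble(rng, fragment_pool, None) for _ in range(n)]


def generate_proteins(n: int, length_range: tuple[int, int] = (100, 300),
                      seed: int = 0, motif: str | None = None,
                      motif_rate: float = 0.0) -> list[str]:
    """Random amino-acid sequences; a motif may be planted at ``motif_rate``."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[int(i)]
                      for i in rng.integers(0, len(AMINO_ACIDS), length))
        if motif and rng.random() < motif_rate:
            pos = int(rng.integers(0, max(1, length - len(motif))))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        out.append(seq)
    return out


def _label(rng: np.random.Generator, has_signal: bool, strength: float,
           noise: float) -> int:
    p1 = strength if has_signal else 1.0 - strength
    label = int(rng.random() < p1)
    if rng.random() < noise:
        label = 1 - label
    return label


def generate_activity_dataset(spec: SyntheticSpec) -> list[ActivityRecord]:
    """Labeled activity records with a planted structure–activity signal.

    Half the compounds carry the signal fragment; labels follow the
    strength/noise model in the module docstring.
    """
    rng = np.random.default_rng(spec.seed)
    query = Chem.MolFromSmiles(spec.signal_fragment)
    records = []
    for i in range(spec.n_compounds):
        has_signal = i % 2 == 0
        smi = _assemble(rng, spec.fragment_pool,
                        spec.signal_fragment if has_signal else None,
                        exclude_query=None if has_signal else query)
        label = _label(rng, has_signal, spec.signal_strength, spec.label_noise)
        records.append(ActivityRecord(compound_id=f"SYN{i:05d}", smiles=smi,
                                      label=label))
    return records


def generate_pair_dataset(spec: SyntheticSpec,
                          target_ratio: float | None = None,
                          n_pairs: int | None = None,
                          ) -> tuple[list[PairRecord], float]:
    """Labeled compound–protein pairs with a planted compatibility rule.

    The ideal label is 1 iff the compound carries the signal fragment AND
    the protein carries the planted motif; strength/noise perturb it as for
    activities.  With ``target_ratio`` set (positives per negative), pairs
    are sampled from the compatible / incompatible strata to hit that class
    balance.  Returns the records and the realized positive:negative ratio.
    """
    rng = np.random.default_rng(spec.seed + 1)
    query = Chem.MolFromSmiles(spec.signal_fragment)

    n_sig = spec.n_compounds // 2
    compounds = []
    for i in range(spec.n_compounds):
        has_signal = i < n_sig
        smi = _assemble(rng, spec.fragment_pool,
                        spec.signal_fragment if has_signal else None,
                        exclude_query=None if has_signal else query)
        compounds.append((f"SYN{i:05d}", smi, has_signal))

    prot_seed = spec.seed + 2
    proteins = generate_proteins(spec.n_proteins, spec.protein_length_range,
                                 seed=prot_seed, motif=None)
    n_motif = spec.n_proteins // 2
    with_motif = []
    for j, seq in enumerate(proteins):
        has_motif = j < n_motif
        if has_motif:
            pos = int(rng.integers(0, max(1, len(seq) - len(spec.protein_motif))))
            seq = (seq[:pos] + spec.protein_motif
                   + seq[pos + len(spec.protein_motif):])
        with_motif.append((f"PROT{j:04d}", seq, has_motif))

    n_pairs = n_pairs or 4 * spec.n_compounds
    compatible = [(c, p) for c in compounds if c[2] for p in with_motif if p[2]]
    incompatible = [(c, p) for c in compounds for p in with_motif
                    if not (c[2] and p[2])]
    if target_ratio is None:
        everything = compatible + incompatible
        chosen = [everything[int(i)]
                  for i in rng.choice(len(everything), size=min(n_pairs,
                                                                len(everything)),
                                      replace=False)]
    else:
        n_pos = int(round(n_pairs * target_ratio / (1.0 + target_ratio)))
        n_neg = n_pairs - n_pos
        chosen = ([compatible[int(i)]
                   for i in rng.choice(len(compatible),
                                       size=min(n_pos, len(compatible)),
                                       replace=False)]
                  + [incompatible[int(i)]
                     for i in rng.choice(len(incompatible),
                                         size=min(n_neg, len(incompatible)),
                                         replace=False)])

    records = []
    for (cid, smi, csig), (pid, seq, pmot) in chosen:
        label = _label(rng, csig and pmot, spec.signal_strength,
                       spec.label_noise)
        records.append(PairRecord(compound_id=cid, protein_id=pid,
                                  protein_sequence=seq, label=label,
                                  smiles=smi))
    n_pos_real = sum(r.label for r in records)
    n_neg_real = len(records) - n_pos_real
    ratio = n_pos_real / max(n_neg_real, 1)
    return records, float(ratio)


def shuffle_labels(records: list, seed: int = 0) -> list:
    """Permutation-null control: same records, labels randomly permuted."""
    rng = np.random.default_rng(seed)
    labels = np.array([r.label for r in records])
    perm = rng.permutation(len(labels))
    out = []
    for r, lab in zip(records, labels[perm]):
        kwargs = {f: getattr(r, f) for f in r.__dataclass_fields__}
        kwargs["label"] = int(lab)
        out.append(type(r)(**kwargs))
    return out
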