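"""Dataset construction and chemical-space characterization.

Implements the labeling and filtering rules used to build the training
sets — a compound (or compound–protein pair) is ACTIVE when its IC50/EC50
is strictly below 50 µM and INACTIVE strictly above (the boundary value is
dropped) — together with the descriptor pipeline: six physicochemical
descriptors (MW, LogP, TPSA, #HBD, #HBA, #RotB), Lipinski-style
drug-likeness and TPSA-based blood–brain-barrier flags, Bemis–Murcko
scaffolds, and a standardized-descriptor PCA of the chemical space against
a packaged reference set of approved drugs.

Activity data are restricted to inhibition of NO production measured in
macrophage cell models (RAW264.7, J774A.1 and the CNS-resident BV-2 by
default); when one compound has several qualifying assay values the most
potent (minimum) is used, and the conflict is flagged.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .tokenize import SmilesParseError, canonical_smiles

logger = logging.getLogger(__name__)

ACTIVITY_THRESHOLD_UM = 50.0
DEFAULT_MACROPHAGE_CELLS = frozenset({"RAW264.7", "J774A.1", "BV-2"})
DESCRIPTOR_COLUMNS = ["MW", "LogP", "TPSA", "HBD", "HBA", "RotB"]
READOUTS = frozenset({"NO", "PGE2", "IL-1b", "IL-6", "IL-12", "TNFa",
                      "cytotoxicity"})
VALUE_TYPES = frozenset({"IC50", "EC50"})


class CurationError(ValueError):
    """Raised on referential-integrity or data-validity failures."""


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    name: str = ""
    inchikey: str = ""
    structure_class: str = ""
    origin: str = "WD"


@dataclass(frozen=True)
class ActivityMeasurement:
    compound_id: str
    readout: str
    cell_type: str
    value_type: str
    value_um: float

    def __post_init__(self):
        if self.value_um <= 0:
            raise CurationError(
                f"non-positive assay value for {self.compound_id}: {self.value_um}")


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    smiles: str
    label: int


@dataclass(frozen=True)
class PairRecord:
    compound_id: str
    protein_id: str
    protein_sequence: str
    label: int
    smiles: str = ""


@dataclass(frozen=True)
class DescriptorSet:
    mw: float
    logp: float
    tpsa: float
    hbd: int
    hba: int
    rotb: int


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label_activity(value_um: float, value_type: str = "IC50",
                   threshold: float = ACTIVITY_THRESHOLD_UM) -> int | None:
    """Strict-threshold binary label: <50 µM -> 1, >50 µM -> 0, =50 -> None.

    The boundary is undefined by the strict inequalities on both sides, so
    a record sitting exactly on it is dropped (None) with a warning.
    """
    if value_um <= 0:
        raise CurationError(f"assay value must be positive, got {value_um}")
    if value_type not in VALUE_TYPES:
        raise CurationError(f"unknown value type {value_type!r}")
    if value_um < threshold:
        return 1
    if value_um > threshold:
        return 0
    logger.warning("value exactly at %g µM: record dropped", threshold)
    return None


def assemble_activity_dataset(
        compounds: list[CompoundRecord],
        measurements: list[ActivityMeasurement],
        cell_filter: frozenset[str] | set[str] = DEFAULT_MACROPHAGE_CELLS,
        readout_filter: frozenset[str] | set[str] = frozenset({"NO"}),
) -> list[ActivityRecord]:
    """Build the labeled activity set from compound and measurement tables.

    Keeps IC50/EC50 measurements of the requested readouts in the requested
    cell types, resolves multiple values per compound to the minimum (most
    potent, flagged), applies the strict 50 µM rule, and returns one record
    per compound.
    """
    by_id = {c.compound_id: c for c in compounds}
    dangling = sorted({m.compound_id for m in measurements
                       if m.compound_id not in by_id})
    if dangling:
        raise CurationError(f"measurements reference unknown compounds: {dangling}")

    best: dict[str, float] = {}
    for m in measurements:
        if m.readout not in readout_filter or m.cell_type not in cell_filter:
            continue
        if m.value_type not in VALUE_TYPES:
            continue
        prev = best.get(m.compound_id)
        if prev is not None:
            logger.info("multiple qualifying assays for %s; keeping minimum",
                        m.compound_id)
        best[m.compound_id] = m.value_um if prev is None else min(prev, m.value_um)

    records = []
    for cid in sorted(best):
        label = label_activity(best[cid])
        if label is None:
            continue
        records.append(ActivityRecord(compound_id=cid,
                                      smiles=by_id[cid].smiles, label=label))
    return records


def assemble_pair_dataset(compounds: list[CompoundRecord],
                          target_table: pd.DataFrame) -> list[PairRecord]:
    """Build deduplicated labeled compound–protein pairs.

    ``target_table`` columns: compound_id, protein_id, protein_sequence,
    value_um (IC50/EC50 in µM) or label.  Labels follow the same strict
    50 µM rule; duplicate (compound, protein) rows with a consistent label
    collapse to one record, inconsistent ones raise.
    """
    by_id = {c.compound_id: c for c in compounds}
    missing_seq = sorted(set(
        target_table.loc[target_table["protein_sequence"].fillna("") == "",
                         "protein_id"].tolist()))
    if missing_seq:
        raise CurationError(f"targets without sequences: {missing_seq}")
    dangling = sorted(set(target_table["compound_id"]) - set(by_id))
    if dangling:
        raise CurationError(f"pairs reference unknown compounds: {dangling}")

    pairs: dict[tuple[str, str], PairRecord] = {}
    for row in target_table.itertuples(index=False):
        if hasattr(row, "label") and not pd.isna(getattr(row, "label", np.nan)):
            label = int(row.label)
        else:
            label = label_activity(float(row.value_um))
            if label is None:
                continue
        key = (row.compound_id, row.protein_id)
        rec = PairRecord(compound_id=row.compound_id, protein_id=row.protein_id,
                         protein_sequence=row.protein_sequence, label=label,
                         smiles=by_id[row.compound_id].smiles)
        if key in pairs and pairs[key].label != label:
            raise CurationError(f"conflicting labels for pair {key}")
        pairs[key] = rec
    return [pairs[k] for k in sorted(pairs)]


# ---------------------------------------------------------------------------
# descriptors & drug-likeness
# ---------------------------------------------------------------------------

def compute_descriptors(smiles: str) -> DescriptorSet:
    """The six physicochemical descriptors (RDKit standard definitions)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotb=Lipinski.NumRotatableBonds(mol),
    )


def druglikeness_flags(d: DescriptorSet) -> dict[str, bool]:
    """Strict-inequality drug-likeness and BBB-permeability heuristics.

    ``lipinski_like``: MW < 500, LogP < 5, #HBD < 5, #HBA < 10, #RotB < 10.
    ``bbb_tpsa``: TPSA < 60 Å².
    """
    return {
        "lipinski_like": (d.mw < 500 and d.logp < 5 and d.hbd < 5
                          and d.hba < 10 and d.rotb < 10),
        "bbb_tpsa": d.tpsa < 60,
    }


def descriptor_table(smiles_list: list[str]) -> pd.DataFrame:
    """DataFrame of the six descriptors, one row per molecule."""
    rows = []
    for smi in smiles_list:
        d = compute_descriptors(smi)
        rows.append({"smiles": smi, "MW": d.mw, "LogP": d.logp, "TPSA": d.tpsa,
                     "HBD": d.hbd, "HBA": d.hba, "RotB": d.rotb})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scaffolds
# ---------------------------------------------------------------------------

def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko framework (rings + linkers, side chains removed).

    Acyclic molecules give an empty scaffold; if the framework is
    disconnected the fragment with the most heavy atoms is kept.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    smi = Chem.MolToSmiles(scaffold)
    if not smi:
        return ""
    if "." in smi:
        parts = smi.split(".")
        sizes = [Chem.MolFromSmiles(p).GetNumAtoms() for p in parts]
        smi = canonical_smiles(parts[int(np.argmax(sizes))])
    return smi


# ---------------------------------------------------------------------------
# chemical-space PCA
# ---------------------------------------------------------------------------

def load_reference_descriptors() -> pd.DataFrame:
    """Descriptor table of the packaged approved-drug reference set.

    Structures are shipped as SMILES and descriptors are computed at call
    time; this small set stands in for a large approved-drug collection
    when sketching where a compound library sits in chemical space.
    """
    path = importlib.resources.files("multitok.data") / "reference_drugs.csv"
    ref = pd.read_csv(path)
    return descriptor_table(ref["smiles"].tolist()).assign(name=ref["name"].values)


def chemspace_pca(descriptors: pd.DataFrame,
                  reference: pd.DataFrame | None = None,
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """2-D PCA of standardized descriptors, optionally pooled with a reference.

    Returns (coordinates, explained_variance_ratio).  Coordinates carry a
    ``source`` column ('query' / 'reference').  Constant descriptor columns
    are dropped with a warning before standardization.
    """
    frames = [descriptors.assign(source="query")]
    if reference is not None:
        frames.append(reference.assign(source="reference"))
    combined = pd.concat(frames, ignore_index=True)
    if len(combined) < 3:
        raise ValueError("PCA needs at least 3 rows")

    cols = [c for c in DESCRIPTOR_COLUMNS]
    keep = []
    for c in cols:
        if combined[c].nunique() <= 1:
            logger.warning("constant descriptor column %r dropped from PCA", c)
        else:
            keep.append(c)
    X = StandardScaler().fit_transform(combined[keep].to_numpy(dtype=float))
    pca = PCA(n_components=2, random_state=0)
    coords = pca.fit_transform(X)
    out = pd.DataFrame({"PC1": coords[:, 0], "PC2": coords[:, 1],
                        "source": combined["source"]})
    return out, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_compounds(path: str, colmap: dict[str, str] | None = None,
                   canonicalize: bool = True) -> list[CompoundRecord]:
    """Read a compound CSV; ``colmap`` maps record fields to CSV headers."""
    colmap = colmap or {}
    df = pd.read_csv(path)
    get = lambda field, default="": colmap.get(field, field)
    records = []
    for row in df.to_dict("records"):
        smi = str(row[get("smiles")])
        records.append(CompoundRecord(
            compound_id=str(row[get("compound_id")]),
            smiles=canonical_smiles(smi) if canonicalize else smi,
            name=str(row.get(get("name"), "")),
            inchikey=str(row.get(get("inchikey"), "")),
            structure_class=str(row.get(get("structure_class"), "")),
            origin=str(row.get(get("origin"), "WD"))))
    return records


def read_measurements(path: str,
                      colmap: dict[str, str] | None = None
                      ) -> list[ActivityMeasurement]:
    colmap = colmap or {}
    df = pd.read_csv(path)
    get = lambda field: colmap.get(field, field)
    return [ActivityMeasurement(
        compound_id=str(row[get("compound_id")]),
        readout=str(row[get("readout")]),
        cell_type=str(row[get("cell_type")]),
        value_type=str(row[get("value_type")]),
        value_um=float(row[get("value_um")]))
        for row in df.to_dict("records")]
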