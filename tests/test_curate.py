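"""Curation tests: strict 50 µM labeling, assay filtering, descriptors,
scaffolds, drug-likeness flags and chemical-space PCA."""

import numpy as np
import pandas as pd
import pytest

from multitok import curate
from multitok.curate import (ActivityMeasurement, CompoundRecord,
                             CurationError, DescriptorSet,
                             assemble_activity_dataset, assemble_pair_dataset,
                             chemspace_pca, compute_descriptors,
                             descriptor_table, druglikeness_flags,
                             label_activity, load_reference_descriptors,
                             murcko_scaffold)


class TestLabeling:
    @pytest.mark.parametrize("value,expected", [
        (10.0, 1), (49.999, 1), (100.0, 0), (50.001, 0),
    ])
    def test_strict_threshold(self, value, expected):
        assert label_activity(value) == expected

    def test_boundary_dropped(self):
        assert label_activity(50.0) is None

    def test_nonpositive_rejected(self):
        with pytest.raises(CurationError):
            label_activity(0.0)
        with pytest.raises(CurationError):
            label_activity(-3.0)

    def test_unknown_value_type_rejected(self):
        with pytest.raises(CurationError):
            label_activity(10.0, value_type="Ki")


@pytest.fixture()
def compounds():
    return [CompoundRecord("C1", "CCO"), CompoundRecord("C2", "c1ccccc1"),
            CompoundRecord("C3", "CCN"), CompoundRecord("C4", "CCCO")]


class TestAssembleActivity:
    def test_filters_and_labels(self, compounds):
        meas = [
            ActivityMeasurement("C1", "NO", "RAW264.7", "IC50", 12.0),
            ActivityMeasurement("C2", "IL-6", "RAW264.7", "IC50", 5.0),
            ActivityMeasurement("C3", "NO", "HeLa", "IC50", 5.0),
            ActivityMeasurement("C4", "NO", "J774A.1", "EC50", 80.0),
        ]
        records = assemble_activity_dataset(compounds, meas)
        by_id = {r.compound_id: r for r in records}
        assert by_id["C1"].label == 1          # NO + macrophage + <50
        assert "C2" not in by_id               # wrong readout
        assert "C3" not in by_id               # non-macrophage cell line
        assert by_id["C4"].label == 0          # >50 µM

    def test_conflicting_values_take_minimum(self, compounds):
        meas = [ActivityMeasurement("C1", "NO", "RAW264.7", "IC50", 80.0),
                ActivityMeasurement("C1", "NO", "BV-2", "IC50", 8.0)]
        records = assemble_activity_dataset(compounds, meas)
        assert records[0].label == 1  # min(80, 8) = 8 < 50

    def test_boundary_measurement_dropped(self, compounds):
        meas = [ActivityMeasurement("C1", "NO", "RAW264.7", "IC50", 50.0)]
        assert assemble_activity_dataset(compounds, meas) == []

    def test_dangling_compound_listed(self, compounds):
        meas = [ActivityMeasurement("ZZ", "NO", "RAW264.7", "IC50", 1.0)]
        with pytest.raises(CurationError, match="ZZ"):
            assemble_activity_dataset(compounds, meas)

    def test_rerun_identical(self, compounds):
        meas = [ActivityMeasurement("C1", "NO", "RAW264.7", "IC50", 12.0)]
        assert assemble_activity_dataset(compounds, meas) == \
            assemble_activity_dataset(compounds, meas)


class TestAssemblePairs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["compound_id", "protein_id",
                                           "protein_sequence", "value_um"])

    def test_threshold_labels(self, compounds):
        table = self._table([("C1", "P1", "MKVLW", 8.0),
                             ("C2", "P1", "MKVLW", 80.0)])
        pairs = assemble_pair_dataset(compounds, table)
        labels = {(p.compound_id, p.protein_id): p.label for p in pairs}
        assert labels == {("C1", "P1"): 1, ("C2", "P1"): 0}
        assert all(p.smiles for p in pairs)

    def test_duplicates_collapse(self, compounds):
        table = self._table([("C1", "P1", "MKVLW", 8.0),
                             ("C1", "P1", "MKVLW", 12.0)])
        assert len(assemble_pair_dataset(compounds, table)) == 1

    def test_conflicting_duplicates_raise(self, compounds):
        table = self._table([("C1", "P1", "MKVLW", 8.0),
                             ("C1", "P1", "MKVLW", 80.0)])
        with pytest.raises(CurationError, match="conflicting"):
            assemble_pair_dataset(compounds, table)

    def test_missing_sequence_listed(self, compounds):
        table = self._table([("C1", "P9", "", 8.0)])
        with pytest.raises(CurationError, match="P9"):
            assemble_pair_dataset(compounds, table)


class TestDescriptors:
    def test_ethanol_hand_counts(self):
        d = compute_descriptors("CCO")
        assert d.hbd == 1       # one OH
        assert d.hba == 1       # one O
        assert d.rotb == 0      # C-O of a terminal hydroxyl is not rotatable
        assert d.mw == pytest.approx(2 * 12.011 + 6 * 1.008 + 15.999, abs=0.01)

    def test_benzene_no_polar_atoms(self):
        d = compute_descriptors("c1ccccc1")
        assert d.hbd == 0 and d.hba == 0
        assert d.tpsa == pytest.approx(0.0)

    def test_parse_error(self):
        with pytest.raises(Exception, match="unparseable"):
            compute_descriptors("][")


class TestDruglikeness:
    @pytest.mark.parametrize("desc,lip,bbb", [
        ((400, 3.0, 70, 2, 5, 4), True, False),
        ((600, 3.0, 50, 2, 5, 4), False, True),
        ((500, 3.0, 50, 2, 5, 4), False, True),   # MW boundary: strict <
        ((499.9, 4.9, 59.9, 4, 9, 9), True, True),
    ])
    def test_flags(self, desc, lip, bbb):
        d = DescriptorSet(mw=desc[0], logp=desc[1], tpsa=desc[2],
                          hbd=desc[3], hba=desc[4], rotb=desc[5])
        flags = druglikeness_flags(d)
        assert flags["lipinski_like"] is lip
        assert flags["bbb_tpsa"] is bbb


class TestScaffolds:
    def test_toluene_reduces_to_benzene(self):
        assert murcko_scaffold("Cc1ccccc1") == "c1ccccc1"

    def test_acyclic_gives_empty(self):
        assert murcko_scaffold("CCO") == ""

    def test_biphenyl_linker_retained(self):
        scaffold = murcko_scaffold("c1ccc(-c2ccccc2)cc1")
        assert scaffold == murcko_scaffold(scaffold)
        from rdkit import Chem
        assert Chem.MolFromSmiles(scaffold).GetNumAtoms() == 12

    def test_idempotence(self, smiles_corpus):
        for smi in smiles_corpus[:25]:
            s = murcko_scaffold(smi)
            if s:
                assert murcko_scaffold(s) == s


class TestChemspacePca:
    def test_variance_ratios_contract(self, smiles_corpus):
        desc = descriptor_table(smiles_corpus[:30])
        coords, evr = chemspace_pca(desc[curate.DESCRIPTOR_COLUMNS])
        assert len(coords) == 30
        assert evr[0] >= evr[1] >= 0
        assert evr.sum() <= 1.0 + 1e-9

    def test_duplicate_rows_project_identically(self, smiles_corpus):
        desc = descriptor_table(smiles_corpus[:10])
        doubled = pd.concat([desc, desc], ignore_index=True)
        coords, _ = chemspace_pca(doubled[curate.DESCRIPTOR_COLUMNS])
        np.testing.assert_allclose(coords.iloc[:10][["PC1", "PC2"]].to_numpy(),
                                   coords.iloc[10:][["PC1", "PC2"]].to_numpy(),
                                   atol=1e-9)

    def test_collinear_data_first_component_total(self):
        t = np.arange(10, dtype=float)
        df = pd.DataFrame({"MW": 100 + 10 * t, "LogP": 1 + t, "TPSA": 20 + 5 * t,
                           "HBD": t, "HBA": 2 * t, "RotB": 3 * t})
        _, evr = chemspace_pca(df)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_dropped_with_warning(self, smiles_corpus, caplog):
        desc = descriptor_table(smiles_corpus[:10])
        desc["HBD"] = 1
        with caplog.at_level("WARNING"):
            chemspace_pca(desc[curate.DESCRIPTOR_COLUMNS])
        assert any("HBD" in r.message for r in caplog.records)

    def test_reference_set_loads_and_pools(self, smiles_corpus):
        ref = load_reference_descriptors()
        assert len(ref) >= 40
        desc = descriptor_table(smiles_corpus[:10])
        coords, _ = chemspace_pca(desc, ref)
        assert (coords["source"] == "reference").sum() == len(ref)
        assert (coords["source"] == "query").sum() == 10
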