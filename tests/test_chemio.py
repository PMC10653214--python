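import pytest
from rdkit import Chem

from pfasqsar.chemio import (
    ActivityLabel,
    TableSchema,
    filter_c3f6,
    filter_cf,
    parse_label,
    read_molecule_table,
    read_sdf,
    write_molecule_table,
    write_reject_log,
)
from pfasqsar.errors import SchemaError, ValidationError
from pfasqsar.synthetic_data import write_dataset

from conftest import make_record


def write_csv(path, rows, header="id,smiles,T1"):
    path.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
    return path


class TestReadMoleculeTable:
    def test_three_valid_rows(self, tmp_path):
        path = write_csv(tmp_path / "m.csv", ["a,CCO,active", "b,CCN,inactive", "c,CCC,"])
        result = read_molecule_table(path)
        assert len(result.records) == 3
        assert result.rejects == []
        assert result.records[0].labels["T1"] is ActivityLabel.ACTIVE
        assert result.records[1].labels["T1"] is ActivityLabel.INACTIVE
        assert result.records[2].labels["T1"] is ActivityLabel.UNLABELED

    def test_bad_smiles_rejected(self, tmp_path):
        path = write_csv(tmp_path / "m.csv", ["a,CCO,active", "b,not_a_molecule,active"])
        result = read_molecule_table(path)
        assert len(result.records) == 1
        assert len(result.rejects) == 1
        assert result.rejects[0].row == 2
        assert "SMILES" in result.rejects[0].reason

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_molecule_table(tmp_path / "absent.csv")

    def test_missing_mandatory_column(self, tmp_path):
        path = (tmp_path / "m.csv")
        path.write_text("id,T1\na,active\n", encoding="utf-8")
        with pytest.raises(SchemaError):
            read_molecule_table(path)

    def test_no_activity_column(self, tmp_path):
        path = (tmp_path / "m.csv")
        path.write_text("id,smiles\na,CCO\n", encoding="utf-8")
        with pytest.raises(SchemaError):
            read_molecule_table(path)

    def test_duplicate_id_names_offender(self, tmp_path):
        path = write_csv(tmp_path / "m.csv", ["dup,CCO,active", "dup,CCN,active"])
        with pytest.raises(ValidationError, match="dup"):
            read_molecule_table(path)

    def test_duplicate_smiles_reported_not_dropped(self, tmp_path):
        path = write_csv(tmp_path / "m.csv", ["a,CCO,active", "b,OCC,active"])
        result = read_molecule_table(path)
        assert len(result.records) == 2  # not auto-deduplicated
        assert result.duplicate_smiles == [("a", "b")]

    def test_smiles_canonicalized_on_ingest(self, tmp_path):
        path = write_csv(tmp_path / "m.csv", ["a,OCC,active"])
        result = read_molecule_table(path)
        assert result.records[0].smiles == Chem.MolToSmiles(Chem.MolFromSmiles("OCC"))

    def test_tsv_delimiter_inferred(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\tsmiles\tT1\na\tCCO\tactive\n", encoding="utf-8")
        assert len(read_molecule_table(path).records) == 1

    def test_custom_schema(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("key,struct,assay\na,CCO,1\n", encoding="utf-8")
        schema = TableSchema(id_col="key", smiles_col="struct", activity_cols={"T1": "assay"})
        result = read_molecule_table(path, schema=schema)
        assert result.records[0].labels["T1"] is ActivityLabel.ACTIVE

    def test_round_trip_with_synthetic_generator(self, tmp_path, small_dataset):
        paths = write_dataset(small_dataset, tmp_path)
        result = read_molecule_table(paths["molecules"])
        assert [r.id for r in result.records] == [r.id for r in small_dataset.records]
        assert [r.smiles for r in result.records] == [
            r.smiles for r in small_dataset.records
        ]
        assert [r.labels for r in result.records] == [
            r.labels for r in small_dataset.records
        ]

    def test_write_read_identity(self, tmp_path):
        from pfasqsar.chemio import canonical_smiles

        records = [
            make_record("a", canonical_smiles("CCO"), ActivityLabel.ACTIVE),
            make_record("b", canonical_smiles("c1ccccc1"), ActivityLabel.INACTIVE),
            make_record("c", canonical_smiles("CC(=O)OC")),
        ]
        path = write_molecule_table(records, tmp_path / "out.csv")
        back = read_molecule_table(path).records
        assert [(r.id, r.smiles, r.labels) for r in back] == [
            (r.id, r.smiles, r.labels) for r in records
        ]


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("active", ActivityLabel.ACTIVE),
        ("ACTIVE", ActivityLabel.ACTIVE),
        ("1", ActivityLabel.ACTIVE),
        ("true", ActivityLabel.ACTIVE),
        ("inactive", ActivityLabel.INACTIVE),
        ("0", ActivityLabel.INACTIVE),
        ("False", ActivityLabel.INACTIVE),
        ("", ActivityLabel.UNLABELED),
        ("na", ActivityLabel.UNLABELED),
        ("unlabeled", ActivityLabel.UNLABELED),
        (None, ActivityLabel.UNLABELED),
    ],
)
def test_parse_label(raw, expected):
    assert parse_label(raw) is expected


def test_parse_label_rejects_garbage():
    with pytest.raises(ValidationError):
        parse_label("maybe")


def test_reject_log_format(tmp_path):
    path = write_csv(tmp_path / "m.csv", ["a,xxx$$,active"])
    result = read_molecule_table(path)
    log = write_reject_log(result.rejects, tmp_path / "rejects.log")
    text = log.read_text(encoding="utf-8")
    assert "row 1" in text and "unparseable" in text


def test_sdf_round_trip(tmp_path):
    records = [make_record("s1", "CCO", ActivityLabel.ACTIVE), make_record("s2", "CCN")]
    sdf = tmp_path / "mols.sdf"
    writer = Chem.SDWriter(str(sdf))
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        mol.SetProp("_Name", rec.id)
        mol.SetProp("T1", rec.labels["T1"].value if rec.labels["T1"] is not ActivityLabel.UNLABELED else "")
        writer.write(mol)
    writer.close()
    result = read_sdf(sdf, activity_props=["T1"])
    assert [(r.id, r.smiles) for r in result.records] == [
        (r.id, r.smiles) for r in records
    ]
    assert result.records[0].labels["T1"] is ActivityLabel.ACTIVE


class TestFilters:
    def test_no_fluorine_excluded(self):
        assert filter_cf([make_record("a", "CCO")]) == []

    def test_cf3_on_carbon_kept(self):
        recs = [make_record("a", "FC(F)(F)c1ccccc1")]
        assert filter_cf(recs) == recs

    def test_aromatic_cf_counts(self):
        recs = [make_record("a", "Fc1ccccc1")]
        assert filter_cf(recs) == recs

    def test_cf_exact_count_on_synthetic(self, small_dataset):
        kept = filter_cf(small_dataset.records)
        assert len(kept) == int(small_dataset.truth["has_cf"].sum())

    def test_c3f6_perfluorobutanoic_acid_kept(self):
        recs = [make_record("a", "FC(F)(F)C(F)(F)C(F)(F)C(=O)O")]
        assert filter_c3f6(recs) == recs

    def test_c3f6_single_perfluorinated_carbon_excluded(self):
        assert filter_c3f6([make_record("a", "FC(F)(F)c1ccccc1")]) == []

    def test_c3f6_two_carbon_chain_excluded(self):
        assert filter_c3f6([make_record("a", "FC(F)(F)C(F)(F)F")]) == []

    def test_c3f6_exact_count_on_synthetic(self, small_dataset):
        kept = filter_c3f6(small_dataset.records)
        assert len(kept) == int(small_dataset.truth["has_c3f6"].sum())

    def test_c3f6_subset_of_cf(self, medium_dataset):
        cf_ids = {r.id for r in filter_cf(medium_dataset.records)}
        c3f6_ids = {r.id for r in filter_c3f6(medium_dataset.records)}
        assert c3f6_ids <= cf_ids

    def test_filters_idempotent(self, small_dataset):
        once_cf = filter_cf(small_dataset.records)
        assert filter_cf(once_cf) == once_cf
        once_c3 = filter_c3f6(small_dataset.records)
        assert filter_c3f6(once_c3) == once_c3

    def test_empty_in_empty_out(self):
        assert filter_cf([]) == []
        assert filter_c3f6([]) == []

    def test_order_preserved(self, small_dataset):
        kept = filter_cf(small_dataset.records)
        order = {r.id: i for i, r in enumerate(small_dataset.records)}
        assert [order[r.id] for r in kept] == sorted(order[r.id] for r in kept)


# --- independent chain-walk oracle for the C3F6 filter ------------------------


def perfluoro_chain_of_three(mol):
    """Brute-force graph walk: is there a path a-b-c of perfluorinated carbons?

    A perfluorinated carbon is saturated, hydrogen-free, bonds only to carbon
    or fluorine, and has at most two carbon neighbours.
    """

    def is_pfc(atom):
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            return False
        if atom.GetTotalNumHs() != 0 or atom.GetDegree() != 4:
            return False
        nbr_z = [n.GetAtomicNum() for n in atom.GetNeighbors()]
        if any(z not in (6, 9) for z in nbr_z):
            return False
        if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
            return False
        return nbr_z.count(6) <= 2

    pfc = {a.GetIdx() for a in mol.GetAtoms() if is_pfc(a)}
    for b in pfc:
        nbrs = [
            n.GetIdx()
            for n in mol.GetAtomWithIdx(b).GetNeighbors()
            if n.GetIdx() in pfc
        ]
        if len(nbrs) >= 2:  # b is the middle of a 3-chain
            return True
    return False


def test_c3f6_filter_agrees_with_chain_walk_oracle(medium_dataset):
    records = medium_dataset.records
    kept_ids = {r.id for r in filter_c3f6(records)}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        assert bool(perfluoro_chain_of_three(mol)) == (rec.id in kept_ids), rec.smiles


@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("FC(F)(F)C(F)(F)C(F)(F)C(=O)O", True),   # perfluorobutanoic acid
        ("FC(F)(F)C(F)(F)C(F)(F)F", True),        # perfluoropropane
        ("FC(F)(F)C(F)(F)F", False),              # only two chain carbons
        ("FC(F)(F)c1ccccc1", False),              # aromatic attachment, one carbon
        ("CCOC(F)(F)C(F)(F)C(F)(F)F", False),     # ether O breaks the chain end
        ("FC(F)(F)C(Cl)(F)C(F)(F)F", False),      # chlorine disqualifies the middle
        ("C1(F)(F)C(F)(F)C(F)(F)C1(F)F", True),   # perfluorocyclobutane
        ("CC(F)(F)C(F)(F)C(F)(F)F", True),        # alkyl-attached chain of three
    ],
)
def test_c3f6_hand_cases_match_oracle(smiles, expected):
    mol = Chem.MolFromSmiles(smiles)
    assert bool(perfluoro_chain_of_three(mol)) is expected
    got = len(filter_c3f6([make_record("x", smiles)])) == 1
    assert got is expected
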