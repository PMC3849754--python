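"""Format readers, provenance-controlled export and histograms."""

import pytest
from rdkit import Chem

from molvault import chem, fileio
from molvault.chem import NormalizationPolicy, RawStructure
from molvault.errors import EntryRejected, MolvaultError
from molvault.fileio import ExportPolicy
from molvault.store import open_store

POLICY = NormalizationPolicy()


class TestSmilesReader:
    def test_comments_and_blanks_skipped(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("# header comment\nCCO ethanol\n\nc1ccccc1 benzene\n")
        entries = list(fileio.read_entries(p, "smiles"))
        assert [i for i, _ in entries] == [0, 1]
        assert [e.name for _, e in entries] == ["ethanol", "benzene"]

    def test_bad_line_yields_rejection_not_abort(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("CCO a\nnot_a_smiles((( b\nCCN c\n")
        items = [e for _, e in fileio.read_entries(p, "smiles")]
        assert isinstance(items[1], EntryRejected)
        assert [e.name for e in items if isinstance(e, RawStructure)] \
            == ["a", "c"]

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "x"
        p.write_text("CCO\n")
        with pytest.raises(MolvaultError, match="unknown format"):
            list(fileio.read_entries(p, "pdb"))


@pytest.fixture
def vendor_sdf(tmp_path):
    """Two-record SDF with vendor-style data fields."""
    records = []
    for smi, name, price, order in (("CCO", "ethanol", "10.50", "A-001"),
                                    ("c1ccccc1", "benzene", "5.25", "B-002")):
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", name)
        block = Chem.MolToMolBlock(mol)
        block += f">  <price>\n{price}\n\n>  <order number>\n{order}\n\n$$$$\n"
        records.append(block)
    p = tmp_path / "vendor.sdf"
    p.write_text("".join(records))
    return p


class TestSdfReader:
    def test_fields_preserved_in_order(self, vendor_sdf):
        entries = [e for _, e in fileio.read_entries(vendor_sdf, "sdf")]
        assert all(list(e.data_fields) == ["price", "order number"]
                   for e in entries)
        assert entries[0].data_fields["price"] == "10.50"
        assert entries[1].name == "benzene"

    def test_corrupt_record_rejected_others_kept(self, vendor_sdf, tmp_path):
        text = vendor_sdf.read_text()
        first, rest = text.split("$$$$\n", 1)
        corrupt = first[:120] + "\nGARBAGE\n$$$$\n" + rest
        p = tmp_path / "corrupt.sdf"
        p.write_text(corrupt)
        items = [e for _, e in fileio.read_entries(p, "sdf")]
        assert isinstance(items[0], EntryRejected)
        assert isinstance(items[1], RawStructure)

    def test_multiline_field_value(self, tmp_path):
        mol = Chem.MolFromSmiles("CCO")
        block = Chem.MolToMolBlock(mol)
        block += ">  <note>\nline one\nline two\n\n$$$$\n"
        p = tmp_path / "m.sdf"
        p.write_text(block)
        (_, entry), = fileio.read_entries(p, "sdf")
        assert entry.data_fields["note"] == "line one\nline two"


class TestMol2Reader:
    # ethanol with explicit hydrogens and 3D coordinates (Tripos MOL2)
    ETHANOL_MOL2 = """@<TRIPOS>MOLECULE
ethanol
 9 8 0 0 0
SMALL
GASTEIGER

@<TRIPOS>ATOM
      1 C           1.0722    0.0728   -0.0226 C.3     1  UNL1       -0.0418
      2 C           2.5865    0.0657   -0.0242 C.3     1  UNL1        0.0414
      3 O           3.0682   -0.8767   -0.9707 O.3     1  UNL1       -0.3953
      4 H           0.6874    0.8022    0.6955 H       1  UNL1        0.0252
      5 H           0.6802   -0.9164    0.2356 H       1  UNL1        0.0252
      6 H           0.6868    0.3185   -1.0177 H       1  UNL1        0.0252
      7 H           2.9780   -0.1968    0.9635 H       1  UNL1        0.0554
      8 H           2.9735    1.0516   -0.2976 H       1  UNL1        0.0554
      9 H           2.7286   -1.7508   -0.7134 H       1  UNL1        0.2094
@<TRIPOS>BOND
     1     1     2    1
     2     2     3    1
     3     1     4    1
     4     1     5    1
     5     1     6    1
     6     2     7    1
     7     2     8    1
     8     3     9    1
"""

    def test_read_mol2_blocks(self, tmp_path):
        p = tmp_path / "e.mol2"
        p.write_text(self.ETHANOL_MOL2 + self.ETHANOL_MOL2.replace(
            "ethanol", "ethanol2"))
        entries = [e for _, e in fileio.read_entries(p, "mol2")]
        assert [isinstance(e, RawStructure) for e in entries] == [True, True]
        assert entries[0].name == "ethanol" and entries[1].name == "ethanol2"
        assert chem.make_molstring(
            chem.keep_largest_component(entries[0])) == "CCO"


class TestImport:
    def test_rejections_counted_not_fatal(self, tmp_path, fresh_store):
        p = tmp_path / "in.smi"
        p.write_text("CCO a\nbroken((( b\nCCN c\n")
        report = fileio.import_file(fresh_store, p, "smiles", POLICY)
        assert (report.n_entries, report.n_accepted, report.n_rejected) \
            == (3, 2, 1)
        src = fresh_store.get_source(report.source_id)
        assert src.n_entries == 3 and src.n_rejected == 1


class TestExport:
    @pytest.fixture
    def two_vendor_store(self, tmp_path, vendor_sdf):
        store = open_store(tmp_path / "v.db")
        rep_a = fileio.import_file(store, vendor_sdf, "sdf", POLICY)
        other = tmp_path / "vendorB.smi"
        other.write_text("CCO ethanol-B\nCCN amineB\n")
        rep_b = fileio.import_file(store, other, "smiles", POLICY)
        store.create_set("every", [r[0] for r in store.db.execute(
            "SELECT mol_key FROM molecule")])
        yield store, rep_a.source_id, rep_b.source_id
        store.close()

    def test_first_instance_respects_priority(self, tmp_path, two_vendor_store):
        store, sid_a, sid_b = two_vendor_store
        out = tmp_path / "out.smi"
        fileio.export_set(store, "every", out, "smiles",
                          ExportPolicy("first_instance", (sid_b, sid_a)))
        names = [line.split(None, 1)[1].strip()
                 for line in out.read_text().splitlines()]
        # ethanol exists in both vendors; priority B wins
        assert "ethanol-B" in names and "ethanol" not in names

    def test_all_instances_doubles_shared_molecules(self, tmp_path,
                                                    two_vendor_store):
        store, sid_a, sid_b = two_vendor_store
        ms = chem.make_molstring(
            RawStructure(mol=Chem.MolFromSmiles("CCO")))
        shared = store.create_set("shared", [store.mol_key_of(ms)])
        out = tmp_path / "all.sdf"
        report = fileio.export_set(store, shared, out, "sdf",
                                   ExportPolicy("all_instances", ()))
        assert report.n_molecules == 1 and report.n_records == 2

    def test_sd_fields_byte_identical_through_export(self, tmp_path,
                                                     two_vendor_store):
        store, sid_a, _ = two_vendor_store
        out = tmp_path / "round.sdf"
        fileio.export_set(store, "every", out, "sdf",
                          ExportPolicy("all_instances", (sid_a,)))
        entries = [e for _, e in fileio.read_entries(out, "sdf")]
        by_name = {e.name: e for e in entries}
        assert by_name["ethanol"].data_fields \
            == {"price": "10.50", "order number": "A-001"}

    def test_export_import_closure(self, tmp_path, populated):
        store, *_ = populated
        out = tmp_path / "closure.smi"
        fileio.export_set(store, "all", out, "smiles", ExportPolicy())
        with open_store(tmp_path / "closure.db") as second:
            fileio.import_file(second, out, "smiles", POLICY)
            reimported = {r[0] for r in second.db.execute(
                "SELECT molstring FROM molecule")}
        original = {store.molstring(k) for k in store.members("all")}
        assert reimported == original

    def test_empty_set_gives_valid_empty_file(self, tmp_path, populated):
        store, *_ = populated
        empty = store.create_set("export_empty", [], if_exists="rename")
        out = tmp_path / "empty.smi"
        report = fileio.export_set(store, empty, out, "smiles")
        assert report.n_records == 0 and out.read_text() == ""


class TestHistogram:
    def test_single_bin_counts_whole_set(self, populated):
        store, *_ = populated
        table = fileio.histogram(store, ["all"], "mw", bins=1)
        assert sum(table.counts["all"]) == store.set_size("all")

    def test_per_set_totals_preserved(self, populated):
        store, *_ = populated
        members = store.members("all")
        a = store.create_set("hist_a", members[:40], if_exists="rename")
        b = store.create_set("hist_b", members[40:100], if_exists="rename")
        table = fileio.histogram(store, [a, b], "logp", bins=7)
        assert sum(table.counts[a.name]) == 40
        assert sum(table.counts[b.name]) == 60

    def test_counts_match_linear_scan_oracle(self, populated):
        import numpy as np
        store, *_ = populated
        table = fileio.histogram(store, ["all"], "mw", bins=10)
        values = sorted(store.properties(k).mw for k in store.members("all"))
        edges = table.edges
        oracle = [0] * 10
        for v in values:
            for i in range(10):
                last = i == 9
                if edges[i] <= v < edges[i + 1] or (last and v == edges[10]):
                    oracle[i] += 1
                    break
        assert table.counts["all"] == oracle

    def test_empty_input_raises(self, populated):
        store, *_ = populated
        empty = store.create_set("hist_empty", [], if_exists="rename")
        with pytest.raises(MolvaultError, match="nothing to bin"):
            fileio.histogram(store, [empty], "mw", bins=5)
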