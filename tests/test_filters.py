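"""Elementary filters, m-of-n tolerance semantics and config round trip."""

import random

import pytest
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from molvault import chem, filters, setops
from molvault.chem import RawStructure
from molvault.errors import MolvaultError, SmartsError
from molvault.filters import ElementaryFilter, FilterChain
from molvault.validate import oracle_verdict, random_chain


@pytest.fixture(scope="module")
def store(populated):
    return populated[0]


def key_of(store, smiles):
    ms = chem.make_molstring(RawStructure(mol=Chem.MolFromSmiles(smiles)))
    k = store.mol_key_of(ms)
    if k is None:
        sid = store.add_source("test-inline", "smiles",
                               chem.NormalizationPolicy())
        k, _, _ = store.register(RawStructure(mol=Chem.MolFromSmiles(smiles)),
                                 chem.NormalizationPolicy(), sid, 0)
    return k


class TestElementary:
    def test_mw_range_accepts_benzene(self, store):
        k = key_of(store, "c1ccccc1")
        f = ElementaryFilter.property_range("mw", 0, 500)
        assert filters.eval_elementary(store, f, k)

    def test_exclude_element_fails_chlorobenzene(self, store):
        k = key_of(store, "Clc1ccccc1")
        f = ElementaryFilter.element("Cl", exclude=True)
        assert not filters.eval_elementary(store, f, k)
        assert filters.eval_elementary(store, ElementaryFilter.element("Cl"), k)

    def test_functional_group_filter(self, store):
        k = key_of(store, "NC(=O)c1ccccc1")
        f = ElementaryFilter.functional_group("amide")
        assert filters.eval_elementary(store, f, k)

    def test_smarts_collection_is_one_disjunctive_filter(self, store):
        k = key_of(store, "c1ccccc1")
        f = ElementaryFilter.smarts(["[#8]", "c1ccccc1"])  # either may hit
        assert filters.eval_elementary(store, f, k)

    def test_open_ended_bounds(self, store):
        k = key_of(store, "c1ccccc1")
        assert filters.eval_elementary(
            store, ElementaryFilter.property_range("mw", low=50), k)
        assert not filters.eval_elementary(
            store, ElementaryFilter.property_range("mw", low=1000), k)

    def test_random_verdicts_match_scratch_recomputation(self, store):
        rng = random.Random(4)
        members = store.members("all")[:100]
        for _ in range(15):
            chain = random_chain(store, rng, max_filters=1)
            f = chain.filters[0]
            for k in members[::7]:
                assert filters.eval_elementary(store, f, k) \
                    == oracle_verdict(store.molstring(k), f)

    def test_construction_validates(self):
        with pytest.raises(MolvaultError):
            ElementaryFilter.property_range("mw", 10, 5)
        with pytest.raises(MolvaultError):
            ElementaryFilter.functional_group("no_such_group")
        with pytest.raises(SmartsError):
            ElementaryFilter.smarts("c1ccccc1[")


@pytest.fixture(scope="module")
def chain3():
    return FilterChain((
        ElementaryFilter.property_range("mw", high=300),
        ElementaryFilter.functional_group("aromatic_ring"),
        ElementaryFilter.element("Cl", exclude=True),
    ))


class TestApplyChain:

    def test_conjunction_equals_intersection_of_singles(self, store, chain3):
        full = filters.apply_chain(store, "all", chain3)
        singles = [filters.apply_chain(store, "all",
                                       FilterChain((f,)))
                   for f in chain3.filters]
        expected = set(store.members(singles[0]))
        for s in singles[1:]:
            expected &= set(store.members(s))
        assert set(store.members(full)) == expected

    def test_m_zero_returns_input(self, store, chain3):
        res = filters.apply_chain(
            store, "all", FilterChain(chain3.filters, tolerance_m=0))
        assert store.members(res) == store.members("all")

    def test_monotone_in_m(self, store, chain3):
        results = [set(store.members(filters.apply_chain(
            store, "all", FilterChain(chain3.filters, tolerance_m=m))))
            for m in range(4)]
        for tighter, looser in zip(results[1:], results):
            assert tighter <= looser

    def test_anti_extensive_and_idempotent(self, store, chain3):
        first = filters.apply_chain(store, "all", chain3)
        again = filters.apply_chain(store, first, chain3)
        assert set(store.members(first)) <= set(store.members("all"))
        assert store.members(again) == store.members(first)

    def test_tolerant_chain_matches_vote_count_oracle(self, store):
        rng = random.Random(12)
        members = store.members("all")
        for _ in range(8):
            chain = random_chain(store, rng, max_filters=4)
            res = filters.apply_chain(store, "all", chain)
            expected = {k for k in members
                        if sum(oracle_verdict(store.molstring(k), f)
                               for f in chain.filters) >= chain.m}
            assert set(store.members(res)) == expected


class TestRuleOfFive:
    THRESH = dict(mw=500, logp=5, hbd=5, hba=10)

    @staticmethod
    def violations(smiles):
        mol = Chem.MolFromSmiles(smiles)
        return sum([
            Descriptors.MolWt(mol) > 500,
            Crippen.MolLogP(mol) > 5,
            rdMolDescriptors.CalcNumHBD(mol) > 5,
            rdMolDescriptors.CalcNumHBA(mol) > 10,
        ])

    def test_aspirin_passes_strict(self, store):
        aspirin = "CC(=O)Oc1ccccc1C(=O)O"
        assert self.violations(aspirin) == 0
        k = key_of(store, aspirin)
        s = store.create_set("ro5_aspirin", [k], if_exists="rename")
        res = filters.apply_chain(store, s, filters.rule_of_five_chain(4))
        assert store.members(res) == [k]

    def test_single_violation_passes_m3_fails_m4(self, store):
        hexadecane = "CCCCCCCCCCCCCCCC"  # only logP > 5
        assert self.violations(hexadecane) == 1
        k = key_of(store, hexadecane)
        s = store.create_set("ro5_hexadecane", [k], if_exists="rename")
        assert store.members(filters.apply_chain(
            store, s, filters.rule_of_five_chain(3))) == [k]
        assert store.members(filters.apply_chain(
            store, s, filters.rule_of_five_chain(4))) == []

    def test_m_zero_passes_everything(self, store):
        res = filters.apply_chain(store, "all", filters.rule_of_five_chain(0))
        assert store.members(res) == store.members("all")

    def test_tolerance_out_of_range(self):
        with pytest.raises(MolvaultError):
            filters.rule_of_five_chain(5)


class TestChainConfig:
    def test_yaml_round_trip(self, tmp_path):
        chain = FilterChain((
            ElementaryFilter.property_range("tpsa", 20, 140),
            ElementaryFilter.element("Br", exclude=True),
            ElementaryFilter.functional_group("nitro", exclude=True),
            ElementaryFilter.smarts(["c1ccncc1", "[OX2H]"]),
        ), tolerance_m=3)
        path = tmp_path / "chain.yaml"
        filters.chain_to_yaml(chain, path)
        loaded = filters.chain_from_yaml(path)
        assert loaded == chain

    def test_smarts_file_reference(self, tmp_path):
        (tmp_path / "patts.txt").write_text(
            "# halogen patterns\n[F,Cl]\tany halogen\n\n[Br,I]\n")
        (tmp_path / "chain.yaml").write_text(
            "filters:\n  - kind: smarts\n    patterns_file: patts.txt\n")
        chain = filters.chain_from_yaml(tmp_path / "chain.yaml")
        assert chain.filters[0].patterns == ("[F,Cl]", "[Br,I]")

    def test_malformed_smarts_in_config_is_named(self, tmp_path):
        (tmp_path / "bad.yaml").write_text(
            "filters:\n  - kind: smarts\n    pattern: 'c1ccccc1['\n")
        with pytest.raises(SmartsError, match=r"c1ccccc1\["):
            filters.chain_from_yaml(tmp_path / "bad.yaml")

    def test_smarts_collection_file_rules(self, tmp_path):
        p = tmp_path / "coll.txt"
        p.write_text("# comment\nc1ccccc1\n\n[#7]\tnitrogen label\n")
        assert filters.read_smarts_collection(p) == ["c1ccccc1", "[#7]"]
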