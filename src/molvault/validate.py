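"""Self-validation harnesses for a populated store.

Three independent checks, each comparing the database-backed computation
against a from-scratch oracle:

1. **Round trip** — every instance restored from the store must match a
   fresh run of the import pipeline on its original file entry: same
   topology (valences, charges), same name, byte-identical SD data and
   coordinates equal to 4 decimals.
2. **Set-operation consistency** — for random triples S1, S2, S3 built by
   assigning each molecule to a uniformly random nonempty subset of the
   three sets, the union must equal the union of the three-way symmetric
   difference, the triple intersection and all pairwise intersections;
   both sides are also checked against brute-force membership enumeration.
3. **Filter-oracle equivalence** — random m-of-n chains evaluated through
   the store must return exactly the set found by linearly re-deriving
   every verdict from the MolString (properties, bits and SMARTS matches
   recomputed, not read from the database).
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from . import chem, fileio, setops
from .errors import EntryRejected
from .filters import ElementaryFilter, FilterChain, apply_chain
from .store import Store


@dataclass
class ValidationReport:
    name: str
    n_cases: int = 0
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.n_failed == 0

    def record(self, ok: bool, detail: str = "") -> None:
        self.n_cases += 1
        if not ok:
            self.n_failed += 1
            if len(self.failures) < 20:
                self.failures.append(detail)

    def summary(self) -> str:
        state = "PASS" if self.passed else "FAIL"
        return (f"{self.name}: {state} ({self.n_cases - self.n_failed}"
                f"/{self.n_cases} cases)")


# --------------------------------------------------------------------- #
# 1. round trip

def _atom_table(mol) -> list[tuple[int, int, int, int]]:
    """Per-atom (element, formal charge, total valence, total Hs) in atom
    order — the valence-state signature the round trip must preserve."""
    return [(a.GetAtomicNum(), a.GetFormalCharge(), a.GetTotalValence(),
             a.GetTotalNumHs()) for a in mol.GetAtoms()]


def validate_roundtrip(store: Store, coord_tol: float = 1e-4,
                       source_ids: list[int] | None = None) -> ValidationReport:
    """Re-read every source file, re-run the import pipeline on each entry
    and compare against the instance restored from the store."""
    report = ValidationReport("roundtrip")
    sources = store.list_sources()
    if source_ids is not None:
        sources = [s for s in sources if s.source_id in source_ids]
    for src in sources:
        for idx, item in fileio.read_entries(src.path, src.format):
            if isinstance(item, EntryRejected):
                continue
            row = store.db.execute(
                "SELECT inst_key FROM instance WHERE source_id = ?"
                " AND entry_index = ?", (src.source_id, idx)).fetchone()
            if row is None:
                report.record(False, f"entry {idx} of {src.path}: not stored")
                continue
            expected = chem.normalize(chem.keep_largest_component(item),
                                      src.policy)
            restored = store.restore_instance(row[0])
            report.record(
                _instances_equal(expected, restored, coord_tol),
                f"entry {idx} of {src.path}: mismatch")
    return report


def _instances_equal(expected, restored, coord_tol: float) -> bool:
    if chem.make_molstring(expected) != chem.make_molstring(restored):
        return False
    if expected.name != restored.name:
        return False
    if list(expected.data_fields.items()) != list(restored.data_fields.items()):
        return False
    if sorted(_atom_table(expected.mol)) != sorted(_atom_table(restored.mol)):
        return False
    ec, rc = expected.coords(), restored.coords()
    if (ec is None) != (rc is None):
        return False
    if ec is not None:
        if len(ec) != len(rc):
            return False
        # with coordinates, restored atoms are in the original pipeline order
        if _atom_table(expected.mol) != _atom_table(restored.mol):
            return False
        for (x1, y1, z1), (x2, y2, z2) in zip(ec, rc):
            if max(abs(x1 - x2), abs(y1 - y2), abs(z1 - z2)) > coord_tol:
                return False
    return True


# --------------------------------------------------------------------- #
# 2. set-operation consistency

def validate_setops(store: Store, n_trials: int = 100, seed: int = 0,
                    mol_keys: list[int] | None = None) -> ValidationReport:
    """Random-triple union/Δ consistency, cross-checked by enumeration."""
    rng = random.Random(seed)
    if mol_keys is None:
        mol_keys = [r[0] for r in store.db.execute("SELECT mol_key FROM molecule")]
    report = ValidationReport("setops")
    patterns = [p for p in itertools.product((0, 1), repeat=3) if any(p)]
    for trial in range(n_trials):
        assign = {k: rng.choice(patterns) for k in mol_keys}
        truth = [set(), set(), set()]
        for k, pat in assign.items():
            for i in range(3):
                if pat[i]:
                    truth[i].add(k)
        tag = f"_validate_{trial}"
        s = [store.create_set(f"S{i}{tag}", sorted(truth[i]), if_exists="rename")
             for i in range(3)]
        created = list(s)

        def op(fn, *args):
            res = fn(store, *args)
            created.append(res)
            return res

        lhs = op(setops.union, s)
        rhs = op(setops.union, [
            op(setops.symmetric_difference, s),
            op(setops.intersection, s),
            op(setops.intersection, [s[0], s[1]]),
            op(setops.intersection, [s[0], s[2]]),
            op(setops.intersection, [s[1], s[2]]),
        ])
        lhs_keys = set(store.members(lhs))
        rhs_keys = set(store.members(rhs))
        brute = truth[0] | truth[1] | truth[2]
        report.record(lhs_keys == rhs_keys == brute,
                      f"trial {trial}: |lhs|={len(lhs_keys)}"
                      f" |rhs|={len(rhs_keys)} |brute|={len(brute)}")
        for made in created:
            store.delete_set(made)
    return report


# --------------------------------------------------------------------- #
# 3. filter-oracle equivalence

_ORACLE_PROP_CACHE: dict[str, chem.PropertyVector] = {}

COMMON_ELEMENTS = (6, 7, 8, 9, 15, 16, 17, 35)

EXTRA_PATTERNS = ("c1ccncc1", "[OX2H]", "C(=O)", "[#7;R]", "FC(F)F",
                  "[NX3;H2]", "c1ccccc1O")


def oracle_verdict(molstring: str, f: ElementaryFilter) -> bool:
    """Filter verdict recomputed from the structure, bypassing the store."""
    if f.kind == "property_range":
        props = _ORACLE_PROP_CACHE.get(molstring)
        if props is None:
            props = chem.compute_properties(molstring)
            _ORACLE_PROP_CACHE[molstring] = props
        value = getattr(props, f.prop)
        v = ((f.low is None or value >= f.low)
             and (f.high is None or value <= f.high))
    elif f.kind == "element":
        mol = chem.rebuild(molstring).mol
        v = any(a.GetAtomicNum() == f.atomic_number for a in mol.GetAtoms())
    elif f.kind == "functional_group":
        smarts = dict(chem.GROUP_CATALOG)[f.group]
        v = chem.match_smarts(molstring, smarts)
    else:
        v = any(chem.match_smarts(molstring, p) for p in f.patterns)
    return (not v) if f.polarity == "exclude" else v


def random_chain(store: Store, rng: random.Random,
                 max_filters: int = 5) -> FilterChain:
    """A random mixed-kind chain with random polarities and tolerance."""
    n = rng.randint(1, max_filters)
    filters = []
    for _ in range(n):
        kind = rng.choice(("property_range", "element", "functional_group",
                           "smarts"))
        exclude = rng.random() < 0.5
        if kind == "property_range":
            prop = rng.choice(chem.PROPERTY_NAMES)
            lo_q, hi_q = sorted(rng.uniform(0, 1) for _ in range(2))
            vals = sorted(r[0] for r in store.db.execute(
                f"SELECT {prop} FROM molecule"))
            lo = vals[int(lo_q * (len(vals) - 1))]
            hi = vals[int(hi_q * (len(vals) - 1))]
            filters.append(ElementaryFilter.property_range(prop, lo, hi, exclude))
        elif kind == "element":
            filters.append(ElementaryFilter.element(
                rng.choice(COMMON_ELEMENTS), exclude))
        elif kind == "functional_group":
            filters.append(ElementaryFilter.functional_group(
                rng.choice(chem.GROUP_NAMES), exclude))
        else:
            pool = tuple(s for _, s in chem.GROUP_CATALOG) + EXTRA_PATTERNS
            k = rng.randint(1, 3)
            filters.append(ElementaryFilter.smarts(
                [rng.choice(pool) for _ in range(k)], exclude))
    return FilterChain(tuple(filters), tolerance_m=rng.randint(0, n))


def validate_filters(store: Store, set_ref, n_chains: int = 50,
                     seed: int = 0) -> ValidationReport:
    """Compare apply_chain against the linear per-molecule oracle."""
    rng = random.Random(seed)
    report = ValidationReport("filters")
    members = store.members(set_ref)
    molstrings = {k: store.molstring(k) for k in members}
    for trial in range(n_chains):
        chain = random_chain(store, rng)
        result = apply_chain(store, set_ref, chain,
                             out_name=None)
        got = set(store.members(result))
        expected = set()
        for k in members:
            votes = sum(oracle_verdict(molstrings[k], f) for f in chain.filters)
            if votes >= chain.m:
                expected.add(k)
        report.record(got == expected,
                      f"chain {trial} (m={chain.m}/{chain.n}):"
                      f" got {len(got)}, expected {len(expected)}")
        store.delete_set(result)
    return report
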