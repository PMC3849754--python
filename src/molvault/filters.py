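"""Elementary filters and m-of-n tolerant filter chains.

Four elementary filter kinds are supported: property ranges, chemical
elements, functional groups from the shipped catalog, and SMARTS patterns
(a pattern collection counts as one filter that matches when any of its
patterns hits).  Each filter carries a polarity; ``exclude`` negates its
verdict before counting.  A chain of n filters with tolerance m keeps the
molecules for which at least m verdicts are positive — m = n is plain
conjunction, and the Rule-of-Five preset is the m = 4-of-4 (or, for the
classical "at most one violation" reading, 3-of-4) chain over MW, logP,
H-bond donors and acceptors.

Property, element and group verdicts come from the store's precomputed
columns and bitfields; SMARTS verdicts rebuild each candidate from its
MolString.  With m = n the SMARTS step only sees molecules that survived
the cheap filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml
from rdkit.Chem import GetPeriodicTable

from . import chem
from .errors import MolvaultError, SmartsError
from .store import MoleculeSet, Store

KINDS = ("property_range", "element", "functional_group", "smarts")


@dataclass(frozen=True)
class ElementaryFilter:
    kind: str
    polarity: str = "require"
    # property_range
    prop: str | None = None
    low: float | None = None
    high: float | None = None
    # element
    atomic_number: int | None = None
    # functional_group
    group: str | None = None
    # smarts (one pattern, or a collection treated as a disjunction)
    patterns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise MolvaultError(f"unknown filter kind {self.kind!r}")
        if self.polarity not in ("require", "exclude"):
            raise MolvaultError(f"polarity must be require|exclude, got {self.polarity!r}")
        if self.kind == "property_range":
            if self.prop not in chem.PROPERTY_NAMES:
                raise MolvaultError(f"unknown property {self.prop!r}")
            if self.low is None and self.high is None:
                raise MolvaultError("property_range needs at least one bound")
            if self.low is not None and self.high is not None and self.low > self.high:
                raise MolvaultError("property_range: low > high")
        elif self.kind == "element":
            if not (self.atomic_number and 0 < self.atomic_number < chem.N_ELEMENT_BITS):
                raise MolvaultError(f"bad atomic number {self.atomic_number!r}")
        elif self.kind == "functional_group":
            if self.group not in chem.GROUP_NAMES:
                raise MolvaultError(
                    f"unknown functional group {self.group!r};"
                    f" catalog: {', '.join(chem.GROUP_NAMES)}")
        elif self.kind == "smarts":
            if not self.patterns:
                raise MolvaultError("smarts filter needs at least one pattern")
            for p in self.patterns:
                chem.compile_smarts(p)  # raises SmartsError on bad input

    # -- convenience constructors ------------------------------------- #

    @staticmethod
    def property_range(prop: str, low: float | None = None,
                       high: float | None = None,
                       exclude: bool = False) -> "ElementaryFilter":
        return ElementaryFilter("property_range",
                                "exclude" if exclude else "require",
                                prop=prop, low=low, high=high)

    @staticmethod
    def element(element: int | str, exclude: bool = False) -> "ElementaryFilter":
        if isinstance(element, str):
            element = GetPeriodicTable().GetAtomicNumber(element)
        return ElementaryFilter("element", "exclude" if exclude else "require",
                                atomic_number=element)

    @staticmethod
    def functional_group(group: str, exclude: bool = False) -> "ElementaryFilter":
        return ElementaryFilter("functional_group",
                                "exclude" if exclude else "require", group=group)

    @staticmethod
    def smarts(pattern: str | list[str] | tuple[str, ...],
               exclude: bool = False) -> "ElementaryFilter":
        patterns = (pattern,) if isinstance(pattern, str) else tuple(pattern)
        return ElementaryFilter("smarts", "exclude" if exclude else "require",
                                patterns=patterns)

    def describe(self) -> str:
        body = {
            "property_range": lambda: f"{self.prop} in [{self.low},{self.high}]",
            "element": lambda: f"element Z={self.atomic_number}",
            "functional_group": lambda: f"group {self.group}",
            "smarts": lambda: f"smarts {'|'.join(self.patterns)}",
        }[self.kind]()
        return f"{self.polarity} {body}"


@dataclass(frozen=True)
class FilterChain:
    """Ordered elementary filters plus the tolerance m (of n)."""

    filters: tuple[ElementaryFilter, ...]
    tolerance_m: int | None = None  # None → m = n

    def __post_init__(self):
        if not self.filters:
            raise MolvaultError("a filter chain needs at least one filter")
        if self.tolerance_m is not None and not (
                0 <= self.tolerance_m <= len(self.filters)):
            raise MolvaultError(
                f"tolerance m={self.tolerance_m} outside 0..{len(self.filters)}")

    @property
    def n(self) -> int:
        return len(self.filters)

    @property
    def m(self) -> int:
        return self.n if self.tolerance_m is None else self.tolerance_m


def _raw_verdict(store: Store, f: ElementaryFilter, mol_key: int) -> bool:
    if f.kind == "property_range":
        value = getattr(store.properties(mol_key), f.prop)
        return ((f.low is None or value >= f.low)
                and (f.high is None or value <= f.high))
    ebits, gbits = store.bitfields(mol_key)
    if f.kind == "element":
        return bool(ebits >> f.atomic_number & 1)
    if f.kind == "functional_group":
        return bool(gbits >> chem.GROUP_NAMES.index(f.group) & 1)
    ms = store.molstring(mol_key)
    return any(chem.match_smarts(ms, p) for p in f.patterns)


def eval_elementary(store: Store, f: ElementaryFilter, mol_key: int) -> bool:
    """Verdict of one filter on one molecule, polarity applied."""
    v = _raw_verdict(store, f, mol_key)
    return (not v) if f.polarity == "exclude" else v


def _matching_keys(store: Store, f: ElementaryFilter,
                   candidates: list[int]) -> set[int]:
    """Keys among ``candidates`` with a positive raw verdict (bulk path)."""
    if not candidates:
        return set()
    if f.kind == "property_range":
        cond, params = ["mol_key IN (" + ",".join("?" * len(candidates)) + ")"], \
            list(candidates)
        if f.low is not None:
            cond.append(f"{f.prop} >= ?")
            params.append(f.low)
        if f.high is not None:
            cond.append(f"{f.prop} <= ?")
            params.append(f.high)
        rows = store.db.execute(
            "SELECT mol_key FROM molecule WHERE " + " AND ".join(cond), params)
        return {r[0] for r in rows}
    if f.kind in ("element", "functional_group"):
        if f.kind == "element":
            bit, col = f.atomic_number, "element_bits"
        else:
            bit, col = chem.GROUP_NAMES.index(f.group), "group_bits"
        rows = store.db.execute(
            f"SELECT mol_key, {col} FROM molecule WHERE mol_key IN ("
            + ",".join("?" * len(candidates)) + ")", candidates)
        return {k for k, blob in rows if chem.blob_to_bits(blob) >> bit & 1}
    patts = [chem.compile_smarts(p) for p in f.patterns]
    rows = store.db.execute(
        "SELECT mol_key, molstring FROM molecule WHERE mol_key IN ("
        + ",".join("?" * len(candidates)) + ")", candidates)
    out = set()
    for k, ms in rows:
        mol = chem.rebuild_cached(ms)
        if any(mol.HasSubstructMatch(p) for p in patts):
            out.add(k)
    return out


def apply_chain(store: Store, s, chain: FilterChain,
                out_name: str | None = None) -> MoleculeSet:
    """Filter a molecule set, keeping members that satisfy ≥ m of the n
    elementary filters; the result is persisted as a new set."""
    src = store.get_set(s)
    members = store.members(src)
    m, n = chain.m, chain.n

    # cheap verdicts first so the SMARTS rebuild only sees what it must;
    # with m < n every filter is evaluated anyway.
    order = sorted(range(n), key=lambda i: chain.filters[i].kind == "smarts")
    passed: dict[int, int] = {k: 0 for k in members}
    remaining = n
    for i in order:
        f = chain.filters[i]
        if m == n:
            candidates = [k for k, c in passed.items() if c == n - remaining]
        else:
            candidates = members
        hits = _matching_keys(store, f, candidates)
        for k in candidates:
            ok = (k in hits) if f.polarity == "require" else (k not in hits)
            if ok:
                passed[k] += 1
        remaining -= 1
        if m == n:
            # drop molecules that already failed once
            passed = {k: c for k, c in passed.items() if c == n - remaining}
    keys = sorted(k for k, c in passed.items() if c >= m)
    base = out_name or f"filter({src.name},m={m}/{n})"
    return store.create_set(
        store._unique_set_name(base) if out_name is None else base, keys)


def rule_of_five_chain(tolerance_m: int = 4) -> FilterChain:
    """Lipinski's oral-bioavailability screen: MW ≤ 500, logP ≤ 5,
    H-bond donors ≤ 5, acceptors ≤ 10; pass if ≥ m criteria hold."""
    if not 0 <= tolerance_m <= 4:
        raise MolvaultError("Rule-of-Five tolerance must be 0..4")
    return FilterChain(
        filters=(
            ElementaryFilter.property_range("mw", high=500),
            ElementaryFilter.property_range("logp", high=5),
            ElementaryFilter.property_range("hbd", high=5),
            ElementaryFilter.property_range("hba", high=10),
        ),
        tolerance_m=tolerance_m,
    )


# --------------------------------------------------------------------- #
# config-file round trip

def read_smarts_collection(path) -> list[str]:
    """One SMARTS per line; '#' comments and blank lines skipped; an
    optional tab-separated label after the pattern is ignored."""
    patterns = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            patterns.append(line.split("\t")[0].strip())
    if not patterns:
        raise MolvaultError(f"no SMARTS patterns in {path!r}")
    return patterns


def _filter_to_dict(f: ElementaryFilter) -> dict:
    d: dict = {"kind": f.kind, "polarity": f.polarity}
    if f.kind == "property_range":
        d["property"] = f.prop
        if f.low is not None:
            d["low"] = f.low
        if f.high is not None:
            d["high"] = f.high
    elif f.kind == "element":
        d["element"] = f.atomic_number
    elif f.kind == "functional_group":
        d["group"] = f.group
    else:
        d["patterns"] = list(f.patterns)
    return d


def _filter_from_dict(d: dict, base_dir=None) -> ElementaryFilter:
    kind = d.get("kind")
    exclude = d.get("polarity", "require") == "exclude"
    if kind == "property_range":
        return ElementaryFilter.property_range(
            d.get("property"), d.get("low"), d.get("high"), exclude)
    if kind == "element":
        return ElementaryFilter.element(d.get("element"), exclude)
    if kind == "functional_group":
        return ElementaryFilter.functional_group(d.get("group"), exclude)
    if kind == "smarts":
        if "patterns_file" in d:
            from pathlib import Path
            p = Path(d["patterns_file"])
            if base_dir is not None and not p.is_absolute():
                p = Path(base_dir) / p
            return ElementaryFilter.smarts(read_smarts_collection(p), exclude)
        pats = d.get("patterns", d.get("pattern"))
        return ElementaryFilter.smarts(pats, exclude)
    raise MolvaultError(f"unknown filter kind {kind!r} in chain config")


def chain_to_yaml(chain: FilterChain, path) -> None:
    doc = {"tolerance_m": chain.m,
           "filters": [_filter_to_dict(f) for f in chain.filters]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def chain_from_yaml(path) -> FilterChain:
    from pathlib import Path
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "filters" not in doc:
        raise MolvaultError(f"chain config {path!r} must map 'filters' to a list")
    filters = tuple(_filter_from_dict(d, base_dir=Path(path).parent)
                    for d in doc["filters"])
    return FilterChain(filters=filters, tolerance_m=doc.get("tolerance_m"))
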