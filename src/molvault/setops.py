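"""Exact set algebra and splitting over persisted molecule sets.

All operations are evaluated as SQL over the membership table and return
new persisted sets; inputs are never modified.  The n-ary symmetric
difference uses odd-membership semantics (the left fold of the binary Δ),
so A Δ A = ∅ and the three-set union/Δ consistency identity holds.
"""

from __future__ import annotations

from .chem import PROPERTY_NAMES
from .errors import MolvaultError
from .store import MoleculeSet, Store

SetRef = "int | str | MoleculeSet"


def _ids_and_names(store: Store, sets) -> tuple[list[int], list[str]]:
    resolved = [store.get_set(s) for s in sets]
    if not resolved:
        raise MolvaultError("at least one input set required")
    return [s.set_id for s in resolved], [s.name for s in resolved]


def _auto_name(op: str, names: list[str]) -> str:
    return f"{op}({','.join(names)})"


def _persist(store: Store, op: str, names: list[str], keys: list[int],
             out_name: str | None) -> MoleculeSet:
    base = out_name or _auto_name(op, names)
    return store.create_set(store._unique_set_name(base) if out_name is None
                            else base, keys)


def union(store: Store, sets, out_name: str | None = None) -> MoleculeSet:
    ids, names = _ids_and_names(store, sets)
    keys = [r[0] for r in store.db.execute(
        "SELECT DISTINCT mol_key FROM molset_member WHERE set_id IN ("
        + ",".join("?" * len(ids)) + ")", ids)]
    return _persist(store, "union", names, keys, out_name)


def _multiset_select(ids: list[int]) -> str:
    # one SELECT per input reference so a set passed twice counts twice
    return " UNION ALL ".join(
        "SELECT mol_key FROM molset_member WHERE set_id = ?" for _ in ids)


def intersection(store: Store, sets, out_name: str | None = None) -> MoleculeSet:
    ids, names = _ids_and_names(store, sets)
    keys = [r[0] for r in store.db.execute(
        f"SELECT mol_key FROM ({_multiset_select(ids)})"
        " GROUP BY mol_key HAVING COUNT(*) = ?", (*ids, len(ids)))]
    return _persist(store, "intersect", names, keys, out_name)


def difference(store: Store, a, b, out_name: str | None = None) -> MoleculeSet:
    ids, names = _ids_and_names(store, [a, b])
    keys = [r[0] for r in store.db.execute(
        "SELECT mol_key FROM molset_member WHERE set_id = ?"
        " EXCEPT SELECT mol_key FROM molset_member WHERE set_id = ?", ids)]
    return _persist(store, "diff", names, keys, out_name)


def symmetric_difference(store: Store, sets,
                         out_name: str | None = None) -> MoleculeSet:
    """Keys belonging to an odd number of the input sets (n-ary Δ)."""
    ids, names = _ids_and_names(store, sets)
    if len(ids) < 2:
        raise MolvaultError("symmetric difference needs at least two sets")
    keys = [r[0] for r in store.db.execute(
        f"SELECT mol_key FROM ({_multiset_select(ids)})"
        " GROUP BY mol_key HAVING COUNT(*) % 2 = 1", ids)]
    return _persist(store, "symdiff", names, keys, out_name)


def split_by_property(store: Store, s, prop: str,
                      boundaries: list[float]) -> list[MoleculeSet]:
    """Partition a set into half-open property intervals.

    ``boundaries`` [b1 < b2 < …] produce k+1 sets covering (-inf, b1),
    [b1, b2), …, [bk, inf); their union is the input set.
    """
    if prop not in PROPERTY_NAMES:
        raise MolvaultError(f"unknown property {prop!r}; choose from {PROPERTY_NAMES}")
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise MolvaultError("boundaries must be strictly ascending")
    src = store.get_set(s)
    edges = [float("-inf"), *boundaries, float("inf")]
    out = []
    for lo, hi in zip(edges, edges[1:]):
        cond, params = [], [src.set_id]
        if lo != float("-inf"):
            cond.append(f"m.{prop} >= ?")
            params.append(lo)
        if hi != float("inf"):
            cond.append(f"m.{prop} < ?")
            params.append(hi)
        where = (" AND " + " AND ".join(cond)) if cond else ""
        keys = [r[0] for r in store.db.execute(
            "SELECT mm.mol_key FROM molset_member mm"
            " JOIN molecule m ON m.mol_key = mm.mol_key"
            f" WHERE mm.set_id = ?{where}", params)]
        label = f"{src.name}[{prop}:{lo:g}..{hi:g})"
        out.append(store.create_set(store._unique_set_name(label), keys))
    return out


def split_chunks(store: Store, s, chunk_size: int) -> list[MoleculeSet]:
    """Cut a set into consecutive chunks in ascending molecule-key order."""
    if chunk_size < 1:
        raise MolvaultError("chunk_size must be >= 1")
    src = store.get_set(s)
    members = store.members(src)
    out = []
    for i in range(0, len(members), chunk_size):
        chunk = members[i:i + chunk_size]
        label = f"{src.name}#chunk{i // chunk_size + 1}"
        out.append(store.create_set(store._unique_set_name(label), chunk))
    return out
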