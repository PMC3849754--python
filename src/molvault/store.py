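"""Embedded-SQLite persistence for molecules, instances, sources and sets.

The store keeps one row per unique topology (``molecule``), one row per
file entry mapped onto it (``instance``), one row per imported file
(``source``) and named molecule sets as lists of molecule keys.  Duplicate
detection happens at registration time through a unique index on the
MolString; properties and bitfields are computed once, on first insert.

Schema (version 1)::

    meta(key, value)
    source(source_id, path, format, policy, n_entries, n_rejected, rank)
    molecule(mol_key, molstring UNIQUE, <10 property columns, indexed>,
             element_bits BLOB, group_bits BLOB)
    instance(inst_key, mol_key→molecule, source_id→source, entry_index,
             name, coords, is3d, perm, sd_data,
             UNIQUE(source_id, entry_index))
    molset(set_id, name UNIQUE)
    molset_member(set_id→molset, mol_key→molecule)

Coordinates are stored in canonical (MolString) atom order together with
the original→canonical permutation, so exports can reproduce the original
atom order exactly.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem
from rdkit.Geometry import Point3D

from . import chem
from .chem import (
    ELEMENT_BLOB_LEN,
    GROUP_BLOB_LEN,
    PROPERTY_NAMES,
    NormalizationPolicy,
    PropertyVector,
    RawStructure,
)
from .errors import NameClash, NotFound, SchemaError

SCHEMA_VERSION = 1

_SCHEMA = f"""
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);

CREATE TABLE source (
    source_id   INTEGER PRIMARY KEY,
    path        TEXT NOT NULL,
    format      TEXT NOT NULL CHECK (format IN ('smiles', 'sdf', 'mol2')),
    policy      TEXT NOT NULL,
    n_entries   INTEGER NOT NULL DEFAULT 0,
    n_rejected  INTEGER NOT NULL DEFAULT 0,
    rank        INTEGER NOT NULL
);

CREATE TABLE molecule (
    mol_key             INTEGER PRIMARY KEY,
    molstring           TEXT NOT NULL UNIQUE,
    mw                  REAL NOT NULL,
    heavy_atoms         INTEGER NOT NULL,
    ring_count          INTEGER NOT NULL,
    aromatic_ring_count INTEGER NOT NULL,
    rotatable_bonds     INTEGER NOT NULL,
    hbd                 INTEGER NOT NULL,
    hba                 INTEGER NOT NULL,
    tpsa                REAL NOT NULL,
    logp                REAL NOT NULL,
    net_charge          INTEGER NOT NULL,
    element_bits        BLOB NOT NULL,
    group_bits          BLOB NOT NULL
);

CREATE TABLE instance (
    inst_key    INTEGER PRIMARY KEY,
    mol_key     INTEGER NOT NULL REFERENCES molecule(mol_key),
    source_id   INTEGER NOT NULL REFERENCES source(source_id),
    entry_index INTEGER NOT NULL,
    name        TEXT NOT NULL DEFAULT '',
    coords      TEXT,
    is3d        INTEGER NOT NULL DEFAULT 0,
    perm        TEXT,
    sd_data     TEXT NOT NULL DEFAULT '{{}}',
    UNIQUE (source_id, entry_index)
);
CREATE INDEX idx_instance_mol ON instance(mol_key);

CREATE TABLE molset (
    set_id INTEGER PRIMARY KEY,
    name   TEXT NOT NULL UNIQUE
);

CREATE TABLE molset_member (
    set_id  INTEGER NOT NULL REFERENCES molset(set_id) ON DELETE CASCADE,
    mol_key INTEGER NOT NULL REFERENCES molecule(mol_key),
    PRIMARY KEY (set_id, mol_key)
) WITHOUT ROWID;
"""

# Range filters on any property column should hit an index.
_PROPERTY_INDEX_SQL = "\n".join(
    f"CREATE INDEX idx_molecule_{p} ON molecule({p});" for p in PROPERTY_NAMES
)


@dataclass(frozen=True)
class MoleculeSet:
    """Handle to a persisted, named set of pair-wise distinct molecules."""

    set_id: int
    name: str


@dataclass(frozen=True)
class SourceRecord:
    source_id: int
    path: str
    format: str
    policy: NormalizationPolicy
    n_entries: int
    n_rejected: int
    rank: int


class Store:
    """Single-file molecule database; one writer, any number of readers."""

    def __init__(self, path: str | Path):
        self.path = str(path)
        existed = Path(path).exists() and Path(path).stat().st_size > 0
        self.db = sqlite3.connect(self.path)
        self.db.execute("PRAGMA foreign_keys = ON")
        if existed:
            self._check_schema()
        else:
            with self.db:
                self.db.executescript(_SCHEMA + _PROPERTY_INDEX_SQL)
                self.db.execute(
                    "INSERT INTO meta VALUES ('schema_version', ?)",
                    (str(SCHEMA_VERSION),),
                )

    def _check_schema(self) -> None:
        try:
            row = self.db.execute(
                "SELECT value FROM meta WHERE key = 'schema_version'"
            ).fetchone()
        except sqlite3.DatabaseError as exc:
            self.db.close()
            raise SchemaError(
                f"{self.path!r} is not a molvault database: {exc}"
            ) from exc
        if row is None or int(row[0]) != SCHEMA_VERSION:
            found = row[0] if row else "absent"
            self.db.close()
            raise SchemaError(
                f"schema version {found} in {self.path!r}, expected "
                f"{SCHEMA_VERSION}; re-import into a fresh database to migrate"
            )

    def close(self) -> None:
        self.db.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # ------------------------------------------------------------------ #
    # sources

    def add_source(self, path: str, format: str,
                   policy: NormalizationPolicy) -> int:
        with self.db:
            rank = self.db.execute("SELECT COUNT(*) FROM source").fetchone()[0] + 1
            cur = self.db.execute(
                "INSERT INTO source (path, format, policy, rank) VALUES (?,?,?,?)",
                (path, format, json.dumps(policy.to_dict()), rank),
            )
        return cur.lastrowid

    def update_source_counts(self, source_id: int, n_entries: int,
                             n_rejected: int) -> None:
        with self.db:
            self.db.execute(
                "UPDATE source SET n_entries = ?, n_rejected = ? WHERE source_id = ?",
                (n_entries, n_rejected, source_id),
            )

    def get_source(self, source_id: int) -> SourceRecord:
        row = self.db.execute(
            "SELECT source_id, path, format, policy, n_entries, n_rejected, rank"
            " FROM source WHERE source_id = ?", (source_id,)
        ).fetchone()
        if row is None:
            raise NotFound(f"no source with id {source_id}")
        return SourceRecord(row[0], row[1], row[2],
                            NormalizationPolicy.from_dict(json.loads(row[3])),
                            row[4], row[5], row[6])

    def list_sources(self) -> list[SourceRecord]:
        ids = [r[0] for r in self.db.execute(
            "SELECT source_id FROM source ORDER BY rank")]
        return [self.get_source(i) for i in ids]

    # ------------------------------------------------------------------ #
    # registration

    def register(self, raw: RawStructure, policy: NormalizationPolicy,
                 source_id: int, entry_index: int) -> tuple[int, int, bool]:
        """Run the import pipeline on one entry and persist it.

        Pipeline: largest component → normalization policy → MolString →
        molecule lookup-or-insert (descriptors computed only on insert) →
        instance insert.  Returns (mol_key, inst_key, newly_created).
        """
        processed = chem.keep_largest_component(raw)
        processed = chem.normalize(processed, policy)
        molstring = chem.make_molstring(processed)

        row = self.db.execute(
            "SELECT mol_key FROM molecule WHERE molstring = ?", (molstring,)
        ).fetchone()
        newly_created = row is None
        with self.db:
            if newly_created:
                props = chem.compute_properties(molstring)
                ebits = chem.compute_element_bits(molstring)
                gbits = chem.compute_group_bits(molstring)
                cur = self.db.execute(
                    "INSERT INTO molecule (molstring, " + ",".join(PROPERTY_NAMES)
                    + ", element_bits, group_bits) VALUES (?"
                    + ",?" * (len(PROPERTY_NAMES) + 2) + ")",
                    (molstring, *[getattr(props, p) for p in PROPERTY_NAMES],
                     chem.bits_to_blob(ebits, ELEMENT_BLOB_LEN),
                     chem.bits_to_blob(gbits, GROUP_BLOB_LEN)),
                )
                mol_key = cur.lastrowid
            else:
                mol_key = row[0]

            coords_json = perm_json = None
            is3d = 0
            coords = processed.coords()
            if coords is not None:
                order = chem.canonical_atom_order(processed)
                coords_json = json.dumps(
                    [[round(c, 6) for c in coords[i]] for i in order])
                perm_json = json.dumps(order)
                is3d = int(processed.is_3d())
            cur = self.db.execute(
                "INSERT INTO instance (mol_key, source_id, entry_index, name,"
                " coords, is3d, perm, sd_data) VALUES (?,?,?,?,?,?,?,?)",
                (mol_key, source_id, entry_index, processed.name,
                 coords_json, is3d, perm_json,
                 json.dumps(list(processed.data_fields.items()))),
            )
        return mol_key, cur.lastrowid, newly_created

    # ------------------------------------------------------------------ #
    # restore

    def molstring(self, mol_key: int) -> str:
        row = self.db.execute(
            "SELECT molstring FROM molecule WHERE mol_key = ?", (mol_key,)
        ).fetchone()
        if row is None:
            raise NotFound(f"no molecule with key {mol_key}")
        return row[0]

    def restore_molecule(self, mol_key: int) -> RawStructure:
        """Rebuild the bare topology for a molecule key."""
        return chem.rebuild(self.molstring(mol_key))

    def restore_instance(self, inst_key: int) -> RawStructure:
        """Rebuild one file entry: topology + name, coordinates in the
        original atom order, and SD data verbatim."""
        row = self.db.execute(
            "SELECT mol_key, name, coords, is3d, perm, sd_data"
            " FROM instance WHERE inst_key = ?", (inst_key,)
        ).fetchone()
        if row is None:
            raise NotFound(f"no instance with key {inst_key}")
        mol_key, name, coords_json, is3d, perm_json, sd_json = row
        mol = Chem.MolFromSmiles(self.molstring(mol_key))
        if coords_json is not None:
            canon_coords = json.loads(coords_json)
            order = json.loads(perm_json)
            inv = [0] * len(order)
            for j, i in enumerate(order):
                inv[i] = j
            conf = Chem.Conformer(mol.GetNumAtoms())
            for j, (x, y, z) in enumerate(canon_coords):
                conf.SetAtomPosition(j, Point3D(x, y, z))
            conf.Set3D(bool(is3d))
            mol.AddConformer(conf, assignId=True)
            mol = Chem.RenumberAtoms(mol, inv)
        return RawStructure(mol=mol, name=name,
                            data_fields=dict(json.loads(sd_json)))

    def instance_info(self, inst_key: int) -> dict:
        row = self.db.execute(
            "SELECT inst_key, mol_key, source_id, entry_index, name, sd_data"
            " FROM instance WHERE inst_key = ?", (inst_key,)
        ).fetchone()
        if row is None:
            raise NotFound(f"no instance with key {inst_key}")
        keys = ("inst_key", "mol_key", "source_id", "entry_index", "name", "sd_data")
        d = dict(zip(keys, row))
        d["sd_data"] = dict(json.loads(d["sd_data"]))
        return d

    def instances_of(self, mol_key: int,
                     source_ids: list[int] | None = None) -> list[int]:
        """Instance keys for a molecule, optionally restricted to sources."""
        if source_ids:
            q = ("SELECT inst_key FROM instance WHERE mol_key = ? AND source_id IN ("
                 + ",".join("?" * len(source_ids)) + ") ORDER BY inst_key")
            rows = self.db.execute(q, (mol_key, *source_ids)).fetchall()
        else:
            rows = self.db.execute(
                "SELECT inst_key FROM instance WHERE mol_key = ? ORDER BY inst_key",
                (mol_key,)).fetchall()
        return [r[0] for r in rows]

    def first_instance(self, mol_key: int,
                       source_priority: list[int] | None = None) -> int | None:
        """Lowest instance key from the highest-priority source holding one."""
        if source_priority:
            for sid in source_priority:
                row = self.db.execute(
                    "SELECT MIN(inst_key) FROM instance"
                    " WHERE mol_key = ? AND source_id = ?", (mol_key, sid)
                ).fetchone()
                if row[0] is not None:
                    return row[0]
            return None
        row = self.db.execute(
            "SELECT MIN(inst_key) FROM instance WHERE mol_key = ?", (mol_key,)
        ).fetchone()
        return row[0]

    # ------------------------------------------------------------------ #
    # molecule data access

    def n_molecules(self) -> int:
        return self.db.execute("SELECT COUNT(*) FROM molecule").fetchone()[0]

    def n_instances(self) -> int:
        return self.db.execute("SELECT COUNT(*) FROM instance").fetchone()[0]

    def properties(self, mol_key: int) -> PropertyVector:
        row = self.db.execute(
            "SELECT " + ",".join(PROPERTY_NAMES) + " FROM molecule WHERE mol_key = ?",
            (mol_key,)).fetchone()
        if row is None:
            raise NotFound(f"no molecule with key {mol_key}")
        return PropertyVector(*row)

    def bitfields(self, mol_key: int) -> tuple[int, int]:
        row = self.db.execute(
            "SELECT element_bits, group_bits FROM molecule WHERE mol_key = ?",
            (mol_key,)).fetchone()
        if row is None:
            raise NotFound(f"no molecule with key {mol_key}")
        return chem.blob_to_bits(row[0]), chem.blob_to_bits(row[1])

    def mol_key_of(self, molstring: str) -> int | None:
        row = self.db.execute(
            "SELECT mol_key FROM molecule WHERE molstring = ?", (molstring,)
        ).fetchone()
        return row[0] if row else None

    # ------------------------------------------------------------------ #
    # molecule sets

    def _unique_set_name(self, base: str) -> str:
        name, k = base, 2
        while self.db.execute(
                "SELECT 1 FROM molset WHERE name = ?", (name,)).fetchone():
            name = f"{base}_{k}"
            k += 1
        return name

    def create_set(self, name: str, members: list[int],
                   if_exists: str = "error") -> MoleculeSet:
        """Persist a named set; duplicate member keys collapse.

        ``if_exists``: 'error' raises on a name clash, 'rename' appends a
        numeric suffix.
        """
        if self.db.execute("SELECT 1 FROM molset WHERE name = ?", (name,)).fetchone():
            if if_exists == "rename":
                name = self._unique_set_name(name)
            else:
                raise NameClash(f"a set named {name!r} already exists")
        uniq = sorted(set(members))
        with self.db:
            cur = self.db.execute("INSERT INTO molset (name) VALUES (?)", (name,))
            set_id = cur.lastrowid
            try:
                self.db.executemany(
                    "INSERT INTO molset_member VALUES (?,?)",
                    ((set_id, k) for k in uniq))
            except sqlite3.IntegrityError as exc:
                raise NotFound(f"unknown molecule key among members: {exc}") from exc
        return MoleculeSet(set_id, name)

    def set_from_source(self, source_id: int,
                        name: str | None = None) -> MoleculeSet:
        """Set of all distinct molecules that have an instance in a source."""
        src = self.get_source(source_id)  # raises NotFound if absent
        keys = [r[0] for r in self.db.execute(
            "SELECT DISTINCT mol_key FROM instance WHERE source_id = ?",
            (source_id,))]
        base = name or f"source:{Path(src.path).name}"
        return self.create_set(self._unique_set_name(base), keys)

    def get_set(self, ref: int | str | MoleculeSet) -> MoleculeSet:
        if isinstance(ref, MoleculeSet):
            return ref
        if isinstance(ref, int):
            row = self.db.execute(
                "SELECT set_id, name FROM molset WHERE set_id = ?", (ref,)).fetchone()
        else:
            row = self.db.execute(
                "SELECT set_id, name FROM molset WHERE name = ?", (ref,)).fetchone()
        if row is None:
            raise NotFound(f"no molecule set {ref!r}")
        return MoleculeSet(*row)

    def list_sets(self) -> list[tuple[MoleculeSet, int]]:
        rows = self.db.execute(
            "SELECT m.set_id, m.name, COUNT(mm.mol_key) FROM molset m"
            " LEFT JOIN molset_member mm ON m.set_id = mm.set_id"
            " GROUP BY m.set_id ORDER BY m.set_id").fetchall()
        return [(MoleculeSet(r[0], r[1]), r[2]) for r in rows]

    def members(self, ref: int | str | MoleculeSet) -> list[int]:
        s = self.get_set(ref)
        return [r[0] for r in self.db.execute(
            "SELECT mol_key FROM molset_member WHERE set_id = ? ORDER BY mol_key",
            (s.set_id,))]

    def set_size(self, ref: int | str | MoleculeSet) -> int:
        s = self.get_set(ref)
        return self.db.execute(
            "SELECT COUNT(*) FROM molset_member WHERE set_id = ?",
            (s.set_id,)).fetchone()[0]

    def delete_set(self, ref: int | str | MoleculeSet) -> None:
        s = self.get_set(ref)
        with self.db:
            self.db.execute("DELETE FROM molset WHERE set_id = ?", (s.set_id,))


def open_store(path: str | Path) -> Store:
    """Open (or create) the single-file molecule database at ``path``."""
    return Store(path)
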