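"""Readers and writers for SMILES / SDF / MOL2 entry streams.

Reading yields every record with its 0-based index; records that fail
sanitization are yielded as rejections and never abort the stream.  SDF
data fields are parsed from the record text directly so that keys, order
and values survive the store byte-identically.

Export turns molecules back into instances.  Which instance supplies the
name, coordinates and SD data is controlled by an :class:`ExportPolicy`:
``first_instance`` writes one record per molecule from the
highest-priority source holding one; ``all_instances`` writes one record
per qualifying instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDepictor

from .chem import PROPERTY_NAMES, NormalizationPolicy, RawStructure
from .errors import EntryRejected, MolvaultError
from .store import MoleculeSet, Store

log = logging.getLogger(__name__)

FORMATS = ("smiles", "sdf", "mol2")

Entry = "tuple[int, RawStructure | EntryRejected]"


def read_entries(path, format: str) -> Iterator[tuple[int, RawStructure | EntryRejected]]:
    """Stream (entry_index, structure-or-rejection) pairs from a file."""
    if format == "smiles":
        yield from _read_smiles(path)
    elif format == "sdf":
        yield from _read_sdf(path)
    elif format == "mol2":
        yield from _read_mol2(path)
    else:
        raise MolvaultError(f"unknown format {format!r}; choose from {FORMATS}")


def _read_smiles(path) -> Iterator:
    # dialect: "SMILES [name...]" per line, '#' comments and blanks skipped
    idx = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            name = parts[1].strip() if len(parts) > 1 else ""
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                yield idx, EntryRejected("unparseable SMILES: " + smi,
                                         entry_index=idx, source=str(path))
            else:
                yield idx, RawStructure(mol=mol, name=name)
            idx += 1


def _split_sdf_records(path) -> Iterator[list[str]]:
    record: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.rstrip("\r\n") == "$$$$":
                yield record
                record = []
            else:
                record.append(line.rstrip("\r\n"))
    if any(l.strip() for l in record):
        yield record  # trailing record without $$$$


def _parse_sd_fields(lines: list[str]) -> dict[str, str]:
    fields: dict[str, str] = {}
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            lo, hi = line.find("<"), line.rfind(">")
            key = line[lo + 1:hi] if 0 <= lo < hi else line[1:].strip()
            i += 1
            value_lines = []
            while i < len(lines) and lines[i].strip() != "":
                value_lines.append(lines[i])
                i += 1
            fields[key] = "\n".join(value_lines)
        i += 1
    return fields


def _read_sdf(path) -> Iterator:
    for idx, lines in enumerate(_split_sdf_records(path)):
        try:
            end = next(i for i, l in enumerate(lines) if l.startswith("M  END"))
        except StopIteration:
            yield idx, EntryRejected("no 'M  END' in record",
                                     entry_index=idx, source=str(path))
            continue
        molblock = "\n".join(lines[: end + 1]) + "\n"
        mol = Chem.MolFromMolBlock(molblock)
        if mol is None:
            yield idx, EntryRejected("unparseable/unsanitizable molblock",
                                     entry_index=idx, source=str(path))
            continue
        name = lines[0].strip() if lines else ""
        yield idx, RawStructure(mol=mol, name=name,
                                data_fields=_parse_sd_fields(lines[end + 1:]))


def _read_mol2(path) -> Iterator:
    text = Path(path).read_text(encoding="utf-8")
    blocks = text.split("@<TRIPOS>MOLECULE")
    idx = 0
    for block in blocks[1:]:
        full = "@<TRIPOS>MOLECULE" + block
        mol = Chem.MolFromMol2Block(full)
        if mol is None:
            yield idx, EntryRejected("unparseable MOL2 block",
                                     entry_index=idx, source=str(path))
        else:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            yield idx, RawStructure(mol=mol, name=name)
        idx += 1


# --------------------------------------------------------------------- #
# import orchestration

@dataclass
class ImportReport:
    source_id: int
    n_entries: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    n_new_molecules: int = 0
    rejections: list[str] = field(default_factory=list)


def import_file(store: Store, path, format: str,
                policy: NormalizationPolicy | None = None,
                progress=None) -> ImportReport:
    """Register every entry of a file as a new source; bad records are
    logged and skipped, never fatal."""
    policy = policy or NormalizationPolicy()
    source_id = store.add_source(str(path), format, policy)
    report = ImportReport(source_id=source_id)
    for idx, item in read_entries(path, format):
        report.n_entries += 1
        if isinstance(item, EntryRejected):
            report.n_rejected += 1
            report.rejections.append(str(item))
            log.warning("%s", item)
            continue
        try:
            _, _, new = store.register(item, policy, source_id, idx)
        except EntryRejected as exc:
            report.n_rejected += 1
            report.rejections.append(str(exc))
            log.warning("entry %d of %s: %s", idx, path, exc)
            continue
        report.n_accepted += 1
        report.n_new_molecules += bool(new)
        if progress is not None:
            progress(report.n_entries)
    store.update_source_counts(source_id, report.n_entries, report.n_rejected)
    return report


# --------------------------------------------------------------------- #
# export

@dataclass(frozen=True)
class ExportPolicy:
    """Instance-selection rule for export.

    ``first_instance``: one record per molecule, from the highest-priority
    source that has one (ties → lowest instance key).  ``all_instances``:
    one record per instance in the listed sources (empty list = all).
    """

    mode: str = "first_instance"
    source_priority: tuple[int, ...] = ()

    def __post_init__(self):
        if self.mode not in ("first_instance", "all_instances"):
            raise MolvaultError(f"unknown export mode {self.mode!r}")


@dataclass
class ExportReport:
    n_molecules: int = 0
    n_records: int = 0
    skipped: list[int] = field(default_factory=list)  # mol_keys w/o instance


def _select_instances(store: Store, mol_key: int,
                      policy: ExportPolicy) -> list[int]:
    if policy.mode == "first_instance":
        inst = store.first_instance(mol_key, list(policy.source_priority))
        return [inst] if inst is not None else []
    return store.instances_of(mol_key, list(policy.source_priority))


def _sdf_record(store: Store, inst_key: int) -> str:
    raw = store.restore_instance(inst_key)
    mol = raw.mol
    synthetic_coords = mol.GetNumConformers() == 0
    if synthetic_coords:
        rdDepictor.Compute2DCoords(mol)
    mol.SetProp("_Name", raw.name)
    block = Chem.MolToMolBlock(mol)
    lines = block.split("\n")
    if synthetic_coords:
        lines[2] = "generated 2D coordinates (no stored conformer)"
    out = "\n".join(lines)
    for key, value in raw.data_fields.items():
        out += f">  <{key}>\n{value}\n\n"
    return out + "$$$$\n"


def export_set(store: Store, s, path, format: str,
               policy: ExportPolicy | None = None) -> ExportReport:
    """Write a molecule set to a SMILES or SDF file, reconstituting names,
    coordinates and SD data from the chosen instances."""
    policy = policy or ExportPolicy()
    if format not in ("smiles", "sdf"):
        raise MolvaultError(f"export format must be smiles|sdf, got {format!r}")
    src = store.get_set(s)
    report = ExportReport()
    with open(path, "w", encoding="utf-8") as fh:
        for mol_key in store.members(src):
            insts = _select_instances(store, mol_key, policy)
            if not insts:
                report.skipped.append(mol_key)
                continue
            report.n_molecules += 1
            for inst_key in insts:
                if format == "smiles":
                    info = store.instance_info(inst_key)
                    ms = store.molstring(mol_key)
                    name = info["name"]
                    fh.write(f"{ms} {name}\n" if name else f"{ms}\n")
                else:
                    fh.write(_sdf_record(store, inst_key))
                report.n_records += 1
    if report.skipped:
        log.warning("export skipped %d molecules with no instance in the"
                    " permitted sources", len(report.skipped))
    return report


# --------------------------------------------------------------------- #
# histograms

@dataclass
class HistogramTable:
    property: str
    edges: list[float]
    counts: dict[str, list[int]]  # set name → per-bin counts

    def to_csv(self, path) -> None:
        names = list(self.counts)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("bin_low,bin_high," + ",".join(names) + "\n")
            for i in range(len(self.edges) - 1):
                row = [f"{self.edges[i]:g}", f"{self.edges[i + 1]:g}"]
                row += [str(self.counts[n][i]) for n in names]
                fh.write(",".join(row) + "\n")


def histogram(store: Store, sets, prop: str,
              bins: int | list[float] = 10) -> HistogramTable:
    """Per-set bin counts for one property over shared edges spanning the
    pooled value range; per-set counts sum to the set size."""
    if prop not in PROPERTY_NAMES:
        raise MolvaultError(f"unknown property {prop!r}")
    resolved = [store.get_set(s) for s in sets]
    values = {}
    for s in resolved:
        rows = store.db.execute(
            f"SELECT m.{prop} FROM molset_member mm"
            " JOIN molecule m ON m.mol_key = mm.mol_key"
            " WHERE mm.set_id = ?", (s.set_id,)).fetchall()
        values[s.name] = np.array([r[0] for r in rows], dtype=float)
    pooled = np.concatenate(list(values.values())) if values else np.array([])
    if pooled.size == 0:
        raise MolvaultError("nothing to bin: all input sets are empty")
    if isinstance(bins, int):
        lo, hi = float(pooled.min()), float(pooled.max())
        if lo == hi:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts = {name: np.histogram(v, bins=edges)[0].tolist()
              for name, v in values.items()}
    return HistogramTable(property=prop, edges=edges.tolist(), counts=counts)
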