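"""Canonical molecular identity, normalization and per-molecule descriptors.

A *molecule* in this package is a unique chemical topology.  Identity is
decided by the MolString: the canonical isomeric SMILES of the structure
after the import policy (largest component, optional neutralization,
tautomer canonicalization and stereo stripping) has been applied.  Two file
entries map to the same molecule exactly when their MolStrings are equal.

Everything derived from a molecule — the ten-field property vector, the
element bitfield and the functional-group bitfield — is a pure function of
the MolString, which is what makes it safe to precompute at registration
time and reuse from the store.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import EntryRejected, SmartsError

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rejections are reported through our own channel

N_ELEMENT_BITS = 128
ELEMENT_BLOB_LEN = N_ELEMENT_BITS // 8


@dataclass(frozen=True)
class NormalizationPolicy:
    """Which optional unification steps to apply at import time.

    All flags independent; the all-false default registers entries by their
    plain topology (after largest-component selection, which is always on).
    """

    neutralize: bool = False
    canonical_tautomer: bool = False
    strip_stereo: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationPolicy":
        return cls(**{k: bool(d.get(k, False)) for k in
                      ("neutralize", "canonical_tautomer", "strip_stereo")})


@dataclass
class RawStructure:
    """One file entry at the toolkit level: connection table + metadata.

    Coordinates, when present, live in the RDKit conformer of ``mol``.
    ``data_fields`` preserves SDF data items verbatim and in file order.
    """

    mol: Chem.Mol
    name: str = ""
    data_fields: dict[str, str] = field(default_factory=dict)

    @property
    def num_heavy_atoms(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() != 1)

    def coords(self) -> list[tuple[float, float, float]] | None:
        if self.mol.GetNumConformers() == 0:
            return None
        conf = self.mol.GetConformer()
        return [tuple(conf.GetAtomPosition(i)) for i in range(self.mol.GetNumAtoms())]

    def is_3d(self) -> bool:
        return self.mol.GetNumConformers() > 0 and self.mol.GetConformer().Is3D()


@dataclass(frozen=True)
class PropertyVector:
    """Precomputed physico-chemical descriptors, one vector per molecule.

    mw is in g/mol, tpsa in Å²; logp is the Crippen estimate; the remaining
    fields are topological counts.
    """

    mw: float
    heavy_atoms: int
    ring_count: int
    aromatic_ring_count: int
    rotatable_bonds: int
    hbd: int
    hba: int
    tpsa: float
    logp: float
    net_charge: int

    def as_dict(self) -> dict:
        return asdict(self)


PROPERTY_NAMES: tuple[str, ...] = (
    "mw", "heavy_atoms", "ring_count", "aromatic_ring_count",
    "rotatable_bonds", "hbd", "hba", "tpsa", "logp", "net_charge",
)

# Functional-group catalog: fixed order defines bit positions.  The group
# list is this package's own selection of common medicinal-chemistry motifs;
# bit i of a molecule's group bitfield is set iff SMARTS i matches.
GROUP_CATALOG: tuple[tuple[str, str], ...] = (
    ("carboxylic_acid", "[CX3](=O)[OX2H1,OX1-]"),
    ("ester", "[CX3](=O)[OX2H0][#6]"),
    ("amide", "[CX3](=O)[NX3]"),
    ("primary_amine", "[NX3H2;!$(NC=O);!$(N~[!#6])]"),
    ("secondary_amine", "[NX3H1;!$(NC=O);!$(N~[!#6])]([#6])[#6]"),
    ("tertiary_amine", "[NX3H0;!$(NC=O);!$(N~[!#6])]([#6])([#6])[#6]"),
    ("hydroxyl", "[OX2H][CX4]"),
    ("phenol", "[OX2H][c]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ether", "[OD2;!$(O=*)]([#6])[#6]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("nitro", "[NX3+](=O)[O-]"),
    ("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2H0]([#6])[#6]"),
    ("urea", "[NX3][CX3](=O)[NX3]"),
    ("guanidine", "[NX3][CX3](=[NX2,NX3+])[NX3]"),
    ("halogen_on_carbon", "[F,Cl,Br,I][#6]"),
    ("aromatic_ring", "[a]"),  # an aromatic atom implies an aromatic ring
)

GROUP_NAMES: tuple[str, ...] = tuple(name for name, _ in GROUP_CATALOG)
GROUP_BLOB_LEN = (len(GROUP_CATALOG) + 7) // 8


def _canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def keep_largest_component(raw: RawStructure) -> RawStructure:
    """Reduce a multi-component entry (salt, mixture) to its largest part.

    Size is heavy-atom count; ties go to the component whose canonical
    SMILES sorts first, so selection is deterministic.
    """
    if raw.mol is None or raw.mol.GetNumAtoms() == 0:
        raise EntryRejected("no atoms")
    frags = Chem.GetMolFrags(raw.mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return raw
    best = min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), _canonical_smiles(f)))
    return RawStructure(mol=best, name=raw.name, data_fields=dict(raw.data_fields))


_uncharger: rdMolStandardize.Uncharger | None = None
_tautomerizer: rdMolStandardize.TautomerEnumerator | None = None


def _get_uncharger() -> rdMolStandardize.Uncharger:
    global _uncharger
    if _uncharger is None:
        _uncharger = rdMolStandardize.Uncharger()
    return _uncharger


def _get_tautomerizer() -> rdMolStandardize.TautomerEnumerator:
    global _tautomerizer
    if _tautomerizer is None:
        _tautomerizer = rdMolStandardize.TautomerEnumerator()
        _tautomerizer.SetRemoveSp3Stereo(False)
        _tautomerizer.SetRemoveBondStereo(False)
    return _tautomerizer


def normalize(raw: RawStructure, policy: NormalizationPolicy) -> RawStructure:
    """Apply the enabled unification steps in fixed order.

    Order: neutralize → canonical tautomer → strip stereo.  Neutralization
    moves protons to cancel formal charges where chemically possible;
    permanently charged centers (e.g. quaternary N) are left alone.  A step
    that fails on an otherwise valid molecule falls back to its input and
    logs a warning, so one exotic structure cannot kill an import.
    """
    mol = raw.mol
    if policy.neutralize:
        try:
            mol = _get_uncharger().uncharge(mol)
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - backend-dependent
            log.warning("neutralization failed (%s); keeping charged form", exc)
            mol = raw.mol
    if policy.canonical_tautomer:
        try:
            mol = _get_tautomerizer().Canonicalize(mol)
        except Exception as exc:  # pragma: no cover
            log.warning("tautomer canonicalization failed (%s); keeping input form", exc)
    if policy.strip_stereo:
        mol = Chem.Mol(mol)
        Chem.RemoveStereochemistry(mol)
    if mol is not raw.mol:
        return RawStructure(mol=mol, name=raw.name, data_fields=dict(raw.data_fields))
    return raw


def make_molstring(raw: RawStructure) -> str:
    """Canonical isomeric SMILES of a sanitized, single-component structure.

    Deterministic and invariant under atom/bond reordering and input format,
    so it serves as both molecular identity and serialization form.
    """
    try:
        return Chem.MolToSmiles(raw.mol)
    except Exception as exc:
        raise EntryRejected(f"canonicalization failed: {exc}") from exc


def canonical_atom_order(raw: RawStructure) -> list[int]:
    """Positions of the input atoms in SMILES output order.

    ``order[j]`` is the input-atom index written at position j of the
    canonical SMILES; ``rebuild(make_molstring(raw))`` has its atom j equal
    to input atom ``order[j]``.  Used to store instance coordinates in
    canonical order while retaining the permutation back.
    """
    mol = Chem.Mol(raw.mol)
    Chem.MolToSmiles(mol)
    import ast
    return list(ast.literal_eval(mol.GetProp("_smilesAtomOutputOrder")))


def rebuild(molstring: str) -> RawStructure:
    """Reconstruct a molecule from its MolString (round-trip fixed point)."""
    mol = Chem.MolFromSmiles(molstring)
    if mol is None:
        raise EntryRejected(f"corrupt MolString: {molstring!r}")
    return RawStructure(mol=mol)


# Rebuilt molecules are cached because SMARTS filtering rebuilds every
# member of a set; identity of the cache key (the MolString) guarantees
# purity.
_REBUILD_CACHE: dict[str, Chem.Mol] = {}
_REBUILD_CACHE_MAX = 200_000


def rebuild_cached(molstring: str) -> Chem.Mol:
    mol = _REBUILD_CACHE.get(molstring)
    if mol is None:
        mol = rebuild(molstring).mol
        if len(_REBUILD_CACHE) >= _REBUILD_CACHE_MAX:
            _REBUILD_CACHE.clear()
        _REBUILD_CACHE[molstring] = mol
    return mol


def clear_caches() -> None:
    """Drop the rebuild cache (useful for unbiased timing measurements)."""
    _REBUILD_CACHE.clear()


def compute_properties(molstring: str) -> PropertyVector:
    mol = rebuild_cached(molstring)
    ri = mol.GetRingInfo()
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        ring_count=ri.NumRings(),
        aromatic_ring_count=rdMolDescriptors.CalcNumAromaticRings(mol),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        logp=Crippen.MolLogP(mol),
        net_charge=Chem.GetFormalCharge(mol),
    )


def compute_element_bits(molstring: str) -> int:
    """128-bit field, bit i set iff an atom of atomic number i is present.

    Implicit hydrogens set no bit: the element filter's purpose is excluding
    compound classes (halogenated, organometallic ...), and implicit H would
    match everything.  Explicit hydrogen atoms (isotopic/charged) do count.
    """
    mol = rebuild_cached(molstring)
    bits = 0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if 0 < z < N_ELEMENT_BITS:
            bits |= 1 << z
    return bits


_COMPILED_CATALOG: list[Chem.Mol] | None = None


def compiled_catalog() -> list[Chem.Mol]:
    """The shipped group catalog compiled once; bad SMARTS fail at startup."""
    global _COMPILED_CATALOG
    if _COMPILED_CATALOG is None:
        compiled = []
        for name, smarts in GROUP_CATALOG:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:  # pragma: no cover - catalog is fixed
                raise SmartsError(smarts)
            compiled.append(patt)
        _COMPILED_CATALOG = compiled
    return _COMPILED_CATALOG


def compute_group_bits(molstring: str) -> int:
    """Bit i set iff catalog group i has a substructure match."""
    mol = rebuild_cached(molstring)
    bits = 0
    for i, patt in enumerate(compiled_catalog()):
        if mol.HasSubstructMatch(patt):
            bits |= 1 << i
    return bits


def compile_smarts(pattern: str) -> Chem.Mol:
    """Parse a SMARTS pattern, raising SmartsError with a best-effort
    character position when it is malformed."""
    patt = Chem.MolFromSmarts(pattern)
    if patt is not None:
        return patt
    raise SmartsError(pattern, position=_locate_smarts_error(pattern))


def _locate_smarts_error(pattern: str) -> int | None:
    # Find the first prefix with balanced brackets that itself fails to
    # parse; RDKit does not expose the parser's own error offset.
    depth = 0
    for i, ch in enumerate(pattern):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                return i
        elif depth == 0 and ch not in "()%0123456789":
            prefix = pattern[: i + 1]
            if prefix.count("(") == prefix.count(")"):
                if Chem.MolFromSmarts(prefix) is None:
                    return i
    return None


def match_smarts(molstring: str, pattern: str | Chem.Mol) -> bool:
    """True iff at least one substructure embedding of ``pattern`` exists."""
    patt = compile_smarts(pattern) if isinstance(pattern, str) else pattern
    return rebuild_cached(molstring).HasSubstructMatch(patt)


def bits_to_blob(bits: int, length: int) -> bytes:
    return bits.to_bytes(length, "little")


def blob_to_bits(blob: bytes) -> int:
    return int.from_bytes(blob, "little")
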