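"""Deterministic synthetic molecule corpora with exact ground truth.

Molecules are assembled from a fragment grammar — ring scaffolds decorated
with common substituents — so every generated structure is sanitizable by
construction, no retry-on-invalid loop is needed, and the number of
distinct topologies in a corpus is known exactly.  A corpus is a stream of
entries, each referencing a topology id; an entry can be

* a *novel* topology (never seen before in the corpus),
* a *duplicate*: an earlier topology re-written in a randomized SMILES
  notation (different atom order / notation, identical topology), or
* a *salt form*: the entry with a small counter-ion component appended
  (the import pipeline keeps the largest component, so it registers as
  the same molecule).

The same entry stream is written both as a SMILES file and as an SDF file
(with 2D coordinates and vendor-style SD data fields), plus a ground-truth
table mapping entry index → topology id.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import rdDepictor

from .errors import MolvaultError

SCAFFOLDS = (
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "C1CCCCC1", "C1CCCC1",
    "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "C1CCNCC1", "C1CCOCC1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccc2ncccc2c1", "C1CCC2CCCCC2C1",
)

# attachment atom is always atom 0 of the fragment
SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "[N+](=O)[O-]", "C(=O)O", "C(=O)OC",
    "C(=O)N", "C(=O)C", "C=O", "S", "SC", "C(F)(F)F", "S(=O)(=O)N",
    "c1ccccc1", "NC(=O)C", "OC(=O)C",
)

COUNTER_IONS = ("[Na+]", "[K+]", "[Cl-]", "[Br-]", "O")


@dataclass(frozen=True)
class FixtureSpec:
    """Corpus recipe: entry count, duplicate/salt fractions, RNG seed."""

    n_molecules: int
    duplicate_rate: float = 0.0
    salt_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.duplicate_rate <= 1 and 0 <= self.salt_rate <= 1):
            raise MolvaultError("rates must lie in [0, 1]")
        if self.n_molecules < 1:
            raise MolvaultError("n_molecules must be >= 1")


@dataclass
class CorpusEntry:
    index: int
    smiles: str          # as written to the files (salt component included)
    name: str
    topo_id: int
    is_duplicate: bool
    is_salt: bool


@dataclass
class Corpus:
    spec: FixtureSpec
    entries: list[CorpusEntry]
    topologies: list[str]  # canonical SMILES, index = topo_id
    smiles_path: Path | None = None
    sdf_path: Path | None = None
    truth_path: Path | None = None

    @property
    def n_distinct(self) -> int:
        return len({e.topo_id for e in self.entries})


def _attach(base: Chem.Mol, sub_smiles: str, rng: random.Random) -> Chem.Mol | None:
    """Bond atom 0 of the substituent to a random H-bearing base atom."""
    sub = Chem.MolFromSmiles(sub_smiles)
    sites = [a.GetIdx() for a in base.GetAtoms() if a.GetTotalNumHs() > 0]
    if not sites:
        return None
    site = rng.choice(sites)
    combined = Chem.RWMol(Chem.CombineMols(base, sub))
    combined.AddBond(site, base.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _random_topology(rng: random.Random) -> str:
    """One sanitizable molecule from the fragment grammar, as canonical
    SMILES.  Decoration failures (no free valence, aromaticity clash) just
    redraw the substituent; the scaffold itself is always valid."""
    mol = Chem.MolFromSmiles(rng.choice(SCAFFOLDS))
    for _ in range(rng.randint(0, 3)):
        attempt = _attach(mol, rng.choice(SUBSTITUENTS), rng)
        if attempt is not None:
            mol = attempt
    return Chem.MolToSmiles(mol)


def _alternate_notation(canonical: str, rng: random.Random) -> str:
    """A randomized, non-canonical SMILES of the same topology."""
    mol = Chem.MolFromSmiles(canonical)
    variants = Chem.MolToRandomSmilesVect(mol, 1, rng.randrange(2 ** 31))
    return variants[0]


def generate_corpus(spec: FixtureSpec, out_dir: str | Path | None = None) -> Corpus:
    """Build a corpus; with ``out_dir`` the SMILES/SDF/ground-truth files
    are written (corpus.smi, corpus.sdf, truth.tsv)."""
    rng = random.Random(spec.seed)
    topologies: list[str] = []
    seen: set[str] = set()
    entries: list[CorpusEntry] = []

    for idx in range(spec.n_molecules):
        is_dup = bool(topologies) and rng.random() < spec.duplicate_rate
        if is_dup:
            topo_id = rng.randrange(len(topologies))
            smi = _alternate_notation(topologies[topo_id], rng)
        else:
            cand = _random_topology(rng)
            for _ in range(200):
                if cand not in seen:
                    break
                cand = _random_topology(rng)
            else:  # pragma: no cover - grammar space ≫ corpus sizes used
                raise MolvaultError("fragment grammar exhausted")
            seen.add(cand)
            topologies.append(cand)
            topo_id = len(topologies) - 1
            smi = cand
        is_salt = rng.random() < spec.salt_rate
        if is_salt:
            smi = smi + "." + rng.choice(COUNTER_IONS)
        entries.append(CorpusEntry(index=idx, smiles=smi,
                                   name=f"M{topo_id:05d}_{idx}",
                                   topo_id=topo_id,
                                   is_duplicate=is_dup, is_salt=is_salt))

    corpus = Corpus(spec=spec, entries=entries, topologies=topologies)
    if out_dir is not None:
        write_corpus(corpus, out_dir, rng)
    return corpus


def write_corpus(corpus: Corpus, out_dir: str | Path,
                 rng: random.Random | None = None) -> None:
    rng = rng or random.Random(corpus.spec.seed + 1)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus.smiles_path = out / "corpus.smi"
    corpus.sdf_path = out / "corpus.sdf"
    corpus.truth_path = out / "truth.tsv"

    with open(corpus.smiles_path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic corpus seed=%d\n" % corpus.spec.seed)
        for e in corpus.entries:
            fh.write(f"{e.smiles} {e.name}\n")

    with open(corpus.sdf_path, "w", encoding="utf-8") as fh:
        for e in corpus.entries:
            fh.write(_sdf_record(e, rng))

    with open(corpus.truth_path, "w", encoding="utf-8") as fh:
        fh.write("entry_index\ttopo_id\tis_duplicate\tis_salt\n")
        for e in corpus.entries:
            fh.write(f"{e.index}\t{e.topo_id}\t{int(e.is_duplicate)}"
                     f"\t{int(e.is_salt)}\n")


def _sdf_record(e: CorpusEntry, rng: random.Random) -> str:
    mol = Chem.MolFromSmiles(e.smiles)
    rdDepictor.Compute2DCoords(mol)
    mol.SetProp("_Name", e.name)
    block = Chem.MolToMolBlock(mol)
    fields = {
        "price": f"{rng.uniform(5, 500):.2f}",
        "order number": f"ORD-{e.index:06d}",
        "topology": str(e.topo_id),
    }
    for key, value in fields.items():
        block += f">  <{key}>\n{value}\n\n"
    return block + "$$$$\n"
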