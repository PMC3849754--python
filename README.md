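# molvault

An engine for interactive-style curation of small-molecule collections:
deduplicating registration of chemical structures into an embedded SQLite
store, exact set algebra over named molecule sets, and tolerant (m-of-n)
filter chains — with full round-trip to standard chemical file formats.

## The problem

Compiling and preparing compound datasets is the routine substrate of
cheminformatics: merging vendor catalogs, removing duplicates, filtering
screening libraries by physico-chemical criteria, and comparing compound
collections against reference sets. The recurring difficulty is molecular
*identity*: the same compound appears across files with different atom
orders, notations, coordinates and metadata. molvault separates the two
concepts cleanly:

- a **molecule** is a unique chemical topology, identified by its
  *MolString* — the canonical isomeric SMILES of the structure after the
  import policy has been applied;
- an **instance** is one file entry (name, coordinates, SDF data fields)
  assigned to a molecule; duplicates are detected automatically at import
  time and stored as additional instances.

All operations — set union/intersection/difference/symmetric difference,
splitting, filtering, histograms — act on molecule sets (lists of molecule
keys in the database), while export converts molecules back into instances
so that original names, 3D coordinates and vendor data (prices, order
numbers) are reproduced exactly.

## Core machinery

**Registration pipeline.** Each file entry passes through: largest-component
selection (salts/mixtures reduced to the main component) → optional
normalization (neutralize charges, canonical tautomer, strip
stereochemistry) → canonicalization to the MolString → lookup-or-insert in
the molecule table (unique index on the MolString) → instance insert. Ten
physico-chemical descriptors (MW, heavy atoms, rings, aromatic rings,
rotatable bonds, HBD, HBA, TPSA, Crippen logP, net charge), a 128-bit
element bitfield and a 20-group functional-group bitfield are precomputed
once per molecule and indexed.

**Filter chains.** Four elementary filter kinds — property range, chemical
element, functional group, SMARTS pattern (a pattern collection counts as
one disjunctive filter) — each with require/exclude polarity, combine into
a chain with tolerance *m*: a molecule passes if at least *m* of the *n*
filters match. *m = n* is plain conjunction; the Lipinski Rule-of-Five
preset (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10) with *m* = 3 expresses the
classical "at most one violation". Property/element/group verdicts come
from stored columns and bitfields; SMARTS verdicts rebuild molecules from
their MolStrings.

**Self-validation.** Three harnesses check the engine against independent
oracles: (1) every instance restored from the store must equal a fresh run
of the import pipeline on its file entry (valences, charges, coordinates
to 4 decimals, SD data byte-identical); (2) for random distributions of
molecules over three sets S₁,S₂,S₃,

  S₁ ∪ S₂ ∪ S₃ = (S₁ Δ S₂ Δ S₃) ∪ (S₁∩S₂∩S₃) ∪ (S₁∩S₂) ∪ (S₁∩S₃) ∪ (S₂∩S₃)

must hold and match brute-force enumeration; (3) database-backed filtering
must equal linear per-molecule re-evaluation from scratch.

## Worked example

A synthetic 2,000-entry catalog (30% duplicate entries, 10% salt forms)
is generated, imported, screened with the Rule-of-Five, and the borderline
compounds (exactly one violation) are isolated and inspected:

```console
$ molvault fixtures --n 2000 --dup-rate 0.3 --salt-rate 0.1 --seed 7 -o corpus/
entries=2000
distinct_topologies=1384

$ molvault import --db library.db --format sdf corpus/corpus.sdf
source_id=1
entries=2000
accepted=2000
rejected=0
new_molecules=1384
total_molecules=1384

$ molvault sets --db library.db --from-source 1 --name catalog
set=catalog size=1384

$ molvault filter --db library.db catalog --rule-of-five -o leadlike
set=leadlike size=1368 m=4 n=4

$ molvault filter --db library.db catalog --rule-of-five --tolerance 3 -o leadlike_1violation
set=leadlike_1violation size=1384 m=3 n=4

$ molvault setop --db library.db diff leadlike_1violation leadlike -o borderline
set=borderline size=16

$ molvault hist --db library.db leadlike borderline --property mw --bins 5
set=leadlike counts=150,475,501,201,41
set=borderline counts=0,0,2,5,9

$ molvault export --db library.db leadlike leadlike.sdf --mode all
molecules=1368
records=1981
```

Reading: the 2,000 file entries collapse to 1,384 unique topologies
(duplicate detection); 1,368 satisfy all four Rule-of-Five criteria, all
1,384 satisfy at least three, so 16 compounds carry exactly one violation —
concentrated, as the histogram shows, in the upper molecular-weight bins.
Exporting with `--mode all` writes every stored instance (1,981 records
for 1,368 molecules), reproducing names, coordinates and SD data fields.

Vendor-catalog comparison works the same way: import each catalog as its
own source, build one set per source, intersect to find compounds offered
by both vendors, and export all instances of the intersection with
`--sources vendorA,vendorB` to keep both vendors' price/order fields. For
reference-set checks (e.g. "are any decoys of one collection known actives
or known drugs elsewhere?") import both collections and intersect their
sets; any external SMILES/SDF/MOL2 files can be used.

## Schema

Single SQLite file (choose with `--db`): `molecule` (mol_key, unique
molstring, ten indexed property columns, element/group bitfield blobs),
`instance` (inst_key, mol_key, source_id, entry_index, name, coordinates in
canonical atom order plus the original-order permutation, SD data),
`source` (path, format, normalization policy, entry counts, import rank),
`molset`/`molset_member` (named sets as molecule-key lists), `meta`
(schema version).

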