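# Methods

## Molecular identity

The engine's central object is the *MolString*: the canonical isomeric
SMILES, as produced by RDKit, of a structure after the import policy has
been applied. Two file entries are instances of the same molecule exactly
when their MolStrings are equal. This delegates the definition of identity
to RDKit's canonicalization; it is deterministic, invariant under atom and
bond reordering and under the choice of input format, and losslessly
rebuildable at the topological level. Two consequences are worth stating
explicitly:

- identity is *topological*: conformers and 2D drawings of the same graph
  are one molecule with many instances;
- identity is *toolkit-relative*: a store written with one canonicalization
  algorithm cannot be compared string-for-string with output from another
  toolkit, only molecule-for-molecule through re-canonicalization.

## Import pipeline

Entries pass through a fixed order of steps:

1. **Largest component.** Multi-component records (salts, mixtures) are
   reduced to the component with the most heavy atoms; ties are broken by
   the lexicographically smallest canonical SMILES among the tied
   components so the choice is deterministic. Always applied.
2. **Neutralize** (optional): RDKit's Uncharger adds/removes protons to
   cancel formal charges where chemically possible; permanently charged
   centers such as quaternary nitrogen are left intact.
3. **Canonical tautomer** (optional): RDKit's TautomerEnumerator
   canonical form. Run after neutralization because tautomer scoring is
   better defined on the neutral species.
4. **Strip stereochemistry** (optional): all atom and bond stereo
   descriptors removed.
5. **Canonicalize** to the MolString.

A step that fails on an otherwise valid molecule falls back to its input
and logs a warning; an entry that fails sanitization is logged with source
and entry index and skipped — an import never aborts on one bad record.
The default policy applies no optional step, so plain topology (with
stereo, charges and tautomeric state intact) defines identity.

## Stored per-molecule data

A ten-field property vector is computed once, at first registration, and
each column is individually indexed so range filters compile to indexed
SQL:

| field | unit | computation |
|---|---|---|
| mw | g/mol | average-mass molecular weight |
| heavy_atoms | count | non-hydrogen atoms |
| ring_count | count | SSSR rings |
| aromatic_ring_count | count | aromatic SSSR rings |
| rotatable_bonds | count | strict rotatable-bond definition |
| hbd / hba | count | Lipinski-style donor/acceptor counts |
| tpsa | Å² | topological polar surface area |
| logp | — | Crippen atomic-contribution estimate |
| net_charge | e | sum of formal charges |

Two bitfields are precomputed as little-endian byte blobs: a 128-bit
element field (bit *i* set iff an atom of atomic number *i* occurs;
implicit hydrogens set no bit, since the element filter's purpose is
excluding compound *classes* and implicit H would match everything) and a
20-bit functional-group field over a fixed, ordered SMARTS catalog
(carboxylic acid, ester, amide, primary/secondary/tertiary amine,
hydroxyl, phenol, ketone, aldehyde, ether, nitrile, nitro, sulfonamide,
thiol, thioether, urea, guanidine, halogen-on-carbon, aromatic ring). The
catalog is this package's own selection of common medicinal-chemistry
motifs; the group bit is defined as "the catalog SMARTS matches", so the
SMARTS strings themselves are the specification. Bit tests run in the
application layer — SQL cannot index bitfield containment — which keeps
element/group filters cheaper than SMARTS but dearer than property
ranges.

## Instance fidelity

Instances preserve the entry name, SDF data fields (keys, order and values
verbatim, stored as JSON) and coordinates. Coordinates are stored in
canonical (MolString) atom order together with the original→canonical
permutation, so a restored instance presents its atoms — and an exported
SDF writes them — in the original order. Stored coordinates are rounded to
10⁻⁶; the round-trip harness compares at 10⁻⁴, comfortably inside SDF's
4-decimal print precision. Restoration is checked on valence states,
formal charges, hydrogen counts (atom-by-atom in order when coordinates
fix the order, as multisets otherwise), coordinates and SD data. Entries
whose source was a SMILES file have no conformer; exporting them to SDF
generates 2D coordinates on the fly and flags this in the molblock
comment line.

## Set operations

Sets are lists of distinct molecule keys; all algebra is executed as SQL
over the membership table. The n-ary symmetric difference uses
odd-membership semantics (the left fold of the binary Δ): a key belongs to
the result iff it occurs in an odd number of the input *references*.
References are counted with multiplicity (UNION ALL, not IN), so passing
the same set twice yields Δ(S,S) = ∅ as the fold semantics require.
Property splitting partitions a set into half-open intervals [bᵢ, bᵢ₊₁)
with open outer ends; chunk splitting cuts in ascending-key order. Result
sets are persisted under generated names ("op(a,b)", suffixed on
collision) and empty results are kept, so workflows can test emptiness.

## m-of-n filtering

A chain's verdict is computed by counting per-filter indicator verdicts
per molecule and comparing the count with m, rather than expanding the
C(n,m) conjunctive queries — identical semantics, simpler engineering.
Exclude polarity negates a filter's verdict *before* counting. Property
bounds are inclusive at both ends. When m = n, filters are evaluated
cheap-first (property/element/group before SMARTS) and molecules that
already failed are dropped, so SMARTS rebuilds only touch survivors; when
m < n every filter must be evaluated on every molecule. A SMARTS pattern
collection is one elementary filter that matches when any member pattern
hits; attaching each pattern as its own filter remains expressible.

## Synthetic corpora

The generator emulates the statistical structure that matters for this
engine — identity under renotation, salt stripping, duplicate detection,
SD-data fidelity — rather than chemical realism:

- molecules are assembled from a fragment grammar (14 ring scaffolds,
  up to three of 27 substituents attached at hydrogen-bearing sites), so
  every structure is sanitizable by construction and the distinct-topology
  count of a corpus is exact ground truth;
- duplicate entries re-express an earlier topology through RDKit's
  randomized SMILES writer (different atom order and notation, same
  graph);
- salt entries append one single-heavy-atom counter-ion (Na⁺, K⁺, Cl⁻,
  Br⁻ or water), strictly smaller than any scaffold, so
  largest-component selection is never ambiguous;
- the SDF rendering adds deterministic 2D coordinates and vendor-style SD
  fields (price, order number).

The reference corpus conditions used by the validation runs are 10,000
entries with duplicate rate 0.3 and salt rate 0.1. What the generator does
*not* emulate: stereocenters and stereo-duplicates, tautomer-rich systems,
macrocycles, organometallics, charged parent molecules, 3D conformers and
malformed vendor records. Passing validation therefore demonstrates the
engine's bookkeeping (identity, storage, algebra, filtering) on
well-behaved organic molecules; it does not certify the chemistry backend
on pathological valence models, which is the backend's own concern.

## Validation harnesses and problem sizes

- *Round trip*: every instance of a source is compared against re-running
  the import pipeline on the re-read file entry; run at 10,000 instances.
- *Set identity*: 100 random triples built by assigning each molecule to
  one of the 7 nonempty subsets of {S₁,S₂,S₃} with equal probability; the
  union/Δ decomposition is checked against brute-force enumeration.
- *Filter oracle*: 50 random chains (up to 5 filters of mixed kinds,
  random polarities, random m ≤ n; property bounds drawn from observed
  quantiles) over 5,000 molecules, compared with a linear scan that
  recomputes every verdict from the MolString, bypassing stored columns.
- *Scaling*: import and mixed property+SMARTS filter wall times measured
  over corpora of 10³–3.2×10⁴ entries (geometric steps); both fit a line
  with R² ≥ 0.95. The rebuild cache is cleared before each measurement so
  sizes are independent.

## Numerical and design choices

- Surrogate integer keys are assigned by insertion order; only uniqueness
  is load-bearing.
- Transactions wrap each registration and set mutation; the store follows
  a single-writer/multiple-reader contract.
- SMARTS parse errors report a best-effort character position found by
  prefix re-parsing, since the backend does not expose parser offsets.
- Histogram edges span the pooled min–max of all input sets (right edge
  inclusive in the last bin), so per-set counts always sum to set sizes.
- MOL2 is import-only; SMILES export writes the MolString plus the
  instance name and drops coordinates with a logged note.

## Known limitations

Cross-toolkit MolString equality is not promised (identity is
canonicalization-relative). Neutralization is limited to what proton
addition/removal can fix. Tautomer canonicalization picks one canonical
form; it does not enumerate or score alternatives. Schema migrations
across major versions are out of scope — a version mismatch is refused
with a re-import hint.
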