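# Methods

This note records the models, conventions and numerical choices behind
`structmine`, in the order the pipeline runs: decoding, selection,
pruning, calculation, parallel execution, and the synthetic corpus the
tests run against.

## Structure model

A decoded entry is a flat, immutable object graph: an ordered list of
*groups* (the MMTF unit of chemical composition — a residue, ligand,
ion or water), each carrying its atoms, intra-group bonds and a chain
index; inter-group bonds (peptide/nucleic links, covalent ligand
attachments) as `((group, atom), (group, atom), order)` triples; chain
labels; and a per-chain biological-assembly copy label.  All indices
are 0-based; bond pairs are stored lower-index first.  Composition
types (`chem_comp.type`) are stored verbatim, uppercased — the model
is lossless, and all classification lives in the selector stage.

Heavy-atom conventions: hydrogen and deuterium are not heavy; all
size-based selection and all distance tests use heavy atoms only.
Hydrogens are present in a minority of crystal structures, so counting
them would make mining statistics resolution-dependent.

## MMTF codec

The codec implements the binary field strategies real archive files
use: pass-through int8/16/32 and float32, fixed-width strings,
run-length encoding, delta + run-length, run-length + fixed point,
and delta + recursive-index int16 + fixed point (the coordinate
codec).  Unknown strategy ids raise an explicit unsupported-codec
error rather than misparsing.  Numeric work is delegated to numpy
(`np.repeat` for run expansion, `np.cumsum` for delta); only the
recursive-index accumulation is a Python loop.

Choices that matter for exactness:

* **Fixed point.** Coordinates are stored at 1/1000 Å, B-factors at
  1/100, rounding half away from zero.  With that rule stated,
  encode → decode is bit-exact on coordinates that are already milli-Å
  multiples, and the generator pre-quantises everything it emits, so
  whole-corpus round trips are byte-identical and tested as such.
* **Model 1 only.**  Multi-model (NMR) files contribute their first
  model; mining statistics should not count one structure twenty
  times.
* **Alternate locations.**  Only the first-listed conformer of each
  atom (by atom name within a group) is kept; bonds to dropped
  conformers are dropped with them.  Same rationale: no
  double-counting.
* **Assembly labels.**  Per-chain copy labels have the canonical form
  `<assembly name>.<transform index>`, derived from
  `bioAssemblyList` on decode (first assembly/transform containing
  the chain wins) and reconstructed into it on encode.  Encode
  therefore requires canonical labels (or empty); the generator only
  produces canonical ones.
* **Compression.**  Blobs are gzip-detected by magic bytes; raw
  msgpack is accepted for fixtures.  Encoding gzips with a zeroed
  timestamp so identical entries give identical bytes.

## Hadoop sequence files

The reader/writer targets exactly the dialect the archive is
distributed in: SequenceFile version 6, `Text` keys, `BytesWritable`
values, no container-level compression (the payloads are already
gzipped), sync markers roughly every 2000 bytes.  Record- or
block-compressed files raise an explicit unsupported-dialect error.
Two bit-level details the container requires: `Text` keys carry a
Hadoop variable-length int prefix, and `BytesWritable` values carry a
4-byte big-endian length that must be stripped.  Reading is
single-pass and bounded-memory (one record resident at a time).  The
written sync marker is a fixed 16-byte digest so output files are
byte-reproducible; Hadoop itself uses a random UID, which the reader
accepts equally.

Corrupt shards mid-scan are either fatal (`abort`) or logged and
skipped (`skip`), chosen by configuration — a full-corpus run should
survive one bad shard, but the default for direct scans is to abort
loudly.

## Selection

Selectors work purely on group size and composition type:

* *non-polymer* = comp type containing `NON-POLYMER` or `SACCHARIDE`,
  or an empty comp type on a chain with no polymer-linking groups;
* *small molecule* = non-polymer, not a water (HOH/DOD/WAT), heavy-atom
  count within `[min_heavy_atoms, max_heavy_atoms]` — default 8–200,
  wide enough for real ligands, tight enough to drop most additives;
* *free metal ion* = non-polymer group whose single heavy atom is in
  the metal set (30 PDB-common metals by default); multi-atom groups
  with metal centres (hemes) are ligands, not ions;
* *peptide* / *nucleic* = comp type membership in configurable sets.

All thresholds and sets live in `SelectorConfig`, overridable from a
`key = value` text file and CLI flags.  The defaults are explicit
package choices, not archive-mandated values.

## Pruning

**Identical groups.**  "Biologically identical" is interpreted over
biological-assembly copies: within a selection, groups sharing
`(name, seq_id)` whose chains span at least two distinct copy labels
collapse to the lowest group index.  Classes confined to a single
label — including all-unlabelled chains — are left alone; chains that
merely repeat a ligand at different residue numbers are untouched.
Other readings (sequence-identical chains, symmetry mates) exist; this
one is the package's documented choice.

**Common groups.**  A plain name blocklist, shipped with 18 frequent
crystallisation additives and ions, fully replaceable from a text
file.

**Spatial pruning.**  `keep_interactions` keeps (or removes) groups
of the selection with a heavy atom within `cutoff` Å of a heavy atom
of another group in the `against` selection.  The search uses a cell
list: atoms hash into cubic cells of edge `cutoff`
(`cell = floor(p / cutoff)` per axis), so each query scans 27 cells.
The comparison is closed (`d² ≤ cutoff²`) and computed on squared
distances with the same float64 expression as a naive double loop, so
the cell-list result is *set-identical* to the O(n²) oracle — no
boundary tolerance needed.  A group is never its own neighbour, so a
selection can be tested against itself.  Translation invariance holds
up to floating error at the cutoff boundary: a pair whose distance
sits within ~1e-10 of the cutoff could in principle flip under a
large shared translation; random corpora never produce such pairs.

## Calculators

**Bond geometry.**  Lengths are collected for every intra-group bond
of a selected group and every inter-group bond with both endpoints
selected; angles for every unordered pair of those bonds sharing an
atom.  Bins are left-closed: 0.01 Å for lengths, 1° for angles (a
perfectly straight angle lands in the `[180, 181)` bin).  Histogram
keys are canonical — element pairs sorted, triples with the centre
element fixed in the middle and flanks sorted — so histograms merge
across entries by key-wise addition.  Angles at coincident atoms
(zero-length arm) are undefined and skipped.

**Superposition.**  Standard Kabsch: centre both point sets, SVD the
cross-covariance, flip the smallest singular direction when the best
orthogonal map would be a reflection (proper rotations only).
Degenerate inputs — fewer than 3 points, all points coincident, or a
cross-covariance of rank < 2 (collinear points, detected as
`σ₂ ≤ 1e-8·σ₁`) — raise a degeneracy error rather than returning an
arbitrary rotation.  Correspondence is positional: the Cα trace of
the moving entry is matched to the reference index-by-index, truncated
to the common length.  No sequence alignment is attempted; the
calculator measures conformational difference under a fixed
correspondence.  Cα extraction requires atom name `CA` *and* element
C, so calcium ions never enter a protein trace.

## Engine

The unit of parallelism is the shard, not the entry: each worker
thread opens its own shard stream and decodes its own entries, so no
structure is ever shipped between workers and memory stays bounded.
Two scheduling models are provided — `sync` (contiguous near-equal
static partitions, sizes differing by ≤ 1, the first remainder
partitions taking the extra shard) and `async` (a bounded thread pool
with one task per shard).  Per-shard results are combined in manifest
order regardless of completion order; since floating-point addition is
not associative, this fixed order is what makes results bit-identical
across modes and worker counts, and the suite asserts byte equality
over all six (mode, 1/2/4 workers) combinations.

Threads (not processes) carry the work: the per-entry cost is
dominated by numpy and decompression, and result merging is pure
Python either way.  Workers must be pure per entry; each invocation
receives a freshly decoded entry and shares nothing.  Failures follow
`on_error`: `skip` (default) logs the PDB ID and continues, `abort`
re-raises naming the entry.  The run log (processed IDs, skipped IDs
with reasons, shard errors) is part of the return value.

Result shapes are a count map (key-wise addition), a row table
(concatenate then sort lexicographically, keeping outputs
byte-comparable), and a scalar accumulator (component-wise addition).
The bond-geometry workflow serialises its histograms into count-map
keys (`kind|elements|bin`) so the generic merge applies.

## Synthetic corpora

The generator emulates the corpus shape the miner consumes — multi-
chain protein/ligand/metal/water entries with assembly copies, MMTF
encoding, sharded container files — without claiming physical realism
(no rotamers, no real secondary-structure geometry, no
crystallographic packing).  Passing tests therefore demonstrate
correctness of parsing, selection logic, exact neighbour search,
merging and scheduling; they say nothing about, e.g., force-field
quality on real conformations.

Construction, per assembly copy:

* protein chains on an ideal α-helix (radius 2.3 Å, rise 1.5 Å,
  100°/residue → Cα–Cα ≈ 3.8 Å), alternating Ala/Gly with N, CA, C, O
  (+ CB) at fixed local offsets, plus per-residue isotropic gaussian
  jitter (σ = 0.25 Å) so conformations genuinely differ between
  entries — without it every alignment RMSD would be zero;
* ligands as connected random-walk graphs of C/N/O (bond lengths
  1.3–1.6 Å, ≥ 1 Å clash distance, 80 retries per atom before a
  generation error);
* ligand and metal placement by bisection on the translation distance
  along a random ray from the protein centroid until the minimum
  heavy-atom separation equals the requested offset (a bracket always
  exists by the triangle inequality at
  `t = R_protein + R_shape + offset + 1`); ligand *i* sits at
  `offset + 2i` Å so multi-ligand entries straddle typical cutoffs;
* waters by rejection sampling, ≥ 2.5 Å from everything (300 tries
  per water before a generation error);
* assembly copies as rigid 80 Å translations with canonical copy
  labels.

Every coordinate is pre-quantised to 1/1000 Å, making whole-entry
MMTF round trips bit-exact.  Each entry draws from its own random
stream seeded `corpus_seed XOR ordinal`, so corpora are reproducible
under any generation order and any shard can be rebuilt independently.
Corpus generation varies ligand sizes (±~5 heavy atoms around the
base of 12) and water counts per entry so selector tests exercise both
sides of the default size window; `vary=False` pins every entry to
the base spec.  The ground-truth log records every group's role and
heavy-atom count plus all group-pair contacts under 10 Å (brute-force
minimum heavy-atom distances), giving the selector and pruning tests
an exact expected answer.

## Problem sizes and defaults

The test suite and acceptance script run at desk scale as the
package's own study conditions: corpora of 100 entries over 20 shards
(entries of roughly 100–400 atoms), 200 randomised entries for codec
round trips, 100 entries × 4 cutoffs (2, 4.5, 6, 10 Å) for the
neighbour-search oracle, 50-point traces with σ = 0.5 Å noise for
superposition cross-checks, and worker counts 1/2/4 under both
scheduling modes.  The shard-count worked example (578 shards, the
layout the real archive ships in) is exercised directly in the
static-partition arithmetic.  Default interaction cutoff: 6 Å.

## Known limitations

* No HDFS or network access; shards are local files.  No record- or
  block-compressed sequence files.
* No crystallographic symmetry expansion or periodic images; spatial
  pruning sees only the deposited coordinates.
* Alignment correspondence is positional, so comparing unrelated
  proteins is meaningless (by design — correspondence search is out
  of scope).
* The GIL bounds thread scaling for pure-Python map functions; the
  engine guarantees result invariance, not any particular speed-up.
* Entity/SEQRES-level records, occupancies and secondary structure
  are decoded where cheap but unused.
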