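# Methods

This note records the model, the tunable parameters, the synthetic data the
tests rely on, and the design choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Contact model

Atoms *i*, *j* from opposite chain groups of an interface are in contact
when their Euclidean distance lies inside the closed window of an
interaction type whose endpoint-label condition they satisfy:

| type | condition | min (Å) | max (Å) |
|---|---|---|---|
| aromatic_stacking | two aromatic atoms | 1.5 | 3.5 |
| hydrogen_bond | one acceptor + one donor | 2.0 | 3.0 |
| hydrophobic | two hydrophobic atoms | 2.0 | 3.8 |
| repulsive | two like charges | 2.0 | 6.0 |
| salt_bridge | two opposite charges | 2.0 | 6.0 |

A pair may satisfy several types (a carboxylate oxygen against a
guanidinium nitrogen at 2.8 Å is both hydrogen bond and salt bridge), so
interface graphs are multigraphs, with at most one edge per (pair, type):
the windows define types, not multiplicities. After contact computation
each node keeps only the labels exercised by at least one incident edge
(an acceptor/negative oxygen involved only in a salt bridge remains just
"negative"); atoms without contacts are dropped, and each connected
component becomes one dataset graph.

### Atom typing

The per-(residue, atom) role table is shipped as
`src/ifacemine/data/atom_types.yaml` and can be replaced via
configuration. It covers the 20 standard residues: backbone N is a donor
(except proline, whose ring nitrogen has no amide hydrogen), backbone O an
acceptor, aliphatic carbons hydrophobic, ring atoms of PHE/TYR/TRP/HIS
aromatic, carboxylates acceptor/negative, guanidinium and ammonium
nitrogens donor/positive, histidine's imidazole nitrogens
aromatic/positive/donor/acceptor, and hydroxyls acceptor/donor. Published
atom-typing dictionaries differ in fine detail (e.g. whether ring carbons
are also hydrophobic); this table is one defensible instantiation, and
analyses sensitive to typing should re-run with a custom table.

Parsing (Biopython) keeps heavy atoms of the first model, drops waters and
hydrogens, keeps the highest-occupancy altloc, and excludes HETATM ligands
by default. Author residue numbering is kept verbatim.

## Fingerprints and reduction

The counting matrix *X* has one row per graph and one column per
pair-label: each unordered *adjacent* node pair contributes one count to
the column formed by serializing both endpoint label sets (sorted short
codes joined by `/`) and joining the two sides in lexicographic order with
`-`. Adjacency, not edge multiplicity, is what counts — a pair with two
parallel edges still adds 1. Columns are sorted lexicographically for
reproducible serialization.

Truncated SVD runs on the raw, uncentered *X* (counts are non-negative
magnitudes; no centering is implied by the construction), and the retained
rank is the smallest *d* whose cumulative squared singular values reach
the variance threshold (default 0.95). The clustering input is
Θ = *U_d* Σ*_d*, whose rows preserve the dot-product geometry of *X* up
to the discarded tail.

## Clustering

* Similarity: Euclidean distance between rows of Θ; kNN graph
  symmetrized by union (edge if either endpoint lists the other among its
  k nearest), binary weights by default with an optional Gaussian kernel.
  Union symmetrization makes the connectivity criterion well-defined on an
  undirected graph.
* k sweep: k = max(1, round(p·r)) for p = 1%, 2%, …, 90% of the row count
  r; the selected k is the first whose graph is connected, since
  disconnected components would trivially impose themselves as clusters.
* Cluster count: normalized symmetric Laplacian
  L = I − D^(−1/2) A D^(−1/2); n is the position of the largest
  consecutive gap in the ascending spectrum, searched over n ∈ [2, n_max]
  (default n_max = 30), ties toward smaller n. n = 1 is excluded: a single
  cluster defeats the per-group mining design.
* Partition: rows embedded into the n smallest eigenvectors,
  row-normalized, then seeded k-means (default seed 0; all pipeline
  randomness flows from this one seed).
* Rank sweep: for every d meeting the variance threshold, (k, n) is
  recomputed; the selected triple has minimal k, then the modal n across
  qualifying ranks, then the smallest d. The full per-rank table is always
  emitted so the selection can be audited.

## Frequent subgraph mining

Multigraphs are flattened to simple graphs (one edge per adjacent pair,
parallel interaction types joined into a sorted edge label) and mined with
an in-package gSpan: patterns grow edge by edge along the rightmost path
of their DFS tree, are identified by their minimum DFS code, and support
is transaction-based (number of distinct graphs containing the pattern;
the count threshold is ceil(minSup·|cluster|)). Patterns have at least one
edge — an isolated atom is not an interaction arrangement. Mining compares
labels by exact string equality; the subset-label phenomenon (a pattern
node showing fewer roles than its source atoms) is produced afterwards by
`derive_display_labels`, which keeps, per pattern node, the roles its own
pattern edges exercise (hydrogen bonds orient acceptor against donor;
salt bridges keep the charge opposed by the partner; an inconsistent
combination falls back to the mined label with a warning). An optional
`max_pattern_nodes` cap (default none) guards against pathological inputs.
Maximal filtering removes every pattern label-exactly contained in
another, leaving an antichain.

## Pattern-to-atom mapping

Available VF2 implementations match vertex-induced subgraphs, but mined
patterns are edge subgraphs. The line-graph route restores inducedness:
an edge subgraph of H appears as a vertex-induced subgraph of L(H), so
VF2 runs on L(pattern) → L(graph) with node matching on both the joined
edge labels and the endpoint label pairs under the subset rule (either
direction; the pattern side uses display labels, the graph side retained
labels). Every line-level match is translated back to an atom-level node
map and re-verified on the original graphs — injectivity, adjacency and
label compatibility — which makes the line graphs purely a search device:
Whitney's exceptional pair (K3 and K1,3 share a line graph) is eliminated
by the verification rather than assumed away. All embeddings are
enumerated and deduplicated by node-map image. `map_all` additionally
asserts that every occurrence claimed by the miner yields at least one
verified mapping.

## Evaluation

A pattern is relevant if it matches any reference item: a residue item
(residue name + author number, optionally restricted to a chain group)
matches when some mapping touches that residue; a micro-structure item (a
small labeled graph, e.g. two donors hydrogen-bonded to one acceptor)
matches when it embeds in the pattern under the same subset-label rule.
Per group, precision = relevant patterns / patterns and recall = matched
ids / reference ids; the overall row pools patterns for precision and
counts ids matched anywhere for recall. Reports round to 2 decimals.
Reference items with several admissible residues (positional motifs whose
identity varies per complex) take explicit per-complex residue lists.

## Synthetic data

The fixture generators define the conditions under which the pipeline is
tested:

* **Toy complexes**: each planted contact is an isolated residue pair in
  its own lattice cell (25 Å spacing, 0.5 Å jitter; the separation vector
  has a random direction and an exact planted length), with decoy atoms
  placed ≥ 40 Å across chains, far beyond the 6 Å maximum cutoff. Planted
  distances must lie strictly inside the window of their declared type.
  This exercises parsing, typing, windows and component extraction with
  exact ground truth, but has no physical realism: no torsions, no
  clashes, no crowded interfaces, no altloc/insertion-code pathology
  beyond what unit tests add by hand.
* **Graph datasets**: a connected motif (default: donor — acceptor/negative
  — donor/positive path with a hydrogen bond and a salt bridge) is embedded
  verbatim in round(fraction·n) graphs (default 8 of 10); noise nodes and
  edges are rejection-sampled so no accidental motif copy appears anywhere,
  which pins the motif's mining support to the planted fraction by
  construction. Real interface graphs are larger (tens of nodes), have
  correlated labels, and patterns appear with label variation; passing
  these tests therefore demonstrates algorithmic correctness, not
  biological recall on deposited structures.
* **Block matrices**: Gaussian blobs (unit within-block spread, orthogonal
  centers scaled so the between/within distance ratio is ≥ 5, 25 points
  per block) for the eigen-gap and spectral stages.

Problem sizes in the acceptance tests (≤ 8 graphs of ≤ 6 nodes for the
mining oracle, ≤ 8-node targets for the mapping oracle, 20–50 seeds per
property) are chosen so the exhaustive oracles stay exact and the whole
suite runs in seconds; the algorithms themselves have no such limits.

## Numerical choices and edge cases

* Singular values below max(r, c)·eps·σ₁ are treated as rank-deficient
  and never enter Θ.
* `select_rank` uses a 1e-12 slack when comparing the cumulative variance
  fraction to the threshold, so exact-threshold spectra select the smaller
  rank.
* DFS-code extension order breaks label ties lexicographically on
  (edge label, endpoint labels); graph node keys order by `repr` so mixed
  key types stay deterministic.
* k-means runs with `n_init=10` and the configured seed; cluster ids are
  renumbered by first appearance for stable output.
* Degenerate inputs raise early with actionable messages: empty datasets,
  k ≥ r, non-connected similarity graphs at all swept k, edgeless
  patterns, empty reference sets.

## Known limitations

* The typing table is an instantiation, not a community standard; results
  shift with the table (which is why it is a replaceable data file).
* mmCIF input, water-mediated contacts, solvent accessibility and
  interface-area computation are out of scope.
* Mining is label-exact; arrangements conserved only up to label
  generalization are found via display-label subset matching at mapping
  time, not during mining. An alternative — mining over edge-role-projected
  labels — would find strictly more general patterns and is noted as a
  possible future mining mode.
* The evaluation requires the user to supply reference residues; it does
  not mine the literature.
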