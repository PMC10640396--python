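# Methods

## Residue representation

Each standard amino-acid residue is reduced to two pseudoatoms: the
alpha-carbon Cα and the side-chain centroid Cμ, defined as the unweighted
mean of the heavy (non-hydrogen) side-chain atom coordinates. Backbone
atoms (N, CA, C, O) and the terminal OXT never contribute to the centroid.
Glycine has no heavy side-chain atoms; by convention its Cμ equals its Cα
and its orientation vector is taken from the backbone instead:
**R** = Cα − C_NC with C_NC the midpoint of the backbone N and C atoms.
For all other residues **R** = Cα − Cμ.

A residue pair is described by three quantities invariant under any proper
rigid-body motion: the Cα–Cα distance, the Cμ–Cμ distance, and the angle
between the two **R** vectors (the dot product is clamped to [−1, 1]
before the arccosine). Using side-chain centroids rather than Cβ atoms
makes the description sensitive to actual side-chain placement, which is
what distinguishes a catalytic arrangement from a merely similar backbone.

Parsing policy (PDB and mmCIF, via gemmi): first model only; all chains,
and inter-chain pairs are indexed, since functional sites can span chain
boundaries; per atom name the highest-occupancy alternate location wins,
ties going to the first listed; hetero and chemically modified residues
(e.g. MSE) are skipped rather than remapped — the index namespace is
defined over the 20 standard types only. A residue missing its Cα, or a
non-glycine missing all heavy side-chain atoms, is skipped with a warning.

## The inverted index

All residue pairs with Cα–Cα distance ≤ 20 Å (structural motifs are by
definition compact, so longer pairs are uninformative) are filed under a
key composed of the canonically ordered pair type (210 possibilities) and
a geometry bin: 1 Å bins for the two distances, 20° bins for the angle.
Exact boundary values fold into the last bin (a 20.0 Å Cα distance into
Cα bin 19, a 180° angle into angle bin 8). Cμ distances can legitimately
exceed 20 Å when centroids point away from each other, so Cμ bins are not
capped. Within a record, residues are stored in canonical order
(alphabetically smaller type first, ties by residue id); the descriptors
are symmetric so no values depend on this.

During a build, occurrences are appended to plain per-bin CSV files;
a finalize pass sorts each bin by (structure, residue, residue),
deduplicates, rewrites it as a compressed columnar table (parquet), and
deletes the CSVs. Structures are parsed in parallel (joblib) but the
sorted finalize makes the finished index byte-identical for any worker
count. The index also stores one small pseudoatom table per structure
(residue id, type, Cα, Cμ, **R**), so the later search stages can
recompute descriptors and superpose hits without reopening the original
structure files — the index is self-contained and survives the source
directory moving. A human-readable JSON manifest records the build
parameters, the structure inventory, and per-bin record counts; the
counts double as the selectivity estimates used to weight the query
spanning tree.

## Motif search

The query is a set of residue ids in a user-supplied structure file,
represented as a fully connected weighted graph (nodes: residues; edges:
the three descriptors). The search has four stages:

1. **Spanning-tree pruning.** Pairwise geometric constraints are
   transitive, so for motifs of ≥ 4 residues only a spanning tree of n−1
   edges needs to be looked up in the index. Kruskal's algorithm is run
   with edge weights equal to the estimated number of index rows in the
   bins overlapped by that edge's tolerance window, which minimizes the
   amount of data loaded. Motifs of 2–3 residues keep all edges. An edge
   whose Cα distance window lies entirely beyond the 20 Å indexing cutoff
   cannot be served by the index; such queries return no hits through
   that edge (a motif wider than the cutoff is outside the method's
   design envelope).
2. **Bin loading and interval filtering.** For each tree edge, every bin
   overlapping [v − tol, v + tol] per descriptor is loaded (bins are only
   a prefilter) and rows are tested against the closed intervals on the
   raw values. Defaults mirror the bin widths: 1 Å and 20°.
3. **Iterative join.** Edge hits are grouped by structure and joined in a
   connected edge order: each new edge must extend an existing partial
   assignment through its shared query node, injectively. Structures that
   cannot thread all tree edges are discarded; survivors hold at least
   one complete tree embedding.
4. **Monomorphism filter and ranking.** The tree stage never checks
   non-tree edges, so a survivor may contain the right pairs wired
   differently than the query. The identified residues form a fully
   connected graph with freshly computed descriptors, and a subgraph
   monomorphism (networkx `GraphMatcher`) keeps only injective,
   type-compatible mappings in which **all** C(n,2) query edges satisfy
   the tolerances. Every distinct mapping is reported — a structure can
   contain a motif twice. Each mapping is scored by minimal least-squares
   RMSD under the quaternion characteristic-polynomial superposition
   (proper rotations only; Biopython's implementation). Because the
   closed-form `sqrt(E0 − 2λ_max)` residual loses precision near zero,
   the RMSD is evaluated explicitly from the optimal rotation, which is
   exact to machine precision. The default RMSD mode is `both`
   (concatenated Cα and Cμ points per residue), the mode most sensitive
   to side-chain positioning; `ca` and `cm` are available. Hits are
   sorted by RMSD, then structure id.

### Mutation-tolerant searches

A substitution policy (strict / PSE / relaxed / fully relaxed, plus a
simultaneous-mutation bound; default bound 1 for mutation-permitting
strategies, keeping variant counts tractable) is expanded into the full
set of residue-type variants, each searched independently with a shared
bin-load cache — the geometry of the query is unchanged by a mutation,
only the pair types looked up. Pooled hits are deduplicated by
(structure, residue mapping) keeping the lowest mutation count; the RMSD
of a mapping does not depend on which variant found it. The relaxed
groups partition the alphabet: nonpolar {G,A,V,L,I}, polar {S,T,P,N,Q},
sulfur {M,C}, positive {K,R,H}, negative {D,E}, aromatic {F,Y,W}; His is
treated only as positively charged, exactly as grouped.

## Synthetic structures

The fixture generator writes minimal, valid PDB files whose parsed
pseudoatoms equal the generator's intent exactly: each residue carries a
backbone (N, CA, C, O) plus a single CB atom placed at the intended Cμ
(the centroid of one atom is that atom); glycine's backbone N and C are
placed so their midpoint reproduces the intended **R** vector. Decoy
residues get uniform random positions with a 3 Å minimum Cα separation
inside a 40 Å box (default 25–30 residues per structure — a compact
single-domain protein's worth of spatial density) and uniform random
types; side-chain centroids sit 1.5–3 Å from the Cα in a random
direction. A planted motif is inserted after a random proper rigid
transform, clash-checked against the decoys, and recorded in a sidecar
`truth.json`. The same seed always yields byte-identical files.

What this emulates — and what it does not: the fixtures have realistic
*spatial* statistics (density, pair-distance spectrum within the cutoff)
but no chemistry, no backbone connectivity, no rotamer structure, and no
homology between structures. Passing tests therefore demonstrate the
correctness of the geometric indexing and matching machinery, not
retrieval performance on evolutionarily related proteins.

## Numerical choices and limitations

* PDB coordinates carry three decimals, so any geometry that round-trips
  through a file acquires up to ~5·10⁻⁴ Å of noise per coordinate.
  Consequences: a rigidly transplanted motif is recovered at RMSD of a
  few 10⁻⁴ Å rather than 0; descriptor preservation across file-level
  rigid transforms is asserted at 5·10⁻³ Å/°, while the in-memory
  transform invariance of descriptors holds to 10⁻⁶.
* Tolerance intervals are closed; a record exactly at the boundary
  matches. Exact bin boundaries fold downward (floor), with the two
  terminal boundary cases (20 Å, 180°) folded into the last bin.
* Equal spanning-tree edge weights are broken deterministically by the
  lexicographic edge order, so repeated runs and any worker count give
  identical output.
* Test and acceptance problem sizes (50 structures × 30 residues,
  queries of 3–5 residues, 13-structure planted sets) are chosen so the
  exhaustive reference searchers remain fast; the index machinery itself
  is size-agnostic.
* Incremental index updates and index merging are not supported; a build
  either finalizes or leaves an explicit incomplete marker.
* Querying by raw descriptors without a structure file is unsupported:
  query residues always come from a parsed structure.
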