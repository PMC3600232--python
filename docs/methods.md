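# Methods

## Residue networks

A structure is reduced to its first model's standard amino-acid residues
(waters, hetero groups and hydrogens are dropped; for alternate locations the
highest-occupancy copy is kept, ties going to the first in file; residues
with no remaining heavy atom are dropped).  Residue identity is the author
triple (chain, residue number, insertion code), and annotation ranges are
inclusive on both ends in author numbering.

Vertices are representable residues in chain-then-file order.  A residue that
cannot be represented under a strategy (e.g. a missing Cα) is excluded and
logged, never an exception.  Under **CA** the representative is the alpha
carbon; under **CENTROID** the unweighted mean of the side-chain heavy atoms
(everything but N, CA, C, O, OXT), with glycine and side-chain-less residues
falling back to the Cα so every residue stays representable; under
**ANYATOM** every heavy atom carries a van der Waals radius (built-in table
C 1.70, N 1.55, O 1.52, S 1.80 Å, overridable) and the residue-pair distance
is the *minimum surface gap*: center distance minus both radii, floored at
zero.  The surface-gap reading is why the any-atom cutoff grid starts at
0 Å — a center-to-center cutoff of 0 would be meaningless, whereas a surface
gap of 0 means "the atomic spheres touch".  The radius table validates
radii ≥ 0 rather than > 0 so that a degenerate all-zero table can reproduce
plain center distances (used by the equivalence tests); the built-in table is
strictly positive.

Edges use inclusive comparison (distance ≤ cutoff; the choice is arbitrary
but fixed) and sequence neighbours get no special treatment: the near-zero
accuracy of Cα networks below the ~3.8 Å backbone spacing is a real property
of a pure distance rule, not an artifact.  Multi-chain proteins form one
network over all annotated chains.  Default sweep grids: Cα and centroid
3–10 Å in 0.5 Å steps (15 values), any-atom 0–6 Å in 0.5 Å steps (13
values), random-walk lengths 3–10.

## Community division

**Edge betweenness / divisive.**  The betweenness of an edge is the number
of shortest paths between unordered vertex pairs traversing it, with each
pair's unit of flow split equally among its equal-length shortest paths.  It
is computed exactly by a Brandes-style algorithm vectorised over sources
(level-synchronous BFS for path counts, a level-by-level backward sweep for
dependencies); ordered-pair totals are halved.  The divisive run removes the
single maximum-betweenness edge, *recomputing betweenness after every
removal* (the classic formulation), with ties broken by the lexicographically
smallest vertex-index pair so builds are reproducible.  Component splits are
snapshotted to form the dendrogram.  When the caller only needs K
communities the run may stop at the first point with ≥ K components; the
truncated dendrogram refuses cuts it never reached.

**Short random walks / agglomerative.**  Transition probabilities are the
degree-normalised adjacency raised to the t-th power — exact matrix powers,
no sampling, no self-loops — and the distance between vertices or communities
is the degree-weighted Euclidean distance between their t-step probability
profiles (a community profile is the mean of its members').  Merging starts
from singletons and always joins the *adjacent* pair whose merge minimally
increases the total within-community squared distance (Ward-style increment
|C1||C2|/(|C1|+|C2|) · r² / n), ties again to the smallest id pair.  Isolated
vertices are permanent singletons and merging never crosses components.
Note one parity quirk of the no-self-loop walk: on a single edge the two
2-step profiles are orthogonal (the walk alternates endpoints), so their
distance is √2, not 0; the pair is still the only available merge.  Lazy
(self-loop) walks would remove the parity effect but are deliberately not
used.

**Cutting at K.**  The divisive dendrogram is cut at the first recorded state
with ≥ K components (the initial components if the graph starts above K);
the agglomerative one replays merges to exactly K when reachable, otherwise
to the closest reachable count above K.  In the evaluation pipeline K is
always the annotated domain count — domain-count *prediction* is out of
scope, though the dendrograms retain full histories should a modularity-based
selector be added.

## Scoring

Acc = 100 × matched / total, where total counts residues inside any
annotated domain range and matched counts those whose community is assigned
to their domain by a maximum-weight one-to-one community–domain matching on
overlap counts (scipy's linear-sum assignment).  This is the strictest
defensible reading of "correctly identified": a community can claim at most
one domain, unmatched domains contribute zero, and residues outside every
domain (linkers, tails) are excluded from numerator and denominator alike. A
majority-vote mapping (each community votes for its plurality domain; not
injective) is available as `mapping="majority"` for sensitivity analysis.
Single-domain proteins with a connected network trivially score 100% at
K = 1; they are well defined but uninformative.  Dataset aggregates are
unweighted means of per-protein Acc by default, with a residue-weighted mean
behind a flag, because the text sources for this statistic do not determine
either choice.

## Synthetic structures

The generator emulates the one property the method consumes: contact density.
Each domain is a self-avoiding Cα walk (fixed 3.8 Å step, non-consecutive
pairs kept ≥ 3.0 Å apart) confined to a sphere of radius 3·N^(1/3) Å around
its center — the radius that gives roughly protein-like packing density for
an N-residue globule.  Domain centers sit on the x axis at a configurable
separation (default 40 Å for the default 60-residue domains, comfortably
more than twice the ~11.7 Å domain radius, so inter-domain Cα contacts at
≤ 10 Å essentially never occur).  Consecutive domains are joined by a linker
of L residues (default 6) laid along a circular arc whose chord steps are
exactly 3.8 Å; the arc construction pins both endpoints while preserving
bond geometry, and the tail of each domain walk is steered toward the next
linker's take-off point so the arc can reach.  Specs whose linker cannot
possibly span the inter-sphere gap (L · step < separation − 2·radius) are
rejected up front; satisfiable but unlucky geometries are retried a bounded
number of times before a generation error.  Every residue gets a
configurable number of pseudo side-chain carbon atoms (default 2) uniformly
within 2.5 Å of its Cα so the centroid and any-atom strategies see
non-trivial geometry.  Output is written as standard PDB plus the annotation
TSV; identical specs give byte-identical files.

What this does *not* emulate: secondary structure, Ramachandran statistics,
rotamers, chemically realistic side-chain sizes, domain–domain interfaces, or
discontinuous (sequence-interleaved) domains.  Passing tests on synthetic
chains therefore demonstrate that the pipeline recovers planted contact-dense
communities under controlled conditions — not that any particular cutoff is
optimal for real proteins, where domains share interfaces and linkers are
not the only inter-domain contacts.

## Study conditions used by the test-bench

The default synthetic conditions (2 domains × 60 residues, 6-residue linker,
40 Å separation, 3.8 Å step, 2 side-chain atoms, 50 seeds for benchmark
means) are fixed once and used everywhere: they produce chains whose Cα
networks are connected at cutoffs ≥ 4 Å and edgeless at 3 Å, reproducing the
qualitative shape of the cutoff–accuracy curve (a collapse below the backbone
spacing, a broad productive window at 5.0–7.5 Å).  The sweep harness runs
whole grids; aggregate rows are exact means of the per-protein rows, parse
failures are reported (status column, evaluated/total counts), never silently
dropped, and re-runs are bit-identical.  The stability mode draws *nested*
subsets (each size extends the previous, from one seeded permutation),
treating the cumulative-dataset design as such.

## Numerical choices and degenerate inputs

* Betweenness ties during divisive removal are resolved by exact float
  comparison then lexicographic pair order; all arithmetic is deterministic,
  so identical inputs give identical dendrograms.
* Edgeless networks flow through the pipeline as all-singleton partitions
  (Acc ≈ K/total) rather than raising.
* An empty structure or a network with no representable residues raises a
  typed error; Acc with zero domain-region residues is a typed
  undefined-accuracy error.
* Walk profiles use exact matrix powers; costs are O(n³) in the vertex
  count, fine for single chains (n ≲ 10³).
* The divisive run recomputes betweenness in O(n·m) vectorised work per
  removal; early stopping at K components keeps multi-structure sweeps fast.

## Known limitations

* Betweenness recomputation makes a *complete* divisive dendrogram O(m²·n)
  in the worst case; use `stop_at_components` (the evaluation pipeline does).
* The walktrap merge loop recomputes community distances directly rather
  than via Lance–Williams updates; adequate at chain scale, wasteful beyond.
* PDB input only (no mmCIF); first model only; no structure repair or
  missing-atom reconstruction.
* Discontinuous domains are supported in annotations (multiple ranges per
  domain) but the synthetic generator only produces sequence-contiguous
  domains.
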