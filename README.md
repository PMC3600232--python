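# rindom

Residue interaction networks and community-division domain decomposition for
protein structures.

## The problem

A folded protein can be read as a graph: amino-acid residues are vertices and
spatial proximity relations are edges.  Structural domains — the
semi-independent, compactly folded units that structure classifications such
as SCOP annotate — then appear as *communities*: groups of vertices that are
densely connected internally and sparsely connected to the rest.  How well
this picture works depends strongly on how the graph is defined, and that is
what this package lets you measure.  It is aimed at structural
bioinformaticians who want to calibrate contact definitions (which vertex
representation, which distance cutoff) against domain annotations, or who
simply need a clean, deterministic implementation of community-based domain
decomposition.

## The method

For a structure with residues *i = 1…n* an undirected, unweighted network is
built under one of three vertex strategies:

* **Cα** — residues connect when their alpha-carbon distance
  *R*<sub>Cα</sub> ≤ cutoff (grid 3–10 Å, step 0.5 Å);
* **centroid** — side-chain centroid distance *R*<sub>cent</sub> ≤ cutoff
  (same grid; glycine falls back to its Cα);
* **any-atom** — minimum surface gap over heavy-atom pairs,
  min<sub>a∈i, b∈j</sub> (‖x<sub>a</sub> − x<sub>b</sub>‖ − r<sub>a</sub> −
  r<sub>b</sub>) ≤ *R*<sub>atm</sub>, with van der Waals radii r (grid 0–6 Å).

The network is split into K communities (K = the number of annotated
domains) by either

* **Girvan–Newman**: iteratively remove the edge with the highest edge
  betweenness (shortest-path flow, recomputed after every removal), or
* **walktrap**: agglomerate singleton communities by Ward-style merging on
  the degree-weighted Euclidean distance between exact t-step random-walk
  probability profiles (t grid 3–10).

The partition is scored against the reference annotation with

**Acc = 100 × (domain-region residues in the community matched to their
domain) / (all domain-region residues)**,

where communities are matched one-to-one to domains by maximum-weight
bipartite matching and linker/tail residues are excluded.  A sweep harness
evaluates full cutoff × strategy × method × step grids over a manifest of
structures, plus a nested-subsample stability mode.  A synthetic generator
produces multi-domain pseudo-proteins (self-avoiding Cα walks in spherical
domains joined by exact-step arc linkers) with known ground truth, so the
whole pipeline is testable without downloading anything.

## Worked example

```sh
$ rindom simulate --seed 11 -o syn.pdb -a syn_domains.tsv
SYN2D00011: 126 residues, 2 domains -> syn.pdb, syn_domains.tsv

$ rindom build syn.pdb -s CA -r 5.0 -o edges.tsv
syn: 126 vertices, 273 edges -> edges.tsv

$ rindom eval --pdb syn.pdb -a syn_domains.tsv -s CA -r 5.0 -m EDGE_BETWEENNESS
syn	CA	5	EDGE_BETWEENNESS	steps=None	k=2	Acc=100.00%

$ rindom eval --pdb syn.pdb -a syn_domains.tsv -s CA -r 7.0 -m RANDOM_WALK -t 10
syn	CA	7	RANDOM_WALK	steps=10	k=2	Acc=100.00%

$ rindom eval --pdb syn.pdb -a syn_domains.tsv -s CA -r 3.0 -m EDGE_BETWEENNESS
syn	CA	3	EDGE_BETWEENNESS	steps=None	k=2	Acc=1.67%
```

The simulated chain has two 60-residue domains and a 6-residue linker.  At a
Cα cutoff of 5.0 Å the network is connected and both division methods cut it
exactly at the linker, so every domain residue lands in the community matched
to its domain (Acc = 100%).  At 3.0 Å — below the ~3.8 Å backbone spacing —
the network is edgeless, the partition degenerates to singletons, and only
the two single residues matched to the two domains count as correct
(2/120 = 1.67%).  `rindom sweep --manifest … -o outdir` runs the same
evaluation over full parameter grids and writes per-protein and aggregate
TSV tables; `--stability` repeats it on nested random subsets.

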