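# Methods

## The residue interaction graph

A structure is reduced to an undirected simple graph. Nodes are the
polymer residues of the analyzed segment — every residue, including
isolated ones, because the closeness formula's `n` counts all analyzed
residues and dropping isolates would silently rescale every value. Edges
are residue pairs with at least one non-covalent interatomic contact; a
pair with twelve atomic contacts and a pair with one are the same single
edge. When requested, the co-crystallized ligand enters as one extra
node: all atoms of the declared het group(s) are pooled, and an edge is
drawn to every residue touching any ligand atom. Multi-copy ligands merge
into that single node by default (`merge_ligands=False` keeps one node
per copy).

## Contact inference

All criteria act on heavy atoms; hydrogens are discarded at parse time.
Two modes:

- `distance_cutoff` (default 4.5 Å): a fixed interatomic threshold.
- `csu_like`: spheres inflated by a solvent probe must overlap,
  `d ≤ r_vdw(a) + r_vdw(b) + 2·r_probe`, with Bondi radii
  (C 1.70, N 1.55, O 1.52, S/P 1.80, halogens per Bondi; fallback 1.70 Å
  for anything else, configurable off) and probe 1.4 Å.

The `csu_like` mode approximates an excluded-solvent-accessible-surface
contact definition; it deliberately ignores occlusion by third atoms, so
residue lists computed on real structures are labeled with the criterion
used and are expected to differ in detail from surface-based programs.
Candidate pairs come from a k-d tree queried at the largest possible
pairwise threshold, then the exact per-pair threshold is applied —
subquadratic in atom count and, by construction, identical in output to
the all-pairs scan (asserted in the tests).

Three filters then remove what is not a non-covalent residue–residue
interaction: intra-residue pairs; backbone–backbone pairs between
sequence-adjacent residues of one chain (the peptide bond neighborhood —
side-chain contacts between neighbors are kept); and, by default, Cys
SG–SG pairs under 2.5 Å (disulfides, covalent). A gap in author numbering
is treated as a chain break and suppresses the adjacency filter across
it.

## Closeness-centrality

Connectivity distance is the edge count along a shortest path, computed
by breadth-first search; with unit edge weights this is exactly what
Dijkstra's algorithm yields, so BFS is an equivalence, not an
approximation. Closeness is `C(x) = (n−1)/Σ_y d(x,y)`. On disconnected
graphs the default convention sets `C = 0` for every node with an
unreachable partner and warns with the component sizes, since the formula
sums over all nodes; a Wasserman–Faust per-component scaling
(`(n_r−1)²/((n−1)·Σd)`) is available as an explicit alternative. Values
are stored at full precision; two-decimal rounding is applied only in
display and in the acceptance report.

## Comparative analyses and thresholds

All three analyses share one recipe: a per-residue quantity, its mean and
*sample* (n−1 denominator) standard deviation across residues, and flags
beyond `mean ± k·SD`. Defaults: `k = 1` (upper side, inclusive ≥) for the
high-centrality set; `k = 2.5` (two-sided) for deltas between two
structures; `k = 2.5` (upper side) for the ligand-presence delta. The
choice of sample over population SD is a convention, surfaced in every
report header. Cross-structure matching uses author residue numbering
only — appropriate when all compared structures share one numbering, as
alignment is out of scope.

Two deliberate conventions where inputs are degenerate:

- High-centrality set with `SD = 0` (all values equal): the cutoff equals
  the mean and the inclusive rule flags every residue — all residues are
  equally central, and the operation reports exactly that.
- Delta analyses with `SD = 0` and `k > 0`: nothing is flagged. A
  constant shift between two tables carries no per-residue signal, and
  flagging everything would drown real runs in noise.

Threshold comparisons carry an absolute tolerance of 1e-12 so that the
inclusive `≥` survives floating-point rounding of `mean + k·SD`.

In ligand-present runs the ligand node counts toward `n` inside the
closeness formula (it is a network member) but is excluded from the
delta vector and from threshold statistics — reports concern residues.
The per-structure threshold is the default; `pooled_delta_thresholds`
recomputes the cutoff over several structures' deltas for the pooled
variant.

## Structure input

PDB files are read with gemmi (first model only). Alternate locations
collapse to one conformer per atom — highest occupancy, ties broken by
altloc label order ("first" is available); a single coordinate set is
required for deterministic contacts. Residues are classified by name:
standard amino acids → polymer, waters → solvent, common ions/additives
→ ion, declared names → ligand, everything else → other-het. Only
polymer and ligand residues ever enter the network. Segment trimming
(inclusive author-numbered ranges) restricts the analysis to the portion
solved in all compared structures; ligands survive trimming. Fusion
partners are removed by selecting the receptor chain.

## Ballesteros–Weinstein numbering

TM boundaries are configuration, not computation. The shipped scheme
encodes the β₂ adrenergic receptor: anchors 1.50 = Asn 51, 2.50 = Asp 79,
3.50 = Arg 131, 4.50 = Trp 158, 5.50 = Pro 211, 6.50 = Pro 288,
7.50 = Pro 323, with helix spans of roughly 25–34 residues around them
and the loop/terminus regions filling the gaps. The spans are editable in
the YAML config; residues outside every declared range are labeled
`unassigned` rather than guessed.

## Synthetic data: what it emulates, and what it does not

The generators provide ground truth for every pipeline stage without any
structure downloads.

**Toy designs** place one carbon pseudo-atom per residue so that exactly
a designed adjacency is recovered: contacts at 4.0 Å, non-contacts at or
beyond 5.5 Å, leaving every cutoff in (4.2, 5.2) Å a faithful decoder.
Placement is found by seeded L-BFGS-B minimisation of a smooth penalty
(edges pulled to the contact spacing, non-edges pushed past the
non-contact spacing) with random restarts, then verified pair-by-pair
against the design; an unrealisable design raises a generation error,
never a silent mismatch. The spacings are bounded by solid geometry: the
diagonals of a chordless 4-cycle with 4 Å sides average at most 4√2 Å,
and two-step paths bound their endpoints at 8 Å, which is why the
non-contact spacing sits at 5.5 Å rather than higher, and why random
designs cap node degree at 4 and exclude K₂,₃ motifs (two non-adjacent
residues sharing three neighbors), which have essentially zero
realisation volume. Pseudo-residues are numbered 1, 3, 5, … so the
adjacent-backbone filter never fires on them; that filter is exercised by
dedicated two-residue full-backbone fixtures.

**The bundle** emulates the 7TM architecture only at the level the
centrality analysis sees: seven antiparallel helical chains of 30
C-beta-like pseudo-atoms (1.5 Å rise, 100° twist per residue), standing
on a circle whose radius follows a parabola in height — 5.0 Å at
mid-height, 12.0 Å at both mouths. Inter-helix contacts are therefore
dense only near mid-height, and closeness concentrates there: each
helix's maximum falls in its middle third, and the mean+1·SD set lies
within the middle half of the bundle height. An optional ligand
pseudo-residue (one atom per designated pocket site, dropped 3.5 Å
inward) binds at one mouth across three helices, reproducing the
situation in which a bound ligand lends centrality to its pocket. The
bundle has no side chains, no realistic packing, no loops connecting the
helices, and no sequence; passing these tests shows the pipeline's
machinery is correct on a knot-shaped network, not that any particular
real receptor's residue lists would be reproduced — those depend on the
exact contact criterion and on the structures themselves.

**Random graphs** are connected Erdős–Rényi draws (resampled until
connected within a retry budget, deterministic under seed), used to pit
the BFS closeness against an independent Floyd–Warshall oracle.

## Problem sizes and numerics

The test suite and the acceptance script run entirely on generated
inputs: 5-residue worked example, ≤8-residue random designs (100 round
trips), a 210-residue bundle (~500 contacts), 200 random graphs with
n ≤ 50, and 500-atom contact-detection fixtures — sizes at which the
brute-force oracles (all-pairs distance scans, O(n³) min-plus closure,
exhaustive enumeration of all 1024 labeled 5-node graphs) are exact and
fast. Oracle agreement is asserted to 1e-12; geometric verifications use
a 5% margin on the design spacings.

## Known limitations

- The `csu_like` criterion is an overlap test, not a true
  excluded-surface computation; contact lists on real structures are
  approximate by construction.
- Insertion-code-bearing residues never count as sequence-adjacent for
  the backbone filter.
- mmCIF input, hydrogen placement, protonation states, assembly
  generation, and alignment-based residue matching across different
  receptors are out of scope.
- Covalently anchored ligands are connected by contact evidence like any
  other ligand; the covalent bond itself is not modeled.
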