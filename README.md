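# gpcrnet

Residue interaction networks and closeness-centrality analysis for
G protein-coupled receptor (GPCR) structures.

## The problem

A folded receptor can be read as a "social network" of its amino acids:
each residue is a node, and every non-covalent residue–residue contact is
an edge. On that graph, *closeness-centrality* measures how few steps
separate a residue from everyone else:

```
C(x) = (n − 1) / Σ_{y ∈ U, y ≠ x} d(x, y)
```

where `n` is the number of nodes, `U` the node set, and `d(x, y)` the
*connectivity distance* — the number of edges on the shortest path
between `x` and `y` (not a physical distance). `C` reaches 1 exactly when
a residue contacts every other residue, and falls toward 0 for peripheral
residues. In a seven-transmembrane (7TM) receptor the most central
residues cluster in the membrane-buried core — the "knot" of a bow-tie
architecture whose two flared ends host the ligand-binding and
G-protein-binding cavities.

`gpcrnet` builds that graph from a PDB coordinate file and runs three
analyses:

1. **High-centrality set** — residues with `C ≥ mean + 1·SD` across the
   structure.
2. **Activation deltas** — per-residue `ΔC` between two conformations
   (e.g. active vs inactive), flagged beyond `mean ± 2.5·SD`.
3. **Ligand effect** — `ΔC` when the co-crystallized small molecule is
   added to the network as a single extra node, flagged at
   `mean + 2.5·SD`.

Residues are annotated with Ballesteros–Weinstein identifiers (`X.50` at
each helix's reference position; `6.48`, `6.52`, … relative to it), so
results are comparable across receptors. Contacts are inferred on heavy
atoms either by a plain distance cutoff (default 4.5 Å) or by a
solvent-extended van-der-Waals overlap test
(`d ≤ r_vdw(a) + r_vdw(b) + 2·r_probe`).

It is written for structural bioinformaticians who want a transparent,
scriptable residue-network pipeline with synthetic ground-truth fixtures
for every stage.

## Worked example

The package ships a generator for a five-residue structure (Val 86,
Asp 113, Phe 289, Asn 312, Tyr 316 of the β₂ adrenergic receptor, with
their known contact pattern) on which the closeness values can be checked
by hand:

```bash
gpcrnet simulate --kind fig1 --out fig1.pdb
gpcrnet centrality --pdb fig1.pdb --criterion distance --cutoff 4.5 --out-dir out/
cat out/fig1_centrality.tsv
```

```
node_key  res_name  bw_id  closeness
A:86      VAL       2.57   0.571429
A:113     ASP       3.32   0.571429
A:289     PHE       6.51   0.444444
A:312     ASN       7.39   0.666667
A:316     TYR       7.43   0.800000
```

Reading the table: Tyr 316 (7.43) touches three of the four other
residues, so its distances sum to 5 and `C = 4/5 = 0.80`; Phe 289 (6.51)
sits three steps from the Val86/Asp113 pair, giving `C = 4/9 ≈ 0.44`.
The `bw_id` column carries each residue's helix-relative identifier —
Asp 113 is the orthosteric-site aspartate 3.32.

A full-receptor-scale synthetic check is one command away:

```bash
gpcrnet simulate --kind bundle --out bundle.pdb
gpcrnet centrality --pdb bundle.pdb --criterion distance --out-dir out/
```

The 210-residue bundle's centrality profile shows seven peaks, one per
helix, each at mid-membrane height — the knot.

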