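# Methods

This note records the model assumptions, parameter choices, numerical
details and known limitations of mimomap's implementation.

## Problem and model

Given an antigen chain and a set of mimotopes (affinity-selected peptides,
typically ≤ 15 residues), the task is to locate the surface region the
peptides collectively mimic. The antigen surface is modelled as overlapping
patches; each patch is a graph whose vertices are surface residues and whose
edges link spatially close residue pairs; a mimotope is matched to the best
simple path in each graph; evidence is aggregated per patch. The model
assumptions are:

* antibody contact is mediated by side chains, so the Cβ atom is the residue
  anchor for all distances (Cα for glycine and other Cβ-less residues);
* an epitope fits inside a 15 Å-radius surface patch, and patches of more
  than 50 residues (dense cores) are not epitope-like and are discarded;
* mimotopes resemble a *path* of neighbouring surface residues — spatial
  adjacency in the graph stands in for peptide backbone adjacency;
* raw alignment scores across graphs and query lengths are comparable only
  after calibration, handled by an extreme-value null per (graph, length).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| probe radius | 1.4 | Å | rolling-ball solvent probe |
| sphere points | 960 | – | golden-spiral lattice per atom |
| RSA threshold | 0.05 | fraction | surface-residue cut-off |
| patch radius | 15 | Å | Cβ-distance patch membership |
| max patch size | 50 | residues | dense-core exclusion |
| CF band | 0.73 ± 0.06 | – | target compactness e/(4k) |
| start threshold | 6.5 | Å | ADT start, also the FDT value |
| ADT step | 0.01 | Å | threshold increment |
| threshold bounds | [3, 20] | Å | termination guard |
| a constant | 4 | – | expected edges per vertex |
| gap penalty δ | −5 | score | linear gap cost |
| EVD samples | 1000 | peptides | per-(graph,length) calibration |
| EVD seed policy | derived | – | sub-seed per (graph, length) |

The geometric and band parameters are the method's published operating
point. The gap penalty is not published; −5 sits between BLOSUM62's worst
mismatch (−4) and a double mismatch, making a gap costlier than any single
substitution but cheaper than two, and is configurable. The EVD sample count
(1000) balances tail resolution against runtime; the Gumbel fit needs ≥ 200
samples.

## Solvent accessibility

Shrake–Rupley areas use a *deterministic* golden-spiral lattice rather than
random sphere points, so results are reproducible without a seed; 960 points
give < 2% deviation from a 4000-point reference on test structures and an
exact result for isolated spheres. Van der Waals radii are a fixed
element-keyed table (C 1.70, N 1.55, O 1.52, S 1.80 Å), configurable.
Maximum exposed areas default to the Tien et al. (2013) theoretical set; the
table is swappable because published RSA scales differ. Hydrogens are
ignored. ASA is computed on the antigen chain alone — prediction consumes
only the antigen, never the antibody.

## Graph construction

The compactness factor CF = e/(a·k) uses a = 4: in a neighbour-limited
residue graph the expected edge count grows linearly with the vertex count,
not quadratically. The edge rule is distance ≤ threshold (ties at exact grid
distances are measure-zero for real coordinates). The ADT walk starts at
6.5 Å and steps 0.01 Å toward the band; because the edge count is monotone in
the threshold the walk can only approach the band from one side. Three edge
cases are handled explicitly: (a) a band unreachable in principle (e.g. a
2-vertex patch has CF ≤ 1/8) terminates at a threshold bound with
`band_reached=False`; (b) a walk that jumps across the band in one step (many
equidistant pairs, common in idealised geometry) keeps the side whose CF is
closer to 0.73; (c) bounds default to [3, 20] Å so the walk always
terminates. Reported average CF includes unreached-band graphs by default
(flag to exclude).

## Path alignment

States are (end vertex, visited set) pairs; the visited set fits a 64-bit
mask because graphs are capped at 50 vertices. Repeated paths — same end
vertex, same visited set, different permutation — collapse to the single
best-scoring representative at every step. Alignment semantics are local
with free ends: leading/trailing query positions are free, each internal
skipped query position costs δ, and the final score is floored at zero. The
default gap model is deletion-only — every DP step consumes one query
position, matched either to a vertex or to a path gap — which mirrors a
recursion that grows the query one residue per step. Insertion-type gaps
(unmatched path vertices bridging two matched ones) are implemented exactly
behind `allow_insertions=True`; they inflate the reachable state space
combinatorially (every connected vertex superset becomes a state) and are
off by default.

Branch-and-bound uses the admissible bound *score + remaining × max matrix
entry* against the best complete alignment found so far (seeded by a greedy
pass; every DP state is itself a complete alignment because tails are free).
Pruning is strict (`upper < lower`), so scores are provably unchanged —
verified exhaustively against brute-force path enumeration in the tests.
A calibration-oriented batch variant runs the same DP once per graph with a
score *vector* per state (one entry per random peptide) and elementwise
bounds; it is bit-identical to the scalar DP and used wherever only scores,
not explicit paths, are needed. Explicit paths are reconstructed only for
the reported top patches.

## Substitution model

NNK codons (N = A/C/G/T, K = G/T) encode the 20 amino acids with 31 of 32
codons (TAG is the one stop), biasing amino-acid frequencies (e.g. Leu, Arg,
Ser 3/32 vs Met, Trp 1/32). The default matrix replaces BLOSUM62's
query-side background with f_i = codons_i/32 on the half-bit log-odds scale,
rounding to integers: s′(q,t) = round(s(q,t) + 2·log₂(f_q^BLOSUM/f_q^NNK)).
The result is square but asymmetric (rows = library peptide residue,
columns = antigen residue) — an unavoidable consequence of adjusting only
one margin. The matrix ships as a plain-text NCBI-format file and any matrix
in that format can be substituted. Substituting the original background
reproduces BLOSUM62 exactly (tested).

## Score calibration and ranking

Per (graph, query length), 1000 random peptides drawn with NNK amino-acid
frequencies (normalised over the 20 coding letters) are aligned and a
Gumbel(μ, β) is fitted by the method of moments (β = s·√6/π,
μ = mean − γβ) — chosen over maximum likelihood for determinism and a closed
form that tests can verify; ML is available behind a flag. Degenerate
(zero-variance) score samples get a floored scale and a flag. P-values use
the upper tail P = 1 − exp(−exp(−(x−μ)/β)), clamped away from 0 and 1.
"Sum of P-value scores" is implemented as Σ −log₁₀ P so that higher is
better and one strong alignment can outweigh several mediocre ones; summing
raw P-values would reward bad alignments. Ties in patch ranking break by
smaller patch, then center residue number, making ranking deterministic.
Because raw scores are integer-valued, the fitted null is discrete: P-values
of null peptides are uniform only up to score point masses (KS distance
≈ 0.07 at n = 2000 on toy graphs), which the calibration test allows for.
A cheaper `per_antigen` calibration scope (one null per length, fitted on
the largest graph) is available; per-graph is the default because graph size
and composition shift the null noticeably.

## Evaluation

Confusion counts are residue-level over a universe that defaults to the
surface residues of the analysed chain — the method can only ever predict
surface residues, so counting buried residues as true negatives would
inflate MCC; the full-chain universe is selectable. Metrics with a zero
denominator report 0 with a flag rather than NaN.

## Synthetic data

The generator builds ideal-geometry backbones (NeRF chain extension;
N, Cα, C, O plus a pseudo-Cβ at the standard tetrahedral offset for *every*
residue, glycine included) either as an α-helix (φ = −57°, ψ = −47°) — high
surface exposure, non-degenerate patches — or as a jittered "coil"
(±45–75° torsion noise) producing the dense and sparse packing regimes that
exercise the ADT. Epitope planting relabels a connected chain of surface
residues (consecutive anchors within 6.5 Å) found by seeded DFS; mimotopes
are copies of the epitope with per-position NNK-distributed substitutions.

What the toys do *not* emulate: real side-chain atoms (so RSA saturates near
the table maximum only for Ala/Gly), packing defects, multi-chain context,
discontinuous multi-segment epitopes, and realistic mimotope length
heterogeneity. Passing the recovery benchmark therefore demonstrates that
the pipeline's machinery — surface, patches, CF regulation, DP search,
EVD scoring, ranking — is internally sound and sensitive to planted signal
at realistic noise (20% per-position mutation), not that real-antigen
accuracy matches any published benchmark.

The recovery benchmark's study conditions: 28-residue helical antigens with
random sequence, one planted 5-mer epitope (YGVKN), 10 mimotopes at 20%
per-position mutation, 20 seeded replicates, success = top patch containing
≥ 80% of planted residues. 28 residues keeps patch graphs at ≤ ~17 vertices
so a full 20-replicate run with per-graph calibration finishes in a few
minutes; the idealised helix makes distances degenerate enough that the CF
band is often unreachable exactly (handled case (b) above), which the coil
geometry avoids.

## Known limitations

* Single antigen chain only; no assemblies, no mmCIF.
* The exact DP is exponential in the worst case; the 50-vertex patch cap,
  CF regulation and branch-and-bound keep it practical, and an optional
  beam bound (off by default, results then approximate) exists for
  pathological dense graphs with long queries.
* EVD calibration assumes mimotope lengths are few and repeated; a set with
  many distinct lengths multiplies calibration cost.
* The NNK matrix derivation starts from BLOSUM62's rounded integer scores,
  not the unpublished exact log-odds, so entries can differ by ±1 from a
  derivation that re-derives from raw target frequencies.
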