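# Methods

This note records the models, conventions and numerical choices behind
`varmd`, and what its tests do and do not demonstrate.

## The classification model

The working hypothesis is that a functionally impairing substitution changes
the conformational ensemble of the enzyme's active site, and that this
change is visible as dissimilarity between the variant's MD trajectory and
the wild type's when both are projected into a low-dimensional,
catalysis-relevant coordinate system.  The pipeline therefore never scores a
variant in isolation: every statement is relative to the wild-type
trajectory processed identically.

Three coordinate systems are supported:

* **all active-site torsions** — dihedral PCA over every φ/ψ/χ (protein) and
  α…ζ/χ (nucleotide) torsion of the residues within 5 Å of the damaged
  nucleoside;
* **divergent torsions only** — the same after a screen keeping torsions
  whose circular mean in at least one mutant deviates from the wild type by
  more than 36°;
* **catalytic geometry** — the two distances and one angle that position the
  catalytic lysine nucleophile relative to the everted nucleotide
  (d₁, d₂, a₁).

Fewer, mechanism-chosen variables separate trajectories better than the
full torsion set; high dimensionality spreads the projections and washes out
the cluster structure.  This is a property of the method worth keeping in
mind when adapting it to another enzyme: the geometric mode requires real
mechanistic knowledge to pick its variables.

## Conventions and formulas

**Torsions.**  Signed dihedrals in degrees, in (−180°, 180°], IUPAC sign
(right-hand rule about the central bond).  The implementation was
cross-validated against two independent MD packages' dihedral routines.  ω
backbone torsions are excluded by default (near-constant; they only inflate
dimensionality), as is sugar pseudorotation; both are configurable at the
enumeration step.  Torsions whose first/last atom lives in a neighbouring
residue are included when the central bond belongs to a selected residue;
torsions with missing atoms (termini, truncated models) are dropped with a
log entry.

**Circular statistics.**  Means are resultant-vector means
(atan2 of averaged sin/cos); differences are minimal signed differences on
the circle.  A mean is flagged undefined (NaN) when the resultant length is
numerically zero.  The >36° screen additionally requires a two-sample
permutation test on the absolute circular-mean difference to reach
p < 0.001 (10⁴ label permutations, seeded).  Because trajectory frames are
serially correlated, the test operates on frames thinned by a stride
(default 10); the permutation test is distribution-free but thinning is
what makes its nominal level honest for autocorrelated series.

**Dihedral PCA.**  Each torsion θ contributes (cos θ, sin θ) — the standard
dPCA construction, chosen because raw angles are discontinuous at ±180°.
Geometric mode z-scores d₁/d₂/a₁ over the pooled frames (they mix Å and
degrees; disable with `standardize=False`).  The PCA is a single
eigendecomposition of the covariance of the pooled frames of *all*
variants; every variant is projected with the same loadings, otherwise
projections would not be comparable.  Sign convention: the
largest-magnitude element of each loading is positive.  Eigenvalues are
checked non-increasing, loadings orthonormal to 1e−8, and the trace
identity Σλ = total feature variance to 1e−6 relative.

**Trajectory overlap.**  The (PC1, PC2) plane is partitioned into a 10×10
grid whose bounds are the pooled min/max over all variants — shared bins
are what make occupancy overlap meaningful.  Bins are half-open with the
top/right edge closed so every point is binned exactly once.  Overlap is
the Bhattacharyya coefficient on *counts*, BC = Σ√(pᵢqᵢ), so 0 ≤ BC ≤ N by
Cauchy–Schwarz, and N − BC is the distance.  Equal frame counts N across
variants are enforced (the distance scales with N).  N − BC is not a
metric — the triangle inequality is neither claimed nor needed by UPGMA.
Note the coefficient is sometimes written without the radical; only the
radical form satisfies the 0 ≤ BC ≤ N bound that makes N − BC a sensible
distance, so that is what is implemented.

**UPGMA.**  Average linkage computed from the original distances
(unweighted: the mean over all cross pairs), merge height = half the merge
distance, so the tree is ultrametric by construction.  Tied merges are
broken by lexicographic order of the clusters' smallest labels, making the
tree deterministic under label permutation.  Verified against an
independent naive recomputation and against scipy's average-linkage
cophenetic matrices on random inputs.

**Branch classification.**  The root separates the WT-side subtree from the
far subtree; splitting the far subtree once more yields three branches.
The distal branch is the one whose members lie farthest from the wild type
on average.  A subtlety: cophenetic distances cannot rank the two far
branches (both sit at exactly twice the root height from the wild type),
so the implementation uses the original N − BC distances when available and
falls back to cophenetic distances with deterministic tie-breaking.
`distal_affected` calls distal members affected; `proximal_unaffected`
calls everything outside the WT branch affected.  The distal rule
overpredicts less and agrees better with experiment — the proximal rule
inherits every variant that merely fails to cluster tightly with the WT.

**Cohen's κ.**  κ = (p₀ − pₑ)/(1 − pₑ) on 2×2 confusion counts;
pairwise-complete (items with a tie/NA in either rater are dropped); κ is
flagged undefined when fewer than two usable items remain or pₑ = 1.
Summary tables round to 3 decimals, half-up.  Benchmarks include the wild
type as an item (experimentally unaffected, predicted unaffected by every
method) — with only ~13 characterized variants the WT row measurably moves
κ, and the packaged reference values assume it.  Combined-score ties are
excluded from that method's κ by default (count-as-affected/unaffected
policies are selectable).  The MD augmentation adds ±1 to the combined
score by distal-branch membership, after which ties are impossible.

## The synthetic generator

Real inputs are 40 ns solvated MD runs (5000 snapshots at 8 ps; the last
2500 analyzed, after equilibration).  Those cannot be regenerated at desk
scale, so the generator emulates the *statistical* structure the analysis
consumes, not the physics:

* torsions: per-variant hidden metastable states under a Markov switch
  matrix, each state emitting von Mises angles per torsion — circular data
  with clustered populations and temporal correlation;
* geometry: iid Gaussian-mixture draws around conformational cluster
  centres.  The "optimal" catalytic cluster sits at (3.2 Å, 2.8 Å, 160°)
  with σ = (0.3 Å, 0.3 Å, 8°); a displaced cluster at (6.5 Å, 5.5 Å, 100°)
  is >3σ away in every coordinate.  Wild-type-like variants weight the
  optimal cluster ~0.9; impaired variants 0.05.  A second wt-like group
  (weight ~0.35) samples both clusters: real cohorts show such a secondary
  cluster of unaffected variants, and its overlap with both extremes is
  what places the impaired clade as the distal branch rather than as the
  far half of a trivial two-way split;
* the toy complex: 8 amino acids, 3 nucleotides, a damaged-nucleoside
  ligand, choreographed waters and counter-ions.  Atoms are placed by
  internal-coordinate (NeRF) construction, so the scripted side-chain and
  nucleotide-backbone dihedrals are exact by construction; frames are rigid
  global motions, so all internal coordinates are frame-invariant.

Defaults mirror the study conditions: 21 variants (wild type + 20 mutants),
2500 analyzed frames, 3 planted impaired variants.  All generators are pure
functions of (spec, n_frames, seed), with per-variant substreams derived
from the seed and the variant id.

What passing tests therefore show: the analysis machinery — screening, PCA,
overlap, tree, branch calls — recovers planted ensemble differences of the
designed magnitude essentially always (≥95 of 100 seeds, observed 100/100).
What they do not show: that real force-field trajectories of a particular
enzyme separate this cleanly, that 40 ns suffices for convergence, or that
the geometric variables chosen for one enzyme transfer to another.

## Degenerate inputs and edge policies

* Multi-model files with inconsistent atom tables are rejected, naming the
  first divergent atom and model.
* Collinear central atoms make a dihedral undefined: the frame gets NA and
  is logged; NA frames are dropped per variant at feature assembly and all
  variants are trimmed to the common frame count (equal N is required
  downstream).
* A degenerate grid axis (max = min) is expanded by a machine-scale epsilon
  with a warning.
* A far subtree that is a single leaf degenerates the three branches to
  {WT side, that leaf, ∅}; handled with a warning.
* Mutated models truncate side chains to Cβ (to CA for glycine) rather than
  rebuilding rotamers — the standard hand-off convention to downstream
  modelling tools, which rebuild and refine anyway.
* Residue numbering is taken as authored, insertion codes included in the
  residue key; identity of the mapped reference residue is always verified
  (a mismatch is an error, not an "unmapped").

## Known limitations

* The Bhattacharyya distance saturates at N for non-overlapping clouds, so
  very distinct variants become mutually equidistant; the tree then orders
  them by their residual overlaps only.
* κ confidence intervals and weighted/multi-class κ are out of scope.
* The variant catalogue reader is offline-only by design (local TSV
  snapshots); live database access belongs in a separate fetcher.
* Active-site extraction on a real crystallographic complex (e.g. the
  OGG1–DNA reference structure, where the 5 Å rule yields 23 amino acids
  and 3 nucleotides) requires an external structure download and is left as
  an optional check outside the test suite.
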