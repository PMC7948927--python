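# varmd

Functional classification of protein missense variants from
molecular-dynamics trajectory analysis.

Tumour genomes carry many missense variants of unknown significance in DNA
repair genes.  For an enzyme like 8-oxoguanine DNA glycosylase (OGG1), the
question is whether a given substitution impairs catalysis.  Sequence-based
predictors (SIFT, FATHMM, MutationTaster, PROVEAN) answer from conservation
alone and frequently disagree; `varmd` implements the complementary,
structure-dynamics route: compare the MD trajectory of each variant with the
wild type in a functionally meaningful coordinate system and call variants
whose active-site dynamics are most dissimilar "affected".

## What the pipeline computes

1. **Variant → structure mapping.**  Missense records (`p.Arg229Gln`) from a
   catalogue snapshot are mapped through a global Needleman–Wunsch alignment
   (BLOSUM62, gap 10/0.5) onto the structure's residues — isoform numbering
   differences are handled by alignment, and the reference residue identity
   is always verified.  A seeded uniform sample of variants is emitted as
   single-mutation PDB models (side chains truncated to Cβ for downstream
   rebuilding).  Kabsch superposition is provided for model assembly.
2. **Active-site features.**  The active site is every protein/DNA residue
   with an atom within 5 Å of the damaged nucleoside.  From trajectories
   (multi-model PDB; binary readers plug in via the same atom-table/frames
   contract) the pipeline extracts all active-site torsions (φ, ψ, χₙ; for
   nucleotides α…ζ and χ) and the three catalytic-geometry parameters of the
   OGG1 dyad: d₁ = Nζ(K249)–C1′(oxodG), d₂ = min Oδ1/Oδ2(D268)–O4′(oxodG),
   a₁ = Nζ–C1′–N9.  Bulk solvent is stripped; waters within 5 Å of the
   ligand in ≥10 % of frames are kept.
3. **Dimensionality reduction.**  Dihedral PCA (each torsion enters as
   cos θ, sin θ, avoiding the ±180° seam) or PCA of the z-scored geometric
   variables, fitted once on the pooled frames of all variants.  An optional
   screen keeps only torsions whose circular mean deviates >36° from the
   wild type in some mutant (permutation test, p < 0.001).
4. **Trajectory clustering.**  The (PC1, PC2) plane is partitioned into a
   shared 10×10 grid; each trajectory becomes an occupancy count grid, and
   overlap is the Bhattacharyya coefficient on counts,

   BC(p, q) = Σᵢ √(pᵢ qᵢ),  0 ≤ BC ≤ N,

   with N − BC the inter-trajectory distance.  UPGMA (average linkage)
   turns the distance matrix into an ultrametric tree (Newick export), and
   variants are called affected/unaffected by their branch relative to the
   wild type (distal-branch-affected or proximal-branch-unaffected rules).
5. **Agreement statistics.**  Cohen's κ = (p₀ − pₑ)/(1 − pₑ) quantifies
   agreement between any two binary raters; the module builds rater-vs-rater
   κ matrices, the four-predictor combined score (+1 tolerated / −1
   deleterious), and benchmark tables of predictions against experimental
   activity labels under explicit scenarios for ambiguous variants.

A seeded synthetic generator (`varmd.synthetic_data`) produces torsion
trajectories (hidden-state von Mises mixtures) and catalytic-geometry
trajectories (Gaussian mixtures with a dense "optimal" cluster) with planted
impaired variants, plus a toy protein–DNA–ligand complex with analytically
known torsions for validating the structure-handling code.

## Worked example

```python
from varmd.synthetic_data import ogg1_like_preset, gen_geometry_set
from varmd.pipeline import run_pipeline

specs, truth = ogg1_like_preset(n_variants=21, n_impaired=3, seed=1)
geo = gen_geometry_set(specs, n_frames=2500, seed=1)
res = run_pipeline("geometric", geo, "WT", rule="distal_affected")
print("planted impaired:", truth["impaired"])
print("called affected :", sorted(v for v, c in res.calls.items() if c == "affected"))
```

prints

```
planted impaired: ['M09', 'M10', 'M16']
called affected : ['M09', 'M10', 'M16']
```

— the distal branch of the overlap tree contains exactly the three variants
whose generative model barely populates the catalytically optimal geometry
cluster.  PC1 carries 94.7 % of the pooled variance in this run, i.e. the
optimal-vs-displaced conformational axis.

Benchmarking the packaged OGG1 predictor calls against the experimental
labels (wild type included; combined-score ties excluded; `combined+md`
augments the combined score with the distal-branch membership of the
geometric-PCA tree):

```python
from varmd import agreement as ag
rep = ag.benchmark(ag.load_ogg1_calls(), ag.load_ogg1_labels(),
                   ag.ogg1_scenarios(), md_affected=set(ag.OGG1_MD_DISTAL))
print(rep.rounded())
```

```
                ambiguous_neutral  ambiguous_affected
SIFT                        0.340               0.314
FATHMM                      0.152               0.317
MutationTaster              0.263               0.208
PROVEAN                     0.533               0.553
combined                    0.519               0.530
combined+md                 0.533               0.553
```

The columns are the two ways of resolving the two mildly affected variants
(R161W, S292N); each cell is Cohen's κ between that method's calls and the
experimental classification over the 14 characterized items.

The same stages are available as a CLI:
`varmd simulate | features | reduce | cluster | classify | kappa | benchmark |
map-variants` (see `varmd --help`).

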