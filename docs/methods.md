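# Methods

## Problem and approach

`seqsubtype` discovers functional subtypes within an enzyme family from
protein sequences alone, without alignments or homology, and trains a
classifier to assign new sequences to the discovered subtypes.  The
motivating use case is enzyme families (such as the multi-copper oxidase
laccases, EC 1.10.3.2) whose conventional classification follows species
taxonomy rather than enzymatic properties, while measurable physicochemical
signals — charge composition, isoelectric point — track function.

The pipeline is: descriptor encoding → repeated SOM-seeded clustering with
a Davies–Bouldin-guided cluster count → consensus selection → one-vs-rest
RBF-SVM classification → evaluation and feature attribution.

## Descriptor encodings

Ten fixed-length encodings are implemented (dimensions in parentheses):
amino acid composition (20), dipeptide composition (400), conjoint triad
over 7 residue groups (343), composition/transition/distribution (63),
Moran, Geary and Moreau–Broto autocorrelation (240 each), a
physicochemical summary (24), split amino acid composition (60) and the
AAC‖physicochemical composite (44).  Conventions worth noting:

- All composition-type values are fractions in [0, 1] (not percentages);
  dipeptide and triad windows overlap, with denominators L−1 and L−2.
- CTD distribution features are the sequence positions (percent of length)
  of the first, 25%, 50%, 75% and 100% occurrence of each residue group,
  with the j-th quantile occurrence taken as occurrence ⌈q·count⌉; absent
  groups report 0 at all five positions.
- Autocorrelation uses eight classical residue scales (hydrophobicity,
  flexibility, polarizability, free energy of solution in water,
  accessible surface area, volume, steric parameter, relative mutability),
  z-normalized over the 20 residues.  The scales ship as a plain-text
  table (`data/aa_properties.tsv`) and can be replaced via `PropertySet`.
  Constant property profiles would zero the Moran/Geary denominators; the
  value is defined as 0 in that case.  Moreau–Broto is divided by the
  number of terms (N−d) by default so magnitudes are length-independent;
  a flag restores the raw sum.
- The physicochemical vector contains log- and titin-scaled molecular
  weight and length (denominators 7, 5, 4×10⁶ and 38,000), 19 residue-class
  fractions, and pI/14, so every element lies in [0, 1].  Molecular weight
  is the sum of average residue masses plus one water.  The isoelectric
  point solves net charge = 0 by bisection on pH ∈ (0, 14), using a
  Henderson–Hasselbalch charge model over both termini and the D, E, C, Y,
  H, K, R side chains (pKa set: N-term 9.69, C-term 2.34, D 3.65, E 4.25,
  C 8.3, Y 10.07, H 6.0, K 10.53, R 12.48), to |charge| < 1e-4.

## Cluster-count selection and consensus

A rectangular online SOM (default 10,000 iterations, learning rate 0.05 →
0.01, prototypes initialized from data points, Gaussian neighborhood) maps
the data; the occupied neurons, with member-mean centroids, form an
initial over-clustering.  All pairwise merges are then evaluated and the
merge yielding the lowest Davies–Bouldin index is accepted while it
improves the current index; the surviving count k and centroids seed Lloyd
k-means (assignment ties to the lowest index; an emptied cluster is
re-seeded with the point farthest from its centroid).  The DBI uses
root-mean-square within-cluster scatter (exponent q = 2) and Euclidean
centroid separation (Minkowski p = 2); coincident centroids are rejected
as degenerate.

Because a single run is stochastic, the procedure repeats over a sweep of
grid dimensions (default {5×5, 5×6, 6×5, 6×6, 7×7, 8×8}, 500 runs per
dimension by default, scaled down in tests), each run with a seed derived
from the base seed.  The modal k across runs (ties to the smaller k) is
the consensus subtype count; among modal-k runs the best run maximizes
inter-cluster minus intra-cluster variance (mean pairwise centroid
distance minus mean point-to-centroid distance), with ties broken by
smaller DBI and then smaller seed.  A sample co-occurrence matrix (how
often each pair shares a cluster across runs) summarizes stability.

**Neighborhood schedule.**  The SOM radius decays linearly from
max(rows, cols)/2 to 80% of that value by default (configurable).  This
"stiff map" choice is deliberate and load-bearing: a conventional decay to
radius 1 turns the SOM into a fine vector quantizer that carves each data
mode into many crisp, well-separated micro-clusters, and greedy DBI
pair-merging then fails in two characteristic ways — it stalls far above
the true cluster count (merging two crisp micro-clusters raises the
index), or, in higher dimensions, it prefers merging clusters from
*different* modes, because a huge diffuse cluster centred in the empty
space between modes has a low worst-case scatter-to-separation ratio and
its creation removes two high-ratio clusters from the mean.  Keeping the
map stiff leaves the occupied neurons of one mode overlapping, which is
the regime in which the greedy merge cascades to the correct count.  On
planted Gaussian blobs at 10× separation-to-spread the stiff default
recovers k ∈ {2..5}; the decay-to-1 schedule recovers k = 2 in under a
quarter of consensus runs.

**Known limitation.**  At realistic (non-blob) class separations the
merge over- or undershoots the planted count by one to three clusters
from run to run even when the partition itself agrees well with the
planted one (adjusted Rand 0.8–0.98); the consensus mode inherits some of
this scatter.  The greedy, single-step-lookahead minimization of a
mean-of-max index is intrinsically local; no claim of global DBI
optimality is made.

## Supervised stage

A stratified 90/10 split reserves an independent test set; the training
side is dealt round-robin (after per-class shuffling) into 5 stratified
folds.  One binary RBF-kernel SVM per class is trained class-vs-rest
(scikit-learn SVC; shared C and gamma); prediction is the argmax of the
per-class decision values.  C and gamma default to a powers-of-two grid
(C ∈ 2⁻²..2⁸, gamma ∈ 2⁻⁸..2²) selected by mean cross-validated overall
accuracy on the training folds only, ties to the smallest values; class
reweighting is off by default and exposed as a flag.

Per-class metrics follow the one-vs-rest confusion counts: SEN, SPE, ACC,
ERR, PER on percent scale and MCC; zero-denominator metrics report 0 with
an explicit flag.  ERR is computed as 100 − ACC.  The overall row is the
unweighted macro-average; the pooled multiclass accuracy is reported
separately.  ROC curves sweep score thresholds; the trapezoid AUC equals
the Mann–Whitney pairwise-comparison probability, ties counted half.

## Feature attribution

Features are ranked by one-way ANOVA F across subtype labels (only the
ranking is interpreted).  Class-pairwise tests use Welch's unequal-variance
t-test — discovered subtypes are typically very unequal in size, which
makes the pooled-variance test anticonservative — with raw p-values by
default and optional Bonferroni correction.  Per class pair, the three
features with the largest two-class F are listed.  Zero-variance features
within a pair are flagged degenerate with p = 1.

## Synthetic data

`fixtures.gen_labeled_sequences` draws i.i.d.-residue sequences with
lengths uniform on 200–600.  The default twelve classes lie on a 4×3 grid
of acidic (D+E ∈ {0.02, 0.18, 0.34, 0.50}) by basic (K+R ∈ {0.03, 0.16,
0.29}) composition, the remaining mass spread uniformly over the other 16
residues; classes therefore separate on the charged/acidic/basic residue
fractions and on pI, the axes that dominate real enzyme-subtype
separations.  The tier spacing is about eight multinomial sampling
standard deviations at the shortest length, so the planted structure
dominates sampling noise while class tails still overlap.  The model has
no positional structure — no motifs, domains or conserved sites — so
passing tests demonstrate recovery of composition-scale structure, not of
homology-scale structure in real proteins.

`fixtures.gen_blobs` places k Gaussian blob centroids on a randomly
rotated regular simplex (k ≤ dim), making every pairwise centroid distance
exactly the requested separation; for k > dim it falls back to an axis
lattice.  Equal spacing matters: with strongly unequal centroid distances,
merging the closest pair of genuine clusters can legitimately lower the
DBI, which turns a cluster-count benchmark into a test of the centroid
layout instead.

## Problem sizes and numerical choices

Tests and the acceptance script run the study at desk scale: 12 classes ×
30 sequences (360 records, 24 physicochemical features), consensus sweeps
of 10–20 runs over one or two grid dimensions, and blob benchmarks with
25 points per cluster in 5 dimensions.  Determinism is enforced
throughout: every stochastic step derives its seed from a caller-supplied
base seed, ties (equal distances, equal DBI, modal-k ties) resolve to the
lowest index/value, and re-running any stage with the same inputs and seed
reproduces its artifacts byte-for-byte.  Candidate merges during neuron
merging are evaluated incrementally from cached member sums and
sums-of-squares (exact at q = 2), so a merge step costs O(k² (k + d))
rather than a full re-clustering pass per candidate.
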