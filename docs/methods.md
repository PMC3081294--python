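# Methods

## Coarse-grain structure model

A protein partner is reduced to one node per residue: the unweighted mean
of the side-chain heavy atoms plus Cα (glycine: Cα alone; hydrogens
excluded; alternate locations resolved to the highest occupancy; waters
and hetero groups skipped). Coordinates are Å, used as read, with no
re-centering. Residues with partially missing side chains use the atoms
present — a robustness choice for unbound experimental structures.
Residues lacking a Cα are skipped with a warning; fewer than four usable
residues is an error, since a 3-D triangulation needs four non-coplanar
points.

Each node carries a residue type, its category under the six-way
partition hydrophobic {I,L,V,M}, aromatic {F,Y,W}, small {A,G,S,T,C,P},
polar {N,Q}, positive {H,K,R}, negative {D,E}, and a mean residue volume.
The default volumes are the Pontius et al. (1996) Voronoi mean volumes
(Å³), shipped as `voroscore/data/pontius1996_volumes.tsv`. The table is
replaceable data, not a correctness anchor: any 20-entry positive table
can be supplied via `load_volume_table(path)`.

## Voronoi tessellation and interface definition

The merged receptor+ligand node set is tessellated with qhull
(scipy.spatial). Two dummy point sets close the diagram and never appear
in outputs:

* **Solvent layer.** Surface cells are unbounded, and the shared facet of
  a cross-partner pair at the interface *rim* extends arbitrarily far into
  solvent, which would make "interface area" depend on where the diagram
  is truncated. We therefore cap every exposed cell locally: dummy
  "waters" are placed ~4 Å above each exposed node (and above exposed
  surface edges) along the outward radial direction, iterating up to
  three times until no real cell reaches the outer shell. Because the
  layer is built from the node coordinates alone it moves rigidly with
  the structure, making adjacency, cell volumes, and facet areas
  invariant under rigid motions (verified to 1e-6 relative tolerance)
  and insensitive to the outer shell (doubling its radius changes the
  interface area of a compact complex by < 0.1 %). An early shell-only
  closure failed both properties; the solvent layer is also the natural
  reading of interfaces that include residues in contact with solvent.
* **Bounding shell.** A sphere of twice the cloud's bounding radius,
  sampled at ~8 Å spacing (capped at 1500 points), bounds the water
  cells themselves.

The interface is the set of residues whose Voronoi cell shares a
positive-area facet with a cell of the other partner; facet areas are
counted once per unordered pair, and their sum is the Voronoi interface
area (Å²). Solvent contact never removes a residue from the interface.
Degenerate inputs (duplicate/coplanar points) trigger one deterministic
jitter-and-retry pass (1e-6 Å Gaussian noise seeded by the node count)
before erroring.

Per-partner Delaunay triangulations (no closure) are a separate
computation used only for pseudo-normals.

## Pose generation

Each node's pseudo-normal is the negated sum of edge vectors to its
Delaunay neighbors; when it still points into the body it is flipped.
The inward test — negative dot product with the node's offset from the
partner centroid — is a deliberately cheap heuristic, exact for
star-convex bodies. Near-zero sums (symmetric interior nodes) are
dropped. Vector length is the radius of a sphere with the residue's mean
volume, (3V/4π)^(1/3).

A pose is built per (receptor vector u, ligand vector v, spin angle):
translate the ligand so the vector tips coincide, rotate it so v opposes
u exactly (the paired normals are always anti-parallel; the inter-normal
angle is not a degree of freedom), then spin about the u axis in 5°
steps. The spin origin aligns the projection of the ligand's first
principal axis onto the plane perpendicular to u with a reference vector
derived from u alone, so the stream is a pure function of its inputs
(byte-identical across runs).

Decoy selection keeps poses with interface area ≥ 400 Å² and ligand-node
RMSD to the native > 10 Å, then samples a fixed number per native
(default 15) uniformly with a caller-supplied seed. RMSD is computed
over ligand nodes with the receptor frame fixed — no re-superposition,
since generation already shares the receptor frame. A pose whose
partners' closest nodes are > 16 Å apart is screened out before
tessellation (no facet can cross two solvent-layer thicknesses).

## Interface descriptor (96 attributes)

c₁ area; c₂ interface residue count; c₃–c₂₂ residue-type fractions and
c₂₃–c₄₂ mean cell volumes (alphabetical one-letter order, both partners
pooled); c₄₃–c₆₃ category-pair fractions of cross pairs and c₆₄–c₈₄ mean
node–node distances (21 unordered pairs, row-major upper-triangle order
over hydrophobic, aromatic, small, polar, positive, negative); c₈₅–c₉₀
category fractions; c₉₁–c₉₆ category mean cell volumes. Fractions are
over the entities present, so each fraction block sums to 1 on a
non-empty interface. Block-internal ordering is a documented convention;
learning is order-agnostic.

Missing values are a mask, not a number: an attribute whose defining set
is empty (e.g. no polar–negative cross pair) gets mask=True and a 0.0
sentinel that downstream code never reads as data. Learning-set assembly
drops any decoy with more than twice its native's missing count
(configurable factor), mirroring the idea that heavily masked negatives
carry little signal and distort training.

## Evolution-strategy scoring

S(x) = Σᵢ wᵢ(xᵢ − cᵢ) over unmasked attributes; higher is more
native-like. An absolute-deviation variant Σ wᵢ|xᵢ − cᵢ| sits behind
`form="absolute"` for sensitivity checks. Masked attributes contribute
zero — consistent with training on low-missingness data.

Training is a (μ+λ) ES per cross-validation fold: individuals are
(w, c, σ) with one self-adapted step size per gene (d = 192); children
arise by discrete (default) or intermediate recombination of two uniform
parents, a log-normal σ update with the standard rates τ = 1/√(2√d),
τ′ = 1/√(2d), and Gaussian gene mutation; the best μ of parents ∪
children survive, so best fitness is non-decreasing. Fitness is the
Mann–Whitney (rank-based, tie-averaged) ROC AUC on the training fold;
non-finite individuals are discarded. Defaults μ=10, λ=70 (the
conventional 1:7 ratio), σ₀=0.1, at most 500 generations with a
50-generation stagnation stop. Folds are split at complex level
(GroupKFold on complex id) so a native and its decoys never straddle the
train/test boundary.

Because the ES is stochastic, each fold is trained over several seeded
runs (default 30) and candidates are ranked by the *sum of ranks* across
the whole family (lower = better, average-rank ties). On synthetic data
the across-resample variance of held-out AUC falls monotonically as the
number of runs grows from 1 to 30, which is why 30 is the default.

## Collaborative filtering

The roster mirrors a 12-learner ensemble: logistic regression, SVM with
RBF and quadratic kernels, and nine decision-tree variants of graded
structure (entropy trees at min-leaf 2/5/10; shallow gini trees and
depth-limited entropy trees as rule-learner analogues). The original
C4.5/RIPPER/PART and SVMlight implementations are not reimplemented —
the CF layer treats base learners as black boxes with a fit/predict
contract, and any sklearn-style binary classifier can be plugged in.
Precisions are measured on stratified 10-fold held-out predictions;
members below 0.5 (worse than random) are discarded.

Uniform voting ranks by the number of + votes (k classifiers ⇒ k+1
categories). Weighted voting ranks by S⁺ − S⁻, the precision sums of
positive and negative voters; with k *generic* distinct precisions all
2ᵏ sign patterns map to distinct scores. Caveat: arithmetic-progression
or low-precision (e.g. 3-decimal) precision vectors create subset-sum
collisions and fewer reachable categories — the module logs a warning
when precisions are not distinct, and `reachable_categories` measures the
actual count by enumeration.

CF–GA fusion assigns each positively-voted pose the value
GA_rank × exp(S⁻ − S⁺) and sorts ascending; all-negative poses take a
maximal sentinel and occupy the last ranks in stable input order. This
ascending-better / sentinel-worst convention is fixed here as the only
orientation under which all-negative poses rank last and unanimous
positives with GA rank 1 attain the global minimum. The alternative
cascade (`cf_then_ga`) keeps the weighted-CF top T and orders it by GA
rank, with the remainder following in CF order; T is configurable.
Granularity — distinct scores divided by set size — quantifies how far a
ranking is from a total order. A greedy diversity pass keeps a pose only
if its ligand-node RMSD to every better-ranked kept pose exceeds 5 Å.

## Quality assessment

All measures operate on coarse nodes; the package never rebuilds
all-atom models, and every rendered report says so. Native contacts are
cross-partner node pairs within 5 Å by default (the atom-level contact
convention carried to the coarse model) or, optionally, Voronoi cross
neighbors. fnat is the fraction of native contacts present in the
prediction. I_RMSD superposes the native-interface nodes (both partners)
by least squares and measures their RMSD; L_RMSD superposes the larger
partner and measures the smaller.

The fnat-only classes use the 0.5/0.3/0.1 thresholds. The full CAPRI
classes use the standard cascade: High requires fnat ≥ 0.5 with
I ≤ 1 or L ≤ 1; Medium fnat ≥ 0.3 with I ≤ 2 or L ≤ 5 (not High);
Acceptable fnat ≥ 0.1 with I ≤ 4 or L ≤ 10 (not better); else
Incorrect. High-fnat poses failing an RMSD test cascade downward to the
tier whose caps they meet. Printed renderings of these rules elsewhere
contain transcription slips (a disjunct that would promote arbitrary
bad-RMSD poses); this module implements the standard criteria and the
cascade guarantees the CAPRI tier never exceeds the fnat-only tier.
Missing RMSDs fall back to the fnat-only class with a flag.

Enrichment compares the proportion of level-or-better poses in the best
(and worst) ⌈20 %⌉ of ranks with the complete-set proportion, flagged
undefined when the set contains none. Report tables give per target and
method the best class in the top 10, N (level-or-better poses in the top
10), and R (rank of the first such pose anywhere); summary means can
exclude targets whose first hit is too deep to be meaningful. The
concordance summarizer reduces an fnat-class × CAPRI-class contingency
table to the three agreement percentages used to compare the schemes.

## Synthetic fixtures

Toy "proteins" are compact residue-node clouds: points packed in a ball
at ≥ 3.8 Å nearest-neighbor spacing (the Cα virtual-bond distance), with
uniformly random residue types, serialized as valid PDB (Cα plus one
pseudo side-chain atom straddling each node so the loader exercises its
real averaging path; glycine writes Cα only). A native complex is built
by sliding the ligand cloud along an axis until a requested number of
contact pairs falls within 6 Å; decoys re-dock the ligand from random
directions, sliding inward until the Voronoi interface reaches 400 Å²,
at > 10 Å RMSD from the native — reproducing the native:decoy structure
of a docking learning set (1 positive : 15 negatives per complex by
default) without pose enumeration. Planted feature sets draw positives
and negatives from 96-dimensional Gaussians differing by a configurable
effect size in the first ~10 % of coordinates, with planted missingness
around the twice-native filter threshold. Vote fixtures simulate
classifiers that answer correctly with probability equal to their
nominal precision, plus a GA ranking correlated with the labels.

Everything is a pure function of (spec, seed): same seed, byte-identical
PDB output.

What the fixtures do *not* emulate: real fold geometry, secondary
structure, chemically plausible residue neighborhoods, bound/unbound
conformational change, or the size and redundancy structure of a real
benchmark. Passing tests therefore demonstrate algorithmic correctness
and the qualitative behaviors of the stack (signal recovery, run-count
stabilization, ensemble FNR decrease, enrichment), not attainable
accuracy on experimental complexes.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: toy
complexes of 30+30 residues, feature sets of ~160 vectors over 10
complexes, ES budgets of μ=5, λ=20, 50 generations and 3 runs per fold
for recovery checks (μ=4, λ=12, 8–10 generations for trend checks), vote
fixtures of ≤ 400 items, and geometry oracles on ≤ 50-node clouds.
Facet areas below 1e-9 Å² are treated as zero; AUC improvements below
1e-12 count as stagnation; the category-score enumeration rounds to 12
decimals before counting distinct values. Ties are averaged everywhere a
ranking is formed; sentinel-ranked items preserve input order.

## Known limitations

* The pseudo-normal inward test assumes roughly star-convex partners;
  deeply concave pockets can retain an inward vector.
* The solvent layer caps cells at a fixed 4 Å offset; unusually sparse
  coarse models (inter-node gaps ≫ 4 Å) could leak facets to the outer
  shell, logged as a warning.
* Rank sums of few functions over few items collide occasionally, so
  aggregate rankings are near-total rather than total orders.
* Trimeric or multi-interface assemblies are out of scope: the stack
  searches for a single best interface.
* Protein–nucleic-acid partners are not modeled.
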