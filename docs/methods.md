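# Methods

This note documents the models behind `socioglia`'s measurements and
synthetic-data generators, the defaults and why they were chosen, the
numerical conventions, and the limits of what passing tests demonstrate.

## Behavior

A trajectory is a per-frame 2D position (mm) with an optional heading
channel (degrees), a frame rate, a body length, and an arena with the
divider on a named wall. Metrics are per-frame averages with no
temporal smoothing.

- **Orienting** uses the heading folded against the divider *line* into
  [0°, 90°]: both toward- and away-facing headings inside the 45–90°
  band count, since only the angular band defines the behavior. With
  headings uniform on the circle the folded angle is uniform on
  [0°, 90°], so baseline orienting is exactly 50%.
- **Heading when absent** is derived from displacement vectors. Frames
  with (numerically) zero displacement carry the last defined heading;
  frames before the first movement have no heading and are dropped from
  the orienting denominator, because a displacement heading is
  undefined at rest. Whether the original assay measured body-axis or
  displacement orientation is not determinable from the assay
  definition; both channels are supported and displacement is the
  default.
- **Motion filter**: a frame is in motion if the fish displaced at
  least body_length/3 since the previous frame; frame 0 inherits frame
  1's state. Fish in motion for strictly less than 10% of the assay
  are excluded; exactly 10% is retained.
- **Proximity** is reported on the 1 − d/L scale (1 = at the divider)
  so that larger values mean more social; the raw mean distance is also
  retained.

### Dyad generator

Swimming is bout-structured: bout onsets are Bernoulli per frame
(Poisson at `bout_rate` = 1/s in continuous time), each bout lasts 2
frames (0.2 s, a beat-and-glide timescale at 10 fps), and per moving
frame the displacement is drawn around `swim_speed_mean/fps` with the
burst speed defaulting to 20 mm/s so that bout displacements
(~2 mm/frame) clear the 4/3 mm motion threshold of a 4 mm fish —
without bouts the in-motion filter would be degenerate. Between bouts
the fish is stationary.

`sociality` ∈ [0, 1] controls the probability that a bout is *social*:
the fish steers into an 8 mm divider-adjacent strip with its folded
divider angle drawn uniformly from [45°, 90°]; non-social bouts head
uniformly on the circle. Socially engaged fish also swim more — the
bout rate scales by (1 + 0.5·sociality) and burst speed by
(1 + 0.2·sociality) — so that *all four* reported metrics (proximity,
orienting, percent in motion, swim speed) increase with social drive,
which is the generator's defining contract. At sociality 0 the fish is
a bout-structured random walk (proximity ≈ 0.5, orienting ≈ 50%); at
sociality 1 it hovers at the divider (proximity ≈ 0.94, orienting
≈ 100%).

The optomotor generator emits distance-to-centre traces at 30 frames/s:
20 s of centerward drift at `attraction` mm/s plus optional Gaussian
noise, then 20 s of mild outward drift, from a 30 mm start radius in a
50 mm dish. When the trial count is unspecified it is drawn uniformly
from [46, 59], the per-fish range of a one-hour session.

## Morphometry

SWC trees are validated on construction (single root, no dangling
parents, no cycles, finite coordinates). Lengths are center-line sums;
node radii are carried through I/O but never enter any metric (no
frustum corrections).

**Sholl profile.** Spheres are centred on the root (soma) coordinate;
the soma radius is ignored. The shell step defaults to 1 µm radius
increments, configurable: the assay description ("increasing in
diameter by 1 µm") literally implies 0.5 µm radius steps, but
conventional Sholl and the figure axes (radii in µm up to 160) indicate
1 µm radii, so 1 µm is the default. Crossings are counted exactly per
edge from the convex distance function |p(t)|: each edge is split at
its interior distance minimum (if any) into monotone halves; a monotone
half crossing from the parent side counts shells in a parent-exclusive,
child-inclusive interval, so a node lying exactly on a sphere
contributes one crossing attributed to its parent-side edge, and an
edge exactly tangent to a sphere counts once. Equality with a sphere is
detected with a 1e-9 relative tolerance.

**Features.** The 13-feature vector is: total_length,
mean_branch_length, arbor_depth, n_branch_points, n_tips, n_branches,
max_euclidean_distance, max_path_distance, sholl_total, sholl_max,
sholl_max_radius, sholl_radius_at_max, bounding_box_volume. The
original workflow extracted 13 Imaris features but enumerates only
seven (lengths, depth, four Sholl statistics); the remainder here are
standard skeleton statistics, a documented reconstruction. A *branch*
is a maximal path between consecutive topological nodes (root, branch
points, tips); *arbor depth* counts bifurcations strictly after the
root on the deepest root-to-tip path (a root of degree ≥ 3 counts as a
bifurcation). Note the identity n_branches = n_branch_points + n_tips
holds by construction, which makes the 13-feature correlation matrix
exactly singular — see Morphotyping.

**Microglial skeletons.** Endpoints are non-root degree-1 nodes; the
root counts as an endpoint only for an unbranched path (both ends are
then process tips). Time-series variability is the sample variance
across timepoints divided by the mean (var/mean); var/mean² (CV²) is
available via a flag since the naming is ambiguous in common usage.

### Arbor generator

A branching process grown in 1.7 µm steps: at each step a tip
bifurcates with probability `branch_prob_per_um · step` (15% of branch
events are trifurcations, as occur in real reconstructions), continues
with a 15° direction wobble (tortuosity), or stops. Tips stop at a
territory boundary 45 µm from the soma — emulating arborization within
a bounded connective zone — or when their path reaches 120 µm, and
growth stops globally at 400 µm of total cable. The trunk leaves the
soma within a 60° cone of a preferred axis, as for a projection neuron
population. Stochastic per-step termination is available but defaults
to zero: a death rate d gives every arbor an extinction probability
d/b of collapsing to an uninformative stub, which destroys the
identifiability of the branching rate from morphology; boundary-limited
growth matches the biology (neurons fill a target territory) and keeps
both planted populations unimodal.

The step length (1.7 µm) is deliberately incommensurate with the 1 µm
shell step, and the wobble prevents collinear node runs; without these,
nodes fall exactly on Sholl spheres systematically and the exact-versus-
sampled comparison would be dominated by ties that cannot occur in real
reconstructions.

Scale note: the territory (45 µm) and cable budget (400 µm) are a
desk-scale version of real vTel arbors (connective zones beyond 100 µm,
arbors to hundreds of µm); all geometry code is scale-free, verified by
the isotropic-scaling invariance tests.

## Morphotyping

Features are z-scored per column (sample SD; constant columns map to
zeros with a warning). Clustering is agglomerative with average
linkage — the same algorithm SPSS calls "between-groups linkage" — on
squared Euclidean distances, with merge heights reported on the squared
scale; flat labels come from cutting the tree to k clusters (k is a
user choice; the original dendrograms are shown uncut).

Factor analysis is principal-axis factoring on the sample correlation
matrix: communalities start at squared multiple correlations and are
iterated to 1e-6; the factor count defaults to the number of
eigenvalues above 1; retained loadings are varimax-rotated (via
statsmodels' rotation routines) and per-observation scores use the
regression (Thurstone) method. Because n_branches = n_branch_points +
n_tips exactly, the correlation matrix of the 13 features is always
rank-deficient; communalities and score weights therefore use the
pseudoinverse, with a warning naming the dependent columns. Exactly
duplicated features (|r| = 1 pairs) are rejected as ill-posed instead.

The complex/simple boundary is data-driven: on the score of the factor
most loaded on total length, a two-component 1-D Gaussian mixture
(deterministically initialized at the score quartiles) supplies the
posterior-crossing threshold. An equal-variance split (Otsu-style,
minimizing within-class variance) is available as `method="otsu"` but
is not the default: when the simple class is much more dispersed than
the complex one — the typical case for arbor morphologies — the
variance-minimizing cut provably lands inside the dispersed class
rather than in the between-class density gap, mislabeling 10–15% of
neurons. A fixed threshold can be supplied to mimic a hand-drawn
boundary.

**Known limitation.** At roughly 1 in 20 random draws of the planted
two-morphotype experiment (n = 60 + 60), the k = 2 average-linkage cut
isolates a single extreme arbor instead of splitting the two
populations, collapsing label agreement to ~51% on that draw while
neighboring draws give 97–100%. This is classic average-linkage
outlier behavior, not a property of the planted effect; the acceptance
script therefore reports the median agreement over five independent
draws.

## Volumetrics

Voxel convention: 0-based indices, world coordinate = index × voxel
size (voxel centres). Density metrics are invariant to background
padding; microglial abundance is reported per 10⁶ µm³ of forebrain
(the original normalization "to total forebrain volume" is unitless).
Positional metrics normalize each axis to the forebrain mask's bounding
extent, a concrete choice for the unstated "normalized to forebrain
size".

Registration is correspondence-based least squares for the
12-parameter affine (the upstream intensity-based registration is out
of scope; only transform fitting and application to SWC neurons are
needed). Decomposition uses the fixed order translate-to-center →
scale → shear → rotate → translate via a QR factorization with positive
diagonal; negative-determinant linear parts are flagged as reflections
and absorbed into a negative z scale. compose(decompose(T)) round-trips
to 1e-9.

The volume generator builds an ellipsoidal forebrain on the grid
(default 48 × 64 × 32 voxels at 2 µm), grows the neuropil sub-mask
outward from an interior focus until it holds exactly the requested
voxel fraction, and samples microglia centroids from forebrain voxels
with weight exp(dorsal_bias · z_norm), so dorsal_bias = 0 is uniform
in z and positive values shift cells dorsally.

## Single-cell expression

The workflow mirrors the standard subclustering recipe: library-size
normalization to 10,000 counts, log1p, per-gene z-scaling, truncated
SVD to 4 components, a k = 20 nearest-neighbor graph with
shared-nearest-neighbor Jaccard weights (edges below 1/15 pruned), and
Leiden optimization of RB-configuration modularity at resolution 1.25
with a fixed seed. All genes enter the reduction (no variable-gene
selection), configurable.

The microglial fingerprint score of a cluster is the mean expressing
fraction over the 75 fingerprint genes; clusters at or above 0.5 are
flagged microglial. This formalizes the qualitative rule that
microglial clusters express most of the fingerprint in most cells
(often > 80% of cells per gene) while macrophage clusters do not; with
the generator's defaults microglia score ≈ 0.99 and macrophages ≈ 0.09,
so the 0.5 cutoff sits far from both modes. Condition markers within a
cluster use a two-sided Wilcoxon rank-sum on the log-normalized layer
for genes expressed in ≥ 10% of either group, Bonferroni adjustment
over tested genes, and log2 fold changes of mean normalized expression
with pseudocount 1 (positive = higher in the first group, GF by
default).

### Expression generator

Four default cell types — ramified, amoeboid and proliferative
microglia and macrophages, 40 cells each — with negative-binomial
counts (mean/dispersion 2.0; zeros arise naturally). Fingerprint genes
(75, including c1qa/c1qb/apoeb/hexb among stand-in names) have mean 20
in microglial types and background 0.1 elsewhere; each type gets 25
exclusive marker genes at mean 10; remaining genes are background.
Condition log-fold changes map gene → type → log2(CVZ/GF), applied
symmetrically about the base mean; the default plants the complement
genes c1qa/c1qb lower in GF ramified microglia and higher in GF
amoeboid microglia.

Two deliberate design choices:

- **40 cells per type.** Modularity at resolution 1.25 subdivides
  internally homogeneous clusters larger than ~50 cells on SNN graphs
  (a well-known over-clustering behavior); with larger types, the
  planted-partition comparison would measure the algorithm's
  granularity rather than its recovery. At 40 cells/type the four types
  are recovered exactly across seeds. Larger populations can be
  generated explicitly where subdivision behavior is itself of
  interest.
- **Null calibration uses background_mean = 0.02.** Rank-sum p-values
  for genes at the 10%-expressing detection boundary are intrinsically
  discrete (few distinct count values), which fails a literal KS
  uniformity test even though the test is conservative there. With the
  lower background the min-pct filter removes boundary genes, and the
  p-values of the well-expressed tested genes are KS-uniform. Type-I
  error stays below 1.5× nominal in both regimes.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, library-size heterogeneity beyond NB sampling, or the
continuum between microglial states — passing tests show the pipeline
recovers planted discrete structure, not that it resolves subtle real
transcriptional gradients.

## Statistics harness

The two-group decision rule is a pure function of three p-values:
D'Agostino–Pearson normality per group (needs n ≥ 8; smaller samples
fall back to Mann–Whitney with a warning) and, when both pass at 0.05,
a two-sided F-ratio variance test at 0.05 choosing Student vs Welch.
The F-ratio criterion is a concrete stand-in for the original's
unspecified "unequal standard deviation" trigger. Dunn's post hoc uses
tie-corrected mean-rank z tests with Bonferroni adjustment over pairs.
Percentages are analyzed untransformed. Neurons are treated as
independent units (no larva-of-origin nesting), replicating the
original analysis; a mixed model would be the natural extension.

## Problem sizes

The test suite and acceptance script use: 100 arbors for oracle
equivalence (with a 0.01 µm dense-sampling oracle), 20 dyads per
sociality level at 600 s × 10 fps, 60 + 60 arbors for morphotype
recovery, 100 seeded draws of the 3-factor model (n = 500 × 13),
160-cell default expression matrices (500 genes) plus 500-cell
configurations for marker recovery and null calibration, and 50–300
simulation replicates per stats-harness check. These sizes make every
property measurable with comfortable statistical margin while keeping
a full run in tens of seconds.
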