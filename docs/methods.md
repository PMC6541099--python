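# Methods

This note documents the models, statistical procedures, numerical choices
and known limitations behind `morphobias`. The README describes what the
package does; this is the account of *why* it does it that way.

## Morphology representation and preprocessing

A reconstruction is a rooted tree of 3-D points with radii and parent
links (standard 7-column SWC). On read, node order is normalised to
parent-before-child and the structure is validated (single root, no
orphans, no cycles). Files with multi-point somata are collapsed to a
single root placed at the centroid of the type-1 points, which is kept as
the soma reference for the global angle; deposited files do not follow a
single convention here, and a single reference point is what the global
angle needs. Structure codes above 4 are kept as `other` on read and
removed, together with axons, by dendrite selection.

**Equidistant resampling.** Tracing software samples neurites at
arbitrary, software-dependent densities, which would contaminate any
node-level statistic. The normalisation keeps every critical node (root,
branch nodes, terminals) at its exact coordinates and re-places interior
nodes on the original polyline at arc-length multiples of the spacing
(10 µm default), suppressing the last interior candidate when it falls
within one spacing of the downstream critical node. Interior nodes lie on
the original polyline (no smoothing); radii are interpolated linearly
along arc length. Consequences worth knowing:

- resampling never increases total length (chords of a polyline), with
  equality exactly on straight segments;
- branch-point counts and segment arc lengths are invariant;
- resampling is idempotent on already-equidistant trees;
- a stem shorter than twice the spacing gets no interior node (the
  suppression rule applies to it like to any segment).

**Resampling is not scale-equivariant.** The feature definitions are
similarity-equivariant: rotating or translating a tree fixes all six
features, and scaling a tree *together with the spacing* scales exactly
the two length-valued features. But the pipeline resamples every tree at
a *fixed* spacing, and a scaled tree re-gridded at 10 µm places its
interior nodes elsewhere on the polyline. For curved neurites this
couples a pure scale bias weakly into the node-level angle features: a
0.8-scaled tree re-gridded at 10 µm averages tracing noise over longer
stretches of neurite, shortening chords by roughly 0.2% and raising the
mean local angle by about 0.01 rad under the default generator. This is a
real property of fixed-grid morphometry, not an implementation artifact —
any nonzero-curvature neurite behaves this way. Analyses that need
angle features free of this interaction should extract features with
`resample_tree=False` (CLI `--no-resample`); the effect-recovery
validation in the test suite does exactly that, because only on raw trees
is "scaling changes lengths and provably nothing else" an exact statement.

## Features

Granularities are fixed: branch-point count and total length are
per-neuron; global, branch and local angles are per-node; segment length
is per-segment. All angles are `arccos` of a clipped normalised dot
product, in [0, π]. Conventions chosen where the definitions leave room:

- a k-furcation is one branch point but contributes all C(k, 2) child
  pairs to the branch angle (consistent with L-measure-style counting);
- the root/soma is never a branch point and its stems contribute no
  branch angle — stems leaving the soma are not dendritic branching
  events;
- edges whose direction or soma-vector vanishes (the soma's own stems)
  contribute no global angle;
- features are computed on the resampled tree by default, raw-tree
  computation behind a flag (see above).

## Cohort construction

Records are kept when integrity = complete, condition = control, species
is rat or mouse, and every matching attribute is reported; unreported
labels cannot be matched on, so those records are dropped rather than
imputed. Age classes are young = [1, 2) months, young adult = [2, 6]
(6.0 inclusive — "between 2 and 6" read as a closed interval), adult
> 6; animals under one month fall outside all classes and are excluded.
Matching uses the finest reported level of the region and cell-type
hierarchies; an empty tertiary level matches only records that also lack
it. The three sex classes (male, female, male/female) never merge.
Within a candidate group, methods with fewer than `min_samples` (5)
neurons are dropped and the group is eligible if `min_methods` (2)
survive. Group and method ordering is lexicographic, making every
downstream artifact deterministic. Strain can be added to the matching
key (`match_strain`), which only ever refines the partition.

## Statistics

**Rank-sum test.** Exact enumeration of all C(n, n0) group assignments
(mid-ranks, so ties are handled exactly) when the combined sample size is
at most 12; above that, the tie-corrected normal approximation with
continuity correction (scipy). The two-sided exact p is twice the smaller
tail probability, capped at 1 — with ties the permutation null of U need
not be symmetric, and this convention matches the exhaustive-enumeration
oracles used in the tests.

**Multiplicity.** Bonferroni, with the family defaulting to all
(group × feature) tests of one staining pair — the aggregation level of
the proportion matrix; a single global family is available. The
intersection null for a feature is rejected when any member test rejects
after correction.

**Average effect.** β is the *unweighted* mean over groups of the
difference in pooled means, matching an expectation over groups in which
each matched class counts equally rather than proportionally to its
(deposition-driven) size. The permutation null relabels *neurons*, not
pooled values: node-level values within a neuron are strongly correlated,
and value-level permutation would be wildly anticonservative for the
pooled features. Labels are permuted within each group independently,
preserving method sample sizes; the permutation stream depends only on
the unordered pair, so swapping the pair negates β and leaves the p-value
unchanged under the same seed. The p-value uses the add-one estimator
(1 + #{|β*| ≥ |β|}) / (1 + n_perm), n_perm = 10,000 by default. Null
calibration of this estimator on unbiased cohorts is at the nominal level
(verified in the test suite at α = 0.05).

**Power analysis.** Monte-Carlo: for each per-group n, draw sample pairs
from a unit-variance base distribution with means d apart, test two-sided
at level α, report the rejection rate. The base is normal by default or
bootstrap-resampled from a supplied empirical feature sample. The
simulated power agrees with the asymptotic (Noether-style) Mann-Whitney
power approximation to within 0.02 for n ≥ 50. One number worth
remembering: at d = 0.5 and α = 0.05, a *two-sample* design needs about
85–100 neurons per group for 90% power (n = 50 per group gives ≈ 0.68);
claims of "50 data points" for that power correspond to a one-sample or
paired design. The function exposes the design choices rather than fixing
them.

## Synthetic cohorts

The generator's job is to produce SWC cohorts whose every measured
feature has a known generative expectation, with staining bias planted as
a per-label transform.

**Tree model.** Each tree has a random number of dendritic stems
(uniform on 2–4 by default) growing from a soma at the origin. Each stem
carries a bifurcating scaffold: segments bifurcate with probability
`branch_prob` (default 1, a full binary arbor) to a depth cap (default
2), child directions deviating ±½·`branch_angle_mean` (default 1 rad)
in bifurcation planes that alternate with depth inside a randomly rotated
tree frame. Segments are 1 + Poisson(mean/step − 1) steps of 10 µm
(mean segment 40 µm), so the expected segment count, branch-point count
and total length are closed-form. Observed node-to-node directions are
independent von Mises-Fisher draws about the scaffold direction
(concentration 40, ≈ 11° tracing noise per edge); the scaffold itself
meanders with concentration 10⁴ (essentially straight). For consecutive
edges the expected cosine of the deviation from straightness is exactly
A(κ_tr)²·A(κ_step) with A(κ) = coth κ − 1/κ, which the tests verify.

Why this shape, rather than a topologically random branching process with
an accumulated direction walk? Because the pipeline's pooled node-level
rank tests implicitly assume weak between-neuron correlation of node
values. Strongly random topology or accumulated meander gives each tree
a shared random "profile" — neuron-level random effects — under which
pooled tests are invalid *regardless of implementation* (familywise error
near 20% in pilots). The scaffold model keeps all node-level randomness
independent across edges while the random stem count supplies genuine
between-neuron variance for the per-neuron features, since stems are iid
blocks with identical node-value profiles. This is a deliberate modelling
regime, and it bounds what the passing tests certify: on real cohorts,
where neurons *do* carry individual geometry, pooled node-level p-values
understate the true uncertainty (they treat correlated nodes as
independent). The neuron-level permutation average effect does not suffer
this and is the robust summary; the same concern applies to any analysis
that pools node-level values across neurons.

**Bias transforms.** Per staining label: subtree pruning distal to
branch points with probability `prune_prob` per child (partial
labelling; stems always survive, so trees stay valid), uniform coordinate
scaling about the soma (`length_scale`, differential shrinkage), and
per-edge direction jitter preserving edge lengths (`angle_jitter`,
tracing noise). Expected total length after pruning replaces (2p)^d by
(2p(1−q))^d in the branching-process sum (each depth adds one
independent survival), giving a closed-form planted expectation that the
ground-truth sidecar records. One interaction to be aware of: pruning a
bifurcation down to one child *merges* its two segments, so pruning
lengthens the surviving segment-length distribution even as scaling
shortens it — at scale 0.8 with prune 0.1 the two nearly cancel on
segment length while total length and branch counts still drop.

**What the generator does not emulate.** Real between-neuron morphological
individuality (see above), depth-dependent branch statistics, diameter
taper, spines, reconstruction errors other than isotropic direction
noise, and any actual staining chemistry. Passing tests demonstrate that
the estimators recover planted effects under controlled conditions, not
that any particular real staining method biases features by any
particular amount.

**Determinism.** Every neuron's RNG is seeded by (cohort seed, group
index, method index, neuron index), so single neurons are reproducible
independently of generation order; all stochastic stages are bit-identical
under a fixed seed, and the pipeline writes byte-identical CSV/JSON on
re-runs with the same configuration.

## Validation problem sizes

The statistical test suite uses: 500 null cohorts of 2 groups × 2
methods × 10 neurons for familywise level and p-uniformity of the full
resampled pipeline; 100 cohorts of 5 groups × 12 neurons per method for
planted-effect recovery (raw-tree features; the 0.8 scale gives an
expected effect of ≈ 3.9 standard errors, chosen by power calibration so
recovery is expected in well over 90% of replicates); exhaustive rank-sum
enumeration up to combined n = 10; and 10⁴ simulations per power point.
The acceptance script runs a 3-group planted study, 150 null cohorts and
the d = 0.5 power curve in about two minutes.

## Known limitations

- Region and cell-type strings are matched verbatim; there is no ontology
  mapping, so nomenclature drift across archives splits groups.
- Bonferroni is the only built-in correction (per-pair or global family);
  no FDR control.
- The pooled node-level rank tests inherit the independence caveat
  discussed above on real data.
- The average effect is unweighted across groups; a size-weighted variant
  is a one-line change but changes the estimand.
- Figures are secondary artifacts; the CSV/JSON outputs are the contract.
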