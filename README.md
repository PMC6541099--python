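# morphobias

Quantify how the choice of staining method biases measured neuron dendrite
morphology.

Public morphology repositories pool reconstructions from dozens of labs
that visualised neurons with different staining techniques — heavy metals
(Golgi variants), genetic markers (GFP/RFP), immunostaining and direct dye
injection. If different stains capture different parts of a neuron, or
shrink tissue differently, then "morphological differences" between
datasets may be measurement artifacts. `morphobias` implements an
observational pipeline for estimating that bias from matched data, plus a
synthetic-cohort generator with planted biases so every stage can be
validated against known ground truth.

## The method

**Matched groups.** Neurons are filtered to complete, control-condition
rodent reconstructions and grouped into classes identical on species, sex
(male / female / the mixed male-female deposition class), age class
(young = [1, 2) months, young adult = [2, 6], adult > 6), the brain-region
hierarchy and the cell-type hierarchy (optionally also strain). A group
enters the analysis when it contains at least two staining methods with at
least five neurons each — so any within-group difference between methods
cannot be explained by the matched biology.

**Features.** Dendritic trees (axons dropped) are normalised by
equidistant resampling: branch points and terminals are kept exactly, and
interior nodes are re-placed on the original polyline every 10 µm of arc
length (the last candidate is suppressed within 10 µm of the downstream
critical node). Six features are measured: number of branch points, total
dendritic length, and global angle (between each edge and the direction to
the soma); branch angle (between sibling edges at a branch point), segment
length (arc length between consecutive critical nodes), and local angle
(at pass-through nodes; π for a perfectly straight neurite). Node- and
segment-level values are pooled over all neurons of a group.

**Tests.** For a group *b*, feature *M* and staining pair (*s₀*, *s₁*) the
two-sided Wilcoxon rank-sum test compares the pooled samples,

> H₀(b): median(M | b, s₀) = median(M | b, s₁),

with exact enumeration of the permutation null for small samples and the
tie-corrected normal approximation otherwise. The global hypothesis "no
effect for this feature anywhere" is the intersection ∩_b H₀(b), rejected
when any member test survives Bonferroni correction (family = all
group × feature tests of a method pair, by default). Fractions of
significant tests per method pair summarise the comparison matrix.

**Average effect.** The size of the bias for feature *j* is

> β_j = E_b [ E(M_j | b, s₁) − E(M_j | b, s₀) ],

the unweighted mean over groups of the difference in pooled means. Its
null distribution is generated by permuting staining labels across
*neurons* within each group (respecting within-neuron correlation of
pooled node values); the permutation p-value uses the add-one estimator.

**Power.** A resampling power analysis of the rank-sum test reports the
simulated rejection rate as a function of the standardized effect *d* and
the per-group sample size, with either a normal base distribution or
resampling from an empirical feature sample.

## Worked example

Generate a two-group synthetic cohort in which the `biocytin` neurons are
shrunk to 0.8 scale (modelling differential tissue shrinkage), then run
the full analysis:

```yaml
# cohort.yaml
seed: 7
groups:
  - key: {species: mouse, sex: male, age_class: adult,
          region_primary: hippocampus, region_secondary: CA1,
          celltype_primary: principal cell, celltype_secondary: pyramidal}
    methods: {Golgi: 25, biocytin: 25}
    biases:
      biocytin: {length_scale: 0.8}
  - key: {species: mouse, sex: male, age_class: adult,
          region_primary: neocortex, region_secondary: somatosensory,
          celltype_primary: principal cell, celltype_secondary: pyramidal}
    methods: {Golgi: 25, biocytin: 25}
    biases:
      biocytin: {length_scale: 0.8}
```

```bash
morphobias simulate --spec cohort.yaml --out cohort/
cat > run.yaml <<'YAML'
swc_dir: cohort/swc
metadata: cohort/metadata.csv
out_dir: out
n_perm: 2000
seed: 1
YAML
morphobias run --config run.yaml
```

`out/effects.csv` then contains (abridged):

```
        feature method_0 method_1        beta  p_perm  significant
n_branch_points    Golgi biocytin   -0.360000 0.56072        False
   total_length    Golgi biocytin -222.848235 0.00050         True
   global_angle    Golgi biocytin    0.002016 0.67966        False
   branch_angle    Golgi biocytin   -0.020238 0.18041        False
 segment_length    Golgi biocytin    -9.084426 0.00050        True
    local_angle    Golgi biocytin    0.091630 0.00050         True
```

The coverage features respond as planted: the generator's expected arbor
is 840 µm, so the 0.8 scale forces a −168 µm mean total-length difference
(this draw recovers −223 µm; the replicate-to-replicate spread of β at
25 neurons per method is about 48 µm) and −8 µm per segment (recovered
−9.1 µm). Branch counts and branch/global angles — untouched by pure
scaling — stay at their null level. The
significant positive `local_angle` effect (+0.091 rad) is a real
discretisation interaction, not a planted one: shrunken trees re-gridded at
a fixed 10 µm spacing average out tracing noise over longer stretches of
neurite and therefore look slightly straighter. See `docs/methods.md` for
why fixed-spacing resampling couples scale bias into the local angle, and
how to quantify features free of that artifact (`--no-resample` /
`resample_tree=False`).

`out/comparisons.csv` holds the per-group rank-sum tests,
`out/proportions.json` the fraction of corrected tests significant per
method pair (here 0.42 at both p < 0.05 and p < 0.001), and
`out/figures/` the group histograms, proportion matrix and effect
matrices.

The library mirrors the CLI one-to-one (`morphobias.generate_cohort`,
`extract_all`, `build_groups`, `compare_all`, `bonferroni`,
`average_effect`, `power_analysis`, `run_all`), so everything above is
scriptable.

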