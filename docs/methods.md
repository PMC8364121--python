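# Methods

This note records the model choices, numerical conventions and known
limitations of `gmnet`, in the order the pipeline runs.

## Single-subject network extraction

**Nodes.** The grey-matter image is tiled into non-overlapping 3×3×3-voxel
cubes (6×6×6 mm³ at the 2 mm working resolution; images are zero-padded to
a multiple of 3). A cube is a node iff it contains at least one voxel with
positive intensity and the fraction of positive voxels reaches
`min_gm_fraction` (default 0: any grey matter qualifies; the criterion that
real processing chains use is not standardised, so the cut-off is exposed
as a parameter). The cube label is the majority atlas label among its
nonzero-GM voxels, ties broken toward the smallest region id — a fixed,
reproducible rule for an arbitrary convention. `gm_volume` is the summed
intensity over the block.

**Rotation set.** The edge statistic is the maximum Pearson correlation of
one cube against rotated versions of the other, with angles restricted to
multiples of 45° about each axis. On the discrete 3×3×3 grid a 45° axis
rotation is realised by sending each value to the grid point nearest its
rotated centre; for 45° multiples this is a bijection. The canonical set is
all compositions Rx^i·Ry^j·Rz^k (i, j, k ∈ 0..7; 208 unique permutations),
closed under inverse (288) and then under conjugation by the 24 exact 90°
rotations, giving **432 permutations** — a frozen regression constant.
Inverse closure makes the statistic symmetric in its arguments, hence the
similarity matrix exactly symmetric; conjugation closure makes the whole
extraction equivariant under right-angle rotation of the image (the network
is isomorphic under the induced node relabelling — property-tested). The
group *generated* by the 45° maps was rejected: because nearest-point 45°
maps are not isometries, it explodes to >7×10⁵ permutations with no
geometric meaning. Cubes with zero intensity variance get correlation 0 by
convention (Pearson is undefined there, and 0 guarantees exclusion at any
positive threshold).

**Thresholding.** The null distribution is built by repeatedly drawing two
distinct cubes, independently permuting the 27 intensities within each
(destroying spatial pattern, preserving the intensity histogram), and
recording the rotation-maximised correlation. The threshold is the
(1 − α/M) empirical quantile of this null — the smallest order statistic at
or above that fraction — with M = n(n−1)/2 distinct node pairs, i.e. a
per-edge level corrected for the number of comparisons; α defaults to 0.05
and the sample size to 1000 permutations. With α/M far below 1/1000 the
rule effectively takes the null maximum, which is intentionally
conservative; the acceptance script verifies that on pure-noise images the
retained-edge share stays well below 5%. Edges require correlations
*strictly above* the threshold, so ties are excluded and only positive
correlations can survive. The null dialect, quantile rule, seed and null
sample summary are stored in `ThresholdResult` for provenance.

## Graph measures

Binary undirected conventions throughout: Watts–Strogatz clustering
(degree-<2 nodes contribute 0; triangle counts are exact-integer matrix
products), characteristic path length as the mean over ordered node pairs
with a *finite* shortest path. Excluding disconnected pairs keeps L defined
for the near-connected graphs this method produces and degrades gracefully;
an edgeless graph yields NaN with a warning. Global "degree" is reported as
the **mean node degree** (the raw edge count is emitted alongside as
`n_edges`): mean degree is the quantity comparable across networks of
different size and the scale on which cohort summaries of this method are
reported.

γ and λ divide C and L by their *means over* `n_reference` (default 5)
degree-preserving reference networks — ratio-of-means, the common
convention. References come from double-edge swaps with 10 attempts per
edge (a standard mixing heuristic), rejecting self-loops and multi-edges;
the degree sequence is preserved exactly (asserted in tests) and graphs
with no legal swap (complete graphs) return unchanged. Reference seeds
derive from one master seed. σ = γ/λ holds exactly by construction. Very
sparse graphs can have zero reference clustering; γ and σ then propagate as
NaN rather than failing. Regional metrics are unweighted means of nodal
degree, clustering, nodal path length (mean finite distance to all other
nodes) and gm_volume over each region's nodes; regions without nodes are
reported missing, not zero.

## Tau composites

Braak-stage composites and the temporal meta-ROI (stages I–IV, the primary
tau measure) are volume-weighted averages of member-region SUVRs. Weights
are the subject's own parcel volumes (voxel count × voxel volume from the
label image) — the natural reading of "volume-weighted" when parcel sizes
vary by subject. Composites are bounded by member extremes and invariant to
rescaling all volumes (property-tested). Real atlas membership lists vary
by atlas version, so they load from a user-editable YAML
(`gmnet/data/braak_rois_synthetic.yaml` is a synthetic format example, not
an authoritative list); the synthetic atlas uses a deterministic 20/30/50%
split of region ids into stages I–II / III–IV / V–VI.

## Statistics

Network measures are z-scored to the control group (sample sd, ddof 1);
zero reference variance is an error at the function level, and the pipeline
skips such degenerate outcomes with a logged warning. Associations are OLS
with complete cases, requiring ≥10 residual degrees of freedom, adjusted
for age, sex and TIV, plus connectivity density for the higher-order
measures (C, L, γ, λ, σ), which are known to depend on edge count.
Rank-deficient designs raise an error naming the collinear columns (QR with
pivoting). Multiplicity follows a two-tier scheme: Benjamini–Hochberg FDR
across the global outcomes within one tier (whole-sample, and each
diagnostic stratum separately), Bonferroni across regions within one
regional measure. Regional models adjust for age, sex, TIV and local GM
volume, plus local degree for clustering and path length.

Mediation is the linear product-of-coefficients decomposition: a
(treatment→mediator), b and c′ (outcome on treatment + mediator), c (total
effect); ACME = a·b and proportion mediated = a·b/c, with the exact linear
identity c = c′ + a·b holding in every replicate (tested to 1e−10).
Uncertainty comes from a nonparametric percentile bootstrap over subjects
(≥500 replicates, default 1000, seeded) rather than quasi-Bayesian
machinery: it is distribution-free, and in nested linear models the two
agree asymptotically. The proportion is reported even outside [0, 1] and
flagged when the total effect is near zero.

## Synthetic cohort generator

The generator emulates exactly the features the analysis relies on, and no
more. Texture prototypes (27 standard-normal values per region, 6
prototypes shared among 10 regions by default) are drawn once per cohort
and shared across subjects, so between-subject network differences reflect
only degradation. Each block is `offset + (1−m)·prototype + m·N(0, sd²)`
clipped at 0, with mixing `m = d/(1+d)` (monotone, bounded by 1) and latent
degradation `d = base + slope·max(0, meta-ROI SUVR − control mean)`.
`base = 0.3 > 0` keeps control images stochastic — at m = 0 all control
subjects would be bit-identical (shared prototypes) and control-referenced
z-scoring undefined. `slope = 0.2` gives a graded density decline across
stages rather than network collapse, matching the modest group differences
this family of methods reports on clinical cohorts. Meta-ROI SUVR means
rise 1.15 → 1.35 → 1.90 → 2.40 across control/preclinical/prodromal/
dementia (the range typical of second-generation tau tracers), with
stage-I–IV regions loading tau more heavily than neocortical ones.
Covariates: age ~ N(66–73, 7–8) by group, sex Bernoulli(0.5),
TIV ~ N(1450, 140) ml, all independent of cognition by construction.

Cognition is `intercept + c′·tau + b·E[integrity] + noise` where
E[integrity] = (1−m)²/((1−m)² + m²·sd²) is the *analytic expectation* of
same-prototype cube correlation — generation never runs the network
extractor, avoiding circularity. Consequence: conditional on tau, the
*realised* σ adds no information about cognition, so mediation estimated on
pipeline-extracted σ attenuates the b path. Mediation calibration therefore
uses the dedicated linear-Gaussian generator
(`simulate_mediation_table`), where outcome depends on the realised
mediator and the mediated share is analytically a·b/(a·b + c′). Similarly,
`simulate_association_table` produces merged tables directly (null or with
injected tau effects) for type-I-error and sign-recovery simulations at
hundreds of repetitions, where image synthesis would add nothing.

What passing tests do *not* show about real data: the toy images have no
anatomy, no scanner noise model, no partial-volume effects, and their
networks are far more modular than real GM networks (toy σ ≈ 7 versus ≈1.5
on real cortical data; toy λ can drop below 1), so the suite validates the
*machinery* — calibration, exactness of graph measures, estimator
recovery — not empirical effect sizes.

## Problem sizes and determinism

The test suite exercises the full image pipeline at 12³–15³ voxels (64–125
nodes) with 150–1000 threshold permutations, the noise-calibration check at
50 images of 30³ voxels (1000 nodes), graph-measure oracles up to n = 500,
and statistical recovery at 200 repetitions × n = 150–200 plus mediation at
n = 500 with 1000 bootstraps — sizes chosen so the whole suite runs in
about two minutes on one CPU while every component is still tested at a
scale where its asymptotic behaviour shows. All randomness flows from
explicit seeds (numpy `default_rng` / `SeedSequence`); the pipeline is
bitwise reproducible under a fixed config, and each output table carries
the analysis-config hash (path fields excluded) and stage seed in a header
comment.

## Known limitations

- The discrete 45° rotation realisation is one defensible dialect; others
  (e.g. trilinear resampling with re-binning) would give slightly different
  similarity values. The chosen set is frozen and regression-tested.
- The threshold quantile rule is effectively a null-maximum at default
  settings; spurious-edge control is conservative rather than exact.
- Mean-degree reporting differs from summaries that report total edge
  count; both are emitted.
- The mediation proportion is unstable when the total effect is small; it
  is flagged, not suppressed.
- Regional models silently skip regions whose design cannot support the
  required residual degrees of freedom at very small n (they are absent
  from the output, and exclusions at the network stage are logged to
  `exclusions.tsv`).
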