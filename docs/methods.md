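# Methods

This note records the models, conventions and design choices behind
`panelfish`, and what the synthetic data do and do not establish.

## Panel RT-qPCR pipeline

**Data model.** A `CqPanel` is a float matrix of quantification cycles
(miRNA assays × samples) with an explicit *undetected* state per cell
(stored as NaN) and case/control group labels.  Detected Cq must lie in
(0, 45].  Undetected is never silently replaced by a number: the only
numeric substitution in the package is the opt-in `undetected_cq`
argument of `normalize_to_reference` (default value 41 when enabled),
used for single-assay quantification where a non-amplifying sample must
still enter a group mean.

**Detection filter.** An assay is excluded when the fraction of samples
with Cq above `cq_max` (default 35 cycles; undetected counts as above) is
at least `undetected_frac` (default 0.5).  The boundary is exclusion-side:
exactly half the samples above the cutoff excludes.  Lowering `cq_max` can
only shrink the retained set (tested as a property).

**Global-mean normalization.** ΔCq[i,s] = Cq[i,s] − mean over the
reference set of Cq[·,s].  The default reference rule,
`all_samples_detected`, takes assays with Cq ≤ 35 in *every* sample.  This
is deliberately stricter than the detection filter: a panel can retain an
assay that failed in a minority of samples, but such an assay would inject
missing values into the per-sample mean.  The rule is configurable
(`retained`, or an explicit id list).  By construction the per-sample mean
ΔCq over the reference set is 0 (checked to 1e−9).

**Fold-changes.** ΔΔCq is taken against the control-group mean ΔCq and
FC = 2^−ΔΔCq, so log2 FC = −ΔΔCq exactly.  The headline `mean_fc_case` is
the *arithmetic* mean of per-sample case FCs; the geometric version
2^−(mean ΔΔCq) is emitted alongside (`geom_fc_case`) because the two
diverge for noisy assays and both conventions circulate in panel reports.

**Control-variability filter.** An assay is excluded when any single
control sample shows FC > 2 or FC < 0.5 against the control mean
(equivalently |ΔΔCq| > 1 cycle at the default bounds).  It is applied to
the significant candidates as the last selection step; the DE table keeps
it as a flag (`excluded_by_control_filter`) next to `significant`
(p < alpha) so both readings — "flagged up-differential by the test" and
"in the final selection list" (`in_de_list`) — are available.  This filter
is purely control-noise driven: with 0.5-cycle technical noise it removes
each assay with probability ≈ 0.2 regardless of any case effect, which is
why power statements below are phrased on the test-stage flag.

**Differential test.** Two-sided two-sample t-test on ΔCq per assay;
default Student (pooled variance), Welch by flag — panel-era software
defaulted to Student, and the reproduction command tries both and reports
which variant matched.  No multiple-testing correction is applied to the
selection (the historical workflow thresholds raw p < 0.05); BH q-values
are emitted for information only.  Degenerate rows are resolved by
convention and logged: both groups constant with equal means → p = 1,
constant with unequal means → p = 0.

**Clustering.** Samples are agglomerated by Ward.D2 on Euclidean ΔCq
distances over the differential subset (scipy's `ward` on a Euclidean
condensed matrix produces exactly the Ward.D2 heights; verified against a
hand-coded Lance–Williams recursion).  Heights are non-decreasing and
invariant to sample order; leaf order ties follow input order.  A
two-cluster cut is reported as the group assignment.

**Enrichment.** Upper-tail hypergeometric P(X ≥ k) with X ~
Hypergeom(N, K, n): universe N = retained assays that carry an annotation
(unannotated retained assays are listed in the report and excluded from
the universe), K = cluster members in the universe, n = the differential
subset (run separately for up, down and combined), k = cluster members in
it.  K = 0 yields p = 1 with a warning.  Verified against exact rational
arithmetic and literal draw enumeration for all parameter sets with
N ≤ 20.

## 3D-FISH topology

**Geometry.** A nucleus is a closed surface: an ellipsoid (center,
semi-axes, μm) or a watertight triangulated mesh (PLY).  The reference
and scaling center is the center of the axis-aligned bounding cuboid (the
volumetric centroid is also exposed).  Mesh containment is decided by
ray-crossing parity with a fixed irrationally-oriented ray (vectorized
Möller–Trumbore over all faces); point-to-mesh distance is the exact
minimum over all triangles.  No spatial index is used — nuclei meshes are
small (10³–10⁴ faces) and exhaustive vectorized sweeps are both exact and
fast.

**Equal-volume shells.** Rather than constructing 10 discrete reduced
copies of the envelope in a rendering tool, the continuous scale factor s
(smallest s such that the envelope scaled by s about the cuboid center
contains the probe) is solved directly — analytically for ellipsoids,
by bisection to 1e−6 on containment for meshes — and discretized as
zone = ⌈n_zones · s³⌉, clipped to [1, n_zones].  A copy scaled by s holds
volume s³·V, so these bands are exactly equal-volume; s is also the
equivalent-sphere radius fraction of the reduced copy, since affine
scaling preserves that ratio.  Boundary conventions: zone intervals are
((k−1)/10, k/10] in s³; s = 0 (the center) is zone 1; a point on the
envelope has s = 1, zone 10.  `shell_zone` is invariant under global
isotropic rescaling.

**Envelope distance.** Minimum Euclidean distance from the probe gravity
center to the surface (gravity centers, not nearest signal voxels, are
the anchors throughout).  Ellipsoids use multi-start local minimization
over the spherical parametrization seeded from a 512-direction coarse
scan (spheres are analytic); agreement with a ≥10⁶-sample dense-sampling
oracle is within 1e−3 μm on spheres, triaxial ellipsoids and an irregular
mesh fixture.  Points outside the surface report a negative distance with
an `outside` flag; such probes (segmentation noise) are excluded from
shell assignment but kept in the per-nucleus record.

**Colocalization.** Default mode `overlap`: a pair is colocalized when
the center distance does not exceed the sum of the two equivalent-sphere
radii (3V/4π)^(1/3) — i.e. the reconstructed signals intersect.  Mode
`threshold` uses a fixed cutoff, default 0.5 μm, the empirical scale at
which overlap calls typically turn over.  Comparisons are boundary
inclusive, and the call is symmetric in its two probes.  Which of the two
operationalizations generated any given published percentage is usually
unstated; both are first-class here and the mode is recorded in every
call.

**Condition statistics.** Colocalization: chi-square without continuity
correction on the conditions × {colocalized, separated} table, plus
Fisher's exact (two-sided) when there are exactly two conditions; when one
outcome is never observed anywhere the distributions are reported as
trivially identical (statistic 0, p 1) rather than erroring on a zero
margin.  Distances: Mann-Whitney U (exact when the pooled sample is ≤ 20
without ties, otherwise normal approximation with tie correction),
Kruskal-Wallis, or one-way ANOVA; descriptives are mean ± SEM per
condition.  All-tied inputs return p = 1 by convention.  Radial profiles
report per-zone occupancy fractions (summing to 1 per channel per
condition) and a chi-square comparison of zone counts between conditions
per channel.

## Synthetic data

**Panels** follow Cq[i,s] = baseline_i + shift_s − δ·[case]·[cluster] + ε:
assay baselines uniform on 20–34 cycles, per-sample global shifts (sd 0.3
cycles — they cancel exactly under global-mean normalization, and 0.3 is a
typical inter-run drift), technical noise ε ~ N(0, σ²) with σ = 0.5
cycles, effects planted on the cycle scale so true FC = 2^δ exactly.
Defaults mirror the profiled design: 375 assays, 8 cases vs 7 controls, a
7-member cluster with δ = 1.  Censoring: values above 40 cycles become
undetected; values in (35, 40] stay as detected-but-high, so the
detection filter — not the generator — decides expression.  The censoring
rate rises monotonically with the baseline mean.

What the simulator does *not* emulate: amplification-efficiency
differences between assays, inter-plate calibrators, correlated
(batch-structured) noise, and the heavy right tail of real Cq error near
the detection limit.  Passing recovery tests therefore demonstrate the
selection logic and its power under idealized noise, not performance on
instrument exports.

**Nuclei** are ellipsoids with semi-axes drawn from flattened-fibroblast
ranges (a 6–9, b 5–8, c 2.5–3.5 μm), a subtelomeric probe placed at a
controlled radial scale fraction, and a cluster probe displaced by a
controlled separation in a uniform random direction (resampled until
inside; >1000 failures raise, meaning the separation cannot fit the
geometry).  Probe volumes ~ N(0.15, 0.04²) μm³ floored at 0.01.  Two
qualitative presets ship: `control_like` (radial fraction 0.92 ± 0.03,
separation 0.25 ± 0.10 μm → envelope-proximal, overlapping pairs) and
`case_like` (0.60 ± 0.10, 1.6 ± 0.4 μm → interior, separated pairs).
They encode only the direction of the biological effect and are not
fitted to any imaging dataset.  Optional anisotropic voxel quantization
(0.1 × 0.1 × 0.24 μm) rounds probe coordinates to the microscope sampling
grid; it is a degradation of synthetic data only and is never applied to
analytic geometry.

**Constructed fixture.** `synthetic_reference_panel` builds a
deterministic 375 × 15 panel — a synthetic stand-in for a deposited
miRNome table — whose pipeline outcome is known exactly by construction:
187 assays read Cq 39 everywhere (excluded), 114 are detected everywhere
(the reference set), 74 carry a single high-Cq control cell (retained but
non-reference), within-sample noise uses paired ±patterns that cancel in
every per-sample mean, and the 14 planted effects sum to zero so every
non-differential assay tests at exactly p = 1.  The top assay's effect is
exactly log2(2.22), making its arithmetic mean case fold-change 2.22.  No
parameter in this fixture was fitted to any measurement; every count
follows from the construction.

## Numerical and reproducibility choices

* All simulators take a single integer seed (`numpy.random.default_rng`)
  and are bit-reproducible under it.
* Mesh bisection tolerance 1e−6 on s; ellipsoid scale factors analytic.
* Ray-parity epsilon 1e−10 on barycentric bounds; the fixed ray direction
  avoids axis-aligned degeneracies of grid-like meshes.
* Problem sizes in the shipped checks — 200 simulated panels for power
  estimates, 10⁵ points for shell calibration, 10⁶ surface samples for
  distance oracles, 30 nuclei per condition (about the number of nuclei
  scored per condition in typical 3D-FISH experiments) — were chosen so
  each estimate's Monte-Carlo error is well inside the tolerance it is
  compared against.

## Known limitations

* The mirnome arm models unpaired designs only; passage-matched pairing
  is not implemented (group sizes in the motivating design are unequal).
* Mesh shell assignment assumes the surface is star-shaped about the
  cuboid center to the extent that scaled-copy containment is monotone in
  s; strongly non-convex invaginations could violate this.
* The control-variability filter's noise sensitivity (see above) means
  final-list recovery of true effects is materially below test-stage
  recovery at σ = 0.5 cycles; reports expose both so users can see the
  filter's cost on their data.
* No parsing of instrument-native qPCR exports, no image segmentation,
  no inter-plate calibration modeling, and no reference-gene selection
  algorithms; the package starts from Cq matrices and segmented
  geometry.
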