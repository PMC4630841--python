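# Methods

This note documents the statistical machinery implemented in `morphotraj`,
the defaults it ships with, and what the synthetic-data validation does and
does not demonstrate.

## Shape variables

A specimen is a configuration of k landmarks in R³ (k = 36 for the
bilaterally symmetric cranium template, k = 9 for the one-sided mandible).
Size is measured by **centroid size**, CS = √Σᵢ‖xᵢ − x̄‖², in the units of
the digitized coordinates (mm).  Superimposition is **partial Procrustes**:
every configuration is centred, scaled to unit centroid size, and rotated
(proper rotations only) to minimise the summed squared distance to the
consensus; the consensus is re-estimated as the unit-size mean and the
scheme iterates until the relative drop in total Procrustes sum of squares
falls below 1e-10 (at most 100 iterations; both the rotation step and the
consensus step are exact minimisers, so the SS trace is monotone).
Downstream linear analyses (PCA, regression, group means) treat the aligned
coordinates as tangent-space variables — the standard small-variation
approximation, amply justified at the Procrustes distances involved
(≤ ~0.15).

### Object symmetry

For structures digitized on both sides, each configuration enters the GPA
together with its reflected-and-relabelled copy (x-axis negated, paired
landmarks swapped).  The **symmetric component** of a specimen is the mean
of its two aligned copies, the **asymmetric component** the half-difference;
the two are orthogonal, so total SS = symmetric SS + asymmetric SS.  With p
landmark pairs and m midline landmarks the symmetric tangent space has
dimension 3p + 2m − 4 (3p + 2m symmetric coordinates, minus the two
in-plane translations, the rotation about the symmetry axis, and scale);
for the 36-landmark cranium this is 54, and it is the default null
dimension for the trajectory-angle test on cranial data.  Covariance
matrices and all downstream statistics for symmetric structures use the
symmetric components only.  One-sided templates (the mandible) bypass the
decomposition; their tangent dimension is min(n − 1, 3k − 7).

## Missing-landmark estimation

Fossil specimens may lack landmarks.  Each incomplete specimen is completed
by (1) superimposing a complete reference shape — by default the Procrustes
grand mean of the complete specimens — on the specimen's observed landmarks
with a full Procrustes fit (translation, rotation, scale), (2) fitting the
interpolating 3D thin-plate spline (kernel U(r) = r, full affine term) from
the superimposed reference's observed subset to the specimen's observed
landmarks, and (3) reading the missing landmarks off the warped reference.
The procedure is exact when the specimen is an affine image of the
reference, equivariant under rigid motion of the specimen, and requires at
least 5 non-coplanar observed landmarks.  Near-singular spline systems are
retried with a ridge of 1e-10 × trace(K) before failing.

## Allometry and trajectory angles

The allometric model is the per-coordinate least-squares regression of the
flattened Procrustes coordinates on log centroid size (natural log;
the angle and variance-explained statistics are invariant to the base).
Significance comes from permuting sizes among specimens with the predicted
sum of squares as statistic, p = (b + 1)/(N + 1) (never zero).
"Non-allometric" coordinates are the residuals plus the mean shape.

The **ontogenetic trajectory** of a group is its regression coefficient
vector; two groups are compared by the angle between their vectors (fitted
in one joint superimposition), with the one-sided-toward-similarity null
that both directions are uniform on the unit sphere in d dimensions:
P(θ ≤ t) follows from (cos θ + 1)/2 ~ Beta((d−1)/2, (d−1)/2), evaluated
analytically or by Monte-Carlo sampling.  The p-value depends strongly on
d; the default is the effective dimension of the shape data (symmetric
subspace dimension for symmetric structures, capped at n − 1), exposed as a
parameter.

## Group comparison

Group differentiation uses the partial Procrustes distance between group
mean shapes (means of aligned coordinates, re-standardised to unit centroid
size before the distance).  Each pair of groups gets its own two-group
label permutation test (add-one convention); the analysis is run twice, on
raw and on non-allometric coordinates, so size-driven contrasts (juveniles
vs adults) visibly attenuate in the corrected track.  No multiple-testing
correction is applied across pairs by default.  CVA on leading PCs (enough
to explain 95 % of variance, capped at n − g − 1 so the within-group
covariance is invertible) is provided as an auxiliary ordination with
Mahalanobis distances.  The Kruskal–Wallis test (tie-corrected H against
χ² with g − 1 df) with the normal-approximation mean-rank post hoc
(critical difference at α/(g(g−1))) supports univariate contrasts such as
PC scores across dietary categories; the diet mapping (cave bear herbivore,
brown/black bear omnivore, polar bear carnivore) lives in the run
configuration, not in code.

## Phylogenetic signal

Species-mean size-corrected PC score vectors of adults are mapped onto the
4-species topology (americanus, (spelaeus, (arctos, maritimus))) by
**squared-change parsimony**: internal-node values minimise
Σ_branches ‖child − parent‖²/w, with w the branch length or 1 (both modes
are reported; zero-length branches become equality constraints).  The
minimised tree length is compared with the lengths obtained by permuting
the tip vectors; with ≤ 8 tips all permutations are enumerated, making the
test exact — with 4 species only 24 assignments exist, so p-values are
multiples of 1/24 and the test is intrinsically coarse.  Divergence-time
branch lengths default to approximate molecular estimates (root 5.05,
cave-bear split 2.75, brown/polar split 1.2 Ma) and are configurable.

## Synthetic data

The generator emulates the study design so that each stage can be checked
against ground truth:

- **Design**: the published group sizes (253 crania, 183 mandibles across
  4 species × age classes), species-specific mean shapes, and per-species
  centroid-size ranges chosen at realistic skull scales (e.g. adult cave
  bear crania 400–560 mm centroid size, juveniles from 160 mm); age class
  is assigned from size against the midpoint between the juvenile and
  adult ranges, so labels match the generating groups exactly.
- **Model**: specimen shape = species mean + `allometry_scale` ×
  (log CS − log CS_ref) × species direction + isotropic noise, then random
  rotation/translation and scaling to the drawn size.  Defaults:
  `allometry_scale` 0.15 per log-size unit and `noise_sd` 0.002 (shape
  units), which put within-group scatter and juvenile–adult contrasts in
  the 0.03–0.15 Procrustes-distance range typical of such data.  All
  species share one trajectory direction except the fossil species, whose
  direction sits at a controllable angle (default 40°).
- **Geometry**: cranial means and directions are projected into the
  object-symmetric subspace, and trajectory directions additionally into
  the *horizontal* tangent space at the mean (orthogonal to translation,
  scale and rotation generators).  With noise off, rigid motion off and a
  symmetric (grid) log-size design, the aligned data are exactly linear in
  log size and the regression recovers the generating direction to
  numerical precision — the basis of the exact-recovery tests.
- **Missing data**: a configurable fraction (default 10 %) of cranial
  landmarks in the fossil species is masked, with at least 5 observed
  landmarks retained.
- **Phylogeny**: species mean offsets are independent draws by default
  (no signal); a Brownian-motion mode evolves them on the study topology.

What passing these checks does **not** show: the generator draws isotropic,
independent landmark noise and linear trajectories, so it cannot expose
violations seen in real data — correlated landmark errors, digitizer drift,
curved ontogenetic trajectories, sexual dimorphism, or non-isotropic
within-group covariance.  Results on real material depend on those
assumptions holding approximately.

## Numerical and design choices

- PCA axis signs are fixed (largest-magnitude loading positive) so scores
  are reproducible across platforms; PC signs carry no meaning.
- Components with eigenvalue < 1e-12 × the leading eigenvalue are dropped
  as superimposition null directions.
- Confidence ellipses are equal-frequency (data) ellipses — mean and
  covariance scaled by √χ²₂(level) — matching scatter plots of specimens,
  not standard errors of means.
- All permutation and Monte-Carlo procedures take explicit seeds and are
  bit-reproducible; the pipeline derives per-stage seeds from one master
  seed via a name hash, recorded in the manifest.
- Default permutation count is 10,000; tests use smaller counts (99–999)
  for speed, which only coarsens attainable p-values.  The calibration
  suites use 100–500 replicates, sized so binomial envelopes are tight
  enough to detect miscalibration while keeping the suite around ten
  seconds.
- The end-to-end validation runs the full 253/183-specimen design; the
  acceptance script completes in roughly half a minute on one CPU.

## Known limitations

- Tangent-space linearity is assumed, not tested; at Procrustes distances
  beyond ~0.3 the optional orthogonal projection would matter.
- The trajectory-angle null treats the two estimated directions as
  independent uniform directions; estimation noise in short size ranges
  biases observed angles upward, making the test conservative for
  similarity.
- Squared-change parsimony with 4 tips has very low power by construction;
  only gross signal can be detected, and p-values are coarse multiples of
  1/24.
- The CVA is an ordination aid only; no cross-validated classification
  rates are computed.
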