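# Methods

## The measurement problem

Outer hair cells (OHCs) of the cochlea are elongated, gently curved cells
whose nucleus normally sits near the basal pole. Loss of the LINC-complex
protein Nesprin-4 (*Syne4*) mislocalizes the nucleus apically, and the
downstream biology (electromotility onset, cell survival, submembrane
cisternae organization) is read out through a handful of bespoke image
quantifications. This package implements those quantifications as a tested,
reusable pipeline, together with a synthetic-data generator that provides
ground truth for every stage.

## Relative nuclear position along a fitted cell axis

Each cell is summarized by three manually placed reference points in
physical μm: the apical surface **A**, the nucleus centroid **N** and the
basal end **B**. A smooth curve through the three points represents the cell
axis. We use the unique quadratic parametric polynomial (Lagrange
interpolation) with the nucleus assigned the chord-length parameter

    t_N = |AN| / (|AN| + |NB|).

This family is C^∞, reduces exactly to the straight segment when the
landmarks are collinear, and is the lowest-order family that three points
determine uniquely. Total cell length `L` is the arc length of the curve on
[0, 1]; the nuclear arc `s_N` is the arc length on [0, t_N]; the relative
nuclear position is `p = s_N / L` (0 = apical surface, 1 = basal pole).

Arc lengths are evaluated with the exact closed-form antiderivative of the
quadratic speed `‖C′(t)‖ = sqrt(A t² + B t + C)`. A first-order series branch
handles the nearly collinear regime, where differencing the closed-form
antiderivative would lose precision to cancellation; the crossover threshold
(`|B| + A ≤ 1e−8·C`) keeps both branches accurate to double precision. No
quadrature error enters the metrics; against a 10⁶-sample polyline and
adaptive quadrature at rtol 1e−11 the agreement is ~1e−12 relative.

Degenerate inputs: coincident apical/basal landmarks are an error; a nucleus
centroid coinciding with a pole collapses the quadratic nodes and the
straight chord is used (p = 0 or 1 exactly). A nucleus whose perpendicular
offset from the A–B chord exceeds the chord length (configurable factor)
triggers a warning — that geometry almost always means a mis-annotated
landmark — but is still fitted.

Properties guaranteed (and tested): arc ≥ chord with equality iff collinear;
`p` invariant to rigid motion and uniform scaling; `p` strictly increasing
as the nucleus moves basally; pole exchange maps p → 1 − p.

## Nuclear-envelope recruitment index

Given a three-channel single-cell stack (DAPI, cytoplasm/microtubules,
reporter), the nucleus is segmented from DAPI by global auto-threshold (Otsu
by default, IsoData selectable; method and threshold recorded as
provenance), keeping the largest connected component and filling holes. The
whole cell is segmented the same way from the cytoplasmic channel, with a
physical closing of radius 0.3 μm first (cytoskeletal staining is textured;
the closing is implemented with two Euclidean distance transforms so the
radius is honored under anisotropic voxels). The nucleus must lie ≥ 90%
inside the cell mask (a channel mix-up guard); the remainder is absorbed.

The *perinuclear band* is the set of voxels outside the nucleus whose
Euclidean distance to the nucleus — computed by a distance transform with
physical voxel spacing — is at most the band width (1.1 μm by default).
The recruitment index is

    index = mean reporter intensity over (band ∩ cell)
          / mean reporter intensity over (cell \ nucleus \ band).

Excluding the band from the cytoplasmic denominator keeps envelope signal
out of its own reference; a flag restores the literal cell-minus-nucleus
denominator for comparison. The index is exactly 1 for a uniform reporter,
invariant under multiplicative intensity rescaling, and — deliberately
documented and tested as such — *not* invariant under additive background:
offsets pull the ratio toward 1, so acquisition offsets should be removed
upstream if absolute values matter.

Because the band (1.1 μm) is much wider than a nuclear envelope shell
(~0.3 μm), the index dilutes true envelope enrichment: a generative
enrichment k = 3 yields an index near 1.45, not 3. Comparisons between
groups measured with the same geometry are unaffected; tests verify strict
monotonicity of the index in k and agreement within 15% with an oracle that
averages the known generative intensity field over the exact band geometry.

## Cisternae gap lengths

Submembrane cisternae are annotated as ordered, non-overlapping intervals
`[start, end]` (μm) along the lateral membrane contour. The statistic is the
interior gap `gap_i = start_{i+1} − end_i`; a profile with n segments
contributes n − 1 gaps and a single-segment profile has an undefined (NaN)
mean. Edge runs from the contour ends to the first/last cisterna are not
gaps between adjacent cisternae and are excluded. Group comparison pools
gaps per genotype and applies the two-sided Mann–Whitney test; both per-gap
and per-cell-mean aggregations are emitted since either convention is
defensible.

## Cohort statistics

* **Normality pre-tests** — Shapiro–Wilk plus Kolmogorov–Smirnov with the
  Lilliefors correction (parameters are estimated from the data, so the
  plain KS null would be anticonservative). A group "passes" when both
  p > α. Note the joint pass rate of two level-α tests lies in
  [1 − 2α, 1 − α], i.e. 90–95% at α = 0.05, not 95%.
* **Kruskal–Wallis + Dunn** — tie-corrected H with the χ² approximation
  (scipy), then Dunn's pairwise z-tests on pooled mean ranks with the
  standard tie term Σ(t³−t)/(12(N−1)) and Bonferroni adjustment over all
  pairs (the convention of common interactive analysis software; recorded
  in provenance). All-identical observations are reported as the degenerate
  H = 0, p = 1 rather than an error.
* **ANOVA + Tukey HSD** — one- or two-way via ordinary least squares; the
  two-way design is fitted with interaction and type-II sums of squares so
  mildly unbalanced cohorts (attrition) remain interpretable, reproducing
  the classical decomposition when balanced. Tukey HSD runs over the levels
  of each factor.
* **Per-condition Welch t + two-stage step-up FDR** — Welch (unequal
  variance) t-tests per condition, corrected across conditions with the
  Benjamini–Krieger–Yekutieli two-stage linear step-up procedure at
  q = 0.05. Conditions with n < 2 in either group are NA and excluded from
  the family. A step-by-step implementation of the published two-stage
  algorithm serves as the oracle in tests.
* **Mann–Whitney** — exact enumeration of all group-label assignments when
  both arms have ≤ 8 observations (the enumeration recomputes U from pooled
  ranks per assignment, so ties are handled exactly); tie-corrected normal
  approximation with continuity correction otherwise. The two paths agree
  within |Δp| ≤ 0.01 for 8–12 observations per arm.
* **Region counts** — cells per type within the half-open interval
  [center − span/2, center + span/2), span 200 μm by default, so boundary
  cells are counted exactly once when regions tile the cochlear axis.
* **Onset analysis** — per-age Welch t + BKY across ages; reports the first
  age (in table order) flagged as a discovery.

A calibration note on the onset design: the two-stage step-up procedure
controls the false discovery rate, not the familywise error rate. With two
strong effects among four ages its adaptive second stage tests the
remaining null ages at an effective level near q·m/m₀ = 0.10 each, so even
with ideal p-values the probability that the discovery set is *exactly* the
two truly separated ages plateaus around 0.85; the power to find both true
ages exceeds 0.99 and the all-null false-onset rate stays at ~α. The tests
assert these honestly derived rates.

## Synthetic data generator

The generator emulates the study's imaging conditions with known truth.

* **Cell geometry.** A midline of prescribed arc length (default 30 μm,
  within the 25–40 μm range of postnatal OHCs) with a dimensionless bend
  parameter (default 0.3). The default midline is a *sinusoidal* bend —
  deliberately outside the quadratic family the axis fitter uses, so
  recovery tests measure genuine model-mismatch error rather than fitting
  the model to itself; a quadratic midline is selectable. The cell body is
  a tube of radius 3.0 μm around the midline; the nucleus is a sphere of
  radius 2.2 μm centred on the midline at the requested arc fraction
  (defaults: 0.75 for controls, matching the basal position seen in
  wild-type cells; mutants are generated with smaller fractions).
  Ground-truth lengths come from dense (0.01 μm) polyline integration.
* **Channels.** DAPI: two-level (background 10, nucleus 200), so a midpoint
  threshold reproduces the true mask exactly. Cytoplasm channel: two-level
  over the cell body. Reporter: cytoplasmic intensity (100) over the cell,
  multiplied by the enrichment factor k in a 0.3 μm shell at the nuclear
  rim — thin relative to the 1.1 μm measurement band, as a nuclear envelope
  is.
* **Noise.** Poisson shot noise on photon-scaled intensities (default 50
  expected photons at cytoplasmic intensity) plus additive Gaussian read
  noise (default SD = 2% of cytoplasmic intensity) — typical confocal
  statistics. Voxels default to (0.5, 0.1, 0.1) μm (z, y, x), a plausible
  confocal sampling; these acquisition parameters are declared defaults,
  not values inferred from data.
* **Cohorts.** Per-cell relative positions drawn from normals truncated to
  [0, 1], per group × age. The onset design has control and mutant
  coinciding at mean 0.75 (SD 0.05 and 0.08) at P8/P10 and the mutant mean
  dropping by 0.25 from P12, n = 10 per group per age.
* **Cisternae.** Segments packed along a contour with prescribed gaps;
  cohorts draw per-cell gaps from truncated normals (defaults 0.5 μm vs
  2.0 μm mean, SD 0.1, seven 2 μm segments per cell).

All generators are pure functions of (spec, seed). What the generator does
*not* emulate: point-spread blurring, chromatic shifts, multi-cell crowding,
intensity gradients with depth, or real TEM texture. Passing tests therefore
demonstrate correctness of the measurement algorithms under the stated
noise model — not robustness to every artifact of real microscopy, where
landmark placement and segmentation quality dominate the error budget.

## Numerical and problem-size choices

Simulation sizes used by the test suite and the acceptance script: 10⁴
random straight cells for the closed-form check; 50 noisy bent cells for
position recovery; 200 replicates for onset rates; 2000 replicates for
type-I calibration of each test; 3 cells per condition for recruitment
calibration (the index SE per cell is ~0.002, so small groups suffice).
These sizes give Monte-Carlo error comfortably below the asserted
tolerances. Sub-seeds are derived from the user seed via
`numpy.random.SeedSequence`, keeping every generator independent and
reproducible.

## Known limitations

* The quadratic axis model slightly underestimates strongly curved lengths
  (it cannot represent an inflected midline); with the default bend the
  position bias is ~0.01, well inside the 0.05 per-cell tolerance.
* The recruitment index is band-diluted (see above) and sensitive to
  additive background by construction.
* Cisternae quantification starts from annotated intervals; no detection
  from raw electron micrographs is attempted.
* Landmark detection from images is out of scope except for the
  segmentation-derived nucleus centroid used in tests; apical/basal poles
  are taken as annotated.
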