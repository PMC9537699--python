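# ohcquant

Quantification pipeline for nuclear positioning and nuclear-envelope (NE)
biology in cochlear hair cells. Outer hair cells (OHCs) are elongated,
gently curved cells whose nucleus normally sits near the basal pole; loss of
the LINC-complex component Nesprin-4 mislocalizes it apically. This package
implements the image-derived statistics used to establish such phenotypes,
for microscopists and quantitative biologists who have per-cell landmark
annotations, single-cell fluorescence stacks, or cisternae segment
annotations and need reproducible numbers and group comparisons:

* **Relative nuclear position** — a smooth quadratic curve C(t) is fitted
  through three annotated reference points (apical surface *A*, nucleus
  centroid *N*, basal end *B*, chord-length parameterization
  t_N = |AN|/(|AN|+|NB|)); total cell length L and the apical→nucleus arc
  s_N come from the exact arc length of the curve, and the statistic is
  p = s_N / L ∈ [0, 1] (0 = apical, 1 = basal).
* **NE recruitment index** — nucleus segmented from DAPI by auto-threshold,
  whole cell from the cytoplasmic/microtubule channel; the index is the mean
  reporter intensity in a 1.1 μm perinuclear band (Euclidean distance
  transform in physical units, anisotropic voxels honored) divided by the
  mean cytoplasmic intensity (cell minus nucleus minus band).
* **Submembrane cisternae gaps** — interior gap lengths
  gap_i = start_{i+1} − end_i between annotated cisternae intervals along
  the lateral membrane contour, with per-gap and per-cell aggregation.
* **Cohort statistics** — Shapiro–Wilk + Lilliefors-KS normality pre-tests;
  Kruskal–Wallis with Dunn's post hoc comparisons; one-/two-way ANOVA with
  Tukey HSD; per-condition Welch t-tests with the Benjamini–Krieger–
  Yekutieli two-stage step-up FDR correction (and the derived developmental
  "onset" analysis); exact/tie-corrected Mann–Whitney; hair-cell counts per
  200 μm region.
* **Synthetic data with ground truth** — curved-cell image stacks
  (Poisson + Gaussian noise, anisotropic voxels, optional NE-enriched
  reporter shell), position cohorts, and cisternae profiles, so every stage
  is testable without the original imaging.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from ohcquant import (SyntheticCellSpec, generate_cell_image, fit_cell_axis,
                      relative_nuclear_position)
from ohcquant.synthetic import segmented_nucleus_landmarks
from ohcquant.recruitment import measure_stack

# a 30 um bent cell, nucleus at arc fraction 0.75, 3x NE-enriched reporter
spec = SyntheticCellSpec(axis_curvature=0.3, true_relative_position=0.75,
                         ne_enrichment_factor=3.0)
stack, truth = generate_cell_image(spec, seed=7)

# landmarks: true poles + nucleus centroid measured from the noisy DAPI channel
landmarks = segmented_nucleus_landmarks(stack, truth)
pos = relative_nuclear_position(fit_cell_axis(landmarks))
print(f"total length: {pos.total_length:.2f} um")
print(f"relative position: {pos.value:.3f} (true {truth.true_relative_position:.2f})")

m = measure_stack(stack)
print(f"recruitment index: {m.recruitment_index:.3f}")
```

prints

```
total length: 28.80 um
relative position: 0.738 (true 0.75)
recruitment index: 1.445
```

The fitted quadratic slightly under-measures the sinusoidally bent midline
(28.80 vs 30.00 μm true length) yet recovers the nuclear position within
0.012 — the statistic is a ratio, so correlated length errors largely
cancel. The recruitment index of 1.445 reflects the 3× envelope enrichment
diluted over the 1.1 μm measurement band, which is much wider than the
~0.3 μm envelope shell itself; group comparisons at fixed geometry are
unaffected by this dilution.

A command-line interface mirrors the library
(`ohcquant simulate|position|recruit|gaps|compare|run`), e.g.:

```sh
ohcquant simulate cohort --seed 3 --out work/
ohcquant compare --table work/cohort.csv --test onset --out work/stats/
ohcquant run --seed 1 --out results/   # end-to-end simulate -> quantify -> compare
```

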