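# Methods

## Measurement model and assumptions

The pipeline assumes detection-level measurements of tumor nuclei from a
scanned slide: per nucleus the cross-section area *A* (µm²), contour
perimeter *P* (µm) and long axis *L* (µm), plus either a per-cell whole-cell
area or pooled region measurements (region area + nucleus count) where
cell borders cannot be traced. Everything downstream rests on two
geometric idealizations:

1. **Elliptic nucleus.** The small axis is not measured; it is derived
   from *A* = π·r₁·r₂ with r₁ = L/2. This caps the admissible area at
   π·(L/2)² (otherwise r₂ > r₁), which the ingestion layer enforces as a
   hard invariant.
2. **Ellipsoid volume.** The 3-D nucleus is modelled with two axes equal
   to the small axis: V = (4/3)·π·r₁·r₂², identically (2/3)·A·(2r₂). This
   identity is the main internal consistency check and holds to float
   precision for every cell.

The two dysmorphism grades divide the measured perimeter by ideal
reference perimeters. Acyclicity (reference: circle of equal area) is ≥ 1
for any simple closed contour by the isoperimetric inequality. For
anellipticity the reference is the root-mean-square ellipse-perimeter
approximation 2π·√((r₁²+r₂²)/2), which *overestimates* the true arc length
(it is exact for circles and ≈ +2.5% at axis ratio 2), so a perfectly
elliptic nucleus grades slightly **below** 1; values above 1 indicate
boundary folding beyond the fitted ellipse. The implementation follows
the square-root form; a `code-compat` mode reproduces a published
code variant without the root (dimensionally a length², useful only for
auditing that code's outputs).

The mean internuclear distance √(mean cell area) comes from a packing
argument: tiling the measured area into equal squares, one nucleus per
square, makes the nearest-neighbour spacing the square's side. It is only
meaningful in dense tumor areas with minimal stroma, which is how the
input measurements are expected to be taken.

**Selection filter.** Before aggregation, nuclei with area below half a
reference area are dropped (small profiles may be off-plane caps of larger
nuclei). "Half the average dimension of the largest nuclei" is read as
half the mean *area* of the top decile by area; a `max_area` reference and
other fractions are configurable through `SelectionPolicy`.

**Aggregation order.** Two modes are first-class because both appear in
practice: `per_cell` (descriptor per cell, then average — the default when
per-cell perimeters exist) and `from_means` (average the raw measurements,
apply each descriptor once — the mean-input convention of manual
calculation). They coincide exactly on homogeneous samples; on real,
heterogeneous samples they differ by Jensen-gap terms of a few tenths of a
percent to a few percent, which is also the likely explanation for small
internal inconsistencies among published group means (e.g. a derived small
axis of 6.446 µm vs a printed 6.404 µm).

## The panel and its cut-offs

Eight criteria with strict inequalities: area < 55 µm², N/C > 1.1,
acyclicity > 1.145, internuclear distance < 10.5 µm, long axis < 9 µm,
small axis < 7 µm, volume < 200 µm³, anellipticity > 1.14. Ties at a
cut-off fail, matching the reference decision logic's `<`/`>` comparisons.
The axis ratio criterion (> 1.2) is derivative of the two axes and is
reported but never counted. Risk tiers: high for n_cr ≥ 6, intermediate
for 3–5, low for ≤ 2. All cut-offs are overridable (YAML config or
`--set` on the CLI), and every run logs the values actually applied; in
particular a stricter 9.5 µm distance cut-off that appears in part of the
source literature can be set explicitly, while 10.5 µm is the default
because it is the value the panel's decision logic uses.

Patients without any cytoplasm information keep their six nuclear
criteria; N/C and distance evaluate false with a warning finding rather
than failing the patient. The result therefore under-counts rather than
errors; rescaling tiers to the six available criteria was deliberately not
done, since the tier thresholds are defined on eight.

## Between-group statistics

Per parameter and group: n, mean, sd (withheld for n = 1), median,
quartiles and range. The between-group test defaults to univariate
logistic regression of status on the parameter with a Wald p on the slope;
Welch's t is the alternative. The predictor is standardized inside the
fit, making the Wald p exactly invariant under affine rescaling of the
parameter. Degenerate variance and complete separation are detected and
flagged with the p-value omitted — relevant in practice, because several
parameters separate the groups almost perfectly, and the Wald statistic of
a near-separating logistic fit collapses (Hauck–Donner effect) instead of
becoming small. Power-style checks on strongly separated groups should
therefore use the Welch route, and the package's tests do. No
multiple-testing correction is applied by default; Bonferroni and
Benjamini–Hochberg adjustments are available explicitly.

## Synthetic data

**Measurement cohorts.** Each cell is generated from four primitives —
long axis L, axis ratio q ≥ 1, folding factor f and N/C ratio — through
the same elliptic model the descriptors invert: r₁ = L/2, r₂ = r₁/q,
A = π·r₁·r₂, P = f·2π·√((r₁²+r₂²)/2), cell area A·(1 + 1/NC). The folding
factor is the single dysmorphism knob and maps analytically onto both
grades: anellipticity = f and acyclicity = f·√((q + 1/q)/2). Primitives
are drawn from a two-level truncated-normal hierarchy (patient means
around group means with the between-patient sd; cells around their patient
mean with a within-patient sd), with supports kept positive, q ≥ 1 and
f ≥ 1/1.03 (the RMS formula overestimates smooth-ellipse perimeters by up
to ~3%, so real smooth nuclei can grade slightly below 1).

Preset group profiles encode the published two-group study structure
(7 bone-metastasis vs 34 control patients, 60–100 cells per patient):
metastasis L = 8.411 ± 0.619 µm, q = 1.323 ± 0.123, f = 1.151 ± 0.012,
N/C = 1.405 ± 0.62; control L = 10.630 ± 1.676 µm, q = 1.268 ± 0.063,
f = 1.126 ± 0.028, N/C = 0.561 ± 0.39. Where only a median (range) is
published, the parenthesized values are treated as quartiles and
sd ≈ IQR/1.349. Within-patient dispersions are not published anywhere, so
they are fixed package choices (10% cv on the long axis, 0.10 on q, 0.02
on f, 0.15 on N/C) reflecting that single nuclei vary several-fold more
than patient means. A consistency check supports the generative model:
from the printed q and f alone it reproduces the printed acyclicity grades
of both groups to ≈0.3%.

"Configured targets" for the nine patient-level parameters are defined by
`expected_parameters`: a seeded large-sample run of the full generate →
select → aggregate chain. This is deliberate — plug-in closed forms
ignore the selection filter and Jensen terms, which shift the nonlinear
parameters by up to a few percent at realistic dispersions.

What the generator does **not** emulate: spatial structure (no positions,
no real neighbour distances — the distance statistic flows through the
cell-area route only), measurement noise of an annotation tool,
within-patient correlation between size and shape, stromal content, and
any texture/staining features. Passing tests on synthetic cohorts
therefore validate the computational chain and the panel logic under the
published group profiles, not the biological claim that these profiles
discriminate real patients.

**Ellipse phantoms.** Ground-truth ellipses (r₁, r₂, orientation, center,
µm) are rasterized with center-in-ellipse pixel semantics after an exact
non-overlap and in-canvas check (shapely polygons; tangency is allowed).
Measurement mimics an annotation tool: area = pixel count × (µm/px)²;
perimeter = arc length of the marching-squares 0.5-level contour after a
5-point circular moving-average smooth — the raw staircase polygon
overestimates smooth boundaries by ≈5%, the smoothed one is accurate to
≈0.1–0.5% at the tested sizes (radii 3–10 µm at 0.1 µm/px); long axis =
maximum caliper (Feret) diameter over the convex hull of the contour,
which equals the major axis for ellipses, floored at the equal-area-circle
diameter 2√(A/π) so that discretization jitter on near-circles cannot
violate the elliptic area bound. Recovery accuracy at 0.1 µm/px is ≈1% on
area and ≈2% on the long axis, improving at 0.05 µm/px.

## Numerical choices and degenerate inputs

- Geometry tolerances: the elliptic area bound and r₂ ≤ r₁ checks allow a
  1e-9 relative slack for float round-off; violations beyond that raise
  `GeometryError` naming the cell.
- Aggregation uses exact running means (`statistics.fmean`); report CSVs
  round the nine parameters to three decimals (matching the conventional
  presentation), and round-trip tests compare at that precision.
- Pooled-region N/C contributes one identical ratio per counted nucleus,
  so mixed per-cell/pooled patients average with region weights equal to
  nucleus counts.
- Empty cohorts score to empty result lists; a patient whose measurements
  fail mid-pipeline yields an error finding and a zero-count result rather
  than aborting the cohort.
- All randomness flows from a single `numpy` `default_rng` seed; identical
  seeds give byte-identical simulate → score outputs.

## Problem sizes used by the test suite

Property tests run on 500–1000 randomized parameter vectors; the null
calibration of the default group test uses 2000 replicates of 50 + 50
observations; generator-faithfulness checks use 24 patients × 200 cells
against targets from 40 × 500; phantom-recovery checks use single objects
of 3–10 µm radius at 0.1 and 0.05 µm/px. These sizes give stable
assertions (3-standard-error bands, 1–2% geometric tolerances) while the
whole suite runs in well under a minute.

## Known limitations

- The panel is a deterministic rule, not a calibrated probabilistic model;
  no uncertainty accompanies the tier assignment.
- The elliptic/ellipsoid idealizations bias volume and small axis for
  strongly non-elliptic nuclei in ways the grades flag but do not correct.
- The published cut-offs come from a single 41-patient cohort and are
  applied as given; the package makes no attempt to re-estimate them.
- Pooled-region cytoplasm assumes uniform distribution over nuclei of mean
  area, which flattens real cell-to-cell variation in N/C.
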