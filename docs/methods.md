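# Methods

This note documents the models, conventions and numerical choices behind
jzquant, in the spirit of a methods section: what each quantification
assumes, which parameters matter, what the synthetic data emulate, and where
the design was genuinely open.

## Coordinate frame and regions

All spatial analytics consult a `TissueFrame`: real-valued micrometre
coordinates in a right-handed frame, x mediolateral (ML), y anteroposterior
(AP), z dorsoventral (DV) by default, with `ventral_sign = +1` meaning that
increasing z is deeper tissue. The midline is a single ML coordinate; the
half-width is the midline-to-lateral-edge extent used to normalise start
positions. When no half-width is supplied, `analyze tracks` uses the 95th
percentile of |x − midline| over track starting positions — robust to the
occasional stray track, since the lateral edge itself is not part of any
export. Two region schemes coexist because both are in common use: equal
thirds of the half-width (default) and a fixed band (default 100 µm) at the
midline and at each lateral edge; every analysis records which scheme
produced its labels. At the default half-width of 300 µm the two schemes
coincide.

## Trajectory analytics

Tracks are tables of (embryo, track, time, x, y, z) with at least two
strictly increasing timepoints per track. Registration subtracts a
per-timepoint landmark position (linearly interpolated between its
endpoints); origin subtraction moves each track's first point to (0,0,0)
and is idempotent.

Toward-midline displacement is defined midline-relatively as
|x_start − midline| − |x_end − midline|, which stays meaningful for
midline-crossing tracks and is mirror-symmetric by construction. Ventral
displacement is `ventral_sign · (z_end − z_start)`.

Polar directionality histograms use degrees in [0°, 360°), 0° along +ML,
counterclockwise, half-open bins [lo, hi) of 20° by default (the bin width
must divide 360). The default trajectory unit is the per-track *net*
displacement vector — one vote per cell, consistent with per-track
displacement weighting — with a per-step mode available in the configuration
because binning individual steps is an equally defensible reading of "the 2D
trajectory". Per-bin weight is count × mean vector magnitude (the sum of
magnitudes). Zero-magnitude vectors carry no direction and are excluded with
a logged count. In the transverse (XZ) plane the second coordinate is the
ventral component, so ventral motion occupies (0°, 180°).

Displacement profiles bin normalised start distance into ten equal intervals
covering (0, 100 %] (a start exactly at the midline joins the first bin);
empty bins are reported with n = 0. s.e.m. is sample SD (n−1 denominator)
over √n throughout.

## Junction polarity

A junction's orientation is the acute angle between its endpoint chord and
the ML axis; curved junctions would use the endpoint chord for angle and
their full pixel trace for intensity. Junctions strictly below 45° are ML,
otherwise AP — a chord at exactly 45° counts as AP, the strict reading of
"less than". The per-ROI polarity ratio is the ratio of class means,
mean(ML)/mean(AP), rather than a mean of per-vertex junction-pair ratios:
the pairing of junctions sharing a vertex is ambiguous in practice, whereas
class means are well defined for any junction sample. The ratio is invariant
under global intensity scaling and junction relabelling; ROIs missing a
class are flagged rather than imputed.

## Polar-coordinate cortex

The apical cortex-interior of a cell is the pixel set within a radial
fraction f (default 0.8) of the centroid-to-boundary distance: a pixel at
angle θ and distance r belongs to the mask iff r ≤ f · R(θ), with R(θ) the
distance to the *first* crossing of the traced boundary polygon along the
ray at θ. The implementation ray-casts each pixel against every polygon edge
exactly (linear interpolation between boundary samples is exactly the
ray-segment intersection); for star-shaped cells this equals containment in
the polygon scaled by f about the centroid, which is how the independent
test oracle computes it. For non-star-shaped cells the first-crossing rule
under-covers distal lobes — accepted, since the transform presumes
roughly convex apical outlines and the synthetic tessellation produces them.
A centroid outside the polygon (extreme concavity) falls back to the pole of
inaccessibility, logged. On rasterised disks the cortex/cell pixel ratio
converges to f² = 0.64 (within ±0.02, ±0.01 and ±0.005 at radii 25, 50 and
100 px in the test suite).

Apical-enrichment calls automate what is otherwise scored by eye: a cell is
flagged when its cortical mean exceeds the population median by more than
k·MAD (default k = 3). The threshold is configurable; it exists so the
fraction-of-enriched-cells statistic is reproducible.

## Nuclear positivity

Background statistics are the mean and *population* SD over all pixels
outside every nucleus (sample-vs-population is negligible at pixel counts;
population SD keeps the value deterministic in meaning). No dilation margin
is applied around nuclei by default. A nucleus is positive iff its mean
intensity strictly exceeds background mean + k·SD (default k = 2); the
classifier is monotone in intensity and anti-monotone in k. At a true
positive offset of 5 background SDs, sensitivity and specificity both exceed
0.99 at n = 1000 across seeds.

## Depth statistics

Relative depth is D/(D+V) × 100 %, 0 % at the dorsal surface;
antisymmetric by construction (swapping D and V complements to 100).
Histograms use half-open 10 % bins with the final bin closed at 100 so
totals are conserved; group-vs-reference comparisons report per-bin relative
frequency ratios, undefined where the reference bin is empty. Tissue thirds
are exact thirds of relative depth, the same definition everywhere a
"ventral third" or "dorsal third" statistic is reported.

## Constriction kinetics

Each cell's area series (≥ 3 timepoints, positive maximum) is normalised by
its largest area and aligned so that time 0 is the earliest maximal-area
timepoint; aligned means are suppressed below n = 3 contributing cells.
Ingression is the first timepoint at which the normalised area is strictly
below the threshold fraction (default 0.1) *and never recovers* — the
persistence rule avoids false calls from segmentation flicker; a cell whose
label disappears satisfies it trivially at its final collapse.

## Statistics

Unpaired comparisons default to Welch's unequal-variance t-test (the safer
default when group variances are unknown; the pooled form is selectable),
paired comparisons to the paired t-test, distribution comparisons to the
two-sided two-sample Kolmogorov–Smirnov test; all p-values are two-sided and
no multiple-testing correction is applied. A paired comparison with constant
nonzero within-pair difference is degenerate (zero variance) and is reported
as p = 0 rather than an arbitrary large statistic. Significance bands: ns
P > 0.05; \* < 0.05; \*\* < 0.01; \*\*\* < 0.001; \*\*\*\* < 0.0001. Under
the null both wrapped tests reject at 3.5–6.5 % at α = 0.05 (2000
replicates; the calibration check uses n = 20 per group for the t-tests and
n = 500 per sample for KS, where the asymptotic KS null distribution is
accurate and p-value discreteness is negligible).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analytics assume,
not microscopy appearance:

* **Tracks** start uniformly over [−half-width, half-width] × AP extent at
  the dorsal surface. Each cell drifts toward the midline at
  `v_conv · d₀` (a linear convergence gradient in normalised start distance
  d₀) and ventrally at `v_ing` only while within the medial band, plus
  isotropic Gaussian step noise. Defaults — 180 min at 5 min intervals,
  half-width 300 µm, v_conv = 0.18 µm/min, v_ing = 0.035 µm/min, medial band
  100 µm, step noise SD 1 µm — were chosen so that a 3 h acquisition yields a
  mean convergent displacement near 16 µm and a medial ventral displacement
  near 6 µm, the magnitudes characteristic of junctional-zone imaging at
  these stages. Ground truth stores each track's drift and the noise-free
  displacement obtained by running the identical step recursion without
  noise, so recovery tests compare against the exact discrete drift
  integral.
* **Epithelia** are Voronoi tessellations of jittered grid seeds — convex-ish
  cells for which the cortex transform is well posed. Shared boundaries are
  painted at the AP base intensity or `f ×` it for ML junctions (f is the
  planar-polarity factor, default 2); vertex pixels claimed by several
  junctions take the maximum and are excluded from per-junction intensity
  measurement, so the noise-free pipeline recovers f exactly. Cortical
  patches and nuclear positives are assigned in known per-region subsets;
  noise is additive Gaussian clipped at zero — the simplest model that
  exercises every threshold.
* **Constriction series** hold a gentle plateau rising to the maximum at the
  end of the non-constriction phase, then decay linearly (default rate 1/90
  per min); 40 % of cells by default ingress through zero while the others
  floor at 35 % of their maximum. The true ingression time is recorded from
  the noise-free signal with the same threshold rule the detector uses.
* **Depth sections** draw the tissue third from the requested mixture and
  the relative depth uniformly within it.

None of this captures real-data pathologies — segmentation errors, uneven
illumination, tracking gaps, curved-surface projection artefacts, non-convex
cell shapes, spatially correlated noise. Passing tests therefore demonstrate
that the estimators are correct for data satisfying their stated
assumptions, not that those assumptions hold for any particular microscope
or embryo.

## Problem sizes

The test suite and the acceptance script run the generators at moderate
scale — 925 tracks for the headline displacement statistics (the scale of a
three-embryo tracking experiment), 100-cell epithelia, 1000-nucleus fields,
2000-cell depth samples, 2000-replicate null calibrations — sizes at which
every Monte-Carlo tolerance (3 s.e.m. / 3 binomial SE) is meaningful while
the whole suite completes in well under a minute of compute.

## Known limitations

* The cortex transform is exact only for star-shaped outlines; heavily
  lobed cells are under-covered beyond the first boundary crossing.
* Junction orientation uses the endpoint chord; strongly curved junctions
  get a coarse angle.
* Rasters are strictly 2-D: the pipeline consumes projected images and does
  not reason about the projection itself.
* The ingression detector needs the collapse to persist to the end of the
  series; late re-appearances of a recycled label would mask a genuine
  ingression.
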