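# Methods

## The measurement model

Dorsal closure is quantified through two movies per embryo: a *closure*
movie (frame interval 4 min) showing the eye-shaped dorsal hole, and an
*AS* movie (frame interval 30 s) of the segmented amnioserosa sheet.
Timepoint zero is the frame right after germ-band retraction; all kinetic
series are aligned to it.

**Hole kinetics.** Each hole contour yields a length L (extent along the
anterior-posterior axis, by default the image x-axis; a supplied axis
angle rotates it) and a width W (maximal perpendicular extent). The
leading-edge convergence speed is the rate of width decrease; the zipping
speed is the per-frame finite difference of the length,
v(t_x) = (length(t_x) − length(t_x+1))/Δt, with no smoothing. Closure
duration is the time from t₀ to the first frame with W ≤ threshold
(0 µm by default, suitable for exact synthetic widths; pass ~2 µm for
pixelated data). The length-to-width ratio is evaluated at the 30-µm width
crossing with linear interpolation between the bracketing frames, which
removes most of the 4-min quantization.

*Convergence-speed smoothing.* A raw forward difference of a 4-min series
is noisy and has no well-defined maximum on real data. The curve is
therefore smoothed over a three-frame centered window of the width series
— the central difference (W(t_x−1) − W(t_x+1))/(2Δt) — with the plain
forward/backward difference retained at the two ends. Averaging the raw
differences themselves over three frames was considered and rejected: its
six-interval footprint flattens a piecewise-linear speed peak by
~0.05 µm/min at the profile kink, while the central difference keeps the
bias within ~0.03 µm/min and is equally robust to frame noise. Whether
"convergence" means the full-width rate or the per-edge (half-width) rate
is a convention; the full-width rate is used throughout, in generator and
analyzer alike.

**AS pulsation.** The analysis window opens at the first frame where
W ≤ 50 µm and lasts exactly 15 min (31 samples at 30 s). The six tracks
whose centroids are nearest the hole centroid at the window start are
selected. Each area series is normalized as n(t) = A(t)/Ā − 1 with Ā the
window mean — zero-mean by construction and size-independent; this
function is the single place to swap in an alternative normalization.
Pulses are local maxima of n with topographic prominence ≥ 0.02 (about
20% of a healthy wild-type amplitude; configurable). Pulse height is peak
minus the preceding detected trough. A peak with no interior preceding
trough — a cycle truncated by the window edge — counts toward the pulse
*number* but not the amplitude mean; using the window-start value as a
surrogate trough (the fallback when no pulse has an interior trough) would
under-estimate the mean by up to 12% depending on the pulsation phase,
whereas excluding partial first cycles keeps the recovered amplitude
within 5% of truth at every phase. "Height" here is peak-to-trough; a
peak-to-baseline variant can be obtained from the stored pulse tuples.

**Shape.** N = area/convex-hull-area is computed on the polygon vertices
(not the raster), is invariant to similarity transforms, lies in (0, 1],
and equals 1 exactly for convex cells.

**Tracking.** Cells are linked frame to frame by greedy bipartite matching
on descending intersection-over-union with acceptance threshold 0.5 (ties:
larger IoU, then smaller incoming label). AS cells move far less than a
cell diameter per 30-s frame, so greedy matching equals optimal assignment
in practice; the matcher is isolated and replaceable. Division and fusion
are not handled — neither occurs in the measured window. Cell boundaries
are traced at the half-pixel level (marching squares at level 0.5), and
areas/perimeters are computed on the traced polygons, so a label's polygon
area tracks its pixel count to ~1 px².

**Filopodia.** Consumed as polyline annotations (mirroring manual
line-tool measurement — no detector is implied by the data), six
engrailed stripes per embryo, restricted to frames where the leading edges
are 30–50 µm apart (closed interval). Length is the Euclidean polyline
length; the per-embryo statistic is the mean across the six stripes. A
filopodium spanning two stripes is counted in the stripe containing its
base.

**Statistics.** All tests are two-sided. Non-normal metrics (assessed by
the D'Agostino–Pearson omnibus test, which needs n ≥ 8) use
Kruskal–Wallis (tie-corrected) with Dunn's post hoc: mean ranks from the
pooled ranking, tie-corrected variance, Bonferroni adjustment over the
mutant-vs-reference comparisons only (full-pairwise available by flag).
Normal metrics use ordinary one-way ANOVA with Dunnett's many-to-one
comparisons (adjusted p from the multivariate-t distribution; its
quasi-Monte-Carlo evaluation is seeded, with residual fluctuation ~1e-5).
Phenotype-category counts are compared per mutant against the reference
row in 2×k tables with Pearson chi-square, no continuity correction. The
star mapping closes every boundary: p = 0.05 earns *.

## The synthetic-embryo generator

The generator provides ground-truthed inputs whose recoverable parameters
equal published wild-type and formin-mutant values.

**Speed profiles.** Convergence and zipping speeds are piecewise-linear in
time, defined by knot tables per genotype. The initial hole width W₀ and
length L₀ are *derived* as the exact integral of the corresponding profile
over [0, duration], so closure lands exactly on the printed duration (no
initial hole size is printed anywhere to copy). Wild-type knots encode:
initial convergence 0.55 µm/min, maximum 1.12 µm/min at 40 min, duration
174 min; zipping rising 0.7 → 1.7 µm/min over ~90 min (first-84-min mean
exactly 1.1 µm/min), a plateau, then a final boost to 2.5 µm/min. Mutant
convergence knots encode initial speeds 0.28 (form3) and 0.27 (dia)
µm/min, the frl maximum of 0.71 µm/min, a sub-wild-type DAAM peak
(0.95 µm/min, chosen), the 12-min dia peak delay, and durations
204/219/245/274 min (frl/DAAM/form3/dia). Mutant *zipping* knots are not
individually published as tables; they are package choices anchored to the
printed start speeds (0.4 frl, 0.6 dia µm/min), lowered first-phase maxima
(1.2 DAAM, 1.1 form3 µm/min) with 48/68-min peak delays for dia/frl, and
first-84-min means of 0.7/0.4/0.7/0.5 µm/min (DAAM/frl/form3/dia).

**Hole rendering.** The contour is two symmetric parabolic arcs meeting at
the canthi (±L/2, 0) with mid-width W, 121 vertices per arc so the vertex
extents equal (W, L) exactly. Noise adds Gaussian vertex jitter
(sd = 0.5 px × 0.2 µm/px); noisy widths are re-measured as vertex extents.

**AS sheet.** 24 cells tile a 60 × 30 µm ellipse by centroidal Voronoi
tessellation (8 Lloyd iterations). Each cell's rest polygon is its
tessellation cell sampled radially at 96 angles, shrunk to 80% about its
centroid — the gap standing in for the membrane signal, as in watershed
segmentations — and perturbed by a six-lobed sinusoidal radial waviness
(relative amplitude 0.15 for wavy genotypes, 0.03 for round ones). Through
time the polygon scales uniformly so its area follows
A0ᵢ(1 + a sin(2πf t/T + φᵢ)) with phases φᵢ uniform per seed. Since each
rendered polygon stays strictly inside its own convex tessellation cell
(the worst-case radial factor 0.80·1.15·√1.1 ≈ 0.97 < 1 is checked, and
waviness is damped with a warning if a parameter set would violate it),
labels can never overlap. Frames are rasterized at 0.2 µm/px over the
window plus nothing more — 31 frames of 350 × 650 px.

Pulsation parameters are not printed anywhere: period 230 s and wild-type
relative amplitude a = 0.10 are chosen to give ~4 pulses per 15-min
window, consistent with the qualitative pulsatility of healthy AS cells;
mutants use a = 0.045, a 55% reduction sitting inside the measured 50–60%
band, with frequency multipliers 0.9 (frl, DAAM) and 1.1 (form3, dia)
matching the reported (non-significant) frequency tendencies. The
ground-truth normalized peak-to-trough amplitude is 2a to first order.

**Filopodia.** Per stripe, count ~ Poisson(8) and length ~ Gamma(shape 4,
mean 3 µm) — typical leading-edge filopodia scales — rendered as 3-segment
polylines with jittered headings; the drawn lengths are recorded as truth.

**What the generator does not emulate.** No mechanics (no force balance or
vertex model — areas are prescribed, not emergent), no cell
delamination/apoptosis, no neighbor exchanges, no segmentation errors, no
photobleaching or z-projection artifacts, and 2-D geometry only. Passing
recovery tests therefore demonstrates that the *measurement* chain is
unbiased on clean, geometrically faithful input; it does not certify
robustness to segmentation failure modes of real microscopy.

## Numerical choices and degenerate inputs

* Piecewise-linear profile integrals are evaluated exactly (trapezoid on
  the union of knot and query times); widths below 1e-9 µm snap to zero so
  float residue cannot defer the closure frame.
* Closure series extend two frames past completion so forward differences
  exist at the last measured frame.
* `closure_duration` errors if the hole never closes (reporting the final
  width); `lw_ratio_at` errors if the width never crosses the query value,
  and returns L(0)/W(0) if the movie already starts below it.
* Curve averaging treats shorter curves as missing beyond their end
  (mean/sd over available embryos; sample sd, 0 where only one embryo).
* Degenerate polygons (< 3 vertices, zero area, self-intersection) raise
  rather than return silently wrong indices; multi-component labels keep
  the largest component with a logged warning.
* All-identical data in Kruskal–Wallis returns H = 0, p = 1 with a flag
  (not an exception); ANOVA with zero variance everywhere raises.

## Problem sizes

The validation suite and the acceptance script run entirely on synthetic
embryos: five genotypes, one embryo each, 24 AS cells, 31 AS frames, and
closure movies of 46–71 frames — the scale at which every printed value is
recoverable and a full five-genotype benchmark completes in seconds on one
CPU. Statistical calibration checks use 1000-replicate type-I-error
simulations at n = 8–10 per group.

## Known limitations

* The AP axis must be supplied (or be the image x-axis); there is no
  automatic embryo-axis estimation.
* The temporal arrest of closure seen in some mutants is visible in the
  width curves but no arrest-calling algorithm is provided.
* Track linking assumes displacements are small relative to cell size; it
  is not suitable for fast-moving or dividing cells.
* Filopodia must be annotated; there is no detector from raw masks.
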