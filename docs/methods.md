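# Methods

This note records the models, numerical choices and limitations behind
`origamiqc`, in the spirit of a package's statistical documentation.

## Height-mixture decomposition

**Model.** Pixel heights on a flattened AFM micrograph of DNA origami on
mica are treated as draws from a three-component Gaussian mixture: mica
background, staple strands, origami. The quantity of interest is the weight
vector `P = (P_mica, P_staple, P_origami)`, `ΣP = 1`; the component means
and SDs are nuisance parameters.

**Fit.** We fit the mixture CDF to the empirical CDF of pixel heights by
unweighted least squares over the nine parameters. Fitting the CDF rather
than a histogram avoids binning choices; every (subsampled) pixel height
contributes one residual. The empirical CDF uses `F(z_i) = i/n` with tied
heights collapsed to the highest rank. Maps larger than 50,000 pixels are
uniformly subsampled (seeded) before fitting; the cap is overridable and
exists purely for tractability.

**Parameterisation and constraints.** Two free logits with the third
fraction by complement (softmax) enforce `ΣP = 1` and `P_k ∈ [0, 1]`;
log-SDs enforce `σ > 0` (clipped to e±30 to avoid overflow); means are
unconstrained. Optimisation is Levenberg–Marquardt
(`scipy.optimize.least_squares`), best of `n_restarts` starts: the first at
the 25th/60th/95th height percentiles with `σ = (IQR/1.35)/2` and
`P = (0.6, 0.3, 0.1)`, later starts jittered with a seeded RNG.

**Label canonicalisation.** After fitting, components are sorted by mean so
the labels mica/staple/origami always mean lowest/middle/highest
population. A component whose weight falls below 1% has an unidentifiable
mean (the fit has collapsed onto fewer populations); such components are
parked after the substantive ones with their mean snapped to the highest
substantive mean. In the single-population limit this keeps the dominant
weight on `P_mica`. Consequence: when a genuine population carries < 1% of
pixels its label can shift down by one place; at the staple fractions this
analysis targets (tens of percent) this does not arise.

**Degenerate inputs.** Maps with under 100 pixels or with constant heights
are refused with an explicit error. Non-convergence of every restart is
reported via `converged=False`, never silently.

**Optional flattening.** A least-squares plane subtraction is available
(`flatten=True`, default off) as a minimal stand-in for instrument-side
levelling; synthetic maps are already flat.

## Particle census

Detection thresholds the raw height map and labels 8-connected regions.
The binary mask is morphologically closed (3×3 element, 2 iterations by
default) before labelling: a 6-hb tube is only ~2 px wide at 4 nm/px, so
isolated sub-threshold pixels would otherwise sever it; closing bridges
gaps up to ~4 px while the rod-placement buffer in the synthetic scenes
(and typical inter-particle spacing on a usable micrograph) keeps distinct
particles from merging. Regions below `min_area_px` (default 6 in the
pipeline) are discarded, which also removes staple blobs that poke above
threshold.

Contour length is the longest geodesic along the skeleton
(`skimage.morphology.skeletonize`, Dijkstra between skeleton endpoints,
axis steps 1 px, diagonal steps √2 px). For a closed or blob-like skeleton
with fewer than two endpoints a two-sweep farthest-point heuristic is used.
Skeleton lengths of wide or smoothed regions read a few percent high
(staircase effect) and the skeleton is shortened slightly at rounded ends;
both effects are far inside the ±50% classification windows.

Classification uses reference lengths 500/1000 nm by default (the rounded
field convention for the 6-hb monomer/dimer), a ±50% window around each,
and the midpoint (750 nm) as the class boundary, with the boundary value
assigned to the dimer (half-open rule). Everything outside both windows —
fragments, aggregates, merged pairs — is "other" and excluded from the
dimer-content denominator. Touching rods are not split (no watershed); on
crowded fields this undercounts both classes and is a documented
limitation, mirroring that manual counting also skips ambiguous objects.

The design-length helper is exact arithmetic
(`segments × bp/segment × 0.34 nm`), with a separate 2-significant-figure
presentation helper: 32 × 42 × 0.34 = 456.96 → 460 nm;
64⅔ × 42 × 0.34 = 923.44 → 920 nm.

## Half-subset bootstrap

The resampling scheme draws `round(N/2)` elements without replacement
(round half up, so N = 273 → m = 137), records the subset mean, repeats
(default 10,000, vectorised via row-wise permutations), and reports the SD
of the subset means with `ddof = 1`. Because the data are binary, the
subset mean is a scaled hypergeometric variable and the scheme has the
closed form `SE = √(p(1−p)/m · (N−m)/(N−1))`, which serves as an exact
oracle in the tests (plus exhaustive subset enumeration for N ≤ 8). Note
this SE is smaller than a conventional resampling-with-replacement SE by
the finite-population factor; it quantifies half-sample stability, not the
sampling error of the underlying field.

## Gradient QC

Profiles are per-row means over a rectangular ROI of a grayscale tube
photograph, mapped to depth 0 (meniscus) → 1 (bottom) and min–max
normalized; a constant ROI is returned unnormalized with a flag. The
pre-normalization intensity span, referenced to the image dtype's full
scale, is kept on the profile (`raw_range`) because the uniform test needs
it: a tube is called **uniform** when that span is below 5% of full scale,
**step** when a single depth increment carries more than half of the total
rise, and **smooth** otherwise. Both thresholds are configurable; the
defaults encode the qualitative outcomes of interest (unmixed step at short
spin, quasi-linear gradient at the optimal spin, fully mixed solution at
long spins).

Reproducibility across replicate tubes: profiles are linearly interpolated
onto a common depth grid, and each replicate's mean absolute deviation from
the pointwise mean profile is expressed in % of the normalized range,
summarised as mean ± SD (ddof = 1). With N replicates of i.i.d. noise of SD
σ, the expected per-replicate deviation is the folded-normal mean
`σ√(2/π)` shrunk by `√((N−1)/N)` because deviations are taken from the
sample mean; the tests assert against this exact finite-N expectation.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes:
three height populations (defaults mica 0 ± 0.15 nm, staple 0.5 ± 0.3 nm,
origami 2.0 ± 0.5 nm — plausible values for oligos and a 6-hb on mica,
since only the separability of the groups matters), additive instrument
noise (0.05 nm SD), straight capsule-shaped rods of the 6-hb design
lengths (2% length CV) and width 8 nm, and staple strands as 5-px blobs.
Rods are placed by rejection sampling with a buffer that keeps them from
touching; overlapping classes resolve origami > staple > mica. Default
calibration is 4 nm/px (a 1 µm scan at 256 px).

What the generator does **not** model: tip convolution, scan-line
artifacts, drift, surface curvature, rod curvature, aggregates and
misfolds, or touching particles. Passing recovery tests therefore shows the
estimators are correct under the stated noise model — not that detection is
robust to every real-world imaging artifact.

Problem sizes in the test and acceptance suites (256²-pixel mixture scenes,
twenty seeds; 512²-pixel census scenes, eight rods each, ten seeds across
five dimer fractions; 10,000 bootstrap resamples; 20 gradient replicates of
400 points) were chosen to make each statistical check decisive at
desk scale.

## Determinism

Every stochastic routine takes an explicit seed and uses
`numpy.random.default_rng`; identical inputs including the seed produce
bit-identical outputs. The pipeline derives fixed per-stage seed offsets
from the config seed and writes a byte-reproducible `report.json`
(provenance carries the config hash, seed and package version; no
timestamps).
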