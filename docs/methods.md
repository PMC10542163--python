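# Methods

This note documents the models, numerical choices and limitations behind
each endokit stage, and what the synthetic-data generators do and do not
emulate.

## Coordinate and unit conventions

Images use raster coordinates: origin at the top-left corner, x rightward
(columns), y downward (rows), positions in nm, pixel centers at
(index + 0.5)·pitch.  The default pixel pitch is 30 nm, so the default
30×30-pixel bouton ROI covers 0.81 µm².  EM annotations are stored in pixel
units with a per-record nm/pixel scale and converted to nm on parsing.
Times are in seconds, concentrations in nM, chemical shifts in ppm.

## STED stage

**Preprocessing.**  Images are first smoothed with a Gaussian of σ = 1.2 px
to suppress shot noise ("radius" of such filters is read as the Gaussian σ;
configurable).  Deconvolution is blind Richardson–Lucy: each iteration
multiplicatively updates the PSF (holding the image estimate) and then the
image (with the refreshed PSF), renormalizing the PSF to unit sum.  Two
rounds of 10 iterations are run, the second seeded with the PSF returned by
the first.  Convolutions use reflective boundary handling, which makes a
constant image an exact fixed point and keeps total flux conserved to
within 1%; intensities are clipped at zero after every update, and a PSF
that collapses to zero raises an error.  The initial PSF is supplied as a
kernel (e.g. a Gaussian built by `gaussian_psf` from a measured width);
automatic PSF estimation from point-like sources is not implemented.

**Boundaries and puncta.**  Active-zone boundaries are traced per local
peak of the reference channel as the marching-squares contour (linear
subpixel interpolation on cell edges) at level = peak/2, keeping the
smallest closed component whose interior contains the peak.  Open contours
— level sets that cross the ROI border — are discarded, implementing the
rule that signals crossing the ROI are excluded.  Overlapping boundaries
from distinct peaks are kept separate; distances simply use the nearest
one.  Puncta are local maxima above threshold, refined by a 1-D quadratic
fit along each axis of the 3×3 neighborhood (offsets clipped to ±0.5 px);
minimum pairwise separation keeps the brighter peak, ties broken by scan
order.  Defaults, both exposed in every entry point because no standard
values exist: minimum separation 120 nm; intensity threshold = ROI
mean + 2·SD.

**Signed distances.**  The magnitude is the exact minimum distance to the
boundary polyline (shapely segment arithmetic); the sign is negative iff
the point is inside the polygon (even-odd rule), with points exactly on the
boundary reported as 0 with positive sign.  Tests verify agreement with an
independent brute-force oracle (10⁵-point contour densification plus
hand-written ray casting) to below 0.1 nm.

## EM morphometry

Vesicle classification is a partition by diameter: < 60 nm synaptic
vesicle, 60–100 nm (both bounds inclusive, since the stated range names no
endpoint convention) large endocytic vesicle, > 100 nm endosome; annotated
endosome polygons are endosomes regardless of shape, and the
circular/irregular distinction is taken from annotation labels, not
inferred.  Pit width is the Euclidean length of the base chord joining the
pit polyline's first and last vertices; depth is the maximum perpendicular
distance from that chord to any vertex.  Measuring depth to the chord
rather than to a local membrane tangent is a declared choice: it is robust
when the flanking membrane is curved and reproduces the analytic
semicircle (width 2r, depth r) exactly.  Pit-to-PSD position is the
along-membrane arc distance from the base midpoint to the nearest PSD
interval edge.  No distance cutoff is applied to pit eligibility — the pit
list is taken as annotated.  Summaries report per-profile counts,
group means ± SEM (SD/√n, ddof = 1), stimulation-induced increases over the
matching no-stim control, summed LEV + endosome means, and pit width/depth
medians with distribution-free CIs.

## pHluorin kinetics

The generative model is baseline F₀, a linear rise across the stimulus
window (onset to onset + n_stim/rate; 10 pulses at 20 Hz from 5 s end at
5.5 s), then decay A·[p + (1−p)·e^(−t/τ)] toward a plateau fraction p,
all multiplied by mono-exponential bleaching e^(−t/K).  Correction
multiplies by e^(+t/K) with K fitted on a no-stimulation control
(log-linear start, nonlinear refinement); a non-decaying control returns
K = ∞ and the identity correction.  Normalization uses the single frame
before stimulus onset (baseline) and the maximum corrected value in
(onset, onset + 10 s] (peak), so the normalized trace is exactly 0 and 1 at
those frames.

**Decay fitting.**  The post-peak decay is fit by trust-region nonlinear
least squares with analytic Jacobian and a fixed multi-start grid
(τ₀ ∈ {2, 10, 50} s) for determinism, with bounds τ ∈ (0, 10×duration],
p ∈ [−0.1, 1.1], a ∈ [0.2, 2].  The model carries a free amplitude a,
y = a·[p + (1−p)·e^(−s/τ)], rather than being anchored at y(0) = 1: the
normalization peak is a single noisy frame (the maximum of ~20 samples, so
biased upward by roughly twice the noise SD), and anchoring the model to it
propagates that one frame's error into τ and p — simulations at 5% noise
show the anchored fit's median τ error at ~37% versus ~8% for the
free-amplitude fit, whose plateau is reported as a fraction of the fitted
amplitude and is invariant to the normalization scale.  For noise-free
traces a = 1 and both parameters are exact.  Plateau recovery is assessed
in absolute terms (fraction-of-peak points) because the plateau is itself
a fraction and generating values include 0.  Field summaries average
normalized y values — never fitted parameters — and report
100·ȳ(t = 60 s) (nearest sample, measured from imaging start;
configurable) plus a decay fit of the mean trace.

## Binding metrics

The ELISA model is plain one-site saturation, B(c) = B_max·c/(K_d + c),
with no depletion or cooperativity; standard errors come from the Jacobian
at the optimum, and fits whose titration never reaches K_d/10 are flagged
unreliable (K_d and B_max become a ridge).  Chemical shift perturbations
use the weighted Euclidean norm √(ΔδH² + (ΔδN/s)²) with the conventional
¹⁵N scale s = 5 (configurable).

## Statistics

All tests are implemented directly for auditability.  Mann–Whitney uses the
exact null distribution (dynamic-programming recurrence over rank
assignments) for tie-free samples with n_a·n_b ≤ 400, otherwise the normal
approximation with tie correction and no continuity correction — the
latter so that the two-group Kruskal–Wallis test (H = z²) reproduces the
same p-value.  Kruskal–Wallis applies the standard tie correction;
significant omnibus tests (α = 0.05, configurable) are followed by Dunn's
pairwise z-tests on pooled mean ranks with Bonferroni adjustment
(min(1, m·p), m = k(k−1)/2).  Median CIs are distribution-free order
statistic intervals: the k-th smallest/largest values with k the largest
rank keeping each binomial(n, ½) tail within (1−level)/2; samples too
small for the requested level return (min, max) with a flag.  The
D'Agostino–Pearson omnibus K² combines the transformed skewness and
kurtosis z-scores against χ²(2); SciPy's implementation serves as an
independent cross-check in the tests, never as the implementation.

## Synthetic data: what it does and does not emulate

Generators return their ground truth alongside the data; recovery tests
consume only the data and compare only against the truth, and fixed seeds
give bit-identical outputs.  STED fields are sums of isotropic Gaussian
blobs convolved with a Gaussian PSF — evaluated in closed form (variances
add, flux conserved) so noise-free fields equal direct evaluation of the
stated formula — with optional Poisson noise (applied to expected counts
after scaling by a photons-per-intensity factor, default 1; the true noise
statistics of STED detection are not documented, so Poisson is an
assumption) or additive Gaussian noise.  Not emulated: optical
aberrations, anisotropic or measured PSFs, detector artifacts, 3-D stacks,
background structure from neighboring neurons.  Ω-pits are parameterized
as a circular bulb (radius 0.9 of the maximum feasible given base, neck
and depth) joined to the membrane by straight neck segments; emitted
coordinates honor the stated base, neck and depth exactly.  Traces add
i.i.d. Gaussian noise to the bleached ideal trace; they do not emulate
stimulus-locked artifacts, drift, or bouton-to-bouton heterogeneity.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated models, not robustness to every artifact of
real recordings.

## Verification problem sizes

`scripts/acceptance.py` uses: 100 random punctum/contour pairs against the
brute-force distance oracle; Gaussian blobs of σ = 2–4 px for contour
radii; 200 seeded traces (τ ∈ [5, 150] s, p ∈ [0, 0.5], noise 5% of the
response amplitude, 2 Hz, 120 s) for kinetic recovery plus 100 controls at
2% noise for K; 100 noisy binding fits (3% of B_max, 8 concentrations × 4
replicates); and 5000 simulations each for Mann–Whitney type-I error,
Kruskal–Wallis + Dunn family-wise error, and median-CI coverage.  These
sizes make the whole script run in well under a minute on one CPU while
keeping the Monte-Carlo standard error of each rate below ~0.4 points.

## Known limitations

Bouton selection is manual (ROI centers are inputs); no automatic cell
segmentation, drift or chromatic correction; no 3-D reconstruction across
serial EM sections; late endosomes/multivesicular bodies are not
classified; multi-stimulus train deconvolution and two-site or competitive
binding models are out of scope.
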