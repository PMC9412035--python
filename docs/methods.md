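# Methods

## Measurement model

The package treats membrane stretching as an approximately affine, in-plane,
time-periodic deformation of a small fiducial dot grid near the membrane
center. With reference dot positions X and current positions x(t), the
displacement field is u(t) = x(t) − X, and the quantity of interest is the
infinitesimal (linear) strain

    ε(t) = ½(∇u + ∇uᵀ),

evaluated at the dot positions. Using the linear strain rather than
Green–Lagrange is deliberate: at stretches of at most ~10 % the quadratic term
E_GL − ε = ½∇uᵀ∇u is of order ε²/2 ≤ 0.005 and lies below the optical noise
floor of dot-centroid tracking. The known cost is a lack of objectivity: a
rigid rotation by θ produces a spurious linear strain ≈ θ²/2 (5·10⁻⁵ at
θ = 0.01 rad). Both properties are asserted by tests.

### From pixels to strain

**Localization.** Frames are converted to grayscale in [0, 1] (Rec. 709 luma
for RGB input) and binarized after polarity normalization, so dark-on-bright
and bright-on-dark dot patterns are handled identically. The automatic
threshold is Otsu's method — parameter-free and appropriate for bimodal
dot/background histograms; a fixed threshold can be given instead.
Morphological opening (radius 1 px) removes speckle, and border-touching
components are discarded because truncated dots have biased centroids. Each
remaining component becomes an intensity-weighted centroid. Two refinements
matter for sub-pixel accuracy and are on by default in the sequence pipeline:

- a Gaussian pre-filter (σ = 1.5 px) acting as a matched filter for the
  blurred dot profile — it suppresses pixel noise without displacing
  symmetric dots;
- the weighting region for the centroid is the component grown by 3 px
  (per-label expansion, so close dots never merge). A hard Otsu mask cuts
  through the dot's blurred tail, and as the dot moves sub-pixel the mask
  jumps discretely, biasing the centroid by up to ~0.1 px; including the
  tail, whose background-subtracted weight decays to zero, removes that
  truncation bias (measured residual ≈ 0.02 px on noise-free renders).

**Tracking.** The first frame defines the reference configuration and the
row-major dot labels. Frame-to-frame correspondence is the optimal one-to-one
assignment minimizing total squared displacement (Hungarian algorithm);
greedy nearest-neighbour would be marginally cheaper but can swap tracks. The
default displacement gate is 0.45× the minimum reference inter-dot spacing,
which makes swaps geometrically impossible for sub-spacing motion. Missing
interior detections are filled by linear interpolation along the track;
missing detections at the ends are an error because extrapolation is
unreliable. Row ordering tolerates sub-pixel y-noise: centers whose y differ
by < 2 px are treated as one grid row, so noise cannot scramble labels.

**FE strain.** The reference dots are Delaunay-triangulated. The perfect
square grid is fully degenerate for Delaunay (every quad co-circular); qhull's
triangulation of the sorted input is deterministic, and for affine fields the
nodal strains are provably independent of the diagonal choice (tested against
a fixed-diagonal mesh). On each linear triangle the displacement gradient is
constant: with edge matrices D = [X₂−X₁, X₃−X₁] and d = [u₂−u₁, u₃−u₁],
∇u = d·D⁻¹, and ε = ½(∇u + ∇uᵀ) — exact for affine deformation (tested to
1e−12 over 100 random affine maps). Nodal tensors are area-weighted averages
of the incident element tensors, the standard FE nodal-recovery choice; the
mean traces E_xx(t), E_yy(t) are unweighted node averages.

**Cycle analysis.** Peaks must have prominence ≥ 25 % of the trace range and
separation ≥ 0.6 cycle periods; valleys are peaks of the negated trace. The
period comes from the user-supplied loading frequency (1 Hz in the standard
protocol) or, absent that, the dominant autocorrelation lag. Before peak
picking the trace is smoothed with a Savitzky–Golay filter (window 0.4
periods, order 4). This choice is load-bearing: picking raw samples at noisy
extrema biases mean peaks up and mean valleys down by roughly the noise scale,
which at 1 % strain is a several-percent amplitude error; the short quartic
fit removes the bias while distorting a clean raised cosine by < 10⁻⁵. Because
the filter is linear, the offset-invariance and positive-scaling properties of
the analysis hold exactly. The amplitude is mean(peak values) − mean(valley
values) with no per-cycle pairing, so unpaired boundary extrema are harmless;
same-type runs of extrema are collapsed to the most extreme one so that peaks
and valleys strictly alternate. At least 3 peaks are required per sample.

The equibiaxial strain level is (A_xx + A_yy)/2. When the two amplitudes
disagree by more than 20 % of the larger, the result carries an `anisotropy`
QC flag rather than an error — the level is then only a rough summary of a
non-equibiaxial loading.

**Reference-frame sensitivity.** The amplitude is a peak-minus-valley
difference, so the additive strain offset from choosing a different reference
frame cancels. What does not cancel is geometric: measuring relative to a
configuration pre-stretched by ε_ref rescales all strains, hence the
amplitude, by 1/(1 + ε_ref) — a 3.8 % effect for a peak-phase reference at 4 %
loading, and < 2 % for any reference in the lower half of the cycle. The first
frame (typically near rest) is the default reference.

## Synthetic scenes

The renderer emulates the experimental recording: a 3×3 grid (80 px spacing,
5 px dot radius) of dark dots on a bright membrane, deformed by
x(t) = R(θw)·(I + wG)·(X − c) + c + vt with the raised-cosine modulation
w(t) = ½(1 − cos 2πft), so valleys sit at zero strain like a pump stretching
from rest. G carries the equibiaxial/anisotropic and shear components; f
defaults to 1 Hz, recording 10 s at 30 fps. Dots are drawn with analytic
anti-aliased coverage (linear edge ramp of one pixel), blurred (σ = 1 px) and
given seeded Gaussian pixel noise (σ = 0.02 of full scale) — values chosen to
resemble a consumer camera filming a marked membrane. Identical scenes render
bit-identically.

What the scene does **not** emulate: lens distortion and perspective,
illumination gradients and shadows, membrane out-of-plane motion, specular
reflections, and spatially heterogeneous (non-affine) strain beyond an
optional quadratic test field. Passing the recovery tests therefore shows the
algorithmic chain is correct and noise-robust at realistic SNR, not that an
arbitrary real recording will be handled; real footage may need the ROI crop,
a fixed threshold, or area limits tuned to the marker size.

## qPCR statistics

Relative expression is 2^(−ΔCt) with ΔCt = Ct(target) − Ct(housekeeping);
amplification-efficiency correction is omitted (a single verified reference
gene, efficiencies near 1), which is a documented limitation. Expression is
normalized to the geometric mean of the designated control group — the
natural choice for log-scale fold-change data, and it makes the control
group's normalized geometric mean exactly 1. Strain–expression association
uses the Spearman rank correlation: ρ is the Pearson correlation of
average-ranked data, and the two-sided p-value is exact for n ≤ 9 (full
enumeration of the n! rank permutations, feasible in seconds) and a
t-approximation (t = ρ√((n−2)/(1−ρ²)), df = n−2) beyond; the two agree within
0.02 at n = 9. Significance is declared at p < 0.05, with no multiple-testing
correction across genes.

## Problem sizes and numerical choices

Rendered test scenes use the default geometry (3×3 grid, 300 frames of
~250×250 px), which one pipeline pass processes in a few seconds; the
end-to-end recovery check spans ε₀ ∈ {0.01, 0.02, 0.04, 0.08} and achieves
< 1 % relative error at every level under the default noise. Degenerate
inputs fail loudly rather than silently: constant frames (no automatic
threshold), collinear dot patterns (no mesh), constant strain traces (no
cycles), fewer than 3 peaks, missing leading/trailing detections, negative
amplitudes. Assignment and triangulation tie-breaks are deterministic
(sorted element node order; stable sorts throughout), so identical inputs
give identical outputs everywhere.
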