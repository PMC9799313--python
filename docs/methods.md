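# Methods

## The detection model

The observable is a 2D grayscale raster whose objects are 2D
projections of 3D fluorescent deposits. Their radial intensity profile
is modelled as a generalized normal, A·exp(−(d/α)^β) with shape
β ∈ [1, 3]; β = 2 is the isotropic Gaussian PSF, with α = σ√2 so that
the profile reduces to exp(−d²/2σ²). For a bell-shaped profile the
image Laplacian is negative inside a disk of radius ≈ σ√2 around the
peak and positive outside, so the clamped negative Laplacian
V = |min(∇², 0)| outlines object cores while suppressing background
and edges. The discrete Laplacian is the 4-neighbour stencil
[[0,1,0],[1,−4,1],[0,1,0]] with reflect padding — the simplest stencil
consistent with a two-stage smoothing design; a Gaussian after the
Laplacian smooths the stencil's rectilinear artefacts, and an optional
Gaussian before it suppresses noise (skip it when the acquisition
pipeline already deconvolves).

### Self-tuning threshold

A fixed absolute threshold on V does not transfer across images whose
intensity distributions differ. The self-tuning rule uses the excess
kurtosis k of V (all pixels, population 1/n moments — the zero
background carries the tailed-ness information) and its fourth root
z = k^(1/4), a lower bound on the expected standardised score of V via
the Cauchy–Schwarz inequality. The default threshold is geometric:

    T = μ_g(V⁺) · σ_g(V⁺)^(z / PRC)

over the strictly positive support V⁺. Multiplicative thresholding is
natural for a nonnegative, heavy-tailed response, and dividing the
exponent by PRC makes PRC > 1 lower T (favour recall), PRC ≤ 1 raise
it (favour precision). The rule is exactly scale-equivariant:
T(cV) = cT(V), so detection is invariant to global intensity
rescaling.

The geometric reading presumes a noise floor under V⁺. On noise-free
(or aggressively denoised) images the positive support decays over
many decades of smoothed Gaussian tail; σ_g then reaches ≈ 5 and
σ_g^(z/PRC) overshoots the maximum response, detecting nothing. For
such data the package ships an arithmetic reading
(`threshold_mode="arithmetic"`): T = mean(V) + std(V)·z/PRC over all
pixels, which recovers clean synthetic fields exactly (50/50 sources,
zero false positives, every tested seed). The geometric default is
validated under the realistic noisy regime, where it delivers the
tight cross-scenario consistency the self-tuning rule exists for.

Negative excess kurtosis (possible at very low SNR, where the response
distribution becomes platykurtic) makes z = k^(1/4) a domain error.
The default raises with a message advising denoising; a clamp-to-zero
fallback (T degrades to μ_g) is selectable.

### Components and pruning

Pixels with V > T are decomposed into connected components (4- or
8-adjacency; ids assigned in raster order of each component's first
pixel, a deterministic tie-break). Components below `min_area` are
dropped; a useful physical floor is the half-max footprint area of the
narrowest expected PSF (~(2σ)² pixels), below which a component cannot
be a resolved object. An optional heuristic prunes components lacking
any pixel that is ≥ all 8 neighbours in the smoothed image — such
components ride monotone intensity ramps, a smoothing artefact of
severe noise, rather than peaks.

## The labelling model

Objects are described by three raw-unit features: summed intensity,
pixel area, summed V. No per-image feature normalisation is applied;
all standardisation happens downstream so that reference and target
features stay commensurable. A reference model for a label is the
sample mean μ and covariance Σ (1/(n−1)) of the features of objects
detected in images carrying that label; if cond(Σ) > 1e12 a ridge of
1e−9·tr(Σ)/d is added and recorded. Fitting requires n ≥ d+1 objects
and all-positive feature variances.

A target object's Mahalanobis distance D = √((x−μ)ᵀΣ⁻¹(x−μ)) is
z-normalised across the objects of its own image (population std;
z = 0 when an image has one object or zero spread). Per-image
normalisation is the default because acquisition varies per image; a
dataset-pooled option exists. Cantelli's inequality
Pr[Z ≥ z] ≤ 1/(1+z²) turns z into a plausibility — a distribution-free
upper bound on the probability that the object belongs to the
reference population.

Two conventions handle negative z (below-mean distances). The literal
convention squares z as given, penalising unusually *central* objects
symmetrically; it is the default for fidelity to the algorithm as
stated. The one-sided convention clamps z at 0 first, so below-mean
objects keep plausibility 1 — this matches what Cantelli actually
bounds (the upper tail only) and is the convention under which
plausibility ranking discriminates a reference population from a
shifted one (the literal convention scores z = −1 and z = +1
identically and has no ranking power in a pooled z-group; measured AUC
≈ 0.5 vs > 0.99 one-sided in the two-population experiment).

### Triplets and nested labels

With q_J = Pl(o → L_J) from the target model and q_I from the swapped
model, belief for L_J is p = 1 − q_I (Bel(A) = 1 − Pl(Ā)), disbelief
q = 1 − q_J, and uncertainty r = q_J − p. When q_I + q_J < 1 the raw r
is negative — a case the framework leaves open; the package clamps
r to 0, sets p = q_J, and raises an explicit `clamped` flag rather
than dropping the object. Nested labels use two algebraic helpers: the
plausibility unique to an enclosing stratum is max(q_super − q_sub, 0)
(the floor guarantees outliers that score higher under the nested
model receive zero), and the belief that an object belongs to none of
a set of labels is ∏(1 − q_i).

## Fusion and conflict

For a singleton proposition with masses t, s from two independent
models, belief equals mass, and Dempster's rule gives
m = ts/(1 − κ), κ = (1−s)t + (1−t)s, with weight of conflict
W = −log(1−κ) (natural log by default; base 2 selectable). W = 0 only
at certain agreement (t = s ∈ {0,1}); total contradiction
((t,s) = (0,1) or (1,0)) is flagged with W = ∞ instead of raising, so
batch fusion completes and the sanity check surfaces in the output.
An opt-in helper nudges exact 0/1 masses inward by machine epsilon.
Near t = 1 or s = 1 the 1−κ form is numerically cancellative; the
implementation falls back to the algebraically identical stable
denominator ts + (1−t)(1−s) when 1−κ underflows to 0.

## The simulator: what it emulates and what it does not

Defaults state the in-silico validation world: 512×512 8-bit fields;
bright sources with Gaussian PSF σ = 3 and dim sources with σ = 6 and
peak intensity divided by 4; uniformly random placement (optionally
with a minimum separation via rejection sampling); additive Gaussian
noise (std = fraction·255) plus additive Poisson background
(mean = fraction·255), both 0.062 at baseline; clipping to [0, 255].
The bright peak amplitude defaults to 200 — bright but below
saturation, realistic headroom for a well-exposed 8-bit acquisition.
Whether the stated Poisson parameter describes additive background or
signal-dependent shot noise is ambiguous; additive is the default and
a shot mode (Poisson(signal + λ·255)) is available. Ground-truth
footprints are the ≥ 50%-of-peak (half-max) discs; matching is greedy
one-to-one by descending overlap with ≥ 1 pixel sufficing, ties to the
lower component id.

The simulator does **not** emulate anisotropic or spatially varying
PSFs, structured background (e.g. cytosolic labelling gradients),
detector artefacts, sample drift, or 3D sectioning. A green test on
simulated data establishes the self-tuning and belief calculus under
the stated noise model — not performance on any real acquisition.

## Evaluation experiment configuration

The in-silico evaluation harness (consistency across bright/dim
compositions; noise-robustness sweep) runs the detector as a matched
filter at the faint-population scale: pre-Laplacian σ = 6 (the dim
PSF), post σ = 1, PRC = 2, local-maxima pruning on, min_area = 36
(the half-max footprint area of the narrowest PSF). Smoothing at the
faintest objects' scale is what allows their recovery once noise
exceeds their peak intensity; the sub-PSF area floor prevents noise
speckle from inflating apparent recall through chance overlap. The
fixed-threshold baseline in the consistency experiment shares this
entire configuration and differs only in using an absolute V cut,
calibrated once as the adaptive threshold of the balanced scenario's
first field.

At the scaled-down 256×256 evaluation size with the full scenario grid
(1/25/50 bright vs 50/25/1 dim), source density is 4× the original
512×512 protocol; absolute recalls are therefore lower than at full
size (where the adaptive detector reaches recall 0.98–1.0 with
precision 1.0 across all three scenarios at baseline noise), but the
comparative statements — stable dim recall from 16/255 to 64/255 with
degradation at 96/255, and a narrower cross-scenario recall range than
the fixed baseline — hold and are what the tests assert.

## Numerical and design choices

- Coordinates are 0-based (row, col), masks raster-ordered, intervals
  half-open; CSV is comma-separated UTF-8 with '.' decimals.
- Thresholding is strict (V > T), per the rule "zero everything ≤ T".
- Excess kurtosis uses biased (1/n) moments; model covariance uses
  1/(n−1). Geometric stats use population std of log values.
- Detection, labelling and fusion are fully deterministic; all
  simulator randomness flows through one seeded generator, and derived
  per-scenario seeds are mixed through a seed sequence and kept below
  2³¹.
- Component ids, table orderings and JSON layouts are stable so that
  identical inputs produce byte-identical outputs.

## Known limitations

- Objects whose profile departs from a generalized normal (hollow
  rings, filaments) are fragmented rather than detected whole.
- The geometric threshold requires a noise floor (see above); on
  denoised data use the arithmetic mode.
- Very low SNR can push excess kurtosis negative; detection then
  refuses (or clamps, if asked) rather than silently degrade.
- The Mahalanobis distance loses discriminative power if many
  non-informative features are added; the shipped descriptor is
  deliberately three-dimensional.
- Fusion covers two sources per call (iterate pairwise for more) and
  assumes both models scored the identical object set.
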