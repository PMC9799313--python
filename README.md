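# beliefspot

Self-tuning detection of small fluorescent objects in 2D microscopy
images, with belief-theoretic (Dempster–Shafer) labelling of each
detected object against image-level labels, and conflict-quantified
fusion of models trained on heterogeneous datasets.

## Who this is for

Fluorescence microscopy (confocal through super-resolution) produces
images whose intensity distributions vary strongly across channels,
cells and datasets, so a fixed detection threshold tuned on one image
systematically over- or under-detects on the next. When only
image-level labels are available ("this image is a knockout", "this
donor is disease-positive"), objects cannot be classified crisply
either — the evidence for a label is graded. This package addresses
both problems for puncta-like objects (caveolae-scale structures in
STED, amyloid deposits in confocal tissue sections, and similar
bell-shaped fluorescent deposits).

## The method

**Detection.** The response to a bell-shaped deposit is the clamped
negative Laplacian V = |min(∇²I, 0)| of the (optionally pre-smoothed)
image; its connected components outline objects. The threshold is
self-tuning: with excess kurtosis k of V over all pixels and
z = k^(1/4),

    T = μ_g(V⁺) · σ_g(V⁺)^(z / PRC),

where μ_g, σ_g are the geometric mean and standard deviation of the
strictly positive response and PRC is the operator's precision–recall
intent (PRC > 1 favours recall, PRC ≤ 1 precision). Since kurtosis and
σ_g are invariant under global intensity rescaling while V and μ_g are
equivariant, the detected masks do not change when the image is
rescaled — the same PRC transfers across images and channels.

**Labelling.** Each object is described by (Σ intensity, area, Σ V).
A reference model for label L_J is the sample mean and covariance of
objects from images carrying that label. A target object's Mahalanobis
distance to the model, z-normalised per image, converts to a
plausibility through Cantelli's one-sided bound Pl = 1/(1 + z²). Two
directional scores (target model and swapped model) form the Dempster
triplet (p, q, r) = (belief for, belief against, uncertainty), p+q+r=1.

**Fusion.** Beliefs from two independently trained models (masses t, s
on a singleton proposition) combine by Dempster's rule,
m = ts / (1 − κ) with κ = (1−s)t + (1−t)s, and the weight of conflict
W = −ln(1−κ) reports how much the models disagree (W = ∞ flags total
contradiction).

A synthetic-image simulator (Gaussian-PSF point sources in bright and
dim populations, Gaussian + Poisson noise on the 8-bit range) and an
overlap-based precision/recall evaluator make every stage testable
without external data.

## Worked example

```python
import numpy as np
from beliefspot import (SimulationConfig, SpotDetector, simulate_image,
                        match_objects)

cfg = SimulationConfig(n_bright=25, n_dim=25, min_separation=40, seed=1)
image, truth = simulate_image(cfg)          # 512x512, noise 0.062
det = SpotDetector(post_sigma=3.0, prc=2.0, min_area=9)
components = det.detect(image)
result = match_objects(components, truth)
print(f"kurtosis={det.kurtosis_:.1f} z={det.z_score_:.2f} "
      f"threshold={det.threshold_:.3f}")
print(f"components={len(components)} recall={result.recall:.2f} "
      f"precision={result.precision:.2f}")
```

prints

```
kurtosis=190.0 z=3.71 threshold=1.286
components=49 recall=0.98 precision=1.00
```

The image's response kurtosis (190.0) reflects its heavy-tailed
Laplacian distribution; its fourth root (3.71), divided by PRC = 2,
exponentiates the geometric spread to give a threshold (1.286) that
recovers 49 of the 50 sources with no false positives. The same call on
`3.7 * image` returns the identical label map.

The same workflow is available from the shell:

```sh
beliefspot simulate --seed 1 --out field.tif --truth truth.json
beliefspot detect --in field.tif --out run/ --post-sigma 3 --min-area 9
beliefspot model --objects run/objects.csv --label bright --out model.json
beliefspot label --objects run/objects.csv --model model.json --out labelled.csv
beliefspot combine --a labelled.csv --b labelled.csv --mass-col pl --out joint.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computations from
scratch on simulated data: the detection-consistency experiment across
bright/dim composition scenarios, the noise-robustness sweep
(16/255 → 96/255), and the full belief pipeline (two reference
populations → models → triplets → Dempster fusion), printing the
summary statistics each computes. Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model's assumptions, parameter guidance,
and known limitations.
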