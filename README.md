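# sacbias

Humans make far more horizontal saccades than vertical or oblique ones —
during free viewing, search, driving, even fixation in the dark.  `sacbias`
is a library (with a thin CLI) for dissecting that bias into its two
candidate sources:

- an **allocentric**, image-driven component: natural scenes put their
  spectral energy, their salient objects, and their structural cues along
  cardinal orientations, so an observer following scene content inherits a
  horizontal bias from the image;
- an **egocentric**, observer-anchored component: a direction preference
  baked into the oculomotor system itself, which stays put when the image
  is tilted.

Tilting an image dissociates the two: a purely image-driven bias rotates
with the scene, a purely egocentric one does not, and human behaviour lands
in between.  The package provides the full analysis chain for
investigating this on eye-tracking corpora — and a synthetic-data module
that generates every input with known ground truth, so the whole chain is
testable without any recordings.

## What's inside

| module | contents |
| --- | --- |
| `circular_stats` | wrapped-Gaussian circular KDE (σ = 0.1 rad); horizontal-bias metric (mean density at 0°/180°); Rayleigh uniformity test; circular cross-correlation and the tilt reorientation index |
| `eye_preprocess` | blink/artifact cleaning; Engbert–Kliegl velocity-threshold saccade detection (elliptic criterion, robust SD, λ presets 8 and 15); main-sequence / amplitude / direction summaries |
| `image_features` | ring-and-wedge Fourier orientation profile; saccade simulation from saliency maps (maps are *inputs* — any fixation-probability map works); structural orientation-likelihood proxy with a pluggable-classifier contract |
| `target_model` | the generative targeting model `l = l_ego(x′,y′)^α · l_allo(x,y)^β` with `l_ego = f·v·s` (Cauchy amplitude bias, 4-lobe von Mises direction mixture, small-saccade penalty); scanpath simulation; 13-parameter maximum-likelihood fitting |
| `analysis_pipeline` | per-image bias table; shuffle-based chance F test; OLS regression of saccade bias on the three feature biases + PLSR/VIP; tilt-reorientation experiment; amplitude-quartile reorientation |
| `synthetic_data` | orientation-controlled 1/f noise images, anisotropic saliency maps, main-sequence eye traces with injected blinks/saccades, and model-generated scanpath corpora — all pure functions of spec + seed |

The model in one screen: from the current fixation (xₙ, yₙ), every pixel
gets likelihood

```
l(x, y)      = l_ego(x − xₙ, y − yₙ)^α · l_allo(x, y)^β        α = 0.7, β = 1.3
l_ego(x′,y′) = f(x′,y′) · v(θ) · s(x′,y′)                      θ = atan2(y′, x′)
f(x′,y′)     = 1 / (π a (1 + r²/a²))                           Cauchy amplitude bias
v(θ)         = Σᵢ wᵢ exp(κᵢ cos(θ − μᵢ)) / (2π I₀(κᵢ))         4 lobes, Σwᵢ = 1
s(x′,y′)     = 1 − exp(−r² / (2 · 0.9²))                       small-saccade penalty
```

maps are normalized over the pixel grid and the next fixation is sampled
from `l`; α = 0 reduces to pure saliency sampling, β = 0 to a pure
egocentric walker.

## Worked example

Simulate an egocentric-only corpus from known parameters, recover them by
maximum likelihood, then run the tilt experiment on a horizontally
arranged synthetic saliency corpus:

```python
import numpy as np
from sacbias import circular_kde, horizontal_bias
from sacbias.synthetic_data import CorpusSpec, default_truth_params, gen_model_corpus
from sacbias.target_model import (CombinationWeights, fit_egocentric_params,
                                  match_lobes, simulate_scanpath)
from sacbias.image_features import SaliencyMap
from sacbias.analysis_pipeline import tilt_reorientation_experiment

truth = default_truth_params()
uniform = SaliencyMap(np.full((64, 64), 1 / 4096), deg_per_px=0.35)
path = simulate_scanpath(uniform, truth, CombinationWeights(alpha=1.0, beta=0.0),
                         n_saccades=5000, rng=11)
print(f"ego-only horizontal bias: "
      f"{horizontal_bias(circular_kde(np.deg2rad(path.directions_deg))):.3f}")

fit = fit_egocentric_params(path.to_saccades(), (64, 64), 0.35, n_starts=8, seed=0)
print(f"fitted a = {fit.params.a:.2f} deg (truth 1.50)")
for lb, ref in zip(match_lobes(fit.params, truth), truth.lobes):
    print(f"  mu {lb.mu_deg % 360:6.1f}  kappa {lb.kappa:4.1f}  w {lb.weight:.3f}")

spec = CorpusSpec(n_images=6, rng_seed=3)
tables, gt = gen_model_corpus(truth, CombinationWeights(), spec, n_saccades=400, rng_seed=3)
ref = {(i, t): np.array([s.direction_deg for s in tables[(i, t)]])
       for i in range(6) for t in (-30.0, 0.0, 30.0)}
records, rho = tilt_reorientation_experiment(gt["maps"], ref, truth, n_saccades=500, rng=9)
print(records.groupby("source")["index"].mean().round(2))
```

Output:

```
ego-only horizontal bias: 0.347
fitted a = 1.55 deg (truth 1.50)
  mu    0.9  kappa  7.5  w 0.358
  mu   89.1  kappa  5.1  w 0.146
  mu  181.3  kappa  7.2  w 0.297
  mu  270.6  kappa  5.3  w 0.199
source
allo         1.01
ego          0.03
full         0.54
reference    0.52
```

Reading it: the ego-only walker's direction distribution scores a
horizontal-bias metric of 0.35, well above the uniform baseline of 0.16
(a purely horizontal distribution would score 2).  The fit recovers all 13
generating parameters (means within ~1°, concentrations within ~10%,
weights within ~0.01).  Under ±30° image tilt, the allocentric-only
variant rotates fully with the image (mean reorientation index 1.01), the
egocentric-only variant barely rotates (0.03), and the full model (0.54)
tracks the reference corpus (0.52) — the signature pattern that motivates
combining the two components.

To reproduce the fitting protocol that selects weakly biased images first
(so the egocentric estimate is as image-free as possible), rank images by
their saliency bias and fit on the weakest 15%:

```python
weak = table.nsmallest(int(0.15 * len(table)), "saliency_bias")["image_id"]
```

A `sacbias` CLI wraps the common steps (`synth`, `detect`, `features`,
`fit`, `simulate`); `sacbias synth out/ --n-images 6` writes a complete
corpus tree consumable by the other subcommands.

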