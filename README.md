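# gutspat

Micro-scale spatial structure of gut bacteria, and the physics that
shapes it.

Bacteria in the proximal large intestine are not well mixed even at
scales where pH, oxygen, and nutrients are constant: cells of the same
species sit in small clonal clumps a few micrometres across. A
parsimonious mechanism explains this: digesta behaves as a yield-stress
gel, so between contractions daughter cells stay where division left
them and microcolonies grow; a sufficiently strong contraction fluidizes
the gel and disperses them. `gutspat` implements the quantitative
toolchain for that story, end to end, for researchers working on
microbiota biogeography, quantitative microscopy, or gut biophysics:

* **Spatial statistics** — inhomogeneous Ripley K/L/H functions with
  border correction, K̂(r) = [Σ_{b_i≥r} λ_i⁻¹ Σ_{d_ij≤r} λ_j⁻¹] /
  [Σ_{b_i≥r} λ_i⁻¹], L = √(K/π), H = L − r (H > 0 ⇒ clustering),
  ratio pooling across images with confidence bands, a cluster-radius
  readout (argmax_r H / 2), and a Studentized permutation test between
  groups of H curves.
* **Cell detection** — top-hat filtering, mean-relative thresholding,
  morphological classification of single cells vs. clusters vs. food
  particles, and edge-based cluster splitting, yielding per-cell µm
  coordinates.
* **Community divergence** — Jensen-Shannon divergence
  JSD(P,Q) = ½D_KL(P‖M) + ½D_KL(Q‖M) between relative-abundance
  profiles, with base/tip group comparison by one-sided Mann-Whitney U.
* **Rheology** — yield stress from the intersection of power-law fits to
  amplitude sweeps, from the G′/G″ crossover, and from creep
  fluidization.
* **Contraction mixing** — Stokes' second problem for an oscillating
  gut wall under Newtonian digesta: τ(y,t) = Aω√(ρωμ) e^{−ky}
  sin(ωt − ky − π/4), and the mixing depth
  D = −√(2ν/ω) ln[τ_y/(Aω√(ρωμ))].
* **Synthetic data** — generators with known ground truth for all of the
  above (Poisson / Thomas / hard-core / growth-dispersal patterns,
  FISH-like images, two-regime rheology curves, Dirichlet abundance
  tables), so the whole pipeline is testable without any external data.

## Worked example

```python
import numpy as np
from gutspat import (Window, default_radii, estimate_intensity,
                     kinhom_border, pool_and_ci, cluster_radius,
                     studentized_permutation_test, mixing_depth,
                     StokesParameters)
from gutspat.synth import gen_thomas_pattern, gen_poisson_pattern

w = Window.square(184.5)           # one 184.5 µm microscopy field
radii = default_radii()            # 0-20 µm, 0.1 µm step

clustered = [gen_thomas_pattern(0.002, 20, 2.0, w, seed=s) for s in range(6)]
random    = [gen_poisson_pattern(0.04, w, seed=100 + s) for s in range(6)]
summ = lambda pats: [kinhom_border(p, estimate_intensity(p), radii) for p in pats]

pooled, lo, hi = pool_and_ci(summ(clustered))
print(f"max pooled H = {np.nanmax(pooled.Hhat):.2f} µm")
print(f"cluster radius ≈ {cluster_radius(pooled):.2f} µm")

res = studentized_permutation_test([summ(clustered), summ(random)],
                                   r_max=20, n_perm=999, seed=1)
print(f"clustered vs random: p = {res.p_value:.3f}")

depth = mixing_depth(StokesParameters(amplitude=0.03, omega=1.0))
print(f"mixing depth at A=3 cm, ω=1 rad/s: {depth.D:.3f} m")
```

Output:

```
max pooled H = 6.91 µm
cluster radius ≈ 2.80 µm
clustered vs random: p = 0.002
mixing depth at A=3 cm, ω=1 rad/s: 0.206 m
```

The pooled H curve rises well above 0, so the cells are clustered; the
peak location puts the typical microcolony radius near 3 µm (a clump of
a handful of cells); the permutation test confirms the difference from
spatial randomness at p = 0.002; and with measured
digesta properties (yield 45 Pa, viscosity 2237 Pa·s, density
1250 kg/m³) a 3 cm, 1 rad/s contraction fluidizes content to about 21 cm
from the wall — centimeter scale, i.e., deep enough to disperse
microcolonies through much of a cecum.

## The analysis pipeline

The numbered scripts under `analysis/` run the full story and write
tables and figures to `results/`:

1. `01_simulate_patterns.py` — clustered / random / regular /
   growth-dispersal patterns at image scale.
2. `02_spatial_clustering.py` — pooled H(r) with CI bands, permutation
   tests (Bonferroni-corrected), cluster radii.
3. `03_detect_cells.py` — a rendered FISH-like image through the
   detector, with truth-matching metrics.
4. `04_community_divergence.py` — Dirichlet abundance tables, pairwise
   JSD, base/tip group tests.
5. `05_yield_stress.py` — yield summaries of the reported per-sample
   measurements and estimator recovery on generated sweeps.
6. `06_contraction_mixing.py` — wall stress and mixing-depth maps over
   contraction amplitude and frequency.

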