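# Methods

`gutspat` quantifies micro-scale spatial structure of bacteria in gut
content and the physical mechanism proposed to control it: growth builds
clonal microcolonies in a gel-like digesta, and peristaltic contractions
periodically fluidize the gel and disperse them. The package implements
the full quantitative chain — synthetic data with known ground truth,
cell detection from microscopy-like images, inhomogeneous point-pattern
statistics with a group permutation test, community-composition
divergence, yield-stress rheology, and a Stokes-second-problem mixing
model — so every stage is testable against constructions whose answer is
known.

## Spatial point-pattern statistics

**Model.** Cell centers in a rectangular window W (µm scale) are treated
as a planar point process. Clustering is measured with the inhomogeneous
Ripley K function, which weights each point by the reciprocal of its
local intensity λ(x) so that density gradients (crowding by food
particles, uneven illumination) do not masquerade as clustering. With
border correction, only focal points at distance ≥ r from the window edge
count:

    K̂(r) = [ Σ_{i: b_i ≥ r} λ_i⁻¹ Σ_{j≠i, d_ij ≤ r} λ_j⁻¹ ]
           / [ Σ_{i: b_i ≥ r} λ_i⁻¹ ],

with no further renormalization. The variance-stabilized transforms are
L = √(K/π) and H = L − r; H > 0 indicates clustering, H < 0 regularity,
H = 0 complete spatial randomness (CSR). Numerator and denominator are
kept per radius so a group of images pools as a ratio (ΣN/ΣD), not a mean
of ratios. The default analysis grid is 201 radii from 0 to 20 µm
(0.1 µm step).

**Intensity estimation.** λ̂(x_i) is a leave-one-out isotropic Gaussian
kernel estimate with a rectangle edge correction (kernel mass inside W,
separable product of normal CDFs). The default bandwidth is 0.15 × the
shorter window side; it is a configuration knob, and values are floored
at 10⁻¹² µm⁻² so reciprocal weights stay finite. No claim of equivalence
to any other package's default smoother is made.

**Cluster-radius readout.** The radius maximizing the pooled H curve
approximates the diameter of a typical cluster within a factor of about
two, so the reported cluster radius is argmax_r Ĥ(r) / 2, undefined when
Ĥ never exceeds 0. On Thomas-process patterns (σ = 2 µm, nominal radius
2σ = 4 µm) the estimate is typically ~3 µm, inside the factor-2 band.

**Group comparison.** Groups of per-image H curves are compared with a
Studentized permutation statistic,

    T = Σ_{i<j} ∫₀^rmax (H̄_i − H̄_j)² / (s_i²/m_i + s_j²/m_j) dr,

integrated by the trapezoid rule, with the null distribution from
re-assigning whole images to groups (sizes preserved) and the add-one
p-value (1 + #{T* ≥ T}) / (1 + n_perm). Radii where the pooled variance
vanishes contribute nothing. Curves are lexicographically ordered
internally before sampling labelings, which makes the Monte-Carlo
p-value exactly invariant to reordering or renaming the input groups.
The statistic is applied to H curves; H is a deterministic transform of
K, so this choice changes the weighting across radii but not the null.
Testing one condition against CSR is a reconstruction: a matched CSR
group is simulated (same per-image point count and window) and the
two-group test applied.

**Calibration found empirically.** With 6 images per group and the
default estimated intensity, the type-I error of the test at α = 0.05 is
binomial-consistent with 0.05 (199 permutations, 200 trials). The
pointwise t band on pooled H covers 0 at ~89–91% of radii under CSR,
slightly below the nominal 95%: the kernel intensity estimate biases H
marginally negative. Power runs use 999 permutations; with only 199, the
chance of re-drawing the observed labeling (924 distinct 6+6 labelings)
inflates the attainable p floor above 0.01.

## Cell detection

The image pipeline is a classical fluorescence recipe with every
threshold exposed: white top-hat (disk radius 1.5 µm) removes background
larger than cells; a percentile contrast stretch maps the 99.9th
percentile to full scale; binarization at 2.0 × the mean filtered
intensity (mean-relative, hence invariant to affine intensity rescaling);
8-connected labeling; then a rule-based partition of regions. Food
particles are regions with area ≥ 20 µm² and major/minor axis ratio ≥ 3.
Single cells have area 0.2–3 µm², eccentricity ≤ 0.95, solidity ≥ 0.8.
Remaining above-minimum-area regions are candidate clusters and are
split in two passes: the region's boundary edge map is dilated into a
barrier (default radius 4 px; it must exceed the neck half-width of
touching blobs), the barrier is removed, remaining cores are relabeled,
and the whole region is reassigned to cores geodesically; cores passing
the single-cell rule are emitted as `from_cluster` cells, and anything
unsplittable contributes one intensity-weighted centroid so no region is
silently dropped. Centroids are intensity-weighted and reported in
continuous µm with pixel centers at (i + 0.5)·pixel size.

All numeric defaults were tuned on synthetic fixtures and are not
canonical values of any published instrument pipeline; they are fields of
`DetectionParams`.

## Synthetic data

Generators provide ground truth for every downstream stage. Point
patterns: homogeneous/inhomogeneous Poisson (CSR null), Thomas cluster
process (closed-form K(r) = πr² + κ⁻¹(1 − e^{−r²/4σ²}) as an oracle;
parents simulated with a 4σ guard margin), Matérn type-II hard core
(regularity), and a growth–dispersal simulator: synchronous division
with Gaussian placement jitter, punctuated every few generations by
shear events that scatter whole lineages uniformly. The growth rules are
a minimal invented mechanism — the hypothesis they emulate names no
simulation — and every rule is configurable.

Images: cells are Gaussian blobs of scale cell_radius/2 (≈95% of mass
inside the cell radius) on a default 184.5 µm field at 2048 px
(0.0901 µm/px); food particles are bright rotated rectangles with
footprint ≥ 10× a cell's and aspect ≥ 3 — deliberately the same rule the
detector removes, so generator truth and filter agree. Particles are
placed clear of cells and of each other; overlapping particles would
merge into footprints that violate their own defining rule. Additive
Gaussian noise, truth carried alongside.

Rheology: stress–strain follows two power-law branches meeting exactly at
(γ_y, τ_y), with exponents b1 > b2 (flattening above yield); G′/G″ are
power laws crossing by default at 2γ_y, just past yield. Creep compliance
is J(t) = (1/G)(1 − e^{−t/t_r}), plus a steady-flow term t/η once the
applied stress reaches τ_y — the late-time linear growth that defines
fluidization. Abundance tables are Dirichlet draws around per-site mean
compositions with a single precision knob.

What the generators do **not** emulate: optical blur anisotropy,
deconvolution artifacts, z-projection effects, autofluorescence texture,
rheometer inertia and wall slip, or compositional correlations between
taxa. Passing round trips therefore demonstrate correctness of the
estimators under their stated models, not robustness to every real-data
artifact.

## Community divergence

Relative-abundance profiles are compared with the Jensen-Shannon
divergence, JSD(P,Q) = ½D_KL(P‖M) + ½D_KL(Q‖M), M = (P+Q)/2, with the
0·log 0 := 0 convention and taxa outer-joined as zeros. Natural log is
the default (bound ln 2); base 2 is an option and outputs state their
base. Family-level analysis is a column group-by with a taxon→family
map. Site comparisons aggregate all within-base, within-tip, and
base-to-tip pair divergences; a one-sided Mann-Whitney U test (exact for
group sizes ≤ 20, normal approximation with tie correction otherwise)
requires the tested direction as an explicit argument, because a default
direction would silently encode a scientific claim. When every pooled
value is identical the statistic is permutation-invariant and p = 1 is
returned directly.

## Yield-stress rheology

Three estimators, in decreasing order of resolution:

* **Power-law intersection** — least-squares lines in log σ vs log γ on a
  below-yield and an above-yield region; intersection
  γ* = (a₂/a₁)^{1/(b₁−b₂)}, τ_yield = a₁γ*^{b₁}. The default region rule
  takes strains below half the G′/G″ crossover (below) and the top strain
  decade (above); both are configurable and recorded in the estimate's
  metadata. Degenerate geometry (b₁ ≤ b₂) raises. The estimator is
  exactly scale-equivariant in stress.
* **G′/G″ crossover** — first sign change of G′ − G″, log-log
  interpolated; absence of a crossover is a signal, not an exception.
* **Creep fluidization** — a line is fitted to the final half of each
  compliance record; a curve is fluidized when its tail slope exceeds a
  threshold (default 10× the median tail slope of the lower-stress
  curves) **and** the tail fit has R² ≥ 0.98. τ_yield is the lowest
  fluidized applied stress, which makes creep a quantized upper estimate
  on a 10 Pa grid. The R² rule is deliberately strict; noisy tails at the
  margin fail it rather than fluidize spuriously.

Replicates are summarized as mean ± sample SD (n−1).

## Contraction-mixing model

The gut wall is an in-plane oscillating rigid plane under a semi-infinite
Newtonian digesta (the Newtonian idealization is retained deliberately;
no shear-thinning viscosity enters the flow solution). Velocity and
stress are the classical solutions

    u(y,t) = Aω e^{−ky} cos(ωt − ky),
    τ(y,t) = Aω√(ρωμ) e^{−ky} sin(ωt − ky − π/4),  k = √(ω/2ν),

and the mixing depth equates the stress amplitude with the digesta yield
stress: D = −√(2ν/ω) ln[τ_yield/(Aω√(ρωμ))], clamped to 0 with an
explicit flag when even the wall amplitude stays sub-yield (the formula's
negative branch is unphysical). Everything is SI; the stress formula is
verified against μ·∂u/∂y by central finite differences in the tests.

Default material parameters are the measured values for mouse cecum
content: τ_yield 45 Pa, μ 2237 Pa·s, ρ 1250 kg/m³ (the mean of density
replicates 1.16/1.29/1.31 g/ml at three significant figures). Measured
yield estimates scatter — 46.4 ± 8.7 Pa by oscillatory intersection,
35 ± 13.2 Pa by creep, and a 60 Pa figure also circulates for the same
material — so τ_yield is an explicit parameter of every entry point and
the package does not adjudicate between the estimates. With plausible
contraction grids (A ≈ 2–5 cm, ω ≈ 0.5–5 rad/s) the model yields
mixing depths on the centimeter scale.

## Problem sizes and numerical choices

Simulation-backed tests use sizes chosen to make their statistical
bounds sharp while keeping the suite fast: CSR calibration at the full
study scale (200×200 µm, λ = 0.05 µm⁻², 6 images, 100 seeds), the Thomas
closed-form oracle with 200 replicates, permutation type-I calibration
with 200 trials of 6+6 patterns at 150×150 µm and λ = 0.02 µm⁻² (the
calibration is size-free, so a lighter pattern suffices), and detection
round trips on 512-px fields (the geometry per µm² is identical to the
2048-px default). The K estimator accumulates pair contributions sparsely
(KD-tree pairs within r_max, difference-array over the radius grid) and
agrees with a brute-force double loop to 10⁻¹⁰. Degenerate inputs are
defined, not accidental: empty patterns give all-undefined summaries
with a warning; radii with no eligible focal point are NaN; ties in the
cluster-radius argmax break to the smallest radius.

## Interfaces

The library under `src/gutspat/` is the interface, with the numbered
drivers in `analysis/` as the worked pipeline (simulate → spatial stats →
detection → divergence → rheology → mixing model); no console script is
installed, since every entry point is a plain function or a runnable
script. Patterns travel as delimited text with a `# window ...` header
line; images as single-channel TIFF with the pixel size in metadata;
curves and tables as CSV.

## Known limitations

* The growth–dispersal generator is a caricature: synchronous divisions,
  lineage-level dispersal, no nutrient field, no cell death.
* The intensity-estimation bandwidth default is a rule of thumb; strongly
  inhomogeneous patterns deserve a sensitivity scan (the bandwidth is an
  argument everywhere).
* Border correction is the only implemented edge correction.
* The creep estimator cannot resolve yield below the spacing of the
  applied-stress grid.
* The mixing-depth model ignores gut curvature, lumen closure, and
  non-Newtonian rheology; it is an order-of-magnitude tool.
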