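# Methods

## Model

The package fits the standard closed-population Bayesian SCR model with
data augmentation.  For individual `i` (of `M = n_detected + n_augmented`)
and detector `j`:

* `s_i ~ Uniform(S_suitable)` — activity centers are a homogeneous point
  process over suitable habitat of the state-space `S`;
* `z_i ~ Bernoulli(ψ_i)` — inclusion of (augmented) individual `i` in the
  population; `z_i ≡ 1` for detected individuals;
* `y_ij | z_i=1 ~ Bernoulli(p0 · exp(−D_ij²/(2σ²)))`, and `y_ij ≡ 0` when
  `z_i = 0`;
* abundance `N = Σ_i z_i`, density `d = N / area(S)`.

Local evaluation replaces the global likelihood with per-individual
windows.  Detected individuals get a square AC window of width `w` centered
on the centroid of their detections (binary data: each detector with a
detection counts once) and a concentric detector window of width
`w + 2·extension`; only detectors inside the detector window enter the
likelihood, and the AC is constrained to the AC window.  Windows are
half-open (`lo ≤ v < hi`), which makes juxtaposed tiles an exact partition
of the domain and gives the width-18-du window on a unit lattice its
maximum of 18 × 18 = 324 detectors.

Augmented individuals get AC windows tiled edge-to-edge from the domain's
lower-left corner, truncated at the boundary, in `n_layers` identical
superimposed layers; the default layer count is the smallest making the
augmented pool strictly larger than four times the expected population.

### Habitat correction

AC windows may include unusable area (non-habitat, or — for detected
individuals, whose windows are deliberately not clipped — area outside the
domain).  Each individual's inclusion probability is corrected by the
suitable fraction of its window:

```
ψ_i = 1 − (1 − ψ0)^prop_habitat_i ,   ψ0 ~ Uniform(0, 1).
```

`prop_habitat` is the exact geometric overlap of the window with suitable
habitat cells divided by the window's **nominal** area.  For
boundary-truncated tiles the nominal area is the full `width²`, not the
truncated rectangle: a truncated tile concentrates as many augmented ACs
in less area, and only the nominal-area denominator keeps the expected
density of included augmented ACs (`≈ ψ0/width²` per layer) constant over
the domain.  This is the single most consequential geometric choice in the
package — with the truncated-area denominator, abundance is overestimated
by tens of percent on small domains.  The correction is applied to all
individuals (for detected ones it only enters the ψ0 conditional).  An
augmented window with `prop_habitat = 0` has `ψ_i = 0`; its inclusion flag
is permanently 0 and it is skipped by every update.

## Sampler

A Metropolis-within-Gibbs sweep per iteration:

1. **Activity centers** — per-individual Gaussian random-walk proposals,
   reflected at the AC-window boundary (symmetric); proposals in
   non-suitable habitat are rejected outright (this rejection is exactly
   the habitat constraint, not an approximation).  Excluded augmented
   individuals (`z_i = 0`) have a flat likelihood, so any in-habitat
   proposal is accepted — their marginal is uniform over window ∩ habitat.
2. **Inclusion flags** — exact Bernoulli draws from the full conditional
   `P(z_i=1|·) = ψ_i q_i / (ψ_i q_i + 1 − ψ_i)` with
   `q_i = Π_j (1 − p_ij)` over the individual's detector index.
3. **σ** (log scale, Jacobian-corrected) and **p0** (logit scale) —
   Metropolis against the likelihood summed over included individuals.
4. **ψ0** (logit scale) — Metropolis against `Π_i Bernoulli(z_i | ψ_i)`.
   When all `prop_habitat = 1` this conditional is conjugate,
   `Beta(1 + Σz, 1 + M − Σz)`, which the test suite verifies in
   distribution.

Per-individual log-likelihoods are evaluated lazily over each individual's
detector index only and cached; a full individuals × detectors distance
matrix is never formed in the windowed path (this locality is the speed
mechanism).  Proposal scales adapt in batches of 50 iterations during the
adaptive phase only (Robbins–Monro on the log scale, target acceptance
0.35, step `min(0.25, 1/√batch)`), and are frozen afterwards to preserve
detailed balance.  Initial AC proposal scale is `σ_init/2`.

**Priors.** `p0 ~ U(0,1)`, `ψ0 ~ U(0,1)`, `σ ~ U(0, σ_max)` with `σ_max`
defaulting to the AC window width — the window construction already
presumes σ is known to that order, and a window-spanning σ is
geometrically meaningless.  All three are configurable (`PriorSpec`).

**Initialization.** Detected ACs start at their detection centroid (nudged
to the nearest suitable cell center in-window when the centroid is
unsuitable; a window with no suitable habitat is an immediate error);
augmented ACs start uniform over window ∩ habitat; `z ~ Bernoulli(0.5)`
for augmented individuals; σ starts at the RMS per-axis spread of
detections about their centroids and p0 at a matching moment estimate,
both overdispersed per chain (factors `e^{U(−0.5,0.5)}` on σ, `±1` on
logit p0).  A non-finite initial log-likelihood raises with a diagnostic.

**Randomness.** Chain `c` of master seed `s` uses the first 32-bit word of
`SeedSequence([s, c])` for its kernel RNG and `SeedSequence([s, c, 0xACC])`
for its initial values; a fit is a pure function of data, configuration
and `s`.  The default protocol is a 1,000-iteration adaptive phase, then
3,000 iterations of three chains thinned by three.

**Classical (no-window) fits** are the same code with windows spanning the
whole domain, built by the same index builder (`SCRModel.no_less`); the
suite asserts bitwise chain identity between the two construction paths
and 1e-12 agreement of the windowed likelihood with an independent
full-matrix oracle.

## Synthetic data

The generator reproduces the validation design: a 50 × 50 unit-spaced
detector array; a domain extending a 4-du (2σ) buffer beyond it, gridded
into 1 × 1-du habitat cells centered on the detector lattice (58 × 58
cells, of which the central 50 × 50 block is non-buffer); ACs drawn
continuously uniform over suitable habitat; binary Bernoulli detections
with σ = 2 du and p0 = 0.07.  Under these defaults about 66 % of
individuals are detected at least once.  Undetected individuals are
dropped from the capture history but retained in the truth for scoring.
Replicate `k` of master seed `s` uses seed `s + k`.

The generator emulates the study conditions, not field data: it has no
detector-level or individual heterogeneity, no behavioral response, no
movement or open-population dynamics, and perfectly known detector
locations.  Passing validation therefore demonstrates correctness of the
estimator under the model's own assumptions; it says nothing about
robustness to their violation.

## Scoring

Replicated fits are scored by relative bias
`RB = (1/(θn)) Σ (θ̂_i − θ)`, across-replicate coefficient of variation
`CV = 100·SD(θ̂)/mean(θ̂)` (the across-replicate reading; the within-
posterior CV is available from each fit's summary), and 95 %
credible-interval coverage.  Point estimates are posterior means and
intervals are equal-tailed 2.5/97.5 percentiles.  Replicates with any
monitored Brooks–Gelman PSRF above 1.1 are excluded from scenario
summaries and counted.  The PSRF uses the classic corrected form and is
floored at 1 (values below 1 are finite-sample artifacts of the
`(n−1)/n` correction).

Density surfaces: the true map evaluates each individual's half-normal
kernel (without p0) at the 1 × 1-du habitat cell centers and sums over
individuals; the predicted map does the same over `z = 1` individuals per
posterior draw and averages draws (optionally a random subset — full s/z
storage is memory-heavy).  The **mean relative error (MRE)** between maps
restricts both to non-buffer cells, normalizes each to sum to one, and
averages the absolute per-cell difference.  A per-cell ratio variant
(`|D̂−D|/D` averaged over `D > 0` cells) is available behind a flag but is
not the default: with ~2,500 non-buffer cells the normalized per-cell
masses are O(4 × 10⁻⁴), and the absolute-difference reading is the one
consistent with reported MRE magnitudes of ~10⁻⁴.

## Problem sizes used in validation

The full published-scale experiment (100 replicates per scenario on the
50 × 50 array) is deliberately not run in the test suite; the package's
validation uses a reduced design chosen to keep the whole suite in the
tens of minutes on one core while leaving Monte-Carlo error small enough
for the bias contracts to be meaningful:

* recommended-settings bias check: 25 × 25 detectors, N = 40, 24
  replicates, full chain protocol; contracts asserted with a 2-SE
  Monte-Carlo allowance on top of their stated tolerances;
* misspecification signature (3σ AC window): same design, 12 replicates;
* equivalence and distributional checks: 15 × 15 and smaller fixtures,
  where they are exact (bitwise / 1e-12) or use 3,000–5,000 thinned
  draws (Kolmogorov–Smirnov at p > 0.01).

## Known limitations

* Binary detections only; no count (Poisson/binomial) observation models.
* Static windows: individuals are assumed stationary over the study;
  moving or dispersing ACs are out of scope.
* No covariates on density or detection, no behavioral response, single
  session, closed population.
* Square windows slightly over-cover the circular detection kernel; that
  is the price of O(1) indexing.
* The ψ correction makes augmented-AC density exactly constant only in
  the small-ψ0 limit; at large ψ0 the curvature of
  `1 − (1−ψ0)^prop` leaves a slight excess near truncated tiles.  The
  validation suite bounds the practical consequence (no detectable
  abundance bias at the recommended settings).
* Windows narrower than 5σ (or extensions below 2σ) bias σ̂ and p̂0 in
  compensating directions — that is a property of the method the package
  reproduces, not a defect it hides.
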