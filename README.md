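# lesscr

Bayesian **spatial capture–recapture (SCR)** with **local evaluation of the
individual state-space**: per-individual square evaluation windows that make
large-domain density estimation tractable on a single desktop core, without
biasing the estimators.

## The problem and the model

SCR estimates animal density from detections of recognizable individuals at
known detector locations (camera traps, hair snares, searched grid cells).
Each individual `i` has a latent activity center `s_i`, uniform over the
suitable habitat of a state-space `S`, and is detected at detector `j` with
the half-normal detection function

```
p_ij = p0 · exp(−D_ij² / (2σ²)),        y_ij ~ Bernoulli(p_ij)
```

where `D_ij = ‖s_i − x_j‖`, `p0` is the detection probability at the
activity center and `σ` scales with home-range size.  Abundance is
estimated by data augmentation: the `n` observed individuals are padded
with all-zero pseudo-individuals carrying inclusion flags
`z_i ~ Bernoulli(ψ_i)`, and `N = Σ z_i`, density `d = N / area(S)`.

The cost of a naive Bayesian fit grows with (individuals × detectors),
although almost all of those terms are detections that are essentially
impossible (`p_ij ≈ 0`).  This package restricts each individual to

* an **AC evaluation window** — a square centered on the centroid of its
  detections within which its activity center must lie, and
* a **detector evaluation window** — a concentric square extending a fixed
  distance beyond the AC window; only detectors inside it enter the
  individual's likelihood.

Augmented individuals receive AC windows tiled edge-to-edge across the
domain (in superimposed layers, keeping augmented-AC density constant), and
each individual's inclusion probability is corrected for the suitable
fraction of its window, `ψ_i = 1 − (1 − ψ0)^prop_habitat_i` with
`ψ0 ~ U(0,1)`, so unusable window area cannot bias density.  With an AC
window of `5σ` and a detector-window extension of `2σ` (a `9σ` detector
window, covering 99.9993 % of the detection kernel's range), estimates are
indistinguishable from the full model while evaluating, e.g., at most 324
of 2,500 detectors per individual on the standard simulated design.

Fitting uses a bespoke adaptive Metropolis-within-Gibbs sampler (numba-
accelerated): reflected random-walk updates of each activity center with
outright rejection of non-habitat proposals, exact Gibbs draws of the
inclusion flags, and Metropolis updates of `σ` (log scale), `p0` and `ψ0`
(logit scale).  A classical no-window SCR fit is the same code with windows
spanning the whole domain.

## Worked example

```python
from lesscr import SCRModel, default_design, simulate_population, simulate_captures

detectors, domain = default_design()            # 50x50 unit-spaced array + 4-du buffer
truth = simulate_population(100, domain, rng=1) # N=100, sigma=2, p0=0.07
captures = simulate_captures(truth, detectors, rng=2)
model = SCRModel.from_captures(captures, detectors, domain,
                               ac_width=10, extension=4, expected_n=100)
results = model.fit(seed=3)                     # 1,000 adapt + 3,000 iter, 3 chains, thin 3
print(results.summary().round(4))
```

prints (on this machine, ~35 s):

```
58 of 100 individuals detected (112 detections)
M = 490 (58 detected + 432 augmented), max detectors per individual = 324 of 2500

            mean      sd    ci_lo     ci_hi    rhat
param
sigma     2.0679  0.1411   1.8204    2.3662  1.0028
p0        0.0618  0.0108   0.0431    0.0849  1.0001
psi0      0.1969  0.0259   0.1497    0.2514  1.0008
N        90.3227  8.5842  76.0000  110.0000  1.0007
density   0.0268  0.0026   0.0226    0.0327  1.0007
```

`sigma` and `p0` are recovered near their simulated values (2 and 0.07);
the 95 % credible interval for abundance `N` (truth 100) is 76–110, and all
potential scale-reduction factors are ≤ 1.1 (converged).  For data on disk
the same pipeline is available from the shell:

```
lesscr simulate --nx 50 --ny 50 --n 100 --seed 1 --out sim/
lesscr windows  --detectors sim/detectors.csv --detections sim/detections.csv \
                --ac-width 10 --extension 4 --expected-n 100 --out less.json
lesscr fit      --detectors sim/detectors.csv --detections sim/detections.csv \
                --ac-width 10 --extension 4 --expected-n 100 --seed 3 --out fit/
lesscr scenario --config config.yaml --out grid/     # factorial experiments
```

`src/lesscr/configs/wolverine.yaml` packages the settings of the
large-scale wolverine application (σ ≈ 6 km, 2-km search-grid detectors, AC
window 5σ, extension 2σ); the detection data are an external DRYAD deposit
and are not shipped.

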