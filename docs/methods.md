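# Methods

## Model

The observed series X₁..X_p are assumed to be monotone marginal distortions
of a latent jointly Gaussian VAR(L): there exist increasing functions f_i
such that z_i = f_i(X_i) follows

z_i(t) = Σ_j Σ_{ℓ=1..L} β_{j,i}(ℓ) · z_j(t−ℓ) + ε_i(t),  ε_i(t) ~ N(0, σ_i²),

with independent innovations. Under this (nonparanormal) assumption the
directed-dependence structure is identified by ranks alone, so the marginals
are estimated nonparametrically and inference proceeds linearly in copula
space. Variable j Granger-causes variable i iff the lag-coefficient block
β_{j,i} is not identically zero.

## Pipeline and parameters

**Copula transform** (`ecgc.copula`). Empirical CDF with weak inequality
(ties share a value; the column maximum maps to 1), Winsorized into
[δ_n, 1−δ_n], then z = μ̂ + σ̂·Φ⁻¹(u) per column using the sample mean and
standard deviation (ddof=1) of the raw column. Defaults:

- δ_n = 1/(4·n^{1/4}·√(π ln n)) — the standard nonparanormal truncation rate;
  overridable via `copula_transform(..., delta_n=...)`. It exists solely to
  keep Φ⁻¹ finite; δ_n ∈ (0, 0.5) for every n ≥ 2.
- Because several extreme order statistics can fall outside [δ_n, 1−δ_n],
  the transform is weakly monotone (clamped extremes tie) and strictly
  monotone on the interior. Edge decisions are unaffected: identical ranks
  give bit-identical transforms.
- μ̂/σ̂ rescaling is cosmetic for inference — designs are re-standardized
  before fitting — but keeps the transformed series on the data's scale for
  inspection. A constant column cannot be rescaled (σ̂ = 0) and triggers a
  warning.

**Lagged design** (`ecgc.var_design`). Response z_i(t) for t = L+1..T;
p·L predictor columns ordered source-major, lag-minor, so each source's L
coefficients are contiguous — that block is the unit over which an edge is
declared. No intercept: predictors are standardized to mean 0/variance 1 and
the response is centered and scaled to unit variance inside the solver.
Standardizing the response makes every tolerance scale-free and, in copula
mode, makes the fitted problem exactly invariant to monotone marginal
distortion (AIC selection is unchanged either way: rescaling y shifts all
candidate AICs by the same constant).

**Elastic net** (`ecgc.sparse_fit`). Objective
(1/2n)‖y−Xβ‖² + λ(α‖β‖₁ + ((1−α)/2)‖β‖₂²), solved by cyclic coordinate
descent on the precomputed Gram matrix (each full pass is O(m²) independent
of n; the inner loop is numba-compiled). Defaults: α grid {0.1,…,1.0}
(α = 1 alone gives the LASSO baseline), 50 log-spaced λ from
λ_max = max_j|x_jᵀy|/(nα) down to 0.01·λ_max with warm starts, convergence
when the largest coefficient change in a pass is < 1e−7, at most 10⁵ passes
(non-convergence warns and returns the current iterate, never silently).
Coefficients with |β| ≤ 1e−8 are structural zeros (coordinate descent
produces exact zeros for α > 0; the threshold only guards numerics).

**Selection** (`ecgc.sparse_fit.fit_path`). Gaussian-likelihood AIC,
n·ln(max(RSS, 1e−12)/n) + 2·df with df = nonzero count — the standard
penalized-VAR choice requiring nothing beyond the fit itself. Ties broken
toward larger λ, then larger α (sparser first). Note AIC's fixed penalty of
2 per coefficient admits each spurious coefficient with probability
≈ P(χ²₁ > 2) ≈ 0.16 at large n, so the pipeline's operating point is
high-recall / moderate-precision; the benchmark FDR values near 0.4–0.6
(consistent with the published tables) follow from this, not from a defect.

**Edges** (`ecgc.network`). Edge j → i iff any selected coefficient of
source j in target i's regression is nonzero. Self-edges are estimated
identically, stored on the diagonal, and excluded from scoring by default
(cross-edge recovery is the scientific claim; `include_self=True` flips it).

## Simulated benchmark systems

`simulate_dataset1` (p = 3, L = 2, 3 true cross edges) and
`simulate_dataset2` (p = 5, max lag 4, 7 true cross edges) follow the
published generation protocol literally: the first max-lag values are i.i.d.
N(0,1), then the printed equations are iterated with independent N(0,1)
innovations; no burn-in is discarded by default.

That default matters: the 3-variable system **as printed is marginally
explosive** — its companion-matrix spectral radius is ≈ 1.00228 (a complex
eigenvalue pair just outside the unit circle). It therefore has no
stationary law, and a burn-in would not "converge" the process but multiply
the near-unit-root oscillation by ~10 per 1000 steps, systematically
changing the benchmark's difficulty. Two further consequences, verified
empirically:

- least-squares recovery of the generating coefficients is accurate at
  T = 10⁴ (max error ≤ 0.02) but numerically impossible at T = 10⁵, where
  the explosive mode (~10¹⁰⁰) swamps the O(1) stationary variation that
  identifies the coefficients in float64;
- first-half/second-half moment comparisons are meaningful only for the
  stationary 5-variable system (ρ ≈ 0.877) and for `simulate_random_var`
  systems (rescaled until ρ ≤ 0.9 by construction, burn-in 1000).

Benchmark lag orders are the maximal generating lags: L = 2 (system 1) and
L = 4 (system 2) — with L < 4 the lag-4 dependency of system 2 is
unreachable by construction.

## Monte-Carlo evaluation

`score_network` evaluates the p(p−1) ordered cross pairs: precision
TP/(TP+FP), FDR = FP/(TP+FP) = 1 − precision whenever anything is predicted
(both set to 0 on an empty prediction), recall TP/(TP+FN), F1. `run_benchmark`
repeats simulate→infer→score with seed base_seed+r and reports arithmetic
means per (method, T) — including the mean of per-replicate F1, which is not
the harmonic mean of the averaged precision and recall. Replicate failures
are logged, counted, and excluded rather than aborting a sweep.

Default suite sizes: the package's own test suite sweeps the full series-
length grid at 150 (system 1) and 80 (system 2) replicates; the acceptance
script uses 500 replicates per cell. At these sizes Monte-Carlo standard
errors per cell are ≈ 0.01–0.02.

## What the simulations do and do not show

The generators produce linear-Gaussian VAR data with known graphs, which is
exactly what the benchmark tables describe, and monotone-distorted versions
of them are covered by the rank-invariance property tests. They do not
emulate measurement noise with heavy tails, irregular sampling, latent
confounders, or the p ≫ T regime of genome-scale panels; passing benchmarks
here demonstrates correct mechanics and calibration of the pipeline, not
performance on such data.

A structural observation from running both methods in this shared harness:
with the identical λ path and AIC selection, the elastic-net grid (which
contains α = 1) and the pure-LASSO baseline almost always select the same
support, so their benchmark curves nearly coincide — the elastic net's mean
recall is never below the baseline's, but the margin is small. Published
comparisons showing large elastic-net gains used different λ-selection
machinery for each method; reproducing those gaps requires reproducing that
machinery, not just the penalty family.

## Known limitations

- AIC (2·df) overselects at large n; BIC-style penalties would trade recall
  for precision but are not what this pipeline specifies.
- "Statistically nonzero" is implemented as structurally nonzero after AIC
  selection; no post-hoc significance test is performed.
- Coefficients are reported on the standardized scale; signs and magnitudes
  are comparable within a fit, not across raw data scales.
- The reader accepts only complete numeric tables (no missing values);
  irregular sampling must be interpolated upstream.
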