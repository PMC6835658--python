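# Methods

This note documents the models, conventions and design choices behind
`printopt`, in the order the pipeline runs them.

## Mixture models

The three variable resin components (PEGDA, PEG 400, water, % w/w) sum to a
near-constant mixture total (94.6–94.9 % in the reference tables; the
remainder is 0.10 % riboflavin and 5.00 % ibuprofen).  Responses are
therefore modeled with Scheffé canonical polynomials — no intercept, the
constant being absorbed by the sum constraint:

* linear: `β₁x₁ + β₂x₂ + β₃x₃`
* quadratic: adds `x_i x_j` pairs
* special cubic: adds `x₁x₂x₃`
* full cubic: adds the `x_i x_j (x_i − x_j)` differences (10 terms total)

Fitting is ordinary least squares **in actual percent units**, not
pseudo-components: the published coefficient equations are in actual values,
and with the mixture total nearly constant the two parametrizations are
equivalent up to coefficient scaling (the reparametrization-invariance test
checks exactly this).  Rows with a missing response (hardness of a tablet
too elastic to break) are dropped, never imputed.

Summary statistics follow mixture-design software conventions:

* `R² = 1 − SS_res / SS_total` with the **mean-corrected** total sum of
  squares, even though the model has no intercept;
* adjusted `R² = 1 − (1 − R²)(n − 1)/(n − p)` for a p-term model — the
  model spends `p − 1` effective degrees of freedom (linear model on 11
  runs: residual df 8);
* `PRESS = Σ (eᵢ/(1 − hᵢᵢ))²` via the hat diagonal (computed from the thin
  QR of the model matrix), identical to explicitly refitting with each run
  held out — an identity the tests verify against brute-force refits and
  against statsmodels' influence measures;
* predicted `R² = 1 − PRESS/SS_total`, which is strongly negative for
  overfitted models.

A saturated model (`n == p`) interpolates the data and has unit leverages;
it is reported as unavailable ("n.d.") rather than fitted.

**Model selection** maximizes `min(adjusted R², predicted R²)`, breaking
ties by predicted then adjusted R².  Reading the two statistics jointly is
the point: on the reference data the full cubic has the best adjusted R²
for weight (0.53 vs 0.48) while its predicted R² is around −16000, and the
joint rule selects the linear model for all three responses, as the
original analysis did.

**D-optimal design generation** uses Fedorov exchange: a candidate set of
polytope vertices (every pair of components at a bound with a feasible
remainder), all pairwise vertex midpoints, the centroid and seeded random
in-bounds fill; greedy single-point exchanges are accepted while
`det(XᵀX)` increases.  The determinant trace is non-decreasing by
construction and the final design is checked against 100 random candidate
subsets.  The exact run list of the original study is not reproducible (its
candidate set and exchange settings are unknown) and is not claimed.

## Release kinetics

Four classical models are fitted on their linearized forms with fixed
intercepts where the model form implies one (through the origin for
zero-order and Higuchi; intercept ln 100 for first-order; free intercept
only for the power law).  R² is reported on the linearized regression with
mean-corrected total SS, the convention of dissolution-modeling tools; for
a bad through-origin fit it can be negative.

Rate constants are reported **per minute** (k₀ %/min, k₁ 1/min,
k_H %/min^0.5, k_KP %/minⁿ); published constants of this study are only
dimensionally consistent with minutes (k₀ ≈ 0.07 %/min ≈ 34 % over 480
min).  Profile times are stored in hours and converted internally.

The power-law fit is restricted to points with 0 < Q ≤ 60 % (standard
practice for the Korsmeyer–Peppas short-time approximation; configurable).
At least 3 such points are required, which is why the synthetic time grid
adds a 0.5 h point to the 1/2/4/6/8 h study grid.

Mechanism classification from the exponent: n < 0.45 Fickian diffusion,
0.45 ≤ n ≤ 0.89 anomalous transport (right-inclusive), n > 0.89 labeled
super case II with an explicit extrapolation marker since that band lies
outside the classification the analysis relies on.

Published per-formulation kinetic constants cannot be recomputed here —
they derive from raw dissolution curves that were never printed (fitting
the four published optimal-formulation points alone gives n ≈ 0.69, not
the published 0.4872, so the original fits clearly used earlier time
points).  They are used only as classification fixtures; fit correctness is
established by exact parameter recovery on synthetic data instead.

## Synthetic studies

The generator stands in for the unpublished raw curves and defines the
conditions every stochastic test runs under.  Ground truth is a
composition-linked power law, chosen because the study's own kinetic
analysis selects square-root/power-law behavior — and because it makes
recovery tests analytic:

    k(f) = k_base + k_peg·peg400 + k_pegda·pegda   [%/hⁿ]
    n(f) = clip(n_base + n_water·water, 0.05, 1)
    Q(t) = running-max(clip(k·tⁿ + ε, 0, 100)),  ε ~ N(0, noise_sd²)

Defaults: `k_base = 20`, `k_peg = 0.35`, `k_pegda = −0.10`, `n_base = 0.30`,
`n_water = 0.004`, `noise_sd = 2 %`.  Calibration: across the design region
these give 8 h release of roughly 38–91 % with the fastest release at
maximal PEG 400 and the slowest at maximal PEGDA, matching the reported
extremes (90.72 ± 5.06 % and 38.04 ± 1.41 %), exponents inside the reported
0.35–0.49 Fickian band, and replicate noise of the few-percent magnitude of
the reported standard deviations.

Compositions are sampled uniformly on the bounded simplex slice by
rejection (two components uniform in their boxes, the third the remainder);
feasibility of the bounds is decided by an explicit linear program.
Exposure time is a monotone step function of water content
(<7.5 % → 100 s, then 400/500/600 s bands, ≥22.5 % → 800 s) fitted to the
majority pattern of the printed settings; two printed rows deviate from any
monotone rule, so reference formulations always use their recorded
settings, never the rule.

What the generator does *not* emulate: excipient interactions (the reported
anomaly of a high-PEG formulation releasing slowly), any effect of exposure
time on release, heteroscedastic or correlated replicate error, and curve
flattening below the 100 % cap.  Tests passing on synthetic data therefore
demonstrate correctness of the estimators and optimizer under the stated
model, not predictive validity for real resins.

## Surrogate networks

A plain multilayer perceptron, authored in-package: affine layers with
linear or log-sigmoid activations, full-batch gradient descent on half the
mean squared error with momentum (`Δw_t = −η∇E + αΔw_{t−1}`), default
η = α = 0.6 as in the original software settings, weights initialized
uniform(−0.5, 0.5) from a seeded generator.  Inputs and outputs are min-max
scaled to [0, 1] — required for sigmoid layers, and it makes validation RMS
values of a few hundredths meaningful on a common scale.  Early stopping
monitors validation RMS with patience 200 (default) up to 20 000 epochs and
restores the best weights.  Everything is deterministic given the seed;
training histories are bit-identical across reruns.

Correctness is established structurally: backpropagated gradients match
central finite differences to 1e−6 relative for depths 1–5 and both
activations, an all-linear network driven to convergence reaches the
closed-form least-squares loss, and zero learning rate provably changes
nothing.  The architecture search replays the trial-and-error protocol over
a depth × width grid with a deterministic per-cell seed schedule, selecting
minimal validation RMS with R² as tie-break.  The original training metrics
(RMS 0.0296, R² 0.9994, test R² 0.9478) are not targets: they depend on
unpublished training data and unknown initialization.  The reference
architectures are kept as constants: 3-8-5 all-linear
(composition → release at 1/2/4/6/8 h) and 4-5-5-6-5-6-4 with log-sigmoid
hidden layers (composition + exposure time → release at 2/4/6/8 h; the
"linear and log-sigmoid" description is interpreted as sigmoid hidden
layers with a linear output, exposed as configuration).

## Desirability optimization

Release goals (at most 30/60/70 % at 2/4/6 h, at least 80 % at 8 h,
importances 2/2/3/3) become one-sided desirabilities with a linear ramp of
default width 20 percentage points from d = 1 at the limit to d = 0 at
limit ± width; a hard 0/1 threshold is available.  The ramp default is a
design choice — the original optimum's predicted 79.99 % against an
"at least 80 %" goal only makes sense under a ramped (not hard) transform.
The overall objective is the importance-weighted geometric mean; plus-counts
map directly to the exponents.

Optimization is deterministic multi-start: a coarse grid (2 % steps) over
the simplex slice ranks candidates, the best `n_starts` are refined by
Nelder-Mead in the two free components (water is the simplex remainder)
with out-of-bounds moves penalized.  A fine-grid enumeration oracle in the
tests confirms the optimizer is never beaten at 1 % resolution.  For
four-input surrogates the candidate's exposure time is derived from the
water-content rule.  When every start has D = 0 the result is flagged
infeasible and reports the best-found profile.  Reproducing the original
optimum composition is a non-goal (it depends on their trained network);
the tests instead require the optimizer to dominate that printed
composition under the same surrogate.

## Profile comparison

f1 uses the experimental profile as reference (denominator); f2 includes
all supplied points by default — this reproduces the published values
exactly from the four printed time points — with the regulatory
one-point-above-85 % truncation available as an option.  Closed-form
anchors: identical profiles give f2 = 100, and a uniform offset of √99
≈ 9.95 percentage points gives f2 = 50 exactly.

## Problem sizes and numerics

Reference-data computations are 10–11 observations and 4 time points;
synthetic studies default to 11 formulations on a 6-point grid (up to 50 in
rank-correlation tests, 24 in the exponent-bias check); surrogate training
uses architectures up to 3 × 10 hidden units at a few thousand epochs.
Degenerate inputs fail loudly and early: infeasible bounds (LP), saturated
design matrices, unit leverages, non-positive synthetic rates, non-finite
training losses (reported with the epoch index), constant series in
correlations.  Ties are deterministic everywhere: equal-R² kinetic fits go
to the simpler model, equal-adjusted-R² mixture fits to the higher
predicted R², equal-RMS architectures to the higher R².

## Known limitations

* The stored compositions keep their printed rounding (rows sum to
  99.7–100.0 %); no renormalization is applied before modeling.
* Fitting in actual units means coefficients are only interpretable
  relative to the near-constant mixture total.
* The first-order model anchors at 100 % dose; profiles reaching 100 %
  within the fit window are rejected rather than winsorized.
* The MLP is full-batch only; no regularization, minibatching or modern
  optimizers — faithfulness to the original protocol, not performance, is
  the goal.
* The desirability optimizer is a local multi-start scheme; global
  optimality is checked only against grid enumeration at 1 % resolution.
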