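# Methods

This note documents the statistical models, algorithmic choices and
numerical conventions behind `mixrelease`, and states precisely what the
shipped tests demonstrate.

## Data model

A mixture release study is a table of `n` formulations: `q` component
percentages on the 0–100 scale (never fractions) with a constant sum
(default 82.8 % w/w — the excipient share of the reference tablet), and
cumulative release percentages at `m` ordered time points (default 2, 8,
24 h).  The reference study (25 formulations, 5 excipients) and its
downstream published tables are packaged as CSV fixtures, digit-for-digit
as printed.

**Constant-sum tolerance.**  Printed tables round each component to one
decimal, so a row's sum can deviate from the design total by up to
5 × 0.05 = 0.25 percentage points without any underlying violation; the
validator's default tolerance is therefore 0.25 for printed data.  On the
reference table, 22 rows sum exactly to 82.8, two deviate by 0.1 and one
by 0.2.  Generated data must pass at machine tolerance.

**Correlation structure.**  Both Pearson and Spearman response correlation
matrices are provided.  On the reference data the published heatmap values
(0.23, 0.62, 0.69) are the *magnitudes of the Spearman* coefficients
(−0.234, −0.618, +0.693); plain Pearson gives (−0.156, −0.512, 0.681) and
cannot reproduce them.  The package reports both and the tests pin the
published values to the rank-correlation magnitudes.

**Synthetic generator.**  Compositions are sampled uniformly in the
per-component box (defaults: the observed reference ranges), orthogonally
projected onto the constant-sum hyperplane (the projection adds the same
correction to every component), and rejected if the projection leaves the
box.  Responses are a sparse mixture polynomial plus stationary AR(1)
Gaussian noise across the time-point index, with marginal standard
deviation `noise_sd` (default 2.0, the scale of typical dissolution
replicate error) and lag-1 correlation `rho` (default 0.3, consistent with
the modest rank correlations of the reference data).  The default truth
(`intercept 7.0, X24 −0.01, X3t 0.02, t 8.70, t2 −0.2036`) was chosen so
the mean release profile on the design space follows a realistic sustained
release curve (≈ 20 / 60 / 95 % at 2 / 8 / 24 h): a concave time trend
plus a mild filler-interaction and a matrix-by-time effect.  What the
generator does *not* emulate: pH-dependent mechanistic release, non-Gaussian
or heteroscedastic measurement error, batch effects, and design-optimality
structure (compositions are i.i.d. rather than D-optimal).  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated error model, not robustness to real-world dissolution artifacts.

## Candidate terms

`generate_term_basis(q)` enumerates main effects, all product interactions
of orders 2..q (labels concatenate ascending component indices, `X24` =
X₂·X₄), component-by-time terms `X3t` = X₃·t, pure `t` and `t²`, and an
intercept (kept because the published coefficient table prints one, even
though classical Scheffé mixture models omit it).  Centering of component
columns before products is available but off by default; offsets fitted on
training data are stored on the basis for prediction-time reuse.

A note on the published coefficients: the source prints the fitted model
twice with opposite intercept signs (−4.27112 in the equation, +4.2711 in
the rounded table).  Evaluating raw products with the full-precision
coefficients and the *positive* intercept reproduces the published
candidate release profiles to a median absolute error of ≈ 0.2 points,
while the as-printed equation misses every row by a constant ≈ 8.5 (twice
the intercept): the equation's sign is a typo and no hidden centering is
involved.  All three variants are kept in `reference_model`; the pipeline
nevertheless refits the model to the data rather than reusing printed
numbers.

## Penalized selection

Coordinate descent on columns standardized to mean 0 / variance 1, with an
unpenalized intercept handled by centering.  Prox operators: soft threshold
(LASSO), the SCAD three-branch rule (shape `a` = 3.7), and the firm
threshold (MCP, concavity `γ` = 3) — the literature-standard shape values.
The path runs 100 log-spaced λ from λ_max (the smallest λ zeroing every
penalized coordinate) down to 0.001·λ_max with warm starts; convergence is
a max coefficient change below 1e−7 within 10,000 sweeps (the solver warns,
never fails, if the cap is hit — this happens only deep in the path where
the q-CCP columns are near-collinear).  The inner loop uses Gram-matrix
(covariance) updates compiled with numba.

Cross-validation folds partition *formulations*, never individual time
rows, so validation error is measured on unseen formulations; fold
shuffling uses a fixed seed (20251101) so the shipped pipeline is
deterministic; CV ties resolve toward the larger λ (sparser model).

On the reference data this protocol is more conservative than the
published row-level CV: the non-convex penalties retain only the dominant
time trend ({t, t²}), while LASSO keeps ~14 terms including composition
effects.  The sparsity ordering |MCP| ≤ |SCAD| ≤ |LASSO| — the study's
qualitative finding — holds; the exact published counts (10/12/16) are a
function of the unstated fold construction and are not reproduced.  Because
a time-only model is composition-independent, the shipped optimization
stage uses the QIF refit of the *published* ten-term support as its
reference release model; the pipeline's own MCP branch remains available
and, when it degenerates, the ranking stage falls back to equal weights.

## QIF estimation

Clusters are formulations (size m = number of time points); responses are
Gaussian with identity link and unit variance function (the release model
is linear — no GLM machinery).  The inverse working correlation is expanded
in basis matrices: identity plus the 0/1 first-sub/super-diagonal matrix
(the AR(1) pair) by default, with an exchangeable pair as an option.  The
extended score stacks `g_i = [X_iᵀM_k(y_i − X_iβ)]_k`; the estimate
minimizes `Q_N = N·ḡᵀC⁻¹ḡ` with `C = mean(g_igᵢᵀ)` via the iterated
two-step closed form for linear models: initialize at OLS, rebuild C,
solve the weighted normal equations, iterate to |Δβ|∞ < 1e−8.
`vcov = (B̄ᵀC⁻¹B̄)⁻¹/N`.  C is ridge-regularized by 1e−10 relative to its
mean diagonal (so conditioning is scale- and order-invariant); a singular C
falls back to the Moore–Penrose pseudoinverse with a warning.  With the
identity basis alone the estimator is exactly OLS — the tests verify this
to 1e−8.

**Information criteria.**  `AIC = Q_N + 2p`, `BIC = Q_N + p·ln(n_obs)` with
`n_obs` the long-format row count.  The convention is fixed by the
published AIC/BIC *difference* (45.2951 − 19.8028 = 25.4923 = 11·(ln 75 −
2)); the published absolute AIC cannot be pinned because its base term is
unstated, and is not asserted.  A Gaussian −2·log-likelihood base is
available as an option.

**Identifiability.**  The reference table contains several duplicated
compositions, so the full 39-term candidate design has rank 27 of 39 on the
long data; `fit_qif` raises on rank-deficient selections, and the
"no-selection" comparison variant is operationalized as the maximal
identifiable column subset (pivoted QR).

## Objectives and constraint handling

The equality constraint Σx = 82.8 is enforced by a quadratic exterior
penalty `σ·(Σx − total)²` with σ = 1000 and even exponent 2 — the canonical
differentiable choice (the penalty function itself is not specified in the
source beyond σ).  Box bounds are left to the optimizers (clipping), and
the penalty uses a single fixed σ; an escalation schedule is deliberately
omitted.  Pharmacopoeia limits (15–25 / 55–65 / 80–110 % with closed
bounds) act as a post-hoc filter on optimizer output, not inside the
search.

## Metaheuristics

All three optimizers share: population 100, 200 generations, 15 runs,
per-run integer seeds spawned deterministically from one master seed,
bound clipping, and per-generation history of best-so-far and
population-mean scalarized fitness −(Q₁+Q₂+Q₃) (a reporting convention —
the search itself is fully multi-objective).

- **NSGA-III**: binary tournament by front rank; "single-point crossover"
  is interpreted as a tail swap of the real-coded 5-vector at a random
  locus (P_c = 0.8); per-gene uniform-reset mutation (P_m = 0.05);
  environmental selection by non-dominated sorting with ideal-point
  normalization and Das–Dennis reference-direction niching (p = 13 → 105
  directions ≈ population size, the standard sizing rule).
- **MOGWO**: external archive (capacity 100) on an adaptive hypercube grid
  (10 divisions per objective, inflation α = 0.1); three leaders drawn by
  roulette over inverse cell density to the power β = 5; over-full archives
  evict from crowded cells with pressure γ = 2; wolf positions move to the
  mean of the three leader-guided updates with coefficient a linear 2→0.
- **NSWOA**: whale operators (encircling with a linear 2→0, logarithmic
  spiral with b = 1, random-leader exploration; branch probability 0.5),
  elitist merge of parents and offspring followed by non-dominated sorting
  and crowding-distance truncation; progress logged every `ishow` = 10
  generations.

**Initialization.**  NSGA-III and MOGWO populations start on the
constant-sum plane (box draws orthogonally projected, out-of-box rejected)
whenever the objective set carries a constant-sum penalty: any off-plane
point costs 10³–10⁵ fitness units at σ = 1000, so box-uniform populations
spend dozens of generations merely approaching feasibility, which is
neither useful search nor consistent with the few-generation convergence
such penalized mixture problems exhibit.  NSWOA keeps plain uniform box
initialization (its generation-0 distribution is part of its tested
contract).  Plane initialization is a config flag (`init_on_plane`).

**Convergence behavior.**  With plane initialization NSGA-III typically
saturates within ~10 generations and shows no further best-so-far change;
MOGWO and NSWOA keep finding genuinely better near-plane points late into
the run (a few tenths to a few units on a fitness scale of ≈ 181, i.e.
continued optimization, not instability).  Population-mean fitness for the
leader-based searchers cannot stabilize tightly under an exterior penalty,
because exploring members always carry large penalty values; archive
contents, not population means, are the convergence-relevant quantity.

**Pooling.**  Each run's final archive is pharmacopoeia-filtered; one
representative per run is picked by equal-weight TOPSIS on the feasible
release matrix (classical vector normalization, zero negative ideal) —
a deterministic stand-in for the unstated per-run distillation of the
source protocol — and 15 × 3 representatives form the candidate table
(values reported to 3 decimals; full precision retained alongside).

## Entropy-weight TOPSIS

Two dialects are implemented.  The default (and the one that reproduces
the published Table of D⁺/D⁻/C values *exactly at 3 decimals, all 15
printed rows*) follows the SPSS entropy-method convention: each benefit
column is min-max normalized; probabilities are column shares of that
normalized matrix; `e_j = −(1/ln n)Σ P ln P` (0·ln 0 := 0) and
`w_j ∝ 1 − e_j`; the TOPSIS matrix is the min-max matrix rescaled to unit
column L2 norm, weighted; positive ideal = column-wise maximum; negative
ideal = the zero vector (release is a pure benefit indicator).  Constant
columns get weight 0; all-constant matrices are rejected.  The classical
raw-matrix dialect (column-sum probabilities, vector normalization) is
available via `preprocess=None` — on the reference candidates it puts
almost all weight on the 2-h release and ranks a different candidate
first, which contradicts both the published ranking and the published
statement that the 8-h release received the highest weight; this
reconciliation fixed the default.  Ties in closeness break by input order
(stable sort).

## Pipeline

`run_pipeline` is a pure function of (data, configuration, master seed):
data → terms → selection (all three penalties) → QIF per selection →
objectives from the configured final model → 15 × 3 optimizer runs →
pooling → entropy-TOPSIS ranking → baseline comparison, with per-stage
logging and fail-fast stage-labeled errors.  The optimizer stage can be
skipped by supplying a candidate table (e.g. the packaged published one),
in which case the ranking stage reproduces the published ordering.
Reported tables are rounded to 3 decimals next to full-precision "raw"
copies.

## What is, and is not, reproduced

Reproduced exactly: the correlation heatmap values (as Spearman
magnitudes), constant-sum validation, the complete published TOPSIS table
(weights, D⁺, D⁻, C, all ranks), the baseline comparison (changes 1.847 /
5.483 / 8.727; 24-h rate 9.538 %), and the AIC−BIC difference identity.
Reproduced as properties: selection sparsity ordering, MCP winning the IC
comparison, optimizer archive contracts, 45 feasible pooled candidates,
and parameter recovery on synthetic data.  Not reproduced, by design: the
exact published decision vectors (stochastic optimizer output), the exact
16/12/10 selection counts (fold-construction dependent), the absolute AIC
(base term unstated), and sub-0.1-unit best-so-far flatness after
generation 50 for the leader-based optimizers (they keep improving; see
Convergence behavior).

## Known limitations

Single equality constraint only; no repair operators or constraint-
domination; no GLM links or missing-data handling in the QIF; no
elastic-net/adaptive variants in selection; the no-selection IC variant
depends on the pivoted-QR subset when the design is unidentifiable; CLI is
a thin convenience layer, not a stable API.
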