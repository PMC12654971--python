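# mixrelease

Modeling and multi-objective optimization of sustained-release tablet
formulations from mixture-design dissolution studies.

## The problem

A sustained-release matrix tablet is built from `q` excipients whose
percentages are constrained to a fixed total (here five excipients — HPMC
K4M, HPMC K100LV, MgO, lactose, anhydrous CaHPO₄ — summing to 82.8 % w/w).
A dissolution study measures the cumulative drug release `Y_t` of each
candidate formulation at several time points (2, 8 and 24 h, covering the
initial, intermediate and terminal release phases).  The formulation
designer wants compositions that maximize release at every phase while
staying inside the pharmacopoeia acceptance windows
(Y₂ ∈ [15, 25], Y₈ ∈ [55, 65], Y₂₄ ∈ [80, 110] %).

`mixrelease` implements the full workflow on such data:

1. **Candidate terms** — the q-component (centered) polynomial family: all
   product interactions `X_iX_j…` up to order q, component-by-time terms
   `X_i·t`, and `t`, `t²` (38 candidates for q = 5).
2. **Sparse selection** — LASSO, SCAD and MCP penalized least squares by
   coordinate descent (prox operators: soft threshold, SCAD three-branch,
   firm threshold), with formulation-level 10-fold cross-validation so
   repeated measurements never leak across folds.
3. **QIF estimation** — quadratic inference functions for the
   repeated-measures release model: the inverse working correlation is
   expanded in basis matrices (identity + AR(1) tridiagonal pair), the
   stacked per-formulation scores `g_i(β) = X_iᵀM_k(y_i − X_iβ)` enter the
   GMM objective `Q_N(β) = N·ḡᵀC⁻¹ḡ`, and `Q_N + 2p` / `Q_N + p·ln n`
   serve as AIC/BIC analogs for model comparison.
4. **Penalized objectives** — the fitted model becomes three minimization
   objectives `Q_k(x) = −Ŷ(x, t_k) + σ(Σx − 82.8)²` with exterior penalty
   factor σ = 1000 enforcing the constant-sum mixture constraint.
5. **Metaheuristics** — NSGA-III (reference-direction niching, single-point
   crossover P_c = 0.8, mutation P_m = 0.05), MOGWO (gridded external
   archive, leader pressure β = 5) and NSWOA (whale encircle / bubble-net /
   random-search operators with non-dominated sorting), population 100,
   200 generations, 15 independent seeded runs each; one
   pharmacopoeia-feasible representative per run is pooled into a
   45-candidate table.
6. **Entropy-weight TOPSIS** — criterion weights from the information
   entropy of the min-max normalized release matrix, then ranking by
   relative closeness `C = D⁻/(D⁺ + D⁻)` to the ideal solution (zero
   negative ideal for pure benefit criteria), plus a change/rate report
   against the original formulation.

The 25-run reference study and its published downstream tables are packaged
as fixtures and all stages reproduce the published deterministic results on
them (correlation structure, TOPSIS table, comparison report).

## Worked example

```python
import mixrelease as mr
from mixrelease.mcdm_rank import rank_candidates, rank_report
from mixrelease.pipeline import compare_to_baseline, reference_baseline

candidates = mr.load_candidate_table()          # 45 pooled Pareto candidates
result, weights = rank_candidates(candidates)   # entropy weights + TOPSIS
print(weights.weights.round(4))                 # [0.2752 0.3646 0.3602]
print(rank_report(result, candidates).head(3)[
    ["scheme", "Y_2", "Y_8", "Y_24", "d_plus", "d_minus", "closeness", "rank"]])
```

```
 scheme    Y_2    Y_8    Y_24  d_plus  d_minus  closeness  rank
     45 22.747 64.983 100.227   0.009    0.129      0.932     1
     29 22.160 64.703 100.765   0.013    0.128      0.908     2
     15 22.456 64.749 100.145   0.014    0.123      0.901     3
```

The 8-h release carries the largest entropy weight (0.3646): it varies most
informatively across candidates.  Candidate 45 sits closest to the ideal
profile (closeness C = 0.932) and becomes the recommended formulation;
comparing it with the original:

```python
top = rank_report(result, candidates).iloc[0]
keys = ["X1", "X2", "X3", "X4", "X5", "Y_2", "Y_8", "Y_24"]
print(compare_to_baseline(top[keys], reference_baseline()).to_frame())
```

```
              X1      X2      X3      X4      X5     Y_2     Y_8     Y_24
baseline  40.000  10.000   5.000  15.000  12.800  20.900  59.500   91.500
candidate 38.422  13.513   6.275  17.068   7.523  22.747  64.983  100.227
change    -1.578   3.513   1.275   2.068  -5.277   1.847   5.483    8.727
rate_pct  -3.945  35.130  25.500  13.787 -41.227   8.837   9.215    9.538
```

Release improves by 1.85 / 5.48 / 8.73 percentage points at 2 / 8 / 24 h
(a 9.5 % relative gain at 24 h), achieved mainly by trading anhydrous
CaHPO₄ for the low-viscosity gel former HPMC K100LV and lactose.

The `examples/` directory walks through every capability: loading and
validating the reference study, selection + QIF fitting, synthetic-data
generation and parameter recovery, the optimizer stage, and ranking.  A
thin CLI mirrors the stages: `mixrelease simulate|fit|optimize|rank|compare|pipeline`.

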