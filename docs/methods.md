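# Methods

`idionet` estimates, for each person separately, a sparse lag-1 graphical
vector autoregression (graphical VAR) from ecological momentary assessment
(EMA) time series, derives two symptom networks from the fit, ranks symptoms
by strength centrality, and aggregates the top-two "treatment targets"
across a cohort. This note documents the model, the estimation choices, the
synthetic-data generator, and the limits of what the shipped tests
demonstrate.

## Data model

A study schedules `beeps_per_day` prompts on each of `days` days (the
shipped defaults are 5 × 15 = 75 beeps). At each beep the participant rates
every item of a symptom catalog on a 0–100 scale. A skipped beep is a fully
missing row; individual items can also be missing. No imputation is
performed anywhere: analysis uses pairwise-complete lag-1 pairs only.

**Lag-1 pairs.** A pair (t−1, t) enters estimation only when both beeps are
fully observed on the modeled items, belong to the same day, and have
consecutive beep indices. The process is never lagged across the overnight
gap — sleep is assumed to break the momentary dynamics — so a complete
5-beep/15-day record yields at most 15 × 4 = 60 pairs, not 74.

**Standardization.** Before fitting, both design matrices are z-scored per
item with shared constants (mean and n−1 sd over the stacked rows). This
makes the penalties scale-free, the reported edge weights comparable across
items, and the transform invertible. Items with zero variance over the used
rows cannot be modeled and raise an error naming the item.

## Item selection

With 55 assessed items and ~45–60 usable pairs, a full network is hopelessly
underpowered. Each person's model is built on the k items with the highest
observed means (default; highest variance is the shipped alternative), with
k = 15 and k = 8 as presets. Ties are broken by catalog order so the
selection is a pure function of data and rule. Items with zero variance are
ineligible. Means are computed over observed values only; no
missingness adjustment is attempted.

## The graphical VAR estimator

With z-scored observations x_t on k items,

    x_t = B x_{t−1} + e_t,   e_t ~ N(0, K⁻¹),

where b_ij is the lagged effect of item j on item i and K is the residual
precision. Estimation minimizes the penalized negative average Gaussian
log-likelihood

    f(B, K) = ½[−log det K + tr(S_res(B) K)]
              + λ_B Σ|b_ij| + λ_K Σ_{i≠j}|κ_ij|

by alternating two exact half-steps until the largest parameter change falls
below `tol` (default 1e-5) or `max_iter` (200) is reached:

* **B given K** — cyclic coordinate descent on all k² entries, operating on
  k × k sufficient statistics (cost independent of the number of pairs; the
  sweep kernel is JIT-compiled). Soft-threshold results below 1e-12 are
  snapped to exact zero.
* **K given B** — graphical lasso on the residual covariance via
  scikit-learn. Our λ_K maps to its `alpha = 2λ_K` because of the ½ factor
  above. The solver's dual-gap tolerance is set to 1e-3: the default 1e-4
  can oscillate just above threshold and burn the entire iteration budget
  with no material change in the solution. Because the K half-step is only
  solved to that tolerance, the alternation can cycle with sub-1e-3
  amplitude forever; when the parameter change stalls below 1e-3 for eight
  consecutive iterations the fit is accepted as converged at solver
  precision. Near-singular residual covariances are ridge-inflated and
  retried; persistent failure raises an estimation error.

Each half-step solves its subproblem exactly (to solver tolerance), so the
penalized objective is monotone non-increasing — a property the test suite
checks directly. Initialization is deterministic (B = 0, K = inverse
diagonal sample covariance); there is no randomness anywhere in fitting.

**Diagonal policy.** Autoregressive diagonal entries of B are penalized like
any other entry (configurable); the K diagonal is never penalized and is
always counted as free in the degrees of freedom.

**Off-diagonal zero tolerance for K.** The graphical-lasso solver leaves
numerically tiny residues on shrunk coordinates; off-diagonal entries below
1e-6 are treated as structural zeros for degrees of freedom, networks, and
centralities (the zeroed matrix is verified positive definite, else kept).

## Penalty selection

Fits are computed over an n_λ × n_λ log-spaced grid (default 10 × 10) from
data-derived maxima down to 0.01·λ_max, and the fit minimizing

    EBIC = −2·loglik + df·log(n) + 4γ·df·log(k² + k(k−1)/2),  γ = 0.5

is returned, with df = nonzero entries of B plus nonzero upper-triangle
off-diagonals of K, and exact EBIC ties resolved toward larger penalties.
λ_max for B is max_ij |(X_lagᵀX_now/n)_ij| / var_i: the per-outcome variance
scaling makes the empty model an exact fixed point of the coordinate
descent at the top of the grid (the stationarity threshold for entry (i, j)
scales with κ_ii ≈ 1/var_i, which exceeds 1 whenever a sample variance
falls below 1). λ_max for K is the largest absolute off-diagonal of the
B = 0 residual covariance.

**Grid density.** The 10-point default is a runtime choice appropriate for
~60-pair clinical series. At larger n the EBIC optimum becomes sensitive to
penalty resolution: consecutive grid points differ by a factor ~0.6, and
the shrinkage-bias/df trade-off can then prefer a slightly denser neighbor
of the true model. For structure-recovery studies at n ≈ 500 we use (and
recommend) a 20-point grid; the shipped recovery study does so.

**Detection threshold intuition.** At γ = 0.5, k = 8 and n ≈ 45 pairs, one
extra edge costs log(45) + 2·log(92) ≈ 12.8 EBIC points, so a (shrunk) edge
survives only when its standardized magnitude clears roughly 0.6. This is
why sparse idiographic networks at the study's data budget frequently come
back empty — the temporal-NA phenomenon — and why eight-item models
identify more temporal targets than fifteen-item models (the candidate set,
hence the EBIC term, is smaller).

## Networks and centrality

From a fit, edges are reported on standardized scales with exact zeros
preserved:

* contemporaneous (undirected): PCC_ij = −κ_ij / √(κ_ii κ_jj), zero
  diagonal;
* temporal (directed, edge j→i): PDC = b_ij / √(σ_ii κ_jj + b_ij²) with
  σ = K⁻¹; the form guarantees |PDC| ≤ 1.

Centralities are absolute-value sums: strength (contemporaneous row sums),
out-strength (temporal column sums) and in-strength (temporal row sums),
excluding self-loops by default — an autoregressive loop is not an
inter-symptom pathway, and including it would let highly autocorrelated
symptoms dominate (a flag restores it). Absolute values are used because
the standard strength definition ignores edge sign; signed "expected
influence" variants are out of scope.

## Target rules

Per statistic: if every centrality is exactly zero the participant has no
identifiable target (NA). Otherwise items with nonzero centrality are
ranked descending; exact ties (within 1e-12 on standardized weights) at the
top place all tied items in rank 1 with rank 2 empty; a tie between the
second and third values places both items in rank 2; items with exactly
zero centrality are never listed, so a one-edge network yields a rank-1
pair (both endpoints tied) and a single-nonzero-item network yields rank 1
only.

**Cohort accounting.** Every listed item increments its rank column; a
rank-1 tie therefore inflates the rank-1 column and deflates rank 2. In
temporal tables an NA participant increments a dedicated NA row in each
affected column; a participant with a rank-1 item but no second
nonzero-centrality item is NA in the rank-2 column only — this per-column
rule is what makes the two NA counts differ. Percentages are
100·count/column-total rounded half-up to one decimal; the total column
uses the grand total (sum of column totals, 2n for contemporaneous and 4n
for temporal before tie adjustments).

## Synthetic cohort generator

Each simulated participant has 8 "active" items following a stationary
VAR(1) with known (B*, K*), restarted each day from the stationary
distribution (consistent with never lagging overnight); the remaining
catalog items are independent low-mean noise so highest-mean selection
recovers the active set. Beeps go missing whole-survey with probability 0.1
by default. Each active item is mapped to the 0–100 scale with its
stationary sd divided out (location 60, marginal sd 10), keeping truncation
below ~1% regardless of dynamics strength; partial correlations and the
z-scoring estimator are invariant to that diagonal scaling.

The default 34-participant cohort is heterogeneous by construction: hub
participants (one item drives three others at raw coefficient 1.2, ~0.75
standardized, plus weaker extras, and a contemporaneous 3-item chain with
partials 0.7/0.65 whose true strengths are distinct), 10 participants with
B* = 0 (exercising the temporal-NA pathway), and 4 with exactly tied true
out-strengths (exercising the tie rules). The effect sizes are deliberately
strong: with a γ = 0.5 EBIC at ~45 pairs, weaker dynamics are invisible and
every network comes back empty, which would contradict the phenomenon the
cohort is meant to emulate — contemporaneous targets for essentially every
participant, temporal targets for roughly two thirds at eight items, fewer
at fifteen, with wide between-person variability in which symptom is
central.

**What the generator does not emulate:** item-level (as opposed to
whole-beep) nonresponse, circadian or weekday structure, floor effects and
skew of real symptom ratings, diagnosis-specific profiles, and any
between-person correlation in network structure. Passing tests therefore
demonstrate correct recovery of the model class the estimator assumes, not
performance on real EMA data.

## Problem sizes in the shipped studies

The test suite and the acceptance script run, by design: the full default
cohort (34 participants × {15, 8} items, 10-point grid); support recovery
on k = 6, 500 pairs, 50 independent draws, 20-point grid; white-noise null
behavior on k = 8, 60 pairs, 100 draws; the closed-form oracles (OLS VAR(1)
at zero penalty; brute-force centrality over 1000 random networks); and a
byte-level determinism check on a 4-participant re-run from the echoed
configuration.

## Known limitations

* EBIC on the penalized likelihood under-selects near the detection
  threshold (shrinkage bias trades against the df penalty); a relaxed/refit
  selection step would sharpen it but is not the convention this estimator
  follows.
* Estimated networks at 15 items on ~45 pairs are overparameterized
  (~345 candidate parameters); the pipeline warns (parameters-per-pair
  ratio > 4) rather than refusing, matching the design intent of comparing
  k = 15 against k = 8.
* Day/beep indices are the only time structure used; clock timestamps,
  unequal beep spacing and response-window drift are ignored.
* Linear-trend removal is available (`detrend` is off by default and the
  study's convention is followed: none).
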