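# Methods

## Model and estimation

Binary items are modelled as a pairwise Markov random field over {0,1}
states ("Ising model"): node thresholds τᵢ set base endorsement rates and
symmetric couplings ω_ij are conditional log-odds-ratios. The {0,1}
parameterization (rather than {−1,+1}) is used throughout so that couplings
live on the same scale as the nodewise logistic-regression estimator: the
full conditional of node i is logistic(τᵢ + Σⱼ ω_ij xⱼ).

**eLasso estimation.** Each node is regressed on all remaining nodes with an
ℓ1 penalty along a log-spaced path of `n_lambda = 100` penalties from the
node's λ_max (the smallest penalty with an all-zero slope vector, computed
from the KKT conditions at the intercept-only fit) down to
`λ_max × lambda_min_ratio` (`0.01`). Per node, the extended BIC
(−2ℓ + k ln n + 2γ k ln(p−1), γ = 0.25) selects the penalty; the
log-likelihood is that of the penalized solution, without refitting. Edges
are symmetrized with the AND rule (both directed coefficients nonzero) and
mean aggregation; the OR rule substitutes zero for a missing coefficient.
γ, the path geometry and the AND/mean defaults follow the conventions
established for this estimator in the psychometric-network literature; all
are configurable through `EstimationSettings`.

**Solver.** The inner problem is solved by iteratively reweighted least
squares with cyclic coordinate descent on the weighted quadratic
subproblem, warm-started from penalty to penalty. Because the networks here
have at most a few dozen nodes, the subproblem is solved on its Gram matrix
("covariance updates"): each reweighting costs one O(np²) BLAS product and
each coordinate pass only O(p²), which makes bootstrap re-estimation and
multi-seed simulation studies tractable on one CPU. Convergence is declared
when the largest linear-predictor change falls below 1e−7; tests verify the
solution against liblinear's penalized objective and, at the smallest
penalty, against the unpenalized maximum-likelihood fit. Coefficients with
absolute value below 1e−10 are snapped to exact zero so "no edge" is a hard
zero. If coefficients diverge at small penalties (quasi-separation, which
rare items make possible), the path is truncated at the last converged
penalty with a warning. Nodes that are constant in a bootstrap resample can
be skipped (`on_constant="skip"`), recording all their edges as absent for
that resample.

**Mixed graphical model.** For the sensitivity analysis with continuous risk
factors, each node's regression uses the family matching its scale
(ℓ1-logistic for binary, ℓ1-linear for continuous, with the plug-in
variance RSS/n in the Gaussian log-likelihood). Continuous columns are
standardized internally, so cross-family weights are on the
standardized-predictor conditional-logit scale and are not numerically
comparable to pure Ising weights (edge *sets* and ranks are compared, not
magnitudes). With an all-binary input the MGM reduces exactly to the Ising
estimator — same solver, same paths — which the tests assert.

## Centrality and bridges

Strength Σ|w|, one-step expected influence Σw, two-step expected influence
ei1 + W·ei1; closeness and betweenness on shortest paths with edge distance
1/|w| (strong edges are short). Closeness is 1 / (sum of distances to all
reachable nodes), computed within each connected component to avoid
infinite distances; empty networks return zero path-based indices with a
warning. Bridge expected influence over predefined communities:
bei1ᵢ = Σ_{j∉c(i)} w_ij and
bei2ᵢ = bei1ᵢ + Σ_{j≠i} w_ij · Σ_{k∉c(i),k≠i} w_jk,
i.e. indirect influence routed through any neighbour's own cross-community
connectivity. Negative edges enter strength absolutely and the
expected-influence family with sign. Bridges are the ⌈0.25·p⌉ top nodes by
bei2 — the only count rule consistent with 4 bridges among 14 nodes and 5
among 20; boundary ties break by node order with a warning.

## Bootstrap stability

Case-dropping bootstrap: for each drop proportion in {0.05, …, 0.75}, B
subsamples without replacement are re-estimated and their centralities
Spearman-correlated with the full-sample values; CS(cor = 0.7) is the
largest drop proportion at which ≥ 95% of subsamples correlate ≥ 0.7 (and
all smaller drops also qualify). Degenerate subsamples (constant
centrality) are excluded and counted. Edge bootstrap: B resamples with
replacement, full re-estimation, percentile 95% intervals and the nonzero
("retention") fraction per edge; reported networks keep edges with
retention ≥ 0.70. Edge presence per resample — not CI-excludes-zero — is
the retention notion used. B defaults to 1000; per-resample RNG substreams
spawn from the master seed, so runs are bit-reproducible. Tests and the
acceptance script use B between 10 and 30 and n of a few thousand, sizes
chosen so the whole suite runs in minutes on one CPU while the checked
properties (true edges retained, CIs covering full-sample estimates,
CS ≥ 0.5 on a strongly connected graph) are already stable.

## Preprocessing

Continuous/ordinal risk factors are dichotomized at the sample 75th centile
(linear-interpolation quantile, strict ">", so tie mass at the cut is coded
0 — a tie-free measure flags 25.0%). Polygenic scores are residualized on
five genetic principal components by OLS before dichotomization. The
cumulative-trauma composite sums 15 ordinal items (five childhood, five
adult, five PTSD-relevant recoded {0 → 0, yes → 4}; reverse-coding map
supplied as configuration), range 0–60. The goldbricker redundancy screen
flags a pair as measuring the same construct when |r| ≥ 0.5 with p < 0.01
and fewer than 25% of the dependent-correlation comparisons against all
third nodes reject (Hittner–May–Silver back-transformed-z test, two-sided
α = 0.01). Pearson correlations on 0/1 items are phi coefficients.

## Synthetic cohorts

Because the motivating data are access-controlled, the generator emulates
their statistical structure: 14 binary symptom/impairment items from a
community-structured Ising model (9 depression + 5 psychosis, with
endorsement rates matching a large published questionnaire cohort —
depression items 21–41%, psychosis items 0.6–2.7%), questionnaire skip
logic (non-core depression items and depression impairment gated on the
core mood items; psychosis impairment gated on any psychosis symptom;
absences coded 0), and six risk-factor covariates that are linear-Gaussian
functions of the symptoms and of each other, dichotomized at their 75th
centile for the binary analyses and kept continuous for the MGM.

Key generator decisions:

* **Calibration targets are post-gating rates.** Published item frequencies
  are observed after skip logic, so thresholds are calibrated by exact
  moment matching (full state enumeration, p ≤ 20) on the *gated* state
  table, to within 0.01 of the targets; damping 0.5 keeps the fixed-point
  iteration stable under gating feedback. Samplers: exact categorical
  sampling over the enumerated distribution (p ≤ 20), or a vectorized
  many-chain Gibbs sampler for larger graphs (burn-in 500 sweeps, verified
  against the exact sampler).
* **Strong planted couplings.** The planted bridge pairs
  (worthlessness–conspiracy, depression impairment–psychosis impairment)
  carry couplings 3.0 and 2.2, and within-psychosis couplings are ~1.5–2.2:
  with items endorsed by 0.6% of participants, weaker cross-community
  couplings would not be detectable under the AND rule at realistic sample
  sizes, and real psychotic symptoms show comparably strong (tetrachoric
  ≈ 0.8) dependence. Polygenic and area-level couplings are deliberately
  weak, mirroring their peripheral position in the motivating analysis.
* **What passing tests do and do not show.** The generator reproduces
  endorsement rates, skip-logic structure, community structure and
  designated bridges; it does not reproduce latent-severity (factor-like)
  dependence, item-level measurement error, or any temporal structure.
  Recovery results on this fixture therefore demonstrate the pipeline's
  correctness and its behaviour under realistic marginals, not field
  performance on real questionnaire data.

## Known limitations

* **Down-sampling sensitivity and rare-item colliders.** Balancing a cohort
  on "any psychosis symptom" (all positives plus matched negatives) is
  selection on a common effect. In the balanced cohort the rare psychosis
  items acquire strong *negative* conditional associations (Berkson bias)
  even though their generating couplings are positive; the signed two-step
  bridge expected influence of the cumulative-trauma node multiplies these
  negative cross sums, so its down-sampled bridge rank becomes unstable
  (roughly a coin toss across seeds) while the four symptom bridges remain
  stable in every run. This is a property of the pairwise generative design,
  persists at larger cohort sizes, and is the reason the down-sampled runs
  do not reliably reproduce the full-sample bridge set on this fixture.
* Gated items sharing a skip-logic gate have a structural phi-correlation
  floor (shared forced zeros) that can exceed the redundancy screen's 0.5
  gate when their endorsement rates are near 1/3; at the study scale the
  dependent-correlation tests have enough power to separate their profiles,
  but at a few thousand participants the screen can flag such pairs — runs
  on small cohorts may need `allow_redundant`.
* Exact enumeration limits calibration and exact sampling to p ≤ 20 nodes;
  beyond that only the Gibbs sampler is available and calibration is not
  provided.
* The eLasso solver assumes p up to a few dozen (dense Gram updates); it is
  not intended for hundreds of nodes.
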