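# Methods notes

This note records the statistical model implemented by `episubnet`, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not demonstrate.

## Differential networks

For genes measured in both conditions and connected in the PPI network,
the change in co-expression is scored by the Fisher-z statistic
Z = (F(ρ_t) − F(ρ_n)) / √(1/(n_t−3) + 1/(n_n−3)). The statistic is
asymptotically standard normal under the null of equal correlations; its
two-sided p-values are BH-corrected across all tested edges, and |Z| is
the edge weight whether or not the edge is significant (only *genes* are
filtered). Under a simulated null the edge p-values are uniform
(Kolmogorov–Smirnov check on 10,000 independent edges in the test suite).

Choices:

- **Degenerate correlations.** A gene constant in either condition has an
  undefined Fisher transform; its edges are dropped with a warning rather
  than scored Z = 0. Correlations within 1e−12 of ±1 are clipped.
- **Gene filter.** A gene is retained iff it has at least one significant
  differential edge whose partner is differentially expressed. The DE
  anchor set comes from a per-gene Welch t-test with BH at FDR 0.05 —
  the simplest defensible two-sample test; it only gates gene retention,
  so the pipeline is not sensitive to its exact form. Note that under a
  global null BH flags essentially no genes (its per-gene flagging rate
  is far below the nominal FDR), which is the intended control.
- **Missing data.** The loader drops genes with any missing entry (the
  Pearson and SVD stages assume complete matrices) and logs the count.

## Symmetric NMF and rank selection

min_{H≥0} ‖A − HHᵀ‖²_F is solved by projected gradient descent with
Armijo-style backtracking, which makes the loss sequence provably
nonincreasing — the property the tests assert. Defaults: relative-loss
tolerance 1e−5, max 500 iterations, H initialised uniform(0, 2√(mean(A)/K))
from the seed. Because the objective is nonconvex, each call runs 5
seeded restarts and keeps the lowest final loss; with planted block
structure this recovers the partition (ARI = 1) in 20/20 seeded runs of
the acceptance check. Genes join the module of their largest loading;
ties break to the lowest module index and all-zero rows stay unassigned.

Module density (mean within-module weight over ordered distinct pairs;
singletons defined as 0) is tested against B random same-size gene sets
drawn uniformly from the retained background — not degree-matched, by
design, to match the stated null of "random modules of the same size".
p = #{null ≥ observed}/B, so p = 0 is attainable; a 1e−9 relative
tolerance makes a redraw of the observed set count as a tie despite
summation-order floating noise (the Monte Carlo p agrees with exhaustive
enumeration on ≤8-node graphs within 3 binomial SDs). Within each
candidate rank the density p-values are Bonferroni-corrected by the number
of modules at that rank, and the rank with the most significant modules
wins (ties to the smallest rank). The default grid is 5..70.

Two caveats worth knowing:

- The uniform null does not correct for the selection effect of
  clustering itself: on pure-noise similarity matrices SymNMF still
  groups chance-correlated genes, and those modules can beat random sets.
  Significant density therefore means "denser than random same-size sets",
  not "non-random data".
- Separability uses the same permutation scheme with the upper tail
  (high separability = well separated). Null draws where a random module
  has zero density give an undefined score and are discarded; p is
  computed over valid draws.

## Eigengenes

Rows (genes) are standardised with the n−1 variance convention; constant
rows are dropped. The eigengene is the first right-singular vector of the
standardised module matrix over tumor samples only — the regression and
survival stages model tumor biology, so normal samples are excluded
(configurable). SVD sign is fixed so the mean correlation between the
eigengene and the module rows is nonnegative, making downstream
coefficient signs reproducible. var_explained = d₁²/Σd_j².

## Bayesian regression with a vector g-prior

With y the (standardised) response eigengene and X the standardised
predictor eigengenes of a candidate subset, the model is y = Xβ + ε,
ε ~ N(0, σ²I), β|σ² ~ N(β0, g σ²(XᵀX)⁻¹), p(σ²) ∝ 1/σ², with β0 = 0.
For scalar g this is the standard Zellner setup with posterior mean
(g/(1+g))·β_ols, posterior covariance σ²(g/(1+g))(XᵀX)⁻¹, and
σ²|y ~ IG(n/2, b), b = SSR_ols/2 + (β0−β_ols)ᵀXᵀX(β0−β_ols)/(2(1+g)).
The implementation matches an independent completion-of-the-square oracle
to below 1e−10 on random problems.

The per-predictor extension sets g_j = μ·r_ij from the biological
relatedness r_ij = 2E_ij/N_ij (PPI cross-edge count over total genes of
the two modules). Exact per-coordinate Zellner shrinkage has no symmetric
conjugate prior when the g_j differ (the implied prior covariance
diag(g)(XᵀX)⁻¹ is asymmetric), so the vector case is *defined* by the
G-construction: β̃_j = (g_j/(1+g_j))·β_ols_j, posterior covariance factor
S(XᵀX)⁻¹S with S = diag(√(g_j/(1+g_j))), and b's quadratic taken through
G = diag(√(1/(1+g_j))). For equal g this reduces exactly to the conjugate
scalar case.

Subset scoring uses the expected BIC,
E[BIC] = n(ln b − ψ(n/2)) + k_γ ln n, with smaller = better; the digamma
term is E[ln σ²] under the IG(n/2, b) posterior. A predictor with high
prior relatedness incurs a smaller shrinkage penalty inside b, which is
the entire mechanism by which the network prior steers selection — it
never changes the fit itself. All nonempty subsets are scored (all sizes
when ≤ 15 predictors, else up to `max_size`, default 5); ties prefer
smaller then lexicographically earlier subsets.

Coefficient significance is a two-sided z-test of β = 0 under the
posterior with σ² plugged in at its mean b/(n/2 − 1); it is exact-normal
conditional on σ² and calibrated in the tests (null p-values uniform by
KS). Subnetworks whose coefficients are all non-significant at 0.05 are
dropped. The per-predictor "confidence score" is the drop-one incremental
R² — a documented stand-in, since no closed-form definition of a variance
contribution is canonical for correlated predictors.

μ is tuned on the grid (0, 0.2, 0.4, 0.6, 0.8, 1, 2, 4, 6, 8, 10) by
combining each subnetwork's permutation p-value (statistic: R² of the
response on its selected predictors; null: B permutations of the response's
sample order; p = (1+hits)/(B+1)) through Fisher's method,
χ² = −2Σln p with 2·#subnetworks df. μ = 0 maps to the ordinary OLS/BIC
baseline: a literal g = 0 prior is a point mass at zero, which cannot be
what "no prior information" means, and the baseline is the only reading
consistent with nonzero performance at μ = 0. One permutation stream per
response is shared across the μ grid so the comparison is paired.

## Survival

Cox partial-likelihood fits (Efron tie handling, via lifelines) on module
eigengenes give coefficients β^cox; the per-patient prognostic index is
PI_i = Σ_c β_c^cox E_ci. Patients strictly below the 30th / strictly above
the 70th percentile (linear-interpolation percentiles; nearest-rank is the
documented alternative) form low/high-risk groups; the middle 40% are
excluded from the two-group Kaplan–Meier/log-rank comparison, a literal
reading of the two-tail grouping rule. The eigengene-vs-survival screen
correlates eigengenes with observed survival times on patients whose
death was observed (event = 1), with a label-permutation null.

## Synthetic-data generator

The generator emulates a controlled module-level study: each module's
covariance is drawn once as Σ ~ InverseWishart(df = 60, (1−c)I + cJ)
(scale-matrix convention, mean Ψ/(df − dim − 1); empirically the mean
pairwise correlation is ≈ c), then n = 200 samples are drawn from
N(0, Σ). Defaults: four predictor modules of p = 25 genes with
c_p = (0.3, 0.5, 0.3, 0.5); four response modules of q = 30 genes sharing
one c_r ∈ {0.3, 0.5, 0.7} per dataset; wiring y1←{x1}, y2←{x2},
y3←{x1,x2}, y4←∅ via y_S = y + Σ x·A + E with A constant at the
association signal a ∈ {0.03, 0.05, 0.1, 0.2, 0.3} (a uniform(a/2, a)
alternative is exposed) and E unit-variance Gaussian noise; a bipartite
prior network with edge probability 0.1 inside true subnetworks and 0.05
elsewhere. The fourth response module is generated even though only three
are wired, because the evaluation grid includes a no-predictor response.
All draws are bit-reproducible from (config, seed).

What the generator does **not** emulate: methylation beta-value
distributions and their bounded support, batch effects, missingness,
degree-heterogeneous PPI topology, and any tumor/normal structure beyond
the optional add-on below. Passing the synthetic acceptance checks
therefore demonstrates correctness of the inferential machinery under the
stated model, not robustness to real-data artefacts.

Because the reference study conditions contain no normal samples (module
detection is bypassed there — eigengenes feed the regression directly),
the generator has an optional `n_normal` knob for end-to-end pipeline
testing: normal-condition samples are drawn independently per gene at the
tumor scale with a one-SD mean shift, and the emitted network gains
within-module scaffold edges, so both differential co-expression and
differential expression exist and the network/module stages can run. The
pipeline smoke test also raises the association signal (a = 1.0) and
within-module correlations (0.7–0.8): at the reference signal levels the
wired responses' pairwise correlations are noise-dominated (r ≈ 0.2), far
below what edge-level Fisher-z testing can flag at test-suite sample
sizes — detecting them is not what that test is for.

## Problem sizes and numerical choices

The test suite and acceptance script run the simulation study at 10–20
replicates per condition cell, permutation tests at B = 200–2000, and the
rank scan over 2..6 on planted 30-gene matrices; these sizes give the
stochastic checks comfortable margins (binomial SDs well inside the
asserted thresholds) while keeping the whole suite under a minute of
compute for the unit tests and a few minutes for the study-level checks.
Design matrices are rejected when cond(XᵀX) > 1e10; symmetric-matrix
inputs are validated to 1e−8; subset-score ties use a 1e−12 margin so
smaller subsets win exact ties. Seeds fan out from a single master seed
via `numpy.random.SeedSequence` so every permutation test, factorisation
restart and simulated dataset is independently reproducible.

## Known limitations

- The rank scan refits SymNMF per candidate rank with independent
  restarts; there is no consensus clustering across seeds, and soft or
  overlapping membership is out of scope.
- The g-prior steers selection only through the E[BIC] penalty; when the
  prior network is misleading (cross-edges denser outside true
  subnetworks), selection degrades toward — but not below — the no-prior
  baseline's behaviour.
- The survival stage models a single module or subnetwork at a time with
  no clinical covariate adjustment, no competing risks and no
  time-varying effects.
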