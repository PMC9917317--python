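# Methods

## Model

One gene, N species on a rooted tree with branch lengths, M_i biological
replicates per species. The species-level trait X_i(t) evolves from the root
state X(0) by an Ornstein–Uhlenbeck process

    dX_i(t) = α (β_i(t) − X_i(t)) dt + σ dB_i(t),

where β_i(t) is piecewise constant along branches: each branch belongs to one
of R regimes, regime r having optimum θ_r. α = 0 gives Brownian motion
(neutral drift). The observation for replicate k is
y_{i,k} = X_i(T_i) + δ_{i,k} with δ_{i,k} ~ N(0, γσ²) i.i.d.; γ is the ratio
of within-species to evolutionary variance and is assumed ≤ 1 (and, for a
simulation setting to be considered biologically plausible, within-species
variance should not exceed the stationary between-species variance σ²/2α,
i.e. αγ ≤ 1/2).

Stacking observations species-major/replicate-minor gives

    y ~ N(Wθ, V),   V = σ² (Ṽ(α) + γI)            (OU)
    y ~ N(1θ0, V),  V = σ² (S + γI)                 (BM)

* S_{(i,k),(j,l)} = s_ij, the root-to-MRCA time of tips i, j (s_ii = T_i);
* Ṽ_{(i,k),(j,l)} = e^{−α(T_i+T_j−2 s_ij)} (1 − e^{−2α s_ij}) / (2α);
* W row for species i, column r:
  Σ_τ [e^{−α(T_i−t_iτ)} − e^{−α(T_i−t_iτ−1)}] β_{i,r}^τ over the lineage's
  branch segments (epochs t_iτ), plus the root-state weight e^{−αT_i} added
  to the **root regime's** column.

**Root-column absorption.** The general mean has a separate root-state term
e^{−αT_i}·X(0). We merge that column into the root regime's column so the
constrained model has exactly one free optimum and an R-regime model exactly
R, and W keeps full column rank (on an ultrametric tree the unmerged root
column is collinear with the regime columns). The unmerged variant (free
root-state parameter) is available via `merge_root=False` for sensitivity
checks. With absorption, W rows sum to 1 by the telescoping identity.

## Estimation

For fixed (α, γ), A = Ṽ + γI is factorized once (Cholesky; no explicit
inverses) and the remaining parameters are profiled in closed form:

    θ̂ = (Wᵀ A⁻¹ W)⁻¹ Wᵀ A⁻¹ y,
    σ̂² = (y − Wθ̂)ᵀ A⁻¹ (y − Wθ̂) / n,   n = Σ_i M_i,

giving the profile objective Ũ(α, γ) = n(1 + log 2πσ̂²) + log det A. This is
plain maximum likelihood (not REML) — the σ̂² denominator is the total
observation count.

Numerical choices:

* γ is restricted to (1e−6, 1]: at γ = 0 with any M_i ≥ 2 the matrix A has
  duplicate rows and is singular; the upper bound encodes the assumption
  γ ≤ 1. Optimization uses logit-transformed γ.
* α is optimized on the log scale inside [1e−9, 1e3/depth]. The floor sits
  far below any resolvable attraction so the constrained fit can approach
  the BM boundary; Ṽ is evaluated with `expm1` so Ṽ(α) → S smoothly and the
  nested-optimum chain U_BM ≥ U_OU1 holds to 1e−6.
* Search scheme (deterministic, no RNG): a 4×4 coarse grid over
  α ∈ [1e−3/depth, 1e2/depth] × γ ∈ [1e−4, ~1] is scanned; Nelder-Mead runs
  from the three best grid points; L-BFGS-B polishes the winner. BM needs
  only a bracketed 1-D search in γ. `fit_gene_models` additionally seeds the
  constrained fit with the BM optimum (at the α floor) and the adaptive fit
  with the constrained optimum; since the profiled adaptive objective is
  pointwise ≤ the constrained one at equal (α, γ) (the ones vector lies in
  the adaptive column space), the optimal −2 log L chain
  BM ≥ OU1 ≥ adaptive is guaranteed numerically.
* All-M_i = 1 data make γ unidentifiable; it is fixed at 0 (A = S or Ṽ must
  then be positive definite, which holds for distinct tips with positive
  terminal branches). This is exactly the replicate-averaging baseline:
  `fit_averaged_baseline` collapses replicates to species means and refits
  with γ = 0.
* Constant observation vectors are degenerate (σ̂² → 0, −2 log L → −∞); fits
  return the exact θ̂ = c with a `degenerate` flag instead of optimizing.
* Fits report a flag when α̂γ̂ > 1/2; the inequality is treated as a
  simulation-validity filter, not an estimation constraint, so the
  estimator is unchanged by it.

Known estimator properties at small N (documented because the package's own
acceptance checks measure them): with N = 9 species and M = 4 replicates,
the per-gene ML attraction strength α̂ is strongly upward biased (median
≈ 1.7× the truth at α = 2 on a unit-depth tree), and the median of σ̂² under
BM with jointly estimated (θ0, γ) sits ≈ 20–25% below the truth (ML variance
bias plus the median of a right-skewed ~χ² quantity; with γ known the median
is within 5%). These are properties of maximum likelihood on small trees,
not of the implementation: the likelihood matches an independent
multivariate-normal oracle to < 1e−6 and the optimizer matches dense grid
scans. Ratios of optima (θ_shift/θ_background) are recovered essentially
unbiased.

## Hypothesis testing and classification

Nested pairs are compared with the likelihood-ratio statistic
Λ = U_null − U_alt (clipped at 0) against a chi-square with df equal to the
parameter-count difference (BM→OU1: 1; BM→R-regime: R; OU1→R-regime: R−1;
for the default two-regime painting: 1, 2, 1). The α > 0 boundary under the
null makes this reference conservative (the exact distribution is a mixture);
the calibration test asserts the type-I rate does not exceed the nominal
level. A gene is called **adaptive** when the multi-regime model rejects
both BM and OU1 (decision on the max of the two p-values), else
**constrained** when OU1 rejects BM, else **neutral**. Across genes, p-values
are BH-adjusted per test family by default (the study does not state its
correction; "bonferroni" and "none" are available).

## Simulator

Exact branch-wise transition sampling in preorder: over a branch of length Δ
in regime r,

    X_child ~ N(X_parent e^{−αΔ} + θ_r (1 − e^{−αΔ}), σ²(1 − e^{−2αΔ})/2α),

reducing to N(X_parent, σ²Δ) at α = 0, then replicate noise N(0, γσ²) per
observation. One standard-normal draw per branch is consumed in preorder from
a per-gene substream `default_rng([seed, gene_index])`, so datasets are
bitwise reproducible and independent of generation order. Defaults are the
study conditions: root expression 1000; σ² grid {1, 2, 5, 10, 20, 50, 100}
(0.1%–10% of the root level per unit time); γ grid {1, 1/2, …, 1/64}; α grid
{1/8, …, 32}; fold grid {0.5, …, 2} (ratio of the shifted regime's optimum
to the background's); 4 replicates; 1000 genes per grid cell; validity
filter αγ ≤ 1/2 attached per cell. The constrained mode's optimum defaults
to the root value (no transient); adaptive simulations start at the
background regime's optimum.

What the generator emulates: OU/BM trait dynamics with Gaussian, homoskedastic,
exchangeable replicate noise and a single shared tree. What it does not:
count noise (Poisson/NB), normalization artifacts, batch effects,
gene–gene correlation, rate heterogeneity across branches, and gene-specific
baselines (except in the divergence-kinetics checks, which draw per-gene
root values from a normal distribution on the log-expression scale to mimic
the spread of baseline expression in a real gene set). Passing tests
therefore certify the inference machinery under the model's own assumptions,
not robustness to real-data artifacts.

## Trees and units

Branch lengths are used as-is; rate parameters are per unit branch length.
The bundled nine-taxon tree has the Drosophila study topology with the two
subgenera (Sophophora: dmel, dyak, dana, dpse, dper, dwil; Drosophila: dvir,
dmoj, dgri), scaled to unit depth with split depths chosen to match published
divergence-time estimates; the α and σ² grids are interpreted relative to
that depth. `scale_branches` produces the 5× and 10× stretched variants.
Regimes are painted on branches (identified by the child node's label);
`paint_clades` paints a clade and its stem from the clade's tip set. The
root carries no branch; the "root regime" used for W-column absorption is
configurable and defaults to the first-named (background) regime.

## Benchmark metric

auPRC_R is the area under the precision–recall step curve restricted to
recall ≤ R, normalized by R (a perfect ranking scores 1 at every R;
auPRC_1 is the standard auPRC/average precision). Tied scores are grouped
into a single step; no linear PR interpolation. Genes are ranked by the LRT
p-value of the relevant test (ascending); the study does not name its
ranking score, and the p-value is the model-selection output a practitioner
would use. `pooled_benchmark` concatenates positive and negative gene pools
across all γ cells passing the validity filter before ranking, mirroring the
study's aggregation; at desk scale it uses 50 genes per class per γ cell
(200+200 pooled), a size chosen to keep a full benchmark run in minutes on
one CPU. At these sizes, and with the unit-depth reading of the α grid,
α = 1/8 carries almost no detectable constraint signal (test power ≈ type-I),
so low-α auPRC comparisons between the replicate-aware fits and the
averaging baseline are dominated by sampling noise; the replicate-aware
advantage is visible in the high-γ (γ = 1) cells where unmodeled replicate
noise inflates the baseline's false positives.

## Divergence kinetics

For a gene group and a reference tip, each other species contributes a point
(x, y): x the patristic distance to the reference (equals 2(depth − s_ij) on
an ultrametric tree) and y = 1 − ρ², ρ the Spearman correlation of
replicate-averaged expression across the group's genes (sign-invariant and
invariant to monotone per-species transformations). The saturating curve
f(x) = x·Vmax/(K + x) is fitted by plain (unweighted) nonlinear least squares
with f(0) = 0 implied by the functional form — the origin is not added as a
data point. Initialization Vmax0 = max y, K0 = median x; bounds
Vmax ∈ (0, 1.5], K ∈ (0, 10·max x] keep the asymptote interpretable.
f(K) = Vmax/2 holds identically. Vmax estimates the equilibrium divergence of
the group, K the distance at which half of it is reached; constrained groups
show smaller Vmax and smaller K than neutral groups.

## Problem sizes used in the checks

Parameter-recovery medians use 500 genes per condition; simulator moment
checks 1 000–10 000 genes; the type-I calibration 300 genes; the pooled
benchmark 200+200 genes per seed over 3 seeds. These sizes make the checks
reproducible in minutes on a single CPU while keeping Monte-Carlo error well
inside the stated tolerances.
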