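# Methods

This note records the model, the numerical choices, and the open design
decisions behind `longgblup`, at the level of detail a maintainer or a
careful user needs. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model

For line *i*, day *t* (days after planting, DAP), environment×replication
*k*:

y_ijk = Env_k + Σ_m b_m φ_m(t) + Σ_m a_im φ_m(t) + e_ijk

- `Env_k` — fixed effect of the environment×replication combination,
  treated as a single opaque factor label.
- `b` — fixed population-curve coefficients, on the same basis as the
  random part: this keeps the fixed and random parts commensurate and is
  the common choice in random regression practice.
- `a_i` — per-line random regression coefficients,
  var(vec(a)) = G ⊗ G0 in *line-major* ordering (the m coefficients of a
  line are contiguous). The Kronecker ordering is pure bookkeeping; a
  permutation-invariance test pins it down.
- `e` — independent residuals, either one variance or one variance per DAP
  class.

### Time bases

Both bases operate on DAP standardized affinely to [−1, 1].

- **Legendre**: column k is √((2k+1)/2)·P_k(t), the L²-orthonormal scaling.
  No particular normalization is canonical in the literature — any fixed
  scaling is absorbed by G0 — but it must be fixed for reproducibility, so
  the orthonormal one is used.
- **B-splines** of degree p ∈ {1, 2} with user-supplied interior knots, via
  the Cox–de Boor recursion with 0/0 := 0. Boundary knots at the range ends
  carry multiplicity p+1 (clamped convention), giving
  `#interior + p + 1` basis functions that sum to one everywhere; the last
  basis function is closed on the right so the design matrix has no zero
  row at the range end. The recursion is implemented directly because this
  exact parameterization *is* the modeled covariance function; tests
  cross-check it against `scipy.interpolate.BSpline.design_matrix`.

### Residual classes

The default heterogeneous map ships 19 intervals:
27–33, 34–36, 37, 38–41, 42–43, 44–45, 46, 47–49, 50–53, 54–58, 59–61, 62,
63–65, 66–71, 72–74, 75–76, 77–80, 81–82, 83 — one class per
ground-collection period on a typical biomass sampling calendar. This
grouping is sometimes counted as 18 classes; the map here carries 19
explicit intervals, and every parameter count uses the intervals actually
present. During estimation, classes with fewer than two
records are merged rightward with a warning; at fixed variance components
empty classes are harmless and the map is kept as given.

## Estimation

Variance components (vech(G0), per-class σ²_e) are estimated by restricted
maximum likelihood. The restricted log-likelihood is evaluated through the
mixed-model-equation (MME) factorization,

−2·logL = log|R| + m·log|G| + n·log|G0| + log|C| + y′Py + (N−p)·log 2π,

so the cost scales with (number of lines × coefficients)³ per iteration,
never with the record count. Updates are average-information (AI) Newton
steps; the AI matrix is the Gram matrix ½·W′PW of working variates, hence
positive semi-definite. Each step is accepted only if the restricted
likelihood does not decrease (step-halving, up to 12 halvings); if no AI
step is acceptable, one EM step is taken (guaranteed uphill and inside the
parameter space). Convergence requires both the relative parameter change
and a scaled gradient norm below `tol` (default 1e-6); hitting `max_iter`
returns `converged=False` with the last iterate rather than raising, since
boundary cases (e.g. a true genetic variance of zero) legitimately fail to
converge while still yielding usable estimates.

Numerical safeguards, all logged:

- G is lifted by 1e-8 on the diagonal wherever an inverse or log-determinant
  is needed.
- G0 iterates are kept positive definite with an eigenvalue floor of
  `1e-6 × var(y)` (`g0_floor_ratio`); residual variances are floored at
  `1e-8 × var(y)`. The G0 floor bounds the estimated genetic variance away
  from exact zero, which is visible only below the 10⁻⁶ level.
- Phenotypes are centered by their grand mean internally (REML and BLUPs
  are invariant to a constant shift; the centering avoids cancellation in
  y′Py for large baselines) and the mean is added back to the environment
  effects.
- Initialization: G0 = (var(y)/(2m))·I, σ²_e(class) = half the per-class
  phenotypic variance — scale-aware and deterministic.
- The fixed design is the full set of env_rep indicators plus the basis
  columns *minus the first*: the constant direction (Legendre column 0, or
  the B-spline partition of unity) is absorbed by the env_rep means,
  keeping X full rank. Rank is verified by QR; a deficiency error names the
  confounded columns.

AIC = −2·logL + 2·q with q = m(m+1)/2 + (#residual classes); fixed effects
are not counted — every candidate shares the same fixed structure, so only
AIC differences within one dataset matter and the constant cancels.
Non-converged fits are listed but excluded from the AIC ranking.

Approximate standard errors of variance components come from the inverse AI
matrix at the last iterate. Information about G0 is capped by the number of
*lines*; only the residual components gain information proportionally with
records (the test suite asserts the √2 law on the residual SE when the
design is doubled with fresh noise).

## Genetic parameters, prediction, GWAS

- Σ = T·G0·T′ on any grid inside the basis range (default: every integer
  DAP). h²(j) uses the residual variance of day j's class: with a
  heterogeneous residual structure the class-specific variance is the only
  denominator consistent with the declared model, even though the h²
  formula is often written with a single σ²_e.
- The genetic correlation uses the product form
  Σ(j,j′)/√(Σ(j,j)·Σ(j′,j′)). A sum of the two variances under the root
  occasionally appears in print, but only the product form normalizes
  (r(j,j)=1), so the product is used.
- Cross-validation: lines are partitioned uniformly at random into k folds
  (sizes differing by at most one). Validation lines lose their phenotypes
  but stay in G — that relatedness is what makes prediction of
  unphenotyped lines possible. Variance components are re-estimated on each
  training fold by default (`reestimate_varcomps=False` reuses the
  full-data components, for speed). Accuracy and bias are per-fold values
  averaged per DAP; `pool_validation=True` pools validation lines across
  folds first instead — both conventions are in circulation.
- GWAS back-solving uses û_m = DZ′(ZDZ′)⁻¹ĝ_m with D = I (a weights hook
  exists but is off by default), computed through ZZ′ = k·G with a
  Hermitian pseudo-inverse: Z centered on the panel's own allele
  frequencies always has rank ≤ n−1, and the pseudo-inverse equals the
  ordinary inverse on full-rank instances. Relevance is deliberately
  rank-based — the top-k per day by |effect| (default 10), ties broken by
  (chromosome, position) — and no p-values are computed.
  Duration categories over a SNP's presence days: multiple maximal runs →
  intermittent; one run of d days → long (d > 30), mid (10 ≤ d ≤ 30), or
  short (d < 10). Runs of exactly 10 or exactly 30 days are boundary
  cases; both are assigned to **mid**.
- Candidate windows are closed 1-based intervals [pos−w, pos+w] (default
  w = 25 kb) intersected with BED/GFF3 annotation via pyranges; SNPs inside
  a feature are flagged `within_gene`.

## Synthetic data

The generator exists to give every downstream stage a ground truth, not to
imitate any particular dataset beyond its structure.

- **Genotypes**: biparental families of fully inbred lines. Two founder
  haplotypes per family with Bernoulli(½) alleles; each RIL chromosome is a
  founder mosaic from a Markov chain with per-interval switch probability
  (default: two expected crossovers per chromosome), doubled to dosages
  {0, 2}; a residual-heterozygosity rate (default 1%, roughly an
  F5-derived line) sets calls to dosage 1. Defaults: 32 families × 12
  lines, 10,000 SNPs on 20 chromosomes, positions uniform per chromosome.
  No linkage-disequilibrium realism beyond the family Markov structure, no
  selection, no genotyping error — so tests exercise the estimator, not a
  population-genetic model.
- **Phenotypes**: exactly the RRM above. Coefficients are drawn with
  covariance G ⊗ G0 using a Cholesky (or eigen, if singular) square root of
  the panel's own VanRaden G. G0 may be supplied directly or derived from a
  target heritability profile: the target time covariance
  s(t)s(t′)·exp(−|t−t′|/ℓ) (ℓ = 30 days) with s² = σ²_e·h²/(1−h²) is
  projected onto the basis, G0 = T⁺·Σ*·T⁺′, and clipped to the PSD cone.
  The realized profile diag(T·G0·T′) only approximates the request, so all
  truth (including the h² profile) is recomputed from the realized G0.
  The default profile is V-shaped (0.30 at the range ends to 0.05
  mid-season), mirroring the strong mid-season dip reported for biomass;
  the default grid is every integer DAP in 27–83 with six env_rep labels
  (3 environments × 2 replications). The trait scale is arbitrary
  (unit-agnostic): the analysis is invariant to it, and the real trait's
  absolute scale is not publicly documented.
- Unequal replication is emulated by per-env_rep record-dropout rates.

## Verification scales

The recovery and calibration checks run at sizes chosen for a single CPU
(minutes, not hours); all thresholds are unchanged from the design targets:

- parameter recovery: 256 lines (32 families × 8), 800 SNPs, full 57-day
  grid, 2 env_reps, 19 heterogeneous residual classes, 6 replicates —
  h² profile MAE < 0.05, genetic-correlation MAE < 0.1;
- null calibration: 150 lines, 10 replicates — genetic variance ≤ 5% of
  residual in ≥ 90%;
- model recovery: 150 lines, 10 replicates — the generating linear
  B-spline basis beats a third-order Legendre alternative by AIC in ≥ 70%.

## Known limitations

- The full-vs-reduced GEBV correlation ("accuracy") is *not* null-centered:
  the two estimates share 80% of training records and all sibling
  information, so even with zero genetic variance their correlation is
  strongly positive (≈0.5–0.8 on a family panel in our null simulations).
  It is reported because it is the field's standard summary, but it should
  be read as an upper bound on predictive ability; the independent-pairs
  band 2/√n is not its null distribution
  (`tests/test_acceptance.py::test_null_simulation_cv_accuracy_within_independence_band`
  documents this).
- No pedigree/single-step H matrix, no dominance or epistasis, no MCMC
  alternative, no standard errors on h² trajectories, no free-knot
  optimization, no forward (time-truncated) or leave-family-out CV.
- AI-REML standard errors are asymptotic and computed at the last iterate;
  they are indicative, not inferential guarantees.
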