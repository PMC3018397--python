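# Methods

## Problem and approach

Case/control association studies are confounded when cases and controls
have different ancestral compositions: allele-frequency differences between
ancestry strata masquerade as trait associations and inflate test
statistics genome-wide.  The two standard remedies are covariate adjustment
for leading principal components (PCs) of the genotype matrix, and genetic
matching of cases to controls.  Matching needs discrete, well-defined
ancestry strata; this package derives them by clustering subjects on their
informative PCs and selecting the number of clusters with a
permutation-referenced **Scoring Index (SI)**.

The pipeline is:

1. **QC and LD pruning** (`genotype_io`) — keep variants with call rate
   > 0.95 and MAF > 0.05 (defaults); optionally remove one SNP of every
   pair with r² > 0.30 inside a 50-SNP window sliding by 5, so PCs reflect
   genome-wide ancestry rather than local haplotype structure.
2. **Standardized PCA** (`pca`) — per SNP, impute missing calls to the
   SNP mean, center, and divide by `sqrt(p(1-p))` with `p` the sample
   alternate-allele frequency (the binomial allele-draw SD; unit-variance
   scaling is available as a switch).  Components come from an SVD, exact
   or seeded-randomized for large matrices; signs are fixed so each
   component's largest-magnitude loading is positive.
3. **Informative-PC choice** — a log-eigenvalue scree table (with an
   advisory elbow: the component maximizing the second difference, flagged
   low-confidence when the maximum curvature is < 0.1) and a
   row-standardized heatmap table ordered by average-linkage hierarchical
   clustering.  The final count is a user decision: both diagnostics are
   visual aids, and on real data they can disagree.
4. **Cluster-number selection** (`scoring`) — the core algorithm, below.
5. **Matching and GWAS** (`gwas`) — frequency matching of controls to
   cases within clusters, additive logistic association scans, the
   genomic-control factor λ, QQ tables, and per-cluster odds ratios for
   locus-heterogeneity checks.

## The Scoring Index

For each candidate cluster count `k` in `2..K`, run `M` independent
k-means executions on the informative PCs.  Each execution `m` is scored
on three [0,1] criteria:

* **Accuracy** `A_O`: leave-one-out cross-validated agreement between the
  k-means labels and a linear discriminant model (pooled within-class
  covariance, empirical priors) fit to them.  A_O = NA_O/N with NA_O the
  number of subjects re-predicted into their own cluster.
* **Stability** `S_O`: the Rand statistic `R = (S+D)/T` against one
  uniformly chosen partner execution at the same k (S pairs together in
  both partitions, D pairs apart in both, T all pairs).  S_O = NS_O/NS
  with NS_O the concordant-pair count.
* **Distance** `B_O`: the normalized between-cluster scatter
  `B(C)/Total`, where distances are *squared* Euclidean over the
  informative PCs, `Total = ½ΣΣ d(x_i, x_i')` over all ordered pairs,
  `W(C)` the same restricted to same-cluster pairs, and
  `B(C) = Total − W(C)`.  Computed exactly through the centroid identity.

None of the three is comparable across k on its own (accuracy falls and
distance rises mechanically with k), so each execution's labels are
randomly permuted once — preserving cluster sizes — and the same three
quantities are computed on the permuted labels (permuted stability is the
Rand statistic between the two permuted partners).  Each criterion enters
as its **relative gain** over the permutation referent,

    g = (obs − perm) / (1 − perm),

floored at 0 (an observed value can fall below its referent by chance;
the floor keeps the index in [0,1] and the beta moment matching valid —
unfloored gains remain available from the per-execution records).  The
index is

    SI_k = (1/M) Σ_m ( g_accuracy + g_distance + g_stability ) / 3 .

The per-execution contribution is the *mean* of the three gains: the
variance formula below carries a factor 1/9 per execution and the index
is a [0,1] quantity, which fixes the 1/3 normalization.

### Variance and confidence interval

Each gain is treated as a beta-distributed proportion whose parameters
come from the underlying counts, e.g. the accuracy gain at execution m is
`beta(NA_O − NA_P, N − NA_O)`; the distance gain uses the between-cluster
sums of squares against `SST`, and the stability gain the concordant-pair
counts against `NS`.  Then

    Var(SI_k) = (1/(9M)) Σ_m [ v_A,m + v_B,m + v_S,m ]

with each `v` the matched beta variance; a term whose moment-matched α is
non-positive (observed below the referent, the flooring regime)
contributes zero.  Note that this is the *average per-execution* variance
of the three-gain score — the intrinsic spread of one execution — not the
(M times smaller) variance of the M-execution mean.  The parsimony rule
below needs a tolerance band on that intrinsic scale: the variance of the
mean vanishes as M grows, which would collapse the optimal rule onto the
maximum rule and defeat its purpose.  The 95% CI around SI_k is the
2.5th/97.5th quantile of
`beta(α, β)` with `α = (1−SI)SI²/Var − SI`, `β = α(1−SI)/SI`; when
Var < 1e-12 (or the moment match degenerates) the CI collapses to the
mean.

### Selection rules

`k_max_si` maximizes the mean SI.  Because the curve can be nearly flat
across several k, the **optimal** (parsimonious) choice is the smallest k
whose mean SI lies at or above the lower CI bound of `k_max_si`.  Worked
check: means (0.85, 0.879, 0.886) at k = (7, 9, 11) with the maximizer's
CI (0.876, 0.896) select 9.

### Numerical choices

* **k-means**: Lloyd iterations (tol 1e-6, max 300), *one* start per
  execution — the M executions are the restarts and their disagreement is
  the stability signal — seeded by k-means++.  With pure random-point
  starts, single-start executions at the *true* k fall into split/merge
  local optima often enough (measured stability 0.86 at k=K vs 0.96 at
  k=K+1 on a K=4, Fst 0.01 run) that the index maximizes above K;
  k-means++ keeps the true-k executions reliable while surplus-center
  placement still varies between executions at over-clustered k.
  Labels are canonicalized by first appearance; executions returning an
  empty cluster are re-seeded up to 5 times, then flagged degenerate.
* **LOOCV-LDA**: exact leave-one-out via rank-one (Sherman–Morrison)
  downdates of the pooled within-class scatter, O(n·p²) per execution and
  verified against a naive refit-per-holdout oracle.  The scatter gets a
  ridge `1e-6·trace/p` on the diagonal when its condition number exceeds
  1e8 (routine under permuted labels).  Singleton clusters cannot be held
  out and recovered; their member counts as misclassified.
* **Seeds**: one master seed; per-(k, m) execution, permutation and
  partner seeds are drawn deterministically from it, so the whole curve is
  bit-reproducible from `(scores, K, M, seed)`.

### Known limitations of the variance model

The count-based beta variance models sampling noise in the counts with
executions held fixed.  At the SI maximizer it tracks the seed-to-seed
spread of SI_k within an order of magnitude (measured ratio ~9 on a K=3
run); at over-clustered k, where run-to-run variability is dominated by
which cluster the surplus centers split, it can understate the spread by
1–2 orders of magnitude.  The selection rule only ever uses the CI at the
maximizer.  The formula also ignores covariance between the three gains.

## Simulators

`simulate_null` draws per-SNP allele frequencies from U(0.05, 0.95) and
genotypes from Hardy–Weinberg proportions — no structure, no missingness.

`simulate_structured` is a Balding–Nichols-style divergence model: founder
frequency `p ~ U(0.05, 0.50)` per SNP; per-cluster frequency
`p_k ~ Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst)` (mean p, variance
Fst·p(1−p)); within-cluster genotype frequencies

    ( Fst(1−p_k) + (1−Fst)(1−p_k)²,  2(1−Fst)p_k(1−p_k),
      Fst·p_k + (1−Fst)p_k² )

— HWE plus an Fst-sized excess-homozygosity term.  The default Fst = 0.01
corresponds to divergent European subpopulations; a Weir–Cockerham
estimate on simulated data recovers it.  Cluster sizes are equal
(ceiling-rounded) or drawn uniformly on the simplex subject to a 5%
minimum share.

`simulate_case_control` confounds ancestry with phenotype through
different cluster-membership probability vectors (defaults (0.4, 0.3,
0.2, 0.1) for cases against (0.1, 0.2, 0.3, 0.4) for controls).  Causal
SNPs multiply the control genotype-frequency vector by (1, R, R²) — R the
per-allele relative risk — and renormalize; their founder frequency is
fixed at the specified MAF.  The R² term multiplies the control
homozygote frequency `Fst·p_k + (1−Fst)p_k²`; a variant reading with a
linear `p_k` in the homozygote term is available behind
`literal_case_hom=True` but reduces to `R²p_k`, inconsistent with the
control model it parallels, and is not the default.  The default causal
grid is R ∈ {1.2, 1.3, 1.4, 1.5} × MAF ∈ {0.1, …, 0.5} (20 SNPs); count
and grid are configurable.

**What the generator does not emulate**: linkage disequilibrium (all SNPs
are independent, so LD pruning is exercised only on toy fixtures),
admixed individuals (membership is discrete), relatedness, genotyping
error or missingness patterns, and continuous clines.  Consequently the
simulated clusters are unusually crisp: with m SNPs the squared
between-centroid separation on the informative PCs is ≈ 2·m·Fst times the
within-cluster spread (≈100× at 5,000 SNPs), so selection-rule successes
here do not imply equal sensitivity on real, clinal data — the two
selection rules nearly coincide on these conditions, whereas on real data
the maximum-SI rule is known to over-cluster and the parsimony rule is
the one to trust.

## Matching and GWAS evaluation

`match_controls` implements frequency matching: the achievable
control:case ratio r is the minimum over case-bearing clusters of
available-controls/cases; each cluster's target is cases·r, allocated by
largest-remainder rounding and sampled without replacement under a seed.
Clusters without cases contribute nothing; case clusters without controls
are flagged unmatched.

`assoc_scan` fits an additive logistic regression per SNP (intercept,
optional covariates, alternate-allele count) by a batched Newton–Raphson
solver vectorized across SNPs, warm-started at the covariates-only fit;
per-SNP missing genotypes are dropped through zero IRLS weights.  Wald
chi-squares agree with per-SNP `statsmodels` fits to ~1e-5; non-converged
or separated fits fall back to a bounded likelihood-ratio statistic and,
failing that, are excluded from λ.  λ = median(χ²)/0.4549364.

The **power study** compares (a) a *matched* design — controls share the
cases' cluster probabilities, the state within-cluster matching produces,
scanned without covariates — against (b) an *unmatched* design with
opposing control probabilities, scanned with the top 10 PCs recomputed on
each analysis sample, at equal n and with extra controls added from a
pool.  Power is measured at an empirical per-design threshold (the
1−α quantile of that design's own pooled null-SNP statistics, α = 1e-3 by
default), which equalizes realized type-I error across designs; at scaled
problem sizes (500/500, 2,000 null SNPs) a genome-wide α near 1e-6 is not
resolvable, and 1e-3 keeps the causal grid in the informative power range.
Because the reported minimum and maximum gain over the grid are extreme
statistics, their Monte Carlo noise is the dominant error at tens of
replicates; `causal_repeats` simulates several independent causal SNPs
per (MAF, R) cell and pools them, tightening each cell without changing
the design.
The matched design is simulated directly rather than by running
`match_controls` on an opposing pool, which at equal target n is the same
state without discarding controls; `stratification_lambdas` demonstrates
the matching operation itself (λ ≈ 2 unmatched vs ≈ 1 matched on opposing
mixtures).

## Problem sizes

Default study sizes are scaled for minutes-level runs: sensitivity uses
500 samples × 5,000 SNPs, M = 20 executions, k swept to K_true + 2, 20
replicates per scenario, and p = K_true − 1 informative PCs (the
dimensionality spanned by K_true cluster centroids — an automated harness
cannot reproduce a per-dataset visual choice); the power study uses 500
cases/500 controls, 2,000 null SNPs, the R ∈ {1.3, 1.5} × MAF ∈ {0.2,
0.4} causal grid and 50 replicates.  A `--profile full` flag on the CLI
restores the full-scale sensitivity settings (1,000 × 10,000, M = 100,
100 replicates).  The generating model and algorithms are identical at
any scale; only Monte Carlo resolution changes.
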