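# ancestryclust

Clustering by genetic ancestry from genome-wide SNP data, and
stratification-aware case/control matching for GWAS.

Population stratification — systematic allele-frequency differences
between cases and controls driven by ancestry rather than the trait —
inflates association statistics genome-wide.  The usual fix is to adjust
each test for the leading principal components (PCs) of the standardized
genotype matrix.  An alternative is to *match* cases and controls on
ancestry, which additionally yields a stratification-free dataset that
can be reused (e.g. for prediction models) without study-specific PC
covariates.  Matching needs discrete ancestry strata; this package builds
them by k-means clustering of the informative PCs, with the number of
clusters chosen by a permutation-referenced **Scoring Index**.

For each candidate cluster count k (k = 2..K), M single-start k-means
executions are scored on three [0,1] criteria — leave-one-out linear
discriminant **accuracy** A, Rand-statistic **stability** S between
random pairs of executions, and normalized between-cluster **distance**
B(C)/Total under squared Euclidean distance — each referenced against the
same quantity on size-preserving random permutations of the labels:

    SI_k = (1/M) Σ_m  [ (A_O−A_P)/(1−A_P) + (B_O−B_P)/(1−B_P)
                        + (S_O−S_P)/(1−S_P) ] / 3

Var(SI_k) follows from beta-distribution moment matching on the
underlying counts, giving a 95% CI; the *optimal* k is the smallest one
whose mean SI falls inside the CI of the maximizer (parsimony rule).
See `docs/methods.md` for the full derivation and the numerical choices.

The package also ships the genotype simulators used to validate the
method (Hardy–Weinberg null data; Balding–Nichols-style Fst-structured
clusters; confounded case/control studies with relative-risk causal
SNPs), frequency matching of controls within clusters, a fast additive
logistic association scan with genomic-control λ, QQ and per-cluster
odds-ratio tables, and two replicate study harnesses (cluster-number
sensitivity; matched vs PC-adjusted power).

## Worked example

Simulate three ancestry clusters (Fst = 0.01, the divergence of distinct
European subpopulations), run PCA, and select the cluster number:

```python
from ancestryclust import (StructureSimConfig, simulate_structured,
                           run_pca, scoring_index_curve, rand_index)

cfg = StructureSimConfig(n_samples=600, n_snps=6000, n_clusters=3,
                         fst=0.01, seed=7)
genotypes, truth = simulate_structured(cfg)
pca = run_pca(genotypes, n_components=2, svd="auto")
curve = scoring_index_curve(pca.scores, k_max=6, m_executions=20, seed=11)
print(curve.as_table().round(4).to_string(index=False))
print("k_max_si =", curve.k_max_si, " k_optimal =", curve.k_optimal)
print("Rand vs truth at k=3:",
      rand_index(curve.best_assignments[3], truth).rand)
```

prints

```
 k  si_mean  si_var  ci_low  ci_high
 2   0.6747     0.0  0.6743   0.6751
 3   0.9901     0.0  0.9900   0.9901
 4   0.9188     0.0  0.9152   0.9224
 5   0.8680     0.0  0.8625   0.8735
 6   0.8743     0.0  0.8683   0.8802
k_max_si = 3  k_optimal = 3
Rand vs truth at k=3: 1.0
```

The SI peaks sharply at the true k = 3 (merging clusters at k = 2 costs
distance; splitting them at k ≥ 4 costs stability), both selection rules
agree, and the best execution at k = 3 reproduces the true labels exactly
(Rand = 1).  Variances are tiny here because the simulated clusters are
crisply separated; on real data the curve is flatter and the parsimony
rule matters.

The same pipeline is available from the shell:

```sh
ancestryclust simulate structured --samples 600 --snps 6000 --clusters 3 \
    --seed 7 --out geno.tsv --labels-out truth.tsv
ancestryclust pca --geno geno.tsv --components 10 --out-prefix study
ancestryclust cluster --scores study.eigenvec --pcs 2 --kmax 6 --m 20 \
    --seed 11 --out-prefix study
ancestryclust simulate casecontrol --cases 500 --controls 500 --seed 3 \
    --out cc.tsv --truth-out clusters.tsv --pheno-out pheno.tsv
ancestryclust match --clusters clusters.tsv --pheno pheno.tsv --out sel.tsv
ancestryclust gwas --geno cc.tsv --pheno pheno.tsv --out assoc.tsv
```

`ancestryclust experiment sensitivity|power` run the replicate studies
(`--profile full` restores full-scale sensitivity settings).

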