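"""Matching, association scan, genomic control and locus heterogeneity."""

import numpy as np
import pytest

from ancestryclust import (
    CaseControlSimConfig,
    assoc_scan,
    cluster_specific_effects,
    genomic_lambda,
    match_controls,
    qq_table,
    simulate_case_control,
    simulate_null,
)
from ancestryclust.gwas import CHI2_1_MEDIAN


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _cohort(case_counts, ctrl_counts):
    ids, clusters, pheno = [], [], []
    i = 0
    for c, (nc, nk) in enumerate(zip(case_counts, ctrl_counts), start=1):
        for _ in range(nc):
            ids.append(f"case{i}"); clusters.append(c); pheno.append("case")
            i += 1
        for _ in range(nk):
            ids.append(f"ctl{i}"); clusters.append(c); pheno.append("control")
            i += 1
    return ids, np.array(clusters), pheno


def test_match_identical_distribution_selects_all():
    ids, cl, ph = _cohort([30, 20], [30, 20])
    plan = match_controls(ids, cl, ph, seed=0)
    assert len(plan.selected_controls) == 50
    assert plan.excluded_controls == []
    assert plan.target_ratio == pytest.approx(1.0)


def test_match_zero_case_cluster_contributes_nothing():
    ids, cl, ph = _cohort([100, 0], [50, 50])
    plan = match_controls(ids, cl, ph, seed=0)
    sel_clusters = cl[[ids.index(s) for s in plan.selected_controls]]
    assert (sel_clusters == 1).all()
    assert len(plan.selected_controls) == 50


def test_match_ratio_balancing_largest_remainder():
    """Cases (40,30,20,10) on pool (10,20,30,40): r = 10/40 = 0.25 and
    the per-cluster quotas round by largest remainder."""
    ids, cl, ph = _cohort([40, 30, 20, 10], [10, 20, 30, 40])
    plan = match_controls(ids, cl, ph, seed=1)
    assert plan.target_ratio == pytest.approx(0.25)
    sel = np.array([cl[ids.index(s)] for s in plan.selected_controls])
    counts = [int((sel == c).sum()) for c in (1, 2, 3, 4)]
    assert counts[0] == 10 and counts[2] == 5
    assert counts[1] in (7, 8) and counts[3] in (2, 3)
    assert sum(counts) == 25
    # deterministic under the seed
    plan2 = match_controls(ids, cl, ph, seed=1)
    assert plan2.selected_controls == plan.selected_controls


def test_match_cluster_without_controls_flagged():
    ids, cl, ph = _cohort([10, 10], [20, 0])
    plan = match_controls(ids, cl, ph, seed=0)
    assert plan.unmatched_case_clusters == [2]


# ---------------------------------------------------------------------------
# Association scan and lambda
# ---------------------------------------------------------------------------

def test_genomic_lambda_definition_and_scale():
    assert genomic_lambda(np.full(100, CHI2_1_MEDIAN)) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    draws = rng.chisquare(1, size=500_000)
    assert genomic_lambda(draws) == pytest.approx(1.0, abs=0.01)
    assert genomic_lambda(1.5 * draws) == pytest.approx(1.5, abs=0.02)
    # permutation invariance
    v = rng.chisquare(1, size=101)
    assert genomic_lambda(v) == genomic_lambda(v[::-1])


def test_assoc_scan_matches_contingency_table_or():
    """Single-SNP OR equals the closed-form per-allele (2x2 allele table)
    estimate computed independently from the counts."""
    rng = np.random.default_rng(3)
    n = 2000
    p_case, p_ctrl = 0.35, 0.25
    g_case = rng.binomial(2, p_case, n)
    g_ctrl = rng.binomial(2, p_ctrl, n)
    calls = np.concatenate([g_case, g_ctrl])[:, None].astype(np.int8)
    from ancestryclust.genotype_io import VariantRecord, make_genotype_matrix
    g = make_genotype_matrix([f"s{i}" for i in range(2 * n)],
                             [VariantRecord(id="v0")], calls,
                             phenotype=["case"] * n + ["control"] * n)
    res = assoc_scan(g, min_maf=0.01)
    # independent oracle: statsmodels logistic fit
    import statsmodels.api as sm
    y = np.array([1.0] * n + [0.0] * n)
    x = sm.add_constant(calls.astype(float))
    fit = sm.Logit(y, x).fit(disp=0)
    assert res.table["beta"].iloc[0] == pytest.approx(fit.params[1], abs=1e-6)
    assert res.table["chisq"].iloc[0] == pytest.approx(
        (fit.params[1] / fit.bse[1]) ** 2, rel=1e-5)


def test_assoc_scan_null_lambda_near_one():
    """Phenotype independent of unstructured genotypes: lambda ~ 1 and
    roughly uniform p-values."""
    g = simulate_null(n_samples=400, n_snps=1500, seed=6)
    rng = np.random.default_rng(7)
    pheno = ["case" if v else "control" for v in rng.random(400) < 0.5]
    res = assoc_scan(g, phenotype=pheno, min_maf=0.01)
    assert 0.9 < res.lambda_gc < 1.1
    p = res.table["p"].dropna().to_numpy()
    from scipy import stats
    assert stats.kstest(p, "uniform").pvalue > 1e-3


def test_assoc_scan_covariate_agreement_with_statsmodels():
    """Multi-covariate batched fits agree with per-SNP statsmodels fits."""
    import statsmodels.api as sm

    cfg = CaseControlSimConfig(n_cases=300, n_controls=300, null_snps=30,
                               causal_specs=[(0.3, 1.5)], seed=12)
    g, clusters, _ = simulate_case_control(cfg)
    cov = np.column_stack([np.asarray(clusters, float),
                           np.random.default_rng(0).normal(size=600)])
    res = assoc_scan(g, covariates=cov, min_maf=0.01)
    y = np.array([ph == "case" for ph in g.phenotype], float)
    x0 = np.column_stack([np.ones(600), cov])
    ids = res.table["snp"].tolist()
    for snp in [ids[0], ids[10], ids[-1]]:
        j = g.variant_ids().index(snp)
        fit = sm.Logit(y, np.column_stack([x0, g.calls[:, j].astype(float)])
                       ).fit(disp=0)
        row = res.table.set_index("snp").loc[snp]
        assert row["beta"] == pytest.approx(fit.params[-1], abs=1e-5)
        assert row["chisq"] == pytest.approx((fit.params[-1] / fit.bse[-1])**2,
                                             rel=1e-4)


def test_qq_table_shapes():
    p = np.linspace(1 / 101, 100 / 101, 100)
    t = qq_table(p)
    np.testing.assert_allclose(t["expected_neglog10"], t["observed_neglog10"],
                               atol=0.01)
    # one extreme p stands far above the diagonal at the tail
    t2 = qq_table(np.append(p, 1e-8))
    assert (t2["observed_neglog10"] - t2["expected_neglog10"]).max() > 5
    with pytest.raises(ValueError):
        qq_table(np.array([0.0, 0.5]))


def test_cluster_specific_effects_recovery():
    """A SNP with opposite effects by cluster yields ordered ORs; clusters
    with no minor alleles report NA."""
    rng = np.random.default_rng(5)
    n = 1200
    clusters = np.repeat([1, 2, 3], n // 3)
    y = rng.random(n) < 0.5
    gcol = np.zeros(n, dtype=np.int8)
    # cluster 1: protective (freq lower in cases); cluster 2: null;
    # cluster 3: monomorphic
    for i in range(n):
        if clusters[i] == 1:
            p = 0.15 if y[i] else 0.4
            gcol[i] = rng.binomial(2, p)
        elif clusters[i] == 2:
            gcol[i] = rng.binomial(2, 0.3)
    from ancestryclust.genotype_io import VariantRecord, make_genotype_matrix
    g = make_genotype_matrix(
        [f"s{i}" for i in range(n)], [VariantRecord(id="rsX")],
        gcol[:, None], phenotype=["case" if v else "control" for v in y])
    t = cluster_specific_effects(g, g.phenotype, clusters, "rsX")
    t = t.set_index("cluster")
    assert t.loc[1, "odds_ratio"] < 0.6
    assert t.loc[2, "odds_ratio"] == pytest.approx(1.0, abs=0.35)
    assert np.isnan(t.loc[3, "odds_ratio"])
    assert t.loc[1, "freq_cases"] < t.loc[1, "freq_controls"]
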