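"""Simulation studies: cluster-number sensitivity and matched-GWAS power.

Two harnesses, both deterministic given a master seed:

* :func:`run_sensitivity` measures how often the Scoring Index recovers the
  true number of ancestry clusters — by the maximum-SI rule and by the
  parsimonious optimal-SI rule — with perfect allocation of every subject,
  over replicate Fst-structured simulations.
* :func:`run_power_study` compares the power and false-positive behaviour
  of a genetically matched case/control GWAS against an unmatched design
  adjusted for leading principal components, including the effect of
  enlarging the unmatched control group.

Scaled-down default problem sizes (500-1000 samples, a few thousand SNPs,
tens of executions/replicates) keep a full study in the minutes range; the
generating model and the algorithms are identical at any scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import assoc_scan
from .pca import run_pca
from .scoring import rand_index, scoring_index_curve
from .simulate import (
    CaseControlSimConfig,
    StructureSimConfig,
    simulate_case_control,
    simulate_structured,
)

logger = logging.getLogger(__name__)


def wilson_ci(hits: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return 0.0, 1.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = hits / n
    denom = 1.0 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


@dataclass
class SensitivityResult:
    """Recovery rates of the true cluster number with perfect allocation."""

    k_true: int
    scenario: str
    replicates: int
    hits_max_si: int
    hits_optimal_si: int
    records: pd.DataFrame = field(repr=False, default=None)

    @property
    def power_max_si(self) -> float:
        return self.hits_max_si / self.replicates

    @property
    def power_optimal_si(self) -> float:
        return self.hits_optimal_si / self.replicates

    def ci_max_si(self) -> tuple[float, float]:
        return wilson_ci(self.hits_max_si, self.replicates)

    def ci_optimal_si(self) -> tuple[float, float]:
        return wilson_ci(self.hits_optimal_si, self.replicates)


def run_sensitivity(
    k_true: int,
    scenario: str = "equal",
    replicates: int = 20,
    n_samples: int = 500,
    n_snps: int = 5000,
    m_executions: int = 20,
    k_max: int | None = None,
    fst: float = 0.01,
    n_pcs: int | None = None,
    seed: int = 0,
) -> SensitivityResult:
    """Replicate simulation study of cluster-number recovery.

    Per replicate: simulate an Fst-structured dataset with ``k_true``
    clusters (``scenario``: "equal" sizes or "unequal" = random shares with
    a 5% minimum), run PCA, score k = 2..k_max (default k_true + 2) over
    the leading ``n_pcs`` PCs (default k_true - 1, the dimensionality
    spanned by k_true cluster centroids), and record whether each selection
    rule returns k_true with Rand = 1 against the true labels.  Perfect
    allocation is judged on the execution with the best k-means objective
    at the selected k.
    """
    if scenario not in ("equal", "unequal"):
        raise ValueError("scenario must be 'equal' or 'unequal'")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    k_max = k_max if k_max is not None else k_true + 2
    n_pcs = n_pcs if n_pcs is not None else max(k_true - 1, 1)
    master = np.random.default_rng(seed)
    rows = []
    hits_max = hits_opt = 0
    for rep in range(replicates):
        s1, s2 = master.integers(0, 2**31, size=2)
        cfg = StructureSimConfig(
            n_samples=n_samples, n_snps=n_snps, n_clusters=k_true, fst=fst,
            cluster_sizes="equal" if scenario == "equal" else "random_min5pct",
            seed=int(s1))
        g, truth = simulate_structured(cfg)
        pca = run_pca(g, n_components=max(n_pcs, 2), svd="auto")
        scores = pca.scores[:, :n_pcs]
        curve = scoring_index_curve(scores, k_max=k_max,
                                    m_executions=m_executions, seed=int(s2))

        def _hit(k_sel: int) -> bool:
            if k_sel != k_true:
                return False
            assign = curve.best_assignments[k_sel]
            return rand_index(assign, truth).rand == 1.0

        hit_max = _hit(curve.k_max_si)
        hit_opt = _hit(curve.k_optimal)
        hits_max += hit_max
        hits_opt += hit_opt
        rows.append({"replicate": rep, "k_max_si": curve.k_max_si,
                     "k_optimal": curve.k_optimal, "hit_max_si": hit_max,
                     "hit_optimal_si": hit_opt, "sim_seed": int(s1),
                     "algo_seed": int(s2)})
        logger.info("sensitivity K=%d %s rep %d: max=%d opt=%d",
                    k_true, scenario, rep, curve.k_max_si, curve.k_optimal)
    return SensitivityResult(k_true=k_true, scenario=scenario,
                             replicates=replicates, hits_max_si=hits_max,
                             hits_optimal_si=hits_opt,
                             records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Power study
# ---------------------------------------------------------------------------

@dataclass
class PowerStudyResult:
    """Power and false-positive summary of matched vs PC-adjusted designs.

    ``power`` has one row per (design, added_controls, maf, rr);
    ``gains`` holds the matched-minus-unmatched power difference at equal
    sample size per causal cell, in percentage points.
    """

    power: pd.DataFrame
    fpr: pd.DataFrame
    gains: pd.DataFrame
    alpha: float
    replicates: int

    @property
    def min_gain(self) -> float:
        return float(self.gains["gain_pct"].min())

    @property
    def max_gain(self) -> float:
        return float(self.gains["gain_pct"].max())


def run_power_study(
    replicates: int = 50,
    n_cases: int = 500,
    n_controls: int = 500,
    null_snps: int = 2000,
    causal_specs: list[tuple[float, float]] | None = None,
    causal_repeats: int = 1,
    added_controls: tuple[int, ...] = (250, 500),
    extra_control_pool: int | None = None,
    n_pcs: int = 10,
    alpha: float = 1e-3,
    fst: float = 0.01,
    case_cluster_probs: tuple = (0.4, 0.3, 0.2, 0.1),
    control_cluster_probs: tuple = (0.1, 0.2, 0.3, 0.4),
    seed: int = 0,
) -> PowerStudyResult:
    """Matched vs unmatched-PC-adjusted GWAS power over a causal-SNP grid.

    Per replicate two studies are simulated.  In the *matched* design the
    controls share the cases' cluster-membership probabilities (the state
    that within-cluster matching produces) and the scan uses no covariates.
    In the *unmatched* design the controls' cluster probabilities oppose
    the cases', and the scan adjusts for the top ``n_pcs`` PCs recomputed
    on each analysis sample; the design is also rerun with extra controls
    drawn from a pool with the unmatched probabilities.

    Power is estimated per (maf, relative-risk) cell at an empirical
    per-design chi-square threshold: the (1 - alpha) quantile of that
    design's own pooled null-SNP statistics, which equalizes the type-I
    error across designs.  ``causal_repeats`` independent causal SNPs are
    simulated per cell and replicate and pooled, tightening the per-cell
    power estimate without changing the design.  ``fpr`` reports each
    design's rate of null statistics exceeding the theoretical
    chi-square(1) quantile at alpha.
    """
    if causal_specs is None:
        causal_specs = [(maf, rr) for rr in (1.3, 1.5) for maf in (0.2, 0.4)]
    causal_specs = [tuple(c) for c in causal_specs]
    cells = list(dict.fromkeys(causal_specs))
    spec_list = [c for c in cells for _ in range(causal_repeats)]
    extra = (extra_control_pool if extra_control_pool is not None
             else (max(added_controls) if added_controls else 0))
    master = np.random.default_rng(seed)
    designs = ["matched", "unmatched"] + [f"unmatched+{a}" for a in added_controls]
    null_stats: dict[str, list[np.ndarray]] = {d: [] for d in designs}
    causal_stats: dict[str, list[np.ndarray]] = {d: [] for d in designs}

    def _scan(g, sample_idx, adjust_pcs):
        sub = g.subset_samples(sample_idx)
        cov = None
        if adjust_pcs:
            pca = run_pca(sub, n_components=n_pcs, svd="auto")
            cov = pca.scores
        return assoc_scan(sub, covariates=cov)

    for rep in range(replicates):
        s_m, s_u = master.integers(0, 2**31, size=2)
        cfg_m = CaseControlSimConfig(
            n_cases=n_cases, n_controls=n_controls,
            case_cluster_probs=case_cluster_probs,
            control_cluster_probs=case_cluster_probs,  # matched state
            null_snps=null_snps, causal_specs=spec_list,
            extra_control_pool=0, fst=fst, seed=int(s_m))
        g_m, _, causal_m = simulate_case_control(cfg_m)
        cfg_u = CaseControlSimConfig(
            n_cases=n_cases, n_controls=n_controls,
            case_cluster_probs=case_cluster_probs,
            control_cluster_probs=control_cluster_probs,
            null_snps=null_snps, causal_specs=spec_list,
            extra_control_pool=extra, fst=fst, seed=int(s_u))
        g_u, _, causal_u = simulate_case_control(cfg_u)

        base_n = n_cases + n_controls
        res_m = _scan(g_m, np.arange(base_n), adjust_pcs=False)
        _collect(res_m, causal_m, null_stats["matched"],
                 causal_stats["matched"])
        res_u = _scan(g_u, np.arange(base_n), adjust_pcs=True)
        _collect(res_u, causal_u, null_stats["unmatched"],
                 causal_stats["unmatched"])
        for a in added_controls:
            idx = np.arange(base_n + a)
            res_a = _scan(g_u, idx, adjust_pcs=True)
            _collect(res_a, causal_u, null_stats[f"unmatched+{a}"],
                     causal_stats[f"unmatched+{a}"])
        logger.info("power study: replicate %d/%d done", rep + 1, replicates)

    chi_alpha = stats.chi2.isf(alpha, 1)
    power_rows, fpr_rows, thresholds = [], [], {}
    for d in designs:
        nulls = np.concatenate(null_stats[d])
        thresholds[d] = float(np.quantile(nulls, 1.0 - alpha))
        fpr_rows.append({"design": d, "n_null": nulls.size,
                         "fpr_at_nominal": float(np.mean(nulls > chi_alpha)),
                         "empirical_threshold": thresholds[d]})
        cs = np.vstack(causal_stats[d])  # replicates x len(spec_list)
        for maf, rr in cells:
            cols = [j for j, c in enumerate(spec_list) if c == (maf, rr)]
            power_rows.append({
                "design": d, "maf": maf, "rr": rr,
                "power": float(np.mean(cs[:, cols] > thresholds[d]))})
    power = pd.DataFrame(power_rows)
    gains = []
    for maf, rr in cells:
        pm = power.query("design == 'matched' and maf == @maf and rr == @rr"
                         )["power"].iloc[0]
        pu = power.query("design == 'unmatched' and maf == @maf and rr == @rr"
                         )["power"].iloc[0]
        gains.append({"maf": maf, "rr": rr, "power_matched": pm,
                      "power_unmatched": pu, "gain_pct": 100.0 * (pm - pu)})
    return PowerStudyResult(power=power, fpr=pd.DataFrame(fpr_rows),
                            gains=pd.DataFrame(gains), alpha=alpha,
                            replicates=replicates)


def _collect(res, causal_flags, null_sink, causal_sink):
    """Split a scan's chi-squares into null and causal streams by SNP ID."""
    tab = res.table.set_index("snp")
    ordered_ids = tab.index.to_numpy()
    is_causal = np.asarray([sid.startswith("causal") for sid in ordered_ids])
    chis = tab["chisq"].to_numpy()
    ok = np.isfinite(chis)
    null_sink.append(chis[ok & ~is_causal])
    causal = tab.loc[is_causal, "chisq"]
    causal_sink.append(causal.to_numpy())


def stratification_lambdas(
    n_cases: int = 500,
    n_controls: int = 500,
    null_snps: int = 2000,
    fst: float = 0.01,
    seed: int = 0,
) -> dict[str, float]:
    """Genomic-control lambdas with and without within-cluster matching.

    Simulates an opposing-mixture case/control study (case cluster
    probabilities (0.4, 0.3, 0.2, 0.1) against (0.1, 0.2, 0.3, 0.4) for
    controls), then computes lambda for the unmatched unadjusted scan and
    for the scan restricted to frequency-matched controls (matched within
    the true clusters).  An extra control pool of the same size keeps the
    matched sample from collapsing.
    """
    from .gwas import match_controls

    cfg = CaseControlSimConfig(
        n_cases=n_cases, n_controls=n_controls,
        null_snps=null_snps, causal_specs=[],
        extra_control_pool=n_controls, fst=fst, seed=seed)
    g, clusters, _ = simulate_case_control(cfg)
    res_un = assoc_scan(g.subset_samples(np.arange(n_cases + n_controls)))
    plan = match_controls(g.samples, clusters, g.phenotype, seed=seed)
    keep_ids = set(plan.selected_controls)
    idx = [i for i, s in enumerate(g.samples)
           if g.phenotype[i] == "case" or s in keep_ids]
    res_m = assoc_scan(g.subset_samples(np.asarray(idx)))
    return {"lambda_unmatched": res_un.lambda_gc,
            "lambda_matched": res_m.lambda_gc,
            "n_matched_controls": len(plan.selected_controls)}
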