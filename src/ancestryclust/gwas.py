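"""Cluster-based case/control matching and per-SNP association scans.

Matching is frequency matching: controls are drawn within each ancestry
cluster so that every cluster's case:control ratio equals the overall
achievable ratio, which removes the allele-frequency confounding that
inflates association statistics when cases and controls have different
ancestry mixes.  The association model is the standard additive logistic
regression of case status on alternate-allele count, optionally with
covariates (e.g. leading principal components); residual stratification is
summarized by the genomic-control inflation factor

    lambda = median(observed 1-df chi-square) / 0.4549364,

the denominator being the median of the chi-square distribution with one
degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, annotate_stats

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 df.
CHI2_1_MEDIAN = 0.4549364


@dataclass
class MatchPlan:
    """Outcome of frequency matching controls to cases within clusters."""

    case_counts: dict[int, int]
    available_controls: dict[int, int]
    selected_controls: list[str]
    excluded_controls: list[str]
    target_ratio: float
    unmatched_case_clusters: list[int] = field(default_factory=list)

    def as_table(self) -> pd.DataFrame:
        clusters = sorted(set(self.case_counts) | set(self.available_controls))
        return pd.DataFrame({
            "cluster": clusters,
            "cases": [self.case_counts.get(c, 0) for c in clusters],
            "available_controls": [self.available_controls.get(c, 0)
                                   for c in clusters],
        })


@dataclass
class AssocTable:
    """Per-SNP association results plus the genomic-control factor."""

    table: pd.DataFrame  # snp, chr, pos, beta, odds_ratio, chisq, p, n_used, converged
    lambda_gc: float


def match_controls(
    sample_ids: list[str],
    clusters: np.ndarray,
    phenotype: list[str],
    pool: list[str] | None = None,
    seed: int = 0,
) -> MatchPlan:
    """Frequency-match controls to cases within ancestry clusters.

    The achievable overall control:case ratio r is the minimum over
    case-bearing clusters of (available controls)/(cases); each cluster's
    target control count is cases*r, allocated by largest-remainder
    rounding, and controls are sampled without replacement within the
    cluster under ``seed``.  Clusters without cases contribute no controls;
    clusters with cases but no candidate controls are flagged unmatched.
    """
    clusters = np.asarray(clusters)
    if len(sample_ids) != len(clusters) or len(sample_ids) != len(phenotype):
        raise ValueError("sample_ids, clusters and phenotype lengths differ")
    pheno = np.asarray(phenotype)
    is_case = pheno == "case"
    if pool is None:
        pool_idx = np.where(pheno == "control")[0]
    else:
        pool_set = set(pool)
        pool_idx = np.asarray([i for i, s in enumerate(sample_ids)
                               if s in pool_set and not is_case[i]])
    if is_case.sum() == 0:
        raise ValueError("no cases to match")
    labels = sorted(set(clusters.tolist()))
    case_counts = {c: int(np.sum(is_case & (clusters == c))) for c in labels}
    avail = {c: int(np.sum(clusters[pool_idx] == c)) for c in labels}
    unmatched = [c for c in labels if case_counts[c] > 0 and avail[c] == 0]
    for c in unmatched:
        logger.warning("cluster %s has %d cases but no candidate controls",
                       c, case_counts[c])
    matchable = [c for c in labels if case_counts[c] > 0 and avail[c] > 0]
    if not matchable:
        raise ValueError("no cluster has both cases and candidate controls")
    r = min(avail[c] / case_counts[c] for c in matchable)
    quotas = {c: case_counts[c] * r for c in matchable}
    floors = {c: int(np.floor(quotas[c] + 1e-9)) for c in matchable}
    total_target = int(round(sum(quotas.values())))
    remainder = total_target - sum(floors.values())
    by_frac = sorted(matchable, key=lambda c: (quotas[c] - floors[c], c),
                     reverse=True)
    targets = dict(floors)
    for c in by_frac[:remainder]:
        targets[c] += 1
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for c in matchable:
        members = pool_idx[clusters[pool_idx] == c]
        take = min(targets[c], len(members))
        chosen = rng.choice(members, size=take, replace=False)
        selected.extend(sample_ids[i] for i in np.sort(chosen))
    excluded = [sample_ids[i] for i in pool_idx
                if sample_ids[i] not in set(selected)]
    return MatchPlan(case_counts=case_counts, available_controls=avail,
                     selected_controls=selected, excluded_controls=excluded,
                     target_ratio=r, unmatched_case_clusters=unmatched)


# ---------------------------------------------------------------------------
# Batched additive logistic scan
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _logit_scan_chunk(
    y: np.ndarray, cov: np.ndarray, geno: np.ndarray, mask: np.ndarray,
    max_iter: int = 25, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-Raphson logistic fits for a chunk of SNPs sharing covariates.

    ``cov`` is (n, q) including the intercept; ``geno`` (n, s) with missing
    entries zeroed and excluded through ``mask`` (n, s) of 0/1 weights.
    Returns (beta_snp, wald_chisq, converged) each of length s.
    """
    n, q = cov.shape
    s = geno.shape[1]
    d = q + 1
    beta = np.zeros((s, d))
    # warm start: covariates-only fit (shared; per-SNP missingness only
    # perturbs it slightly), SNP coefficient 0
    b0 = np.zeros(q)
    for _ in range(20):
        mu0 = _sigmoid(cov @ b0)
        w0 = mu0 * (1 - mu0)
        grad0 = cov.T @ (y - mu0)
        hess0 = (cov * w0[:, None]).T @ cov
        try:
            step0 = np.linalg.solve(hess0, grad0)
        except np.linalg.LinAlgError:
            break
        b0 += step0
        if np.max(np.abs(step0)) < 1e-10:
            break
    beta[:, :q] = b0
    converged = np.zeros(s, dtype=bool)
    active = np.ones(s, dtype=bool)
    h = np.zeros((s, d, d))
    for _ in range(max_iter):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        b = beta[idx]
        g = geno[:, idx]
        mk = mask[:, idx]
        eta = cov @ b[:, :q].T + g * b[:, q][None, :]
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu) * mk
        r = (y[:, None] - mu) * mk
        grad = np.empty((idx.size, d))
        grad[:, :q] = r.T @ cov
        grad[:, q] = np.einsum("ns,ns->s", g, r)
        hq = np.einsum("np,ns,nq->spq", cov, w, cov, optimize=True)
        hx = np.einsum("ns,ns,np->sp", g, w, cov, optimize=True)
        hg = np.einsum("ns,ns,ns->s", g, w, g, optimize=True)
        hh = np.empty((idx.size, d, d))
        hh[:, :q, :q] = hq
        hh[:, :q, q] = hx
        hh[:, q, :q] = hx
        hh[:, q, q] = hg
        # small ridge keeps near-separated fits solvable
        hh[:, np.arange(d), np.arange(d)] += 1e-10
        try:
            delta = np.linalg.solve(hh, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack([np.linalg.lstsq(hh[i], grad[i], rcond=None)[0]
                              for i in range(idx.size)])
        step = np.clip(delta, -5.0, 5.0)
        beta[idx] += step
        h[idx] = hh
        done = np.max(np.abs(delta), axis=1) < tol
        diverged = np.max(np.abs(beta[idx]), axis=1) > 30.0
        converged[idx[done]] = True
        active[idx] = ~(done | diverged)
    # Wald variance of the SNP coefficient
    chisq = np.full(s, np.nan)
    for i in range(s):
        try:
            hinv = np.linalg.inv(h[i])
            var = hinv[q, q]
            if var > 0:
                chisq[i] = beta[i, q] ** 2 / var
        except np.linalg.LinAlgError:
            pass
    return beta[:, q], chisq, converged


def _logit_loglik(y, x, mask, beta):
    eta = x @ beta
    return float(np.sum(mask * (y * eta - np.logaddexp(0.0, eta))))


def _lrt_fallback(y, cov, g, mask) -> float:
    """Likelihood-ratio chi-square for a SNP whose Wald fit failed
    (e.g. complete separation); coefficients are bounded to keep the
    likelihood finite."""
    x_full = np.column_stack([cov, g])

    def _fit(x):
        b = np.zeros(x.shape[1])
        for _ in range(50):
            eta = x @ b
            mu = _sigmoid(eta)
            w = mu * (1 - mu) * mask + 1e-10
            grad = x.T @ ((y - mu) * mask)
            hess = (x * w[:, None]).T @ x
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            b = np.clip(b + np.clip(step, -5, 5), -15, 15)
            if np.max(np.abs(step)) < 1e-8:
                break
        return b

    b_full = _fit(x_full)
    b_null = _fit(cov)
    ll_full = _logit_loglik(y, x_full, mask, b_full)
    ll_null = _logit_loglik(y, cov, mask, b_null)
    return max(2.0 * (ll_full - ll_null), 0.0)


def assoc_scan(
    g: GenotypeMatrix,
    phenotype: list[str] | None = None,
    covariates: np.ndarray | None = None,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    chunk_size: int = 512,
) -> AssocTable:
    """Additive logistic association scan across all SNPs passing QC.

    Per SNP: logistic regression of case status on alternate-allele count
    (plus ``covariates``, if given; an intercept is always included), Wald
    chi-square and p-value.  Samples with a missing genotype are dropped
    per SNP.  SNPs failing QC (call rate <= ``min_call_rate`` or MAF <=
    ``min_maf``) are excluded; fits that do not converge fall back to a
    likelihood-ratio statistic and, when even that is unavailable, are
    excluded from the genomic-control factor.
    """
    from scipy import stats

    pheno = phenotype if phenotype is not None else g.phenotype
    if pheno is None:
        raise ValueError("no phenotype labels available")
    pheno = np.asarray(pheno)
    use = pheno != "unknown"
    y = (pheno[use] == "case").astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both cases and controls")
    calls = g.calls[use]
    g_ann = annotate_stats(
        GenotypeMatrix([g.samples[i] for i in np.where(use)[0]],
                       list(g.variants), calls))
    keep = [j for j, v in enumerate(g_ann.variants)
            if v.call_rate > min_call_rate and v.maf > min_maf]
    if covariates is not None:
        cov = np.column_stack([np.ones(len(y)),
                               np.asarray(covariates, float)[use]])
    else:
        cov = np.ones((len(y), 1))

    rows = []
    for start in range(0, len(keep), chunk_size):
        cols = keep[start:start + chunk_size]
        sub = calls[:, cols].astype(float)
        mask = (sub != MISSING).astype(float)
        sub[sub == MISSING] = 0.0
        beta, chisq, conv = _logit_scan_chunk(y, cov, sub, mask)
        for i, j in enumerate(cols):
            b, c2, ok = beta[i], chisq[i], bool(conv[i])
            if not ok or not np.isfinite(c2):
                c2 = _lrt_fallback(y, cov, sub[:, i], mask[:, i])
                ok = np.isfinite(c2)
            v = g.variants[j]
            rows.append({
                "snp": v.id, "chr": v.chromosome, "pos": v.position,
                "allele": v.alleles[1], "beta": b,
                "odds_ratio": float(np.exp(np.clip(b, -30, 30))),
                "chisq": c2,
                "p": float(stats.chi2.sf(c2, 1)) if np.isfinite(c2) else np.nan,
                "n_used": int(mask[:, i].sum()), "converged": ok,
            })
    table = pd.DataFrame(rows)
    ok_chisq = table.loc[table["converged"], "chisq"].to_numpy()
    lam = genomic_lambda(ok_chisq) if len(ok_chisq) else np.nan
    return AssocTable(table=table, lambda_gc=lam)


def genomic_lambda(chisq: np.ndarray) -> float:
    """Genomic-control inflation: median 1-df statistic over 0.4549364."""
    chisq = np.asarray(chisq, float)
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValueError("empty chi-square vector")
    return float(np.median(chisq) / CHI2_1_MEDIAN)


def qq_table(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p-values sorted ascending against uniform quantiles i/(n+1).
    """
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    p = np.sort(p)
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    return pd.DataFrame({"expected_neglog10": -np.log10(expected),
                         "observed_neglog10": -np.log10(p)})


def cluster_specific_effects(
    g: GenotypeMatrix,
    phenotype: list[str],
    clusters: np.ndarray,
    snp_id: str,
    min_cluster_size: int = 20,
) -> pd.DataFrame:
    """Per-cluster allele frequencies and additive logistic odds ratios.

    Each cluster gets its own logistic regression of case status on allele
    count; clusters below ``min_cluster_size`` or monomorphic within the
    cluster are reported as NA.  Used to examine locus heterogeneity.
    """
    from scipy import stats

    ids = g.variant_ids()
    if snp_id not in ids:
        raise KeyError(f"SNP {snp_id!r} not present")
    j = ids.index(snp_id)
    col = g.calls[:, j]
    pheno = np.asarray(phenotype)
    clusters = np.asarray(clusters)
    labels = sorted(set(clusters.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for c in labels:
        inc = (clusters == c) & (col != MISSING) & (pheno != "unknown")
        gi = col[inc].astype(float)
        yi = (pheno[inc] == "case").astype(float)
        freq_case = (gi[yi == 1].sum() / (2 * (yi == 1).sum())
                     if (yi == 1).any() else np.nan)
        freq_ctrl = (gi[yi == 0].sum() / (2 * (yi == 0).sum())
                     if (yi == 0).any() else np.nan)
        row = {"cluster": c, "n": int(inc.sum()),
               "freq_cases": freq_case, "freq_controls": freq_ctrl,
               "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan}
        poly = len(np.unique(gi)) > 1 and len(np.unique(yi)) > 1
        if inc.sum() >= min_cluster_size and poly:
            cov = np.ones((len(yi), 1))
            mask = np.ones(len(yi))
            beta, chisq, conv = _logit_scan_chunk(yi, cov, gi[:, None],
                                                  mask[:, None])
            if conv[0] and np.isfinite(chisq[0]) and chisq[0] > 0:
                se = abs(beta[0]) / np.sqrt(chisq[0])
                z = stats.norm.ppf(0.975)
                row["odds_ratio"] = float(np.exp(beta[0]))
                row["ci_low"] = float(np.exp(beta[0] - z * se))
                row["ci_high"] = float(np.exp(beta[0] + z * se))
        rows.append(row)
    return pd.DataFrame(rows)
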