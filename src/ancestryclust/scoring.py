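"""Cluster-number selection by a permutation-referenced Scoring Index.

For each candidate cluster count k, k-means is executed M times over the
informative principal components.  Each execution is scored on three
[0,1] criteria:

* **accuracy** — leave-one-out cross-validated agreement between the
  k-means labels and a linear discriminant model fit to them;
* **stability** — Rand agreement with one randomly chosen partner
  execution at the same k;
* **distance** — normalized between-cluster scatter B(C)/Total, where
  distances are squared Euclidean over the informative PCs.

Each criterion is referenced against the same quantity computed on a
random permutation of the labels (which preserves cluster sizes), via the
relative gain (obs - perm)/(1 - perm).  The Scoring Index SI_k is the mean
over executions of the mean of the three gains; its variance follows from
beta-distribution moment matching on the underlying counts, and a beta
95% CI around the maximum SI supports a parsimony rule: the optimal k is
the smallest k whose mean SI falls inside the CI of the maximizer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_KMEANS_RETRY_CAP = 5


@dataclass(frozen=True)
class ClusterExecution:
    """One k-means execution: labels in 1..k, numbered by first appearance."""

    k: int
    m: int
    assignment: np.ndarray
    seed: int
    degenerate: bool = False


@dataclass(frozen=True)
class DistanceDecomposition:
    """Pairwise squared-distance decomposition Total = W(C) + B(C)."""

    total: float
    within: float
    between: float
    between_normalized: float


@dataclass(frozen=True)
class RandCounts:
    """Pair-concordance counts behind the Rand statistic R = (S+D)/T."""

    same_same: int
    diff_diff: int
    total_pairs: int

    @property
    def rand(self) -> float:
        return (self.same_same + self.diff_diff) / self.total_pairs


@dataclass(frozen=True)
class MetricTriplet:
    """Observed and permuted accuracy/distance/stability for one (k, m).

    ``counts`` is ``(N, NA_O, NA_P, SST, SSB_O, SSB_P, NS, NS_O, NS_P)``:
    the sample size and correctly-predicted counts behind the accuracies,
    the total and between-cluster sums of squares behind the distances, and
    the pair totals and concordant-pair counts behind the stabilities.
    These back the beta-moment variance of the Scoring Index.
    """

    k: int
    m: int
    accuracy_obs: float
    accuracy_perm: float
    distance_obs: float
    distance_perm: float
    stability_obs: float
    stability_perm: float
    counts: tuple
    partner: int = -1

    def gains(self, floor: bool = True) -> tuple[float, float, float]:
        ga = relative_gain(self.accuracy_obs, self.accuracy_perm, floor=floor)
        gb = relative_gain(self.distance_obs, self.distance_perm, floor=floor)
        gs = relative_gain(self.stability_obs, self.stability_perm, floor=floor)
        return ga, gb, gs


@dataclass
class SiCurve:
    """Per-k Scoring Index summary plus the cluster-number selections.

    ``k_max_si`` maximizes the mean SI; ``k_optimal`` is the smallest k
    whose mean SI lies at or above the lower 95% beta confidence bound of
    the maximizer (parsimony rule).
    """

    k_values: np.ndarray
    si_mean: np.ndarray
    si_var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    beta_alpha: np.ndarray
    beta_beta: np.ndarray
    k_max_si: int = 0
    k_optimal: int = 0
    triplets: list[MetricTriplet] = field(default_factory=list)
    best_assignments: dict[int, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({
            "k": self.k_values, "si_mean": self.si_mean, "si_var": self.si_var,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(labels.shape, dtype=np.int32)
    nxt = 1
    for i, lab in enumerate(labels):
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def kmeans_execute(scores: np.ndarray, k: int, seed: int) -> ClusterExecution:
    """One Lloyd k-means execution with a single seeded k-means++ start.

    No multi-restart is performed within an execution: the M executions of
    the Scoring Index are the restarts, and their disagreement is the
    stability signal.  The k-means++ seeding keeps single-start executions
    reliable at the true cluster number (a pure random-point start falls
    into split/merge local optima often enough to destabilize the correct
    k, which masks the instability signal the index relies on) while the
    placement of surplus centers still varies between executions when k is
    too large.  Executions that come back with an empty cluster are retried
    with a fresh seed up to a small cap, then flagged degenerate.
    """
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds n_samples = {n}")
    attempt_seed = int(seed) % (2**31)
    for attempt in range(_KMEANS_RETRY_CAP + 1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                    tol=1e-6, algorithm="lloyd", random_state=attempt_seed)
        labels = km.fit_predict(scores)
        if len(np.unique(labels)) == k:
            return ClusterExecution(k=k, m=-1,
                                    assignment=_canonicalize(labels),
                                    seed=attempt_seed,
                                    degenerate=attempt > 0)
        attempt_seed = (attempt_seed + 7919) % (2**31)
    logger.warning("k-means degenerate after %d retries (k=%d)",
                   _KMEANS_RETRY_CAP, k)
    return ClusterExecution(k=k, m=-1, assignment=_canonicalize(labels),
                            seed=attempt_seed, degenerate=True)


def distance_decomposition(
    scores: np.ndarray, assignment: np.ndarray
) -> DistanceDecomposition:
    """Decompose total pairwise squared distance into within + between.

    d(x_i, x_i') is SQUARED Euclidean (no square root); W(C) sums d over
    same-cluster pairs and Total over all pairs, each with the 1/2
    double-counting factor; B(C) = Total - W(C).  Computed through the
    centroid identity (sum over ordered pairs of d equals 2n times the
    scatter about the mean), which is exact.
    """
    x = np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    a = np.asarray(assignment)
    n = x.shape[0]
    if a.shape[0] != n:
        raise ValueError("assignment length != sample count")
    total = float(n * ((x - x.mean(axis=0)) ** 2).sum())
    if total <= 0.0:
        raise ValueError("degenerate input: all points identical (Total = 0)")
    within = 0.0
    for lab in np.unique(a):
        xk = x[a == lab]
        within += float(len(xk) * ((xk - xk.mean(axis=0)) ** 2).sum())
    between = total - within
    return DistanceDecomposition(total=total, within=within, between=between,
                                 between_normalized=between / total)


def rand_index(a1: np.ndarray, a2: np.ndarray) -> RandCounts:
    """Exact Rand pair counts between two partitions of the same samples.

    S counts pairs together in both partitions, D pairs apart in both,
    T all unordered pairs; R = (S+D)/T.  Label-permutation invariant.
    """
    a1 = np.asarray(a1)
    a2 = np.asarray(a2)
    if a1.shape != a2.shape:
        raise ValueError("assignment length mismatch")
    n = a1.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    _, i1 = np.unique(a1, return_inverse=True)
    _, i2 = np.unique(a2, return_inverse=True)
    k1, k2 = i1.max() + 1, i2.max() + 1
    table = np.zeros((k1, k2), dtype=np.int64)
    np.add.at(table, (i1, i2), 1)

    def _c2(v):
        return int((v.astype(np.int64) * (v - 1) // 2).sum())

    t = n * (n - 1) // 2
    s = _c2(table.ravel())
    same1 = _c2(table.sum(axis=1))
    same2 = _c2(table.sum(axis=0))
    d = t - same1 - same2 + s
    return RandCounts(same_same=s, diff_diff=d, total_pairs=t)


def permute_labels(assignment: np.ndarray, seed: int) -> np.ndarray:
    """Uniform random permutation of the label vector (sizes preserved)."""
    rng = np.random.default_rng(seed)
    return np.asarray(assignment)[rng.permutation(len(assignment))]


def relative_gain(observed: float, permuted: float, floor: bool = True) -> float:
    """Gain of an observed [0,1] criterion over its permutation referent.

    (obs - perm)/(1 - perm); negative gains (observed worse than the
    permuted referent by chance) are floored at 0 by default so the
    Scoring Index stays in [0,1].
    """
    if not (0.0 <= observed <= 1.0 and 0.0 <= permuted <= 1.0):
        raise ValueError("observed and permuted must lie in [0,1]")
    if permuted >= 1.0:
        raise ValueError("permuted = 1 is a degenerate referent")
    gain = (observed - permuted) / (1.0 - permuted)
    return max(gain, 0.0) if floor else gain


# ---------------------------------------------------------------------------
# LOOCV linear-discriminant accuracy
# ---------------------------------------------------------------------------

def accuracy_loocv(
    scores: np.ndarray, assignment: np.ndarray
) -> tuple[float, int, int]:
    """Leave-one-out linear-discriminant accuracy of a cluster assignment.

    For every sample, a linear discriminant model (pooled within-class
    covariance, empirical class priors) is fit on the remaining samples and
    the held-out sample is predicted; the accuracy is the proportion
    predicted into their own cluster.  Returns ``(accuracy, N, NA)`` where
    NA is the number correctly predicted.

    Singleton clusters cannot be held out and recovered: their member
    counts as misclassified (with a warning).  Leave-one-out refits are
    exact but computed through rank-one downdates of the pooled scatter
    (Sherman-Morrison), so the cost is O(n p^2) rather than O(n^2 p^2).
    The scatter is ridge-regularized when ill-conditioned, as happens
    routinely under permuted labels.
    """
    x = np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    y_raw = np.asarray(assignment)
    n, p = x.shape
    if y_raw.shape[0] != n:
        raise ValueError("assignment length != sample count")
    classes, y = np.unique(y_raw, return_inverse=True)
    k = len(classes)
    counts = np.bincount(y, minlength=k)
    if (counts == 1).any():
        logger.warning("%d singleton cluster(s): members counted as "
                       "misclassified", int((counts == 1).sum()))
    means = np.zeros((k, p))
    for c in range(k):
        means[c] = x[y == c].mean(axis=0)
    v = x - means[y]
    s = v.T @ v
    tr = float(np.trace(s))
    if tr <= 0.0:
        s = s + np.eye(p)
    else:
        cond = np.linalg.cond(s)
        if not np.isfinite(cond) or cond > 1e8:
            s = s + (1e-6 * tr / p) * np.eye(p)
    sinv = np.linalg.inv(s)
    mm_diag = np.einsum("cp,pq,cq->c", means, sinv, means)
    nu = max(n - 1 - k, 1)  # pooled-covariance dof on the training set
    log_counts = np.log(counts.astype(float))
    correct = 0
    for c in range(k):
        nc = int(counts[c])
        if nc == 1:
            continue
        idx = np.where(y == c)[0]
        xc = x[idx]
        u = xc - means[c]
        f = nc / (nc - 1.0)
        w = u @ sinv
        uw = np.einsum("ij,ij->i", u, w)
        d = np.maximum(1.0 - f * uw, 1e-12)
        a = (xc @ sinv) @ means.T                     # x' Sinv mu_j
        b = w @ means.T                               # u' Sinv mu_j
        xw = np.einsum("ij,ij->i", xc, w)             # x' Sinv u
        fd = (f / d)[:, None]
        xm = a + fd * xw[:, None] * b                 # x' S_i^-1 mu_j
        qm = mm_diag[None, :] + fd * b**2             # mu_j' S_i^-1 mu_j
        # held-out class mean shifts to mu_c - u/(nc-1)
        xm_c = xm[:, c] - (xw / d) / (nc - 1)
        qm_c = (qm[:, c] - 2.0 * (b[:, c] / d) / (nc - 1)
                + (uw / d) / (nc - 1) ** 2)
        disc = nu * (xm - 0.5 * qm) + log_counts[None, :]
        disc[:, c] = nu * (xm_c - 0.5 * qm_c) + math.log(nc - 1.0)
        pred = np.argmax(disc, axis=1)
        correct += int((pred == c).sum())
    return correct / n, n, correct


# ---------------------------------------------------------------------------
# Scoring Index curve
# ---------------------------------------------------------------------------

def _beta_var_term(alpha: float, beta: float) -> float:
    """Variance of beta(alpha, beta); 0 when the moment-matched alpha is
    non-positive (observed below the permutation referent by chance)."""
    if alpha <= 0.0 or beta <= 0.0:
        return 0.0
    tot = alpha + beta
    return alpha * beta / (tot * tot * (tot + 1.0))


def _beta_ci(si: float, var: float) -> tuple[float, float, float, float]:
    """(ci_low, ci_high, alpha, beta) of the moment-matched beta."""
    if var < 1e-12 or si <= 0.0 or si >= 1.0:
        return si, si, math.nan, math.nan
    alpha = (1.0 - si) * si * si / var - si
    if alpha <= 0.0:
        return si, si, math.nan, math.nan
    beta = alpha * (1.0 - si) / si
    lo, hi = stats.beta.ppf([0.025, 0.975], alpha, beta)
    return float(lo), float(hi), alpha, beta


def scoring_index_curve(
    scores: np.ndarray,
    k_max: int,
    m_executions: int = 100,
    seed: int = 0,
    k_min: int = 2,
) -> SiCurve:
    """Run the full Scoring Index algorithm over k = k_min..k_max.

    For each k, M executions of k-means are scored on accuracy, stability
    and normalized between-cluster distance against per-execution permuted
    referents (one label permutation per execution; permuted stability is
    the Rand statistic between the two permuted partner assignments).
    Returns the per-k SI mean, beta-moment variance and 95% CI, all metric
    triplets, and for each k the assignment of the execution with the best
    k-means objective (largest between-cluster scatter).
    """
    x = np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k_max < 2 or k_max < k_min:
        raise ValueError("need k_max >= k_min >= 2")
    if k_max > n:
        raise ValueError("k_max exceeds n_samples")
    if m_executions < 2:
        raise ValueError("need at least 2 executions (stability partner)")
    master = np.random.default_rng(seed)
    sst = distance_decomposition(x, np.zeros(n, dtype=int)).total
    k_values, si_mean, si_var, ci_lo, ci_hi, b_a, b_b = [], [], [], [], [], [], []
    triplets: list[MetricTriplet] = []
    best_assignments: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        exec_seeds = master.integers(0, 2**31, size=m_executions)
        perm_seeds = master.integers(0, 2**31, size=m_executions)
        partner_rng = np.random.default_rng(master.integers(0, 2**31))
        executions, degenerate = [], 0
        for m in range(m_executions):
            ex = kmeans_execute(x, k, int(exec_seeds[m]))
            if ex.degenerate and len(np.unique(ex.assignment)) < k:
                degenerate += 1
            executions.append(ex.assignment)
        if degenerate == m_executions:
            logger.warning("all executions degenerate at k=%d; skipping", k)
            continue
        perms = [permute_labels(executions[m], int(perm_seeds[m]))
                 for m in range(m_executions)]
        # per-execution observed/permuted metrics
        na_o, na_p, ssb_o, ssb_p = [], [], [], []
        for m in range(m_executions):
            _, _, na = accuracy_loocv(x, executions[m])
            _, _, nap = accuracy_loocv(x, perms[m])
            na_o.append(na)
            na_p.append(nap)
            ssb_o.append(distance_decomposition(x, executions[m]).between)
            ssb_p.append(distance_decomposition(x, perms[m]).between)
        ns = n * (n - 1) // 2
        si_terms, var_terms = [], []
        for m in range(m_executions):
            partner = int(partner_rng.integers(0, m_executions - 1))
            if partner >= m:
                partner += 1
            rc_o = rand_index(executions[m], executions[partner])
            rc_p = rand_index(perms[m], perms[partner])
            ns_o = rc_o.same_same + rc_o.diff_diff
            ns_p = rc_p.same_same + rc_p.diff_diff
            trip = MetricTriplet(
                k=k, m=m,
                accuracy_obs=na_o[m] / n, accuracy_perm=na_p[m] / n,
                distance_obs=ssb_o[m] / sst, distance_perm=ssb_p[m] / sst,
                stability_obs=ns_o / ns, stability_perm=ns_p / ns,
                counts=(n, na_o[m], na_p[m], sst, ssb_o[m], ssb_p[m],
                        ns, ns_o, ns_p),
                partner=partner,
            )
            triplets.append(trip)
            ga, gb, gs = trip.gains(floor=True)
            si_terms.append((ga + gb + gs) / 3.0)
            var_terms.append(
                _beta_var_term(na_o[m] - na_p[m], n - na_o[m])
                + _beta_var_term(ssb_o[m] - ssb_p[m], sst - ssb_o[m])
                + _beta_var_term(ns_o - ns_p, ns - ns_o))
        si = float(np.mean(si_terms))
        # dispersion band of a single execution's score (mean per-execution
        # beta variance / 9), NOT the variance of the M-execution mean: the
        # parsimony rule needs a tolerance band of the score's intrinsic
        # spread, and the variance of the mean vanishes as M grows, which
        # would collapse the optimal rule onto the maximum rule
        var = float(np.sum(var_terms)) / (m_executions * 9.0)
        lo, hi, al, be = _beta_ci(si, var)
        k_values.append(k)
        si_mean.append(si)
        si_var.append(var)
        ci_lo.append(lo)
        ci_hi.append(hi)
        b_a.append(al)
        b_b.append(be)
        best_assignments[k] = executions[int(np.argmax(ssb_o))]
    curve = SiCurve(
        k_values=np.asarray(k_values), si_mean=np.asarray(si_mean),
        si_var=np.asarray(si_var), ci_low=np.asarray(ci_lo),
        ci_high=np.asarray(ci_hi), beta_alpha=np.asarray(b_a),
        beta_beta=np.asarray(b_b), triplets=triplets,
        best_assignments=best_assignments, seed=seed,
    )
    curve.k_max_si, curve.k_optimal = select_optimal_k(curve)
    return curve


def select_optimal_k(curve: SiCurve) -> tuple[int, int]:
    """(k_max_si, k_optimal) from an SI curve.

    k_max_si maximizes the mean SI; k_optimal is the smallest k whose mean
    SI is at or above the lower 95% CI bound of k_max_si (parsimony rule).
    """
    if len(curve.k_values) == 0:
        raise ValueError("empty SI curve")
    i_max = int(np.argmax(curve.si_mean))
    k_max_si = int(curve.k_values[i_max])
    lo = curve.ci_low[i_max]
    inside = np.where(curve.si_mean >= lo)[0]
    k_optimal = int(curve.k_values[inside[0]]) if len(inside) else k_max_si
    return k_max_si, min(k_optimal, k_max_si)
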