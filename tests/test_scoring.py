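"""Scoring Index machinery: metrics, referents, variance and k selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ancestryclust import (
    accuracy_loocv,
    distance_decomposition,
    kmeans_execute,
    permute_labels,
    rand_index,
    relative_gain,
    scoring_index_curve,
    select_optimal_k,
)
from ancestryclust.scoring import SiCurve


# ---------------------------------------------------------------------------
# Rand statistic
# ---------------------------------------------------------------------------

def _brute_rand(a1, a2):
    n = len(a1)
    s = d = t = 0
    for i, j in itertools.combinations(range(n), 2):
        t += 1
        same1, same2 = a1[i] == a1[j], a2[i] == a2[j]
        s += same1 and same2
        d += (not same1) and (not same2)
    return s, d, t


def _all_partitions(n):
    """Every set partition of range(n), as a label vector."""
    if n == 0:
        yield []
        return
    for part in _all_partitions(n - 1):
        k = max(part, default=-1) + 1
        for lab in range(k + 1):
            yield part + [lab]


def test_rand_trivial_and_label_invariance():
    assert rand_index([1, 1, 2, 2], [1, 1, 2, 2]).rand == 1.0
    assert rand_index([1, 1, 2, 2], [2, 2, 1, 1]).rand == 1.0
    rc = rand_index([1, 1, 2, 2], [1, 2, 1, 2])
    assert (rc.same_same, rc.diff_diff, rc.total_pairs) == (0, 2, 6)
    assert rc.rand == pytest.approx(1 / 3)


def test_rand_equals_pair_enumeration_exhaustively():
    """Every partition pair of <=5 items, and every partition of 8 items
    against sampled partners, agrees with brute-force pair enumeration."""
    for n in (3, 5):
        parts = [p for p in _all_partitions(n)]
        for a1, a2 in itertools.product(parts, parts):
            rc = rand_index(a1, a2)
            assert (rc.same_same, rc.diff_diff, rc.total_pairs) == \
                _brute_rand(a1, a2)
    rng = np.random.default_rng(0)
    parts8 = [p for p in _all_partitions(8)]
    partners = rng.integers(0, len(parts8), size=(len(parts8), 2))
    for i, p1 in enumerate(parts8):
        for j in partners[i]:
            rc = rand_index(p1, parts8[j])
            assert (rc.same_same, rc.diff_diff, rc.total_pairs) == \
                _brute_rand(p1, parts8[j])


# ---------------------------------------------------------------------------
# Distance decomposition
# ---------------------------------------------------------------------------

def test_distance_decomposition_hand_examples():
    d = distance_decomposition(np.array([0.0, 2.0]), np.array([1, 2]))
    assert (d.total, d.within, d.between) == (4.0, 0.0, 4.0)
    assert d.between_normalized == 1.0
    d = distance_decomposition(np.array([0.0, 1.0, 10.0]), np.array([1, 1, 2]))
    assert d.total == pytest.approx(182.0)
    assert d.within == pytest.approx(1.0)
    assert d.between == pytest.approx(181.0)
    assert d.between_normalized == pytest.approx(181 / 182)
    # single cluster: between 0
    d = distance_decomposition(np.array([0.0, 1.0, 10.0]), np.array([1, 1, 1]))
    assert d.between == pytest.approx(0.0, abs=1e-9)


def test_distance_decomposition_degenerate_input():
    with pytest.raises(ValueError, match="degenerate"):
        distance_decomposition(np.ones((4, 2)), np.array([1, 1, 2, 2]))


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=10_000))
def test_within_plus_between_equals_total(seed):
    """Conservation W + B = Total on random inputs and partitions."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 30))
    x = rng.normal(size=(n, int(rng.integers(1, 4))))
    a = rng.integers(1, int(rng.integers(2, 6)) + 1, size=n)
    d = distance_decomposition(x, a)
    assert d.within + d.between == pytest.approx(d.total, rel=1e-8)
    assert 0.0 <= d.between_normalized <= 1.0


def test_between_non_decreasing_under_refinement():
    """Splitting a cluster cannot decrease the between-cluster scatter."""
    rng = np.random.default_rng(4)
    x = rng.normal(size=(30, 2))
    a = np.array([1] * 15 + [2] * 15)
    refined = a.copy()
    refined[:7] = 3  # split cluster 1
    assert distance_decomposition(x, refined).between >= \
        distance_decomposition(x, a).between


# ---------------------------------------------------------------------------
# LOOCV accuracy
# ---------------------------------------------------------------------------

def _naive_loocv(x, y):
    """Independent oracle: refit the discriminant model for every holdout."""
    classes, yi = np.unique(y, return_inverse=True)
    n, p = x.shape
    k = len(classes)
    counts_full = np.bincount(yi, minlength=k)
    correct = 0
    for i in range(n):
        if counts_full[yi[i]] == 1:
            continue  # singleton cannot be recovered
        tr = np.delete(np.arange(n), i)
        xt, yt = x[tr], yi[tr]
        cts = np.bincount(yt, minlength=k)
        means = np.vstack([xt[yt == c].mean(0) for c in range(k)])
        v = xt - means[yt]
        s = v.T @ v
        trace = np.trace(s)
        if trace <= 0:
            s = s + np.eye(p)
        elif np.linalg.cond(s) > 1e8:
            s = s + (1e-6 * trace / p) * np.eye(p)
        nu = max(n - 1 - k, 1)
        sinv = np.linalg.inv(s)
        disc = [nu * (x[i] @ sinv @ means[c] - 0.5 * means[c] @ sinv @ means[c])
                + math.log(cts[c]) for c in range(k)]
        correct += int(np.argmax(disc) == yi[i])
    return correct / n, n, correct


@pytest.mark.parametrize("seed,k", [(0, 2), (1, 3), (2, 4), (3, 3)])
def test_loocv_matches_refit_oracle(seed, k):
    """Downdated LOOCV equals a naive refit-per-holdout on 20-sample toys,
    for both structured and randomly permuted labels."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(20, 3))
    y = rng.integers(1, k + 1, size=20)
    assert accuracy_loocv(x, y) == _naive_loocv(x, y)
    # labels decoupled from geometry (the permuted-referent regime)
    yp = permute_labels(y, seed=seed + 100)
    assert accuracy_loocv(x, yp) == _naive_loocv(x, yp)


def test_loocv_separated_clouds_perfect():
    rng = np.random.default_rng(8)
    x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(10, 0.1, (10, 2))])
    y = np.array([1] * 10 + [2] * 10)
    acc, n, na = accuracy_loocv(x, y)
    assert (acc, n, na) == (1.0, 20, 20)


def test_loocv_random_labels_near_chance():
    """Random labels on a homogeneous cloud predict near 1/k."""
    rng = np.random.default_rng(15)
    accs = []
    for rep in range(30):
        x = rng.normal(size=(60, 2))
        y = rng.integers(1, 4, size=60)  # k = 3 balanced in expectation
        accs.append(accuracy_loocv(x, y)[0])
    assert np.mean(accs) == pytest.approx(1 / 3, abs=0.06)


def test_loocv_singleton_counted_misclassified():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(10, 2))
    y = np.array([1] * 9 + [2])
    acc, n, na = accuracy_loocv(x, y)
    assert n == 10 and na <= 9


# ---------------------------------------------------------------------------
# Permutation and gains
# ---------------------------------------------------------------------------

def test_permute_labels_sizes_and_determinism():
    a = np.array([1] * 3 + [2] * 5 + [3] * 2)
    p1 = permute_labels(a, seed=11)
    p2 = permute_labels(a, seed=11)
    np.testing.assert_array_equal(p1, p2)
    assert sorted(np.bincount(p1)[1:]) == [2, 3, 5]


def test_permute_labels_uniformity():
    """Each position's label distribution matches overall frequencies."""
    a = np.array([1] * 30 + [2] * 50 + [3] * 20)
    counts = np.zeros((len(a), 3))
    for s in range(400):
        p = permute_labels(a, seed=s)
        for lab in (1, 2, 3):
            counts[:, lab - 1] += p == lab
    freq = counts / 400
    np.testing.assert_allclose(freq.mean(axis=0), [0.3, 0.5, 0.2], atol=0.01)
    from scipy import stats
    expected = np.array([0.3, 0.5, 0.2]) * 400
    chi = ((counts - expected) ** 2 / expected).sum(axis=1)
    # 100 positions, 2 df each: no position wildly off
    assert np.mean(chi) < 4.0


def test_relative_gain_arithmetic():
    assert relative_gain(0.5, 0.5) == 0.0
    assert relative_gain(1.0, 0.7) == pytest.approx(1.0)
    assert relative_gain(0.9, 0.5) == pytest.approx(0.8)
    assert relative_gain(0.3, 0.5) == 0.0  # floored
    assert relative_gain(0.3, 0.5, floor=False) == pytest.approx(-0.4)
    with pytest.raises(ValueError):
        relative_gain(0.5, 1.0)


# ---------------------------------------------------------------------------
# k-means executions
# ---------------------------------------------------------------------------

def test_kmeans_separable_and_canonical():
    rng = np.random.default_rng(2)
    x = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(10, 0.2, (15, 2))])
    ex = kmeans_execute(x, k=2, seed=0)
    assert ex.assignment[0] == 1  # first-appearance numbering
    np.testing.assert_array_equal(ex.assignment[:15], 1)
    np.testing.assert_array_equal(ex.assignment[15:], 2)


def test_kmeans_k_equals_n():
    x = np.arange(6, dtype=float)[:, None] * 10
    ex = kmeans_execute(x, k=6, seed=3)
    assert len(np.unique(ex.assignment)) == 6
    assert distance_decomposition(x, ex.assignment).within == pytest.approx(0.0)
    with pytest.raises(ValueError):
        kmeans_execute(x, k=7, seed=0)


# ---------------------------------------------------------------------------
# Scoring Index curve
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def si_inputs():
    rng = np.random.default_rng(77)
    centers = np.array([[0, 0], [8, 0], [0, 8]], float)
    x = np.vstack([c + rng.normal(0, 0.7, (40, 2)) for c in centers])
    truth = np.repeat([1, 2, 3], 40)
    return x, truth


def test_scoring_curve_recovers_k_and_is_reproducible(si_inputs):
    x, truth = si_inputs
    c1 = scoring_index_curve(x, k_max=5, m_executions=8, seed=123)
    c2 = scoring_index_curve(x, k_max=5, m_executions=8, seed=123)
    np.testing.assert_array_equal(c1.si_mean, c2.si_mean)
    np.testing.assert_array_equal(c1.best_assignments[3],
                                  c2.best_assignments[3])
    assert c1.k_max_si == 3 and c1.k_optimal == 3
    assert rand_index(c1.best_assignments[3], truth).rand == 1.0
    assert ((c1.si_mean >= 0) & (c1.si_mean <= 1)).all()


def test_triplet_counts_reproduce_metrics(si_inputs):
    """(N, NA, SST, SSB, NS, ...) regenerate the six metric values."""
    x, _ = si_inputs
    curve = scoring_index_curve(x, k_max=4, m_executions=5, seed=9)
    for t in curve.triplets:
        n, na_o, na_p, sst, ssb_o, ssb_p, ns, ns_o, ns_p = t.counts
        assert t.accuracy_obs == pytest.approx(na_o / n, abs=1e-10)
        assert t.accuracy_perm == pytest.approx(na_p / n, abs=1e-10)
        assert t.distance_obs == pytest.approx(ssb_o / sst, abs=1e-10)
        assert t.distance_perm == pytest.approx(ssb_p / sst, abs=1e-10)
        assert t.stability_obs == pytest.approx(ns_o / ns, abs=1e-10)
        assert t.stability_perm == pytest.approx(ns_p / ns, abs=1e-10)
        for v in (t.accuracy_obs, t.accuracy_perm, t.distance_obs,
                  t.distance_perm, t.stability_obs, t.stability_perm):
            assert 0.0 <= v <= 1.0


def test_permuted_referents_behave(si_inputs):
    """Permuted accuracy ~ 1/k on balanced clusters; permuted distance
    below observed for genuinely clustered data."""
    x, _ = si_inputs
    curve = scoring_index_curve(x, k_max=3, k_min=3, m_executions=10, seed=4)
    acc_p = np.mean([t.accuracy_perm for t in curve.triplets])
    assert acc_p == pytest.approx(1 / 3, abs=0.08)
    assert np.mean([t.distance_perm for t in curve.triplets]) < \
        np.mean([t.distance_obs for t in curve.triplets])


def _curve(ks, sis, ci_low_max):
    ks = np.asarray(ks)
    sis = np.asarray(sis)
    ci_low = np.full(len(ks), np.nan)
    ci_low[np.argmax(sis)] = ci_low_max
    return SiCurve(k_values=ks, si_mean=sis, si_var=np.zeros(len(ks)),
                   ci_low=ci_low, ci_high=np.full(len(ks), np.nan),
                   beta_alpha=np.zeros(len(ks)), beta_beta=np.zeros(len(ks)))


def test_select_optimal_k_parsimony_rule():
    """The smallest k whose mean lies inside the maximizer's 95% CI wins:
    means (0.85, 0.879, 0.886) at k=(7,9,11) with CI low 0.876 -> k=9."""
    k_max_si, k_opt = select_optimal_k(_curve([7, 9, 11],
                                              [0.85, 0.879, 0.886], 0.876))
    assert (k_max_si, k_opt) == (11, 9)
    # tight CI excluding the rest: the maximizer itself
    k_max_si, k_opt = select_optimal_k(_curve([2, 3, 4],
                                              [0.5, 0.9, 0.6], 0.895))
    assert (k_max_si, k_opt) == (3, 3)
    # flat curve, everyone inside: smallest k
    k_max_si, k_opt = select_optimal_k(_curve([2, 3, 4],
                                              [0.88, 0.881, 0.882], 0.7))
    assert (k_max_si, k_opt) == (4, 2)
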