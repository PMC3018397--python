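"""Genotype-standardized PCA and diagnostics for choosing informative PCs.

The standardization is the one used for ancestry PCA of SNP data: each SNP
column has missing calls mean-imputed, is mean-centered, and is divided by
sqrt(p(1-p)) where p is the sample alternate-allele frequency — the binomial
standard deviation of a single allele draw.  Leading components of the
standardized matrix capture ancestry gradients; how many are "informative"
is a user decision guided by a scree table of log-eigenvalues and a
row-standardized, hierarchically ordered heatmap table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Scores, eigenvalues and loadings of a genotype PCA.

    ``scores[:, j]`` is the j-th principal component, ordered by descending
    eigenvalue; ``eigenvalues`` are the variances of the components
    (singular values squared over n-1); ``loadings`` are the per-SNP weights
    of the retained (polymorphic) SNPs.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    n_components: int
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.scores.shape[1] != self.n_components:
            raise ValueError("scores column count != n_components")
        ev = np.asarray(self.eigenvalues, float)
        if (ev < -1e-12).any() or (np.diff(ev) > 1e-9 * max(1.0, ev[0])).any():
            raise ValueError("eigenvalues must be non-negative, non-increasing")


def standardize_genotypes(
    g: GenotypeMatrix, scaling: str = "binomial"
) -> np.ndarray:
    """Standardized real-valued matrix for PCA.

    Per SNP: impute missing calls to the SNP mean, center, and scale by
    sqrt(p(1-p)) with p = (alternate-allele count)/(2 * n_non-missing)
    (``scaling="binomial"``) or by the sample standard deviation
    (``scaling="unit"``).  Monomorphic SNPs are dropped with a warning.
    """
    if g.n_samples < 2 or g.n_variants < 2:
        raise ValueError("need at least 2 samples and 2 variants")
    if scaling not in ("binomial", "unit"):
        raise ValueError(f"unknown scaling {scaling!r}")
    calls = g.calls.astype(float)
    calls[g.calls == MISSING] = np.nan
    n_called = np.sum(~np.isnan(calls), axis=0)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(calls, axis=0)
    p = col_mean / 2.0
    poly = (n_called > 0) & (p > 0.0) & (p < 1.0)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic SNPs")
    if poly.sum() < g.n_variants:
        logger.warning("dropping %d monomorphic SNPs", g.n_variants - poly.sum())
    calls = calls[:, poly]
    col_mean = col_mean[poly]
    p = p[poly]
    # mean imputation, then center
    inds = np.where(np.isnan(calls))
    calls[inds] = np.take(col_mean, inds[1])
    calls -= col_mean
    if scaling == "binomial":
        scale = np.sqrt(p * (1.0 - p))
    else:
        scale = calls.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
    return calls / scale


def run_pca(
    g: GenotypeMatrix, n_components: int, scaling: str = "binomial",
    svd: str = "full",
) -> PcaResult:
    """PCA of the standardized genotype matrix via SVD.

    Deterministic up to per-component sign; the sign is fixed so that the
    largest-magnitude loading of each component is positive.  ``svd`` may
    be "full" (exact), "randomized" (seeded randomized SVD, accurate for a
    small number of leading components) or "auto" (randomized when the
    matrix is large and few components are requested).
    """
    x = standardize_genotypes(g, scaling=scaling)
    n, m = x.shape
    if n_components > min(n, m):
        raise ValueError(
            f"n_components {n_components} > min(n_samples, n_snps) = {min(n, m)}")
    if svd == "auto":
        svd = ("randomized"
               if min(n, m) > 300 and n_components <= 20 else "full")
    if svd == "randomized":
        from sklearn.utils.extmath import randomized_svd

        u, s, vt = randomized_svd(x, n_components=n_components,
                                  n_oversamples=10, n_iter=7, random_state=0)
    elif svd == "full":
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    else:
        raise ValueError(f"unknown svd mode {svd!r}")
    # sign convention: largest-|.| loading positive
    flip = np.sign(vt[np.arange(n_components),
                      np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    u = u * flip
    vt = vt * flip[:, None]
    eigenvalues = s**2 / (n - 1)
    poly_ids = None
    if g.variants:
        calls = g.calls.astype(float)
        calls[g.calls == MISSING] = np.nan
        pfreq = np.nanmean(calls, axis=0) / 2.0
        keep = np.where(~np.isnan(pfreq) & (pfreq > 0) & (pfreq < 1))[0]
        poly_ids = [g.variants[j].id for j in keep]
    return PcaResult(scores=u * s, eigenvalues=eigenvalues, loadings=vt.T,
                     n_components=n_components, snp_ids=poly_ids)


def scree_table(p: PcaResult) -> pd.DataFrame:
    """Log-eigenvalue scree with an advisory elbow suggestion.

    Columns: component (1-based), log_eigenvalue, first_difference.  The
    attached ``elbow`` attribute suggests the component after which the
    curve straightens (maximizer of the second difference of the log
    eigenvalues); ``elbow_low_confidence`` flags a flat scree where the
    suggestion should not be trusted.  Both are advisory: the number of
    informative PCs is a user decision.
    """
    if p.n_components < 2:
        raise ValueError("need >= 2 components for a scree table")
    ev = np.asarray(p.eigenvalues, float)
    logev = np.log(np.maximum(ev, np.finfo(float).tiny))
    first_diff = np.full(len(ev), np.nan)
    first_diff[1:] = np.diff(logev)
    df = pd.DataFrame({
        "component": np.arange(1, len(ev) + 1),
        "log_eigenvalue": logev,
        "first_difference": first_diff,
    })
    if len(ev) >= 3:
        second = np.diff(logev, n=2)  # second[i] ~ curvature at component i+2
        elbow = int(np.argmax(second) + 2)
        # a real kink bends the log-eigenvalue curve by a sizable amount;
        # sampling noise on a structureless spectrum stays well below 0.1
        low_conf = bool(second.max() < 0.1)
    else:
        elbow = 1
        low_conf = True
    df.attrs["elbow"] = elbow
    df.attrs["elbow_low_confidence"] = low_conf
    return df


def heatmap_table(p: PcaResult, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized scores ordered by hierarchical clustering.

    Each sample's first ``n_pcs`` scores are standardized to mean 0, sd 1
    across the row; rows are ordered by average-linkage agglomerative
    clustering of the standardized rows under Euclidean distance.  Returns
    ``(values, row_order)`` where ``values[i] = standardized[row_order[i]]``.
    """
    if n_pcs < 2:
        raise ValueError("n_pcs must be >= 2 (row sd undefined for 1 value)")
    if n_pcs > p.n_components:
        raise ValueError("n_pcs > available components")
    x = np.asarray(p.scores[:, :n_pcs], float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    order = np.asarray(leaves_list(linkage(z, method="average",
                                           metric="euclidean")))
    return z[order], order


def write_eigen(p: PcaResult, scores_path, values_path,
                sample_ids: list[str] | None = None) -> None:
    """Write whitespace-delimited .eigenvec/.eigenval-style text files."""
    n = p.scores.shape[0]
    ids = sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)]
    with open(scores_path, "w") as fh:
        for i in range(n):
            fh.write(" ".join([str(ids[i])]
                              + [f"{v:.6g}" for v in p.scores[i]]) + "\n")
    with open(values_path, "w") as fh:
        for ev in p.eigenvalues:
            fh.write(f"{ev:.6g}\n")
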