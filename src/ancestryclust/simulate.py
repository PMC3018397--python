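"""Synthetic genotype data: unstructured, Fst-structured, and case/control.

The structured model is a Balding-Nichols-style divergence model: for each
SNP a founder allele frequency p is drawn uniformly (default U(0.05, 0.50));
each of K clusters then receives its own frequency

    p_k ~ Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst),

which has mean p and variance Fst p(1-p).  Genotypes within a cluster are
drawn from the frequency vector

    ( Fst(1-p_k) + (1-Fst)(1-p_k)^2,
      2(1-Fst) p_k (1-p_k),
      Fst p_k + (1-Fst) p_k^2 )

for 0/1/2 copies of the alternate allele — Hardy-Weinberg proportions with
an inbreeding-style excess-homozygosity term of size Fst.  The default
Fst = 0.01 approximates the divergence among European subpopulations.

The case/control model confounds ancestry with phenotype through different
cluster-membership probability vectors for cases and controls.  Causal
SNPs multiply the control genotype frequencies by (1, R, R^2) — R the
per-allele relative risk — and renormalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, VariantRecord, make_genotype_matrix


@dataclass
class StructureSimConfig:
    """Conditions for the Fst-structured cluster model."""

    n_samples: int = 1000
    n_snps: int = 10_000
    n_clusters: int = 2
    fst: float = 0.01
    founder_freq_range: tuple[float, float] = (0.05, 0.50)
    cluster_sizes: list[int] | str = "equal"  # explicit | equal | random_min5pct
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0,1)")
        lo, hi = self.founder_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("founder_freq_range must be within (0,1)")
        if isinstance(self.cluster_sizes, (list, tuple)):
            sizes = list(self.cluster_sizes)
            if sum(sizes) != self.n_samples:
                raise ValueError("explicit cluster sizes must sum to n_samples")
            if len(sizes) != self.n_clusters:
                raise ValueError("explicit cluster sizes length != n_clusters")


@dataclass
class CaseControlSimConfig:
    """Conditions for the confounded case/control study.

    Defaults follow the power-study design: 2000 cases and 2000 controls
    from 4 clusters; when ``control_cluster_probs`` differs from
    ``case_cluster_probs`` (the defaults oppose each other), ancestry
    confounds the phenotype.
    """

    n_cases: int = 2000
    n_controls: int = 2000
    case_cluster_probs: tuple = (0.4, 0.3, 0.2, 0.1)
    control_cluster_probs: tuple = (0.1, 0.2, 0.3, 0.4)
    null_snps: int = 10_000
    causal_specs: list[tuple[float, float]] = field(default_factory=lambda: [
        (maf, rr) for rr in (1.2, 1.3, 1.4, 1.5)
        for maf in (0.1, 0.2, 0.3, 0.4, 0.5)])
    extra_control_pool: int = 0
    fst: float = 0.01
    founder_freq_range: tuple[float, float] = (0.05, 0.50)
    literal_case_hom: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for probs in (self.case_cluster_probs, self.control_cluster_probs):
            p = np.asarray(probs, float)
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("cluster probabilities must be a simplex point")
        if len(self.case_cluster_probs) != len(self.control_cluster_probs):
            raise ValueError("case/control cluster-probability lengths differ")
        for maf, rr in self.causal_specs:
            if not 0.0 < maf <= 0.5:
                raise ValueError("causal maf must be in (0, 0.5]")
            if rr < 1.0:
                raise ValueError("relative risk must be >= 1")


# ---------------------------------------------------------------------------
# Genotype-frequency building blocks
# ---------------------------------------------------------------------------

def control_genotype_freqs(fst: float, pk: np.ndarray) -> np.ndarray:
    """(..., 3) genotype frequencies of the structured (null/control) model."""
    pk = np.asarray(pk, float)
    q = 1.0 - pk
    f = np.stack([fst * q + (1 - fst) * q**2,
                  2 * (1 - fst) * pk * q,
                  fst * pk + (1 - fst) * pk**2], axis=-1)
    return f


def case_genotype_freqs(
    fst: float, pk: np.ndarray, rr: float, literal_hom: bool = False
) -> np.ndarray:
    """Renormalized case genotype frequencies for a causal SNP.

    The heterozygote frequency carries one factor of the relative risk R
    and the alternate homozygote R^2 times the control homozygote
    frequency Fst p_k + (1-Fst) p_k^2.  ``literal_hom=True`` instead uses
    R^2 (Fst p_k + (1-Fst) p_k) for the homozygote term.
    """
    pk = np.asarray(pk, float)
    q = 1.0 - pk
    hom_ctrl = fst * pk + (1 - fst) * (pk if literal_hom else pk**2)
    f = np.stack([fst * q + (1 - fst) * q**2,
                  2 * rr * (1 - fst) * pk * q,
                  rr**2 * hom_ctrl], axis=-1)
    return f / f.sum(axis=-1, keepdims=True)


def draw_cluster_freqs(
    rng: np.random.Generator, p: np.ndarray, fst: float, k: int
) -> np.ndarray:
    """Per-cluster allele frequencies p_k ~ Beta(a, b), shape (k, n_snps)."""
    if fst <= 1e-8:
        raise ValueError("fst too close to 0: beta parameters degenerate")
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a[None, :], b[None, :], size=(k, len(p)))


def _draw_genotypes(rng: np.random.Generator, freqs: np.ndarray,
                    n: int) -> np.ndarray:
    """Draw n samples x n_snps additive genotypes from (n_snps, 3) freqs."""
    u = rng.random((n, freqs.shape[0]))
    c0 = freqs[:, 0][None, :]
    c1 = c0 + freqs[:, 1][None, :]
    return (u >= c0).astype(np.int8) + (u >= c1).astype(np.int8)


def _variant_records(n: int, prefix: str = "snp") -> list[VariantRecord]:
    return [VariantRecord(id=f"{prefix}{j}", chromosome="1", position=j + 1,
                          alleles=("A", "C")) for j in range(n)]


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def simulate_null(
    n_samples: int = 2000,
    n_snps: int = 100_000,
    freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> GenotypeMatrix:
    """Unstructured genotypes: per-SNP p ~ U(freq_range), HWE genotypes.

    Every individual draws i.i.d. from ((1-p)^2, 2p(1-p), p^2); there is no
    population substructure and no missingness.
    """
    lo, hi = freq_range
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("freq_range must be within (0,1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    freqs = np.stack([(1 - p)**2, 2 * p * (1 - p), p**2], axis=-1)
    calls = _draw_genotypes(rng, freqs, n_samples)
    samples = [f"S{i}" for i in range(n_samples)]
    return make_genotype_matrix(samples, _variant_records(n_snps), calls)


def assign_cluster_sizes(
    n_samples: int, k: int, mode: str = "equal", seed: int = 0
) -> np.ndarray:
    """Cluster sizes under the equal or random-minimum-5% scenario.

    ``equal``: ceil(n/k) per cluster with the excess removed from the last
    clusters so sizes sum to n.  ``random_min5pct``: shares drawn uniformly
    on the simplex and redrawn until every share is at least 5%.
    """
    if k < 1 or n_samples < k:
        raise ValueError("need n_samples >= k >= 1")
    if mode == "equal":
        base = -(-n_samples // k)  # ceil
        sizes = np.full(k, base, dtype=int)
        excess = base * k - n_samples
        for i in range(excess):
            sizes[k - 1 - i] -= 1
        return sizes
    if mode == "random_min5pct":
        if 0.05 * k > 1.0 + 1e-12:
            raise ValueError("infeasible: k * 5% exceeds 100%")
        rng = np.random.default_rng(seed)
        for _ in range(100_000):
            shares = rng.dirichlet(np.ones(k))
            if (shares >= 0.05).all():
                sizes = np.floor(shares * n_samples).astype(int)
                # largest-remainder completion
                rem = n_samples - sizes.sum()
                frac = shares * n_samples - sizes
                for i in np.argsort(-frac)[:rem]:
                    sizes[i] += 1
                if (sizes >= max(1, int(np.floor(0.05 * n_samples)))).all():
                    return sizes
        raise RuntimeError("could not draw sizes meeting the 5% minimum")
    raise ValueError(f"unknown mode {mode!r}")


def simulate_structured(
    cfg: StructureSimConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Fst-structured genotypes; returns (matrix, true cluster labels 1..K)."""
    rng = np.random.default_rng(cfg.seed)
    if isinstance(cfg.cluster_sizes, (list, tuple)):
        sizes = np.asarray(cfg.cluster_sizes, int)
    else:
        mode = "equal" if cfg.cluster_sizes == "equal" else "random_min5pct"
        sizes = assign_cluster_sizes(cfg.n_samples, cfg.n_clusters, mode,
                                     seed=int(rng.integers(2**31)))
    p = rng.uniform(*cfg.founder_freq_range, size=cfg.n_snps)
    pk = draw_cluster_freqs(rng, p, cfg.fst, cfg.n_clusters)
    calls = np.empty((cfg.n_samples, cfg.n_snps), dtype=np.int8)
    labels = np.empty(cfg.n_samples, dtype=int)
    start = 0
    for c in range(cfg.n_clusters):
        stop = start + int(sizes[c])
        freqs = control_genotype_freqs(cfg.fst, pk[c])
        calls[start:stop] = _draw_genotypes(rng, freqs, int(sizes[c]))
        labels[start:stop] = c + 1
        start = stop
    samples = [f"S{i}" for i in range(cfg.n_samples)]
    g = make_genotype_matrix(samples, _variant_records(cfg.n_snps), calls)
    return g, labels


def simulate_case_control(
    cfg: CaseControlSimConfig,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Confounded case/control study with null and causal SNPs.

    Returns ``(matrix, true_clusters, causal_flags)``.  The matrix holds
    cases first, then controls, then the extra-control pool (all labeled
    "control"); ``causal_flags`` is a boolean per-variant vector (null
    SNPs first, causal SNPs last, named ``causal<i>_p<maf>_R<rr>``;
    repeated (maf, rr) entries yield independent causal SNPs of the
    same cell).
    Null SNPs follow the structured model in every subject; causal SNPs
    use the control model for controls and the R-weighted renormalized
    model for cases, with the founder frequency fixed at the specified maf.
    """
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.case_cluster_probs)
    n_extra = cfg.extra_control_pool
    n_total = cfg.n_cases + cfg.n_controls + n_extra
    clusters = np.concatenate([
        rng.choice(k, size=cfg.n_cases, p=np.asarray(cfg.case_cluster_probs)),
        rng.choice(k, size=cfg.n_controls,
                   p=np.asarray(cfg.control_cluster_probs)),
        rng.choice(k, size=n_extra, p=np.asarray(cfg.control_cluster_probs)),
    ]) + 1
    is_case = np.zeros(n_total, dtype=bool)
    is_case[:cfg.n_cases] = True

    n_causal = len(cfg.causal_specs)
    n_snps = cfg.null_snps + n_causal
    calls = np.empty((n_total, n_snps), dtype=np.int8)

    p_null = rng.uniform(*cfg.founder_freq_range, size=cfg.null_snps)
    pk_null = draw_cluster_freqs(rng, p_null, cfg.fst, k)
    p_causal = np.asarray([maf for maf, _ in cfg.causal_specs])
    pk_causal = (draw_cluster_freqs(rng, p_causal, cfg.fst, k)
                 if n_causal else np.empty((k, 0)))

    for c in range(k):
        members = np.where(clusters == c + 1)[0]
        if len(members) == 0:
            continue
        cases_c = members[is_case[members]]
        ctrls_c = members[~is_case[members]]
        freqs_null = control_genotype_freqs(cfg.fst, pk_null[c])
        calls[np.ix_(members, np.arange(cfg.null_snps))] = _draw_genotypes(
            rng, freqs_null, len(members))
        for j, (maf, rr) in enumerate(cfg.causal_specs):
            col = cfg.null_snps + j
            pkj = pk_causal[c, j:j + 1]
            if len(ctrls_c):
                f_ctrl = control_genotype_freqs(cfg.fst, pkj)[0]
                calls[ctrls_c, col] = _draw_genotypes(
                    rng, f_ctrl[None, :], len(ctrls_c))[:, 0]
            if len(cases_c):
                f_case = case_genotype_freqs(
                    cfg.fst, pkj, rr, literal_hom=cfg.literal_case_hom)[0]
                calls[cases_c, col] = _draw_genotypes(
                    rng, f_case[None, :], len(cases_c))[:, 0]

    variants = _variant_records(cfg.null_snps)
    for i, (maf, rr) in enumerate(cfg.causal_specs):
        j = len(variants)
        variants.append(VariantRecord(id=f"causal{i}_p{maf}_R{rr}",
                                      chromosome="1", position=j + 1,
                                      alleles=("A", "C")))
    causal = np.zeros(n_snps, dtype=bool)
    causal[cfg.null_snps:] = True
    samples = [f"S{i}" for i in range(n_total)]
    phenotype = ["case" if c else "control" for c in is_case]
    g = make_genotype_matrix(samples, variants, calls, phenotype)
    return g, clusters, causal
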