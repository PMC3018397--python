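import numpy as np
import pytest

from ancestryclust import (
    StructureSimConfig,
    run_pca,
    simulate_structured,
)
from ancestryclust.genotype_io import VariantRecord, make_genotype_matrix


@pytest.fixture
def toy_matrix():
    """3 samples x 4 SNPs with one missing call and known frequencies.

    Alternate alleles are strictly minor so the allele-coding survives a
    PLINK .ped round trip (the .ped dialect carries no allele order and
    counts the minor allele, as PLINK does).
    """
    calls = np.array([
        [0, 1, 2, 0],
        [1, 0, 0, -1],
        [1, 1, 0, 0],
    ], dtype=np.int8)
    variants = [
        VariantRecord(id="rs1", chromosome="1", position=100, alleles=("A", "G")),
        VariantRecord(id="rs2", chromosome="1", position=200, alleles=("C", "T")),
        VariantRecord(id="rs3", chromosome="2", position=50, alleles=("G", "A")),
        VariantRecord(id="rs4", chromosome="2", position=80, alleles=("T", "C")),
    ]
    return make_genotype_matrix(["ind1", "ind2", "ind3"], variants, calls,
                                phenotype=["case", "control", "control"])


@pytest.fixture(scope="session")
def structured_k4():
    """One K=4 Fst-structured dataset with its PCA, reused across tests."""
    cfg = StructureSimConfig(n_samples=400, n_snps=4000, n_clusters=4,
                             fst=0.01, seed=20240)
    g, truth = simulate_structured(cfg)
    pca = run_pca(g, n_components=5, svd="auto")
    return g, truth, pca
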