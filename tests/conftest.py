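import numpy as np
import pandas as pd
import pytest

from landgen.geo_env import env_pca
from landgen.popgen import GenotypeMatrix
from landgen.synthetic_data import SimConfig, simulate_dataset


def make_genotypes(codes, groups=None, chrom=None, pos=None, samples=None):
    """Build a GenotypeMatrix from a (samples x loci) code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    samples = samples or [f"s{i}" for i in range(n)]
    chrom = chrom if chrom is not None else np.array(["chr1"] * L, dtype=object)
    pos = pos if pos is not None else np.arange(1, L + 1) * 100
    g = GenotypeMatrix(
        samples=samples,
        codes=codes,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref=np.array(["A"] * L, dtype=object),
        alt=np.array(["T"] * L, dtype=object),
    )
    if groups is not None:
        g.groups = pd.Series(groups, index=samples)
    return g


@pytest.fixture(scope="session")
def small_bundle():
    """Small deterministic bundle exercised by several modules."""
    cfg = SimConfig(
        n_loci=300, n_eas=6, n_outliers=6, n_pa_regions=30,
        genome_length_bp=400_000, seed=1234, missing_rate=0.02,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def eas_bundle():
    """Bundle sized for association power checks."""
    cfg = SimConfig(
        n_loci=1000, n_eas=10, eas_effect=3.0, fst_within_clade=0.02,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def eas_inputs(eas_bundle):
    """Response vector plus neutral-only structure covariates.

    Structure covariates are computed on non-injected loci: at desk scale
    the injected clinal loci are a far larger fraction of the panel than
    in a real genome and would otherwise dominate a genotype PC.
    """
    from landgen.popgen import genotype_pca, vanraden_kinship

    b = eas_bundle
    pcs = env_pca(b.env_table, k=3)
    resp = pcs.scores["PC1"]
    neutral = ~np.isin(np.arange(b.genotypes.n_loci), b.eas_truth["locus"])
    gn = b.genotypes.subset_loci(neutral)
    return {
        "bundle": b,
        "response": resp,
        "K": vanraden_kinship(gn),
        "Q": genotype_pca(gn, 5),
        "neutral_mask": neutral,
    }
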