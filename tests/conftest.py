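import numpy as np
import pytest

from reintropop.genotype_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CoverageProfile,
    GenotypeMatrix,
)


def make_matrix(calls, chrom=None, pos=None, individuals=None):
    """Build a GenotypeMatrix from a 2-D call array with sensible defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    if chrom is None:
        chrom = ["chr1"] * n_sites
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    if individuals is None:
        individuals = [f"ind{i}" for i in range(n_ind)]
    return GenotypeMatrix(
        individuals=individuals,
        chrom=np.array(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        calls=calls,
    )


def uniform_coverage(gm, depth=14, footprint=180):
    return CoverageProfile(
        depth=np.full(gm.calls.shape, depth, dtype=np.int64),
        site_footprint=np.full(gm.n_sites, footprint, dtype=np.int64),
    )


@pytest.fixture
def toy_two_chrom():
    """2 individuals, 5 sites on two chromosomes."""
    return make_matrix(
        [[HOM_REF, HET, HOM_ALT, MISSING, HET],
         [HET, HOM_REF, HOM_REF, HOM_ALT, HOM_REF]],
        chrom=["chr1", "chr1", "chr1", "chr2", "chr2"],
        pos=[100, 200, 300, 100, 250],
    )


def random_matrix(rng, n_ind=None, n_sites=None, missing_rate=0.1):
    n_ind = n_ind or int(rng.integers(2, 6))
    n_sites = n_sites or int(rng.integers(1, 12))
    calls = rng.choice(
        [HOM_REF, HET, HOM_ALT, MISSING], size=(n_ind, n_sites),
        p=[0.4, 0.3, 0.2, 0.1] if missing_rate else [0.45, 0.3, 0.25, 0.0],
    ).astype(np.int8)
    n_c1 = int(rng.integers(0, n_sites + 1))
    chrom = ["chr1"] * n_c1 + ["chr2"] * (n_sites - n_c1)
    pos = np.concatenate([
        np.sort(rng.choice(np.arange(1, 10_000), size=n_c1, replace=False)),
        np.sort(rng.choice(np.arange(1, 10_000), size=n_sites - n_c1, replace=False)),
    ]).astype(np.int64)
    return make_matrix(calls, chrom=chrom, pos=pos)
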