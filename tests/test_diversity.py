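import itertools
import math

import numpy as np
import pytest

from reintropop.diversity import (
    DiversityError,
    effective_site_coverage,
    heterozygosity_stats,
    pairwise_fst,
    pca,
    resample_snp_density,
    snp_density,
)
from reintropop.genotype_io import HET, HOM_ALT, HOM_REF, MISSING, CoverageProfile
from .conftest import make_matrix, uniform_coverage

R, H, A, M = HOM_REF, HET, HOM_ALT, MISSING


def test_effective_site_coverage_is_fourteen():
    assert effective_site_coverage(7, 2) == 14


class TestSnpDensity:
    def test_direct_arithmetic(self):
        # 10 polymorphic sites, uniform coverage, footprint tuned so the
        # per-individual covered length is 5,000 bp -> 2.0 SNPs/kb
        calls = np.tile([H, R, R], (10, 1)).T  # 3 ind x 10 sites, all with MAC 1
        gm = make_matrix(calls.T if calls.shape[0] != 3 else calls)
        gm = make_matrix(np.tile([[H], [R], [R]], (1, 10)))
        cov = CoverageProfile(depth=np.full((3, 10), 7),
                              site_footprint=np.full(10, 500))
        d = snp_density(gm, cov, gm.individuals, population="p")
        assert d.snp_count == 10
        assert d.median_bp_sequenced == 5000
        assert d.snp_density == pytest.approx(2.0)

    def test_zero_polymorphic(self):
        gm = make_matrix(np.full((3, 4), R, dtype=np.int8))
        d = snp_density(gm, uniform_coverage(gm), gm.individuals)
        assert d.snp_count == 0
        assert d.snp_density == 0.0

    def test_depth_threshold_excludes_sites(self):
        gm = make_matrix(np.full((2, 2), H, dtype=np.int8))
        depth = np.array([[7, 6], [7, 6]])
        cov = CoverageProfile(depth=depth, site_footprint=np.full(2, 100))
        d = snp_density(gm, cov, gm.individuals)
        assert d.median_bp_sequenced == 100  # only site0 reaches depth 7

    def test_zero_median_error(self):
        gm = make_matrix(np.full((2, 2), H, dtype=np.int8))
        cov = CoverageProfile(depth=np.zeros((2, 2), dtype=int),
                              site_footprint=np.full(2, 100))
        with pytest.raises(DiversityError, match="0 bp"):
            snp_density(gm, cov, gm.individuals)


class TestResampling:
    def test_identical_homozygotes_zero_density(self):
        gm = make_matrix(np.full((4, 6), R, dtype=np.int8))
        curve = resample_snp_density(gm, uniform_coverage(gm), gm.individuals,
                                     reps=20, seed=1)
        assert set(curve.densities) == {1, 2, 3}
        for vals in curve.densities.values():
            assert (vals == 0).all()

    def test_exactly_100_replicates_default(self):
        gm = make_matrix(np.full((3, 2), R, dtype=np.int8))
        curve = resample_snp_density(gm, uniform_coverage(gm), gm.individuals,
                                     seed=0)
        assert all(len(v) == 100 for v in curve.densities.values())

    def test_k2_matches_exact_subset_enumeration(self):
        """Mean resampled SNP count at k=2 vs exhaustive C(3,2) average."""
        calls = np.array([
            [H, R, A, R, H],
            [R, R, R, H, R],
            [R, A, A, R, M],
        ], dtype=np.int8)
        gm = make_matrix(calls)
        cov = uniform_coverage(gm, footprint=200)  # 5 sites x 200 bp = 1 kb

        def mac_ge1(rows):
            count = 0
            for j in range(calls.shape[1]):
                col = [calls[i, j] for i in rows if calls[i, j] != M]
                alt = sum(1 for c in col if c == H) + 2 * sum(1 for c in col if c == A)
                tot = 2 * len(col)
                if tot and min(alt, tot - alt) >= 1:
                    count += 1
            return count

        exact = np.mean([mac_ge1(s) for s in itertools.combinations(range(3), 2)])
        curve = resample_snp_density(gm, cov, gm.individuals, reps=400, seed=7)
        mean_count = curve.densities[2].mean()  # density == count (1 kb denom)
        counts = [mac_ge1(s) for s in itertools.combinations(range(3), 2)]
        mc_se = np.std(counts) / math.sqrt(400)
        assert abs(mean_count - exact) < 4 * mc_se + 1e-9

    def test_median_density_nondecreasing_no_missing(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([R, H, A], size=(8, 40), p=[0.5, 0.3, 0.2]).astype(np.int8)
        gm = make_matrix(calls)
        curve = resample_snp_density(gm, uniform_coverage(gm), gm.individuals,
                                     reps=50, seed=2)
        medians = [np.median(curve.densities[k]) for k in sorted(curve.densities)]
        assert all(b >= a - 1e-12 for a, b in zip(medians, medians[1:]))

    def test_reps_validation(self):
        gm = make_matrix(np.full((3, 2), R, dtype=np.int8))
        with pytest.raises(DiversityError):
            resample_snp_density(gm, uniform_coverage(gm), gm.individuals,
                                 reps=0, seed=0)


class TestHeterozygosity:
    def test_forced_values_two_hets(self):
        gm = make_matrix(np.array([[H], [H]], dtype=np.int8))
        d = heterozygosity_stats(gm, gm.individuals)
        assert d.he == pytest.approx(0.5)
        assert d.ho == pytest.approx(1.0)
        assert d.f_is == pytest.approx(-1.0)

    def test_all_hom_ref_flagged(self):
        gm = make_matrix(np.full((3, 2), R, dtype=np.int8))
        d = heterozygosity_stats(gm, gm.individuals)
        assert d.he == 0.0 and d.ho == 0.0
        assert math.isnan(d.f_is)

    def test_hand_computed_toy(self):
        # 4 individuals x 3 sites, site-by-site hand computation:
        # s0: R,H,R,H    p=1/4  He=3/8      Ho=1/2
        # s1: H,H,M,R    p=1/3  He=4/9      Ho=2/3
        # s2: A,R,A,R    p=1/2  He=1/2      Ho=0
        calls = np.array([
            [R, H, A],
            [H, H, R],
            [R, M, A],
            [H, R, R],
        ], dtype=np.int8)
        gm = make_matrix(calls)
        d = heterozygosity_stats(gm, gm.individuals)
        he = (3 / 8 + 4 / 9 + 1 / 2) / 3
        ho = (1 / 2 + 2 / 3 + 0) / 3
        assert d.he == pytest.approx(he)
        assert d.ho == pytest.approx(ho)
        assert d.f_is == pytest.approx((he - ho) / he)

    def test_sample_size_correction_option(self):
        gm = make_matrix(np.array([[H], [H]], dtype=np.int8))
        d = heterozygosity_stats(gm, gm.individuals, sample_size_correction=True)
        assert d.he == pytest.approx(0.5 * 4 / 3)

    def test_all_missing_error(self):
        gm = make_matrix(np.full((2, 2), M, dtype=np.int8))
        with pytest.raises(DiversityError):
            heterozygosity_stats(gm, gm.individuals)

    def test_fis_near_zero_random_mating(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, size=400)
        # HW draws for 30 individuals
        a1 = rng.random((30, 400)) < p
        a2 = rng.random((30, 400)) < p
        calls = (a1.astype(np.int8) + a2.astype(np.int8))
        gm = make_matrix(calls)
        d = heterozygosity_stats(gm, gm.individuals)
        assert abs(d.f_is) < 0.05


def wc_theta_oracle(calls_a, calls_b):
    """Independent scalar-loop Weir & Cockerham theta (r=2)."""
    a_sum = b_sum = c_sum = 0.0
    for j in range(calls_a.shape[1]):
        ga = [int(c) for c in calls_a[:, j] if c != M]
        gb = [int(c) for c in calls_b[:, j] if c != M]
        n1, n2 = len(ga), len(gb)
        if n1 < 1 or n2 < 1:
            continue
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            continue
        p1, p2 = sum(ga) / (2 * n1), sum(gb) / (2 * n2)
        h1 = sum(1 for c in ga if c == H) / n1
        h2 = sum(1 for c in gb if c == H) / n2
        r = 2
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        a_sum += a
        b_sum += b
        c_sum += hbar / 2
    return a_sum / (a_sum + b_sum + c_sum)


class TestPairwiseFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.3, 0.7, size=500)
        mk = lambda seed: (np.random.default_rng(seed).random((40, 500)) < p).astype(np.int8) \
            + (np.random.default_rng(seed + 99).random((40, 500)) < p).astype(np.int8)
        calls = np.vstack([mk(2), mk(3)])
        gm = make_matrix(calls, individuals=[f"i{k}" for k in range(80)])
        theta = pairwise_fst(gm, gm.individuals[:40], gm.individuals[40:])
        assert abs(theta) < 0.01

    def test_fixed_alternative_alleles(self):
        calls = np.vstack([np.full((5, 20), R), np.full((5, 20), A)]).astype(np.int8)
        gm = make_matrix(calls, individuals=[f"i{k}" for k in range(10)])
        theta = pairwise_fst(gm, gm.individuals[:5], gm.individuals[5:])
        assert theta == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        calls = rng.choice([R, H, A, M], size=(10, 30),
                           p=[0.35, 0.3, 0.25, 0.1]).astype(np.int8)
        gm = make_matrix(calls, individuals=[f"i{k}" for k in range(10)])
        theta = pairwise_fst(gm, gm.individuals[:5], gm.individuals[5:])
        oracle = wc_theta_oracle(calls[:5], calls[5:])
        assert theta == pytest.approx(oracle, abs=1e-12)

    def test_too_few_individuals(self):
        gm = make_matrix(np.full((3, 5), H, dtype=np.int8))
        with pytest.raises(DiversityError):
            pairwise_fst(gm, gm.individuals[:1], gm.individuals[1:])

    def test_no_shared_sites_error(self):
        calls = np.array([[M, M], [M, M], [R, H], [H, R]], dtype=np.int8)
        gm = make_matrix(calls)
        with pytest.raises(DiversityError):
            pairwise_fst(gm, gm.individuals[:2], gm.individuals[2:])


class TestPca:
    def test_duplicate_individuals_identical_coords(self):
        rng = np.random.default_rng(3)
        row = rng.choice([R, H, A], size=50).astype(np.int8)
        calls = np.vstack([row, row, rng.choice([R, H, A], size=50)]).astype(np.int8)
        gm = make_matrix(calls)
        ids, coords, _ = pca(gm, maf_min=0.0)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-7)

    def test_variance_explained_properties(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([R, H, A], size=(6, 80)).astype(np.int8)
        gm = make_matrix(calls)
        _, _, var = pca(gm, maf_min=0.0)
        assert (var >= 0).all()
        assert var.sum() == pytest.approx(1.0)
        assert (np.diff(var) <= 1e-12).all()

    def test_hand_eigendecomposition_toy(self):
        # dosages per site: [0,1,2]; centered rows (-1,-1),(0,0),(1,1);
        # covariance [[1,0,-1],[0,0,0],[-1,0,1]] has eigenpair
        # (2, (1,0,-1)/sqrt(2)) -> PC1 coords +-(1, 0, -1)
        calls = np.array([[R, R], [H, H], [A, A]], dtype=np.int8)
        gm = make_matrix(calls)
        _, coords, var = pca(gm, maf_min=0.0, site_rate_min=0.0)
        pc1 = coords[:, 0]
        expected = np.array([1.0, 0.0, -1.0])
        assert (np.allclose(pc1, expected, atol=1e-9)
                or np.allclose(pc1, -expected, atol=1e-9))
        assert var[0] == pytest.approx(1.0)

    def test_gram_identity(self):
        # coords @ coords.T reconstructs the covariance matrix
        rng = np.random.default_rng(8)
        calls = rng.choice([R, H, A, M], size=(5, 60),
                           p=[0.4, 0.3, 0.2, 0.1]).astype(np.int8)
        gm = make_matrix(calls)
        ids, coords, _ = pca(gm, maf_min=0.0, site_rate_min=0.0,
                             individual_rate_min=0.0)
        d = calls.astype(float)
        called = (calls != M).sum(axis=0)
        alt = (calls == H).sum(axis=0) + 2 * (calls == A).sum(axis=0)
        p = alt / (2 * called)
        for j in range(60):
            d[calls[:, j] == M, j] = 2 * p[j]
        d -= d.mean(axis=0)
        cov = d @ d.T / 60
        np.testing.assert_allclose(coords @ coords.T, cov, atol=1e-9)

    def test_too_few_individuals_error(self):
        gm = make_matrix(np.full((3, 4), M, dtype=np.int8))
        with pytest.raises(DiversityError):
            pca(gm)
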