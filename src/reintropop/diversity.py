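"""Per-population genetic-diversity statistics.

SNP density with individual-resampling curves, expected (Nei) and observed
multilocus heterozygosity, the within-population inbreeding coefficient F_IS,
Weir & Cockerham (1984) pairwise FST, and a genotype-covariance PCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CoverageProfile,
    GenotypeMatrix,
    PopulationMap,
)

__all__ = [
    "PopulationDiversity",
    "ResamplingCurve",
    "effective_site_coverage",
    "snp_density",
    "resample_snp_density",
    "heterozygosity_stats",
    "pairwise_fst",
    "pca",
    "diversity_table",
]


class DiversityError(ValueError):
    pass


@dataclass
class PopulationDiversity:
    population: str
    n_individuals: int
    snp_count: int | None = None
    median_bp_sequenced: float | None = None
    snp_density: float | None = None  # SNPs per kb
    he: float | None = None
    ho: float | None = None
    f_is: float | None = None


@dataclass
class ResamplingCurve:
    """100 resampled SNP densities per subsample size k in 1..n-1."""

    group: str
    densities: dict[int, np.ndarray]  # k -> (reps,) SNPs/kb

    def to_records(self) -> list[tuple[str, int, int, float]]:
        out = []
        for k in sorted(self.densities):
            for rep, d in enumerate(self.densities[k]):
                out.append((self.group, k, rep, float(d)))
        return out


def effective_site_coverage(depth_min_per_direction: int = 7,
                            directions: int = 2) -> int:
    """Site-level effective read coverage implied by a per-direction threshold.

    A restriction cut site is sequenced in both directions, so requiring at
    least ``depth_min_per_direction`` reads on each flank means the site
    itself is covered by ``directions * depth_min_per_direction`` reads
    (7 reads per direction -> effective coverage 14).
    """
    return directions * depth_min_per_direction


def _members_idx(gm: GenotypeMatrix, individuals) -> np.ndarray:
    idx_of = {name: i for i, name in enumerate(gm.individuals)}
    try:
        return np.array([idx_of[m] for m in individuals], dtype=int)
    except KeyError as exc:
        raise DiversityError(f"unknown individual {exc.args[0]!r}") from None


def _minor_allele_counts(calls: np.ndarray) -> np.ndarray:
    alt = (calls == HET).sum(axis=0) + 2 * (calls == HOM_ALT).sum(axis=0)
    tot = 2 * (calls != MISSING).sum(axis=0)
    return np.minimum(alt, tot - alt)


def snp_density(
    gm: GenotypeMatrix,
    cov: CoverageProfile,
    individuals,
    population: str = "",
    depth_min: int = 7,
) -> PopulationDiversity:
    """SNP count, median covered bp, and SNP density for one population.

    The SNP count is the number of sites with minor allele count >= 1 among
    the population's non-missing calls.  Each individual's covered sequence
    is the summed site footprint over sites at depth >= ``depth_min``; the
    median across individuals is the denominator, and density is reported
    per kilobase.
    """
    if len(individuals) == 0:
        raise DiversityError("population is empty")
    cov.check_matches(gm)
    idx = _members_idx(gm, individuals)
    calls = gm.calls[idx, :]
    snp_count = int((_minor_allele_counts(calls) >= 1).sum())
    covered_bp = (
        (cov.depth[idx, :] >= depth_min) * cov.site_footprint[None, :]
    ).sum(axis=1)
    median_bp = float(np.median(covered_bp))
    if median_bp <= 0:
        raise DiversityError(
            f"population {population!r}: median covered sequence is 0 bp"
        )
    return PopulationDiversity(
        population=population,
        n_individuals=len(idx),
        snp_count=snp_count,
        median_bp_sequenced=median_bp,
        snp_density=snp_count / (median_bp / 1000.0),
    )


def resample_snp_density(
    gm: GenotypeMatrix,
    cov: CoverageProfile,
    individuals,
    group: str = "",
    reps: int = 100,
    seed: int | None = None,
    depth_min: int = 7,
) -> ResamplingCurve:
    """Resampling curve of SNP density for subsample sizes 1..n-1.

    For each k, ``reps`` random draws of k individuals without replacement;
    each draw counts sites with minor allele count >= 1 and divides by the
    draw's median kb covered at depth >= ``depth_min``.
    """
    if reps < 1:
        raise DiversityError("reps must be >= 1")
    if len(individuals) < 2:
        raise DiversityError("resampling needs a group of at least 2 individuals")
    rng = np.random.default_rng(seed)
    idx = _members_idx(gm, individuals)
    n = len(idx)
    covered_bp = (
        (cov.depth[idx, :] >= depth_min) * cov.site_footprint[None, :]
    ).sum(axis=1)
    densities: dict[int, np.ndarray] = {}
    for k in range(1, n):
        vals = np.empty(reps)
        for rep in range(reps):
            draw = rng.choice(n, size=k, replace=False)
            calls = gm.calls[idx[draw], :]
            count = int((_minor_allele_counts(calls) >= 1).sum())
            med = float(np.median(covered_bp[draw]))
            if med <= 0:
                raise DiversityError("resample draw has 0 bp median coverage")
            vals[rep] = count / (med / 1000.0)
        densities[k] = vals
    return ResamplingCurve(group=group, densities=densities)


def heterozygosity_stats(
    gm: GenotypeMatrix,
    individuals,
    population: str = "",
    sample_size_correction: bool = False,
) -> PopulationDiversity:
    """Multilocus He (Nei), Ho, and F_IS for one population.

    Per site, ``p`` is the alt-allele frequency among non-missing calls;
    He_site = 2p(1-p) (optionally scaled by 2n/(2n-1)); Ho_site is the
    heterozygote fraction among non-missing calls.  Population values are
    means over all sites with at least one non-missing call, and
    F_IS = (He - Ho) / He from the multilocus means (NaN when He = 0).
    """
    idx = _members_idx(gm, individuals)
    if len(idx) == 0:
        raise DiversityError("population is empty")
    calls = gm.calls[idx, :]
    called = (calls != MISSING).sum(axis=0)
    if gm.n_sites == 0 or (called == 0).all():
        raise DiversityError(f"population {population!r}: no genotyped sites")
    use = called > 0
    alt = (calls == HET).sum(axis=0) + 2 * (calls == HOM_ALT).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt[use] / (2.0 * called[use])
        he_site = 2.0 * p * (1.0 - p)
        if sample_size_correction:
            n2 = 2.0 * called[use]
            he_site = he_site * n2 / (n2 - 1.0)
        ho_site = (calls == HET).sum(axis=0)[use] / called[use]
    he = float(he_site.mean())
    ho = float(ho_site.mean())
    f_is = (he - ho) / he if he > 0 else math.nan
    return PopulationDiversity(
        population=population, n_individuals=len(idx),
        he=he, ho=ho, f_is=f_is,
    )


# -----------------------------------------------------------------------------
# Weir & Cockerham FST
# -----------------------------------------------------------------------------

def _wc_components(calls_by_pop: list[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components (a, b, c) for
    ``r`` populations given their call matrices."""
    r = len(calls_by_pop)
    n = np.stack([(c != MISSING).sum(axis=0) for c in calls_by_pop])  # (r, S)
    alt = np.stack([
        (c == HET).sum(axis=0) + 2 * (c == HOM_ALT).sum(axis=0)
        for c in calls_by_pop
    ])
    hetn = np.stack([(c == HET).sum(axis=0) for c in calls_by_pop])
    ok = (n >= 1).all(axis=0)
    n = n[:, ok].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt[:, ok] / (2.0 * n)
        h = hetn[:, ok] / n
    nbar = n.mean(axis=0)
    good = nbar > 1.0
    n, p, h, nbar = n[:, good], p[:, good], h[:, good], nbar[good]
    nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(gm: GenotypeMatrix, individuals_a, individuals_b) -> float:
    """Multi-locus Weir & Cockerham theta between two populations (ratio of
    summed variance components; may be slightly negative)."""
    ia = _members_idx(gm, individuals_a)
    ib = _members_idx(gm, individuals_b)
    if len(ia) < 2 or len(ib) < 2:
        raise DiversityError("pairwise FST needs >= 2 individuals per population")
    a, b, c = _wc_components([gm.calls[ia, :], gm.calls[ib, :]])
    denom = (a + b + c).sum()
    if len(a) == 0 or denom == 0:
        raise DiversityError("no shared genotyped sites between populations")
    return float(a.sum() / denom)


# -----------------------------------------------------------------------------
# PCA
# -----------------------------------------------------------------------------

def pca(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    site_rate_min: float = 0.8,
    individual_rate_min: float = 0.8,
    n_components: int | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """PCA on the individual x individual genotype covariance matrix.

    Individuals below ``individual_rate_min`` genotyping rate are dropped
    first; sites are then filtered to genotyping rate >= ``site_rate_min``
    and MAF >= ``maf_min``.  Dosages (0/1/2) are mean-imputed per site and
    mean-centered; coordinates come from the eigendecomposition of the
    covariance matrix and are deterministic up to component sign.

    Returns (individual IDs, coordinates (n x k), variance explained (k,)).
    """
    ind_rate = (gm.calls != MISSING).mean(axis=1)
    keep_ind = np.flatnonzero(ind_rate >= individual_rate_min)
    if len(keep_ind) < 2:
        raise DiversityError("fewer than 2 individuals pass the genotyping-rate filter")
    calls = gm.calls[keep_ind, :]
    n_ind = len(keep_ind)
    called = (calls != MISSING).sum(axis=0)
    alt = (calls == HET).sum(axis=0) + 2 * (calls == HOM_ALT).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(2.0 * called, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    keep_site = (called / n_ind >= site_rate_min) & (maf >= maf_min)
    if keep_site.sum() == 0:
        raise DiversityError("no sites pass PCA filters")
    d = calls[:, keep_site].astype(float)
    miss = d < 0
    site_mean = 2.0 * p[keep_site]
    d[miss] = np.broadcast_to(site_mean, d.shape)[miss]
    d -= d.mean(axis=0)[None, :]
    cov = d @ d.T / d.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    coords = evecs * np.sqrt(evals)[None, :]
    total = evals.sum()
    var_explained = evals / total if total > 0 else evals
    if n_components is not None:
        coords = coords[:, :n_components]
        var_explained = var_explained[:n_components]
    return [gm.individuals[i] for i in keep_ind], coords, var_explained


# -----------------------------------------------------------------------------
# Report assembly
# -----------------------------------------------------------------------------

def diversity_table(
    gm: GenotypeMatrix,
    cov: CoverageProfile | None,
    popmap: PopulationMap,
    depth_min: int = 7,
) -> list[PopulationDiversity]:
    """Per-population summary rows (SNP density block requires coverage)."""
    popmap.check_covers(gm)
    rows: list[PopulationDiversity] = []
    for pop in popmap.populations:
        members = [i for i in popmap.members(pop) if i in gm.individuals]
        if not members:
            continue
        het = heterozygosity_stats(gm, members, population=pop)
        row = PopulationDiversity(
            population=pop, n_individuals=len(members),
            he=het.he, ho=het.ho, f_is=het.f_is,
        )
        if cov is not None:
            dens = snp_density(gm, cov, members, population=pop, depth_min=depth_min)
            row.snp_count = dens.snp_count
            row.median_bp_sequenced = dens.median_bp_sequenced
            row.snp_density = dens.snp_density
        rows.append(row)
    return rows
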