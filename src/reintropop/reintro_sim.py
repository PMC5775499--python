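"""Forward Wright-Fisher simulation of a serial-bottleneck reintroduction.

The demography is a directed stage graph (source -> captive -> primary ->
secondary).  Each stage is founded by sampling diploid founders without
replacement from its parent stage and then evolves for a fixed number of
non-overlapping, random-mating (monoecious, two distinct parents, no selfing)
Wright-Fisher generations at constant diploid size.

Genetics: fixed biallelic marker positions on a physical map, standing
variation only (no new mutations -- negligible over ~10 generations),
recombination under the Haldane map function at a uniform cM/Mb rate with no
interference.  True haplotypes and founder-gamete ancestry labels are carried
through every meiosis, so autozygous (identity-by-descent) tracts are
available as ground truth for validating ROH calls.

A RAD-seq-like observation model (negative-binomial depth per individual x
site, depth-threshold missingness, symmetric genotype error) converts true
genotypes into the kind of data the downstream filters and statistics see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

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
    "Stage",
    "DemographyModel",
    "GenomeMap",
    "ObservationParams",
    "StageSample",
    "SimulationResult",
    "default_ibex_demography",
    "default_genome",
    "simulate_reintroduction",
    "apply_rad_observation",
]


class SimulationError(ValueError):
    pass


# -----------------------------------------------------------------------------
# Demography
# -----------------------------------------------------------------------------

@dataclass(frozen=True)
class Stage:
    """One node of the reintroduction graph.

    ``founders`` diploid individuals are drawn without replacement from the
    parent stage (``None`` for the root); the stage then runs ``generations``
    Wright-Fisher generations at constant diploid size ``ne``.
    """

    stage_id: str
    parent: str | None
    founders: int | None
    ne: int
    generations: int
    role: str = "secondary"


@dataclass
class DemographyModel:
    stages: list[Stage]

    def __post_init__(self) -> None:
        ids = [s.stage_id for s in self.stages]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate stage IDs")
        by_id = {s.stage_id: s for s in self.stages}
        roots = [s for s in self.stages if s.parent is None]
        if len(roots) != 1:
            raise SimulationError(f"expected exactly one root stage, found {len(roots)}")
        for s in self.stages:
            if s.ne < 1:
                raise SimulationError(f"stage {s.stage_id!r}: Ne must be >= 1")
            if s.generations < 0:
                raise SimulationError(f"stage {s.stage_id!r}: generations must be >= 0")
            if s.parent is not None:
                if s.parent not in by_id:
                    raise SimulationError(
                        f"stage {s.stage_id!r}: unknown parent {s.parent!r}"
                    )
                if s.founders is None or s.founders < 1:
                    raise SimulationError(
                        f"stage {s.stage_id!r}: non-root stage needs founders >= 1"
                    )
                if s.founders > by_id[s.parent].ne:
                    raise SimulationError(
                        f"stage {s.stage_id!r}: founder count {s.founders} exceeds "
                        f"parent Ne {by_id[s.parent].ne}"
                    )
        # cycle check via topological order
        self.topological_order()

    def __getitem__(self, stage_id: str) -> Stage:
        for s in self.stages:
            if s.stage_id == stage_id:
                return s
        raise KeyError(stage_id)

    @property
    def root(self) -> Stage:
        return next(s for s in self.stages if s.parent is None)

    def topological_order(self) -> list[Stage]:
        by_id = {s.stage_id: s for s in self.stages}
        order: list[Stage] = []
        seen: set[str] = set()

        def visit(s: Stage, trail: tuple[str, ...]) -> None:
            if s.stage_id in trail:
                raise SimulationError(f"cycle in demography at {s.stage_id!r}")
            if s.stage_id in seen:
                return
            if s.parent is not None:
                visit(by_id[s.parent], trail + (s.stage_id,))
            seen.add(s.stage_id)
            order.append(s)

        for s in self.stages:
            visit(s, ())
        return order


def default_ibex_demography(
    source_ne: int = 1000,
    captive_founders: int = 88,
    captive_ne: int = 88,
    n_primary: int = 3,
    primary_ne: int = 300,
    primary_founders: int = 40,
    n_secondary: int = 2,
    secondary_ne: int = 80,
    secondary_founders: int = 20,
    generations: int = 10,
    source_generations: int = 10,
) -> DemographyModel:
    """Preset mirroring the documented reintroduction history.

    One large autochthonous source (Ne ~1,000), a captive stock of 88
    founders, three primary populations (Ne ~300 each) founded from the
    captive stock, and secondary populations (Ne ~80) each founded from a
    single primary, with 10 generations of isolated drift post-founding
    (the documented range is 8-10).  Every parameter is overridable.
    """
    stages = [
        Stage("source", None, None, source_ne, source_generations, role="autochthonous"),
        Stage("captive", "source", captive_founders, captive_ne, generations,
              role="captive"),
    ]
    for i in range(1, n_primary + 1):
        stages.append(Stage(f"primary{i}", "captive", primary_founders, primary_ne,
                            generations, role="primary"))
    for i in range(1, n_secondary + 1):
        parent = f"primary{1 + (i - 1) % n_primary}"
        stages.append(Stage(f"secondary{i}", parent, secondary_founders, secondary_ne,
                            generations, role="secondary"))
    return DemographyModel(stages=stages)


# -----------------------------------------------------------------------------
# Genome map
# -----------------------------------------------------------------------------

@dataclass
class GenomeMap:
    """Physical marker map: chromosome lengths, marker positions (1-based bp),
    and a uniform recombination rate in cM per Mb."""

    chromosomes: list[tuple[str, int]]
    marker_positions: dict[str, np.ndarray]
    recombination_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.recombination_rate <= 0:
            raise SimulationError("recombination_rate must be > 0")
        lengths = dict(self.chromosomes)
        for chrom, pos in self.marker_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.marker_positions[chrom] = pos
            if chrom not in lengths:
                raise SimulationError(f"markers on unknown chromosome {chrom!r}")
            if len(pos) and (np.diff(pos) <= 0).any():
                raise SimulationError(f"{chrom!r}: marker positions must increase")
            if len(pos) and (pos[0] < 1 or pos[-1] > lengths[chrom]):
                raise SimulationError(f"{chrom!r}: marker outside [1, length]")

    @property
    def n_markers(self) -> int:
        return sum(len(p) for _, p in self.flat())

    @property
    def total_length_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def flat(self) -> list[tuple[str, np.ndarray]]:
        """(chromosome, positions) in chromosome order, skipping empty ones."""
        return [(c, self.marker_positions[c]) for c, _ in self.chromosomes
                if len(self.marker_positions.get(c, ())) > 0]

    def flat_chrom_pos(self) -> tuple[np.ndarray, np.ndarray]:
        chroms: list[str] = []
        poss: list[np.ndarray] = []
        for c, p in self.flat():
            chroms.extend([c] * len(p))
            poss.append(p)
        return (np.array(chroms, dtype=object),
                np.concatenate(poss) if poss else np.array([], dtype=np.int64))

    def interlocus_recomb(self) -> np.ndarray:
        """Per-marker recombination fraction with the previous marker.

        Haldane: r = (1 - exp(-2d)) / 2 with d in Morgans; the first marker of
        each chromosome (and index 0) gets r = 0.5 (free recombination across
        chromosome boundaries / random start phase).
        """
        rs: list[np.ndarray] = []
        morgans_per_bp = self.recombination_rate / 100.0 / 1e6
        for _, pos in self.flat():
            r = np.empty(len(pos))
            r[0] = 0.5
            if len(pos) > 1:
                d = np.diff(pos) * morgans_per_bp
                r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d))
            rs.append(r)
        return np.concatenate(rs) if rs else np.array([])


def default_genome(
    n_chromosomes: int = 5,
    chromosome_length_bp: int = 100_000_000,
    marker_spacing_bp: int = 50_000,
    recombination_rate: float = 1.0,
) -> GenomeMap:
    """Desk-scale genome: 5 x 100 Mb, one marker per 50 kb (10,000 markers)."""
    chroms = [(f"chr{i}", chromosome_length_bp) for i in range(1, n_chromosomes + 1)]
    positions = {
        c: np.arange(marker_spacing_bp, length + 1, marker_spacing_bp, dtype=np.int64)
        for c, length in chroms
    }
    return GenomeMap(chromosomes=chroms, marker_positions=positions,
                     recombination_rate=recombination_rate)


# -----------------------------------------------------------------------------
# Observation model
# -----------------------------------------------------------------------------

@dataclass
class ObservationParams:
    """RAD-seq-like observation model.

    mean_depth: scalar or per-individual array of mean read depths.
    depth_dispersion: negative-binomial size parameter (smaller = more
        overdispersed); ``None`` gives Poisson depths.
    missing_below_depth: genotypes at depth below this are set to missing
        (the downstream density statistic uses >= 7 reads per direction).
    genotype_error_rate: probability that a retained heterozygote is recorded
        as a random homozygote and vice versa.
    """

    mean_depth: float | Sequence[float] = 14.0
    depth_dispersion: float | None = 5.0
    missing_below_depth: int = 7
    genotype_error_rate: float = 0.0

    def __post_init__(self) -> None:
        md = np.atleast_1d(np.asarray(self.mean_depth, dtype=float))
        if (md < 0).any():
            raise SimulationError("mean_depth must be non-negative")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise SimulationError("depth_dispersion must be > 0")
        if self.missing_below_depth < 0:
            raise SimulationError("missing_below_depth must be >= 0")
        if not 0.0 <= self.genotype_error_rate <= 1.0:
            raise SimulationError("genotype_error_rate must be in [0, 1]")


# -----------------------------------------------------------------------------
# Simulation
# -----------------------------------------------------------------------------

@dataclass
class StageSample:
    """Sampled individuals from one stage: observed-side genotype matrix plus
    the true haplotypes and founder-gamete ancestry labels behind it."""

    genotypes: GenotypeMatrix
    haplotypes: np.ndarray  # (n, 2, L) int8 allele states
    ancestry: np.ndarray    # (n, 2, L) int32 founder-gamete lineage IDs


@dataclass
class SimulationResult:
    demography: DemographyModel
    genome: GenomeMap
    samples: dict[str, StageSample]
    stage_frequencies: dict[str, np.ndarray]  # final alt-allele freq per stage
    stage_founding_frequencies: dict[str, np.ndarray]  # freq right after founding
    init_frequencies: np.ndarray

    def genotype_matrices(self) -> dict[str, GenotypeMatrix]:
        return {sid: s.genotypes for sid, s in self.samples.items()}

    def population_map(self) -> PopulationMap:
        assignments: dict[str, str] = {}
        roles: dict[str, str] = {}
        for sid, sample in self.samples.items():
            roles[sid] = self.demography[sid].role
            for ind in sample.genotypes.individuals:
                assignments[ind] = sid
        return PopulationMap(assignments=assignments, roles=roles)

    def combined_matrix(self) -> GenotypeMatrix:
        """All sampled individuals from all stages in one matrix."""
        sids = list(self.samples)
        first = self.samples[sids[0]].genotypes
        individuals: list[str] = []
        calls = []
        for sid in sids:
            gm = self.samples[sid].genotypes
            individuals.extend(gm.individuals)
            calls.append(gm.calls)
        return GenotypeMatrix(
            individuals=individuals,
            chrom=first.chrom, pos=first.pos, ref=first.ref, alt=first.alt,
            calls=np.concatenate(calls, axis=0),
        )

    def ibd_bed(self, stage_id: str) -> str:
        """Ground-truth autozygous tracts of a stage's sampled individuals as
        BED text (0-based half-open: chrom, start, end, individual)."""
        sample = self.samples[stage_id]
        lines = []
        for i, ind in enumerate(sample.genotypes.individuals):
            for chrom, start, end in self.autozygous_tracts(stage_id, i):
                lines.append(f"{chrom}\t{start - 1}\t{end}\t{ind}")
        return "\n".join(lines) + ("\n" if lines else "")

    def autozygous_tracts(self, stage_id: str, individual_idx: int
                          ) -> list[tuple[str, int, int]]:
        """Maximal marker runs where both haplotypes descend from the same
        founder gamete, as (chromosome, start_bp, end_bp) spans."""
        sample = self.samples[stage_id]
        anc = sample.ancestry[individual_idx]
        ibd = anc[0] == anc[1]
        tracts: list[tuple[str, int, int]] = []
        offset = 0
        for chrom, pos in self.genome.flat():
            n = len(pos)
            mask = ibd[offset:offset + n]
            offset += n
            j = 0
            while j < n:
                if mask[j]:
                    k = j
                    while k + 1 < n and mask[k + 1]:
                        k += 1
                    tracts.append((chrom, int(pos[j]), int(pos[k])))
                    j = k + 1
                else:
                    j += 1
        return tracts


def _resolve_init_freqs(init_freq_spec, n_loci: int, rng: np.random.Generator
                        ) -> np.ndarray:
    if callable(init_freq_spec):
        p = np.asarray(init_freq_spec(rng, n_loci), dtype=float)
    elif isinstance(init_freq_spec, tuple) and init_freq_spec[0] == "uniform":
        _, lo, hi = init_freq_spec
        p = rng.uniform(lo, hi, size=n_loci)
    else:
        p = np.asarray(init_freq_spec, dtype=float)
    if p.shape != (n_loci,):
        raise SimulationError(f"initial frequencies must have length {n_loci}")
    if ((p < 0) | (p > 1)).any():
        raise SimulationError("initial frequencies must lie in [0, 1]")
    return p


def _meiosis(haps: np.ndarray, anc: np.ndarray, parent_idx: np.ndarray,
             r: np.ndarray, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
    """Produce one gamete per entry of ``parent_idx``.

    ``haps``/``anc`` are (2N, L) arrays with individual i's haplotypes at rows
    2i and 2i+1.  Recombination is realized as independent inter-marker
    switch events with probabilities ``r`` (r[first marker of chromosome] =
    0.5), which is exactly the Haldane no-interference model restricted to
    marker loci.
    """
    n_g = len(parent_idx)
    L = haps.shape[1]
    switches = rng.random((n_g, L)) < r[None, :]
    phase = np.cumsum(switches, axis=1) & 1
    rows = 2 * parent_idx[:, None] + phase
    cols = np.arange(L)[None, :]
    return haps[rows, cols], anc[rows, cols]


def _wf_generation(haps: np.ndarray, anc: np.ndarray, n_offspring: int,
                   r: np.ndarray, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One non-overlapping Wright-Fisher generation: each offspring draws two
    distinct parents uniformly and receives one recombinant gamete from each."""
    n_par = haps.shape[0] // 2
    if n_par < 2:
        raise SimulationError("need at least 2 parents for random mating")
    p1 = rng.integers(0, n_par, size=n_offspring)
    p2 = (p1 + 1 + rng.integers(0, n_par - 1, size=n_offspring)) % n_par
    g1, a1 = _meiosis(haps, anc, p1, r, rng)
    g2, a2 = _meiosis(haps, anc, p2, r, rng)
    L = haps.shape[1]
    new_haps = np.empty((2 * n_offspring, L), dtype=np.int8)
    new_anc = np.empty((2 * n_offspring, L), dtype=np.int32)
    new_haps[0::2], new_haps[1::2] = g1, g2
    new_anc[0::2], new_anc[1::2] = a1, a2
    return new_haps, new_anc


def simulate_reintroduction(
    demography: DemographyModel,
    genome: GenomeMap,
    init_freq_spec=("uniform", 0.05, 0.95),
    seed: int | None = None,
    sample_sizes: Mapping[str, int] | int | None = None,
) -> SimulationResult:
    """Run the forward simulation and sample individuals from every stage.

    The root stage is initialized in Hardy-Weinberg / linkage equilibrium at
    the requested allele frequencies, with every root haplotype carrying a
    unique ancestry label.  ``sample_sizes`` is a per-stage map, a single
    integer for all stages, or ``None`` for min(16, Ne) per stage (sampling
    the whole stage when Ne <= the sample size).

    A seed is mandatory: reproducibility is part of the contract.
    """
    if seed is None:
        raise SimulationError("a seed is required (reproducibility is mandatory)")
    rng = np.random.default_rng(seed)
    L = genome.n_markers
    if L == 0:
        raise SimulationError("genome has no markers")
    r = genome.interlocus_recomb()
    p0 = _resolve_init_freqs(init_freq_spec, L, rng)

    pop_haps: dict[str, np.ndarray] = {}
    pop_anc: dict[str, np.ndarray] = {}
    stage_freqs: dict[str, np.ndarray] = {}
    founding_freqs: dict[str, np.ndarray] = {}

    for stage in demography.topological_order():
        if stage.parent is None:
            haps = (rng.random((2 * stage.ne, L)) < p0[None, :]).astype(np.int8)
            anc = np.arange(2 * stage.ne, dtype=np.int32)[:, None] * np.ones(
                (1, L), dtype=np.int32)
        else:
            par_haps = pop_haps[stage.parent]
            par_anc = pop_anc[stage.parent]
            n_par = par_haps.shape[0] // 2
            founders = rng.choice(n_par, size=stage.founders, replace=False)
            rows = np.empty(2 * stage.founders, dtype=np.int64)
            rows[0::2], rows[1::2] = 2 * founders, 2 * founders + 1
            haps, anc = par_haps[rows].copy(), par_anc[rows].copy()
            if stage.ne != stage.founders:
                # grow/shrink to Ne with one round of random mating
                haps, anc = _wf_generation(haps, anc, stage.ne, r, rng)
        founding_freqs[stage.stage_id] = haps.mean(axis=0)
        for _ in range(stage.generations):
            haps, anc = _wf_generation(haps, anc, stage.ne, r, rng)
        pop_haps[stage.stage_id] = haps
        pop_anc[stage.stage_id] = anc
        stage_freqs[stage.stage_id] = haps.mean(axis=0)

    chrom, pos = genome.flat_chrom_pos()
    ref = np.full(L, "A", dtype=object)
    alt = np.full(L, "G", dtype=object)

    samples: dict[str, StageSample] = {}
    for stage in demography.topological_order():
        haps = pop_haps[stage.stage_id]
        anc = pop_anc[stage.stage_id]
        n_pop = haps.shape[0] // 2
        if sample_sizes is None:
            n_s = min(16, n_pop)
        elif isinstance(sample_sizes, int):
            n_s = min(sample_sizes, n_pop)
        else:
            n_s = min(sample_sizes.get(stage.stage_id, min(16, n_pop)), n_pop)
        chosen = np.sort(rng.choice(n_pop, size=n_s, replace=False))
        hap_pairs = np.stack(
            [haps[2 * chosen], haps[2 * chosen + 1]], axis=1)  # (n, 2, L)
        anc_pairs = np.stack([anc[2 * chosen], anc[2 * chosen + 1]], axis=1)
        calls = hap_pairs.sum(axis=1).astype(np.int8)  # dosage 0/1/2 == call code
        gm = GenotypeMatrix(
            individuals=[f"{stage.stage_id}_{i:03d}" for i in range(n_s)],
            chrom=chrom, pos=pos, ref=ref, alt=alt, calls=calls,
        )
        samples[stage.stage_id] = StageSample(
            genotypes=gm, haplotypes=hap_pairs, ancestry=anc_pairs)

    return SimulationResult(
        demography=demography, genome=genome, samples=samples,
        stage_frequencies=stage_freqs, stage_founding_frequencies=founding_freqs,
        init_frequencies=p0,
    )


# -----------------------------------------------------------------------------
# RAD-seq observation model
# -----------------------------------------------------------------------------

def apply_rad_observation(
    gm_true: GenotypeMatrix,
    obs: ObservationParams,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, CoverageProfile]:
    """Overlay sequencing depth, missingness, and genotype error on truth.

    Depth at (individual, site) is negative-binomial with the individual's
    mean and the shared dispersion (Poisson if dispersion is None); calls at
    depth below ``missing_below_depth`` become missing; retained calls are
    perturbed at ``genotype_error_rate`` (het -> random hom, hom -> het).
    """
    if seed is None:
        raise SimulationError("a seed is required (reproducibility is mandatory)")
    rng = np.random.default_rng(seed)
    n_ind, n_sites = gm_true.calls.shape
    mu = np.broadcast_to(
        np.atleast_1d(np.asarray(obs.mean_depth, dtype=float)), (n_ind,)
    ).astype(float)

    if obs.depth_dispersion is None:
        depth = rng.poisson(mu[:, None], size=(n_ind, n_sites))
    else:
        k = obs.depth_dispersion
        # NB as gamma-Poisson mixture: mean mu, variance mu + mu^2/k
        lam = rng.gamma(shape=k, scale=np.maximum(mu, 1e-12)[:, None] / k,
                        size=(n_ind, n_sites))
        depth = rng.poisson(lam)

    calls = gm_true.calls.copy()
    missing_mask = depth < obs.missing_below_depth
    calls[missing_mask] = MISSING

    if obs.genotype_error_rate > 0:
        err = (rng.random((n_ind, n_sites)) < obs.genotype_error_rate) & ~missing_mask
        het = err & (calls == HET)
        hom = err & ((calls == HOM_REF) | (calls == HOM_ALT))
        calls[het] = np.where(rng.random(int(het.sum())) < 0.5, HOM_REF, HOM_ALT)
        calls[hom] = HET

    gm_obs = GenotypeMatrix(
        individuals=list(gm_true.individuals),
        chrom=gm_true.chrom, pos=gm_true.pos, ref=gm_true.ref, alt=gm_true.alt,
        calls=calls,
    )
    cov = CoverageProfile(
        depth=depth,
        site_footprint=np.full(n_sites, 180, dtype=np.int64),
    )
    return gm_obs, cov
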