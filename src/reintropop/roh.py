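"""Windowed run-of-homozygosity (ROH) detection and the F_ROH coefficient.

The caller follows the three-stage sliding-window scheme of the widely used
plink --homozyg implementation:

1. every contiguous window of ``window_snp`` SNPs is scored homozygous iff it
   contains at most ``window_het_max`` heterozygous and ``window_missing_max``
   missing calls (only full windows are formed, so edge SNPs belong to fewer
   windows);
2. a SNP is flagged as lying in a homozygous segment iff at least
   ``window_hit_threshold`` of the windows containing it scored homozygous
   (the threshold is applied to each SNP's actual window count);
3. maximal runs of flagged SNPs -- split wherever the gap between adjacent
   SNPs exceeds ``gap_max_kb`` -- are emitted as segments iff they contain at
   least ``segment_snp_min`` SNPs, span at least ``segment_kb_min`` kb, carry
   at most ``segment_het_max`` heterozygous calls, and average at least one
   SNP per ``density_min_kb_per_snp`` kb.

Segment length is inclusive: end - start + 1 bp.  Heterozygous calls at run
edges are retained (and counted in ``n_het``), not trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import HET, MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "ROHParams",
    "ROHSegment",
    "ROHProfile",
    "call_roh_chromosome",
    "call_roh",
    "roh_profiles",
    "roh_length_distribution",
    "f_roh",
    "DEFAULT_LENGTH_BINS_MB",
]


class ROHError(ValueError):
    pass


@dataclass(frozen=True)
class ROHParams:
    window_snp: int = 25
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.05
    segment_snp_min: int = 25
    segment_kb_min: float = 1000.0
    segment_het_max: int = 1
    density_min_kb_per_snp: float = 50.0
    gap_max_kb: float = 1000.0
    froh_min_mb: float = 10.0

    def __post_init__(self) -> None:
        for name in ("window_snp", "window_het_max", "window_missing_max",
                     "segment_snp_min", "segment_kb_min", "segment_het_max",
                     "density_min_kb_per_snp", "gap_max_kb", "froh_min_mb"):
            if getattr(self, name) < 0:
                raise ROHError(f"{name} must be non-negative")
        if self.window_snp < 1:
            raise ROHError("window_snp must be >= 1")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ROHError("window_hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    individual: str
    chromosome: str
    start: int  # bp, 1-based inclusive
    end: int    # bp, inclusive
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class ROHProfile:
    individual: str
    segments: list[ROHSegment]
    total_length_mb: float
    total_length_gt5mb: float
    f_roh: float


def call_roh_chromosome(
    calls: np.ndarray,
    positions: np.ndarray,
    params: ROHParams = ROHParams(),
    chromosome: str = "?",
    individual: str = "?",
) -> list[ROHSegment]:
    """Call ROH segments on one chromosome of one individual.

    ``calls`` is a 1-D array over the 4-state alphabet; ``positions`` the
    matching sorted 1-based bp positions.  A chromosome with fewer SNPs than
    one full window yields no segments.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    n = len(calls)
    if positions.shape != (n,):
        raise ROHError("calls and positions length mismatch")
    if n > 1 and (np.diff(positions) <= 0).any():
        raise ROHError(f"{chromosome!r}: positions must be strictly increasing")
    w = params.window_snp
    if n < w:
        return []

    het = (calls == HET).astype(np.int64)
    miss = (calls == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    n_win = n - w + 1
    win_het = chet[w:] - chet[:-w]
    win_miss = cmiss[w:] - cmiss[:-w]
    win_hom = ((win_het <= params.window_het_max)
               & (win_miss <= params.window_missing_max)).astype(np.int64)

    # per-SNP: windows containing SNP i are w-indices [i-w+1, i] clipped to
    # [0, n_win-1]; score against the SNP's actual window count
    chom = np.concatenate([[0], np.cumsum(win_hom)])
    i = np.arange(n)
    lo = np.clip(i - w + 1, 0, n_win - 1)
    hi = np.clip(i, 0, n_win - 1)
    hits = chom[hi + 1] - chom[lo]
    counts = hi - lo + 1
    flagged = hits / counts >= params.window_hit_threshold

    gap_max_bp = params.gap_max_kb * 1000.0
    segments: list[ROHSegment] = []
    j = 0
    while j < n:
        if not flagged[j]:
            j += 1
            continue
        k = j
        while (k + 1 < n and flagged[k + 1]
               and positions[k + 1] - positions[k] <= gap_max_bp):
            k += 1
        run = slice(j, k + 1)
        n_snps = k - j + 1
        length_bp = int(positions[k] - positions[j]) + 1
        n_het = int(het[run].sum())
        if (n_snps >= params.segment_snp_min
                and length_bp >= params.segment_kb_min * 1000.0
                and n_het <= params.segment_het_max
                and length_bp / 1000.0 / n_snps <= params.density_min_kb_per_snp):
            segments.append(ROHSegment(
                individual=individual, chromosome=chromosome,
                start=int(positions[j]), end=int(positions[k]),
                n_snps=n_snps, n_het=n_het,
            ))
        j = k + 1
    return segments


def call_roh(gm: GenotypeMatrix, params: ROHParams = ROHParams()
             ) -> dict[str, list[ROHSegment]]:
    """Call ROH for every individual across all chromosomes of a matrix."""
    out: dict[str, list[ROHSegment]] = {ind: [] for ind in gm.individuals}
    for chrom in gm.chromosomes:
        mask = gm.chrom == chrom
        positions = gm.pos[mask]
        sub = gm.calls[:, mask]
        for i, ind in enumerate(gm.individuals):
            out[ind].extend(call_roh_chromosome(
                sub[i], positions, params, chromosome=chrom, individual=ind))
    return out


def f_roh(segments: list[ROHSegment], froh_min_mb: float,
          autosome_length_bp: int) -> float:
    """Total length of ROH longer than ``froh_min_mb`` Mb divided by the
    autosomal genome length."""
    if autosome_length_bp <= 0:
        raise ROHError("autosome_length_bp must be > 0")
    total = sum(s.length_bp for s in segments if s.length_mb > froh_min_mb)
    return total / autosome_length_bp


def roh_profiles(
    gm: GenotypeMatrix,
    params: ROHParams,
    autosome_length_bp: int,
) -> list[ROHProfile]:
    by_ind = call_roh(gm, params)
    profiles = []
    for ind in gm.individuals:
        segs = by_ind[ind]
        profiles.append(ROHProfile(
            individual=ind,
            segments=segs,
            total_length_mb=sum(s.length_mb for s in segs),
            total_length_gt5mb=sum(s.length_mb for s in segs if s.length_mb > 5.0),
            f_roh=f_roh(segs, params.froh_min_mb, autosome_length_bp),
        ))
    return profiles


DEFAULT_LENGTH_BINS_MB = (1.0, 5.0, 10.0, 20.0, 30.0)


def roh_length_distribution(
    profiles: list[ROHProfile],
    popmap: PopulationMap,
    bin_edges_mb: tuple[float, ...] = DEFAULT_LENGTH_BINS_MB,
) -> dict[str, dict[str, float]]:
    """Per population and ROH length class, the proportion of individuals
    carrying at least one segment in that class.

    Default classes: (1-5], (5-10], (10-20], (20-30], >30 Mb.
    """
    edges = list(bin_edges_mb)
    labels = [f"({edges[i]:g}-{edges[i + 1]:g}]" for i in range(len(edges) - 1)]
    labels.append(f">{edges[-1]:g}")

    by_pop: dict[str, list[ROHProfile]] = {}
    for prof in profiles:
        pop = popmap.population_of(prof.individual)
        by_pop.setdefault(pop, []).append(prof)

    out: dict[str, dict[str, float]] = {}
    for pop, profs in by_pop.items():
        if not profs:
            raise ROHError(f"population {pop!r} has no individuals")
        counts = dict.fromkeys(labels, 0)
        for prof in profs:
            classes = set()
            for seg in prof.segments:
                mb = seg.length_mb
                if mb > edges[-1]:
                    classes.add(labels[-1])
                else:
                    for i in range(len(edges) - 1):
                        if edges[i] < mb <= edges[i + 1]:
                            classes.add(labels[i])
                            break
            for c in classes:
                counts[c] += 1
        out[pop] = {c: counts[c] / len(profs) for c in labels}
    return out


def segments_to_bed(segments: list[ROHSegment]) -> str:
    """BED (0-based half-open) text for a list of segments."""
    lines = [
        f"{s.chromosome}\t{s.start - 1}\t{s.end}\t{s.individual}\t{s.n_snps}\t{s.n_het}"
        for s in segments
    ]
    return "\n".join(lines) + ("\n" if lines else "")
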