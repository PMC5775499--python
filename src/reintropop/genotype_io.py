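"""Genotype, population, and coverage data model plus VCF / population-map I/O.

The central object is :class:`GenotypeMatrix`: an individuals x sites matrix of
diploid genotype calls in a four-state alphabet (homozygous reference,
heterozygous, homozygous alternate, missing), with per-site chromosome,
position, and allele metadata.  Positions are stored 1-based, matching VCF,
and all length arithmetic downstream is in base pairs.

Phase is deliberately discarded at the I/O boundary ("0|1" == "0/1"): every
analysis in this package is phase-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "ROLES",
    "GenotypeMatrix",
    "PopulationMap",
    "CoverageProfile",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "subset",
]

# Genotype call codes (int8).
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_VALID_CALLS = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

#: Closed vocabulary of demographic roles a population may carry.
ROLES = ("autochthonous", "captive", "primary", "secondary", "mixed")

#: Default footprint of one RAD locus in bp: SNPs lie within 90 bp of a cut
#: site and each site is sequenced in both directions (2 x 90 bp).
DEFAULT_SITE_FOOTPRINT = 180


class GenotypeIOError(ValueError):
    """Raised for malformed VCF / population-map input."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a set of individuals at biallelic SNP sites.

    Parameters
    ----------
    individuals
        Unique individual identifiers, one per matrix row.
    chrom, pos, ref, alt
        Per-site metadata.  Sites must be grouped by chromosome (chromosomes
        appear in contiguous blocks, in input order) with strictly increasing
        positions within each chromosome.  ``pos`` is 1-based.
    calls
        ``(n_individuals, n_sites)`` int8 array over
        ``{HOM_REF, HET, HOM_ALT, MISSING}``.
    """

    individuals: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise GenotypeIOError("calls must be a 2-D individuals x sites array")
        n_ind, n_sites = self.calls.shape
        if n_ind != len(self.individuals):
            raise GenotypeIOError(
                f"calls has {n_ind} rows but {len(self.individuals)} individuals"
            )
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if arr.shape != (n_sites,):
                raise GenotypeIOError(f"{name} length does not match calls columns")
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeIOError("individual IDs must be unique")
        bad = ~np.isin(self.calls, list(_VALID_CALLS))
        if bad.any():
            raise GenotypeIOError("calls contain values outside the 4-state alphabet")
        self._check_site_order()

    def _check_site_order(self) -> None:
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise GenotypeIOError(
                        f"sites for chromosome {c!r} are not contiguous"
                    )
                seen.add(c)
                prev_chrom = c
                prev_pos = -1
            if p <= prev_pos:
                raise GenotypeIOError(
                    f"positions not strictly increasing on {c!r} at {int(p)}"
                )
            prev_pos = p

    # -- convenience accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome IDs in order of first appearance."""
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def individual_index(self, individual_id: str) -> int:
        try:
            return self.individuals.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual {individual_id!r}") from None

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage as float (0/1/2), NaN where missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationMap:
    """Assignment of individuals to populations and of populations to roles."""

    assignments: dict[str, str]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for pop, role in self.roles.items():
            if role not in ROLES:
                raise GenotypeIOError(
                    f"unknown role {role!r} for population {pop!r}; "
                    f"expected one of {ROLES}"
                )
        for ind, pop in self.assignments.items():
            if pop not in self.roles:
                raise GenotypeIOError(f"individual {ind!r} assigned to population "
                                      f"{pop!r} with no declared role")

    @property
    def populations(self) -> list[str]:
        return list(self.roles)

    def members(self, population: str) -> list[str]:
        return [i for i, p in self.assignments.items() if p == population]

    def population_of(self, individual: str) -> str:
        return self.assignments[individual]

    def role_of(self, population: str) -> str:
        return self.roles[population]

    def check_covers(self, gm: GenotypeMatrix) -> None:
        missing = [i for i in gm.individuals if i not in self.assignments]
        if missing:
            raise GenotypeIOError(
                f"individuals missing from population map: {missing[:5]}"
            )


@dataclass
class CoverageProfile:
    """Per-individual, per-site read depth plus the bp footprint of each site.

    ``depth[i, j]`` is the number of reads covering site ``j`` in individual
    ``i``; ``site_footprint[j]`` is the number of bases of sequence the site
    stands for when converting covered-site counts to covered base pairs.
    """

    depth: np.ndarray
    site_footprint: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.site_footprint = np.asarray(self.site_footprint, dtype=np.int64)
        if self.depth.ndim != 2:
            raise GenotypeIOError("depth must be 2-D")
        if (self.depth < 0).any():
            raise GenotypeIOError("depth must be non-negative")
        if self.site_footprint.shape != (self.depth.shape[1],):
            raise GenotypeIOError("site_footprint length must match depth columns")
        if (self.site_footprint <= 0).any():
            raise GenotypeIOError("site_footprint must be positive")

    def check_matches(self, gm: GenotypeMatrix) -> None:
        if self.depth.shape != gm.calls.shape:
            raise GenotypeIOError(
                f"coverage shape {self.depth.shape} does not match "
                f"genotype matrix shape {gm.calls.shape}"
            )

    def take(self, individual_idx: Sequence[int] | None = None,
             site_idx: np.ndarray | None = None) -> "CoverageProfile":
        depth = self.depth
        fp = self.site_footprint
        if individual_idx is not None:
            depth = depth[np.asarray(individual_idx, dtype=int), :]
        if site_idx is not None:
            site_idx = np.asarray(site_idx)
            depth = depth[:, site_idx]
            fp = fp[site_idx]
        return CoverageProfile(depth=depth, site_footprint=fp)


# -----------------------------------------------------------------------------
# VCF I/O
# -----------------------------------------------------------------------------

_GT_TO_CALL = {
    ("0", "0"): HOM_REF,
    ("0", "1"): HET,
    ("1", "0"): HET,
    ("1", "1"): HOM_ALT,
}


def read_vcf(path, default_site_footprint: int = DEFAULT_SITE_FOOTPRINT
             ) -> tuple[GenotypeMatrix, CoverageProfile | None]:
    """Read a VCF 4.x file of biallelic SNPs.

    Returns the genotype matrix and, if the file carries a per-genotype ``DP``
    field, a :class:`CoverageProfile` whose ``site_footprint`` is uniformly
    ``default_site_footprint``.  Any genotype containing a missing allele
    (``./.``, ``0/.``, ...) is mapped to :data:`MISSING`; phase separators are
    ignored.

    Raises
    ------
    GenotypeIOError
        On multiallelic records (naming the record), unsorted positions,
        or an empty / headerless file.
    """
    samples: list[str] | None = None
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    call_rows: list[list[int]] = []
    depth_rows: list[list[int]] = []
    has_dp = False

    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 9:
                    raise GenotypeIOError(f"{path}: header line has no samples")
                samples = fields[9:]
                continue
            if samples is None:
                raise GenotypeIOError(
                    f"{path}:{lineno}: data line before #CHROM header"
                )
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise GenotypeIOError(
                    f"{path}:{lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise GenotypeIOError(
                    f"{path}:{lineno}: multiallelic record {chrom}:{pos} "
                    f"(ALT={alt!r}) is not supported"
                )
            fmt_keys = fields[8].split(":")
            if "GT" not in fmt_keys:
                raise GenotypeIOError(f"{path}:{lineno}: record lacks GT field")
            gt_i = fmt_keys.index("GT")
            dp_i = fmt_keys.index("DP") if "DP" in fmt_keys else None
            if dp_i is not None:
                has_dp = True
            calls: list[int] = []
            depths: list[int] = []
            for sample_field in fields[9:]:
                parts = sample_field.split(":")
                gt = parts[gt_i].replace("|", "/")
                alleles = tuple(gt.split("/"))
                call = _GT_TO_CALL.get(alleles, MISSING)
                calls.append(call)
                if dp_i is not None and dp_i < len(parts) and parts[dp_i] not in (".", ""):
                    depths.append(int(parts[dp_i]))
                else:
                    depths.append(0)
            chroms.append(chrom)
            poss.append(int(pos))
            refs.append(ref)
            alts.append(alt)
            call_rows.append(calls)
            depth_rows.append(depths)

    if samples is None:
        raise GenotypeIOError(f"{path}: empty file or missing #CHROM header")

    calls_arr = (np.array(call_rows, dtype=np.int8).T if call_rows
                 else np.zeros((len(samples), 0), dtype=np.int8))
    try:
        gm = GenotypeMatrix(
            individuals=samples,
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            alt=np.array(alts, dtype=object),
            calls=calls_arr,
        )
    except GenotypeIOError as exc:
        raise GenotypeIOError(f"{path}: {exc}") from None

    cov = None
    if has_dp:
        depth_arr = np.array(depth_rows, dtype=np.int64).T
        cov = CoverageProfile(
            depth=depth_arr,
            site_footprint=np.full(gm.n_sites, default_site_footprint, dtype=np.int64),
        )
    return gm, cov


def write_vcf(gm: GenotypeMatrix, path, cov: CoverageProfile | None = None) -> None:
    """Write a GenotypeMatrix (and optional per-genotype depths) as VCF 4.2.

    ``read_vcf(write_vcf(gm)) == gm`` for any valid matrix; missing calls are
    emitted as ``./.``.
    """
    if cov is not None:
        cov.check_matches(gm)
    call_to_gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=reintropop\n")
        for c in gm.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if cov is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individuals) + "\n")
        fmt = "GT:DP" if cov is not None else "GT"
        for j in range(gm.n_sites):
            cells = []
            for i in range(gm.n_individuals):
                gt = call_to_gt[int(gm.calls[i, j])]
                if cov is not None:
                    cells.append(f"{gt}:{int(cov.depth[i, j])}")
                else:
                    cells.append(gt)
            fh.write(f"{gm.chrom[j]}\t{int(gm.pos[j])}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                     f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n")


# -----------------------------------------------------------------------------
# Population map I/O
# -----------------------------------------------------------------------------

def read_population_map(path) -> PopulationMap:
    """Read a whitespace-delimited ``individual population role`` table.

    Role strings come from the closed vocabulary :data:`ROLES`.  Duplicate
    individuals, malformed lines, and unknown roles raise
    :class:`GenotypeIOError` with the offending line number.
    """
    assignments: dict[str, str] = {}
    roles: dict[str, str] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise GenotypeIOError(
                    f"{path}:{lineno}: expected 3 fields "
                    f"(individual, population, role), got {len(parts)}"
                )
            ind, pop, role = parts
            if ind in assignments:
                raise GenotypeIOError(f"{path}:{lineno}: duplicate individual {ind!r}")
            if role not in ROLES:
                raise GenotypeIOError(
                    f"{path}:{lineno}: unknown role {role!r}; expected one of {ROLES}"
                )
            if pop in roles and roles[pop] != role:
                raise GenotypeIOError(
                    f"{path}:{lineno}: population {pop!r} given conflicting roles "
                    f"{roles[pop]!r} and {role!r}"
                )
            assignments[ind] = pop
            roles[pop] = role
    if not assignments:
        raise GenotypeIOError(f"{path}: empty population map")
    return PopulationMap(assignments=assignments, roles=roles)


def write_population_map(popmap: PopulationMap, path) -> None:
    with open(path, "wt") as fh:
        for ind, pop in popmap.assignments.items():
            fh.write(f"{ind}\t{pop}\t{popmap.roles[pop]}\n")


# -----------------------------------------------------------------------------
# Subsetting
# -----------------------------------------------------------------------------

def subset(
    gm: GenotypeMatrix,
    individual_ids: Iterable[str] | None = None,
    site_predicate: Callable[[str, int], bool] | None = None,
    cov: CoverageProfile | None = None,
):
    """Order-preserving projection of a GenotypeMatrix.

    Parameters
    ----------
    individual_ids
        Individuals to keep, in matrix order.  Unknown IDs raise ``KeyError``.
    site_predicate
        ``f(chromosome, position) -> bool``; sites where it returns True are
        kept.
    cov
        Optional aligned CoverageProfile; if given, the return value is a
        ``(GenotypeMatrix, CoverageProfile)`` pair subset in lockstep.
    """
    if individual_ids is None:
        ind_idx = list(range(gm.n_individuals))
    else:
        wanted = set(individual_ids)
        unknown = wanted - set(gm.individuals)
        if unknown:
            raise KeyError(f"unknown individuals: {sorted(unknown)}")
        ind_idx = [i for i, name in enumerate(gm.individuals) if name in wanted]

    if site_predicate is None:
        site_mask = np.ones(gm.n_sites, dtype=bool)
    else:
        site_mask = np.fromiter(
            (bool(site_predicate(c, int(p))) for c, p in zip(gm.chrom, gm.pos)),
            dtype=bool, count=gm.n_sites,
        )
    site_idx = np.flatnonzero(site_mask)
    out = GenotypeMatrix(
        individuals=[gm.individuals[i] for i in ind_idx],
        chrom=gm.chrom[site_idx],
        pos=gm.pos[site_idx],
        ref=gm.ref[site_idx],
        alt=gm.alt[site_idx],
        calls=gm.calls[np.ix_(ind_idx, site_idx)],
    )
    if cov is not None:
        cov.check_matches(gm)
        return out, cov.take(ind_idx, site_idx)
    return out


def take_sites(gm: GenotypeMatrix, site_idx: np.ndarray) -> GenotypeMatrix:
    """Project a matrix onto the given (sorted) site indices."""
    site_idx = np.asarray(site_idx)
    return GenotypeMatrix(
        individuals=list(gm.individuals),
        chrom=gm.chrom[site_idx],
        pos=gm.pos[site_idx],
        ref=gm.ref[site_idx],
        alt=gm.alt[site_idx],
        calls=gm.calls[:, site_idx],
    )
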