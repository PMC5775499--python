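"""SNP-panel construction filters.

Builds analysis panels from a raw genotype matrix by composable site filters:
per-group and overall genotyping-rate minima, removal of monomorphic sites,
removal of singletons and private doubletons (minor allele confined to a
single individual), a minor-allele-frequency floor, a coverage-based paralog
filter, and greedy distance thinning.

Filters run in a fixed order (genotyping rate -> monomorphic ->
singleton/private-doubleton -> MAF) because later judgments depend on which
calls survive the missingness step; the order is configurable only by
composing the primitives directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CoverageProfile,
    GenotypeMatrix,
    take_sites,
)

__all__ = [
    "PanelSpec",
    "PANEL_PRESETS",
    "build_panel",
    "panel_site_mask",
    "coverage_paralog_filter",
    "thin_by_distance",
]


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class PanelSpec:
    """Declarative description of one SNP panel.

    ``per_group_rate_min`` maps group IDs to the minimum fraction of
    non-missing calls a site must reach within that group; ``overall_rate_min``
    applies across all individuals.  ``remove_monomorphic`` and
    ``remove_singletons_and_private_doubletons`` are judged within the scope
    of the supplied grouping (all individuals pooled).
    """

    name: str = "custom"
    per_group_rate_min: dict[str, float] = field(default_factory=dict)
    overall_rate_min: float = 0.0
    remove_monomorphic: bool = True
    remove_singletons_and_private_doubletons: bool = True
    maf_min: float | None = None

    def __post_init__(self) -> None:
        for g, f in self.per_group_rate_min.items():
            if not 0.0 <= f <= 1.0:
                raise PanelError(f"group {g!r}: rate minimum {f} outside [0, 1]")
        if not 0.0 <= self.overall_rate_min <= 1.0:
            raise PanelError("overall_rate_min outside [0, 1]")
        if self.maf_min is not None and not 0.0 <= self.maf_min <= 1.0:
            raise PanelError("maf_min outside [0, 1]")

    @classmethod
    def preset(cls, name: str, groups: list[str] | None = None) -> "PanelSpec":
        """Named presets.

        general: overall genotyping rate >= 45%.
        multispecies: rate >= 50% within each group and >= 60% overall.
        intraspecies: rate > 80% within each group.
        All presets drop monomorphic sites, singletons and private doubletons.
        """
        groups = groups or []
        if name == "general":
            return cls(name=name, overall_rate_min=0.45)
        if name == "multispecies":
            return cls(name=name, overall_rate_min=0.60,
                       per_group_rate_min={g: 0.50 for g in groups})
        if name == "intraspecies":
            return cls(name=name, per_group_rate_min={g: 0.80 for g in groups})
        raise PanelError(f"unknown panel preset {name!r}")


PANEL_PRESETS = ("general", "multispecies", "intraspecies")


def _rate(calls: np.ndarray) -> np.ndarray:
    """Fraction of non-missing calls per site (0 for an empty group)."""
    if calls.shape[0] == 0:
        return np.zeros(calls.shape[1])
    return (calls != MISSING).mean(axis=0)


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, total called allele count) per site."""
    alt = ((calls == HET).sum(axis=0) + 2 * (calls == HOM_ALT).sum(axis=0))
    tot = 2 * (calls != MISSING).sum(axis=0)
    return alt.astype(np.int64), tot.astype(np.int64)


def panel_site_mask(
    gm: GenotypeMatrix,
    groups: dict[str, list[str]],
    spec: PanelSpec,
) -> np.ndarray:
    """Boolean mask of sites retained by ``spec``, applying the filters in the
    fixed order: genotyping rate, monomorphic, singleton/private-doubleton,
    MAF."""
    if not groups:
        raise PanelError("empty grouping")
    idx_of = {name: i for i, name in enumerate(gm.individuals)}
    group_idx: dict[str, np.ndarray] = {}
    for g, members in groups.items():
        unknown = [m for m in members if m not in idx_of]
        if unknown:
            raise PanelError(f"group {g!r} names unknown individuals: {unknown[:5]}")
        group_idx[g] = np.array([idx_of[m] for m in members], dtype=int)
    covered = sorted({m for ms in groups.values() for m in ms})
    if covered != sorted(gm.individuals):
        raise PanelError("grouping must cover every individual exactly")

    keep = np.ones(gm.n_sites, dtype=bool)

    # 1. genotyping rate
    keep &= _rate(gm.calls) >= spec.overall_rate_min
    for g, fmin in spec.per_group_rate_min.items():
        if g not in group_idx:
            raise PanelError(f"rate minimum given for unknown group {g!r}")
        keep &= _rate(gm.calls[group_idx[g], :]) >= fmin

    calls = gm.calls
    alt, tot = _allele_counts(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    minor = np.minimum(alt, tot - alt)

    # 2. monomorphic (within the grouping scope, on surviving calls)
    if spec.remove_monomorphic:
        keep &= (minor > 0) & (tot > 0)

    # 3. singletons and private doubletons: minor allele confined to a single
    # individual, either as one het (singleton) or one homozygote (doubleton)
    if spec.remove_singletons_and_private_doubletons:
        minor_is_alt = alt <= tot - alt
        het_n = (calls == HET).sum(axis=0)
        hom_minor_n = np.where(
            minor_is_alt, (calls == HOM_ALT).sum(axis=0),
            (calls == HOM_REF).sum(axis=0))
        carriers = het_n + hom_minor_n
        private = (minor > 0) & (carriers == 1)
        keep &= ~private

    # 4. MAF floor
    if spec.maf_min is not None:
        maf = np.where(tot > 0, np.minimum(p_alt, 1.0 - p_alt), 0.0)
        keep &= maf >= spec.maf_min

    return keep


def build_panel(
    gm: GenotypeMatrix,
    groups: dict[str, list[str]],
    spec: PanelSpec,
    cov: CoverageProfile | None = None,
):
    """Apply ``spec`` and return the retained sites (a projection of ``gm``).

    ``groups`` maps group IDs (species or populations) to individual IDs and
    must cover every individual in ``gm``.  With ``cov`` given, returns the
    panel and the coverage profile subset in lockstep.
    """
    mask = panel_site_mask(gm, groups, spec)
    site_idx = np.flatnonzero(mask)
    out = take_sites(gm, site_idx)
    if cov is not None:
        cov.check_matches(gm)
        return out, cov.take(None, site_idx)
    return out


def coverage_paralog_filter(
    gm: GenotypeMatrix,
    cov: CoverageProfile,
    fold_max: float = 2.0,
    return_cov: bool = False,
):
    """Drop sites whose normalized coverage marks them as likely paralogs.

    Depth is first normalized per individual by that individual's mean depth
    across sites; a site is removed when its mean normalized depth across
    individuals is at least ``fold_max`` (default twofold).  The filter is
    invariant to rescaling any individual's depths.
    """
    cov.check_matches(gm)
    mean_per_ind = cov.depth.mean(axis=1)
    if (mean_per_ind == 0).any():
        raise PanelError("individual with all-zero depth; cannot normalize")
    norm = cov.depth / mean_per_ind[:, None]
    site_score = norm.mean(axis=0)
    keep = site_score < fold_max
    site_idx = np.flatnonzero(keep)
    out = take_sites(gm, site_idx)
    if return_cov:
        return out, cov.take(None, site_idx)
    return out


def thin_by_distance(
    gm: GenotypeMatrix,
    min_bp: int,
    cov: CoverageProfile | None = None,
):
    """Greedy left-to-right thinning: per chromosome keep the first site, then
    every site at least ``min_bp`` from the last kept site."""
    keep = np.zeros(gm.n_sites, dtype=bool)
    last_chrom: str | None = None
    last_pos = None
    for j, (c, p) in enumerate(zip(gm.chrom, gm.pos)):
        if c != last_chrom or last_pos is None or p - last_pos >= min_bp:
            keep[j] = True
            last_chrom, last_pos = c, p
    site_idx = np.flatnonzero(keep)
    out = take_sites(gm, site_idx)
    if cov is not None:
        cov.check_matches(gm)
        return out, cov.take(None, site_idx)
    return out
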