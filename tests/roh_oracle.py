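"""Independent brute-force ROH oracle used by the unit and acceptance suites.

Deliberately written as plain Python loops with no shared code paths with the
package caller: windows are re-enumerated per SNP, runs are scanned naively.
"""

import numpy as np

from reintropop.genotype_io import HET, MISSING
from reintropop.roh import ROHParams


def oracle_roh(calls, positions, p: ROHParams):
    """Return segments as (start_bp, end_bp, n_snps, n_het) tuples."""
    calls = list(int(c) for c in calls)
    positions = list(int(x) for x in positions)
    n = len(calls)
    w = p.window_snp
    if n < w:
        return []

    window_hom = []
    for start in range(n - w + 1):
        win = calls[start:start + w]
        n_het = sum(1 for c in win if c == HET)
        n_mis = sum(1 for c in win if c == MISSING)
        window_hom.append(n_het <= p.window_het_max
                          and n_mis <= p.window_missing_max)

    flagged = []
    for i in range(n):
        containing = [wi for wi in range(len(window_hom))
                      if wi <= i <= wi + w - 1]
        frac = sum(1 for wi in containing if window_hom[wi]) / len(containing)
        flagged.append(frac >= p.window_hit_threshold)

    segments = []
    i = 0
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and flagged[j + 1]
               and positions[j + 1] - positions[j] <= p.gap_max_kb * 1000):
            j += 1
        n_snps = j - i + 1
        length_bp = positions[j] - positions[i] + 1
        n_het = sum(1 for c in calls[i:j + 1] if c == HET)
        if (n_snps >= p.segment_snp_min
                and length_bp >= p.segment_kb_min * 1000
                and n_het <= p.segment_het_max
                and (length_bp / 1000) / n_snps <= p.density_min_kb_per_snp):
            segments.append((positions[i], positions[j], n_snps, n_het))
        i = j + 1
    return segments


def random_fixture(rng, max_snps=400):
    """Random single-chromosome fixture biased toward homozygosity so that
    segments actually occur, with occasional ROH-splitting gaps."""
    n = int(rng.integers(5, max_snps))
    p_het = rng.uniform(0.0, 0.12)
    p_mis = rng.uniform(0.0, 0.12)
    p_hom = 1.0 - p_het - p_mis
    calls = rng.choice([0, 1, 2, -1], size=n,
                       p=[p_hom * 0.6, p_het, p_hom * 0.4, p_mis])
    gaps = rng.integers(1, 120_000, size=n)
    big = rng.random(n) < 0.02
    gaps[big] = rng.integers(900_000, 2_500_000, size=int(big.sum()))
    positions = np.cumsum(gaps)
    return calls.astype("int8"), positions.astype("int64")
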