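"""Window D and fd statistics from population allele frequencies.

For the quartet tree ((P1, P2), P3, O) and derived-allele frequencies
p1, p2, p3, p4, each site contributes

    ABBA = (1 - p1) p2 p3 (1 - p4)
    BABA = p1 (1 - p2) p3 (1 - p4)

D is (sum ABBA - sum BABA) / (sum ABBA + sum BABA). fd normalizes the same
numerator by its value under complete donor sharing, substituting for both P2
and P3 the per-site dynamic donor pD = max(p2, p3):

    fd = sum(ABBA - BABA) / sum(ABBA_D - BABA_D)

fd is reported only for windows where both sums are positive (an excess of
shared derived variation in the tested P3 -> P2 direction); windows with a
zero or negative numerator are never introgression candidates and carry an
undefined fd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import PopSiteFrequencies
from .window_stats import (DEFAULT_MIN_SITES, Window, chrom_slices,
                           usable_sites)


@dataclass(frozen=True)
class QuartetConfig:
    """Role assignment for one ABBA-BABA test; donor_label notes which
    riverine population P3 stands for (e.g. "MM" or "CR")."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    donor_label: str = ""

    def __post_init__(self) -> None:
        labels = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(labels)) != 4:
            raise ValueError(f"quartet roles must be four distinct populations, got {labels}")

    @property
    def focal_pops(self) -> list[str]:
        return [self.p1, self.p2, self.p3, self.outgroup]

    @property
    def label(self) -> str:
        donor = f"[{self.donor_label}]" if self.donor_label else ""
        return f"(({self.p1},{self.p2}),{self.p3}{donor},{self.outgroup})"


@dataclass
class FdResult:
    window: Window
    n_sites_used: int
    abba_sum: float
    baba_sum: float
    s_num: float
    s_den: float
    usable: bool

    @property
    def d(self) -> float:
        tot = self.abba_sum + self.baba_sum
        return (self.abba_sum - self.baba_sum) / tot if tot > 0 else float("nan")

    @property
    def fd(self) -> float:
        """Admixture-proportion estimate; NaN when undefined (unusable window,
        non-positive numerator, or zero denominator)."""
        if not self.usable or self.s_num <= 0 or self.s_den <= 0:
            return float("nan")
        return self.s_num / self.s_den


def site_pattern_terms(p1, p2, p3, p4):
    """Vectorized per-site (ABBA, BABA) terms from derived frequencies."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def d_statistic(abba, baba) -> float:
    """(sum ABBA - sum BABA) / (sum ABBA + sum BABA); NaN on a zero denominator."""
    a, b = float(np.sum(abba)), float(np.sum(baba))
    return (a - b) / (a + b) if a + b > 0 else float("nan")


def fd_statistic(window: Window, freqs: PopSiteFrequencies, quartet: QuartetConfig,
                 min_sites: int = DEFAULT_MIN_SITES,
                 slices: dict[str, tuple[int, int]] | None = None) -> FdResult:
    """Compute D and fd over one window.

    Uses only sites fully called in all four quartet populations; the window
    is unusable (fd undefined) below ``min_sites`` such sites.
    """
    idx = usable_sites(window, freqs, quartet.focal_pops, slices)
    p_der = freqs.derived_frequencies(quartet.outgroup)
    rows = [freqs.pop_index(p) for p in quartet.focal_pops]
    p1, p2, p3, p4 = (p_der[r, idx] for r in rows)
    abba, baba = site_pattern_terms(p1, p2, p3, p4)
    pd_ = np.maximum(p2, p3)
    abba_d, baba_d = site_pattern_terms(p1, pd_, pd_, p4)
    return FdResult(
        window=window,
        n_sites_used=int(idx.size),
        abba_sum=float(np.sum(abba)),
        baba_sum=float(np.sum(baba)),
        s_num=float(np.sum(abba - baba)),
        s_den=float(np.sum(abba_d - baba_d)),
        usable=idx.size >= min_sites,
    )


def fd_scan(windows: list[Window], freqs: PopSiteFrequencies, quartet: QuartetConfig,
            min_sites: int = DEFAULT_MIN_SITES) -> list[FdResult]:
    slices = chrom_slices(freqs)
    return [fd_statistic(w, freqs, quartet, min_sites, slices) for w in windows]


def fd_table(results: list[FdResult], quartet: QuartetConfig):
    """Manhattan-ready DataFrame, 1-based inclusive window coordinates."""
    import pandas as pd

    return pd.DataFrame(
        {
            "quartet": quartet.label,
            "chrom": r.window.chrom,
            "start": r.window.start_1based,
            "end": r.window.end_1based,
            "n_sites_used": r.n_sites_used,
            "D": r.d,
            "fd": r.fd,
            "s_num": r.s_num,
            "s_den": r.s_den,
        }
        for r in results
    )
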