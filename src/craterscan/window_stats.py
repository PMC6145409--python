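"""Sliding windows and per-window diversity (pi) / divergence (Dxy).

Windows are 50 kb by default, advanced in 5-kb steps, internally 0-based
half-open; exported coordinates are 1-based inclusive. A window is *usable*
for a given test when it holds at least ``min_sites`` variant sites at which
every member of every focal population is called (the strictest reading of
"no missing data within a population") and at least one focal population is
polymorphic or fixed differently from another.

pi and Dxy are per-bp, normalized by the full window length by default
(invariant sites are absent from a VCF, so this is a lower bound on the true
per-bp values); ``denominator="sites"`` divides by the usable-site count
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import PopSiteFrequencies

DEFAULT_WINDOW_BP = 50_000
DEFAULT_STEP_BP = 5_000
DEFAULT_MIN_SITES = 100


@dataclass(frozen=True, order=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


@dataclass
class WindowStatRecord:
    window: Window
    n_variant_usable: int
    usable: bool
    pi: dict[str, float] = field(default_factory=dict)
    dxy: dict[tuple[str, str], float] = field(default_factory=dict)


def make_windows(chrom_lengths: dict[str, int], size: int = DEFAULT_WINDOW_BP,
                 step: int = DEFAULT_STEP_BP) -> list[Window]:
    """Sliding windows fully contained in each chromosome.

    Starts at 0, step, 2*step, ...; a trailing span shorter than ``size``
    emits no window.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed window size")
    windows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length - size + 1, step):
            windows.append(Window(chrom, start, start + size))
    return windows


def chrom_slices(freqs: PopSiteFrequencies) -> dict[str, tuple[int, int]]:
    """Contiguous [lo, hi) site-index range per chromosome (sites are sorted)."""
    slices: dict[str, tuple[int, int]] = {}
    chroms = freqs.chroms
    if len(chroms) == 0:
        return slices
    boundaries = np.nonzero(chroms[1:] != chroms[:-1])[0] + 1
    edges = [0, *boundaries.tolist(), len(chroms)]
    for lo, hi in zip(edges, edges[1:]):
        slices[str(chroms[lo])] = (lo, hi)
    return slices


def window_site_indices(window: Window, freqs: PopSiteFrequencies,
                        slices: dict[str, tuple[int, int]] | None = None) -> np.ndarray:
    """Indices of sites whose (1-based) position falls in the window."""
    if slices is None:
        slices = chrom_slices(freqs)
    if window.chrom not in slices:
        return np.empty(0, dtype=np.intp)
    lo, hi = slices[window.chrom]
    pos = freqs.positions[lo:hi]
    # 1-based pos p lies in 0-based half-open [start, end) iff start < p <= end
    a = np.searchsorted(pos, window.start + 1, side="left")
    b = np.searchsorted(pos, window.end, side="right")
    return np.arange(lo + a, lo + b, dtype=np.intp)


def usable_sites(window: Window, freqs: PopSiteFrequencies, focal_pops: list[str],
                 slices: dict[str, tuple[int, int]] | None = None) -> np.ndarray:
    """Variant sites in the window fully called in every focal population.

    A site also has to be variant *within* the focal set: some focal
    population polymorphic, or two focal populations fixed for different
    alleles.
    """
    if not focal_pops:
        raise ValueError("focal_pops must be non-empty")
    idx = window_site_indices(window, freqs, slices)
    if idx.size == 0:
        return idx
    rows = [freqs.pop_index(p) for p in focal_pops]
    full = np.ones(idx.size, dtype=bool)
    for p, r in zip(focal_pops, rows):
        full &= freqs.n_called[r, idx] == 2 * freqs.pop_sizes[p]
    p_sub = freqs.p_alt[np.ix_(rows, idx)]
    poly = ((p_sub > 0) & (p_sub < 1)).any(axis=0)
    fixed_diff = (p_sub.max(axis=0) - p_sub.min(axis=0)) > 0
    return idx[full & (poly | fixed_diff)]


def pi_window(window: Window, freqs: PopSiteFrequencies, pop: str,
              slices: dict[str, tuple[int, int]] | None = None,
              denominator: str = "window") -> float:
    """Per-bp nucleotide diversity: sum over sites of [n/(n-1)] 2p(1-p) / L.

    n is the number of called allele copies at the site; sites with n < 2
    contribute nothing. Returns NaN if the population is uncalled at every
    site in the window.
    """
    idx = window_site_indices(window, freqs, slices)
    r = freqs.pop_index(pop)
    n = freqs.n_called[r, idx]
    ok = n >= 2
    if idx.size and not (n > 0).any():
        return float("nan")
    p = freqs.p_alt[r, idx[ok]]
    nn = n[ok].astype(float)
    total = float(np.sum(nn / (nn - 1.0) * 2.0 * p * (1.0 - p)))
    L = window.length if denominator == "window" else max(int(ok.sum()), 1)
    return total / L


def dxy_window(window: Window, freqs: PopSiteFrequencies, pop_x: str, pop_y: str,
               slices: dict[str, tuple[int, int]] | None = None,
               denominator: str = "window") -> float:
    """Per-bp divergence: sum over sites of pX(1-pY) + pY(1-pX), over L."""
    if pop_x == pop_y:
        raise ValueError("Dxy requires two distinct populations")
    idx = window_site_indices(window, freqs, slices)
    rx, ry = freqs.pop_index(pop_x), freqs.pop_index(pop_y)
    px, py = freqs.p_alt[rx, idx], freqs.p_alt[ry, idx]
    ok = ~(np.isnan(px) | np.isnan(py))
    if idx.size and not ok.any():
        return float("nan")
    total = float(np.sum(px[ok] * (1 - py[ok]) + py[ok] * (1 - px[ok])))
    L = window.length if denominator == "window" else max(int(ok.sum()), 1)
    return total / L


def compute_window_stats(windows: list[Window], freqs: PopSiteFrequencies,
                 pops: list[str], min_sites: int = DEFAULT_MIN_SITES,
                 denominator: str = "window") -> list[WindowStatRecord]:
    """pi per population and Dxy per pair over each window."""
    slices = chrom_slices(freqs)
    records = []
    for w in windows:
        idx = usable_sites(w, freqs, pops, slices)
        rec = WindowStatRecord(w, int(idx.size), idx.size >= min_sites)
        for p in pops:
            rec.pi[p] = pi_window(w, freqs, p, slices, denominator)
        for i, x in enumerate(pops):
            for y in pops[i + 1:]:
                rec.dxy[(x, y)] = dxy_window(w, freqs, x, y, slices, denominator)
        records.append(rec)
    return records


def stats_table(records: list[WindowStatRecord]):
    """Long-to-wide TSV-ready DataFrame (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for rec in records:
        row = {
            "chrom": rec.window.chrom,
            "start": rec.window.start_1based,
            "end": rec.window.end_1based,
            "n_variant_usable": rec.n_variant_usable,
            "usable": rec.usable,
        }
        for p, v in rec.pi.items():
            row[f"pi_{p}"] = v
        for (x, y), v in rec.dxy.items():
            row[f"dxy_{x}_{y}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
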