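"""Genome-wide f4 test with delete-one-block jackknife standard error.

f4(A,B;C,D) is the mean over usable sites of (pA - pB)(pC - pD). Under a
bifurcating history ((A,B),(C,D)) with no gene flow its expectation is zero;
a significant departure indicates differential introgression between one of
{A,B} and one of {C,D}. The statistic is invariant to which allele is counted
at each site (both factors flip sign), so unpolarized alt-allele frequencies
are used.

The standard error comes from a delete-one-block jackknife over blocks of
1000 adjacent usable SNPs (never spanning chromosomes), which absorbs
linkage disequilibrium; Z = f4/SE is referred to the standard normal,
p = 2 Phi(-|Z|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .genotype_io import PopSiteFrequencies

DEFAULT_BLOCK_SIZE = 1000


@dataclass
class F4Result:
    quartet: tuple[str, str, str, str]
    f4: float
    se: float
    z: float
    p: float
    n_sites: int
    n_blocks: int
    block_size: int


def f4_site_products(freqs: PopSiteFrequencies,
                     quartet: tuple[str, str, str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (pA-pB)(pC-pD) over sites where all four populations have at
    least one called genotype; returns (products, site indices)."""
    rows = [freqs.pop_index(p) for p in quartet]
    pa, pb, pc, pd_ = (freqs.p_alt[r] for r in rows)
    ok = ~(np.isnan(pa) | np.isnan(pb) | np.isnan(pc) | np.isnan(pd_))
    idx = np.nonzero(ok)[0]
    return ((pa - pb) * (pc - pd_))[idx], idx


def f4_point(products: np.ndarray) -> float:
    if products.size == 0:
        raise ValueError("f4 requires at least one usable site")
    return float(np.mean(products))


def assign_blocks(chroms: np.ndarray, block_size: int = DEFAULT_BLOCK_SIZE) -> np.ndarray:
    """Block id per site: consecutive runs of ``block_size`` usable SNPs in
    genome order, restarting at chromosome boundaries.

    A trailing partial block keeps its own id if it holds at least half of
    ``block_size`` SNPs, otherwise it is merged into the previous block of the
    same chromosome (a chromosome with fewer than block_size/2 SNPs in total
    still forms one block of its own).
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    ids = np.empty(len(chroms), dtype=np.int64)
    next_id = 0
    i = 0
    n = len(chroms)
    while i < n:
        j = i
        while j < n and chroms[j] == chroms[i]:
            j += 1
        span = j - i
        n_full = span // block_size
        tail = span % block_size
        for b in range(n_full):
            ids[i + b * block_size: i + (b + 1) * block_size] = next_id
            next_id += 1
        if tail:
            if tail >= block_size // 2 or n_full == 0:
                ids[j - tail: j] = next_id
                next_id += 1
            else:
                ids[j - tail: j] = next_id - 1  # merge into previous block
        i = j
    return ids


def block_jackknife(products: np.ndarray, chroms: np.ndarray,
                    block_size: int = DEFAULT_BLOCK_SIZE) -> tuple[float, int]:
    """Delete-one-block jackknife SE of the mean of ``products``.

    se = sqrt[((B-1)/B) * sum_j (theta_-j - mean(theta_-.))^2].
    """
    ids = assign_blocks(chroms, block_size)
    n_blocks = int(ids.max()) + 1 if ids.size else 0
    if n_blocks < 2:
        raise ValueError(
            f"block jackknife needs >= 2 blocks, got {n_blocks}; "
            "reduce block_size or supply more SNPs"
        )
    total = products.sum()
    n = products.size
    block_sums = np.bincount(ids, weights=products, minlength=n_blocks)
    block_ns = np.bincount(ids, minlength=n_blocks)
    theta_minus = (total - block_sums) / (n - block_ns)
    se = float(np.sqrt((n_blocks - 1) / n_blocks
                       * np.sum((theta_minus - theta_minus.mean()) ** 2)))
    return se, n_blocks


def z_and_p(f4: float, se: float) -> tuple[float, float]:
    """Z = f4/SE and the two-sided normal p-value 2 Phi(-|Z|)."""
    if se == 0:
        import logging

        logging.getLogger("craterscan").warning(
            "jackknife SE is exactly 0 (degenerate products); p reported as 0"
        )
        return float("inf") if f4 > 0 else -float("inf") if f4 < 0 else 0.0, 0.0
    z = f4 / se
    return z, float(2.0 * norm.cdf(-abs(z)))


def f4_test(freqs: PopSiteFrequencies, quartet: tuple[str, str, str, str],
            block_size: int = DEFAULT_BLOCK_SIZE) -> F4Result:
    """Full genome-wide f4 test for one quartet (A,B;C,D)."""
    products, idx = f4_site_products(freqs, quartet)
    f4 = f4_point(products)
    se, n_blocks = block_jackknife(products, freqs.chroms[idx], block_size)
    z, p = z_and_p(f4, se)
    return F4Result(tuple(quartet), f4, se, z, p, products.size, n_blocks, block_size)


def f4_table(results: list[F4Result]):
    """One row per quartet test, Table-style layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "A": r.quartet[0],
            "B": r.quartet[1],
            "C": r.quartet[2],
            "D": r.quartet[3],
            "f4": r.f4,
            "se": r.se,
            "z": r.z,
            "p": r.p,
            "n_sites": r.n_sites,
            "n_blocks": r.n_blocks,
        }
        for r in results
    )
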