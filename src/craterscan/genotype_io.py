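"""Variant and population input: VCF -> genotype matrix -> per-population allele frequencies.

Only biallelic SNPs are retained. Genotypes are stored as diploid alt-allele
dosages in {0, 1, 2}, with -1 marking a missing call. Frequencies are computed
per population per site from called allele copies only; a population with no
called genotype at a site has an undefined (NaN) frequency.

Polarization convention: the *derived* allele at a site is the allele that is
minor (frequency < 0.5) in the designated distant outgroup; at an exact tie
(outgroup frequency 0.5) the alt allele is treated as derived so that results
are deterministic. Sites where the outgroup is entirely uncalled cannot be
polarized and carry NaN derived frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger("craterscan")

MISSING = -1


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for all samples.

    ``calls`` is an (n_sites, n_samples) int8 array of alt-allele dosages,
    with :data:`MISSING` for uncalled genotypes. Sites are sorted by
    (chrom, pos) with no duplicates.
    """

    sites: list[VariantSite]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype dosages must be in {0,1,2} or MISSING")
        seen_chroms: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = 0
        for s in self.sites:
            if s.chrom != prev_chrom:
                if s.chrom in seen_chroms:
                    raise ValueError(f"chromosome {s.chrom!r} blocks are interleaved")
                seen_chroms.add(s.chrom)
                prev_chrom, prev_pos = s.chrom, 0
            if s.pos <= prev_pos:
                raise ValueError(
                    f"sites must be position-sorted without duplicates "
                    f"({s.chrom}:{s.pos} after {prev_pos})")
            prev_pos = s.pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)


@dataclass
class PopulationMap:
    """Sample -> population assignment with deterministic population order."""

    assignments: dict[str, str]
    populations: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        pops: dict[str, list[str]] = {}
        for sample, pop in self.assignments.items():
            pops.setdefault(pop, []).append(sample)
        self.populations = {p: pops[p] for p in sorted(pops)}

    def indices(self, matrix: GenotypeMatrix, pop: str) -> np.ndarray:
        """Column indices of ``pop``'s members in ``matrix``."""
        cols = {s: i for i, s in enumerate(matrix.samples)}
        return np.array([cols[s] for s in self.populations[pop]], dtype=np.intp)


@dataclass
class PopSiteFrequencies:
    """Per-population allele counts and frequencies at every site.

    ``n_called[p, i]`` is the number of called allele copies (2 per called
    diploid) of population ``p`` at site ``i``; ``p_alt[p, i]`` the alt-allele
    frequency (NaN when ``n_called`` is 0). Site coordinates are carried along
    so downstream window modules need no separate handle on the matrix.
    """

    pops: list[str]
    pop_sizes: dict[str, int]
    chroms: np.ndarray
    positions: np.ndarray
    n_called: np.ndarray
    p_alt: np.ndarray

    def pop_index(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None

    def derived_frequencies(self, outgroup: str) -> np.ndarray:
        """Frequencies of the derived allele, polarized by the outgroup.

        Derived = the outgroup's minor allele; ties (outgroup frequency exactly
        0.5) treat alt as derived. Sites with an uncalled outgroup get NaN in
        every population.
        """
        o = self.pop_index(outgroup)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
            alt_is_derived = ~(self.p_alt[o] > 0.5)
        p_der = np.where(alt_is_derived[None, :], self.p_alt, 1.0 - self.p_alt)
        p_der[:, np.isnan(self.p_alt[o])] = np.nan
        return p_der


def read_vcf(path: str, min_samples_called: int = 1) -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Keeps only biallelic SNP records; drops indels, multiallelic sites,
    records with fewer than ``min_samples_called`` called genotypes, and
    records monomorphic across all remaining calls. Record order is preserved.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except OSError as exc:
        raise FileNotFoundError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            continue
        # gts012 mode: gt_types is 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        dosage = rec.gt_types.astype(np.int8)
        missing = dosage == 3
        dosage[missing] = MISSING
        n_called = int((~missing).sum())
        if n_called < min_samples_called:
            continue
        called = dosage[~missing]
        if called.min() == called.max() and called[0] in (0, 2):
            continue  # monomorphic after filtering
        sites.append(VariantSite(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        rows.append(dosage)
    if not sites:
        logger.warning("no usable biallelic SNPs in %s", path)
        return GenotypeMatrix([], samples, np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(sites, samples, np.array(rows, dtype=np.int8))


def read_population_map(path: str, matrix: GenotypeMatrix) -> PopulationMap:
    """Read a two-column TSV (sample<TAB>population); must cover all samples.

    Samples in the TSV but not in the matrix are ignored with a warning;
    matrix samples missing from the TSV, or listed twice, are fatal.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected sample<TAB>population")
            sample, pop = parts
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
    in_matrix = set(matrix.samples)
    missing = [s for s in matrix.samples if s not in assignments]
    if missing:
        raise ValueError(f"population map misses samples: {', '.join(missing)}")
    extras = sorted(set(assignments) - in_matrix)
    if extras:
        logger.warning("population map lists samples absent from VCF: %s", ", ".join(extras))
        assignments = {s: p for s, p in assignments.items() if s in in_matrix}
    return PopulationMap(assignments)


def allele_frequencies(matrix: GenotypeMatrix, popmap: PopulationMap) -> PopSiteFrequencies:
    """Per-population alt-allele frequencies at every site.

    p_alt = (alt allele copies) / (2 x called diploids); missing genotypes are
    excluded from numerator and denominator.
    """
    pops = list(popmap.populations)
    n_pops, n_sites = len(pops), matrix.n_sites
    n_called = np.zeros((n_pops, n_sites), dtype=np.int64)
    p_alt = np.full((n_pops, n_sites), np.nan)
    for k, pop in enumerate(pops):
        sub = matrix.calls[:, popmap.indices(matrix, pop)]
        called = sub != MISSING
        n = 2 * called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        n_called[k] = n
        ok = n > 0
        p_alt[k, ok] = alt[ok] / n[ok]
    sizes = {p: len(popmap.populations[p]) for p in pops}
    return PopSiteFrequencies(pops, sizes, matrix.chroms, matrix.positions, n_called, p_alt)
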