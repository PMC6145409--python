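"""Candidate introgressed regions: calling, sharing categories, hybrid-swarm
overlap and sweep screening.

Windows whose fd exceeds the simulation-calibrated threshold are merged
(overlapping or abutting) into maximal candidate regions per focal species
and donor. Regions are then compared *across* species scans against the same
donor and placed into exactly one of three sharing categories:

``PRIVATE``
    found in a single lake species only;
``SHARED_SUBCLADE``
    overlapping (>= 1 bp) a candidate region of another species of the same
    subclade — introgression before the subclade diverged;
``SHARED_CLADE``
    overlapping a candidate of a species in a different subclade — secondary
    gene flow into multiple subclades or differential sorting out of an
    ancestral hybrid swarm. Takes precedence over SHARED_SUBCLADE.

Two further boolean flags: ``hybrid_swarm_overlap`` marks regions whose span
is also a candidate in the other donor's scan (dual-donor signal), and
``sweep_flag`` marks regions whose focal-species diversity is an order of
magnitude below the linkage-group average (strict <0.1x), the hard-sweep
screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .abba_baba import FdResult
from .window_stats import WindowStatRecord

PRIVATE = "PRIVATE"
SHARED_SUBCLADE = "SHARED_SUBCLADE"
SHARED_CLADE = "SHARED_CLADE"

SWEEP_RATIO = 0.1  # "order of magnitude" diversity drop


@dataclass
class CandidateRegion:
    chrom: str
    start: int  # 0-based half-open span of the merged windows
    end: int
    focal_species: str
    donor_label: str
    peak_fd: float
    category: str | None = None
    hybrid_swarm_overlap: bool = False
    sweep_flag: bool = False

    def overlaps(self, other: "CandidateRegion") -> bool:
        return (self.chrom == other.chrom and self.start < other.end
                and other.start < self.end)

    @property
    def start_1based(self) -> int:
        return self.start + 1


def call_candidates(scan: list[FdResult], threshold: float, focal_species: str,
                    donor_label: str = "") -> list[CandidateRegion]:
    """Merge above-threshold windows of one quartet scan into maximal regions."""
    hits = sorted(
        (r for r in scan if math.isfinite(r.fd) and r.fd > threshold),
        key=lambda r: (r.window.chrom, r.window.start),
    )
    regions: list[CandidateRegion] = []
    for r in hits:
        w = r.window
        prev = regions[-1] if regions else None
        if prev is not None and prev.chrom == w.chrom and w.start <= prev.end:
            prev.end = max(prev.end, w.end)
            prev.peak_fd = max(prev.peak_fd, r.fd)
        else:
            regions.append(CandidateRegion(w.chrom, w.start, w.end,
                                           focal_species, donor_label, r.fd))
    return regions


def categorize(regions_by_species: dict[str, list[CandidateRegion]],
               subclade_map: dict[str, str]) -> None:
    """Assign the three sharing categories in place.

    All per-species scans against the same donor must be supplied together;
    SHARED_CLADE takes precedence over SHARED_SUBCLADE over PRIVATE.
    """
    for species in regions_by_species:
        if species not in subclade_map:
            raise ValueError(f"species {species!r} missing from subclade map")
    for species, regions in regions_by_species.items():
        for region in regions:
            shared_subclade = shared_clade = False
            for other, other_regions in regions_by_species.items():
                if other == species:
                    continue
                if any(region.overlaps(o) for o in other_regions):
                    if subclade_map[other] == subclade_map[species]:
                        shared_subclade = True
                    else:
                        shared_clade = True
            region.category = (SHARED_CLADE if shared_clade
                               else SHARED_SUBCLADE if shared_subclade
                               else PRIVATE)


def hybrid_swarm_overlap(regions_mm: list[CandidateRegion],
                         regions_cr: list[CandidateRegion]) -> None:
    """Flag (in place) regions overlapping any region of the other donor's scan."""
    for region in regions_mm:
        region.hybrid_swarm_overlap = any(region.overlaps(o) for o in regions_cr)
    for region in regions_cr:
        region.hybrid_swarm_overlap = any(region.overlaps(o) for o in regions_mm)


def sweep_flag(region_pi_values: list[float], linkage_group_mean_pi: float) -> bool:
    """Strict order-of-magnitude diversity drop relative to the linkage group."""
    values = [v for v in region_pi_values if math.isfinite(v)]
    if not values or not math.isfinite(linkage_group_mean_pi):
        import logging

        logging.getLogger("craterscan").warning(
            "pi undefined for sweep screen; flag not assigned")
        return False
    return sum(values) / len(values) < SWEEP_RATIO * linkage_group_mean_pi


def annotate_sweeps(regions: list[CandidateRegion], stats: list[WindowStatRecord],
                    species: str) -> None:
    """Set sweep_flag on each region from per-window pi of the focal species.

    Linkage group = the region's chromosome as given; the baseline is the mean
    pi of the species over all usable windows of that chromosome.
    """
    for region in regions:
        lg = [r.pi.get(species, float("nan")) for r in stats
              if r.window.chrom == region.chrom and r.usable]
        lg = [v for v in lg if math.isfinite(v)]
        in_region = [r.pi.get(species, float("nan")) for r in stats
                     if r.window.chrom == region.chrom
                     and r.window.start < region.end and region.start < r.window.end]
        baseline = sum(lg) / len(lg) if lg else float("nan")
        region.sweep_flag = sweep_flag(in_region, baseline)


def regions_table(regions: list[CandidateRegion]):
    """Annotated TSV-ready DataFrame (1-based inclusive coordinates)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": r.chrom,
            "start": r.start_1based,
            "end": r.end,
            "focal_species": r.focal_species,
            "donor": r.donor_label,
            "peak_fd": r.peak_fd,
            "category": r.category,
            "hybrid_swarm_overlap": r.hybrid_swarm_overlap,
            "sweep_flag": r.sweep_flag,
        }
        for r in regions
    )


def summary(regions_by_species: dict[str, list[CandidateRegion]]) -> dict:
    """Counts per category and flag, echoing a candidate-region table layout."""
    counts = {PRIVATE: 0, SHARED_SUBCLADE: 0, SHARED_CLADE: 0}
    n_swarm = n_sweep = n_total = 0
    for regions in regions_by_species.values():
        for r in regions:
            n_total += 1
            if r.category:
                counts[r.category] += 1
            n_swarm += r.hybrid_swarm_overlap
            n_sweep += r.sweep_flag
    return {
        "n_regions": n_total,
        "by_category": counts,
        "hybrid_swarm_flagged": n_swarm,
        "sweep_flagged": n_sweep,
        "per_species": {s: len(r) for s, r in regions_by_species.items()},
    }
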