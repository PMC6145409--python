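"""Structured-coalescent simulation: null fd distributions and full synthetic
scenario datasets with known introgressed tracts.

The simulator runs a backwards-in-time Hudson coalescent over labelled demes
with piecewise-constant diploid sizes, clean splits (all lineages of a derived
deme move to its ancestor), and admixture pulses (each lineage in the
recipient moves to the donor independently with probability f). Mutations are
dropped on the resulting genealogy under the infinite-sites model, Poisson
per branch with rate mu * L * branch_length, each at a fresh uniform position.

Recombination is approximated by concatenating independent non-recombining
sub-blocks within each window (default 10 per 50-kb window). This preserves
the intra-window averaging that fd thresholding depends on without an
ancestral-recombination-graph machinery; an exact-ARG backend could be
slotted in behind :func:`simulate_window` unchanged.

Three scenario kinds emulate the competing colonization histories of a
crater-lake radiation with two riverine relatives and one distant outgroup:

``none``
    strict isolation after each split — the no-migration null;
``secondary_pulse``
    a post-divergence pulse from the MM-like riverine deme into exactly one
    lake species, applied only in designated truth windows;
``hybrid_swarm``
    two pre-divergence pulses (MM-like and CR-like donors) into the common
    lake ancestor, again applied only in truth windows.

Times are generations before present; sizes are diploid Ne.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .abba_baba import QuartetConfig, fd_statistic
from .genotype_io import GenotypeMatrix, PopulationMap, VariantSite, allele_frequencies
from .window_stats import Window

# Default demographic parameters: order-of-magnitude plausibility for a young
# crater-lake radiation nested inside much older riverine lineages.
DEFAULT_NE_LAKE = 20_000
DEFAULT_NE_RIVERINE = 50_000
DEFAULT_MU = 3.5e-9  # per bp per generation
T_SISTER_SPLIT = 3_000  # sister-species splits inside each subclade
T_SUBCLADE_ROOT = 6_000  # third species joins its subclade
T_LAKE_ROOT = 10_000  # radiation root
T_RIVER_SPLIT = 100_000  # MM/CR riverine split (10x lake root)
T_LAKE_RIVER = 150_000  # lake clade joins the riverine ancestor
T_OUTGROUP = 500_000  # distant outgroup (50x lake root)

SCENARIO_KINDS = ("none", "secondary_pulse", "hybrid_swarm")


@dataclass(frozen=True)
class Pulse:
    """Admixture pulse: lineages in ``recipient`` move to ``donor`` at ``time``.

    With ``designated`` unset each lineage moves independently with
    probability ``fraction``. When ``designated`` holds haplotype (leaf) ids,
    a lineage moves iff the majority of its descendant haplotypes are
    designated (ties: move iff its smallest descendant id is designated) —
    this pins one coherent ancestry assignment per simulated tract instead of
    re-randomizing it in every non-recombining sub-block.
    """

    time: float
    recipient: str
    donor: str
    fraction: float
    designated: frozenset[int] | None = None


@dataclass(frozen=True)
class Split:
    time: float
    derived: str
    ancestral: str


@dataclass
class DemographicModel:
    """Demes with piecewise-constant sizes, split events and admixture pulses.

    ``demes`` maps each label to [(start_time, Ne), ...] epochs with strictly
    increasing start times, the first at 0. ``samples_per_deme`` gives diploid
    sample counts (0 for unsampled/ancestral-only demes is allowed simply by
    omission).
    """

    demes: dict[str, list[tuple[float, float]]]
    splits: list[Split]
    pulses: list[Pulse] = field(default_factory=list)
    mu: float = DEFAULT_MU
    samples_per_deme: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for deme, epochs in self.demes.items():
            times = [t for t, _ in epochs]
            if not epochs or times[0] != 0 or any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"deme {deme!r}: epochs must start at 0 with increasing times")
            if any(ne <= 0 for _, ne in epochs):
                raise ValueError(f"deme {deme!r}: sizes must be positive")
        end = self.split_times()
        for s in self.splits:
            for d in (s.derived, s.ancestral):
                if d not in self.demes:
                    raise ValueError(f"split references unknown deme {d!r}")
            if s.time >= end.get(s.ancestral, np.inf):
                raise ValueError(f"deme {s.ancestral!r} already merged at split time {s.time}")
        for p in self.pulses:
            if not 0 <= p.fraction <= 1:
                raise ValueError(f"pulse fraction {p.fraction} outside [0, 1]")
            for d in (p.recipient, p.donor):
                if d not in self.demes:
                    raise ValueError(f"pulse references unknown deme {d!r}")
                if p.time >= end.get(d, np.inf):
                    raise ValueError(f"pulse at {p.time} after deme {d!r} merged")
        for deme in self.samples_per_deme:
            if deme not in self.demes:
                raise ValueError(f"samples requested from unknown deme {deme!r}")

    def split_times(self) -> dict[str, float]:
        """Time at which each deme merges into its ancestor (inf for the root)."""
        return {s.derived: s.time for s in self.splits}

    def size_at(self, deme: str, t: float) -> float:
        ne = self.demes[deme][0][1]
        for start, size in self.demes[deme]:
            if start <= t:
                ne = size
            else:
                break
        return ne

    @property
    def sample_names(self) -> list[str]:
        return [f"{deme}_{i + 1}" for deme, n in self.samples_per_deme.items()
                for i in range(n)]

    def sample_demes(self) -> dict[str, str]:
        return {f"{deme}_{i + 1}": deme for deme, n in self.samples_per_deme.items()
                for i in range(n)}


class _Node:
    __slots__ = ("time", "children", "leaf_id", "leafset")

    def __init__(self, time: float, children=(), leaf_id: int = -1):
        self.time = time
        self.children = list(children)
        self.leaf_id = leaf_id
        if children:
            self.leafset = children[0].leafset | children[1].leafset
        else:
            self.leafset = frozenset([leaf_id])


def _is_designated(node: _Node, designated: frozenset[int]) -> bool:
    inside = len(node.leafset & designated)
    outside = len(node.leafset) - inside
    if inside != outside:
        return inside > outside
    return min(node.leafset) in designated


@dataclass
class Genealogy:
    root: _Node
    n_leaves: int


def simulate_genealogy(model: DemographicModel, rng: np.random.Generator) -> Genealogy:
    """One realization of the backwards-time coalescent for all sampled lineages.

    Within a deme holding k lineages at time t, pairs coalesce at rate
    k(k-1)/2 / (2 Ne(t)); piecewise-constant sizes are handled by treating
    epoch boundaries as events and redrawing the (memoryless) exponential
    waiting time in each constant segment.
    """
    active: dict[str, list[_Node]] = {}
    leaf = 0
    for deme, n in model.samples_per_deme.items():
        lineages = []
        for _ in range(2 * n):  # two haploid lineages per diploid
            lineages.append(_Node(0.0, leaf_id=leaf))
            leaf += 1
        active[deme] = lineages
    if leaf < 2:
        raise ValueError("need at least two sampled lineages")

    events: list[tuple[float, int, object]] = []
    for s in model.splits:
        events.append((s.time, 1, s))
    for p in model.pulses:
        events.append((p.time, 0, p))
    for deme, epochs in model.demes.items():
        for start, _ in epochs[1:]:
            events.append((start, 2, deme))
    events.sort(key=lambda e: (e[0], e[1], str(e[2])))

    t = 0.0
    ev = 0
    n_lineages = leaf
    while n_lineages > 1:
        t_event = events[ev][0] if ev < len(events) else np.inf
        # candidate coalescence: min of per-deme exponentials at current rates
        t_coal, coal_deme = np.inf, None
        for deme in sorted(active):
            k = len(active[deme])
            if k < 2:
                continue
            rate = k * (k - 1) / 2.0 / (2.0 * model.size_at(deme, t))
            cand = t + rng.exponential(1.0 / rate)
            if cand < t_coal:
                t_coal, coal_deme = cand, deme
        if t_coal < t_event:
            lin = active[coal_deme]
            i, j = sorted(rng.choice(len(lin), size=2, replace=False))
            b = lin.pop(j)
            a = lin.pop(i)
            lin.append(_Node(t_coal, children=(a, b)))
            n_lineages -= 1
            t = t_coal
        elif ev < len(events):
            t = t_event
            _, kind, payload = events[ev]
            ev += 1
            if kind == 1:  # split: derived deme folds into its ancestor
                s = payload
                if s.derived in active:
                    active.setdefault(s.ancestral, []).extend(active.pop(s.derived))
            elif kind == 0:  # pulse: per-lineage migration
                p = payload
                src = active.get(p.recipient, [])
                if src:
                    if p.designated is None:
                        moved = (rng.random(len(src)) < p.fraction).tolist()
                    else:
                        moved = [_is_designated(node, p.designated) for node in src]
                    stay, go = [], []
                    for node, m in zip(src, moved):
                        (go if m else stay).append(node)
                    active[p.recipient] = stay
                    if go:
                        active.setdefault(p.donor, []).extend(go)
        else:
            raise ValueError(
                "lineages stranded in demes that never share an ancestor; "
                "check the model's split events"
            )
    (root,) = [n for lin in active.values() for n in lin]
    return Genealogy(root, leaf)


def drop_mutations(gen: Genealogy, mu: float, block_bp: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites mutations: Poisson(mu * block_bp * branch length) per
    branch, each at a fresh uniform position carried by the branch's leaves.

    Returns (positions, carriers): positions are 0-based ints in
    [0, block_bp), sorted; carriers is a (n_variants, n_leaves) bool array.
    """
    positions: list[int] = []
    carriers: list[np.ndarray] = []

    def visit(node: _Node) -> np.ndarray:
        if node.leaf_id >= 0:
            leafset = np.zeros(gen.n_leaves, dtype=bool)
            leafset[node.leaf_id] = True
        else:
            leafset = np.zeros(gen.n_leaves, dtype=bool)
            for child in node.children:
                child_set = visit(child)
                n_mut = rng.poisson(mu * block_bp * (node.time - child.time))
                for _ in range(n_mut):
                    positions.append(int(rng.integers(0, block_bp)))
                    carriers.append(child_set)
                leafset |= child_set
        return leafset

    visit(gen.root)
    if not positions:
        return np.empty(0, dtype=np.int64), np.empty((0, gen.n_leaves), dtype=bool)
    pos = np.array(positions, dtype=np.int64)
    # enforce unique positions (infinite sites) by redrawing collisions
    while True:
        uniq, counts = np.unique(pos, return_counts=True)
        if (counts == 1).all():
            break
        taken = set(uniq.tolist())
        for i in np.nonzero(np.isin(pos, uniq[counts > 1]))[0][1:]:
            p = int(rng.integers(0, block_bp))
            while p in taken:
                p = int(rng.integers(0, block_bp))
            pos[i] = p
            taken.add(p)
    order = np.argsort(pos)
    return pos[order], np.array(carriers, dtype=bool)[order]


@dataclass
class SimWindow:
    """Genotypes for one simulated window, with provenance truth flags."""

    positions: np.ndarray  # 0-based within [0, window_bp)
    dosages: np.ndarray  # (n_sites, n_diploids) alt dosage
    samples: list[str]
    sample_demes: dict[str, str]
    window_bp: int
    introgressed: bool = False
    donor: str | None = None


def simulate_window(model: DemographicModel, window_bp: int, blocks_per_window: int,
                    rng: np.random.Generator) -> SimWindow:
    """Concatenate independent genealogy+mutation blocks into one window."""
    if blocks_per_window < 1:
        raise ValueError("blocks_per_window must be >= 1")
    if window_bp % blocks_per_window:
        raise ValueError(f"window_bp {window_bp} not divisible by {blocks_per_window} blocks")
    block_bp = window_bp // blocks_per_window
    pos_parts, carrier_parts = [], []
    for b in range(blocks_per_window):
        gen = simulate_genealogy(model, rng)
        pos, carr = drop_mutations(gen, model.mu, block_bp, rng)
        pos_parts.append(pos + b * block_bp)
        carrier_parts.append(carr)
    positions = np.concatenate(pos_parts)
    carriers = np.vstack(carrier_parts) if positions.size else np.empty(
        (0, 2 * sum(model.samples_per_deme.values())), dtype=bool)
    dosages = (carriers[:, 0::2].astype(np.int8) + carriers[:, 1::2].astype(np.int8))
    return SimWindow(positions, dosages, model.sample_names, model.sample_demes(), window_bp)


def window_genotypes(win: SimWindow, chrom: str = "sim_1") -> GenotypeMatrix:
    """SimWindow -> GenotypeMatrix (positions become 1-based)."""
    sites = [VariantSite(chrom, int(p) + 1, "A", "T") for p in win.positions]
    return GenotypeMatrix(sites, list(win.samples), win.dosages)


def window_frequencies(win: SimWindow, chrom: str = "sim_1"):
    matrix = window_genotypes(win, chrom)
    return allele_frequencies(matrix, PopulationMap(dict(win.sample_demes)))


@dataclass
class NullThreshold:
    threshold: float
    fd_values: np.ndarray  # defined fd values of the simulated null windows
    n_windows: int
    rule: str


def null_fd_threshold(model: DemographicModel, quartet: QuartetConfig, n_windows: int,
                      rng: np.random.Generator, rule: str = "max", q: float = 0.95,
                      window_bp: int = 50_000, blocks_per_window: int = 10,
                      min_sites: int = 100) -> NullThreshold:
    """fd significance threshold from no-migration simulations.

    Simulates ``n_windows`` windows under ``model`` (which must contain no
    pulses), computes fd on each usable window, and returns the max (default)
    or the q-quantile of the defined fd values together with the full list
    for audit.
    """
    if model.pulses:
        raise ValueError("null threshold model must contain no pulses")
    if n_windows < 100:
        raise ValueError("need at least 100 simulated windows for a threshold")
    values = null_fd_values(model, quartet, n_windows, rng, window_bp,
                            blocks_per_window, min_sites)
    if values.size < 50:
        raise ValueError(
            f"only {values.size} usable simulated windows; increase mu or sample sizes"
        )
    return NullThreshold(threshold_from_values(values, rule, q), values, n_windows, rule)


def threshold_from_values(values, rule: str = "max", q: float = 0.95) -> float:
    """Apply the threshold rule to a list of simulated null fd values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no fd values to threshold")
    if rule == "max":
        return float(values.max())
    if rule == "quantile":
        return float(np.quantile(values, q))
    raise ValueError(f"unknown threshold rule {rule!r}")


def null_fd_values(model: DemographicModel, quartet: QuartetConfig, n_windows: int,
                   rng: np.random.Generator, window_bp: int = 50_000,
                   blocks_per_window: int = 10, min_sites: int = 100) -> np.ndarray:
    """Defined fd values from ``n_windows`` fresh windows under ``model``."""
    out = []
    span = Window("sim_1", 0, window_bp)
    for _ in range(n_windows):
        win = simulate_window(model, window_bp, blocks_per_window, rng)
        freqs = window_frequencies(win)
        res = fd_statistic(span, freqs, quartet, min_sites)
        if np.isfinite(res.fd):
            out.append(res.fd)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Scenario generation


def default_radiation_model(ne_lake: float = DEFAULT_NE_LAKE,
                            ne_riverine: float = DEFAULT_NE_RIVERINE,
                            mu: float = DEFAULT_MU,
                            samples_per_deme: int = 2) -> DemographicModel:
    """A six-species lake radiation (two subclades of three species each)
    nested inside MM-like and CR-like riverine demes plus a distant outgroup.

    Topology per subclade X: ((lake_X1,lake_X2),lake_X3); the two subclades
    join at the radiation root, which attaches as sister to the
    (riverine_MM, riverine_CR) pair, with a distant outgroup below. Sister
    species split at 3 kgen, subclades close at 6 kgen, the radiation root
    sits at 10 kgen, the riverine MM/CR split 10x deeper, the distant
    outgroup 50x deeper. Three-species subclades mirror the focal subclades
    of the Barombi Mbo radiation and are what makes within-subclade sharing
    of candidate regions expressible (two species can both be candidates
    against the third).
    """
    lake = [f"lake_{sub}{i}" for sub in "AB" for i in (1, 2, 3)]
    river = ["riverine_MM", "riverine_CR"]
    demes = {d: [(0.0, ne_lake)] for d in lake}
    # above the radiation root the lake lineage is the (pre-colonization)
    # riverine ancestor, so it reverts to the riverine size
    demes["lake_A1"] = [(0.0, ne_lake), (float(T_LAKE_ROOT), ne_riverine)]
    demes |= {d: [(0.0, ne_riverine)] for d in [*river, "outgroup"]}
    splits = [
        Split(T_SISTER_SPLIT, "lake_A2", "lake_A1"),
        Split(T_SISTER_SPLIT, "lake_B2", "lake_B1"),
        Split(T_SUBCLADE_ROOT, "lake_A3", "lake_A1"),
        Split(T_SUBCLADE_ROOT, "lake_B3", "lake_B1"),
        Split(T_LAKE_ROOT, "lake_B1", "lake_A1"),
        Split(T_RIVER_SPLIT, "riverine_CR", "riverine_MM"),
        Split(T_LAKE_RIVER, "lake_A1", "riverine_MM"),
        Split(T_OUTGROUP, "riverine_MM", "outgroup"),
    ]
    samples = {d: samples_per_deme for d in [*lake, *river, "outgroup"]}
    return DemographicModel(demes, splits, [], mu, samples)


LAKE_SUBCLADES = {"A": ["lake_A1", "lake_A2", "lake_A3"],
                  "B": ["lake_B1", "lake_B2", "lake_B3"]}


def subclade_quartets(donor: str, outgroup: str = "outgroup",
                      donor_label: str = "") -> list[QuartetConfig]:
    """All directed within-subclade species pairs against one donor: the
    scan design of the study (every ordered sister combination as (P1, P2))."""
    quartets = []
    for members in LAKE_SUBCLADES.values():
        for p2 in members:
            for p1 in members:
                if p1 != p2:
                    quartets.append(QuartetConfig(p1, p2, donor, outgroup, donor_label))
    return quartets


@dataclass(frozen=True)
class ScenarioSpec:
    """What to simulate and where the truth tracts are."""

    kind: str
    n_windows: int
    window_bp: int = 50_000
    blocks_per_window: int = 10
    introgressed_window_ids: frozenset[int] = frozenset()
    seed: int = 0
    recipient: str = "lake_A2"  # secondary_pulse target species
    mm_donor: str = "riverine_MM"
    cr_donor: str = "riverine_CR"
    lake_ancestor: str = "lake_A1"  # deme carrying the lake root lineage
    pulse_fraction: float = 0.8  # secondary pulse admixture fraction
    swarm_fraction: float = 0.5  # per-donor fraction for the hybrid swarm
    secondary_pulse_time: float = 1_000.0
    swarm_pulse_times: tuple[float, float] = (11_000.0, 11_500.0)

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"scenario kind must be one of {SCENARIO_KINDS}")
        if (self.kind == "none") != (not self.introgressed_window_ids):
            raise ValueError("introgressed_window_ids must be empty iff kind == 'none'")
        if any(not 0 <= i < self.n_windows for i in self.introgressed_window_ids):
            raise ValueError("truth window ids outside [0, n_windows)")


def choose_truth_windows(n_windows: int, fraction: float, seed: int) -> frozenset[int]:
    """Seeded uniform choice of truth window ids (no replacement)."""
    n_truth = max(1, round(fraction * n_windows))
    rng = np.random.default_rng(seed)
    return frozenset(int(i) for i in rng.choice(n_windows, size=n_truth, replace=False))


def haplotype_ids(model: DemographicModel) -> dict[str, list[int]]:
    """Leaf (haplotype) id range per sampled deme, in simulation order."""
    ids: dict[str, list[int]] = {}
    i = 0
    for deme, n in model.samples_per_deme.items():
        ids[deme] = list(range(i, i + 2 * n))
        i += 2 * n
    return ids


def _lake_demes(base: DemographicModel, spec: ScenarioSpec) -> list[str]:
    """Sampled demes whose lineages sit in the lake-ancestor deme at the
    swarm pulse time (the lake clade)."""
    t_pulse = min(spec.swarm_pulse_times)
    merged_into = {s.derived: (s.time, s.ancestral) for s in base.splits}
    lake = []
    for deme in base.samples_per_deme:
        d = deme
        while d != spec.lake_ancestor and d in merged_into:
            t, anc = merged_into[d]
            if t > t_pulse:
                break
            d = anc
        if d == spec.lake_ancestor:
            lake.append(deme)
    return lake


def scenario_pulses(spec: ScenarioSpec, base: DemographicModel,
                    rng: np.random.Generator) -> list[Pulse]:
    """Pulses for one truth window, with a window-level ancestry assignment.

    Which haplotypes carry donor ancestry is drawn once per window and pinned
    via designated-lineage pulses, so the introgressed tract is coherent
    across the window's sub-blocks (one recombination-free ancestry decision
    per sampled chromosome per tract).
    """
    for deme in (spec.recipient, spec.mm_donor, spec.cr_donor, spec.lake_ancestor):
        if deme not in base.demes:
            raise ValueError(f"scenario deme {deme!r} missing from the model")
    haps = haplotype_ids(base)
    if spec.kind == "secondary_pulse":
        designated = frozenset(h for h in haps[spec.recipient]
                               if rng.random() < spec.pulse_fraction)
        return [Pulse(spec.secondary_pulse_time, spec.recipient, spec.mm_donor,
                      1.0, designated)]
    # hybrid_swarm: the founding lake population is a mixture of the two
    # riverine colonists — every ancestral-lake lineage descends from one of
    # them; swarm_fraction sets the MM:CR mixing ratio per haplotype
    t_mm, t_cr = spec.swarm_pulse_times
    lake_haps = [h for deme in _lake_demes(base, spec) for h in haps[deme]]
    mm_set = frozenset(h for h in lake_haps if rng.random() < spec.swarm_fraction)
    return [Pulse(t_mm, spec.lake_ancestor, spec.mm_donor, 1.0, mm_set),
            Pulse(t_cr, spec.lake_ancestor, spec.cr_donor, 1.0)]


def simulate_scenario(spec: ScenarioSpec,
                      base_model: DemographicModel | None = None) -> list[SimWindow]:
    """All windows of a scenario, truth windows under per-window pulsed models."""
    base = base_model if base_model is not None else default_radiation_model()
    if base.pulses:
        raise ValueError("base model must be pulse-free; pulses are added per scenario")
    rng = np.random.default_rng(spec.seed)
    windows = []
    for k in range(spec.n_windows):
        truth = k in spec.introgressed_window_ids
        model = (replace(base, pulses=scenario_pulses(spec, base, rng))
                 if truth else base)
        win = simulate_window(model, spec.window_bp, spec.blocks_per_window, rng)
        win.introgressed = truth
        if truth:
            win.donor = spec.mm_donor if spec.kind == "secondary_pulse" else "both"
        windows.append(win)
    return windows


def write_scenario_vcf(windows: list[SimWindow], path: str) -> None:
    """Windows as VCF 4.2 text, one contig sim_k per window (GT only)."""
    samples = windows[0].samples
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=craterscan-coalescent-sim\n")
        for k, win in enumerate(windows, 1):
            fh.write(f"##contig=<ID=sim_{k},length={win.window_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for k, win in enumerate(windows, 1):
            for pos, row in zip(win.positions, win.dosages):
                gts = "\t".join(gt_strings[int(d)] for d in row)
                fh.write(f"sim_{k}\t{int(pos) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def generate_scenario(spec: ScenarioSpec, base_model: DemographicModel | None = None,
                      out_dir: str = ".") -> dict[str, str]:
    """Simulate a scenario and write VCF + popmap TSV + truth BED + manifest.

    Returns the paths written. Identical spec and seed give byte-identical
    output files.
    """
    import os

    base = base_model if base_model is not None else default_radiation_model()
    windows = simulate_scenario(spec, base)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "scenario.vcf"),
        "popmap": os.path.join(out_dir, "popmap.tsv"),
        "truth_bed": os.path.join(out_dir, "truth.bed"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_scenario_vcf(windows, paths["vcf"])
    with open(paths["popmap"], "w") as fh:
        for sample, deme in windows[0].sample_demes.items():
            fh.write(f"{sample}\t{deme}\n")
    with open(paths["truth_bed"], "w") as fh:
        for k in sorted(spec.introgressed_window_ids):
            donor = windows[k].donor or "."
            fh.write(f"sim_{k + 1}\t0\t{spec.window_bp}\t{donor}\n")
    manifest = {
        "seed": spec.seed,
        "scenario": {f: getattr(spec, f) for f in (
            "kind", "n_windows", "window_bp", "blocks_per_window", "recipient",
            "mm_donor", "cr_donor", "lake_ancestor", "pulse_fraction",
            "swarm_fraction", "secondary_pulse_time")},
        "truth_windows": sorted(spec.introgressed_window_ids),
        "model": {
            "mu": base.mu,
            "demes": {d: e for d, e in base.demes.items()},
            "splits": [[s.time, s.derived, s.ancestral] for s in base.splits],
            "samples_per_deme": base.samples_per_deme,
        },
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
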