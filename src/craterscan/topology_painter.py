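"""Per-window topology painting: distance matrix -> neighbor-joining tree ->
rule-based classification of the lake clade's relationship to riverine demes.

This is a deterministic window-based analogue of HMM genome segmentation
approaches: instead of self-proposed segments, every fixed window gets an
allele-sharing distance matrix among individuals, a neighbor-joining tree,
and one of four classes after rooting with the distant outgroup:

``LAKE_MONOPHYLETIC``
    all lake individuals form a single clade (the species-tree expectation);
``GROUP_WITH_RIVERINE``
    a configured species/subclade groups with riverine individuals to the
    exclusion of the rest of the lake flock (the introgression/hybrid-swarm
    signature);
``OTHER_POLYPHYLETIC``
    lake and riverine individuals interleave in some other way;
``UNINFORMATIVE``
    too few usable sites, a pair of individuals with no co-called sites, or
    a non-monophyletic outgroup after rooting.

Genomic proportions per class summarize how much of the genome supports each
relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .genotype_io import MISSING, GenotypeMatrix
from .window_stats import Window

LAKE_MONOPHYLETIC = "LAKE_MONOPHYLETIC"
GROUP_WITH_RIVERINE = "GROUP_WITH_RIVERINE"
OTHER_POLYPHYLETIC = "OTHER_POLYPHYLETIC"
UNINFORMATIVE = "UNINFORMATIVE"


@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distances in [0, 1] with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape inconsistent with labels")
        if not np.allclose(v, v.T) or np.diag(v).any():
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v


@dataclass
class TopologyCall:
    window: Window
    klass: str
    group: str | None = None  # set iff klass == GROUP_WITH_RIVERINE
    tree: str | None = None  # newick


def window_distance(calls: np.ndarray, samples: list[str]) -> DistanceMatrix | None:
    """Pairwise mean |dosage_i - dosage_j| / 2 over co-called sites.

    Returns None (window uninformative) when any pair has zero co-called
    sites or there are no sites at all.
    """
    if len(samples) < 4:
        raise ValueError("distance matrix needs at least 4 samples")
    calls = np.asarray(calls)
    n = len(samples)
    if calls.shape[0] == 0:
        return None
    called = calls != MISSING
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                return None
            d[i, j] = d[j, i] = float(
                np.abs(calls[both, i] - calls[both, j]).sum()) / (2.0 * m)
    return DistanceMatrix(list(samples), d)


def nj_tree(dm: DistanceMatrix):
    """Neighbor-joining tree (skbio), deterministic under label permutation.

    Labels are sorted before agglomeration so that ties in the Q-matrix break
    lexicographically regardless of input order.
    """
    if not np.isfinite(dm.values).all():
        raise ValueError("non-finite distances")
    order = np.argsort(dm.labels)
    labels = [dm.labels[i] for i in order]
    return _skbio_nj(_SkbioDM(dm.values[np.ix_(order, order)], ids=labels))


def _tip_sets(tree) -> dict[int, frozenset[str]]:
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip():
            sets[id(node)] = frozenset([node.name])
        else:
            sets[id(node)] = frozenset().union(*(sets[id(c)] for c in node.children))
    return sets


def classify_topology(tree, lake_samples: list[str], riverine_samples: list[str],
                      outgroup_samples: list[str],
                      groups: dict[str, list[str]],
                      window: Window | None = None) -> TopologyCall:
    """Classify one window's tree after rooting on the outgroup edge.

    The outgroup must form one side of a split of the unrooted tree (else the
    window is UNINFORMATIVE). Inside the ingroup, the lake flock is monophyletic
    or some configured group g (largest first) attaches to riverine samples
    with no other lake sample inside the joint clade.
    """
    lake, riverine, outgroup = map(frozenset, (lake_samples, riverine_samples,
                                               outgroup_samples))
    ingroup = lake | riverine
    newick = str(tree).strip()
    win = window if window is not None else Window("", 0, 1)
    sets = _tip_sets(tree)
    all_tips = sets[id(tree)]
    if all_tips != ingroup | outgroup:
        raise ValueError("tree tips do not match the configured sample sets")

    # Each edge of the (arbitrarily rooted) NJ tree is a split; in the tree
    # rooted on the outgroup attachment edge, the clades are exactly the
    # outgroup-free sides of those splits. The outgroup is monophyletic iff
    # some split has the full ingroup as its outgroup-free side.
    clades: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node.parent is None:
            continue
        s = sets[id(node)]
        side = all_tips - s if s & outgroup else s
        if side and not side & outgroup:
            clades.add(side)
    if ingroup not in clades:
        return TopologyCall(win, UNINFORMATIVE, tree=newick)
    return _classify_clades(clades, lake, riverine, groups, win, newick)


def _classify_clades(clades, lake, riverine, groups, win, newick):
    clade_sets = {c for c in clades}
    if lake in clade_sets:
        return TopologyCall(win, LAKE_MONOPHYLETIC, tree=newick)
    for name, members in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        g = frozenset(members)
        if not g or not g <= lake:
            continue
        # minimal clade containing g and at least one riverine sample
        candidates = [c for c in clade_sets if g <= c and c & riverine]
        if not candidates:
            continue
        smallest = min(candidates, key=len)
        if smallest & lake == g:
            return TopologyCall(win, GROUP_WITH_RIVERINE, group=name, tree=newick)
    return TopologyCall(win, OTHER_POLYPHYLETIC, tree=newick)


def classify_window(window: Window, matrix: GenotypeMatrix,
                    lake_samples: list[str], riverine_samples: list[str],
                    outgroup_samples: list[str], groups: dict[str, list[str]],
                    min_sites: int = 10) -> TopologyCall:
    """Distance -> NJ -> classification for one window of a genotype matrix."""
    chroms, positions = matrix.chroms, matrix.positions
    in_win = (chroms == window.chrom) & (positions > window.start) & (positions <= window.end)
    wanted = [*lake_samples, *riverine_samples, *outgroup_samples]
    cols = [matrix.samples.index(s) for s in wanted]
    calls = matrix.calls[np.ix_(np.nonzero(in_win)[0], cols)]
    if calls.shape[0] < min_sites:
        return TopologyCall(window, UNINFORMATIVE)
    dm = window_distance(calls, wanted)
    if dm is None:
        return TopologyCall(window, UNINFORMATIVE)
    tree = nj_tree(dm)
    return classify_topology(tree, lake_samples, riverine_samples,
                             outgroup_samples, groups, window)


@dataclass
class PaintedRun:
    chrom: str
    start: int  # 0-based half-open
    end: int
    klass: str
    group: str | None


def paint_genome(calls: list[TopologyCall]) -> tuple[dict[str, float], list[PaintedRun]]:
    """Merge consecutive same-class windows into runs and summarize proportions.

    Runs merge adjacent or overlapping windows of the same class (and same
    matched group) on the same chromosome. The proportion of each class is
    its total merged span over the total painted span (sum over classes), so
    proportions always sum to 1.
    """
    runs: list[PaintedRun] = []
    for call in sorted(calls, key=lambda c: (c.window.chrom, c.window.start)):
        w = call.window
        prev = runs[-1] if runs else None
        if (prev is not None and prev.chrom == w.chrom and prev.klass == call.klass
                and prev.group == call.group and w.start <= prev.end):
            prev.end = max(prev.end, w.end)
        else:
            runs.append(PaintedRun(w.chrom, w.start, w.end, call.klass, call.group))
    span_per_class: dict[str, float] = {}
    for run in runs:
        span_per_class[run.klass] = span_per_class.get(run.klass, 0) + (run.end - run.start)
    total = sum(span_per_class.values())
    proportions = {k: v / total for k, v in span_per_class.items()} if total else {}
    return proportions, runs
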