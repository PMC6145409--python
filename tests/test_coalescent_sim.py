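"""Coalescent simulator: analytic expectations, reproducibility, thresholds,
and scenario generation with known truth."""

import json
from dataclasses import replace

import numpy as np
import pytest

import craterscan as cs
from craterscan.coalescent_sim import (DemographicModel, Genealogy, Pulse,
                                       Split, drop_mutations, haplotype_ids,
                                       scenario_pulses, simulate_genealogy,
                                       threshold_from_values)
from craterscan.window_stats import Window

ONE_DEME = DemographicModel({"d": [(0.0, 1000.0)]}, [], [], 1e-8, {"d": 1})


def tree_height(gen: Genealogy) -> float:
    return gen.root.time


def total_branch_length(gen: Genealogy) -> float:
    total = 0.0
    stack = [gen.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            total += node.time - child.time
            stack.append(child)
    return total


class TestGenealogy:
    def test_pair_tmrca_matches_expectation(self):
        """n = 2 lineages, constant Ne: mean TMRCA ~ 2 Ne over 2000 reps."""
        rng = np.random.default_rng(11)
        times = [tree_height(simulate_genealogy(ONE_DEME, rng))
                 for _ in range(2000)]
        assert np.mean(times) == pytest.approx(2 * 1000, rel=0.05)

    def test_full_pulse_moves_all_lineages(self):
        """With f = 1 every recipient lineage is in the donor before the
        pulse time, so all coalescences happen above it."""
        model = DemographicModel(
            {"a": [(0.0, 500.0)], "b": [(0.0, 500.0)]}, [],
            [Pulse(100.0, "a", "b", 1.0)], 1e-8, {"a": 2, "b": 2})
        rng = np.random.default_rng(3)
        for _ in range(20):
            gen = simulate_genealogy(model, rng)
            internal = [n.time for n in _internal_nodes(gen)
                        if _spans_demes(n, gen)]
            # cross-deme coalescence cannot precede the pulse
            assert all(t >= 100.0 for t in internal)

    def test_split_conserves_lineages_and_roots(self):
        model = DemographicModel(
            {"a": [(0.0, 800.0)], "b": [(0.0, 800.0)]},
            [Split(50.0, "b", "a")], [], 1e-8, {"a": 2, "b": 2})
        gen = simulate_genealogy(model, np.random.default_rng(4))
        assert gen.n_leaves == 8
        assert gen.root.leafset == frozenset(range(8))

    def test_disconnected_demes_fatal(self):
        model = DemographicModel(
            {"a": [(0.0, 100.0)], "b": [(0.0, 100.0)]}, [], [], 1e-8,
            {"a": 1, "b": 1})
        with pytest.raises(ValueError, match="ancestor"):
            simulate_genealogy(model, np.random.default_rng(0))

    def test_piecewise_size_changes_rate(self):
        """A huge ancient epoch stretches TMRCA accordingly."""
        grown = DemographicModel({"d": [(0.0, 1000.0), (500.0, 100_000.0)]},
                                 [], [], 1e-8, {"d": 1})
        rng = np.random.default_rng(5)
        times = np.array([tree_height(simulate_genealogy(grown, rng))
                          for _ in range(500)])
        # P(TMRCA < 500) = 1 - exp(-500/2000); beyond that the rate is 200x slower
        frac_recent = (times < 500).mean()
        assert frac_recent == pytest.approx(1 - np.exp(-0.25), abs=0.06)
        assert times[times >= 500].mean() > 50_000


def _internal_nodes(gen):
    out = []
    stack = [gen.root]
    while stack:
        n = stack.pop()
        if n.children:
            out.append(n)
            stack.extend(n.children)
    return out


def _spans_demes(node, gen):
    # leaves 0-3 are deme a, 4-7 deme b (two diploids each)
    return (min(node.leafset) < 4) and (max(node.leafset) >= 4)


class TestMutations:
    def test_zero_mu_zero_variants(self):
        gen = simulate_genealogy(ONE_DEME, np.random.default_rng(1))
        pos, carriers = drop_mutations(gen, 0.0, 10_000, np.random.default_rng(1))
        assert len(pos) == 0

    def test_pairwise_diversity_matches_theta(self):
        """n = 2: mean pairwise differences ~ 4 Ne mu L over 2000 reps."""
        rng = np.random.default_rng(12)
        mu, L, ne = 1e-7, 50_000, 1000.0
        model = replace(ONE_DEME, mu=mu)
        diffs = []
        for _ in range(2000):
            gen = simulate_genealogy(model, rng)
            pos, carriers = drop_mutations(gen, mu, L, rng)
            diffs.append(sum(c.sum() == 1 for c in carriers))
        assert np.mean(diffs) == pytest.approx(4 * ne * mu * L, rel=0.05)

    def test_carrier_sets_are_proper_subsets(self):
        model = DemographicModel({"d": [(0.0, 2000.0)]}, [], [], 5e-7, {"d": 3})
        rng = np.random.default_rng(13)
        gen = simulate_genealogy(model, rng)
        pos, carriers = drop_mutations(gen, model.mu, 50_000, rng)
        assert len(pos) > 0
        assert len(np.unique(pos)) == len(pos)
        assert all(0 < c.sum() < 6 for c in carriers)

    def test_matches_msprime_diversity(self):
        """Independent cross-check: mean pairwise diversity in a two-deme
        split model agrees with msprime at matched parameters."""
        msprime = pytest.importorskip("msprime")
        ne, t_split, mu, L, reps = 1000.0, 2000.0, 5e-8, 20_000, 800
        model = DemographicModel(
            {"x": [(0.0, ne)], "y": [(0.0, ne)]},
            [Split(t_split, "y", "x")], [], mu, {"x": 1, "y": 1})
        rng = np.random.default_rng(14)
        ours = []
        for _ in range(reps):
            gen = simulate_genealogy(model, rng)
            pos, carriers = drop_mutations(gen, mu, L, rng)
            # mean pairwise difference over the 4 cross-deme haplotype pairs
            d = 0.0
            for c in carriers:
                cx, cy = int(c[:2].sum()), int(c[2:].sum())
                d += (cx * (2 - cy) + cy * (2 - cx)) / 4.0
            ours.append(d)
        dem = msprime.Demography()
        dem.add_population(name="x", initial_size=ne)
        dem.add_population(name="y", initial_size=ne)
        dem.add_population(name="anc", initial_size=ne)
        dem.add_population_split(time=t_split, derived=["x", "y"], ancestral="anc")
        theirs = []
        seed_rng = np.random.default_rng(17)
        for ts in msprime.sim_ancestry({"x": 1, "y": 1}, demography=dem,
                                       sequence_length=L, num_replicates=reps,
                                       random_seed=99):
            mts = msprime.sim_mutations(ts, rate=mu,
                                        random_seed=int(seed_rng.integers(1, 2**31)))
            theirs.append(mts.divergence([[0, 1], [2, 3]], mode="site",
                                         span_normalise=False))
        assert np.mean(ours) == pytest.approx(np.mean(theirs), rel=0.10)


class TestSimulateWindow:
    def test_block_divisibility(self, base_model):
        with pytest.raises(ValueError, match="divisible"):
            cs.simulate_window(base_model, 50_000, 7, np.random.default_rng(0))

    def test_reproducibility(self, base_model):
        a = cs.simulate_window(base_model, 50_000, 10, np.random.default_rng(8))
        b = cs.simulate_window(base_model, 50_000, 10, np.random.default_rng(8))
        c = cs.simulate_window(base_model, 50_000, 10, np.random.default_rng(9))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert not (len(a.positions) == len(c.positions)
                    and np.array_equal(a.positions, c.positions))

    def test_more_blocks_reduce_fd_variance(self, base_model, quartet_mm):
        """10 sub-blocks per window damp the per-window fd spread relative to
        single-genealogy windows of the same total length."""
        span = Window("sim_1", 0, 20_000)
        variances = {}
        for blocks in (1, 10):
            rng = np.random.default_rng(77)
            vals = []
            for _ in range(500):
                w = cs.simulate_window(base_model, 20_000, blocks, rng)
                r = cs.fd_statistic(span, cs.window_frequencies(w), quartet_mm,
                                    min_sites=10)
                if np.isfinite(r.fd):
                    vals.append(r.fd)
            variances[blocks] = np.var(vals)
        assert variances[10] < variances[1]


class TestThreshold:
    def test_rule_arithmetic(self):
        assert threshold_from_values([0.05, 0.12, 0.30], "max") == 0.30
        values = np.arange(100) / 100.0
        assert threshold_from_values(values, "quantile", 0.95) == pytest.approx(
            np.quantile(values, 0.95))
        with pytest.raises(ValueError):
            threshold_from_values([0.1], "median")

    def test_model_with_pulses_rejected(self, base_model, quartet_mm):
        pulsed = replace(base_model,
                         pulses=[Pulse(1000.0, "lake_A2", "riverine_MM", 0.5)])
        with pytest.raises(ValueError, match="no pulses"):
            cs.null_fd_threshold(pulsed, quartet_mm, 100, np.random.default_rng(0))

    def test_max_rule_rarely_exceeded_by_fresh_nulls(self, null_fd_mm, null_fd_fresh):
        """A max-rule threshold from 1000 null windows is exceeded by < 2% of
        an independent 500-window null run."""
        threshold = threshold_from_values(null_fd_mm, "max")
        fresh = null_fd_fresh[:500]
        assert (fresh > threshold).mean() < 0.02


class TestScenarios:
    def test_none_scenario_truth_bed_empty(self, tmp_path):
        spec = cs.ScenarioSpec(kind="none", n_windows=3, seed=1)
        paths = cs.generate_scenario(spec, out_dir=str(tmp_path))
        assert (tmp_path / "truth.bed").read_text() == ""
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 1 and manifest["truth_windows"] == []

    def test_byte_identical_reproducibility(self, tmp_path):
        spec = cs.ScenarioSpec(kind="secondary_pulse", n_windows=4,
                               introgressed_window_ids=frozenset({1}), seed=33)
        p1 = cs.generate_scenario(spec, out_dir=str(tmp_path / "a"))
        p2 = cs.generate_scenario(spec, out_dir=str(tmp_path / "b"))
        for key in ("vcf", "popmap", "truth_bed"):
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_truth_ids_constraints(self):
        with pytest.raises(ValueError, match="iff"):
            cs.ScenarioSpec(kind="none", n_windows=5,
                            introgressed_window_ids=frozenset({1}))
        with pytest.raises(ValueError, match="iff"):
            cs.ScenarioSpec(kind="secondary_pulse", n_windows=5)
        with pytest.raises(ValueError, match="outside"):
            cs.ScenarioSpec(kind="secondary_pulse", n_windows=5,
                            introgressed_window_ids=frozenset({9}))

    def test_unknown_scenario_deme_fatal(self, base_model):
        spec = cs.ScenarioSpec(kind="secondary_pulse", n_windows=2,
                               introgressed_window_ids=frozenset({0}),
                               recipient="lake_Z9")
        with pytest.raises(ValueError, match="lake_Z9"):
            scenario_pulses(spec, base_model, np.random.default_rng(0))

    def test_secondary_pulse_elevates_truth_fd(self, base_model, quartet_mm):
        """Mean fd in truth windows exceeds non-truth windows (200 windows)."""
        truth = cs.choose_truth_windows(200, 0.1, 55)
        spec = cs.ScenarioSpec(kind="secondary_pulse", n_windows=200,
                               introgressed_window_ids=truth, seed=55)
        wins = cs.simulate_scenario(spec, base_model)
        span = Window("sim_1", 0, 50_000)
        in_truth, outside = [], []
        for k, w in enumerate(wins):
            r = cs.fd_statistic(span, cs.window_frequencies(w), quartet_mm)
            val = r.fd if np.isfinite(r.fd) else 0.0
            (in_truth if k in truth else outside).append(val)
        assert np.mean(in_truth) > np.mean(outside) + 0.2

    def test_power_monotone_in_pulse_fraction(self, base_model, quartet_mm,
                                              null_fd_mm):
        """Truth-window recall is non-decreasing in the admixture fraction."""
        threshold = threshold_from_values(null_fd_mm, "max")
        span = Window("sim_1", 0, 50_000)
        recalls = []
        for f in (0.05, 0.2, 0.8):
            truth = frozenset(range(60))
            spec = cs.ScenarioSpec(kind="secondary_pulse", n_windows=60,
                                   introgressed_window_ids=truth, seed=60,
                                   pulse_fraction=f)
            wins = cs.simulate_scenario(spec, base_model)
            hits = 0
            for w in wins:
                r = cs.fd_statistic(span, cs.window_frequencies(w), quartet_mm)
                hits += np.isfinite(r.fd) and r.fd > threshold
            recalls.append(hits / len(wins))
        assert recalls[0] <= recalls[1] <= recalls[2]

    def test_hybrid_swarm_signal_spans_subclades(self, base_model):
        """Swarm truth windows show donor sharing in both subclades' tests."""
        truth = frozenset(range(40))
        spec = cs.ScenarioSpec(kind="hybrid_swarm", n_windows=40,
                               introgressed_window_ids=truth, seed=66)
        wins = cs.simulate_scenario(spec, base_model)
        span = Window("sim_1", 0, 50_000)
        hits = {"A": 0, "B": 0}
        for w in wins:
            freqs = cs.window_frequencies(w)
            for sub, members in cs.LAKE_SUBCLADES.items():
                best = 0.0
                for donor in ("riverine_MM", "riverine_CR"):
                    for p2 in members:
                        for p1 in members:
                            if p1 == p2:
                                continue
                            q = cs.QuartetConfig(p1, p2, donor, "outgroup")
                            r = cs.fd_statistic(span, freqs, q)
                            if np.isfinite(r.fd):
                                best = max(best, r.fd)
                hits[sub] += best > 0.2
        assert hits["A"] > 10 and hits["B"] > 10

    def test_haplotype_ids_cover_all_samples(self, base_model):
        ids = haplotype_ids(base_model)
        flat = [h for v in ids.values() for h in v]
        assert sorted(flat) == list(range(2 * sum(
            base_model.samples_per_deme.values())))
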