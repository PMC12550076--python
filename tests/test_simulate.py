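"""Forward simulator: determinism, truth consistency, drift injection."""

import numpy as np
import pytest

from mtfounder.diversity import nucleotide_diversity, rho
from mtfounder.founder import founder_age, identify_founders
from mtfounder.clock import linear_calibration
from mtfounder.network import build_tree
from mtfounder.simulate import (
    IslandSpec,
    Scenario,
    ScenarioError,
    inject_drift,
    pacific_scenario,
    replay_history,
    simulate,
)


def small_scenario(seed=0, T=2000.0, n=30, founders=4):
    return Scenario(
        islands=(
            IslandSpec("West", -3.0, 143.0, 5000.0, 1, 40, None),
            IslandSpec("East", -10.0, 160.0, T, founders, n, "West"),
        ),
        origin_time_bp=5000.0,
        mutation_interval=1000.0,
        seed=seed,
    )


class TestScenarioValidation:
    def test_sink_cannot_predate_source(self):
        with pytest.raises(ScenarioError, match="colonized before"):
            Scenario(
                islands=(
                    IslandSpec("A", 0, 0, 1000.0, 1, 5, None),
                    IslandSpec("B", 0, 1, 2000.0, 2, 5, "A"),
                ),
                origin_time_bp=3000.0,
            )

    def test_unknown_source_rejected(self):
        with pytest.raises(ScenarioError, match="unknown source"):
            Scenario(
                islands=(IslandSpec("A", 0, 0, 100.0, 1, 5, "Nowhere"),),
                origin_time_bp=3000.0,
            )

    def test_exactly_one_origin(self):
        with pytest.raises(ScenarioError, match="origin"):
            Scenario(
                islands=(
                    IslandSpec("A", 0, 0, 100.0, 1, 5, None),
                    IslandSpec("B", 0, 1, 100.0, 1, 5, None),
                ),
                origin_time_bp=300.0,
            )


class TestPacificScenario:
    def test_islands_ordered_west_to_east(self):
        sc = pacific_scenario()
        lons = [i.lon for i in sc.islands]
        assert lons == sorted(lons)

    def test_vanuatu_truth_inside_radiocarbon_range(self):
        sc = pacific_scenario()
        vanuatu = next(i for i in sc.islands if i.name == "Vanuatu")
        assert 3030 <= vanuatu.colonization_time_bp <= 3430

    def test_sample_sizes_mirror_study_regions(self):
        sc = pacific_scenario()
        n = {i.name: i.n_sampled for i in sc.islands}
        assert n["Vanuatu"] == 103 and n["Solomon Islands"] == 555 and n["Niue"] == 21

    def test_deterministic_for_fixed_seed(self):
        d1, t1 = simulate(pacific_scenario(seed=1))
        d2, t2 = simulate(pacific_scenario(seed=1))
        assert [h.variants for h in d1] == [h.variants for h in d2]
        assert t1.sample_history == t2.sample_history
        d3, _ = simulate(pacific_scenario(seed=2))
        assert [h.variants for h in d1] != [h.variants for h in d3]


class TestSimulate:
    def test_zero_age_island_has_no_private_mutations(self):
        sc = Scenario(
            islands=(
                IslandSpec("West", 0, 0, 3000.0, 1, 10, None),
                IslandSpec("Now", 0, 5, 0.0, 3, 10, "West"),
            ),
            origin_time_bp=3000.0,
            mutation_interval=500.0,
            seed=4,
        )
        ds, truth = simulate(sc)
        founders = truth.founder_haplotypes["Now"]
        for h in ds:
            if h.island != "Now":
                continue
            tokens = {m.token() for m in h.variants}
            assert tokens in [set(f) for f in founders]

    def test_expected_private_rho_matches_poisson_mean(self):
        """Over 200 replicates the mean private event count per lineage
        is within 3 Monte-Carlo SE of T / mutation_interval."""
        T, interval = 2000.0, 1000.0
        per_rep = []
        for seed in range(200):
            sc = small_scenario(seed=seed, T=T, n=10)
            ds, truth = simulate(sc)
            k = [
                sum(1 for (t, _, _) in truth.sample_history[h.sample_id] if t < T)
                for h in ds
                if h.island == "East"
            ]
            per_rep.append(np.mean(k))
        per_rep = np.asarray(per_rep)
        mcse = per_rep.std(ddof=1) / np.sqrt(len(per_rep))
        assert abs(per_rep.mean() - T / interval) <= 3 * mcse

    def test_single_founder_gives_single_cluster(self):
        sc = small_scenario(seed=9, founders=1, n=20)
        ds, truth = simulate(sc)
        assert len(truth.founder_haplotypes["East"]) == 1
        tree = build_tree(ds)
        src = [h for h in ds if h.island == "West"]
        snk = [h for h in ds if h.island == "East"]
        clusters = identify_founders(tree, src, snk)
        assert len(clusters) == 1

    def test_truth_replay_reproduces_variant_sets(self):
        ds, truth = simulate(pacific_scenario(seed=6))
        for h in ds:
            tokens = {m.token() for m in h.variants}
            assert replay_history(truth.sample_history[h.sample_id]) == tokens

    def test_diversity_gradient_west_to_east(self):
        """Upstream whole-clade rho exceeds downstream private founder
        rho in expectation (the west-to-east settlement gradient)."""
        upstream, downstream = [], []
        for seed in range(3):
            ds, _ = simulate(pacific_scenario(seed=seed))
            tree = build_tree(ds)
            by_region = {}
            for h in ds:
                by_region.setdefault(h.region, []).append(h)
            src = by_region["PNG North Coast"] + by_region["New Ireland"]
            upstream.append(rho(tree, [h.sample_id for h in src]).rho)
            for sink_name in ("Vanuatu", "Tonga", "Cook Islands"):
                res = founder_age(
                    tree,
                    identify_founders(tree, src, by_region[sink_name]),
                    linear_calibration(3624),
                )
                downstream.append(res.founder_rho)
        assert np.mean(upstream) > np.mean(downstream)


class TestInjectDrift:
    def _island_pi(self, ds, island):
        return nucleotide_diversity([h for h in ds if h.island == island]).pi

    def test_maximal_severity_fixes_one_derived_type(self):
        ds, _ = simulate(small_scenario(seed=12, n=40))
        out = inject_drift(ds, "East", severity=1.0, seed=1)
        east = [h for h in out if h.island == "East"]
        types = {h.variants for h in east}
        assert len(types) == 1
        assert len(next(iter(types))) > 0  # a derived, not the root, type
        assert self._island_pi(out, "East") == 0

    def test_moderate_drift_lowers_diversity(self):
        ds, _ = simulate(small_scenario(seed=13, n=60, T=3000.0))
        before = self._island_pi(ds, "East")
        decreased = 0
        for seed in range(50):
            after = self._island_pi(
                inject_drift(ds, "East", severity=0.5, seed=seed), "East"
            )
            decreased += after < before
        assert decreased >= 45  # concentration lowers pi almost surely

    def test_sample_size_preserved_and_west_untouched(self):
        ds, _ = simulate(small_scenario(seed=14, n=25))
        out = inject_drift(ds, "East", severity=0.8, seed=0)
        assert len(out) == len(ds)
        assert sum(h.island == "East" for h in out) == 25
        west_before = [h.variants for h in ds if h.island == "West"]
        west_after = [h.variants for h in out if h.island == "West"]
        assert west_before == west_after

    def test_absent_island_raises(self):
        ds, _ = simulate(small_scenario(seed=15))
        with pytest.raises(KeyError):
            inject_drift(ds, "Atlantis", severity=0.5, seed=0)

    def test_severity_bounds(self):
        ds, _ = simulate(small_scenario(seed=16))
        with pytest.raises(ValueError):
            inject_drift(ds, "East", severity=0.0, seed=0)

    def test_pacific_scenario_applies_new_britain_drift(self):
        ds, _ = simulate(pacific_scenario(seed=1))
        nb = [h for h in ds if h.island == "New Britain"]
        types = {h.variants for h in nb}
        assert len(types) < len(nb) / 2  # few types at high frequency
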