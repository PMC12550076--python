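"""Source/sink partitioning, founder clusters and founder dating."""

import numpy as np
import pytest

from mtfounder.clock import linear_calibration
from mtfounder.diversity import UndefinedEstimateError, rho
from mtfounder.founder import (
    ConfigurationError,
    FounderConfig,
    founder_age,
    identify_founders,
    partition,
    run_founder_analysis,
)
from mtfounder.network import build_tree
from mtfounder.simulate import default_founder_config, pacific_scenario, simulate

from helpers import hap


@pytest.fixture
def toy():
    """source {root, root+a}; sink {root+a+b, root+a+b+c}."""
    src = [hap("s1", [], region="SRC"), hap("s2", [1000], region="SRC")]
    snk = [
        hap("k1", [1000, 2000], region="SNK"),
        hap("k2", [1000, 2000, 3000], region="SNK"),
    ]
    tree = build_tree(src + snk, root_hint=hap("root", []), method="exact")
    return tree, src, snk


class TestPartition:
    def setup_method(self):
        self.cfg = FounderConfig(
            ordered_areas=(
                ("west", ("A", "B")),
                ("mid", ("C",)),
                ("east", ("D", "E")),
            )
        )
        self.haps = [hap(r.lower() + str(i), [], region=r)
                     for r in "ABCDE" for i in range(2)]

    def test_source_accumulates_all_earlier_areas(self):
        source, sink = partition(self.haps, self.cfg, "east")
        assert {h.region for h in source} == {"A", "B", "C"}
        assert {h.region for h in sink} == {"D", "E"}
        assert not {h.sample_id for h in source} & {h.sample_id for h in sink}

    def test_first_stage_has_empty_source(self):
        source, sink = partition(self.haps, self.cfg, "west")
        assert source == []
        assert {h.region for h in sink} == {"A", "B"}

    def test_unmapped_region_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="Zed"):
            partition(self.haps + [hap("x", [], region="Zed")], self.cfg, "mid")

    def test_duplicate_region_rejected(self):
        with pytest.raises(ConfigurationError):
            FounderConfig(ordered_areas=(("a", ("X",)), ("b", ("X",))))


class TestIdentifyFounders:
    def test_private_path_lengths(self, toy):
        tree, src, snk = toy
        (cluster,) = identify_founders(tree, src, snk)
        assert set(cluster.sink_samples) == {"k1", "k2"}
        assert cluster.private_mutation_sum == 3  # 1 + 2
        founder_vars = tree.graph.nodes[cluster.founder_node]["variants"]
        assert {m.position for m in founder_vars} == {1000}

    def test_sink_identical_to_source_haplotype(self):
        src = [hap("s1", [1000], region="SRC")]
        snk = [hap("k1", [1000], region="SNK")]
        tree = build_tree(src + snk, root_hint=hap("root", []), method="exact")
        (cluster,) = identify_founders(tree, src, snk)
        assert cluster.private_mutation_sum == 0

    def test_distinct_source_paths_give_two_clusters(self):
        src = [hap("s1", [1000], region="SRC"), hap("s2", [2000], region="SRC")]
        snk = [
            hap("k1", [1000, 3000], region="SNK"),
            hap("k2", [2000, 4000], region="SNK"),
        ]
        tree = build_tree(src + snk, root_hint=hap("root", []), method="exact")
        clusters = identify_founders(tree, src, snk)
        assert len(clusters) == 2
        assert all(c.private_mutation_sum == 1 for c in clusters)

    def test_unmatched_path_falls_back_to_root(self):
        # observed mode: no source sample carries any node on the path
        src = [hap("s1", [1000], region="SRC")]
        snk = [hap("k1", [2000, 3000], region="SNK")]
        tree = build_tree(src + snk, root_hint=hap("root", []), method="exact")
        (cluster,) = identify_founders(tree, src, snk, source_presence="observed")
        assert cluster.founder_node == tree.root
        assert not cluster.founder_in_source_sample

    def test_observed_mode_is_stricter(self, toy):
        tree, src, snk = toy
        (clade,) = identify_founders(tree, src, snk, source_presence="clade")
        (observed,) = identify_founders(tree, src, snk, source_presence="observed")
        assert observed.private_mutation_sum >= clade.private_mutation_sum


class TestFounderAge:
    def test_toy_pooled_rho_and_age(self, toy):
        tree, src, snk = toy
        clusters = identify_founders(tree, src, snk)
        res = founder_age(tree, clusters, linear_calibration(1000), region="SNK")
        assert res.founder_rho == pytest.approx(1.5)  # 3 private / 2 samples
        assert res.age.age_bp == pytest.approx(1500.0)

    def test_all_sink_matching_source_dates_to_zero(self):
        src = [hap("s1", [1000], region="SRC")]
        snk = [hap(f"k{i}", [1000], region="SNK") for i in range(3)]
        tree = build_tree(src + snk, root_hint=hap("root", []), method="exact")
        clusters = identify_founders(tree, src, snk)
        res = founder_age(tree, clusters, linear_calibration(1000))
        assert res.founder_rho == 0 and res.age.age_bp == 0

    def test_cluster_weighting_option(self):
        src = [hap("s1", [], region="SRC"), hap("s2", [1000], region="SRC")]
        snk = [
            hap("k1", [2000], region="SNK"),          # cluster at root, 1 private
            hap("k2", [1000, 3000], region="SNK"),    # cluster at root+a
            hap("k3", [1000, 3000, 4000], region="SNK"),
        ]
        tree = build_tree(src + snk, root_hint=hap("root", []), method="exact")
        clusters = identify_founders(tree, src, snk)
        pooled = founder_age(tree, clusters, linear_calibration(1000))
        unweighted = founder_age(
            tree, clusters, linear_calibration(1000), weighting="clusters"
        )
        assert pooled.founder_rho == pytest.approx(4 / 3)
        assert unweighted.founder_rho == pytest.approx((1 + 1.5) / 2)

    def test_no_clusters_is_undefined(self, toy):
        tree, _, _ = toy
        with pytest.raises(UndefinedEstimateError):
            founder_age(tree, [], linear_calibration(1000))


class TestMonotonicity:
    def test_founder_rho_bounded_by_clade_rho_and_source_monotone(self):
        """Subtracting source-borne diversity never increases the
        estimate, and enlarging the source never increases founder rho."""
        sc = pacific_scenario(seed=5)
        dataset, _ = simulate(sc)
        tree = build_tree(dataset)
        by_region = {}
        for h in dataset:
            by_region.setdefault(h.region, []).append(h)
        small_src = by_region["PNG North Coast"]
        big_src = small_src + by_region["New Ireland"] + by_region["Bougainville"]
        for region in ("Vanuatu", "Tonga", "Niue"):
            sink = by_region[region]
            whole = rho(tree, [h.sample_id for h in sink]).rho
            f_small = founder_age(
                tree, identify_founders(tree, small_src, sink),
                linear_calibration(3624),
            ).founder_rho
            f_big = founder_age(
                tree, identify_founders(tree, big_src, sink),
                linear_calibration(3624),
            ).founder_rho
            assert f_small <= whole + 1e-12
            assert f_big <= f_small + 1e-12


def test_run_founder_analysis_shapes(tmp_path):
    dataset, _ = simulate(pacific_scenario(seed=3))
    tree = build_tree(dataset)
    results = run_founder_analysis(
        tree, dataset, default_founder_config(), linear_calibration(3624), min_n=15
    )
    regions = {r.region for r in results}
    assert "Vanuatu" in regions and "PNG North Coast" in regions
    stage0 = next(r for r in results if r.region == "PNG North Coast")
    assert "age estimate" in stage0.caveat and stage0.clusters == ()
    micron = next(r for r in results if r.region == "Micronesia")
    assert "uncertain" in micron.caveat


def test_founder_config_yaml_round_trip(tmp_path):
    cfg = default_founder_config()
    path = tmp_path / "areas.yaml"
    cfg.to_yaml(path)
    back = FounderConfig.from_yaml(path)
    assert back.ordered_areas == cfg.ordered_areas
    assert back.exclusions == cfg.exclusions
    assert dict(back.caveats) == dict(cfg.caveats)
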