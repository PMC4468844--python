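"""Phasing statistics: observed rate, shuffled null, correction, overlap."""

import math

import numpy as np
import pytest

import beadphase as bp
from beadphase.errors import InvalidParameterError, UndefinedResultError
from beadphase.phasing import ClusterCall

T1, T2 = "16S.1", "16S.2"


def call(cid, c1=None, c2=None, hits=None):
    calls = {}
    if c1 is not None:
        calls[T1] = c1
    if c2 is not None:
        calls[T2] = c2
    return ClusterCall(cluster_id=cid, calls=calls, hit_lists=hits or {})


class TestPresenceFractions:
    def test_all_both(self):
        calls = [call(f"c{i}", "A", "A") for i in range(5)]
        fr = bp.target_presence_fractions(calls, T1, T2)
        assert fr == {"only_1": 0.0, "only_2": 0.0, "both": 1.0}

    def test_toy_tally(self):
        calls = (
            [call(f"a{i}", c1="A") for i in range(2)]
            + [call(f"b{i}", c2="B") for i in range(5)]
            + [call(f"c{i}", "A", "B") for i in range(3)]
        )
        fr = bp.target_presence_fractions(calls, T1, T2)
        assert fr == {"only_1": 0.2, "only_2": 0.5, "both": 0.3}


class TestPhasingRate:
    def test_all_matching(self):
        calls = [call(f"c{i}", "A", "A") for i in range(4)]
        assert bp.phasing_rate(calls, T1, T2) == 1.0

    def test_toy_six_of_eight(self):
        calls = [call(f"c{i}", "A", "A") for i in range(6)] + [
            call("c6", "A", "B"),
            call("c7", "B", "A"),
        ]
        assert bp.phasing_rate(calls, T1, T2) == 0.75

    def test_ambiguous_calls_excluded(self):
        calls = [call("c0", "A", "A"), call("c1", "A", bp.AMBIGUOUS)]
        assert bp.phasing_rate(calls, T1, T2) == 1.0

    def test_no_eligible_clusters_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            bp.phasing_rate([call("c0", c1="A")], T1, T2)


class TestRandomMatchRate:
    def test_single_species_always_matches(self):
        calls = [call(f"c{i}", "A", "A") for i in range(10)]
        rate, se = bp.random_match_rate(calls, T1, T2, n_shuffles=20, seed=0)
        assert rate == 1.0 and se == 0.0

    def test_uniform_four_species_converges_to_quarter(self):
        rng = np.random.default_rng(0)
        species = [f"s{i}" for i in range(4)]
        calls = [
            call(f"c{i}", rng.choice(species), rng.choice(species))
            for i in range(5000)
        ]
        rate, se = bp.random_match_rate(calls, T1, T2, n_shuffles=100, seed=1)
        # the collision value of the *empirical* frequencies, not exactly 1/4
        freqs = np.bincount(
            [species.index(c.calls[T2]) for c in calls], minlength=4
        ) / 5000
        expected = bp.analytic_random_match(freqs)
        assert abs(rate - expected) < 3 * max(se, 1e-4)
        assert abs(rate - 0.25) < 0.01

    def test_matches_analytic_collision_probability(self):
        rng = np.random.default_rng(3)
        p = (0.6, 0.3, 0.1)
        species = ["a", "b", "c"]
        calls = [
            call(
                f"c{i}",
                species[rng.choice(3, p=p)],
                species[rng.choice(3, p=p)],
            )
            for i in range(3000)
        ]
        rate, se = bp.random_match_rate(calls, T1, T2, n_shuffles=100, seed=4)
        freqs1 = np.array([
            sum(1 for c in calls if c.calls[T1] == s) for s in species
        ]) / len(calls)
        freqs2 = np.array([
            sum(1 for c in calls if c.calls[T2] == s) for s in species
        ]) / len(calls)
        # shuffling target-2 against fixed target-1: expected match is the
        # cross-collision sum of the two empirical margins
        expected = float((freqs1 * freqs2).sum())
        assert abs(rate - expected) < 5e-3


class TestAnalyticRandomMatch:
    @pytest.mark.parametrize(
        "p, expected",
        [((0.25,) * 4, 0.25), ((1.0,), 1.0), ((0.5, 0.5), 0.5)],
    )
    def test_values(self, p, expected):
        assert bp.analytic_random_match(p) == pytest.approx(expected)

    def test_unnormalized_rejected(self):
        with pytest.raises(InvalidParameterError):
            bp.analytic_random_match((0.5, 0.6))


class TestCorrectedRate:
    def test_reproduces_printed_worked_example(self):
        # observed 91.5%, chance 11.9% -> corrected 90.3% (one decimal)
        assert bp.corrected_phasing_rate(0.915, 0.119) * 100 == pytest.approx(
            90.3, abs=0.1
        )

    def test_no_signal_above_chance_is_zero(self):
        for x in (0.1, 0.5, 0.9):
            assert bp.corrected_phasing_rate(x, x) == 0.0

    def test_perfect_phasing_stays_one(self):
        assert bp.corrected_phasing_rate(1.0, 0.3) == 1.0

    def test_chance_rate_one_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            bp.corrected_phasing_rate(0.9, 1.0)

    def test_equals_observed_when_chance_is_zero(self):
        assert bp.corrected_phasing_rate(0.7, 0.0) == 0.7


class TestRemoveDominant:
    def test_single_species_dataset_is_undefined(self):
        calls = [call(f"c{i}", "A", "A") for i in range(5)]
        table = {"combined": {"A": 10}}
        with pytest.raises(UndefinedResultError):
            bp.remove_dominant_species(calls, table, T1, T2)

    def test_toy_removal_recomputes_on_remainder(self):
        calls = [call(f"d{i}", "A", "A") for i in range(6)] + [
            call("r0", "B", "B"),
            call("r1", "B", "C"),
            call("r2", "C", "C"),
            call("r3", "B", "B"),
        ]
        table = {"combined": {"A": 12, "B": 5, "C": 3}}
        dom, remaining, stats = bp.remove_dominant_species(
            calls, table, T1, T2, seed=0
        )
        assert dom == "A"
        assert len(remaining) == 4
        assert stats["p_obs"] == 0.75

    def test_random_match_drops_toward_minor_collision(self):
        rng = np.random.default_rng(5)
        species = ["big", "m1", "m2", "m3"]
        p = (0.7, 0.1, 0.1, 0.1)
        calls = []
        for i in range(4000):
            s = species[rng.choice(4, p=p)]
            calls.append(call(f"c{i}", s, s))
        table = {"combined": {s: sum(
            1 for c in calls if c.calls[T1] == s) for s in species}}
        dom, remaining, stats = bp.remove_dominant_species(
            calls, table, T1, T2, seed=6
        )
        assert dom == "big"
        # perfectly matched calls: the minor-species chance level is the
        # renormalized collision value 3*(1/3)^2 = 1/3
        assert abs(stats["p_rand"] - 1 / 3) < 0.03
        assert stats["p_obs"] == 1.0


class TestOverlapReduction:
    def test_identical_lists_no_reduction(self):
        r = bp.hitlist_overlap_reduction(
            [(frozenset("ab"), frozenset("ab"))]
        )
        assert r.mean_reduction == 0.0

    def test_disjoint_lists_full_reduction(self):
        r = bp.hitlist_overlap_reduction(
            [(frozenset("ab"), frozenset("cd"))]
        )
        assert r.mean_reduction == 1.0

    def test_partial_overlap_arithmetic(self):
        a = frozenset({"s1", "s2", "s3"})
        b = frozenset({"s2", "s3", "s4"})
        r = bp.hitlist_overlap_reduction([(a, b)])
        assert r.mean_overlap == 2
        assert r.mean_len_1 == 3 and r.mean_len_2 == 3
        assert r.mean_reduction == pytest.approx(1 / 3)

    def test_empty_lists_skipped_and_counted(self):
        r = bp.hitlist_overlap_reduction([(frozenset(), frozenset("a"))])
        assert r.n_skipped == 1 and r.per_cluster == []


class TestDepthSubsample:
    def test_fraction_one_reproduces_full_run(
        self, clean_run, reference
    ):
        from conftest import make_layout

        cfg, reads, _ = clean_run
        layout = make_layout(cfg)

        def run(subset):
            return bp.run_phasing_pipeline(
                subset, reference, layout, seed=7
            ).summary

        full = run(reads)
        table = bp.depth_subsample(reads, [1.0], run, seed=0)
        assert table.loc[0, "n_clusters"] == full.n_clusters
        assert table.loc[0, "frac_both"] == full.frac_both

    def test_cluster_recovery_grows_with_depth(self, clean_run, reference):
        from conftest import make_layout

        cfg, reads, _ = clean_run
        layout = make_layout(cfg)

        def run(subset):
            return bp.run_phasing_pipeline(
                subset, reference, layout, seed=7
            ).summary

        table = bp.depth_subsample(reads, [0.02, 0.3, 1.0], run, seed=1)
        n = table["n_clusters"].tolist()
        assert n[0] <= n[1] <= n[2]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            bp.depth_subsample([], [0.0], lambda s: None)


class TestEndToEndRecovery:
    def test_corrected_rate_tracks_truth_single_fragment_fraction(
        self, pipeline_result, sim_run
    ):
        """P_corr estimates the fraction of both-target clusters whose
        amplicons derive from a single fragment (within 3 points)."""
        from conftest import cluster_truth_lookup

        _, _, truth = sim_run
        info = cluster_truth_lookup(pipeline_result, truth)
        eligible = [
            c
            for c in pipeline_result.calls
            if T1 in c.calls
            and T2 in c.calls
            and bp.AMBIGUOUS not in (c.calls[T1], c.calls[T2])
        ]
        single = sum(
            1
            for c in eligible
            if len(truth.droplet_contents[info[c.cluster_id][0]][1]) == 1
        )
        truth_frac = single / len(eligible)
        assert pipeline_result.summary.p_corr == pytest.approx(
            truth_frac, abs=0.03
        )

    def test_summary_statistics_deterministic_given_seed(
        self, sim_run, reference
    ):
        from conftest import make_layout

        cfg, reads, _ = sim_run
        layout = make_layout(cfg)
        a = bp.run_phasing_pipeline(reads, reference, layout, seed=2).summary
        b = bp.run_phasing_pipeline(reads, reference, layout, seed=2).summary
        assert a.to_dict() == b.to_dict()
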