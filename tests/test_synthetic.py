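import collections

import numpy as np
import pandas as pd
import pytest

from eventdep import synthetic as syn
from eventdep.dependency import dependency_from_outcomes
from eventdep.trial_data import DEFAULT_ROLES, StudyConfig, directed_pairs


class TestDesign:
    def test_separated_encoding_blocks_are_balanced(self):
        sched = syn.generate_design(15, "separated")
        assert len(sched.encoding_blocks) == 3
        for block in sched.encoding_blocks:
            assert len(block) == 15
            assert len({e for e, *_ in block}) == 15  # one pair per event
            type_counts = collections.Counter(frozenset(p[1:]) for p in block)
            assert set(type_counts.values()) == {5}

    def test_each_event_cycles_through_its_associations(self):
        sched = syn.generate_design(15, "separated")
        per_event = collections.defaultdict(set)
        for block in sched.encoding_blocks:
            for e, cue, target in block:
                per_event[e].add(frozenset((cue, target)))
        assert all(len(types) == 3 for types in per_event.values())

    def test_retrieval_tests_every_directed_pair_once(self):
        for n_events in (3, 15, 30):
            sched = syn.generate_design(n_events, "separated")
            assert len(sched.retrieval) == 6 * n_events
            seen = collections.Counter((e, c, t) for e, c, t, *_ in sched.retrieval)
            assert set(seen.values()) == {1}
            for e in range(1, n_events + 1):
                pairs = {(c, t) for ev, c, t, *_ in sched.retrieval if ev == e}
                assert pairs == set(directed_pairs(DEFAULT_ROLES))

    def test_retrieval_blocks_balanced_within_each_direction_set(self):
        sched = syn.generate_design(15, "separated")
        by_block = collections.defaultdict(list)
        for e, c, t, block, _ in sched.retrieval:
            by_block[block].append((e, frozenset((c, t))))
        assert sorted(by_block) == [1, 2, 3, 4, 5, 6]
        for block, trials in by_block.items():
            assert len(trials) == 15
            assert len({e for e, _ in trials}) == 15  # one trial per event
            type_counts = collections.Counter(t for _, t in trials)
            assert set(type_counts.values()) == {5}

    def test_latin_square_rows_cover_each_block_order(self):
        # track which association type of event 1 each retrieval block tests,
        # per counterbalancing index: the three rows must be distinct and
        # start with a different type each (reduced latin square)
        orders = []
        for cb in range(3):
            sched = syn.generate_design(15, "separated", counterbalance=cb)
            order = tuple(
                frozenset((c, t))
                for e, c, t, block, _ in sched.retrieval
                if e == 1 and block <= 3
            )
            orders.append(order)
        assert len(set(orders)) == 3
        assert len({o[0] for o in orders}) == 3

    def test_direction_flip_counterbalance(self):
        a = syn.generate_design(15, "separated", counterbalance=0)
        b = syn.generate_design(15, "separated", counterbalance=3)
        (e0, c0, t0, *_), (e1, c1, t1, *_) = a.retrieval[0], b.retrieval[0]
        assert (c0, t0) == (t1, c1)

    def test_simultaneous_encoding_single_block(self):
        sched = syn.generate_design(15, "simultaneous")
        assert len(sched.encoding_blocks) == 1
        assert len(sched.encoding_blocks[0]) == 45  # all three pairs per event

    def test_indivisible_n_events_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            syn.generate_design(16)


class TestGeneratorConfig:
    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            syn.GeneratorConfig(h=1.5)
        with pytest.raises(ValueError):
            syn.GeneratorConfig(model="telepathic")

    def test_ordering_violation_warns(self):
        with pytest.warns(UserWarning, match="recommended ordering"):
            syn.GeneratorConfig(a_h=0.3, a_i=0.6)

    def test_dict_round_trip(self):
        cfg = syn.GeneratorConfig(n_participants=7, h=0.3, seed=9)
        assert syn.GeneratorConfig.from_dict(cfg.to_dict()) == cfg


class TestSimulation:
    def test_deterministic_under_fixed_seed(self):
        cfg = syn.GeneratorConfig(n_participants=4, seed=123)
        a = [syn.simulate_participant(cfg, k) for k in range(4)]
        b = [syn.simulate_participant(cfg, k) for k in range(4)]
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.trials, y.trials)

    def test_participant_substreams_stable_under_cohort_size(self):
        small = syn.GeneratorConfig(n_participants=2, seed=5)
        large = syn.GeneratorConfig(n_participants=10, seed=5)
        pd.testing.assert_frame_equal(
            syn.simulate_participant(small, 1).trials,
            syn.simulate_participant(large, 1).trials,
        )
        assert np.array_equal(syn.simulate_outcomes(small), syn.simulate_outcomes(large)[:2])

    def test_different_seeds_differ(self):
        a = syn.simulate_outcomes(syn.GeneratorConfig(n_participants=3, seed=1))
        b = syn.simulate_outcomes(syn.GeneratorConfig(n_participants=3, seed=2))
        assert not np.array_equal(a, b)

    def test_perfect_memory_gives_perfect_accuracy(self):
        cfg = syn.GeneratorConfig(
            n_participants=2, model="independent", a_h=1.0, a_i=1.0, hetero_sd=0
        )
        assert syn.simulate_outcomes(cfg).all()

    def test_no_memory_leaves_chance_guessing(self):
        with pytest.warns(UserWarning, match="recommended ordering"):
            cfg = syn.GeneratorConfig(
                n_participants=60, n_events=30, model="independent", a_i=0.0, a_h=0.0,
                guess=0.25, hetero_sd=0, seed=8,
            )
        acc = syn.simulate_outcomes(cfg).mean()
        assert acc == pytest.approx(0.25, abs=0.01)

    def test_pure_holistic_without_guessing_is_all_or_none(self):
        cfg = syn.GeneratorConfig(
            n_participants=40, model="holistic", a_h=0.5, a_i=0.25, guess=0.0,
            hetero_sd=0, seed=4,
        )
        out = syn.simulate_outcomes(cfg)
        per_event = out.sum(axis=2)
        assert set(np.unique(per_event)) <= {0, 6}
        dep = dependency_from_outcomes(out)
        assert dep.mean() == pytest.approx(0.5, abs=0.05)

    def test_trials_laid_on_schedule(self):
        cfg = syn.GeneratorConfig(n_participants=1, seed=0)
        ds = syn.simulate_participant(cfg, 0)
        ds.validate_complete()
        assert ds.trials["block"].nunique() == 6
        assert list(ds.trials["trial_index"]) == list(range(90))


class TestOracle:
    def test_independent_model_is_exactly_zero(self):
        cfg = syn.GeneratorConfig(model="independent", hetero_sd=0)
        assert syn.expected_dependency_oracle(cfg) == 0.0

    def test_pure_holistic_half_memory_no_guessing(self):
        cfg = syn.GeneratorConfig(model="holistic", a_h=0.5, a_i=0.5, guess=0.0, hetero_sd=0)
        assert syn.expected_dependency_oracle(cfg) == pytest.approx(0.5)

    def test_heterogeneity_rejected(self):
        with pytest.raises(ValueError, match="hetero"):
            syn.expected_dependency_oracle(syn.GeneratorConfig(hetero_sd=0.5))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model="mixture", h=0.5, a_h=0.9, a_i=0.6, guess=0.25),
            dict(model="mixture", h=0.2, a_h=0.75, a_i=0.55, guess=0.25),
            dict(model="holistic", a_h=0.7, a_i=0.7, guess=0.25),
        ],
    )
    def test_monte_carlo_mean_matches_enumeration(self, kwargs):
        cfg = syn.GeneratorConfig(
            n_participants=60, n_events=9999, hetero_sd=0, seed=21, **kwargs
        )
        oracle = syn.expected_dependency_oracle(cfg)
        dep = dependency_from_outcomes(syn.simulate_outcomes(cfg))
        se = dep.std(ddof=1) / np.sqrt(len(dep))
        assert abs(dep.mean() - oracle) < 3 * se
        assert oracle > 0


class TestExperiment:
    def test_empty_cohort_is_clean(self):
        datasets, summary = syn.simulate_experiment(syn.GeneratorConfig(n_participants=0))
        assert datasets == []
        assert summary.inference is None
        assert summary.n_included == 0

    def test_null_generator_gives_null_inference(self):
        cfg = syn.GeneratorConfig(n_participants=45, model="independent", seed=77)
        _, summary = syn.simulate_experiment(cfg)
        assert summary.n_included + summary.n_excluded == 45
        assert abs(summary.inference.t) < 3.5  # no systematic dependency signal

    def test_mixture_generator_detects_dependency(self):
        cfg = syn.GeneratorConfig(n_participants=45, h=0.4, seed=13)
        _, summary = syn.simulate_experiment(cfg)
        assert summary.dependency["dependency"].mean() > 0
        assert summary.inference.bf01 < 1 / 3

    def test_ceiling_generators_are_excluded(self):
        cfg = syn.GeneratorConfig(
            n_participants=10, model="independent", a_h=0.999, a_i=0.999, hetero_sd=0, seed=2
        )
        _, summary = syn.simulate_experiment(cfg, StudyConfig(floor_threshold=None))
        assert summary.n_excluded == 10
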