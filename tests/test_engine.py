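"""Simulator core: initialization, demonstrator choice, rules, event loops."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from acqcurves.engine import (
    InvalidPopulationError,
    NoDemonstrator,
    PopulationState,
    RuleConfig,
    apply_rule,
    init_population,
    run_batch,
    run_events,
    select_demonstrator,
    uniform_increment_grid,
)


class TestInitPopulation:
    def test_degenerate_probabilities(self, rng):
        assert init_population(100, 0.0, rng=rng).count("A") == 0
        assert init_population(100, 1.0, rng=rng).count("A") == 100

    def test_binomial_moments(self):
        # Counts over many initialisations should match Binomial(100, 0.5):
        # mean 50 (SE of the mean ~0.05), variance 25.
        rng = np.random.default_rng(5)
        counts = np.array(
            [init_population(100, 0.5, rng=rng).count("A") for _ in range(10_000)]
        )
        assert abs(counts.mean() - 50.0) < 0.2
        assert abs(counts.var() - 25.0) < 1.5

    def test_exact_round_places_exact_count(self, rng):
        state = init_population(100, 0.437, mode="exact_round", rng=rng)
        assert state.count("A") == 44

    def test_too_small_population_rejected(self, rng):
        with pytest.raises(InvalidPopulationError):
            init_population(1, 0.5, rng=rng)


class TestSelectDemonstrator:
    def test_uniform_excluding_focal(self):
        rng = np.random.default_rng(7)
        state = init_population(100, 0.5, rng=rng)
        config = RuleConfig("random_copy")
        draws = np.array(
            [select_demonstrator(state, 7, config, rng) for _ in range(100_000)]
        )
        assert not (draws == 7).any()
        observed = np.bincount(draws, minlength=100)
        observed = np.delete(observed, 7)
        _, p = stats.chisquare(observed)
        assert p > 0.01  # uniform over the remaining 99

    def test_subgroup_membership(self, rng):
        state = dataclasses.replace(
            init_population(100, 0.5, rng=rng), subgroup_ids=(3, 9, 41, 55, 88)
        )
        config = RuleConfig("demonstrator_subgroup", dm=5)
        for _ in range(200):
            assert select_demonstrator(state, 2, config, rng) in {3, 9, 41, 55, 88}

    def test_empty_candidate_set_signals(self, rng):
        state = dataclasses.replace(
            init_population(10, 0.5, rng=rng), subgroup_ids=(3,)
        )
        config = RuleConfig("demonstrator_subgroup", dm=1)
        with pytest.raises(NoDemonstrator):
            select_demonstrator(state, 3, config, rng)

    def test_self_copy_allowed_includes_focal(self):
        rng = np.random.default_rng(8)
        state = init_population(10, 0.5, rng=rng)
        config = RuleConfig("random_copy", allow_self_as_demonstrator=True)
        draws = [select_demonstrator(state, 4, config, rng) for _ in range(2000)]
        assert 4 in draws


class TestApplyRule:
    def test_preferred_variant_always_copied(self, rng):
        config = RuleConfig("variant_preference", p_less=0.2)
        for _ in range(100):
            assert apply_rule("B", "A", config, rng, preferred_variant="A") == ("A", True)

    def test_less_preferred_copied_at_p_less(self):
        rng = np.random.default_rng(9)
        config = RuleConfig("variant_preference", p_less=0.2)
        outcomes = [
            apply_rule("A", "B", config, rng, preferred_variant="A")
            for _ in range(10_000)
        ]
        switched = sum(v == "B" for v, _ in outcomes)
        assert abs(switched / 10_000 - 0.2) < 0.02  # ~5 binomial SE
        assert all(v == "A" and not ok for v, ok in outcomes if v != "B")

    def test_identical_variants_never_change_state(self, rng):
        for rule in ("random_copy", "variant_preference", "conformist_reference"):
            config = RuleConfig(rule)
            variant, _ = apply_rule("A", "A", config, rng, preferred_variant="B")
            assert variant == "A"


def _semantic_check(run):
    """Replay the event log with scalar semantics, verifying every field."""
    variants = run.initial_state.variants.copy()
    n = run.n_individuals
    subgroup = set(run.subgroup_ids)
    for ev in run.iter_events():
        assert variants[ev.focal] == (1 if ev.focal_before == "A" else 0)
        assert ev.freq_state == variants.sum() / n
        if ev.demonstrator is None:
            assert ev.focal_after == ev.focal_before
        else:
            assert ev.demonstrator != ev.focal or run.config.allow_self_as_demonstrator
            if run.config.rule == "demonstrator_subgroup":
                assert ev.demonstrator in subgroup
            if run.config.rule != "conformist_reference":
                assert ev.demo_variant == ("A" if variants[ev.demonstrator] else "B")
            expected_after = ev.demo_variant if ev.copy_succeeded else ev.focal_before
            assert ev.focal_after == expected_after
            if run.config.rule != "variant_preference":
                assert ev.copy_succeeded
            elif ev.demo_variant == run.preferred_variant:
                assert ev.copy_succeeded
        variants[ev.focal] = 1 if ev.focal_after == "A" else 0
    assert (variants == run.final_state.variants).all()


class TestRunEvents:
    @pytest.mark.parametrize(
        "rule", ["random_copy", "variant_preference", "demonstrator_subgroup", "conformist_reference"]
    )
    def test_event_log_semantics_and_replay(self, rule):
        config = RuleConfig(rule, p_less=0.3, dm=4)
        runs = run_batch(config, n_reps=3, base_seed=77, n=25, n_events=400)
        for run in runs:
            _semantic_check(run)
            assert (run.replay_final().variants == run.final_state.variants).all()

    def test_absorbing_state_is_absorbing(self, rng):
        state = init_population(50, 1.0, rng=rng)
        run = run_events(state, RuleConfig("random_copy"), 1000, rng)
        assert (run.focal_before == 1).all() and (run.focal_after == 1).all()
        assert run.final_state.frequency("A") == 1.0

    def test_neutral_copying_is_a_martingale(self):
        # Random copying conserves expected variant-A frequency.
        runs = run_batch(
            RuleConfig("random_copy"), n_reps=500, base_seed=100, p0=0.3, n_events=10_000
        )
        finals = np.array([r.final_state.frequency("A") for r in runs])
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 0.3) < 3 * se

    def test_small_subgroup_drifts_to_fixation(self):
        # A 5-member neutral subgroup should be uniform well before 10000
        # events in essentially every run.
        runs = run_batch(
            RuleConfig("demonstrator_subgroup", dm=5), n_reps=300, base_seed=200
        )
        fixed = sum(
            len({int(r.final_state.variants[i]) for i in r.subgroup_ids}) == 1
            for r in runs
        )
        assert fixed >= 297  # >= 99%

    def test_subgroup_fixation_then_certain_copying(self):
        # Once the subgroup is uniform, every subgroup demonstration shows
        # that variant and is copied with certainty.
        runs = run_batch(
            RuleConfig("demonstrator_subgroup", dm=5), n_reps=5, base_seed=300,
            n_events=10_000,
        )
        for run in runs:
            sub = np.array(run.subgroup_ids)
            variants = run.initial_state.variants.copy()
            fixed_variant = None
            for ev in run.iter_events():
                if fixed_variant is not None and ev.demonstrator is not None:
                    assert ev.demo_variant == fixed_variant
                    assert ev.copy_succeeded
                variants[ev.focal] = 1 if ev.focal_after == "A" else 0
                states = set(int(v) for v in variants[sub])
                fixed_variant = ("A" if states == {1} else "B") if len(states) == 1 else None

    def test_sole_member_subgroup_yields_no_demonstrator_events(self, rng):
        state = dataclasses.replace(init_population(10, 0.5, rng=rng), subgroup_ids=(0,))
        run = run_events(state, RuleConfig("demonstrator_subgroup", dm=1), 500, rng)
        own = run.focal == 0
        assert (run.demonstrator[own] == -1).all()
        assert (run.focal_after[own] == run.focal_before[own]).all()
        assert (run.demonstrator[~own] == 0).all()


class TestRunBatch:
    def test_deterministic_under_fixed_seed(self):
        a = run_batch(RuleConfig("random_copy"), n_reps=4, base_seed=5, n_events=500)
        b = run_batch(RuleConfig("random_copy"), n_reps=4, base_seed=5, n_events=500)
        for ra, rb in zip(a, b):
            assert (ra.focal == rb.focal).all()
            assert (ra.demonstrator == rb.demonstrator).all()
            assert (ra.focal_after == rb.focal_after).all()

    def test_uniform_increments_sweep_the_grid(self):
        grid = uniform_increment_grid(1001)
        assert np.allclose(grid, np.arange(0, 1001) / 1000.0)
        runs = run_batch(
            RuleConfig("random_copy"), n_reps=1001, base_seed=1,
            start_mode="uniform_increments", n_events=1,
        )
        assert [r.params["p0"] for r in runs] == list(grid)

    def test_preference_randomised_per_replicate(self):
        runs = run_batch(
            RuleConfig("variant_preference"), n_reps=1000, base_seed=2, n_events=1
        )
        n_a = sum(r.preferred_variant == "A" for r in runs)
        assert abs(n_a - 500) < 3 * np.sqrt(250)

    def test_rare_starts_are_small_but_nonzero(self):
        runs = run_batch(
            RuleConfig("random_copy"), n_reps=200, base_seed=3,
            start_mode="rare", n_events=1,
        )
        p0s = {r.params["p0"] for r in runs}
        assert p0s <= {round(k / 100, 2) for k in range(1, 11)}
        assert len(p0s) > 3
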