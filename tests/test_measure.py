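"""Frequency measures and adoption conventions, scalar and vectorised."""

import dataclasses

import numpy as np
import pytest

from acqcurves.engine import CopyEvent, RuleConfig, init_population, run_batch
from acqcurves.measure import (
    BehaviourStream,
    FrequencySpec,
    OutcomeSpec,
    event_outcome,
    history_frequency,
    individual_frequency,
    run_frequencies,
    run_outcomes,
)


def _event(demo_variant, focal_before, focal_after, copy_succeeded, demonstrator=3):
    return CopyEvent(
        event_index=0,
        focal=0,
        demonstrator=demonstrator,
        demo_variant=demo_variant,
        focal_before=focal_before,
        focal_after=focal_after,
        copy_succeeded=copy_succeeded,
        freq_state=0.5,
    )


class TestIndividualFrequency:
    def test_direct_count(self, rng):
        state = init_population(100, 0.6, mode="exact_round", rng=rng)
        assert individual_frequency(state, "A") == 0.60
        assert individual_frequency(state, "B") == 0.40

    def test_exclude_focal(self, rng):
        state = init_population(100, 0.6, mode="exact_round", rng=rng)
        focal = int(np.flatnonzero(state.variants == 1)[0])  # an A-individual
        spec = FrequencySpec(exclude_focal_from_state=True)
        assert individual_frequency(state, "A", spec, focal=focal) == 59 / 99

    def test_uniform_population(self, rng):
        state = init_population(10, 1.0, rng=rng)
        assert individual_frequency(state, "A") == 1.0
        assert individual_frequency(state, "B") == 0.0


class TestHistoryFrequency:
    def test_full_history(self):
        stream = ["A", "B", "A", "A"]
        spec = FrequencySpec(source="behaviour_full_history")
        assert history_frequency(stream, "A", spec) == 0.75

    def test_window_uses_most_recent(self):
        spec = FrequencySpec(source="behaviour_window", window_t=3)
        assert history_frequency(["A", "B", "A", "A"], "A", spec) == pytest.approx(2 / 3)

    def test_burn_in_skip_is_undefined(self):
        spec = FrequencySpec(source="behaviour_window", window_t=10)
        assert history_frequency(["A", "B"], "A", spec) is None
        partial = dataclasses.replace(spec, burn_in="use_partial")
        assert history_frequency(["A", "B"], "A", partial) == 0.5

    def test_empty_stream_undefined(self):
        spec = FrequencySpec(source="behaviour_full_history")
        assert history_frequency([], "A", spec) is None

    def test_exclude_own_history(self):
        stream = BehaviourStream(labels=["A", "B", "A"], performers=[0, 1, 0])
        spec = FrequencySpec(source="behaviour_full_history", exclude_own_history=True)
        assert history_frequency(stream, "A", spec, focal=0) == 0.0
        assert history_frequency(stream, "A", spec, focal=2) == pytest.approx(2 / 3)

    def test_window_equal_to_length_matches_full_history(self):
        stream = ["A", "B", "B", "A", "A", "B"]
        full = FrequencySpec(source="behaviour_full_history")
        win = FrequencySpec(source="behaviour_window", window_t=len(stream))
        assert history_frequency(stream, "A", win) == history_frequency(stream, "A", full)


class TestEventOutcome:
    def test_copy_event_does_not_credit_retention(self):
        # Keeping A against a B demonstration is not a copy of A.
        ev = _event("B", "A", "A", copy_succeeded=False)
        assert event_outcome(ev, "A", OutcomeSpec("copy_event")) == (True, False)

    def test_copy_event_credits_redundant_copy(self):
        # "Copying" the variant one already has still counts as adopting it.
        ev = _event("A", "A", "A", copy_succeeded=True)
        assert event_outcome(ev, "A", OutcomeSpec("copy_event")) == (True, True)

    def test_end_state_credits_retention(self):
        ev = _event("B", "A", "A", copy_succeeded=False)
        assert event_outcome(ev, "A", OutcomeSpec("end_state")) == (True, True)

    def test_exposure_conditional_restricts_counting(self):
        ev = _event("B", "A", "B", copy_succeeded=True)
        assert event_outcome(ev, "A", OutcomeSpec("exposure_conditional")) == (False, False)
        assert event_outcome(ev, "B", OutcomeSpec("exposure_conditional")) == (True, True)

    def test_no_demonstrator_never_counted(self):
        ev = CopyEvent(0, 0, None, None, "A", "A", False, 0.5)
        for convention in ("copy_event", "end_state", "exposure_conditional"):
            assert event_outcome(ev, "A", OutcomeSpec(convention)) == (False, False)

    def test_success_implies_counted_and_end_state_partition(self, neutral_runs):
        run = neutral_runs[0]
        for convention in ("copy_event", "end_state", "exposure_conditional"):
            spec = OutcomeSpec(convention)
            counted, success = run_outcomes(run, spec)
            assert (success <= counted).all()
        counted_a, success_a = run_outcomes(run, OutcomeSpec("end_state"), variant="A")
        counted_b, success_b = run_outcomes(run, OutcomeSpec("end_state"), variant="B")
        assert (success_a[counted_a] ^ success_b[counted_a]).all()

    def test_copy_event_under_random_copy_is_demonstrator_sampling(self, neutral_runs):
        # Copying always succeeds, so success(A) <=> an A was demonstrated.
        run = neutral_runs[0]
        _, success = run_outcomes(run, OutcomeSpec("copy_event"), variant="A")
        assert (success == (run.demo_variant == 1)).all()


class TestVectorisedAgainstScalar:
    """The columnar fast path must agree with the scalar per-event API."""

    @pytest.mark.parametrize(
        "spec",
        [
            FrequencySpec(source="individual_state"),
            FrequencySpec(source="individual_state", exclude_focal_from_state=True),
            FrequencySpec(source="behaviour_full_history"),
            FrequencySpec(source="behaviour_window", window_t=7),
            FrequencySpec(source="behaviour_window", window_t=7, burn_in="use_partial"),
            FrequencySpec(source="behaviour_full_history", exclude_own_history=True),
        ],
    )
    def test_run_frequencies_matches_scalar(self, spec):
        run = run_batch(RuleConfig("random_copy"), 1, base_seed=11, n=20, n_events=300)[0]
        fast = run_frequencies(run, spec)
        variants = run.initial_state.variants.copy()
        stream = BehaviourStream()
        for ev in run.iter_events():
            state = dataclasses.replace(run.initial_state, variants=variants.copy())
            if spec.source == "individual_state":
                expected = individual_frequency(state, "A", spec, focal=ev.focal)
            else:
                expected = history_frequency(stream, "A", spec, focal=ev.focal)
            got = fast[ev.event_index]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)
            variants[ev.focal] = 1 if ev.focal_after == "A" else 0
            stream.append(ev.focal_after, ev.focal)

    def test_run_outcomes_matches_scalar(self):
        run = run_batch(
            RuleConfig("variant_preference", p_less=0.4), 1, base_seed=13, n=20,
            n_events=300,
        )[0]
        for convention in ("copy_event", "end_state", "exposure_conditional"):
            spec = OutcomeSpec(convention)
            counted, success = run_outcomes(run, spec)
            for ev in run.iter_events():
                assert (counted[ev.event_index], success[ev.event_index]) == event_outcome(
                    ev, "A", spec
                )
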