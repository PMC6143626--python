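"""Frequency measures and adoption-outcome conventions for copy events.

Two families of choices made when building an acquisition curve are kept
explicit and orthogonal here, because they change its shape:

*Frequency of what?*  :class:`FrequencySpec` selects between the proportion
of individuals currently exhibiting a variant (``individual_state``), the
proportion of that variant among all behaviours performed so far in the run
(``behaviour_full_history``), and the proportion among the most recent
``window_t`` performed behaviours (``behaviour_window``).

*What counts as adopting?*  :class:`OutcomeSpec` selects between three
conventions: ``copy_event`` counts every event and scores a success only
when the tracked variant was demonstrated and actually copied (so retaining
the tracked variant against a rival demonstration is a failure);
``end_state`` counts every event and scores a success whenever the focal
ends the event exhibiting the tracked variant (retention included);
``exposure_conditional`` restricts to events where the tracked variant was
demonstrated and scores the focal's end state.

The behaviour stream of a run is the sequence of post-event focal variants,
one performed behaviour per copying event.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .engine import A_CODE, CopyEvent, PopulationState, SimulationRun, variant_code

__all__ = [
    "FREQUENCY_SOURCES",
    "OUTCOME_CONVENTIONS",
    "BURN_IN_POLICIES",
    "FrequencySpec",
    "OutcomeSpec",
    "BehaviourStream",
    "individual_frequency",
    "history_frequency",
    "event_outcome",
    "run_frequencies",
    "run_outcomes",
]

FREQUENCY_SOURCES = ("individual_state", "behaviour_full_history", "behaviour_window")
OUTCOME_CONVENTIONS = ("copy_event", "end_state", "exposure_conditional")
BURN_IN_POLICIES = ("skip_until_full_window", "use_partial")


@dataclasses.dataclass(frozen=True)
class FrequencySpec:
    """How to measure a variant's prevalence at each event.

    ``exclude_focal_from_state`` drops the focal individual from the
    individual-state count; ``exclude_own_history`` drops the focal's own
    performed behaviours from history counts.  Both default to False,
    matching the original simulation code in which the focal was counted.
    ``burn_in`` controls windowed frequencies before a full window exists:
    ``skip_until_full_window`` marks them undefined, ``use_partial`` uses
    however much history is available.
    """

    source: str = "individual_state"
    window_t: int = 10
    exclude_focal_from_state: bool = False
    exclude_own_history: bool = False
    burn_in: str = "skip_until_full_window"

    def __post_init__(self) -> None:
        if self.source not in FREQUENCY_SOURCES:
            raise ValueError(
                f"source must be one of {FREQUENCY_SOURCES}, got {self.source!r}"
            )
        if self.source == "behaviour_window" and self.window_t < 1:
            raise ValueError(f"window_t must be >= 1, got {self.window_t}")
        if self.burn_in not in BURN_IN_POLICIES:
            raise ValueError(
                f"burn_in must be one of {BURN_IN_POLICIES}, got {self.burn_in!r}"
            )


@dataclasses.dataclass(frozen=True)
class OutcomeSpec:
    """Which events count, and which count as adoption of the variant."""

    convention: str = "copy_event"

    def __post_init__(self) -> None:
        if self.convention not in OUTCOME_CONVENTIONS:
            raise ValueError(
                f"convention must be one of {OUTCOME_CONVENTIONS}, "
                f"got {self.convention!r}"
            )


@dataclasses.dataclass
class BehaviourStream:
    """Ordered record of performed behaviours, one per completed event."""

    labels: list[str] = dataclasses.field(default_factory=list)
    performers: list[int] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.performers):
            raise ValueError("labels and performers must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def append(self, label: str, performer: int) -> None:
        self.labels.append(label)
        self.performers.append(performer)

    @classmethod
    def from_run(cls, run: SimulationRun) -> "BehaviourStream":
        labels = ["A" if v == A_CODE else "B" for v in run.focal_after]
        return cls(labels=labels, performers=[int(f) for f in run.focal])


def individual_frequency(
    state: PopulationState,
    variant: str,
    spec: FrequencySpec = FrequencySpec(),
    focal: Optional[int] = None,
) -> float:
    """Proportion of individuals exhibiting ``variant`` just before an event."""
    code = variant_code(variant)
    count = state.count(code)
    n = state.n_individuals
    if spec.exclude_focal_from_state:
        if focal is None:
            raise ValueError("exclude_focal_from_state requires a focal index")
        count -= int(state.variants[focal] == code)
        n -= 1
    return count / n


def history_frequency(
    stream: BehaviourStream | Sequence[str],
    variant: str,
    spec: FrequencySpec,
    focal: Optional[int] = None,
) -> Optional[float]:
    """Proportion of ``variant`` among prior performed behaviours.

    Returns ``None`` (undefined) for an empty stream, or when a full window
    is required but not yet available.  Callers must exclude undefined
    events from curves.
    """
    if isinstance(stream, BehaviourStream):
        labels = stream.labels
        performers = stream.performers
    else:
        labels = list(stream)
        performers = None
    if spec.exclude_own_history:
        if focal is None:
            raise ValueError("exclude_own_history requires a focal index")
        if performers is None:
            raise ValueError("exclude_own_history requires performer indices")
        labels = [lab for lab, who in zip(labels, performers) if who != focal]
    if spec.source == "behaviour_window":
        if len(labels) < spec.window_t and spec.burn_in == "skip_until_full_window":
            return None
        labels = labels[-spec.window_t :]
    elif spec.source != "behaviour_full_history":
        raise ValueError(f"history_frequency does not apply to source {spec.source!r}")
    if not labels:
        return None
    code = variant_code(variant)
    return sum(variant_code(lab) == code for lab in labels) / len(labels)


def event_outcome(
    event: CopyEvent,
    variant: str,
    spec: OutcomeSpec = OutcomeSpec(),
) -> tuple[bool, bool]:
    """(counted, success) for one event under the chosen convention."""
    if event.demo_variant is None:  # no-demonstrator event
        return False, False
    code = variant_code(variant)
    demo_matches = variant_code(event.demo_variant) == code
    ends_with = variant_code(event.focal_after) == code
    if spec.convention == "copy_event":
        return True, bool(demo_matches and event.copy_succeeded)
    if spec.convention == "end_state":
        return True, ends_with
    # exposure_conditional
    return bool(demo_matches), bool(demo_matches and ends_with)


# ---------------------------------------------------------------------------
# Vectorised per-run versions (the hot path for curve building)
# ---------------------------------------------------------------------------


def _own_excluded_history_counts(
    run: SimulationRun, code: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-event (matching, total) prior-behaviour counts excluding the focal's own."""
    n = run.n_individuals
    per_ind_match = np.zeros(n, dtype=np.int64)
    per_ind_total = np.zeros(n, dtype=np.int64)
    e = run.n_events
    match = np.empty(e, dtype=np.int64)
    total = np.empty(e, dtype=np.int64)
    is_match = (run.focal_after == code).astype(np.int64)
    cum_match = 0
    cum_total = 0
    for i in range(e):
        f = run.focal[i]
        match[i] = cum_match - per_ind_match[f]
        total[i] = cum_total - per_ind_total[f]
        per_ind_match[f] += is_match[i]
        per_ind_total[f] += 1
        cum_match += is_match[i]
        cum_total += 1
    return match, total


def run_frequencies(
    run: SimulationRun,
    spec: FrequencySpec = FrequencySpec(),
    variant: str = "A",
) -> np.ndarray:
    """Frequency measure for every event of a run; NaN where undefined.

    Matches the scalar operations: ``individual_state`` is measured
    immediately before the event; history measures use the behaviour stream
    of prior events (the first event of a run has no history).
    """
    code = variant_code(variant)
    n = run.n_individuals
    e = run.n_events
    if spec.source == "individual_state":
        count = run.count_a_before.astype(np.float64)
        if code != A_CODE:
            count = n - count
        if spec.exclude_focal_from_state:
            count -= run.focal_before == code
            return count / (n - 1)
        return count / n

    if spec.exclude_own_history:
        match, total = _own_excluded_history_counts(run, code)
        if spec.source == "behaviour_window":
            raise NotImplementedError(
                "exclude_own_history with windows is only available through "
                "the scalar history_frequency API"
            )
        with np.errstate(invalid="ignore"):
            out = match / total.astype(np.float64)
        return out  # NaN where total == 0

    is_match = (run.focal_after == code).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_match)))  # cum[i] = matches in events < i
    idx = np.arange(e, dtype=np.int64)
    if spec.source == "behaviour_full_history":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = cum[:e] / idx.astype(np.float64)
        out[0] = np.nan
        return out
    # behaviour_window
    t = spec.window_t
    lo = np.maximum(idx - t, 0)
    have = idx - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (cum[idx] - cum[lo]) / have.astype(np.float64)
    out[0] = np.nan
    if spec.burn_in == "skip_until_full_window":
        out[:t] = np.nan
    return out


def run_outcomes(
    run: SimulationRun,
    spec: OutcomeSpec = OutcomeSpec(),
    variant: str = "A",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (counted, success) boolean arrays for every event."""
    code = variant_code(variant)
    has_demo = run.demo_variant >= 0
    demo_matches = run.demo_variant == code
    ends_with = run.focal_after == code
    if spec.convention == "copy_event":
        counted = has_demo.copy()
        success = demo_matches & (run.copy_succeeded == 1)
    elif spec.convention == "end_state":
        counted = has_demo.copy()
        success = has_demo & ends_with
    else:  # exposure_conditional
        counted = has_demo & demo_matches
        success = counted & ends_with
    return counted, success
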