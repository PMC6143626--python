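"""Named experiment drivers binding simulator, measurement and fitting.

Each scenario reproduces one of the standard analyses of the
sigmoid-detection debate, with the canonical generative settings as
defaults: populations of N = 100 individuals, 10000 copying events per
run, 1000 replicate runs.  Every input a scenario needs, it generates.

The scenarios are:

``variant_preference``
    Direct-bias runs under fixed 50/50 or uniform starts, pooled and
    stratified by which variant is preferred.  Shows the pooled-sigmoid
    artefact under 50/50 starts and the slope-1 / slope-p_less lines that
    compose it.
``subgroup``
    Demonstrator-subgroup (model-bias) runs under fixed, uniform and rare
    starts; drift-to-fixation inside the small subgroup produces the step
    shape.
``dm_boundary``
    The subgroup analysis across a grid of subgroup sizes, reporting the
    largest size at which the sigmoid still beats the line.
``measurement``
    Identical neutral (random-copy) runs measured three ways: current
    individual-state frequency, full behaviour history, and a recent
    window of 10 behaviours.
``window_sweep``
    The neutral runs swept over history-window sizes, locating the window
    size beyond which the full-history sigmoid artefact reappears.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import AcquisitionCurve, build_curve
from .engine import RULES, START_MODES, RuleConfig, SimulationRun, run_batch
from .fitting import (
    FitComparison,
    compare_fits,
    crossover_window,
    default_window_grid,
    window_sweep,
)
from .measure import OUTCOME_CONVENTIONS, FrequencySpec, OutcomeSpec

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "ScenarioResult",
    "scenario_variant_preference",
    "scenario_demonstrator_subgroup",
    "scenario_dm_boundary",
    "scenario_measurement_comparison",
    "scenario_window_sweep",
    "run_scenario",
    "flat_segments",
]

SCENARIOS = (
    "variant_preference",
    "subgroup",
    "dm_boundary",
    "measurement",
    "window_sweep",
)

# Seed offset between independent batches inside one scenario, so their
# per-run seed ranges never overlap.
_BATCH_STRIDE = 1_000_000


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Parameters shared by all scenario drivers (canonical defaults)."""

    scenario: str = "measurement"
    n: int = 100
    n_events: int = 10_000
    n_reps: int = 1000
    start_mode: str = "fixed_half"
    rule: str = "random_copy"
    p_less: float = 0.2
    dm: int = 5
    conformist_sample: int = 3
    allow_self_as_demonstrator: bool = False
    window_t: int = 10
    bin_width: float = 0.01
    outcome: str = "copy_event"
    sigmoid_form: str = "logistic2"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.start_mode not in START_MODES:
            raise ValueError(
                f"start_mode must be one of {START_MODES}, got {self.start_mode!r}"
            )
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.outcome not in OUTCOME_CONVENTIONS:
            raise ValueError(
                f"outcome must be one of {OUTCOME_CONVENTIONS}, got {self.outcome!r}"
            )
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.n_events < 1:
            raise ValueError(f"n_events must be >= 1, got {self.n_events}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not 0.0 <= self.p_less <= 1.0:
            raise ValueError(f"p_less must lie in [0, 1], got {self.p_less}")
        if not 1 <= self.dm <= self.n:
            raise ValueError(f"dm must lie in [1, n], got {self.dm}")

    def rule_config(self, rule: Optional[str] = None) -> RuleConfig:
        return RuleConfig(
            rule=rule or self.rule,
            p_less=self.p_less,
            dm=self.dm,
            conformist_sample=self.conformist_sample,
            allow_self_as_demonstrator=self.allow_self_as_demonstrator,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ScenarioResult:
    """Curves, fit comparisons, tables and verdicts of one scenario run."""

    name: str
    config: dict
    curves: dict[str, AcquisitionCurve] = dataclasses.field(default_factory=dict)
    comparisons: dict[str, FitComparison] = dataclasses.field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)
    verdicts: dict[str, str] = dataclasses.field(default_factory=dict)
    extras: dict = dataclasses.field(default_factory=dict)


def flat_segments(curve: AcquisitionCurve, tol: float = 0.05) -> dict:
    """Count the near-0 and near-1 plateau bins at the curve's two ends.

    The subgroup rule, once the subgroup has fixed, produces adoption
    probabilities pinned at 0 or 1 across wide frequency ranges; this
    reports how many nonempty bins with centres below/above 0.5 sit within
    ``tol`` of those plateaus.
    """
    mask = curve.nonempty()
    centres = curve.bin_centres[mask]
    prob = curve.probability[mask]
    return {
        "low_flat_bins": int(np.sum((centres < 0.5) & (prob <= tol))),
        "high_flat_bins": int(np.sum((centres > 0.5) & (prob >= 1.0 - tol))),
        "tol": tol,
    }


def _convention_appendix(
    runs: Sequence[SimulationRun],
    variant: str,
    freq_spec: FrequencySpec,
    bin_width: float,
    sigmoid_form: str,
) -> pd.DataFrame:
    """Fit verdicts under every adoption convention, not just the default."""
    rows = []
    for convention in OUTCOME_CONVENTIONS:
        curve = build_curve(
            runs,
            variant=variant,
            freq_spec=freq_spec,
            outcome_spec=OutcomeSpec(convention),
            bin_width=bin_width,
        )
        comp = compare_fits(curve, sigmoid_form=sigmoid_form)
        rows.append(
            {
                "convention": convention,
                "r2_linear": comp.linear.r_squared,
                "r2_sigmoid": comp.sigmoid.r_squared if comp.sigmoid else np.nan,
                "relative_fit": comp.relative_fit,
                "better": comp.better,
            }
        )
    return pd.DataFrame(rows)


def scenario_variant_preference(
    start_mode: str = "fixed_half",
    pooling: str = "both",
    p_less: float = 0.2,
    n: int = 100,
    n_events: int = 10_000,
    n_reps: int = 1000,
    base_seed: int = 0,
    bin_width: float = 0.01,
    outcome: str = "copy_event",
    sigmoid_form: str = "logistic2",
    with_appendix: bool = False,
) -> ScenarioResult:
    """Direct-bias runs, pooled and stratified by the preferred variant.

    Tracks variant A throughout.  The ``A_preferred`` / ``B_preferred``
    strata split runs by which variant was (randomly) preferred; under the
    default copy-event convention their curves are lines through the origin
    with slopes ~1 and ~p_less respectively, and the pooled curve is what
    joining or averaging those lines produces under the chosen start mode.
    ``pooling`` may be ``"pooled"``, ``"by_preference"`` or ``"both"``.
    """
    config = RuleConfig(rule="variant_preference", p_less=p_less)
    runs = run_batch(
        config,
        n_reps=n_reps,
        base_seed=base_seed,
        n=n,
        n_events=n_events,
        start_mode=start_mode,
    )
    freq_spec = FrequencySpec(source="individual_state")
    outcome_spec = OutcomeSpec(outcome)
    result = ScenarioResult(
        name="variant_preference",
        config={
            "start_mode": start_mode,
            "pooling": pooling,
            "p_less": p_less,
            "n": n,
            "n_events": n_events,
            "n_reps": n_reps,
            "base_seed": base_seed,
            "outcome": outcome,
        },
    )
    strata: dict[str, list[SimulationRun]] = {}
    if pooling in ("pooled", "both"):
        strata["pooled"] = list(runs)
    if pooling in ("by_preference", "both"):
        strata["A_preferred"] = [r for r in runs if r.preferred_variant == "A"]
        strata["B_preferred"] = [r for r in runs if r.preferred_variant == "B"]
    for label, subset in strata.items():
        if not subset:
            continue
        curve = build_curve(
            subset,
            variant="A",
            freq_spec=freq_spec,
            outcome_spec=outcome_spec,
            bin_width=bin_width,
            metadata={"stratum": label, "start_mode": start_mode},
        )
        comp = compare_fits(curve, sigmoid_form=sigmoid_form)
        result.curves[label] = curve
        result.comparisons[label] = comp
        result.verdicts[label] = comp.better
        if label in ("A_preferred", "B_preferred"):
            result.extras[f"slope_{label}"] = comp.linear.params["slope"]
            result.extras[f"intercept_{label}"] = comp.linear.params["intercept"]
    if with_appendix:
        result.tables["convention_appendix"] = _convention_appendix(
            list(runs), "A", freq_spec, bin_width, sigmoid_form
        )
    return result


def scenario_demonstrator_subgroup(
    start_mode: str = "fixed_half",
    dm: int = 5,
    n: int = 100,
    n_events: int = 10_000,
    n_reps: int = 1000,
    base_seed: int = 0,
    bin_width: float = 0.01,
    outcome: str = "copy_event",
    sigmoid_form: str = "logistic2",
    with_appendix: bool = False,
) -> ScenarioResult:
    """Model-bias runs: copy only members of a fixed subgroup of size dm."""
    config = RuleConfig(rule="demonstrator_subgroup", dm=dm)
    runs = run_batch(
        config,
        n_reps=n_reps,
        base_seed=base_seed,
        n=n,
        n_events=n_events,
        start_mode=start_mode,
    )
    freq_spec = FrequencySpec(source="individual_state")
    curve = build_curve(
        runs,
        variant="A",
        freq_spec=freq_spec,
        outcome_spec=OutcomeSpec(outcome),
        bin_width=bin_width,
        metadata={"dm": dm, "start_mode": start_mode},
    )
    comp = compare_fits(curve, sigmoid_form=sigmoid_form)
    result = ScenarioResult(
        name="subgroup",
        config={
            "start_mode": start_mode,
            "dm": dm,
            "n": n,
            "n_events": n_events,
            "n_reps": n_reps,
            "base_seed": base_seed,
            "outcome": outcome,
        },
        curves={"pooled": curve},
        comparisons={"pooled": comp},
        verdicts={"pooled": comp.better},
        extras={"flat_segments": flat_segments(curve)},
    )
    if with_appendix:
        result.tables["convention_appendix"] = _convention_appendix(
            list(runs), "A", freq_spec, bin_width, sigmoid_form
        )
    return result


def scenario_dm_boundary(
    n: int = 100,
    dm_grid: Sequence[int] = (5, 10, 20, 50),
    start_mode: str = "fixed_half",
    n_events: int = 10_000,
    n_reps: int = 1000,
    base_seed: int = 0,
    bin_width: float = 0.01,
    outcome: str = "copy_event",
    sigmoid_form: str = "logistic2",
) -> ScenarioResult:
    """Subgroup analysis across subgroup sizes: where does the sigmoid die?

    Reports a per-dm verdict table and the largest dm at which the sigmoid
    beats the line (None if it never does).
    """
    rows = []
    result = ScenarioResult(
        name="dm_boundary",
        config={
            "n": n,
            "dm_grid": list(dm_grid),
            "start_mode": start_mode,
            "n_events": n_events,
            "n_reps": n_reps,
            "base_seed": base_seed,
            "outcome": outcome,
        },
    )
    for k, dm in enumerate(sorted(dm_grid)):
        sub = scenario_demonstrator_subgroup(
            start_mode=start_mode,
            dm=dm,
            n=n,
            n_events=n_events,
            n_reps=n_reps,
            base_seed=base_seed + k * _BATCH_STRIDE,
            bin_width=bin_width,
            outcome=outcome,
            sigmoid_form=sigmoid_form,
        )
        comp = sub.comparisons["pooled"]
        result.curves[f"dm_{dm}"] = sub.curves["pooled"]
        result.comparisons[f"dm_{dm}"] = comp
        rows.append(
            {
                "dm": dm,
                "r2_linear": comp.linear.r_squared,
                "r2_sigmoid": comp.sigmoid.r_squared if comp.sigmoid else np.nan,
                "relative_fit": comp.relative_fit,
                "better": comp.better,
            }
        )
    table = pd.DataFrame(rows)
    result.tables["dm_boundary"] = table
    winners = table.loc[table["better"] == "sigmoid", "dm"]
    largest = int(winners.max()) if len(winners) else None
    result.extras["largest_sigmoid_dm"] = largest
    result.verdicts["largest_sigmoid_dm"] = str(largest)
    return result


def scenario_measurement_comparison(
    n: int = 100,
    n_events: int = 10_000,
    n_reps: int = 1000,
    start_mode: str = "fixed_half",
    window_t: int = 10,
    base_seed: int = 0,
    bin_width: float = 0.01,
    outcome: str = "copy_event",
    sigmoid_form: str = "logistic2",
) -> ScenarioResult:
    """One set of neutral runs, three frequency measures, three curves.

    The same random-copy event logs are measured against the current
    individual-state frequency, the full behaviour history, and a recent
    window of ``window_t`` behaviours — isolating the measurement
    convention as the only thing that changes between the curves.
    """
    runs = run_batch(
        RuleConfig(rule="random_copy"),
        n_reps=n_reps,
        base_seed=base_seed,
        n=n,
        n_events=n_events,
        start_mode=start_mode,
    )
    specs = {
        "state": FrequencySpec(source="individual_state"),
        "full_history": FrequencySpec(source="behaviour_full_history"),
        f"window_{window_t}": FrequencySpec(
            source="behaviour_window", window_t=window_t
        ),
    }
    result = ScenarioResult(
        name="measurement",
        config={
            "n": n,
            "n_events": n_events,
            "n_reps": n_reps,
            "start_mode": start_mode,
            "window_t": window_t,
            "base_seed": base_seed,
            "outcome": outcome,
        },
    )
    for label, spec in specs.items():
        curve = build_curve(
            runs,
            variant="A",
            freq_spec=spec,
            outcome_spec=OutcomeSpec(outcome),
            bin_width=bin_width,
            metadata={"measure": label},
        )
        comp = compare_fits(curve, sigmoid_form=sigmoid_form)
        result.curves[label] = curve
        result.comparisons[label] = comp
        result.verdicts[label] = comp.better
        result.extras[f"slope_{label}"] = comp.linear.params["slope"]
    return result


def scenario_window_sweep(
    window_grid: Optional[Sequence[int]] = None,
    n: int = 100,
    n_events: int = 10_000,
    n_reps: int = 1000,
    start_mode: str = "fixed_half",
    base_seed: int = 0,
    bin_width: float = 0.01,
    outcome: str = "copy_event",
    sigmoid_form: str = "logistic2",
) -> ScenarioResult:
    """Sweep the history-window size on the baseline neutral scenario.

    Reports the full (T, r², relative fit) table and the crossover window
    T* — the smallest window from which the sigmoid fit stays ahead.
    """
    if window_grid is None:
        window_grid = default_window_grid(n_events)
    runs = run_batch(
        RuleConfig(rule="random_copy"),
        n_reps=n_reps,
        base_seed=base_seed,
        n=n,
        n_events=n_events,
        start_mode=start_mode,
    )
    table = window_sweep(
        runs,
        windows=window_grid,
        variant="A",
        outcome_spec=OutcomeSpec(outcome),
        bin_width=bin_width,
        sigmoid_form=sigmoid_form,
    )
    t_star = crossover_window(table)
    return ScenarioResult(
        name="window_sweep",
        config={
            "n": n,
            "n_events": n_events,
            "n_reps": n_reps,
            "start_mode": start_mode,
            "base_seed": base_seed,
            "outcome": outcome,
            "window_grid": [int(t) for t in window_grid],
        },
        tables={"sweep": table},
        verdicts={"crossover": str(t_star)},
        extras={"crossover_window": t_star},
    )


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Dispatch a :class:`ScenarioConfig` to the matching driver."""
    common = dict(
        n=config.n,
        n_events=config.n_events,
        n_reps=config.n_reps,
        base_seed=config.base_seed,
        bin_width=config.bin_width,
        outcome=config.outcome,
        sigmoid_form=config.sigmoid_form,
    )
    if config.scenario == "variant_preference":
        return scenario_variant_preference(
            start_mode=config.start_mode, p_less=config.p_less, **common
        )
    if config.scenario == "subgroup":
        return scenario_demonstrator_subgroup(
            start_mode=config.start_mode, dm=config.dm, **common
        )
    if config.scenario == "dm_boundary":
        return scenario_dm_boundary(start_mode=config.start_mode, **common)
    if config.scenario == "measurement":
        return scenario_measurement_comparison(
            start_mode=config.start_mode, window_t=config.window_t, **common
        )
    if config.scenario == "window_sweep":
        return scenario_window_sweep(start_mode=config.start_mode, **common)
    raise ValueError(f"unknown scenario {config.scenario!r}")
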