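"""Agent-based two-variant copying simulator.

A population of ``n`` individuals each exhibits one of two behavioural
variants, labelled ``"A"`` and ``"B"``.  Time advances in discrete copying
events: a focal individual is drawn uniformly at random, observes a
demonstrator selected according to the active learning rule, and adopts (or
declines to adopt) the demonstrated variant.  The full event log is retained
so that downstream modules can recompute any frequency measure or adoption
convention after the fact.

Implemented learning rules
--------------------------
``random_copy``
    Neutral baseline: the demonstrator is a uniformly random other
    individual and its variant is always adopted.  The expected variant
    frequency is a martingale and the population drifts to fixation.
``variant_preference``
    A direct bias: all individuals share a preferred variant.  A
    demonstrated preferred variant is always adopted; the less-preferred
    variant is adopted with probability ``p_less``.
``demonstrator_subgroup``
    A model bias: demonstrators are drawn only from a fixed subset of the
    population of size ``dm`` (subgroup members included, they copy within
    the subgroup themselves).
``conformist_reference``
    A genuinely conformist positive control (not part of the critiques this
    package examines): the focal samples ``conformist_sample`` distinct
    individuals and adopts the majority variant among them.

Variants are stored internally as ``int8`` codes (``A`` = 1, ``B`` = 0);
the public scalar API speaks in the string labels.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "A_CODE",
    "B_CODE",
    "RULES",
    "START_MODES",
    "RuleConfig",
    "PopulationState",
    "CopyEvent",
    "SimulationRun",
    "NoDemonstrator",
    "InvalidPopulationError",
    "init_population",
    "select_demonstrator",
    "apply_rule",
    "run_events",
    "run_batch",
    "uniform_increment_grid",
]

A_CODE = 1
B_CODE = 0
_CODE_OF = {"A": A_CODE, "B": B_CODE}
_LABEL_OF = {A_CODE: "A", B_CODE: "B"}

RULES = (
    "random_copy",
    "variant_preference",
    "demonstrator_subgroup",
    "conformist_reference",
)
_RULE_CODE = {name: i for i, name in enumerate(RULES)}

START_MODES = ("fixed_half", "uniform_increments", "rare")


class InvalidPopulationError(ValueError):
    """Raised when a population cannot be constructed (e.g. n < 2)."""


class NoDemonstrator(Exception):
    """Signals an empty demonstrator candidate set for the focal individual.

    Occurs only in degenerate subgroup settings (e.g. ``dm = 1`` with the
    focal individual being the sole member and self-copying disallowed).
    The corresponding event records no change.
    """


def variant_code(variant: str | int) -> int:
    if variant in (A_CODE, B_CODE):
        return int(variant)
    try:
        return _CODE_OF[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; expected 'A' or 'B'") from None


def variant_label(code: int) -> str:
    return _LABEL_OF[int(code)]


@dataclasses.dataclass(frozen=True)
class RuleConfig:
    """Parameters of a learning rule.

    Parameters
    ----------
    rule : str
        One of :data:`RULES`.
    p_less : float
        Probability of copying the less-preferred variant under
        ``variant_preference`` (the ``q`` of the analytical direct-bias
        model).  Must lie in [0, 1].
    dm : int
        Demonstrator-subgroup size under ``demonstrator_subgroup``.
    conformist_sample : int
        Number of distinct demonstrators sampled under
        ``conformist_reference``; odd, at least 3, so a strict majority
        always exists.
    allow_self_as_demonstrator : bool
        Whether the focal individual may be drawn as its own demonstrator.
        Off by default; switching it on replicates the behaviour of earlier
        simulation code in which self-copying was possible.
    """

    rule: str = "random_copy"
    p_less: float = 0.2
    dm: int = 5
    conformist_sample: int = 3
    allow_self_as_demonstrator: bool = False

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if not 0.0 <= self.p_less <= 1.0:
            raise ValueError(f"p_less must lie in [0, 1], got {self.p_less}")
        if self.dm < 1:
            raise ValueError(f"dm must be >= 1, got {self.dm}")
        if self.conformist_sample < 3 or self.conformist_sample % 2 == 0:
            raise ValueError(
                f"conformist_sample must be an odd integer >= 3, "
                f"got {self.conformist_sample}"
            )


@dataclasses.dataclass(frozen=True)
class PopulationState:
    """Snapshot of who exhibits which variant, plus rule attributes.

    ``variants`` is an ``int8`` array of codes (A = 1, B = 0).
    ``preferred_variant`` is set iff the active rule is
    ``variant_preference``; ``subgroup_ids`` is nonempty iff the rule is
    ``demonstrator_subgroup``.
    """

    variants: np.ndarray
    preferred_variant: Optional[str] = None
    subgroup_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.variants, dtype=np.int8)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidPopulationError(
                f"population needs at least 2 individuals, got shape {arr.shape}"
            )
        if not np.isin(arr, (A_CODE, B_CODE)).all():
            raise ValueError("variants must be 'A'/'B' codes (1/0)")
        object.__setattr__(self, "variants", arr)
        ids = tuple(sorted(int(i) for i in self.subgroup_ids))
        if ids and (ids[0] < 0 or ids[-1] >= arr.size):
            raise ValueError("subgroup_ids out of range")
        if len(set(ids)) != len(ids):
            raise ValueError("subgroup_ids must be distinct")
        object.__setattr__(self, "subgroup_ids", ids)
        if self.preferred_variant is not None:
            object.__setattr__(
                self, "preferred_variant", variant_label(variant_code(self.preferred_variant))
            )

    @property
    def n_individuals(self) -> int:
        return int(self.variants.size)

    def count(self, variant: str | int = "A") -> int:
        code = variant_code(variant)
        n_a = int(self.variants.sum())
        return n_a if code == A_CODE else self.n_individuals - n_a

    def frequency(self, variant: str | int = "A") -> float:
        return self.count(variant) / self.n_individuals

    def labels(self) -> list[str]:
        return [variant_label(v) for v in self.variants]


class CopyEvent(NamedTuple):
    """One copying interaction, fully resolved."""

    event_index: int
    focal: int
    demonstrator: Optional[int]  # None for no-demonstrator events
    demo_variant: Optional[str]
    focal_before: str
    focal_after: str
    copy_succeeded: bool
    freq_state: float  # frequency of A among individuals just before the event


def init_population(
    n: int,
    p0: float,
    mode: str = "binomial",
    rng: Optional[np.random.Generator] = None,
) -> PopulationState:
    """Initialise a population with variant-A probability (or share) ``p0``.

    ``binomial`` draws each individual independently A with probability
    ``p0``; ``exact_round`` places exactly ``round(n * p0)`` A-individuals
    at random positions.
    """
    if n < 2:
        raise InvalidPopulationError(f"population size must be >= 2, got {n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    rng = np.random.default_rng() if rng is None else rng
    if mode == "binomial":
        variants = (rng.random(n) < p0).astype(np.int8)
    elif mode == "exact_round":
        n_a = int(round(n * p0))
        variants = np.zeros(n, dtype=np.int8)
        variants[rng.choice(n, size=n_a, replace=False)] = A_CODE
    else:
        raise ValueError(f"mode must be 'binomial' or 'exact_round', got {mode!r}")
    return PopulationState(variants=variants)


def _candidates(state: PopulationState, focal: int, config: RuleConfig) -> np.ndarray:
    if config.rule == "demonstrator_subgroup":
        pool = np.asarray(state.subgroup_ids, dtype=np.int64)
        if pool.size == 0:
            raise ValueError("demonstrator_subgroup rule requires a nonempty subgroup")
    else:
        pool = np.arange(state.n_individuals, dtype=np.int64)
    if not config.allow_self_as_demonstrator:
        pool = pool[pool != focal]
    return pool


def select_demonstrator(
    state: PopulationState,
    focal: int,
    config: RuleConfig,
    rng: np.random.Generator,
) -> int:
    """Draw a demonstrator for ``focal`` under the configured rule.

    Raises :class:`NoDemonstrator` when the candidate set is empty.
    """
    if not 0 <= focal < state.n_individuals:
        raise IndexError(f"focal index {focal} out of range")
    pool = _candidates(state, focal, config)
    if pool.size == 0:
        raise NoDemonstrator(f"no demonstrator available for focal {focal}")
    return int(pool[rng.integers(pool.size)])


def apply_rule(
    focal_variant: str,
    demo_variant: str,
    config: RuleConfig,
    rng: np.random.Generator,
    preferred_variant: Optional[str] = None,
) -> tuple[str, bool]:
    """Resolve one demonstration into (new focal variant, copy-success flag).

    Under ``random_copy``, ``demonstrator_subgroup`` and
    ``conformist_reference`` the demonstrated variant is always adopted.
    Under ``variant_preference`` the preferred variant is always adopted and
    the less-preferred one with probability ``p_less``; on failure the focal
    keeps its variant and the event is flagged as a failed copy.
    """
    fv = variant_code(focal_variant)
    dv = variant_code(demo_variant)
    if config.rule == "variant_preference":
        if preferred_variant is None:
            raise ValueError("variant_preference requires preferred_variant")
        if dv == variant_code(preferred_variant):
            succeeded = True
        else:
            succeeded = bool(rng.random() < config.p_less)
    else:
        succeeded = True
    new = dv if succeeded else fv
    return variant_label(new), succeeded


# ---------------------------------------------------------------------------
# Event-loop kernel
#
# The sequential loop consumes pre-drawn random numbers, so its output is
# identical whether or not the numba-compiled version is in use.  Uniform
# draws in [0, 1) are mapped to integer ranks; the without-replacement
# sampling for the conformist rule uses the standard rank-skipping scheme.
# ---------------------------------------------------------------------------


def _copy_kernel_py(
    variants,  # int8[n], mutated in place
    pos_in_subgroup,  # int64[n], -1 for non-members
    subgroup,  # int64[dm] sorted (empty unless subgroup rule)
    focals,  # int64[e]
    u_demo,  # float64[e]
    u_copy,  # float64[e]
    u_conf,  # float64[e, k] (empty unless conformist rule)
    rule,  # int
    p_less,  # float
    preferred,  # int: -1 none, 0 B, 1 A
    allow_self,  # bool
    demo_out,  # int32[e]
    demov_out,  # int8[e]
    before_out,  # int8[e]
    after_out,  # int8[e]
    succ_out,  # int8[e]
    counta_out,  # int32[e]
):
    n = variants.shape[0]
    dm = subgroup.shape[0]
    n_events = focals.shape[0]
    k = u_conf.shape[1]
    chosen = np.empty(8, np.int64)  # sorted ranks for without-replacement draws
    counta = 0
    for i in range(n):
        counta += variants[i]
    for i in range(n_events):
        f = focals[i]
        counta_out[i] = counta
        bv = variants[f]
        before_out[i] = bv
        d = -1
        dv = np.int8(-1)
        if rule == 2:  # demonstrator_subgroup
            pf = pos_in_subgroup[f]
            skip_self = (pf >= 0) and (not allow_self)
            m = dm - 1 if skip_self else dm
            if m <= 0:
                demo_out[i] = -1
                demov_out[i] = -1
                succ_out[i] = 0
                after_out[i] = bv
                continue
            j = int(u_demo[i] * m)
            if j >= m:
                j = m - 1
            if skip_self and j >= pf:
                j += 1
            d = subgroup[j]
            dv = variants[d]
        elif rule == 3:  # conformist_reference
            m = n if allow_self else n - 1
            votes_a = 0
            for t in range(k):
                r = int(u_conf[i, t] * (m - t))
                if r >= m - t:
                    r = m - t - 1
                for s in range(t):  # skip previously chosen ranks (ascending)
                    if chosen[s] <= r:
                        r += 1
                pos = t
                while pos > 0 and chosen[pos - 1] > r:
                    chosen[pos] = chosen[pos - 1]
                    pos -= 1
                chosen[pos] = r
            for t in range(k):
                idx = chosen[t]
                if (not allow_self) and idx >= f:
                    idx += 1
                votes_a += variants[idx]
            dv = np.int8(1) if 2 * votes_a > k else np.int8(0)
            for t in range(k):  # representative demonstrator: first majority voter
                idx = chosen[t]
                if (not allow_self) and idx >= f:
                    idx += 1
                if variants[idx] == dv:
                    d = idx
                    break
        else:  # whole-population demonstrator (random_copy, variant_preference)
            m = n if allow_self else n - 1
            j = int(u_demo[i] * m)
            if j >= m:
                j = m - 1
            if (not allow_self) and j >= f:
                j += 1
            d = j
            dv = variants[d]
        succ = np.int8(1)
        if rule == 1 and dv != preferred:  # less-preferred variant demonstrated
            succ = np.int8(1) if u_copy[i] < p_less else np.int8(0)
        av = dv if succ == 1 else bv
        if av != bv:
            variants[f] = av
            counta += 1 if av == 1 else -1
        demo_out[i] = d
        demov_out[i] = dv
        succ_out[i] = succ
        after_out[i] = av
    return counta


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _copy_kernel = njit(cache=True)(_copy_kernel_py)
except Exception:  # pragma: no cover
    _copy_kernel = _copy_kernel_py


@dataclasses.dataclass
class SimulationRun:
    """A complete run: event log (as columnar arrays) plus initial/final state.

    The columnar layout (one array per event field) keeps a 10000-event run
    around 100 kB and lets measurement and curve building operate fully
    vectorised.  ``iter_events`` exposes the same data as scalar
    :class:`CopyEvent` records.
    """

    config: RuleConfig
    seed: Optional[int]
    initial_state: PopulationState
    final_state: PopulationState
    focal: np.ndarray  # int64[e]
    demonstrator: np.ndarray  # int32[e], -1 for no-demonstrator events
    demo_variant: np.ndarray  # int8[e], -1 for no-demonstrator events
    focal_before: np.ndarray  # int8[e]
    focal_after: np.ndarray  # int8[e]
    copy_succeeded: np.ndarray  # int8[e]
    count_a_before: np.ndarray  # int32[e], A-count just before each event
    params: dict = dataclasses.field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return int(self.focal.size)

    @property
    def n_individuals(self) -> int:
        return self.initial_state.n_individuals

    @property
    def preferred_variant(self) -> Optional[str]:
        return self.initial_state.preferred_variant

    @property
    def subgroup_ids(self) -> tuple[int, ...]:
        return self.initial_state.subgroup_ids

    def freq_state(self) -> np.ndarray:
        """Frequency of variant A (all individuals) just before each event."""
        return self.count_a_before / self.n_individuals

    def iter_events(self) -> Iterator[CopyEvent]:
        n = self.n_individuals
        for i in range(self.n_events):
            demo = int(self.demonstrator[i])
            dv = int(self.demo_variant[i])
            yield CopyEvent(
                event_index=i,
                focal=int(self.focal[i]),
                demonstrator=demo if demo >= 0 else None,
                demo_variant=variant_label(dv) if dv >= 0 else None,
                focal_before=variant_label(int(self.focal_before[i])),
                focal_after=variant_label(int(self.focal_after[i])),
                copy_succeeded=bool(self.copy_succeeded[i]),
                freq_state=float(self.count_a_before[i]) / n,
            )

    def replay_final(self) -> PopulationState:
        """Re-apply the event log to the initial state (replay invariant)."""
        variants = self.initial_state.variants.copy()
        for i in range(self.n_events):
            variants[self.focal[i]] = self.focal_after[i]
        return dataclasses.replace(self.initial_state, variants=variants)


def run_events(
    initial: PopulationState,
    config: RuleConfig,
    n_events: int,
    rng: np.random.Generator,
    seed: Optional[int] = None,
    params: Optional[dict] = None,
) -> SimulationRun:
    """Run ``n_events`` sequential copying events from ``initial``.

    Each event draws a uniform focal individual, selects a demonstrator
    under ``config.rule``, applies the rule, and logs the outcome.  Runs
    continue past fixation: an absorbed population keeps producing
    no-change events.
    """
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events}")
    n = initial.n_individuals
    rule_code = _RULE_CODE[config.rule]
    if rule_code == _RULE_CODE["variant_preference"] and initial.preferred_variant is None:
        raise ValueError("variant_preference requires initial.preferred_variant")
    if rule_code == _RULE_CODE["demonstrator_subgroup"]:
        if not initial.subgroup_ids:
            raise ValueError("demonstrator_subgroup requires nonempty subgroup_ids")
        if len(initial.subgroup_ids) != config.dm:
            raise ValueError("len(subgroup_ids) must equal config.dm")
    if config.rule == "conformist_reference":
        pool = n if config.allow_self_as_demonstrator else n - 1
        if config.conformist_sample > pool:
            raise ValueError("conformist_sample exceeds available demonstrators")

    subgroup = np.asarray(initial.subgroup_ids, dtype=np.int64)
    pos_in_subgroup = np.full(n, -1, dtype=np.int64)
    pos_in_subgroup[subgroup] = np.arange(subgroup.size)

    # Pre-drawn randomness: focal indices, demonstrator ranks, copy-success
    # uniforms, and (for the conformist rule) the without-replacement ranks.
    focals = rng.integers(0, n, size=n_events)
    u_demo = rng.random(n_events)
    u_copy = rng.random(n_events)
    if config.rule == "conformist_reference":
        u_conf = rng.random((n_events, config.conformist_sample))
    else:
        u_conf = np.empty((0, 1), dtype=np.float64)

    variants = initial.variants.copy()
    e = n_events
    demo_out = np.empty(e, dtype=np.int32)
    demov_out = np.empty(e, dtype=np.int8)
    before_out = np.empty(e, dtype=np.int8)
    after_out = np.empty(e, dtype=np.int8)
    succ_out = np.empty(e, dtype=np.int8)
    counta_out = np.empty(e, dtype=np.int32)

    preferred = -1
    if initial.preferred_variant is not None:
        preferred = variant_code(initial.preferred_variant)

    _copy_kernel(
        variants,
        pos_in_subgroup,
        subgroup,
        focals,
        u_demo,
        u_copy,
        u_conf,
        rule_code,
        float(config.p_less),
        preferred,
        bool(config.allow_self_as_demonstrator),
        demo_out,
        demov_out,
        before_out,
        after_out,
        succ_out,
        counta_out,
    )

    final = dataclasses.replace(initial, variants=variants)
    return SimulationRun(
        config=config,
        seed=seed,
        initial_state=initial,
        final_state=final,
        focal=focals,
        demonstrator=demo_out,
        demo_variant=demov_out,
        focal_before=before_out,
        focal_after=after_out,
        copy_succeeded=succ_out,
        count_a_before=counta_out,
        params=dict(params or {}),
    )


def uniform_increment_grid(n_reps: int) -> np.ndarray:
    """Initial frequencies sweeping 0..1 on the 0.1%-increment grid.

    With 1001 replicates this is exactly 0, 0.001, ..., 1.000; with fewer
    replicates the grid is subsampled evenly (endpoints included).
    """
    if n_reps == 1:
        return np.array([0.5])
    return np.round(np.linspace(0, 1000, n_reps)) / 1000.0


def run_batch(
    config: RuleConfig,
    n_reps: int,
    base_seed: int,
    n: int = 100,
    n_events: int = 10_000,
    start_mode: str = "fixed_half",
    init_mode: str = "binomial",
    fixed_preference: Optional[str] = None,
    p0: Optional[float] = None,
) -> list[SimulationRun]:
    """Run ``n_reps`` mutually independent replicates.

    Per-run seeds are ``base_seed + run_index``, so a batch is bit-for-bit
    reproducible.  Start modes:

    ``fixed_half``
        Every run starts with per-individual variant-A probability 0.5.
    ``uniform_increments``
        Initial frequencies sweep 0-100% in 0.1% increments across runs.
    ``rare``
        Initial variant-A probability drawn uniformly from
        {0.01, ..., 0.10} per run: small but nonzero, so the rare variant
        can occasionally spread.

    For ``variant_preference`` the shared preferred variant is drawn afresh
    each replicate unless ``fixed_preference`` pins it; for
    ``demonstrator_subgroup`` the subgroup is re-sampled each replicate.
    An explicit ``p0`` overrides the start mode.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if start_mode not in START_MODES:
        raise ValueError(f"start_mode must be one of {START_MODES}, got {start_mode!r}")
    grid = uniform_increment_grid(n_reps) if start_mode == "uniform_increments" else None
    runs: list[SimulationRun] = []
    for i in range(n_reps):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        # Draw order is fixed: rare-start p0, preference, subgroup,
        # initial variants, then the event stream.
        if p0 is not None:
            p0_i = float(p0)
        elif start_mode == "fixed_half":
            p0_i = 0.5
        elif start_mode == "uniform_increments":
            p0_i = float(grid[i])
        else:  # rare
            p0_i = float(rng.integers(1, 11)) / 100.0
        state = None
        preferred = None
        subgroup: tuple[int, ...] = ()
        if config.rule == "variant_preference":
            if fixed_preference is not None:
                preferred = variant_label(variant_code(fixed_preference))
            else:
                preferred = "A" if rng.random() < 0.5 else "B"
        if config.rule == "demonstrator_subgroup":
            if config.dm > n:
                raise ValueError("dm cannot exceed population size")
            subgroup = tuple(int(x) for x in rng.choice(n, size=config.dm, replace=False))
        state = init_population(n, p0_i, mode=init_mode, rng=rng)
        state = dataclasses.replace(
            state, preferred_variant=preferred, subgroup_ids=subgroup
        )
        run = run_events(
            state,
            config,
            n_events,
            rng,
            seed=seed,
            params={"p0": p0_i, "start_mode": start_mode, "run_index": i},
        )
        runs.append(run)
    return runs
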