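"""Closed-form direct-bias (variant preference) model.

Consider a large well-mixed population in which a fraction ``p`` exhibits
variant A, a fraction ``r`` of individuals intrinsically prefers A, and the
less-preferred variant, when demonstrated, is copied with probability ``q``
(the preferred one is always copied).  A randomly chosen individual observes
a random other and keeps or switches its behaviour.  The probability that it
ends up exhibiting A is

    Prob(A) = p * [p + r (1 - p)(1 - q)] + (1 - p) * [r p + (1 - r) p q]

The first term covers an observer that already exhibits A and continues to
do so (it either meets an A, or meets a B and declines to switch); the
second covers an observer exhibiting B that switches to A.  Note that this
end-state accounting counts retention of A against a B demonstration as
exhibiting A — the convention that matches how empirical studies score all
available observations.

Special cases: an even preference mix (r = 1/2) or a vanishing bias (q = 1)
collapses the curve to the identity line; a uniform preference for A
(r = 1) gives the classic concave ("r-shaped") direct-bias curve, and a
uniform preference for B (r = 0) its convex mirror image.

The module also provides two constructions that show how pooling runs can
forge a sigmoid out of non-sigmoidal ingredients: :func:`regime_union_curve`
joins the r = 0 branch below frequency 0.5 to the r = 1 branch above it
(what pooling 50/50-start runs amounts to, since each preference regime
only ever visits one half of the frequency range), and
:func:`mixture_of_lines` averages two lines with a frequency-dependent
weight (what pooling uniform-start runs amounts to).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .curves import AcquisitionCurve

__all__ = [
    "DirectBiasParams",
    "MixtureSpec",
    "prob_adopt_a",
    "direct_bias_curve",
    "regime_union_curve",
    "mixture_of_lines",
    "empirical_preference_weight",
]


def _check_unit(name: str, value: np.ndarray | float) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if np.any((arr < 0.0) | (arr > 1.0)) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return arr


@dataclasses.dataclass(frozen=True)
class DirectBiasParams:
    """(p, q, r): variant-A frequency, less-preferred copy probability,
    fraction of the population preferring A.  All in [0, 1]."""

    p: float
    q: float
    r: float

    def __post_init__(self) -> None:
        for name in ("p", "q", "r"):
            _check_unit(name, getattr(self, name))


def prob_adopt_a(
    p: Union[float, np.ndarray, DirectBiasParams],
    q: Optional[float] = None,
    r: Optional[float] = None,
) -> Union[float, np.ndarray]:
    """Probability that a random individual ends up exhibiting variant A.

    Accepts either a :class:`DirectBiasParams` or (p, q, r) directly; ``p``
    may be an array for vectorised evaluation.
    """
    if isinstance(p, DirectBiasParams):
        params = p
        p, q, r = params.p, params.q, params.r
    if q is None or r is None:
        raise ValueError("q and r are required unless DirectBiasParams is given")
    p = _check_unit("p", p)
    q = float(_check_unit("q", q))
    r = float(_check_unit("r", r))
    stay = p * (p + r * (1.0 - p) * (1.0 - q))
    switch = (1.0 - p) * (r * p + (1.0 - r) * p * q)
    out = stay + switch
    if np.ndim(out) == 0:
        return float(out)
    return out


def direct_bias_curve(
    q: float,
    r: float,
    grid: Optional[Sequence[float]] = None,
    counted: int = 1,
) -> AcquisitionCurve:
    """Direct-bias prediction on the common binned-curve schema.

    ``grid`` gives the bin edges implicitly via its spacing; by default the
    curve is evaluated at the centres of 100 bins of width 0.01, matching
    simulated curves so the two can be fitted and compared uniformly.
    """
    if grid is None:
        edges = np.linspace(0.0, 1.0, 101)
    else:
        edges = np.asarray(grid, dtype=np.float64)
    centres = 0.5 * (edges[:-1] + edges[1:])
    prob = prob_adopt_a(centres, q, r)
    return AcquisitionCurve.from_probabilities(
        edges,
        prob,
        counted=np.full(centres.size, counted, dtype=np.int64),
        metadata={"model": "direct_bias", "q": q, "r": r},
    )


def regime_union_curve(
    q: float,
    grid: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """The pooled-regimes artefact curve.

    For frequencies below 0.5 the population must have come from runs in
    which B is preferred (r = 0); above 0.5, from runs in which A is
    preferred (r = 1).  Joining the two branches — which is what pooling
    50/50-start replicates does — produces a spurious sigmoid even though
    each branch alone is a smooth convex or concave curve.  At p = 0.5 both
    branch values are reported.

    Returns a DataFrame with columns (p, prob, branch) where branch is
    ``"r=0"`` or ``"r=1"``.
    """
    q = float(_check_unit("q", q))
    if grid is None:
        grid = np.arange(0.0, 1.0 + 1e-12, 0.001)
    grid = _check_unit("grid", np.asarray(grid, dtype=np.float64))
    rows = []
    for p in grid:
        p = float(p)
        if p <= 0.5:
            rows.append({"p": p, "prob": prob_adopt_a(p, q, 0.0), "branch": "r=0"})
        if p >= 0.5:
            rows.append({"p": p, "prob": prob_adopt_a(p, q, 1.0), "branch": "r=1"})
    return pd.DataFrame(rows).sort_values(["p", "branch"]).reset_index(drop=True)


@dataclasses.dataclass(frozen=True)
class MixtureSpec:
    """Two component lines through the origin plus a mixing weight.

    ``weight`` maps frequency x to the share of the slope-``b1`` line in
    the average (a callable, or an array aligned with the evaluation grid).
    """

    b1: float = 1.0
    b2: float = 0.2
    weight: Union[Callable[[np.ndarray], np.ndarray], np.ndarray, float] = 0.5


def mixture_of_lines(
    spec: MixtureSpec,
    grid: Sequence[float],
) -> np.ndarray:
    """Weighted average of two lines: y(x) = w(x) b1 x + (1 - w(x)) b2 x.

    With the weight taken from the empirical share of A-preferred events at
    each frequency, this reconstructs the concave-up pooled curve of the
    uniform-start variant-preference simulation.
    """
    x = np.asarray(grid, dtype=np.float64)
    if callable(spec.weight):
        w = np.asarray(spec.weight(x), dtype=np.float64)
    else:
        w = np.broadcast_to(np.asarray(spec.weight, dtype=np.float64), x.shape)
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError("mixture weights must lie in [0, 1] at every grid point")
    return w * spec.b1 * x + (1.0 - w) * spec.b2 * x


def empirical_preference_weight(
    curve_preferred: AcquisitionCurve,
    curve_less_preferred: AcquisitionCurve,
) -> np.ndarray:
    """Per-bin share of events coming from the preferred-variant stratum.

    Computed from the counted-event densities of two stratified curves on
    the same bins; NaN where neither stratum has events.
    """
    c1 = curve_preferred.counted.astype(np.float64)
    c2 = curve_less_preferred.counted.astype(np.float64)
    if c1.shape != c2.shape:
        raise ValueError("stratified curves must share the same bins")
    tot = c1 + c2
    with np.errstate(invalid="ignore", divide="ignore"):
        w = c1 / tot
    w[tot == 0] = np.nan
    return w
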