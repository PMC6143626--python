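"""Linear-versus-sigmoid fit comparison for acquisition curves.

The detection question is always the same: is the binned adoption-probability
curve better described by a straight line (what neutral or directly-biased
copying produces) or by a sigmoid (the signature of conformist,
positively frequency-dependent copying)?  Both models are fitted to the
binned curve by count-weighted least squares and compared on weighted r².

Two sigmoid forms are available:

``logistic2``
    y = 1 / (1 + exp(-(a + b x))), two free parameters — the default,
    deliberately the same complexity as the line so the raw r² comparison
    is fair (a saturating four-parameter logistic can mimic any line and
    would make a "linear is better" verdict unreachable).
``freq_bias``
    y = x**theta / (x**theta + (1 - x)**theta), the one-parameter
    conformity curve with fixed endpoints; theta = 1 is the identity line,
    theta > 1 is conformist.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

from .curves import AcquisitionCurve, EmptyCurveError, bin_events
from .engine import SimulationRun
from .measure import FrequencySpec, OutcomeSpec, run_frequencies, run_outcomes

__all__ = [
    "FitResult",
    "FitComparison",
    "UnderdeterminedFitError",
    "fit_linear",
    "fit_sigmoid",
    "compare_fits",
    "window_sweep",
    "crossover_window",
    "default_window_grid",
    "logistic2",
    "freq_bias",
]

TIE_TOLERANCE = 1e-6
_SS_TOT_FLOOR = 1e-12

FitInput = Union[AcquisitionCurve, tuple]


class UnderdeterminedFitError(ValueError):
    """Raised when too few nonempty bins are available for a fit."""


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Parameters and weighted r² of one fitted model."""

    model: str  # linear | logistic2 | freq_bias
    params: dict
    r_squared: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.model == "linear":
            return self.params["intercept"] + self.params["slope"] * x
        if self.model == "logistic2":
            return logistic2(x, self.params["offset"], self.params["gain"])
        if self.model == "freq_bias":
            return freq_bias(x, self.params["theta"])
        raise ValueError(f"unknown model {self.model!r}")


@dataclasses.dataclass(frozen=True)
class FitComparison:
    """Side-by-side linear and sigmoid fits of the same curve.

    ``relative_fit`` is r²(linear) − r²(sigmoid): negative means the
    sigmoid fits better.  Ties within 1e-6 are reported as linear, the
    null shape — conservative against inferring conformity.
    """

    linear: FitResult
    sigmoid: Optional[FitResult]
    relative_fit: Optional[float]
    better: str  # linear | sigmoid | linear_only

    @property
    def sigmoid_wins(self) -> bool:
        return self.better == "sigmoid"


def logistic2(x: np.ndarray, offset: float, gain: float) -> np.ndarray:
    return expit(offset + gain * np.asarray(x, dtype=np.float64))


def freq_bias(x: np.ndarray, theta: float) -> np.ndarray:
    """Frequency-bias response with fixed endpoints y(0)=0, y(1)=1."""
    x = np.asarray(x, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.power(x, theta)
        den = num + np.power(1.0 - x, theta)
        out = np.where(den > 0, num / den, 0.5)
    out = np.where(x <= 0.0, 0.0, out)
    out = np.where(x >= 1.0, 1.0, out)
    return out


def _fit_points(data: FitInput) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, AcquisitionCurve):
        return data.fit_points()
    x, y, w = data
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=np.float64)
    return x, y, w


def _weighted_r2(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    if ss_res <= 1e-14:
        return 1.0  # zero residuals, including on zero-variance data
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = max(float(np.sum(w * (y - ybar) ** 2)), _SS_TOT_FLOOR)
    return 1.0 - ss_res / ss_tot


def fit_linear(data: FitInput) -> FitResult:
    """Count-weighted least-squares line through the binned curve."""
    x, y, w = _fit_points(data)
    if x.size < 2:
        raise UnderdeterminedFitError(f"need >= 2 nonempty bins, got {x.size}")
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise UnderdeterminedFitError("all bins at the same frequency")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    r2 = _weighted_r2(y, intercept + slope * x, w)
    return FitResult(
        model="linear",
        params={"intercept": intercept, "slope": slope},
        r_squared=r2,
        converged=True,
    )


_GAIN_STARTS = (1.0, -1.0, 5.0, -5.0, 20.0, -20.0)
_THETA_STARTS = (0.5, 1.0, 2.0, 5.0)


def fit_sigmoid(data: FitInput, form: str = "logistic2") -> FitResult:
    """Weighted nonlinear least-squares sigmoid fit with multi-start.

    ``logistic2`` tries gains in {±1, ±5, ±20} (offsets centring the curve
    at x = 0.5) and keeps the best weighted SS; ``converged`` is False if
    the optimiser fails from every start, in which case the result must be
    excluded from comparisons.
    """
    x, y, w = _fit_points(data)
    if form == "logistic2":
        min_bins = 3
    elif form == "freq_bias":
        min_bins = 2
    else:
        raise ValueError(f"form must be 'logistic2' or 'freq_bias', got {form!r}")
    if x.size < min_bins:
        raise UnderdeterminedFitError(f"need >= {min_bins} nonempty bins, got {x.size}")
    sigma = 1.0 / np.sqrt(w)
    best_ss = np.inf
    best_params: Optional[dict] = None
    if form == "logistic2":
        starts = [(-g * 0.5, g) for g in _GAIN_STARTS]
        func = logistic2
    else:
        starts = [(t,) for t in _THETA_STARTS]
        func = freq_bias
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(func, x, y, p0=p0, sigma=sigma, maxfev=10_000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum(w * (y - func(x, *popt)) ** 2))
        if np.isfinite(ss) and ss < best_ss:
            best_ss = ss
            if form == "logistic2":
                best_params = {"offset": float(popt[0]), "gain": float(popt[1])}
            else:
                best_params = {"theta": float(popt[0])}
    if best_params is None:
        return FitResult(model=form, params={}, r_squared=np.nan, converged=False)
    yhat = func(x, *best_params.values())
    return FitResult(
        model=form, params=best_params, r_squared=_weighted_r2(y, yhat, w), converged=True
    )


def compare_fits(data: FitInput, sigmoid_form: str = "logistic2") -> FitComparison:
    """Fit both models and report which describes the curve better."""
    linear = fit_linear(data)
    sigmoid = fit_sigmoid(data, form=sigmoid_form)
    if not sigmoid.converged:
        warnings.warn("sigmoid fit did not converge; reporting linear fit only")
        return FitComparison(
            linear=linear, sigmoid=None, relative_fit=None, better="linear_only"
        )
    relative = linear.r_squared - sigmoid.r_squared
    better = "sigmoid" if relative < -TIE_TOLERANCE else "linear"
    return FitComparison(
        linear=linear, sigmoid=sigmoid, relative_fit=float(relative), better=better
    )


def default_window_grid(n_events: int = 10_000, n_points: int = 28) -> list[int]:
    """~30 log-spaced window sizes from 1 to ``n_events``, plus 10 and 2000."""
    grid = np.unique(np.rint(np.logspace(0, np.log10(n_events), n_points)).astype(int))
    grid = np.union1d(grid, [10, min(2000, n_events)])
    return [int(t) for t in grid if 1 <= t <= n_events]


def window_sweep(
    runs: Sequence[SimulationRun],
    windows: Sequence[int],
    variant: str = "A",
    outcome_spec: OutcomeSpec = OutcomeSpec(),
    bin_width: float = 0.01,
    burn_in: str = "use_partial",
    sigmoid_form: str = "logistic2",
) -> pd.DataFrame:
    """Linear-vs-sigmoid comparison as a function of history-window size.

    ``T = 0`` is interpreted as the full behaviour history.  The default
    burn-in policy here is ``use_partial`` so that the largest windows
    degrade gracefully into the full-history measure instead of discarding
    nearly every event.  Returns one row per window:
    (T, r2_linear, r2_sigmoid, relative_fit, better).
    """
    windows = sorted(int(t) for t in windows)
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # Outcomes do not depend on the window; compute them once per run.
    per_run = [
        (run, *run_outcomes(run, outcome_spec, variant=variant)) for run in runs
    ]
    rows = []
    for t in windows:
        if t == 0:
            spec = FrequencySpec(source="behaviour_full_history")
        else:
            spec = FrequencySpec(source="behaviour_window", window_t=t, burn_in=burn_in)
        counted_tot = np.zeros(n_bins, dtype=np.int64)
        success_tot = np.zeros(n_bins, dtype=np.int64)
        for run, counted, success in per_run:
            x = run_frequencies(run, spec, variant=variant)
            _, c, s, _fs = bin_events(x, counted, success, bin_width=bin_width)
            counted_tot += c
            success_tot += s
        if counted_tot.sum() == 0:
            raise EmptyCurveError(f"window T={t} produced no counted events")
        curve = AcquisitionCurve(
            bin_edges=edges, counted=counted_tot, successes=success_tot
        )
        try:
            comp = compare_fits(curve, sigmoid_form=sigmoid_form)
        except UnderdeterminedFitError:
            # Tiny windows can occupy too few bins for the sigmoid
            # (T = 1 only ever yields frequencies 0 and 1).
            linear = fit_linear(curve)
            comp = FitComparison(
                linear=linear, sigmoid=None, relative_fit=None, better="linear_only"
            )
        rows.append(
            {
                "T": t,
                "r2_linear": comp.linear.r_squared,
                "r2_sigmoid": comp.sigmoid.r_squared if comp.sigmoid else np.nan,
                "relative_fit": comp.relative_fit if comp.relative_fit is not None else np.nan,
                "better": comp.better,
            }
        )
    return pd.DataFrame(rows)


def crossover_window(sweep_table: pd.DataFrame) -> Optional[int]:
    """Smallest window from which the sigmoid fit stays ahead of the line.

    Defined as the smallest sampled T with relative_fit < 0 such that
    relative_fit < 0 at every larger sampled T; ``None`` if the line wins
    at the largest window (no stable crossover).
    """
    if len(sweep_table) == 0:
        raise ValueError("sweep table is empty")
    tab = sweep_table.sort_values("T").reset_index(drop=True)
    negative = (tab["relative_fit"] < 0).to_numpy()
    if not negative[-1]:
        return None
    # walk back over the trailing run of sigmoid-better windows
    i = len(negative) - 1
    while i > 0 and negative[i - 1]:
        i -= 1
    return int(tab["T"].iloc[i])
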