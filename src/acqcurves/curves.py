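"""Binned acquisition curves.

An acquisition curve maps a variant's prevalence (however measured) to the
probability of adopting it (however scored).  Curves are built by binning
counted events on [0, 1] — left-closed, right-open bins, with the final bin
closed so a frequency of exactly 1.0 is kept — and dividing per-bin success
totals by per-bin counted totals.  The default bin width of 0.01 is the
natural resolution of state frequencies in a population of 100, so
state-based curves lose nothing to binning.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationRun
from .measure import FrequencySpec, OutcomeSpec, run_frequencies, run_outcomes

__all__ = ["AcquisitionCurve", "EmptyCurveError", "build_curve", "bin_events"]


class EmptyCurveError(ValueError):
    """Raised when no counted events are available to build a curve."""


@dataclasses.dataclass
class AcquisitionCurve:
    """Binned adoption probability versus variant frequency.

    ``probability`` is NaN for bins with no counted events; such bins carry
    no probability and are excluded from fits.
    """

    bin_edges: np.ndarray  # length n_bins + 1, spanning [0, 1]
    counted: np.ndarray  # int64 per-bin counted-event totals
    successes: np.ndarray  # int64 per-bin success totals
    freq_sum: Optional[np.ndarray] = None  # per-bin sums of event frequencies
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counted = np.asarray(self.counted, dtype=np.int64)
        self.successes = np.asarray(self.successes, dtype=np.int64)
        if self.counted.shape != self.successes.shape:
            raise ValueError("counted and successes must have equal length")
        if self.bin_edges.size != self.counted.size + 1:
            raise ValueError("bin_edges must have one more entry than counted")
        if (self.successes > self.counted).any():
            raise ValueError("successes cannot exceed counted in any bin")
        if self.freq_sum is not None:
            self.freq_sum = np.asarray(self.freq_sum, dtype=np.float64)
            if self.freq_sum.shape != self.counted.shape:
                raise ValueError("freq_sum must have one entry per bin")

    @property
    def n_bins(self) -> int:
        return int(self.counted.size)

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def probability(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.successes / self.counted.astype(np.float64)
        p[self.counted == 0] = np.nan
        return p

    @property
    def total_counted(self) -> int:
        return int(self.counted.sum())

    @property
    def mean_frequency(self) -> np.ndarray:
        """Count-weighted mean event frequency per bin (bin centre where
        unavailable).  Sharper than the centre when events pile up at a
        bin edge, e.g. at exactly 0 or 1 after absorption."""
        centres = self.bin_centres
        if self.freq_sum is None:
            return centres
        out = centres.copy()
        mask = self.counted > 0
        out[mask] = self.freq_sum[mask] / self.counted[mask]
        return out

    def nonempty(self) -> np.ndarray:
        return self.counted > 0

    def fit_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, w) of nonempty bins: centres, probabilities, counted weights."""
        mask = self.nonempty()
        return (
            self.bin_centres[mask],
            self.probability[mask],
            self.counted[mask].astype(np.float64),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_centre": self.bin_centres,
                "counted": self.counted,
                "successes": self.successes,
                "probability": self.probability,
            }
        )

    @classmethod
    def from_probabilities(
        cls,
        bin_edges: Sequence[float],
        probability: Sequence[float],
        counted: Optional[Sequence[int]] = None,
        metadata: Optional[dict] = None,
    ) -> "AcquisitionCurve":
        """Build a curve from known per-bin probabilities (e.g. an analytical
        curve placed on the common curve schema).  Probabilities are scaled
        onto integer success counts against ``counted`` (default 1 per bin),
        accepting the rounding that implies for non-dyadic probabilities."""
        prob = np.asarray(probability, dtype=np.float64)
        if counted is None:
            counted = np.ones(prob.size, dtype=np.int64)
        counted = np.asarray(counted, dtype=np.int64)
        successes = np.rint(prob * counted).astype(np.int64)
        return cls(
            bin_edges=np.asarray(bin_edges, dtype=np.float64),
            counted=counted,
            successes=successes,
            metadata=dict(metadata or {}),
        )


def _bin_index(x: np.ndarray, n_bins: int) -> np.ndarray:
    # Tiny epsilon keeps exact grid values k/N in their own (left-closed)
    # bin despite float rounding; the final bin is closed at 1.0.
    idx = np.floor(x * n_bins + 1e-9).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


def bin_events(
    x: np.ndarray,
    counted: np.ndarray,
    success: np.ndarray,
    bin_width: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accumulate counted/success totals into bins of ``bin_width`` on [0, 1].

    Events with NaN ``x`` (undefined frequency) or ``counted`` False are
    ignored.  Returns (bin_edges, counted_totals, success_totals,
    frequency_sums).
    """
    n_bins = int(round(1.0 / bin_width))
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    x = np.asarray(x, dtype=np.float64)
    keep = np.asarray(counted, dtype=bool) & ~np.isnan(x)
    xk = x[keep]
    sk = np.asarray(success, dtype=bool)[keep]
    idx = _bin_index(xk, n_bins)
    counted_tot = np.bincount(idx, minlength=n_bins).astype(np.int64)
    success_tot = np.bincount(idx, weights=sk, minlength=n_bins).astype(np.int64)
    freq_sum = np.bincount(idx, weights=xk, minlength=n_bins)
    return edges, counted_tot, success_tot, freq_sum


def build_curve(
    runs: Sequence[SimulationRun],
    variant: str = "A",
    freq_spec: FrequencySpec = FrequencySpec(),
    outcome_spec: OutcomeSpec = OutcomeSpec(),
    bin_width: float = 0.01,
    metadata: Optional[dict] = None,
) -> AcquisitionCurve:
    """Pool the events of ``runs`` into one binned acquisition curve.

    Each counted event contributes to the bin containing its frequency
    value; events whose frequency measure is undefined (first events,
    incomplete windows under the skip policy) are excluded.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counted_tot = np.zeros(n_bins, dtype=np.int64)
    success_tot = np.zeros(n_bins, dtype=np.int64)
    freq_sum = np.zeros(n_bins, dtype=np.float64)
    for run in runs:
        x = run_frequencies(run, freq_spec, variant=variant)
        counted, success = run_outcomes(run, outcome_spec, variant=variant)
        _, c, s, fs = bin_events(x, counted, success, bin_width=bin_width)
        counted_tot += c
        success_tot += s
        freq_sum += fs
    if counted_tot.sum() == 0:
        raise EmptyCurveError("no counted events with a defined frequency measure")
    meta = {
        "variant": variant,
        "frequency_source": freq_spec.source,
        "window_t": freq_spec.window_t if freq_spec.source == "behaviour_window" else None,
        "outcome_convention": outcome_spec.convention,
        "bin_width": bin_width,
        "n_runs": len(runs),
    }
    meta.update(metadata or {})
    return AcquisitionCurve(
        bin_edges=edges,
        counted=counted_tot,
        successes=success_tot,
        freq_sum=freq_sum,
        metadata=meta,
    )
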