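"""Figure analogues (cosmetic; not exercised by the test suite).

Renders the standard six-panel and single-panel views: stratified and
pooled variant-preference curves, the mixture-of-lines construction, the
analytical direct-bias curves and their regime union, the subgroup curves
per start mode, the three measurement-convention curves, and the
window-sweep r² traces.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analytic import mixture_of_lines, MixtureSpec, prob_adopt_a, regime_union_curve
from .curves import AcquisitionCurve
from .fitting import FitComparison
from .scenarios import ScenarioResult


def plot_curve(ax, curve: AcquisitionCurve, comparison: FitComparison | None = None,
               title: str = "") -> None:
    x, y, w = curve.fit_points()
    ax.scatter(x, y, s=4 + 40 * w / w.max(), alpha=0.6, color="0.3", lw=0)
    grid = np.linspace(0, 1, 201)
    if comparison is not None:
        ax.plot(grid, comparison.linear.predict(grid), "-", color="tab:blue", label="linear")
        if comparison.sigmoid is not None:
            ax.plot(grid, comparison.sigmoid.predict(grid), "--", color="tab:red", label="sigmoid")
        ax.legend(fontsize=7)
    ax.set_xlim(0, 1)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("frequency of variant A")
    ax.set_ylabel("adoption probability")
    ax.set_title(title, fontsize=9)


def plot_scenario(result: ScenarioResult, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if result.curves:
        n = len(result.curves)
        fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5), squeeze=False)
        for ax, (label, curve) in zip(axes[0], result.curves.items()):
            plot_curve(ax, curve, result.comparisons.get(label), title=label)
        fig.tight_layout()
        p = outdir / f"{result.name}_curves.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    if "sweep" in result.tables:
        tab = result.tables["sweep"]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(tab["T"], tab["r2_linear"], "-", label="linear $r^2$")
        ax.plot(tab["T"], tab["r2_sigmoid"], "--", label="sigmoid $r^2$")
        ax.set_xscale("log")
        ax.set_xlabel("history window size")
        ax.set_ylabel("$r^2$")
        ax.legend()
        fig.tight_layout()
        p = outdir / f"{result.name}_sweep.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_analytic_overview(outdir: Path, q: float = 0.2) -> Path:
    """Direct-bias curves (r = 0, 1/2, 1), the regime union, and the
    mixture-of-lines construction, in one row."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = np.linspace(0, 1, 1001)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for r, style in ((0.0, ":"), (0.5, "-"), (1.0, "--")):
        axes[0].plot(grid, prob_adopt_a(grid, q, r), style, label=f"r = {r}")
    axes[0].set_title("direct bias, end-state adoption")
    axes[0].legend()
    union = regime_union_curve(q)
    for branch, part in union.groupby("branch"):
        axes[1].plot(part["p"], part["prob"], label=branch)
    axes[1].set_title("regime union (pooled 50/50 starts)")
    axes[1].legend()
    spec = MixtureSpec(b1=1.0, b2=q, weight=lambda x: x)
    axes[2].plot(grid, grid, ":", label="y = x")
    axes[2].plot(grid, q * grid, ":", label=f"y = {q}x")
    axes[2].plot(grid, mixture_of_lines(spec, grid), "-", label="weighted mixture")
    axes[2].set_title("mixture of lines")
    axes[2].legend()
    for ax in axes:
        ax.set_xlabel("frequency of variant A")
        ax.set_ylabel("Prob(A)")
    fig.tight_layout()
    p = outdir / "analytic_overview.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    return p
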