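"""Visualization of summary-MR estimates.

Two figures: the estimator scatter plot — instrument-exposure associations
on x, instrument-outcome associations on y, one point per variant with
error bars and one straight line per estimator (the slope of a line through
the origin is a causal-effect estimate; only the Egger line has a free
intercept) — and the ratio-density plot that shows the smoothed density the
mode estimator maximizes, with the mode marked.

SVG output is deterministic (fixed hash salt, no embedded date) so figures
can be regression-tested byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless, deterministic backend
import matplotlib.pyplot as plt

import numpy as np

from .data import SummarySet
from .estimators import EggerEstimate, MREstimate, ratio_density
from .exceptions import ConfigurationError, ValidationError

__all__ = ["PlotSpec", "scatter_plot", "mode_density_plot"]

matplotlib.rcParams["svg.hashsalt"] = "summr"


@dataclass(frozen=True)
class PlotSpec:
    """Declarative description of a figure.

    ``estimator_lines`` holds ``(label, intercept, slope)`` triples; use
    :meth:`from_estimates` to derive them from fitted results (non-Egger
    lines pass through the origin, the Egger line uses its fitted
    intercept).  ``error_bars`` selects outcome-side bars only (default,
    the exposure-side bars are usually omitted for clarity), both, or none;
    bar half-width is ``ci_multiplier`` standard errors.
    """

    estimator_lines: tuple[tuple[str, float, float], ...] = ()
    error_bars: str = "outcome_only"
    ci_multiplier: float = 1.96
    output_path: str = "mr_plot.svg"
    format: str | None = None

    def __post_init__(self) -> None:
        labels = [lab for lab, _, _ in self.estimator_lines]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate estimator line labels: {labels}")
        if self.error_bars not in ("outcome_only", "both", "none"):
            raise ConfigurationError(
                f"error_bars must be outcome_only/both/none, got {self.error_bars!r}"
            )
        fmt = self.resolved_format()
        if fmt not in ("png", "svg", "pdf"):
            raise ConfigurationError(f"unsupported figure format {fmt!r}")

    def resolved_format(self) -> str:
        if self.format:
            return self.format
        suffix = Path(self.output_path).suffix.lstrip(".").lower()
        return suffix or "svg"

    @classmethod
    def from_estimates(cls, estimates, **kwargs) -> "PlotSpec":
        """Build the line list from fitted estimates."""
        lines = []
        for est in estimates:
            if isinstance(est, EggerEstimate):
                lines.append(
                    (est.slope.method, est.intercept.estimate, est.slope.estimate)
                )
            elif isinstance(est, MREstimate):
                lines.append((est.method, 0.0, est.estimate))
            else:
                raise ConfigurationError(f"cannot derive a line from {type(est)!r}")
        return cls(estimator_lines=tuple(lines), **kwargs)


def _save(fig, spec: PlotSpec) -> str:
    path = Path(spec.output_path)
    try:
        # metadata Date=None strips the timestamp for byte-stable SVGs
        kwargs = {"metadata": {"Date": None}} if spec.resolved_format() == "svg" else {}
        fig.savefig(path, format=spec.resolved_format(), **kwargs)
    except OSError as exc:
        raise OSError(f"cannot write figure to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return str(path)


def scatter_plot(
    data: SummarySet, estimates: list, spec: PlotSpec | None = None
) -> str:
    """Scatter of (exposure, outcome) associations with estimator lines.

    One point per variant at :math:`(\\hat\\gamma_j, \\hat\\Gamma_j)`,
    vertical bars of ± ``ci_multiplier`` × :math:`\\sigma_{Yj}` (horizontal
    bars added when ``error_bars='both'``), and one straight line per
    estimator.  Axis limits are set to cover every point plus its bars.
    Returns the written file path.
    """
    if spec is None:
        spec = PlotSpec.from_estimates(estimates)
    elif not spec.estimator_lines and estimates:
        spec = PlotSpec.from_estimates(
            estimates,
            error_bars=spec.error_bars,
            ci_multiplier=spec.ci_multiplier,
            output_path=spec.output_path,
            format=spec.format,
        )
    bx, by = data.beta_exposure, data.beta_outcome
    sx, sy = data.se_exposure, data.se_outcome
    m = spec.ci_multiplier

    fig, ax = plt.subplots(figsize=(6, 4.5))
    xerr = m * sx if spec.error_bars == "both" else None
    yerr = m * sy if spec.error_bars in ("outcome_only", "both") else None
    ax.errorbar(
        bx, by, yerr=yerr, xerr=xerr,
        fmt="o", ms=3.5, color="0.25", ecolor="0.6", elinewidth=0.8, zorder=2,
    )

    # explicit limits covering all points plus their error bars
    x_lo = float(np.min(bx - (m * sx if xerr is not None else 0.0)))
    x_hi = float(np.max(bx + (m * sx if xerr is not None else 0.0)))
    y_lo = float(np.min(by - (m * sy if yerr is not None else 0.0)))
    y_hi = float(np.max(by + (m * sy if yerr is not None else 0.0)))
    x_pad = 0.05 * (x_hi - x_lo) or 0.05 * max(abs(x_hi), 1.0)
    y_pad = 0.05 * (y_hi - y_lo) or 0.05 * max(abs(y_hi), 1.0)
    x_lo, x_hi = x_lo - x_pad, x_hi + x_pad
    y_lo, y_hi = y_lo - y_pad, y_hi + y_pad

    xs = np.array([min(x_lo, 0.0), max(x_hi, 0.0)])
    for label, intercept, slope in spec.estimator_lines:
        ax.plot(xs, intercept + slope * xs, lw=1.4, label=label, zorder=3)
    ax.set_xlim(x_lo, x_hi)
    ax.set_ylim(y_lo, y_hi)
    ax.axhline(0, color="0.85", lw=0.7, zorder=1)
    ax.axvline(0, color="0.85", lw=0.7, zorder=1)
    ax.set_xlabel(f"instrument–{data.exposure_label} association")
    ax.set_ylabel(f"instrument–{data.outcome_label} association")
    if spec.estimator_lines:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return _save(fig, spec)


def mode_density_plot(
    data: SummarySet,
    phi: float = 1.0,
    weighted: bool = True,
    spec: PlotSpec | None = None,
    grid_size: int = 10_000,
) -> str:
    """Smoothed ratio-estimate density with the mode marked.

    Plots exactly the density :func:`summr.estimators.mode_estimator`
    maximizes (same code path, same bandwidth and weights), with a vertical
    marker at its argmax.  Returns the written file path.
    """
    if len(data) < 3:
        raise ValidationError("mode density plot requires at least 3 variants")
    if spec is None:
        spec = PlotSpec(output_path="mode_density.svg")
    grid, density, mode = ratio_density(
        data, phi=phi, weighted=weighted, grid_size=grid_size
    )
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if grid.size == 1:  # degenerate: all ratios identical
        ax.axvline(mode, color="C0", lw=1.6)
    else:
        ax.plot(grid, density, color="C0", lw=1.2)
        ax.fill_between(grid, density, color="C0", alpha=0.15)
    ax.axvline(mode, color="C3", lw=1.2, ls="--", label=f"mode = {mode:.4g}")
    ax.set_xlabel("ratio (Wald) estimate")
    ax.set_ylabel("smoothed density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return _save(fig, spec)
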