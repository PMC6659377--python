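"""Synthetic two-sample summary-statistics generator.

Generates per-variant association summaries under the structural model

.. math::

    \\Gamma_j = \\beta \\gamma_j + \\alpha_j, \\qquad
    \\hat\\gamma_j \\sim N(\\gamma_j, \\sigma_{Xj}^2), \\qquad
    \\hat\\Gamma_j \\sim N(\\Gamma_j, \\sigma_{Yj}^2),

where :math:`\\beta` is the causal effect of interest, :math:`\\gamma_j` the
true instrument-exposure effects, and :math:`\\alpha_j` the direct
(pleiotropic) effects of each variant on the outcome.  Pleiotropy regimes:

``no_pleiotropy``
    every :math:`\\alpha_j = 0` — all instruments valid.
``balanced``
    invalid variants draw :math:`\\alpha_j \\sim N(0, \\sigma_\\alpha^2)`:
    pleiotropy averages out, IVW remains consistent but over-dispersed.
``directional_inside``
    invalid variants draw :math:`\\alpha_j \\sim N(\\mu_\\alpha,
    \\sigma_\\alpha^2)` independently of :math:`\\gamma_j` — directional
    pleiotropy satisfying the InSIDE assumption, biasing IVW but not the
    MR-Egger slope.
``directional_inside_violated``
    :math:`\\alpha_j = \\mu_\\alpha + c\\,\\gamma_j + \\epsilon_j` with
    :math:`c > 0`, correlating pleiotropy with instrument strength so that
    InSIDE fails and MR-Egger is biased too.

The generator emulates LD-pruned, GWAS-significant instrument panels:
independent variants, uniform exposure-effect magnitudes, and per-variant
standard errors drawn around configurable scales.  It does not model allele
frequencies, LD, sample overlap, or winner's-curse selection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .data import SummarySet
from .exceptions import ConfigurationError

__all__ = ["SimulationConfig", "simulate_summary_data"]

REGIMES = (
    "no_pleiotropy",
    "balanced",
    "directional_inside",
    "directional_inside_violated",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic summary dataset.

    Defaults describe a strong-instrument panel: exposure effects uniform
    on (0.05, 0.15) with exposure-side SEs around 0.005 (so instruments
    stand far out of their measurement error and I²GX is near 1) and
    outcome-side SEs around 0.01.  Per-variant SEs are drawn uniformly in
    [0.5, 1.5] times their scale.  ``invalid_fraction`` controls how many
    variants receive a pleiotropic effect in the non-null regimes.
    """

    n_variants: int = 100
    true_beta: float = 0.1
    regime: str = "no_pleiotropy"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    gamma_dist: tuple[float, float] = (0.05, 0.15)
    se_exposure_scale: float = 0.005
    se_outcome_scale: float = 0.01
    inside_violation_slope: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if self.regime not in REGIMES:
            raise ConfigurationError(
                f"unknown regime {self.regime!r}; valid regimes: {REGIMES}"
            )
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ConfigurationError("invalid_fraction must lie in [0, 1]")
        if self.gamma_dist[0] >= self.gamma_dist[1]:
            raise ConfigurationError("gamma_dist must be (low, high) with low < high")
        if self.se_exposure_scale <= 0 or self.se_outcome_scale <= 0:
            raise ConfigurationError("SE scales must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        payload = json.loads(text)
        if "gamma_dist" in payload:
            payload["gamma_dist"] = tuple(payload["gamma_dist"])
        return cls(**payload)


def simulate_summary_data(config: SimulationConfig) -> SummarySet:
    """Draw one synthetic :class:`~summr.data.SummarySet` from ``config``.

    All randomness flows from ``config.seed`` through a single
    ``numpy.random.default_rng`` stream, so identical configs yield
    identical datasets.  Ground truth (true effects, pleiotropy values,
    validity mask, true SEs) is attached under ``result.meta["truth"]`` for
    use in recovery studies; estimators never read it.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_variants
    low, high = config.gamma_dist
    gamma = rng.uniform(low, high, size=j)

    alpha = np.zeros(j)
    n_invalid = int(round(config.invalid_fraction * j))
    invalid = np.zeros(j, dtype=bool)
    if config.regime != "no_pleiotropy" and n_invalid > 0:
        invalid[rng.permutation(j)[:n_invalid]] = True
        mean = 0.0 if config.regime == "balanced" else config.pleiotropy_mean
        noise = rng.normal(0.0, config.pleiotropy_sd, size=n_invalid)
        if config.regime == "directional_inside_violated":
            alpha[invalid] = mean + config.inside_violation_slope * gamma[invalid] + noise
        else:
            alpha[invalid] = mean + noise

    big_gamma = config.true_beta * gamma + alpha
    se_x = rng.uniform(0.5, 1.5, size=j) * config.se_exposure_scale
    se_y = rng.uniform(0.5, 1.5, size=j) * config.se_outcome_scale
    bx = rng.normal(gamma, se_x)
    by = rng.normal(big_gamma, se_y)

    data = SummarySet.from_arrays(
        bx,
        se_x,
        by,
        se_y,
        exposure_label="simulated exposure",
        outcome_label="simulated outcome",
    )
    meta = dict(data.meta)
    meta["truth"] = {
        "true_beta": config.true_beta,
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "se_exposure": se_x,
        "se_outcome": se_y,
    }
    meta["config"] = asdict(config)
    return SummarySet(
        data.records,
        exposure_label=data.exposure_label,
        outcome_label=data.outcome_label,
        meta=meta,
    )
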