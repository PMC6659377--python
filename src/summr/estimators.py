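"""Causal-effect estimators for two-sample summary Mendelian randomization.

Four estimator families operate on a harmonized :class:`~summr.data.SummarySet`:

* :func:`ivw` — the inverse-variance-weighted average of per-variant ratio
  estimates, :math:`\\hat\\beta_{IVW} = \\sum_j w_j \\hat\\beta_j / \\sum_j w_j`
  with :math:`w_j = \\hat\\gamma_j^2 / \\sigma_{Yj}^2`; equivalent to a
  weighted regression of outcome on exposure associations through the origin.
  Unbiased only when no variant has a directional pleiotropic effect.
* :func:`mr_egger` — the same weighted regression with a free intercept.
  The intercept estimates the average directional pleiotropic effect and
  the slope remains a consistent causal estimate under the InSIDE
  assumption (instrument strength independent of direct effects).
* :func:`median_estimator` — simple / weighted / penalized-weighted median
  of the ratio estimates; consistent when variants carrying at least half
  of the (count or weight) mass are valid instruments.
* :func:`mode_estimator` — the maximizer of a Gaussian-kernel-smoothed
  density of the ratio estimates; consistent when the largest group of
  variants sharing a ratio value are the valid ones (zero modal pleiotropy).

Weights throughout use the precision of the instrument-outcome association,
treating the exposure associations as error-free (the NOME assumption);
its violation attenuates the Egger slope toward the null — see
:mod:`summr.diagnostics` for the I²GX measure and SIMEX correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .data import SummarySet, _ratio_arrays
from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "MREstimate",
    "EggerEstimate",
    "ivw",
    "mr_egger",
    "median_estimator",
    "mode_estimator",
    "ratio_density",
    "estimates_to_table",
]

Method = Literal[
    "ivw_fe",
    "ivw_mre",
    "egger",
    "egger_fe",
    "egger_intercept",
    "egger_fe_intercept",
    "median_simple",
    "median_weighted",
    "median_penalized",
    "mode_unweighted",
    "mode_weighted",
]


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect (or intercept) estimate with its inference block."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_variants: int
    ci_level: float = 0.95
    #: reference distribution used: "normal" or "t(df)"
    reference: str = "normal"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError(
                f"{self.method}: CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket the estimate {self.estimate}"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"{self.method}: p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_variants": self.n_variants,
            "ci_level": self.ci_level,
            "reference": self.reference,
        }


@dataclass(frozen=True)
class EggerEstimate:
    """MR-Egger result: causal slope plus average-pleiotropy intercept."""

    slope: MREstimate
    intercept: MREstimate

    def __post_init__(self) -> None:
        if self.slope.n_variants != self.intercept.n_variants:
            raise ValidationError("Egger slope and intercept variant counts differ")
        if self.slope.n_variants < 3:
            raise ValidationError("MR-Egger requires at least 3 variants")

    def to_dict(self) -> dict:
        return {"slope": self.slope.to_dict(), "intercept": self.intercept.to_dict()}


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def _infer(
    method: str,
    estimate: float,
    se: float,
    n_variants: int,
    df: int | None,
    ci_level: float,
) -> MREstimate:
    """Build an MREstimate using a normal (df None) or t(df) reference."""
    if df is None:
        crit = stats.norm.ppf(0.5 + ci_level / 2)
        p = 2 * stats.norm.sf(abs(estimate) / se) if se > 0 else float(estimate == 0.0)
        ref = "normal"
    else:
        crit = stats.t.ppf(0.5 + ci_level / 2, df)
        p = 2 * stats.t.sf(abs(estimate) / se, df) if se > 0 else float(estimate == 0.0)
        ref = f"t({df})"
    return MREstimate(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - crit * se),
        ci_high=float(estimate + crit * se),
        p_value=float(p),
        n_variants=int(n_variants),
        ci_level=ci_level,
        reference=ref,
    )


def _wls_line(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares of ``y`` on ``[1, x]``, vectorized over rows.

    ``x`` may be 1-D (one fit) or 2-D ``(B, J)`` (B independent fits sharing
    ``y`` and ``w``).  Returns (intercept, slope) arrays.  Kept closed-form
    so thousands of SIMEX replicate refits stay cheap.
    """
    x = np.atleast_2d(x)
    sw = w.sum()
    sx = (w * x).sum(axis=1)
    sy = float((w * y).sum())
    sxx = (w * x * x).sum(axis=1)
    sxy = (w * x * y).sum(axis=1)
    denom = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / sw
    return intercept, slope


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(
    data: SummarySet,
    model: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
    ci_level: float = 0.95,
) -> MREstimate:
    """Inverse-variance-weighted causal estimate.

    The point estimate is the :math:`w_j = \\hat\\gamma_j^2/\\sigma_{Yj}^2`
    weighted average of the ratio estimates — identical under both ``model``
    options, which differ only in inference:

    * ``fixed``: :math:`SE = 1/\\sqrt{\\sum_j w_j}` with a normal reference.
    * ``multiplicative_random`` (default): the fixed-effect SE is scaled by
      :math:`\\max(1, \\sqrt{Q/(J-1)})` where :math:`Q` is Cochran's Q about
      the IVW estimate, with a t(J-1) reference — over-dispersion inflates
      the SE, under-dispersion never deflates it.

    With a single variant the estimate reduces exactly to that variant's
    ratio estimate (and ``multiplicative_random`` falls back to ``fixed``
    with a warning, the scaling being undefined at J = 1).
    """
    ratios, ratio_se = _ratio_arrays(data)
    j = len(ratios)
    w = 1.0 / ratio_se**2  # == beta_exposure^2 / se_outcome^2
    estimate = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    if model == "multiplicative_random" and j < 2:
        warnings.warn(
            "multiplicative random-effects IVW needs >= 2 variants; "
            "falling back to fixed-effect inference",
            stacklevel=2,
        )
        model = "fixed"
    if model == "fixed":
        return _infer("ivw_fe", estimate, se_fixed, j, None, ci_level)
    if model != "multiplicative_random":
        raise ConfigurationError(f"unknown IVW model {model!r}")
    q = float(np.sum(w * (ratios - estimate) ** 2))
    scale = max(1.0, np.sqrt(q / (j - 1)))
    return _infer("ivw_mre", estimate, scale * se_fixed, j, j - 1, ci_level)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(
    data: SummarySet,
    fixed_se: bool = False,
    orient: Literal["as_is", "positive_exposure"] = "as_is",
    ci_level: float = 0.95,
) -> EggerEstimate:
    """MR-Egger regression: weighted fit of outcome on exposure associations.

    Weighted least squares of :math:`\\hat\\Gamma_j` on :math:`\\hat\\gamma_j`
    with weights :math:`1/\\sigma_{Yj}^2` and a free intercept.  The slope
    estimates the causal effect under InSIDE; the intercept estimates the
    average directional pleiotropic effect (zero when pleiotropy is absent
    or balanced).

    ``fixed_se=False`` (default) uses a multiplicative random-effects model:
    coefficient SEs carry the residual scale :math:`\\max(1,
    \\sqrt{RSS/(J-2)})` and inference uses a t(J-2) reference.
    ``fixed_se=True`` forces unit residual scale with a normal reference.

    ``orient="positive_exposure"`` jointly sign-flips :math:`(\\hat\\gamma_j,
    \\hat\\Gamma_j)` so every exposure association is non-negative before
    fitting.  The Egger fit — unlike IVW, median and mode — is not invariant
    to allele recoding, so the orientation is part of the model; the default
    leaves the data exactly as supplied.
    """
    j = len(data)
    if j < 3:
        raise ValidationError(
            f"MR-Egger requires at least 3 variants (got {j}): intercept and "
            "slope are not identifiable with meaningful degrees of freedom"
        )
    bx = data.beta_exposure
    by = data.beta_outcome
    if orient == "positive_exposure":
        flip = np.where(bx < 0, -1.0, 1.0)
        bx, by = flip * bx, flip * by
    elif orient != "as_is":
        raise ConfigurationError(f"unknown orientation {orient!r}")
    w = 1.0 / data.se_outcome**2
    intercept, slope = _wls_line(bx, by, w)
    a, b = float(intercept[0]), float(slope[0])
    resid = by - a - b * bx
    rss = float(np.sum(w * resid**2))
    sw, sx, sxx = w.sum(), (w * bx).sum(), (w * bx * bx).sum()
    denom = sw * sxx - sx * sx
    var_b_unit = sw / denom
    var_a_unit = sxx / denom
    if fixed_se:
        scale2, df, meth = 1.0, None, ("egger_fe", "egger_fe_intercept")
    else:
        scale2, df, meth = max(1.0, rss / (j - 2)), j - 2, ("egger", "egger_intercept")
    se_b = float(np.sqrt(scale2 * var_b_unit))
    se_a = float(np.sqrt(scale2 * var_a_unit))
    return EggerEstimate(
        slope=_infer(meth[0], b, se_b, j, df, ci_level),
        intercept=_infer(meth[1], a, se_a, j, df, ci_level),
    )


# ---------------------------------------------------------------------------
# median estimators
# ---------------------------------------------------------------------------

def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Median of the distribution placing ratio_j at its weighted percentile.

    Ratios are sorted ascending; with normalized weights w and cumulative
    sums s_j, ratio_j sits at percentile p_j = 100 (s_j - w_j / 2), and the
    estimate linearly interpolates the (p_j, ratio_j) polyline at the 50th
    percentile, clamping to the extreme ratios outside [p_1, p_J].
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w)
    p = 100.0 * (s - w / 2.0)
    if 50.0 <= p[0]:
        return float(r[0])
    if 50.0 >= p[-1]:
        return float(r[-1])
    return float(np.interp(50.0, p, r))


def _median_point(
    ratios: np.ndarray,
    ratio_se: np.ndarray,
    variant: str,
    penalty: float,
) -> float:
    j = len(ratios)
    if variant == "simple":
        return _weighted_median(ratios, np.full(j, 1.0 / j))
    w = 1.0 / ratio_se**2
    if variant == "weighted":
        return _weighted_median(ratios, w)
    if variant == "penalized":
        center = _weighted_median(ratios, w)
        q_contrib = w * (ratios - center) ** 2
        q_tail = stats.chi2.sf(q_contrib, df=1)
        w_pen = w * np.minimum(1.0, penalty * q_tail)
        if w_pen.sum() == 0.0:  # pathological: every variant fully penalized
            w_pen = w
        return _weighted_median(ratios, w_pen)
    raise ConfigurationError(f"unknown median variant {variant!r}")


def median_estimator(
    data: SummarySet,
    variant: Literal["simple", "weighted", "penalized"] = "weighted",
    n_boot: int = 1000,
    seed: int | None = None,
    penalty: float = 20.0,
    ci_level: float = 0.95,
) -> MREstimate:
    """Median-based causal estimate (simple, weighted, or penalized weighted).

    ``simple`` gives every variant weight 1/J; ``weighted`` uses the inverse
    first-order ratio variance :math:`w_j = \\hat\\gamma_j^2/\\sigma_{Yj}^2`;
    ``penalized`` down-weights heterogeneity outliers by the factor
    :math:`\\min(1, \\text{penalty} \\cdot q_j)` where :math:`q_j` is the
    upper-tail :math:`\\chi^2_1` probability of variant j's Cochran-Q
    contribution about the weighted-median estimate.

    The standard error is the standard deviation of the estimate over
    ``n_boot`` parametric-bootstrap replicates — resampling each
    :math:`\\hat\\gamma_j \\sim N(\\hat\\gamma_j, \\sigma_{Xj}^2)` and
    :math:`\\hat\\Gamma_j \\sim N(\\hat\\Gamma_j, \\sigma_{Yj}^2)` and
    recomputing the full estimator — so ``seed`` is required.  Median
    estimators are consistent when valid instruments carry more than half
    of the total count (simple) or weight (weighted/penalized).
    """
    if n_boot < 1:
        raise ConfigurationError(f"n_boot must be >= 1, got {n_boot}")
    if seed is None:
        raise ConfigurationError("median_estimator requires an explicit seed")
    ratios, ratio_se = _ratio_arrays(data)
    estimate = _median_point(ratios, ratio_se, variant, penalty)
    se = _parametric_bootstrap_se(
        data,
        lambda bx, by: _median_point(by / bx, data.se_outcome / np.abs(bx), variant, penalty),
        n_boot,
        seed,
    )
    return _infer(f"median_{variant}", estimate, se, len(data), None, ci_level)


def _parametric_bootstrap_se(data: SummarySet, point_fn, n_boot: int, seed: int) -> float:
    """SD of ``point_fn(bx*, by*)`` over parametric resamples of both sides."""
    rng = np.random.default_rng(seed)
    bx, sx = data.beta_exposure, data.se_exposure
    by, sy = data.beta_outcome, data.se_outcome
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b[bx_b == 0.0] = np.finfo(float).tiny  # ratio stays defined
        reps[b] = point_fn(bx_b, by_b)
    if n_boot == 1:
        return 0.0
    return float(np.std(reps, ddof=1))


# ---------------------------------------------------------------------------
# mode estimator
# ---------------------------------------------------------------------------

def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified-Silverman bandwidth over the ratio estimates, scaled by phi."""
    j = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if j > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) / 0.6745
    scales = [s for s in (sd, mad) if s > 0]
    if not scales:
        return 0.0
    return phi * 0.9 * min(scales) * j ** (-1 / 5)


def ratio_density(
    data: SummarySet,
    phi: float = 1.0,
    weighted: bool = True,
    grid_size: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Smoothed density of the ratio estimates and its mode.

    Returns ``(grid, density, mode)``: a Gaussian-kernel density of the
    per-variant ratio estimates evaluated on a ``grid_size``-point grid
    spanning the ratio range padded by two bandwidths, with kernels weighted
    by the normalized inverse ratio variances when ``weighted`` (equal
    weights otherwise).  The mode is the smallest grid value attaining the
    density maximum.  This is the single source of truth shared by
    :func:`mode_estimator` and the density plot.
    """
    ratios, ratio_se = _ratio_arrays(data)
    h = _mode_bandwidth(ratios, phi)
    if h == 0.0:  # zero dispersion: degenerate spike at the common ratio
        common = float(ratios[0])
        grid = np.array([common])
        return grid, np.array([1.0]), common
    if weighted:
        w = 1.0 / ratio_se**2
    else:
        w = np.ones_like(ratios)
    w = w / w.sum()
    grid = np.linspace(ratios.min() - 2 * h, ratios.max() + 2 * h, grid_size)
    z = (grid[:, None] - ratios[None, :]) / h
    density = (np.exp(-0.5 * z**2) @ w) / (h * np.sqrt(2 * np.pi))
    mode = float(grid[int(np.argmax(density))])
    return grid, density, mode


def mode_estimator(
    data: SummarySet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    grid_size: int = 10_000,
    ci_level: float = 0.95,
) -> MREstimate:
    """Mode-based causal estimate (kernel-density argmax of the ratios).

    The estimate maximizes a Gaussian-kernel density of the ratio estimates
    with bandwidth :math:`h = \\phi \\times 0.9 \\min(SD, MAD/0.6745)
    J^{-1/5}`; ``weighted=True`` weights each kernel by the variant's
    normalized inverse ratio variance.  Consistent under the "zero modal
    pleiotropy" assumption: the largest subset of variants sharing a common
    ratio value must be the valid instruments — a weaker condition than the
    median's majority-validity.  SE by seeded parametric bootstrap;
    inference from the normal reference.
    """
    j = len(data)
    if j < 3:
        raise ValidationError(f"mode estimator requires at least 3 variants (got {j})")
    if phi <= 0:
        raise ConfigurationError(f"phi must be > 0, got {phi}")
    if n_boot < 1:
        raise ConfigurationError(f"n_boot must be >= 1, got {n_boot}")
    if seed is None:
        raise ConfigurationError("mode_estimator requires an explicit seed")
    _, _, estimate = ratio_density(data, phi=phi, weighted=weighted, grid_size=grid_size)

    sy = data.se_outcome

    def point(bx: np.ndarray, by: np.ndarray) -> float:
        ratios = by / bx
        ratio_se = sy / np.abs(bx)
        h = _mode_bandwidth(ratios, phi)
        if h == 0.0:
            return float(ratios[0])
        w = 1.0 / ratio_se**2 if weighted else np.ones_like(ratios)
        w = w / w.sum()
        grid = np.linspace(ratios.min() - 2 * h, ratios.max() + 2 * h, grid_size)
        z = (grid[:, None] - ratios[None, :]) / h
        density = np.exp(-0.5 * z**2) @ w
        return float(grid[int(np.argmax(density))])

    se = _parametric_bootstrap_se(data, point, n_boot, seed)
    method = "mode_weighted" if weighted else "mode_unweighted"
    return _infer(method, estimate, se, j, None, ci_level)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def estimates_to_table(estimates: list) -> "pd.DataFrame":
    """Flatten estimates into a results table (one row per coefficient).

    Egger results contribute two rows (intercept then effect), mirroring
    the usual presentation of summary-MR results.
    """
    import pandas as pd

    rows = []
    for est in estimates:
        if isinstance(est, EggerEstimate):
            rows.append(est.intercept.to_dict())
            rows.append(est.slope.to_dict())
        else:
            rows.append(est.to_dict())
    frame = pd.DataFrame(rows)
    return frame[
        ["method", "estimate", "se", "p_value", "ci_low", "ci_high", "n_variants"]
    ]
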