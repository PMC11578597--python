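"""Two-sample MR estimators on harmonized instrument sets.

All estimators combine per-instrument Wald ratios
``b_j = beta_outcome_j / beta_exposure_j`` with first-order
delta-method standard errors ``se_j = se_outcome_j / |beta_exposure_j|``
(the exposure-side sampling variance is ignored in the ratio variance,
the conventional first-order weighting in two-sample MR):

* ``wald_ratio`` — single-instrument estimate.
* ``ivw`` — inverse-variance weighted mean of the ratios; by default a
  multiplicative random-effects model that inflates the fixed-effect SE
  by sqrt(Q / (J - 1)) when Cochran's Q exceeds its degrees of freedom.
* ``weighted_median`` — consistent when instruments carrying at least
  half of the total weight are valid; SE by parametric bootstrap.
* ``weighted_mode`` — consistent when the largest weight cluster of
  ratios comes from valid instruments; Gaussian-kernel weighted density
  argmax with a modified Silverman bandwidth, SE by parametric
  bootstrap.

The per-group instrument-strength diagnostic is the mean per-instrument
F-statistic, F_j = (beta_exposure_j / se_exposure_j)^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import EstimationError, ParameterError
from .summary_io import InstrumentRecord

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))

#: Smallest number of instruments accepted by the median/mode estimators.
MIN_INSTRUMENTS_ROBUST = 3

_BANDWIDTH_FLOOR = 1e-12


@dataclass(frozen=True, slots=True)
class RatioEstimate:
    """Wald ratio of one instrument with its first-order SE."""

    variant_id: str
    ratio: float
    ratio_se: float


@dataclass(frozen=True, slots=True)
class MREstimate:
    """One causal-effect estimate (outcome units per exposure unit)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_instruments: int
    f_statistic: float
    heterogeneity_q: float | None = None


def _as_arrays(records: Sequence[InstrumentRecord]):
    be = np.array([r.beta_exposure for r in records])
    se_e = np.array([r.se_exposure for r in records])
    bo = np.array([r.beta_outcome for r in records])
    se_o = np.array([r.se_outcome for r in records])
    if np.any(be == 0):
        raise EstimationError("beta_exposure == 0 encountered; such "
                              "records must be rejected at harmonization")
    return be, se_e, bo, se_o


def ratio_estimates(records: Sequence[InstrumentRecord]) -> list[RatioEstimate]:
    """Per-instrument Wald ratios with first-order standard errors."""
    be, _, bo, se_o = _as_arrays(records)
    return [RatioEstimate(r.variant_id, b / a, s / abs(a))
            for r, a, b, s in zip(records, be, bo, se_o)]


def f_statistic(records: Sequence[InstrumentRecord]) -> float:
    """Mean per-instrument F-statistic, F_j = (b_j / SE_j)^2, a
    weak-instrument diagnostic for a group (rule of thumb: mean F > 10
    suggests weak-instrument bias is limited)."""
    if len(records) == 0:
        raise EstimationError("f_statistic requires at least one instrument")
    be = np.array([r.beta_exposure for r in records])
    se_e = np.array([r.se_exposure for r in records])
    return float(np.mean((be / se_e) ** 2))


def _finalize(method: str, beta: float, se: float, records,
              q: float | None = None) -> MREstimate:
    if not (se > 0 and math.isfinite(se)):
        raise EstimationError(f"{method}: non-positive standard error")
    z = beta / se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(2.0 * stats.norm.sf(abs(z))),
        n_instruments=len(records),
        f_statistic=f_statistic(records),
        heterogeneity_q=q,
    )


def wald_ratio(record: InstrumentRecord) -> MREstimate:
    """Single-instrument causal estimate: beta_outcome / beta_exposure
    with first-order SE se_outcome / |beta_exposure|."""
    if record.beta_exposure == 0:
        raise EstimationError(
            f"{record.variant_id}: beta_exposure is zero")
    beta = record.beta_outcome / record.beta_exposure
    se = record.se_outcome / abs(record.beta_exposure)
    return _finalize("wald_ratio", beta, se, [record])


def ivw(records: Sequence[InstrumentRecord],
        mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    Equivalent to weighted least squares of beta_outcome on
    beta_exposure through the origin with weights 1/se_outcome^2.
    ``mode="fixed"`` reports the fixed-effect SE sqrt(1 / sum w);
    ``mode="multiplicative_random"`` (default) inflates it by
    sqrt(Q / (J - 1)) whenever that factor exceeds 1, where Q is
    Cochran's Q of the ratio estimates (reported as heterogeneity_q).

    A single record delegates to :func:`wald_ratio`.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ParameterError(f"unknown IVW mode {mode!r}")
    if len(records) == 0:
        raise EstimationError("ivw requires at least one instrument")
    if len(records) == 1:
        return wald_ratio(records[0])
    be, _, bo, se_o = _as_arrays(records)
    b = bo / be
    w = (be / se_o) ** 2          # = 1 / ratio_se^2
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = math.sqrt(1.0 / np.sum(w))
    q = float(np.sum(w * (b - beta) ** 2))
    se = se_fixed
    if mode == "multiplicative_random":
        dispersion = q / (len(records) - 1)
        if dispersion > 1.0:
            se = se_fixed * math.sqrt(dispersion)
    return _finalize("ivw", beta, se, records, q=q)


def _check_robust_input(name: str, records, n_boot: int,
                        min_instruments: int) -> None:
    if len(records) < min_instruments:
        raise EstimationError(
            f"{name} requires >= {min_instruments} instruments, got "
            f"{len(records)}; use ivw or wald_ratio for small sets")
    if n_boot < 1:
        raise ParameterError(f"n_boot must be positive, got {n_boot}")


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by cumulative-weight interpolation.

    values: (B, J); weights: (J,) raw (unnormalized) weights shared by
    all rows.  For each row: sort values, attach normalized weights s_j,
    form p_j = cumsum(s) - s/2 and linearly interpolate the sorted
    values at p = 0.5 (clamped at the extremes).
    """
    values = np.atleast_2d(values)
    B, J = values.shape
    order = np.argsort(values, axis=1)
    sv = np.take_along_axis(values, order, axis=1)
    s = (weights / weights.sum())[order]
    p = np.cumsum(s, axis=1) - s / 2.0
    out = np.empty(B)
    idx = (p < 0.5).sum(axis=1)        # first index with p >= 0.5
    for i in range(B):
        j = idx[i]
        if j == 0:
            out[i] = sv[i, 0]
        elif j == J:
            out[i] = sv[i, -1]
        else:
            p0, p1 = p[i, j - 1], p[i, j]
            out[i] = sv[i, j - 1] + (0.5 - p0) * (sv[i, j] - sv[i, j - 1]) / (p1 - p0)
    return out


def weighted_median(records: Sequence[InstrumentRecord],
                    n_boot: int = 1000,
                    seed: int = 0,
                    min_instruments: int = MIN_INSTRUMENTS_ROBUST) -> MREstimate:
    """Weighted-median MR estimate.

    Point estimate: the inverse-variance weighted median of the Wald
    ratios, i.e. linear interpolation of the sorted ratios at cumulative
    standardized weight 0.5.  SE: parametric bootstrap — each ratio is
    resampled from Normal(b_j, ratio_se_j) with weights held fixed, the
    weighted median recomputed, and the SE taken as the standard
    deviation of the ``n_boot`` replicates (seeded, reproducible).
    """
    _check_robust_input("weighted_median", records, n_boot, min_instruments)
    be, _, bo, se_o = _as_arrays(records)
    b = bo / be
    ratio_se = se_o / np.abs(be)
    w = 1.0 / ratio_se ** 2
    beta = float(_weighted_median_rows(b, w)[0])
    rng = np.random.default_rng(seed)
    samples = rng.normal(b, ratio_se, size=(n_boot, len(records)))
    boots = _weighted_median_rows(samples, w)
    se = float(np.std(boots, ddof=1))
    return _finalize("weighted_median", beta, se, records)


def _mode_bandwidth(values: np.ndarray, weights: np.ndarray,
                    bandwidth_factor: float) -> np.ndarray:
    """Modified Silverman bandwidth per row:
    0.9 * min(weighted sd, weighted MAD / 0.6745) * J^(-1/5),
    scaled by ``bandwidth_factor`` and floored at a small epsilon."""
    values = np.atleast_2d(values)
    J = values.shape[1]
    s = weights / weights.sum()
    mean = values @ s
    sd = np.sqrt(((values - mean[:, None]) ** 2) @ s)
    med = _weighted_median_rows(values, weights)
    mad = _weighted_median_rows(np.abs(values - med[:, None]), weights) / 0.6745
    h = bandwidth_factor * 0.9 * np.minimum(sd, mad) * J ** (-0.2)
    if np.any(h <= _BANDWIDTH_FLOOR):
        logger.warning("weighted_mode: zero bandwidth floored at %.0e",
                       _BANDWIDTH_FLOOR)
        h = np.maximum(h, _BANDWIDTH_FLOOR)
    return h


def _mode_rows(values: np.ndarray, weights: np.ndarray,
               bandwidth_factor: float, grid_points: int) -> np.ndarray:
    """Row-wise weighted-KDE mode: argmax of the Gaussian-kernel
    weighted density on a grid spanning [min - 3h, max + 3h].  Exact
    density ties resolve to the lowest grid value (argmax takes the
    first maximum)."""
    values = np.atleast_2d(values)
    B, J = values.shape
    h = _mode_bandwidth(values, weights, bandwidth_factor)
    lo = values.min(axis=1) - 3.0 * h
    hi = values.max(axis=1) + 3.0 * h
    frac = np.linspace(0.0, 1.0, grid_points)
    grid = lo[:, None] + (hi - lo)[:, None] * frac
    dens = np.zeros((B, grid_points))
    for j in range(J):  # accumulate per instrument to bound memory
        dens += weights[j] * np.exp(
            -0.5 * ((grid - values[:, j, None]) / h[:, None]) ** 2)
    return grid[np.arange(B), np.argmax(dens, axis=1)]


def weighted_mode(records: Sequence[InstrumentRecord],
                  bandwidth_factor: float = 1.0,
                  n_boot: int = 1000,
                  seed: int = 0,
                  grid_points: int = 512,
                  min_instruments: int = MIN_INSTRUMENTS_ROBUST) -> MREstimate:
    """Weighted-mode MR estimate.

    Point estimate: the argmax of a Gaussian-kernel density of the Wald
    ratios with per-point mass proportional to 1/ratio_se^2, evaluated
    on a ``grid_points``-point grid; the bandwidth follows a modified
    Silverman rule (see :func:`_mode_bandwidth`).  SE by the same
    parametric bootstrap as :func:`weighted_median` (bandwidth and grid
    recomputed per replicate).
    """
    _check_robust_input("weighted_mode", records, n_boot, min_instruments)
    if bandwidth_factor <= 0:
        raise ParameterError(
            f"bandwidth_factor must be positive, got {bandwidth_factor}")
    if grid_points < 512:
        raise ParameterError("grid_points must be >= 512")
    be, _, bo, se_o = _as_arrays(records)
    b = bo / be
    ratio_se = se_o / np.abs(be)
    w = 1.0 / ratio_se ** 2
    beta = float(_mode_rows(b, w, bandwidth_factor, grid_points)[0])
    rng = np.random.default_rng(seed)
    samples = rng.normal(b, ratio_se, size=(n_boot, len(records)))
    boots = _mode_rows(samples, w, bandwidth_factor, grid_points)
    se = float(np.std(boots, ddof=1))
    return _finalize("weighted_mode", beta, se, records)


#: Registry used by the orchestration layer and the CLI.
METHODS = ("ivw", "weighted_median", "weighted_mode")
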