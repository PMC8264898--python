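"""Causal-effect estimators for summary-data Mendelian randomisation.

Given k harmonised instruments with SNP-exposure effects beta_x_j (SE
s_x_j) and SNP-outcome effects beta_y_j (SE s_y_j):

* Wald ratio: theta_j = beta_y_j / beta_x_j, SE s_y_j / |beta_x_j|
  (first-order delta method).
* IVW: zero-intercept weighted regression of beta_y on beta_x with
  weights 1/s_y^2; the main estimate.  Default SE policy is
  multiplicative random effects, inflating the fixed-effect SE by
  max(1, sqrt(Q/(k-1))).
* MR-Egger: the same regression with a free intercept after orienting
  every instrument to beta_x >= 0; the intercept estimates average
  directional pleiotropy, inference uses t with k-2 df and an
  over-dispersion scale bounded below by 1.
* Weighted median: interpolated median of the ratio estimates under
  inverse-variance weights; consistent when >= 50% of weight comes
  from valid instruments.
* Weighted mode (mode-based estimate): argmax of a weighted normal-
  kernel density of the ratio estimates with a Silverman-type
  bandwidth; consistent when the largest weight cluster is valid.

Median and mode SEs come from a seeded parametric bootstrap that
resamples both betas from normals at their observed values and SEs.
All confidence intervals are two-sided at 95%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MRResult",
    "EstimatorConfig",
    "ratio_estimates",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "weighted_median_point",
    "weighted_mode_point",
    "run_all_estimators",
    "CI_LEVEL",
    "MODE_GRID_POINTS",
]

logger = logging.getLogger(__name__)

#: Two-sided confidence level used throughout.
CI_LEVEL = 0.95
#: Fixed evaluation-grid size for the mode-based estimate (determinism).
MODE_GRID_POINTS = 10_000

_METHOD_MIN_SNPS = {
    "wald_ratio": 1,
    "ivw": 1,
    "egger": 3,
    "weighted_median": 3,
    "weighted_mode": 3,
}


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal-effect estimate.

    ``estimate`` is on the outcome scale per SD of exposure (log-odds
    per SD for a binary outcome); ``or_scale`` fields are its exp
    transform for odds-ratio presentation.
    """

    method: str
    n_snp: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_scale: float
    or_ci_low: float
    or_ci_high: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    q_statistic: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    label: str = ""


def _finish(method, n_snp, estimate, se, *, df=None, **extra) -> MRResult:
    """Attach CI, p and OR-scale fields; normal or t(df) reference."""
    if df is not None:
        crit = stats.t.ppf(0.5 + CI_LEVEL / 2, df)
        pval = 2.0 * stats.t.sf(abs(estimate / se), df) if se > 0 else (1.0 if estimate == 0 else 0.0)
    else:
        crit = stats.norm.ppf(0.5 + CI_LEVEL / 2)
        pval = 2.0 * stats.norm.sf(abs(estimate / se)) if se > 0 else (1.0 if estimate == 0 else 0.0)
    lo, hi = estimate - crit * se, estimate + crit * se
    return MRResult(
        method=method,
        n_snp=n_snp,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        pval=float(min(pval, 1.0)),
        or_scale=float(np.exp(estimate)),
        or_ci_low=float(np.exp(lo)),
        or_ci_high=float(np.exp(hi)),
        **extra,
    )


def _arrays(instruments):
    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    sx = np.array([i.se_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments], dtype=float)
    return bx, sx, by, sy


def ratio_estimates(instruments):
    """Per-variant Wald ratios theta_j, first-order SEs and weights 1/SE^2."""
    bx, _, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("zero SNP-exposure effect; ratio estimate undefined")
    theta = by / bx
    se = sy / np.abs(bx)
    return theta, se, 1.0 / se**2


def cochran_q_from_arrays(bx, by, sy, pooled: float):
    """Cochran's Q about ``pooled`` with IVW weights beta_x^2/s_y^2."""
    theta = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(bx) - 1
    return q, df, float(stats.chi2.sf(q, df)) if df >= 1 else 1.0


def wald_ratio(instrument) -> MRResult:
    """Single-SNP causal estimate beta_y/beta_x with delta-method SE."""
    if instrument.beta_exp == 0:
        raise ValueError("zero SNP-exposure effect; Wald ratio undefined")
    estimate = instrument.beta_out / instrument.beta_exp
    se = instrument.se_out / abs(instrument.beta_exp)
    return _finish("wald_ratio", 1, estimate, se, label=instrument.variant_id)


def ivw(instruments, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate.

    Zero-intercept weighted regression of beta_y on beta_x, weights
    1/s_y^2: theta = sum(bx*by/sy^2) / sum(bx^2/sy^2).  With
    ``random_effects`` (default) the fixed-effect SE is inflated by
    max(1, sqrt(Q/(k-1))) for k >= 2 (multiplicative random effects);
    Cochran's Q is attached either way.  With a single instrument this
    reduces exactly to the Wald ratio.
    """
    instruments = list(instruments)
    if not instruments:
        raise ValueError("IVW requires at least one instrument")
    bx, _, by, sy = _arrays(instruments)
    k = len(instruments)
    if k == 1:  # exact Wald-ratio reduction, free of round-off
        estimate = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
    else:
        w = 1.0 / sy**2
        denom = float(np.sum(bx**2 * w))
        estimate = float(np.sum(bx * by * w)) / denom
        se = float(np.sqrt(1.0 / denom))
    q = df = q_pval = None
    if k >= 2:
        q, df, q_pval = cochran_q_from_arrays(bx, by, sy, estimate)
        if random_effects:
            se *= max(1.0, np.sqrt(q / df))
    return _finish(
        "ivw", k, estimate, se, q_statistic=q, q_df=df, q_pval=q_pval
    )


def mr_egger(instruments) -> MRResult:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    Instruments are first oriented so beta_x >= 0 (both betas negated
    where needed); then beta_y is regressed on beta_x with a free
    intercept and weights 1/s_y^2.  The covariance is scaled by the
    weighted residual mean square bounded below by 1 (multiplicative
    over-dispersion with floor); inference uses t with k-2 df.
    """
    instruments = list(instruments)
    k = len(instruments)
    if k < 3:
        raise ValueError(f"MR-Egger requires at least 3 instruments, got {k}")
    bx, _, by, sy = _arrays(instruments)
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y, w = bx * sign, by * sign, 1.0 / sy**2
    sw, swx, swx2 = np.sum(w), np.sum(w * x), np.sum(w * x**2)
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    xtwx = np.array([[sw, swx], [swx, swx2]])
    intercept, slope = np.linalg.solve(xtwx, np.array([swy, swxy]))
    resid = y - intercept - slope * x
    df = k - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    cov = max(1.0, sigma2) * np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov))
    int_pval = float(2.0 * stats.t.sf(abs(intercept / se_int), df))
    return _finish(
        "egger",
        k,
        slope,
        se_slope,
        df=df,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_pval=int_pval,
    )


def weighted_median_point(theta, w) -> float:
    """Interpolated weighted median of ratio estimates.

    Sort theta ascending; the standardised mid-cumulative weight of the
    j-th value is s_j = (cumsum(w)_j - w_j/2) / sum(w); the estimate is
    theta interpolated linearly in s at 0.5.
    """
    theta = np.asarray(theta, dtype=float)
    w = np.asarray(w, dtype=float)
    order = np.argsort(theta)
    th, ww = theta[order], w[order]
    s = (np.cumsum(ww) - ww / 2.0) / np.sum(ww)
    return float(np.interp(0.5, s, th))


def _silverman_bandwidth(theta, factor: float) -> float:
    k = len(theta)
    sd = float(np.std(theta, ddof=1)) if k > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.34)
    if spread == 0.0:
        spread = sd  # >50% ties but not degenerate: fall back to the SD
    return factor * 0.9 * spread * k ** (-1.0 / 5.0)


def weighted_mode_point(theta, w, bandwidth_factor: float = 1.0) -> float:
    """Argmax of the weighted normal-kernel density of the ratio estimates.

    Bandwidth h = factor * 0.9 * min(sd, IQR/1.34) * k^(-1/5); the
    density is evaluated on a fixed grid of ``MODE_GRID_POINTS`` points
    spanning [min(theta) - 3h, max(theta) + 3h].  With all ratios
    identical (h = 0) the common value is returned.
    """
    theta = np.asarray(theta, dtype=float)
    w = np.asarray(w, dtype=float)
    h = _silverman_bandwidth(theta, bandwidth_factor)
    if h == 0.0 or np.ptp(theta) == 0.0:
        if np.ptp(theta) == 0.0:
            return float(theta[0])
        # spread degenerate but values differ: heaviest value wins
        return float(theta[np.argmax(w)])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, MODE_GRID_POINTS)
    wn = w / np.sum(w)
    density = np.sum(
        wn[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2), axis=0
    )
    return float(grid[np.argmax(density)])


def _parametric_bootstrap(instruments, point_fn, n_boot: int, rng) -> float:
    """SD of ``point_fn`` over parametric resamples of both betas."""
    bx, sx, by, sy = _arrays(instruments)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        bx_star = rng.normal(bx, sx)
        by_star = rng.normal(by, sy)
        bx_star[bx_star == 0.0] = np.finfo(float).tiny  # keep ratios finite
        theta = by_star / bx_star
        w = (bx_star / sy) ** 2
        estimates[b] = point_fn(theta, w)
    return float(np.std(estimates, ddof=1))


def weighted_median(instruments, n_boot: int = 1000, seed: int | None = None) -> MRResult:
    """Weighted-median estimate with parametric-bootstrap SE."""
    instruments = list(instruments)
    if len(instruments) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    theta, _, w = ratio_estimates(instruments)
    estimate = weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    se = _parametric_bootstrap(instruments, weighted_median_point, n_boot, rng)
    return _finish("weighted_median", len(instruments), estimate, se)


def weighted_mode(
    instruments,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MRResult:
    """Mode-based estimate with parametric-bootstrap SE."""
    instruments = list(instruments)
    if len(instruments) < 3:
        raise ValueError("weighted mode requires at least 3 instruments")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    theta, _, w = ratio_estimates(instruments)
    estimate = weighted_mode_point(theta, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    se = _parametric_bootstrap(
        instruments,
        lambda t, ww: weighted_mode_point(t, ww, bandwidth_factor),
        n_boot,
        rng,
    )
    return _finish("weighted_mode", len(instruments), estimate, se)


@dataclass(frozen=True)
class EstimatorConfig:
    """Shared settings for a multi-estimator run."""

    seed: int
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    random_effects: bool = True
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "weighted_mode")


def run_all_estimators(instruments, config: EstimatorConfig) -> list[MRResult]:
    """Run every applicable estimator; skip (with a notice) those below
    their instrument minimum.

    A single :class:`~numpy.random.SeedSequence` derived from
    ``config.seed`` governs all bootstrap draws, so identical inputs and
    seed give bit-identical results.  With fewer than three instruments
    the per-SNP Wald ratios are emitted alongside IVW.
    """
    instruments = list(instruments)
    k = len(instruments)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    results: list[MRResult] = []
    for method in config.methods:
        if k < _METHOD_MIN_SNPS.get(method, 1):
            logger.info(
                "skipping %s: %d instrument(s) below minimum %d",
                method, k, _METHOD_MIN_SNPS[method],
            )
            continue
        if method == "ivw":
            results.append(ivw(instruments, random_effects=config.random_effects))
        elif method == "egger":
            results.append(mr_egger(instruments))
        elif method == "weighted_median":
            results.append(
                weighted_median(instruments, n_boot=config.n_boot, seed=seeds[0])
            )
        elif method == "weighted_mode":
            results.append(
                weighted_mode(
                    instruments,
                    bandwidth_factor=config.bandwidth_factor,
                    n_boot=config.n_boot,
                    seed=seeds[1],
                )
            )
        elif method == "wald_ratio":
            pass  # emitted below when k < 3
        else:
            raise ValueError(f"unknown estimator {method!r}")
    if k < 3:
        results.extend(wald_ratio(inst) for inst in instruments)
    return results
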