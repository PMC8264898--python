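"""Heterogeneity and pleiotropy diagnostics.

Variability of the per-SNP causal estimates signals potential violation
of the instrumental-variable assumptions.  This module provides
Cochran's Q (with the IVW first-order weights beta_x^2/s_y^2), the
MR-Egger intercept test for directional pleiotropy, leave-one-out
re-estimation, the single-SNP Wald-ratio forest series, and funnel-plot
coordinates (ratio estimate against its precision 1/SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .estimators import (
    MRResult,
    cochran_q_from_arrays,
    ivw,
    ratio_estimates,
    wald_ratio,
    _arrays,
)
from .instruments import _chrom_key

__all__ = [
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "single_snp_forest",
    "funnel_data",
    "sensitivity_report",
]


def cochran_q(instruments, pooled_estimate: float | None = None):
    """Cochran's Q statistic about the pooled estimate.

    Q = sum_j w_j (theta_j - pooled)^2 with w_j = beta_x_j^2/s_y_j^2,
    df = k - 1, p from the upper tail of chi-square(df).  When
    ``pooled_estimate`` is omitted the IVW estimate is used.
    """
    instruments = list(instruments)
    if len(instruments) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    bx, _, by, sy = _arrays(instruments)
    if pooled_estimate is None:
        pooled_estimate = ivw(instruments, random_effects=False).estimate
    return cochran_q_from_arrays(bx, by, sy, pooled_estimate)


def egger_intercept_test(egger_result: MRResult):
    """Extract (intercept, SE, two-sided p from t(k-2)) from an Egger fit."""
    if egger_result.method != "egger":
        raise ValueError(f"expected an egger result, got {egger_result.method!r}")
    return egger_result.intercept, egger_result.intercept_se, egger_result.intercept_pval


def _position_sorted(instruments):
    return sorted(instruments, key=lambda i: (_chrom_key(i.chrom), i.pos))


def leave_one_out(instruments, random_effects: bool = True):
    """IVW re-estimated on each size-(k-1) subset.

    Returns ``[(excluded variant_id, MRResult), ...]`` ordered by the
    excluded variant's genomic position.  At k = 2 each subset is a
    single instrument, so each entry is the remaining SNP's Wald ratio
    (to which IVW reduces exactly).
    """
    instruments = list(instruments)
    if len(instruments) < 2:
        raise ValueError("leave-one-out requires at least 2 instruments")
    series = []
    for excluded in _position_sorted(instruments):
        rest = [i for i in instruments if i is not excluded]
        series.append((excluded.variant_id, ivw(rest, random_effects=random_effects)))
    return series


def single_snp_forest(instruments):
    """Per-variant Wald ratios ordered by position, plus a pooled IVW row."""
    instruments = list(instruments)
    if not instruments:
        raise ValueError("single-SNP analysis requires at least 1 instrument")
    series = [(i.variant_id, wald_ratio(i)) for i in _position_sorted(instruments)]
    series.append(("All (IVW)", ivw(instruments)))
    return series


def funnel_data(instruments) -> pd.DataFrame:
    """Funnel coordinates: per-variant ratio estimate, SE and precision 1/SE."""
    instruments = list(instruments)
    if not instruments:
        raise ValueError("funnel data requires at least 1 instrument")
    theta, se, _ = ratio_estimates(instruments)
    return pd.DataFrame(
        {
            "SNP": [i.variant_id for i in instruments],
            "theta": theta,
            "se": se,
            "precision": 1.0 / se,
        }
    )


@dataclass(frozen=True)
class SensitivityReport:
    """Bundle of all sensitivity diagnostics for one instrument set."""

    q_statistic: float
    q_df: int
    q_pval: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pval: float | None
    leave_one_out: tuple
    single_snp: tuple
    funnel: pd.DataFrame


def sensitivity_report(instruments, egger_result: MRResult | None = None) -> SensitivityReport:
    """Compute the full diagnostic bundle.

    ``egger_result`` may be supplied to reuse an existing fit; with
    fewer than three instruments the intercept fields are ``None``.
    """
    from .estimators import mr_egger  # local: avoid re-fit when provided

    instruments = list(instruments)
    q, df, q_pval = cochran_q(instruments)
    if egger_result is None and len(instruments) >= 3:
        egger_result = mr_egger(instruments)
    if egger_result is not None:
        intercept, intercept_se, intercept_pval = egger_intercept_test(egger_result)
    else:
        intercept = intercept_se = intercept_pval = None
    return SensitivityReport(
        q_statistic=q,
        q_df=df,
        q_pval=q_pval,
        egger_intercept=intercept,
        egger_intercept_se=intercept_se,
        egger_intercept_pval=intercept_pval,
        leave_one_out=tuple(leave_one_out(instruments)),
        single_snp=tuple(single_snp_forest(instruments)),
        funnel=funnel_data(instruments),
    )
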