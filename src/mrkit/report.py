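"""Publication-shaped presentation of MR results.

Full-precision results live in the TSV written by
:func:`results_to_frame`; :func:`render_results_table` formats them the
way MR papers print them — odds ratios per SD to two decimals (round
half to even) with "x.xx to y.yy" confidence intervals and the
heterogeneity Q p-value alongside the IVW row.
"""

from __future__ import annotations

import math

import pandas as pd

from .estimators import MRResult

__all__ = [
    "METHOD_LABELS",
    "results_to_frame",
    "render_results_table",
    "format_or",
    "format_ci",
]

METHOD_LABELS = {
    "ivw": "IVW",
    "weighted_median": "Weighted median",
    "weighted_mode": "Weighted mode",
    "egger": "MR Egger",
    "wald_ratio": "Wald ratio",
}

_COLUMNS = [
    "method", "label", "n_snp", "b", "se", "ci_low", "ci_high", "pval",
    "or", "or_ci_low", "or_ci_high",
    "egger_intercept", "egger_intercept_se", "egger_intercept_pval",
    "q", "q_df", "q_pval",
]


def results_to_frame(results: list[MRResult]) -> pd.DataFrame:
    """Full-precision results table, one row per estimator output."""
    rows = [
        {
            "method": r.method,
            "label": r.label,
            "n_snp": r.n_snp,
            "b": r.estimate,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "pval": r.pval,
            "or": r.or_scale,
            "or_ci_low": r.or_ci_low,
            "or_ci_high": r.or_ci_high,
            "egger_intercept": r.intercept,
            "egger_intercept_se": r.intercept_se,
            "egger_intercept_pval": r.intercept_pval,
            "q": r.q_statistic,
            "q_df": r.q_df,
            "q_pval": r.q_pval,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def format_or(value: float) -> str:
    """Two-decimal rendering (Python's round-half-even float formatting)."""
    return f"{value:.2f}"


def format_ci(low: float, high: float) -> str:
    return f"{format_or(low)} to {format_or(high)}"


def _format_p(p) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    return f"{p:.2g}"


def render_results_table(frame: pd.DataFrame) -> str:
    """Render a results frame as the printed-table presentation."""
    header = ["Method", "No. SNPs", "OR per SD", "95% CI", "P value", "Q p-value"]
    rows = [header]
    for r in frame.to_dict("records"):
        method = METHOD_LABELS.get(r["method"], r["method"])
        if r["method"] == "wald_ratio" and r.get("label"):
            method = f"Wald ratio ({r['label']})"
        q_pval = r.get("q_pval")
        rows.append(
            [
                method,
                str(int(r["n_snp"])),
                format_or(r["or"]),
                format_ci(r["or_ci_low"], r["or_ci_high"]),
                _format_p(r["pval"]),
                _format_p(None if q_pval is None or pd.isna(q_pval) else q_pval),
            ]
        )
    widths = [max(len(row[i]) for row in rows) for i in range(len(header))]
    lines = ["  ".join(cell.ljust(widths[i]) for i, cell in enumerate(row)).rstrip()
             for row in rows]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)
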