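"""Instrument selection and filtering.

Candidate instruments pass through, in order: genome-wide significance
selection, greedy LD clumping against a user-supplied LD matrix
(default window 10 000 kb, r^2 threshold 0.001), harmonisation with
palindrome exclusion, and Steiger directionality filtering (drop
variants that explain more variance in the outcome than in the
exposure).  Instrument strength is summarised per variant by
F = beta^2 / SE^2; values above ~10 conventionally indicate low
weak-instrument bias.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import SummaryStatsTable
from .harmonise import (
    DEFAULT_AMBIGUITY_WINDOW,
    HarmonisationResult,
    HarmonisedInstrument,
    harmonise_tables,
)

__all__ = [
    "LDMatrix",
    "InstrumentFilterReport",
    "PipelineConfig",
    "NoInstrumentsError",
    "select_significant",
    "ld_clump",
    "f_statistic",
    "steiger_r2",
    "steiger_filter",
    "run_instrument_pipeline",
]


class NoInstrumentsError(RuntimeError):
    """The filtering pipeline left zero usable instruments."""


@dataclass(frozen=True)
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered set of variants."""

    variant_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        k = len(self.variant_ids)
        if len(set(self.variant_ids)) != k:
            raise ValueError("duplicate variant ids in LD matrix")
        if r2.shape != (k, k):
            raise ValueError(f"r2 shape {r2.shape} does not match {k} variant ids")
        if not np.allclose(r2, r2.T):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if r2.min() < 0.0 or r2.max() > 1.0 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")

    def index_of(self, variant_id: str) -> int | None:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            return None

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, columns=list(self.variant_ids)).to_csv(
            path, sep="\t", index=False
        )


def select_significant(table: SummaryStatsTable, threshold: float) -> SummaryStatsTable:
    """Retain variants with p strictly below ``threshold``, preserving order."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return table.replace_records(r for r in table.records if r.pval < threshold)


def _chrom_key(chrom: str):
    # numeric chromosomes sort numerically, others lexically after them
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


def ld_clump(
    table: SummaryStatsTable,
    ld: LDMatrix | None,
    window_kb: float = 10_000.0,
    r2_threshold: float = 0.001,
) -> SummaryStatsTable:
    """Greedy LD clumping.

    Repeatedly accept the remaining variant with the smallest p-value
    (ties broken by ascending chromosome, position) and discard every
    other variant on the same chromosome within ``window_kb`` kilobases
    whose r^2 with it is at or above ``r2_threshold``.  Variants absent
    from ``ld`` (or all variants, when ``ld`` is None) are treated as
    independent (r^2 = 0) with a warning.  Output is sorted by genomic
    position.
    """
    records = list(table.records)
    if ld is not None:
        missing = [r.variant_id for r in records if ld.index_of(r.variant_id) is None]
        if missing:
            warnings.warn(
                f"{len(missing)} variant(s) absent from LD matrix treated as independent",
                stacklevel=2,
            )

    def pair_r2(a, b) -> float:
        if ld is None:
            return 0.0
        i, j = ld.index_of(a.variant_id), ld.index_of(b.variant_id)
        if i is None or j is None:
            return 0.0
        return float(ld.r2[i, j])

    remaining = sorted(records, key=lambda r: (r.pval, _chrom_key(r.chrom), r.pos))
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [
            r
            for r in remaining
            if r.chrom != index.chrom
            or abs(r.pos - index.pos) > window_kb * 1000
            or pair_r2(index, r) < r2_threshold
        ]
    kept.sort(key=lambda r: (_chrom_key(r.chrom), r.pos))
    return table.replace_records(kept)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, beta^2 / SE^2."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def steiger_r2(beta: float, se: float, n: int) -> float:
    """Variance in a trait explained by one variant, t^2 / (t^2 + n - 2)."""
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def steiger_filter(
    instruments,
    n_exp: int | None = None,
    n_out: int | None = None,
) -> tuple[tuple[HarmonisedInstrument, ...], pd.DataFrame]:
    """Drop variants explaining more outcome than exposure variance.

    A variant is retained iff r^2_exposure > r^2_outcome, where each
    r^2 = t^2/(t^2 + n - 2) from the trait's own association.  Sample
    sizes default to each instrument's per-variant n.  Returns the
    retained instruments and a per-variant report of both r^2 values.
    """
    rows, kept = [], []
    for inst in instruments:
        ne = n_exp if n_exp is not None else inst.n_exp
        no = n_out if n_out is not None else inst.n_out
        r2_exp = steiger_r2(inst.beta_exp, inst.se_exp, ne)
        r2_out = steiger_r2(inst.beta_out, inst.se_out, no)
        retained = r2_exp > r2_out
        rows.append(
            {
                "SNP": inst.variant_id,
                "r2_exposure": r2_exp,
                "r2_outcome": r2_out,
                "retained": retained,
            }
        )
        if retained:
            kept.append(inst)
    report = pd.DataFrame(rows, columns=["SNP", "r2_exposure", "r2_outcome", "retained"])
    return tuple(kept), report


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the instrument-selection pipeline."""

    p_threshold: float = 5e-8
    clump_window_kb: float = 10_000.0
    clump_r2: float = 0.001
    ambiguity_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW
    steiger: bool = True


@dataclass(frozen=True)
class InstrumentFilterReport:
    """Stage-by-stage variant counts plus survivor F statistics."""

    n_input: int
    n_after_significance: int
    n_after_clump: int
    n_after_palindrome: int
    n_after_steiger: int
    f_statistics: tuple[float, ...]
    harmonisation_counts: dict[str, int] = field(default_factory=dict)

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_statistics)) if self.f_statistics else float("nan")

    def stage_counts(self) -> tuple[int, ...]:
        return (
            self.n_input,
            self.n_after_significance,
            self.n_after_clump,
            self.n_after_palindrome,
            self.n_after_steiger,
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_significance": self.n_after_significance,
            "n_after_clump": self.n_after_clump,
            "n_after_palindrome": self.n_after_palindrome,
            "n_after_steiger": self.n_after_steiger,
            "mean_f": self.mean_f,
            "f_statistics": list(self.f_statistics),
            "harmonisation_counts": self.harmonisation_counts,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_instrument_pipeline(
    exp: SummaryStatsTable,
    out: SummaryStatsTable,
    ld: LDMatrix | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[tuple[HarmonisedInstrument, ...], InstrumentFilterReport, HarmonisationResult]:
    """Significance -> LD clump -> harmonise/palindrome -> Steiger.

    Returns the surviving instruments, a stage-count report with the
    survivors' exposure F statistics, and the full harmonisation audit.
    Raises :class:`NoInstrumentsError` when nothing survives.
    """
    n_input = len(exp)
    significant = select_significant(exp, config.p_threshold)
    clumped = ld_clump(significant, ld, config.clump_window_kb, config.clump_r2)
    harmonised = harmonise_tables(clumped, out, config.ambiguity_window)
    kept = harmonised.kept
    if config.steiger and kept:
        kept, _ = steiger_filter(kept)
    report = InstrumentFilterReport(
        n_input=n_input,
        n_after_significance=len(significant),
        n_after_clump=len(clumped),
        n_after_palindrome=len(harmonised.kept),
        n_after_steiger=len(kept),
        f_statistics=tuple(f_statistic(i.beta_exp, i.se_exp) for i in kept),
        harmonisation_counts=harmonised.counts,
    )
    if not kept:
        raise NoInstrumentsError(
            "no instruments survive filtering; stage counts "
            f"{report.stage_counts()}"
        )
    return kept, report, harmonised
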