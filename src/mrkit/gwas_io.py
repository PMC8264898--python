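"""Reading, validating and writing GWAS summary-statistic tables.

Canonical dialect: tab-separated with a header row and columns
``SNP  CHR  BP  EA  OA  EAF  BETA  SE  P  N``.  Source files with other
headers are ingested through a ``column_map`` that translates the source
header names onto these canonical fields.  ``EAF`` is the only field
allowed to be missing; the missing token is ``NA``.

Rows that violate the per-variant invariants (non-positive SE, p outside
(0, 1], identical or non-ACGT alleles, duplicate identifiers, ...) are
rejected individually with a recorded reason; they are never silently
dropped.  Input rows = accepted rows + rejected rows always holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryStatsTable",
    "RowRejection",
    "ConfigurationError",
    "InvalidVariantError",
    "read_summary_stats",
    "write_summary_stats",
    "CANONICAL_COLUMNS",
    "MISSING_TOKEN",
    "TRAIT_SCALES",
]

CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N")
MISSING_TOKEN = "NA"
TRAIT_SCALES = ("continuous_sd", "log_odds")
VALID_ALLELES = frozenset("ACGT")


class ConfigurationError(ValueError):
    """A column map or trait-scale setting is unusable."""


class InvalidVariantError(ValueError):
    """A variant record violates a type invariant."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary-level association with one trait.

    ``beta`` is the additive effect of ``effect_allele`` per SD of a
    continuous trait, or the log-odds for a binary trait; ``eaf`` is the
    effect-allele frequency and may be ``None``.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        reason = self._invalid_reason()
        if reason is not None:
            raise InvalidVariantError(reason)

    def _invalid_reason(self) -> str | None:
        if not self.variant_id:
            return "empty variant id"
        if self.pos <= 0:
            return "non-positive position"
        if self.effect_allele not in VALID_ALLELES:
            return f"invalid effect allele {self.effect_allele!r}"
        if self.other_allele not in VALID_ALLELES:
            return f"invalid other allele {self.other_allele!r}"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            return "EAF outside (0, 1)"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if not (math.isfinite(self.se) and self.se > 0.0):
            return "non-positive SE"
        if not 0.0 < self.pval <= 1.0:
            return "p-value outside (0, 1]"
        if self.n <= 0:
            return "non-positive sample size"
        return None


@dataclass(frozen=True)
class RowRejection:
    """Record of one input row rejected at parse time, with its reason."""

    row_number: int  # 1-based data-row index in the source file
    variant_id: str
    reason: str


@dataclass(frozen=True)
class SummaryStatsTable:
    """An ordered collection of :class:`VariantAssociation` for one trait."""

    trait_label: str
    trait_scale: str
    records: tuple[VariantAssociation, ...]
    rejections: tuple[RowRejection, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.trait_scale not in TRAIT_SCALES:
            raise ConfigurationError(
                f"trait_scale must be one of {TRAIT_SCALES}, got {self.trait_scale!r}"
            )
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise InvalidVariantError("duplicate variant id in table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(r.variant_id for r in self.records)

    def get(self, variant_id: str) -> VariantAssociation | None:
        for r in self.records:
            if r.variant_id == variant_id:
                return r
        return None

    def replace_records(self, records) -> "SummaryStatsTable":
        return SummaryStatsTable(self.trait_label, self.trait_scale, tuple(records))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.variant_id,
                "CHR": r.chrom,
                "BP": r.pos,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": r.eaf,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pval,
                "N": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


_NUMERIC_FIELDS = {"BP": int, "EAF": float, "BETA": float, "SE": float, "P": float, "N": int}


def _parse_row(values: dict[str, str], row_number: int):
    """Parse one raw row; return a VariantAssociation or a RowRejection."""
    variant_id = values["SNP"].strip()
    parsed: dict[str, object] = {}
    for col, caster in _NUMERIC_FIELDS.items():
        raw = values[col].strip()
        if raw == MISSING_TOKEN or raw == "":
            if col == "EAF":
                parsed[col] = None
                continue
            return RowRejection(row_number, variant_id, f"missing {col}")
        try:
            parsed[col] = caster(float(raw)) if caster is int else caster(raw)
        except (TypeError, ValueError):
            return RowRejection(row_number, variant_id, f"unparseable {col} {raw!r}")
    try:
        return VariantAssociation(
            variant_id=variant_id,
            chrom=values["CHR"].strip(),
            pos=parsed["BP"],
            effect_allele=values["EA"].strip().upper(),
            other_allele=values["OA"].strip().upper(),
            eaf=parsed["EAF"],
            beta=parsed["BETA"],
            se=parsed["SE"],
            pval=parsed["P"],
            n=parsed["N"],
        )
    except InvalidVariantError as exc:
        return RowRejection(row_number, variant_id, str(exc))


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_scale: str = "continuous_sd",
    trait_label: str = "",
) -> SummaryStatsTable:
    """Read a summary-statistics TSV into a :class:`SummaryStatsTable`.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    column_map
        Mapping from *source* header names to canonical field names,
        e.g. ``{"rsid": "SNP", "effect": "BETA", ...}``.  ``None`` means
        the file already uses the canonical header.
    trait_scale
        ``"continuous_sd"`` (beta per SD) or ``"log_odds"``.

    Rejected rows are recorded on the returned table's ``rejections``
    with a per-row reason; later duplicates of an already-seen variant
    id are rejected, not the first occurrence.
    """
    if trait_scale not in TRAIT_SCALES:
        raise ConfigurationError(
            f"trait_scale must be one of {TRAIT_SCALES}, got {trait_scale!r}"
        )
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        unknown = set(column_map.values()) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"column_map targets unknown fields: {sorted(unknown)}")
        missing_src = set(column_map) - set(raw.columns)
        if missing_src:
            raise ConfigurationError(
                f"mapped source columns absent from header: {sorted(missing_src)}"
            )
        raw = raw.rename(columns=column_map)
    missing = set(CANONICAL_COLUMNS) - set(raw.columns)
    if missing:
        raise ConfigurationError(f"mandatory columns missing: {sorted(missing)}")

    records: list[VariantAssociation] = []
    rejections: list[RowRejection] = []
    seen: set[str] = set()
    for i, row in enumerate(raw[list(CANONICAL_COLUMNS)].itertuples(index=False), start=1):
        result = _parse_row(dict(zip(CANONICAL_COLUMNS, row)), i)
        if isinstance(result, RowRejection):
            rejections.append(result)
        elif result.variant_id in seen:
            rejections.append(RowRejection(i, result.variant_id, "duplicate variant id"))
        else:
            seen.add(result.variant_id)
            records.append(result)
    return SummaryStatsTable(
        trait_label=trait_label,
        trait_scale=trait_scale,
        records=tuple(records),
        rejections=tuple(rejections),
    )


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write ``table`` in the canonical dialect.

    Floats are serialised with ``str`` (shortest round-trip form), so
    ``read_summary_stats(write_summary_stats(t))`` reproduces ``t``
    field-for-field.  A table with no records yields a header-only file.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in table.records:
            eaf = MISSING_TOKEN if r.eaf is None else str(r.eaf)
            fh.write(
                "\t".join(
                    (
                        r.variant_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        eaf,
                        str(r.beta),
                        str(r.se),
                        str(r.pval),
                        str(r.n),
                    )
                )
                + "\n"
            )
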