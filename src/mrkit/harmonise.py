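"""Harmonisation of exposure/outcome variant pairs onto a common
effect-allele orientation.

Two GWAS may report the same variant with the alleles in either order
and on either strand.  Harmonisation puts the outcome association on
the exposure's effect-allele orientation by (in order of preference)
direct allele match, allele swap (negating the outcome beta), strand
complementation, or — for palindromic A/T and C/G variants, where the
alleles alone cannot resolve the strand — allele-frequency agreement.
Palindromic variants whose frequency is missing or intermediate
(inside the ambiguity window, default [0.42, 0.58]) are excluded as
irrecoverably ambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .gwas_io import SummaryStatsTable, VariantAssociation

__all__ = [
    "HarmonisedInstrument",
    "HarmonisationResult",
    "complement_alleles",
    "is_palindromic",
    "harmonise_pair",
    "harmonise_tables",
    "DEFAULT_AMBIGUITY_WINDOW",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Palindromic variants with either allele frequency inside this closed
#: interval are excluded as strand-ambiguous.
DEFAULT_AMBIGUITY_WINDOW = (0.42, 0.58)


def complement_alleles(allele: str) -> str:
    """Watson–Crick complement of a single-base allele (A<->T, C<->G)."""
    try:
        return _COMPLEMENT[allele]
    except KeyError:
        raise ValueError(f"not a valid allele: {allele!r}") from None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (self-complementary)."""
    for a in (effect_allele, other_allele):
        if a not in _COMPLEMENT:
            raise ValueError(f"not a valid allele: {a!r}")
    return other_allele == _COMPLEMENT[effect_allele]


@dataclass(frozen=True)
class HarmonisedInstrument:
    """One exposure/outcome pair on the exposure's effect-allele orientation."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    n_exp: int
    n_out: int
    status: str = "kept"  # "kept" or "excluded"
    exclusion_reason: str = ""
    orientation_flipped: bool = False
    strand_complemented: bool = False

    @property
    def kept(self) -> bool:
        return self.status == "kept"


def _base_instrument(exp: VariantAssociation, out: VariantAssociation) -> HarmonisedInstrument:
    return HarmonisedInstrument(
        variant_id=exp.variant_id,
        chrom=exp.chrom,
        pos=exp.pos,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=out.beta,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=out.eaf,
        n_exp=exp.n,
        n_out=out.n,
    )


def _flipped(inst: HarmonisedInstrument) -> HarmonisedInstrument:
    eaf = None if inst.eaf_out is None else 1.0 - inst.eaf_out
    return replace(inst, beta_out=-inst.beta_out, eaf_out=eaf, orientation_flipped=True)


def harmonise_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    ambiguity_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW,
) -> HarmonisedInstrument:
    """Harmonise one exposure/outcome pair.

    The exposure orientation is the reference; only the outcome beta and
    frequency are ever flipped.  Palindromic pairs are resolved by
    frequency agreement (both EAFs on the same side of 0.5 keeps the
    orientation, opposite sides flips it) and excluded with reason
    ``"palindromic-ambiguous"`` when either frequency is missing or
    inside ``ambiguity_window``.  Non-palindromic pairs whose alleles
    cannot be reconciled by swap or strand complement are excluded with
    reason ``"allele-mismatch"``.
    """
    if exp.variant_id != out.variant_id:
        raise ValueError(
            f"variant id mismatch: {exp.variant_id!r} vs {out.variant_id!r}"
        )
    inst = _base_instrument(exp, out)
    exp_pair = (exp.effect_allele, exp.other_allele)
    out_pair = (out.effect_allele, out.other_allele)

    if is_palindromic(*exp_pair):
        # Alleles alone cannot fix the strand: a swap and a complement
        # look identical.  Only allele frequencies can disambiguate.
        if set(out_pair) != set(exp_pair):
            return replace(inst, status="excluded", exclusion_reason="allele-mismatch")
        lo, hi = ambiguity_window
        for eaf in (exp.eaf, out.eaf):
            if eaf is None or lo <= eaf <= hi:
                return replace(
                    inst, status="excluded", exclusion_reason="palindromic-ambiguous"
                )
        same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
        return inst if same_side else _flipped(inst)

    if out_pair == exp_pair:
        return inst
    if out_pair == exp_pair[::-1]:
        return _flipped(inst)
    comp_pair = (complement_alleles(out_pair[0]), complement_alleles(out_pair[1]))
    if comp_pair == exp_pair:
        return replace(inst, strand_complemented=True)
    if comp_pair == exp_pair[::-1]:
        return _flipped(replace(inst, strand_complemented=True))
    return replace(inst, status="excluded", exclusion_reason="allele-mismatch")


@dataclass(frozen=True)
class HarmonisationResult:
    """All exposure variants with their harmonisation status (audit log)."""

    instruments: tuple[HarmonisedInstrument, ...]

    @property
    def kept(self) -> tuple[HarmonisedInstrument, ...]:
        return tuple(i for i in self.instruments if i.kept)

    @property
    def counts(self) -> dict[str, int]:
        """Counts per outcome: ``kept`` plus one entry per exclusion reason."""
        c: Counter[str] = Counter()
        for i in self.instruments:
            c["kept" if i.kept else i.exclusion_reason] += 1
        return dict(c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "SNP": i.variant_id,
                    "status": i.status,
                    "reason": i.exclusion_reason,
                    "orientation_flipped": i.orientation_flipped,
                    "strand_complemented": i.strand_complemented,
                }
                for i in self.instruments
            ],
            columns=["SNP", "status", "reason", "orientation_flipped", "strand_complemented"],
        )

    def write_audit(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def harmonise_tables(
    exp: SummaryStatsTable,
    out: SummaryStatsTable,
    ambiguity_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW,
) -> HarmonisationResult:
    """Harmonise every exposure variant against the outcome table.

    One record is produced per exposure variant, in exposure order;
    variants absent from the outcome table are excluded with reason
    ``"not-in-outcome"``.  Matching is by variant id only.
    """
    out_by_id = {r.variant_id: r for r in out.records}
    instruments: list[HarmonisedInstrument] = []
    for e in exp.records:
        o = out_by_id.get(e.variant_id)
        if o is None:
            instruments.append(
                HarmonisedInstrument(
                    variant_id=e.variant_id,
                    chrom=e.chrom,
                    pos=e.pos,
                    effect_allele=e.effect_allele,
                    other_allele=e.other_allele,
                    beta_exp=e.beta,
                    se_exp=e.se,
                    beta_out=float("nan"),
                    se_out=float("nan"),
                    eaf_exp=e.eaf,
                    eaf_out=None,
                    n_exp=e.n,
                    n_out=0,
                    status="excluded",
                    exclusion_reason="not-in-outcome",
                )
            )
        else:
            instruments.append(harmonise_pair(e, o, ambiguity_window))
    return HarmonisationResult(tuple(instruments))
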