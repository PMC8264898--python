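"""Shared builders for summary-stats fixtures and instrument sets."""

from __future__ import annotations

import numpy as np
import pytest

from mrkit.gwas_io import SummaryStatsTable, VariantAssociation
from mrkit.harmonise import HarmonisedInstrument
from mrkit.instruments import LDMatrix


def make_variant(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-10,
    n=100_000,
) -> VariantAssociation:
    return VariantAssociation(
        variant_id=variant_id, chrom=chrom, pos=pos, effect_allele=ea,
        other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_table(records, label="trait", scale="continuous_sd") -> SummaryStatsTable:
    return SummaryStatsTable(label, scale, tuple(records))


def make_instruments(bx, sx, by, sy, n_exp=100_000, n_out=80_000):
    """Instrument set from effect/SE arrays; ids rs1..k, 1 Mb apart."""
    instruments = []
    for j, (b1, s1, b2, s2) in enumerate(zip(bx, sx, by, sy)):
        instruments.append(
            HarmonisedInstrument(
                variant_id=f"rs{j + 1}", chrom="1", pos=(j + 1) * 1_000_000,
                effect_allele="A", other_allele="G",
                beta_exp=float(b1), se_exp=float(s1),
                beta_out=float(b2), se_out=float(s2),
                eaf_exp=0.3, eaf_out=0.3, n_exp=n_exp, n_out=n_out,
            )
        )
    return tuple(instruments)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def instrument_factory():
    return make_instruments


def planted_pipeline_fixture():
    """Five-variant fixture where each pipeline stage removes exactly one.

    rs_weak fails genome-wide significance; rs_ld_b is clumped away by
    the stronger rs_ld_a 1 Mb upstream at r^2 = 0.9; rs_pal is an A/T
    palindrome at EAF 0.5; rs_rev explains more outcome than exposure
    variance (Steiger); rs_ld_a survives everything.
    Expected stage counts: 5, 4, 3, 2, 1.
    """
    exp = [
        make_variant("rs_weak", pos=1_000_000, beta=0.01, se=0.01, pval=0.5),
        make_variant("rs_ld_a", pos=10_000_000, beta=0.20, se=0.01, pval=1e-20),
        make_variant("rs_ld_b", pos=11_000_000, beta=0.18, se=0.01, pval=1e-10),
        make_variant("rs_pal", pos=40_000_000, ea="A", oa="T", eaf=0.5,
                     beta=0.15, se=0.01, pval=1e-15),
        make_variant("rs_rev", pos=60_000_000, beta=0.10, se=0.01, pval=1e-12,
                     n=10_000),
    ]
    out = [
        make_variant("rs_weak", pos=1_000_000, beta=0.001, se=0.01, pval=0.9,
                     n=80_000),
        make_variant("rs_ld_a", pos=10_000_000, beta=0.02, se=0.01, pval=0.05,
                     n=80_000),
        make_variant("rs_ld_b", pos=11_000_000, beta=0.02, se=0.01, pval=0.05,
                     n=80_000),
        make_variant("rs_pal", pos=40_000_000, ea="A", oa="T", eaf=0.5,
                     beta=0.02, se=0.01, pval=0.05, n=80_000),
        make_variant("rs_rev", pos=60_000_000, beta=5.0, se=0.1, pval=1e-30,
                     n=10_000),
    ]
    ids = tuple(v.variant_id for v in exp)
    r2 = np.eye(5)
    r2[1, 2] = r2[2, 1] = 0.9
    ld = LDMatrix(ids, r2)
    return make_table(exp, "exposure"), make_table(out, "outcome"), ld


@pytest.fixture
def pipeline_fixture():
    return planted_pipeline_fixture()
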