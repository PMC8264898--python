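"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the two-sample design: per variant j a true
SNP-exposure effect gamma_j ~ N(0, sd^2) and a direct (pleiotropic)
SNP-outcome effect alpha_j combine into the true SNP-outcome effect
Gamma_j = theta * gamma_j + alpha_j, where theta is the causal effect
of one SD of exposure.  Observed betas are the truths plus independent
sampling noise in each sample (no overlap), with standard errors from
the standardised-genotype formula se = 1/sqrt(2*maf*(1-maf)*n) for a
continuous trait, and 1/sqrt(2*maf*(1-maf)*n*cf*(1-cf)) on the
log-odds scale for a case-control trait with case fraction cf.

Directional pleiotropy (nonzero ``pleiotropy_mean``) is defined
relative to the exposure-increasing allele: the stored alpha_j is
sign(gamma_j) times a N(mu, sigma^2) draw, so the MR-Egger intercept
(computed after beta_x >= 0 orientation) targets mu.  Setting
``inside_violation`` correlates the pleiotropy with instrument
strength |gamma_j|, breaking the InSIDE assumption.

LD is simulated at summary level: variants in a block share their true
gamma and their observed betas are correlated at the block r^2; blocks
are placed far apart so clumping at the default 10 000 kb window keeps
exactly one index variant per block.

All randomness derives from the single config seed through named
:class:`numpy.random.SeedSequence` child streams, so per-component
draws are reproducible independent of evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .gwas_io import SummaryStatsTable, VariantAssociation, write_summary_stats
from .harmonise import HarmonisedInstrument
from .instruments import LDMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_two_sample",
    "scenario_preset",
    "to_instruments",
    "replicate_instruments",
    "write_bundle",
    "SCENARIOS",
    "AD_CASES",
    "AD_CONTROLS",
]

# Case-control make-up of the Alzheimer's outcome GWAS the generator
# mirrors: 24 807 cases, 55 058 controls.
AD_CASES = 24_807
AD_CONTROLS = 55_058

_NONPAL_PAIRS = (("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                 ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"))
_PAL_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


class SimulationConfig(BaseModel, frozen=True):
    """Generative parameters for one paired exposure/outcome dataset."""

    n_snps: int = Field(default=100, gt=0)
    theta: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_effect_sd: float = Field(default=0.03, gt=0)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = Field(default=0.0, ge=0)
    inside_violation: bool = False
    inside_correlation: float = Field(default=0.5, ge=-1, le=1)
    n_exposure: int = Field(default=400_000, gt=2)
    n_outcome: int = Field(default=AD_CASES + AD_CONTROLS, gt=2)
    outcome_scale: Literal["continuous_sd", "log_odds"] = "log_odds"
    case_fraction: float = AD_CASES / (AD_CASES + AD_CONTROLS)
    ld_blocks: Optional[tuple[tuple[int, float], ...]] = None
    palindrome_fraction: float = Field(default=0.0, ge=0, le=1)
    seed: int

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo < hi <= 0.5, got {self.maf_range}")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError(f"case_fraction must be in (0, 1), got {self.case_fraction}")
        if self.ld_blocks is not None:
            for size, r2 in self.ld_blocks:
                if size < 1 or not 0.0 <= r2 <= 1.0:
                    raise ValueError(f"invalid LD block ({size}, {r2})")
            if sum(s for s, _ in self.ld_blocks) > self.n_snps:
                raise ValueError("LD blocks contain more variants than n_snps")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """True per-variant effects underlying one simulated dataset."""

    variant_ids: tuple[str, ...]
    gamma: np.ndarray       # true SNP-exposure effects
    alpha: np.ndarray       # true direct (pleiotropic) SNP-outcome effects
    big_gamma: np.ndarray   # theta*gamma + alpha, exact by construction
    theta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": list(self.variant_ids),
                "gamma": self.gamma,
                "alpha": self.alpha,
                "big_gamma": self.big_gamma,
                "theta": self.theta,
            }
        )


def _groups(config: SimulationConfig):
    """Partition variant indices into LD blocks (+ independent singles)."""
    groups: list[tuple[list[int], float]] = []
    idx = 0
    if config.ld_blocks:
        for size, r2 in config.ld_blocks:
            groups.append((list(range(idx, idx + size)), r2))
            idx += size
    for j in range(idx, config.n_snps):
        groups.append(([j], 0.0))
    return groups


def _correlated_noise(rng, m: int, rho: float) -> np.ndarray:
    if m == 1 or rho == 0.0:
        return rng.standard_normal(m)
    cov = np.full((m, m), rho) + (1.0 - rho) * np.eye(m)
    return np.linalg.cholesky(cov) @ rng.standard_normal(m)


def simulate_two_sample(config: SimulationConfig):
    """Generate one paired dataset.

    Returns ``(exposure_table, outcome_table, ground_truth, ld_matrix)``.
    The two tables share variant ids, positions and alleles (effect
    allele coded identically), with independent sampling noise.
    """
    n = config.n_snps
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_maf, rng_gamma, rng_alpha, rng_x, rng_y, rng_alleles = (
        np.random.default_rng(s) for s in streams
    )

    maf = rng_maf.uniform(*config.maf_range, size=n)
    groups = _groups(config)

    gamma = np.empty(n)
    for members, _ in groups:
        gamma[members] = rng_gamma.normal(0.0, config.instrument_effect_sd)

    eps = rng_alpha.standard_normal(n)
    if config.inside_violation and n > 1:
        strength = np.abs(gamma)
        sd_strength = strength.std()
        z = (strength - strength.mean()) / sd_strength if sd_strength > 0 else np.zeros(n)
        rho = config.inside_correlation
        shock = rho * z + np.sqrt(1.0 - rho**2) * eps
    else:
        shock = eps
    alpha_raw = config.pleiotropy_mean + config.pleiotropy_sd * shock
    alpha = np.where(gamma < 0, -alpha_raw, alpha_raw)
    big_gamma = config.theta * gamma + alpha

    geno_var = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(geno_var * config.n_exposure)
    if config.outcome_scale == "log_odds":
        cf = config.case_fraction
        se_y = 1.0 / np.sqrt(geno_var * config.n_outcome * cf * (1.0 - cf))
    else:
        se_y = 1.0 / np.sqrt(geno_var * config.n_outcome)

    noise_x, noise_y = np.empty(n), np.empty(n)
    for members, r2 in groups:
        noise_x[members] = _correlated_noise(rng_x, len(members), r2)
        noise_y[members] = _correlated_noise(rng_y, len(members), r2)
    beta_x = gamma + se_x * noise_x
    beta_y = big_gamma + se_y * noise_y

    tiny = np.finfo(float).tiny
    p_x = np.clip(2.0 * stats.norm.sf(np.abs(beta_x / se_x)), tiny, 1.0)
    p_y = np.clip(2.0 * stats.norm.sf(np.abs(beta_y / se_y)), tiny, 1.0)

    pal = rng_alleles.random(n) < config.palindrome_fraction
    pair_idx = rng_alleles.integers(0, 8, size=n)
    alleles = [
        _PAL_PAIRS[pair_idx[j] % 4] if pal[j] else _NONPAL_PAIRS[pair_idx[j]]
        for j in range(n)
    ]

    # positions: members of a block sit 1 kb apart; successive groups sit
    # 20 Mb apart (outside the default 10 000 kb clumping window)
    pos = np.empty(n, dtype=int)
    cursor = 1_000_000
    for members, _ in groups:
        for offset, j in enumerate(members):
            pos[j] = cursor + offset * 1_000
        cursor += 20_000_000

    ids = tuple(f"rs{j + 1}" for j in range(n))

    def _table(beta, se, p, n_sample, label, scale) -> SummaryStatsTable:
        records = tuple(
            VariantAssociation(
                variant_id=ids[j],
                chrom="1",
                pos=int(pos[j]),
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                eaf=float(maf[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(p[j]),
                n=n_sample,
            )
            for j in range(n)
        )
        return SummaryStatsTable(label, scale, records)

    exp_table = _table(beta_x, se_x, p_x, config.n_exposure,
                       "simulated_exposure", "continuous_sd")
    out_table = _table(beta_y, se_y, p_y, config.n_outcome,
                       "simulated_outcome", config.outcome_scale)

    r2 = np.eye(n)
    for members, block_r2 in groups:
        for a in members:
            for b in members:
                if a != b:
                    r2[a, b] = block_r2
    ld = LDMatrix(ids, r2)
    truth = GroundTruth(ids, gamma, alpha, big_gamma, config.theta)
    return exp_table, out_table, truth, ld


def to_instruments(
    exp: SummaryStatsTable, out: SummaryStatsTable
) -> tuple[HarmonisedInstrument, ...]:
    """Pair two identically-coded tables directly into kept instruments.

    Fast path for simulation studies where both tables come from
    :func:`simulate_two_sample` (shared ids, alleles and orientation);
    real data should go through :func:`mrkit.harmonise.harmonise_tables`.
    """
    out_by_id = {r.variant_id: r for r in out.records}
    instruments = []
    for e in exp.records:
        o = out_by_id[e.variant_id]
        instruments.append(
            HarmonisedInstrument(
                variant_id=e.variant_id,
                chrom=e.chrom,
                pos=e.pos,
                effect_allele=e.effect_allele,
                other_allele=e.other_allele,
                beta_exp=e.beta,
                se_exp=e.se,
                beta_out=o.beta,
                se_out=o.se,
                eaf_exp=e.eaf,
                eaf_out=o.eaf,
                n_exp=e.n,
                n_out=o.n,
            )
        )
    return tuple(instruments)


def replicate_instruments(
    config: SimulationConfig,
    n_replicates: int,
    seed: int,
    significance_threshold: float | None = None,
):
    """Yield instrument sets for ``n_replicates`` independent datasets.

    Replicate seeds derive from ``seed`` via a SeedSequence, independent
    of ``config.seed``.  When ``significance_threshold`` is given, each
    replicate's exposure table passes through genome-wide-significance
    selection before pairing — mirroring real analyses, where the
    instruments are significant GWAS hits by construction.
    """
    from .instruments import select_significant

    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    for s in child_seeds:
        cfg = config.model_copy(update={"seed": int(s)})
        exp, out, _, _ = simulate_two_sample(cfg)
        if significance_threshold is not None:
            exp = select_significant(exp, significance_threshold)
        yield to_instruments(exp, out)


def _preset_params(name: str) -> dict:
    base = dict(
        n_snps=100,
        instrument_effect_sd=0.03,
        n_exposure=400_000,
        n_outcome=AD_CASES + AD_CONTROLS,
        outcome_scale="log_odds",
        case_fraction=AD_CASES / (AD_CASES + AD_CONTROLS),
    )
    presets = {
        "null": dict(theta=0.0),
        "causal": dict(theta=0.3),
        "balanced_pleiotropy": dict(theta=0.3, pleiotropy_mean=0.0, pleiotropy_sd=0.005),
        "directional_pleiotropy": dict(theta=0.3, pleiotropy_mean=0.003,
                                       pleiotropy_sd=0.002, inside_violation=False),
        # effect spread calibrated so the mean instrument F sits near 10
        "weak_instruments": dict(theta=0.3, instrument_effect_sd=0.008),
        "binary_outcome": dict(theta=0.3),
        "ld_structured": dict(theta=0.3, ld_blocks=tuple(((5, 0.9),) * 10)),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(presets)}")
    return {**base, **presets[name]}


SCENARIOS = ("null", "causal", "balanced_pleiotropy", "directional_pleiotropy",
             "weak_instruments", "binary_outcome", "ld_structured")


def scenario_preset(name: str, seed: int = 20210707) -> SimulationConfig:
    """Fully-specified :class:`SimulationConfig` for a named scenario.

    Scenarios instantiate the textbook instrumental-variable settings:
    ``null`` (no causal effect, no pleiotropy), ``causal`` (theta = 0.3,
    strong instruments, AD-sized case-control outcome),
    ``balanced_pleiotropy`` (zero-mean direct effects),
    ``directional_pleiotropy`` (mean direct effect 0.003 with InSIDE
    holding), ``weak_instruments`` (mean F near 10), ``binary_outcome``
    (explicit ~25k/55k case-control outcome) and ``ld_structured``
    (ten 5-variant blocks at within-block r^2 = 0.9).
    """
    return SimulationConfig(seed=seed, **_preset_params(name))


def write_bundle(config: SimulationConfig, outdir, scenario: str | None = None) -> dict:
    """Write exposure/outcome/ground-truth/LD files plus a manifest.

    Returns the manifest dict.  Identical configs produce byte-identical
    bundles (no timestamps are recorded).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp, out, truth, ld = simulate_two_sample(config)
    write_summary_stats(exp, outdir / "exposure.tsv")
    write_summary_stats(out, outdir / "outcome.tsv")
    truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    ld.to_tsv(outdir / "ld_matrix.tsv")
    manifest = {
        "scenario": scenario,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "files": ["exposure.tsv", "outcome.tsv", "ground_truth.tsv", "ld_matrix.tsv"],
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
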