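# Methods

`mrkit` implements two-sample Mendelian randomisation (MR) at the
summary-statistic level: genetic variants strongly associated with an
exposure serve as instrumental variables for the causal effect of that
exposure on an outcome measured in a second, non-overlapping sample.
This note records the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Model and notation

For variant *j*, let β̂_xj (SE s_xj) be its association with the
exposure (per SD of a continuous trait) and β̂_yj (SE s_yj) its
association with the outcome (log-odds for a case-control trait).
Under the instrumental-variable assumptions the true associations obey
Γ_j = θ γ_j + α_j, where θ is the causal effect per SD of exposure,
γ_j the true SNP-exposure effect, and α_j any direct (horizontally
pleiotropic) effect of the variant on the outcome.  Valid instruments
have α_j = 0.

### Estimators

* **Wald ratio** — θ̂_j = β̂_yj/β̂_xj with first-order delta-method SE
  s_yj/|β̂_xj|.  First-order (rather than second-order) SEs are used
  throughout; with the strong instruments this package targets
  (F ≳ 10) the neglected term is O(1/F) relative.
* **IVW** — the zero-intercept weighted regression of β̂_y on β̂_x with
  weights 1/s_y²; equivalently the inverse-variance-weighted mean of
  the Wald ratios.  Default SE policy is *multiplicative random
  effects*: the fixed-effect SE is inflated by max(1, √(Q/(k−1))), so
  under-dispersion never shrinks the SE below the fixed-effect value.
  A fixed-effect option is exposed.  Inference is normal.
* **MR-Egger** — the same regression with a free intercept, after
  orienting every instrument so β̂_x ≥ 0 (both betas negated where
  needed).  The slope estimates θ under the InSIDE assumption
  (pleiotropy uncorrelated with instrument strength); the intercept
  estimates the average directional pleiotropy on the
  exposure-increasing orientation.  The coefficient covariance is
  scaled by the weighted residual mean square bounded below by 1, and
  inference uses t with k−2 df — the appropriate small-k reference for
  a two-parameter weighted fit.
* **Weighted median** — ratio estimates sorted ascending; with
  normalised mid-cumulative weights s_j = (Σ_{i≤j} w_i − w_j/2)/Σw the
  estimate interpolates θ linearly in s at 0.5.  Consistent when ≥ 50%
  of weight comes from valid instruments.
* **Weighted mode** (mode-based estimate) — argmax of a weighted
  normal-kernel density of the ratio estimates with bandwidth
  h = φ · 0.9 · min(sd θ, IQR θ/1.34) · k^(−1/5) (φ a tunable factor,
  default 1), evaluated on a fixed 10 000-point grid spanning
  [min θ − 3h, max θ + 3h].  The fixed grid makes the estimate
  deterministic.  Degenerate spreads fall back: identical ratios
  return the common value; a zero IQR with nonzero sd uses the sd.

Median and mode SEs come from a parametric bootstrap (default 1000
replicates, explicit seed): both betas are resampled from normals at
their observed values and SEs, the point estimate recomputed, and the
SD over replicates taken.  Confidence intervals are two-sided 95%
throughout; odds-ratio columns are the exact exp transform of the
log-scale estimate and CI.

### Diagnostics

Cochran's Q about the pooled estimate uses the IVW first-order weights
β̂_x²/s_y², df = k−1, upper-tail chi-square p.  The Egger intercept
test reports (intercept, SE, two-sided t(k−2) p).  Leave-one-out
recomputes IVW on every size-(k−1) subset; the single-SNP series is
the per-variant Wald ratios plus a pooled IVW row; funnel coordinates
are (θ̂_j, 1/se(θ̂_j)).  The funnel y-axis is precision (1/SE), the
convention that produces the funnel shape; the export carries both the
SE and precision columns.

## Instrument pipeline

Stages run in a fixed order with counts reported at every stage:

1. **Significance** — retain p strictly below the threshold (default
   5×10⁻⁸; a stricter 5×10⁻⁹ is appropriate where the source GWAS used
   it).
2. **LD clumping** — greedy: accept the smallest-p remaining variant
   (ties broken by chromosome then position, for determinism), discard
   all others on the same chromosome within the window (default
   10 000 kb) with r² at or above the threshold (default 0.001),
   repeat.  Clumping operates on a user-supplied r² matrix; variants
   absent from it are treated as independent with a warning, since no
   offline substitute for a population reference panel exists.
3. **Harmonisation** — outcome associations are placed on the
   exposure's effect-allele orientation by direct match, allele swap
   (negating β̂_y), or strand complementation.  Palindromic (A/T, C/G)
   variants cannot be resolved from alleles alone: they are aligned by
   allele-frequency agreement when both frequencies are available and
   outside the ambiguity window (default [0.42, 0.58], closed), and
   otherwise excluded.  Frequency-based rescue of non-intermediate
   palindromes is attempted rather than dropping all palindromes,
   because only intermediate frequencies are truly ambiguous.
   Matching is by variant identifier only.
4. **Steiger filtering** — per variant, the trait variance explained
   is r² = t²/(t² + n − 2) with t = β̂/SE; a variant is kept iff
   r²_exposure > r²_outcome.  The same formula is applied on the
   reported scale for continuous and binary traits; for binary traits
   this is an approximation (the log-odds scale has no exact variance-
   explained decomposition), acceptable because the statistic is used
   only as a directional screen.  The comparison is strict, with no
   significance test — the conservative reading of "remove variants
   that explain more outcome than exposure variance".

Instrument strength is summarised by F = β̂²/SE² per variant and its
arithmetic mean over the surviving set.

## Synthetic data generator

The generator emulates paired two-sample GWAS output, not individual-
level data.  Per variant: MAF ~ U(maf_range); γ_j ~ N(0, σ_γ²);
α_j ~ N(μ_α, σ_α²) *on the exposure-increasing orientation* (the
stored α_j is sign(γ_j) times the draw, so Γ_j = θγ_j + α_j holds
exactly while a nonzero μ_α survives MR-Egger's β̂_x ≥ 0 orientation —
defining directional pleiotropy relative to random allele coding would
annihilate it).  SEs follow the standardised-genotype formulas above;
observed betas add independent N(0, SE²) noise in each sample (the
two-sample, no-overlap design).  P-values are two-sided normal.
Setting `inside_violation` correlates α_j with |γ_j| (default
correlation 0.5), breaking InSIDE.  LD blocks share one true γ and
correlate the observed noise at the block r²; blocks sit 20 Mb apart
(outside the default clumping window) with members 1 kb apart, and the
emitted r² matrix is block-diagonal.  All draws flow from one seed
through named SeedSequence child streams, so outputs are bit-identical
across runs and independent of evaluation order.

What the generator does **not** emulate: realistic human LD maps and
allele-frequency spectra, winner's-curse correlation between discovery
and reported effect sizes, population stratification, sample overlap,
or selection/survivor bias.  Passing the synthetic checks therefore
demonstrates correctness of the estimators and filters under the
stated generative model, not robustness to those additional features
of real data.

### Scenario presets and study conditions

All presets use 100 candidate SNPs, MAF ∈ (0.05, 0.5), exposure
n = 400 000 (the scale of the largest lung-function GWAS), and a
case-control outcome of 24 807 cases / 55 058 controls (the scale of
the Alzheimer's meta-analysis), giving mean instrument F ≈ 135 at the
default effect spread σ_γ = 0.03 — matching the mean-F magnitudes
(~114) reported for real lung-function instruments.

| scenario | θ | μ_α | σ_α | notes |
|---|---|---|---|---|
| null | 0 | 0 | 0 | type-I-error calibration |
| causal | 0.3 | 0 | 0 | parameter recovery, CI coverage |
| balanced_pleiotropy | 0.3 | 0 | 0.005 | intercept centred at zero |
| directional_pleiotropy | 0.3 | 0.003 | 0.002 | InSIDE holds |
| weak_instruments | 0.3 | 0 | 0 | σ_γ = 0.008, mean F ≈ 10 |
| binary_outcome | 0.3 | 0 | 0 | explicit case-control framing |
| ld_structured | 0.3 | 0 | 0 | ten 5-variant blocks, r² = 0.9 |

`causal` and `binary_outcome` share their generative numbers: the
headline recovery scenario is already the case-control design, and the
separate name is kept for discoverability of the binary-trait SE
formula.

Validation analyses (the calibration tests and `scripts/acceptance.py`)
select genome-wide-significant instruments (p < 5×10⁻⁸) from each
replicate before estimation, mirroring real analyses where instruments
are significant GWAS hits by construction.  This matters for MR-Egger:
near-zero-effect variants are occasionally mis-oriented by the
β̂_x ≥ 0 rule (the observed sign disagrees with the true one), which
attenuates the intercept by roughly 15% when all 100 candidates are
used; restricting to significant instruments removes those variants
and the attenuation with them.  Replicate counts are 200 for mean-bias
checks and 500 for coverage/type-I-error checks, which puts the
Monte-Carlo SE of each reported mean well inside the bound it is
checked against.

## Numerical and design choices

* Reported p-values are clipped below at the smallest positive normal
  double, keeping the (0, 1] invariant under severe z-scores.
* Clumping tie-breaks (equal p) go to the smaller (chromosome,
  position) — determinism over arbitrariness.
* The ambiguity window is closed ([0.42, 0.58] includes its
  endpoints): a frequency exactly at the boundary is treated as
  ambiguous.
* IVW with a single instrument short-circuits to the Wald ratio so the
  reduction identity holds exactly in floating point.
* With fewer than three instruments, Egger/median/mode are skipped
  with a logged notice; per-SNP Wald ratios are emitted alongside IVW.
* Zero exposure effects make ratio estimates undefined and raise a
  domain error; upstream significance filtering makes them unreachable
  in normal use.
* Manifests record config, seed and package version but no
  timestamps, so identical runs are byte-identical.

## Known limitations

* Clumping quality is bounded by the supplied LD matrix; there is no
  reference-panel lookup or proxy-SNP search for instruments missing
  from the outcome study.
* The Steiger screen ignores estimation uncertainty in the two r²
  values (an optional Z-test variant is deliberately not the default,
  matching the simple directional rule).
* The binary-trait effective-sample-size treatment enters only through
  the SE formula; liability-scale conversion of estimates is out of
  scope.
* MR-PRESSO, multivariable MR and contamination-mixture estimators are
  out of scope.
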