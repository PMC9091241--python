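# Methods

## Model

The package works entirely with GWAS summary statistics. For variant j,
exposure X and outcome Y, the two-sample design supplies independent
estimates γ̂ⱼ ~ N(γⱼ, se²ₓⱼ) and Γ̂ⱼ ~ N(Γⱼ, se²ᵧⱼ). Under the three classical
IV assumptions (relevance, exchangeability, exclusion restriction) the
structural relation is Γⱼ = β γⱼ, with β the causal effect of one SD of X
on Y (log odds ratio when Y is binary). Horizontal pleiotropy enters as a
direct effect αⱼ: Γⱼ = β γⱼ + αⱼ. IVW is consistent when all αⱼ = 0;
MR-Egger's slope stays consistent under InSIDE (αⱼ independent of γⱼ) with
its intercept estimating the mean direct effect; the weighted median is
consistent while under half the weight lies on invalid instruments.

## Estimator details and numerical choices

- **IVW**: weighted regression through the origin with wⱼ = se⁻²ᵧⱼ.
  Default SE model is multiplicative-random: se × max(1, √(Q/(J−1))),
  never narrower than fixed-effect. CI and p are Gaussian (1.96).
- **MR-Egger**: instruments first oriented so γ̂ⱼ ≥ 0 (both betas negated),
  which the intercept needs for identifiability; weighted regression with
  intercept; covariance scaled by max(1, weighted residual variance /
  (J−2)); t(J−2) p-values and CI. Requires J ≥ 3.
- **Medians**: Wald ratios ordered, cumulative mid-weights
  pⱼ = (Sⱼ − wⱼ/2)/S_J, linear interpolation at p = 0.5 (clamped at the
  extremes). Simple weighting wⱼ = 1/J; inverse-variance weighting
  wⱼ ∝ (γ̂ⱼ/seᵧⱼ)². SE is a parametric bootstrap (default 1000 draws,
  explicit seed): resample γ̂ⱼ*, Γ̂ⱼ* from Normal(observed, se²), recompute,
  take the SD. A degenerate all-identical bootstrap is floored at 1e-12.
- **MVMR**: weighted regression of Γ̂ on the J×K exposure-effect matrix,
  no intercept, SE floor and t(J−K) inference as for Egger; hard errors on
  J ≤ K and on rank-deficient exposure matrices. K = 1 reproduces IVW
  (multiplicative-random) exactly.
- **Wald SEs** are first-order (|seᵧ/γ̂|) throughout; no second-order term.
- **Harmonization**: matching is by variant id in rsID space; alleles are
  uppercased on read and only single-base alleles are accepted. Swapped
  allele labels negate the outcome beta and reflect its frequency;
  strand-complement labels are accepted as-is. Palindromic (A/T, G/C)
  variants are kept only when both effect-allele frequencies fall on the
  same side of 0.5 and both minor-allele frequencies are below 0.42
  (configurable); they are dropped when a frequency is missing or 0.5.
  Drops are recorded per variant, never raised.
- **Selection**: strict inequalities exactly as conventionally printed —
  significance p < 5e-8, proxy r² > 0.9; clumping discards at r² ≥ 0.01 so
  retained sets satisfy r² < 0.01 pairwise. Greedy clumping sorts by
  (p, variant id) — lexicographic tie-break for determinism — and is
  invariant to input order. Instrument-strength diagnostics use per-SNP n
  where the exposure table provides it, with the per-exposure maximum as
  fallback.
- **Classification**: the family threshold is α/m for m exposures (one
  outcome family). Verdicts: significant iff p < α/m, suggestive iff
  α/m ≤ p < α, else null. The primary p is always IVW; sensitivity
  estimators are reported alongside but never decide the verdict.
- **Leave-one-out** refits IVW (same SE model as the main analysis) with
  each instrument removed and flags variants whose exclusion moves the
  association from p < threshold to p ≥ threshold — the signature of a
  result driven by a single variant.
- Summed instrument r² is clamped just below 1 with a warning: the
  additive rule is only meaningful for near-independent, post-clumping
  instruments.

## The synthetic generator

`simulate_two_sample` draws, per SNP: maf fⱼ ~ U(0.05, 0.45);
γⱼ ~ N(0, γ_sd²); αⱼ = 0 for valid SNPs and sign(γⱼ)·N(μ_α, σ_α²) for the
invalid fraction — direct effects are stated relative to the
exposure-increasing allele, so μ_α ≠ 0 is genuinely directional
(a constant-sign αⱼ with symmetric γⱼ would cancel out of IVW's
Σwγ̂α term and be indistinguishable from balanced pleiotropy). Observed
effects add independent noise with seₓⱼ = (2nₓfⱼ(1−fⱼ))^(−1/2) and, for a
binary outcome with case fraction φ, seᵧⱼ = (2nᵧfⱼ(1−fⱼ)φ(1−φ))^(−1/2) —
log-odds effects generated directly at the summary level, no
individual-level sampling. Exposure and outcome noise are independent
(non-overlapping samples). No significance selection happens at
generation, so winner's curse enters only through the explicit selection
stage and can be measured.

Defaults: γ_sd = 0.15 with nₓ = 1e5 puts per-SNP instrument F in the
hundreds — the strong-instrument regime that post-selection MR instruments
occupy; the study fixture instead uses γ_sd = 0.05 and performs real
p < 5e-8 selection, which yields comparable per-instrument strength by
construction.

LD panels are simulated per block: two latent AR(1)-Gaussian haplotypes
(correlation ρ^|i−j|) thresholded at each variant's maf and summed to
Hardy–Weinberg dosages; r² is the squared empirical dosage correlation of
a reference sample (default 2000). Thresholding attenuates the latent
correlation — a ρ = 0.99 pair yields dosage r² ≈ 0.8 — so the study
fixture uses ρ = 0.999 (r² ≈ 0.93) for its tight pairs, comfortably above
the 0.9 proxy threshold. Variants within a correlated block share one maf;
mismatched thresholds would otherwise attenuate r² further. Blocks are
independent, so cross-block r² is exactly zero in the panel.

The 51-exposure study fixture emulates a many-risk-factor disease study:
each exposure has 45 SNPs (10 tight pairs + 25 singletons), its own
continuous GWAS of 100,000 samples, and a shared binary outcome GWAS of
10,754 cases and 306,882 controls (case fraction 0.0339). True causal
effects cycle through positive, negative and null values. Two instrument
SNPs per exposure are withheld from the outcome table to force proxy
lookups, and a small cross-trait table marks multi-trait SNPs for the
sensitivity rerun.

What the generator does **not** emulate: allele-frequency divergence
between ancestries, sample overlap between the two GWAS, winner's curse at
the source GWAS (selection and estimation in the same sample),
LD-induced correlation between the summary statistics themselves, and
individual-level genotype→phenotype mechanisms. Passing calibration here
therefore demonstrates correctness of the estimators and pipeline under
the stated model, not robustness to those real-data pathologies.

## Calibration studies

`mrkit.calibration` measures, over seeded replicate datasets: CI coverage
and bias per estimator (valid instruments, J = 50 fixed); Egger intercept
consistency and the Egger-vs-IVW bias comparison under directional
pleiotropy; the intercept test's empirical size under balanced pleiotropy;
and weighted-median vs IVW bias at 40% invalid instruments. The
pleiotropy studies pre-filter instruments at genome-wide significance with
the package's own selection rule — the procedure any such study applies —
because an unselected instrument whose exposure association is consistent
with zero gets mis-oriented and smears the directional signal (the
intercept attenuates by a few percent otherwise). The coverage study
deliberately skips selection to keep J fixed and measure pure estimator
calibration.

Two measured calibration facts worth knowing:

- IVW carries a small regression-dilution bias of order
  J·se²ₓ/Σγ̂² (≈ 0.3% of β at the default settings) because
  E[γ̂²] = γ² + se²ₓ and the generator does not select; it is real,
  reproducible, and visible once Monte-Carlo error drops below it.
- The parametric bootstrap SE for medians is conservative (≈ 15% high at
  the default settings — bootstrap draws carry twice the noise of the
  originals around the truth), so median coverage runs ≈ 97–98% rather
  than 95%.

## Problem sizes

Test-suite and reproduction-script studies use 500–1000 replicates, J of
50–100 instruments, and a 12–51-exposure fixture; the full suite and the
reproduction script each complete in about a minute on one CPU.

## Known limitations

No distance-windowed clumping (r² only, as the panel is block-structured);
no VCF input, liftover, or multi-allelic sites; no MR-PRESSO/mode-based/
Steiger-type estimators; forest plots are tabular only. MVMR expects the
caller (or pipeline) to supply instruments shared across exposures —
exposures with disjoint SNP sets skip the joint analysis with a log note.
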