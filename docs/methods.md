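# Methods

## The causal model

Two-sample Mendelian randomization (MR) estimates the effect of an exposure
(here: the genetically proxied relative abundance of a gut-microbiota
taxon) on an outcome (childhood neuroblastoma risk, on the log-odds scale)
using genetic variants as instrumental variables, with the variant–exposure
and variant–outcome associations measured in two non-overlapping GWAS
samples. For instrument *j* with exposure effect β̂_xj (SE σ_xj) and outcome
effect β̂_yj (SE σ_yj), the per-SNP Wald ratio is

    b_j = β̂_yj / β̂_xj ,   se_j = σ_yj / |β̂_xj| ,

the first-order delta-method SE that ignores exposure-side uncertainty.
This is deliberate: it is the convention under which the published per-SNP
table recombines exactly into the published headline estimate, and it is
the dominant convention in summary-data MR software. Its known cost is a
slightly anti-conservative SE when instruments are weak (no second-order
correction, no NOME adjustment).

An instrument is valid if it is (1) associated with the exposure,
(2) independent of confounders, and (3) affects the outcome only through
the exposure. The four estimators trade efficiency against robustness to
violations of (3):

* **IVW** — weighted mean of Wald ratios, w_j = 1/se_j²:
  b = Σw_j b_j / Σw_j. Fixed-effect SE (Σw_j)^(−1/2); the default
  *multiplicative random-effects* mode scales it by √max(1, Q/(k−1)), which
  reduces to fixed-effect exactly when Cochran's Q ≤ k−1 (true of the
  five-SNP worked example, so both modes reproduce the published row).
  p-values are two-sided normal.
* **MR-Egger** — weighted regression β̂_yj = a + b·β̂_xj with weights
  1/σ_yj², pairs oriented so β̂_xj ≥ 0. The slope is consistent under
  InSIDE; the intercept a estimates mean directional pleiotropy. SEs carry
  a residual dispersion factor max(1, σ̂²); p-values use t with k−2 df.
* **Weighted median** — with ratios sorted ascending and standardized
  cumulative weights p_j = (S_j − w_j/2)/S_k, the estimate interpolates b
  at p = 0.5; consistent while valid instruments hold > 50% of total
  weight. SE by seeded parametric bootstrap (b_j* ~ N(b_j, se_j), weights
  fixed), default 5000 replicates.
* **Weighted mode** — maximizer of the weighted Gaussian kernel density
  over the ratios. Bandwidth = factor × 0.9·min(weighted SD, weighted
  MAD·1.4826)·k^(−1/5) (modified Silverman); the maximizer is located on a
  512-point grid spanning the ratio range ± 3 bandwidths and refined by
  golden-section search. If all ratios coincide the estimate is that common
  value. SE by seeded parametric bootstrap with the bandwidth recomputed
  per replicate.

All 95% odds-ratio intervals use exp(b ± 1.959964·se) — the full-precision
normal quantile, which is what reproduces the published CI bounds at three
decimals.

## Instrument selection

Variants pass a p < 1e-5 exposure-association filter (strict inequality),
then greedy LD clumping: repeatedly retain the smallest-p unprocessed
variant and discard unprocessed variants on the same chromosome within
10,000 kb whose r² with it is ≥ 0.001. Ties on p are broken by chromosome,
position, then variant id, making the output invariant to input row order.
A variant absent from the LD matrix is an error, never silently assumed
independent. The LD matrix is an input (tab-separated square matrix);
computing LD from genotype panels is out of scope.

## Harmonization

The outcome table is aligned to the exposure sample's effect allele:
order swaps negate β and reflect the allele frequency; non-palindromic
allele pairs that match only after complementing are treated as strand
flips and re-checked. Palindromic variants (A/T, C/G) cannot be oriented
from allele labels; they are kept only when both effect-allele frequencies
are present and lie outside [0.5−w, 0.5+w] (default w = 0.08), with the
effect flipped when the frequencies sit on opposite sides of 0.5. Anything
else — ambiguous frequency, missing frequency, irreconcilable alleles,
one-sided variants — is dropped with an explicit per-variant reason.
A `palindromic_mode="drop"` policy discards all palindromic variants
unconditionally, since published pipelines differ on this point.

## Sensitivity diagnostics

Cochran's Q = Σw_j (b_j − b_IVW)² against the *fixed-effect* IVW estimate,
referred to χ²(k−1); leave-one-out recomputes fixed-effect IVW on each
(k−1)-subset (fixed-effect regardless of the headline mode, so subsets are
compared on one footing); single-SNP and funnel tables are emitted as data
(plot rendering is a thin optional layer over them).

A note on the five-SNP worked example: the published per-SNP table is
titled as a leave-one-out analysis, but its rows are numerically
single-SNP Wald ratios — their inverse-variance combination reproduces the
published combined estimate exactly, and their SEs (~0.82–0.91) have
single-SNP, not four-SNP, precision. The package implements both analyses
and labels them correctly; the fixture is treated as single-SNP estimates.

## The synthetic-data generator

`simulate_pair` emulates a paired summary-statistics extract with known
truth. Choices and what they emulate:

* **Sample sizes** default to 18,340 (exposure; the scale of the 16S
  microbiome GWAS meta-analysis) and 4,881 (outcome; 1627 cases + 3254
  controls of the neuroblastoma GWAS).
* **Instrument strengths** γ_j ~ N(0, 0.08²) truncated at |γ| ≥ 0.02, so a
  realistic share of instruments clears p < 1e-5 at these sample sizes;
  microbiome-GWAS effect scales are not published, so this is the one
  place the generator's scale is a modelling choice rather than a quoted
  number.
* **Standard errors** follow the GWAS approximation
  se = 1/√(2·maf·(1−maf)·n); observed effects are Gaussian around truth.
  Binary-outcome effects are simulated directly on the log-odds scale —
  two-sample MR never sees individual-level data, so nothing is gained by
  simulating genotypes, and no case/control ascertainment is modelled.
* **Pleiotropy**: a `prop_invalid` fraction of instruments receives a
  direct outcome effect α_j ~ N(pleiotropy_mean, pleiotropy_sd²),
  *expressed on the exposure-increasing allele*: the outcome mean is
  θγ_j + sign(γ_j)·α_j. With symmetric γ this is what makes "directional"
  pleiotropy directional — applied without the sign convention it cancels
  out of both IVW and the Egger intercept and no estimator contrast
  exists. Under this construction the Egger intercept recovers the mean
  direct effect while IVW is biased (verified by Monte Carlo in the test
  suite). `inside_violation=True` ties α to instrument strength
  (α = mean + κ·|γ| + noise), breaking InSIDE on demand.
* **Bookkeeping hazards**: a fraction of variants get palindromic allele
  pairs and a fraction have swapped allele order (negated β, reflected
  eaf) in the outcome table; effect-allele frequencies equal the true MAF
  in both samples. LD is block-diagonal with constant within-block
  correlation.

What the generator does **not** emulate — hence what passing tests do not
show about real data: realistic human LD maps, between-cohort frequency
differences or population stratification, winner's-curse selection of
instruments, taxonomic nesting of microbiome traits (the published
class/family/order triplicate rows), overlapping samples, and
ascertainment of a case/control outcome. Parameter-recovery results here
certify the estimators' arithmetic and their textbook operating
characteristics, not robustness to those real-data features.

## Annotation

Instruments are mapped to the nearest gene on their chromosome within a
window (default 20 kb), reported as `GENE(d)` with d in floor-kilobases (0
inside the gene); ties break by distance then alphabetical symbol, so gene
list order is irrelevant. BED input (0-based half-open) is converted to
the internal 1-based inclusive convention on read. Functional-consequence
strings require a variant-effect database and are out of scope.

## Numerical and reproducibility choices

* Bootstrap SEs require a seed; the pipeline derives one stream per
  estimator from the run seed so adding a method never perturbs another's
  draws. Same seed ⇒ byte-identical outputs, including the simulator's.
* Degenerate inputs: a single ratio is a legal IVW input (returned
  as-is); MR-Egger and the median/mode need ≥ 3 instruments; Q needs ≥ 2;
  β̂_x = 0 makes the Wald ratio undefined and is a named error;
  n_boot < 100 is refused rather than silently returning a noisy SE.
* Output tables print floats at 6 significant digits; read(write(x))
  reproduces values to that precision (property-tested).
* Monte-Carlo problem sizes in tests and the acceptance script — 200
  replicates × 50 instruments for recovery/coverage, 100 replicates × 100
  instruments for the Egger-intercept contrast, 30 replicates for the
  median-robustness comparison — are chosen so Monte-Carlo error is well
  inside the asserted tolerances while the whole suite runs in seconds.

## Known limitations

First-order Wald SEs (anti-conservative under weak instruments); no
MR-PRESSO outlier removal, multivariable MR, Steiger filtering, or
contamination-mixture models; no proxy-SNP lookup for variants missing
from the outcome GWAS; LD must be supplied, not computed; with three
instruments MR-Egger has one residual degree of freedom and its t-based
p-values are close to uninformative.
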