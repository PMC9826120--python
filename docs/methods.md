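# Methods

## Data model and coordinates

All genomic coordinates are 0-based, half-open. Bismark coverage files
(1-based inclusive) are converted at the reader boundary and nowhere else.
A CpG is addressed by the position of its plus-strand cytosine; calls on
the minus-strand C (plus-strand position +1) are summed onto the
plus-strand site during strand merging. With a reference FASTA the merge is
exact and orphan calls (matching no reference CpG) are dropped with a
warning; without one, adjacent-position pairs (p, p+1) are paired
heuristically, which is correct whenever CpGs are ≥2 bp apart. The
locus-by-sample matrix stores (methylated, coverage) integer pairs;
coverage 0 encodes a missing cell, and percent methylation is defined only
where coverage is positive. Sample assembly defaults to the union of
per-sample loci, leaving retention to the coverage filters (the
intersection policy is available).

## Site filtering

Filters run in a fixed order with an audit trail of loci removed per stage:

1. **Extreme coverage** — per sample, cells strictly above that sample's
   99.9th coverage percentile are masked (PCR-duplication guard). The
   percentile uses linear interpolation (numpy/type-7). Note that this
   stage is not exactly idempotent: re-applying it recomputes the
   percentile on the survivors. The same caveat applies, much more weakly,
   to coverage normalization under integer rounding. The three set-based
   filters below are exactly idempotent and tested as such.
2. **Per-group minimum coverage** — a locus is kept iff, in *every*
   temperature–sex group, at least 50% of samples have ≥5 reads (boundary
   inclusive).
3. **Coverage normalization** — per-sample scale factor =
   median(per-sample median coverages) / sample median; counts are scaled
   and rounded with coverage clamped ≥1 where covered and methylated counts
   clamped to [0, coverage]. Per-cell percent methylation is preserved to
   within 1/coverage.
4. **Constitutive sites** — loci >95% methylated in every sample, or <5% in
   every sample, are removed; the inequalities are strict, so a locus at
   exactly 95.0% survives.
5. **Near-zero variance** — caret's rule on percent methylation: removed
   iff (most common value frequency / second most common) ≥ 19 AND distinct
   values ≤ 10% of samples; constant loci are removed unconditionally.
   Percents are compared at 4-decimal precision; the distinct-value
   denominator is the number of non-missing values at the locus.

## The differential-methylation test

With a single binary covariate the binomial-GLM maximum likelihood is
attained at the pooled per-group proportions, so the likelihood-ratio
statistic LRT = 2(ℓ_full − ℓ_null) is closed-form and the whole screen
vectorizes across loci. Overdispersion is estimated from the full model's
Pearson residuals, φ̂ = Σr²/(J−2) over the J samples with coverage, and the
statistic is deflated by max(φ̂, 1).

**Reference distribution.** The default refers the deflated statistic to
F(1, J−2). Because φ̂ is estimated on roughly J−2 degrees of freedom, the
deflated LRT is F- rather than χ²-distributed; using χ²(1) (available via
`correction="chisq"`, the classical quasi-likelihood convention) proved
anti-conservative in the far tail on beta-binomial simulations — nearly all
spurious Benjamini–Hochberg discoveries arose at loci whose noisy φ̂ fell
below 1 by chance, leaving an inflated LRT against the χ² tail. The F
reference is applied whether or not the deflation floor at φ̂ = 1 was
active, which guards exactly that failure mode; with it, all-null
simulations give approximately uniform p-values and essentially zero BH
discoveries at the 10% threshold.

Group percent difference is computed from pooled (coverage-weighted)
per-group counts, matching the model's group proportion, not the mean of
per-sample percents. FDR is adjusted within each contrast independently.
Temperature contrasts are oriented lower-minus-higher, so a negative
difference means methylation rises with temperature.

**Classification with sex precedence.** universal-sex requires FvM
significance; sex requires FvM or F34.5vM34.5; temperature requires a
significant pairwise temperature contrast *and* no sex significance. The
threshold is strict (q < FDR). Direction is taken from the most significant
contributing contrast. In a TSD design sex and temperature are confounded
(e.g. all 30 °C hatchlings are female), so a fraction of genuinely
temperature-responsive loci is unavoidably absorbed into the sex classes —
a property of the design, not of the implementation.

**Screens.** Spearman correlations of imputed percent methylation with a
numeric covariate (temperature, plasma E2 or testosterone) use average
ranks and the t approximation on n−2 df. Missing percents are imputed once,
before all correlation and prediction analyses, by k-nearest-neighbour
loci (k = 10, Euclidean distance over jointly observed samples;
scikit-learn's `KNNImputer` supplies the neighbour machinery) with a
fall-back to the locus mean above 50% missingness. Absolute correlation
strengths of DMC vs non-DMC sets are compared by a two-sided Mann–Whitney
U (exact enumeration when both sides ≤8, tie-corrected normal otherwise).

## Annotation

Gene context uses precedence promoter > exon > intron > intergenic, with
half-open interval conventions (a locus at an exon's end coordinate is
intronic). The promoter is TSS −1000/+200 bp, strand-aware — the window is
a convention, not a measurement, and is configurable; promoter-level
enrichment results move with it. Nearest-gene distance is 0 inside the
transcript span, otherwise the gap to the span boundary; ties break to the
lower transcript start, then the lexicographically smaller id.

CpG islands: each 100-bp window is scored by GC% and observed/expected
CpG = N_CG·len/(N_C·N_G); positions covered by any window with GC ≥ 50 and
O/E ≥ 0.6 are merged, and runs ≥200 bp are islands. This per-position
covering-window rule (rather than any particular tool's smoothing pass) is
this package's normative definition, enforced against an exhaustive
brute-force oracle in the tests. Shores are the ±2-kb flanks of islands
minus islands; shelves the ±2-kb flanks of shores minus both; open sea the
remainder — clipped at scaffold edges and merged where islands sit <4 kb
apart, so the four classes partition every scaffold exactly. 'N' bases
count as neither C nor G and break CG dinucleotides. Density tiles are
non-overlapping 1-kb windows (final partial tile included, so tile counts
sum to the genome CG total) binned at 20 CpG/kb. Mean-methylation bins are
right-closed with 0 in the first bin.

Enrichment: per category, a 2×2 two-sided Fisher exact test of the DMC set
against the covered background *excluding those DMCs*, BH-adjusted across
categories; zero-margin tables report p = 1 and an undefined odds ratio.

## Motif scanning

JASPAR count matrices become probabilities with a background-weighted
pseudocount of 0.8, and scores are log2(p/background) against a zero-order
background (genome composition or uniform). The score threshold for a
target p-value (default 2×10⁻⁶) comes from the exact score distribution
under the background model, computed by dynamic programming over scores
discretized to 0.01 bits; the enumeration oracle in the tests shares that
grid, so agreement is exact for widths ≤8. Both strands are scanned, hits
are reported in plus-strand coordinates, windows containing N are skipped,
and overlapping opposite-strand hits are both retained. Proximity analysis
uses the minimal bp gap to any hit (0 if overlapping, infinite on hit-free
scaffolds) at 1/2.5/5-kb cutoffs, with Fisher tests of DMC vs background
proportions. The shipped response-element consensus and count matrices are
synthetic constructions for simulation and testing, not database entries.

## Predictors

Candidates for the sex (temperature) model are loci classified
sex-associated (temperature-associated) both in the training subset at
FDR 0.05 and in the full data at FDR 0.1. The elastic net minimizes
(1/N)Σ loss + λ[α|β|₁ + (1−α)/2 |β|₂²] with α = 0.5 on internally
standardized features; scikit-learn's `ElasticNet` (gaussian) and
saga-solver `LogisticRegression` (binomial, C = 1/(Nλ)) solve each λ of a
50-point log-spaced path from the all-zero λ_max down 4 decades. λ is
chosen to minimize mean cross-validated squared error — on predicted
probabilities for the binomial family — over 5 folds (class-stratified for
sex), at the CV minimum rather than the 1-SE rule. Coefficients are
reported back on the percent-methylation scale. λ = 0 falls back to exact
least squares / unpenalized logistic. The default split holds out one
random individual per temperature–sex cell (4 of 24); a half/half scheme is
provided. Imputation is performed jointly over train and test samples by
default (impute-then-split); the strict alternative of imputing separately
is left to the caller by imputing the submatrices explicitly.

## The synthetic study

The generator reproduces the statistical structure the pipeline assumes.
Defaults are the study conditions and are not tuned per test:

* **Design**: 24 blood samples — 8 F at 30 °C, 8 M at 33.5 °C, 4 F + 4 M at
  34.5 °C — over five clutches with the clutch-balanced layout of the
  incubation experiment; a gonad design (four temperatures 29–34.5 °C, sex
  unknown, 22 samples) supports the cross-tissue comparison.
* **Coverage**: negative binomial, mean 30×, size 5 (long-tailed RRBS-like
  depth, occasional dropout giving natural missing cells).
* **Baseline methylation**: mixture of Beta(0.5, 10) (hypomethylated),
  Uniform(0.2, 0.8), Beta(10, 0.5) (hypermethylated) with weights
  0.35/0.25/0.40 — the bimodal methylome that makes the constitutive filter
  meaningful.
* **Noise**: beta-binomial intra-locus correlation ρ = 0.02 and clutch
  random effects of SD 0.3 on the logit scale, drawn per locus × clutch.
  Together these give marginal dispersion factors of ~1.5–2 at 30×, the
  range RRBS analyses typically estimate from biological replicates, and a
  regime in which the dispersion-corrected test is calibrated. (An early
  provisional ρ of 0.10 implies dispersion ≈ 4, where *no* per-locus
  plug-in correction is calibrated; it was replaced by the realistic value
  when the noise model was frozen.)
* **Effects**: 1% of loci carry a sex effect — a hypermethylated baseline
  (≥80%) shifted by −2 logits toward intermediate methylation in one sex,
  the empirically observed pattern of sexually dimorphic CpGs — and half of
  those are expressed only at 34.5 °C, mirroring the observed
  high-temperature-specific dimorphism; 1% carry a ±0.4 logit/°C linear
  temperature slope. Recovery tests use "strong" settings (sex shift 2.5,
  slope 0.5, unconditional) because conditional effects at a 4-vs-4
  subdesign are intrinsically underpowered.
* **Hormones**: lognormal plasma E2 (meanlog 5.5, sdlog 0.4, female offset
  +0.25 — deliberately near the detection threshold) and testosterone
  (meanlog 5.0, sdlog 0.5, no sex offset).
* **Genome**: scaffolds with CpG-depleted Markov background (G after C
  down-weighted to O/E ≈ 0.2, as in vertebrate genomes — without depletion
  a random sequence has O/E ≈ 1 and sprouts spurious islands), CG-rich
  tracts at recorded island positions, grid-placed genes with three exons,
  and response-element consensus sequences planted at recorded sites.

What the generator does *not* emulate: read-level errors and bisulphite
non-conversion, linkage between neighbouring CpGs (loci are independent),
cell-type composition effects, and genuinely shared individuals across
tissues. Passing recovery tests therefore demonstrates correctness of the
analysis chain under the stated count model, not robustness to artefacts
upstream of methylation calls.

## Problem sizes and numerical choices

Simulation-backed tests use 800–5,000 loci × 24 samples — large enough for
stable rate estimates while keeping each suite run in tens of seconds — and
fixed seeds recorded in the tests; the acceptance script derives all
sub-seeds from its single `--seed`. Log-likelihoods use xlogy (0·log 0 = 0);
cells with fitted proportion 0 or 1 contribute zero Pearson residual by
continuity. BH is implemented as the standard step-up with NaN
pass-through and is cross-checked against statsmodels. The reaction norm
centres temperature before the IRLS fit and back-transforms coefficients
and covariance (delta method); perfect separation is flagged, not raised.

## Known limitations

* The per-locus plug-in dispersion correction, even under the F reference,
  loses power relative to shrinkage-based beta-binomial methods; it is used
  here because it is the analysis convention this package reimplements.
* Clutch is balanced in the FvM and 30v33.5 contrasts but only partially in
  the contrasts involving 34.5 °C, so strong clutch effects can leak into
  temperature DMC calls — again a property of the design.
* The CpG-island definition is normative for this package; boundaries can
  differ by a few bases from tools that smooth window statistics before
  thresholding.
* `compare_abs_rho`'s exact mode refuses ties and silently falls back to
  the tie-corrected normal approximation.
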