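# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices, and the places where the design was genuinely open.

## Dose–response summarization

Viability is modelled with the three-parameter Hill / log-logistic curve
`v(d) = e_inf + (1 − e_inf) / (1 + (d/EC50)^HS)` with `e_inf ∈ [0, 1]`
(lower asymptote), `EC50 > 0` (µM), and Hill slope `HS > 0`. Fitting is
nonlinear least squares on log10 dose over a fixed multi-start grid —
EC50 ∈ {d_min, median dose, d_max}, slope ∈ {0.5, 1, 2}, e_inf ∈ {0, 0.5} —
with bounds keeping EC50 within 10^±3 of the tested range; the start with
the smallest SSE wins and ties go to the smallest slope, so the fit is
deterministic. Viabilities are clipped to [0, 1.2] before fitting to
tolerate modest growth above control. A plate whose dose-mean viabilities
are flat (range < 1e-9) is unidentifiable in (EC50, HS); it is returned as
a degenerate fit pinning the level on `e_inf` with the decline pushed below
the dose range, flagged `converged=False`.

SRB (sulforhodamine B) plate preprocessing: the mean cell-free (PBS) blank
signal is subtracted from every well; treated wells are divided by the mean
blank-corrected control; a dose is discarded when its replicate set has
standard deviation > 0.2 **or** coefficient of variation > 0.2 on the
normalized scale. The replicate-agreement rule is stated ambiguously in
common protocols ("standard deviation and coefficient"); we read
"coefficient" as coefficient of variation and apply both at 0.2, which can
only discard more points than either alone. The transform is idempotent:
after one pass blanks are zero and controls have mean one.

AUC is the mean fitted viability over log10 dose on the tested range
(composite Simpson, ≥1001 points — agreement with adaptive quadrature is
~1e-10, tested), normalized by the range width so AUC ∈ [0, 1] when
viability is; AAC = 1 − AUC clipped to [0, 1]. The integration domain and
normalization are a package choice; raw-dose trapezoids would weight the
top decade of dose much more heavily.

## Association models

Per (feature, drug, study): OLS of z-scored AAC on tissue indicators plus
the z-scored feature. Standardization uses exactly the cell lines entering
the fit. Tissue enters as cell-means coding (one indicator per level, no
separate intercept) — the same column space as intercept plus
reference-level dummies, so the expression coefficient, its t test and the
fitted values are identical while no reference level needs to be chosen.
Tissues with fewer than 2 cell lines are merged into an `other` level to
keep the design full rank. The default minimum sample size is n_min = 20
cell lines per (drug, study); below that the fit is refused rather than
returned noisy, which stabilizes the ~1/3 out-of-bag split.

The computation is vectorized over features by Frisch–Waugh–Lovell
residualization (within-tissue centering of y and of every feature row),
which reproduces the full-design OLS coefficient and t-test exactly
(cross-checked against statsmodels in the tests) at a fraction of the cost
— discovery over thousands of features is a few matrix products.

The p-value of the expression term is the usual two-sided t test of the
standardized coefficient with df = n − (#tissue levels) − 1. A numerically
perfect fit (zero residual) reports p at the smallest positive float rather
than 0, keeping p ∈ (0, 1].

## Concordance index

CI = fraction of pairs, unordered and not tied on the observation, whose
prediction ordering matches the observation ordering; prediction ties score
0.5 (Harrell's convention), observation ties are excluded from the
denominator; all observations tied ⇒ not evaluable (NaN). The
implementation is a vectorized pair matrix over the upper triangle and is
property-tested against a brute-force enumerator.

CI is computed on the model's **full linear prediction** (tissue +
expression terms) against raw AAC, so gene, isoform and null models are
compared on the same footing. Consequence worth knowing: when tissue
explains much of the sensitivity, even a null feature's full-model CI is
well above 0.5 — the CI > 0.55 filter then mostly reflects tissue signal
and the discrimination between features comes from the FDR filter and the
paired Wilcoxon test against the tissue-only model, which share the tissue
term and isolate the expression contribution.

## Bootstrap model comparison

100 resamples of the eligible cell lines with replacement (in-bag ≈ 2/3
unique lines; resamples with an empty out-of-bag set are redrawn). Models
are refit in-bag — including recomputing the z-scoring and tissue means
in-bag and applying them out-of-bag; tissues absent from a resample predict
at the in-bag grand mean — and scored by out-of-bag CI. Identical resample
indices are reused for the null, gene and isoform models so the one-sided
Wilcoxon signed-rank test (model − null > 0, zeros dropped) is validly
paired; fewer than 10 non-missing pairs ⇒ not evaluable. Resamples are
drawn once per (drug, study) and shared across all features, for speed and
cross-feature comparability. Dependence between overlapping out-of-bag test
sets can deflate the Wilcoxon p-values; the bias is shared by the gene and
isoform arms, so their comparison is fair, and the test suite asserts only
the joint FDR + CI calling behaviour, not raw Wilcoxon calibration.

The reported CI summary is the **median** of the pooled (concatenated
across studies) out-of-bag CI vector; the Wilcoxon test likewise runs on
the pooled paired vectors. Applying the CI filter per study instead would
be slightly more conservative; pooling was chosen so that a single summary
corresponds to the meta-combined coefficient.

## Meta-combination and calling

Two studies' coefficients and p-values are combined as arithmetic means
weighted by study sample size: `meta_β = (n₁β₁ + n₂β₂)/(n₁+n₂)` and the
same for p. Averaging p-values is unconventional (Fisher or Stouffer would
be the textbook choices) but is kept deliberately: it is monotone in each
argument, symmetric, idempotent on identical studies, and conservative —a
weighted-mean p can never be driven to significance by one study alone. A
single evaluable study passes through flagged `single_study`; coefficient
sign disagreement is flagged, not an error.

Benjamini–Hochberg FDR runs per drug over two separate families — all genes,
and all selected best isoforms. Per-drug (rather than global) families were
chosen because drugs are analyzed independently and the per-drug family is
the unit a practitioner screens; the alternative global family would couple
unrelated drugs through their p-value ranks.

A level is significant iff FDR < 1 % AND pooled median out-of-bag CI > 0.55
AND Wilcoxon-vs-null p < 0.05. Categories: gene only → `gene_specific`,
best isoform only → `isoform_specific`, both → `common`, neither → `none`.

## Validation

Pan-cancer validation refits the model on the independent dataset with the
tissue covariate; single-tissue validation omits it (a constant covariate).
A candidate validates iff unadjusted p < α (default 0.05) and the
coefficient sign matches training. Under a null validation set the expected
validation rate is α/2 (significance × coin-flip sign), which the tests
confirm by Monte Carlo. Tissue-restricted pre-selection refits within one
tissue and keeps candidates with out-of-bag bootstrap CI > 0.55 (out-of-bag
rather than in-sample CI, consistent with discovery and less optimistic)
and training significance. The display statistic is `(CI − 0.5)·sign(β)`;
for validation outcomes the CI in this statistic is the in-sample CI of the
fitted validation model, since validation sets are typically too small to
re-bootstrap informatively.

## Synthetic data model

The generator's defaults define the study conditions used throughout the
tests:

- **Expression.** Isoform values on log2(FPKM+1), clipped at 0:
  per-isoform baseline (uniform 2–6), a per-(gene, tissue) shift
  (SD 0.5), and unit-SD cell noise sharing a within-gene latent factor with
  weight √0.3 (within-gene isoform correlation 0.3, configurable; no
  canonical empirical value exists). Gene matrices are always the FPKM-sum
  aggregate of the isoform matrix, `log2(1 + Σ(2^iso − 1))`, and the tests
  assert this identity.
- **Planted effects.** A planted isoform-specific gene has mutually
  independent isoforms; the signal isoform is a minor transcript (baseline
  log2 ≈ 2) among high-abundance siblings (baseline ≈ 5), so the gene-level
  FPKM sum is dominated by the siblings and the signal is diluted at gene
  level — the regime the isoform-level analysis exists for. Under the
  defaults the gene-level correlation with AAC stays below ~0.35 while the
  isoform carries the full effect.
- **Sensitivity.** AAC = clip(0.5 + 0.125·LP/sd(LP), 0, 1) where
  LP = tissue effect (i.i.d. N(0,1) per tissue per drug) + Σ β·z(feature) +
  N(0, noise_sd²). The affine map keeps β interpretable in standardized
  units; the 0.125 scale puts ±4 SD of the linear predictor inside [0, 1],
  so clipping is rare and Spearman structure is preserved. Default
  noise_sd = 0.3 and planted β = 0.8 give a strong, realistic marker
  (partial correlation ≈ 0.9 given tissue).
- **Study replicates.** Studies share the linear signal and draw
  independent noise from named substreams of `SeedSequence(seed, labels)`,
  so outputs are bit-reproducible and platform-stable. When a target
  between-study Spearman ρ_S is requested, the noise SD is calibrated via
  the bivariate-normal relation ρ_P = 2 sin(πρ_S/6) and
  σ² = var(signal)(1−ρ_P)/ρ_P; realized Spearman at ρ_S = 0.5, n = 200 is
  within ±0.1 (tested). ρ_S = 0 is generated as pure independent noise.

What the generator does **not** emulate: read-level RNA-seq noise,
mappability and length biases in FPKM, batch effects between expression and
sensitivity platforms, non-linear dose–response of expression, and
heavy-tailed AAC distributions. Passing tests therefore demonstrate the
statistical machinery (calibration, ranking, selection, sign rules) under a
faithful structural model, not performance on any real screen.

## Problem sizes in the test and acceptance runs

Type-I control runs 20 all-null studies of 1000 genes × 3 isoforms at
n = 100 (tests) and 10 studies of 500 genes (acceptance script);
planted-effect recovery uses 100-gene panels over 20 seeds; validation
calibration pools 2000 null candidate tests over 50 seeds. These sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
while keeping a full run on one CPU in a few minutes.

## Known limitations

- Weighted-mean p-value combination has no frequentist calibration
  guarantee; a Stouffer option would be a natural extension.
- The CI > 0.55 absolute threshold is assay- and panel-dependent; with
  strong tissue structure it is dominated by the tissue term (see above).
- Univariate linear associations only — no interactions, no multivariate
  models, no mutation/CNV covariates.
- The identity filter consumes a precomputed cross-study concordance table;
  fingerprinting itself is out of scope. The 0.80 cutoff is inclusive
  (concordance exactly 0.80 is retained).
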