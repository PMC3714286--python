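# Methods

## The ratio score

For a sample with linear-scale expression values `x_gs` (MAS5-style
intensities or RPKM-like quantities; non-negative, un-normalized by design),
the Yin/Yang mean ratio is the arithmetic mean of the Yin-gene values divided
by the arithmetic mean of the Yang-gene values; the geometric variant (gYMR)
replaces both means by geometric means, computed in log space. gYMR is
implemented as a ratio of geometric means, which is algebraically identical to
the geometric mean of per-pair ratios for equal groups and well defined for
the unequal 31/32 split.

Key properties the implementation preserves and the test suite asserts:

- **Scale invariance.** Multiplying all values of one sample by `c > 0`
  leaves both scores unchanged, so no between-sample normalization is ever
  required and a single patient sample can be scored alone.
- **Order invariance.** Scores are invariant to gene and sample ordering.
- **Partial coverage.** Genes missing on a platform are dropped from the
  means, with per-group counts (`n_yin_used`, `n_yang_used`) recorded and a
  warning when a group's coverage falls below 80% (configurable).

Scores are always computed on raw linear values — never log-transformed —
since the ratio's interpretation (fold of Yin over Yang) assumes linear
units. gYMR on RNA-seq data with zeros is undefined at the default
pseudocount of 0; affected samples get a NaN score and are reported rather
than failing the cohort, and a positive `pseudocount` is the documented
escape hatch.

## The gene sets

The packaged default carries 31 Yin (tumor-upregulated) and 32 Yang
(tumor-downregulated) genes identified on HG-U95Av2, shipped as a TSV
resource with probe id, symbol, and group. Composite probe annotations
covering paralogue pairs (`HIST1H4J///HIST1H4K`, `DDT///DDTL`) are kept as
single entries with the composite symbol; each probe row counts as one gene
in the 31/32 tallies. Validation enforces unique probe ids, disjoint groups
(by probe and by symbol component), and non-empty groups.

## Cross-platform mapping

Signature genes are resolved onto an arbitrary platform in priority order:

1. features whose declared `best_match_of` equals the signature probe id
   (vendor best-match tables);
2. features whose gene symbol matches any `///` component of the signature
   symbol, case-insensitively; multiple same-symbol features are combined by
   the arithmetic mean **of raw values** (averaging precedes any transform,
   consistent with linear-scale inputs).

Unmatched genes are a reported state, not an error: platforms with partial
coverage remain scoreable. Identity platforms (features already the signature
probes) resolve entirely through rule 1.

## Risk stratification

The default cutoff is 2.0 — the conventional two-fold exceedance of Yin over
Yang. Two data-driven strategies are provided: `NORMAL_ANCHORED` scales 2.0
by the normal-cohort mean score (a normal cohort at ratio balance leaves the
cutoff untouched), and `COHORT_MEAN` uses the cohort's own mean score, the
common mean-risk-score split when no normal samples exist. The resolved value
is used exactly (no rounding); a `FIXED` override reproduces any externally
chosen threshold. Ties go to the low-risk arm: high risk is a strict
exceedance.

## Survival analysis

Kaplan–Meier product-limit curves and the two-sided log-rank test compare the
risk arms; Cox proportional-hazards models (fit with `lifelines`, Efron
approximation for tied event times) provide hazard ratios, 95% CIs and Wald
p-values with the score dichotomous, continuous, or joint with clinical
covariates. Stage is encoded ordinally (I=1, II=2, III=3) by default, with a
one-hot option (stage I reference). Collinear covariate sets are rejected by
a rank check on the centered design; zero-event or zero-variance inputs raise
a diagnostic error rather than returning an unstable fit. The log-rank p is
reported as the headline p for a dichotomous stratification, with the Cox
Wald p alongside, since the two are used interchangeably in the survival
literature. Follow-up restriction is plain administrative censoring: times
beyond the horizon are truncated and their events cleared (idempotent);
life-table rate variants are intentionally not implemented. Subgroup panels
(by stage, by chemotherapy) reuse the cohort-level cutoff; a subgroup whose
arm falls below a minimum size (default 2) is skipped with a warning.

## Random-gene-group null

Significance of the fixed signature is judged against size-matched random
pairs: disjoint groups of 31 and 32 features drawn without replacement from
the full feature pool (signature genes included by default, matching the
stated sampling frame; an exclusion option exists), scored, dichotomized,
and refit with the same dichotomous Cox model. Replicates whose cutoff
leaves one arm empty are kept and flagged as degenerate (p and HR recorded
as NA) rather than redrawn. Sub-seeds are spawned per replicate from the
master seed, so the draw is reproducible bit-for-bit and independent of
execution order. The null summary (mean/sd of p, quantiles of p and HR)
excludes degenerate replicates and reports their count.

For calibration runs on synthetic data, the per-replicate `COHORT_MEAN`
cutoff is used: random-group ratios concentrate near 1, so a fixed threshold
of 2.0 would leave one arm empty in nearly every replicate, and the
mean-split is the configuration under which null uniformity of p is a
meaningful check. The fixed-2.0 mode remains the default for real cohorts.

## Drop-off sensitivity

`drop_analysis` re-runs the full evaluation (map → score → cutoff →
stratify → Cox) with genes removed from the signature, one row per
(drop set × score type × variable type). Drop names may be probe ids or
symbols (composite components match); names the signature does not carry are
ignored, so dropping a gene a platform never matched is a no-op, and the
empty drop set reproduces the baseline exactly because it follows the
identical code path. Convenience expansions generate all single-gene drops
per group (31 yin rows, 32 yang rows for the default) and a named
three-gene preset (`HIST1H4J`, `CDC25A`, `IGFBP5`).

## Synthetic cohort generator

The generator emulates the data structure the method assumes, not any
particular real cohort:

- **Expression.** Per-feature baselines are log-normal (natural-log mean 5.0,
  sd 1.0 — intensities in the hundreds, right-skewed); yin and yang group
  baselines are rescaled to a common mean so configured fold changes map
  directly onto cohort YMR targets. Normal samples shrink yin by the factor
  0.9 (target normal mean YMR ≈ 0.9); tumors scale yin by 2.2 times a
  mean-one log-normal per-sample heterogeneity (log-sd 0.35), centering the
  tumor cohort near YMR ≈ 2.2 with both risk arms populated at the 2.0
  cutoff. Multiplicative log-normal noise (log-sd 0.3, mean-corrected)
  applies to every value. 12,625 background features mirror a
  discovery-scale array.
- **Survival.** The realized YMR of each tumor (computed from the generated
  matrix) is thresholded at the configured cutoff to define the *true* risk
  group; event times are exponential with hazard 0.005/month in the low arm
  and `true_hr` (default 2.7) times that in the high arm. Because the hazard
  acts on the thresholded group, the dichotomous Cox analysis is correctly
  specified and CI coverage of `true_hr` is a clean recovery test. A
  `continuous_link` mode instead ties the log hazard to the centered log2
  YMR with log-HR `ln(true_hr)` per log2 unit, for exercising the continuous
  model. A `censor_rate` fraction of samples (default 0.2) is lost to
  follow-up uniformly within their own follow-up window; everyone is
  administratively censored at 72 months. At the defaults this yields
  roughly 40% observed events. Stage, chemotherapy, age and sex covariates
  are drawn independently of the hazard — they exist to exercise interfaces,
  not to plant confounding.
- **Determinism.** One `numpy` Generator seeded from the config; identical
  configs produce byte-identical matrices, clinical tables and truth records.

What the generator does **not** emulate: gene–gene correlation beyond the
group shifts, batch effects, probe-level artifacts, platform-specific
distributions, or informative censoring tied to covariates. Passing tests on
synthetic cohorts therefore demonstrate correctness of the computations and
the stated statistical behavior under the assumed model — not clinical
validity on real cohorts, which requires external expression data.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations at 50 replicates of
the default cohort (100 normals + 400 tumors) for CI-coverage checks, 100
random-pair replicates for null calibration, and n = 2000 for the
closed-form exponential Cox check — sizes at which the expected sampling
error is several times smaller than the asserted bands. Scoring oracles are
checked to 1e-10 relative error; scale invariance to 1e-9 (one division and
one multiplication of double-precision values per score). Degenerate inputs
follow one rule throughout: per-sample score failures (zero Yang mean, zeros
under a zero pseudocount) are reported and skipped; cohort-level
impossibilities (empty group, no events, no variance, collinearity) raise
typed errors; resampling degeneracies are flagged in-place.
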