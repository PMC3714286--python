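# ymrsig — training-free Yin/Yang mean-ratio signature for lung cancer prognosis

`ymrsig` implements a gene-expression ratio risk score for lung adenocarcinoma
that requires **no training and no cohort normalization**. Two fixed, opposing
gene sets — 31 *Yin* genes upregulated in lung tumors and 32 *Yang* genes
downregulated in tumors, defined on the Affymetrix HG-U95Av2 platform — are
summarized per sample as the **Yin/Yang mean ratio**

```
YMR_s = mean_{g ∈ Yin} x_gs  /  mean_{g ∈ Yang} x_gs
```

on linear-scale expression values (microarray intensities or RPKM-like
quantities), with a geometric-mean analogue

```
gYMR_s = geomean_{g ∈ Yin} x_gs / geomean_{g ∈ Yang} x_gs .
```

Because both are within-sample ratios, rescaling a sample by any constant
leaves its score unchanged: the score of a single patient can be computed in
isolation, on any platform, without reference to a training cohort. Normal
lung tissue scores below 1 (Yang-dominant); tumors score above 1; patients
with YMR above a cutoff (2.0 by convention, optionally anchored to the
normal-cohort or cohort mean) form the high-risk arm. The package targets
researchers evaluating expression-based prognostic classifiers who need the
scoring, the survival statistics, and the significance machinery in one place.

Beyond scoring, the package provides:

- **Cross-platform mapping** (`ymrsig.mapping`): vendor best-match probe
  resolution, then gene-symbol matching with `///`-composite splitting and
  multi-probe averaging; partial platform coverage is tolerated and reported.
- **Survival evaluation** (`ymrsig.survival`): Kaplan–Meier curves, log-rank
  tests, and univariate/multivariate Cox proportional-hazards models
  (via `lifelines`, Efron ties), with follow-up restriction and
  stage/chemotherapy subgroup panels.
- **Resampling significance** (`ymrsig.resampling`): a size-matched
  random-gene-group null distribution (e.g. 500 random 31+32 pairs) and
  gene drop-off sensitivity analysis.
- **Synthetic cohorts** (`ymrsig.synthetic`): a seeded generator producing
  expression matrices and linked survival outcomes with a planted hazard
  ratio, used throughout the test suite.

## Worked example

Simulate a cohort (20 normals, 200 tumors, 500 background features), then
evaluate the packaged signature against the simulated follow-up:

```sh
$ ymrsig simulate --n-normal 20 --n-tumor 200 --n-background 500 --seed 42 --outdir demo
wrote cohort (563 features x 220 samples) to demo

$ ymrsig evaluate --expression demo/expression.tsv --clinical demo/clinical.tsv --out demo/report.json
n=200 (HIGH 101 / LOW 99) cutoff=2 logrank_p=9.346e-09 HR=4.16 (2.45-7.04)
```

The 200 tumors split 101 high-risk / 99 low-risk at the fixed YMR cutoff of
2.0; the arms differ strongly in survival (log-rank p ≈ 9×10⁻⁹), and the
high-risk arm carries a hazard ratio of 4.16 (95% CI 2.45–7.04) for death in
the dichotomous Cox model — the generator planted a true group hazard ratio
of 2.7, which the CI of any single medium-sized cohort estimates noisily.
Per-sample scores work without clinical data, even for a single column:

```sh
$ ymrsig score --expression demo/expression.tsv --cutoff 2.0 | head -4
sample_id       ymr                  n_yin_used  n_yang_used  risk_label
N001            1.0579926655649332   31          32           LOW
N002            0.8682834824707201   31          32           LOW
N003            0.8795200293438945   31          32           LOW
```

`ymrsig null` draws size-matched random gene-group pairs and reports the
(p, HR) distribution they produce; `ymrsig dropout` re-evaluates the signature
with genes removed. All subcommands are deterministic under `--seed`.

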