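"""Synthetic cohorts with the statistical structure the ratio signature assumes.

The generator emulates a mixed normal/tumor expression study on a microarray-
like platform: linear-scale, right-skewed (log-normal) intensities over the 63
signature probes plus thousands of background features, with

* normal lung samples Yang-dominant (cohort mean YMR ≈ 0.9),
* tumor samples Yin-dominant with per-sample heterogeneity spreading the
  cohort (mean YMR ≈ 2.2) across the 2.0 risk cutoff, and
* exponential event times whose hazard is tied to the sample's *generated*
  risk group (HIGH-vs-LOW hazard ratio ``true_hr``), with uniform independent
  censoring and administrative censoring at the follow-up horizon.

Because the hazard acts on the thresholded group, the dichotomous Cox analysis
is correctly specified and parameter recovery is a clean test. A
``continuous_link`` mode instead ties the log hazard to the centered log YMR
for exercising the continuous Cox path. Everything is reproducible
byte-for-byte from the seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .mapping import identity_annotation
from .scoring import DEFAULT_CUTOFF, RISK_HIGH, RISK_LOW
from .signature import SignatureGeneSets, load_default_signature

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "AnnotationDialect",
    "simulate_cohort",
    "simulate_platform_annotation",
]


class AnnotationDialect(str, enum.Enum):
    IDENTITY = "IDENTITY"
    SYMBOL_ONLY = "SYMBOL_ONLY"
    MULTI_PROBE = "MULTI_PROBE"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a discovery-scale microarray study: 12,625 background
    probes, ~100 normal and ~400 tumor samples, normal cohort sitting just
    below ratio balance (target mean YMR 0.9), tumors centered at 2.2 with
    log-normal per-sample heterogeneity so both risk arms are populated at
    the 2.0 cutoff, and a HIGH-vs-LOW hazard ratio of 2.7 at ~40% events
    within a 72-month horizon.
    """

    n_normal: int = 100
    n_tumor: int = 400
    n_background_features: int = 12_625
    baseline_log_mean: float = 5.0  # natural-log scale of intensities
    baseline_log_sd: float = 1.0
    normal_ymr: float = 0.9  # target normal-cohort mean ratio
    yin_tumor_fold: float = 2.2  # median multiplicative yin shift in tumors
    yang_tumor_fold: float = 1.0
    tumor_heterogeneity_sd: float = 0.35  # log-sd of the per-tumor yin shift
    noise_sd: float = 0.3  # log-sd of per-value multiplicative noise
    true_hr: float = 2.7  # HIGH-vs-LOW hazard ratio
    baseline_hazard: float = 0.005  # events per month in the LOW arm
    censor_rate: float = 0.2  # probability of early uniform censoring
    horizon: float = 72.0  # months of administrative follow-up
    cutoff: float = DEFAULT_CUTOFF  # threshold defining the true risk group
    continuous_link: bool = False  # hazard from centered log2 YMR instead of group
    seed: int = 0

    def validate(self) -> None:
        if self.n_normal < 0 or self.n_tumor < 0 or self.n_background_features < 0:
            raise ValueError("sample and feature counts must be non-negative")
        for name in ("normal_ymr", "yin_tumor_fold", "yang_tumor_fold", "true_hr",
                     "baseline_hazard", "cutoff"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")


@dataclass
class SimulationTruth:
    """Ground truth aligned 1:1 with the generated sample ids."""

    table: pd.DataFrame  # index sample_id; cohort, ymr, risk_group (tumor only)
    true_hr: float
    seed: int
    config: dict = field(default_factory=dict)


def _gene_baselines(
    rng: np.random.Generator, sig: SignatureGeneSets, cfg: SimulationConfig
) -> tuple[pd.Series, list[str]]:
    """Per-feature baseline intensities; yin and yang group means equalized.

    Equalizing the group means pins the systematic ratio of a balanced sample
    at 1.0, so the configured fold changes translate directly into cohort YMR
    targets instead of depending on which baselines happened to be drawn.
    """
    n_sig = len(sig.genes)
    background_ids = [f"BG{i:05d}" for i in range(1, cfg.n_background_features + 1)]
    ids = sig.probe_ids + background_ids
    base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(ids))
    baselines = pd.Series(base, index=ids)

    target = float(np.exp(cfg.baseline_log_mean + cfg.baseline_log_sd**2 / 2))
    yin_ids = [g.probe_id for g in sig.yin]
    yang_ids = [g.probe_id for g in sig.yang]
    baselines[yin_ids] *= target / baselines[yin_ids].mean()
    baselines[yang_ids] *= target / baselines[yang_ids].mean()
    return baselines, background_ids


def simulate_cohort(
    cfg: SimulationConfig | None = None,
    sig: SignatureGeneSets | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (expression matrix, clinical table, truth record).

    The expression matrix carries the signature genes under their HG-U95
    probe ids plus ``BGxxxxx`` background features; samples are ``N###``
    normals then ``T###`` tumors. The clinical table covers tumor samples
    only (normals contribute no follow-up), with stage/chemo/age/sex
    covariates drawn independently of the hazard.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    sig = sig or load_default_signature()
    rng = np.random.default_rng(cfg.seed)

    baselines, _ = _gene_baselines(rng, sig, cfg)
    n_features = len(baselines)
    n_samples = cfg.n_normal + cfg.n_tumor
    sample_ids = [f"N{i:03d}" for i in range(1, cfg.n_normal + 1)] + [
        f"T{i:03d}" for i in range(1, cfg.n_tumor + 1)
    ]

    yin_ids = [g.probe_id for g in sig.yin]
    yang_ids = [g.probe_id for g in sig.yang]
    yin_pos = [baselines.index.get_loc(i) for i in yin_ids]
    yang_pos = [baselines.index.get_loc(i) for i in yang_ids]

    # effect[g, s]: multiplicative group shift; background rows stay at 1.
    effect = np.ones((n_features, n_samples))
    normal_cols = np.arange(cfg.n_normal)
    tumor_cols = np.arange(cfg.n_normal, n_samples)
    effect[np.ix_(yin_pos, normal_cols)] = cfg.normal_ymr

    het_sd = cfg.tumor_heterogeneity_sd
    # mean-one log-normal heterogeneity keeps the tumor cohort mean at the fold
    het = rng.lognormal(-het_sd**2 / 2, het_sd, size=cfg.n_tumor)
    effect[np.ix_(yin_pos, tumor_cols)] = cfg.yin_tumor_fold * het[None, :]
    effect[np.ix_(yang_pos, tumor_cols)] = cfg.yang_tumor_fold

    noise = rng.lognormal(-cfg.noise_sd**2 / 2, cfg.noise_sd, size=(n_features, n_samples))
    values = baselines.to_numpy()[:, None] * effect * noise
    expr = pd.DataFrame(values, index=baselines.index.copy(), columns=sample_ids)
    expr.index.name = "feature_id"

    # Realized per-sample YMR on the generated matrix defines the true group.
    ymr = expr.iloc[yin_pos].mean(axis=0) / expr.iloc[yang_pos].mean(axis=0)
    cohort = pd.Series(
        ["normal"] * cfg.n_normal + ["tumor"] * cfg.n_tumor, index=sample_ids
    )
    risk_group = pd.Series(pd.NA, index=sample_ids, dtype="object")
    tumor_mask = cohort == "tumor"
    risk_group[tumor_mask] = np.where(
        ymr[tumor_mask] > cfg.cutoff, RISK_HIGH, RISK_LOW
    )

    clinical = _simulate_survival(rng, cfg, ymr[tumor_mask], risk_group[tumor_mask])

    truth = SimulationTruth(
        table=pd.DataFrame(
            {"cohort": cohort, "ymr": ymr, "risk_group": risk_group}
        ).rename_axis("sample_id"),
        true_hr=cfg.true_hr,
        seed=cfg.seed,
        config=asdict(cfg),
    )
    return expr, clinical, truth


def _simulate_survival(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    tumor_ymr: pd.Series,
    tumor_group: pd.Series,
) -> pd.DataFrame:
    n = len(tumor_ymr)
    if cfg.continuous_link:
        log2_ymr = np.log2(tumor_ymr.to_numpy(dtype=float))
        centered = log2_ymr - log2_ymr.mean()
        hazard = cfg.baseline_hazard * np.power(cfg.true_hr, centered)
    else:
        high = (tumor_group == RISK_HIGH).to_numpy()
        hazard = np.where(high, cfg.baseline_hazard * cfg.true_hr, cfg.baseline_hazard)

    event_time = rng.exponential(1.0 / hazard) if n else np.empty(0)
    # censor_rate is the probability a sample is lost to follow-up before its
    # event; lost samples are censored uniformly within their own follow-up,
    # and everyone is administratively censored at the horizon.
    lost = rng.random(n) < cfg.censor_rate
    capped = np.minimum(event_time, cfg.horizon)
    time = np.where(lost, rng.uniform(0.0, 1.0, size=n) * capped, capped)
    event = (~lost) & (event_time <= cfg.horizon)

    stage = rng.choice(["I", "II", "III"], size=n, p=[0.6, 0.2, 0.2])
    chemo = rng.random(n) < 0.3
    age = np.round(rng.normal(65.0, 8.0, size=n), 1)
    sex = rng.choice(["M", "F"], size=n)
    return pd.DataFrame(
        {
            "time": np.round(time, 3),
            "event": event,
            "stage": stage,
            "chemo": chemo,
            "age": age,
            "sex": sex,
        },
        index=tumor_ymr.index.rename("sample_id"),
    )


def simulate_platform_annotation(
    sig: SignatureGeneSets | None = None,
    dialect: AnnotationDialect | str = AnnotationDialect.IDENTITY,
    seed: int = 0,
    drop_fraction: float = 0.0,
    min_probes_per_gene: int = 1,
    max_probes_per_gene: int = 3,
) -> pd.DataFrame:
    """Annotation tables exercising each feature-resolution rule.

    IDENTITY reuses the signature probe ids (every gene resolves by best
    match); SYMBOL_ONLY renames features so only symbol matching applies,
    deleting a ``drop_fraction`` of genes at random; MULTI_PROBE emits
    ``min_probes_per_gene``–``max_probes_per_gene`` same-symbol features per
    gene to exercise multi-probe averaging.
    """
    sig = sig or load_default_signature()
    dialect = AnnotationDialect(dialect)
    rng = np.random.default_rng(seed)

    if dialect is AnnotationDialect.IDENTITY:
        return identity_annotation(sig)

    rows: list[dict] = []
    if dialect is AnnotationDialect.SYMBOL_ONLY:
        keep = rng.random(len(sig.genes)) >= drop_fraction
        for i, (gene, kept) in enumerate(zip(sig.genes, keep), start=1):
            if kept:
                rows.append(
                    {"feature_id": f"ALT{i:04d}", "gene_symbol": gene.gene_symbol}
                )
        return pd.DataFrame(rows, columns=["feature_id", "gene_symbol"])

    # MULTI_PROBE
    counter = 1
    for gene in sig.genes:
        n_probes = int(rng.integers(min_probes_per_gene, max_probes_per_gene + 1))
        for _ in range(n_probes):
            rows.append(
                {"feature_id": f"MP{counter:05d}", "gene_symbol": gene.gene_symbol}
            )
            counter += 1
    return pd.DataFrame(rows, columns=["feature_id", "gene_symbol"])
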