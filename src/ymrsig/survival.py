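"""Time-to-event evaluation of the ratio signature.

Kaplan–Meier product-limit curves with a two-sided log-rank test compare the
HIGH and LOW risk arms; Cox proportional-hazards models quantify the effect,
with the score either dichotomized (HIGH vs LOW hazard ratio) or entered as a
continuous covariate (HR per unit of score). Multivariate fits add clinical
covariates (ordinal stage I<II<III, chemotherapy, age, sex). Tied event times
use the Efron approximation. Times are in months throughout.

The log-rank p is the headline p for a dichotomous stratification, with the
Cox Wald p reported alongside — figure annotations in the survival literature
mix the two, so the report carries both.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .mapping import (
    CoverageReport,
    build_probe_map,
    coverage_report,
    identity_annotation,
    summarize_gene_expression,
)
from .scoring import (
    CutoffSpec,
    CutoffStrategy,
    ScoreType,
    compute_gymr,
    compute_ymr,
    resolve_cutoff,
    scores_of,
    stratify,
    RISK_HIGH,
    RISK_LOW,
)
from .signature import SignatureGeneSets

__all__ = [
    "ModelType",
    "CoxResult",
    "KMEstimate",
    "SurvivalError",
    "DegenerateAnalysisError",
    "read_clinical",
    "km_logrank",
    "cox_univariate",
    "cox_multivariate",
    "restrict_followup",
    "EvaluationConfig",
    "SubgroupResult",
    "EvaluationReport",
    "evaluate_signature",
]

STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3}
_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


class SurvivalError(ValueError):
    """Malformed survival inputs or a fit that cannot be interpreted."""


class DegenerateAnalysisError(SurvivalError):
    """Stratified analysis undefined: an arm is empty or has no usable variance."""


class ModelType(str, enum.Enum):
    CONTINUOUS = "CONTINUOUS"
    DICHOTOMOUS = "DICHOTOMOUS"
    MULTIVARIATE = "MULTIVARIATE"


@dataclass(frozen=True)
class CoxResult:
    covariate_name: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model_type: ModelType

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise SurvivalError(
                f"inconsistent CI for {self.covariate_name}: "
                f"[{self.ci_low}, {self.ci_high}] vs HR {self.hr}"
            )


@dataclass
class KMEstimate:
    """Per-group product-limit curves plus the cross-group log-rank test."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    logrank_stat: float
    logrank_p: float
    group_sizes: dict[str, int] = field(default_factory=dict)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)) and not pd.isna(value):
        return bool(int(value))
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise SurvivalError(f"cannot interpret boolean value {value!r}")


def read_clinical(path: Union[str, Path], sep: str | None = None) -> pd.DataFrame:
    """Read a clinical table: required sample_id,time,event; optional stage,chemo,age,sex.

    Events accept 0/1, true/false, yes/no; times are months and must be >= 0.
    Returns a DataFrame indexed by sample_id with ``event`` as bool.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise SurvivalError(f"{path}: missing column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise SurvivalError(f"{path}: duplicate sample ids")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    df["time"] = pd.to_numeric(df["time"])
    if (df["time"] < 0).any():
        raise SurvivalError(f"{path}: negative survival times")
    df["event"] = df["event"].map(_parse_bool)
    if "chemo" in df.columns:
        df["chemo"] = df["chemo"].map(_parse_bool)
    if "stage" in df.columns:
        df["stage"] = df["stage"].astype(str).str.strip().str.upper()
        bad = sorted(set(df["stage"]) - set(STAGE_ORDINAL))
        if bad:
            raise SurvivalError(f"{path}: unknown stage label(s) {bad}")
    return df


def km_logrank(surv: pd.DataFrame, groups: pd.Series | Mapping[str, str]) -> KMEstimate:
    """Kaplan–Meier curves per group and the two-sided log-rank test across groups.

    ``groups`` maps sample id to a group label; samples missing a label are
    excluded. Any group present in the labels must contain at least one
    aligned sample.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    groups = groups.dropna()
    requested = set(groups.unique())
    common = surv.index.intersection(groups.index)
    groups = groups.loc[common]
    if len(requested - set(groups.unique())) or not requested:
        raise SurvivalError("each group must contain at least one sample")
    if groups.nunique() < 2:
        raise DegenerateAnalysisError("log-rank needs at least two non-empty groups")

    aligned = surv.loc[groups.index]
    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for name, idx in groups.groupby(groups).groups.items():
        sub = aligned.loc[idx]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(int), label=str(name))
        table = kmf.event_table
        curves[str(name)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": table["at_risk"].reindex(
                    kmf.survival_function_.index, method="ffill"
                ).to_numpy(dtype=float),
            }
        )
        sizes[str(name)] = len(sub)

    if aligned["event"].sum() == 0:
        # All censored: curves are flat and the test statistic is undefined.
        return KMEstimate(curves, float("nan"), float("nan"), sizes)

    result = multivariate_logrank_test(
        aligned["time"], groups.astype(str), aligned["event"].astype(int)
    )
    return KMEstimate(curves, float(result.test_statistic), float(result.p_value), sizes)


def _as_numeric_covariate(values: pd.Series) -> pd.Series:
    """Numeric encoding for Cox design columns (risk labels -> 1/0, stage -> ordinal)."""
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        uniques = set(values.dropna().astype(str).str.upper())
        if uniques <= {RISK_HIGH, RISK_LOW}:
            return values.astype(str).str.upper().map({RISK_HIGH: 1.0, RISK_LOW: 0.0})
        if uniques <= set(STAGE_ORDINAL):
            return values.astype(str).str.upper().map(STAGE_ORDINAL).astype(float)
        if len(uniques) == 2:
            lo, hi = sorted(uniques)
            return values.astype(str).str.upper().map({lo: 0.0, hi: 1.0})
        raise SurvivalError(f"cannot encode covariate values {sorted(uniques)[:5]}")
    return pd.to_numeric(values)


def _fit_cox(design: pd.DataFrame, model_type: ModelType) -> list[CoxResult]:
    covariates = [c for c in design.columns if c not in ("time", "event")]
    n = len(design)
    if design["event"].sum() == 0:
        raise DegenerateAnalysisError("no observed events; Cox model undefined")
    for c in covariates:
        if design[c].nunique() < 2:
            raise DegenerateAnalysisError(f"covariate {c!r} has no variance")
    X = design[covariates].to_numpy(dtype=float)
    if len(covariates) > 1:
        centered = X - X.mean(axis=0)
        if np.linalg.matrix_rank(centered) < len(covariates):
            raise SurvivalError(f"collinear covariates among {covariates}")

    cph = CoxPHFitter()  # Efron tie handling is the lifelines default
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(design, duration_col="time", event_col="event")
    summary = cph.summary
    results = []
    for c in covariates:
        row = summary.loc[c]
        results.append(
            CoxResult(
                covariate_name=c,
                hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
                n=n,
                model_type=model_type,
            )
        )
    return results


def cox_univariate(
    surv: pd.DataFrame,
    covariate: pd.Series,
    model_type: ModelType | str = ModelType.CONTINUOUS,
    name: str | None = None,
) -> CoxResult:
    """Univariate Cox PH fit of a score or risk label against time/event.

    DICHOTOMOUS expects HIGH/LOW labels (or any 0/1 encoding) and reports the
    HIGH-vs-LOW hazard ratio; CONTINUOUS reports the HR per unit of score.
    """
    model_type = ModelType(model_type)
    cov = _as_numeric_covariate(covariate).dropna()
    common = surv.index.intersection(cov.index)
    if common.empty:
        raise SurvivalError("no samples shared between survival table and covariate")
    design = pd.DataFrame(
        {
            "time": surv.loc[common, "time"].to_numpy(dtype=float),
            "event": surv.loc[common, "event"].to_numpy(dtype=int),
            name or "score": cov.loc[common].to_numpy(dtype=float),
        },
        index=common,
    )
    return _fit_cox(design, model_type)[0]


def cox_multivariate(
    surv: pd.DataFrame,
    covariate: pd.Series,
    clinical_covariates: Sequence[str],
    name: str | None = None,
    stage_one_hot: bool = False,
) -> list[CoxResult]:
    """Joint Cox PH fit of the score plus named clinical covariates.

    Stage is encoded ordinally (I=1, II=2, III=3) unless ``stage_one_hot``;
    returns one :class:`CoxResult` per covariate from the single joint fit.
    """
    cov = _as_numeric_covariate(covariate).dropna()
    common = surv.index.intersection(cov.index)
    design = pd.DataFrame(
        {
            "time": surv.loc[common, "time"].to_numpy(dtype=float),
            "event": surv.loc[common, "event"].to_numpy(dtype=int),
            name or "score": cov.loc[common].to_numpy(dtype=float),
        },
        index=common,
    )
    for c in clinical_covariates:
        if c not in surv.columns:
            raise SurvivalError(f"clinical covariate {c!r} not in survival table")
        if c == "stage" and stage_one_hot:
            stage = surv.loc[common, "stage"].astype(str).str.upper()
            for level in ("II", "III"):  # stage I is the reference
                design[f"stage_{level}"] = (stage == level).astype(float)
        else:
            design[c] = _as_numeric_covariate(surv.loc[common, c]).to_numpy(dtype=float)
    design = design.dropna()
    return _fit_cox(design, ModelType.MULTIVARIATE)


def restrict_followup(surv: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon`` months.

    Times beyond the horizon are truncated to it and their events cleared.
    Idempotent; ``horizon=inf`` is the identity.
    """
    if not horizon > 0:
        raise SurvivalError("horizon must be positive")
    out = surv.copy()
    beyond = out["time"] > horizon
    out.loc[beyond, "time"] = horizon
    out.loc[beyond, "event"] = False
    return out


@dataclass
class EvaluationConfig:
    """Knobs for the end-to-end evaluation pipeline."""

    score_type: ScoreType = ScoreType.YMR
    cutoff_strategy: CutoffStrategy = CutoffStrategy.FIXED
    cutoff_value: float | None = None  # FIXED strategy only; default 2.0
    pseudocount: float = 0.0  # gYMR only
    followup_horizon: float | None = None  # months; None = no restriction
    stages: tuple[str, ...] | None = None  # e.g. ("II", "III"); None = all
    chemo: bool | None = None  # None = any
    min_arm_size: int = 2


@dataclass
class SubgroupResult:
    label: str
    n: int
    n_high: int
    n_low: int
    cutoff: CutoffSpec
    km: KMEstimate | None
    cox_dichotomous: CoxResult | None
    cox_continuous: CoxResult | None
    skipped: str | None = None


@dataclass
class EvaluationReport:
    scores: pd.DataFrame
    cutoff: CutoffSpec
    coverage: CoverageReport
    overall: SubgroupResult
    subgroups: dict[str, SubgroupResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _sub(s: SubgroupResult) -> dict:
            d = {
                "label": s.label,
                "n": s.n,
                "n_high": s.n_high,
                "n_low": s.n_low,
                "cutoff": s.cutoff.value,
                "skipped": s.skipped,
            }
            if s.km is not None:
                d["logrank_p"] = s.km.logrank_p
                d["logrank_stat"] = s.km.logrank_stat
            for key, res in (("dichotomous", s.cox_dichotomous), ("continuous", s.cox_continuous)):
                if res is not None:
                    d[f"cox_{key}"] = {
                        "hr": res.hr,
                        "ci": [res.ci_low, res.ci_high],
                        "p": res.p,
                        "n": res.n,
                    }
            return d

        return {
            "cutoff": {"strategy": self.cutoff.strategy.value, "value": self.cutoff.value},
            "coverage": {
                "yin": f"{self.coverage.n_yin_matched}/{self.coverage.n_yin_total}",
                "yang": f"{self.coverage.n_yang_matched}/{self.coverage.n_yang_total}",
            },
            "overall": _sub(self.overall),
            "subgroups": {k: _sub(v) for k, v in self.subgroups.items()},
        }


def _evaluate_arm(
    label: str,
    surv: pd.DataFrame,
    stratified: pd.DataFrame,
    cutoff: CutoffSpec,
    min_arm_size: int,
) -> SubgroupResult:
    common = surv.index.intersection(stratified.index)
    sub_scores = stratified.loc[common]
    labels = sub_scores["risk_label"].dropna()
    n_high = int((labels == RISK_HIGH).sum())
    n_low = int((labels == RISK_LOW).sum())
    base = dict(label=label, n=len(common), n_high=n_high, n_low=n_low, cutoff=cutoff)
    if min(n_high, n_low) < min_arm_size:
        warnings.warn(
            f"subgroup {label!r} skipped: arm sizes ({n_low} LOW, {n_high} HIGH) "
            f"below minimum {min_arm_size}",
            stacklevel=3,
        )
        return SubgroupResult(
            **base, km=None, cox_dichotomous=None, cox_continuous=None,
            skipped="arm below minimum size",
        )
    sub_surv = surv.loc[common]
    km = km_logrank(sub_surv, labels)
    cox_d = cox_univariate(sub_surv, labels, ModelType.DICHOTOMOUS, name="risk")
    cox_c = cox_univariate(
        sub_surv, scores_of(sub_scores), ModelType.CONTINUOUS, name="score"
    )
    return SubgroupResult(**base, km=km, cox_dichotomous=cox_d, cox_continuous=cox_c)


def evaluate_signature(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    sig: SignatureGeneSets,
    config: EvaluationConfig | None = None,
    annotation: pd.DataFrame | None = None,
    normal_scores: pd.DataFrame | None = None,
    subgroup_specs: Mapping[str, dict] | None = None,
) -> EvaluationReport:
    """Full pipeline: map → score → cutoff → stratify → KM/log-rank + Cox.

    ``annotation`` defaults to the identity platform (expression rows already
    the signature probes). ``subgroup_specs`` maps a label to filter kwargs
    (``stages=('II','III')``, ``chemo=True``); each subgroup is evaluated at
    the cohort-level cutoff, mirroring stage/chemotherapy panel analyses.
    Subgroups with an arm below ``config.min_arm_size`` are reported as
    skipped with a warning rather than failing the run.
    """
    config = config or EvaluationConfig()
    if annotation is None:
        annotation = identity_annotation(sig)
    pmap = build_probe_map(sig, annotation)
    coverage = coverage_report(pmap)
    gene_expr = summarize_gene_expression(expr, pmap)

    if config.score_type is ScoreType.YMR:
        scores = compute_ymr(gene_expr, sig)
    else:
        scores = compute_gymr(gene_expr, sig, pseudocount=config.pseudocount)

    cutoff = resolve_cutoff(
        scores=scores,
        strategy=config.cutoff_strategy,
        fixed_value=config.cutoff_value,
        normal_scores=normal_scores,
    )
    stratified = stratify(scores, cutoff)

    surv = clinical
    if config.followup_horizon is not None:
        surv = restrict_followup(surv, config.followup_horizon)
    surv = _filter_subgroup(surv, stages=config.stages, chemo=config.chemo)

    overall = _evaluate_arm("overall", surv, stratified, cutoff, config.min_arm_size)
    subgroups: dict[str, SubgroupResult] = {}
    for label, spec in (subgroup_specs or {}).items():
        sub = _filter_subgroup(surv, **spec)
        subgroups[label] = _evaluate_arm(label, sub, stratified, cutoff, config.min_arm_size)
    return EvaluationReport(
        scores=stratified, cutoff=cutoff, coverage=coverage,
        overall=overall, subgroups=subgroups,
    )


def _filter_subgroup(
    surv: pd.DataFrame,
    stages: Sequence[str] | None = None,
    chemo: bool | None = None,
) -> pd.DataFrame:
    out = surv
    if stages is not None:
        if "stage" not in out.columns:
            raise SurvivalError("stage filter requested but no stage column present")
        wanted = {str(s).strip().upper() for s in stages}
        out = out[out["stage"].isin(wanted)]
    if chemo is not None:
        if "chemo" not in out.columns:
            raise SurvivalError("chemo filter requested but no chemo column present")
        out = out[out["chemo"] == chemo]
    return out
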