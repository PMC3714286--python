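"""Random-gene-group null distribution and gene drop-off sensitivity.

The significance of a fixed two-group ratio signature is judged against a
size-matched null: repeatedly draw disjoint random groups of the same sizes
(31 "yin-like", 32 "yang-like") from the platform's features, score every
sample with the random ratio, dichotomize at a cutoff, and fit the same
dichotomous Cox model. A real signature should sit far below the bulk of the
null p-values. Replicates whose cutoff puts every sample in one arm are
*degenerate*: they are kept and flagged (p and HR recorded as NA) rather than
redrawn, since such anomalies are informative about the cutoff.

Drop-off sensitivity re-runs the full evaluation with one or more genes
removed from the signature, mapping out how much any single gene carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .scoring import (
    CutoffSpec,
    CutoffStrategy,
    ScoreType,
    resolve_cutoff,
)
from .signature import Group, SignatureGene, SignatureGeneSets, subset_signature
from .survival import (
    DegenerateAnalysisError,
    EvaluationConfig,
    ModelType,
    SurvivalError,
    cox_univariate,
    evaluate_signature,
)

__all__ = [
    "NullDistribution",
    "ResamplingError",
    "random_group_pairs",
    "null_distribution",
    "summarize_null",
    "drop_analysis",
    "drop_one",
    "THREE_GENE_PRESET",
]

# Symbol-based so the preset survives platform changes; the first component
# of a composite annotation is enough to match it.
THREE_GENE_PRESET: tuple[str, ...] = ("HIST1H4J", "CDC25A", "IGFBP5")


class ResamplingError(ValueError):
    pass


@dataclass
class NullDistribution:
    """(p, HR) records over size-matched random gene-group pairs."""

    replicates: pd.DataFrame  # columns: rep, p, hr, degenerate
    n_yin: int
    n_yang: int
    cutoff_rule: CutoffSpec | None
    seed: int

    def valid(self) -> pd.DataFrame:
        return self.replicates[~self.replicates["degenerate"]]


def random_group_pairs(
    feature_ids: Sequence[str],
    n_yin: int,
    n_yang: int,
    reps: int,
    seed: int,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Draw ``reps`` disjoint (yin-like, yang-like) feature-id pairs.

    Within a pair the two groups never overlap (one draw without replacement,
    split); across replicates draws are independent. Substreams are spawned
    deterministically from the master seed, so results are reproducible and
    independent of evaluation order.
    """
    feature_ids = list(feature_ids)
    if reps < 1:
        raise ResamplingError("reps must be >= 1")
    if len(feature_ids) < n_yin + n_yang:
        raise ResamplingError(
            f"need at least {n_yin + n_yang} features, got {len(feature_ids)}"
        )
    streams = np.random.SeedSequence(seed).spawn(reps)
    pairs = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        picked = rng.choice(len(feature_ids), size=n_yin + n_yang, replace=False)
        yin = tuple(feature_ids[i] for i in picked[:n_yin])
        yang = tuple(feature_ids[i] for i in picked[n_yin:])
        pairs.append((yin, yang))
    return pairs


def _ratio_scores(expr: pd.DataFrame, yin: Sequence[str], yang: Sequence[str]) -> pd.Series:
    with np.errstate(divide="ignore", invalid="ignore"):
        s = expr.loc[list(yin)].mean(axis=0) / expr.loc[list(yang)].mean(axis=0)
    return s.replace([np.inf, -np.inf], np.nan)


def null_distribution(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    n_yin: int,
    n_yang: int,
    reps: int,
    cutoff: Union[CutoffSpec, float] = 2.0,
    seed: int = 0,
    exclude: Iterable[str] | None = None,
) -> NullDistribution:
    """Size-matched random-group null for the dichotomous ratio analysis.

    Per replicate: random-ratio scores, dichotomized at ``cutoff`` (a fixed
    value, or a :class:`CutoffSpec` — the COHORT_MEAN strategy re-resolves the
    threshold on each replicate's own scores), then a dichotomous Cox fit
    yielding (p, HR). Random groups are drawn from all features of the matrix
    by default, the signature's own genes included; pass ``exclude`` to remove
    ids from the pool.
    """
    pool = list(expr.index.astype(str))
    if exclude is not None:
        banned = {str(x) for x in exclude}
        pool = [f for f in pool if f not in banned]
    pairs = random_group_pairs(pool, n_yin, n_yang, reps, seed)

    spec = (
        cutoff
        if isinstance(cutoff, CutoffSpec)
        else CutoffSpec(CutoffStrategy.FIXED, float(cutoff), "null fixed cutoff")
    )
    common = expr.columns.intersection(clinical.index)
    surv = clinical.loc[common]

    records = []
    for rep, (yin, yang) in enumerate(pairs):
        scores = _ratio_scores(expr, yin, yang).loc[common]
        if spec.strategy is CutoffStrategy.COHORT_MEAN:
            value = float(scores.dropna().mean())
        else:
            value = spec.value
        label = pd.Series(
            np.where(scores > value, "HIGH", "LOW"), index=scores.index
        )[scores.notna()]
        p = hr = np.nan
        degenerate = label.nunique() < 2
        if not degenerate:
            try:
                res = cox_univariate(surv, label, ModelType.DICHOTOMOUS, name="ratio")
                p, hr = res.p, res.hr
            except (DegenerateAnalysisError, SurvivalError):
                degenerate = True
        records.append({"rep": rep, "p": p, "hr": hr, "degenerate": degenerate})

    return NullDistribution(
        replicates=pd.DataFrame.from_records(records),
        n_yin=n_yin,
        n_yang=n_yang,
        cutoff_rule=spec,
        seed=seed,
    )


def summarize_null(nd: NullDistribution) -> dict:
    """Mean/sd/quantiles of p and HR over non-degenerate replicates."""
    valid = nd.valid()
    if valid.empty:
        raise ResamplingError("all replicates are degenerate; nothing to summarize")
    q = [0.05, 0.25, 0.5, 0.75, 0.95]
    return {
        "n_replicates": len(nd.replicates),
        "n_degenerate": int(nd.replicates["degenerate"].sum()),
        "mean_p": float(valid["p"].mean()),
        "sd_p": float(valid["p"].std(ddof=1)) if len(valid) > 1 else 0.0,
        "p_quantiles": {str(k): float(v) for k, v in valid["p"].quantile(q).items()},
        "hr_quantiles": {str(k): float(v) for k, v in valid["hr"].quantile(q).items()},
        "median_hr": float(valid["hr"].median()),
    }


def drop_one(sig: SignatureGeneSets, group: Group | str) -> list[list[str]]:
    """All single-gene drop sets (by probe id) for one signature group."""
    group = Group(group) if not isinstance(group, Group) else group
    genes = sig.yin if group is Group.YIN else sig.yang
    return [[g.probe_id] for g in genes]


def drop_analysis(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    sig: SignatureGeneSets,
    drop_sets: Sequence[Sequence[str]],
    score_types: Sequence[ScoreType | str] = (ScoreType.YMR,),
    variable_types: Sequence[ModelType | str] = (ModelType.DICHOTOMOUS,),
    cutoff: float = 2.0,
    annotation: pd.DataFrame | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Sensitivity of (p, HR) to removing genes from the signature.

    One row per (drop set x score type x variable type); the empty drop set
    reproduces the baseline evaluation. Drop names may be probe ids or gene
    symbols; names the signature does not carry are ignored, so dropping a
    gene the platform never matched is a no-op. A drop set that would empty a
    group is an error.
    """
    score_types = [ScoreType(s) for s in score_types]
    variable_types = [ModelType(v) for v in variable_types]
    for vt in variable_types:
        if vt is ModelType.MULTIVARIATE:
            raise ResamplingError("drop analysis supports CONTINUOUS/DICHOTOMOUS only")

    rows = []
    for drop in drop_sets:
        reduced = subset_signature(sig, drop) if drop else sig
        for st in score_types:
            config = EvaluationConfig(
                score_type=st,
                cutoff_strategy=CutoffStrategy.FIXED,
                cutoff_value=cutoff,
                pseudocount=pseudocount,
                min_arm_size=2,
            )
            report = evaluate_signature(
                expr, clinical, reduced, config=config, annotation=annotation
            )
            for vt in variable_types:
                res = (
                    report.overall.cox_dichotomous
                    if vt is ModelType.DICHOTOMOUS
                    else report.overall.cox_continuous
                )
                rows.append(
                    {
                        "dropped": ";".join(drop) if drop else "",
                        "score_type": st.value,
                        "variable_type": vt.value,
                        "p": res.p if res is not None else np.nan,
                        "hr": res.hr if res is not None else np.nan,
                        "n_high": report.overall.n_high,
                        "n_low": report.overall.n_low,
                    }
                )
    return pd.DataFrame.from_records(rows)


def write_null(nd: NullDistribution, path: Union[str, Path]) -> None:
    nd.replicates.to_csv(path, sep="\t", index=False)


def write_sensitivity(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", index=False)
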