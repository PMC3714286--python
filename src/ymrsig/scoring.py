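"""Per-sample YMR / gYMR computation, cutoff resolution, and risk stratification.

The Yin/Yang mean ratio of a sample is

    YMR = mean(Yin gene expression) / mean(Yang gene expression)

with arithmetic means over the signature genes available on the platform, and
gYMR its geometric-mean analogue. Both are within-sample ratios on linear-scale
values: multiplying every value of a sample by a constant leaves its score
unchanged, which is what makes the signature usable on a single un-normalized
patient sample.

Score tables are DataFrames indexed by sample id with the score column
(``ymr`` or ``gymr``), ``n_yin_used``/``n_yang_used`` coverage counts, and an
optional ``risk_label`` column added by :func:`stratify`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .signature import Group, SignatureGeneSets

__all__ = [
    "ScoreType",
    "CutoffStrategy",
    "CutoffSpec",
    "ScoringError",
    "compute_ymr",
    "compute_gymr",
    "resolve_cutoff",
    "stratify",
    "cohort_summary",
    "RISK_HIGH",
    "RISK_LOW",
    "DEFAULT_CUTOFF",
]

RISK_HIGH = "HIGH"
RISK_LOW = "LOW"

# Default dichotomization threshold: two-fold Yin over Yang.
DEFAULT_CUTOFF = 2.0


class ScoringError(ValueError):
    """Raised for structurally unusable scoring inputs (not per-sample failures)."""


class ScoreType(str, enum.Enum):
    YMR = "ymr"
    GYMR = "gymr"


class CutoffStrategy(str, enum.Enum):
    FIXED = "FIXED"
    NORMAL_ANCHORED = "NORMAL_ANCHORED"
    COHORT_MEAN = "COHORT_MEAN"


@dataclass(frozen=True)
class CutoffSpec:
    strategy: CutoffStrategy
    value: float
    rationale: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ScoringError(f"cutoff must be positive, got {self.value}")


def _split_groups(
    gene_expr: pd.DataFrame, sig: SignatureGeneSets
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition signature-gene rows (labeled by probe id) into yin and yang blocks."""
    yin_ids = [g.probe_id for g in sig.yin if g.probe_id in gene_expr.index]
    yang_ids = [g.probe_id for g in sig.yang if g.probe_id in gene_expr.index]
    if not yin_ids or not yang_ids:
        raise ScoringError(
            "expression matrix must contain at least one yin and one yang gene row "
            f"(found {len(yin_ids)} yin, {len(yang_ids)} yang)"
        )
    return gene_expr.loc[yin_ids], gene_expr.loc[yang_ids]


def _score_frame(
    score: pd.Series,
    name: str,
    n_yin: int,
    n_yang: int,
    failed: list[str],
) -> pd.DataFrame:
    out = pd.DataFrame({name: score})
    out.index.name = "sample_id"
    out["n_yin_used"] = n_yin
    out["n_yang_used"] = n_yang
    out.attrs["score_type"] = name
    out.attrs["failed_samples"] = failed
    if failed:
        warnings.warn(
            f"{name} undefined for {len(failed)} sample(s): {failed[:5]}",
            stacklevel=3,
        )
    return out


def compute_ymr(gene_expr: pd.DataFrame, sig: SignatureGeneSets) -> pd.DataFrame:
    """Arithmetic Yin/Yang mean ratio per sample.

    ``gene_expr`` rows must be signature genes labeled by probe id (the output
    of :func:`ymrsig.mapping.summarize_gene_expression`, or a raw matrix
    already restricted to signature probes). Samples whose Yang mean is zero
    get a NaN score, are listed in ``result.attrs['failed_samples']`` and
    trigger a warning; all other samples are scored normally.
    """
    yin, yang = _split_groups(gene_expr, sig)
    yin_mean = yin.mean(axis=0)
    yang_mean = yang.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = yin_mean / yang_mean
    bad = yang_mean == 0
    score[bad] = np.nan
    return _score_frame(score, "ymr", len(yin), len(yang), list(score.index[bad]))


def compute_gymr(
    gene_expr: pd.DataFrame, sig: SignatureGeneSets, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Geometric-mean Yin/Yang ratio per sample.

    gYMR = geomean(yin + pseudocount) / geomean(yang + pseudocount), computed
    in log space. With the default pseudocount of 0 a sample containing any
    zero signature value gets a NaN score (reported, not fatal); pass a small
    pseudocount for RNA-seq matrices with zeros.
    """
    if pseudocount < 0:
        raise ScoringError("pseudocount must be non-negative")
    yin, yang = _split_groups(gene_expr, sig)
    yin_v = yin.to_numpy(dtype=float) + pseudocount
    yang_v = yang.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(yin_v).mean(axis=0) - np.log(yang_v).mean(axis=0)
    score = pd.Series(np.exp(log_ratio), index=gene_expr.columns)
    bad = (yin_v <= 0).any(axis=0) | (yang_v <= 0).any(axis=0)
    score[bad] = np.nan
    return _score_frame(score, "gymr", len(yin), len(yang), list(score.index[bad]))


def scores_of(table: pd.DataFrame) -> pd.Series:
    """The score column of a score table (whichever of ymr/gymr it carries)."""
    name = table.attrs.get("score_type") or (
        "ymr" if "ymr" in table.columns else "gymr"
    )
    return table[name]


def resolve_cutoff(
    scores: pd.DataFrame | None = None,
    strategy: CutoffStrategy | str = CutoffStrategy.FIXED,
    fixed_value: float | None = None,
    normal_scores: pd.DataFrame | None = None,
) -> CutoffSpec:
    """Resolve a risk cutoff.

    FIXED           → ``fixed_value`` (default 2.0, the two-fold convention);
    NORMAL_ANCHORED → 2.0 scaled by the normal-cohort mean score (a normal
                      cohort sitting at 1.0 leaves the cutoff at 2.0);
    COHORT_MEAN     → mean score of the cohort being stratified, the common
                      mean-risk-score split when no normal samples exist.
    """
    strategy = CutoffStrategy(strategy)
    if strategy is CutoffStrategy.FIXED:
        value = DEFAULT_CUTOFF if fixed_value is None else float(fixed_value)
        return CutoffSpec(strategy, value, f"fixed cutoff {value}")
    if strategy is CutoffStrategy.NORMAL_ANCHORED:
        if normal_scores is None:
            raise ScoringError("NORMAL_ANCHORED cutoff requires normal-cohort scores")
        normal_mean = float(scores_of(normal_scores).dropna().mean())
        return CutoffSpec(
            strategy,
            DEFAULT_CUTOFF * normal_mean,
            f"2.0 x normal-cohort mean {normal_mean:.4g}",
        )
    # COHORT_MEAN
    if scores is None:
        raise ScoringError("COHORT_MEAN cutoff requires cohort scores")
    mean = float(scores_of(scores).dropna().mean())
    return CutoffSpec(strategy, mean, f"cohort mean score {mean:.4g}")


def stratify(scores: pd.DataFrame, cutoff: CutoffSpec) -> pd.DataFrame:
    """Add a ``risk_label`` column: HIGH iff score > cutoff, LOW iff score <= cutoff.

    Ties go LOW (high risk is a strict exceedance of the threshold). NaN
    scores get a missing label.
    """
    out = scores.copy()
    s = scores_of(scores)
    label = pd.Series(pd.NA, index=s.index, dtype="object")
    label[s > cutoff.value] = RISK_HIGH
    label[s <= cutoff.value] = RISK_LOW
    out["risk_label"] = label
    out.attrs.update(scores.attrs)
    out.attrs["cutoff"] = cutoff
    return out


def cohort_summary(
    scores: pd.DataFrame | pd.Series,
    cohorts: pd.Series | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cohort n / mean / sd / min / quartiles / max of the score.

    ``cohorts`` labels samples (e.g. ``normal`` vs ``tumor``); omitted, the
    whole table is one cohort named ``all``. Empty cohorts are an error.
    """
    s = scores_of(scores) if isinstance(scores, pd.DataFrame) else scores
    if cohorts is None:
        groups = pd.Series("all", index=s.index)
    else:
        groups = pd.Series(list(cohorts), index=s.index)

    records = []
    for name, values in s.groupby(groups):
        values = values.dropna()
        if values.empty:
            raise ScoringError(f"cohort {name!r} has no scored samples")
        q = values.quantile([0.25, 0.5, 0.75])
        records.append(
            {
                "cohort": name,
                "n": len(values),
                "mean": values.mean(),
                "sd": values.std(ddof=1) if len(values) > 1 else 0.0,
                "min": values.min(),
                "q25": q.loc[0.25],
                "median": q.loc[0.5],
                "q75": q.loc[0.75],
                "max": values.max(),
            }
        )
    return pd.DataFrame.from_records(records).set_index("cohort")
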