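"""Cross-platform feature mapping and gene-level expression summarization.

Expression matrices are plain pandas DataFrames: rows are platform features
(probe sets, genes, transcripts), columns are samples, values are linear-scale
non-negative intensities or RPKM-like quantities. Signature genes defined on
HG-U95Av2 are projected onto an arbitrary platform in two steps:

1. vendor-declared *best-match* feature (a ``best_match_of`` column naming the
   source-platform probe id the feature corresponds to), else
2. exact gene-symbol match, splitting ``///`` composites on both sides,
   case-insensitive; several features sharing the symbol are averaged.

Genes with no match are dropped from scoring with a warning — the method
tolerates partial platform coverage by construction.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .signature import SignatureGene, SignatureGeneSets

logger = logging.getLogger(__name__)

__all__ = [
    "MatchKind",
    "ProbeMapEntry",
    "ProbeMap",
    "CoverageReport",
    "MappingError",
    "read_expression",
    "read_annotation",
    "identity_annotation",
    "build_probe_map",
    "summarize_gene_expression",
    "coverage_report",
]


class MappingError(ValueError):
    """Raised on malformed annotation/expression inputs or map/matrix mismatch."""


class MatchKind(str, enum.Enum):
    BEST_MATCH = "BEST_MATCH"
    SINGLE_SYMBOL = "SINGLE_SYMBOL"
    MULTI_SYMBOL_AVG = "MULTI_SYMBOL_AVG"
    UNMATCHED = "UNMATCHED"


@dataclass(frozen=True)
class ProbeMapEntry:
    gene: SignatureGene
    feature_ids: tuple[str, ...]
    match_kind: MatchKind


@dataclass
class ProbeMap:
    """Resolution of every signature gene onto a platform's features."""

    entries: list[ProbeMapEntry] = field(default_factory=list)

    def matched(self) -> list[ProbeMapEntry]:
        return [e for e in self.entries if e.match_kind is not MatchKind.UNMATCHED]

    def entry_for(self, probe_id: str) -> ProbeMapEntry:
        for e in self.entries:
            if e.gene.probe_id == probe_id:
                return e
        raise KeyError(probe_id)


@dataclass
class CoverageReport:
    n_yin_matched: int
    n_yin_total: int
    n_yang_matched: int
    n_yang_total: int
    warn_threshold: float
    warnings: list[str] = field(default_factory=list)

    @property
    def yin_fraction(self) -> float:
        return self.n_yin_matched / self.n_yin_total if self.n_yin_total else 0.0

    @property
    def yang_fraction(self) -> float:
        return self.n_yang_matched / self.n_yang_total if self.n_yang_total else 0.0

    @property
    def n_matched(self) -> int:
        return self.n_yin_matched + self.n_yang_matched

    @property
    def warning(self) -> bool:
        return bool(self.warnings)


def read_expression(path: Union[str, Path], sep: str | None = None) -> pd.DataFrame:
    """Read an expression matrix: first column feature ids, remaining columns samples.

    Accepts TSV/CSV (delimiter inferred from extension unless given) and
    GCT 1.2 (``.gct``: two header lines skipped, ``Description`` column dropped).
    Validates non-negativity and unique sample ids.
    """
    path = Path(path)
    if path.suffix.lower() == ".gct":
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if df.columns.size and df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
    else:
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    validate_expression(df, source=str(path))
    return df


def validate_expression(expr: pd.DataFrame, source: str = "expression matrix") -> None:
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise MappingError(f"{source}: duplicate sample ids {dupes}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise MappingError(f"{source}: non-numeric expression values")
    if np.isfinite(values).all() and (values < 0).any():
        raise MappingError(f"{source}: negative expression values (linear scale expected)")


def read_annotation(path: Union[str, Path], sep: str | None = None) -> pd.DataFrame:
    """Read a platform annotation table (`feature_id`, `gene_symbol`[, `best_match_of`])."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"feature_id", "gene_symbol"} - set(df.columns)
    if missing:
        raise MappingError(f"{path}: missing column(s) {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        dupes = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise MappingError(f"{path}: duplicate feature ids {dupes[:5]}")
    return df


def identity_annotation(sig: SignatureGeneSets) -> pd.DataFrame:
    """Annotation for a platform whose features are the signature probes themselves."""
    return pd.DataFrame(
        {
            "feature_id": [g.probe_id for g in sig.genes],
            "gene_symbol": [g.gene_symbol for g in sig.genes],
            "best_match_of": [g.probe_id for g in sig.genes],
        }
    )


def _norm_symbols(composite: str) -> set[str]:
    return {s.strip().upper() for s in str(composite).split("///") if s.strip()}


def build_probe_map(sig: SignatureGeneSets, annot: pd.DataFrame) -> ProbeMap:
    """Resolve each signature gene to platform features.

    Resolution order per gene: (1) features whose ``best_match_of`` equals the
    signature probe id; (2) features whose symbol matches (any ``///``
    component, case-insensitive). Unmatched genes are flagged, not errors.
    """
    if annot.empty:
        raise MappingError("annotation table is empty")
    missing = {"feature_id", "gene_symbol"} - set(annot.columns)
    if missing:
        raise MappingError(f"annotation table missing column(s) {sorted(missing)}")
    if annot["feature_id"].duplicated().any():
        raise MappingError("annotation table has duplicate feature ids")

    has_best = "best_match_of" in annot.columns
    best_index: dict[str, list[str]] = {}
    if has_best:
        for fid, src in zip(annot["feature_id"], annot["best_match_of"]):
            if pd.isna(src) or not str(src).strip():
                continue
            best_index.setdefault(str(src).strip(), []).append(str(fid))

    symbol_index: dict[str, list[str]] = {}
    for fid, sym in zip(annot["feature_id"], annot["gene_symbol"]):
        if pd.isna(sym):
            continue
        for component in _norm_symbols(sym):
            symbol_index.setdefault(component, []).append(str(fid))

    entries: list[ProbeMapEntry] = []
    for gene in sig.genes:
        features = best_index.get(gene.probe_id, [])
        if features:
            kind = MatchKind.BEST_MATCH
        else:
            hits: list[str] = []
            for component in _norm_symbols(gene.gene_symbol):
                for fid in symbol_index.get(component, []):
                    if fid not in hits:
                        hits.append(fid)
            features = hits
            if not features:
                kind = MatchKind.UNMATCHED
            elif len(features) == 1:
                kind = MatchKind.SINGLE_SYMBOL
            else:
                kind = MatchKind.MULTI_SYMBOL_AVG
        entries.append(ProbeMapEntry(gene, tuple(features), kind))

    unmatched = [e.gene.gene_symbol for e in entries if e.match_kind is MatchKind.UNMATCHED]
    if unmatched:
        logger.warning(
            "%d signature gene(s) unmatched on this platform: %s",
            len(unmatched),
            ", ".join(unmatched),
        )
    return ProbeMap(entries)


def summarize_gene_expression(expr: pd.DataFrame, pmap: ProbeMap) -> pd.DataFrame:
    """One row per matched signature gene: arithmetic mean over its mapped features.

    Row order is signature order (yin block then yang block); rows are labeled
    by the signature probe id so downstream scoring can identify groups on any
    platform. Unmatched genes are absent from the output.
    """
    rows = []
    index = []
    for entry in pmap.matched():
        missing = [f for f in entry.feature_ids if f not in expr.index]
        if missing:
            raise MappingError(
                f"mapped feature(s) {missing} for gene {entry.gene.gene_symbol} "
                "absent from expression matrix"
            )
        block = expr.loc[list(entry.feature_ids)]
        rows.append(block.mean(axis=0))
        index.append(entry.gene.probe_id)
    if not rows:
        raise MappingError("no signature gene matched the expression platform")
    out = pd.DataFrame(rows, index=pd.Index(index, name=expr.index.name))
    out.columns = expr.columns
    return out


def coverage_report(pmap: ProbeMap, warn_threshold: float = 0.8) -> CoverageReport:
    """Matched/unmatched counts per group, warning when a group falls below threshold."""
    from .signature import Group

    counts = {Group.YIN: [0, 0], Group.YANG: [0, 0]}  # [matched, total]
    for entry in pmap.entries:
        counts[entry.gene.group][1] += 1
        if entry.match_kind is not MatchKind.UNMATCHED:
            counts[entry.gene.group][0] += 1

    report = CoverageReport(
        n_yin_matched=counts[Group.YIN][0],
        n_yin_total=counts[Group.YIN][1],
        n_yang_matched=counts[Group.YANG][0],
        n_yang_total=counts[Group.YANG][1],
        warn_threshold=warn_threshold,
    )
    for label, frac in (("yin", report.yin_fraction), ("yang", report.yang_fraction)):
        if frac < warn_threshold:
            msg = f"{label} group coverage {frac:.0%} below {warn_threshold:.0%}"
            report.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    return report
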