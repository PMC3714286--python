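"""Yin/Yang signature gene sets: loading, validation, serialization.

The default signature is the 31-Yin / 32-Yang lung adenocarcinoma gene list
defined on the Affymetrix HG-U95Av2 platform. Yin genes are upregulated in
lung tumors relative to normal lung tissue; Yang genes are downregulated.
Composite probe annotations covering two paralogues (e.g. ``HIST1H4J///HIST1H4K``)
are kept as a single entry with the composite symbol; cross-platform symbol
matching splits on ``///`` (see :mod:`ymrsig.mapping`).
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "Group",
    "SignatureGene",
    "SignatureGeneSets",
    "ValidationIssue",
    "ValidationReport",
    "SignatureError",
    "load_default_signature",
    "load_signature_file",
    "write_signature_file",
    "validate_signature",
]

DEFAULT_SIGNATURE_NAME = "yin-yang-lung"
DEFAULT_SIGNATURE_VERSION = "1.0"
_DEFAULT_RESOURCE = "default_signature.tsv"

# Default signature dimensions on HG-U95Av2.
N_YIN_DEFAULT = 31
N_YANG_DEFAULT = 32


class SignatureError(ValueError):
    """Raised when a signature file or object fails validation."""


class Group(str, enum.Enum):
    """Signature gene group: YIN (tumor-upregulated) or YANG (tumor-downregulated)."""

    YIN = "yin"
    YANG = "yang"

    @classmethod
    def parse(cls, label: str) -> "Group":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise SignatureError(f"unknown group label: {label!r}") from None


@dataclass(frozen=True)
class SignatureGene:
    """One signature entry: a platform probe id, its gene symbol, and its group.

    ``gene_symbol`` may be a ``///``-joined composite covering more than one
    HGNC symbol, kept verbatim from the source annotation.
    """

    probe_id: str
    gene_symbol: str
    group: Group

    def symbols(self) -> tuple[str, ...]:
        """Individual symbols of a possibly composite annotation."""
        return tuple(s.strip() for s in self.gene_symbol.split("///") if s.strip())


@dataclass
class SignatureGeneSets:
    """The two opposing gene groups of a ratio signature."""

    yin: list[SignatureGene]
    yang: list[SignatureGene]
    name: str = DEFAULT_SIGNATURE_NAME
    version: str = DEFAULT_SIGNATURE_VERSION

    @property
    def genes(self) -> list[SignatureGene]:
        """All genes, yin first then yang (the canonical row order for scoring)."""
        return list(self.yin) + list(self.yang)

    @property
    def probe_ids(self) -> list[str]:
        return [g.probe_id for g in self.genes]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureGeneSets):
            return NotImplemented
        return self.yin == other.yin and self.yang == other.yang

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [g.probe_id for g in self.genes],
                "gene_symbol": [g.gene_symbol for g in self.genes],
                "group": [g.group.value for g in self.genes],
            }
        )


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # DUPLICATE | OVERLAP | EMPTY_GROUP
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.issues


def validate_signature(sig: SignatureGeneSets) -> ValidationReport:
    """Check structural invariants: non-empty groups, unique probes, disjoint groups.

    Report-based: never raises; ``report.valid`` is True iff no issue was found.
    """
    issues: list[ValidationIssue] = []
    for label, genes in (("yin", sig.yin), ("yang", sig.yang)):
        if not genes:
            issues.append(ValidationIssue("EMPTY_GROUP", f"{label} group is empty"))

    seen: dict[str, str] = {}
    for gene in sig.genes:
        if gene.probe_id in seen:
            issues.append(
                ValidationIssue(
                    "DUPLICATE",
                    f"probe_id {gene.probe_id} appears more than once",
                )
            )
        seen[gene.probe_id] = gene.group.value

    yin_syms = {s.upper() for g in sig.yin for s in g.symbols()}
    yang_syms = {s.upper() for g in sig.yang for s in g.symbols()}
    for sym in sorted(yin_syms & yang_syms):
        issues.append(
            ValidationIssue("OVERLAP", f"gene symbol {sym} present in both groups")
        )
    return ValidationReport(issues)


def _from_frame(df: pd.DataFrame, name: str, version: str, source: str) -> SignatureGeneSets:
    required = {"probe_id", "gene_symbol", "group"}
    missing = required - set(df.columns)
    if missing:
        raise SignatureError(f"{source}: missing column(s) {sorted(missing)}")

    yin: list[SignatureGene] = []
    yang: list[SignatureGene] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        probe = str(row.probe_id).strip()
        symbol = str(row.gene_symbol).strip()
        if not probe:
            raise SignatureError(f"{source}: empty probe_id at row {row_no}")
        gene = SignatureGene(probe, symbol, Group.parse(row.group))
        (yin if gene.group is Group.YIN else yang).append(gene)

    sig = SignatureGeneSets(yin=yin, yang=yang, name=name, version=version)
    report = validate_signature(sig)
    if not report.valid:
        detail = "; ".join(i.message for i in report.issues)
        raise SignatureError(f"{source}: invalid signature ({detail})")
    return sig


def load_signature_file(
    path: Union[str, Path],
    sep: str | None = None,
    name: str | None = None,
    version: str = "unversioned",
) -> SignatureGeneSets:
    """Read a signature from a delimited text table.

    Expects a header with columns ``probe_id``, ``gene_symbol``, ``group``
    (group labels case-insensitive ``yin``/``yang``). The delimiter is
    inferred from the extension (``.csv`` → comma, otherwise tab) unless
    given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    return _from_frame(df, name or path.stem, version, source=str(path))


def write_signature_file(sig: SignatureGeneSets, path: Union[str, Path]) -> None:
    """Write a signature as a tab-delimited table (round-trips with the reader)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    sig.to_frame().to_csv(path, sep=sep, index=False)


def load_default_signature() -> SignatureGeneSets:
    """Load the packaged 31-Yin / 32-Yang HG-U95Av2 lung signature.

    Deterministic and idempotent; raises :class:`SignatureError` if the
    packaged resource is corrupted or does not have the expected 31+32 shape.
    """
    resource = importlib.resources.files("ymrsig.data").joinpath(_DEFAULT_RESOURCE)
    with importlib.resources.as_file(resource) as fp:
        sig = load_signature_file(
            fp, sep="\t", name=DEFAULT_SIGNATURE_NAME, version=DEFAULT_SIGNATURE_VERSION
        )
    if len(sig.yin) != N_YIN_DEFAULT or len(sig.yang) != N_YANG_DEFAULT:
        raise SignatureError(
            "packaged default signature is corrupted: expected "
            f"{N_YIN_DEFAULT} yin + {N_YANG_DEFAULT} yang, got "
            f"{len(sig.yin)} + {len(sig.yang)}"
        )
    return sig


def subset_signature(
    sig: SignatureGeneSets, drop: Iterable[str]
) -> SignatureGeneSets:
    """Return a copy of ``sig`` without the genes named in ``drop``.

    ``drop`` entries may be probe ids or gene symbols (any ``///`` component
    matches, case-insensitively). Names absent from the signature are ignored
    — dropping a gene the platform never matched is a no-op by design.
    Raises :class:`SignatureError` if a group would be emptied.
    """
    targets = {str(d).strip().upper() for d in drop}

    def keep(g: SignatureGene) -> bool:
        if g.probe_id.upper() in targets:
            return False
        return not any(s.upper() in targets for s in g.symbols())

    yin = [g for g in sig.yin if keep(g)]
    yang = [g for g in sig.yang if keep(g)]
    if not yin or not yang:
        raise SignatureError("drop set would empty a signature group")
    return SignatureGeneSets(yin=yin, yang=yang, name=sig.name, version=sig.version)
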