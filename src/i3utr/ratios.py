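"""Fractional 3'UTR/CDS ratio, Hi/Lo gene classification, replicate concordance.

The fractional ratio utr / (utr + cds) runs from 0 (pure CDS expression) to
1 (pure 3'UTR expression). Expressed genes with ratio strictly above the Hi
threshold are called HI_UTR; strictly below the Lo threshold, HI_CDS; values
exactly at a threshold are INTERMEDIATE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class GeneClass(str, enum.Enum):
    HI_UTR = "HI_UTR"
    HI_CDS = "HI_CDS"
    INTERMEDIATE = "INTERMEDIATE"
    NOT_EXPRESSED = "NOT_EXPRESSED"


class UndefinedRatioError(ValueError):
    """Both region expressions are zero: the fractional ratio is undefined."""


@dataclass(frozen=True)
class ClassificationParams:
    hi_threshold: float = 0.6
    lo_threshold: float = 0.4
    min_reads: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.lo_threshold < self.hi_threshold <= 1:
            raise ValueError(
                "thresholds must satisfy 0 <= lo < hi <= 1, got "
                f"lo={self.lo_threshold}, hi={self.hi_threshold}"
            )


@dataclass
class GeneRatioRecord:
    gene_id: str
    utr_expression: float
    cds_expression: float
    expressed: bool
    ratio: float | None = None
    klass: GeneClass | None = None

    def __post_init__(self) -> None:
        if self.ratio is None and (self.utr_expression + self.cds_expression) > 0:
            self.ratio = fractional_ratio(self.utr_expression, self.cds_expression)


@dataclass(frozen=True)
class ConcordanceResult:
    set_a_size: int
    set_b_size: int
    intersection_size: int
    percent_identity: float
    metric: str = "jaccard"


def fractional_ratio(utr_expression: float, cds_expression: float) -> float:
    """3'UTR share of total expression: utr / (utr + cds), in [0, 1]."""
    if utr_expression < 0 or cds_expression < 0:
        raise ValueError("expressions must be non-negative")
    total = utr_expression + cds_expression
    if total == 0:
        raise UndefinedRatioError(
            "ratio undefined when both region expressions are zero"
        )
    return utr_expression / total


def classify_gene(
    record: GeneRatioRecord, params: ClassificationParams = ClassificationParams()
) -> GeneClass:
    """Assign HI_UTR / HI_CDS / INTERMEDIATE / NOT_EXPRESSED (strict thresholds)."""
    if not record.expressed:
        record.klass = GeneClass.NOT_EXPRESSED
        return record.klass
    if record.ratio is None:
        raise UndefinedRatioError(
            f"{record.gene_id}: expressed gene with undefined ratio"
        )
    if record.ratio > params.hi_threshold:
        record.klass = GeneClass.HI_UTR
    elif record.ratio < params.lo_threshold:
        record.klass = GeneClass.HI_CDS
    else:
        record.klass = GeneClass.INTERMEDIATE
    return record.klass


def classify_records(
    records: Iterable[GeneRatioRecord],
    params: ClassificationParams = ClassificationParams(),
) -> list[GeneRatioRecord]:
    records = list(records)
    for rec in records:
        classify_gene(rec, params)
    return records


def replicate_concordance(
    hi_set_a: set[str] | Sequence[str],
    hi_set_b: set[str] | Sequence[str],
    metric: str = "jaccard",
) -> ConcordanceResult:
    """Percent identity between two gene-call sets.

    ``jaccard``: 100 x |A∩B| / |A∪B| (default). ``overlap_smaller``:
    100 x |A∩B| / min(|A|, |B|). Both are reported since "identity" between
    replicate call sets is a convention, not a single formula.
    """
    a, b = set(hi_set_a), set(hi_set_b)
    if not a and not b:
        raise ValueError("concordance undefined for two empty sets")
    inter = len(a & b)
    if metric == "jaccard":
        denom = len(a | b)
    elif metric == "overlap_smaller":
        denom = min(len(a), len(b)) or max(len(a), len(b))
    else:
        raise ValueError(f"unknown concordance metric {metric!r}")
    return ConcordanceResult(
        set_a_size=len(a),
        set_b_size=len(b),
        intersection_size=inter,
        percent_identity=100.0 * inter / denom,
        metric=metric,
    )


def records_to_frame(records: Sequence[GeneRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "utr_expr": [r.utr_expression for r in records],
            "cds_expr": [r.cds_expression for r in records],
            "ratio": [r.ratio for r in records],
            "expressed": [r.expressed for r in records],
            "class": [r.klass.value if r.klass else "" for r in records],
        }
    )


def export_class_lists(
    records: Sequence[GeneRatioRecord],
    out_dir: str | Path,
    params: ClassificationParams = ClassificationParams(),
) -> dict[str, object]:
    """Write ranked HI_UTR / HI_CDS gene lists for downstream enrichment tools.

    HI_UTR is sorted by descending ratio, HI_CDS ascending; ties break on
    gene_id for stable output. Returns each class's share of expressed genes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = classify_records(records, params)
    expressed = [r for r in records if r.expressed]
    shares: dict[str, object] = {"n_expressed": len(expressed)}
    for klass, ascending in ((GeneClass.HI_UTR, False), (GeneClass.HI_CDS, True)):
        members = [r for r in expressed if r.klass is klass]
        members.sort(key=lambda r: ((r.ratio if ascending else -r.ratio), r.gene_id))
        df = pd.DataFrame(
            {"gene_id": [r.gene_id for r in members],
             "ratio": [r.ratio for r in members]}
        )
        path = out_dir / f"{klass.value.lower()}_genes.tsv"
        df.to_csv(path, sep="\t", index=False)
        shares[klass.value] = {
            "n": len(members),
            "share_of_expressed": (len(members) / len(expressed)) if expressed else 0.0,
            "path": str(path),
        }
    return shares
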