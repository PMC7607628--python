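"""PI3K-pathway somatic alteration calls and response crosstabs.

A sample is pathway-altered when it carries a qualifying event in PIK3CA,
AKT1 or PTEN: any non-synonymous small variant in the three genes,
amplification of PIK3CA/AKT1, or deep (likely homozygous) deletion of PTEN
called from a strongly negative copy-number log ratio (default cutoff
≤ −2.0; the archetypal deep deletion in this setting printed −2.87).
Pathogenicity is deliberately not adjudicated — any non-synonymous event in
the gene set qualifies.

Pathway status is cross-tabulated against best overall response, optionally
collapsing the SD ≥ 4 months and SD < 4 months subgroups into a single SD
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AlterationType",
    "VariantRecord",
    "GeneRules",
    "PathwayStatus",
    "ResponseCrosstab",
    "SNV_CLASSES",
    "classify_alteration",
    "sample_pathway_status",
    "crosstab_with_response",
]


class AlterationType(str, Enum):
    MISSENSE = "MISSENSE"
    TRUNCATING = "TRUNCATING"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICE = "SPLICE"
    AMPLIFICATION = "AMPLIFICATION"
    DELETION = "DELETION"


SNV_CLASSES = frozenset(
    {
        AlterationType.MISSENSE,
        AlterationType.TRUNCATING,
        AlterationType.FRAMESHIFT,
        AlterationType.SPLICE,
    }
)


@dataclass(frozen=True)
class VariantRecord:
    sample_id: str
    gene: str
    alteration_type: AlterationType
    protein_change: str | None = None
    cn_log_ratio: float | None = None

    def __post_init__(self) -> None:
        is_cn = self.alteration_type in (
            AlterationType.AMPLIFICATION,
            AlterationType.DELETION,
        )
        if is_cn and self.cn_log_ratio is None:
            raise ValueError(
                f"{self.gene} {self.alteration_type.value}: cn_log_ratio required"
            )
        if not is_cn and self.cn_log_ratio is not None:
            raise ValueError(
                f"{self.gene} {self.alteration_type.value}: cn_log_ratio not applicable"
            )


@dataclass(frozen=True)
class GeneRules:
    """Which events in which genes count as pathway-activating."""

    snv_amp_genes: frozenset[str] = frozenset({"PIK3CA", "AKT1"})
    snv_del_genes: frozenset[str] = frozenset({"PTEN"})
    deep_deletion_log_ratio: float = -2.0
    amplification_log_ratio: float = 1.0


@dataclass(frozen=True)
class PathwayStatus:
    sample_id: str
    altered: bool
    evidence: tuple[VariantRecord, ...] = ()


def classify_alteration(v: VariantRecord, rules: GeneRules = GeneRules()) -> bool:
    """True iff the variant is a pathway-qualifying alteration."""
    if not isinstance(v.alteration_type, AlterationType):
        raise ValueError(f"unknown alteration type {v.alteration_type!r}")
    if v.gene in rules.snv_amp_genes:
        if v.alteration_type in SNV_CLASSES:
            return True
        if v.alteration_type is AlterationType.AMPLIFICATION:
            return v.cn_log_ratio >= rules.amplification_log_ratio
        return False
    if v.gene in rules.snv_del_genes:
        if v.alteration_type in SNV_CLASSES:
            return True
        if v.alteration_type is AlterationType.DELETION:
            return v.cn_log_ratio <= rules.deep_deletion_log_ratio
        return False
    return False


def sample_pathway_status(
    sample_id: str,
    variants: Sequence[VariantRecord],
    rules: GeneRules = GeneRules(),
) -> PathwayStatus:
    """Pathway status for one sample: altered iff any qualifying variant."""
    evidence = tuple(v for v in variants if classify_alteration(v, rules))
    return PathwayStatus(sample_id=sample_id, altered=bool(evidence), evidence=evidence)


@dataclass(frozen=True)
class ResponseCrosstab:
    """Counts of altered / unaltered samples per response group."""

    counts: pd.DataFrame  # index: [altered, unaltered]; columns: response groups

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def altered_fraction(self, group: str | None = None) -> float:
        """Fraction of altered samples overall or within one response group."""
        if group is None:
            return float(self.counts.loc["altered"].sum() / self.n)
        col = self.counts[group]
        return float(col.loc["altered"] / col.sum())


def crosstab_with_response(
    statuses: Sequence[PathwayStatus],
    responses: Mapping[str, str],
    collapse_sd: bool = False,
) -> ResponseCrosstab:
    """Tabulate pathway status against best-overall-response groups.

    ``responses`` maps sample id to a response-group label; only samples
    present in both inputs are counted.  With ``collapse_sd`` the labels
    ``SD>=4mo`` and ``SD<4mo`` merge into ``SD``.
    """
    ids = [s.sample_id for s in statuses]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids in pathway statuses")
    rows = []
    for s in statuses:
        if s.sample_id not in responses:
            continue
        group = responses[s.sample_id]
        if collapse_sd and group in ("SD>=4mo", "SD<4mo"):
            group = "SD"
        rows.append(("altered" if s.altered else "unaltered", group))
    if not rows:
        raise ValueError("no samples shared between statuses and responses")
    df = pd.DataFrame(rows, columns=["status", "group"])
    counts = (
        pd.crosstab(df["status"], df["group"])
        .reindex(index=["altered", "unaltered"], fill_value=0)
        .rename_axis(index=None, columns=None)
    )
    return ResponseCrosstab(counts=counts)
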