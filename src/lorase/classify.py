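"""Allelic-ratio computation, informativeness filtering, and allelic calls.

The allelic ratio of a feature is maternal / (maternal + paternal)
assigned reads: 1 means fully maternal, 0 fully paternal. A feature is
informative when enough of its reads overlap at least one phased SNV
(default 10 for long reads, 20 for short reads). Informative features are
classified with hard cutoffs: ratio >= 0.7 maternal, ratio <= 0.3
paternal (boundaries inclusive on the allele-specific side), anything
between biallelic.

Under a fully skewed X-inactivation design with the maternal X active,
reads from the paternal allele of an X-linked gene diagnose expression
from the inactive X: genes with ratio above the subject cutoff (default
0.9) are subject to inactivation, genes below it with enough paternal
reads are escape candidates, and a gene expressed only from the inactive
X (an Xist-like pattern) is flagged separately.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Thresholds",
    "SHORT_READ_MIN_INFORMATIVE",
    "Category",
    "XciFlag",
    "AllelicCall",
    "allelic_ratio",
    "classify_feature",
    "classify_table",
    "detect_escape",
]

SHORT_READ_MIN_INFORMATIVE = 20


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs for informativeness, allelic classification and XCI calls.

    min_informative_reads: minimum SNV-overlapping reads per feature
        (10 is the long-read default; use 20 for short-read tables).
    low_cut / high_cut: allelic-ratio boundaries; ratio <= low_cut is
        paternal, ratio >= high_cut maternal, in between biallelic.
    xci_subject_ratio: X-linked genes above this ratio (maternal-active
        design) are subject to X inactivation.
    min_inactive_reads: paternal reads required before an X-linked gene
        is flagged as an escape candidate.
    """

    min_informative_reads: int = 10
    low_cut: float = 0.3
    high_cut: float = 0.7
    xci_subject_ratio: float = 0.9
    min_inactive_reads: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_cut < self.high_cut <= 1.0):
            raise ValueError("require 0 <= low_cut < high_cut <= 1")
        if self.min_informative_reads < 1 or self.min_inactive_reads < 1:
            raise ValueError("minimum read counts must be >= 1")
        if not (0.0 <= self.xci_subject_ratio <= 1.0):
            raise ValueError("xci_subject_ratio must lie in [0, 1]")


class Category(enum.Enum):
    MATERNAL = "MATERNAL"
    PATERNAL = "PATERNAL"
    BIALLELIC = "BIALLELIC"
    NOT_INFORMATIVE = "NOT_INFORMATIVE"


class XciFlag(enum.Enum):
    SUBJECT = "SUBJECT"
    ESCAPE_CANDIDATE = "ESCAPE_CANDIDATE"
    INACTIVE_X_EXPRESSED = "INACTIVE_X_EXPRESSED"
    NOT_CALLED = "NOT_CALLED"


@dataclass(frozen=True)
class AllelicCall:
    feature_id: str
    maternal: int
    paternal: int
    snp_overlap_reads: int
    ratio: float  # NaN when maternal + paternal == 0
    informative: bool
    category: Category


def allelic_ratio(maternal: int, paternal: int) -> float:
    """Maternal fraction of tagged reads; NaN when no read is tagged."""
    if maternal < 0 or paternal < 0:
        raise ValueError("counts must be non-negative")
    total = maternal + paternal
    if total == 0:
        return math.nan
    return maternal / total


def classify_feature(
    feature_id: str,
    maternal: int,
    paternal: int,
    snp_overlap_reads: int,
    thresholds: Thresholds = Thresholds(),
) -> AllelicCall:
    """Call one feature maternal / paternal / biallelic / not informative.

    Boundary ratios are allele-specific: exactly ``high_cut`` is maternal
    and exactly ``low_cut`` paternal. Features failing the informativeness
    filter — including those with an undefined ratio — are never
    classified biallelic.
    """
    ratio = allelic_ratio(maternal, paternal)
    informative = snp_overlap_reads >= thresholds.min_informative_reads and not math.isnan(ratio)
    if not informative:
        category = Category.NOT_INFORMATIVE
    elif ratio >= thresholds.high_cut:
        category = Category.MATERNAL
    elif ratio <= thresholds.low_cut:
        category = Category.PATERNAL
    else:
        category = Category.BIALLELIC
    return AllelicCall(
        feature_id=feature_id,
        maternal=maternal,
        paternal=paternal,
        snp_overlap_reads=snp_overlap_reads,
        ratio=ratio,
        informative=informative,
        category=category,
    )


def classify_table(
    counts: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> tuple[pd.DataFrame, dict]:
    """Classify every row of an allelic count table.

    ``counts`` needs columns feature_id, maternal, paternal,
    snp_overlap_reads; chrom / is_x_linked / biotype are carried through
    when present. Returns the call table plus a summary with category
    counts split by autosome/X and coding/noncoding where available.
    """
    required = {"feature_id", "maternal", "paternal", "snp_overlap_reads"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    calls = counts.copy()
    results = [
        classify_feature(
            row.feature_id, int(row.maternal), int(row.paternal),
            int(row.snp_overlap_reads), thresholds,
        )
        for row in counts.itertuples(index=False)
    ]
    calls["ratio"] = [c.ratio for c in results]
    calls["informative"] = [c.informative for c in results]
    calls["category"] = [c.category.value for c in results]

    informative = calls[calls["informative"]]
    summary: dict = {
        "n_features": int(len(calls)),
        "n_informative": int(len(informative)),
        "categories": informative["category"].value_counts().to_dict(),
    }
    if "is_x_linked" in calls.columns:
        summary["n_informative_autosomal"] = int((~informative["is_x_linked"]).sum())
        summary["n_informative_x"] = int(informative["is_x_linked"].sum())
    if "biotype" in calls.columns:
        summary["n_informative_coding"] = int((informative["biotype"] == "coding").sum())
        summary["n_informative_noncoding"] = int((informative["biotype"] != "coding").sum())
    return calls, summary


def detect_escape(
    calls: pd.DataFrame,
    x_chrom: str = "chrX",
    design: str = "skewed-maternal",
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Flag X-linked informative genes under a skewed-XCI design.

    With the maternal X forced active, every informative X-linked gene is
    flagged: ratio above ``xci_subject_ratio`` -> SUBJECT (inactivated);
    ratio at or below ``low_cut`` -> INACTIVE_X_EXPRESSED (the Xist-like
    pattern); otherwise ESCAPE_CANDIDATE when at least
    ``min_inactive_reads`` paternal reads back the inactive-X signal.
    """
    if design != "skewed-maternal":
        raise ValueError(f"unsupported XCI design: {design!r}")
    if "chrom" not in calls.columns:
        raise ValueError("calls table needs a chrom column for escape detection")
    x_calls = calls[(calls["chrom"] == x_chrom) & calls["informative"]].copy()
    flags = []
    for row in x_calls.itertuples(index=False):
        if row.ratio > thresholds.xci_subject_ratio:
            flags.append(XciFlag.SUBJECT.value)
        elif row.ratio <= thresholds.low_cut:
            flags.append(XciFlag.INACTIVE_X_EXPRESSED.value)
        elif row.paternal >= thresholds.min_inactive_reads:
            flags.append(XciFlag.ESCAPE_CANDIDATE.value)
        else:
            flags.append(XciFlag.NOT_CALLED.value)
    x_calls["xci_flag"] = flags
    return x_calls
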