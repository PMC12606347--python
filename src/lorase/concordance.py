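"""Concordance between two allelic call tables (e.g. long- vs short-read).

Joins the two tables on features informative in both, measures how the
biallelic and allele-specific labels overlap, whether shared
allele-specific genes agree in parental direction, and how well the
allelic ratios correlate (Pearson), overall and over an optional gene
subset such as known imprinted genes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import Category

__all__ = [
    "ConcordanceReport",
    "join_calls",
    "pearson",
    "direction_agreement",
    "concordance_report",
]

_ALLELE_SPECIFIC = {Category.MATERNAL.value, Category.PATERNAL.value}


def join_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Inner join on features informative in both tables.

    Suffixes ``_a`` / ``_b`` distinguish the two sides' ratios and
    categories. Warns on an empty intersection.
    """
    cols = ["feature_id", "maternal", "paternal", "ratio", "category"]
    a = calls_a.loc[calls_a["informative"], cols]
    b = calls_b.loc[calls_b["informative"], cols]
    joined = a.merge(b, on="feature_id", suffixes=("_a", "_b"))
    if joined.empty:
        warnings.warn("no shared informative features between the two call tables")
    return joined.sort_values("feature_id", ignore_index=True)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-transform p (n-2 df).

    Zero variance on either side yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson requires two equal-length vectors of length >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("undefined ratios must be removed before correlating")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def direction_agreement(joined: pd.DataFrame) -> dict:
    """Direction agreement among shared allele-specific features.

    Among features called allele-specific on BOTH sides, counts genes
    whose parental direction matches; also reports how many of all shared
    features carry the same category label.
    """
    both_as = joined[
        joined["category_a"].isin(_ALLELE_SPECIFIC)
        & joined["category_b"].isin(_ALLELE_SPECIFIC)
    ]
    same = int((both_as["category_a"] == both_as["category_b"]).sum())
    n_as = int(len(both_as))
    return {
        "n_allele_specific_shared": n_as,
        "n_direction_agree": same,
        "direction_agreement_pct": 100.0 * same / n_as if n_as else math.nan,
        "n_categories_agree": int((joined["category_a"] == joined["category_b"]).sum()),
    }


@dataclass
class ConcordanceReport:
    """Overlap, agreement and correlation between two call tables."""

    n_shared_informative: int
    biallelic_a_only: int
    biallelic_b_only: int
    biallelic_both: int
    allele_specific_a_only: int
    allele_specific_b_only: int
    allele_specific_both: int
    n_direction_agree: int
    direction_agreement_pct: float
    pearson_r: float
    pearson_p: float
    subset_pearson_r: float = math.nan
    subset_pearson_p: float = math.nan
    joined: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "joined"}
        return {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in d.items()}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _venn(joined: pd.DataFrame, labels: set[str]) -> tuple[int, int, int]:
    in_a = joined["category_a"].isin(labels)
    in_b = joined["category_b"].isin(labels)
    return int((in_a & ~in_b).sum()), int((~in_a & in_b).sum()), int((in_a & in_b).sum())


def concordance_report(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    subset: Iterable[str] | None = None,
) -> ConcordanceReport:
    """Full comparison of two allelic call tables.

    ``subset`` restricts an additional Pearson correlation to the given
    feature ids (e.g. known imprinted genes); with fewer than 3 shared
    subset genes that correlation is reported undefined.
    """
    joined = join_calls(calls_a, calls_b)
    bi_a, bi_b, bi_both = _venn(joined, {Category.BIALLELIC.value})
    as_a, as_b, as_both = _venn(joined, _ALLELE_SPECIFIC)
    agree = direction_agreement(joined)
    if len(joined) >= 3:
        r, p = pearson(joined["ratio_a"], joined["ratio_b"])
    else:
        r, p = math.nan, math.nan
    sub_r = sub_p = math.nan
    if subset is not None:
        sub = joined[joined["feature_id"].isin(set(subset))]
        if len(sub) >= 3:
            sub_r, sub_p = pearson(sub["ratio_a"], sub["ratio_b"])
    return ConcordanceReport(
        n_shared_informative=int(len(joined)),
        biallelic_a_only=bi_a,
        biallelic_b_only=bi_b,
        biallelic_both=bi_both,
        allele_specific_a_only=as_a,
        allele_specific_b_only=as_b,
        allele_specific_both=as_both,
        n_direction_agree=agree["n_direction_agree"],
        direction_agreement_pct=agree["direction_agreement_pct"],
        pearson_r=r,
        pearson_p=p,
        subset_pearson_r=sub_r,
        subset_pearson_p=sub_p,
        joined=joined,
    )
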