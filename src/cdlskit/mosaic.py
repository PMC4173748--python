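"""Mosaic variant-allele-fraction quantification and cross-sample comparison.

A constitutional heterozygous mutation is expected at a variant allele
fraction (VAF) of ~0.5 in diploid DNA; a somatic mosaic mutation, present in
only a fraction of cells, shows a VAF well below 0.5 and may differ between
tissues (blood, saliva, buccal) and over time. This module turns
(alternate, total) read or pyrosequencing-signal counts into VAF point
estimates with Wilson score 95% confidence intervals (chosen over the Wald
interval for stability at small counts), compares levels between samples,
and classifies a quantification as consistent with heterozygosity, with
mosaicism, or indeterminate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import percent_truncated

TISSUES = ("blood", "saliva", "buccal", "other")

#: default half-width of the VAF band around 0.5 treated as heterozygous
HET_MARGIN = 0.05


@dataclass
class ReadCounts:
    """Variant-supporting and total read counts for one variant in one sample."""

    alt: int
    total: int
    sample_id: str = ""
    tissue: str = "other"
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total read count must be positive")
        if not (0 <= self.alt <= self.total):
            raise ValueError("alt count must satisfy 0 <= alt <= total")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")

    @classmethod
    def from_percent(
        cls, percent: float, n_equivalent: int, **kwargs
    ) -> "ReadCounts":
        """Build counts from a bare instrument percentage with a stated n-equivalent
        (e.g. pyrosequencing allele-quantification output)."""
        return cls(alt=round(percent / 100.0 * n_equivalent), total=n_equivalent, **kwargs)


@dataclass
class AlleleQuantification:
    """VAF point estimate with truncated whole-number percent and Wilson 95% CI."""

    vaf: float
    percent: int
    ci_low: float
    ci_high: float
    alt: int
    total: int
    sample_id: str = ""
    tissue: str = "other"
    age_years: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def wilson_interval(alt: int, total: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    lo, hi = proportion_confint(alt, total, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def quantify(counts: ReadCounts, alpha: float = 0.05) -> AlleleQuantification:
    """VAF = alt/total, reported as a truncated whole-number percent with Wilson CI."""
    lo, hi = wilson_interval(counts.alt, counts.total, alpha)
    return AlleleQuantification(
        vaf=counts.alt / counts.total,
        percent=int(percent_truncated(counts.alt, counts.total, 0)),
        ci_low=lo,
        ci_high=hi,
        alt=counts.alt,
        total=counts.total,
        sample_id=counts.sample_id,
        tissue=counts.tissue,
        age_years=counts.age_years,
    )


@dataclass
class LevelComparison:
    """Fold change between two quantifications and whether their CIs overlap."""

    ratio: float  # a.vaf / b.vaf; NaN when b.vaf == 0
    ci_overlap: bool


def compare_levels(a: AlleleQuantification, b: AlleleQuantification) -> LevelComparison:
    """Fold ratio a/b of the point estimates plus a 95%-CI overlap flag.

    When b has VAF 0 the ratio is undefined (NaN); the overlap flag is still
    computed from the intervals.
    """
    ratio = a.vaf / b.vaf if b.vaf > 0 else math.nan
    overlap = (a.ci_low <= b.ci_high) and (b.ci_low <= a.ci_high)
    return LevelComparison(ratio=ratio, ci_overlap=overlap)


CONSISTENT_WITH_HET = "consistent-with-heterozygous"
CONSISTENT_WITH_MOSAIC = "consistent-with-mosaic"
INDETERMINATE = "indeterminate"


def flag_mosaic(
    q: AlleleQuantification, het_expectation: float = 0.5, margin: float = HET_MARGIN
) -> str:
    """Classify a quantification against the heterozygous expectation.

    Mosaic if the CI lies entirely below ``het_expectation - margin``;
    heterozygous if the CI covers the whole band
    [het_expectation - margin, het_expectation + margin]; otherwise
    indeterminate.
    """
    lo_band, hi_band = het_expectation - margin, het_expectation + margin
    if q.ci_high < lo_band:
        return CONSISTENT_WITH_MOSAIC
    if q.ci_low <= lo_band and q.ci_high >= hi_band:
        return CONSISTENT_WITH_HET
    return INDETERMINATE


# ---------------------------------------------------------------------------
# tabular I/O

def read_counts_csv(path: str | Path) -> list[ReadCounts]:
    """CSV with columns sample_id, tissue, age, alt, total (age optional/blank)."""
    df = pd.read_csv(path)
    required = {"sample_id", "alt", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        age = row.get("age")
        out.append(
            ReadCounts(
                alt=int(row["alt"]),
                total=int(row["total"]),
                sample_id=str(row["sample_id"]),
                tissue=str(row.get("tissue", "other")) if not pd.isna(row.get("tissue")) else "other",
                age_years=None if age is None or pd.isna(age) else float(age),
            )
        )
    return out


def quantification_table(
    counts: Sequence[ReadCounts], margin: float = HET_MARGIN
) -> list[dict]:
    """Quantify a batch and attach the mosaic/heterozygous call to each row."""
    rows = []
    for c in counts:
        q = quantify(c)
        row = q.to_dict()
        row["call"] = flag_mosaic(q, margin=margin)
        rows.append(row)
    return rows
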