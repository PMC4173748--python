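"""Cohort data model, delimited-text I/O, mutation-yield summaries and severity categories.

The cohort file is UTF-8 delimited text (comma or tab, autodetected) with one
row per patient. Growth measurements are consumed as z-scores (SD units
against an age/sex growth reference); converting raw measurements to z-scores
is out of scope. Missing values ("NA" or empty) are kept missing — nothing in
this module imputes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

GENE_GROUPS = (
    "NIPBL",
    "SMC1A",
    "SMC3",
    "HDAC8",
    "RAD21",
    "ANKRD11",
    "CNV",
    "negative",
)
SEXES = ("male", "female", "unknown")

#: severity-score category boundaries: < MILD_BELOW is mild,
#: [MILD_BELOW, MODERATE_UPTO] moderate, > MODERATE_UPTO severe.
MILD_BELOW = 15.0
MODERATE_UPTO = 22.0

_Z_FIELDS = ("birth_weight_sd", "weight_sd", "height_sd", "ofc_sd")


class CohortValidationError(ValueError):
    """A cohort record or file failed validation."""


@dataclass
class PatientRecord:
    """One individual: growth z-scores, severity score, genotype group, gestalt ratings.

    ``None`` marks a missing value. ``gestalt_ratings`` holds 0-3 per-rater
    facial gestalt scores, each on the 1 (highly atypical) to 10 (highly
    typical) scale.
    """

    patient_id: str
    sex: str = "unknown"
    birth_weight_sd: float | None = None
    weight_sd: float | None = None
    height_sd: float | None = None
    ofc_sd: float | None = None
    severity_score: float | None = None
    gene_group: str = "negative"
    mosaic: bool = False
    gestalt_ratings: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortValidationError(f"unknown sex {self.sex!r}")
        if self.gene_group not in GENE_GROUPS:
            raise CohortValidationError(f"unknown gene_group {self.gene_group!r}")
        for name in _Z_FIELDS:
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise CohortValidationError(f"{name} must be finite, got {v!r}")
        if self.severity_score is not None:
            if not math.isfinite(self.severity_score) or self.severity_score < 0:
                raise CohortValidationError(
                    f"severity_score must be a finite nonnegative number, "
                    f"got {self.severity_score!r}"
                )
        self.gestalt_ratings = tuple(float(r) for r in self.gestalt_ratings)
        for r in self.gestalt_ratings:
            if not (1.0 <= r <= 10.0):
                raise CohortValidationError(
                    f"gestalt rating {r!r} outside the 1-10 scale"
                )

    @property
    def gestalt_mean(self) -> float | None:
        """Mean over present per-rater gestalt scores, or None if unrated."""
        if not self.gestalt_ratings:
            return None
        return float(sum(self.gestalt_ratings) / len(self.gestalt_ratings))


def categorize_severity(score: float) -> str:
    """Map a composite clinical severity score to mild / moderate / severe.

    Scores below 15 are mild, 15-22 inclusive moderate, above 22 severe.
    """
    if not math.isfinite(score) or score < 0:
        raise ValueError(f"severity score must be nonnegative, got {score!r}")
    if score < MILD_BELOW:
        return "mild"
    if score <= MODERATE_UPTO:
        return "moderate"
    return "severe"


def percent_truncated(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage truncated (not rounded) toward zero at ``decimals`` places.

    This is the reporting convention used throughout the cohort summaries:
    44/56 prints as 78, not 79; 6/163 prints as 3.6, not 3.7. Computed in
    exact rational arithmetic so the truncation never suffers binary
    floating-point artefacts.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be nonnegative")
    scale = 10**decimals
    return math.floor(Fraction(100 * numerator * scale, denominator)) / scale


@dataclass
class YieldSummary:
    """Per-gene mutation counts and truncated percentages of the cohort."""

    cohort_size: int
    counts: dict[str, int]
    percents: dict[str, float]
    total: int

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)


def summarize_yield(
    records: Sequence[PatientRecord], decimals: int = 1
) -> YieldSummary:
    """Count mutation-positive cases per gene group and report truncated percents.

    Every non-``negative`` gene group appears in the output, including groups
    with zero positives; ``total`` is the sum of gene-positive counts.
    """
    if not records:
        raise ValueError("cannot summarise an empty cohort")
    n = len(records)
    counts = {g: 0 for g in GENE_GROUPS if g != "negative"}
    for rec in records:
        if rec.gene_group != "negative":
            counts[rec.gene_group] += 1
    percents = {g: percent_truncated(c, n, decimals) for g, c in counts.items()}
    return YieldSummary(
        cohort_size=n, counts=counts, percents=percents, total=sum(counts.values())
    )


# ---------------------------------------------------------------------------
# delimited-text I/O

_SCALAR_COLUMNS = (
    "patient_id",
    "sex",
    "birth_weight_sd",
    "weight_sd",
    "height_sd",
    "ofc_sd",
    "severity_score",
    "gene_group",
    "mosaic",
)


def _gestalt_columns(columns: Iterable[str]) -> list[str]:
    cols = [c for c in columns if c.startswith("gestalt_")]
    return sorted(cols, key=lambda c: c.split("_")[-1])


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort table. Comma/tab autodetected; "NA" or empty = missing.

    Raises :class:`CohortValidationError` naming the offending line for any
    malformed row or out-of-range rating.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        dtype=str,
        keep_default_na=False,
        na_values=["", "NA"],
    )
    missing_cols = {"patient_id"} - set(df.columns)
    if missing_cols:
        raise CohortValidationError(f"{path}: missing columns {sorted(missing_cols)}")
    gestalt_cols = _gestalt_columns(df.columns)

    def _num(row, col, line):
        val = row.get(col)
        if val is None or pd.isna(val):
            return None
        try:
            return float(val)
        except ValueError:
            raise CohortValidationError(
                f"{path} line {line}: field {col!r} is not numeric: {val!r}"
            ) from None

    records: list[PatientRecord] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        line = i + 2  # header is line 1
        ratings = [
            _num(row, c, line) for c in gestalt_cols if not pd.isna(row.get(c, None))
        ]
        mosaic_raw = row.get("mosaic")
        mosaic = (
            str(mosaic_raw).strip().lower() in ("true", "1", "yes")
            if mosaic_raw is not None and not pd.isna(mosaic_raw)
            else False
        )
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    sex=row.get("sex") if not pd.isna(row.get("sex")) else "unknown",
                    birth_weight_sd=_num(row, "birth_weight_sd", line),
                    weight_sd=_num(row, "weight_sd", line),
                    height_sd=_num(row, "height_sd", line),
                    ofc_sd=_num(row, "ofc_sd", line),
                    severity_score=_num(row, "severity_score", line),
                    gene_group=(
                        row.get("gene_group")
                        if not pd.isna(row.get("gene_group"))
                        else "negative"
                    ),
                    mosaic=mosaic,
                    gestalt_ratings=[r for r in ratings if r is not None],
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path} line {line}: {exc}") from None
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort as tab-delimited text; round-trips bit-exactly via repr."""
    path = Path(path)
    n_raters = max((len(r.gestalt_ratings) for r in records), default=0)
    gestalt_cols = [f"gestalt_{i + 1}" for i in range(n_raters)]
    header = list(_SCALAR_COLUMNS) + gestalt_cols

    def fmt(v) -> str:
        if v is None:
            return "NA"
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records:
            row = [fmt(getattr(rec, c)) for c in _SCALAR_COLUMNS]
            ratings = list(rec.gestalt_ratings) + [None] * (
                n_raters - len(rec.gestalt_ratings)
            )
            row += [fmt(r) for r in ratings]
            fh.write("\t".join(row) + "\n")
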