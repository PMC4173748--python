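"""Facial gestalt score aggregation and inter-rater concordance.

Facial typicality is scored by several clinical geneticists on a 1-10 scale
(1 = highly atypical, 10 = highly typical) from a single anteroposterior
photograph, blinded to genotype. The per-patient mean over available raters
is the score used downstream, and this is only justified if raters agree;
the concordance gate requires every pairwise Pearson correlation to reach
the threshold (0.60 by default). The p-value of each correlation is reported
for completeness but the pass/fail decision keys on r alone, since p is a
function of the number of jointly rated patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

CONCORDANCE_THRESHOLD = 0.60


class GestaltPanel:
    """Ratings matrix: rows = patients, columns = raters, NaN = missing.

    Entries must lie on the 1-10 gestalt scale.
    """

    def __init__(self, ratings, patient_ids: Sequence[str] | None = None):
        arr = np.asarray(ratings, dtype=float)
        if arr.ndim != 2:
            raise ValueError("ratings must be a 2-D patients x raters matrix")
        present = ~np.isnan(arr)
        if ((arr[present] < 1.0) | (arr[present] > 10.0)).any():
            raise ValueError("gestalt ratings must lie in [1, 10]")
        self.ratings = arr
        self.patient_ids = (
            list(patient_ids)
            if patient_ids is not None
            else [f"P{i:04d}" for i in range(1, arr.shape[0] + 1)]
        )
        if len(self.patient_ids) != arr.shape[0]:
            raise ValueError("patient_ids length must match the number of rows")

    @classmethod
    def from_records(cls, records) -> "GestaltPanel":
        """Build a panel from PatientRecords, padding short rating lists with NaN."""
        n_raters = max((len(r.gestalt_ratings) for r in records), default=0)
        mat = np.full((len(records), n_raters), np.nan)
        for i, rec in enumerate(records):
            mat[i, : len(rec.gestalt_ratings)] = rec.gestalt_ratings
        return cls(mat, [r.patient_id for r in records])

    @property
    def n_patients(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]


def aggregate_ratings(panel: GestaltPanel) -> np.ndarray:
    """Per-patient mean gestalt score over present ratings (NaN if none).

    Patients with no ratings get NaN and a logged warning.
    """
    out = np.full(panel.n_patients, np.nan)
    for i, row in enumerate(panel.ratings):
        present = row[~np.isnan(row)]
        if present.size == 0:
            logger.warning(
                "patient %s has no gestalt ratings; mean score missing",
                panel.patient_ids[i],
            )
        else:
            out[i] = present.mean()
    return out


@dataclass
class PairConcordance:
    raters: tuple[int, int]
    r: float  # NaN when undefined (constant ratings)
    p_value: float
    n: int


@dataclass
class ConcordanceReport:
    pairs: list[PairConcordance]
    threshold: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "passed": self.passed,
            "pairs": [
                {
                    "raters": list(p.raters),
                    "r": None if np.isnan(p.r) else p.r,
                    "p_value": None if np.isnan(p.p_value) else p.p_value,
                    "n": p.n,
                }
                for p in self.pairs
            ],
        }


def rater_concordance(
    panel: GestaltPanel, threshold: float = CONCORDANCE_THRESHOLD
) -> ConcordanceReport:
    """Pairwise Pearson correlations between raters, pairwise-complete.

    ``passed`` is True iff every rater pair has a defined correlation
    >= ``threshold``. A rater pair with a constant rating vector has an
    undefined correlation, reported as NaN, and fails the gate.
    """
    pairs: list[PairConcordance] = []
    for i, j in combinations(range(panel.n_raters), 2):
        a, b = panel.ratings[:, i], panel.ratings[:, j]
        mask = ~(np.isnan(a) | np.isnan(b))
        n = int(mask.sum())
        if n < 3:
            raise ValueError(
                f"raters {i} and {j} share only {n} rated patients; need >= 3"
            )
        x, y = a[mask], b[mask]
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            pairs.append(PairConcordance((i, j), np.nan, np.nan, n))
            continue
        res = stats.pearsonr(x, y)
        pairs.append(PairConcordance((i, j), float(res.statistic), float(res.pvalue), n))
    passed = bool(pairs) and all(
        (not np.isnan(p.r)) and p.r >= threshold for p in pairs
    )
    return ConcordanceReport(pairs=pairs, threshold=threshold, passed=passed)
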