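"""Gestalt-score QC: aggregate the three raters and check pairwise concordance.

Reads results/cohort.tsv, reports every pairwise Pearson correlation between
raters and whether all pairs clear the 0.60 gate that justifies using the
per-patient mean score downstream. Output: results/gestalt_concordance.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cdlskit.cohort import read_cohort
from cdlskit.gestalt import GestaltPanel, aggregate_ratings, rater_concordance


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    panel = GestaltPanel.from_records(read_cohort(args.cohort))
    means = aggregate_ratings(panel)
    report = rater_concordance(panel)

    out = args.outdir / "gestalt_concordance.json"
    out.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    for pair in report.pairs:
        print(f"raters {pair.raters}: r = {pair.r:.3f} (n = {pair.n}, p = {pair.p_value:.2e})")
    print(f"all pairs >= {report.threshold}: {report.passed}")
    print(f"mean of per-patient mean scores: {np.nanmean(means):.2f} -> {out}")


if __name__ == "__main__":
    main()
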