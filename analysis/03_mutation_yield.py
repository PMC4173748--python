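"""Per-gene mutation yield and severity-category breakdown of the cohort.

Counts gene-positive cases, reports each as a truncated percentage of the
cohort (the reporting convention under which 46/163 prints as 28.2 and
6/163 as 3.6), and tabulates mild/moderate/severe severity categories.
Output: results/yield.json.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

from cdlskit.cohort import categorize_severity, read_cohort, summarize_yield


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_cohort(args.cohort)
    ys = summarize_yield(records)
    severities = Counter(
        categorize_severity(r.severity_score)
        for r in records
        if r.severity_score is not None
    )

    print(f"cohort n = {ys.cohort_size}; total gene-positive = {ys.total}")
    for gene, count in ys.counts.items():
        if count:
            print(f"  {gene:8s} {count:3d}  ({ys.percents[gene]}%)")
    print("severity:", dict(severities))

    out = args.outdir / "yield.json"
    out.write_text(
        json.dumps(
            {
                "yield": {
                    "cohort_size": ys.cohort_size,
                    "counts": ys.counts,
                    "percents": ys.percents,
                    "total": ys.total,
                },
                "severity_categories": dict(severities),
            },
            indent=2,
        )
        + "\n"
    )
    print(f"-> {out}")


if __name__ == "__main__":
    main()
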