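"""End-to-end pipeline: cohort -> gestalt QC -> yield -> tree/filter -> faces -> mosaic.

One global seed is expanded into fixed per-stage substreams, so disabling a
stage never perturbs another stage's randomness and two runs with the same
config are byte-identical (timestamps appear only in the log, never in the
JSON report).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (
    categorize_severity,
    read_cohort,
    summarize_yield,
    write_cohort,
)
from .facegen import FaceSimConfig, generate_faces, write_png
from .faces import build_average_face
from .gestalt import CONCORDANCE_THRESHOLD, GestaltPanel, aggregate_ratings, rater_concordance
from .mosaic import HET_MARGIN, ReadCounts, quantification_table, compare_levels, quantify
from .simulate import default_cohort_config, generate_cohort
from .tree import (
    DEFAULT_FEATURES,
    NipblLikeFilter,
    TreeConfig,
    apply_nipbl_like_filter,
    branch_purity,
    fit_tree,
    records_to_matrix,
)

logger = logging.getLogger(__name__)

STAGES = ("cohort", "gestalt", "yield", "tree", "filter", "faces", "mosaic")

#: mosaic read-count table bundled with the demo: the reported mosaic variants
#: (exome NIPBL nonsense 31/206 reads; pyrosequencing/panel percentages
#: converted to count-equivalents at their stated or nominal depths)
DEMO_MOSAIC_COUNTS = [
    {"sample_id": "NIPBL_exome_blood", "tissue": "blood", "alt": 31, "total": 206},
    {"sample_id": "SMC1A_saliva_14.3y", "tissue": "saliva", "alt": 53, "total": 100, "age": 14.3},
    {"sample_id": "SMC1A_saliva_18.3y", "tissue": "saliva", "alt": 10, "total": 100, "age": 18.3},
    {"sample_id": "het_control", "tissue": "blood", "alt": 100, "total": 200},
]


@dataclass
class PipelineConfig:
    """All stage parameters with their published defaults.

    Defaults: tree min_split 3 / max_depth 3; filter thresholds -2.4 / -4.4 SD;
    gestalt concordance threshold 0.60; severity cutoffs 15 / 22 (owned by
    cohort_core); heterozygous VAF margin 0.05.
    """

    seed: int = 0
    out_dir: str = "results/pipeline"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    cohort_path: str | None = None  # load instead of synthesise
    cohort_missingness: float = 0.1
    gestalt_threshold: float = CONCORDANCE_THRESHOLD
    tree_features: tuple = DEFAULT_FEATURES
    tree_min_split: int = 3
    tree_max_depth: int = 3
    tree_missing_policy: str = "exclude"
    filter_weight_below: float = -2.4
    filter_birth_weight_at_least: float = -4.4
    faces_n_per_group: dict = field(default_factory=lambda: {"NIPBL-like": 4, "other": 4})
    faces_image_size: int = 128
    faces_landmark_noise_sd: float = 2.0
    mosaic_counts: list = field(default_factory=lambda: [dict(d) for d in DEMO_MOSAIC_COUNTS])
    mosaic_margin: float = HET_MARGIN

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.tree_features = tuple(cfg.tree_features)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tree_features"] = list(self.tree_features)
        return d


def _stage_seed(global_seed: int, stage: str) -> int:
    """Fixed substream per stage: toggling one stage leaves the others unchanged."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def _group_offsets_nipbl_like() -> dict[str, np.ndarray]:
    """Stylised shape offsets: the NIPBL-like group gets lower-set brows, a
    shorter nose and a thinner, downturned mouth relative to the template."""
    off_a = np.zeros((36, 2))
    off_a[13:19, 1] += 3.0  # brows down
    off_a[28:31, 1] -= 3.0  # nose tip/nostrils up (shorter nose)
    off_a[31, 1] += 2.5  # mouth corners down
    off_a[33, 1] += 2.5
    off_a[34, 1] -= 2.0  # thinner lower lip
    return {"NIPBL-like": off_a, "other": np.zeros((36, 2))}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and write the report bundle.

    Returns the report dict; on a stage failure the report carries an error
    record for that stage and ``run_pipeline`` re-raises after writing the
    partial report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("cdlskit")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "errors": {},
    }
    enabled = {s: bool(config.stages.get(s, True)) for s in STAGES}
    records = None
    failed = False
    try:
        if enabled["cohort"]:
            if config.cohort_path:
                records = read_cohort(config.cohort_path)
                logger.info("loaded cohort of %d from %s", len(records), config.cohort_path)
            else:
                sim = default_cohort_config(
                    seed=_stage_seed(config.seed, "cohort"),
                    missingness=config.cohort_missingness,
                )
                records = generate_cohort(sim)
                write_cohort(records, out / "cohort.tsv")
                logger.info("synthesised cohort of %d records", len(records))
            sev = {"mild": 0, "moderate": 0, "severe": 0, "missing": 0}
            for r in records:
                if r.severity_score is None:
                    sev["missing"] += 1
                else:
                    sev[categorize_severity(r.severity_score)] += 1
            report["stages"]["cohort"] = {
                "n": len(records),
                "severity_categories": sev,
                "source": config.cohort_path or "synthetic",
            }

        if enabled["gestalt"] and records is not None:
            panel = GestaltPanel.from_records(records)
            means = aggregate_ratings(panel)
            conc = rater_concordance(panel, threshold=config.gestalt_threshold)
            report["stages"]["gestalt"] = {
                "concordance": conc.to_dict(),
                "n_scored": int(np.isfinite(means).sum()),
                "mean_of_means": float(np.nanmean(means)),
            }

        if enabled["yield"] and records is not None:
            ys = summarize_yield(records)
            report["stages"]["yield"] = {
                "cohort_size": ys.cohort_size,
                "counts": ys.counts,
                "percents": ys.percents,
                "total": ys.total,
            }

        if enabled["tree"] and records is not None:
            positives = [r for r in records if r.gene_group != "negative"]
            X = records_to_matrix(positives, config.tree_features)
            y = ["NIPBL" if r.gene_group == "NIPBL" else "non-NIPBL" for r in positives]
            tree = fit_tree(
                X,
                y,
                feature_names=list(config.tree_features),
                config=TreeConfig(
                    min_split=config.tree_min_split,
                    max_depth=config.tree_max_depth,
                    missing_policy=config.tree_missing_policy,
                ),
            )
            # training purity of the NIPBL-majority leaves
            def leaf_stats(node, acc):
                if node.is_leaf:
                    acc.append(node)
                else:
                    leaf_stats(node.left, acc)
                    leaf_stats(node.right, acc)
                return acc

            leaves = leaf_stats(tree.root, [])
            nipbl_leaves = [l for l in leaves if l.prediction == "NIPBL"]
            n_branch = sum(sum(l.counts.values()) for l in nipbl_leaves)
            n_target = sum(l.counts.get("NIPBL", 0) for l in nipbl_leaves)
            report["stages"]["tree"] = {
                "tree": tree.to_dict(),
                "depth": tree.depth(),
                "nipbl_branch_n": n_branch,
                "nipbl_branch_purity_percent": (
                    branch_purity(n_target, n_branch) if n_branch else None
                ),
            }
            (out / "tree.txt").write_text(tree.format_text() + "\n", encoding="utf-8")

        if enabled["filter"] and records is not None:
            negatives = [r for r in records if r.gene_group == "negative"]
            filt = NipblLikeFilter(
                weight_below=config.filter_weight_below,
                birth_weight_at_least=config.filter_birth_weight_at_least,
            )
            res = apply_nipbl_like_filter(negatives, filt)
            report["stages"]["filter"] = {
                "n_negative": res.n_total,
                "n_flagged": res.n_flagged,
                "percent": res.percent,
                "weight_below": filt.weight_below,
                "birth_weight_at_least": filt.birth_weight_at_least,
            }

        if enabled["faces"]:
            fcfg = FaceSimConfig(
                image_size=config.faces_image_size,
                group_offsets=_group_offsets_nipbl_like(),
                landmark_noise_sd=config.faces_landmark_noise_sd,
                seed=_stage_seed(config.seed, "faces"),
            )
            samples = generate_faces(fcfg, dict(config.faces_n_per_group))
            face_report = {}
            for group in config.faces_n_per_group:
                members = [s for s in samples if s.group == group]
                avg = build_average_face(
                    [s.image for s in members],
                    [s.landmarks for s in members],
                    group=group,
                    size=config.faces_image_size,
                )
                png = out / f"average_face_{group}.png"
                write_png(avg.appearance, png)
                face_report[group] = {
                    "n": avg.n,
                    "gpa_iterations": avg.gpa_iterations,
                    "gpa_converged": avg.gpa_converged,
                    "mean_constellation": np.round(avg.mean_constellation, 6).tolist(),
                    "png": png.name,
                }
            report["stages"]["faces"] = face_report

        if enabled["mosaic"]:
            counts = [
                ReadCounts(
                    alt=int(d["alt"]),
                    total=int(d["total"]),
                    sample_id=str(d.get("sample_id", "")),
                    tissue=str(d.get("tissue", "other")),
                    age_years=d.get("age"),
                )
                for d in config.mosaic_counts
            ]
            table = quantification_table(counts, margin=config.mosaic_margin)
            comparisons = []
            by_id = {c.sample_id: quantify(c) for c in counts}
            ids = list(by_id)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = by_id[ids[i]], by_id[ids[j]]
                    cmp_res = compare_levels(a, b)
                    comparisons.append(
                        {
                            "a": ids[i],
                            "b": ids[j],
                            "ratio": None if np.isnan(cmp_res.ratio) else round(cmp_res.ratio, 6),
                            "ci_overlap": cmp_res.ci_overlap,
                        }
                    )
            report["stages"]["mosaic"] = {"table": table, "comparisons": comparisons}
    except Exception as exc:  # partial report + nonzero exit is the contract
        failed = True
        report["errors"]["stage_failure"] = f"{type(exc).__name__}: {exc}"
        logger.exception("pipeline stage failed")
        raise
    finally:
        report_path = out / "report.json"
        report_path.write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )
        logger.info("report written to %s (failed=%s)", report_path, failed)
        root_logger.removeHandler(handler)
        handler.close()
    return report


# ---------------------------------------------------------------------------
# worked examples: the published counts recomputed through the package


def worked_examples() -> list[dict]:
    """Recompute the published worked-example quantities from their printed inputs.

    Each entry reports the value computed by the package alongside the value
    printed in the source cohort report, with a pass flag.
    """
    from .cohort import percent_truncated

    entries = []

    def add(name, computed, expected):
        entries.append(
            {
                "name": name,
                "computed": computed,
                "expected": expected,
                "pass": computed == expected,
            }
        )

    add("NIPBL yield percent (46/163)", percent_truncated(46, 163, 1), 28.2)
    add("HDAC8 yield percent (6/163)", percent_truncated(6, 163, 1), 3.6)
    add("total mutations (46+5+5+6+1)", 46 + 5 + 5 + 6 + 1, 63)
    add("NIPBL branch purity percent (44/56)", branch_purity(44, 56), 78)
    add("strict branch purity percent (32/34)", branch_purity(32, 34), 94)
    add("exome mosaic VAF percent (31/206)", quantify(ReadCounts(31, 206)).percent, 15)

    # NIPBL-like filter on a constructed mutation-negative cohort of 103
    from .cohort import PatientRecord

    negs = [
        PatientRecord(patient_id=f"N{i:03d}", weight_sd=-3.0, birth_weight_sd=-2.0)
        for i in range(19)
    ] + [
        PatientRecord(patient_id=f"N{i:03d}", weight_sd=-1.0, birth_weight_sd=-2.0)
        for i in range(19, 103)
    ]
    res = apply_nipbl_like_filter(negs)
    add("NIPBL-like filter percent (19/103)", res.percent, 18)

    q_a = quantify(ReadCounts.from_percent(53.0, 100, tissue="saliva"))
    q_b = quantify(ReadCounts.from_percent(10.0, 100, tissue="saliva"))
    add(
        "SMC1A saliva fold change (53% vs 10%)",
        round(compare_levels(q_a, q_b).ratio, 1),
        5.3,
    )
    return entries
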