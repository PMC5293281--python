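"""End-to-end composition: register -> segment -> extract -> select -> classify.

``run_pipeline`` takes a cohort of cases (in memory, or a directory written
by the ``simulate`` CLI subcommand), runs every stage, and renders a report
with per-class ROC/AUC, operating points, the selection-frequency table and
a Kruskal-Wallis screen of the selected features.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import (
    DceCase,
    FeatureTable,
    FeatureVector,
    PipelineConfig,
    TumorMask,
    feature_schema,
    read_volume,
    write_volume,
)
from .features import extract_features
from .modeling import Chromosome, CvReport, EAConfig, ea_search, kruskal_wallis, loocv_evaluate
from .registration import register_series
from .segmentation import segment_breast, segment_tumor

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    table: FeatureTable
    pool: Chromosome
    report: CvReport
    kruskal: dict[int, tuple[float, float]]  # feature index -> (H, p)
    markdown: str


def process_case(case: DceCase, config: PipelineConfig | None = None) -> tuple[DceCase, FeatureVector]:
    """Register the series, segment breast and tumor, extract features.

    The case must carry a tumor seed (an existing ``tumor_mask.seed`` or a
    ground-truth mask from the generator); segmentation is re-run from it.
    """
    cfg = config or PipelineConfig()
    if case.tumor_mask is None:
        raise ValueError(f"case {case.case_id}: no tumor seed available")
    seed = case.tumor_mask.seed
    t0 = time.perf_counter()
    registered, shifts = register_series(case, cfg)
    t1 = time.perf_counter()
    breast = segment_breast(registered.s0)
    side = "left" if breast.left[seed] else "right"
    breast.laterality_of_lesion = side
    registered.breast_mask = breast
    tumor = segment_tumor(registered, seed, cfg)
    registered.tumor_mask = tumor
    t2 = time.perf_counter()
    vec = extract_features(registered, cfg)
    t3 = time.perf_counter()
    log.info(
        "case %s: register %.2fs (s1 %s, s2 %s), segment %.2fs, extract %.2fs",
        case.case_id, t1 - t0, (shifts["s1"].dx, shifts["s1"].dy),
        (shifts["s2"].dx, shifts["s2"].dy), t2 - t1, t3 - t2,
    )
    return registered, vec


def build_feature_table(cases: list[DceCase], config: PipelineConfig | None = None) -> FeatureTable:
    rows = []
    for case in cases:
        _, vec = process_case(case, config)
        rows.append(vec)
    return FeatureTable(rows=rows, labels=[c.subtype for c in cases], case_ids=[c.case_id for c in cases])


def run_pipeline(cases: list[DceCase], config: PipelineConfig | None = None) -> PipelineResult:
    """Full analysis on a cohort of cases; reproducible given config + seed."""
    cfg = config or PipelineConfig()
    table = build_feature_table(cases, cfg)
    return run_analysis(table, cfg)


def run_analysis(table: FeatureTable, config: PipelineConfig | None = None) -> PipelineResult:
    """Feature selection, LOOCV classification and reporting on a table."""
    cfg = config or PipelineConfig()
    best, _trace = ea_search(table, EAConfig.from_pipeline(cfg))
    report = loocv_evaluate(table, best.feature_indices, cfg)
    X = table.matrix
    y = np.asarray(table.labels)
    kw = {}
    for idx, frequency in report.selection_table():
        if frequency > 0:
            kw[idx] = kruskal_wallis(X[:, idx - 1], y)
    return PipelineResult(table=table, pool=best, report=report, kruskal=kw, markdown=render_report(best, report, kw))


def render_report(pool: Chromosome, report: CvReport, kw: dict[int, tuple[float, float]]) -> str:
    schema = feature_schema()
    lines = ["# Molecular-subtype classification report", ""]
    lines.append(f"EA optimal pool: {len(pool.feature_indices)} features, fitness AUC {pool.fitness:.3f}")
    union = sorted({i for s in report.per_fold_selected for i in s})
    lines.append(f"Union of per-fold selections: {len(union)} features")
    lines += ["", "## Per-class ROC/AUC", "", "| subtype | AUC | 95% CI | sens | spec |", "|---|---|---|---|---|"]
    for cls, est in report.per_class_auc.items():
        thr, sens, spec = report.operating_points[cls]
        lines.append(f"| {cls} | {est.auc:.3f} | [{est.ci_low:.3f}, {est.ci_high:.3f}] | {sens:.3f} | {spec:.3f} |")
    lines += [
        "",
        f"Overall AUC (prevalence-weighted): {report.overall_auc_weighted:.3f}",
        f"Overall AUC (unweighted): {report.overall_auc_unweighted:.3f}",
        "",
        "## Selection frequency",
        "",
        "| feature | name | frequency | KW H | KW p |",
        "|---|---|---|---|---|",
    ]
    for idx, frequency in report.selection_table():
        if frequency == 0:
            continue
        h, p = kw.get(idx, (float("nan"), float("nan")))
        lines.append(f"| F{idx} | {schema[idx]} | {frequency:.0%} | {h:.2f} | {p:.3f} |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cohort directory layout used by the CLI: one sub-directory per case with
# s0/s1/s2 NIfTI volumes and a JSON sidecar of clinical data + ground truth.


def save_case(case: DceCase, directory: str | Path, truth=None) -> None:
    d = Path(directory) / case.case_id
    d.mkdir(parents=True, exist_ok=True)
    for name, vol in zip(("s0", "s1", "s2"), case.series):
        write_volume(vol, d / f"{name}.nii.gz")
    meta = {
        "case_id": case.case_id,
        "age": case.age,
        "menopausal": case.menopausal,
        "subtype": case.subtype,
        "tumor_seed": list(case.tumor_mask.seed) if case.tumor_mask else None,
    }
    if truth is not None:
        meta["ground_truth"] = {
            "shifts": {k: list(v) for k, v in truth.shifts.items()},
            "laterality": truth.laterality,
            "rng_seed": truth.rng_seed,
        }
    (d / "case.json").write_text(json.dumps(meta, indent=2))


def load_case(directory: str | Path) -> DceCase:
    d = Path(directory)
    meta = json.loads((d / "case.json").read_text())
    series = tuple(read_volume(d / f"{name}.nii.gz") for name in ("s0", "s1", "s2"))
    tumor_mask = None
    if meta.get("tumor_seed") is not None:
        seed = tuple(meta["tumor_seed"])
        placeholder = np.zeros(series[0].shape, dtype=bool)
        placeholder[seed] = True  # seed-only mask: segmentation will replace it
        tumor_mask = TumorMask(mask=placeholder, seed=seed)
    return DceCase(
        case_id=meta["case_id"],
        series=series,
        age=meta["age"],
        menopausal=meta["menopausal"],
        subtype=meta["subtype"],
        tumor_mask=tumor_mask,
    )


def load_cohort(directory: str | Path) -> list[DceCase]:
    root = Path(directory)
    case_dirs = sorted(p for p in root.iterdir() if (p / "case.json").exists())
    if not case_dirs:
        raise FileNotFoundError(f"no cases under {root}")
    return [load_case(p) for p in case_dirs]
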