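"""End-to-end screening pipeline with a machine-readable run report.

Wires the stages together: replicate QC → time-point profiles, stage
segmentation and lag estimate → the three screens (COR, CV, DAM) → the
candidate intersection → trajectory patterns → module annotation.  Every
threshold, mode switch and seed is echoed into the report together with a
hash of the configuration, and every number in the report is recomputable
from the emitted intermediate files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    InputError,
    MetabolomeMatrix,
    read_annotations,
    read_metabolome,
    read_phenotype,
    write_network,
    write_phenotype,
    write_metabolome,
)
from .modules import annotate_modules, load_module_fixtures, module_direction_summary
from .patterns import patterns_long_format, trajectory_patterns
from .qc import drop_flagged, replicate_concordance
from .screen import (
    DEFAULT_COR_TIMEPOINTS,
    cor_screen,
    cv_screen,
    dam_screen,
    intersect_screens,
)
from .stages import estimate_lag, profile_correlation, segment_stages, timepoint_profiles
from .synthetic import SyntheticConfig, generate, truth_confusion

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Either ``simulate`` (a :class:`~germscreen.synthetic.SyntheticConfig`)
    or the three input paths must be set.  All thresholds and mode
    switches are recorded in the run report.
    """

    # inputs
    metabolome_path: str | None = None
    metabolome_layout: str = "wide"
    phenotype_path: str | None = None
    annotations_path: str | None = None
    simulate: SyntheticConfig | None = None
    # QC
    qc_threshold: float = 0.9
    qc_drop: bool = False
    # screens
    alpha: float = 0.05
    r_min: float = 0.8
    cv_min: float = 0.30
    cv_basis: str = "means"
    fc_min: float = 2.0
    dam_gate: str = "adjusted"  # or "raw"
    combine_mode: str = "union"  # or "intersection" across varieties
    screen_timepoints: tuple = DEFAULT_COR_TIMEPOINTS
    # stages
    n_stages: int = 3
    # output
    outdir: str = "germscreen_out"

    def validate(self) -> None:
        if self.simulate is None and (
            self.metabolome_path is None or self.phenotype_path is None
        ):
            raise InputError(
                "config needs either a simulate block or metabolome + phenotype paths"
            )
        if self.simulate is not None:
            self.simulate.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        d["screen_timepoints"] = list(self.screen_timepoints)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SyntheticConfig(**sim)
        return cfg


def _load_inputs(cfg: RunConfig):
    if cfg.simulate is not None:
        matrix, phenotype, truth = generate(cfg.simulate)
        return matrix, phenotype, truth
    annotations = (
        read_annotations(cfg.annotations_path) if cfg.annotations_path else None
    )
    matrix = read_metabolome(
        cfg.metabolome_path, layout=cfg.metabolome_layout, annotations=annotations
    )
    phenotype = read_phenotype(cfg.phenotype_path)
    return matrix, phenotype, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full screen and write all artifacts under ``cfg.outdir``.

    Returns the run report (also written as ``report.json`` and a
    human-readable ``report.txt``).  Deterministic given config + seed.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, phenotype, truth = _load_inputs(cfg)
    write_metabolome(matrix, outdir / "metabolome.csv", layout="wide")
    write_phenotype(phenotype, outdir / "phenotype.csv")
    if truth is not None:
        truth.metabolites.to_csv(outdir / "truth_metabolites.csv")
        truth.samples.to_csv(outdir / "truth_samples.csv")

    # ---- QC --------------------------------------------------------------
    qc_report = replicate_concordance(matrix, threshold=cfg.qc_threshold)
    qc_report.table.to_csv(outdir / "qc_report.csv")
    if cfg.qc_drop:
        matrix = drop_flagged(matrix, qc_report)

    # ---- stages ----------------------------------------------------------
    profiles = timepoint_profiles(matrix)
    corr = profile_correlation(profiles)
    corr.to_csv(outdir / "profile_correlation.csv")
    stage_rows = []
    segmentations = {}
    for variety in matrix.varieties:
        seg = segment_stages(corr, variety, k=min(cfg.n_stages, len(matrix.timepoints)))
        segmentations[variety] = seg
        for i, stage in enumerate(seg.stages, start=1):
            for t in stage:
                stage_rows.append(
                    {"variety": variety, "stage": i, "timepoint_hai": t}
                )
    pd.DataFrame(stage_rows).to_csv(outdir / "stages.csv", index=False)
    varieties = matrix.varieties
    lag = None
    if len(varieties) == 2:
        fast, slow = varieties[0], varieties[1]
        if cfg.simulate is not None:
            fast, slow = cfg.simulate.varieties
        lag = estimate_lag(corr, fast_variety=fast, slow_variety=slow)
        lag.table.to_csv(outdir / "lag_estimate.csv", index=False)

    # ---- screens ---------------------------------------------------------
    edges = cor_screen(
        matrix,
        phenotype,
        timepoints=cfg.screen_timepoints,
        alpha=cfg.alpha,
        r_min=cfg.r_min,
    )
    edges.to_csv(outdir / "cor_edges.csv", index=False)
    write_network(
        edges[edges["passes"]],
        matrix.metabolites,
        outdir / "cor_network",
    )
    cv_sets, cv_series = {}, []
    for variety in matrix.varieties:
        passing, series = cv_screen(
            matrix, variety, threshold=cfg.cv_min, basis=cfg.cv_basis
        )
        cv_sets[variety] = passing
        cv_series.append(series)
    pd.concat(cv_series, axis=1).to_csv(outdir / "cv_values.csv")
    dam_records, dam_set = dam_screen(
        matrix,
        timepoints=cfg.screen_timepoints,
        fc_min=cfg.fc_min,
        alpha=cfg.alpha,
        gate=cfg.dam_gate,
    )
    dam_records.to_csv(outdir / "dam_records.csv", index=False)

    thresholds = {
        "alpha": cfg.alpha,
        "r_min": cfg.r_min,
        "cv_min": cfg.cv_min,
        "cv_basis": cfg.cv_basis,
        "fc_min": cfg.fc_min,
        "dam_gate": cfg.dam_gate,
        "combine_mode": cfg.combine_mode,
        "qc_threshold": cfg.qc_threshold,
        "screen_timepoints": list(cfg.screen_timepoints),
    }
    result = intersect_screens(
        edges,
        cv_sets,
        dam_set,
        annotations=matrix.metabolites,
        mode=cfg.combine_mode,
        thresholds=thresholds,
    )
    candidates = sorted(result.intersection_set)
    cand_table = matrix.metabolites.loc[candidates].copy()
    cand_table["in_cor"] = True
    cand_table["in_cv"] = True
    cand_table["in_dam"] = True
    cand_table.to_csv(outdir / "candidates.csv")
    pd.DataFrame(
        {
            "method": ["COR", "CV", "DAM"],
            "n": [len(result.cor_set), len(result.cv_set), len(result.dam_set)],
            "members": [
                ";".join(sorted(result.cor_set)),
                ";".join(sorted(result.cv_set)),
                ";".join(sorted(result.dam_set)),
            ],
        }
    ).to_csv(outdir / "method_sets.csv", index=False)

    # ---- patterns --------------------------------------------------------
    pattern_table = trajectory_patterns(matrix, metabolites=candidates)
    pattern_table.to_csv(outdir / "patterns.csv", index=False)
    patterns_long_format(pattern_table).to_csv(outdir / "patterns_long.csv", index=False)

    # ---- modules ---------------------------------------------------------
    fixtures = load_module_fixtures()
    cand_names = matrix.metabolites.loc[candidates, "name"].tolist()
    annotated, unmatched = annotate_modules(cand_names, fixtures)
    annotated.insert(0, "metabolite_id", candidates)
    annotated.to_csv(outdir / "module_annotation.csv", index=False)
    unmatched.to_csv(outdir / "module_unmatched.csv", index=False)
    name_of = matrix.metabolites["name"].to_dict()
    module_summary = module_direction_summary(
        annotated.rename(columns={"metabolite_id": "_id"}).assign(
            candidate=lambda df: df["candidate"]
        ),
        pattern_table,
        name_of=name_of,
    )
    module_summary.to_csv(outdir / "module_summary.csv", index=False)

    # ---- report ----------------------------------------------------------
    report = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "thresholds": thresholds,
        "n_samples": int(matrix.n_samples),
        "n_metabolites": int(matrix.n_metabolites),
        "qc": {
            "flagged": qc_report.flagged,
            "removed": qc_report.removed,
            "threshold": cfg.qc_threshold,
        },
        "stages": {
            str(v): [list(map(int, s)) for s in seg.stages]
            for v, seg in segmentations.items()
        },
        "stage_boundaries": {
            str(v): [int(b) for b in seg.boundaries] for v, seg in segmentations.items()
        },
        "lag": {
            "median_lag_hours": lag.median_lag if lag is not None else None,
            "per_timepoint": lag.table.to_dict(orient="records") if lag is not None else [],
        },
        "screen_counts": {
            "cor_per_variety": {str(v): len(s) for v, s in result.cor_by_variety.items()},
            "cv_per_variety": {str(v): len(s) for v, s in result.cv_by_variety.items()},
            "cor": len(result.cor_set),
            "cv": len(result.cv_set),
            "dam": len(result.dam_set),
            "n_edges_passing": int(edges["passes"].sum()) if len(edges) else 0,
            "candidates": len(candidates),
        },
        "class_counts": {
            str(k): int(v)
            for k, v in (
                result.class_counts
                if result.class_counts is not None
                else pd.Series(dtype=int)
            ).items()
        },
        "pattern_counts": {
            str(k): int(v)
            for k, v in pattern_table["label"].value_counts().sort_index().items()
        },
        "module_summary": module_summary.to_dict(orient="records"),
    }
    if truth is not None:
        report["truth_confusion"] = truth_confusion(result, truth)
    blob = json.dumps(report, indent=2, sort_keys=True, default=str)
    (outdir / "report.json").write_text(blob, encoding="utf-8")
    (outdir / "report.txt").write_text(_human_report(report), encoding="utf-8")
    return report


def _human_report(report: dict) -> str:
    lines = [
        f"germscreen {report['package_version']}  (config {report['config_hash']})",
        f"samples: {report['n_samples']}   metabolites: {report['n_metabolites']}",
        f"QC flagged: {report['qc']['flagged'] or 'none'}  removed: {report['qc']['removed'] or 'none'}",
        "",
        "stage boundaries (last HAI of each stage):",
    ]
    for v, b in report["stage_boundaries"].items():
        lines.append(f"  {v}: {b}")
    if report["lag"]["median_lag_hours"] is not None:
        lines.append(f"median lag: {report['lag']['median_lag_hours']:.1f} h")
    sc = report["screen_counts"]
    lines += [
        "",
        f"COR {sc['cor']}  CV {sc['cv']}  DAM {sc['dam']}  →  candidates {sc['candidates']}",
        "per-class counts: "
        + ", ".join(f"{k}: {v}" for k, v in sorted(report["class_counts"].items())),
        "pattern labels: "
        + ", ".join(f"{k}: {v}" for k, v in sorted(report["pattern_counts"].items())),
    ]
    if "truth_confusion" in report:
        tc = report["truth_confusion"]
        lines.append(
            f"vs planted truth: sensitivity {tc['sensitivity']:.3f}, "
            f"precision {tc['precision']:.3f}"
        )
    return "\n".join(lines) + "\n"
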