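"""End-to-end orchestration: cohort → screen → score → signatures → report.

``run_pipeline`` executes the full analysis as a fixed, replayable sequence
and writes every table it produces plus a run manifest (configuration echo,
input hashes, stage counts, output list) so a run can be reproduced
byte-for-byte from its seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .clical_core import (assign_subscores, clical_score, enumerate_score_grid,
                          form_signatures, median_table, stratified_curves)
from .cohort_io import PatientRecord, read_cohort, validate_cohort, write_cohort
from .cutpoint_search import (CutpointSpec, ScreenResult, SearchConfig,
                              describe_intervals, screen_variables,
                              DEFAULT_DESIGNATIONS)
from .errors import MissingDataError, PipelineError
from .radiobiology import DEFAULT_PARAMS, RadiobiologyParams, classify_intent
from .survival_stats import curve_to_frame, kaplan_meier, median_time
from .synthetic_cohort import (SimulationConfig, default_config,
                               generate_cohort, planted_truth)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "spec_to_dict", "spec_from_dict",
           "partition_to_dict"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    With ``patients_path``/``lesions_path`` unset, a synthetic cohort is
    generated from ``simulation`` (written to the output directory so the
    run is self-contained).
    """

    patients_path: str | None = None
    lesions_path: str | None = None
    output_dir: str = "clical-run"
    seed: int = 0
    search: SearchConfig = field(default_factory=SearchConfig)
    radiobiology: RadiobiologyParams = field(default_factory=RadiobiologyParams)
    signature_alpha: float = 0.05
    designations: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DESIGNATIONS))
    simulation: SimulationConfig = field(default_factory=default_config)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "search" in kwargs:
            kwargs["search"] = SearchConfig(**kwargs["search"])
        if "radiobiology" in kwargs:
            kwargs["radiobiology"] = RadiobiologyParams(**kwargs["radiobiology"])
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        return cls(**kwargs)


def spec_to_dict(spec: CutpointSpec) -> dict:
    return {
        "variable": spec.variable,
        "cutpoints": list(spec.cutpoints),
        "interval_subscores": list(spec.interval_subscores),
        "intervals": describe_intervals(spec),
        "chi_square": spec.chi_square,
        "p_value": spec.p_value,
        "group_sizes": None if spec.group_sizes is None else list(spec.group_sizes),
    }


def spec_from_dict(d: dict) -> CutpointSpec:
    return CutpointSpec(
        variable=d["variable"],
        cutpoints=tuple(d["cutpoints"]),
        interval_subscores=tuple(d["interval_subscores"]),
        chi_square=d.get("chi_square"),
        p_value=d.get("p_value"),
        group_sizes=None if d.get("group_sizes") is None else tuple(d["group_sizes"]),
    )


def partition_to_dict(partition) -> dict:
    return {
        "alpha": partition.alpha,
        "n_groups": partition.n_groups,
        "blocks": [
            {"label": b.label, "scores": list(b.scores),
             "n": len(b.member_ids), "member_ids": list(b.member_ids)}
            for b in partition.blocks
        ],
        "adjacent_tests": [
            {"chi_square": t.chi_square, "p_value": t.p_value,
             "degrees_of_freedom": t.degrees_of_freedom}
            for t in partition.adjacent_tests
        ],
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _screen_report(screen: ScreenResult) -> str:
    lines = ["Variables with p <= alpha (entering the score):"]
    for s in screen.selected:
        lines.append(f"  {s.variable:<22s} {describe_intervals(s):<22s} "
                     f"chi2={s.chi_square:8.3f}  p={s.p_value:.4g}  "
                     f"sizes={s.group_sizes}")
    if screen.rejected:
        lines.append("Variables with p > alpha (excluded):")
        for s in screen.rejected:
            lines.append(f"  {s.variable:<22s} chi2={s.chi_square:8.3f}  "
                         f"p={s.p_value:.4g}")
    for name, reason in screen.skipped:
        lines.append(f"  {name}: skipped ({reason})")
    lines.append("")
    lines.append("Note: cut-points are maximally selected; the log-rank "
                 "p-values above are not corrected for the search over "
                 "candidate thresholds or for testing several variables.")
    lines.append("Note: trichotomy intervals are half-open and cover the "
                 "whole line (e.g. <5 / 5–9 / ≥10 leaves no gap at the "
                 "boundaries).")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the manifest (also written to
    ``manifest.json``).  Any stage failure raises :class:`PipelineError`
    naming the stage, after writing a manifest marked invalid."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            "search": dataclasses.asdict(config.search),
            "radiobiology": dataclasses.asdict(config.radiobiology),
            "signature_alpha": config.signature_alpha,
            "designations": config.designations,
        },
        "stages": [],
        "inputs_sha256": {},
        "outputs": [],
    }
    outputs: list[str] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        outputs.append(name)
        return path

    stage = "read"
    try:
        if config.patients_path is None:
            stage = "simulate"
            cohort = generate_cohort(
                dataclasses.replace(config.simulation, seed=config.seed))
            emit("patients.csv", lambda p: write_cohort(
                cohort, p, outdir / "lesions.csv"))
            outputs.append("lesions.csv")
            emit("truth.json", lambda p: p.write_text(
                json.dumps(planted_truth(config.simulation), indent=2)))
        else:
            cohort = read_cohort(config.patients_path, config.lesions_path)
            for p in (config.patients_path, config.lesions_path):
                manifest["inputs_sha256"][str(p)] = _sha256(Path(p))
        if len(cohort) == 0:
            raise PipelineError(stage, "cohort is empty")
        n_read = len(cohort)
        manifest["stages"].append({"stage": stage, "n": n_read})

        stage = "validate"
        report = validate_cohort(cohort)
        emit("validation.json", lambda p: p.write_text(report.to_json()))
        if not report.ok:
            log.warning("cohort has %d invariant violations", len(report.violations))
        manifest["stages"].append(
            {"stage": stage, "n_violations": len(report.violations)})

        stage = "intent"
        intents = {r.patient_id: classify_intent(r, config.radiobiology)
                   for r in cohort}
        emit("intent.csv", lambda p: pd.DataFrame(
            sorted(intents.items()), columns=["patient_id", "intent"]
        ).to_csv(p, index=False))
        manifest["stages"].append({
            "stage": stage,
            "n_curative": sum(v == "curative" for v in intents.values())})

        stage = "fit-cutpoints"
        screen = screen_variables(cohort, config.designations, config.search)
        emit("cutpoints.json", lambda p: p.write_text(json.dumps(
            [spec_to_dict(s) for s in screen.selected], indent=2,
            ensure_ascii=False)))
        emit("cutpoints_report.txt", lambda p: p.write_text(_screen_report(screen)))
        if not screen.selected:
            raise PipelineError(stage, "no variable passed the significance screen")
        manifest["stages"].append({"stage": stage,
                                   "n_selected": len(screen.selected),
                                   "n_rejected": len(screen.rejected)})

        stage = "score"
        rows, scored = [], []
        for r in cohort:
            try:
                subs = assign_subscores(r, screen.selected)
            except MissingDataError as exc:
                log.info("excluded from scoring: %s", exc)
                continue
            score = clical_score(subs)
            scored.append((r, score))
            rows.append({"patient_id": r.patient_id,
                         **{f"sub_{s.variable}": v
                            for s, v in zip(screen.selected, subs)},
                         "score": round(score, 1)})
        n_scored = len(scored)
        n_excluded = n_read - n_scored
        emit("scores.csv", lambda p: pd.DataFrame(rows).to_csv(p, index=False))
        manifest["stages"].append({"stage": stage, "n_scored": n_scored,
                                   "n_excluded_missing": n_excluded})
        manifest["n_read"] = n_read
        manifest["n_excluded_missing"] = n_excluded
        manifest["n_scored"] = n_scored
        manifest["score_grid"] = list(enumerate_score_grid(screen.selected))

        stage = "signatures"
        partition = form_signatures(
            [s for _, s in scored], [r.ttr for r, _ in scored],
            alpha=config.signature_alpha,
            patient_ids=[r.patient_id for r, _ in scored])
        emit("signatures.json", lambda p: p.write_text(
            json.dumps(partition_to_dict(partition), indent=2)))
        manifest["stages"].append({"stage": stage,
                                   "n_groups": partition.n_groups})

        stage = "report"
        by_id = {r.patient_id: r for r in cohort}
        km_frames = []
        for b in partition.blocks:
            curve = kaplan_meier([by_id[pid].ttr for pid in b.member_ids])
            f = curve_to_frame(curve)
            f.insert(0, "signature", b.label)
            km_frames.append(f)
        emit("km_signatures.csv", lambda p: pd.concat(
            km_frames, ignore_index=True).to_csv(p, index=False))
        med_frames = []
        for strat in ("intent", "lung_only"):
            cells = stratified_curves(partition, cohort, strat,
                                      config.radiobiology)
            f = median_table(cells)
            f.insert(0, "stratifier", strat)
            med_frames.append(f)
        emit("stratified_medians.csv", lambda p: pd.concat(
            med_frames, ignore_index=True).to_csv(p, index=False))
        whole = kaplan_meier([r.ttr for r in cohort if r.ttr is not None])
        manifest["cohort_median_ttr_months"] = median_time(whole)
        manifest["stages"].append({"stage": stage, "n_tables": 3})

        manifest["outputs"] = outputs
        manifest["status"] = "ok"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except PipelineError:
        manifest["status"] = f"failed at stage {stage}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(exc)) from exc
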