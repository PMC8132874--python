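"""End-to-end pipeline driver: streams → core temps → pairs → filter → report.

One call runs the whole validation analysis deterministically from a
:class:`~thermoagree.io.RunConfig`: simulate (or read) the per-patient
streams, derive double-sensor core temperatures, time-match against the
reference, apply the 2-SD artifact filter once over the pooled pairs, and
compute the agreement battery. Every stage logs its counts (samples,
candidate pairs, artifacts, retained) so a run's log reads like a study's
accounting trail, and every stage's output is persisted to the output
directory alongside the fully resolved configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .agreement import AgreementReport, bland_altman_plot_data, build_report
from .io import RunConfig, read_stream, write_pairs, write_stream
from .pairing import PairedDataset, concat_datasets, pair_streams, remove_artifacts
from .synthetic import simulate_cohort

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    report: AgreementReport
    candidates: PairedDataset
    filtered: PairedDataset
    outdir: Path


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig, outdir) -> PipelineResult:
    """Run the full analysis and persist all stage outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    if config.inputs:
        pairs_per_patient = []
        for pid, (ds_path, ref_path) in enumerate(config.inputs):
            ds = _stage("read")(read_stream, ds_path, "ds")
            ref = _stage("read")(read_stream, ref_path, "ref")
            logger.info(
                "patient %d: %d DS samples, %d reference samples", pid, len(ds), len(ref)
            )
            pairs_per_patient.append(
                _stage("pairing")(
                    pair_streams, ds, ref, config.model, config.window_s,
                    config.pairing_mode,
                )
            )
    else:
        bundles = _stage("simulate")(
            simulate_cohort, config.cohort, config.protocol, config.patient,
            config.model,
        )
        pairs_per_patient = []
        for b in bundles:
            logger.info(
                "patient %d: %d DS samples, %d reference samples",
                b.patient_id, len(b.ds), len(b.ref),
            )
            if config.save_streams:
                write_stream(outdir / f"ds_{b.patient_id:02d}.csv", b.ds)
                write_stream(outdir / f"ref_{b.patient_id:02d}.csv", b.ref)
            pairs_per_patient.append(
                _stage("pairing")(
                    pair_streams, b.ds, b.ref, config.model, config.window_s,
                    config.pairing_mode,
                )
            )

    candidates = concat_datasets(pairs_per_patient)
    logger.info(
        "pooled %d candidate pairs (%d ticks skipped)",
        candidates.n_total, candidates.skipped_ticks,
    )
    filtered = _stage("artifact-filter")(
        remove_artifacts, candidates, config.artifact_center,
        config.artifact_per_patient,
    )
    assert filtered.n_retained + filtered.n_artifact == candidates.n_total
    report = _stage("agreement")(
        build_report, filtered, config.threshold, config.alpha, config.icc_absolute
    )

    write_pairs(outdir / "pairs.csv", filtered)
    (outdir / "report.txt").write_text(report.to_text(), encoding="utf-8")
    (outdir / "report.json").write_text(report.to_json(indent=2), encoding="utf-8")
    points, lines = bland_altman_plot_data(filtered, report)
    for name, level in lines.items():
        points[name] = level
    points.to_csv(outdir / "bland_altman.csv", index=False, float_format="%.6g")
    logger.info(
        "report: n=%d bias=%.3f sd=%.3f icc=%.3f (%s)",
        report.n, report.bias, report.sd, report.icc, report.icc_class,
    )
    return PipelineResult(
        report=report, candidates=candidates, filtered=filtered, outdir=outdir
    )
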