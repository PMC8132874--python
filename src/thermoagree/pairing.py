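"""Time-matching of the two streams and the 2-SD artifact filter.

The double sensor logs at ~1 Hz while the esophageal reference logs every
30 minutes, so the analysis works on one candidate pair per reference tick:
the double-sensor core temperature is aggregated over a short centered
window around the tick (mean over a 60 s window by default; a
nearest-sample mode exists for sensitivity analysis). Artifacts are then
excluded in a single pass: a pair is flagged when its difference deviates
from the pooled mean difference by more than two pooled standard
deviations. The filter is applied exactly once per analysis; it is not
idempotent and is never iterated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sensor_model import HeatFluxModel, compute_core_temp
from .streams import DualSensorStream, ReferenceStream

__all__ = ["PairedDataset", "pair_streams", "remove_artifacts", "concat_datasets"]

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["t", "ds_core", "ref", "diff", "artifact"]


@dataclass
class PairedDataset:
    """Time-matched (double-sensor core, reference) pairs with artifact flags.

    ``frame`` holds one row per retained candidate pair with columns
    ``t, ds_core, ref, diff, artifact`` (and optionally ``patient``);
    ``diff`` is always ``ds_core - ref``. ``skipped_ticks`` counts reference
    ticks whose pairing window contained no double-sensor sample.
    """

    frame: pd.DataFrame
    skipped_ticks: int = 0
    filtered: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in PAIR_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"paired frame missing columns {missing}")

    @property
    def n_total(self) -> int:
        return int(len(self.frame))

    @property
    def n_artifact(self) -> int:
        return int(self.frame["artifact"].sum())

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_artifact

    @property
    def artifact_fraction_pct(self) -> float:
        """Flagged pairs as a percentage of all candidate pairs."""
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.n_artifact / self.n_total

    @property
    def retained(self) -> pd.DataFrame:
        """Pairs surviving the artifact filter (all pairs if unfiltered)."""
        return self.frame.loc[~self.frame["artifact"]]

    @property
    def diffs(self) -> np.ndarray:
        return self.retained["diff"].to_numpy()


def pair_streams(
    ds: DualSensorStream,
    ref: ReferenceStream,
    model: HeatFluxModel,
    window_s: float = 60.0,
    mode: str = "mean",
) -> PairedDataset:
    """Build one candidate pair per reference tick.

    For each reference time ``t`` the double-sensor samples in the centered
    window ``[t - window_s/2, t + window_s/2]`` are reduced to a single core
    temperature (window mean by default, ``mode="nearest"`` for the sample
    closest to the tick). Ticks with an empty window are skipped and
    counted. An empty overlap yields an empty dataset with a logged
    warning rather than an error.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if mode not in ("mean", "nearest"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    if len(ds) == 0 or len(ref) == 0:
        raise ValueError("both streams must be non-empty")

    core = np.atleast_1d(compute_core_temp(ds.th1, ds.th2, model))
    half = window_s / 2.0
    lo = np.searchsorted(ds.t, ref.t - half, side="left")
    hi = np.searchsorted(ds.t, ref.t + half, side="right")
    counts = hi - lo
    has_data = counts > 0

    if mode == "mean":
        csum = np.concatenate([[0.0], np.cumsum(core)])
        with np.errstate(invalid="ignore"):
            ds_core = (csum[hi] - csum[lo]) / np.where(counts > 0, counts, 1)
    elif len(ds) == 1:
        ds_core = np.full(len(ref), core[0])
    else:
        # index of the DS sample nearest each tick, restricted to the window
        idx = np.clip(np.searchsorted(ds.t, ref.t), 1, len(ds) - 1)
        left_closer = np.abs(ds.t[idx - 1] - ref.t) <= np.abs(ds.t[idx] - ref.t)
        idx = np.where(left_closer, idx - 1, idx)
        ds_core = core[idx]

    frame = pd.DataFrame(
        {
            "t": ref.t[has_data],
            "ds_core": ds_core[has_data],
            "ref": ref.temp[has_data],
        }
    )
    frame["diff"] = frame["ds_core"] - frame["ref"]
    frame["artifact"] = False
    skipped = int((~has_data).sum())
    if len(frame) == 0:
        logger.warning(
            "no overlap between double-sensor and reference streams; "
            "empty paired dataset"
        )
    logger.info(
        "paired %d reference ticks (%d skipped, empty window)", len(frame), skipped
    )
    return PairedDataset(frame=frame, skipped_ticks=skipped, filtered=False)


def _flag(diff: np.ndarray, center: str) -> np.ndarray:
    m = diff.mean() if center == "mean" else 0.0
    s = diff.std(ddof=1)
    return np.abs(diff - m) > 2.0 * s


def remove_artifacts(
    data: PairedDataset, center: str = "mean", per_patient: bool = False
) -> PairedDataset:
    """Flag pairs whose difference deviates from the mean by more than 2 SD.

    Mean and SD of the differences are computed once over the pooled input
    (single pass — the rule is deliberately not iterated). ``center="zero"``
    measures deviations from 0 instead of the mean difference, and
    ``per_patient=True`` pools within each patient; both are sensitivity
    variants, the pooled mean-centered rule is the default.
    """
    if center not in ("mean", "zero"):
        raise ValueError(f"unknown artifact center {center!r}")
    if data.n_total < 3:
        raise ValueError(
            f"artifact filter needs >= 3 pairs (SD undefined), got {data.n_total}"
        )
    frame = data.frame.copy()
    diff = frame["diff"].to_numpy()
    if per_patient:
        if "patient" not in frame.columns:
            raise ValueError("per_patient filtering requires a 'patient' column")
        flags = np.zeros(len(frame), dtype=bool)
        for _, idx in frame.groupby("patient").indices.items():
            if len(idx) < 3:
                raise ValueError("per-patient filter needs >= 3 pairs per patient")
            flags[idx] = _flag(diff[idx], center)
    else:
        flags = _flag(diff, center)
    frame["artifact"] = flags
    out = PairedDataset(frame=frame, skipped_ticks=data.skipped_ticks, filtered=True)
    logger.info(
        "artifact filter: %d of %d pairs flagged (%.1f%%), %d retained",
        out.n_artifact,
        out.n_total,
        out.artifact_fraction_pct,
        out.n_retained,
    )
    return out


def concat_datasets(
    datasets: list[PairedDataset], patient_ids: list[int] | None = None
) -> PairedDataset:
    """Pool per-patient paired datasets into one cohort dataset.

    Adds a ``patient`` column so the per-patient artifact-filter variant and
    per-patient summaries stay possible after pooling.
    """
    if not datasets:
        raise ValueError("need at least one dataset to pool")
    if patient_ids is None:
        patient_ids = list(range(len(datasets)))
    frames = []
    for pid, d in zip(patient_ids, datasets):
        f = d.frame.copy()
        f["patient"] = pid
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    return PairedDataset(
        frame=pooled,
        skipped_ticks=sum(d.skipped_ticks for d in datasets),
        filtered=all(d.filtered for d in datasets),
    )
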