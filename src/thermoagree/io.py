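"""Delimited stream/pair files and run configuration.

Streams are plain comma-separated UTF-8 text with a header row; timestamps
are seconds from stream start with a decimal point, strictly increasing.
Double-sensor files carry ``t_s, th1_c, th2_c`` plus an optional
``ambient_c`` column; reference files carry ``t_s, temp_c``. Missing values
are empty fields (allowed only for ambient), never sentinels. The format is
deliberately open and minimal: bedside logger exports are proprietary, so
anything feeding this pipeline is converted to this layout first.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pairing import PairedDataset
from .sensor_model import HeatFluxModel
from .streams import DualSensorStream, ReferenceStream
from .synthetic import CohortConfig, PatientParams, ProtocolConfig

__all__ = [
    "StreamParseError",
    "EmptyStreamError",
    "read_stream",
    "write_stream",
    "read_pairs",
    "write_pairs",
    "RunConfig",
]

DS_COLUMNS = ["t_s", "th1_c", "th2_c"]
DS_OPTIONAL = ["ambient_c"]
REF_COLUMNS = ["t_s", "temp_c"]


class StreamParseError(ValueError):
    """Malformed stream file (bad header, bad row, bad ordering)."""


class EmptyStreamError(StreamParseError):
    """Structurally valid stream file containing no data rows."""


def write_stream(path, stream: DualSensorStream | ReferenceStream) -> None:
    # default float repr round-trips exactly through read_stream
    stream.to_frame().to_csv(path, index=False)


def _parse_rows(path: Path, columns: list[str], optional: list[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise StreamParseError(f"{path}: file is empty, no header")
        header = [h.strip() for h in header]
        if header[: len(columns)] != columns or any(
            h not in optional for h in header[len(columns) :]
        ):
            raise StreamParseError(
                f"{path}: header {header} does not match expected "
                f"{columns} (+ optional {optional})"
            )
        rows = []
        prev_t = -np.inf
        for lineno, raw in enumerate(reader, start=2):
            if not raw or all(f.strip() == "" for f in raw):
                continue
            if len(raw) != len(header):
                raise StreamParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(raw)}"
                )
            values = []
            for name, fieldval in zip(header, raw):
                fieldval = fieldval.strip()
                if fieldval == "":
                    if name in optional:
                        values.append(np.nan)
                        continue
                    raise StreamParseError(
                        f"{path}: line {lineno}: missing value for {name!r}"
                    )
                try:
                    values.append(float(fieldval))
                except ValueError:
                    raise StreamParseError(
                        f"{path}: line {lineno}: cannot parse {name!r} "
                        f"value {fieldval!r}"
                    ) from None
            if values[0] <= prev_t:
                raise StreamParseError(
                    f"{path}: line {lineno}: timestamps not strictly "
                    f"increasing ({values[0]:g} after {prev_t:g})"
                )
            prev_t = values[0]
            rows.append(values)
    if not rows:
        raise EmptyStreamError(f"{path}: no data rows")
    return header, np.asarray(rows, dtype=float)


def read_stream(path, kind: str) -> DualSensorStream | ReferenceStream:
    """Read and validate a stream file.

    ``kind`` is ``"ds"`` for double-sensor files or ``"ref"`` for reference
    files. Errors name the offending line; an empty data section raises
    :class:`EmptyStreamError`, distinct from parse failures.
    """
    path = Path(path)
    if kind == "ds":
        header, data = _parse_rows(path, DS_COLUMNS, DS_OPTIONAL)
        ambient = data[:, 3] if len(header) > 3 else None
        return DualSensorStream(
            t=data[:, 0], th1=data[:, 1], th2=data[:, 2], ambient=ambient
        )
    if kind == "ref":
        _, data = _parse_rows(path, REF_COLUMNS, [])
        return ReferenceStream(t=data[:, 0], temp=data[:, 1])
    raise ValueError(f"unknown stream kind {kind!r} (expected 'ds' or 'ref')")


def write_pairs(path, dataset: PairedDataset) -> None:
    dataset.frame.to_csv(path, index=False)


def read_pairs(path) -> PairedDataset:
    frame = pd.read_csv(path)
    if "artifact" in frame.columns:
        frame["artifact"] = frame["artifact"].astype(bool)
    filtered = bool(frame["artifact"].any()) if "artifact" in frame.columns else False
    return PairedDataset(frame=frame, filtered=filtered)


@dataclass
class RunConfig:
    """Fully resolved configuration for one pipeline run.

    All nested configs validate at construction, so an invalid parameter
    (e.g. a zero heat-flux ratio) fails before any stage executes. When
    ``inputs`` lists (ds_path, ref_path) file pairs those are analyzed;
    otherwise a cohort is simulated from ``cohort``/``protocol``/``patient``.
    """

    model: HeatFluxModel = field(default_factory=HeatFluxModel)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    patient: PatientParams = field(default_factory=PatientParams)
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(n_patients=25))
    inputs: list[tuple[str, str]] = field(default_factory=list)
    window_s: float = 60.0
    pairing_mode: str = "mean"
    artifact_center: str = "mean"
    artifact_per_patient: bool = False
    icc_absolute: bool = False
    threshold: float = 0.5
    alpha: float = 0.05
    save_streams: bool = False

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.pairing_mode not in ("mean", "nearest"):
            raise ValueError(f"unknown pairing_mode {self.pairing_mode!r}")
        if self.artifact_center not in ("mean", "zero"):
            raise ValueError(f"unknown artifact_center {self.artifact_center!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = [list(pair) for pair in self.inputs]
        d["patient"]["lag_range_min"] = list(d["patient"]["lag_range_min"])
        d["patient"]["dropout_segments"] = [
            list(seg) for seg in d["patient"]["dropout_segments"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for key, typ in (
            ("model", HeatFluxModel),
            ("protocol", ProtocolConfig),
            ("patient", PatientParams),
            ("cohort", CohortConfig),
        ):
            if key in d:
                sub = dict(d.pop(key))
                if key == "patient":
                    if "lag_range_min" in sub:
                        sub["lag_range_min"] = tuple(sub["lag_range_min"])
                    if "dropout_segments" in sub:
                        sub["dropout_segments"] = tuple(
                            tuple(seg) for seg in sub["dropout_segments"]
                        )
                kwargs[key] = typ(**sub)
        if "inputs" in d:
            kwargs["inputs"] = [tuple(pair) for pair in d.pop("inputs")]
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
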