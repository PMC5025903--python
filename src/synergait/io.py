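"""Text-format readers and writers.

All interchange is plain text: wide CSV for EMG signals (first column time in
seconds, one column per muscle), long CSV for normalized stride sets, CSV for
gait events (time_s, event, side), JSON for synergy sets / impairment reports
/ stimulation strategies, and CSV for stimulator command logs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .envelope import EnvelopeRecording, EnvelopeStrideSet, N_CYCLE_POINTS, RawEmgRecording
from .errors import DataError
from .gait import GaitEventStream
from .impairment import ImpairmentReport
from .stimulation import StimulationStrategy
from .synergy import SynergySet

__all__ = [
    "read_emg_csv",
    "write_emg_csv",
    "read_strideset_csv",
    "write_strideset_csv",
    "read_events_csv",
    "write_events_csv",
    "read_synergies_json",
    "write_synergies_json",
    "write_synergies_csv",
    "read_report_json",
    "write_report_json",
    "write_report_csv",
    "read_strategy_json",
    "write_strategy_json",
    "write_commands_csv",
    "read_thresholds_json",
    "write_thresholds_json",
    "file_digest",
]


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_emg_csv(path, kind: str = "raw", side: str = "dominant"):
    """Wide EMG CSV (time_s + one column per muscle) -> recording object.

    The sample rate is inferred from the median time step and must be
    uniform to 1 part in 1e-6.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataError(f"{path}: need a time column plus at least one muscle")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    steps = np.diff(t)
    if steps.size == 0 or np.any(steps <= 0):
        raise DataError(f"{path}: time column must be strictly increasing")
    dt = np.median(steps)
    if np.max(np.abs(steps - dt)) > 1e-4 * max(dt, 1e-12):
        raise DataError(f"{path}: non-uniform sampling")
    muscles = list(df.columns[1:])
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    cls = RawEmgRecording if kind == "raw" else EnvelopeRecording
    return cls(muscles, 1.0 / dt, data, side=side)


def write_emg_csv(path, recording) -> None:
    t = np.arange(recording.n_samples) / recording.sample_rate
    df = pd.DataFrame(recording.data.T, columns=recording.muscle_names)
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False, float_format="%.10g")


def write_strideset_csv(path, strideset: EnvelopeStrideSet) -> None:
    """Long CSV: stride, point, one column per muscle (normalized envelopes)."""
    n, m, p = strideset.strides.shape
    df = pd.DataFrame(
        strideset.strides.transpose(0, 2, 1).reshape(n * p, m),
        columns=strideset.muscle_names,
    )
    df.insert(0, "point", np.tile(np.arange(p), n))
    df.insert(0, "stride", np.repeat(np.arange(n), p))
    df.to_csv(path, index=False, float_format="%.8g")


def read_strideset_csv(path, side: str = "dominant") -> EnvelopeStrideSet:
    df = pd.read_csv(path)
    for col in ("stride", "point"):
        if col not in df.columns:
            raise DataError(f"{path}: missing '{col}' column")
    muscles = [c for c in df.columns if c not in ("stride", "point")]
    n = int(df["stride"].max()) + 1
    p = int(df["point"].max()) + 1
    if p != N_CYCLE_POINTS or len(df) != n * p:
        raise DataError(f"{path}: expected {n} strides x {N_CYCLE_POINTS} points")
    df = df.sort_values(["stride", "point"], kind="stable")
    arr = df[muscles].to_numpy(dtype=float).reshape(n, p, len(muscles)).transpose(0, 2, 1)
    return EnvelopeStrideSet(muscles, arr, side=side)


def read_events_csv(path) -> GaitEventStream:
    df = pd.read_csv(path)
    for col in ("time_s", "event", "side"):
        if col not in df.columns:
            raise DataError(f"{path}: missing '{col}' column")
    return GaitEventStream.from_frame(df)


def write_events_csv(path, stream: GaitEventStream) -> None:
    stream.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_synergies_json(path) -> SynergySet:
    return SynergySet.from_json(Path(path).read_text())


def write_synergies_json(path, synergies: SynergySet) -> None:
    Path(path).write_text(synergies.to_json())


def write_synergies_csv(weights_path, activations_path, synergies: SynergySet) -> None:
    """Paired CSV matrices: weights (muscles x J) and activation profiles (J x T)."""
    pd.DataFrame(
        synergies.W, index=synergies.muscle_names, columns=synergies.labels
    ).to_csv(weights_path, index_label="muscle", float_format="%.8g")
    pd.DataFrame(
        synergies.mean_profiles(), index=synergies.labels
    ).to_csv(activations_path, index_label="synergy", float_format="%.8g")


def read_report_json(path) -> ImpairmentReport:
    return ImpairmentReport.from_json(Path(path).read_text())


def write_report_json(path, report: ImpairmentReport) -> None:
    Path(path).write_text(report.to_json())


def write_report_csv(path, report: ImpairmentReport) -> None:
    df = report.to_frame()
    df.loc["impaired"] = [report.impaired[lab] for lab in report.labels] + [""]
    df.to_csv(path, index_label="metric")


def read_strategy_json(path) -> StimulationStrategy:
    return StimulationStrategy.from_json(Path(path).read_text())


def write_strategy_json(path, strategy: StimulationStrategy) -> None:
    Path(path).write_text(strategy.to_json())


def write_commands_csv(path, commands: pd.DataFrame) -> None:
    commands.to_csv(path, index=False, float_format="%.6f")


def read_thresholds_json(path) -> dict:
    import json

    return json.loads(Path(path).read_text())


def write_thresholds_json(path, thresholds: dict) -> None:
    import json

    Path(path).write_text(json.dumps(thresholds, indent=2))
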