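"""Reading and writing IMU recording formats.

Two delimited-text dialects are supported:

* PAMAP2-style ``.dat``: space-separated, 54 columns per line (timestamp,
  activity ID, heart rate, then three 17-column IMU blocks at 100 Hz).  Only
  the 16 g accelerometer and the gyroscope triples of each IMU are retained
  (18 channels); temperature, the saturating 6 g accelerometer, magnetometer
  and orientation columns are dropped.
* A simple CSV dialect for arbitrary IMU layouts: ``time_s``, ``activity_id``,
  then one column per channel named ``<site>_<modality>_<axis>``.

Missing readings are represented by NaN in the samples matrix and never in
timestamps.  Readers never silently drop rows: kept + filtered counts always
add up to the number of data lines, and the tally is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan  #: sentinel for a missing sensor reading


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class ChannelMeta:
    """Identity of one sensor channel: body site, modality and axis."""

    site: str
    modality: str  # "acc" | "gyro"
    axis: str  # "x" | "y" | "z"

    @property
    def name(self) -> str:
        return f"{self.site}_{self.modality}_{self.axis}"


@dataclass
class SensorRecording:
    """A timestamped multi-channel IMU stream with per-sample activity labels.

    Attributes
    ----------
    timestamps : (T,) float array, seconds, monotone non-decreasing.
    samples : (T, D) float array; accelerometer in m/s^2, gyroscope in rad/s;
        missing readings are NaN.
    channel_meta : length-D channel descriptions.
    labels : (T,) int array of activity indices, every label >= 0.
    rate_hz : nominal sampling frequency.
    label_map : original activity ID -> dense 0..A-1 index, when the reader
        remapped labels.
    """

    timestamps: np.ndarray
    samples: np.ndarray
    channel_meta: list[ChannelMeta]
    labels: np.ndarray
    rate_hz: float
    label_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        T, D = self.samples.shape
        if len(self.timestamps) != T or len(self.labels) != T:
            raise ValueError("timestamps, samples and labels disagree on length")
        if len(self.channel_meta) != D:
            raise ValueError(f"{D} sample columns but {len(self.channel_meta)} channel_meta entries")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")
        if np.any(np.isnan(self.timestamps)):
            raise ValueError("timestamps may not contain the missing sentinel")
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")
        triples = [(m.site, m.modality, m.axis) for m in self.channel_meta]
        if len(set(triples)) != len(triples):
            raise ValueError("channel_meta (site, modality, axis) triples must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel_names(self) -> list[str]:
        return [m.name for m in self.channel_meta]


# --- PAMAP2 dialect ---------------------------------------------------------

#: columns per line: timestamp, activityID, heart rate, 3 IMUs x 17 columns
PAMAP2_N_COLUMNS = 54
PAMAP2_SITES = ("wrist", "chest", "ankle")
# within each 17-column IMU block: temperature(1) acc16g(3) acc6g(3) gyro(3)
# magnetometer(3) orientation(4); we keep acc16g + gyro
_IMU_BLOCK = 17
_ACC16G_OFFSET = 1
_GYRO_OFFSET = 7


def pamap2_channel_meta() -> list[ChannelMeta]:
    """The 18 retained channels of the PAMAP2 layout (3 sites x acc/gyro x xyz)."""
    meta = []
    for site in PAMAP2_SITES:
        for modality in ("acc", "gyro"):
            for axis in ("x", "y", "z"):
                meta.append(ChannelMeta(site, modality, axis))
    return meta


def _pamap2_keep_columns() -> list[int]:
    cols = []
    for imu in range(3):
        base = 3 + imu * _IMU_BLOCK
        cols.extend(range(base + _ACC16G_OFFSET, base + _ACC16G_OFFSET + 3))
        cols.extend(range(base + _GYRO_OFFSET, base + _GYRO_OFFSET + 3))
    return cols


def read_pamap2(path: str | Path, keep_activities: Iterable[int]) -> SensorRecording:
    """Read a PAMAP2-dialect ``.dat`` file, keeping only the given activity IDs.

    Activity 0 is the transient (non-activity) marker and should normally not
    be in ``keep_activities``.  Labels are remapped to a dense 0..A-1 index in
    ascending original-ID order; the mapping is stored on the recording.

    Raises
    ------
    FormatError
        On a malformed column count (names the 1-based line number).
    ValueError
        If no rows survive the activity filter.
    """
    keep = set(int(a) for a in keep_activities)
    if not keep:
        raise ValueError("keep_activities must be non-empty")
    rows: list[list[float]] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            n_lines += 1
            if len(parts) != PAMAP2_N_COLUMNS:
                raise FormatError(
                    f"{path}: line {lineno}: expected {PAMAP2_N_COLUMNS} "
                    f"space-separated columns, found {len(parts)}"
                )
            rows.append([float(p) for p in parts])  # "NaN" parses to nan
    data = np.array(rows, dtype=float)
    mask = np.isin(data[:, 1].astype(int), list(keep))
    n_filtered = int((~mask).sum())
    data = data[mask]
    if data.shape[0] == 0:
        raise ValueError(f"{path}: no data rows remain after filtering to activities {sorted(keep)}")
    logger.info(
        "read_pamap2(%s): %d lines -> %d kept, %d filtered by activity",
        path, n_lines, data.shape[0], n_filtered,
    )
    raw_labels = data[:, 1].astype(int)
    label_map = {orig: dense for dense, orig in enumerate(sorted(set(raw_labels.tolist())))}
    labels = np.array([label_map[a] for a in raw_labels])
    return SensorRecording(
        timestamps=data[:, 0],
        samples=data[:, _pamap2_keep_columns()],
        channel_meta=pamap2_channel_meta(),
        labels=labels,
        rate_hz=100.0,
        label_map=label_map,
    )


# --- CSV dialect ------------------------------------------------------------

_CSV_FIXED = ["time_s", "activity_id"]


def read_csv_recording(
    path: str | Path,
    channel_meta: Sequence[ChannelMeta],
    rate_hz: float,
) -> SensorRecording:
    """Read the package's CSV recording dialect.

    The header must be ``time_s, activity_id`` followed by the channel names
    of ``channel_meta`` in order; a mismatch raises :class:`FormatError`
    listing expected vs found columns.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    expected = _CSV_FIXED + [m.name for m in channel_meta]
    found = list(df.columns)
    if found != expected:
        raise FormatError(
            f"{path}: header mismatch: expected {expected}, found {found}"
        )
    logger.info("read_csv_recording(%s): %d rows, %d channels", path, len(df), len(channel_meta))
    return SensorRecording(
        timestamps=df["time_s"].to_numpy(float),
        samples=df[[m.name for m in channel_meta]].to_numpy(float),
        channel_meta=list(channel_meta),
        labels=df["activity_id"].to_numpy(int),
        rate_hz=rate_hz,
    )


def write_csv_recording(recording: SensorRecording, path: str | Path) -> None:
    """Write a recording in the CSV dialect with round-trip-exact floats."""
    df = pd.DataFrame({"time_s": recording.timestamps, "activity_id": recording.labels})
    for j, m in enumerate(recording.channel_meta):
        df[m.name] = recording.samples[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def infer_channel_meta(columns: Sequence[str]) -> list[ChannelMeta]:
    """Recover channel metadata from ``site_modality_axis`` column names."""
    meta = []
    for name in columns:
        parts = name.rsplit("_", 2)
        if len(parts) != 3:
            raise FormatError(f"channel column {name!r} is not of the form site_modality_axis")
        meta.append(ChannelMeta(*parts))
    return meta


def read_csv_recording_auto(path: str | Path, rate_hz: float) -> SensorRecording:
    """Read the CSV dialect, inferring channel metadata from the header."""
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header[: len(_CSV_FIXED)] != _CSV_FIXED:
        raise FormatError(f"{path}: header must start with {_CSV_FIXED}, found {header[:2]}")
    meta = infer_channel_meta(header[len(_CSV_FIXED):])
    return read_csv_recording(path, meta, rate_hz)


# --- label-map sidecar ------------------------------------------------------

def write_label_map(label_map: dict[int, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in label_map.items()}, fh, indent=2)


def read_label_map(path: str | Path) -> dict[int, int]:
    with open(path) as fh:
        return {int(k): int(v) for k, v in json.load(fh).items()}
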