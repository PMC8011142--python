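"""Reading and writing accelerometer streams, label intervals and dataset configuration.

All downstream modules consume the types defined here. Acceleration is
expressed in g (1 g = 9.8 m/s²) and time in seconds from stream start;
wall-clock timestamps in input files are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AccParseError",
    "ValidationError",
    "AxisMap",
    "AccSample",
    "AccSeries",
    "LabelInterval",
    "DatasetConfig",
    "read_acc_csv",
    "write_acc_csv",
    "read_labels",
    "write_labels",
    "read_config",
    "write_config",
]

PLACEMENTS = ("back", "collar", "leg", "ear")

#: label value used for samples not covered by any observation interval
UNLABELLED = None


class AccParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (ordering, overlap, range...)."""


@dataclass(frozen=True)
class AxisMap:
    """Maps the animal's body axes to columns of the stored x/y/z triplet.

    Files always store columns x, y, z; which physical axis is surge
    (longitudinal), sway (lateral) or heave (vertical) depends on the
    tracker attachment and lives here, not in the file dialect.
    """

    surge: int = 0
    sway: int = 1
    heave: int = 2

    def __post_init__(self) -> None:
        if sorted((self.surge, self.sway, self.heave)) != [0, 1, 2]:
            raise ValidationError(
                f"axis map must be a permutation of columns 0,1,2, got "
                f"({self.surge}, {self.sway}, {self.heave})"
            )


@dataclass(frozen=True)
class AccSample:
    """A single triaxial acceleration record."""

    t: float  # seconds since stream start
    x: float  # g
    y: float  # g
    z: float  # g


@dataclass
class AccSeries:
    """A uniformly sampled triaxial acceleration stream.

    Attributes
    ----------
    t : (n,) float array of seconds since stream start, strictly increasing
    xyz : (n, 3) float array of acceleration in g, columns x, y, z
    fs : sampling frequency in Hz
    axis_map : semantic mapping of body axes onto the x/y/z columns
    """

    t: np.ndarray
    xyz: np.ndarray
    fs: float
    axis_map: AxisMap = field(default_factory=AxisMap)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValidationError("xyz must be an (n, 3) array")
        if len(self.t) != len(self.xyz):
            raise ValidationError("t and xyz lengths differ")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("sample times must be strictly increasing")
        if not np.all(np.isfinite(self.xyz)):
            bad = int(np.argwhere(~np.isfinite(self.xyz))[0, 0])
            raise ValidationError(f"non-finite acceleration at sample {bad}")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> AccSample:
        return AccSample(float(self.t[i]), *map(float, self.xyz[i]))


@dataclass(frozen=True, order=True)
class LabelInterval:
    """A ground-truth observation interval [t_start, t_end) with one behaviour.

    A sample at time t carries the label of the interval with
    t_start <= t < t_end (half-open, so boundaries are never double-labelled).
    """

    t_start: float
    t_end: float
    label: str

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValidationError(
                f"interval must have t_start < t_end, got "
                f"[{self.t_start}, {self.t_end}) '{self.label}'"
            )

    def covers(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class DatasetConfig:
    """Recording and segmentation settings for one deployment.

    ``bout_len_records`` is the fixed window length in ACC records;
    ``placement`` (back / collar / leg / ear) determines the simplified
    feature set; ``bytes_per_value`` is the raw storage width of one
    acceleration value on the tracker (12-bit samples packed in 2 bytes
    on typical hardware).
    """

    fs: float
    bout_len_records: int
    sensor_range_g: float = 4.0
    bytes_per_value: int = 2
    placement: str = "back"
    behaviours: list[str] = field(default_factory=list)
    axis_map: AxisMap = field(default_factory=AxisMap)

    def __post_init__(self) -> None:
        if self.bout_len_records < 2:
            raise ValidationError("bout_len_records must be >= 2")
        if self.bytes_per_value < 1:
            raise ValidationError("bytes_per_value must be >= 1")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.placement not in PLACEMENTS:
            raise ValidationError(
                f"placement must be one of {PLACEMENTS}, got {self.placement!r}"
            )


# ---------------------------------------------------------------------------
# ACC CSV  (header t,x,y,z; comma-delimited; '.' decimal)
# ---------------------------------------------------------------------------

def read_acc_csv(path: str | Path, config: DatasetConfig) -> AccSeries:
    """Read a triaxial ACC stream from delimited text.

    The time column may hold seconds (numeric) or wall-clock timestamps;
    the latter are converted to seconds from the first sample. Samples
    outside the configured sensor range are kept but trigger a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["t", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise AccParseError(
            f"{path.name}: expected header {expected}, got {list(df.columns)}"
        )
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise AccParseError(
                f"{path.name}: cannot parse column '{col}' on line {bad[0] + 2}"
            )
        df[col] = vals
    t = pd.to_numeric(df["t"], errors="coerce")
    if t.isna().any():
        # wall-clock timestamps: convert to seconds from stream start
        try:
            stamps = pd.to_datetime(df["t"])
        except (ValueError, TypeError) as exc:
            raise AccParseError(f"{path.name}: cannot parse time column: {exc}") from None
        t = (stamps - stamps.iloc[0]).dt.total_seconds()
    t = t.to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValidationError(
            f"{path.name}: time not strictly increasing at line {bad + 2}"
        )
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if np.any(np.abs(xyz) > config.sensor_range_g):
        n_bad = int(np.sum(np.any(np.abs(xyz) > config.sensor_range_g, axis=1)))
        warnings.warn(
            f"{path.name}: {n_bad} samples exceed the ±{config.sensor_range_g} g "
            "sensor range; kept as-is",
            stacklevel=2,
        )
    return AccSeries(t=t, xyz=xyz, fs=config.fs, axis_map=config.axis_map)


def write_acc_csv(series: AccSeries, path: str | Path) -> None:
    """Write an ACC stream as `t,x,y,z` CSV with 6-decimal values."""
    df = pd.DataFrame(
        {"t": series.t, "x": series.xyz[:, 0], "y": series.xyz[:, 1], "z": series.xyz[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Label intervals  (header t_start,t_end,label)
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> list[LabelInterval]:
    """Read behaviour observation intervals; returns them sorted by start.

    Overlapping intervals are rejected: one sample must never carry two
    ground-truth behaviours.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["t_start", "t_end", "label"]
    if list(df.columns[:3]) != expected:
        raise AccParseError(
            f"{path.name}: expected header {expected}, got {list(df.columns)}"
        )
    intervals = [
        LabelInterval(float(r.t_start), float(r.t_end), str(r.label))
        for r in df.itertuples(index=False)
    ]
    intervals.sort()
    for a, b in zip(intervals, intervals[1:]):
        if b.t_start < a.t_end:
            raise ValidationError(
                f"{path.name}: intervals overlap: [{a.t_start}, {a.t_end}) "
                f"'{a.label}' and [{b.t_start}, {b.t_end}) '{b.label}'"
            )
    return intervals


def write_labels(intervals: Sequence[LabelInterval], path: str | Path) -> None:
    df = pd.DataFrame(
        [(iv.t_start, iv.t_end, iv.label) for iv in intervals],
        columns=["t_start", "t_end", "label"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset configuration (YAML key/value file mirroring DatasetConfig)
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> DatasetConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise AccParseError(f"{Path(path).name}: config must be a key/value mapping")
    axis_map = AxisMap(**raw.pop("axis_map", {}))
    known = {"fs", "bout_len_records", "sensor_range_g", "bytes_per_value",
             "placement", "behaviours"}
    unknown = set(raw) - known
    if unknown:
        raise AccParseError(f"{Path(path).name}: unknown config keys {sorted(unknown)}")
    return DatasetConfig(axis_map=axis_map, **raw)


def write_config(config: DatasetConfig, path: str | Path) -> None:
    data = {
        "fs": config.fs,
        "bout_len_records": config.bout_len_records,
        "sensor_range_g": config.sensor_range_g,
        "bytes_per_value": config.bytes_per_value,
        "placement": config.placement,
        "behaviours": list(config.behaviours),
        "axis_map": {
            "surge": config.axis_map.surge,
            "sway": config.axis_map.sway,
            "heave": config.axis_map.heave,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
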