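"""Fixed-length bout segmentation of labelled accelerometer streams.

A bout is the unit of classification: a window of ``bout_len_records``
consecutive ACC records ideally containing a single behaviour. Windows
whose samples do not all share one behaviour label (or that contain
unlabelled time) are pruned, so the retained bouts satisfy the
single-label invariant by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AccSeries, DatasetConfig, LabelInterval, ValidationError

__all__ = ["Bout", "bout_records_for", "sample_labels", "segment_series",
           "write_bout_table", "read_bout_table"]


@dataclass
class Bout:
    """A fixed-length, single-behaviour ACC segment.

    ``samples`` is an (n, 3) array in g (columns x, y, z), ``label`` the
    behaviour of every constituent sample (None for unlabelled bouts) and
    ``source_offset`` the index of the first sample in the parent series.
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    source_offset: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError("bout samples must be an (n, 3) array")
        if len(self.samples) < 2:
            raise ValidationError("a bout needs at least 2 records")

    def __len__(self) -> int:
        return len(self.samples)


def bout_records_for(duration_s: float, fs: float) -> int:
    """Number of ACC records in a bout of ``duration_s`` seconds at ``fs`` Hz.

    Rounded to the nearest record: 3.8 s at 10.54 Hz gives 40 records,
    9.1 s at 3.3 Hz gives 30.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValidationError("duration and sampling rate must be positive")
    return int(round(duration_s * fs))


def sample_labels(
    series: AccSeries, labels: Sequence[LabelInterval]
) -> np.ndarray:
    """Per-sample behaviour labels (object array; None where unlabelled).

    A sample at time t carries the label of the interval with
    t_start <= t < t_end.
    """
    out = np.full(len(series), None, dtype=object)
    if not labels:
        return out
    ivs = sorted(labels)
    starts = np.array([iv.t_start for iv in ivs])
    idx = np.searchsorted(starts, series.t, side="right") - 1
    for i, j in enumerate(idx):
        if j >= 0 and ivs[j].covers(series.t[i]):
            out[i] = ivs[j].label
    return out


def segment_series(
    series: AccSeries,
    labels: Sequence[LabelInterval],
    config: DatasetConfig,
) -> tuple[list[Bout], int]:
    """Cut a stream into consecutive fixed-length bouts and prune mixed ones.

    Windows are non-overlapping, start at sample 0, and the trailing
    partial window is discarded. A window is retained iff every sample in
    it carries the same non-null behaviour label; all other full windows
    count toward ``pruned_count``.

    Returns
    -------
    (retained, pruned_count) with
    ``len(retained) + pruned_count == len(series) // bout_len_records``.
    """
    n = config.bout_len_records
    if len(series) < n:
        warnings.warn(
            f"series of {len(series)} records is shorter than one "
            f"{n}-record bout; nothing to segment",
            stacklevel=2,
        )
        return [], 0
    lab = sample_labels(series, labels)
    retained: list[Bout] = []
    pruned = 0
    for start in range(0, len(series) - n + 1, n):
        window = lab[start : start + n]
        first = window[0]
        if first is not None and all(l == first for l in window):
            retained.append(
                Bout(
                    samples=series.xyz[start : start + n].copy(),
                    fs=series.fs,
                    label=str(first),
                    source_offset=start,
                )
            )
        else:
            pruned += 1
    return retained, pruned


# ---------------------------------------------------------------------------
# Bout table round-trip: a metadata CSV (bout_id,label,offset) plus a wide
# companion CSV of samples (bout_id,record,x,y,z). Burst-mode recordings
# (one recorded burst = one candidate bout) can be written in this shape
# directly.
# ---------------------------------------------------------------------------

def write_bout_table(
    bouts: Sequence[Bout], meta_path: str | Path, samples_path: str | Path
) -> None:
    meta = pd.DataFrame(
        [(i, b.label if b.label is not None else "", b.source_offset, b.fs)
         for i, b in enumerate(bouts)],
        columns=["bout_id", "label", "offset", "fs"],
    )
    meta.to_csv(meta_path, index=False)
    rows = []
    for i, b in enumerate(bouts):
        for r, (x, y, z) in enumerate(b.samples):
            rows.append((i, r, x, y, z))
    pd.DataFrame(rows, columns=["bout_id", "record", "x", "y", "z"]).to_csv(
        samples_path, index=False, float_format="%.6f"
    )


def read_bout_table(
    meta_path: str | Path, samples_path: str | Path
) -> list[Bout]:
    meta = pd.read_csv(meta_path, keep_default_na=False)
    samples = pd.read_csv(samples_path)
    bouts = []
    grouped = {k: g for k, g in samples.groupby("bout_id")}
    for row in meta.itertuples(index=False):
        g = grouped[row.bout_id].sort_values("record")
        bouts.append(
            Bout(
                samples=g[["x", "y", "z"]].to_numpy(dtype=float),
                fs=float(row.fs),
                label=str(row.label) if row.label != "" else None,
                source_offset=int(row.offset),
            )
        )
    return bouts
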