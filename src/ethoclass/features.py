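"""Per-bout summary statistics for behaviour classification.

The full catalogue holds 78 features per bout, grouped as

* per-axis moments and extremes: mean, variance, sd, coefficient of
  variation, skewness, kurtosis, max, min, range, Euclidean norm (30);
* per-pair covariance, Pearson correlation, mean difference and sd of
  the difference between two axes (12);
* posture/movement decomposition: variance of static and of dynamic
  acceleration, mean and max dynamic body acceleration per axis, plus
  ODBA (13);
* device orientation: pitch and roll from the mean gravity vector (2);
* per-axis mean and variance of successive-sample differences (6);
* per-axis dominant frequency and its amplitude from the DFT (6);
* per-axis 25/50/75 % quartiles (9).

The simplified sets mirror what a power-constrained tracker would
compute: mean and sd of the posture-bearing axes plus ODBA (back,
collar and leg attachments: mean/sd of surge and heave, 5 features), or
mean/sd of heave, ODBA and the heave main frequency for ear tags, where
the frequency term picks up jaw movement (4 features).

Angles are reported in degrees; every value is finite by construction
(zero-variance denominators yield 0, never NaN, so classifiers always
receive usable inputs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AxisMap, ValidationError
from .segmentation import Bout

__all__ = [
    "FeatureVector",
    "PlacementProfile",
    "FULL_FEATURE_NAMES",
    "FEATURE_GROUP_SIZES",
    "static_dynamic_decompose",
    "compute_odba",
    "compute_pitch_roll",
    "compute_main_frequency",
    "compute_full_features",
    "compute_simplified_features",
    "feature_table",
]

_AXES = ("x", "y", "z")
_PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))


def _catalogue() -> list[str]:
    names: list[str] = []
    for stat in ("mean", "var", "sd", "cv", "skew", "kurt", "max", "min",
                 "range", "norm"):
        names += [f"{stat}_{a}" for a in _AXES]
    for stat in ("cov", "corr", "meandiff", "sddiff"):
        names += [f"{stat}_{a}{b}" for a, b in _PAIRS]
    for stat in ("statvar", "dynvar", "meandba", "maxdba"):
        names += [f"{stat}_{a}" for a in _AXES]
    names += ["odba", "pitch", "roll"]
    for stat in ("meandl", "vardl"):
        names += [f"{stat}_{a}" for a in _AXES]
    for stat in ("mainfreq", "mainamp"):
        names += [f"{stat}_{a}" for a in _AXES]
    for q in (25, 50, 75):
        names += [f"q{q}_{a}" for a in _AXES]
    return names


#: catalogue order of the full feature set (78 names)
FULL_FEATURE_NAMES: tuple[str, ...] = tuple(_catalogue())

#: group sizes in catalogue order: per-axis stats, per-pair stats,
#: static/dynamic block incl. ODBA, angles, successive differences,
#: frequency, quartiles
FEATURE_GROUP_SIZES: tuple[int, ...] = (30, 12, 13, 2, 6, 6, 9)


@dataclass
class FeatureVector:
    """Ordered, named per-bout features; ``set_kind`` is 'full' or 'simplified'."""

    values: dict[str, float]
    set_kind: str = "full"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass(frozen=True)
class PlacementProfile:
    """Which axes carry the behavioural signal for a given attachment."""

    placement: str
    primary_axes: tuple[str, ...]
    include_main_frequency: bool

    @classmethod
    def for_placement(cls, placement: str) -> "PlacementProfile":
        if placement in ("back", "collar", "leg"):
            return cls(placement, ("surge", "heave"), False)
        if placement == "ear":
            return cls(placement, ("heave",), True)
        raise ValidationError(f"unknown placement {placement!r}")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def static_dynamic_decompose(
    bout: Bout, window: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split raw acceleration into its static (gravity) and dynamic parts.

    The static component is a centred moving average of each axis; with
    the default window (the whole bout) it is simply the per-axis bout
    mean replicated, which suits bouts short enough to hold a single
    posture. ``static + dynamic == raw`` elementwise by construction.

    Parameters
    ----------
    window : smoothing window in records; None means the full bout.
    """
    raw = bout.samples
    if window is None or window >= len(raw):
        static = np.broadcast_to(raw.mean(axis=0), raw.shape).copy()
    else:
        static = (
            pd.DataFrame(raw)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return static, raw - static


def compute_odba(bout: Bout, window: int | None = None) -> float:
    """Overall dynamic body acceleration in g.

    Mean over samples of the summed absolute dynamic acceleration across
    the three axes — the mean form makes ODBA comparable across bout
    lengths.
    """
    _, dyn = static_dynamic_decompose(bout, window)
    return float(np.abs(dyn).sum(axis=1).mean())


def compute_pitch_roll(
    bout: Bout, axis_map: AxisMap | None = None
) -> tuple[float, float]:
    """Device pitch and roll in degrees from the mean gravity vector.

    pitch = atan2(mean_surge, sqrt(mean_sway² + mean_heave²)),
    roll  = atan2(mean_sway, mean_heave).
    """
    axis_map = axis_map or AxisMap()
    m = bout.samples.mean(axis=0)
    surge, sway, heave = m[axis_map.surge], m[axis_map.sway], m[axis_map.heave]
    if np.allclose([surge, sway, heave], 0.0):
        warnings.warn("zero mean acceleration vector; pitch/roll set to 0",
                      stacklevel=2)
        return 0.0, 0.0
    pitch = np.degrees(np.arctan2(surge, np.hypot(sway, heave)))
    roll = np.degrees(np.arctan2(sway, heave))
    return float(pitch), float(roll)


def compute_main_frequency(
    axis_signal: np.ndarray, fs: float
) -> tuple[float, float]:
    """Dominant frequency (Hz) and its amplitude (g) of one axis.

    DFT of the mean-removed signal; the DC bin is excluded and ties go
    to the lowest frequency. Amplitude is scaled by 2/N so a unit
    sinusoid sitting on an exact bin scores 1. An effectively constant
    signal reports the first non-DC bin with amplitude 0.
    """
    sig = np.asarray(axis_signal, dtype=float)
    if sig.ndim != 1 or len(sig) < 2:
        raise ValidationError("signal must be 1-D with at least 2 samples")
    n = len(sig)
    spec = np.fft.rfft(sig - sig.mean())
    amps = 2.0 / n * np.abs(spec)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    k = 1 + int(np.argmax(amps[1:]))  # argmax takes the first (lowest) max
    return float(freqs[k]), float(amps[k])


# ---------------------------------------------------------------------------
# full catalogue
# ---------------------------------------------------------------------------

def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_full_features(
    bout: Bout,
    axis_map: AxisMap | None = None,
    static_window: int | None = None,
) -> FeatureVector:
    """Compute the full 78-feature catalogue for one bout.

    Conventions: variance, sd and covariance use the n−1 denominator;
    skewness is m3/m2^{3/2} and kurtosis the excess m4/m2² − 3 (both 0
    on a zero-variance axis); the coefficient of variation is sd/mean
    (0 when the mean or sd is 0); 'mean difference of continuous points'
    is the mean ABSOLUTE successive difference (the signed mean
    telescopes to ~0), while its variance uses signed differences;
    quartiles use linear interpolation.
    """
    axis_map = axis_map or AxisMap()
    raw = bout.samples
    v: dict[str, float] = {}

    cols = {a: raw[:, i] for i, a in enumerate(_AXES)}
    mean = {a: float(c.mean()) for a, c in cols.items()}
    var = {a: float(c.var(ddof=1)) for a, c in cols.items()}
    sd = {a: float(np.sqrt(var[a])) for a in _AXES}

    for a in _AXES:
        v[f"mean_{a}"] = mean[a]
    for a in _AXES:
        v[f"var_{a}"] = var[a]
    for a in _AXES:
        v[f"sd_{a}"] = sd[a]
    for a in _AXES:
        v[f"cv_{a}"] = _safe_div(sd[a], mean[a]) if sd[a] != 0 else 0.0
    for a in _AXES:
        v[f"skew_{a}"] = float(stats.skew(cols[a])) if sd[a] != 0 else 0.0
    for a in _AXES:
        v[f"kurt_{a}"] = float(stats.kurtosis(cols[a])) if sd[a] != 0 else 0.0
    for a in _AXES:
        v[f"max_{a}"] = float(cols[a].max())
    for a in _AXES:
        v[f"min_{a}"] = float(cols[a].min())
    for a in _AXES:
        v[f"range_{a}"] = v[f"max_{a}"] - v[f"min_{a}"]
    for a in _AXES:
        v[f"norm_{a}"] = float(np.linalg.norm(cols[a]))

    for a, b in _PAIRS:
        v[f"cov_{a}{b}"] = float(np.cov(cols[a], cols[b], ddof=1)[0, 1])
    for a, b in _PAIRS:
        denom = sd[a] * sd[b]
        v[f"corr_{a}{b}"] = _safe_div(v[f"cov_{a}{b}"], denom)
    for a, b in _PAIRS:
        v[f"meandiff_{a}{b}"] = mean[a] - mean[b]
    for a, b in _PAIRS:
        v[f"sddiff_{a}{b}"] = float(np.std(cols[a] - cols[b], ddof=1))

    static, dyn = static_dynamic_decompose(bout, static_window)
    for i, a in enumerate(_AXES):
        v[f"statvar_{a}"] = float(static[:, i].var(ddof=1))
    for i, a in enumerate(_AXES):
        v[f"dynvar_{a}"] = float(dyn[:, i].var(ddof=1))
    for i, a in enumerate(_AXES):
        v[f"meandba_{a}"] = float(np.abs(dyn[:, i]).mean())
    for i, a in enumerate(_AXES):
        v[f"maxdba_{a}"] = float(np.abs(dyn[:, i]).max())
    v["odba"] = float(np.abs(dyn).sum(axis=1).mean())

    v["pitch"], v["roll"] = compute_pitch_roll(bout, axis_map)

    diffs = {a: np.diff(cols[a]) for a in _AXES}
    for a in _AXES:
        v[f"meandl_{a}"] = float(np.abs(diffs[a]).mean())
    for a in _AXES:
        v[f"vardl_{a}"] = float(diffs[a].var(ddof=1)) if len(diffs[a]) > 1 else 0.0

    spectra = {a: compute_main_frequency(cols[a], bout.fs) for a in _AXES}
    for a in _AXES:
        v[f"mainfreq_{a}"] = spectra[a][0]
    for a in _AXES:
        v[f"mainamp_{a}"] = spectra[a][1]

    for q in (25, 50, 75):
        for a in _AXES:
            v[f"q{q}_{a}"] = float(np.percentile(cols[a], q))

    assert tuple(v) == FULL_FEATURE_NAMES
    return FeatureVector(values=v, set_kind="full")


# ---------------------------------------------------------------------------
# simplified placement-specific sets
# ---------------------------------------------------------------------------

_ROLE_TO_COLUMN = {"surge": "surge", "sway": "sway", "heave": "heave"}


def compute_simplified_features(
    bout: Bout,
    profile: PlacementProfile | str,
    axis_map: AxisMap | None = None,
) -> FeatureVector:
    """Compute the reduced on-board feature set for a tracker placement.

    back / collar / leg: mean and sd of surge and heave plus ODBA
    (5 features); ear: mean and sd of heave, ODBA and the heave main
    frequency (4 features). Every value equals its full-catalogue
    counterpart.
    """
    if isinstance(profile, str):
        profile = PlacementProfile.for_placement(profile)
    axis_map = axis_map or AxisMap()
    col_of = {"surge": axis_map.surge, "sway": axis_map.sway,
              "heave": axis_map.heave}
    v: dict[str, float] = {}
    for role in profile.primary_axes:
        c = bout.samples[:, col_of[role]]
        v[f"mean_{role}"] = float(c.mean())
        v[f"sd_{role}"] = float(c.std(ddof=1))
    v["odba"] = compute_odba(bout)
    if profile.include_main_frequency:
        freq, _ = compute_main_frequency(
            bout.samples[:, col_of["heave"]], bout.fs
        )
        v["mainfreq_heave"] = freq
    return FeatureVector(values=v, set_kind="simplified")


def feature_table(
    bouts: Sequence[Bout],
    set_kind: str = "full",
    placement: str | PlacementProfile = "back",
    axis_map: AxisMap | None = None,
) -> pd.DataFrame:
    """Feature matrix for a list of bouts: one row per bout.

    Columns are ``bout_id``, ``label`` and the feature names of the
    requested set.
    """
    if set_kind not in ("full", "simplified"):
        raise ValidationError("set_kind must be 'full' or 'simplified'")
    rows = []
    for i, b in enumerate(bouts):
        if set_kind == "full":
            fv = compute_full_features(b, axis_map)
        else:
            fv = compute_simplified_features(b, placement, axis_map)
        rows.append({"bout_id": i, "label": b.label, **fv.values})
    return pd.DataFrame(rows)
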