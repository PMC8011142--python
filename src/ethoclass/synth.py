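"""Synthetic labelled triaxial accelerometer data.

Behaviours are emulated as the sum of three components that real ACC
signals decompose into: a static gravity projection encoding posture
(a unit vector in g), a per-axis sinusoid encoding cyclic dynamic
movement (wingbeat, stride, chewing), and white Gaussian sensor noise.
Streams alternate behaviour episodes with exponentially distributed
dwell times; the sinusoid-plus-noise form gives closed-form feature
expectations (mean ≈ posture; ODBA → (2/π)·Σ amplitudes as noise → 0;
the dominant frequency equals the driving frequency), which makes every
downstream module testable without field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import AccSeries, AxisMap, DatasetConfig, LabelInterval, ValidationError
from .segmentation import Bout

__all__ = ["BehaviourSpec", "generate_series", "generate_labelled_bouts",
           "preset", "PRESETS"]


@dataclass(frozen=True)
class BehaviourSpec:
    """Signal model of one behaviour.

    posture : unit gravity projection in g (body orientation at rest)
    dyn_amplitude : per-axis sinusoid amplitude in g
    dyn_freq : driving frequency in Hz (must stay below fs/2)
    noise_sd : Gaussian sensor/jitter noise in g
    dwell : mean episode duration in seconds
    """

    name: str
    posture: tuple[float, float, float]
    dyn_amplitude: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dyn_freq: float = 0.0
    noise_sd: float = 0.02
    dwell: float = 30.0

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.posture))
        if abs(norm - 1.0) > 0.02:
            raise ValidationError(
                f"{self.name}: posture must be a unit gravity vector "
                f"(|posture| = {norm:.3f} g)"
            )
        if self.noise_sd < 0 or self.dwell <= 0 or self.dyn_freq < 0:
            raise ValidationError(f"{self.name}: negative signal parameter")


def _episode_signal(
    spec: BehaviourSpec, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / fs
    sig = np.tile(np.asarray(spec.posture, dtype=float), (n, 1))
    if spec.dyn_freq > 0 and any(a > 0 for a in spec.dyn_amplitude):
        phases = rng.uniform(0, 2 * np.pi, size=3)
        for ax in range(3):
            sig[:, ax] += spec.dyn_amplitude[ax] * np.sin(
                2 * np.pi * spec.dyn_freq * t + phases[ax]
            )
    if spec.noise_sd > 0:
        sig += rng.normal(0.0, spec.noise_sd, size=(n, 3))
    return sig


def _check_aliasing(specs: Sequence[BehaviourSpec], fs: float) -> None:
    for s in specs:
        if s.dyn_freq >= fs / 2:
            raise ValidationError(
                f"{s.name}: dyn_freq {s.dyn_freq} Hz aliases at fs {fs} Hz "
                f"(Nyquist {fs / 2} Hz)"
            )


def generate_series(
    specs: Sequence[BehaviourSpec],
    total_s: float,
    fs: float,
    seed: int = 0,
    axis_map: AxisMap | None = None,
) -> tuple[AccSeries, list[LabelInterval]]:
    """Generate a continuous labelled stream of alternating behaviour episodes.

    Episode behaviours are drawn uniformly (never repeating the current
    one when more than one spec is given) with Exp(dwell) durations, so
    expected label time-fractions follow the dwell proportions.
    """
    if not specs:
        raise ValidationError("need at least one behaviour spec")
    _check_aliasing(specs, fs)
    if total_s <= max(s.dwell for s in specs):
        raise ValidationError("total_s must exceed the longest mean dwell")
    rng = np.random.default_rng(seed)
    n_total = int(round(total_s * fs))
    chunks: list[np.ndarray] = []
    intervals: list[LabelInterval] = []
    pos = 0
    current = int(rng.integers(len(specs)))
    while pos < n_total:
        spec = specs[current]
        dur = rng.exponential(spec.dwell)
        n = max(1, min(int(round(dur * fs)), n_total - pos))
        chunks.append(_episode_signal(spec, n, fs, rng))
        intervals.append(
            LabelInterval(pos / fs, (pos + n) / fs, spec.name)
        )
        pos += n
        if len(specs) > 1:
            step = int(rng.integers(1, len(specs)))
            current = (current + step) % len(specs)
    xyz = np.vstack(chunks)
    series = AccSeries(
        t=np.arange(n_total) / fs, xyz=xyz, fs=fs,
        axis_map=axis_map or AxisMap(),
    )
    return series, intervals


def generate_labelled_bouts(
    specs: Sequence[BehaviourSpec],
    n_per_class: int,
    bout_records: int,
    fs: float,
    seed: int = 0,
) -> list[Bout]:
    """Generate exactly ``n_per_class`` pure single-behaviour bouts per spec.

    Each bout gets fresh random phases and noise, so bouts are i.i.d.
    realisations of their behaviour's signal model.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    _check_aliasing(specs, fs)
    rng = np.random.default_rng(seed)
    bouts = []
    for spec in specs:
        for _ in range(n_per_class):
            bouts.append(
                Bout(
                    samples=_episode_signal(spec, bout_records, fs, rng),
                    fs=fs,
                    label=spec.name,
                )
            )
    return bouts


# ---------------------------------------------------------------------------
# presets: a back-mounted bird configuration (short 40-record bursts at
# 10.54 Hz, a four-behaviour ethogram with distinct postures and wing/gait
# frequencies) and an ear-tag ruminant configuration (1-min bouts at 25 Hz,
# where jaw-movement frequency separates eating from ruminating).
# ---------------------------------------------------------------------------

def _stork_specs() -> list[BehaviourSpec]:
    return [
        BehaviourSpec("standing", posture=(0.0, 0.0, 1.0),
                      noise_sd=0.03, dwell=60.0),
        BehaviourSpec("walking", posture=(0.174, 0.0, 0.985),
                      dyn_amplitude=(0.25, 0.10, 0.35), dyn_freq=2.0,
                      noise_sd=0.05, dwell=30.0),
        BehaviourSpec("passive_flight", posture=(-0.342, 0.0, 0.940),
                      dyn_amplitude=(0.08, 0.06, 0.10), dyn_freq=0.8,
                      noise_sd=0.04, dwell=120.0),
        BehaviourSpec("active_flight", posture=(0.259, 0.0, 0.966),
                      dyn_amplitude=(0.60, 0.25, 0.90), dyn_freq=3.9,
                      noise_sd=0.08, dwell=45.0),
    ]


def _cow_specs() -> list[BehaviourSpec]:
    return [
        BehaviourSpec("eating", posture=(0.5, 0.0, 0.866),
                      dyn_amplitude=(0.10, 0.08, 0.25), dyn_freq=1.2,
                      noise_sd=0.05, dwell=600.0),
        BehaviourSpec("ruminating", posture=(0.0, 0.0, 1.0),
                      dyn_amplitude=(0.04, 0.03, 0.12), dyn_freq=0.9,
                      noise_sd=0.03, dwell=900.0),
        BehaviourSpec("other", posture=(0.0, 0.259, 0.966),
                      dyn_amplitude=(0.15, 0.15, 0.15), dyn_freq=0.5,
                      noise_sd=0.10, dwell=300.0),
    ]


PRESETS = {
    "stork": (
        lambda: DatasetConfig(
            fs=10.54, bout_len_records=40, placement="back",
            behaviours=[s.name for s in _stork_specs()],
        ),
        _stork_specs,
    ),
    "cow": (
        lambda: DatasetConfig(
            fs=25.0, bout_len_records=1500, placement="ear",
            behaviours=[s.name for s in _cow_specs()],
        ),
        _cow_specs,
    ),
}


def preset(name: str) -> tuple[DatasetConfig, list[BehaviourSpec]]:
    """Return (DatasetConfig, behaviour specs) for a named preset."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg_fn, specs_fn = PRESETS[name]
    return cfg_fn(), specs_fn()
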