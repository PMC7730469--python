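"""Synthetic heel-IMU walking cohorts with known gait structure.

The simulator emulates a treadmill brisk-walking bout recorded by a single
heel-mounted IMU at 50 Hz: each gait cycle is one period of a per-channel
harmonic template, cycles are strung together with lognormal
cycle-duration jitter, white sensor noise is added, and values are clipped
or wrapped to the device's full-scale ranges. Because cycles are laid down
one at a time, the true heel-strike sample indices are known exactly and
are returned as ground truth alongside the recording.

Progressive "fatigue" is injected as time-ramped modifications of the
per-cycle template parameters (amplitude scaling, offset scaling, or
cycle-duration variability scaling). A multiplier holds at 1 across the
baseline analysis window, ramps linearly between windows, and holds at its
target across the 30th- and 60th-minute windows, so each window sits
exactly at its configured effect level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io import (
    ACCEL_CHANNELS,
    ACCEL_FULL_SCALE_G,
    ANGLE_CHANNELS,
    CHANNELS,
    GYRO_CHANNELS,
    GYRO_FULL_SCALE_DPS,
    ImuRecording,
    wrap_angle_90,
    wrap_angle_180,
)

#: Fraction of the cycle by which the medial-lateral angular-velocity peak
#: trails the heel strike (peak angular velocity occurs just after contact;
#: 4% of a ~1 s cycle is ~2 samples at 50 Hz, so peak-detected cycle
#: boundaries sit within 2 samples of the true strike).
_WX_PEAK_OFFSET = 0.04

EFFECT_PROPERTIES = ("amplitude_scale", "offset_shift", "cycle_variability_scale")


@dataclass(frozen=True)
class ChannelTemplate:
    """One channel's periodic waveform: offset plus harmonics of the cycle.

    ``amplitudes[h]`` and ``phases[h]`` describe harmonic ``h+1`` of the
    cycle frequency, i.e. the waveform is
    ``offset + sum_h amplitudes[h] * cos(2*pi*(h+1)*phi + phases[h])``
    with ``phi`` in [0, 1) the within-cycle phase.
    """

    amplitudes: tuple[float, ...]
    phases: tuple[float, ...]
    offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.phases):
            raise ConfigError("amplitudes and phases must have equal length")

    def evaluate(self, phi: np.ndarray) -> np.ndarray:
        out = np.zeros_like(phi)
        for h, (a, p) in enumerate(zip(self.amplitudes, self.phases), start=1):
            out += a * np.cos(2.0 * math.pi * h * phi + p)
        return out


def default_templates() -> dict[str, ChannelTemplate]:
    """Harmonic templates mimicking heel kinematics of elderly brisk walking.

    Amplitudes are in channel units (g, deg/s, deg). The dominant feature
    is the medial-lateral angular-velocity (wx) spike shortly after heel
    strike, the standard IMU gait landmark; az carries the 1 g gravity
    offset; angle channels carry small constant offsets removed later by
    baseline-relative orientation.
    """
    wx_phases = tuple(-2.0 * math.pi * h * _WX_PEAK_OFFSET for h in (1, 2, 3, 4))
    return {
        "ax": ChannelTemplate((0.35, 0.18, 0.08), (1.0, 2.2, 0.6), 0.0),
        "ay": ChannelTemplate((0.55, 0.30, 0.12), (2.0, 0.8, 1.5), 0.05),
        "az": ChannelTemplate((0.60, 0.35, 0.15), (0.3, 1.8, 2.6), 1.0),
        "wx": ChannelTemplate((150.0, 100.0, 60.0, 30.0), wx_phases, 0.0),
        "wy": ChannelTemplate((90.0, 45.0, 20.0), (0.9, 2.4, 0.2), 0.0),
        "wz": ChannelTemplate((70.0, 35.0, 15.0), (1.7, 0.4, 2.9), 0.0),
        "gx": ChannelTemplate((25.0, 10.0, 4.0), (0.5, 1.2, 2.0), 4.0),
        "gy": ChannelTemplate((6.0, 2.5, 1.0), (1.1, 0.3, 2.2), 2.0),
        "gz": ChannelTemplate((10.0, 4.0, 2.0), (1.9, 2.7, 0.7), 6.0),
    }


def default_noise_sd() -> dict[str, float]:
    """Additive white-noise scale per channel (g, deg/s, deg)."""
    sd = {ch: 0.05 for ch in ACCEL_CHANNELS}
    sd.update({ch: 5.0 for ch in GYRO_CHANNELS})
    sd.update({ch: 0.5 for ch in ANGLE_CHANNELS})
    return sd


@dataclass(frozen=True)
class FatigueEffect:
    """Time-progressive modification of one channel's cycle template.

    ``multiplier_30`` / ``multiplier_60`` are the unitless targets reached
    (and held) across the 30th- and 60th-minute analysis windows;
    the baseline window is always at the implicit multiplier 1.
    """

    channel: str
    property: str
    multiplier_30: float = 1.0
    multiplier_60: float = 1.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ConfigError(f"unknown channel {self.channel!r}")
        if self.property not in EFFECT_PROPERTIES:
            raise ConfigError(f"unknown effect property {self.property!r}")
        if self.multiplier_30 <= 0 or self.multiplier_60 <= 0:
            raise ConfigError("effect multipliers must be positive")


def default_fatigue_effects() -> list[FatigueEffect]:
    """Directions of change seen in fatigued elderly brisk walking.

    Magnitudes are modest, plausible choices (the direction of each change
    is the established observation; sizes are not): rising medial-lateral
    acceleration and angular velocity, and rising variability/power of the
    orientation angles, strongest for vertical-axis rotation (pronation).
    """
    return [
        FatigueEffect("ax", "amplitude_scale", 1.03, 1.10),
        FatigueEffect("wx", "amplitude_scale", 1.05, 1.15),
        FatigueEffect("gx", "amplitude_scale", 1.05, 1.15),
        FatigueEffect("gy", "amplitude_scale", 1.05, 1.12),
        FatigueEffect("gz", "amplitude_scale", 1.15, 1.30),
    ]


@dataclass(frozen=True)
class GaitSimConfig:
    """Configuration of one simulated walking bout.

    Defaults emulate the study conditions: a 60-minute bout at 50 Hz with
    cadence in the elderly brisk-walking range (stride rate ~1 Hz at
    3.9 km/h) and mild cycle-duration jitter.
    """

    sample_rate: float = 50.0
    duration_min: float = 60.0
    cadence_hz: float = 0.95
    cadence_jitter_cv: float = 0.03
    templates: dict[str, ChannelTemplate] = field(default_factory=default_templates)
    noise_sd: dict[str, float] = field(default_factory=default_noise_sd)
    effects: tuple[FatigueEffect, ...] = ()
    window_minutes: tuple[int, int, int] = (1, 30, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.duration_min <= 0:
            raise ConfigError("duration must be positive")
        if self.cadence_hz <= 0:
            raise ConfigError("cadence must be positive")
        if self.cadence_jitter_cv < 0:
            raise ConfigError("cadence_jitter_cv must be non-negative")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigError("noise_sd must be non-negative")
        missing = [ch for ch in CHANNELS if ch not in self.templates]
        if missing:
            raise ConfigError(f"missing template(s) for {missing}")
        object.__setattr__(self, "effects", tuple(self.effects))


@dataclass
class SimulatedBout:
    """A simulated recording plus its ground-truth heel-strike indices.

    ``strikes`` contains every cycle boundary from sample 0 up to and
    including the boundary at (or just past) the end of the recording, so
    ``len(strikes) - 1`` complete cycles are delimited within the bout.
    """

    recording: ImuRecording
    strikes: np.ndarray
    config: GaitSimConfig


def _effect_ramp(
    t: np.ndarray, m30: float, m60: float, window_minutes: Sequence[int]
) -> np.ndarray:
    """Plateau-and-ramp multiplier: 1 across the baseline window, linear
    between windows, held at each target across its analysis window."""
    b_end = window_minutes[0] * 60.0
    w30_start, w30_end = (window_minutes[1] - 1) * 60.0, window_minutes[1] * 60.0
    w60_start = (window_minutes[2] - 1) * 60.0
    return np.interp(
        t,
        [b_end, w30_start, w30_end, w60_start],
        [1.0, m30, m30, m60],
    )


def _cycle_multipliers(
    config: GaitSimConfig, channel: str, prop: str, t_cycle: np.ndarray
) -> np.ndarray:
    """Combined multiplier of all matching effects, per cycle start time."""
    out = np.ones_like(t_cycle)
    for eff in config.effects:
        if eff.channel == channel and eff.property == prop:
            out *= _effect_ramp(
                t_cycle, eff.multiplier_30, eff.multiplier_60, config.window_minutes
            )
    return out


def simulate_bout(config: GaitSimConfig) -> SimulatedBout:
    """Synthesize one walking bout cycle by cycle.

    Cycle durations are drawn as ``T * lognormal(0, cv)`` and rounded to
    whole samples, so with zero jitter every cycle shares an identical
    sample grid (bit-identical waveforms). Template modifications are
    evaluated at each cycle's start time and held constant within the
    cycle. Identical configs and seeds give bit-identical recordings.
    """
    fs = config.sample_rate
    n_total = int(round(config.duration_min * 60.0 * fs))
    rng = np.random.default_rng(config.seed)

    nominal_samples = fs / config.cadence_hz
    # enough cycles to cover the bout even with shortened cycles
    n_guess = int(math.ceil(n_total / nominal_samples * 1.25)) + 8

    var_scaled = any(e.property == "cycle_variability_scale" for e in config.effects)
    if config.cadence_jitter_cv > 0:
        z = rng.standard_normal(n_guess)
    else:
        z = np.zeros(n_guess)

    if var_scaled and config.cadence_jitter_cv > 0:
        # duration variability depends on elapsed time -> accumulate serially
        lengths: list[int] = []
        pos = 0
        i = 0
        while pos < n_total:
            if i >= len(z):
                z = np.concatenate([z, np.random.default_rng(
                    rng.integers(0, 2**31)).standard_normal(len(z))])
            scale = 1.0
            for eff in config.effects:
                if eff.property == "cycle_variability_scale":
                    scale_arr = _effect_ramp(
                        np.array([pos / fs]), eff.multiplier_30,
                        eff.multiplier_60, config.window_minutes,
                    )
                    scale *= float(scale_arr[0])
            dur = nominal_samples * math.exp(config.cadence_jitter_cv * scale * z[i])
            lengths.append(max(1, int(round(dur))))
            pos += lengths[-1]
            i += 1
        lengths_arr = np.asarray(lengths, dtype=int)
    else:
        mult = np.exp(config.cadence_jitter_cv * z)
        lengths_arr = np.maximum(1, np.rint(nominal_samples * mult)).astype(int)
        while lengths_arr.sum() < n_total:  # pragma: no cover - generous guess
            extra = np.maximum(
                1, np.rint(nominal_samples * np.exp(
                    config.cadence_jitter_cv * rng.standard_normal(16)))
            ).astype(int)
            lengths_arr = np.concatenate([lengths_arr, extra])
        n_keep = int(np.searchsorted(np.cumsum(lengths_arr), n_total) + 1)
        lengths_arr = lengths_arr[:n_keep]

    starts = np.concatenate([[0], np.cumsum(lengths_arr)])
    strikes = starts[starts <= n_total]

    # per-sample cycle id and within-cycle phase
    n_cycles = len(lengths_arr)
    cycle_id = np.repeat(np.arange(n_cycles), lengths_arr)[:n_total]
    sample_idx = np.arange(n_total)
    phi = (sample_idx - starts[cycle_id]) / lengths_arr[cycle_id]
    t_cycle_start = starts[:n_cycles] / fs

    data = np.empty((len(CHANNELS), n_total))
    for ci, ch in enumerate(CHANNELS):
        tpl = config.templates[ch]
        amp = _cycle_multipliers(config, ch, "amplitude_scale", t_cycle_start)
        off = _cycle_multipliers(config, ch, "offset_shift", t_cycle_start)
        sig = tpl.evaluate(phi) * amp[cycle_id] + tpl.offset * off[cycle_id]
        sd = config.noise_sd.get(ch, 0.0)
        if sd > 0:
            sig = sig + rng.normal(0.0, sd, n_total)
        if ch in ACCEL_CHANNELS:
            sig = np.clip(sig, -ACCEL_FULL_SCALE_G, ACCEL_FULL_SCALE_G)
        elif ch in GYRO_CHANNELS:
            sig = np.clip(sig, -GYRO_FULL_SCALE_DPS, GYRO_FULL_SCALE_DPS)
        elif ch == "gy":
            sig = wrap_angle_90(sig)
        else:
            sig = wrap_angle_180(sig)
        data[ci] = sig

    recording = ImuRecording(
        sample_rate=fs,
        data=data,
        subject_id=f"sim-seed{config.seed}",
        meta={
            "simulated": True,
            "cadence_hz": config.cadence_hz,
            "cadence_jitter_cv": config.cadence_jitter_cv,
            "seed": config.seed,
            "n_effects": len(config.effects),
        },
    )
    return SimulatedBout(recording=recording, strikes=strikes, config=config)


def simulate_cohort(
    n_subjects: int = 18,
    config: GaitSimConfig | None = None,
    seed: int = 0,
    cadence_range: tuple[float, float] = (0.8, 1.1),
    subject_gain_cv: float = 0.1,
) -> list[SimulatedBout]:
    """Simulate a cohort of subjects with between-subject variability.

    Each subject draws a cadence uniformly from ``cadence_range`` (stride
    rates of elderly brisk walking) and a lognormal whole-body amplitude
    gain with coefficient of variation ``subject_gain_cv`` applied to all
    template amplitudes; the gain cancels in baseline-normalized ratios
    but makes raw traces heterogeneous. Fatigue effects and noise levels
    come from ``config`` and are shared by all subjects.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be at least 1")
    base = config if config is not None else GaitSimConfig()
    master = np.random.default_rng(seed)
    bouts: list[SimulatedBout] = []
    for s in range(n_subjects):
        cadence = float(master.uniform(*cadence_range))
        gain = float(np.exp(master.normal(0.0, subject_gain_cv)))
        templates = {
            ch: replace(
                tpl, amplitudes=tuple(a * gain for a in tpl.amplitudes)
            )
            for ch, tpl in base.templates.items()
        }
        sub_cfg = replace(
            base,
            cadence_hz=cadence,
            templates=templates,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        bout = simulate_bout(sub_cfg)
        bout.recording.subject_id = f"S{s + 1:02d}"
        bouts.append(bout)
    return bouts
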