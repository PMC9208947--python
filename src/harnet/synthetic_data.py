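"""Synthetic labeled multi-IMU recordings for end-to-end testing.

Each activity class is emulated as a quasi-periodic signature: every channel
is a sinusoid with a class-specific frequency and per-channel offset (a
gravity-like constant for accelerometer channels) plus Gaussian noise and a
random per-channel phase.  This is deliberately minimal — enough periodic and
cross-channel structure to exercise the lateral/longitudinal convolutions and
the recurrent head, with no attempt at biomechanical realism.

The default 3-class set uses distinct frequencies 1, 2 and 4 Hz with distinct
offsets, which makes the classes separable after windowing in both the mean
and the spectral sense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, ChannelMeta, SensorRecording, pamap2_channel_meta


def selfbuilt_channel_meta() -> list[ChannelMeta]:
    """The 2-IMU layout (abdomen + leg, acc/gyro, xyz): 12 channels."""
    meta = []
    for site in ("abdomen", "leg"):
        for modality in ("acc", "gyro"):
            for axis in ("x", "y", "z"):
                meta.append(ChannelMeta(site, modality, axis))
    return meta


@dataclass
class ActivityProfile:
    """Signal signature of one activity class.

    ``offsets`` and ``amplitudes`` are per-channel (length D); ``freq_hz`` is
    the oscillation frequency, ``phase_jitter`` the s.d. of the random
    per-channel phase perturbation (radians), ``noise_sd`` the additive
    Gaussian noise level in sensor units.
    """

    name: str
    offsets: np.ndarray
    freq_hz: float
    amplitudes: np.ndarray
    phase_jitter: float = 0.3
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        self.offsets = np.atleast_1d(np.asarray(self.offsets, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))


def default_profiles(n_channels: int, n_classes: int = 3) -> list[ActivityProfile]:
    """Distinct-frequency (1/2/4/... Hz doubling), distinct-offset class set."""
    profiles = []
    for c in range(n_classes):
        offsets = np.full(n_channels, float(c)) + 0.1 * np.arange(n_channels)
        amplitudes = np.full(n_channels, 1.0)
        profiles.append(ActivityProfile(
            name=f"class{c}", offsets=offsets, freq_hz=float(2**c),
            amplitudes=amplitudes,
        ))
    return profiles


def generate_recording(
    profiles: list[ActivityProfile],
    rate_hz: float = 25.0,
    seconds_per_class: float = 40.0,
    seed: int = 0,
    channel_meta: list[ChannelMeta] | None = None,
) -> SensorRecording:
    """Concatenate one labeled segment per class.

    channel value = offset + amplitude * sin(2*pi*f*t + phi) + noise, with a
    fixed per-channel phase spread plus seeded jitter.  Deterministic for a
    fixed seed.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 activity profiles")
    if rate_hz <= 0 or seconds_per_class <= 0:
        raise ValueError("rate_hz and seconds_per_class must be positive")
    channel_meta = channel_meta or selfbuilt_channel_meta()
    D = len(channel_meta)
    nyquist = rate_hz / 2.0
    rng = np.random.default_rng(seed)
    per_class = int(round(rate_hz * seconds_per_class))
    segments, labels = [], []
    for label, prof in enumerate(profiles):
        if prof.freq_hz >= nyquist:
            raise ValueError(f"profile {prof.name}: {prof.freq_hz} Hz is at/above Nyquist ({nyquist} Hz)")
        offsets = np.broadcast_to(prof.offsets, (D,))
        amps = np.broadcast_to(prof.amplitudes, (D,))
        t = (np.arange(per_class) + label * per_class) / rate_hz
        phase = 2 * np.pi * np.arange(D) / D + prof.phase_jitter * rng.normal(size=D)
        clean = offsets + amps * np.sin(2 * np.pi * prof.freq_hz * t[:, None] + phase)
        segments.append(clean + prof.noise_sd * rng.normal(size=(per_class, D)))
        labels.append(np.full(per_class, label, dtype=int))
    T = per_class * len(profiles)
    return SensorRecording(
        timestamps=np.arange(T) / rate_hz,
        samples=np.vstack(segments),
        channel_meta=channel_meta,
        labels=np.concatenate(labels),
        rate_hz=rate_hz,
    )


def inject_missing(recording: SensorRecording, fraction: float, seed: int = 0) -> SensorRecording:
    """Replace ``round(fraction * T * D)`` interior cells with the missing
    sentinel, never in a channel's first or last row.  Deterministic."""
    if not 0.0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    T, D = recording.samples.shape
    n_cells = int(round(fraction * T * D))
    samples = recording.samples.copy()
    if n_cells:
        rng = np.random.default_rng(seed)
        interior = (T - 2) * D  # rows 1..T-2 of every channel
        flat = rng.choice(interior, size=n_cells, replace=False)
        rows, cols = 1 + flat // D, flat % D
        samples[rows, cols] = MISSING
    from dataclasses import replace as _replace
    return _replace(recording, samples=samples)


def preset_recording(preset: str = "selfbuilt-like", seed: int = 0,
                     seconds_per_class: float = 40.0,
                     n_classes: int = 3) -> SensorRecording:
    """The two built-in study layouts.

    ``"selfbuilt-like"``: 2 IMUs (abdomen, leg), 12 channels at 25 Hz.
    ``"pamap2-like"``: 3 IMUs (wrist, chest, ankle), 18 channels at 100 Hz.
    """
    if preset == "selfbuilt-like":
        meta, rate = selfbuilt_channel_meta(), 25.0
    elif preset == "pamap2-like":
        meta, rate = pamap2_channel_meta(), 100.0
    else:
        raise ValueError(f"unknown preset {preset!r}")
    profiles = default_profiles(len(meta), n_classes)
    return generate_recording(profiles, rate_hz=rate, seconds_per_class=seconds_per_class,
                              seed=seed, channel_meta=meta)
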