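"""Synthetic two-class multichannel EEG cohorts.

Real interictal EEG of PNES patients and healthy controls is clinical data and
not redistributable, so this module generates surrogate cohorts with the
statistical structure the downstream pipeline assumes: 19-channel recordings at
256 Hz, a 1/f^beta pink-noise background spatially correlated across channels
through a shared source, and class-specific oscillatory content.  By default
controls carry a sustained 10 Hz (alpha-like) rhythm while patients carry
stronger intermittent 2-6 Hz (delta/theta-like) bursts, so the two classes
differ in the timing and relative strength of their low-frequency periodic
components — the qualitative contrast the wavelet front end is built to pick up.

All randomness flows from the single integer seed of the
:class:`CohortSpec` through a documented splitting scheme:
``SeedSequence(seed, spawn_key=(class_code, subject_index))`` yields one
subject stream, which is spawned into a shared-source stream, an oscillation
stream, and one stream per channel.  Identical specs therefore produce
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import signal as sps

from .core import CHANNELS_1020, CLASS_CNT, CLASS_PNES, CLASSES, EEGRecording

_CLASS_CODE = {CLASS_CNT: 0, CLASS_PNES: 1}


@dataclass(frozen=True)
class Oscillation:
    """One oscillatory component of a class profile.

    ``duty_cycle`` is the fraction of time the oscillation is on; with
    ``duty_cycle = 1`` it is sustained, otherwise it appears as bursts of
    ``burst_duration_s`` seconds (Hann-windowed) placed once per duty cycle at
    a jittered onset.  ``channel_weights`` scales the oscillation per channel
    (default: equal on all channels).
    """

    freq_hz: float
    amplitude: float
    duty_cycle: float = 1.0
    burst_duration_s: float = 1.0
    channel_weights: tuple[float, ...] | None = None

    def validate(self, fs: float) -> None:
        if not self.freq_hz < fs / 2:
            raise ValueError(f"oscillation freq_hz {self.freq_hz} must be < fs/2 = {fs / 2}")
        if self.amplitude < 0:
            raise ValueError(f"oscillation amplitude must be >= 0, got {self.amplitude}")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError(f"duty_cycle must be in [0, 1], got {self.duty_cycle}")
        if self.burst_duration_s <= 0:
            raise ValueError(f"burst_duration_s must be positive, got {self.burst_duration_s}")


@dataclass(frozen=True)
class SpectralProfile:
    """Per-class generative profile: pink-noise background plus oscillations.

    ``channel_mixing`` in [0, 1] is the variance fraction of the background
    shared across channels (a single common source), ``subject_jitter`` the
    relative per-subject perturbation applied to oscillation amplitudes and
    frequencies.
    """

    background_exponent: float = 1.0
    oscillations: tuple[Oscillation, ...] = ()
    channel_mixing: float = 0.6
    subject_jitter: float = 0.05

    def validate(self, fs: float) -> None:
        if not 0.0 <= self.channel_mixing <= 1.0:
            raise ValueError(f"channel_mixing must be in [0, 1], got {self.channel_mixing}")
        if self.subject_jitter < 0:
            raise ValueError(f"subject_jitter must be >= 0, got {self.subject_jitter}")
        for osc in self.oscillations:
            osc.validate(fs)


def default_class_profiles() -> dict[str, SpectralProfile]:
    """Default CNT / PNES profiles.

    CNT: sustained 10 Hz oscillation over the 1/f background.  PNES:
    intermittent 3 and 5 Hz bursts with higher relative strength.  Amplitudes
    are in the same microvolt-like units as the background (RMS 10 by
    default), sized so that class-averaged low-frequency band power differs
    clearly while single epochs remain realistic-looking.
    """
    return {
        CLASS_CNT: SpectralProfile(
            oscillations=(Oscillation(freq_hz=10.0, amplitude=8.0, duty_cycle=1.0),),
        ),
        CLASS_PNES: SpectralProfile(
            oscillations=(
                Oscillation(freq_hz=3.0, amplitude=14.0, duty_cycle=0.5, burst_duration_s=1.0),
                Oscillation(freq_hz=5.0, amplitude=10.0, duty_cycle=0.5, burst_duration_s=1.0),
            ),
        ),
    }


def null_class_profiles() -> dict[str, SpectralProfile]:
    """Identical profiles for both classes (no class signal), for null runs.

    ``subject_jitter`` is zero: under epoch-level leave-one-out, a per-subject
    amplitude offset is leakable subject identity, which would move a
    no-class-signal cohort away from chance for reasons unrelated to class.
    """
    p = SpectralProfile(
        oscillations=(Oscillation(freq_hz=10.0, amplitude=8.0, duty_cycle=1.0),),
        subject_jitter=0.0,
    )
    return {CLASS_CNT: p, CLASS_PNES: p}


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; generation is a pure function of it."""

    n_cnt: int = 10
    n_pnes: int = 6
    duration_s: float = 1800.0
    fs: float = 256.0
    n_channels: int = 19
    seed: int = 0
    class_params: dict[str, SpectralProfile] = field(default_factory=default_class_profiles)
    noise_rms: float = 10.0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.n_cnt < 0 or self.n_pnes < 0:
            raise ValueError("n_cnt and n_pnes must be >= 0")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.noise_rms <= 0:
            raise ValueError(f"noise_rms must be positive, got {self.noise_rms}")
        for label in CLASSES:
            if label not in self.class_params:
                raise ValueError(f"class_params is missing a profile for {label!r}")
            self.class_params[label].validate(self.fs)

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == len(CHANNELS_1020):
            return CHANNELS_1020
        return tuple(f"ch{i}" for i in range(self.n_channels))


def _pink_noise(n: int, beta: float, rng: Generator) -> np.ndarray:
    """Unit-RMS 1/f^beta noise via spectral shaping of white Gaussian noise."""
    spec = rng.normal(size=n // 2 + 1) + 1j * rng.normal(size=n // 2 + 1)
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * amp, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_envelope(n: int, fs: float, osc: Oscillation, rng: Generator) -> np.ndarray:
    """0/1-ish envelope: one Hann burst per duty cycle at a jittered onset."""
    if osc.duty_cycle >= 1.0:
        return np.ones(n)
    env = np.zeros(n)
    if osc.duty_cycle <= 0.0:
        return env
    cycle_s = osc.burst_duration_s / osc.duty_cycle
    burst_n = max(int(round(osc.burst_duration_s * fs)), 2)
    window = sps.windows.hann(burst_n)
    t = 0.0
    total_s = n / fs
    while t < total_s:
        slack = max(cycle_s - osc.burst_duration_s, 0.0)
        onset = t + rng.uniform(0.0, slack)
        i0 = int(round(onset * fs))
        i1 = min(i0 + burst_n, n)
        if i0 < n:
            env[i0:i1] = np.maximum(env[i0:i1], window[: i1 - i0])
        t += cycle_s
    return env


def generate_recording(class_label: str, spec: CohortSpec, subject_index: int) -> EEGRecording:
    """Generate one subject's recording, reproducible from (seed, class, index).

    The background of channel c is ``sqrt(1-m) * own_c + sqrt(m) * shared``
    (each unit RMS, m = ``channel_mixing``) scaled to ``noise_rms``;
    oscillations are added coherently across channels with per-channel weights.
    """
    if class_label not in CLASSES:
        raise ValueError(f"class_label must be one of {CLASSES}, got {class_label!r}")
    n_in_class = spec.n_cnt if class_label == CLASS_CNT else spec.n_pnes
    if not 0 <= subject_index < max(n_in_class, 1):
        raise ValueError(
            f"subject_index {subject_index} out of range for {class_label} "
            f"(class count {n_in_class})"
        )
    profile = spec.class_params[class_label]
    n = int(round(spec.duration_s * spec.fs))
    subject_ss = SeedSequence(spec.seed, spawn_key=(_CLASS_CODE[class_label], subject_index))
    shared_ss, osc_ss, *chan_ss = subject_ss.spawn(2 + spec.n_channels)

    shared = _pink_noise(n, profile.background_exponent, default_rng(shared_ss))
    m = profile.channel_mixing
    x = np.empty((spec.n_channels, n))
    for c, ss in enumerate(chan_ss):
        own = _pink_noise(n, profile.background_exponent, default_rng(ss))
        x[c] = spec.noise_rms * (np.sqrt(1.0 - m) * own + np.sqrt(m) * shared)

    t = np.arange(n) / spec.fs
    osc_rng = default_rng(osc_ss)
    for osc in profile.oscillations:
        jitter = profile.subject_jitter
        amp = osc.amplitude * (1.0 + jitter * osc_rng.uniform(-1.0, 1.0))
        freq = osc.freq_hz * (1.0 + jitter * osc_rng.uniform(-1.0, 1.0))
        phase = osc_rng.uniform(0.0, 2.0 * np.pi)
        env = _burst_envelope(n, spec.fs, osc, osc_rng)
        wave = amp * np.sin(2.0 * np.pi * freq * t + phase) * env
        if osc.channel_weights is None:
            weights = np.ones(spec.n_channels)
        else:
            weights = np.asarray(osc.channel_weights, dtype=float)
            if weights.shape != (spec.n_channels,):
                raise ValueError(
                    f"channel_weights must have length n_channels={spec.n_channels}"
                )
        x += weights[:, None] * wave[None, :]

    subject_id = f"{class_label}{subject_index:02d}"
    return EEGRecording(
        samples=x,
        fs=spec.fs,
        channel_labels=spec.channel_labels,
        subject_id=subject_id,
        class_label=class_label,
    )


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate the full cohort: ``n_cnt`` controls then ``n_pnes`` patients."""
    recs = [generate_recording(CLASS_CNT, spec, i) for i in range(spec.n_cnt)]
    recs += [generate_recording(CLASS_PNES, spec, i) for i in range(spec.n_pnes)]
    return recs


def inject_artifact(
    recording: EEGRecording,
    kind: str,
    t_start: float,
    duration: float,
    amplitude: float,
    channels: list[int] | None = None,
    seed: int = 0,
) -> EEGRecording:
    """Return a copy of ``recording`` with an artifact added in one window.

    Kinds: ``spike`` (triangular transient), ``drift`` (linear ramp to
    ``amplitude``), ``muscle`` (20-100 Hz noise scaled to peak ``amplitude``).
    Only ``[t_start, t_start + duration)`` is modified; the peak absolute added
    amplitude in that window equals ``amplitude``.
    """
    if kind not in ("spike", "drift", "muscle"):
        raise ValueError(f"unknown artifact kind {kind!r}")
    if t_start < 0 or t_start + duration > recording.duration_s + 1e-9:
        raise ValueError(
            f"artifact window [{t_start}, {t_start + duration}) outside recording "
            f"of {recording.duration_s} s"
        )
    i0 = int(round(t_start * recording.fs))
    i1 = int(round((t_start + duration) * recording.fs))
    i1 = min(i1, recording.n_samples)
    w = i1 - i0
    out = recording.copy()
    if w <= 0 or amplitude == 0:
        return out
    if kind == "spike":
        shape = 1.0 - np.abs(np.linspace(-1.0, 1.0, w))
        shape = shape / shape.max()  # even w has no sample at the apex
    elif kind == "drift":
        shape = np.linspace(0.0, 1.0, w)
    else:  # muscle
        rng = default_rng(seed)
        noise = rng.normal(size=w + 256)
        sos = sps.butter(4, [20.0, min(100.0, 0.45 * recording.fs)], "bandpass",
                         fs=recording.fs, output="sos")
        shape = sps.sosfilt(sos, noise)[256:]
        shape = shape / np.max(np.abs(shape))
    rows = slice(None) if channels is None else channels
    out.samples[rows, i0:i1] += amplitude * shape
    return out


def band_power(x: np.ndarray, fs: float, fmin: float, fmax: float) -> float:
    """Mean Welch PSD in [fmin, fmax], averaged over channels if 2-D."""
    x = np.atleast_2d(x)
    nper = min(x.shape[1], int(4 * fs))
    f, pxx = sps.welch(x, fs=fs, nperseg=nper, axis=1)
    mask = (f >= fmin) & (f <= fmax)
    return float(pxx[:, mask].mean())
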