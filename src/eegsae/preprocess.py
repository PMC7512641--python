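"""Filtering, artifact screening and epoch extraction.

Recordings are band-pass filtered (0.5-70 Hz) with a 50 Hz notch, screened
for artifacts with a simple amplitude/flatline rule, and cut into
non-overlapping 5 s epochs.  The screening is an automated stand-in for
visual artifact rejection: it flags any epoch whose peak absolute amplitude
exceeds a threshold or whose range collapses below a flatline tolerance, and
can be disabled for pre-cleaned data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import Epoch, EEGRecording

#: Defaults for the artifact screen, in the same microvolt-like units as the data.
DEFAULT_AMPLITUDE_THRESHOLD = 100.0
DEFAULT_FLATLINE_TOL = 1e-3


class EpochShortfallError(RuntimeError):
    """Raised when a recording holds fewer clean epochs than requested."""

    def __init__(self, found: int, requested: int, subject_id: str = ""):
        self.found = found
        self.requested = requested
        super().__init__(
            f"requested {requested} clean epochs but only {found} were found"
            + (f" for subject {subject_id}" if subject_id else "")
        )


def bandpass_notch(
    recording: EEGRecording,
    hp: float = 0.5,
    lp: float = 70.0,
    notch: float | None = 50.0,
) -> EEGRecording:
    """Zero-phase band-pass plus optional notch filter.

    Second-order Butterworth high- and low-pass sections (12 dB/oct each)
    applied forward-backward (``sosfiltfilt``), then an IIR notch at ``notch``
    Hz.  Zero-phase filtering avoids phase distortion at epoch boundaries.
    """
    fs = recording.fs
    if not (0 < hp < lp < fs / 2):
        raise ValueError(f"need 0 < hp < lp < fs/2, got hp={hp}, lp={lp}, fs={fs}")
    if notch is not None and not (hp < notch < lp):
        raise ValueError(f"notch {notch} Hz must lie inside the passband ({hp}, {lp})")
    # Mirror-pad by 2 s so the high-pass's long edge transients (0.5 Hz corner,
    # ~0.6 s time constant) live in the padding, not the data.
    pad = min(recording.n_samples - 1, int(round(2.0 * fs)))
    x = np.pad(recording.samples, ((0, 0), (pad, pad)), mode="reflect")
    sos_hp = sps.butter(2, hp, "highpass", fs=fs, output="sos")
    sos_lp = sps.butter(2, lp, "lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, x, axis=1)
    x = sps.sosfiltfilt(sos_lp, x, axis=1)
    if notch is not None:
        b, a = sps.iirnotch(notch, Q=30.0, fs=fs)
        x = sps.filtfilt(b, a, x, axis=1)
    x = x[:, pad : pad + recording.n_samples]
    return replace(recording, samples=x)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening one epoch: clean, or rejected with a named reason."""

    clean: bool
    reason: str | None = None
    channel: str | None = None

    def __bool__(self) -> bool:
        return self.clean


def screen_epoch(
    epoch: Epoch,
    amplitude_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
    flatline_tol: float = DEFAULT_FLATLINE_TOL,
) -> ScreenResult:
    """Reject an epoch if any channel exceeds the amplitude threshold or flatlines."""
    if not amplitude_threshold > 0:
        raise ValueError(f"amplitude_threshold must be positive, got {amplitude_threshold}")
    peaks = np.max(np.abs(epoch.samples), axis=1)
    over = np.nonzero(peaks > amplitude_threshold)[0]
    if over.size:
        c = int(over[0])
        return ScreenResult(False, "amplitude", epoch.channel_labels[c])
    ranges = np.ptp(epoch.samples, axis=1)
    flat = np.nonzero(ranges < flatline_tol)[0]
    if flat.size:
        c = int(flat[0])
        return ScreenResult(False, "flatline", epoch.channel_labels[c])
    return ScreenResult(True)


def extract_epochs(
    recording: EEGRecording,
    n_epochs: int | None = 20,
    T_epoch: float = 5.0,
    screen: bool = True,
    amplitude_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
    flatline_tol: float = DEFAULT_FLATLINE_TOL,
) -> list[Epoch]:
    """Cut clean, non-overlapping ``T_epoch``-second epochs, greedily from t=0.

    Windows are taken on the fixed grid ``[k*T, (k+1)*T)``; windows failing
    the screen are skipped, not truncated, so the survivors remain
    non-overlapping and time-ordered.  With ``n_epochs=None`` all clean
    epochs are returned; otherwise a shortfall raises
    :class:`EpochShortfallError` reporting how many were found.
    """
    if T_epoch <= 0:
        raise ValueError(f"T_epoch must be positive, got {T_epoch}")
    win = int(round(T_epoch * recording.fs))
    n_windows = recording.n_samples // win
    epochs: list[Epoch] = []
    for k in range(n_windows):
        if n_epochs is not None and len(epochs) >= n_epochs:
            break
        seg = recording.samples[:, k * win : (k + 1) * win]
        ep = Epoch(
            samples=seg,
            fs=recording.fs,
            T_epoch=T_epoch,
            subject_id=recording.subject_id,
            class_label=recording.class_label,
            epoch_index=len(epochs),
            t_start=k * T_epoch,
            channel_labels=recording.channel_labels,
        )
        if screen and not screen_epoch(ep, amplitude_threshold, flatline_tol):
            continue
        epochs.append(ep)
    if n_epochs is not None and len(epochs) < n_epochs:
        raise EpochShortfallError(len(epochs), n_epochs, recording.subject_id)
    return epochs


def extract_cohort_epochs(
    recordings: list[EEGRecording],
    n_epochs: int = 20,
    T_epoch: float = 5.0,
    filter_first: bool = False,
    **screen_kwargs,
) -> list[Epoch]:
    """Epochs from every recording, concatenated in cohort order."""
    out: list[Epoch] = []
    for rec in recordings:
        if filter_first:
            rec = bandpass_notch(rec)
        out.extend(extract_epochs(rec, n_epochs=n_epochs, T_epoch=T_epoch, **screen_kwargs))
    return out
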