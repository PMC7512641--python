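"""Core containers shared across the pipeline.

An :class:`EEGRecording` is a channels x time matrix in microvolt-like units
with its sampling rate and 10-20 channel labels; an :class:`Epoch` is one
fixed-length artifact-free window of a recording, the unit record of the
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19 scalp electrodes of the International 10-20 system, in canonical order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Class labels: PNES (psychogenic non-epileptic seizure patients) is the
#: positive class, CNT (healthy controls) the negative class.
CLASS_CNT = "CNT"
CLASS_PNES = "PNES"
CLASSES = (CLASS_CNT, CLASS_PNES)


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array in microvolt-like units.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered channel names; length must equal the row count of ``samples``.
    subject_id
        Opaque subject identifier.
    class_label
        ``"CNT"``, ``"PNES"`` or ``"unknown"``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_1020
    subject_id: str = ""
    class_label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError(f"samples must be 2-D (channels x time), got ndim={self.samples.ndim}")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"channel_labels has {len(self.channel_labels)} entries but samples has "
                f"{self.samples.shape[0]} rows"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, samples=self.samples.copy())


@dataclass
class Epoch:
    """A fixed-length window of a recording, the unit record of the pipeline.

    ``half_length_T`` is half the epoch length: the window is treated as
    supported on ``[-T, T]`` when the wavelet transform integrates over it.
    """

    samples: np.ndarray
    fs: float
    T_epoch: float
    subject_id: str = ""
    class_label: str = "unknown"
    epoch_index: int = 0
    t_start: float = 0.0
    channel_labels: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("epoch samples must be 2-D (channels x time)")
        expected = int(round(self.T_epoch * self.fs))
        if self.samples.shape[1] != expected:
            raise ValueError(
                f"epoch has {self.samples.shape[1]} samples per channel, "
                f"expected T_epoch*fs = {expected}"
            )

    @property
    def half_length_T(self) -> float:
        return self.T_epoch / 2.0

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]
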