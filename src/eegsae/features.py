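"""Continuous wavelet transform features.

Each 5 s epoch channel is transformed with a Mexican-hat (Ricker) CWT,

    CWT(a, tau) = (1/sqrt(a)) * integral eeg(t) * psi((t - tau)/a) dt,

discretized as a Riemann sum with dt = 1/fs over the epoch support (the epoch
is treated as compactly supported: zero outside its window, no reflection).
The mother wavelet is the L2-normalized Ricker

    psi(t) = 2 / (sqrt(3*sigma) * pi**(1/4)) * (1 - t**2/sigma**2) * exp(-t**2 / (2*sigma**2)),

real and zero-mean, so the conjugate in the transform is the identity.  The
fast path evaluates the exact same discrete sum via FFT correlation and is
oracle-equivalent to brute-force evaluation up to rounding.

Scales map to pseudo-frequencies through f(a) = sqrt(5/2) / (2*pi*sigma*a):
the frequency at which the 1/sqrt(a)-normalized transform of a pure sinusoid
is maximal, so a sinusoid's energy ridge sits at its own frequency on the
pseudo-frequency axis.

The scale axis is split into three contiguous sub-bands (default edges
0.5 / 4 / 8 / 32 Hz — the two lower bands roughly cover the delta and theta
rhythms) and the mean, standard deviation and skewness of the coefficients of
the whole map and of each sub-band map form 12 features per channel:
12 x 19 channels = 228 features per epoch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft

from .core import Epoch

#: Pseudo-frequency constant: peak of a**2.5 * exp(-a**2/2) is at a = sqrt(5/2).
RICKER_PSEUDO_FREQ_CONST = np.sqrt(2.5) / (2.0 * np.pi)

REGIONS = ("all", "b1", "b2", "b3")
STATS = ("mu", "sd", "skew")
FEATURES_PER_CHANNEL = len(REGIONS) * len(STATS)  # 12


class EdgeDominatedScaleWarning(UserWarning):
    """A scale whose dilated wavelet support dwarfs the epoch; coefficients are edge-dominated."""


def mexican_hat(t, sigma: float = 1.0):
    """L2-normalized Ricker wavelet evaluated at time(s) ``t`` (seconds)."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    t = np.asarray(t, dtype=float)
    norm = 2.0 / (np.sqrt(3.0 * sigma) * np.pi ** 0.25)
    u2 = (t / sigma) ** 2
    out = norm * (1.0 - u2) * np.exp(-u2 / 2.0)
    return out if out.ndim else float(out)


def scale_for_freq(freq_hz, sigma: float = 1.0):
    """Scale whose pseudo-frequency is ``freq_hz``."""
    return RICKER_PSEUDO_FREQ_CONST / (sigma * np.asarray(freq_hz, dtype=float))


def pseudo_freq_for_scale(scale, sigma: float = 1.0):
    """Pseudo-frequency (Hz) of ``scale``; inverse of :func:`scale_for_freq`."""
    return RICKER_PSEUDO_FREQ_CONST / (sigma * np.asarray(scale, dtype=float))


@dataclass(frozen=True)
class WaveletSpec:
    """Mexican-hat CWT configuration: width, scale grid, sampling rate.

    ``value_transform`` selects what the sub-band statistics are computed on:
    raw coefficients (default), their absolute value, or their square.
    """

    scales: tuple[float, ...]
    fs: float = 256.0
    sigma: float = 1.0
    value_transform: str = "identity"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if len(self.scales) == 0:
            raise ValueError("scales must be non-empty")
        s = np.asarray(self.scales)
        if not np.all(np.diff(s) > 0):
            raise ValueError("scales must be strictly increasing")
        if self.value_transform not in ("identity", "abs", "square"):
            raise ValueError(f"unknown value_transform {self.value_transform!r}")

    @classmethod
    def default(
        cls,
        fs: float = 256.0,
        n_scales: int = 64,
        fmin: float = 0.5,
        fmax: float = 32.0,
        sigma: float = 1.0,
        value_transform: str = "identity",
    ) -> "WaveletSpec":
        """Log-spaced scale grid covering pseudo-frequencies [fmin, fmax]."""
        freqs = np.geomspace(fmax, fmin, n_scales)  # descending => scales ascending
        scales = tuple(float(a) for a in scale_for_freq(freqs, sigma))
        return cls(scales=scales, fs=fs, sigma=sigma, value_transform=value_transform)

    @property
    def pseudo_freqs(self) -> np.ndarray:
        """Pseudo-frequency (Hz) per scale, strictly decreasing."""
        return pseudo_freq_for_scale(np.asarray(self.scales), self.sigma)

    def to_dict(self) -> dict:
        return {
            "scales": list(self.scales),
            "fs": self.fs,
            "sigma": self.sigma,
            "value_transform": self.value_transform,
        }


@dataclass
class TFMap:
    """CWT coefficient matrix (scales x time) for one channel of one epoch."""

    coefficients: np.ndarray
    scales: np.ndarray
    pseudo_freqs: np.ndarray
    times: np.ndarray
    channel: str = ""


# FFT kernel plans keyed on (n_samples, scales, sigma, fs); tiny cache, the
# pipeline uses one epoch length and one scale grid at a time.
_PLAN_CACHE: dict[tuple, np.ndarray] = {}
_PLAN_CACHE_MAX = 8


def _kernel_ffts(n: int, spec: WaveletSpec) -> tuple[np.ndarray, int]:
    """rfft of the reversed discrete correlation kernels, one row per scale."""
    key = (n, spec.scales, spec.sigma, spec.fs)
    nfft = next_fast_len(3 * n - 2)
    if key in _PLAN_CACHE:
        return _PLAN_CACHE[key], nfft
    dt = 1.0 / spec.fs
    offsets = np.arange(-(n - 1), n) * dt  # t_i - tau_j over all index pairs
    kernels = np.empty((len(spec.scales), 2 * n - 1))
    for r, a in enumerate(spec.scales):
        kernels[r] = mexican_hat(offsets / a, spec.sigma) * (dt / np.sqrt(a))
    kfft = rfft(kernels[:, ::-1], nfft, axis=1)
    if len(_PLAN_CACHE) >= _PLAN_CACHE_MAX:
        _PLAN_CACHE.pop(next(iter(_PLAN_CACHE)))
    _PLAN_CACHE[key] = kfft
    return kfft, nfft


def cwt_map(channel_signal: np.ndarray, spec: WaveletSpec, channel: str = "") -> TFMap:
    """CWT of one epoch channel on the spec's scale grid.

    Exactly evaluates ``coeff[r, j] = (1/sqrt(a_r)) * sum_i x[i] *
    psi((t_i - tau_j)/a_r) * dt`` with ``tau_j`` on the sample grid, via FFT
    correlation (oracle-equivalent to the double-loop sum up to rounding).
    Scales whose dilated support (10*sigma*a) exceeds ten epoch lengths are
    flagged with :class:`EdgeDominatedScaleWarning`.
    """
    x = np.asarray(channel_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("channel_signal must be 1-D")
    n = x.size
    if n < 2:
        raise ValueError("signal must have at least 2 samples")
    duration = n / spec.fs
    worst = 10.0 * spec.sigma * max(spec.scales)
    if worst > 10.0 * duration:
        warnings.warn(
            f"largest scale {max(spec.scales):g} has support {worst:g} s "
            f"> 10x epoch length {duration:g} s; coefficients are edge-dominated",
            EdgeDominatedScaleWarning,
            stacklevel=2,
        )
    kfft, nfft = _kernel_ffts(n, spec)
    xfft = rfft(x, nfft)
    full = irfft(xfft[None, :] * kfft, nfft, axis=1)
    coeff = full[:, n - 1 : 2 * n - 1]
    times = np.arange(n) / spec.fs
    return TFMap(
        coefficients=coeff,
        scales=np.asarray(spec.scales),
        pseudo_freqs=spec.pseudo_freqs,
        times=times,
        channel=channel,
    )


@dataclass(frozen=True)
class SubBandPartition:
    """Three contiguous pseudo-frequency intervals covering the scale axis.

    ``edges = (e0, e1, e2, e3)`` in Hz, ascending; bands are [e0, e1),
    [e1, e2), [e2, e3] ordered low to high frequency.
    """

    edges: tuple[float, float, float, float] = (0.5, 4.0, 8.0, 32.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.shape != (4,) or not np.all(np.diff(e) > 0):
            raise ValueError(f"edges must be 4 strictly increasing values, got {self.edges}")

    def band_intervals(self) -> list[tuple[float, float]]:
        e = self.edges
        return [(e[0], e[1]), (e[1], e[2]), (e[2], e[3])]

    def assign(self, pseudo_freqs: np.ndarray) -> np.ndarray:
        """Band index (0, 1, 2) per scale; every scale must be covered."""
        f = np.asarray(pseudo_freqs, dtype=float)
        e = self.edges
        tol = 1e-9 * max(abs(e[0]), abs(e[3]), 1.0)
        if np.any(f < e[0] - tol) or np.any(f > e[3] + tol):
            bad = f[(f < e[0] - tol) | (f > e[3] + tol)]
            raise ValueError(
                f"pseudo-frequencies {bad} fall outside the partition range "
                f"[{e[0]}, {e[3]}]"
            )
        idx = np.searchsorted(e[1:3], f, side="right")  # 0,1,2; top edge inclusive
        for b, (lo, hi) in enumerate(self.band_intervals()):
            if not np.any(idx == b):
                raise ValueError(f"sub-band [{lo}, {hi}) Hz contains no scales")
        return idx


def _moments(values: np.ndarray) -> tuple[float, float, float]:
    """Population mean, standard deviation, and skewness (0 when sd == 0)."""
    v = np.asarray(values, dtype=float).ravel()
    mu = v.mean()
    d = v - mu
    var = np.mean(d * d)
    sd = np.sqrt(var)
    if sd == 0.0:
        return float(mu), 0.0, 0.0
    skew = np.mean(d * d * d) / sd**3
    return float(mu), float(sd), float(skew)


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return values
    if transform == "abs":
        return np.abs(values)
    return values**2


def subband_statistics(
    tfmap: TFMap,
    partition: SubBandPartition = SubBandPartition(),
    value_transform: str = "identity",
) -> np.ndarray:
    """The 12 statistics of one TF map.

    Order: whole-map (mu, sd, skew), then band 1 (lowest frequencies), band 2,
    band 3 — matching the documented feature layout.
    """
    coeff = _apply_transform(tfmap.coefficients, value_transform)
    idx = partition.assign(tfmap.pseudo_freqs)
    out = np.empty(FEATURES_PER_CHANNEL)
    out[0:3] = _moments(coeff)
    for b in range(3):
        out[3 * (b + 1) : 3 * (b + 2)] = _moments(coeff[idx == b])
    return out


def feature_names(channel_labels: tuple[str, ...]) -> list[str]:
    """Column names in the fixed channel-major layout ``<ch>_<region>_<stat>``."""
    return [f"{ch}_{region}_{stat}" for ch in channel_labels for region in REGIONS for stat in STATS]


@dataclass
class FeatureVector:
    """Engineered representation of one epoch: 12 statistics per channel."""

    values: np.ndarray
    names: list[str]
    subject_id: str = ""
    class_label: str = "unknown"
    epoch_index: int = 0


def build_feature_vector(
    epoch: Epoch,
    spec: WaveletSpec | None = None,
    partition: SubBandPartition = SubBandPartition(),
    allow_any_channel_count: bool = False,
) -> FeatureVector:
    """228-element feature vector of one epoch (12 x 19 at defaults)."""
    if spec is None:
        spec = WaveletSpec.default(fs=epoch.fs)
    if epoch.fs != spec.fs:
        raise ValueError(f"epoch fs {epoch.fs} does not match wavelet spec fs {spec.fs}")
    if epoch.n_channels != 19 and not allow_any_channel_count:
        raise ValueError(
            f"expected 19 channels, got {epoch.n_channels} "
            "(pass allow_any_channel_count=True to override)"
        )
    values = np.empty(FEATURES_PER_CHANNEL * epoch.n_channels)
    for c in range(epoch.n_channels):
        tfm = cwt_map(epoch.samples[c], spec, channel=epoch.channel_labels[c])
        values[FEATURES_PER_CHANNEL * c : FEATURES_PER_CHANNEL * (c + 1)] = subband_statistics(
            tfm, partition, spec.value_transform
        )
    return FeatureVector(
        values=values,
        names=feature_names(epoch.channel_labels),
        subject_id=epoch.subject_id,
        class_label=epoch.class_label,
        epoch_index=epoch.epoch_index,
    )


_ID_COLS = ["subject_id", "class_label", "epoch_index"]


@dataclass
class FeatureDataset:
    """One row per epoch: identifiers plus the 228 named feature columns."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in _ID_COLS]

    @property
    def X(self) -> np.ndarray:
        return self.table[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table["class_label"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def save(self, path: str | Path) -> None:
        """Write the TSV table plus a JSON sidecar with wavelet provenance."""
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(self.meta, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureDataset":
        path = Path(path)
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = {}
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(table=table, meta=meta)


def build_feature_dataset(
    epochs: list[Epoch],
    spec: WaveletSpec | None = None,
    partition: SubBandPartition = SubBandPartition(),
    allow_any_channel_count: bool = False,
) -> FeatureDataset:
    """Feature table over a list of epochs; one record per epoch."""
    if not epochs:
        raise ValueError("epochs must be non-empty")
    counts = {ep.n_channels for ep in epochs}
    if len(counts) != 1:
        raise ValueError(f"mixed channel counts across epochs: {sorted(counts)}")
    if spec is None:
        spec = WaveletSpec.default(fs=epochs[0].fs)
    rows = []
    for ep in epochs:
        fv = build_feature_vector(ep, spec, partition, allow_any_channel_count)
        rows.append(
            {"subject_id": fv.subject_id, "class_label": fv.class_label,
             "epoch_index": fv.epoch_index, **dict(zip(fv.names, fv.values))}
        )
    table = pd.DataFrame(rows)
    meta = {
        "wavelet": spec.to_dict(),
        "partition_edges_hz": list(partition.edges),
        "n_epochs": len(epochs),
        "n_channels": epochs[0].n_channels,
    }
    return FeatureDataset(table=table, meta=meta)
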