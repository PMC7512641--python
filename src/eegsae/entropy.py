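"""Entropy-based interpretation of the learned representations.

For each hidden node of the two compression stages, the activations of that
node over all epochs of one class form a vector in (0, 1); its Shannon
entropy (histogram plug-in estimator, 32 equal-width bins on [0, 1], base-2
logarithm) measures how much of the node's dynamic range that class occupies.
Two empirical regularities are probed: mean node entropy decreases from the
first (50-node) to the second (20-node) stage, and the between-class entropy
difference is concentrated at the second stage — the deeper code carries the
class information even though no label ever touched the encoders.

As a control, Shannon entropy and normalized permutation entropy of the raw
EEG signals are computed per epoch and channel and contrasted between
classes; amplitude histograms use the per-epoch min-max range, and ordinal
patterns (order m, delay tau) break ties by order of occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial, log

import numpy as np
import pandas as pd
from numpy.random import default_rng
from numpy.lib.stride_tricks import sliding_window_view

from .core import CLASS_CNT, CLASS_PNES, Epoch
from .features import FeatureDataset
from .stack import EncoderStack

LAYERS = ("H1", "H2")


def shannon_entropy(values, bins: int = 32) -> float:
    """Plug-in Shannon entropy (bits) of values in [0, 1].

    Histogram with ``bins`` equal-width cells over [0, 1] (last cell
    right-closed), probabilities by relative frequency, ``0 * log 0 := 0``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise ValueError("values must lie in [0, 1] (sigmoid activations)")
    counts, _ = np.histogram(v, bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def _entropies_from_bin_indices(idx: np.ndarray, n_bins: int) -> np.ndarray:
    """Entropy (bits) per column of a (n_samples, n_nodes) bin-index matrix."""
    n, m = idx.shape
    out = np.empty(m)
    for j in range(m):
        counts = np.bincount(idx[:, j], minlength=n_bins)
        p = counts[counts > 0] / n
        out[j] = -(p * np.log2(p)).sum()
    return out


def _bin_indices(A: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin index on [0, 1] per activation, last cell right-closed."""
    idx = np.floor(A * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


@dataclass
class EntropyProfile:
    """Per (layer, class, node) Shannon entropies of node activation vectors."""

    table: pd.DataFrame  # layer, class_label, node, entropy_bits
    bins: int
    meta: dict = field(default_factory=dict)

    def values(self, layer: str, class_label: str) -> np.ndarray:
        t = self.table
        sel = t[(t["layer"] == layer) & (t["class_label"] == class_label)]
        return sel.sort_values("node")["entropy_bits"].to_numpy()

    def mean(self, layer: str, class_label: str) -> float:
        return float(self.values(layer, class_label).mean())

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["layer", "class_label"])["entropy_bits"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


def layer_entropy_profile(
    stack: EncoderStack,
    features: FeatureDataset,
    bins: int = 32,
) -> EntropyProfile:
    """Shannon entropy of every hidden node's activation vector, per class.

    Encodings are computed from features alone; the labels only split the
    epochs into the two class groups afterwards.
    """
    y = features.y
    groups = {}
    for cls in (CLASS_CNT, CLASS_PNES):
        mask = y == cls
        if not mask.any():
            raise ValueError(f"no epochs of class {cls} in the dataset")
        groups[cls] = mask
    X = features.X
    acts = {"H1": stack.encode_h1(X), "H2": stack.encode_h2(X)}
    rows = []
    for layer, A in acts.items():
        idx = _bin_indices(A, bins)
        for cls, mask in groups.items():
            ent = _entropies_from_bin_indices(idx[mask], bins)
            for node, e in enumerate(ent):
                rows.append({"layer": layer, "class_label": cls, "node": node,
                             "entropy_bits": float(e)})
    return EntropyProfile(
        table=pd.DataFrame(rows),
        bins=bins,
        meta={"bins": bins, "range": [0.0, 1.0],
              "n_epochs": {c: int(m.sum()) for c, m in groups.items()}},
    )


@dataclass
class ContrastResult:
    """Between-class entropy contrast at one layer, with a permutation null."""

    layer: str
    statistic: float  # mean(SE_PNES) - mean(SE_CNT) over nodes
    p_value: float
    per_node_diff: np.ndarray
    n_permutations: int


def class_entropy_contrast(
    stack: EncoderStack,
    features: FeatureDataset,
    layer: str = "H2",
    bins: int = 32,
    n_permutations: int = 999,
    seed: int = 0,
) -> ContrastResult:
    """mean(SE_PNES) - mean(SE_CNT) over a layer's nodes, with permutation p.

    The null permutes the class labels of epochs (encodings are fixed — they
    never depended on labels) and recomputes the statistic; the two-sided
    p-value is ``(1 + #{|T_perm| >= |T_obs|}) / (n_permutations + 1)``.
    With ``n_permutations=0`` only the statistic is returned (p = NaN).
    """
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}, got {layer!r}")
    y = features.y
    mask_pnes = y == CLASS_PNES
    mask_cnt = y == CLASS_CNT
    if not mask_pnes.any() or not mask_cnt.any():
        raise ValueError("both classes must be present")
    X = features.X
    A = stack.encode_h1(X) if layer == "H1" else stack.encode_h2(X)
    idx = _bin_indices(A, bins)

    def stat(pnes_mask: np.ndarray) -> tuple[float, np.ndarray]:
        e_p = _entropies_from_bin_indices(idx[pnes_mask], bins)
        e_c = _entropies_from_bin_indices(idx[~pnes_mask], bins)
        return float(e_p.mean() - e_c.mean()), e_p - e_c

    observed, per_node = stat(mask_pnes)
    if n_permutations == 0:
        return ContrastResult(layer, observed, float("nan"), per_node, 0)
    rng = default_rng(seed)
    n_pnes = int(mask_pnes.sum())
    n = len(y)
    hits = 0
    for _ in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_pnes, replace=False)] = True
        t, _ = stat(perm)
        if abs(t) >= abs(observed) - 1e-15:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return ContrastResult(layer, observed, p, per_node, n_permutations)


def signal_shannon_entropy(samples, bins: int = 64) -> float:
    """Shannon entropy (bits) of a raw signal's amplitude histogram.

    The histogram spans the signal's own min-max range (``bins`` equal-width
    cells); a constant signal occupies a single cell and scores 0 bits.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def permutation_entropy(samples, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy in [0, 1] of a 1-D signal.

    Ordinal patterns of length ``order`` at lag ``delay``; ties are broken by
    order of occurrence (stable argsort), so a constant signal yields a
    single pattern and entropy 0.  Normalization is by ``log(order!)``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if order < 2:
        raise ValueError(f"order must be >= 2, got {order}")
    if delay < 1:
        raise ValueError(f"delay must be >= 1, got {delay}")
    span = (order - 1) * delay + 1
    if x.size < span:
        raise ValueError(
            f"signal of length {x.size} too short for order {order} at delay {delay} "
            f"(needs >= {span})"
        )
    emb = sliding_window_view(x, span)[:, ::delay]  # (n_patterns, order)
    ranks = np.argsort(emb, axis=1, kind="stable")
    weights = factorial(order) ** np.arange(order)  # encode each pattern as an integer
    codes = ranks @ weights
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    h = -(p * np.log(p)).sum()
    return float(h / log(factorial(order)))


@dataclass
class RawEntropyReport:
    """Per-class raw-signal entropy means and their permutation test."""

    table: pd.DataFrame  # class_label, measure, mean, sd, n
    p_shannon: float
    p_permutation_entropy: float
    underpowered: bool
    n_permutations: int


def raw_signal_entropy_contrast(
    epochs: list[Epoch],
    bins: int = 64,
    pe_order: int = 3,
    pe_delay: int = 1,
    n_permutations: int = 999,
    seed: int = 0,
) -> RawEntropyReport:
    """Do the raw signals already separate the classes, entropy-wise?

    Shannon and normalized permutation entropy are computed per epoch and
    channel, averaged over channels to one value per epoch, then averaged
    per class; the class difference of means is tested by permuting epoch
    labels.  With fewer than two epochs in a class the test is flagged
    underpowered (p = NaN).
    """
    labels = np.array([ep.class_label for ep in epochs])
    if not ((labels == CLASS_CNT).any() and (labels == CLASS_PNES).any()):
        raise ValueError("both classes must be present")
    se = np.array([
        np.mean([signal_shannon_entropy(ch, bins) for ch in ep.samples]) for ep in epochs
    ])
    pe = np.array([
        np.mean([permutation_entropy(ch, pe_order, pe_delay) for ch in ep.samples])
        for ep in epochs
    ])
    mask = labels == CLASS_PNES
    rows = []
    for cls, m in ((CLASS_PNES, mask), (CLASS_CNT, ~mask)):
        for measure, vals in (("shannon", se), ("permutation", pe)):
            v = vals[m]
            rows.append({"class_label": cls, "measure": measure,
                         "mean": float(v.mean()),
                         "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
                         "n": int(v.size)})
    underpowered = min(mask.sum(), (~mask).sum()) < 2
    if underpowered or n_permutations == 0:
        p_se = p_pe = float("nan")
    else:
        rng = default_rng(seed)
        obs_se = abs(se[mask].mean() - se[~mask].mean())
        obs_pe = abs(pe[mask].mean() - pe[~mask].mean())
        hits_se = hits_pe = 0
        n = len(labels)
        k = int(mask.sum())
        for _ in range(n_permutations):
            pm = np.zeros(n, dtype=bool)
            pm[rng.choice(n, size=k, replace=False)] = True
            if abs(se[pm].mean() - se[~pm].mean()) >= obs_se - 1e-15:
                hits_se += 1
            if abs(pe[pm].mean() - pe[~pm].mean()) >= obs_pe - 1e-15:
                hits_pe += 1
        p_se = (1 + hits_se) / (n_permutations + 1)
        p_pe = (1 + hits_pe) / (n_permutations + 1)
    return RawEntropyReport(
        table=pd.DataFrame(rows),
        p_shannon=p_se,
        p_permutation_entropy=p_pe,
        underpowered=bool(underpowered),
        n_permutations=0 if underpowered else n_permutations,
    )


def plot_entropy_profile(profile: EntropyProfile, path=None):
    """Scatter of per-node entropies per layer, classes color-coded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, layer in zip(axes, LAYERS):
        for cls, color in ((CLASS_PNES, "tab:red"), (CLASS_CNT, "tab:blue")):
            v = profile.values(layer, cls)
            ax.plot(np.arange(len(v)), v, "o", ms=4, color=color, label=cls)
        ax.set_title(f"{layer} node entropies")
        ax.set_xlabel("hidden node")
    axes[0].set_ylabel("Shannon entropy (bits)")
    axes[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
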