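"""Leave-one-out evaluation, classification metrics, and shallow baselines.

The study protocol is epoch-level leave-one-out: every epoch is held out in
turn and a fresh classifier (scaler included) is trained on the remaining
epochs, giving 20 test sessions per subject with 20 epochs each.  Note this
protocol leaks subject identity across folds — other epochs of the test
subject stay in training — so the stricter leave-one-subject-out protocol is
also provided.

Metrics treat PNES as the positive class:

    sensitivity = TP/(TP+FN) * 100      specificity = TN/(TN+FP) * 100
    PPV = TP/(TP+FP) * 100              NPV = TN/(TN+FN) * 100
    accuracy = (TP+TN)/(TP+FN+TN+FP) * 100

Any zero-denominator ratio is reported as NaN with an explicit flag, never
silently as 0.  A per-subject decision is formed cumulatively over the
subject's epochs, by mean posterior or majority vote.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .core import CLASS_CNT, CLASS_PNES
from .features import FeatureDataset
from .stack import SoftmaxConfig, SparseAEConfig, train_stack, fine_tune

PROTOCOLS = ("epoch_loo", "subject_loso")
METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """The five ratios in percent; NaN entries are listed in ``undefined``."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, PPV, NPV and accuracy from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated items")

    def ratio(num: int, den: int, name: str, flags: list[str]) -> float:
        if den == 0:
            flags.append(name)
            return float("nan")
        return 100.0 * num / den

    flags: list[str] = []
    return MetricsReport(
        sensitivity=ratio(counts.TP, counts.TP + counts.FN, "sensitivity", flags),
        specificity=ratio(counts.TN, counts.TN + counts.FP, "specificity", flags),
        ppv=ratio(counts.TP, counts.TP + counts.FP, "ppv", flags),
        npv=ratio(counts.TN, counts.TN + counts.FN, "npv", flags),
        accuracy=100.0 * (counts.TP + counts.TN) / counts.total,
        undefined=tuple(flags),
    )


def make_folds(dataset: FeatureDataset, protocol: str = "epoch_loo") -> list[np.ndarray]:
    """Held-out index sets: one per epoch (epoch_loo) or one per subject (subject_loso)."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}, got {protocol!r}")
    n = len(dataset)
    if protocol == "epoch_loo":
        return [np.array([i]) for i in range(n)]
    subjects = dataset.subjects
    return [np.nonzero(subjects == s)[0] for s in pd.unique(subjects)]


def fold_checksum(folds: list[np.ndarray]) -> str:
    """Stable digest of a fold split, to audit that classifiers share folds."""
    h = hashlib.sha256()
    for f in folds:
        h.update(np.asarray(f, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


@dataclass
class LOOResult:
    """Per-epoch held-out predictions plus protocol provenance."""

    records: pd.DataFrame  # subject_id, epoch_index, true, p_pnes, predicted
    protocol: str
    seed: int
    config: dict = field(default_factory=dict)
    fold_digest: str = ""

    def confusion_counts(self) -> ConfusionCounts:
        t, p = self.records["true"], self.records["predicted"]
        return ConfusionCounts(
            TP=int(((t == CLASS_PNES) & (p == CLASS_PNES)).sum()),
            TN=int(((t == CLASS_CNT) & (p == CLASS_CNT)).sum()),
            FP=int(((t == CLASS_CNT) & (p == CLASS_PNES)).sum()),
            FN=int(((t == CLASS_PNES) & (p == CLASS_CNT)).sum()),
        )

    def metrics(self) -> MetricsReport:
        return compute_metrics(self.confusion_counts())

    @property
    def n_folds(self) -> int:
        return self.config.get("n_folds", len(self.records))

    def sessions_per_subject(self) -> pd.Series:
        return self.records.groupby("subject_id").size()


def _default_stack_trainer(
    cfg1: SparseAEConfig | None = None,
    cfg2: SparseAEConfig | None = None,
    softmax_cfg: SoftmaxConfig | None = None,
    fine_tune_epochs: int = 0,
):
    """Trainer factory: per-fold seeds are derived from (base seed, fold index)."""

    def trainer(X_train, y_train, fold_seed: int):
        c1 = cfg1 or SparseAEConfig(hidden_size=50)
        c2 = cfg2 or SparseAEConfig(hidden_size=20)
        sm = softmax_cfg or SoftmaxConfig()
        c1 = SparseAEConfig(**{**c1.__dict__, "seed": fold_seed})
        c2 = SparseAEConfig(**{**c2.__dict__, "seed": fold_seed + 1})
        sm = SoftmaxConfig(**{**sm.__dict__, "seed": fold_seed + 2})
        stack = train_stack(X_train, y_train, c1, c2, sm)
        if fine_tune_epochs:
            stack = fine_tune(stack, X_train, y_train, epochs=fine_tune_epochs)
        return stack

    return trainer


def _fold_seed(base_seed: int, fold_index: int) -> int:
    return int(SeedSequence([base_seed, fold_index]).generate_state(1)[0] % (2**31 - 3))


def loo_evaluate(
    dataset: FeatureDataset,
    trainer=None,
    protocol: str = "epoch_loo",
    seed: int = 0,
    cfg1: SparseAEConfig | None = None,
    cfg2: SparseAEConfig | None = None,
    softmax_cfg: SoftmaxConfig | None = None,
    fine_tune_epochs: int = 0,
) -> LOOResult:
    """Run the leave-one-out protocol, retraining everything inside each fold.

    ``trainer(X_train, y_train, fold_seed) -> model`` must return an object
    with ``predict_proba(X) -> (n, 2)`` posteriors ``[p_cnt, p_pnes]``; the
    default trains the full encoder stack.  The scaler is refit on each
    fold's training rows only, inside the trainer — the held-out epoch never
    touches any fitted statistic.
    """
    y_all = dataset.y
    for cls in (CLASS_CNT, CLASS_PNES):
        if len(pd.unique(dataset.subjects[y_all == cls])) < 1:
            raise ValueError(f"need at least one {cls} subject")
    if trainer is None:
        trainer = _default_stack_trainer(cfg1, cfg2, softmax_cfg, fine_tune_epochs)
    folds = make_folds(dataset, protocol)
    X = dataset.X
    table = dataset.table
    rows = []
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(len(dataset), dtype=bool)
        train_mask[test_idx] = False
        y_train = y_all[train_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"fold {k} (held-out {table.iloc[test_idx[0]]['subject_id']}) "
                "leaves a single-class training set"
            )
        model = trainer(X[train_mask], y_train, _fold_seed(seed, k))
        proba = np.atleast_2d(model.predict_proba(X[test_idx]))
        for j, i in enumerate(test_idx):
            p_pnes = float(proba[j, 1])
            rows.append({
                "fold": k,
                "subject_id": table.iloc[i]["subject_id"],
                "epoch_index": int(table.iloc[i]["epoch_index"]),
                "true": y_all[i],
                "p_pnes": p_pnes,
                "predicted": CLASS_PNES if p_pnes > 0.5 else CLASS_CNT,
            })
    return LOOResult(
        records=pd.DataFrame(rows),
        protocol=protocol,
        seed=seed,
        config={"n_folds": len(folds), "fine_tune_epochs": fine_tune_epochs},
        fold_digest=fold_checksum(folds),
    )


def subject_decision(result: LOOResult, rule: str = "mean_posterior") -> pd.DataFrame:
    """Cumulative per-subject decision over all of the subject's epochs.

    ``mean_posterior``: PNES iff the subject's mean p_pnes exceeds 0.5.
    ``majority_vote``: by count of epoch predictions, ties broken toward the
    mean posterior (and flagged).  The mean posterior is reported as the
    confidence either way.
    """
    if rule not in ("mean_posterior", "majority_vote"):
        raise ValueError(f"unknown rule {rule!r}")
    out = []
    for subject, grp in result.records.groupby("subject_id", sort=False):
        mean_p = float(grp["p_pnes"].mean())
        votes_pnes = int((grp["predicted"] == CLASS_PNES).sum())
        votes_cnt = len(grp) - votes_pnes
        tie_broken = False
        if rule == "mean_posterior":
            decision = CLASS_PNES if mean_p > 0.5 else CLASS_CNT
        else:
            if votes_pnes != votes_cnt:
                decision = CLASS_PNES if votes_pnes > votes_cnt else CLASS_CNT
            else:
                decision = CLASS_PNES if mean_p > 0.5 else CLASS_CNT
                tie_broken = True
        out.append({
            "subject_id": subject,
            "true": grp["true"].iloc[0],
            "decision": decision,
            "mean_posterior": mean_p,
            "n_epochs": len(grp),
            "n_correct_epochs": int((grp["predicted"] == grp["true"]).sum()),
            "tie_broken": tie_broken,
        })
    df = pd.DataFrame(out)
    df["correct"] = df["decision"] == df["true"]
    return df


class _SklearnPosteriorAdapter:
    """Wrap an sklearn pipeline so predict_proba columns are [p_cnt, p_pnes]."""

    def __init__(self, pipeline):
        self.pipeline = pipeline

    def fit(self, X, y):
        self.pipeline.fit(X, y)
        classes = list(self.pipeline.classes_)
        self._order = [classes.index(CLASS_CNT), classes.index(CLASS_PNES)]
        return self

    def predict_proba(self, X):
        return self.pipeline.predict_proba(X)[:, self._order]


def _baseline_factories():
    # 228 features exceed the per-class sample counts, so both discriminant
    # baselines need covariance regularization: Ledoit-Wolf shrinkage for the
    # linear one, a ridge term for the quadratic one.
    def lda():
        return make_pipeline(MinMaxScaler(clip=True),
                             LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"))

    def qda(shrinkage="auto"):
        return make_pipeline(
            MinMaxScaler(clip=True),
            QuadraticDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage))

    def lsvm():
        return make_pipeline(MinMaxScaler(clip=True),
                             SVC(kernel="linear", C=1.0, probability=False))

    def qsvm():
        return make_pipeline(MinMaxScaler(clip=True),
                             SVC(kernel="poly", degree=2, coef0=1.0, C=1.0))

    return {"LDA": lda, "QDA": qda, "L-SVM": lsvm, "Q-SVM": qsvm}


def _run_sklearn_baseline(name, factory, X, y_all, folds) -> pd.Series:
    preds = np.empty(len(y_all), dtype=object)
    regularized_folds = []
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(len(y_all), dtype=bool)
        train_mask[test_idx] = False
        clf = factory()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                clf.fit(X[train_mask], y_all[train_mask])
                yhat = clf.predict(X[test_idx])
            except np.linalg.LinAlgError:
                # near-singular within-class covariance: force heavy shrinkage
                clf = _baseline_factories()["QDA"](shrinkage=0.5)
                clf.fit(X[train_mask], y_all[train_mask])
                yhat = clf.predict(X[test_idx])
                regularized_folds.append(k)
        preds[test_idx] = yhat
    if regularized_folds:
        warnings.warn(f"{name}: ridge regularization applied in folds {regularized_folds}")
    return pd.Series(preds, dtype=object)


def _counts_from_arrays(true: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        TP=int(((true == CLASS_PNES) & (pred == CLASS_PNES)).sum()),
        TN=int(((true == CLASS_CNT) & (pred == CLASS_CNT)).sum()),
        FP=int(((true == CLASS_CNT) & (pred == CLASS_PNES)).sum()),
        FN=int(((true == CLASS_PNES) & (pred == CLASS_CNT)).sum()),
    )


def run_baselines(
    dataset: FeatureDataset,
    protocol: str = "epoch_loo",
    seed: int = 0,
    include_stack: bool = True,
    stack_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Five-classifier comparison table on identical folds.

    Rows: the encoder stack (SAE) plus linear/quadratic discriminant analysis
    and linear/quadratic-kernel SVMs; columns: the five metrics in percent.
    All rows share the same fold split (``fold_digest`` column).
    """
    folds = make_folds(dataset, protocol)
    digest = fold_checksum(folds)
    X, y_all = dataset.X, dataset.y
    rows = {}
    if include_stack:
        res = loo_evaluate(dataset, protocol=protocol, seed=seed, **(stack_kwargs or {}))
        rows["SAE"] = res.metrics()
    for name, factory in _baseline_factories().items():
        preds = _run_sklearn_baseline(name, factory, X, y_all, folds)
        rows[name] = compute_metrics(_counts_from_arrays(y_all, preds.to_numpy()))
    table = pd.DataFrame({name: rep.as_dict() for name, rep in rows.items()}).T
    table.index.name = "classifier"
    table["fold_digest"] = digest
    return table


def plot_subject_posteriors(result: LOOResult, path=None):
    """Bar chart per subject: held-out posterior of the true class per epoch,
    with the subject's mean as a dashed line (the cumulative-decision view)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subjects = list(result.records.groupby("subject_id", sort=False).groups)
    ncol = 4
    nrow = int(np.ceil(len(subjects) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2 * nrow), squeeze=False)
    for ax, subject in zip(axes.ravel(), subjects):
        grp = result.records[result.records["subject_id"] == subject]
        correct_p = np.where(grp["true"] == CLASS_PNES, grp["p_pnes"], 1 - grp["p_pnes"])
        ax.bar(range(len(grp)), correct_p, color="steelblue")
        ax.axhline(correct_p.mean(), color="red", linestyle=":")
        ax.set_ylim(0, 1)
        ax.set_title(subject, fontsize=8)
    for ax in axes.ravel()[len(subjects):]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
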