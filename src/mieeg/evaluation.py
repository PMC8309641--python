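"""Metrics, the repeated cross-validation protocol, and table aggregation.

Cohen's kappa for the balanced binary task uses a chance accuracy of
``p_e = 0.5``:  ``kappa = (p0 - pe) / (1 - pe)``, which reduces to
``kappa = 2 p0 - 1`` — so accuracy tables and kappa tables carry the same
information under a fixed linear map (and their dispersions scale by 2).

The evaluation protocol is 10 repetitions of stratified 10-fold
cross-validation: repetition ``r`` reshuffles the trials with seed
``seed + r``; every trial is tested exactly once per repetition.  The
reported mean is over all 100 folds; the reported std is the sample std
across the 10 repetition means (less optimistic than the fold-level std).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .model import encode_labels

VARIANTS = ("UD-CNN", "IS-CNN", "IS-CBAM-CNN")


# ---------------------------------------------------------------------------
# metrics


def accuracy(predictions, labels) -> float:
    """Fraction of exact matches between two equal-length label sequences."""
    p = np.asarray(predictions)
    t = np.asarray(labels)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} predictions vs {t.shape} labels")
    if p.size == 0:
        raise ValueError("cannot score an empty prediction set")
    return float((p == t).mean())


def kappa(p0: float, pe: float = 0.5) -> float:
    """Chance-corrected agreement ``(p0 - pe) / (1 - pe)``."""
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be a proportion in [0, 1]")
    if not 0 <= pe < 1:
        raise ValueError("pe must lie in [0, 1); pe = 1 leaves nothing to correct")
    return (p0 - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class EvaluationReport:
    """Per-fold accuracies of one repeated-CV run plus their aggregates."""

    variant: str
    fold_accuracies: np.ndarray  # (n_repetitions, n_folds)
    seed: int

    mean_accuracy: float = field(init=False)
    accuracy_std: float = field(init=False)
    mean_kappa: float = field(init=False)
    kappa_std: float = field(init=False)

    def __post_init__(self) -> None:
        acc = np.asarray(self.fold_accuracies, dtype=float)
        if acc.ndim != 2:
            raise ValueError("fold_accuracies must be (n_repetitions, n_folds)")
        if acc.min() < 0 or acc.max() > 1:
            raise ValueError("accuracies must be proportions")
        self.fold_accuracies = acc
        rep_means = acc.mean(axis=1)
        self.mean_accuracy = float(acc.mean())
        self.accuracy_std = (
            float(rep_means.std(ddof=1)) if len(rep_means) > 1 else 0.0
        )
        self.mean_kappa = kappa(self.mean_accuracy)
        self.kappa_std = 2.0 * self.accuracy_std

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "seed": self.seed,
            "mean_accuracy": self.mean_accuracy,
            "accuracy_std": self.accuracy_std,
            "mean_kappa": self.mean_kappa,
            "kappa_std": self.kappa_std,
            "fold_accuracies": self.fold_accuracies.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        n_rep, n_fold = self.fold_accuracies.shape
        df = pd.DataFrame(
            {
                "repetition": np.repeat(range(n_rep), n_fold),
                "fold": np.tile(range(n_fold), n_rep),
                "accuracy": self.fold_accuracies.ravel(),
            }
        )
        df.to_csv(path, index=False)


def fold_assignments(
    labels, seed: int, n_repetitions: int = 10, n_folds: int = 10
) -> list[list[np.ndarray]]:
    """Test-fold index sets per repetition (repetition r uses seed + r).

    Shared across ablation variants so their comparisons are paired.
    """
    y = encode_labels(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV needs at least {n_folds} trials per "
            f"class; got class counts {counts.tolist()}"
        )
    assignments = []
    for rep in range(n_repetitions):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        assignments.append([test for _, test in skf.split(np.zeros(len(y)), y)])
    return assignments


def cross_validate(
    images,
    labels,
    model_builder,
    seed: int,
    n_repetitions: int = 10,
    n_folds: int = 10,
    variant: str = "IS-CBAM-CNN",
) -> EvaluationReport:
    """Repeated stratified k-fold CV of ``model_builder`` on featurised trials.

    ``model_builder(seed)`` must return a fresh estimator with ``fit(X, y)``
    and ``predict(X)``.  All trainable state is re-created inside each
    training fold; featurisation is per-trial (no cross-trial statistics),
    so images may be computed once up front without leakage.
    """
    x = np.asarray(images)
    y = encode_labels(labels)
    acc = np.empty((n_repetitions, n_folds))
    for rep, folds in enumerate(fold_assignments(y, seed, n_repetitions, n_folds)):
        for k, test_idx in enumerate(folds):
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            model_seed = (seed + 100_003 * rep + 7_919 * k) % (2**31)
            model = model_builder(model_seed)
            model.fit(x[train_mask], y[train_mask])
            acc[rep, k] = accuracy(model.predict(x[test_idx]), y[test_idx])
    return EvaluationReport(variant=variant, fold_accuracies=acc, seed=seed)


def cross_validate_10x10(images, labels, model_builder, seed: int, **kwargs):
    """The canonical 10 x 10-fold protocol (alias with both counts fixed)."""
    return cross_validate(
        images, labels, model_builder, seed, n_repetitions=10, n_folds=10, **kwargs
    )


# ---------------------------------------------------------------------------
# table aggregation


def summarize_methods(
    table: dict[str, dict[str, np.ndarray | None]],
) -> pd.DataFrame:
    """Aggregate a per-subject results table into one summary row per method.

    ``table`` maps method name to ``{"mean": per-subject means,
    "std": per-subject stds or None}``.  Emits the mean of subject means,
    the mean of subject stds, and the max - min spread.
    """
    if not table:
        raise ValueError("need at least one method to aggregate")
    rows = {}
    for method, vals in table.items():
        means = np.asarray(vals["mean"], dtype=float)
        stds = vals.get("std")
        rows[method] = {
            "mean": means.mean(),
            "mean_std": None if stds is None else float(np.mean(stds)),
            "spread": float(means.max() - means.min()),
        }
    return pd.DataFrame(rows).T


def method_differences(table: dict[str, dict[str, np.ndarray | None]],
                       reference: str) -> pd.Series:
    """``mean(reference) - mean(other)`` for every other method."""
    summary = summarize_methods(table)
    if reference not in summary.index:
        raise KeyError(f"unknown method {reference!r}")
    ref = summary.loc[reference, "mean"]
    others = summary.drop(index=reference)
    return ref - others["mean"]


def format_mean_std(mean: float, std: float | None, decimals: int) -> str:
    if std is None:
        return f"{mean:.{decimals}f}"
    return f"{mean:.{decimals}f} ± {std:.{decimals}f}"


def aggregate_table(
    table: dict[str, dict[str, np.ndarray | None]],
    decimals: int = 1,
    subject_names=None,
) -> pd.DataFrame:
    """Render a per-subject table plus its Average row as formatted strings.

    ``decimals=1`` suits accuracy-percent tables, ``decimals=3`` kappa
    tables.
    """
    methods = list(table)
    n_subj = len(np.asarray(table[methods[0]]["mean"]))
    if subject_names is None:
        subject_names = [str(i + 1) for i in range(n_subj)]
    out = {}
    for method, vals in table.items():
        means = np.asarray(vals["mean"], dtype=float)
        stds = vals.get("std")
        col = [
            format_mean_std(m, None if stds is None else stds[i], decimals)
            for i, m in enumerate(means)
        ]
        col.append(
            format_mean_std(
                means.mean(), None if stds is None else float(np.mean(stds)), decimals
            )
        )
        out[method] = col
    return pd.DataFrame(out, index=[*subject_names, "Average"])


def reports_to_table(
    reports: list[EvaluationReport], scale: float = 100.0
) -> dict[str, dict[str, np.ndarray]]:
    """Adapt EvaluationReports into the aggregation-table input format."""
    table: dict[str, dict[str, np.ndarray]] = {}
    for rep in reports:
        entry = table.setdefault(rep.variant, {"mean": [], "std": []})
        entry["mean"].append(rep.mean_accuracy * scale)
        entry["std"].append(rep.accuracy_std * scale)
    return {
        m: {"mean": np.asarray(v["mean"]), "std": np.asarray(v["std"])}
        for m, v in table.items()
    }
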