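"""Performance metrics, tie resolution, and mismatch-sample identification.

Clinical labels serve as ground truth with periodontitis (+1) as the positive
class; accuracy, sensitivity and specificity are computed per realization and
summarized as mean ± SD over realizations.  A sample whose voted label
contradicts its clinical label in a strict majority of realizations is a
*mismatch* sample — read as biological heterogeneity, not misclassification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import DegenerateFoldError, check_training_fold, predict, train
from .ensemble import SVAConfig, SVAResult, make_folds
from .io import BiomarkerTable


@dataclass
class PerformanceSummary:
    """Mean ± SD of (ACC, SEN, SPC) over realizations, plus mismatch IDs."""

    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_sd: float
    sensitivity_sd: float
    specificity_sd: float
    mismatch_ids: list[str]
    per_realization: np.ndarray = field(repr=False)  # (N_b, 3) columns acc/sen/spc

    def as_dict(self) -> dict:
        return {
            "accuracy": {"mean": self.accuracy, "sd": self.accuracy_sd},
            "sensitivity": {"mean": self.sensitivity, "sd": self.sensitivity_sd},
            "specificity": {"mean": self.specificity, "sd": self.specificity_sd},
            "mismatch_ids": list(self.mismatch_ids),
        }


def resolve_ties(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace tie codes (0) by −1 or +1 with probability 1/2 each."""
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    ties = labels == 0
    out[ties] = rng.choice([-1, 1], size=int(ties.sum()))
    return out


def performance(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with periodontitis (+1) positive."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if not set(np.unique(pred)) <= {-1, 1}:
        raise ValueError("pred contains unresolved ties; call resolve_ties first")
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both clinical classes must be present in truth")
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == -1) & (truth == -1)).sum())
    acc = (tp + tn) / truth.size
    sen = tp / n_pos
    spc = tn / n_neg
    return acc, sen, spc


def identify_mismatch(
    per_realization_labels: np.ndarray,
    truth: np.ndarray,
    sample_ids: list[str] | None = None,
) -> list[str]:
    """Samples contradicting their clinical label in a strict majority of runs.

    Tie realizations (label 0) carry no directional evidence and are excluded
    from both sides of the majority comparison.
    """
    lam = np.asarray(per_realization_labels, dtype=int)
    truth = np.asarray(truth, dtype=int)
    disagree = ((lam != 0) & (lam != truth[None, :])).sum(axis=0)
    agree = (lam == truth[None, :]).sum(axis=0)
    flags = disagree > agree
    n = truth.shape[0]
    if sample_ids is None:
        sample_ids = [str(k) for k in range(n)]
    return [sample_ids[k] for k in np.flatnonzero(flags)]


def summarize(
    per_realization_labels: np.ndarray,
    truth: np.ndarray,
    sample_ids: list[str] | None = None,
    seed: int | None = None,
) -> PerformanceSummary:
    """Per-realization metrics (ties randomly assigned) plus mismatch calls."""
    lam = np.asarray(per_realization_labels, dtype=int)
    truth = np.asarray(truth, dtype=int)
    rng = np.random.default_rng(seed)
    metrics = np.empty((lam.shape[0], 3))
    for r in range(lam.shape[0]):
        resolved = resolve_ties(lam[r], rng)
        metrics[r] = performance(resolved, truth)
    sd = metrics.std(axis=0, ddof=1) if lam.shape[0] > 1 else np.zeros(3)
    mean = metrics.mean(axis=0)
    return PerformanceSummary(
        accuracy=float(mean[0]), sensitivity=float(mean[1]), specificity=float(mean[2]),
        accuracy_sd=float(sd[0]), sensitivity_sd=float(sd[1]), specificity_sd=float(sd[2]),
        mismatch_ids=identify_mismatch(lam, truth, sample_ids),
        per_realization=metrics,
    )


def summarize_sva(result: SVAResult, truth: np.ndarray | None = None,
                  seed: int | None = None) -> PerformanceSummary:
    """Score an SVA run against clinical labels (defaults: loop seed)."""
    if truth is None:
        raise ValueError("clinical truth labels are required")
    if seed is None:
        seed = result.config.seed
    return summarize(result.per_realization_labels, truth, result.sample_ids, seed)


def run_traditional(table: BiomarkerTable, cfg: SVAConfig | None = None) -> PerformanceSummary:
    """Single classifier on all m markers under the same repeated CV scheme.

    Shares the fold-drawing procedure (fresh permutation per realization,
    consecutive windows of k1, redraw on degenerate folds) with the voting
    loop, so with m = 2 the traditional per-realization predictions coincide
    with the lone pair-classifier's votes at equal seed.
    """
    cfg = cfg or SVAConfig()
    if not table.normalized:
        raise ValueError("table must be log-normalized first")
    X, y = table.to_arrays()
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    lam = np.zeros((cfg.n_realizations, n), dtype=np.int8)
    for r in range(cfg.n_realizations):
        for attempt in range(cfg.max_redraws + 1):
            folds = make_folds(n, cfg.fold_size, rng)
            try:
                preds = np.zeros(n, dtype=int)
                for test_idx in folds:
                    train_mask = np.ones(n, dtype=bool)
                    train_mask[test_idx] = False
                    check_training_fold(y[train_mask])
                    clf = train(cfg.classifier, X[train_mask], y[train_mask],
                                svm_c=cfg.svm_c, qda_reg=cfg.qda_reg,
                                nb_var_smoothing=cfg.nb_var_smoothing)
                    preds[test_idx] = predict(clf, X[test_idx])
                break
            except DegenerateFoldError:
                if attempt == cfg.max_redraws:
                    raise
        lam[r] = preds
    return summarize(lam, y, table.sample_ids, cfg.seed)
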