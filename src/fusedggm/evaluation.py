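"""Performance metrics: Frobenius loss, edge-recovery F-score, clustering accuracy."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class EvalReport:
    """Replicate-level metric collection with JSON export."""

    frobenius: list[float] = field(default_factory=list)
    f_score: list[float] = field(default_factory=list)
    k_correct: float | None = None
    membership_accuracy: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "frobenius": self.frobenius,
                    "f_score": self.f_score,
                    "k_correct": self.k_correct,
                    "membership_accuracy": self.membership_accuracy,
                },
                fh,
                indent=2,
            )


def frobenius_loss(estimate: np.ndarray, truth: np.ndarray) -> float:
    """sqrt of the summed squared element-wise differences."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("matrices must have the same shape")
    return float(np.sqrt(np.sum((estimate - truth) ** 2)))


def f_score(est_adjacency: np.ndarray, true_adjacency: np.ndarray) -> float:
    """Harmonic mean of edge precision and recall over the upper triangle.

    Returns 0 when no edge is predicted or present (both precision and
    recall undefined/zero).
    """
    est = np.asarray(est_adjacency) != 0
    tru = np.asarray(true_adjacency) != 0
    if est.shape != tru.shape:
        raise ValueError("matrices must have the same shape")
    iu = np.triu_indices(est.shape[0], 1)
    e, t = est[iu], tru[iu]
    tp = np.sum(e & t)
    if tp == 0:
        return 0.0
    precision = tp / e.sum()
    recall = tp / t.sum()
    return float(2.0 * precision * recall / (precision + recall))


def membership_accuracy(est_Z: np.ndarray, true_Z: np.ndarray) -> float:
    """Best-permutation agreement between two label vectors.

    Optimal one-to-one label matching (Hungarian assignment on the confusion
    matrix), which equals the exhaustive permutation scan.
    """
    est_Z = np.asarray(est_Z)
    true_Z = np.asarray(true_Z)
    if est_Z.shape != true_Z.shape:
        raise ValueError("label vectors must have the same length")
    est_labels, est_idx = np.unique(est_Z, return_inverse=True)
    true_labels, true_idx = np.unique(true_Z, return_inverse=True)
    K = max(len(est_labels), len(true_labels))
    confusion = np.zeros((K, K))
    np.add.at(confusion, (est_idx, true_idx), 1)
    r, c = linear_sum_assignment(-confusion)
    return float(confusion[r, c].sum() / est_Z.size)


def clustering_accuracy(est_Z_list, true_Z_list, est_K=None,
                        true_K=None) -> EvalReport:
    """Replicate-level clustering report.

    membership_accuracy per replicate; k_correct is the fraction of
    replicates whose estimated component count equals the truth (when counts
    are supplied).
    """
    report = EvalReport()
    for est, tru in zip(est_Z_list, true_Z_list):
        report.membership_accuracy.append(membership_accuracy(est, tru))
    if est_K is not None and true_K is not None:
        est_K = np.asarray(est_K)
        true_K = np.asarray(true_K)
        report.k_correct = float(np.mean(est_K == true_K))
    return report
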