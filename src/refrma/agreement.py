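"""Inter-method reproducibility statistics for two classification runs.

Agreement between two sets of categorical calls is summarized by a
confusion matrix, overall accuracy with an exact (Clopper-Pearson) binomial
CI, and Cohen's weighted kappa in which disagreements involving the middle
category (unclassified / intermediate) carry half weight.  Agreement between
the underlying class probabilities is summarized by Pearson's correlation of
the logit-transformed probabilities (Fisher-z CI) and by the total
least squares line, appropriate because both probability estimates carry
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.proportion import proportion_confint

from .probe_io import ProbeDataError

__all__ = [
    "AgreementReport",
    "confusion_matrix",
    "accuracy_ci",
    "weighted_kappa",
    "pearson_logit_ci",
    "total_least_squares",
    "compare_runs",
]

_PROB_CLIP = 1e-6


@dataclass
class AgreementReport:
    confusion: pd.DataFrame
    accuracy: float
    accuracy_ci: tuple[float, float]
    kappa_w: float
    kappa_ci: tuple[float, float]
    pearson_r: float | None = None
    pearson_ci: tuple[float, float] | None = None
    tls_slope: float | None = None
    tls_intercept: float | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": {a: {b: int(self.confusion.loc[a, b]) for b in self.confusion.columns}
                          for a in self.confusion.index},
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "kappa_w": self.kappa_w,
            "kappa_ci": list(self.kappa_ci),
        }
        if self.pearson_r is not None:
            d["pearson_r"] = self.pearson_r
            d["pearson_ci"] = list(self.pearson_ci)
            d["tls_slope"] = self.tls_slope
            d["tls_intercept"] = self.tls_intercept
        return d


def confusion_matrix(
    calls_a: list[str], calls_b: list[str], label_order: list[str]
) -> pd.DataFrame:
    """K x K count table; entry (i, j) counts samples called i by A, j by B."""
    if len(calls_a) != len(calls_b):
        raise ProbeDataError("call vectors differ in length")
    known = set(label_order)
    for name, calls in (("A", calls_a), ("B", calls_b)):
        unknown = sorted(set(calls) - known)
        if unknown:
            raise ProbeDataError(f"unknown labels in run {name}: {unknown}")
    table = pd.DataFrame(0, index=label_order, columns=label_order, dtype=int)
    for a, b in zip(calls_a, calls_b):
        table.loc[a, b] += 1
    return table


def accuracy_ci(confusion: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Observed agreement rate with an exact Clopper-Pearson 95% CI.

    The middle category counts as a class of its own: only the diagonal is
    agreement.
    """
    counts = confusion.to_numpy()
    total = int(counts.sum())
    if total == 0:
        raise ProbeDataError("empty confusion table")
    agree = int(np.trace(counts))
    lo, hi = proportion_confint(agree, total, alpha=0.05, method="beta")
    return agree / total, (float(lo), float(hi))


def _disagreement_weights(labels: list[str], middle_label: str) -> np.ndarray:
    if middle_label not in labels:
        raise ProbeDataError(f"middle label {middle_label!r} not in {labels}")
    k = len(labels)
    w = np.ones((k, k))
    mid = labels.index(middle_label)
    w[mid, :] = 0.5
    w[:, mid] = 0.5
    np.fill_diagonal(w, 0.0)
    return w


def weighted_kappa(
    confusion: pd.DataFrame, middle_label: str
) -> tuple[float, tuple[float, float]]:
    """Cohen's weighted kappa with half-weight middle-category disagreements.

    Disagreement weights: 0 on the diagonal, 1/2 when either rater chose the
    middle (unclassified / intermediate) category, 1 otherwise.  kappa_w =
    1 - sum(w*O) / sum(w*E) with E the outer product of the marginals.  The
    95% CI uses the large-sample SE of Fleiss, Cohen & Everitt.
    """
    labels = list(confusion.index)
    counts = confusion.to_numpy(dtype=float)
    n = counts.sum()
    if n == 0:
        raise ProbeDataError("empty confusion table")
    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    w_dis = _disagreement_weights(labels, middle_label)
    exp_dis = float((w_dis * expected).sum())
    if exp_dis == 0.0:
        raise ProbeDataError(
            "degenerate marginals: chance disagreement is zero, kappa undefined"
        )
    obs_dis = float((w_dis * p).sum())
    kappa = 1.0 - obs_dis / exp_dis

    # SE via the agreement-weight formulation (v = 1 - w).
    v = 1.0 - w_dis
    po = float((v * p).sum())
    pe = float((v * expected).sum())
    v_row = (v * col[None, :]).sum(axis=1)  # E[v | rater A chose i]
    v_col = (v * row[:, None]).sum(axis=0)  # E[v | rater B chose j]
    term = (v * (1.0 - pe) - (v_row[:, None] + v_col[None, :]) * (1.0 - po)) ** 2
    var = ((p * term).sum() - (po * pe - 2.0 * pe + po) ** 2) / (n * (1.0 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    half = 1.959963984540054 * se
    return kappa, (kappa - half, min(kappa + half, 1.0))


def pearson_logit_ci(
    p_a: np.ndarray, p_b: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation of logit probabilities with a Fisher-z 95% CI.

    Probabilities are clipped to [1e-6, 1 - 1e-6] before the logit.
    """
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    if a.size != b.size:
        raise ProbeDataError("probability vectors differ in length")
    if a.size < 4:
        raise ProbeDataError("need >= 4 pairs for a correlation CI")
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ProbeDataError("probabilities outside [0, 1]")
    x = special.logit(np.clip(a, _PROB_CLIP, 1 - _PROB_CLIP))
    y = special.logit(np.clip(b, _PROB_CLIP, 1 - _PROB_CLIP))
    if np.std(x) == 0 or np.std(y) == 0:
        raise ProbeDataError("zero variance after logit transform")
    r = float(np.corrcoef(x, y)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(a.size - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def total_least_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orthogonal-distance regression line through the centroid.

    The line runs along the principal axis (largest-eigenvalue eigenvector)
    of the centered (x, y) scatter, oriented with positive x-component.
    Returns (slope, intercept); a vertical principal axis is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ProbeDataError("need >= 2 (x, y) pairs of equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    cov = np.array([[xc @ xc, xc @ yc], [xc @ yc, yc @ yc]])
    if cov[0, 0] + cov[1, 1] == 0.0:
        raise ProbeDataError("all points identical: no principal axis")
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, np.argmax(eigvals)]
    if direction[0] < 0:
        direction = -direction
    if direction[0] == 0.0:
        raise ProbeDataError("principal axis is vertical: slope undefined")
    slope = float(direction[1] / direction[0])
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def compare_runs(
    calls_a: list[str],
    calls_b: list[str],
    label_order: list[str],
    middle_label: str,
    p_a: np.ndarray | None = None,
    p_b: np.ndarray | None = None,
) -> AgreementReport:
    """Full agreement report between two classification runs."""
    conf = confusion_matrix(calls_a, calls_b, label_order)
    acc, acc_ci = accuracy_ci(conf)
    kap, kap_ci = weighted_kappa(conf, middle_label)
    report = AgreementReport(conf, acc, acc_ci, kap, kap_ci)
    if p_a is not None and p_b is not None:
        report.pearson_r, report.pearson_ci = pearson_logit_ci(p_a, p_b)
        x = special.logit(np.clip(np.asarray(p_a, float), _PROB_CLIP, 1 - _PROB_CLIP))
        y = special.logit(np.clip(np.asarray(p_b, float), _PROB_CLIP, 1 - _PROB_CLIP))
        report.tls_slope, report.tls_intercept = total_least_squares(x, y)
    return report
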