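"""Elastic-net classification of expression profiles.

Training follows the glmnet-style parameterization: the penalized
log-likelihood objective is (1/n) sum(loss) + lambda * [alpha*||b||_1 +
(1-alpha)/2*||b||_2^2], with the (alpha, lambda) pair chosen on a grid by
seeded, stratified 10-fold cross-validation minimizing the per-observation
deviance (-2 x mean held-out log-likelihood).  Dichotomous models (e.g.
ABC/GCB cell-of-origin) are binomial logistic regressions called at
0.1/0.9 probability thresholds; multiclass models (e.g. the five-subtype
B-cell signature) are multinomial regressions called at 0.5; tertile models
(drug-resistance signatures) are binomial models whose cohort probabilities
are cut at the 33rd/66th percentiles.  Graham's formula combines individual
drug-resistance probabilities into a combination-therapy probability under
conditional independence and uniform priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .probe_io import ClassifierModel, ProbeDataError, ReferenceArchive
from .rma import ExpressionMatrix
from .single import ExpressionProfile

__all__ = [
    "TrainingConfig",
    "CallTable",
    "train_elastic_net",
    "rescale_profile",
    "predict_probabilities",
    "call_dichotomous",
    "call_multiclass",
    "call_tertile",
    "graham_combine",
    "UNCLASSIFIED",
    "INTERMEDIATE",
]

UNCLASSIFIED = "unclassified"
INTERMEDIATE = "intermediate"

_PROB_CLIP = 1e-6  # probability clip before logit transforms


@dataclass
class TrainingConfig:
    """Cross-validation grid for elastic-net training.

    Defaults reproduce the published training protocol for the U133 Plus 2.0
    classifiers: alpha from 0.1 to 1 in steps of 0.025 and log(lambda) from
    -10 to 2 in steps of 0.06, searched by 10-fold CV.  The full grid is
    expensive; pass coarser grids for small studies.
    """

    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.1, 1.0 + 1e-9, 0.025), 4))
    log_lambda_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(-10.0, 2.0 + 1e-9, 0.06), 4))
    n_folds: int = 10
    seed: int = 0
    family: str = "binomial"

    def __post_init__(self) -> None:
        self.alpha_grid = np.atleast_1d(np.asarray(self.alpha_grid, dtype=float))
        self.log_lambda_grid = np.atleast_1d(np.asarray(self.log_lambda_grid, dtype=float))
        if self.alpha_grid.size == 0 or self.log_lambda_grid.size == 0:
            raise ProbeDataError("empty (alpha, lambda) grid")
        if np.any(self.alpha_grid <= 0) or np.any(self.alpha_grid > 1):
            raise ProbeDataError("alpha grid values must lie in (0, 1]")
        if self.n_folds < 2:
            raise ProbeDataError("need at least 2 CV folds")
        if self.family not in ("binomial", "multinomial"):
            raise ProbeDataError(f"unknown family {self.family!r}")


@dataclass
class CallTable:
    """Per-sample class probabilities and categorical calls."""

    sample_ids: list[str]
    probabilities: pd.DataFrame
    calls: list[str]
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        P = self.probabilities.to_numpy(dtype=float)
        if np.any(P < -1e-9) or np.any(P > 1 + 1e-9):
            raise ProbeDataError("probabilities outside [0, 1]")
        if len(self.calls) != len(self.sample_ids):
            raise ProbeDataError("one call per sample required")

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.insert(0, "sample_id", self.sample_ids)
        out["call"] = self.calls
        return out


def _deviance(log_lik: np.ndarray) -> float:
    return float(-2.0 * np.mean(log_lik))


def _refit_intercepts(est, X, y) -> None:
    """Re-solve the unpenalized intercept(s) exactly, coefficients fixed.

    The stochastic solver can stop with the intercept far from its optimum
    when the penalty is strong (every coefficient pinned at zero satisfies
    its stopping rule immediately), which would corrupt the deviance
    surface at the sparse end of the lambda path.  With coefficients held
    fixed the intercept problem is a tiny convex fit solved by Newton
    iteration.
    """
    classes = est.classes_
    y_idx = np.searchsorted(classes, y)
    if len(classes) == 2:
        offset = X @ est.coef_[0]
        target = (y_idx == 1).astype(float)
        b = float(est.intercept_[0])
        for _ in range(100):
            p = 1.0 / (1.0 + np.exp(-(offset + b)))
            grad = float(np.mean(p - target))
            hess = float(np.mean(p * (1.0 - p)))
            step = grad / max(hess, 1e-12)
            b -= step
            if abs(step) < 1e-12:
                break
        est.intercept_ = np.array([b])
    else:
        offsets = X @ est.coef_.T  # n x K
        onehot = np.zeros_like(offsets)
        onehot[np.arange(len(y_idx)), y_idx] = 1.0
        b = est.intercept_.astype(float).copy()
        for _ in range(200):
            scores = offsets + b
            scores -= scores.max(axis=1, keepdims=True)
            P = np.exp(scores)
            P /= P.sum(axis=1, keepdims=True)
            grad = (P - onehot).mean(axis=0)
            hess = np.maximum((P * (1.0 - P)).mean(axis=0), 1e-12)
            step = grad / hess  # diagonal-Newton; convex, small problem
            b -= step
            if np.abs(step).max() < 1e-12:
                break
        # softmax intercepts are identified only up to an additive constant
        est.intercept_ = b - b.mean()


def _fit_glmnet_style(X, y, alpha, lam, warm=None):
    """One elastic-net fit in glmnet parameterization (C = 1/(n*lambda)).

    sklearn chooses binomial vs multinomial likelihood from the number of
    classes, matching the requested family after the class-count checks.
    """
    n = X.shape[0]
    est = LogisticRegression(
        solver="saga", l1_ratio=float(alpha),
        C=1.0 / (n * float(lam)), max_iter=5000, tol=1e-5,
        warm_start=warm is not None, random_state=0,
    )
    if warm is not None:
        est.coef_ = warm[0].copy()
        est.intercept_ = warm[1].copy()
        est.classes_ = warm[2]
    with warnings.catch_warnings():
        # at the weakly-penalized end of the path near-separable fits hit
        # the iteration cap; the CV deviance handles them like glmnet does
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    _refit_intercepts(est, X, y)
    return est


def train_elastic_net(
    expr: ExpressionMatrix,
    labels: list[str] | np.ndarray,
    config: TrainingConfig,
    model_kind: str | None = None,
    name: str = "",
) -> ClassifierModel:
    """Train a penalized logistic/multinomial classifier with CV model choice.

    The expression matrix (probe-sets x samples) is median-centered per
    probe-set on the full training cohort before fitting; the per-probe-set
    SDs of the (uncentered) training data are stored in the model for SD
    rescaling of profiles normalized against other references.
    """
    labels = np.asarray([str(l) for l in np.asarray(labels)])
    if len(labels) != len(expr.sample_ids):
        raise ProbeDataError("one label per sample required")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ProbeDataError("training labels cover a single class")
    counts = pd.Series(labels).value_counts()
    if config.n_folds > counts.min():
        raise ProbeDataError(
            f"{config.n_folds} folds exceed the minority class count ({counts.min()})"
        )
    if config.family == "binomial" and len(classes) != 2:
        raise ProbeDataError("binomial family requires exactly 2 classes")

    V = expr.values  # probesets x samples
    medians = np.median(V, axis=1)
    sds = np.std(V, axis=1, ddof=1)
    X = (V - medians[:, None]).T  # samples x probesets
    y = labels

    lambdas = np.exp(config.log_lambda_grid)
    # Descending lambda within each alpha so warm starts walk the path from
    # the sparse end, as coordinate-descent solvers conventionally do.
    lam_order = np.argsort(-lambdas)

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    n_grid = (config.alpha_grid.size, lambdas.size)
    loglik_sum = np.zeros(n_grid)

    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.asarray([class_index[c] for c in y])

    for ia, alpha in enumerate(config.alpha_grid):
        for train_idx, test_idx in folds:
            warm = None
            for il in lam_order:
                est = _fit_glmnet_style(X[train_idx], y[train_idx], alpha,
                                        lambdas[il], warm)
                warm = (est.coef_, est.intercept_, est.classes_)
                P = est.predict_proba(X[test_idx])
                # est.classes_ is sorted, matching `classes`
                p_true = np.clip(P[np.arange(len(test_idx)), y_idx[test_idx]],
                                 _PROB_CLIP, 1.0)
                loglik_sum[ia, il] += np.sum(np.log(p_true))

    cv_dev = -2.0 * loglik_sum / len(y)
    best_flat = np.argmin(cv_dev)
    ia, il = np.unravel_index(best_flat, cv_dev.shape)
    # Ties: favour the sparser model (larger lambda, then larger alpha).
    ties = np.argwhere(np.isclose(cv_dev, cv_dev[ia, il], rtol=0, atol=1e-12))
    ia, il = max(ties.tolist(), key=lambda t: (lambdas[t[1]], config.alpha_grid[t[0]]))
    best_alpha = float(config.alpha_grid[ia])
    best_lambda = float(lambdas[il])

    final = _fit_glmnet_style(X, y, best_alpha, best_lambda)

    if len(classes) == 2:
        # sklearn stores one row of coefficients for the second class.
        coef = final.coef_[0]
        intercepts = np.asarray([float(final.intercept_[0])])
        nonzero = np.flatnonzero(coef != 0)
        coefficients = {expr.probeset_ids[k]: np.asarray([coef[k]]) for k in nonzero}
    else:
        coef = final.coef_  # n_classes x n_features
        intercepts = np.asarray(final.intercept_, dtype=float)
        nonzero = np.flatnonzero(np.any(coef != 0, axis=0))
        coefficients = {expr.probeset_ids[k]: coef[:, k].copy() for k in nonzero}

    kind = model_kind or ("dichotomous" if len(classes) == 2 else "multiclass")
    if kind in ("dichotomous", "tertile"):
        thresholds = {"lower": 0.1, "upper": 0.9} if kind == "dichotomous" else \
            {"lower_percentile": 33.0, "upper_percentile": 66.0}
    else:
        thresholds = {"threshold": 0.5}

    return ClassifierModel(
        model_kind=kind,
        class_labels=list(final.classes_),
        intercepts=intercepts,
        coefficients=coefficients,
        training_sds=pd.Series(sds, index=expr.probeset_ids),
        alpha=best_alpha,
        log_lambda=float(np.log(best_lambda)),
        cv_deviance=float(cv_dev[ia, il]),
        thresholds=thresholds,
        name=name,
    )


def rescale_profile(
    profile: ExpressionProfile,
    model: ClassifierModel,
    archive: ReferenceArchive,
    reference_is_training: bool = False,
) -> ExpressionProfile:
    """SD-rescale a centered profile onto the classifier's training scale.

    Each probe-set value is multiplied by training_sd / reference_sd so the
    profile is comparable to the training cohort.  When the supplied
    reference archive IS the classifier's training cohort the data are used
    directly (factor 1 everywhere).
    """
    if not profile.centered:
        raise ProbeDataError("profile must be median-centered before rescaling")
    values = pd.Series(profile.values, index=profile.probeset_ids)
    if reference_is_training or (
        archive.cohort_label is not None and archive.cohort_label == model.name and model.name != ""
    ):
        out = values
    else:
        ps_ids = model.probeset_ids
        missing = [ps for ps in ps_ids if ps not in values.index]
        if missing:
            raise ProbeDataError(f"profile lacks model probe-sets: {missing[:5]}")
        ref_sd = archive.probeset_sds.reindex(values.index)
        if ref_sd.isna().any():
            missing = list(values.index[ref_sd.isna()])[:5]
            raise ProbeDataError(f"archive lacks SDs for probe-sets: {missing}")
        zero = [ps for ps in ps_ids if ref_sd[ps] == 0.0]
        if zero:
            raise ProbeDataError(
                f"reference SD is 0 for model probe-sets {zero[:5]}; "
                "archive unusable for this model"
            )
        factor = model.training_sds.reindex(values.index) / ref_sd
        factor = factor.fillna(1.0).replace([np.inf, -np.inf], 1.0)
        out = values * factor
    return ExpressionProfile(
        probeset_ids=list(out.index),
        values=out.to_numpy(),
        centered=True,
        rescaled_for=model.name or model.model_kind,
        sample_id=profile.sample_id,
    )


def predict_probabilities(
    model: ClassifierModel, profile: ExpressionProfile
) -> dict[str, float]:
    """Class probabilities for one centered, rescaled profile.

    Binomial models return the probability of each of the two classes, the
    second (alphabetically later) class playing the positive role in the
    logistic link; multinomial models return the softmax over per-class
    linear scores.
    """
    if not profile.centered:
        raise ProbeDataError("profile must be centered before prediction")
    if profile.rescaled_for is None:
        raise ProbeDataError(
            "profile has not been SD-rescaled for a classifier; "
            "call rescale_profile first"
        )
    values = pd.Series(profile.values, index=profile.probeset_ids)
    missing = [ps for ps in model.probeset_ids if ps not in values.index]
    if missing:
        raise ProbeDataError(f"profile lacks model probe-sets: {missing[:5]}")

    n_classes = len(model.class_labels)
    if model.model_kind in ("dichotomous", "tertile"):
        score = float(model.intercepts[0])
        for ps, coef in model.coefficients.items():
            score += float(coef[0]) * float(values[ps])
        p_pos = 1.0 / (1.0 + np.exp(-score))
        return {model.class_labels[0]: 1.0 - p_pos, model.class_labels[1]: p_pos}
    scores = model.intercepts.astype(float).copy()
    for ps, coef in model.coefficients.items():
        scores = scores + coef * float(values[ps])
    scores -= scores.max()
    exps = np.exp(scores)
    probs = exps / exps.sum()
    return {c: float(p) for c, p in zip(model.class_labels, probs)}


def call_dichotomous(
    p: float,
    lower: float = 0.1,
    upper: float = 0.9,
    positive: str = "ABC",
    negative: str = "GCB",
) -> str:
    """Call a dichotomous class from the positive-class probability.

    The positive class requires p strictly above ``upper`` and the negative
    class p strictly below ``lower``; boundary values are unclassified.
    """
    if not 0.0 <= p <= 1.0:
        raise ProbeDataError(f"probability {p} outside [0, 1]")
    if p > upper:
        return positive
    if p < lower:
        return negative
    return UNCLASSIFIED


def call_multiclass(probs: dict[str, float], threshold: float = 0.5) -> str:
    """Call the highest-probability class if it strictly exceeds the
    threshold; unclassified otherwise."""
    values = np.asarray(list(probs.values()), dtype=float)
    if abs(values.sum() - 1.0) > 1e-6:
        raise ProbeDataError(f"class probabilities sum to {values.sum():.6f}, not 1")
    best = max(probs, key=lambda c: probs[c])
    return best if probs[best] > threshold else UNCLASSIFIED


def call_tertile(
    probs: np.ndarray,
    lower_percentile: float = 33.0,
    upper_percentile: float = 66.0,
    labels: tuple[str, str, str] = ("sensitive", INTERMEDIATE, "resistant"),
) -> list[str]:
    """Tertile calls for a cohort of resistance probabilities.

    Thresholds are the cohort's 33rd and 66th percentiles (linear
    interpolation): probability <= 33rd percentile -> sensitive, >= 66th ->
    resistant, otherwise intermediate.  When the two percentiles coincide
    (e.g. all probabilities equal) the conflicting samples are called
    intermediate, since the cohort carries no evidence to separate them.
    """
    p = np.asarray(probs, dtype=float)
    if p.size < 3:
        raise ProbeDataError("tertile calling needs >= 3 samples")
    lo = np.percentile(p, lower_percentile)
    hi = np.percentile(p, upper_percentile)
    out = []
    for v in p:
        sensitive = v <= lo
        resistant = v >= hi
        if sensitive and resistant:
            out.append(labels[1])
        elif sensitive:
            out.append(labels[0])
        elif resistant:
            out.append(labels[2])
        else:
            out.append(labels[1])
    return out


def graham_combine(*probs: float) -> float:
    """Posterior probability of resistance to a combination therapy.

    Under conditional independence and uniform priors,

        P = prod(p_i) / (prod(p_i) + prod(1 - p_i)).

    Leaving a drug out of the combination simply drops its term.  A 0/0 form
    (one probability exactly 1 and another exactly 0) encodes contradictory
    certainty and raises an error.
    """
    if len(probs) == 0:
        raise ProbeDataError("at least one probability required")
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ProbeDataError(f"probabilities outside [0, 1]: {probs}")
    num = float(np.prod(p))
    den = num + float(np.prod(1.0 - p))
    if den == 0.0:
        raise ProbeDataError(
            f"contradictory certainty in {probs}: both the resistance and "
            "sensitivity products vanish"
        )
    return num / den
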