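"""Synthetic validation studies for the one-by-one normalization stack.

Each function simulates a study with known truth, runs the full pipeline
(cohort RMA, reference building, one-by-one normalization, elastic-net
classification, RLE QC) and returns summary statistics.  They are the
package's reproducible miniature of the original validation design:
in-laboratory versus external-laboratory references, classifier parameter
recovery, call agreement between normalization routes, and QC behaviour
under batch shifts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agreement import confusion_matrix, weighted_kappa
from .classify import (
    UNCLASSIFIED,
    TrainingConfig,
    call_dichotomous,
    predict_probabilities,
    rescale_profile,
    train_elastic_net,
)
from .probe_io import ProbeMatrix
from .qc import compute_rle
from .rma import ExpressionMatrix, rma_cohort
from .single import ExpressionProfile, build_reference, normalize_single
from .synthetic import SimConfig, simulate_batch_shift_sweep, simulate_two_lab_study

__all__ = [
    "one_by_one_agreement_study",
    "classifier_recovery_study",
    "call_agreement_study",
    "qc_shift_study",
]

# Coarse (alpha, log-lambda) grid used by the synthetic studies; the
# published full grid is far finer but the simulated signals are strong
# enough that a coarse grid finds an equivalent optimum.
_STUDY_ALPHAS = np.array([0.1, 0.5, 1.0])
_STUDY_LOG_LAMBDAS = np.linspace(-6.0, 0.0, 7)


def _series(matrix: ProbeMatrix, sid: str) -> pd.Series:
    return pd.Series(matrix.column(sid), index=matrix.probe_ids, name=sid)


def one_by_one_agreement_study(
    seed: int,
    n_probesets: int = 2000,
    n_samples: int = 60,
    n_ref: int = 30,
    batch_shift_sd: float = 0.8,
) -> dict:
    """Per-sample correlation of one-by-one vs cohort RMA expressions.

    Simulates ``n_samples`` arrays from one laboratory plus a batch-shifted
    laboratory, builds a reference from ``n_ref`` of them, one-by-one
    normalizes the held-out arrays against (a) their own lab's reference and
    (b) the shifted lab's reference, and correlates each normalized profile
    with the cohort-RMA expression of the full same-lab cohort.
    """
    cfg = SimConfig(n_probesets=n_probesets, n_samples=n_samples,
                    batch_shift_sd=batch_shift_sd, seed=seed)
    study = simulate_two_lab_study(cfg, n_ref=n_ref)
    combined = ProbeMatrix(
        study.reference.probe_ids,
        study.reference.sample_ids + study.inlab.sample_ids,
        np.hstack([study.reference.intensities, study.inlab.intensities]),
    )
    cohort = rma_cohort(combined, study.layout).to_frame()
    archive_in = build_reference(study.reference, study.layout)
    archive_ex = build_reference(study.exlab, study.layout)

    r_inlab, r_exlab = [], []
    for sid in study.inlab.sample_ids:
        s = _series(study.inlab, sid)
        col = cohort[sid].to_numpy()
        prof_in = normalize_single(s, archive_in, study.layout, center=False)
        prof_ex = normalize_single(s, archive_ex, study.layout, center=False)
        r_inlab.append(float(np.corrcoef(prof_in.values, col)[0, 1]))
        r_exlab.append(float(np.corrcoef(prof_ex.values, col)[0, 1]))
    return {
        "r_inlab": r_inlab,
        "r_exlab": r_exlab,
        "min_r_inlab": min(r_inlab),
        "median_r_inlab": float(np.median(r_inlab)),
        "median_r_exlab": float(np.median(r_exlab)),
    }


def classifier_recovery_study(
    seed: int,
    class_effect: float = 1.5,
    n_train: int = 120,
    n_test: int = 40,
    n_probesets: int = 300,
    n_informative: int = 50,
) -> dict:
    """Held-out accuracy of a CV-trained elastic net on simulated two-class
    expression data (class effect in log2 units on the informative
    probe-sets; ``class_effect=0`` gives the null study)."""
    from .synthetic import simulate_probe_data

    cfg = SimConfig(n_probesets=n_probesets, n_samples=n_train + n_test,
                    n_informative=n_informative, class_effect=class_effect,
                    seed=seed)
    pm, layout, truth = simulate_probe_data(cfg)
    expr = rma_cohort(pm, layout)
    labels = np.asarray(truth.labels)

    train_idx = np.arange(n_train)
    test_idx = np.arange(n_train, n_train + n_test)
    expr_train = ExpressionMatrix(
        expr.probeset_ids, [expr.sample_ids[i] for i in train_idx],
        expr.values[:, train_idx])
    config = TrainingConfig(alpha_grid=_STUDY_ALPHAS,
                            log_lambda_grid=_STUDY_LOG_LAMBDAS,
                            n_folds=10, seed=seed)
    model = train_elastic_net(expr_train, labels[train_idx], config, name="sim")

    medians = np.median(expr.values[:, train_idx], axis=1)
    correct = 0
    for i in test_idx:
        profile = ExpressionProfile(expr.probeset_ids,
                                    expr.values[:, i] - medians,
                                    centered=True, rescaled_for=model.name,
                                    sample_id=expr.sample_ids[i])
        probs = predict_probabilities(model, profile)
        if max(probs, key=probs.get) == labels[i]:
            correct += 1
    return {
        "accuracy": correct / len(test_idx),
        "alpha": model.alpha,
        "log_lambda": model.log_lambda,
        "cv_deviance": model.cv_deviance,
        "n_selected": len(model.coefficients),
    }


def call_agreement_study(
    seed: int,
    n_probesets: int = 300,
    n_ref: int = 30,
    n_val: int = 120,
    n_informative: int = 50,
    class_effect: float = 1.5,
    batch_shift_sd: float = 0.8,
    include_exlab: bool = True,
) -> dict:
    """Weighted-kappa agreement between cohort-based and one-by-one calls.

    A dichotomous classifier is trained on the cohort-RMA expressions of the
    validation samples; the same samples are then called twice — from their
    cohort-RMA profiles and from one-by-one profiles normalized against the
    in-lab reference (and optionally an external batch-shifted reference) —
    and the calls are compared with the half-weight kappa, the unclassified
    group playing the middle role.
    """
    cfg = SimConfig(n_probesets=n_probesets, n_samples=n_ref + n_val,
                    n_informative=n_informative, class_effect=class_effect,
                    batch_shift_sd=batch_shift_sd, seed=seed)
    study = simulate_two_lab_study(cfg, n_ref=n_ref)
    combined = ProbeMatrix(
        study.reference.probe_ids,
        study.reference.sample_ids + study.inlab.sample_ids,
        np.hstack([study.reference.intensities, study.inlab.intensities]),
    )
    cohort = rma_cohort(combined, study.layout)
    val_ids = study.inlab.sample_ids
    val_cols = {sid: j for j, sid in enumerate(cohort.sample_ids)}

    expr_train = ExpressionMatrix(
        cohort.probeset_ids, val_ids,
        cohort.values[:, [val_cols[s] for s in val_ids]])
    config = TrainingConfig(alpha_grid=np.array([0.1, 1.0]),
                            log_lambda_grid=np.linspace(-5.0, -1.0, 5),
                            n_folds=10, seed=seed)
    model = train_elastic_net(expr_train, study.inlab_truth.labels, config,
                              name="sim")
    positive, negative = model.class_labels[1], model.class_labels[0]
    medians = np.median(expr_train.values, axis=1)

    archive_in = build_reference(study.reference, study.layout)
    archive_ex = build_reference(study.exlab, study.layout) if include_exlab else None

    def call_of(profile: ExpressionProfile, archive, is_training: bool) -> tuple[str, float]:
        rescaled = rescale_profile(profile, model, archive or archive_in,
                                   reference_is_training=is_training)
        p = predict_probabilities(model, rescaled)[positive]
        return call_dichotomous(p, positive=positive, negative=negative), p

    calls_cohort, calls_in, calls_ex = [], [], []
    p_cohort, p_in = [], []
    for sid in val_ids:
        prof_c = ExpressionProfile(cohort.probeset_ids,
                                   cohort.values[:, val_cols[sid]] - medians,
                                   centered=True, sample_id=sid)
        call, p = call_of(prof_c, None, True)
        calls_cohort.append(call)
        p_cohort.append(p)

        s = _series(study.inlab, sid)
        prof_in = normalize_single(s, archive_in, study.layout)
        call, p = call_of(prof_in, archive_in, False)
        calls_in.append(call)
        p_in.append(p)

        if include_exlab:
            prof_ex = normalize_single(s, archive_ex, study.layout)
            calls_ex.append(call_of(prof_ex, archive_ex, False)[0])

    label_order = [negative, positive, UNCLASSIFIED]
    kappa_in, _ = weighted_kappa(
        confusion_matrix(calls_cohort, calls_in, label_order), UNCLASSIFIED)
    out = {
        "kappa_inlab": kappa_in,
        "calls_cohort": calls_cohort,
        "calls_inlab": calls_in,
        "p_cohort": p_cohort,
        "p_inlab": p_in,
    }
    if include_exlab:
        kappa_ex, _ = weighted_kappa(
            confusion_matrix(calls_cohort, calls_ex, label_order), UNCLASSIFIED)
        out["kappa_exlab"] = kappa_ex
        out["calls_exlab"] = calls_ex
    return out


def qc_shift_study(
    seed: int,
    shifts: tuple[float, ...] = (0.0, 0.2, 0.4, 0.8),
    n_probesets: int = 300,
    n_samples: int = 60,
    n_ref: int = 30,
    n_qc: int = 15,
    threshold: float = 0.6,
) -> dict:
    """Median RLE IQR of one-by-one normalized arrays versus the magnitude
    of the batch shift between sample and reference laboratories, plus the
    pass rate of clean (same-lab) samples at the QC threshold.

    The shifted arrays form a paired sweep (identical draws, scaled shift)
    so the IQR comparison across shift magnitudes is free of simulation
    noise between levels.
    """
    cfg = SimConfig(n_probesets=n_probesets, n_samples=n_samples, seed=seed)
    layout, reference, inlab, swept, _ = simulate_batch_shift_sweep(
        cfg, n_ref=n_ref, shift_sds=list(shifts))
    archive = build_reference(reference, layout)

    median_iqrs = []
    for shift in shifts:
        matrix = swept[shift]
        iqrs = []
        for sid in matrix.sample_ids[:n_qc]:
            prof = normalize_single(_series(matrix, sid), archive, layout)
            iqrs.append(compute_rle(prof, threshold=threshold).rle_iqr)
        median_iqrs.append(float(np.median(iqrs)))

    passes = []
    for sid in inlab.sample_ids:
        prof = normalize_single(_series(inlab, sid), archive, layout)
        passes.append(compute_rle(prof, threshold=threshold).pass_)
    return {
        "shifts": list(shifts),
        "median_rle_iqr": median_iqrs,
        "clean_pass_rate": float(np.mean(passes)),
    }
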