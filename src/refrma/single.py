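"""Reference-based one-by-one RMA normalization.

A reference cohort is frozen into a :class:`~refrma.probe_io.ReferenceArchive`
holding (i) the mean quantile vector of the background-corrected reference,
(ii) per-probe effects from median polish, and (iii) per-probe-set medians
and SDs of the reference's cohort-RMA expression values.  A single new array
can then be normalized without any cohort: background-correct it with its
own normexp parameters, quantile-map it onto the reference quantile vector,
subtract the frozen probe effects and summarize each probe-set by the median
of its probes, and finally subtract the reference probe-set medians so that
the profile is centered the same way the classifiers' training data were.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probe_io import ChipLayout, ProbeDataError, ProbeMatrix, ReferenceArchive
from .rma import (
    _map_to_target,
    background_correct,
    estimate_normexp_params,
    median_polish,
    quantile_normalize_cohort,
)

__all__ = [
    "ExpressionProfile",
    "build_reference",
    "quantile_map_single",
    "summarize_single",
    "normalize_single",
]


@dataclass
class ExpressionProfile:
    """One sample's probe-set expression values (log2 scale).

    ``centered`` records whether reference probe-set medians have been
    subtracted; ``rescaled_for`` names the classifier the profile has been
    SD-rescaled for (None until rescaling).
    """

    probeset_ids: list[str]
    values: np.ndarray
    centered: bool = False
    rescaled_for: str | None = None
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids),):
            raise ProbeDataError("profile needs exactly one value per probe-set")
        if not np.all(np.isfinite(self.values)):
            raise ProbeDataError("profile values must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.probeset_ids, name=self.sample_id)


def build_reference(
    raw: ProbeMatrix,
    layout: ChipLayout,
    cohort_label: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ReferenceArchive:
    """Freeze a reference cohort into the quantities needed for one-by-one
    normalization.

    At least 2 arrays are required; 30 or more from the user's own
    laboratory is the recommended practice, since the scheme assumes the
    sample and the reference share a distribution.
    """
    if raw.n_samples < 2:
        raise ProbeDataError(f"reference needs >= 2 arrays, got {raw.n_samples}")
    if raw.probe_ids != layout.probe_ids:
        raise ProbeDataError("reference matrix is not in layout probe order")

    corrected = np.empty_like(raw.intensities)
    for j in range(raw.n_samples):
        params = estimate_normexp_params(raw.intensities[:, j])
        corrected[:, j] = background_correct(raw.intensities[:, j], params)
    quantile_vector = np.sort(corrected, axis=0).mean(axis=1)

    log2_norm = np.log2(quantile_normalize_cohort(corrected))
    probe_effects = np.empty(layout.n_probes)
    expr = np.empty((layout.n_probesets, raw.n_samples))
    for k, ps in enumerate(layout.probeset_ids):
        rows = layout.probe_rows(ps)
        overall, row_eff, col_eff, _, _ = median_polish(
            log2_norm[rows, :], tol=tol, max_iter=max_iter)
        probe_effects[rows] = row_eff
        expr[k, :] = overall + col_eff

    return ReferenceArchive(
        chip_id=layout.chip_id,
        n_reference=raw.n_samples,
        quantile_vector=quantile_vector,
        probe_effects=pd.Series(probe_effects, index=layout.probe_ids),
        probeset_medians=pd.Series(np.median(expr, axis=1), index=layout.probeset_ids),
        probeset_sds=pd.Series(np.std(expr, axis=1, ddof=1), index=layout.probeset_ids),
        cohort_label=cohort_label,
    )


def quantile_map_single(sample: np.ndarray, quantile_vector: np.ndarray) -> np.ndarray:
    """Map one array onto a frozen reference quantile vector.

    The value of rank k in the sample is replaced by quantile_vector[k];
    tied values receive the mean of the quantile entries their tied ranks
    span.  Input order is preserved.
    """
    return _map_to_target(np.asarray(sample, dtype=float),
                          np.asarray(quantile_vector, dtype=float))


def summarize_single(
    log2_probes: pd.Series, probe_effects: pd.Series, layout: ChipLayout
) -> pd.Series:
    """Probe-effect subtraction + per-probe-set median summarization.

    expression(ps) = median over probes of (log2 intensity - probe effect),
    with the mean-of-middle-two convention for even probe counts.
    """
    missing = [p for p in layout.probe_ids if p not in probe_effects.index]
    if missing:
        raise ProbeDataError(f"no probe effect for {len(missing)} probes: {missing[:5]}")
    missing = [p for p in layout.probe_ids if p not in log2_probes.index]
    if missing:
        raise ProbeDataError(f"no intensity for {len(missing)} probes: {missing[:5]}")
    adjusted = (log2_probes.reindex(layout.probe_ids)
                - probe_effects.reindex(layout.probe_ids)).to_numpy()
    values = np.empty(layout.n_probesets)
    for k, ps in enumerate(layout.probeset_ids):
        values[k] = np.median(adjusted[layout.probe_rows(ps)])
    return pd.Series(values, index=layout.probeset_ids)


def normalize_single(
    sample: ProbeMatrix | pd.Series,
    archive: ReferenceArchive,
    layout: ChipLayout,
    center: bool = True,
) -> ExpressionProfile:
    """One-by-one RMA normalization of a single array against a reference.

    Pipeline: background-correct with the sample's own normexp parameters ->
    quantile-map onto the archive's quantile vector -> log2 -> subtract the
    archive's probe effects and take per-probe-set medians -> subtract the
    archive's probe-set medians (centering; skipped if ``center=False``,
    e.g. to inspect uncentered expression).
    """
    if isinstance(sample, ProbeMatrix):
        if sample.n_samples != 1:
            raise ProbeDataError(
                f"normalize_single expects one array, got {sample.n_samples}; "
                "loop over columns or use cohort mode"
            )
        series = pd.Series(sample.intensities[:, 0], index=sample.probe_ids,
                           name=sample.sample_ids[0])
    else:
        series = sample
    missing = [p for p in layout.probe_ids if p not in series.index]
    if missing:
        raise ProbeDataError(
            f"{len(missing)} layout probes missing from sample: {missing[:5]}"
        )
    extra = [p for p in series.index if p not in layout.probe_to_probeset]
    if extra:
        raise ProbeDataError(
            f"{len(extra)} sample probes absent from archive/layout: {extra[:5]}"
        )
    if len(archive.quantile_vector) != layout.n_probes:
        raise ProbeDataError(
            f"archive quantile vector length {len(archive.quantile_vector)} does "
            f"not match layout probe count {layout.n_probes}"
        )

    x = series.reindex(layout.probe_ids).to_numpy(dtype=float)
    params = estimate_normexp_params(x)
    corrected = background_correct(x, params)
    mapped = quantile_map_single(corrected, archive.quantile_vector)
    log2_probes = pd.Series(np.log2(mapped), index=layout.probe_ids)
    expr = summarize_single(log2_probes, archive.probe_effects, layout)
    if center:
        expr = expr - archive.probeset_medians.reindex(expr.index)
    return ExpressionProfile(
        probeset_ids=list(expr.index),
        values=expr.to_numpy(),
        centered=center,
        sample_id=str(series.name) if series.name is not None else "sample",
    )
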