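"""Relative log expression (RLE) quality control.

The RLE of a probe-set is the sample's log2 expression minus the reference
cohort's median for that probe-set.  A well-normalized array has RLE values
tightly centered on zero; a large RLE inter-quartile range flags either a
poor-quality array or normalization against an improper reference (e.g. one
from a different laboratory).  The recommended rejection rule is
RLE IQR > 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probe_io import ProbeDataError
from .single import ExpressionProfile

__all__ = ["QCReport", "compute_rle", "flag_sample", "DEFAULT_RLE_IQR_THRESHOLD"]

DEFAULT_RLE_IQR_THRESHOLD = 0.6


@dataclass
class QCReport:
    """RLE summary for one normalized sample."""

    sample_id: str
    rle_median: float
    rle_iqr: float
    threshold: float = DEFAULT_RLE_IQR_THRESHOLD
    pass_: bool = True

    def __post_init__(self) -> None:
        if self.rle_iqr < 0:
            raise ProbeDataError("RLE IQR cannot be negative")
        self.pass_ = bool(self.rle_iqr <= self.threshold)


def compute_rle(
    profile: ExpressionProfile,
    probeset_medians: pd.Series | None = None,
    threshold: float = DEFAULT_RLE_IQR_THRESHOLD,
) -> QCReport:
    """RLE median and IQR of one profile against reference medians.

    For an uncentered profile the reference probe-set medians are required
    and RLE(ps) = expression(ps) - median(ps).  A centered profile already
    IS the RLE vector (the same medians were subtracted during
    normalization), so the medians argument is not used — passing it anyway
    is an error to avoid double subtraction.
    """
    values = pd.Series(profile.values, index=profile.probeset_ids)
    if profile.centered:
        if probeset_medians is not None:
            raise ProbeDataError(
                "profile is already centered; passing reference medians would "
                "subtract them twice"
            )
        rle = values.to_numpy()
    else:
        if probeset_medians is None:
            raise ProbeDataError("uncentered profile needs reference probe-set medians")
        medians = probeset_medians.reindex(values.index)
        if medians.isna().any():
            missing = list(values.index[medians.isna()])[:5]
            raise ProbeDataError(f"reference medians missing for probe-sets: {missing}")
        rle = (values - medians).to_numpy()
    q25, q50, q75 = np.percentile(rle, [25.0, 50.0, 75.0])
    return QCReport(
        sample_id=profile.sample_id,
        rle_median=float(q50),
        rle_iqr=float(q75 - q25),
        threshold=threshold,
    )


def flag_sample(report: QCReport, threshold: float = DEFAULT_RLE_IQR_THRESHOLD) -> bool:
    """True (pass) iff the RLE IQR does not strictly exceed the threshold."""
    if threshold < 0:
        raise ProbeDataError("threshold must be nonnegative")
    return report.rle_iqr <= threshold
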