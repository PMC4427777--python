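"""Segmentation overlap metrics and the paired statistical comparison.

With Vm the reference (manual) voxel set and Va the segmented set:

    Dice      = |Vm ∩ Va| / ((|Vm| + |Va|) / 2)
    Precision = |Vm ∩ Va| / |Va|
    Recall    = |Vm ∩ Va| / |Vm|

Dice is the harmonic mean of precision and recall.  Empty-mask edge cases
raise rather than scoring 0: an empty segmentation is a pipeline failure,
not a result.  Method comparisons across cases use a two-sided paired
t-test; significance is never auto-thresholded — the caller interprets p.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError
from .volume_io import BinaryMask, require_same_geometry


@dataclass(frozen=True)
class EvalReport:
    """Overlap counts and metrics for one (reference, segmentation) pair."""

    n_ref: int          # |Vm|
    n_seg: int          # |Va|
    n_intersect: int    # |Vm ∩ Va|
    dice: float
    precision: float
    recall: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    t_statistic: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _counts(ref: BinaryMask, seg: BinaryMask):
    require_same_geometry(ref, seg, "reference and segmentation masks")
    n_ref = int(ref.data.sum())
    n_seg = int(seg.data.sum())
    n_int = int((ref.data & seg.data).sum())
    return n_ref, n_seg, n_int


def dice(ref: BinaryMask, seg: BinaryMask) -> float:
    """Dice similarity index, 2|Vm∩Va| / (|Vm|+|Va|)."""
    n_ref, n_seg, n_int = _counts(ref, seg)
    if n_ref == 0 and n_seg == 0:
        raise ValueError("dice undefined: both masks are empty")
    return 2.0 * n_int / (n_ref + n_seg)


def precision(ref: BinaryMask, seg: BinaryMask) -> float:
    """|Vm∩Va| / |Va| — fraction of segmented voxels that are correct."""
    n_ref, n_seg, n_int = _counts(ref, seg)
    if n_seg == 0:
        raise ValueError("precision undefined: segmentation mask is empty")
    return n_int / n_seg


def recall(ref: BinaryMask, seg: BinaryMask) -> float:
    """|Vm∩Va| / |Vm| — fraction of reference voxels recovered."""
    n_ref, n_seg, n_int = _counts(ref, seg)
    if n_ref == 0:
        raise ValueError("recall undefined: reference mask is empty")
    return n_int / n_ref


def evaluate(ref: BinaryMask, seg: BinaryMask) -> EvalReport:
    """All counts and metrics for a mask pair in one pass."""
    n_ref, n_seg, n_int = _counts(ref, seg)
    if n_ref == 0 and n_seg == 0:
        raise ValueError("evaluate undefined: both masks are empty")
    if n_seg == 0:
        raise ValueError("evaluate: segmentation mask is empty")
    if n_ref == 0:
        raise ValueError("evaluate: reference mask is empty")
    return EvalReport(
        n_ref=n_ref, n_seg=n_seg, n_intersect=n_int,
        dice=2.0 * n_int / (n_ref + n_seg),
        precision=n_int / n_seg,
        recall=n_int / n_ref)


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on a - b.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample sd (n-1 denominator);
    p from the t distribution with n-1 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_ttest requires two equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("paired_ttest requires n >= 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateFitError(
            "paired_ttest degenerate: all paired differences are identical")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(mean_diff=float(d.mean()), t_statistic=float(t),
                            p_value=float(p), n=int(n))
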