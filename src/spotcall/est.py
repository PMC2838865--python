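"""EST-level aggregation of replicated features.

Every EST (clone) is printed several times; the per-spot P-calls are
condensed into one EST P-call by ordered majority rules, and the
replicate ratios into a centre (mean or median), spread and *relative
error* — 100 * sd/mean of the replicate ratios, the pipeline's
reliability measure.

EST P-call rules, evaluated in order on the fractions of valid-feature
calls (first match wins, threshold t defaulting to 0.60):

1. frac(P) >= t            -> P
2. frac(M) >= t            -> M
3. frac(A) >= t            -> A
4. frac(M) + frac(P) >= t  -> M
5. frac(M) + frac(A) >= t  -> A

If no rule matches (possible only for t > 0.5, e.g. P and A split
50/50) the call falls back to M: the evidence is genuinely mixed and M
propagates the least confidence without discarding the EST.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cutoffs import CutoffSet
from .feature import FeatureEval, PCall, Regulation, classify_ratio

__all__ = ["ESTEval", "AggregationError", "est_p_call", "summarize_est"]

logger = logging.getLogger(__name__)

#: Comparisons of count fractions against the threshold tolerate one
#: part in 1e12 so that e.g. 3/5 >= 0.6 holds despite binary rounding.
_FRACTION_EPS = 1e-12


class AggregationError(ValueError):
    """EST-level aggregation received unusable input."""


@dataclass(frozen=True)
class ESTEval:
    """Aggregated evaluation of one EST across its replicate spots."""

    clone_id: str
    gene_name: str
    n_features: int
    frac_P: float
    frac_M: float
    frac_A: float
    est_p_call: PCall
    mean_ratio: float
    median_ratio: float
    sd_ratio: float
    relative_error: float  # percent, 100 * sd/mean of replicate ratios
    est_regulation: Regulation
    p_call_threshold: float = 0.60
    feature_ratios: tuple[float, ...] = field(default=())
    comment: str = ""

    @property
    def mean_log2_ratio(self) -> float:
        if self.mean_ratio > 0 and math.isfinite(self.mean_ratio):
            return math.log2(self.mean_ratio)
        return math.nan


def est_p_call(calls: Sequence[PCall | str], threshold: float = 0.60) -> PCall:
    """Ordered majority-rule EST P-call (see module docstring).

    Raises
    ------
    AggregationError
        For an empty call list.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    calls = [PCall(c) for c in calls]
    if not calls:
        raise AggregationError("cannot aggregate an empty call list")
    n = len(calls)
    f_p = calls.count(PCall.P) / n
    f_m = calls.count(PCall.M) / n
    f_a = calls.count(PCall.A) / n
    t = threshold - _FRACTION_EPS
    if f_p >= t:
        return PCall.P
    if f_m >= t:
        return PCall.M
    if f_a >= t:
        return PCall.A
    if f_m + f_p >= t:
        return PCall.M
    if f_m + f_a >= t:
        return PCall.A
    logger.debug(
        "EST P-call fallback to M (P=%.2f M=%.2f A=%.2f, t=%.2f)", f_p, f_m, f_a, threshold
    )
    return PCall.M


def summarize_est(
    group: Iterable[FeatureEval],
    cut: CutoffSet,
    threshold: float = 0.60,
    center: str = "mean",
    ratio_scale: str = "linear",
) -> ESTEval:
    """Aggregate one EST's replicate features into an :class:`ESTEval`.

    Only valid features contribute.  The regulation flag compares the
    centre ratio (mean by default, median via ``center``) against the
    ratio cut-offs with the same strict semantics used per feature.
    ``ratio_scale='log2'`` computes the centre on log2 ratios and
    back-transforms (geometric mean/median); the spread and relative
    error always refer to the linear ratios, on which the reliability
    threshold downstream is defined.

    A group with no valid feature yields an absent, unregulated EST with
    zero relative error; a single-replicate group is annotated in the
    comment since its spread is undefined.
    """
    group = list(group)
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    if ratio_scale not in ("linear", "log2"):
        raise ValueError("ratio_scale must be 'linear' or 'log2'")

    clone_id = group[0].clone_id if group else ""
    gene_name = group[0].gene_name if group else ""
    valid = [fe for fe in group if fe.valid]
    n = len(valid)
    if n == 0:
        return ESTEval(
            clone_id=clone_id,
            gene_name=gene_name,
            n_features=0,
            frac_P=0.0,
            frac_M=0.0,
            frac_A=0.0,
            est_p_call=PCall.A,
            mean_ratio=math.nan,
            median_ratio=math.nan,
            sd_ratio=0.0,
            relative_error=0.0,
            est_regulation=Regulation.NONE,
            p_call_threshold=threshold,
            feature_ratios=(),
            comment="no valid features",
        )

    calls = [fe.p_call for fe in valid]
    ratios = tuple(fe.ratio for fe in valid)
    arr = np.asarray(ratios, dtype=float)
    if ratio_scale == "log2":
        logs = np.log2(arr)
        mean_ratio = float(2.0 ** np.mean(logs))
        median_ratio = float(2.0 ** np.median(logs))
    else:
        mean_ratio = float(np.mean(arr))
        median_ratio = float(np.median(arr))
    sd_ratio = float(np.std(arr, ddof=1)) if n >= 2 else 0.0
    lin_mean = float(np.mean(arr))
    relative_error = 100.0 * sd_ratio / lin_mean if n >= 2 and lin_mean > 0 else 0.0

    centre = mean_ratio if center == "mean" else median_ratio
    return ESTEval(
        clone_id=clone_id,
        gene_name=gene_name,
        n_features=n,
        frac_P=calls.count(PCall.P) / n,
        frac_M=calls.count(PCall.M) / n,
        frac_A=calls.count(PCall.A) / n,
        est_p_call=est_p_call(calls, threshold),
        mean_ratio=mean_ratio,
        median_ratio=median_ratio,
        sd_ratio=sd_ratio,
        relative_error=relative_error,
        est_regulation=classify_ratio(centre, cut),
        p_call_threshold=threshold,
        feature_ratios=ratios,
        comment="single replicate" if n == 1 else "",
    )
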