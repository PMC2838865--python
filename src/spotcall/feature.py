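"""Single-feature evaluation: P-call, regulation flag, EST grouping.

Each spot gets a presence call (P/M/A) by comparing its per-channel
log2 intensities against the background cut-off, and a regulation flag
(UP/DOWN/NONE) by comparing its channel ratio against the spike-in
derived ratio cut-offs.  Equality with a cut-off counts as *not
exceeding* it (strict inequalities throughout), so a signal sitting
exactly on the background cut-off does not count as present and a ratio
exactly on a ratio cut-off is not regulated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

from .cutoffs import CutoffSet
from .io import CONTROL_CATEGORIES, Category, SpotRecord

__all__ = ["PCall", "Regulation", "FeatureEval", "evaluate_feature", "group_features_by_est"]


class PCall(str, enum.Enum):
    P = "P"  # present: above background in both channels
    M = "M"  # marginal: above background in exactly one channel
    A = "A"  # absent: above background in neither channel


class Regulation(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


@dataclass(frozen=True)
class FeatureEval:
    """Per-spot evaluation result.

    ``ratio`` is the raw linear ch1/ch2 ratio (experimental/control
    orientation is resolved later, during dye-swap analysis); it is NaN
    exactly when the spot is invalid.
    """

    spot: SpotRecord
    log_ch1: float
    log_ch2: float
    ratio: float
    p_call: PCall
    regulation: Regulation
    valid: bool

    @property
    def clone_id(self) -> str:
        return self.spot.clone_id

    @property
    def gene_name(self) -> str:
        return self.spot.gene_name


def classify_ratio(ratio: float, cut: CutoffSet) -> Regulation:
    """UP above the upper cut-off, DOWN below the lower, else NONE."""
    if not math.isfinite(ratio) or ratio <= 0:
        return Regulation.NONE
    if ratio > cut.ratio_upper:
        return Regulation.UP
    if ratio < cut.ratio_lower:
        return Regulation.DOWN
    return Regulation.NONE


def evaluate_feature(spot: SpotRecord, cut: CutoffSet) -> FeatureEval:
    """Assign P-call and regulation flag to one spot.

    Spots with non-positive or unparseable signals are marked invalid
    and conservatively called absent / not regulated.
    """
    if not spot.usable_signals:
        return FeatureEval(
            spot=spot,
            log_ch1=math.nan,
            log_ch2=math.nan,
            ratio=math.nan,
            p_call=PCall.A,
            regulation=Regulation.NONE,
            valid=False,
        )
    log1 = math.log2(spot.signal_ch1)
    log2_ = math.log2(spot.signal_ch2)
    above1 = log1 > cut.bg_ch1
    above2 = log2_ > cut.bg_ch2
    if above1 and above2:
        p_call = PCall.P
    elif above1 or above2:
        p_call = PCall.M
    else:
        p_call = PCall.A
    ratio = spot.signal_ch1 / spot.signal_ch2
    return FeatureEval(
        spot=spot,
        log_ch1=log1,
        log_ch2=log2_,
        ratio=ratio,
        p_call=p_call,
        regulation=classify_ratio(ratio, cut),
        valid=True,
    )


def group_features_by_est(
    evals: Iterable[FeatureEval],
) -> dict[str, list[FeatureEval]]:
    """Partition gene-spot evaluations by clone (EST) id.

    Control spots are excluded; within each group the file order is
    preserved.
    """
    groups: dict[str, list[FeatureEval]] = {}
    for fe in evals:
        if fe.spot.category in CONTROL_CATEGORIES:
            continue
        groups.setdefault(fe.clone_id, []).append(fe)
    return groups
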