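"""Dye-swap reliability analysis.

A dye-swap pair hybridizes the same two samples twice with the Cy5/Cy3
labels exchanged.  In raw ch1/ch2 orientation a genuine expression
change therefore shows *opposite* regulation directions across the two
arrays, while a dye artefact shows the *same* direction on both.  Per
EST the two orientations are combined into a reliability flag:

``absent``         both EST P-calls are A;
``TRUE``           opposite raw directions with P or M calls, or one
                   clearly regulated orientation (P call) while the
                   other is unregulated but *tends* in the consistent
                   direction;
``non_reliable``   identical raw directions (both UP or both DOWN), or
                   any combination the flag table leaves undefined;
``non_regulated``  neither orientation regulated and no tendency.

The tendency criterion — the flag table invokes one without defining
it — is: the unregulated orientation's mean log2 ratio exceeds a
configurable fraction (default 0.5) of the corresponding log2 ratio
cut-off, in the direction consistent with the regulated orientation.

The combined per-EST ratio is the geometric mean of the forward ratio
and the reciprocal of the reverse ratio, i.e. the orientation-corrected
experimental/control fold.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .cutoffs import CutoffSet
from .est import ESTEval
from .feature import PCall, Regulation, classify_ratio

__all__ = ["DyeSwapFlag", "DyeSwapEval", "PairingError", "assign_dyeswap_flag", "pair_experiments"]

logger = logging.getLogger(__name__)


class DyeSwapFlag(str, enum.Enum):
    ABSENT = "absent"
    NON_RELIABLE = "non_reliable"
    NON_REGULATED = "non_regulated"
    TRUE = "TRUE"


class PairingError(ValueError):
    """Forward and reverse evaluations do not refer to the same EST."""


@dataclass(frozen=True)
class DyeSwapEval:
    """Combined evaluation of one EST across a dye-swap pair.

    ``combined_ratio`` is oriented experimental/control (forward
    orientation); ``oriented_feature_ratios`` pools the underlying
    replicate ratios of both arrays in that same orientation and feeds
    the transcript-level pooled relative error.
    """

    clone_id: str
    gene_name: str
    eval_fwd: ESTEval | None
    eval_rev: ESTEval | None
    ds_flag: DyeSwapFlag
    combined_ratio: float
    combined_regulation: Regulation
    tendency_fraction: float = 0.5
    oriented_feature_ratios: tuple[float, ...] = field(default=())
    oriented_replicate_ratios: tuple[float, ...] = field(default=())
    comment: str = ""


def _tendency_consistent(
    unregulated: ESTEval,
    cut: CutoffSet,
    expected: Regulation,
    fraction: float,
) -> bool:
    """Does an unregulated EST lean far enough in the expected direction?

    ``expected`` is the direction (in this array's raw orientation) that
    would corroborate the other array's regulated call.
    """
    m = unregulated.mean_log2_ratio
    if not math.isfinite(m):
        return False
    if expected is Regulation.UP:
        bound = cut.log_ratio_upper
        return bound > 0 and m >= fraction * bound
    if expected is Regulation.DOWN:
        bound = cut.log_ratio_lower
        return bound < 0 and m <= fraction * bound
    return False


_OPPOSITE = {Regulation.UP: Regulation.DOWN, Regulation.DOWN: Regulation.UP}


def assign_dyeswap_flag(
    fwd: ESTEval,
    rev: ESTEval,
    cut_fwd: CutoffSet,
    cut_rev: CutoffSet,
    tendency_fraction: float = 0.5,
) -> DyeSwapEval:
    """Combine the two orientations of one EST into a reliability flag.

    The decision order matters: opposite-direction evidence (TRUE) is
    checked before the identical-direction artefact rule, and both
    before the unregulated fallbacks.

    Raises
    ------
    PairingError
        When ``fwd`` and ``rev`` carry different clone ids.
    """
    if fwd.clone_id != rev.clone_id:
        raise PairingError(
            f"clone mismatch: {fwd.clone_id!r} (fwd) vs {rev.clone_id!r} (rev)"
        )

    lf, lr = fwd.mean_log2_ratio, rev.mean_log2_ratio
    if math.isfinite(lf) and math.isfinite(lr):
        combined_ratio = 2.0 ** ((lf - lr) / 2.0)
    elif math.isfinite(lf):
        combined_ratio = 2.0 ** lf
    elif math.isfinite(lr):
        combined_ratio = 2.0 ** (-lr)
    else:
        combined_ratio = math.nan

    fwd_ratios = tuple(r for r in fwd.feature_ratios if r > 0 and math.isfinite(r))
    rev_ratios = tuple(
        1.0 / r for r in rev.feature_ratios if r > 0 and math.isfinite(r)
    )
    pooled = fwd_ratios + rev_ratios
    # oriented per-orientation EST means: the replicate estimates whose
    # agreement the transcript-level relative error gauges
    replicates = tuple(
        r
        for r in (
            2.0 ** lf if math.isfinite(lf) else math.nan,
            2.0 ** (-lr) if math.isfinite(lr) else math.nan,
        )
        if math.isfinite(r) and r > 0
    )

    pm = (PCall.P, PCall.M)
    regulated = (Regulation.UP, Regulation.DOWN)
    rf, rr = fwd.est_regulation, rev.est_regulation
    comment = ""

    # (1) absent on both arrays
    if fwd.est_p_call is PCall.A and rev.est_p_call is PCall.A:
        flag = DyeSwapFlag.ABSENT
    # (2) opposite raw directions with P or M calls
    elif (
        rf in regulated
        and rr is _OPPOSITE[rf]
        and fwd.est_p_call in pm
        and rev.est_p_call in pm
    ):
        flag = DyeSwapFlag.TRUE
    # (3) one orientation regulated (P call), the other unregulated but
    #     tending in the consistent (opposite raw) direction
    elif (
        rf in regulated
        and fwd.est_p_call is PCall.P
        and rr is Regulation.NONE
        and rev.est_p_call in pm
        and _tendency_consistent(rev, cut_rev, _OPPOSITE[rf], tendency_fraction)
    ):
        flag = DyeSwapFlag.TRUE
    elif (
        rr in regulated
        and rev.est_p_call is PCall.P
        and rf is Regulation.NONE
        and fwd.est_p_call in pm
        and _tendency_consistent(fwd, cut_fwd, _OPPOSITE[rr], tendency_fraction)
    ):
        flag = DyeSwapFlag.TRUE
    # (4) identical raw directions: dye artefact
    elif rf in regulated and rr is rf:
        flag = DyeSwapFlag.NON_RELIABLE
    # (5) unregulated on both arrays
    elif rf is Regulation.NONE and rr is Regulation.NONE:
        flag = DyeSwapFlag.NON_REGULATED
    else:
        # combinations the flag table leaves undefined (e.g. one-sided
        # regulation without the tendency/P-call requirements)
        flag = DyeSwapFlag.NON_RELIABLE
        comment = "undefined flag combination"
        logger.debug(
            "undefined dye-swap combination for %s: fwd (%s, %s) rev (%s, %s)",
            fwd.clone_id,
            fwd.est_p_call.value,
            rf.value,
            rev.est_p_call.value,
            rr.value,
        )

    if flag is DyeSwapFlag.TRUE and math.isfinite(combined_ratio):
        combined_regulation = classify_ratio(combined_ratio, cut_fwd)
    else:
        combined_regulation = Regulation.NONE

    return DyeSwapEval(
        clone_id=fwd.clone_id,
        gene_name=fwd.gene_name or rev.gene_name,
        eval_fwd=fwd,
        eval_rev=rev,
        ds_flag=flag,
        combined_ratio=combined_ratio,
        combined_regulation=combined_regulation,
        tendency_fraction=tendency_fraction,
        oriented_feature_ratios=pooled,
        oriented_replicate_ratios=replicates,
        comment=comment,
    )


def pair_experiments(
    fwd_evals: Sequence[ESTEval],
    rev_evals: Sequence[ESTEval],
    cut_fwd: CutoffSet,
    cut_rev: CutoffSet,
    tendency_fraction: float = 0.5,
) -> list[DyeSwapEval]:
    """Match ESTs of the two orientations by clone id and combine them.

    ESTs present in only one orientation are emitted as non_reliable
    with a missing-pair annotation.  Output order: forward-table order,
    then unmatched reverse-only ESTs in their own order.
    """
    rev_by_clone = {e.clone_id: e for e in rev_evals}
    seen: set[str] = set()
    out: list[DyeSwapEval] = []
    for fwd in fwd_evals:
        seen.add(fwd.clone_id)
        rev = rev_by_clone.get(fwd.clone_id)
        if rev is None:
            out.append(_unpaired(fwd, orientation="fwd"))
            continue
        out.append(
            assign_dyeswap_flag(fwd, rev, cut_fwd, cut_rev, tendency_fraction)
        )
    for rev in rev_evals:
        if rev.clone_id not in seen:
            out.append(_unpaired(rev, orientation="rev"))
    return out


def _unpaired(one: ESTEval, orientation: str) -> DyeSwapEval:
    m = one.mean_log2_ratio
    if orientation == "fwd":
        ratio = 2.0 ** m if math.isfinite(m) else math.nan
        pooled = tuple(r for r in one.feature_ratios if r > 0 and math.isfinite(r))
        fwd_eval, rev_eval = one, None
    else:
        ratio = 2.0 ** (-m) if math.isfinite(m) else math.nan
        pooled = tuple(
            1.0 / r for r in one.feature_ratios if r > 0 and math.isfinite(r)
        )
        fwd_eval, rev_eval = None, one
    replicates = (ratio,) if math.isfinite(ratio) and ratio > 0 else ()
    return DyeSwapEval(
        clone_id=one.clone_id,
        gene_name=one.gene_name,
        eval_fwd=fwd_eval,
        eval_rev=rev_eval,
        ds_flag=DyeSwapFlag.NON_RELIABLE,
        combined_ratio=ratio,
        combined_regulation=Regulation.NONE,
        oriented_feature_ratios=pooled,
        oriented_replicate_ratios=replicates,
        comment=f"missing {'reverse' if orientation == 'fwd' else 'forward'} pair",
    )
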