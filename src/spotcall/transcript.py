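"""Transcript-level grouping of ESTs.

A gene is represented by several ESTs; each arrives here with a
dye-swap reliability flag, an oriented combined ratio and the pooled
replicate ratios underneath it.  Two ESTs are merged by a fixed rule
table; three or more are merged by applying the two-EST rule as a left
fold over the members in input order (optionally sorted by clone id for
order-independence), with the running result re-interpreted as a
pseudo-EST.

Two-EST rule table (symmetric in the members):

=================  =================  ================================
member flags        condition          result (flag, value, regulation)
=================  =================  ================================
absent + absent                       absent, 0, NONE
absent + non_regulated                non_reliable, 0, NONE
absent + non_reliable                 non_reliable, 0, NONE
absent + TRUE                         non_reliable, average, NONE
non_reg + non_reg                     non_regulated, average, NONE
non_reg + non_reliable                non_reliable, 0, NONE
non_reg + TRUE                        non_reliable, average, NONE
non_rel + non_rel                     non_reliable, 0, NONE
non_rel + TRUE                        non_reliable, average, NONE
TRUE + TRUE        same direction,    TRUE, average, direction
                   rel. error <= 15%
TRUE + TRUE        same direction,    non_reliable, average, direction
                   rel. error > 15%
TRUE + TRUE        opposite/unclear   non_reliable, average, NONE
=================  =================  ================================

"average" is the arithmetic mean of the members' oriented combined
ratios (members without a defined ratio contribute nothing).  The
relative error of a group is recomputed from the pooled *replicate
estimates* of its members — each EST contributes one oriented mean
ratio per array orientation — rather than combined from the members'
individual spreads, so the 15% reliability gate measures how well the
independent replicate estimates of the fold change agree.  A relative
error of exactly 15% passes (the gate trips only strictly above the
threshold).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dyeswap import DyeSwapEval, DyeSwapFlag
from .feature import Regulation

__all__ = [
    "TranscriptEval",
    "GroupingError",
    "pooled_relative_error",
    "group_two_ests",
    "group_est_set",
]

logger = logging.getLogger(__name__)

#: Grouping handles up to this many ESTs per gene without complaint;
#: larger families are folded anyway but trigger a warning.
MAX_EXPECTED_MEMBERS = 6


class GroupingError(ValueError):
    """Transcript grouping received inconsistent members."""


@dataclass(frozen=True)
class TranscriptEval:
    """Grouped per-gene result.

    ``value`` is the oriented linear ratio (0 where the rule table says
    so); ``regulation`` is UP/DOWN only when the members agreed on a
    direction.  ``replicate_ratios`` pools the members' oriented
    per-orientation mean ratios (the replicate estimates the relative
    error is computed over); ``feature_ratios`` pools every underlying
    spot ratio for diagnostics.  Both feed further (recursive)
    grouping.
    """

    gene_name: str
    member_clones: tuple[str, ...]
    final_flag: DyeSwapFlag
    value: float
    regulation: Regulation
    relative_error: float  # percent
    rel_error_threshold: float = 15.0
    replicate_ratios: tuple[float, ...] = field(default=())
    feature_ratios: tuple[float, ...] = field(default=())


@dataclass(frozen=True)
class _Member:
    """Uniform view of a DyeSwapEval or a running TranscriptEval."""

    clones: tuple[str, ...]
    gene_name: str
    flag: DyeSwapFlag
    ratio: float  # NaN when undefined
    direction: Regulation
    replicate_ratios: tuple[float, ...]
    feature_ratios: tuple[float, ...]


def _as_member(obj: DyeSwapEval | TranscriptEval) -> _Member:
    if isinstance(obj, DyeSwapEval):
        return _Member(
            clones=(obj.clone_id,),
            gene_name=obj.gene_name,
            flag=obj.ds_flag,
            ratio=obj.combined_ratio,
            direction=obj.combined_regulation,
            replicate_ratios=obj.oriented_replicate_ratios,
            feature_ratios=obj.oriented_feature_ratios,
        )
    return _Member(
        clones=obj.member_clones,
        gene_name=obj.gene_name,
        flag=obj.final_flag,
        ratio=obj.value if obj.value > 0 else math.nan,
        direction=obj.regulation,
        replicate_ratios=obj.replicate_ratios,
        feature_ratios=obj.feature_ratios,
    )


def pooled_relative_error(ratios: Sequence[float]) -> float:
    """100 * sample SD / mean over a pooled set of replicate ratios."""
    vals = [r for r in ratios if math.isfinite(r) and r > 0]
    if len(vals) < 2:
        return 0.0
    arr = np.asarray(vals, dtype=float)
    mean = float(np.mean(arr))
    if mean <= 0:
        return 0.0
    return 100.0 * float(np.std(arr, ddof=1)) / mean


def _average_ratio(members: Sequence[_Member]) -> float:
    vals = [m.ratio for m in members if math.isfinite(m.ratio) and m.ratio > 0]
    if not vals:
        return 0.0
    return float(np.mean(vals))


def _merge(a: _Member, b: _Member, rel_error_threshold: float) -> TranscriptEval:
    if a.gene_name != b.gene_name:
        raise GroupingError(
            f"gene mismatch: {a.gene_name!r} vs {b.gene_name!r}"
        )
    pooled_reps = a.replicate_ratios + b.replicate_ratios
    pooled_feats = a.feature_ratios + b.feature_ratios
    rel_err = pooled_relative_error(pooled_reps)
    avg = _average_ratio((a, b))
    flags = {a.flag, b.flag}

    if flags == {DyeSwapFlag.ABSENT}:
        flag, value, reg = DyeSwapFlag.ABSENT, 0.0, Regulation.NONE
    elif DyeSwapFlag.TRUE in flags and flags != {DyeSwapFlag.TRUE}:
        # TRUE with any weaker partner: keep the average, drop reliability
        flag, value, reg = DyeSwapFlag.NON_RELIABLE, avg, Regulation.NONE
    elif flags == {DyeSwapFlag.NON_REGULATED}:
        flag, value, reg = DyeSwapFlag.NON_REGULATED, avg, Regulation.NONE
    elif flags == {DyeSwapFlag.TRUE}:
        dirs = {a.direction, b.direction}
        if dirs == {Regulation.UP} or dirs == {Regulation.DOWN}:
            direction = a.direction
            if rel_err <= rel_error_threshold:
                flag = DyeSwapFlag.TRUE
            else:
                flag = DyeSwapFlag.NON_RELIABLE
            value, reg = avg, direction
        else:
            flag, value, reg = DyeSwapFlag.NON_RELIABLE, avg, Regulation.NONE
    else:
        # absent/non_regulated/non_reliable mixtures without a TRUE member
        flag, value, reg = DyeSwapFlag.NON_RELIABLE, 0.0, Regulation.NONE

    return TranscriptEval(
        gene_name=a.gene_name,
        member_clones=a.clones + b.clones,
        final_flag=flag,
        value=value,
        regulation=reg,
        relative_error=rel_err,
        rel_error_threshold=rel_error_threshold,
        replicate_ratios=pooled_reps,
        feature_ratios=pooled_feats,
    )


def group_two_ests(
    a: DyeSwapEval | TranscriptEval,
    b: DyeSwapEval | TranscriptEval,
    rel_error_threshold: float = 15.0,
) -> TranscriptEval:
    """Merge two (possibly pseudo-) ESTs of the same gene.

    Raises
    ------
    GroupingError
        When the members carry different gene names.
    """
    return _merge(_as_member(a), _as_member(b), rel_error_threshold)


def _promote(m: _Member, rel_error_threshold: float) -> TranscriptEval:
    value = m.ratio if math.isfinite(m.ratio) and m.ratio > 0 else 0.0
    if m.flag is DyeSwapFlag.ABSENT:
        value = 0.0
    return TranscriptEval(
        gene_name=m.gene_name,
        member_clones=m.clones,
        final_flag=m.flag,
        value=value,
        regulation=m.direction if m.flag is DyeSwapFlag.TRUE else Regulation.NONE,
        relative_error=pooled_relative_error(m.replicate_ratios),
        rel_error_threshold=rel_error_threshold,
        replicate_ratios=m.replicate_ratios,
        feature_ratios=m.feature_ratios,
    )


def group_est_set(
    members: Sequence[DyeSwapEval],
    rel_error_threshold: float = 15.0,
    sort_members: bool = False,
) -> TranscriptEval:
    """Group all ESTs of one gene into a transcript-level result.

    A single member is promoted directly; larger sets are merged by a
    left fold of the two-EST rule in input order (the fold is not
    order-invariant in general; ``sort_members=True`` sorts by clone id
    first for reproducibility across differently ordered files).

    Raises
    ------
    GroupingError
        For an empty member list or mixed gene names.
    """
    if not members:
        raise GroupingError("cannot group an empty EST set")
    genes = {m.gene_name for m in members}
    if len(genes) > 1:
        raise GroupingError(f"members span multiple genes: {sorted(genes)}")
    if len(members) > MAX_EXPECTED_MEMBERS:
        warnings.warn(
            f"gene {members[0].gene_name!r} has {len(members)} ESTs; the "
            f"grouping rules were designed for up to {MAX_EXPECTED_MEMBERS}",
            stacklevel=2,
        )
    ordered = sorted(members, key=lambda m: m.clone_id) if sort_members else list(members)
    running = _promote(_as_member(ordered[0]), rel_error_threshold)
    for nxt in ordered[1:]:
        running = group_two_ests(running, nxt, rel_error_threshold)
    return running
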