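"""Final per-gene report and batch driving.

The report prints one row per gene with the regulation direction, the
final reliability flag, the fold change in the signed display
convention (a ratio r < 1 prints as -1/r, so 2-fold down-regulation is
-2.0 rather than 0.5) with a propagated error, and an aggregate
presence call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .feature import PCall, Regulation
from .transcript import TranscriptEval

__all__ = ["ReportRow", "to_signed_ratio", "from_signed_ratio", "final_report", "run_batch", "BatchResult"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReportRow:
    """One gene in the final report."""

    gene_name: str
    regulation: Regulation
    final_flag: str
    signed_ratio: float  # >= 1, <= -1, or 0 for absent genes
    ratio_error: float
    p_call: PCall


def to_signed_ratio(r: float) -> float:
    """Map a linear ratio onto the signed fold-change display scale.

    ``r >= 1`` stays as is; ``r < 1`` becomes ``-1/r``.  The map is a
    bijection from (0, inf) onto (-inf, -1] u [1, inf).

    Raises
    ------
    ValueError
        For non-positive ratios.
    """
    if not (r > 0) or not math.isfinite(r):
        raise ValueError(f"ratio must be a positive finite number, got {r!r}")
    return r if r >= 1.0 else -1.0 / r


def from_signed_ratio(s: float) -> float:
    """Inverse of :func:`to_signed_ratio`."""
    if s >= 1.0:
        return s
    if s <= -1.0:
        return -1.0 / s
    raise ValueError(f"signed ratio must lie outside (-1, 1), got {s!r}")


def _majority_p_call(calls: Sequence[PCall]) -> PCall:
    """Most frequent call; any tie for the top count yields M."""
    if not calls:
        return PCall.A
    counts = {c: calls.count(c) for c in PCall}
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else PCall.M


def _signed_error(value: float, sd: float) -> float:
    """Propagate a linear-ratio SD onto the signed fold scale.

    For r >= 1 the scales coincide; for r < 1 the signed value is -1/r,
    whose first-order error is sd / r^2.
    """
    if value <= 0 or not math.isfinite(sd):
        return 0.0
    return sd if value >= 1.0 else sd / (value * value)


def final_report(
    transcripts: Sequence[TranscriptEval],
    est_index: Mapping[str, PCall] | None = None,
) -> list[ReportRow]:
    """Build the final per-gene table, sorted by signed ratio descending.

    ``est_index`` maps clone ids to per-EST presence calls; the row's
    aggregate P-call is the majority over the transcript's member
    clones (ties give M).  Genes without a defined value (absent) print
    a signed ratio of 0.
    """
    est_index = est_index or {}
    rows: list[ReportRow] = []
    for t in transcripts:
        if t.value > 0 and math.isfinite(t.value):
            signed = to_signed_ratio(t.value)
            sd = t.value * t.relative_error / 100.0
            err = _signed_error(t.value, sd)
        else:
            signed, err = 0.0, 0.0
        member_calls = [est_index[c] for c in t.member_clones if c in est_index]
        rows.append(
            ReportRow(
                gene_name=t.gene_name,
                regulation=t.regulation,
                final_flag=t.final_flag.value,
                signed_ratio=signed,
                ratio_error=err,
                p_call=_majority_p_call(member_calls),
            )
        )
    rows.sort(key=lambda r: r.signed_ratio, reverse=True)
    return rows


@dataclass
class BatchResult:
    """Outcome of one experiment within a batch run."""

    name: str
    ok: bool
    message: str
    report: list[ReportRow] | None = None


def run_batch(
    manifest: Sequence[Mapping[str, object]],
    runner: Callable[[Mapping[str, object]], list[ReportRow]],
) -> list[BatchResult]:
    """Run many experiments independently; one failure never aborts the rest.

    ``manifest`` holds one descriptor per experiment (at minimum a
    ``name`` and one or two input files); ``runner`` executes a single
    descriptor and returns its report rows.
    """
    results: list[BatchResult] = []
    for entry in manifest:
        name = str(entry.get("name", f"experiment-{len(results) + 1}"))
        try:
            report = runner(entry)
        except Exception as exc:  # deliberate blanket: isolation contract
            logger.error("experiment %s failed: %s", name, exc)
            results.append(BatchResult(name=name, ok=False, message=str(exc)))
        else:
            results.append(
                BatchResult(name=name, ok=True, message="ok", report=report)
            )
    return results
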