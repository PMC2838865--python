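"""Data-driven cut-off estimation.

Two thresholds drive the decision tables downstream:

* the **background cut-off** — per-channel median log2 intensity of all
  background and negative-control spots; a spot must exceed it to count
  as present in that channel;
* the **ratio cut-off** — spike-in controls carry no differential
  signal, so the spread of their log ratios measures the array's
  technical ratio noise.  The interval
  ``2^(mean ± k_sigma * sd)`` of spike-in log2 ratios (sample SD,
  ``k_sigma`` defaulting to 2) bounds the ratios compatible with no
  regulation.

Both constructions can be overridden with manual values through
:class:`~spotcall.config.AnalysisConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import Category, SpotRecord

__all__ = [
    "CutoffSet",
    "CutoffEstimationError",
    "compute_background_cutoff",
    "compute_ratio_cutoff",
    "derive_cutoffs",
]

logger = logging.getLogger(__name__)

BACKGROUND_CATEGORIES = frozenset({Category.BACKGROUND, Category.NEGATIVE_CONTROL})


class CutoffEstimationError(ValueError):
    """Cut-offs could not be derived from the available control spots."""


@dataclass(frozen=True)
class CutoffSet:
    """Background and ratio thresholds for one hybridization.

    ``bg_ch1``/``bg_ch2`` are log2 intensities; ``ratio_lower`` and
    ``ratio_upper`` are on the linear fold scale.  With unbiased
    spike-ins the ratio bounds straddle 1 and are reciprocal; a dye bias
    shifts both bounds by the same log2 offset, so ``lower <= 1 <=
    upper`` is typical but not enforced.
    """

    bg_ch1: float
    bg_ch2: float
    ratio_lower: float
    ratio_upper: float
    k_sigma: float = 2.0

    def __post_init__(self) -> None:
        if not (self.ratio_lower > 0 and self.ratio_upper > 0):
            raise ValueError("ratio cut-offs must be positive")
        if self.ratio_lower > self.ratio_upper:
            raise ValueError("ratio_lower must not exceed ratio_upper")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        for v in (self.bg_ch1, self.bg_ch2):
            if not math.isfinite(v):
                raise ValueError("background cut-offs must be finite")

    @property
    def log_ratio_upper(self) -> float:
        return math.log2(self.ratio_upper)

    @property
    def log_ratio_lower(self) -> float:
        return math.log2(self.ratio_lower)


def _control_log_signals(
    spots: Iterable[SpotRecord],
) -> tuple[list[float], list[float]]:
    ch1: list[float] = []
    ch2: list[float] = []
    for spot in spots:
        if spot.category not in BACKGROUND_CATEGORIES:
            continue
        if not spot.valid:
            continue
        if spot.signal_ch1 > 0 and math.isfinite(spot.signal_ch1):
            ch1.append(math.log2(spot.signal_ch1))
        if spot.signal_ch2 > 0 and math.isfinite(spot.signal_ch2):
            ch2.append(math.log2(spot.signal_ch2))
    return ch1, ch2


def compute_background_cutoff(
    spots: Iterable[SpotRecord],
    offset: float = 0.0,
    pooled: bool = False,
) -> tuple[float, float]:
    """Median log2 intensity of background + negative-control spots.

    Parameters
    ----------
    spots
        Any spot list; only background and negative-control spots with
        valid, positive signals contribute.
    offset
        Additive log2 offset applied to both channel cut-offs.
    pooled
        Pool both channels into a single median instead of estimating
        per channel.

    Returns
    -------
    (bg_ch1, bg_ch2)
        Per-channel log2 cut-offs.

    Raises
    ------
    CutoffEstimationError
        If no usable control spot exists for a channel; supply manual
        cut-offs via the configuration in that case.
    """
    ch1, ch2 = _control_log_signals(spots)
    if pooled:
        both = ch1 + ch2
        if not both:
            raise CutoffEstimationError(
                "no valid background/negative-control spots; "
                "set manual background cut-offs in the configuration"
            )
        med = float(np.median(both)) + offset
        return med, med
    if not ch1 or not ch2:
        raise CutoffEstimationError(
            "no valid background/negative-control spots in at least one "
            "channel; set manual background cut-offs in the configuration"
        )
    return float(np.median(ch1)) + offset, float(np.median(ch2)) + offset


def compute_ratio_cutoff(
    spike_spots: Iterable[SpotRecord],
    k_sigma: float = 2.0,
) -> tuple[float, float]:
    """Ratio cut-offs from the spread of spike-in control log ratios.

    ``ratio_upper = 2^(mean + k_sigma*sd)`` and
    ``ratio_lower = 2^(mean - k_sigma*sd)`` where mean/sd are taken over
    ``log2(ch1/ch2)`` of the usable spike-in spots and sd is the sample
    standard deviation (n-1 denominator).  Identical spike-in ratios
    give sd = 0 and a degenerate (zero-width) interval, which is legal.

    Raises
    ------
    CutoffEstimationError
        With fewer than two usable spike-in spots.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    log_ratios = [
        math.log2(s.signal_ch1 / s.signal_ch2)
        for s in spike_spots
        if s.category is Category.SPIKE_IN and s.usable_signals
    ]
    if len(log_ratios) < 2:
        raise CutoffEstimationError(
            f"need >= 2 usable spike-in spots, found {len(log_ratios)}; "
            "set manual ratio cut-offs in the configuration"
        )
    mean = float(np.mean(log_ratios))
    sd = float(np.std(log_ratios, ddof=1))
    return 2.0 ** (mean - k_sigma * sd), 2.0 ** (mean + k_sigma * sd)


def derive_cutoffs(
    spots: Sequence[SpotRecord],
    k_sigma: float = 2.0,
    background_offset: float = 0.0,
    pooled_background: bool = False,
    manual_bg: tuple[float, float] | None = None,
    manual_ratio: tuple[float, float] | None = None,
) -> CutoffSet:
    """Derive the full :class:`CutoffSet` for one array.

    Manual overrides win over data-driven estimates; every derived
    value is logged.
    """
    if manual_bg is not None:
        bg1, bg2 = manual_bg
    else:
        bg1, bg2 = compute_background_cutoff(
            spots, offset=background_offset, pooled=pooled_background
        )
    if manual_ratio is not None:
        lower, upper = manual_ratio
    else:
        lower, upper = compute_ratio_cutoff(spots, k_sigma=k_sigma)
    cut = CutoffSet(
        bg_ch1=bg1, bg_ch2=bg2, ratio_lower=lower, ratio_upper=upper, k_sigma=k_sigma
    )
    logger.info(
        "cut-offs: bg_ch1=%.4f bg_ch2=%.4f (log2), ratio=[%.4f, %.4f]"
        " (k_sigma=%.2f%s%s)",
        cut.bg_ch1,
        cut.bg_ch2,
        cut.ratio_lower,
        cut.ratio_upper,
        k_sigma,
        ", manual bg" if manual_bg is not None else "",
        ", manual ratio" if manual_ratio is not None else "",
    )
    return cut
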