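"""Shared fixtures and builders for the evaluation-pipeline tests."""

from __future__ import annotations

import math

import pytest

from spotcall import (
    Category,
    CutoffSet,
    DyeSwapEval,
    DyeSwapFlag,
    ESTEval,
    PCall,
    Regulation,
    SpotRecord,
)

#: Symmetric ratio cut-offs used throughout: lower = 3/4, upper = 4/3.
LOWER = 0.75
UPPER = 4.0 / 3.0


@pytest.fixture
def cutoffs() -> CutoffSet:
    return CutoffSet(bg_ch1=6.0, bg_ch2=6.0, ratio_lower=LOWER, ratio_upper=UPPER)


def make_spot(
    s1: float,
    s2: float,
    spot_id: str = "S1",
    clone: str = "CLONE1",
    gene: str = "GENE1",
    category: Category = Category.GENE,
) -> SpotRecord:
    return SpotRecord(
        spot_id=spot_id,
        clone_id=clone,
        gene_name=gene,
        category=category,
        signal_ch1=s1,
        signal_ch2=s2,
    )


def make_est(
    p_call: PCall,
    regulation: Regulation,
    mean_ratio: float,
    clone: str = "CLONE1",
    gene: str = "GENE1",
    ratios: tuple[float, ...] | None = None,
) -> ESTEval:
    """Hand-built EST summary for decision-table tests.

    ``mean_ratio`` must be consistent with ``regulation`` under the
    module-wide cut-offs (callers pick it that way).
    """
    if ratios is None:
        ratios = (mean_ratio,) * 6 if math.isfinite(mean_ratio) else ()
    fr = {
        PCall.P: (1.0, 0.0, 0.0),
        PCall.M: (0.0, 1.0, 0.0),
        PCall.A: (0.0, 0.0, 1.0),
    }[p_call]
    return ESTEval(
        clone_id=clone,
        gene_name=gene,
        n_features=len(ratios),
        frac_P=fr[0],
        frac_M=fr[1],
        frac_A=fr[2],
        est_p_call=p_call,
        mean_ratio=mean_ratio,
        median_ratio=mean_ratio,
        sd_ratio=0.0,
        relative_error=0.0,
        est_regulation=regulation,
        feature_ratios=ratios,
    )


def make_ds(
    flag: DyeSwapFlag,
    direction: Regulation,
    ratio: float,
    clone: str = "CLONE1",
    gene: str = "GENE1",
    replicates: tuple[float, ...] | None = None,
) -> DyeSwapEval:
    """Hand-built dye-swap evaluation for grouping-rule tests."""
    if replicates is None:
        replicates = (ratio, ratio) if math.isfinite(ratio) and ratio > 0 else ()
    return DyeSwapEval(
        clone_id=clone,
        gene_name=gene,
        eval_fwd=None,
        eval_rev=None,
        ds_flag=flag,
        combined_ratio=ratio,
        combined_regulation=direction,
        oriented_feature_ratios=replicates,
        oriented_replicate_ratios=replicates,
    )
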