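"""Model/Results facade over the evaluation pipeline.

Two model classes mirror the two experiment shapes:

* :class:`SingleArrayModel` — one hybridization; ``fit()`` estimates
  the cut-offs from the array's own control spots and evaluates every
  feature and EST.
* :class:`DyeSwapModel` — a dye-swap pair; ``fit()`` runs both arrays,
  combines orientations per EST, groups ESTs into transcripts and
  builds the final per-gene report.

Both return Results objects carrying the estimates (cut-offs), the
per-level evaluation tables as pandas DataFrames and a ``summary()``
text table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from .config import AnalysisConfig
from .cutoffs import CutoffSet, derive_cutoffs
from .dyeswap import DyeSwapEval, pair_experiments
from .est import ESTEval, summarize_est
from .feature import FeatureEval, PCall, evaluate_feature, group_features_by_est
from .io import ColumnMap, SpotRecord, read_array_table
from .report import ReportRow, final_report
from .transcript import TranscriptEval, group_est_set

__all__ = ["SingleArrayModel", "SingleArrayResults", "DyeSwapModel", "DyeSwapResults"]

_CALL_RANK = {PCall.P: 2, PCall.M: 1, PCall.A: 0}


def _evaluate_single(
    records: Sequence[SpotRecord], config: AnalysisConfig
) -> tuple[CutoffSet, list[FeatureEval], list[ESTEval]]:
    cutoffs = derive_cutoffs(
        records,
        k_sigma=config.ratio_k_sigma,
        background_offset=config.background_offset,
        pooled_background=config.pooled_background,
        manual_bg=config.manual_bg,
        manual_ratio=config.manual_ratio,
    )
    features = [evaluate_feature(s, cutoffs) for s in records]
    groups = group_features_by_est(features)
    ests = [
        summarize_est(
            group,
            cutoffs,
            threshold=config.est_p_call_threshold,
            center=config.est_center,
            ratio_scale=config.ratio_scale,
        )
        for group in groups.values()
    ]
    return cutoffs, features, ests


def _feature_frame(features: Sequence[FeatureEval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": [f.spot.spot_id for f in features],
            "clone_id": [f.clone_id for f in features],
            "gene_name": [f.gene_name for f in features],
            "category": [f.spot.category.value for f in features],
            "log_ch1": [f.log_ch1 for f in features],
            "log_ch2": [f.log_ch2 for f in features],
            "ratio": [f.ratio for f in features],
            "p_call": [f.p_call.value for f in features],
            "regulation": [f.regulation.value for f in features],
            "valid": [f.valid for f in features],
        }
    )


def _est_frame(ests: Sequence[ESTEval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clone_id": [e.clone_id for e in ests],
            "gene_name": [e.gene_name for e in ests],
            "n_features": [e.n_features for e in ests],
            "frac_P": [e.frac_P for e in ests],
            "frac_M": [e.frac_M for e in ests],
            "frac_A": [e.frac_A for e in ests],
            "est_p_call": [e.est_p_call.value for e in ests],
            "mean_ratio": [e.mean_ratio for e in ests],
            "median_ratio": [e.median_ratio for e in ests],
            "sd_ratio": [e.sd_ratio for e in ests],
            "relative_error": [e.relative_error for e in ests],
            "est_regulation": [e.est_regulation.value for e in ests],
        }
    )


@dataclass
class SingleArrayResults:
    """Fit result of one hybridization."""

    cutoffs: CutoffSet
    features: list[FeatureEval]
    ests: list[ESTEval]
    config: AnalysisConfig

    @property
    def feature_table(self) -> pd.DataFrame:
        return _feature_frame(self.features)

    @property
    def est_table(self) -> pd.DataFrame:
        return _est_frame(self.ests)

    def summary(self) -> str:
        cut = self.cutoffs
        n_valid = sum(f.valid for f in self.features)
        calls = pd.Series([e.est_p_call.value for e in self.ests])
        lines = [
            "Single-array evaluation",
            "=======================",
            f"spots evaluated:      {len(self.features)} ({n_valid} valid)",
            f"ESTs:                 {len(self.ests)}",
            f"background cut-off:   ch1 {cut.bg_ch1:.4f}, ch2 {cut.bg_ch2:.4f} (log2)",
            f"ratio cut-offs:       [{cut.ratio_lower:.4f}, {cut.ratio_upper:.4f}]"
            f" (k_sigma={cut.k_sigma:g})",
            "EST P-calls:          "
            + ", ".join(f"{k}={v}" for k, v in calls.value_counts().sort_index().items()),
        ]
        return "\n".join(lines)


class SingleArrayModel:
    """Evaluation model for one two-colour hybridization.

    Parameters
    ----------
    records
        Parsed spot records (already normalized intensities).
    config
        Analysis configuration; defaults throughout when omitted.
    """

    def __init__(
        self,
        records: Sequence[SpotRecord],
        config: AnalysisConfig | None = None,
    ) -> None:
        self.records = list(records)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_file(
        cls,
        source: str | Path | IO[str],
        config: AnalysisConfig | None = None,
        column_map: ColumnMap | None = None,
    ) -> "SingleArrayModel":
        config = config or AnalysisConfig()
        cmap = column_map or config.column_map
        records = read_array_table(source, cmap)
        return cls(records, config)

    def fit(self) -> SingleArrayResults:
        cutoffs, features, ests = _evaluate_single(self.records, self.config)
        return SingleArrayResults(
            cutoffs=cutoffs, features=features, ests=ests, config=self.config
        )


@dataclass
class DyeSwapResults:
    """Fit result of a dye-swap experiment pair."""

    fwd: SingleArrayResults
    rev: SingleArrayResults
    pairs: list[DyeSwapEval]
    transcripts: list[TranscriptEval]
    report: list[ReportRow]
    config: AnalysisConfig

    @property
    def pair_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": [p.clone_id for p in self.pairs],
                "gene_name": [p.gene_name for p in self.pairs],
                "ds_flag": [p.ds_flag.value for p in self.pairs],
                "combined_ratio": [p.combined_ratio for p in self.pairs],
                "combined_regulation": [p.combined_regulation.value for p in self.pairs],
                "comment": [p.comment for p in self.pairs],
            }
        )

    @property
    def report_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_name": [r.gene_name for r in self.report],
                "regulation": [r.regulation.value for r in self.report],
                "final_flag": [r.final_flag for r in self.report],
                "signed_ratio": [r.signed_ratio for r in self.report],
                "ratio_error": [r.ratio_error for r in self.report],
                "p_call": [r.p_call.value for r in self.report],
            }
        )

    def summary(self) -> str:
        flags = pd.Series([t.final_flag.value for t in self.transcripts])
        lines = [
            "Dye-swap evaluation",
            "===================",
            f"ESTs paired:          {len(self.pairs)}",
            f"genes reported:       {len(self.report)}",
            "final flags:          "
            + ", ".join(f"{k}={v}" for k, v in flags.value_counts().sort_index().items()),
            "",
            "Final report (fold changes signed, down-regulation negative):",
            self.report_table.to_string(
                index=False,
                float_format=lambda v: f"{v:.2f}",
            ),
        ]
        return "\n".join(lines)


class DyeSwapModel:
    """Evaluation model for a dye-swap pair of hybridizations.

    The forward array carries the experimental sample in channel 1; the
    reverse array has the labels exchanged, so genuine regulation shows
    opposite raw directions across the pair.
    """

    def __init__(
        self,
        fwd_records: Sequence[SpotRecord],
        rev_records: Sequence[SpotRecord],
        config: AnalysisConfig | None = None,
    ) -> None:
        self.fwd_records = list(fwd_records)
        self.rev_records = list(rev_records)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_files(
        cls,
        fwd: str | Path | IO[str],
        rev: str | Path | IO[str],
        config: AnalysisConfig | None = None,
        column_map: ColumnMap | None = None,
    ) -> "DyeSwapModel":
        config = config or AnalysisConfig()
        cmap = column_map or config.column_map
        return cls(read_array_table(fwd, cmap), read_array_table(rev, cmap), config)

    def fit(self) -> DyeSwapResults:
        cfg = self.config
        cut_f, feats_f, ests_f = _evaluate_single(self.fwd_records, cfg)
        cut_r, feats_r, ests_r = _evaluate_single(self.rev_records, cfg)
        pairs = pair_experiments(
            ests_f, ests_r, cut_f, cut_r, tendency_fraction=cfg.tendency_fraction
        )

        by_gene: dict[str, list[DyeSwapEval]] = {}
        for p in pairs:
            by_gene.setdefault(p.gene_name, []).append(p)
        transcripts = [
            group_est_set(
                members,
                rel_error_threshold=cfg.rel_error_threshold,
                sort_members=cfg.sort_members,
            )
            for members in by_gene.values()
        ]

        # per-clone presence: the better of the two orientations
        est_index: dict[str, PCall] = {}
        for p in pairs:
            calls = [
                e.est_p_call for e in (p.eval_fwd, p.eval_rev) if e is not None
            ]
            est_index[p.clone_id] = max(calls, key=_CALL_RANK.__getitem__)

        report = final_report(transcripts, est_index)
        return DyeSwapResults(
            fwd=SingleArrayResults(cut_f, feats_f, ests_f, cfg),
            rev=SingleArrayResults(cut_r, feats_r, ests_r, cfg),
            pairs=pairs,
            transcripts=transcripts,
            report=report,
            config=cfg,
        )
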