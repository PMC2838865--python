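"""Synthetic two-colour array generator.

Emulates the structure of a custom spotted array with heavy
replication: every gene is represented by two or more ESTs, every EST
by six or more replicate spots, plus large blocks of spike-in
(positive) and background/negative control spots, and dye-swap pairs of
arrays.  Intensities follow a log-normal noise model: log2 signals are
``baseline ± fc/2`` plus independent Gaussian replicate noise per
channel, with an optional additive log2 dye bias on channel 1.

Defaults mirror a realistic design of this class: 520 genes x 2 ESTs x
6 spots, 1400 spike-in spots and 2400 background-class control spots.
With a fixed seed the output is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import Category, SpotRecord

__all__ = ["SimulationSpec", "simulate_array", "simulate_dyeswap_pair", "ground_truth"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated hybridization design.

    ``true_log2_fc`` maps gene names (``GENE0001`` ...) to their true
    log2 fold change in forward orientation; unlisted genes are
    unregulated.  ``noise_sd`` is the per-channel replicate noise on the
    log2 scale; ``dye_bias`` an additive log2 offset on channel 1
    affecting every spot (what the dye-swap design exists to cancel).
    """

    n_genes: int = 520
    ests_per_gene: int | tuple[int, int] = 2
    spots_per_est: int = 6
    n_spike_spots: int = 1400
    n_background_spots: int = 2400
    true_log2_fc: Mapping[str, float] = field(default_factory=dict)
    baseline_log2_intensity: float = 10.0
    background_log2_intensity: float = 6.0
    noise_sd: float = 0.15
    dye_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.spots_per_est <= 0:
            raise ValueError("counts must be positive")
        if isinstance(self.ests_per_gene, tuple):
            lo, hi = self.ests_per_gene
            if not (1 <= lo <= hi):
                raise ValueError("invalid ests_per_gene range")
        elif self.ests_per_gene <= 0:
            raise ValueError("ests_per_gene must be positive")
        if self.n_spike_spots < 0 or self.n_background_spots < 0:
            raise ValueError("control spot counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"GENE{i + 1:0{width}d}" for i in range(self.n_genes)]


def ground_truth(spec: SimulationSpec) -> list[tuple[str, float]]:
    """(gene, true log2 fold change) sidecar for recovery tests."""
    return [(g, float(spec.true_log2_fc.get(g, 0.0))) for g in spec.gene_names()]


def _est_counts(spec: SimulationSpec, rng: np.random.Generator) -> list[int]:
    if isinstance(spec.ests_per_gene, tuple):
        lo, hi = spec.ests_per_gene
        return [int(k) for k in rng.integers(lo, hi + 1, size=spec.n_genes)]
    return [int(spec.ests_per_gene)] * spec.n_genes


def _simulate(
    spec: SimulationSpec,
    rng: np.random.Generator,
    sign: float,
    est_counts: list[int],
) -> list[SpotRecord]:
    records: list[SpotRecord] = []
    spot_no = 0

    def add(clone: str, gene: str, category: Category, l1: float, l2: float) -> None:
        nonlocal spot_no
        spot_no += 1
        records.append(
            SpotRecord(
                spot_id=f"S{spot_no:06d}",
                clone_id=clone,
                gene_name=gene,
                category=category,
                signal_ch1=float(2.0 ** l1),
                signal_ch2=float(2.0 ** l2),
            )
        )

    base = spec.baseline_log2_intensity
    bias = spec.dye_bias
    for gene, n_ests in zip(spec.gene_names(), est_counts):
        fc = sign * float(spec.true_log2_fc.get(gene, 0.0))
        for e in range(n_ests):
            clone = f"{gene}_E{e + 1}"
            eps = rng.normal(0.0, spec.noise_sd, size=(spec.spots_per_est, 2))
            for k in range(spec.spots_per_est):
                add(
                    clone,
                    gene,
                    Category.GENE,
                    base + fc / 2.0 + bias + eps[k, 0],
                    base - fc / 2.0 + eps[k, 1],
                )
    eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_spike_spots, 2))
    for k in range(spec.n_spike_spots):
        name = f"SPIKE-{k + 1:04d}"
        add(name, name, Category.SPIKE_IN, base + bias + eps[k, 0], base + eps[k, 1])
    bg = spec.background_log2_intensity
    eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_background_spots, 2))
    for k in range(spec.n_background_spots):
        # alternate background / negative-control labels; both feed the
        # background cut-off
        if k % 2 == 0:
            name, cat = f"BG-{k + 1:04d}", Category.BACKGROUND
        else:
            name, cat = f"NEG-{k + 1:04d}", Category.NEGATIVE_CONTROL
        add(name, name, cat, bg + bias + eps[k, 0], bg + eps[k, 1])
    return records


def simulate_array(spec: SimulationSpec) -> list[SpotRecord]:
    """Simulate one array (forward orientation) from the design spec."""
    counts = _est_counts(spec, np.random.default_rng([spec.seed, 0]))
    return _simulate(spec, np.random.default_rng([spec.seed, 1]), +1.0, counts)


def simulate_dyeswap_pair(
    spec: SimulationSpec,
) -> tuple[list[SpotRecord], list[SpotRecord]]:
    """Simulate a dye-swap pair sharing one design layout.

    The reverse array inverts the sign of every true fold change (the
    channels trade sample roles) and draws fresh replicate noise; the
    dye bias stays on channel 1 of both arrays, as a dye effect would.
    The forward array is identical to :func:`simulate_array` of the
    same spec.
    """
    counts = _est_counts(spec, np.random.default_rng([spec.seed, 0]))
    fwd = _simulate(spec, np.random.default_rng([spec.seed, 1]), +1.0, counts)
    rev = _simulate(spec, np.random.default_rng([spec.seed, 2]), -1.0, counts)
    return fwd, rev
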