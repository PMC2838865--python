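# spotcall

Decision-tree quality evaluation for two-colour custom microarrays with
heavily replicated spots, spike-in/background controls and dye-swap
experiment pairs.

## The problem

Custom spotted cDNA arrays trade genome-wide coverage for redundancy: a
few hundred genes, each represented by two or more ESTs, each EST
printed six or more times, plus large blocks of spike-in (positive) and
background/negative control spots. Generic array software averages
replicate spots at best; it does not exploit this design to *grade the
reliability* of every measurement. `spotcall` evaluates such arrays on
three levels, propagating quality flags upward:

1. **Feature level.** Signals are log2-transformed. The *background
   cut-off* is the per-channel median log2 intensity of all background
   and negative-control spots. Each spot gets a presence call —
   P (above background in both channels), M (one channel), A (neither)
   — and a regulation flag from its ratio `r = ch1/ch2` against the
   spike-in-derived cut-offs: with spike-in log2 ratios having mean m
   and sample SD s, the interval is

   `ratio_lower = 2^(m - k·s)`, `ratio_upper = 2^(m + k·s)` (k = 2 by default),

   UP above it, DOWN below it, NONE inside. Equality never exceeds a
   cut-off.
2. **EST level.** The replicate spots of each EST are condensed by
   ordered majority rules (threshold 60%): P≥60% → P; M≥60% → M;
   A≥60% → A; else M+P≥60% → M; else M+A≥60% → A; else M. The replicate
   ratios give a centre (mean or median), spread, and the *relative
   error* `100·sd/mean` — the pipeline's reliability currency.
3. **Dye-swap and transcript level.** In a dye-swap pair a genuine
   effect shows *opposite* raw directions across the two arrays, a dye
   artefact the *same* direction. Each EST gets a reliability flag
   (absent / non_reliable / non_regulated / TRUE) and an
   orientation-corrected combined ratio (geometric mean of forward and
   inverted reverse ratio). ESTs of one gene are then merged by a fixed
   rule table — two TRUE ESTs in the same direction stay TRUE only if
   the relative error of their replicate estimates is ≤ 15% — applied
   recursively (left fold) for three or more ESTs. The final report
   prints signed fold changes (r < 1 shown as −1/r).

Input is any generic tab-delimited spot table with a configurable
column mapping (a ChipSkipper-style preset is included); output is
TSV/CSV. A synthetic-array module simulates the whole design —
including dye-swap pairs, dye bias and log-normal replicate noise — so
every stage is testable without real data.

## Worked example

```python
from spotcall import DyeSwapModel, SimulationSpec, simulate_dyeswap_pair

spec = SimulationSpec(
    n_genes=6, n_spike_spots=50, n_background_spots=50,
    noise_sd=0.1, seed=42,
    true_log2_fc={"GENE0001": 1.5, "GENE0002": -1.0},
)
fwd, rev = simulate_dyeswap_pair(spec)
results = DyeSwapModel(fwd, rev).fit()
print(results.summary())
```

prints

```
Dye-swap evaluation
===================
ESTs paired:          12
genes reported:       6
final flags:          TRUE=2, non_regulated=4

Final report (fold changes signed, down-regulation negative):
gene_name regulation    final_flag  signed_ratio  ratio_error p_call
 GENE0001         UP          TRUE          2.77         0.13      P
 GENE0004       NONE non_regulated          1.00         0.03      P
 GENE0006       NONE non_regulated          1.00         0.05      P
 GENE0005       NONE non_regulated         -1.01         0.04      P
 GENE0003       NONE non_regulated         -1.02         0.01      P
 GENE0002       DOWN          TRUE         -2.03         0.09      P
```

The two genes simulated with true log2 fold changes of +1.5 and −1.0
(true folds 2.83 and −2.0) are recovered as TRUE with the right
direction and fold change; the four null genes are non_regulated with
folds near ±1. `results` also carries the per-spot, per-EST and
per-pair tables as pandas DataFrames (`results.fwd.feature_table`,
`results.pair_table`, `results.report_table`).

The same analysis from the shell:

```sh
spotcall simulate --seed 42 --n-genes 6 --n-regulated 2 --out demo/
spotcall dyeswap --fwd demo/simulated_fwd.tsv --rev demo/simulated_rev.tsv \
    --preset simulated --out demo/
```

Other subcommands: `evaluate` (single array), `report` (regenerate a
report from a saved per-EST table), `batch` (manifest-driven multi-
experiment runs with failure isolation). `--config FILE` accepts a YAML
file overriding any threshold and the column mapping; see
`spotcall/config.py` for the schema.

## Limitations

Upstream image quantification, background subtraction and
normalization are out of scope — inputs must already be normalized,
background-compensated intensities. The published validation experiment
(hemin vs. desferrioxamine-treated HeLa cells) can be re-analysed with
`spotcall dyeswap` once its raw tables are placed under
`data/validation/`; the original distribution archive is not
redistributable here. See `docs/methods.md` for the full model
description and design choices.
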