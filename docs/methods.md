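# Methods

## Scope and model of the data

`spotcall` evaluates two-colour spotted microarrays whose design
provides internal redundancy: each gene is represented by ≥ 2 ESTs,
each EST by ≥ 6 replicate spots, plus spike-in controls (material with
no differential signal between channels) and background/negative
controls (spots expected to show only background fluorescence). Inputs
are assumed to be *normalized, background-compensated* linear
intensities from both channels; nothing upstream of that (image
quantification, within-array normalization) is modelled or corrected
here.

All evaluation is rule-based: the pipeline assigns categorical quality
flags by comparing summary statistics against data-driven cut-offs, and
propagates those flags feature → EST → transcript. There is no
distributional test; the replicate structure itself carries the
statistical weight.

## Cut-off estimation

**Background cut-off.** Per channel, the median of log2 intensities
over all background *and* negative-control spots. The median is robust
to the occasional bright contaminant among thousands of control spots.
A configurable additive log2 offset (default 0) lets users demand a
margin above background; `pooled_background: true` pools both channels
into one median. With no usable control spot the estimate is refused
(manual overrides via config are accepted instead).

**Ratio cut-off.** Spike-ins carry no true differential signal, so
their log2 ratio spread measures the array's technical ratio noise
including dye bias. With mean m and sample SD s (n−1 denominator) of
spike-in log2 ratios, the no-regulation band is
[2^(m − k·s), 2^(m + k·s)], k = 2 by default (≈ 95% of null ratios
under approximate normality). The bounds are *not* forced to straddle
1: under a strong dye bias m ≠ 0 and the whole band shifts — which is
exactly what makes the comparison fair in raw orientation. At least two
usable spike-ins are required; identical ratios legally give a
zero-width band.

## Decision rules and tie-breaks

* **Presence (P/M/A)** uses strict inequalities: a signal exactly equal
  to the background cut-off counts as *not above*. Rationale: the rules
  are phrased as "higher"/"lower", and demotion is the conservative
  reading. The same strictness applies to the ratio band (a ratio
  exactly on a bound is NONE).
* **EST P-call**: the five majority rules are evaluated in fixed order
  with a ≥ threshold (default 0.60) on fractions of *valid* features
  only; invalid spots (non-numeric/non-positive signals) never enter
  any denominator. When no rule matches (possible only for thresholds
  > 0.5, e.g. a 50/50 P/A split) the call falls back to M — the
  evidence is genuinely mixed, and M propagates minimal confidence
  without discarding the EST. Fraction comparisons tolerate one part in
  1e12 to absorb binary-float artifacts; since fractions are ratios of
  small integers this cannot flip a genuinely failing comparison.
* **Dye-swap flag**: decision order (1) both P-calls A → absent;
  (2) opposite raw directions with P or M calls → TRUE; (3) one
  orientation regulated with a P call, the other unregulated (P or M)
  but *tending* in the consistent direction → TRUE; (4) identical raw
  directions → non_reliable; (5) both unregulated → non_regulated; any
  remaining combination is undefined in the flag table and falls to
  non_reliable (logged). The tendency criterion is defined here as the
  unregulated orientation's mean log2 ratio reaching a configurable
  fraction (default 0.5) of the corresponding log2 ratio cut-off, with
  the matching sign — dimensionally "based on the ratio cut-off", and
  fully exposed in config since the original rule was stated only
  qualitatively.
* **Combined ratio**: geometric mean of the forward ratio and the
  inverted reverse ratio, i.e. `2^((log2 r_fwd − log2 r_rev)/2)` —
  symmetric under exchanging the pair (the value maps to its
  reciprocal, the flag is unchanged).
* **Transcript grouping**: the two-EST rule table (see
  `spotcall/transcript.py`) is applied literally, including its
  asymmetries (an absent member zeroes the value next to non_regulated
  or non_reliable partners but not next to a TRUE partner, whose
  average survives with a non_reliable flag). For ≥ 3 ESTs the table is
  left-folded over the members in input order, the running result
  acting as a pseudo-EST; the fold is not order-invariant in general,
  so `sort_members: true` optionally sorts by clone id first. Groups
  larger than six members are folded anyway but trigger a warning,
  since the rule set was designed for up to six ESTs per gene.
* **15% reliability gate**: a relative error exactly equal to the
  threshold passes (non_reliable only strictly above); the boundary
  belongs to the data-retaining side.

## The transcript-level relative error

The relative error is defined as `100 · SD / mean` of replicate ratios.
At the EST level the replicates are the spot ratios. At the transcript
level this package computes the gate over the members' *oriented
replicate estimates* — each EST contributes its forward mean ratio and
its inverted reverse mean ratio — rather than pooling all raw spot
ratios. The distinction matters: with per-channel log2 noise σ, a raw
spot ratio has CV ≈ √2·ln 2·σ ≈ 98%·σ, so at a typical σ = 0.15 the
per-spot CV (~14.7%) sits on top of the 15% gate and would flag half of
all well-behaved genes non-reliable regardless of replication. The gate
is meant to measure whether *independent estimates of the fold change
agree*; per-EST, per-orientation means are those estimates, their
spread shrinks with replication, and the resulting report errors match
the few-percent magnitudes such experiments actually report. The raw
pooled spot ratios are still carried on every result object for
diagnostics.

The reported `ratio_error` per gene propagates the replicate SD onto
the signed-fold scale by the delta method (sd for r ≥ 1, sd/r² for
r < 1).

## Report conventions

Fold changes are displayed signed: r ≥ 1 prints as r, r < 1 as −1/r, a
bijection onto (−∞,−1] ∪ [1,∞) that makes down-regulation legible at a
glance. Rows sort by signed ratio, descending. The per-gene presence
call is the majority over member ESTs' calls (each clone contributing
the better of its two orientations, P > M > A); ties give M. This
aggregation is reporting plumbing, not part of the decision tree.

## Synthetic data generator

`simulate_array`/`simulate_dyeswap_pair` emulate the replicated design:
log2 signals are `baseline ± fc/2` per channel plus independent
Gaussian noise (log-normal multiplicative noise on the linear scale,
the standard first-order microarray noise model), an additive log2 dye
bias on channel 1 everywhere, spike-ins at baseline with fc = 0, and
background-class spots (alternating background/negative labels) around
a low baseline. Defaults mirror a realistic design of this class: 520
genes × 2 ESTs × 6 spots, 1400 spike-in and 2400 background-class
spots, baseline log2 intensity 10 and background 6 (mid- and low-range
values for typical fluorescence scanners), replicate noise 0.15 log2
units. The reverse array of a pair shares the layout, inverts every
fold change and draws fresh noise.

Not emulated: spatial/print-tip artefacts, intensity-dependent dye
bias, saturation, specificity-control spots and missing values. Passing
recovery tests therefore demonstrate the decision logic under the
declared noise model, not robustness to spatially structured artefacts
— those must be handled by upstream normalization.

With a fixed seed the generated tables are byte-identical across runs;
layout and noise use separate deterministic random streams so the
forward array of a pair equals the single-array output of the same
spec.

## Numerical and degenerate-input choices

* Floats are written with full round-trip precision (`repr`), so
  write → read preserves values exactly (beyond 12 significant digits).
* Invalid spots (non-numeric or negative signals) are retained with an
  annotated comment, marked invalid, and conservatively called A/NONE;
  they are excluded from every statistic.
* An EST group with zero valid features yields A/NONE with relative
  error 0; a single-replicate EST is annotated, its spread undefined
  and reported as 0.
* Unpaired ESTs in a dye-swap analysis are emitted as non_reliable with
  a missing-pair annotation rather than dropped.
* Empty clone ids inherit the gene name so grouping always has a key.

## Problem sizes used in the checks

The bundled acceptance script enumerates the decision tables
exhaustively (12 feature cells, 164 call multisets, 225 dye-swap side
combinations, 49 grouping pairs), runs the recovery experiment at 50
genes (1 000 gene spots + 400 control spots per array, dye-swap pair),
and measures throughput on a ~9 000-feature virtual array — sizes
chosen to match one realistic custom array.
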