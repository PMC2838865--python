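"""Dye-swap reliability flag: exhaustive decision-order oracle."""

from __future__ import annotations

import itertools
import math

import pytest

from spotcall import (
    DyeSwapFlag,
    PairingError,
    PCall,
    Regulation,
    assign_dyeswap_flag,
    pair_experiments,
)
from tests.conftest import UPPER, make_est

UP, DOWN, NONE = Regulation.UP, Regulation.DOWN, Regulation.NONE
P, M, A = PCall.P, PCall.M, PCall.A

# mean ratios consistent with each regulation under the fixture cut-offs
# (lower 0.75, upper 4/3, log2 upper ~ 0.415); the NONE variants encode
# whether the EST leans far enough (>= 0.5 * log cut-off) to count as a
# "tendency" and in which direction
RATIO_FOR = {
    (UP, None): 2.0,
    (DOWN, None): 0.5,
    (NONE, "tend_up"): 2.0 ** 0.3,
    (NONE, "tend_down"): 2.0 ** -0.3,
    (NONE, "flat"): 1.0,
}


def flag_oracle(p_f, r_f, tend_f, p_r, r_r, tend_r):
    """Literal transcription of the documented decision order."""
    regulated = (UP, DOWN)
    opposite = {UP: DOWN, DOWN: UP}
    pm = (P, M)
    if p_f is A and p_r is A:
        return DyeSwapFlag.ABSENT
    if r_f in regulated and r_r is opposite[r_f] and p_f in pm and p_r in pm:
        return DyeSwapFlag.TRUE
    if (
        r_f in regulated and p_f is P and r_r is NONE and p_r in pm
        and tend_r == {UP: "tend_down", DOWN: "tend_up"}[r_f]
    ):
        return DyeSwapFlag.TRUE
    if (
        r_r in regulated and p_r is P and r_f is NONE and p_f in pm
        and tend_f == {UP: "tend_down", DOWN: "tend_up"}[r_r]
    ):
        return DyeSwapFlag.TRUE
    if r_f in regulated and r_r is r_f:
        return DyeSwapFlag.NON_RELIABLE
    if r_f is NONE and r_r is NONE:
        return DyeSwapFlag.NON_REGULATED
    return DyeSwapFlag.NON_RELIABLE


def all_sides():
    for p_call in (P, M, A):
        for reg in (UP, DOWN, NONE):
            variants = ("tend_up", "tend_down", "flat") if reg is NONE else (None,)
            for v in variants:
                yield p_call, reg, v


class TestDecisionOrder:
    def test_exhaustive_combinations_match_oracle(self, cutoffs):
        n = 0
        for (p_f, r_f, t_f), (p_r, r_r, t_r) in itertools.product(
            all_sides(), all_sides()
        ):
            fwd = make_est(p_f, r_f, RATIO_FOR[(r_f, t_f)])
            rev = make_est(p_r, r_r, RATIO_FOR[(r_r, t_r)])
            ds = assign_dyeswap_flag(fwd, rev, cutoffs, cutoffs)
            expected = flag_oracle(p_f, r_f, t_f, p_r, r_r, t_r)
            assert ds.ds_flag is expected, (p_f, r_f, t_f, p_r, r_r, t_r)
            n += 1
        assert n == 225  # 15 x 15 side states (>= the 81 p-call/direction pairs)

    def test_documented_rows(self, cutoffs):
        # both absent
        ds = assign_dyeswap_flag(
            make_est(A, NONE, 1.0), make_est(A, NONE, 1.0), cutoffs, cutoffs
        )
        assert ds.ds_flag is DyeSwapFlag.ABSENT
        # opposite raw directions with P calls -> genuine regulation
        ds = assign_dyeswap_flag(
            make_est(P, UP, 2.0), make_est(P, DOWN, 0.5), cutoffs, cutoffs
        )
        assert ds.ds_flag is DyeSwapFlag.TRUE
        assert ds.combined_regulation is UP
        # identical raw directions -> dye artefact
        ds = assign_dyeswap_flag(
            make_est(P, UP, 2.0), make_est(P, UP, 2.0), cutoffs, cutoffs
        )
        assert ds.ds_flag is DyeSwapFlag.NON_RELIABLE
        # regulated + unregulated-with-tendency -> still TRUE
        ds = assign_dyeswap_flag(
            make_est(P, UP, 2.0),
            make_est(P, NONE, 2.0 ** -0.3),
            cutoffs,
            cutoffs,
        )
        assert ds.ds_flag is DyeSwapFlag.TRUE

    def test_tendency_fraction_is_configurable(self, cutoffs):
        fwd = make_est(P, UP, 2.0)
        rev = make_est(P, NONE, 2.0 ** -0.3)  # |log ratio| = 0.3
        # 0.3 >= f * log2(4/3) ~ f * 0.415: passes at f=0.5, fails at f=0.9;
        # without the tendency the combination is undefined in the flag
        # table and falls to non_reliable
        assert (
            assign_dyeswap_flag(fwd, rev, cutoffs, cutoffs, 0.5).ds_flag
            is DyeSwapFlag.TRUE
        )
        assert (
            assign_dyeswap_flag(fwd, rev, cutoffs, cutoffs, 0.9).ds_flag
            is DyeSwapFlag.NON_RELIABLE
        )

    def test_swap_symmetry(self, cutoffs):
        for (p_f, r_f, t_f), (p_r, r_r, t_r) in itertools.product(
            all_sides(), all_sides()
        ):
            fwd = make_est(p_f, r_f, RATIO_FOR[(r_f, t_f)])
            rev = make_est(p_r, r_r, RATIO_FOR[(r_r, t_r)])
            a = assign_dyeswap_flag(fwd, rev, cutoffs, cutoffs)
            b = assign_dyeswap_flag(rev, fwd, cutoffs, cutoffs)
            assert a.ds_flag is b.ds_flag
            if math.isfinite(a.combined_ratio) and math.isfinite(b.combined_ratio):
                assert b.combined_ratio == pytest.approx(1.0 / a.combined_ratio)

    def test_clone_mismatch_raises(self, cutoffs):
        with pytest.raises(PairingError):
            assign_dyeswap_flag(
                make_est(P, UP, 2.0, clone="X"),
                make_est(P, DOWN, 0.5, clone="Y"),
                cutoffs,
                cutoffs,
            )


class TestCombinedRatio:
    def test_reciprocal_pair_recovers_ratio_exactly(self, cutoffs):
        r = 2.0
        ds = assign_dyeswap_flag(
            make_est(P, UP, r), make_est(P, DOWN, 1.0 / r), cutoffs, cutoffs
        )
        assert ds.combined_ratio == pytest.approx(r, rel=1e-12)

    def test_geometric_mean_of_orientations(self, cutoffs):
        ds = assign_dyeswap_flag(
            make_est(P, UP, 2.0), make_est(P, DOWN, 0.4), cutoffs, cutoffs
        )
        assert ds.combined_ratio == pytest.approx(math.sqrt(2.0 / 0.4))

    def test_combined_regulation_none_unless_true(self, cutoffs):
        ds = assign_dyeswap_flag(
            make_est(P, UP, 2.0), make_est(P, UP, 2.0), cutoffs, cutoffs
        )
        assert ds.ds_flag is DyeSwapFlag.NON_RELIABLE
        assert ds.combined_regulation is NONE


class TestPairing:
    def test_full_overlap(self, cutoffs):
        fwd = [make_est(P, UP, 2.0, clone=f"C{i}") for i in range(10)]
        rev = [make_est(P, DOWN, 0.5, clone=f"C{i}") for i in range(10)]
        out = pair_experiments(fwd, rev, cutoffs, cutoffs)
        assert len(out) == 10
        assert all(d.ds_flag is DyeSwapFlag.TRUE for d in out)

    def test_missing_partner_annotated_non_reliable(self, cutoffs):
        fwd = [make_est(P, UP, 2.0, clone=f"C{i}") for i in range(10)]
        rev = [make_est(P, DOWN, 0.5, clone=f"C{i}") for i in range(9)]
        out = pair_experiments(fwd, rev, cutoffs, cutoffs)
        assert len(out) == 10
        unpaired = [d for d in out if "missing" in d.comment]
        assert len(unpaired) == 1
        assert unpaired[0].clone_id == "C9"
        assert unpaired[0].ds_flag is DyeSwapFlag.NON_RELIABLE

    def test_empty_inputs(self, cutoffs):
        assert pair_experiments([], [], cutoffs, cutoffs) == []
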